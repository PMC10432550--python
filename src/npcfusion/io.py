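"""Localization-table and parameter I/O.

On-disk units are nm throughout.  Two dialects carry the same schema —
CSV (columns ``x_nm, y_nm, z_nm, particle_id`` plus optional ``sx, sy,
sz, emitter_id``) and HDF5 (one dataset per column under
``/localizations``) — and round-trip losslessly to well below 1e-6 nm.
Parameter sets travel as flat YAML blocks (nm / degrees at the interface).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .geometry import UnitRingParams
from .simulate import LocalizationCloud, SimulationConfig

__all__ = [
    "clouds_to_frame",
    "frame_to_clouds",
    "write_localizations",
    "read_localizations",
    "write_ground_truth",
    "read_ground_truth",
    "write_ring_params",
    "read_ring_params",
]

_REQUIRED = ("x_nm", "y_nm", "z_nm", "particle_id")
_OPTIONAL = ("sx", "sy", "sz", "emitter_id")


class SchemaError(ValueError):
    """A localization table is missing required columns."""


def clouds_to_frame(clouds: list[LocalizationCloud]) -> pd.DataFrame:
    frames = []
    for c in clouds:
        df = pd.DataFrame(c.positions, columns=["x_nm", "y_nm", "z_nm"])
        df["particle_id"] = c.particle_id
        if c.precision is not None:
            df[["sx", "sy", "sz"]] = c.precision
        if c.emitter_id is not None:
            df["emitter_id"] = c.emitter_id
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def frame_to_clouds(df: pd.DataFrame) -> list[LocalizationCloud]:
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"localization table is missing required "
                          f"column(s): {', '.join(missing)}")
    clouds = []
    for pid, grp in df.groupby("particle_id", sort=True):
        prec = (grp[["sx", "sy", "sz"]].to_numpy(float)
                if set(("sx", "sy", "sz")) <= set(df.columns) else None)
        emit = (grp["emitter_id"].to_numpy(int)
                if "emitter_id" in df.columns else None)
        clouds.append(LocalizationCloud(
            positions=grp[["x_nm", "y_nm", "z_nm"]].to_numpy(float),
            particle_id=int(pid), precision=prec, emitter_id=emit))
    return clouds


def _dialect(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        return dialect
    return "hdf5" if path.suffix.lower() in (".h5", ".hdf5") else "csv"


def write_localizations(path: str | Path, clouds: list[LocalizationCloud],
                        dialect: str | None = None) -> None:
    path = Path(path)
    df = clouds_to_frame(clouds)
    if _dialect(path, dialect) == "csv":
        df.to_csv(path, index=False)
        return
    with h5py.File(path, "w") as fh:
        grp = fh.create_group("localizations")
        for col in df.columns:
            grp.create_dataset(col, data=df[col].to_numpy())


def read_localizations(path: str | Path,
                       dialect: str | None = None) -> list[LocalizationCloud]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _dialect(path, dialect) == "csv":
        return frame_to_clouds(pd.read_csv(path))
    with h5py.File(path, "r") as fh:
        grp = fh["localizations"]
        df = pd.DataFrame({col: np.asarray(grp[col]) for col in grp})
    return frame_to_clouds(df)


def write_ground_truth(path: str | Path, record: dict) -> None:
    """Ground-truth sidecar (YAML): config, emitter table, per-particle poses."""
    truth = record["truth"]
    cfg: SimulationConfig = record["config"]
    doc = {
        "config": {k: (v.to_dict() if isinstance(v, UnitRingParams) else v)
                   for k, v in vars(cfg).items()},
        "emitters": {
            "positions_nm": np.asarray(truth.positions).tolist(),
            "ring": np.asarray(truth.ring).tolist(),
            "unit": np.asarray(truth.unit).tolist(),
            "emitter": np.asarray(truth.emitter).tolist(),
        },
        "poses": [{"rotation": np.asarray(p["rotation"]).tolist(),
                   "translation": np.asarray(p["translation"]).tolist()}
                  for p in record["poses"]],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_ground_truth(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def write_ring_params(path: str | Path,
                      params: dict[str, UnitRingParams],
                      extra: dict | None = None) -> None:
    doc = {lab: p.to_dict() for lab, p in params.items()}
    if extra:
        doc["meta"] = extra
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_ring_params(path: str | Path) -> dict[str, UnitRingParams]:
    doc = yaml.safe_load(Path(path).read_text())
    return {lab: UnitRingParams.from_dict(blk)
            for lab, blk in doc.items() if lab in ("NR", "CR")}
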