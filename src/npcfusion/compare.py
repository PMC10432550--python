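"""Comparison of the SMLM-fitted emitter model with the cryo-EM reference.

Both structures are expressed in the same six-parameter eight-fold
symmetric ring model, regenerated in a common frame (shared first-unit
azimuth, shared in-plane origin, inter-ring midplanes aligned at z = 0)
and compared site by site:

    b_xy = sqrt((m_x - s_x)^2 + (m_y - s_y)^2)      in-plane discrepancy
    b_z  = m_z - s_z                                 signed axial discrepancy

where m are the cryo-EM-derived SNAP positions and s the SMLM emitter
estimates.  Eight-fold symmetry of both inputs collapses the 32 values to
four distinct b_xy and four distinct b_z (two rings x two emitters per
unit).  Summary quantities: the mean in-plane error (mean of the four
b_xy) and the NPC thickness bias (mean over emitters of b_z,NR - b_z,CR).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .geometry import SiteSet, UnitRingParams, expand_eightfold

__all__ = [
    "BiasTable",
    "load_cryoem_reference",
    "regenerate_aligned_models",
    "bias_table",
]


def load_cryoem_reference() -> dict:
    """Shipped cryo-EM-derived reference: per-ring UnitRingParams + separation."""
    with resources.files("npcfusion.data").joinpath(
            "cryoem_reference.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    rings = {label: UnitRingParams.from_dict({**blk, "ring_label": label})
             for label, blk in raw["rings"].items()}
    return {"rings": rings, "ring_separation": float(raw["ring_separation_nm"]),
            "version": raw.get("version")}


def _recenter(params: dict[str, UnitRingParams], psi: float
              ) -> dict[str, UnitRingParams]:
    """Common frame: shared first-unit azimuth, inter-ring midplane at z=0."""
    mid = 0.5 * (params["NR"].c1z + params["CR"].c1z)
    return {lab: UnitRingParams.from_polar(
                R=p.R, psi=psi, c1z=p.c1z - mid, d=p.d, theta=p.theta,
                phi=p.phi, ring_label=lab)
            for lab, p in params.items()}


def regenerate_aligned_models(params_em: dict[str, UnitRingParams],
                              params_smlm: dict[str, UnitRingParams],
                              ) -> dict[str, tuple[SiteSet, SiteSet]]:
    """Expand both models into site sets sharing the first-unit frame.

    Both models are regenerated with the same first-unit azimuth (the
    SMLM one) and the same in-plane origin; axially, each model keeps its
    own ring separation but their inter-ring midplanes coincide, so the
    per-ring b_z values carry the separation discrepancy symmetrically.
    Returns ``{ring: (M, S)}`` with M the cryo-EM and S the SMLM sites.
    """
    for d in (params_em, params_smlm):
        if set(d) != {"NR", "CR"}:
            raise ValueError("parameter sets must carry both 'NR' and 'CR'")
    psi = params_smlm["NR"].psi
    em = _recenter(params_em, psi)
    sm = _recenter(params_smlm, psi)
    out = {}
    for lab in ("NR", "CR"):
        M = expand_eightfold(em[lab])
        M = SiteSet(sites=M.sites, kind="cryoEM", ring_label=lab)
        S = expand_eightfold(sm[lab])
        out[lab] = (M, S)
    return out


@dataclass
class BiasTable:
    """Per-emitter cryo-EM/SMLM discrepancies.

    ``b_xy`` and ``b_z`` are (2,)-arrays per ring indexed by emitter j
    (j=0 above the unit midplane, j=1 below); the four distinct values
    each follow from the eight-fold symmetry of both inputs.
    """

    b_xy: dict[str, np.ndarray]
    b_z: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for lab in ("NR", "CR"):
            self.b_xy[lab] = np.asarray(self.b_xy[lab], dtype=float)
            self.b_z[lab] = np.asarray(self.b_z[lab], dtype=float)
            if (self.b_xy[lab] < 0).any():
                raise ValueError("b_xy is a distance and must be >= 0")

    @property
    def mean_lateral_error(self) -> float:
        """Mean of the four distinct in-plane discrepancies, nm."""
        return float(np.mean(np.concatenate([self.b_xy["NR"], self.b_xy["CR"]])))

    @property
    def thickness_bias(self) -> float:
        """Mean over emitters of b_z,NR - b_z,CR: the bias in estimated NPC
        thickness between cryo-EM and SMLM, nm."""
        return float(np.mean(self.b_z["NR"] - self.b_z["CR"]))

    def to_frame(self) -> pd.DataFrame:
        rows = [{"ring": lab, "emitter": j + 1,
                 "b_xy_nm": float(self.b_xy[lab][j]),
                 "b_z_nm": float(self.b_z[lab][j])}
                for lab in ("NR", "CR") for j in range(len(self.b_xy[lab]))]
        return pd.DataFrame(rows)


def _per_ring_bias(M: SiteSet, S: SiteSet, symmetry_tol: float = 1e-6
                   ) -> tuple[np.ndarray, np.ndarray]:
    m, s = M.sites, S.sites          # (8, 2, 3), matched (k, j) indexing
    if m.shape != s.shape:
        raise ValueError("site sets must have matching (k, j) indexing")
    dxy = np.linalg.norm((m - s)[..., :2], axis=-1)   # (8, 2)
    dz = m[..., 2] - s[..., 2]
    for arr, name in ((dxy, "b_xy"), (dz, "b_z")):
        spread = float(np.ptp(arr, axis=0).max())
        if spread > symmetry_tol:
            raise ValueError(
                f"{name} varies with unit index k by {spread:.3g} nm; "
                "inputs are not eight-fold symmetric in a common frame")
    return dxy.mean(0), dz.mean(0)


def bias_table(models: dict[str, tuple[SiteSet, SiteSet]]) -> BiasTable:
    """Evaluate the per-emitter discrepancies for both rings.

    ``models`` maps ring label to an (M, S) pair from
    :func:`regenerate_aligned_models`.  Swapping M and S flips the sign of
    every b_z and leaves b_xy unchanged.
    """
    b_xy, b_z = {}, {}
    for lab, (M, S) in models.items():
        b_xy[lab], b_z[lab] = _per_ring_bias(M, S)
    return BiasTable(b_xy=b_xy, b_z=b_z)


def compare_to_cryoem(params_smlm: dict[str, UnitRingParams],
                      reference: dict | None = None) -> BiasTable:
    """One-call comparison of fitted per-ring parameters to the shipped
    cryo-EM reference."""
    ref = reference if reference is not None else load_cryoem_reference()
    return bias_table(regenerate_aligned_models(ref["rings"], params_smlm))
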