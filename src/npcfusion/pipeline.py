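"""End-to-end orchestration: simulate/load -> fuse -> canonicalize ->
filter -> blob analysis -> site fitting -> cryo-EM comparison.

One :func:`run_pipeline` call performs ``n_repeats`` independent fusions
(the joint registration starts from a random mixture, so repeats sample
the reconstruction variability), analyses every reconstruction, pools the
per-ring parameter estimates as medians with quartile boxes, and compares
the pooled symmetric model against the cryo-EM reference.  Every random
draw descends from one master seed; reruns are bit-identical.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import blobs as blob_mod
from . import canonical, compare, filtering, fusion
from .geometry import UnitRingParams
from .simulate import LocalizationCloud, SimulationConfig, simulate_dataset
from .sites import EightfoldRingModel

__all__ = ["PipelineConfig", "RepeatResult", "PipelineResult", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of the analysis, defaulting to the study conditions.

    K = 34 mixture components (32 sites + 2 false-positive collectors),
    initial fusion sigma 33 nm, canonical template 50 nm separation /
    55 nm radius, tilt refinement +/-3 deg in 0.2 deg steps, 9-component
    outlier mixture initialized in a 100 nm box, density threshold 0.95,
    10 fusion repeats.
    """

    sim: SimulationConfig | None = None
    input_path: str | None = None
    n_repeats: int = 10
    seed: int = 0
    K: int = 34
    sigma0: float = 33.0
    fusion_max_iter: int = 100
    classify: bool = True
    template_separation: float = 50.0
    template_radius: float = 55.0
    tilt_range_deg: float = 3.0
    tilt_step_deg: float = 0.2
    outlier_components: int = 9
    outlier_box_diameter: float = 100.0
    density_threshold: float = 0.95
    density_method: str = "radius"
    density_radius: float = 21.0
    density_k: int = 10
    fit_restarts: int = 10
    phi_mode: str = "random"


@dataclass
class RepeatResult:
    repeat: int
    ring_separation: float
    z_fit: canonical.ZHistogramFit
    ring_results: dict
    blob_table: pd.DataFrame
    filter_fractions: dict
    error: str | None = None


@dataclass
class PipelineResult:
    repeats: list[RepeatResult]
    pooled_params: dict[str, UnitRingParams]
    pooled_stats: pd.DataFrame
    bias: compare.BiasTable | None
    config: PipelineConfig
    errors: list[str] = field(default_factory=list)

    def summary(self) -> str:
        ok = [r for r in self.repeats if r.error is None]
        lines = [
            "NPC particle-fusion pipeline summary",
            "=" * 44,
            f"repeats analysed: {len(ok)} / {len(self.repeats)}",
        ]
        if ok:
            seps = [r.ring_separation for r in ok]
            lines.append(f"ring separation [nm]: median "
                         f"{np.median(seps):.1f} (min {min(seps):.1f}, "
                         f"max {max(seps):.1f})")
        lines.append("")
        lines.append(self.pooled_stats.to_string(index=False,
                                                 float_format="%.2f"))
        if self.bias is not None:
            lines += ["",
                      f"mean in-plane error vs cryo-EM: "
                      f"{self.bias.mean_lateral_error:.1f} nm",
                      f"NPC thickness bias vs cryo-EM: "
                      f"{self.bias.thickness_bias:.1f} nm"]
        return "\n".join(lines)


def _analyse_reconstruction(sp: LocalizationCloud, cfg: PipelineConfig,
                            rng: np.random.Generator, repeat: int
                            ) -> RepeatResult:
    posed, _ = canonical.register_to_template(
        sp, separation=cfg.template_separation, radius=cfg.template_radius)
    corrected, tilt, fwhm = canonical.refine_tilt(
        posed, tilt_range_deg=cfg.tilt_range_deg,
        tilt_step_deg=cfg.tilt_step_deg)
    zfit = canonical.fit_z_bimodal(corrected, seed=int(rng.integers(2 ** 31)))
    nr, cr, _ = canonical.split_rings(corrected, zfit)

    # canonical orientation: NR (majority ring) on the +z side
    if nr.positions[:, 2].mean() < cr.positions[:, 2].mean():
        flip = np.diag([1.0, -1.0, -1.0])
        nr = LocalizationCloud(nr.positions @ flip.T, nr.particle_id,
                               nr.precision, nr.emitter_id)
        cr = LocalizationCloud(cr.positions @ flip.T, cr.particle_id,
                               cr.precision, cr.emitter_id)

    ring_results, fractions, tables = {}, {}, []
    for lab, cloud in (("NR", nr), ("CR", cr)):
        rep1 = filtering.gmm_outlier_filter(
            cloud, seed=int(rng.integers(2 ** 31)),
            n_components=cfg.outlier_components,
            box_diameter=cfg.outlier_box_diameter)
        labels = blob_mod.assign_blobs(rep1.kept,
                                       seed=int(rng.integers(2 ** 31)))
        rep2 = filtering.density_filter(rep1.kept, labels,
                                        threshold=cfg.density_threshold,
                                        method=cfg.density_method,
                                        radius=cfg.density_radius,
                                        k=cfg.density_k)
        kept_labels = np.asarray(rep2.detail["kept_blob_labels"])
        tables.append(blob_mod.blob_table({lab: rep2.kept},
                                          {lab: kept_labels}))
        model = EightfoldRingModel(rep2.kept, ring_label=lab,
                                   phi_mode=cfg.phi_mode)
        ring_results[lab] = model.fit(seed=int(rng.integers(2 ** 31)),
                                      restarts=cfg.fit_restarts)
        fractions[lab] = {"gmm_outlier": rep1.removed_fraction,
                          "density": rep2.removed_fraction,
                          "combined": 1.0 - (1 - rep1.removed_fraction)
                          * (1 - rep2.removed_fraction)}
    return RepeatResult(repeat=repeat, ring_separation=zfit.separation,
                        z_fit=zfit, ring_results=ring_results,
                        blob_table=pd.concat(tables, ignore_index=True),
                        filter_fractions=fractions)


def _pool(repeats: list[RepeatResult]) -> tuple[dict, pd.DataFrame]:
    rows, pooled = [], {}
    for lab in ("NR", "CR"):
        vals = {k: [] for k in ("R", "d", "theta", "phi", "c1z", "psi")}
        for r in repeats:
            if r.error is not None or lab not in r.ring_results:
                continue
            p = r.ring_results[lab].params
            for k in vals:
                vals[k].append(getattr(p, k))
        if not vals["R"]:
            continue
        med = {k: float(np.median(v)) for k, v in vals.items()}
        pooled[lab] = UnitRingParams.from_polar(
            R=med["R"], psi=med["psi"], c1z=med["c1z"], d=med["d"],
            theta=float(np.clip(med["theta"], 0, np.pi / 2)), phi=med["phi"],
            ring_label=lab)
        for k, v in vals.items():
            arr = np.asarray(v)
            if k in ("theta", "phi", "psi"):
                arr = np.degrees(arr)
            rows.append({"ring": lab, "parameter": k,
                         "median": float(np.median(arr)),
                         "q1": float(np.percentile(arr, 25)),
                         "q3": float(np.percentile(arr, 75)),
                         "n": arr.size})
    return pooled, pd.DataFrame(rows)


def run_pipeline(cfg: PipelineConfig,
                 particles: list[LocalizationCloud] | None = None,
                 ) -> PipelineResult:
    """Run the full analysis; see module docstring.

    ``particles`` may carry pre-loaded clouds; otherwise ``cfg.sim`` is
    simulated (or ``cfg.input_path`` read).  Stage failures inside one
    repeat are caught and recorded in the error manifest; the remaining
    repeats still contribute.
    """
    master = np.random.default_rng(cfg.seed)
    if particles is None:
        if cfg.sim is not None:
            sim_cfg = cfg.sim
            particles, _ = simulate_dataset(sim_cfg)
        elif cfg.input_path is not None:
            from .io import read_localizations
            particles = read_localizations(cfg.input_path)
        else:
            raise ValueError("provide particles, cfg.sim or cfg.input_path")

    repeats: list[RepeatResult] = []
    errors: list[str] = []
    for rep in range(cfg.n_repeats):
        rng = np.random.default_rng(master.integers(2 ** 31))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                fused = fusion.fuse_particles(
                    particles, K=cfg.K, sigma0=cfg.sigma0,
                    max_iter=cfg.fusion_max_iter, rng=rng,
                    classify=cfg.classify)
                result = _analyse_reconstruction(fused.super_particle, cfg,
                                                 rng, rep)
        except Exception as err:  # partial results + manifest
            log.exception("repeat %d failed", rep)
            errors.append(f"repeat {rep}: {type(err).__name__}: {err}")
            result = RepeatResult(repeat=rep, ring_separation=np.nan,
                                  z_fit=None, ring_results={},
                                  blob_table=pd.DataFrame(),
                                  filter_fractions={}, error=str(err))
        repeats.append(result)

    pooled, stats = _pool(repeats)
    bias = None
    if set(pooled) == {"NR", "CR"}:
        try:
            bias = compare.compare_to_cryoem(pooled)
        except ValueError as err:
            errors.append(f"cryo-EM comparison: {err}")
    return PipelineResult(repeats=repeats, pooled_params=pooled,
                          pooled_stats=stats, bias=bias, config=cfg,
                          errors=errors)
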