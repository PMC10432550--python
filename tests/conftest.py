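"""Shared fixtures: synthetic datasets and (expensive) fused reconstructions.

Everything is generated programmatically from fixed seeds; the heavier
fusion products are session-scoped so the registration cost is paid once.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import npcfusion as nf


@pytest.fixture(scope="session")
def reference_nr_params() -> nf.UnitRingParams:
    """Cryo-EM reference geometry for the nuclear ring, centered at z=0."""
    return nf.UnitRingParams.from_polar(
        R=54.2, psi=0.0, c1z=0.0, d=11.8, theta=np.radians(76.8),
        phi=np.radians(-32.6), ring_label="NR")


def make_synthetic_ring(n_per_emitter: int = 120, sigma=(5.0, 5.0, 12.0),
                        bg_fraction: float = 0.0, seed: int = 2,
                        c1z: float = 24.0, phi_deg: float = -32.6,
                        ring_label: str = "NR") -> nf.LocalizationCloud:
    """One well-registered ring cloud straight from the reference geometry,
    optionally with a uniform background; emitter_id carries the truth
    (-1 = background)."""
    rng = np.random.default_rng(seed)
    p = nf.UnitRingParams.from_polar(R=54.2, psi=0.0, c1z=c1z, d=11.8,
                                     theta=np.radians(76.8),
                                     phi=np.radians(phi_deg),
                                     ring_label=ring_label)
    sites = nf.expand_eightfold(p).flat
    pos = (np.repeat(sites, n_per_emitter, 0)
           + rng.standard_normal((16 * n_per_emitter, 3)) * np.asarray(sigma))
    emit = np.repeat(np.arange(16), n_per_emitter)
    if bg_fraction > 0:
        n_bg = int(bg_fraction / (1 - bg_fraction) * len(pos))
        ang = rng.uniform(0, 2 * np.pi, n_bg)
        rad = 90.0 * np.sqrt(rng.random(n_bg))
        bg = np.column_stack([rad * np.cos(ang), rad * np.sin(ang),
                              rng.uniform(c1z - 30, c1z + 30, n_bg)])
        pos = np.concatenate([pos, bg])
        emit = np.concatenate([emit, np.full(n_bg, -1)])
    return nf.LocalizationCloud(positions=pos, particle_id=0, emitter_id=emit)


@pytest.fixture(scope="session")
def synthetic_ring() -> nf.LocalizationCloud:
    return make_synthetic_ring()


@pytest.fixture(scope="session")
def small_dataset():
    """80 simulated particles under the default study conditions."""
    cfg = nf.SimulationConfig(n_particles=80, seed=7)
    clouds, record = nf.simulate_dataset(cfg)
    return cfg, clouds, record


@pytest.fixture(scope="session")
def fused_small(small_dataset):
    """Joint registration of the 80-particle dataset (one fusion pass)."""
    _, clouds, _ = small_dataset
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return nf.jrmpc_register(clouds, rng=3, max_iter=150)


@pytest.fixture(scope="session")
def canonical_small(fused_small):
    """Canonically posed, tilt-refined super-particle with its z fit."""
    posed, _ = nf.register_to_template(fused_small.super_particle)
    corrected, _, _ = nf.refine_tilt(posed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        zfit = nf.fit_z_bimodal(corrected)
    return corrected, zfit
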