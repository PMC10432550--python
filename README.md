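# npcfusion

Particle fusion and eight-fold-symmetric model fitting for 3D
single-molecule localization microscopy (SMLM) of the Nuclear Pore Complex
(NPC).

Nup96, a scaffold nucleoporin, occurs in 32 copies per pore: a nuclear
ring (NR) and a cytoplasmic ring (CR), each built from 8 *units* of two
binding sites ~12 nm apart.  Individual SMLM images of NPCs cannot resolve
this — labelling is incomplete and the localization noise is comparable to
the site spacing.  `npcfusion` is for microscopists and structural
biologists who have segmented thousands of NPC particles (3D localization
tables) and want to fuse them into one super-particle and read off the
underlying unit geometry, including a quantitative comparison with the
cryo-EM-derived SNAP-tag reference positions.

The core model: a ring is described by six parameters
(c<sub>1x</sub>, c<sub>1y</sub>, c<sub>1z</sub>, d, θ, φ) — the first-unit
center, the within-unit site distance, the tilt of the site-connecting
line to the optical axis, and its in-plane inclination to the ring
tangent.  The two sites of the first unit are

    s₁₁ = (R cos ψ, R sin ψ, c₁z) + (d/2)·(−sin θ sin(φ+ψ), sin θ cos(φ+ψ), cos θ)
    s₁₂ = (R cos ψ, R sin ψ, c₁z) − (d/2)·(…)

with R = √(c₁x² + c₁y²), ψ = atan2(c₁y, c₁x), and the other 7 units their
rotations by multiples of π/4 about z.  The pipeline estimates the 16 free
site positions per ring with a shared-covariance 16-component Gaussian
mixture and then fits this symmetric model to them; the lateral and axial
extents of a unit are d·sin θ and d·cos θ.

## Worked example

Fit one synthetic nuclear ring (reference geometry R = 54.2 nm,
d = 11.8 nm, θ = 76.8°, φ = −32.6°, with 5 nm lateral / 12 nm axial
localization noise):

```python
import numpy as np
import npcfusion as nf

p = nf.UnitRingParams.from_polar(R=54.2, psi=0.0, c1z=24.0, d=11.8,
                                 theta=np.radians(76.8),
                                 phi=np.radians(-32.6), ring_label="NR")
rng = np.random.default_rng(2)
sites = nf.expand_eightfold(p).flat
pos = np.repeat(sites, 120, 0) + rng.standard_normal((1920, 3)) * [5, 5, 12]
ring = nf.LocalizationCloud(pos, particle_id=0)

res = nf.EightfoldRingModel(ring, ring_label="NR").fit(seed=1, restarts=5)
print(res.summary())
```

```
Eight-fold symmetric ring fit (NR)
==============================================
n localizations                   1920
GMM log-likelihood            -23882.6
ring radius R [nm]               54.09  (+/- 0.09)
unit distance d [nm]             12.37  (+/- 0.27)
tilt theta [deg]                  74.5  (+/- 2.6)
inclination phi [deg]            -32.2  (+/- 23.5)
ring plane z [nm]                23.86
lateral split [nm]               11.92
axial split [nm]                  3.31
mean |S-G| [nm]                   1.23  (sd 0.50)
```

The radius, unit distance, tilt and inclination come back at the planted
values; `mean |S-G|` is the average distance between the free mixture
centers and the symmetry-constrained sites — about 1 nm here, meaning the
data are consistent with exact eight-fold symmetry.  The `(+/- …)` figures
are the spread of per-unit estimates across the 8 units (the in-plane
inclination of a single unit is poorly determined, hence its wide spread;
the pooled value is tight).

A full synthetic study — simulate, fuse, split, filter, fit both rings,
compare with the cryo-EM reference — is one call:

```python
cfg = nf.PipelineConfig(sim=nf.SimulationConfig(n_particles=300, seed=1),
                        n_repeats=3, seed=1)
result = nf.run_pipeline(cfg)
print(result.summary())
```

or `npcfusion run-all --n-particles 300 --repeats 3 --seed 1`.

## Data formats

Localization tables are read and written as CSV
(`x_nm, y_nm, z_nm, particle_id[, sx, sy, sz, emitter_id]`) or HDF5 with
the same columns; fitted parameters travel as flat YAML (nm / degrees).
The synthetic generator stores its ground truth (emitter table, poses,
config) in a YAML sidecar.  See `docs/methods.md` for the model,
algorithms, defaults and known limitations.
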