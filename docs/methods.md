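# Methods

`npcfusion` reconstructs the arrangement of Nup96 binding sites in the
nuclear pore complex (NPC) from 3D single-molecule localization microscopy
(SMLM) point clouds.  Nup96, a scaffold nucleoporin, occurs in 32 copies
per pore: two rings (nuclear, NR, and cytoplasmic, CR) of 8 *units*, each
unit holding two labelled binding sites ~12 nm apart.  A single NPC image
never shows this — labelling is incomplete and localization noise is
comparable to the site spacing — so thousands of segmented NPC particles
are fused into one high-signal super-particle and the unit geometry is
estimated from that.

## The two-site unit model

A ring is parameterized by six numbers: the center of the first unit
`(c1x, c1y, c1z)`, the within-unit site distance `d`, the polar angle
`theta` of the site-connecting line to the optical (z) axis, and the
in-plane angle `phi` between that line's xy-projection and the ring
tangent.  With `R = hypot(c1x, c1y)` and `psi = atan2(c1y, c1x)`:

    s11 = (R cos psi, R sin psi, c1z) + (d/2) u
    s12 = (R cos psi, R sin psi, c1z) - (d/2) u
    u   = (-sin theta sin(phi+psi), sin theta cos(phi+psi), cos theta)

and the other 7 units are rotations of this pair by multiples of 45 deg
about z.  Emitter 1 is the site above the ring plane, restricting `theta`
to [0, pi/2] (the wider range [0, pi] is redundant under the emitter-swap).
`psi` and `phi` are counterclockwise viewed from +z with the NR on top;
viewing from the CR side flips the sign of `phi` — a projection-handedness
effect to keep in mind when comparing reconstructions rendered from the
other side.  The lateral and axial extent of a unit are `d sin theta` and
`d cos theta`.

Inverting 16 unlabeled sites back to parameters requires pairing them into
units; we use greedy mutual-nearest-neighbour pairing with a disjointness
guard and raise on ties (an equidistant site makes the units ambiguous).
For `theta = 0` the in-plane angle is undefined and is returned as 0 with
`phi_defined=False`.

## Pipeline

1. **Fusion** (`fusion`): all particles are jointly registered to a
   Gaussian mixture whose means, isotropic widths and weights are updated
   in the same EM loop as the per-particle rigid transforms
   (expectation-conditional-maximization: rotations by weighted orthogonal
   Procrustes against per-point virtual targets, then closed-form mixture
   updates; the observed-data log-likelihood is non-decreasing).
   K = 34 components — 32 for the binding sites, 2 to absorb false
   positives — plus one uniform outlier slot with fixed weight 0.005.
   Means start uniform in a 120-nm cylinder; all sigmas start at 33 nm,
   below the particle size, so EM contracts quickly.  Because the joint
   registration is local, particle groups can lock into poses differing by
   z-rotations; groups are detected by k-medoids clustering of zero-lag
   correlations between the particles' angular intensity profiles about z
   (the silhouette score selects k <= 8, threshold 0.25), rotated onto the
   largest group by a kernel-correlation scan over [0, 45) deg plus a
   180-deg flip, and the whole set is refined by a short second EM pass.
   The super-particle keeps every input localization.

2. **Canonical posing** (`canonical`): the super-particle is registered to
   a fixed 16-point two-ring template (separation 50 nm, radius 55 nm) by
   an isotropic-mixture rigid EM, multi-started from the PCA ring axis at
   4 z-rotations and both axis signs.  Residual tilt is refined by grid
   search (+/-3 deg, 0.2-deg steps about x and y) minimizing the FWHM of
   the z histogram (1-nm bins, interpolated crossings, ties to the
   smallest tilt).  Note: with the ~12 nm axial blur typical of this data
   the FWHM objective varies by only ~1% across that grid, so the selected
   tilt is essentially the sample's own optimum within noise; the step is
   kept because it is cheap and strictly non-harmful (the FWHM never
   increases).  The z distribution is then fitted with a two-component
   Gaussian (maximum likelihood on unbinned z) and localizations are split
   at the likelihood-equality point between the means.  The ring with more
   localizations is called NR (the NR typically collects ~22% more) and
   the super-particle is flipped if needed so the NR sits at +z.

3. **Outlier filtering** (`filtering`): first a 9-component isotropic
   Gaussian mixture with *fixed equal priors* is fitted to each ring
   (random xy centers in a 100-nm box, z at the super-particle midplane,
   sigma 33 nm).  Equal priors matter: with free weights the sparse
   background can never hold a component.  The off-plane z start matters
   too: it reliably lands EM in the basin where eight components contract
   onto the eight blobs and the ninth stays wide; starting in-plane tends
   to split a blob instead (that basin even has slightly higher
   likelihood, so best-of-N restarts would pick the wrong one — we use a
   single run).  Localizations hard-assigned to the widest component are
   removed (~5%); if no component is clearly widest (sigma ratio < 1.5)
   nothing is removed and a warning is raised.  Second, localizations with
   local density below 0.95 x the mean density of their blob are removed.
   The density estimator is a neighbour count in a fixed 21-nm radius —
   half the arc spacing between adjacent blobs (2 pi R / 16 at R = 54 nm),
   the scale at which the filter is meant to discriminate.  The choice of
   scale is substantive: an (essentially unsmoothed) k-NN estimate tracks
   the peaked blob profile, for which the fraction of samples below
   0.95 x mean density is P(chi^2_3 > 2.18) ~ 0.53 for Gaussian-like
   blobs, regardless of k; the 21-nm counter removes ~1/3, which separates
   adjacent blobs without eating the blob cores.  The rule is not
   idempotent — the threshold is relative to the surviving blob's mean, so
   re-running trims again, though each pass removes less than the last.

4. **Blob analysis** (`blobs`): rings are segmented into 8 angularly
   contiguous blobs (k-means on the polar-angle circle embedding, then
   circular-mean reassignment to a fixed point, which makes the partition
   rotation-equivariant; a concentration guard rejects structureless
   rings).  Each blob's xy projection is summarized by its second-moment
   ellipse: semi-axes a >= b as 1-sigma principal standard deviations
   (the scaling cancels in e = b/a), and the signed inclination of the
   long axis to the local ring tangent.  Equal and opposite median
   inclinations in the two rings are the model-free signature of the
   two-site substructure: a registration artefact would align the long
   axes with the tangent.

5. **Site fitting** (`sites`): per ring, a 16-component anisotropic
   Gaussian mixture with one shared diagonal covariance (all units are
   identical copies; initial sigma_z = 2 x sigma_xy because axial
   precision is 2-3x worse) is fitted by EM; its centers are the free site
   estimates G.  The eight-fold-symmetric model S(params) is then fitted
   to G by minimizing the mean squared matched-site distance with BFGS,
   reparameterized so d > 0 (log) and theta in (0, pi/2) (scaled
   logistic), under a correspondence fixed by optimal assignment
   (Hungarian) and re-checked at convergence; 10 restarts over random phi
   guard the pi/4-folded local minima.  The symmetric initializer places
   units at (0, 53.5 nm, +/-24 nm, 13 nm, pi/2, phi) with phi drawn
   uniformly in [0, pi) (a fixed pi/4 is available behind `phi_mode`).
   Exposed as `EightfoldRingModel.fit() -> EightfoldRingResults` with
   parameter estimates, per-unit spread as internal uncertainty, and a
   `summary()` table.

6. **Cryo-EM comparison** (`compare`): the fitted parameters and the
   shipped cryo-EM-derived SNAP-tag reference (R = 54.2 nm, d = 11.8 nm,
   theta = 76.8 deg, phi = -32.6 deg NR / +32.1 deg CR, ring separation
   57.2 nm) are both regenerated with a shared first-unit azimuth, a
   shared in-plane origin and their inter-ring midplanes at z = 0; then
   b_xy (in-plane distance) and b_z (signed axial difference) are
   evaluated per site.  Eight-fold symmetry collapses these to four values
   each.  The midplane convention makes a ring-separation mismatch appear
   as symmetric positive-NR / negative-CR axial biases; the *thickness
   bias* is the mean over emitters of b_z,NR - b_z,CR, and the *mean
   in-plane error* is the mean of the four b_xy.

## Synthetic data

The generator (`simulate`) works at localization level (no PSF or camera
model): 32 ground-truth sites from the unit model; Bernoulli labelling
(default efficiency 0.8); per labelled emitter a geometric number of
localizations (mean 10 — a heavy-tailed stand-in for fluorophore blinking;
real blinking statistics are not emulated); anisotropic Gaussian noise
(defaults sigma_xy = 5 nm, sigma_z = 12 nm, within the 2-3x axial factor);
uniform false positives (5%) in a 90-nm-radius, 120-nm-high cylinder; a
random rigid pose per particle (uniform z-rotation, tilt up to 3 deg from
the optical axis — NPCs sit in the envelope roughly parallel to the
coverslip — and +/-10 nm translations); and ~22% more localizations in the
NR than the CR.  Two geometry presets ship: `cryoEM` (ring separation
57.2 nm) and `smlm` (48.0 nm, the separation SMLM itself measures).  What
the generator does not emulate: structural heterogeneity between pores,
drift and sample deformation, blinking-correlated localization clusters,
and localization-precision variation across emitters — so passing
synthetic tests demonstrates the correctness and calibration of the
algorithms under the stated noise model, not performance on real data.

## Numerical choices and limitations

- EM loops use log-space responsibilities; component variances are floored
  (1 nm^2 fusion, 1e-4 nm^2 site fit) against collapse; starvation in the
  16-component fit triggers a reseeded restart (up to 5).
- The z-split threshold solves the likelihood-equality equation between
  the two fitted Gaussians by bracketed root finding, falling back to the
  midpoint when one component dominates; a separation smaller than the sum
  of widths raises a unimodality warning.
- Template registration subsamples to 15k localizations (a rigid pose
  needs far fewer points); the transform is applied to the full cloud.
- All randomness flows from one master seed; a pipeline run is
  bit-reproducible on one platform.
- Known estimation biases under the default synthetic conditions, all
  shared in direction with analyses of this kind: the density filter
  truncates blob tails, and the truncation-blind 16-component fit then
  shrinks the within-unit distance d (by ~2.5 nm here) and pushes theta
  toward 90 deg; blob-level registration blur adds ~1 nm more shrinkage.
  Radius, ring separation and the inclination signs are recovered
  essentially without bias.
- Pipeline problem sizes used in the shipped tests and acceptance script —
  300 particles, 10 (tests) or 3 (script) fusion repeats — are the
  package's default desk-scale study conditions; the library itself
  handles thousands of particles.
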