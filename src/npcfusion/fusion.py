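"""Template-free particle fusion by joint rigid registration (JRMPC).

All particles are simultaneously rotated and translated to fit one Gaussian
mixture model whose means, widths and weights are re-estimated in the same
EM loop (joint registration of multiple point clouds).  Because the joint
registration is a local optimizer, the aligned particles can split into a
few groups locked into different z-rotation poses of the eight-fold
symmetric structure; those groups are detected from angular intensity
profiles, rotated onto a common pose, and the whole set is refined once
more into a single well-aligned super-particle that contains every input
localization.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.spatial import cKDTree

from .simulate import LocalizationCloud

__all__ = [
    "RigidTransform",
    "MixtureModel",
    "FusionResult",
    "jrmpc_register",
    "classify_poses",
    "recombine",
    "fuse_particles",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform x -> R x + t (rotation orthonormal, det +1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation must have det +1 (no reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other: apply ``other`` first."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m


@dataclass
class MixtureModel:
    """Isotropic-or-diagonal Gaussian mixture with a uniform outlier slot.

    ``variances`` is (K,) for isotropic components or (K, 3) for shared /
    per-component diagonal covariances.  ``weights`` sum to
    ``1 - outlier_weight``; the remainder is a uniform component over the
    working volume.
    """

    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    outlier_weight: float = 0.0
    outlier_density: float = 0.0

    def __post_init__(self) -> None:
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.variances = np.asarray(self.variances, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < -1e-12):
            raise ValueError("mixture weights must be non-negative")
        if self.weights.sum() > 1.0 + 1e-9:
            raise ValueError("mixture weights must sum to <= 1")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be positive")

    @property
    def n_components(self) -> int:
        return self.means.shape[0]


def _log_gauss_iso(points: np.ndarray, means: np.ndarray,
                   var: np.ndarray) -> np.ndarray:
    """(N, K) isotropic log-density; var is (K,)."""
    d2 = (np.sum(points ** 2, axis=1)[:, None]
          + np.sum(means ** 2, axis=1)[None, :]
          - 2.0 * points @ means.T)
    return -0.5 * d2 / var[None, :] - 1.5 * np.log(2 * np.pi * var)[None, :]


def weighted_kabsch(x: np.ndarray, y: np.ndarray,
                    w: np.ndarray) -> RigidTransform:
    """Weighted orthogonal Procrustes: rigid T minimizing sum w |T(x)-y|^2."""
    w = np.asarray(w, dtype=float)
    wsum = w.sum()
    xc = (w[:, None] * x).sum(0) / wsum
    yc = (w[:, None] * y).sum(0) / wsum
    H = (x - xc).T @ (w[:, None] * (y - yc))
    U, _, Vt = np.linalg.svd(H)
    S = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ S @ U.T
    return RigidTransform(R, yc - R @ xc)


@dataclass
class FusionResult:
    transforms: list[RigidTransform]
    mixture: MixtureModel | None
    super_particle: LocalizationCloud
    particle_index: np.ndarray          # (N,) source particle of each loc
    log_likelihoods: np.ndarray
    converged: bool
    pose_labels: np.ndarray | None = None


def _stack(particles: list[LocalizationCloud]
           ) -> tuple[np.ndarray, np.ndarray, list[slice]]:
    pts = np.concatenate([p.positions for p in particles])
    idx = np.concatenate([np.full(len(p), i) for i, p in enumerate(particles)])
    slices, start = [], 0
    for p in particles:
        slices.append(slice(start, start + len(p)))
        start += len(p)
    return pts, idx, slices


def _make_super(particles: list[LocalizationCloud],
                transforms: list[RigidTransform]) -> tuple[LocalizationCloud, np.ndarray]:
    pos = np.concatenate([t.apply(p.positions)
                          for p, t in zip(particles, transforms)])
    idx = np.concatenate([np.full(len(p), i) for i, p in enumerate(particles)])
    prec = (np.concatenate([p.precision for p in particles])
            if all(p.precision is not None for p in particles) else None)
    emit = (np.concatenate([p.emitter_id for p in particles])
            if all(p.emitter_id is not None for p in particles) else None)
    return LocalizationCloud(positions=pos, particle_id=-1, precision=prec,
                             emitter_id=emit), idx


def jrmpc_register(particles: list[LocalizationCloud], K: int = 34,
                   sigma0: float = 33.0, max_iter: int = 100,
                   rng: np.random.Generator | int | None = None,
                   outlier_weight: float = 0.005, tol: float = 1e-6,
                   init_cylinder_diameter: float = 120.0,
                   means_init: np.ndarray | None = None,
                   transforms_init: list[RigidTransform] | None = None,
                   ) -> FusionResult:
    """Jointly register all particles to a Gaussian mixture by EM.

    K = 34 components by default: 32 for the 32 Nup96 binding sites plus 2
    to absorb false-positive localizations of the two rings.  Mixture means
    are initialized uniformly in a cylinder (120 nm diameter) around the
    data center and all component standard deviations start at
    ``sigma0`` = 33 nm — smaller than the NPC so EM contracts onto the
    structure quickly.  One uniform component of fixed weight absorbs
    outliers.  The observed-data log-likelihood is non-decreasing across
    iterations (the update is an expectation-conditional-maximization step).
    """
    if len(particles) < 2:
        raise ValueError("joint registration needs at least 2 particles")
    for p in particles:
        if len(p) < 1:
            raise ValueError("empty particle")
    rng = np.random.default_rng(rng)

    pts, idx, slices = _stack(particles)
    N = pts.shape[0]
    center = pts.mean(0)

    if transforms_init is None:
        transforms = [RigidTransform.identity() for _ in particles]
    else:
        transforms = list(transforms_init)
    T = np.concatenate([t.apply(p.positions)
                        for p, t in zip(particles, transforms)])

    if means_init is None:
        r = init_cylinder_diameter / 2 * np.sqrt(rng.random(K))
        a = rng.uniform(0, 2 * np.pi, K)
        z = rng.uniform(-init_cylinder_diameter / 2, init_cylinder_diameter / 2, K)
        means = center + np.column_stack([r * np.cos(a), r * np.sin(a), z])
    else:
        means = np.array(means_init, dtype=float)
        K = means.shape[0]
    var = np.full(K, sigma0 ** 2)
    gamma = outlier_weight
    weights = np.full(K, (1.0 - gamma) / K)

    span = pts.max(0) - pts.min(0) + 1.0
    u_density = 1.0 / float(np.prod(span))      # uniform outlier density
    log_out = np.log(gamma * u_density) if gamma > 0 else -np.inf
    var_floor = 1.0  # nm^2; keeps components from collapsing on duplicates

    logliks = []
    converged = False
    for it in range(max_iter):
        # E-step
        lg = _log_gauss_iso(T, means, var) + np.log(weights)[None, :]
        lse = logsumexp(np.column_stack([lg, np.full(N, log_out)]), axis=1)
        alpha = np.exp(lg - lse[:, None])        # (N, K), rows sum to <= 1
        ll = float(lse.sum())
        logliks.append(ll)
        if it > 0 and abs(ll - logliks[-2]) <= tol * abs(logliks[-2]):
            converged = True
            break

        # CM-1: per-particle rigid transforms (virtual weighted targets)
        a_over_v = alpha / var[None, :]
        lam = a_over_v.sum(1)
        ok = lam > 1e-300
        y = np.where(ok[:, None], (a_over_v @ means) / np.maximum(lam, 1e-300)[:, None], T)
        for i, sl in enumerate(slices):
            w = lam[sl]
            if w.sum() <= 0:
                continue
            transforms[i] = weighted_kabsch(particles[i].positions, y[sl], w)
            T[sl] = transforms[i].apply(particles[i].positions)

        # CM-2: mixture means / variances / weights
        Nk = alpha.sum(0)
        nz = Nk > 1e-12
        means[nz] = (alpha.T @ T)[nz] / Nk[nz, None]
        d2 = (np.sum(T ** 2, 1)[:, None] + np.sum(means ** 2, 1)[None, :]
              - 2.0 * T @ means.T)
        var[nz] = np.maximum(
            (alpha * d2).sum(0)[nz] / (3.0 * Nk[nz]), var_floor)
        weights = np.maximum(Nk, 1e-12)
        weights = weights / weights.sum() * (1.0 - gamma)

    if not converged:
        warnings.warn("JRMPC did not converge within max_iter; returning "
                      "best-so-far registration", RuntimeWarning)
    super_cloud, pidx = _make_super(particles, transforms)
    mix = MixtureModel(means=means, variances=var, weights=weights,
                       outlier_weight=gamma, outlier_density=u_density)
    return FusionResult(transforms=transforms, mixture=mix,
                        super_particle=super_cloud, particle_index=pidx,
                        log_likelihoods=np.asarray(logliks), converged=converged)


# ---------------------------------------------------------------------------
# pose classification and recombination


def _angular_profile(points: np.ndarray, center: np.ndarray,
                     n_bins: int) -> np.ndarray:
    ang = np.arctan2(points[:, 1] - center[1], points[:, 0] - center[0])
    hist, _ = np.histogram(ang, bins=n_bins, range=(-np.pi, np.pi))
    prof = hist.astype(float)
    prof -= prof.mean()
    nrm = np.linalg.norm(prof)
    return prof / nrm if nrm > 0 else prof


def _profile_distance_matrix(profiles: np.ndarray) -> np.ndarray:
    """1 - zero-lag correlation between angular profiles.

    The particles are already in the jointly registered frame, so the
    *relative rotation* between them is the signal: profiles of particles
    locked into the same pose correlate positively, profiles offset by
    e.g. half a blob period anti-correlate.  (A shift-maximized
    correlation would erase exactly this information.)
    """
    D = 1.0 - profiles @ profiles.T
    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    return np.maximum(D, 0.0)


def _kmedoids(D: np.ndarray, k: int, max_iter: int = 100) -> np.ndarray:
    """Deterministic PAM-style k-medoids on a precomputed distance matrix."""
    n = D.shape[0]
    medoids = [int(D.sum(1).argmin())]
    while len(medoids) < k:
        mind = D[:, medoids].min(1)
        medoids.append(int(mind.argmax()))
    medoids = np.asarray(medoids)
    for _ in range(max_iter):
        labels = D[:, medoids].argmin(1)
        new = medoids.copy()
        for c in range(k):
            members = np.where(labels == c)[0]
            if members.size:
                sub = D[np.ix_(members, members)]
                new[c] = members[sub.sum(1).argmin()]
        if np.array_equal(new, medoids):
            break
        medoids = new
    return D[:, medoids].argmin(1)


def classify_poses(particles: list[LocalizationCloud],
                   transforms: list[RigidTransform],
                   max_clusters: int = 8, n_bins: int = 72,
                   silhouette_threshold: float = 0.25) -> np.ndarray:
    """Assign each registered particle a pose-cluster label.

    The joint registration leaves groups of particles locked into different
    z-rotations of the eight-fold-symmetric structure; these are separated
    by clustering the particles' angular intensity profiles about z
    (rotation-sensitive fingerprints) with k-medoids under a
    cross-correlation distance, choosing k by silhouette.  Returns labels
    0..k-1; a single cluster when no split is supported.
    """
    from sklearn.metrics import silhouette_score

    n = len(particles)
    if n < 3:
        return np.zeros(n, dtype=int)
    aligned = [t.apply(p.positions) for p, t in zip(particles, transforms)]
    center = np.concatenate(aligned).mean(0)
    profiles = np.stack([_angular_profile(a, center, n_bins) for a in aligned])
    D = _profile_distance_matrix(profiles)

    best_labels = np.zeros(n, dtype=int)
    best_score = silhouette_threshold
    for k in range(2, min(max_clusters, n - 1) + 1):
        labels = _kmedoids(D, k)
        if np.unique(labels).size < 2:
            continue
        score = silhouette_score(D, labels, metric="precomputed")
        if score > best_score:
            best_score, best_labels = score, labels
    return best_labels


def _kernel_score(a: np.ndarray, b: np.ndarray, h: float = 8.0,
                  max_points: int = 2000,
                  rng: np.random.Generator | None = None) -> float:
    """Gaussian kernel correlation between two clouds (alignment score)."""
    rng = np.random.default_rng(rng)
    if len(a) > max_points:
        a = a[rng.choice(len(a), max_points, replace=False)]
    if len(b) > max_points:
        b = b[rng.choice(len(b), max_points, replace=False)]
    tree = cKDTree(b)
    pairs = tree.query_ball_point(a, 3.0 * h)
    s = 0.0
    for i, js in enumerate(pairs):
        if js:
            d2 = np.sum((b[js] - a[i]) ** 2, axis=1)
            s += np.exp(-d2 / (2 * h * h)).sum()
    return s / (len(a) * len(b))


def _rotz_t(angle: float) -> RigidTransform:
    c, s = np.cos(angle), np.sin(angle)
    return RigidTransform(np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]]),
                          np.zeros(3))


_FLIP_X = RigidTransform(np.diag([1.0, -1.0, -1.0]), np.zeros(3))


def recombine(particles: list[LocalizationCloud], labels: np.ndarray,
              transforms: list[RigidTransform],
              rng: np.random.Generator | int | None = None,
              refine_iter: int = 40, angle_step_deg: float = 1.0,
              K: int = 34, sigma_refine: float = 12.0) -> FusionResult:
    """Rotate pose clusters onto the reference cluster and refine jointly.

    The largest cluster serves as reference; every other cluster is scanned
    over z-rotations in [0, 45) deg (the eight-fold symmetry folds the
    search) combined with an optional 180-degree flip about x, keeping the
    rotation maximizing a Gaussian-kernel overlap with the reference.  A
    final short joint-registration pass then polishes all transforms.  The
    output super-particle contains every input localization.
    """
    rng = np.random.default_rng(rng)
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    transforms = list(transforms)

    if uniq.size == 1:  # nothing to recombine: pass the registration through
        super_cloud, pidx = _make_super(particles, transforms)
        return FusionResult(transforms=transforms, mixture=None,
                            super_particle=super_cloud, particle_index=pidx,
                            log_likelihoods=np.asarray([]), converged=True,
                            pose_labels=labels)

    if uniq.size > 1:
        ref_lab = uniq[counts.argmax()]
        ref_cloud = np.concatenate(
            [t.apply(p.positions) for p, t, l in
             zip(particles, transforms, labels) if l == ref_lab])
        angles = np.radians(np.arange(0.0, 45.0, angle_step_deg))
        for lab in uniq:
            if lab == ref_lab:
                continue
            members = np.where(labels == lab)[0]
            cloud = np.concatenate(
                [transforms[i].apply(particles[i].positions) for i in members])
            best, best_T = -np.inf, RigidTransform.identity()
            for flip in (False, True):
                base = _FLIP_X.apply(cloud) if flip else cloud
                for ang in angles:
                    Trot = _rotz_t(ang)
                    sc = _kernel_score(Trot.apply(base), ref_cloud,
                                       rng=np.random.default_rng(0))
                    if sc > best:
                        best = sc
                        best_T = Trot.compose(_FLIP_X) if flip else Trot
            for i in members:
                transforms[i] = best_T.compose(transforms[i])

    # final joint refinement from the recombined pose
    super_cloud, _ = _make_super(particles, transforms)
    pick = rng.choice(len(super_cloud), size=min(K, len(super_cloud)),
                      replace=False)
    means0 = super_cloud.positions[pick]
    result = jrmpc_register(particles, K=K, sigma0=sigma_refine,
                            max_iter=refine_iter, rng=rng,
                            means_init=means0, transforms_init=transforms)
    result.pose_labels = labels
    return result


def fuse_particles(particles: list[LocalizationCloud], K: int = 34,
                   sigma0: float = 33.0, max_iter: int = 100,
                   rng: np.random.Generator | int | None = None,
                   classify: bool = True) -> FusionResult:
    """Full fusion pass: joint registration, pose classification,
    recombination.  One call = one reconstruction."""
    rng = np.random.default_rng(rng)
    reg = jrmpc_register(particles, K=K, sigma0=sigma0, max_iter=max_iter,
                         rng=rng)
    if not classify:
        return reg
    labels = classify_poses(particles, reg.transforms)
    if np.unique(labels).size == 1:
        reg.pose_labels = labels
        return reg
    log.info("recombining %d pose clusters", np.unique(labels).size)
    return recombine(particles, labels, reg.transforms, rng=rng)
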