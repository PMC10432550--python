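"""Eight-fold-symmetric two-emitter unit geometry of the NPC rings.

The nuclear (NR) and cytoplasmic (CR) rings of the nuclear pore complex each
carry 8 *units* of two Nup96 binding sites.  A ring is described by six
parameters: the 3D center of the first unit ``(c1x, c1y, c1z)``, the
within-unit site separation ``d``, the polar angle ``theta`` of the
site-connecting line to the +z (optical) axis, and the in-plane angle ``phi``
between the xy-projection of that line and the local ring tangent.  The two
sites of the first unit are

    s11 = (R cos psi, R sin psi, c1z) + (d/2) u
    s12 = (R cos psi, R sin psi, c1z) - (d/2) u
    u   = (-sin theta sin(phi + psi), sin theta cos(phi + psi), cos theta)

with ``R = hypot(c1x, c1y)`` the ring radius and ``psi = atan2(c1y, c1x)``
the azimuth of the unit center.  The remaining 7 units follow by rotating
both sites by ``(k - 1) * pi/4`` about z.

Angles are radians internally; ``psi`` and ``phi`` are measured
counterclockwise when viewed from +z with the NR on the +z side.  Viewing the
structure from the opposite side flips the sign of ``phi`` (a projection
handedness effect, relevant when comparing against reconstructions rendered
from the other ring's side).  Emitter 1 is the site above the ring's center
plane, which restricts ``theta`` to [0, pi/2].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "UnitRingParams",
    "SiteSet",
    "unit_sites",
    "expand_eightfold",
    "extract_unit_params",
    "lateral_axial_split",
    "wrap_angle",
    "wrap_axis_angle",
]

RingLabel = Literal["NR", "CR"]


def wrap_angle(a: float | np.ndarray) -> float | np.ndarray:
    """Wrap an angle to (-pi, pi]."""
    out = np.asarray(-((-np.asarray(a) + np.pi) % (2.0 * np.pi) - np.pi))
    return float(out) if out.ndim == 0 else out


def wrap_axis_angle(a: float | np.ndarray) -> float | np.ndarray:
    """Wrap an *axis* (orientation-free, mod pi) angle to (-pi/2, pi/2]."""
    out = np.asarray(-((-np.asarray(a) + np.pi / 2) % np.pi - np.pi / 2))
    return float(out) if out.ndim == 0 else out


class InvalidParameterError(ValueError):
    """Raised for unit-ring parameters outside their domain."""


class PairingError(ValueError):
    """Raised when 16 sites cannot be unambiguously paired into 8 units."""


@dataclass(frozen=True)
class UnitRingParams:
    """Six-parameter description of one eight-fold-symmetric ring.

    Parameters
    ----------
    c1x, c1y, c1z : float
        Center of the first unit, nm.
    d : float
        Distance between the two binding sites of a unit, nm. Must be > 0.
    theta : float
        Polar angle of the site-connecting line to +z, radians, in
        [0, pi/2] (emitter 1 lies above the ring's center plane).
    phi : float
        In-plane inclination of the projected line to the ring tangent,
        radians, stored wrapped to (-pi, pi].
    ring_label : {"NR", "CR"}, optional
    phi_defined : bool
        False when phi was unrecoverable (theta ~ 0, vertical unit).
    """

    c1x: float
    c1y: float
    c1z: float
    d: float
    theta: float
    phi: float
    ring_label: RingLabel | None = None
    phi_defined: bool = field(default=True, compare=False)

    def __post_init__(self) -> None:
        if not np.isfinite([self.c1x, self.c1y, self.c1z, self.d,
                            self.theta, self.phi]).all():
            raise InvalidParameterError("non-finite unit-ring parameter")
        if self.d <= 0:
            raise InvalidParameterError(f"d must be > 0, got {self.d}")
        if not (0.0 <= self.theta <= np.pi / 2 + 1e-12):
            raise InvalidParameterError(
                f"theta must lie in [0, pi/2], got {self.theta}")
        object.__setattr__(self, "phi", float(wrap_angle(self.phi)))

    @property
    def R(self) -> float:
        """Ring radius, nm."""
        return float(np.hypot(self.c1x, self.c1y))

    @property
    def psi(self) -> float:
        """In-plane azimuth of the first-unit center, radians."""
        return float(np.arctan2(self.c1y, self.c1x))

    @classmethod
    def from_polar(cls, R: float, psi: float, c1z: float, d: float,
                   theta: float, phi: float,
                   ring_label: RingLabel | None = None) -> "UnitRingParams":
        return cls(R * np.cos(psi), R * np.sin(psi), c1z, d, theta, phi,
                   ring_label=ring_label)

    # -- flat (de)serialization; degrees at the interface, radians inside --

    def to_dict(self) -> dict:
        """Flat key:value block with nm / degrees units."""
        return {
            "c1x_nm": float(self.c1x),
            "c1y_nm": float(self.c1y),
            "c1z_nm": float(self.c1z),
            "d_nm": float(self.d),
            "theta_deg": float(np.degrees(self.theta)),
            "phi_deg": float(np.degrees(self.phi)),
            "R_nm": self.R,
            "psi_deg": float(np.degrees(self.psi)),
            "ring_label": self.ring_label,
        }

    @classmethod
    def from_dict(cls, dd: dict) -> "UnitRingParams":
        if "c1x_nm" in dd:
            return cls(dd["c1x_nm"], dd["c1y_nm"], dd["c1z_nm"], dd["d_nm"],
                       np.radians(dd["theta_deg"]), np.radians(dd["phi_deg"]),
                       ring_label=dd.get("ring_label"))
        return cls.from_polar(dd["R_nm"], np.radians(dd["psi_deg"]),
                              dd["c1z_nm"], dd["d_nm"],
                              np.radians(dd["theta_deg"]),
                              np.radians(dd["phi_deg"]),
                              ring_label=dd.get("ring_label"))


@dataclass(frozen=True)
class SiteSet:
    """16 binding-site positions of one ring, indexed (unit k, emitter j).

    ``sites`` has shape (8, 2, 3), nm.  ``kind`` records provenance:
    ``"constrained"`` (symmetry model S), ``"unconstrained"`` (free GMM
    centers G) or ``"cryoEM"`` (reference SNAP positions M).  For
    constrained sets the 8 units are exact pi/4-rotation images of unit 1.
    """

    sites: np.ndarray
    kind: Literal["constrained", "unconstrained", "cryoEM"]
    ring_label: RingLabel | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.sites, dtype=float)
        if arr.shape == (16, 3):
            arr = arr.reshape(8, 2, 3)
        if arr.shape != (8, 2, 3):
            raise ValueError(f"sites must be (8,2,3) or (16,3), got {arr.shape}")
        if not np.isfinite(arr).all():
            raise ValueError("non-finite site coordinate")
        object.__setattr__(self, "sites", arr)

    @property
    def flat(self) -> np.ndarray:
        """(16, 3) view in (k, j) order."""
        return self.sites.reshape(16, 3)

    def midpoints(self) -> np.ndarray:
        """(8, 3) unit centers."""
        return self.sites.mean(axis=1)


def _offset_vector(theta: float, phi_plus_psi: float) -> np.ndarray:
    return np.array([-np.sin(theta) * np.sin(phi_plus_psi),
                     np.sin(theta) * np.cos(phi_plus_psi),
                     np.cos(theta)])


def unit_sites(params: UnitRingParams) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates of the two binding sites of the first unit.

    Returns ``(s11, s12)``; s11 carries the +d/2 offset along the unit axis
    (the emitter above the ring plane for theta < pi/2), s12 the -d/2 offset.
    Their midpoint is the unit center ``(R cos psi, R sin psi, c1z)`` and
    their separation is exactly ``d``.
    """
    c = np.array([params.R * np.cos(params.psi),
                  params.R * np.sin(params.psi), params.c1z])
    off = 0.5 * params.d * _offset_vector(params.theta, params.phi + params.psi)
    return c + off, c - off


def _rotz(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def expand_eightfold(params: UnitRingParams) -> SiteSet:
    """Expand the first unit into the full 16-site constrained set S.

    Units k = 2..8 are the images of unit 1 under rotation by (k-1) pi/4
    about z; z-coordinates therefore take exactly the two values
    ``c1z +/- (d/2) cos theta``.
    """
    s11, s12 = unit_sites(params)
    pair = np.stack([s11, s12])  # (2, 3)
    ks = np.arange(8)
    rots = np.stack([_rotz(k * np.pi / 4) for k in ks])  # (8, 3, 3)
    sites = np.einsum("kab,jb->kja", rots, pair)
    return SiteSet(sites=sites, kind="constrained", ring_label=params.ring_label)


def _pair_units(flat: np.ndarray, rtol: float = 1e-6) -> np.ndarray:
    """Pair 16 unlabeled sites into 8 disjoint units by mutual nearest
    neighbours (greedy over increasing pair distance, disjointness guarded).

    Returns an (8, 2) index array.  Raises PairingError when a site is
    equidistant (relative tol) to two candidate partners.
    """
    n = flat.shape[0]
    dist = np.linalg.norm(flat[:, None, :] - flat[None, :, :], axis=-1)
    np.fill_diagonal(dist, np.inf)
    order = np.argsort(dist, axis=None)
    used = np.zeros(n, dtype=bool)
    pairs: list[tuple[int, int]] = []
    for idx in order:
        i, j = divmod(int(idx), n)
        if i > j or used[i] or used[j]:
            continue
        # ambiguity guard: another free site at (numerically) the same distance
        row = np.where(~used, dist[i], np.inf)
        row[j] = np.inf
        if np.isfinite(row.min()) and abs(row.min() - dist[i, j]) <= rtol * max(dist[i, j], 1e-12):
            raise PairingError(
                f"site {i} is equidistant to sites {j} and {int(row.argmin())} "
                f"(d = {dist[i, j]:.6g} nm); unit pairing is ambiguous")
        used[i] = used[j] = True
        pairs.append((i, j))
        if len(pairs) == n // 2:
            break
    if len(pairs) != n // 2:
        raise PairingError("could not form 8 disjoint unit pairs")
    return np.asarray(pairs)


def extract_unit_params(sites: SiteSet | np.ndarray,
                        pairing: np.ndarray | None = None) -> UnitRingParams:
    """Invert :func:`expand_eightfold`: recover the six ring parameters.

    For an exactly symmetric set this is the identity (up to angle wrapping
    and unit re-indexing); for a noisy/unconstrained set it returns the
    least-squares average of the per-unit parameters.  Unit pairing is taken
    from ``sites`` when it is an (8,2,3) SiteSet with meaningful pairing, or
    recovered by mutual-nearest-neighbour pairing when ``pairing`` is None
    and the input is flat.
    """
    ring_label = None
    if isinstance(sites, SiteSet):
        ring_label = sites.ring_label
        units = sites.sites
        if sites.kind == "unconstrained" and pairing is None:
            pairing = _pair_units(sites.flat)
            units = sites.flat[pairing]
    else:
        flat = np.asarray(sites, dtype=float).reshape(-1, 3)
        if pairing is None:
            pairing = _pair_units(flat)
        units = flat[pairing]

    mids = units.mean(axis=1)                      # (8, 3)
    z0 = mids[:, 2].mean()
    # emitter 1 = site above the unit midplane (theta in [0, pi/2])
    axes = units[:, 0] - units[:, 1]               # (8, 3)
    flip = axes[:, 2] < 0
    axes[flip] *= -1.0

    d_k = np.linalg.norm(axes, axis=1)
    if np.any(d_k <= 0):
        raise PairingError("degenerate unit with coincident sites")
    theta_k = np.arccos(np.clip(axes[:, 2] / d_k, -1.0, 1.0))

    R_k = np.hypot(mids[:, 0], mids[:, 1])
    psi_k = np.arctan2(mids[:, 1], mids[:, 0])
    # phi: angle from the ring tangent t=(-sin psi, cos psi) to the projected
    # unit axis, signed about +z, orientation-free when the axis had to be
    # disambiguated by the z-sign convention above
    tx, ty = -np.sin(psi_k), np.cos(psi_k)
    ax, ay = axes[:, 0], axes[:, 1]
    phi_k = np.arctan2(tx * ay - ty * ax, tx * ax + ty * ay)

    sin_theta = np.sin(theta_k)
    phi_ok = sin_theta > 1e-9
    if phi_ok.any():
        # circular mean, weighted by in-plane axis length
        w = sin_theta * d_k
        phi = float(np.arctan2(np.sum(w * np.sin(phi_k) * phi_ok),
                               np.sum(w * np.cos(phi_k) * phi_ok)))
        phi_defined = True
    else:
        phi, phi_defined = 0.0, False

    # first-unit azimuth: remove the k pi/4 lattice, then circular-average
    order = np.argsort(np.mod(psi_k, 2 * np.pi))
    psi_res = psi_k[order] - np.arange(8) * np.pi / 4
    psi1 = float(np.arctan2(np.sin(psi_res).sum(), np.cos(psi_res).sum()))

    p = UnitRingParams.from_polar(
        R=float(R_k.mean()), psi=psi1, c1z=float(z0),
        d=float(d_k.mean()), theta=float(np.clip(theta_k.mean(), 0, np.pi / 2)),
        phi=phi, ring_label=ring_label)
    if not phi_defined:
        p = replace(p, phi_defined=False)
    return p


def lateral_axial_split(params: UnitRingParams) -> tuple[float, float]:
    """Decompose the within-unit separation ``d`` into its in-plane and
    axial components ``(d sin theta, d cos theta)`` in nm."""
    return (float(params.d * np.sin(params.theta)),
            float(params.d * np.cos(params.theta)))
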