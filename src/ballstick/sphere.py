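"""Spherical geometry for diffusion-gradient schemes.

Conventions used throughout the package:

* A *direction* is a unit 3-vector.  Its spherical coordinates are the
  **elevation** angle ``theta`` (angle from the XY-plane, in ``[-90, 90]``
  degrees, so ``theta = 90`` is the +Z pole -- this is *not* colatitude) and
  the **azimuth** ``phi`` (angle in the XY-plane from +X, in ``[0, 360)``).
* The diffusion-weighted signal is antipodally symmetric, so most distance
  computations use the *axial* angle ``arccos |u . v|`` in ``[0, 90]`` deg.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

__all__ = [
    "DWIProtocol",
    "direction_from_angles",
    "angles_from_direction",
    "angular_separation",
    "rotation_to_z",
    "generate_uniform_directions",
    "generate_hypothetical_directions",
    "read_bvals_bvecs",
    "write_bvals_bvecs",
]


def direction_from_angles(theta: float, phi: float, degrees: bool = True) -> np.ndarray:
    """Unit vector from elevation ``theta`` and azimuth ``phi``.

    ``(0, 0) -> (1, 0, 0)`` and ``(90, anything) -> (0, 0, 1)``.
    Accepts arrays and broadcasts.
    """
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if not (np.all(np.isfinite(theta)) and np.all(np.isfinite(phi))):
        raise ValueError("angles must be finite")
    if degrees:
        theta = np.deg2rad(theta)
        phi = np.deg2rad(phi)
    ct = np.cos(theta)
    return np.stack([ct * np.cos(phi), ct * np.sin(phi), np.sin(theta)], axis=-1)


def angles_from_direction(u: np.ndarray, degrees: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`direction_from_angles`; azimuth returned in [0, 360)."""
    u = np.asarray(u, dtype=float)
    theta = np.arcsin(np.clip(u[..., 2], -1.0, 1.0))
    phi = np.mod(np.arctan2(u[..., 1], u[..., 0]), 2.0 * np.pi)
    if degrees:
        return np.rad2deg(theta), np.rad2deg(phi)
    return theta, phi


def _as_unit(u: np.ndarray, name: str = "direction") -> np.ndarray:
    u = np.asarray(u, dtype=float)
    n = np.linalg.norm(u, axis=-1)
    if np.any(n < 1e-12):
        raise ValueError(f"{name} must be a nonzero vector")
    return u / n[..., None]


def angular_separation(u: np.ndarray, v: np.ndarray, axial: bool = True,
                       degrees: bool = True) -> np.ndarray:
    """Angle between two directions.

    With ``axial=True`` antipodal directions are identified and the result is
    ``arccos |u.v|`` in ``[0, 90]`` degrees; otherwise ``arccos(u.v)`` in
    ``[0, 180]``.
    """
    u = _as_unit(u, "u")
    v = _as_unit(v, "v")
    c = np.clip(np.sum(u * v, axis=-1), -1.0, 1.0)
    if axial:
        c = np.abs(c)
    ang = np.arccos(c)
    return np.rad2deg(ang) if degrees else ang


def rotation_to_z(r_l: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping the longitudinal axis ``r_l`` onto +Z.

    Built as a rotation about Z by the axis azimuth followed by a rotation
    about Y by (90 deg - elevation):

        R = [[ sin(t)cos(p),  sin(t)sin(p), -cos(t)],
             [      -sin(p),        cos(p),       0],
             [ cos(t)cos(p),  cos(t)sin(p),  sin(t)]]

    satisfying ``R @ r_l = (0, 0, 1)``; the inverse map is ``R.T``.
    """
    r_l = _as_unit(r_l, "r_l")
    t, p = angles_from_direction(r_l, degrees=False)
    st, ct = np.sin(t), np.cos(t)
    sp, cp = np.sin(p), np.cos(p)
    return np.array([
        [st * cp, st * sp, -ct],
        [-sp, cp, 0.0],
        [ct * cp, ct * sp, st],
    ])


# ---------------------------------------------------------------------------
# Gradient-scheme generation
# ---------------------------------------------------------------------------

def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform axes (z >= 0 hemisphere) used as a start."""
    i = np.arange(n) + 0.5
    z = i / n                       # axes: cover one hemisphere
    r = np.sqrt(1.0 - z * z)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=-1)


def _repulsion_energy(flat: np.ndarray, n: int) -> tuple[float, np.ndarray]:
    """Electrostatic energy of n axes (point + antipode) with gradient."""
    x = flat.reshape(n, 3)
    norms = np.linalg.norm(x, axis=1)
    u = x / norms[:, None]
    energy = 0.0
    grad_u = np.zeros_like(u)
    for sign in (1.0, -1.0):
        d = u[:, None, :] - sign * u[None, :, :]
        dist2 = np.sum(d * d, axis=-1)
        np.fill_diagonal(dist2, np.inf)
        dist = np.sqrt(dist2)
        energy += 0.5 * np.sum(1.0 / dist)
        grad_u += -np.sum(d / (dist ** 3)[..., None], axis=1)
    # chain rule through the normalization x -> x/|x|
    dot = np.sum(grad_u * u, axis=1)
    grad = (grad_u - dot[:, None] * u) / norms[:, None]
    return energy, grad.ravel()


@functools.lru_cache(maxsize=16)
def _uniform_directions_cached(n: int, seed: int) -> tuple[tuple[float, ...], ...]:
    rng = np.random.default_rng(seed)
    x0 = _fibonacci_hemisphere(n)
    # small seeded jitter breaks the perfect spiral symmetry before relaxing
    x0 = _as_unit(x0 + 0.01 * rng.standard_normal(x0.shape))
    res = minimize(_repulsion_energy, x0.ravel(), args=(n,), jac=True,
                   method="L-BFGS-B", options={"maxiter": 2000, "ftol": 1e-14})
    u = _as_unit(res.x.reshape(n, 3))
    u[u[:, 2] < 0] *= -1.0          # canonical hemisphere
    return tuple(map(tuple, u))


def generate_uniform_directions(n: int, seed: int = 0) -> np.ndarray:
    """``n`` approximately uniformly distributed gradient axes.

    Minimizes the electrostatic (Coulomb) energy of ``n`` antipodal point
    pairs on the sphere, the standard construction for "evenly distributed"
    diffusion gradient schemes.  Deterministic for a given ``(n, seed)``.
    """
    if n < 6:
        raise ValueError("need at least 6 directions for a gradient scheme")
    return np.array(_uniform_directions_cached(int(n), int(seed)))


def _min_axial_angle_to(set_a: np.ndarray, set_b: np.ndarray) -> float:
    """Smallest axial angle (deg) from any vector in set_a to any in set_b."""
    c = np.abs(set_a @ set_b.T)
    return float(np.rad2deg(np.arccos(np.clip(np.max(c, axis=1), -1, 1)).min()))


def generate_hypothetical_directions(observed: np.ndarray, n_extra: int | None = None,
                                     seed: int = 0, n_candidates: int = 1000) -> np.ndarray:
    """Extra search directions for smoothing-based maximum localization.

    One rigid rotation is applied to the whole observed scheme; the rotation
    is chosen, by search over ``n_candidates`` seeded random rotations plus a
    local refinement pass, to maximize the minimum axial angle between the
    rotated (hypothetical) and the observed directions.  No data is acquired
    along these directions; they only refine the argmax grid.
    """
    observed = _as_unit(np.atleast_2d(observed))
    if len(observed) == 0:
        raise ValueError("observed direction set must be nonempty")
    if n_extra is None:
        n_extra = len(observed)
    rng = np.random.default_rng(seed)
    cands = Rotation.random(n_candidates, random_state=rng)
    best_rot, best_score = None, -1.0
    for rot in cands:
        score = _min_axial_angle_to(rot.apply(observed), observed)
        if score > best_score:
            best_rot, best_score = rot, score
    # local refinement: small perturbations around the incumbent
    for scale in (5.0, 1.0):
        for _ in range(100):
            pert = Rotation.from_rotvec(np.deg2rad(scale) * rng.standard_normal(3))
            rot = pert * best_rot
            score = _min_axial_angle_to(rot.apply(observed), observed)
            if score > best_score:
                best_rot, best_score = rot, score
    hyp = best_rot.apply(observed)[:n_extra]
    hyp[hyp[:, 2] < 0] *= -1.0
    return hyp


# ---------------------------------------------------------------------------
# Protocol container and FSL-style text IO
# ---------------------------------------------------------------------------

@dataclass
class DWIProtocol:
    """A single-voxel acquisition scheme.

    Parameters
    ----------
    bvecs : (N, 3) array
        Gradient unit vectors; rows for b=0 entries may be zero.
    bvals : (N,) array
        Diffusion weightings in s/mm^2 (0 allowed).
    hypothetical : (M, 3) array, optional
        Hypothetical directions used only when searching smoothed maxima;
        they never carry observed signal.
    """

    bvecs: np.ndarray
    bvals: np.ndarray
    hypothetical: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))

    def __post_init__(self) -> None:
        self.bvecs = np.atleast_2d(np.asarray(self.bvecs, dtype=float))
        self.bvals = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        self.hypothetical = np.atleast_2d(np.asarray(self.hypothetical, dtype=float))
        if self.hypothetical.size == 0:
            self.hypothetical = np.empty((0, 3))
        if len(self.bvecs) != len(self.bvals):
            raise ValueError("bvecs and bvals must have equal length")
        dw = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        if np.any(norms < 1e-12):
            raise ValueError("b>0 acquisitions need a nonzero gradient direction")
        if np.any(np.abs(norms - 1.0) > 1e-3):
            import warnings

            warnings.warn("non-unit b-vectors renormalized", stacklevel=2)
        self.bvecs = self.bvecs.copy()
        self.bvecs[dw] /= norms[:, None]

    @property
    def dw_mask(self) -> np.ndarray:
        return self.bvals > 0

    @property
    def dw_bvecs(self) -> np.ndarray:
        return self.bvecs[self.dw_mask]

    @property
    def dw_bvals(self) -> np.ndarray:
        return self.bvals[self.dw_mask]

    @property
    def search_directions(self) -> np.ndarray:
        """Observed b>0 plus hypothetical directions (argmax grid)."""
        return np.vstack([self.dw_bvecs, self.hypothetical])

    def __len__(self) -> int:
        return len(self.bvals)

    def rotated(self, R: np.ndarray) -> "DWIProtocol":
        """Protocol with every direction mapped through rotation ``R``."""
        return DWIProtocol(self.bvecs @ R.T, self.bvals.copy(),
                           self.hypothetical @ R.T if len(self.hypothetical) else self.hypothetical)


def read_bvals_bvecs(bval_path, bvec_path) -> tuple[np.ndarray, np.ndarray]:
    """Read FSL-style ``bval`` (1 x N) and ``bvec`` (3 x N) text files."""
    bvals = np.loadtxt(bval_path, ndmin=1).ravel()
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        bvecs = bvecs.T  # FSL convention: 3 rows
    if bvecs.shape[0] != bvals.size:
        raise ValueError(
            f"bval/bvec length mismatch: {bvals.size} b-values vs {bvecs.shape[0]} vectors")
    return bvals, bvecs


def write_bvals_bvecs(bval_path, bvec_path, bvals: np.ndarray, bvecs: np.ndarray) -> None:
    """Write FSL-style bval/bvec text files (bvec as 3 rows)."""
    np.savetxt(bval_path, np.asarray(bvals, dtype=float)[None, :], fmt="%.6g")
    np.savetxt(bvec_path, np.asarray(bvecs, dtype=float).T, fmt="%.9f")
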