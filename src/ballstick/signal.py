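"""Ball-and-Stick signal synthesis and synthetic-voxel scenarios.

The partial-volume model splits the diffusion-weighted signal of a voxel
into one isotropic "ball" compartment and ``L`` anisotropic "stick"
compartments (idealized fibers with diffusion only along their axis):

    S_i = S0 [ (1 - sum_k f_k) exp(-b_i d) + sum_k f_k exp(-b_i d (r_i . t_k)^2) ]

where ``r_i`` is the i-th gradient axis, ``t_k`` the k-th fiber axis, ``f_k``
its volume fraction and ``d`` a common diffusivity.  Noise is i.i.d. Gaussian
with standard deviation ``sigma`` across acquisitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sphere import (DWIProtocol, direction_from_angles,
                     generate_hypothetical_directions,
                     generate_uniform_directions)

__all__ = [
    "FiberComponent",
    "VoxelGroundTruth",
    "stick_attenuation",
    "predict_signal",
    "predict_signal_simplified",
    "add_noise",
    "make_scenario",
    "list_scenarios",
]

# Ground truth shared by all simulation scenarios: S0 = 400 a.u.,
# b = 1500 s/mm^2 and d = 1/1500 mm^2/s so that b*d = 1; SNR = S0/sigma = 20.
DEFAULT_S0 = 400.0
DEFAULT_B = 1500.0
DEFAULT_D = 1.0 / 1500.0
DEFAULT_SIGMA = 20.0
DEFAULT_N_B0 = 8


@dataclass
class FiberComponent:
    """One stick: volume fraction ``f`` and orientation axis (unit vector)."""

    f: float
    orientation: np.ndarray

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("volume fraction must lie in [0, 1]")
        self.orientation = np.asarray(self.orientation, dtype=float)
        n = np.linalg.norm(self.orientation)
        if n < 1e-12:
            raise ValueError("fiber orientation must be a nonzero vector")
        self.orientation = self.orientation / n

    @classmethod
    def from_angles(cls, f: float, theta: float, phi: float) -> "FiberComponent":
        return cls(f, direction_from_angles(theta, phi))


@dataclass
class VoxelGroundTruth:
    """Ground-truth parameters of a synthetic voxel."""

    S0: float = DEFAULT_S0
    d: float = DEFAULT_D
    fibers: list[FiberComponent] = field(default_factory=list)
    sigma: float = DEFAULT_SIGMA

    def __post_init__(self) -> None:
        if self.S0 <= 0 or self.d <= 0 or self.sigma < 0:
            raise ValueError("require S0 > 0, d > 0, sigma >= 0")
        if self.total_fraction > 1.0 + 1e-12:
            raise ValueError("fiber volume fractions must sum to at most 1")

    @property
    def total_fraction(self) -> float:
        return float(sum(fb.f for fb in self.fibers))

    @property
    def orientations(self) -> np.ndarray:
        return np.array([fb.orientation for fb in self.fibers]).reshape(-1, 3)

    @property
    def fractions(self) -> np.ndarray:
        return np.array([fb.f for fb in self.fibers])


def stick_attenuation(r: np.ndarray, t: np.ndarray, b: float, d: float) -> np.ndarray:
    """Attenuation ``exp(-b d (r.t)^2)`` of a stick along ``t`` for gradient ``r``.

    ``(r.t)^2 = cos^2(Delta)`` with ``Delta`` the angle between gradient and
    fiber, which is the scalar form of the quadratic form through the fiber's
    rotation matrix.
    """
    if b < 0 or d < 0:
        raise ValueError("b and d must be non-negative")
    r = np.asarray(r, dtype=float)
    t = np.asarray(t, dtype=float)
    c = np.sum(r * t, axis=-1)
    return np.exp(-b * d * c * c)


def predict_signal(truth: VoxelGroundTruth, protocol: DWIProtocol) -> np.ndarray:
    """Noiseless model signal for every acquisition in the protocol."""
    F = truth.total_fraction
    bd = protocol.bvals * truth.d
    out = (1.0 - F) * np.exp(-bd)
    for fb in truth.fibers:
        c = protocol.bvecs @ fb.orientation
        out = out + fb.f * np.exp(-bd * c * c)
    return truth.S0 * out


def predict_signal_simplified(f1: float, phi1p: float, phi2p: float,
                              S0_hat: float, d_hat: float, F_hat: float,
                              rotated_protocol: DWIProtocol) -> np.ndarray:
    """Signal of the 2-stick model in the rotated frame.

    After rotating the longitudinal axis (the common perpendicular of the two
    fibers) onto +Z, both sticks lie in the XY-plane and are described by a
    single azimuth each:

        S_i = S0^ [ (1 - F^) e^{-b d^}
                    + f1 e^{-b d^ (r'_x cos(phi'_1) + r'_y sin(phi'_1))^2}
                    + (F^ - f1) e^{-b d^ (r'_x cos(phi'_2) + r'_y sin(phi'_2))^2} ]

    with ``F^`` the estimated total stick fraction and angles in radians,
    in ``[0, pi)``.
    """
    if not 0.0 <= f1 <= F_hat + 1e-12:
        raise ValueError("f1 must lie in [0, total stick fraction]")
    bd = rotated_protocol.bvals * d_hat
    rx = rotated_protocol.bvecs[:, 0]
    ry = rotated_protocol.bvecs[:, 1]
    c1 = rx * np.cos(phi1p) + ry * np.sin(phi1p)
    c2 = rx * np.cos(phi2p) + ry * np.sin(phi2p)
    out = ((1.0 - F_hat) * np.exp(-bd)
           + f1 * np.exp(-bd * c1 * c1)
           + (F_hat - f1) * np.exp(-bd * c2 * c2))
    return S0_hat * out


def add_noise(signal: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """Add i.i.d. Gaussian noise; deterministic for a given seed."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    signal = np.asarray(signal, dtype=float)
    if sigma == 0:
        return signal.copy()
    rng = np.random.default_rng(seed)
    return signal + sigma * rng.standard_normal(signal.shape)


# ---------------------------------------------------------------------------
# Scenario registry
# ---------------------------------------------------------------------------

def _two_fiber(phi1: float, phi2: float, f1: float = 0.4, f2: float = 0.5,
               sigma: float = DEFAULT_SIGMA) -> VoxelGroundTruth:
    return VoxelGroundTruth(fibers=[FiberComponent.from_angles(f1, 0.0, phi1),
                                    FiberComponent.from_angles(f2, 0.0, phi2)],
                            sigma=sigma)


def _scenario_registry() -> dict:
    reg: dict[str, VoxelGroundTruth] = {}
    reg["paper-default"] = _two_fiber(60.0, 120.0)
    for sep in (30, 40, 50, 60, 90):
        reg[f"sep-{sep}"] = _two_fiber(90.0 - sep / 2.0, 90.0 + sep / 2.0)
    reg["one-fiber"] = VoxelGroundTruth(
        fibers=[FiberComponent.from_angles(0.9, 0.0, 60.0)])
    # three crossing fibers, sigma = 5% of S0 = 20  ((phi, theta) per fiber)
    reg["threefiber-1"] = VoxelGroundTruth(fibers=[
        FiberComponent.from_angles(0.30, 0.0, 0.0),
        FiberComponent.from_angles(0.25, 0.0, 90.0),
        FiberComponent.from_angles(0.20, 45.0, 45.0)])
    reg["threefiber-2"] = VoxelGroundTruth(fibers=[
        FiberComponent.from_angles(0.40, 25.0, 25.0),
        FiberComponent.from_angles(0.25, 0.0, 0.0),
        FiberComponent.from_angles(0.10, 0.0, 25.0)])
    reg["threefiber-3"] = VoxelGroundTruth(fibers=[
        FiberComponent.from_angles(0.25, 0.0, 0.0),
        FiberComponent.from_angles(0.25, 0.0, 90.0),
        FiberComponent.from_angles(0.25, 90.0, 90.0)])
    return reg


_SCENARIOS = _scenario_registry()


def list_scenarios() -> list[str]:
    names = []
    for base in sorted(_SCENARIOS):
        names += [f"{base}-64", f"{base}-128"]
    return names


def make_protocol(n_directions: int = 64, n_b0: int = DEFAULT_N_B0,
                  b: float = DEFAULT_B, with_hypothetical: bool = True,
                  seed: int = 0) -> DWIProtocol:
    """Single-shell protocol with evenly distributed gradients.

    The hypothetical set (same size as the observed set) is attached for
    smoothed-maximum searches.  The scheme is deterministic for a given seed,
    so every replicate of an experiment shares the same gradients.
    """
    dirs = generate_uniform_directions(n_directions, seed=seed)
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, b)])
    hyp = (generate_hypothetical_directions(dirs, seed=seed)
           if with_hypothetical else np.empty((0, 3)))
    return DWIProtocol(bvecs, bvals, hyp)


def make_scenario(name: str, n_b0: int = DEFAULT_N_B0,
                  with_hypothetical: bool = True) -> tuple[VoxelGroundTruth, DWIProtocol]:
    """Registered ground truth + protocol, e.g. ``paper-default-64``.

    The trailing element of the name selects 64 or 128 gradient directions.
    """
    parts = name.rsplit("-", 1)
    if len(parts) != 2 or parts[1] not in ("64", "128") or parts[0] not in _SCENARIOS:
        raise KeyError(
            f"unknown scenario {name!r}; known: {', '.join(list_scenarios())}")
    truth = _SCENARIOS[parts[0]]
    protocol = make_protocol(int(parts[1]), n_b0=n_b0,
                             with_hypothetical=with_hypothetical)
    return truth, protocol
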