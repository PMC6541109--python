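"""Stage-1 closed-form estimation of the non-fiber ("nuisance") parameters.

Two moment equations identify the diffusivity ``d`` and the total stick
fraction ``F = sum_k f_k`` without any regression on orientations:

* the spherical mean of the single-shell signal is orientation-free,

      mean(S) = S0 [ (1-F) e^{-bd} + F sqrt(pi) erf(sqrt(bd)) / (2 sqrt(bd)) ]

  because averaging ``exp(-bd cos^2 Delta)`` over uniformly distributed
  gradients (density f(Delta) = sin(Delta)/2 on (0, pi)) gives the erf term;
* the signal maximum, attained along the common perpendicular of the sticks,

      max(S) = S0 [ (1-F) e^{-bd} + F ].

Eliminating ``F`` through the second equation leaves a monotone 1-D root
problem in ``x = b d`` which is solved by bracketed Brent iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import erf

from .sphere import DWIProtocol, rotation_to_z
from .smoothing import (SmoothingConfig, estimate_longitudinal_axis,
                        estimate_max_signal)

__all__ = [
    "NuisanceEstimates",
    "estimate_S0",
    "spherical_mean",
    "theoretical_mean",
    "solve_d_F",
    "estimate_nuisance",
]


@dataclass
class NuisanceEstimates:
    """Stage-1 estimates feeding the simplified model."""

    S0_hat: float
    d_hat: float
    F_hat: float               # total stick fraction, sum of f_k
    r_l_hat: np.ndarray        # longitudinal axis (unit, z >= 0)
    R_rot: np.ndarray          # rotation mapping r_l_hat onto +Z

    def to_dict(self) -> dict:
        return {"S0_hat": self.S0_hat, "d_hat": self.d_hat, "F_hat": self.F_hat,
                "r_l_hat": list(map(float, self.r_l_hat))}


def estimate_S0(signal: np.ndarray, protocol: DWIProtocol) -> float:
    """Mean of the b=0 intensities, the standard baseline estimator."""
    signal = np.asarray(signal, dtype=float)
    b0 = signal[~protocol.dw_mask]
    if b0.size == 0:
        raise ValueError("no b=0 acquisitions; supply a known S0 instead")
    return float(b0.mean())


def spherical_mean(signal: np.ndarray, protocol: DWIProtocol) -> float:
    """Unweighted mean of the raw b>0 intensities."""
    signal = np.asarray(signal, dtype=float)
    dw = signal[protocol.dw_mask]
    if dw.size == 0:
        raise ValueError("no b>0 acquisitions")
    return float(dw.mean())


def _mean_stick_factor(x) -> np.ndarray:
    """E[exp(-x cos^2 Delta)] = sqrt(pi) erf(sqrt(x)) / (2 sqrt(x)).

    Continuous at x -> 0 (limit 1); a 6th-order series is used below 1e-8.
    """
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = x < 1e-8
    xs = x[small]
    out[small] = 1.0 - xs / 3.0 + xs**2 / 10.0 - xs**3 / 42.0
    xl = x[~small]
    out[~small] = np.sqrt(np.pi) * erf(np.sqrt(xl)) / (2.0 * np.sqrt(xl))
    return out if out.ndim else float(out)


def theoretical_mean(S0: float, d: float, F: float, b: float) -> float:
    """Model value of the spherical mean for given (S0, d, F, b)."""
    x = b * d
    if x < 0:
        raise ValueError("b*d must be non-negative")
    return float(S0 * ((1.0 - F) * np.exp(-x) + F * _mean_stick_factor(x)))


def solve_d_F(S_bar: float, max_S: float, S0: float, b: float) -> tuple[float, float]:
    """Solve the spherical-mean and maximum-signal equations for (d, F).

    ``F`` is eliminated via the maximum equation,
    ``F(x) = (max_S/S0 - e^{-x}) / (1 - e^{-x})`` with ``x = b d``, and the
    spherical-mean residual is root-found on ``x``.  Degenerate inputs are
    clipped with a warning: ``max_S > S0`` clips to ``S0``; ``max_S <= S_bar``
    returns an isotropic voxel (F=0, d from the ball-only mean).
    """
    if S_bar <= 0 or S0 <= 0 or b <= 0:
        raise ValueError("require positive S_bar, S0 and b")
    if max_S > S0:
        warnings.warn("max(S) exceeds S0; clipping to S0", stacklevel=2)
        max_S = S0
    if max_S <= S_bar:
        # no detectable anisotropy: ball-only inversion of the mean equation
        x = -np.log(min(S_bar, S0) / S0) if S_bar < S0 else 1e-6
        return max(x, 1e-6) / b, 0.0
    m = max_S / S0

    def F_of(x: float) -> float:
        return (m - np.exp(-x)) / (1.0 - np.exp(-x))

    def resid(x: float) -> float:
        F = min(max(F_of(x), 0.0), 1.0)
        return (1.0 - F) * np.exp(-x) + F * _mean_stick_factor(x) - S_bar / S0

    # F(x) >= 0 requires x >= -log(m); below that the ball alone exceeds max_S
    x_lo = max(-np.log(m), 1e-6) if m < 1.0 else 1e-6
    x_hi = 20.0
    r_lo, r_hi = resid(x_lo), resid(x_hi)
    if r_lo <= 0.0:
        x = x_lo
    elif r_hi >= 0.0:
        warnings.warn("spherical mean too low for bracket; d clipped high",
                      stacklevel=2)
        x = x_hi
    else:
        x = brentq(resid, x_lo, x_hi, xtol=1e-12)
    F = F_of(x)
    if not 0.0 <= F <= 1.0:
        warnings.warn("total stick fraction clipped into [0, 1]", stacklevel=2)
        F = min(max(F, 0.0), 1.0)
    return x / b, F


def estimate_nuisance(signal: np.ndarray, protocol: DWIProtocol,
                      config: SmoothingConfig | None = None,
                      known_S0: float | None = None) -> NuisanceEstimates:
    """Full stage-1 pipeline: S0, smoothed max, (d, F), axis and rotation.

    ``known_S0`` bypasses the b0-mean estimator (used in simulation studies
    where the baseline is part of the stated ground truth).
    """
    config = config or SmoothingConfig()
    S0_hat = float(known_S0) if known_S0 is not None else estimate_S0(signal, protocol)
    bvals = protocol.dw_bvals
    b = float(bvals[0])
    if np.any(np.abs(bvals - b) > 1e-6):
        raise ValueError("single-shell data required (constant b > 0)")
    S_bar = spherical_mean(signal, protocol)
    max_S = estimate_max_signal(signal, protocol, config.kappa,
                                use_hypothetical=config.use_hypothetical)
    d_hat, F_hat = solve_d_F(S_bar, max_S, S0_hat, b)
    if config.kappa is None:
        # unsmoothed fallback: raw argmax over observed directions
        axis_cfg = SmoothingConfig(kappa=50.0, kappa2=1e6,
                                   use_hypothetical=False)
    else:
        axis_cfg = config
    r_l = estimate_longitudinal_axis(signal, protocol, axis_cfg)
    return NuisanceEstimates(S0_hat, d_hat, F_hat, r_l, rotation_to_z(r_l))
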