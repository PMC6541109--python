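"""Adaptive Metropolis-within-Gibbs samplers for the Ball-and-Stick models.

Two samplers are provided:

* the **simplified** model, where stage-1 estimates of (S0, d, F, r_l) are
  plugged in and only ``(f1, phi'_1, phi'_2, sigma)`` remain -- the fiber
  azimuths live in the rotated frame whose XY-plane contains both sticks;
* the **full** 9-parameter model ``(S0, d, f1, f2, theta1, phi1, theta2,
  phi2, sigma)`` fitted directly, used as the head-to-head benchmark.

Both use symmetric Gaussian random-walk proposals per parameter, a conjugate
Gibbs step for the noise precision ``sigma^-2 ~ Gamma(alpha=200, rate=1)``,
and batch adaptation of the proposal scales: every 50 iterations the scale is
multiplied (acceptance > 0.44) or divided (< 0.44) by
``delta = exp(min(0.01, 1/sqrt(batch)))``, which diminishes over time.
Out-of-support proposals are rejected through the prior (no reflection), so
the Metropolis ratio stays the plain posterior ratio.

The inner loops are JIT-compiled with numba; chains are bit-reproducible for
a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .sphere import DWIProtocol, angles_from_direction
from .nuisance import NuisanceEstimates

__all__ = [
    "MCMCConfig",
    "ChainState",
    "PosteriorSummary",
    "log_likelihood",
    "propose",
    "gibbs_update_precision",
    "adapt_proposals",
    "run_simplified_mcmc",
    "run_full_mcmc",
    "summarize_posterior",
    "iteration_cost",
]

# conjugate prior on the noise precision sigma^-2: Gamma(shape, rate)
PRECISION_PRIOR_SHAPE = 200.0
PRECISION_PRIOR_RATE = 1.0


@dataclass
class MCMCConfig:
    n_iter: int = 100_000
    burn_in_fraction: float = 0.5
    thin: int = 10
    adapt_interval: int = 50
    target_accept: float = 0.44
    seed: int = 0
    precision_prior_shape: float = PRECISION_PRIOR_SHAPE
    precision_prior_rate: float = PRECISION_PRIOR_RATE

    def __post_init__(self) -> None:
        if not 0.0 < self.burn_in_fraction < 1.0:
            raise ValueError("burn_in_fraction must be in (0, 1)")
        if self.thin < 1 or self.adapt_interval < 10:
            raise ValueError("require thin >= 1 and adapt_interval >= 10")


@dataclass
class ChainState:
    """Raw MCMC output: one row per iteration, one column per parameter."""

    samples: np.ndarray
    names: list[str]
    proposal_sd: np.ndarray
    accept_rate: np.ndarray
    model: str                      # "simplified" | "full"
    stopped_at: int | None = None   # iteration of dynamic stop, if any
    meta: dict = field(default_factory=dict)

    def column(self, name: str) -> np.ndarray:
        return self.samples[:, self.names.index(name)]


@dataclass
class PosteriorSummary:
    median: dict
    sd: dict
    directions: np.ndarray          # (n_fibers, 3) in the original frame
    fractions: np.ndarray           # (n_fibers,) posterior-median fractions
    model: str


# ---------------------------------------------------------------------------
# Elementary building blocks (pure-python reference versions)
# ---------------------------------------------------------------------------

def log_likelihood(signal: np.ndarray, predicted: np.ndarray, sigma: float) -> float:
    """Gaussian i.i.d. log likelihood: -n/2 log(2 pi s^2) - SSR/(2 s^2)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    signal = np.asarray(signal, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    n = signal.size
    ssr = float(np.sum((signal - predicted) ** 2))
    return -0.5 * n * np.log(2.0 * np.pi * sigma * sigma) - ssr / (2.0 * sigma * sigma)


def propose(current: float, epsilon: float, rng: np.random.Generator) -> float:
    """Symmetric Gaussian random-walk proposal."""
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    return current + epsilon * rng.standard_normal()


def gibbs_update_precision(residuals: np.ndarray, prior_shape: float,
                           prior_rate: float, rng: np.random.Generator) -> float:
    """Draw sigma from the conjugate Gamma posterior on the precision.

    precision ~ Gamma(prior_shape + n/2, rate = prior_rate + SSR/2)
    """
    residuals = np.asarray(residuals, dtype=float)
    ssr = float(np.sum(residuals ** 2))
    tau = rng.gamma(prior_shape + 0.5 * residuals.size,
                    1.0 / (prior_rate + 0.5 * ssr))
    return 1.0 / np.sqrt(tau)


def adaptation_factor(batch_index: int) -> float:
    """delta = exp(min(0.01, 1/sqrt(batch_index))), the diminishing step."""
    if batch_index < 1:
        raise ValueError("batch_index starts at 1")
    return float(np.exp(min(0.01, 1.0 / np.sqrt(batch_index))))


def adapt_proposals(proposal_sd: np.ndarray, accept_rates: np.ndarray,
                    batch_index: int, target: float = 0.44) -> np.ndarray:
    """Scale each proposal sd up/down by the diminishing factor."""
    delta = adaptation_factor(batch_index)
    out = np.asarray(proposal_sd, dtype=float).copy()
    rates = np.asarray(accept_rates, dtype=float)
    out[rates > target] *= delta
    out[rates < target] /= delta
    return out


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _simplified_kernel(sig, rx, ry, bd, S0, Fhat, state, eps, n_iter, start_iter,
                       adapt_every, target, g_shape, g_rate, seed):
    np.random.seed(seed)
    n = sig.size
    f1, p1, p2, sigma = state[0], state[1], state[2], state[3]
    ball = np.empty(n)
    s1 = np.empty(n)
    s2 = np.empty(n)
    for i in range(n):
        ball[i] = (1.0 - Fhat) * np.exp(-bd[i])
        c1 = rx[i] * np.cos(p1) + ry[i] * np.sin(p1)
        c2 = rx[i] * np.cos(p2) + ry[i] * np.sin(p2)
        s1[i] = np.exp(-bd[i] * c1 * c1)
        s2[i] = np.exp(-bd[i] * c2 * c2)
    ssr = 0.0
    for i in range(n):
        r = sig[i] - S0 * (ball[i] + f1 * s1[i] + (Fhat - f1) * s2[i])
        ssr += r * r
    samples = np.empty((n_iter, 4))
    acc = np.zeros(3)
    acc_batch = np.zeros(3)
    s_new = np.empty(n)
    for t in range(n_iter):
        # --- f1: linear in the cached stick attenuations, no exp needed
        cand = f1 + eps[0] * np.random.normal()
        if 0.0 <= cand <= Fhat:
            ssr_new = 0.0
            for i in range(n):
                r = sig[i] - S0 * (ball[i] + cand * s1[i] + (Fhat - cand) * s2[i])
                ssr_new += r * r
            if np.log(np.random.random()) < (ssr - ssr_new) / (2.0 * sigma * sigma):
                f1 = cand
                ssr = ssr_new
                acc_batch[0] += 1.0
        # --- phi'_1
        cand = p1 + eps[1] * np.random.normal()
        if 0.0 <= cand < np.pi:
            cc, sc = np.cos(cand), np.sin(cand)
            ssr_new = 0.0
            for i in range(n):
                c = rx[i] * cc + ry[i] * sc
                s_new[i] = np.exp(-bd[i] * c * c)
                r = sig[i] - S0 * (ball[i] + f1 * s_new[i] + (Fhat - f1) * s2[i])
                ssr_new += r * r
            if np.log(np.random.random()) < (ssr - ssr_new) / (2.0 * sigma * sigma):
                p1 = cand
                ssr = ssr_new
                for i in range(n):
                    s1[i] = s_new[i]
                acc_batch[1] += 1.0
        # --- phi'_2
        cand = p2 + eps[2] * np.random.normal()
        if 0.0 <= cand < np.pi:
            cc, sc = np.cos(cand), np.sin(cand)
            ssr_new = 0.0
            for i in range(n):
                c = rx[i] * cc + ry[i] * sc
                s_new[i] = np.exp(-bd[i] * c * c)
                r = sig[i] - S0 * (ball[i] + f1 * s1[i] + (Fhat - f1) * s_new[i])
                ssr_new += r * r
            if np.log(np.random.random()) < (ssr - ssr_new) / (2.0 * sigma * sigma):
                p2 = cand
                ssr = ssr_new
                for i in range(n):
                    s2[i] = s_new[i]
                acc_batch[2] += 1.0
        # --- Gibbs step for the precision
        tau = np.random.gamma(g_shape + 0.5 * n, 1.0 / (g_rate + 0.5 * ssr))
        sigma = 1.0 / np.sqrt(tau)
        # --- batch adaptation of proposal scales
        tt = start_iter + t + 1
        if tt % adapt_every == 0:
            batch = tt // adapt_every
            delta = np.exp(min(0.01, 1.0 / np.sqrt(batch)))
            for k in range(3):
                rate = acc_batch[k] / adapt_every
                if rate > target:
                    eps[k] *= delta
                elif rate < target:
                    eps[k] /= delta
                acc[k] += acc_batch[k]
                acc_batch[k] = 0.0
        samples[t, 0] = f1
        samples[t, 1] = p1
        samples[t, 2] = p2
        samples[t, 3] = sigma
    for k in range(3):
        acc[k] += acc_batch[k]
    state_out = np.array([f1, p1, p2, sigma])
    return samples, state_out, eps, acc / n_iter


@njit(cache=True)
def _full_ssr(sig, gx, gy, gz, b, S0, d, f1, f2, t1x, t1y, t1z, t2x, t2y, t2z):
    ssr = 0.0
    for i in range(sig.size):
        bd = b[i] * d
        c1 = gx[i] * t1x + gy[i] * t1y + gz[i] * t1z
        c2 = gx[i] * t2x + gy[i] * t2y + gz[i] * t2z
        pred = S0 * ((1.0 - f1 - f2) * np.exp(-bd)
                     + f1 * np.exp(-bd * c1 * c1)
                     + f2 * np.exp(-bd * c2 * c2))
        r = sig[i] - pred
        ssr += r * r
    return ssr


@njit(cache=True)
def _full_kernel(sig, gx, gy, gz, b, state, eps, S0_max, d_lo, d_hi,
                 n_iter, start_iter, adapt_every, target, g_shape, g_rate, seed):
    np.random.seed(seed)
    n = sig.size
    # state: S0, d, f1, f2, th1, ph1, th2, ph2, sigma
    p = state[:8].copy()
    sigma = state[8]
    half_pi = 0.5 * np.pi
    t1x = np.cos(p[4]) * np.cos(p[5])
    t1y = np.cos(p[4]) * np.sin(p[5])
    t1z = np.sin(p[4])
    t2x = np.cos(p[6]) * np.cos(p[7])
    t2y = np.cos(p[6]) * np.sin(p[7])
    t2z = np.sin(p[6])
    ssr = _full_ssr(sig, gx, gy, gz, b, p[0], p[1], p[2], p[3],
                    t1x, t1y, t1z, t2x, t2y, t2z)
    samples = np.empty((n_iter, 9))
    acc = np.zeros(8)
    acc_batch = np.zeros(8)
    for t in range(n_iter):
        for k in range(8):
            cand = p[k] + eps[k] * np.random.normal()
            ok = True
            log_prior = 0.0
            if k == 0:
                ok = 0.0 < cand < S0_max
            elif k == 1:
                ok = d_lo < cand < d_hi
            elif k == 2:
                ok = 0.0 <= cand <= 1.0 and cand + p[3] <= 1.0
            elif k == 3:
                ok = 0.0 <= cand <= 1.0 and p[2] + cand <= 1.0
            elif k == 4 or k == 6:
                # elevation: area-uniform prior has density cos(theta)
                ok = -half_pi < cand < half_pi
                if ok:
                    log_prior = np.log(np.cos(cand)) - np.log(np.cos(p[k]))
            else:
                ok = 0.0 <= cand < 2.0 * np.pi
            if not ok:
                continue
            old = p[k]
            p[k] = cand
            u1x = np.cos(p[4]) * np.cos(p[5])
            u1y = np.cos(p[4]) * np.sin(p[5])
            u1z = np.sin(p[4])
            u2x = np.cos(p[6]) * np.cos(p[7])
            u2y = np.cos(p[6]) * np.sin(p[7])
            u2z = np.sin(p[6])
            ssr_new = _full_ssr(sig, gx, gy, gz, b, p[0], p[1], p[2], p[3],
                                u1x, u1y, u1z, u2x, u2y, u2z)
            if np.log(np.random.random()) < (ssr - ssr_new) / (2.0 * sigma * sigma) + log_prior:
                ssr = ssr_new
                acc_batch[k] += 1.0
            else:
                p[k] = old
        tau = np.random.gamma(g_shape + 0.5 * n, 1.0 / (g_rate + 0.5 * ssr))
        sigma = 1.0 / np.sqrt(tau)
        tt = start_iter + t + 1
        if tt % adapt_every == 0:
            batch = tt // adapt_every
            delta = np.exp(min(0.01, 1.0 / np.sqrt(batch)))
            for k in range(8):
                rate = acc_batch[k] / adapt_every
                if rate > target:
                    eps[k] *= delta
                elif rate < target:
                    eps[k] /= delta
                acc[k] += acc_batch[k]
                acc_batch[k] = 0.0
        for k in range(8):
            samples[t, k] = p[k]
        samples[t, 8] = sigma
    for k in range(8):
        acc[k] += acc_batch[k]
    state_out = np.empty(9)
    state_out[:8] = p
    state_out[8] = sigma
    return samples, state_out, eps, acc / n_iter


# ---------------------------------------------------------------------------
# Drivers
# ---------------------------------------------------------------------------

SIMPLIFIED_NAMES = ["f1", "phi1p", "phi2p", "sigma"]
FULL_NAMES = ["S0", "d", "f1", "f2", "theta1", "phi1", "theta2", "phi2", "sigma"]


def _grid_init_azimuths(sig, rx, ry, bd, S0, Fhat, n_grid: int = 24):
    """Deterministic coarse scan of (phi'_1, phi'_2) pairs by SSR."""
    phis = np.linspace(0.0, np.pi, n_grid, endpoint=False)
    sticks = np.exp(-bd[None, :] * (np.outer(np.cos(phis), rx)
                                    + np.outer(np.sin(phis), ry)) ** 2)
    ball = (1.0 - Fhat) * np.exp(-bd)
    half = 0.5 * Fhat
    best, best_pair = np.inf, (np.pi / 4.0, 3.0 * np.pi / 4.0)
    for a in range(n_grid):
        pred = S0 * (ball + half * sticks[a] + half * sticks)
        ssr = np.sum((sig[None, :] - pred) ** 2, axis=1)
        ssr[a] = np.inf  # coincident sticks are a degenerate start
        j = int(np.argmin(ssr))
        if ssr[j] < best:
            best, best_pair = ssr[j], (float(phis[a]), float(phis[j]))
    return best_pair


def _grid_init_single_azimuth(sig, rx, ry, bd, S0, Fhat, n_grid: int = 48):
    """Best single stick azimuth (one-fiber restricted model) by SSR."""
    phis = np.linspace(0.0, np.pi, n_grid, endpoint=False)
    sticks = np.exp(-bd[None, :] * (np.outer(np.cos(phis), rx)
                                    + np.outer(np.sin(phis), ry)) ** 2)
    pred = S0 * ((1.0 - Fhat) * np.exp(-bd)[None, :] + Fhat * sticks)
    ssr = np.sum((sig[None, :] - pred) ** 2, axis=1)
    return float(phis[int(np.argmin(ssr))])


def _chunk_seeds(seed: int, n_chunks: int) -> np.ndarray:
    ss = np.random.SeedSequence(seed)
    return (ss.generate_state(max(n_chunks, 1)) & 0x7FFFFFFF).astype(np.int64)


def _run_chunked(kernel_call, n_iter, rule):
    """Run a kernel in chunks, optionally stopping early via a rule."""
    from .convergence import should_stop  # local import: avoid cycle

    pieces = []
    done = 0
    stopped_at = None
    while done < n_iter:
        step = min(rule.check_interval, n_iter - done) if rule else n_iter - done
        samples = kernel_call(done, step)
        pieces.append(samples)
        done += step
        if rule is not None and done >= rule.min_iterations:
            stop, _ = should_stop(np.vstack(pieces), rule, elapsed=done)
            if stop:
                stopped_at = done
                break
    return np.vstack(pieces), stopped_at


def run_simplified_mcmc(signal: np.ndarray, protocol: DWIProtocol,
                        nuisance: NuisanceEstimates,
                        config: MCMCConfig | None = None,
                        stopping_rule=None, n_fibers: int = 2) -> ChainState:
    """Adaptive MCMC over (f1, phi'_1, phi'_2, sigma) in the rotated frame.

    The protocol's gradients are rotated by ``R_rot`` so the stick azimuths
    are sampled in the frame where the fiber plane is XY.  ``f1`` has support
    ``[0, F_hat]`` (so ``f2 = F_hat - f1`` stays non-negative), the azimuths
    ``[0, pi)``; out-of-support proposals are rejected.  Initialization:
    ``f1 = F_hat/2`` and the best azimuth pair of a coarse grid scan.

    ``n_fibers=1`` fits the restricted one-stick model of the step-down
    screen: ``f1`` is pinned at ``F_hat`` (zero proposal scale), leaving only
    ``(phi'_1, sigma)`` free.
    """
    config = config or MCMCConfig()
    if nuisance.F_hat <= 0.0:
        raise ValueError("F_hat = 0: voxel is isotropic; fit 0/1-fiber model upstream")
    if n_fibers not in (1, 2):
        raise ValueError("n_fibers must be 1 or 2")
    rot = protocol.rotated(nuisance.R_rot)
    sig = np.asarray(signal, dtype=float)[rot.dw_mask]
    rx = np.ascontiguousarray(rot.dw_bvecs[:, 0])
    ry = np.ascontiguousarray(rot.dw_bvecs[:, 1])
    bd = np.ascontiguousarray(rot.dw_bvals * nuisance.d_hat)
    p1, p2 = _grid_init_azimuths(sig, rx, ry, bd, nuisance.S0_hat, nuisance.F_hat)
    if n_fibers == 1:
        p1 = _grid_init_single_azimuth(sig, rx, ry, bd, nuisance.S0_hat,
                                       nuisance.F_hat)
        state = np.array([nuisance.F_hat, p1, 0.0, 0.05 * nuisance.S0_hat])
        eps = np.array([0.0, 0.1, 0.0])
    else:
        state = np.array([0.5 * nuisance.F_hat, p1, p2, 0.05 * nuisance.S0_hat])
        eps = np.array([0.05, 0.1, 0.1])
    seeds = _chunk_seeds(config.seed, 1 + config.n_iter // max(
        stopping_rule.check_interval if stopping_rule else config.n_iter, 1))
    holder = {"state": state, "eps": eps, "acc": None, "i": 0}

    def call(start, step):
        samples, st, ep, acc = _simplified_kernel(
            sig, rx, ry, bd, nuisance.S0_hat, nuisance.F_hat,
            holder["state"], holder["eps"], step, start,
            config.adapt_interval, config.target_accept,
            config.precision_prior_shape, config.precision_prior_rate,
            int(seeds[holder["i"]]))
        holder.update(state=st, eps=ep, acc=acc, i=holder["i"] + 1)
        return samples

    samples, stopped_at = _run_chunked(call, config.n_iter, stopping_rule)
    return ChainState(samples, list(SIMPLIFIED_NAMES), holder["eps"],
                      holder["acc"], "simplified", stopped_at,
                      meta={"F_hat": nuisance.F_hat, "seed": config.seed})


def run_full_mcmc(signal: np.ndarray, protocol: DWIProtocol,
                  config: MCMCConfig | None = None,
                  init: dict | None = None,
                  stopping_rule=None) -> ChainState:
    """Adaptive MCMC over the full 9-parameter Ball-and-Stick model.

    Priors: S0 ~ U(0, 2 max(signal)); d ~ U(1e-5, 1e-2) mm^2/s; f1, f2 ~
    U(0,1) restricted to f1+f2 <= 1; orientations area-uniform on the sphere
    (azimuth uniform, elevation cos-weighted); sigma^-2 conjugate Gamma.
    ``init`` may carry starting values (e.g. stage-1 estimates).
    """
    config = config or MCMCConfig()
    sig = np.ascontiguousarray(np.asarray(signal, dtype=float))
    gx = np.ascontiguousarray(protocol.bvecs[:, 0])
    gy = np.ascontiguousarray(protocol.bvecs[:, 1])
    gz = np.ascontiguousarray(protocol.bvecs[:, 2])
    b = np.ascontiguousarray(protocol.bvals)
    S0_max = 2.0 * float(sig.max())
    init = dict(init or {})
    S0_0 = float(init.get("S0", min(sig.max(), 0.99 * S0_max)))
    d_0 = float(init.get("d", 1.0 / 1500.0))
    f1_0 = float(init.get("f1", 0.35))
    f2_0 = float(init.get("f2", 0.35))
    th1_0 = float(init.get("theta1", 0.0))
    ph1_0 = float(init.get("phi1", np.pi / 3.0))
    th2_0 = float(init.get("theta2", 0.0))
    ph2_0 = float(init.get("phi2", 2.0 * np.pi / 3.0))
    sigma_0 = float(init.get("sigma", 0.05 * S0_0))
    state = np.array([S0_0, d_0, f1_0, f2_0, th1_0, ph1_0, th2_0, ph2_0, sigma_0])
    eps = np.array([0.02 * S0_0, 0.1 * d_0, 0.05, 0.05, 0.1, 0.1, 0.1, 0.1])
    seeds = _chunk_seeds(config.seed + 1, 1 + config.n_iter // max(
        stopping_rule.check_interval if stopping_rule else config.n_iter, 1))
    holder = {"state": state, "eps": eps, "acc": None, "i": 0}

    def call(start, step):
        samples, st, ep, acc = _full_kernel(
            sig, gx, gy, gz, b, holder["state"], holder["eps"], S0_max,
            1e-5, 1e-2, step, start, config.adapt_interval,
            config.target_accept, config.precision_prior_shape,
            config.precision_prior_rate, int(seeds[holder["i"]]))
        holder.update(state=st, eps=ep, acc=acc, i=holder["i"] + 1)
        return samples

    samples, stopped_at = _run_chunked(call, config.n_iter, stopping_rule)
    return ChainState(samples, list(FULL_NAMES), holder["eps"], holder["acc"],
                      "full", stopped_at, meta={"seed": config.seed})


def kept_samples(state: ChainState, config: MCMCConfig) -> np.ndarray:
    """Post-burn-in, thinned draws."""
    n = len(state.samples)
    burn = int(config.burn_in_fraction * n)
    if burn >= n:
        raise ValueError("chain shorter than burn-in")
    return state.samples[burn::config.thin]


def summarize_posterior(state: ChainState, config: MCMCConfig | None = None,
                        nuisance: NuisanceEstimates | None = None) -> PosteriorSummary:
    """Medians/sds of the kept draws; orientations back in the original frame.

    For the simplified model ``f2 = F_hat - f1`` per draw and the stick
    azimuths ``(0, phi'_k)`` are back-rotated through ``R_rot^T``.
    """
    config = config or MCMCConfig()
    kept = kept_samples(state, config)
    med = {n: float(np.median(kept[:, i])) for i, n in enumerate(state.names)}
    sd = {n: float(np.std(kept[:, i], ddof=1)) for i, n in enumerate(state.names)}
    if state.model == "simplified":
        if nuisance is None:
            raise ValueError("simplified summaries need the nuisance estimates")
        f1 = kept[:, state.names.index("f1")]
        f2 = nuisance.F_hat - f1
        med["f2"] = float(np.median(f2))
        sd["f2"] = float(np.std(f2, ddof=1))
        dirs = []
        for key in ("phi1p", "phi2p"):
            phip = med[key]
            t = nuisance.R_rot.T @ np.array([np.cos(phip), np.sin(phip), 0.0])
            dirs.append(t)
        directions = np.array(dirs)
        fractions = np.array([med["f1"], med["f2"]])
    else:
        dirs = []
        for k in (1, 2):
            th, ph = med[f"theta{k}"], med[f"phi{k}"]
            dirs.append(np.array([np.cos(th) * np.cos(ph),
                                  np.cos(th) * np.sin(ph), np.sin(th)]))
        directions = np.array(dirs)
        fractions = np.array([med["f1"], med["f2"]])
    # canonical axial representation: z >= 0
    flip = directions[:, 2] < 0
    directions[flip] *= -1.0
    theta_deg, phi_deg = angles_from_direction(directions)
    for k in (0, 1):
        med[f"theta{k + 1}_deg"] = float(theta_deg[k])
        med[f"phi{k + 1}_deg"] = float(np.mod(phi_deg[k], 180.0))
    return PosteriorSummary(med, sd, directions, fractions, state.model)


def iteration_cost(model: str, n_dw: int, n_total: int | None = None) -> float:
    """Stick-attenuation evaluations per MCMC iteration.

    Mirrors the kernels: the simplified sampler recomputes one cached stick
    per azimuth update (the ``f1`` update is linear in the cache), i.e.
    ``2 * n_dw`` exponentials; the full sampler recomputes all three
    compartments for each of its 8 Metropolis updates, ``8 * 3 * n_total``.
    """
    if model == "simplified":
        return 2.0 * n_dw
    if model == "full":
        return 8.0 * 3.0 * float(n_total if n_total is not None else n_dw)
    raise ValueError("model must be 'simplified' or 'full'")
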