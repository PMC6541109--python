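# ballstick

Simplified two-fiber **Ball-and-Stick** modelling of diffusion-weighted MRI
(dMRI), with a full 9-parameter Ball-and-Stick sampler for head-to-head
benchmarking.

## The problem

In a brain voxel crossed by two white-matter fiber bundles, the
diffusion-weighted signal along gradient axis `r_i` follows the
partial-volume Ball-and-Stick model

```
S_i = S0 [ (1 - f1 - f2) exp(-b d) + f1 exp(-b d (r_i . t1)^2)
                                   + f2 exp(-b d (r_i . t2)^2) ]
```

with baseline `S0`, diffusivity `d`, stick fractions `f_k` and stick axes
`t_k`.  Fitting all nine parameters by MCMC (as probabilistic tractography
pipelines do, voxel by voxel) is slow and fragile.  This package implements
a two-stage estimator that removes the non-fiber parameters in closed form
before any sampling:

1. **Spherical mean.** For a single shell, the average signal over evenly
   distributed gradients is orientation-free:
   `mean(S) = S0 [ (1-F) e^{-bd} + F sqrt(pi) erf(sqrt(bd)) / (2 sqrt(bd)) ]`
   with `F = f1 + f2`.
2. **Smoothed maximum.** The signal is maximal along the *longitudinal axis*
   (the common perpendicular of the two sticks), where
   `max(S) = S0 [ (1-F) e^{-bd} + F ]`.  The maximum's magnitude and
   direction are estimated from von-Mises-kernel-smoothed data (axial
   angles; concentration `kappa = 50` for the magnitude, `kappa2 = 0.1` for
   the direction, searched over observed plus *hypothetical* gradient
   directions).
3. Solving the two equations gives `d` and `F`; rotating the longitudinal
   axis onto +Z puts both sticks in the XY-plane, so each is a single
   azimuth.  Only `(f1, phi'_1, phi'_2, sigma)` remain for an adaptive
   Metropolis-within-Gibbs sampler (symmetric Gaussian proposals adapted
   toward 0.44 acceptance every 50 iterations, conjugate Gibbs step for the
   noise precision, Geweke-diagnostic dynamic stopping), roughly 13x cheaper
   per iteration than the full sampler.

## Worked example

```python
import numpy as np, ballstick as bs

truth, protocol = bs.make_scenario("paper-default-64")   # S0=400, b=1500,
# d=1/1500, sticks f=0.4/0.5 at 60/120 deg azimuth, 64 gradients, SNR 20
noisy = bs.add_noise(bs.predict_signal(truth, protocol), truth.sigma, seed=7)

nuis = bs.estimate_nuisance(noisy, protocol, known_S0=400.0)
print(round(nuis.d_hat * 1500, 3), round(nuis.F_hat, 3))
# 1.024 0.882     <- b*d_hat and total stick fraction (truth: 1.0, 0.9)

cfg = bs.MCMCConfig(n_iter=20_000, thin=5, seed=1)
chain = bs.run_simplified_mcmc(noisy, protocol, nuis, cfg)
summ = bs.summarize_posterior(chain, cfg, nuis)
print(np.round(summ.fractions, 3), np.round(summ.median["phi1_deg"], 1),
      np.round(summ.median["phi2_deg"], 1))
# [0.474 0.408] 64.7 126.3   <- fractions and azimuths (truth: 0.4/0.5, 60/120)
```

The replication engine reruns the whole pipeline over many noise draws and
permutation-matches estimated to true sticks:

```python
df = bs.run_experiment("paper-default-64", ("simplified", "full"), (50.0,),
                       n_replicates=25, config=bs.fast_config(), seed=1)
print(bs.aggregate_table(df)[["model", "f1_bias_mean", "ang_bias_2_mean"]])
#         model  f1_bias_mean  ang_bias_2_mean
# 0        full      0.004655         5.290509
# 1  simplified      0.010153         6.400373
```

A command-line interface wraps the same machinery for NIfTI volumes with
FSL-style `bval`/`bvec` files:

```sh
ballstick simulate --scenario paper-default-64 --seed 1 --out sim
ballstick fit sim.nii --bval sim.bval --bvec sim.bvec --fast --out fit
ballstick experiment --fast --replicates 25 --out table.csv
ballstick three-fiber --scenario 3 --fast --replicates 100
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
recomputes the benchmark quantities from scratch — replicated simulations of
the default two-fiber voxel (fraction bias, angular bias and posterior
spread for both models at `kappa = 50`), the smoothed-maximum relative
error, the longitudinal-axis accuracy at 90 and 50 degree separations, the
40-degree-separation experiment with 64 vs 128 gradients, and the
three-fiber stress test — and writes one JSON entry per quantity.  MCMC
experiments run at reduced scale (25 replicates, 20 000 iterations);
smoothing-only quantities use 100 replicates.
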