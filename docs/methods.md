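# Methods

## Model

A voxel's single-shell diffusion-weighted signal is modelled as one
isotropic "ball" plus `L` anisotropic "sticks":

    S_i = S0 [ (1 - F) exp(-b_i d) + sum_k f_k exp(-b_i d (r_i . t_k)^2) ],
    F = sum_k f_k,

with i.i.d. Gaussian noise of standard deviation `sigma` across
acquisitions.  `(r . t)^2 = cos^2(Delta)` depends only on the axial angle
between gradient and stick, so the signal is antipodally symmetric; all
angular machinery in the package therefore uses axial angles
(`arccos |u.v|`) unless stated otherwise.  Spherical coordinates are
elevation/azimuth: `theta` is measured from the XY-plane (`theta = 90 deg`
is +Z), `phi` from +X in the XY-plane.

Assumptions inherited by everything downstream: a single nonzero b-value;
one shared diffusivity for ball and sticks; Gaussian (not Rician) noise;
at most two sticks in the fitted model.

## Two-stage estimation

**Stage 1 (closed form).** Three statistics of the observed signal identify
the non-fiber parameters:

* `S0` — mean of the b=0 acquisitions (or supplied externally in
  simulation studies, where it is part of the stated ground truth);
* the spherical mean over gradients, whose model value for uniformly
  distributed axes is orientation-free:
  `mean(S)/S0 = (1-F) e^{-x} + F sqrt(pi) erf(sqrt(x)) / (2 sqrt(x))`,
  `x = b d` (the erf term is the exact average of `exp(-x cos^2 Delta)`
  under the axis density `sin(Delta)/2`; a 6th-order series replaces it
  below `x = 1e-8`);
* the signal maximum, attained along the common perpendicular of the two
  sticks ("longitudinal axis"): `max(S)/S0 = (1-F) e^{-x} + F`.

Eliminating `F` through the maximum equation leaves a monotone scalar
equation in `x`, solved by Brent iteration on `x` in
`[max(-log(max(S)/S0), 1e-6), 20]` to `1e-12`.  Degenerate inputs are
clipped with warnings: `max(S) > S0` clips to `S0`; `max(S) <= mean(S)`
returns an isotropic voxel (`F = 0`).

Because the raw maximum of noisy data is upward-biased and coarse, both the
magnitude and the direction of the maximum are taken from von-Mises-kernel
smoothed data: each candidate direction receives a convex combination of
the observed b>0 intensities with weights `exp(kappa cos x_ij)` (axial
angles; the `2 pi I0(kappa)` normalization cancels in the ratio, and the
row maximum of `kappa cos x` is subtracted before exponentiation so
`kappa ~ 700` cannot overflow).  Two concentrations are used:

* `kappa = 50` (default, useful range ~35-70, warn outside [1, 200]) for
  the magnitude `max(S)`;
* `kappa2 = 0.1` (default) for the argmax that estimates the longitudinal
  axis.

The argmax is searched over the observed directions plus an equal number of
*hypothetical* directions: one rigid rotation of the whole observed scheme,
chosen by seeded search (1000 random rotations plus local refinement) to
maximize the minimum axial angle to the observed set.  This doubles the
angular resolution of the search grid without pretending to new data.

**Stage 2 (MCMC).** Rotating the estimated axis onto +Z (rotation about Z
by the axis azimuth, then about Y by 90 deg minus its elevation) puts both
sticks in the XY-plane, so the remaining parameters are
`(f1, phi'_1, phi'_2, sigma)` with `f2 = F - f1` by construction.
An adaptive Metropolis-within-Gibbs sampler draws them:

* symmetric Gaussian random-walk proposals per parameter; support
  enforcement by rejection (`f1` in `[0, F]` — the nominal U(0,1) prior
  would allow a negative second fraction — and azimuths in `[0, pi)`);
* a conjugate Gibbs step for the precision,
  `sigma^-2 ~ Gamma(200 + n/2, rate 1 + SSR/2)` under the Gamma(200, 1)
  prior (see "Numerical and design choices");
* every 50 iterations each proposal scale is multiplied (batch acceptance
  > 0.44) or divided (< 0.44) by `delta = exp(min(0.01, 1/sqrt(batch)))`,
  a diminishing-adaptation schedule;
* summaries are medians/sds of the thinned post-burn-in draws (defaults:
  burn-in 1/2, thin 10 at 100 000 iterations; the reduced preset uses
  20 000 iterations with thin 5), and stick axes are rotated back to the
  original frame through the transpose of the alignment rotation.

The benchmark **full model** samples all of
`(S0, d, f1, f2, theta1, phi1, theta2, phi2, sigma)` with the same
machinery.  Priors: `S0 ~ U(0, 2 max(signal))`; `d ~ U(1e-5, 1e-2)` mm^2/s;
`f1, f2 ~ U(0,1)` restricted to `f1 + f2 <= 1`; orientations area-uniform
(uniform azimuth, cos-weighted elevation).  It starts from the stage-1
estimates (and a coarse grid scan of the rotated-frame azimuths), which is
this package's choice where the benchmark's initialization was genuinely
open; with a vaguer start its bias would likely be larger.

Per iteration the simplified sampler recomputes one cached stick
attenuation per azimuth update and none for the fraction update
(`2 n` exponentials for `n` gradients); the full sampler recomputes all
three compartments for each of 8 Metropolis updates (`24 n`), a ~13.5x
per-iteration cost ratio at 64 gradients — the package asserts the
accounting ratio, not wall-clock.

## Convergence control and model screening

Sampling may stop early per voxel: at checkpoints (default every 5000
iterations after a 10 000 minimum) the Geweke z-score — first 10% vs last
50% window means standardized by spectral-density-at-zero variances
(Bartlett window over 4% of lags) — must satisfy `|z| < 2` for every
sampled parameter.  A constant chain is defined as converged (`z = 0`).

A within-run screen flags 2-fiber fits of 1-fiber data.  Calibrated on
simulations of the default scenarios (the source of the thresholds is not
public), one fiber is declared when any of:

* median of `min(f1, F - f1)` below **0.15** — on one-fiber data the
  maximum-signal equation overestimates `F` (the maximum is a full ring, so
  smoothing shrinks it less and noise inflates it more), leaving a spurious
  minor stick of ~0.09-0.13, while genuine crossings at the default
  fractions sit at ~0.26+;
* median axial angle between sticks below 10 deg (coincident sticks);
* posterior sd of `f1` above 0.05 — with one fiber the split wanders a flat
  likelihood ridge (sd ~0.1-0.17 vs ~0.02 for a genuine crossing).

The trade-off is deliberate: a true crossing with a very small second
fraction (< 0.15) will be screened as one fiber.  A restricted one-stick
sampler (`n_fibers=1`: `f1` pinned at `F`) supports the step-down refit;
having no split ridge, it stops no later than the 2-fiber fit.

## Synthetic data

The generator emulates single-voxel, single-shell acquisitions:
`S0 = 400`, `b = 1500 s/mm^2`, `d = 1/1500 mm^2/s` (so `b d = 1`), two
sticks of fractions 0.4/0.5 in the XY-plane at azimuths 60/120 deg (or a
symmetric pair at separations 30-90 deg), SNR 20 (`sigma = S0/20 = 20`),
64 or 128 electrostatically-even gradient axes plus 8 b=0 acquisitions,
and i.i.d. Gaussian noise.  The printed b-unit in the source material
("s/m^2") is read as s/mm^2 — the standard convention, and the only one
that makes `b d = 1` dimensionally coherent.  Three 3-fiber stress
scenarios (including three orthogonal equal-fraction sticks at
`sigma = 5%` of `S0`) and a one-fiber scenario are registered.

What a green test does *not* establish: behaviour under Rician noise,
multi-shell acquisitions, spatially correlated noise, fiber dispersion or
real-scanner artifacts — none of which the generator emulates.  Two
documented consequences of the synthetic grid itself: the discrete argmax
that estimates the longitudinal axis can be no closer to the true axis
than the nearest grid direction (~9 deg for this scheme, the floor of the
axis-bias benchmark at 50 deg separation), and a single rigid rotation of
the observed scheme cannot push the combined grid's covering radius below
~11 deg.

## Numerical and design choices

* **Uniform gradient axes**: electrostatic-repulsion minimization of
  antipodal point pairs (L-BFGS from a jittered Fibonacci start), seeded
  and cached; minimum pairwise axial angle ~17.6 deg at n = 64.
* **Precision prior**: the stated noise prior ("Inverse-Gamma(200, 1)" on
  `sigma^-2`, called non-informative) is internally inconsistent — it is
  sharp however read.  Implemented as the conjugate Gamma(shape 200,
  rate 1) prior on the precision (equivalently `sigma^2 ~ IG(200, 1)`),
  hyperparameters exposed in `MCMCConfig`.  At SNR 20 this pulls the
  sampled `sigma` to the prior-data compromise (~7.5, not 20), sharpening
  all posteriors; the benchmark's published posterior spreads are only
  reproducible *with* this prior, so it is kept.
* **Adaptation batch index**: `c = sqrt(t div 50)` (the `t mod 50` reading
  would break diminishing adaptation).
* **Initialization**: `f1 = F/2`; azimuths from a deterministic 24-point
  grid scan of the rotated-frame SSR (fallback pi/4, 3pi/4);
  `sigma0 = 0.05 S0`.
* **Label permutation**: estimated sticks are matched to truth by the
  permutation minimizing the average axial angle (nulls padded at 90 deg
  when counts differ); fraction and angular biases are reported for the
  matched pairing, bias = estimate - truth.
* **Replicate pairing**: per-replicate noise seeds are derived from the
  master seed by counter-based splitting, so smoothing kernels and models
  are compared on identical noise realizations.
* **Degenerate inputs**: `b d -> 0` handled by series expansion; zero
  vectors rejected; isotropic voxels (F = 0) are reported as 0-fiber
  rather than sampled.

## Known limitations

* No more than two sticks are fitted; three-way crossings are out of the
  model class (the stress tests quantify, not fix, this).
* The axis estimator is a discrete argmax; its accuracy is bounded by the
  search grid (see above), and at small fiber separations or near-isotropic
  signals (three balanced orthogonal fibers) it is noise-dominated.
* Stage-2 posteriors condition on stage-1 estimates; the uncertainty of
  `S0, d, F` and the rotation is not propagated.
* Single shell only; the multi-shell extension (pooling per-shell
  estimates) is not implemented.
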