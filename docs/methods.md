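# Methods

`athresh` thresholds single-subject statistical parametric maps with a
data-driven cluster-forming threshold derived from a Gamma-Gaussian
mixture model, followed by random-field ("topological") FDR over cluster
extents.  This note records the model, the procedure, the numerical
choices, and what the synthetic benchmark does and does not establish.

## The mixture model

The T-values of all in-mask voxels are treated as an i.i.d. sample from
one of three nested mixtures:

* **Model 1 (no signal):** `p(x) = N(x | mu, sigma)`
* **Model 2 (activation):**
  `p(x) = pi_N N(x | mu, sigma) + pi_A Gamma(x - mu | k_A, theta_A)`
* **Model 3 (activation + deactivation):** model 2 plus
  `pi_D Gamma(mu - x | k_D, theta_D)`

The Gaussian models the null; the Gamma components model the tails and
are *anchored at the fitted Gaussian mean*: the activation component has
open support `x > mu`, the deactivation component `x < mu`.  Anchoring is
what gives the procedure its immunity to "global effects" — a constant
added to every T-value is absorbed into `mu` and every downstream
quantity shifts with it.  With the degrees of freedom typical of fMRI
time series the Student-t null is close enough to Gaussian for the
Gaussian component to absorb it.

Model 1 is fitted in closed form (ML).  Models 2 and 3 are fitted by EM:

* E-step: posterior responsibilities from the weighted component
  densities (log-domain, densities floored at 1e-300).
* M-step: exact weighted ML updates for `mu`, `sigma` and the weights;
  weighted method-of-moments updates for each Gamma's `(k, theta)` using
  the responsibilities of the points inside its support, with the origin
  tracking the current `mu`.  Method-of-moments is used because it is
  stable when a tail component carries little weight; the log-likelihood
  is monitored and is non-decreasing in practice (asserted to 1e-8
  relative slack in the tests).
* Initialisation is deterministic: `mu`, `sigma` from the
  interquartile-trimmed sample (the trimmed SD rescaled by the
  truncated-normal factor 0.3903 so it is consistent under a Gaussian),
  Gamma parameters by moments of the values beyond one sigma from `mu`.
  EM runs from two starts — signal weight 0.1 and 0.01 — and the higher
  final log-likelihood wins.  The second, almost-null start protects the
  nesting property (a signal model never scores materially below the
  Gaussian it contains).  A start in which a weight falls below 1e-4 or
  `sigma` below 1e-6 is discarded as collapsed.
* Convergence: relative log-likelihood change below 1e-6, at most 1000
  iterations.

Models are compared by BIC on the higher-is-better convention
`2 log L - p ln n` with `p` = 2, 5, 8 free parameters.  Voxels are
labeled by posterior argmax (ties resolve conservatively to noise), and
the **adaptive threshold** is the largest T-value labeled noise — the
empirical crossing point of the weighted null and activation densities.
A model-1 win is reported as "no signal" and yields an empty activation
map.

## Topological inference

Smoothness of the noise field is estimated from the GLM residual frames:
each voxel's residual series is normalized to unit temporal RMS and the
per-axis variance `lambda` of spatial first differences gives
`FWHM = sqrt(4 ln 2 / lambda)` per axis (independent unit voxels give
`lambda = 2`, i.e. FWHM 1.18).  Resel counts `R_0..R_D` of the search
region come from an Euler-characteristic decomposition (voxels, edges,
faces, cubes), exact for box masks; the scalar resel volume is mask
voxels over the FWHM product.

Cluster inference uses the standard stationary t-field machinery:

* Expected Euler characteristic `E[EC](u) = sum_d R_d rho_d(u)` with the
  unified t-field EC densities.  The FWE forming threshold solves
  `E[EC](u) = p` by bisection on `u in [1, 50]`.
* A cluster of `k` resels formed at `u` gets
  `P(K >= k) = exp(-beta k^(2/D))`, `beta = (Gamma(D/2+1) / E[n])^(2/D)`,
  where the expected cluster size `E[n]` is the expected supra-threshold
  resel volume over `E[EC](u)`.  Extents enter in resels (standard
  practice).
* In adaptive mode the extent p-values are evaluated at the excursion
  height above the fitted noise mean (`u - mu_hat`): the random-field
  formulas describe a zero-mean field, and the mixture's whole point is
  that the null may sit away from zero (global effects).  Fixed modes use
  the raw threshold, as standard software does.
* Benjamini-Hochberg over the cluster p-values at `q = 0.05` marks the
  surviving clusters; adjusted p-values are monotone-enforced.
* Fallback: when a signal model was selected but no cluster survives,
  the cluster with the highest sum of T-values is reported active (ties:
  higher peak, then smallest coordinate).  This mirrors the clinical
  use-case where a winning signal model implies some activation exists.

Connectivity is 8 in 2D and 26 in 3D.  The extent formula assumes
stationarity; the simulated fields are stationary by construction, and no
non-stationarity correction is attempted.  With a known (nominal) FWHM,
the 128x128 / FWHM-6 / df-78 field gives an FWE forming threshold of
4.50; residual-estimated smoothness moves it by a few hundredths.  Note
the cluster-extent approximation becomes generous at low forming
thresholds (below ~2.5), exactly where the adaptive threshold tends to
sit for weak signals; this is inherent to the method, not a defect of
this implementation.

## The simulation benchmark

Each replicate is 80 planes of 128x128: 40 rest frames of N(0,1) noise,
then 40 task frames in which the signal height is added on six squares
(sides 4, 8, 12, 16, 20, 24, laid out deterministically in rows with
8-voxel margins and gaps — 1456 true voxels), after which *every* frame
is convolved with an isotropic FWHM-6-voxel Gaussian (reflect boundary,
kernel truncated at 4 sigma).  A two-column GLM (intercept + task
indicator; no temporal modeling) yields the T-map (df 78) and residuals.
Degenerate zero-residual voxels report T capped at 1e6.

Because the pre-smoothing noise has unit variance, the signal height is
the voxel-wise SNR.  The benchmark levels are 0.08–0.16: after FWHM-6
smoothing the noise SD is ~0.11, so plateau T-values run from ~3.2
(borderline at the fixed p=0.001 threshold) to ~6.5 (comfortably
supra-threshold) — the regime in which thresholding methods actually
disagree.  Below 0.08 every method misses essentially everything and
above it they all converge; 0.08 is also the level used for the
global-offset experiment.

Per replicate and method the benchmark records: false positive clusters
(surviving clusters sharing no voxel with any true square), false
negative squares (true squares overlapped by no surviving cluster, 0–6),
their difference (trade-off) and sum (total errors), map-wide border
over/underestimation, and Dice against the truth.  Method comparisons
are paired per replicate; summaries use the mean paired difference of
the absolute trade-offs and of the totals, with 2000-resample percentile
bootstrap CIs and B-H q-values across SNR levels.  Spatial accuracy per
square restricts to squares detected by every compared method; a cluster
spanning several squares contributes its outside voxels to the nearest
overlapped square (ties to the larger).

The global-effects experiment adds a N(0,1) constant to each low-SNR
T-map, thresholds shifted and unshifted maps with every method, and
compares Dice overlap between the two masks.  Dice of two empty masks is
defined as 1 (the two maps agree that nothing is active); one empty mask
gives 0.

Replicate RNG streams derive from the master seed through a documented
counter scheme (`SeedSequence(master, spawn_key=(condition, replicate))`),
so every table is bit-reproducible from its seed.

## What the benchmark does and does not show

The generator reproduces the spatial statistics that drive cluster
inference — stationary Gaussian-correlated noise, block signal with
smoothing-graded edges, a correct t null — but deliberately omits
temporal autocorrelation, hemodynamic convolution, drift, motion and
physiological artifacts, and non-stationary smoothness.  Passing
benchmarks therefore support the *thresholding* logic, not robustness
to realistic fMRI noise structure; on real data the GLM residuals carry
those burdens.  The false-negative count saturates at six (the number of
true clusters), which compresses differences between very weak methods
at very low SNR.

## Problem sizes and reproduction

`scripts/acceptance.py` recomputes the headline numbers with 200
benchmark replicates and 150 global-shift replicates at SNR 0.08 (the
published study used 500); the test suite uses 150 and 100.  At these
sizes the Monte-Carlo standard error of the cluster-error differences is
about 0.06–0.12 clusters and of the Dice improvements about 0.02, so the
AT-vs-FT(0.001) cluster-error differences wander by roughly ±0.15
between seeds.

Known quantitative deviations from the published tables: our adaptive
thresholds average ~2.4 at SNR 0.08 and across seeds come out the same
or slightly more favourable to AT against FT(0.001) than printed; the
FWE comparisons, the Dice gains and the shift-tracking correlation
reproduce within sampling error.  Because our pipeline is exactly
shift-equivariant, AT's Dice between shifted and unshifted maps is
identically 1, so the correlation between Dice gain and |shift| (~0.86)
exceeds the published 0.69, which embedded residual AT variability.
The original EM's update and initialisation details are not published;
we did not tune ours to match.

## Defaults

| parameter | default | meaning |
| --- | --- | --- |
| `fdr_q` | 0.05 | FDR level over cluster p-values |
| `fixed_p` | 0.001 | uncorrected fixed forming threshold |
| `fixed_fwe_p` | 0.05 | FWE fixed forming threshold |
| `em_tol` | 1e-6 | relative log-likelihood convergence |
| `em_max_iter` | 1000 | EM iteration cap |
| `n_boot` | 2000 | bootstrap resamples |
| `smooth_fwhm` | 6.0 voxels | simulation smoothing kernel |
| `n_frames` / `rest_frames` | 80 / 40 | simulated design |
| `signal_height` | 0.08 | default simulated SNR |
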