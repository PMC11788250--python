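# Methods

`mokin` models dynamic Na[18F]F total-body PET of five murine organs —
heart, lungs, liver, kidneys and femur — as compartment systems driven by
one shared arterial input, and estimates all kinetic parameters in a single
joint fit. This note records the model, its assumptions, the defaults and
the numerical choices.

## Compartment models

Each organ's volume of interest (VOI) signal is

    CT(t) = (1 - vb) * [C1(t) + C2(t)] + vb * Ca_org(t)

where `vb` is the fraction of the VOI signal contributed by blood, and the
tissue compartments obey

    dC1/dt = K1 * Ca_org - (k2 + k3) * C1
    dC2/dt = k3 * C1 - k4 * C2

* **Heart, lungs, liver** — one reversible compartment (`k3 = k4 = 0`).
  Fluoride exchanges with tissue water, so the efflux rate is tied to the
  uptake rate through a fixed volume of distribution, `k2 = K1 / Vd`, with
  Vd set to the tissue water fraction: 0.665 (heart), 0.763 (lungs),
  0.751 (liver) mL/cm^3. `k2` is therefore never a free parameter for
  these organs.
* **Femur** — a second, irreversible compartment: `k3` models fluoride
  incorporation into bone hydroxyapatite, `k4 = 0`.
* **Kidneys** — trapping plus clearance to the bladder (`k3, k4 > 0`).

The serial topology (blood -> C1 -> C2, with k4 leaving C2 and not
returning) is assumed throughout. The blood-fraction term uses the organ's
own corrected input (delayed, dispersed, gamma-scaled) as the vascular
signal; parenchyma is weighted by `(1 - vb)`. Spillover between adjacent
organs and the liver's dual (portal) blood supply are out of scope.

The macro-parameter `Ki = K1 * k3 / (k2 + k3)` (net influx rate) is
reported for the trapping organs; it remains estimable when `K1` and `k2`
individually ride their exchange degeneracy.

## Exponential-sum algebra

The vena-cava input is represented analytically (below), and every model
curve is then an exact member of the family
`sum_j A_j (t - t0_j)^p_j exp(-a_j (t - t0_j))`. Convolution with a causal
exponential maps this family into itself, so tissue solutions, dispersion
and frame averaging are all evaluated in closed form — no ODE solver and no
discrete convolution grid, which matters during the first minutes of a
bolus where the curves change faster than any practical sampling grid.
Degenerate rate collisions (two rates within 1e-9 /min) use the limiting
`t * exp(-a t)` form. Definite integrals use `expm1` for plain
exponentials and the regularized lower incomplete gamma function for
polynomial-weighted terms; both are stable for arbitrarily small rates.

Model values are compared to data as **frame averages** (exact integrals
over each frame divided by its length), not midpoint samples: with frames
up to 300 s, midpoint evaluation is biased wherever the kinetics are fast.

## Input function and corrections

The image-derived input function (IDIF) from the vena cava is fitted with a
Feng-type bolus: zero before onset `t0`, a linear rise of duration `r`,
then a sum of 2-4 decaying exponentials whose amplitudes sum to the peak
(continuity is built into the parameterization). The fit is weighted
least squares with counting-statistics weights and a small Latin-hypercube
multistart; a nested single-exponential solution seeds one start, so the
final fit can never be worse than a single-exponential fit.

Three corrections map the IDIF to each organ's arterial input:

* **Partial volume (gamma):** the true AIF is modeled as `C_IDIF / gamma`.
  The opposite convention is available via `gamma_mode="multiply"` since
  the direction is a modeling convention, not a physical fact.
* **Dispersion (tau):** convolution with the causal unit-mass kernel
  `exp(-t/tau)/tau`, one tau shared by all organs (per-organ dispersion is
  not identifiable alongside the other corrections).
* **Delay (dt):** one per organ; may be negative (the vena cava sees the
  bolus after some organs do).

Corrections are applied scale -> dispersion -> delay; delay and dispersion
commute, so the order is presentational.

## Noise model

Frame noise is Gaussian, independent across frames and organs, with

    sigma(t) = Sc * exp(lambda * t) * sqrt(CT(t) / dt)

where `lambda = ln 2 / 109.77 min` is the 18F decay constant (the
exponential undoes the variance reduction that decay correction hides),
`CT` is the frame activity, `dt` the frame length in minutes, and `Sc` a
per-organ scale chosen qualitatively. Defaults: `Sc = 0.5` for organ VOIs
and `1.5` for the IDIF, which yields roughly 5% relative noise in the
early 10 s frames and 1-2% in the late 300 s frames for organs at a
~12 MBq-class dose — typical of small-animal scanners — with a clearly
noisier image-derived input. Negative simulated activities are kept, not
clipped, preserving the noise symmetry that weighted fitting assumes.

The same sigma formula supplies the weights of the joint fit, evaluated on
the observed activities clipped to a small positive floor (0.1% of each
curve's maximum) so that pre-bolus frames cannot produce zero weights.

## Joint fitting

The free-parameter vector has 22 entries: gamma, tau, five delays, five
blood fractions, K1 for the three Vd-tied organs, (K1, k2, k3, k4) for the
kidneys and (K1, k2, k3) for the femur. A config switch (`free_heart_k2`)
releases the heart efflux rate as a 23rd parameter for sensitivity
analyses. Bounds: K1 in [0, 10] mL/mL/min; k2, k3, k4 in [0, 10] /min;
vb in [0, 1]; gamma in [0.1, 3]; tau in [1e-3, 2] min; delays in
[-0.5, 1] min.

Minimization is bounded trust-region least squares (a Levenberg-Marquardt-
type algorithm with box constraints). The Jacobian exploits the model's
block structure — only gamma and tau couple organs — and uses exact
columns for gamma (the model is proportional to 1/gamma), the blood
fractions (the model is affine in vb) and the untied K1 parameters (the
parenchymal response is linear in K1); the remaining columns are one-sided
finite differences per organ block.

**Multistart:** starting points are a centered Latin hypercube over the
bounds (seeded, hence fully reproducible). Every restart's endpoint is
retained, converged or not; restarts run under a capped iteration budget
and the best member is re-polished to full convergence, so the cap is an
evaluation-budget choice that does not affect the final estimate. The
default restart count is configurable (production 5000; tests and examples
use 150-200, which locates the global basin reliably in this 22-parameter
problem).

**Mode selection:** a Gaussian-kernel KDE (Scott bandwidth, computed on
standardized parameters of the converged fits, zero-variance directions
dropped) scores every converged member; the mode is the highest-density
member itself rather than an off-grid argmax, for reproducibility. The
reported point estimate is the polished minimum-chi2 fit; the mode is
exposed alongside it.

## Goodness of fit, error bars, identifiability

The reduced chi-square uses noise-model weights,
`chi2_nu = (1/nu) sum ((O_i - C_i)/sigma_i)^2` with
`nu = N_obs - n_free` (short scale: 5 x 18 - 22 = 68; long:
5 x 33 - 22 = 143). Per-organ contributions are each organ's weighted sum
of squares over the same nu, so they add up to the total.

Error bars scan each parameter away from its optimum until the reduced
chi-square rises by 1 (bisection to a relative tolerance of 1e-6), by
default holding the other parameters fixed; `profile=True` re-optimizes
them at every trial point. A scan that reaches a bound first is flagged
bound-censored. Note that a Delta of 1 on the *reduced* chi-square equals
Delta-chi2 = nu on the raw statistic, a deliberately generous interval.

Practical identifiability is diagnosed from the restart ensemble: the
near-optimal set (chi2_nu within 1 of the best), per-organ Pearson
correlation matrices over that set (shared gamma/tau columns appended;
zero-variance parameters yield missing values, never 0), 2-D KDE summaries
of chosen pairs, and an exact two-sided Wilcoxon signed-rank test of each
pair's correlation across subjects at p < 0.05 (zero correlations dropped,
as in the standard treatment; at least five subjects required).

## Synthetic data

The generator emulates the study conditions: the 33-frame schedule
(18 x 10, 2 x 30, 1 x 60, 2 x 120, 10 x 300 s; 3540 s total; the first
3 min = 18 frames form the short scale), a bolus input peaking near
3000 kBq/mL at ~0.4 min with a tri-exponential tail, per-subject injected
dose drawn as 12 +/- 8 MBq (floored at a usable 3 MBq), and per-subject
kinetic parameters drawn from normal priors centered on the long-scale
population means with the reported spreads, truncated to the fitting
bounds and with rates floored at 0.01 (so every subject has nonzero
perfusion and a defined influx rate). Values the study does not print
numerically — kidney long-scale k2, the blood fractions, delays, gamma,
tau, and the bolus shape — use physiologically plausible centers (e.g.
kidney k2 = 2.4 +/- 1.0 /min, consistent with its short-scale estimate;
vb from heart 0.60 down to femur 0.05; gamma 0.8 +/- 0.2; tau
0.2 +/- 0.1 min; delays 0.2-0.3 min).

What the generator does **not** emulate: image reconstruction, scatter and
randoms, VOI placement variability, inter-organ spillover, the liver's
dual blood supply, and model misspecification in general — simulated data
come from the same model family that is fitted. Passing recovery tests
therefore demonstrate the estimator's correctness and conditioning, not
robustness to the mismatch real tissue exhibits; the study's own long-scale
misfit (reduced chi-square far above 1) has no analogue here.

## Known limitations

* With a correctly specified model at realistic noise, the kidney K1-k2
  exchange correlation within the near-optimal set stays high on *both*
  time scales; the long-scale de-correlation the real data showed appears
  to require model mismatch, which the generator deliberately lacks. The
  near-optimal set on the long scale is also small at test-scale restart
  counts (the chi-square basins are sharp), making its correlation
  estimate coarse.
* Kidney K1 at default noise carries roughly 25% median error through the
  vb/K1/k2 trade-off even for fits started at truth with the exact input
  function, and more (up to ~50%) through the full pipeline where the
  fitted input's peak shape adds its own noise-limited bias; this is an
  information limit of the data, not an optimizer failure (the distorted
  input fits can have lower weighted cost than the generating truth).
  Liver K1 and femur Ki recover to a few percent under the same
  conditions.
* The heart VOI is treated like any other organ; the very high blood
  fraction that makes the real heart hard to fit is represented only
  through its vb prior.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the study at desk scale:
6 (tests) or 3 (script) subjects, 150-200 restarts per fit, 100-200
replicates for the chi-square calibration, and 100 parameter draws for the
ODE-oracle equivalence. These sizes were chosen as the package's own
defaults for routine verification; the restart count and subject count are
ordinary configuration knobs for larger runs.
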