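# Methods

## The modeling problem

In a probabilistic spatial-cueing (Posner) experiment, a central cue
predicts the upcoming target location with 80% validity; invalidly cued
targets require attentional reorienting and slow the response.  This
package implements a *joint* generative model of the two measurements such
an experiment produces — regional BOLD time series and trial-wise reaction
times — so that a single set of parameters explains both, together with
the machinery needed to estimate, compare, evaluate, and perturb such
models on synthetic data.

## Generative model

**Neural layer.** Hidden neural states `x` of R regions follow the
bilinear flow

    dx/dt = A x + Σ_j u_j B_j x + C u

with fixed connectivity `A` (target-row, source-column), input-dependent
modulation `B_j`, and driving gains `C`.  Input `u1` carries a unit
impulse at every target onset; `u2` an impulse at invalidly cued targets
only.  Streams live on a micro-time grid (default 1.1/8 = 0.1375 s) and
are mean-centered before entering the model.  Self-connections are
estimated as `A[i,i] = -0.5 * exp(d_i)`, which keeps every node
dissipative regardless of the latent value `d_i`.

**Hemodynamic layer.** Each region's activity drives the standard
four-state balloon/Windkessel cascade — vasodilatory signal `s`, inflow
`f`, venous volume `v`, deoxyhemoglobin `q` — with the static BOLD
nonlinearity `y = V0 (k1 (1-q) + k2 (1-q/v) + k3 (1-v))`,
`k1 = 7 E0, k2 = 2, k3 = 2 E0 - 0.2`.  Constants (shared across regions,
i.e. a homogeneous hemodynamic response): signal decay κ = 0.64 /s,
autoregulation γ = 0.32 /s, transit time τ = 2.0 s, stiffness α = 0.32,
resting extraction E0 = 0.4, V0 = 4 (signal-percent units).  Two shared
log-scaling factors on κ and τ are estimated by default (prior sd 0.125 in
log units).  Flow, volume, and deoxyhemoglobin are integrated in log space
so they stay positive; their log-states are clamped to ±10 inside the
integration kernel — far outside physiology — so that a diverging trial
step during optimization produces screenable garbage rather than a
division by zero.

**Behavioral layer.** A scalar response state follows the discrete
per-micro-step map

    r[k+1] = (A_r x[k] + Σ_j u_j[k] B_rj x[k] + C_r u[k]) - decay * r[k]

and is read out through a steep bounded sigmoid

    s(r) = 3 / (1 + exp(-100 (rho + r)))   [seconds]

so predicted reaction times lie strictly in (0, 3): 3 s is the slowest
response the model can predict.  The behavioral layer reads the neural
states but never feeds back on them; BOLD predictions are therefore
bitwise invariant to the behavioral parameters (tested).  A model with all
behavioral parameters fixed at zero is a classical DCM of the BOLD channel.

**Readout timing.** Each trial's RT prediction is read at the first
resampled-grid point (1.1 s grid) strictly after its target onset.  This
mirrors the downsampling of behavioral observations to the BOLD half-grid,
guarantees the trial's own input has entered the response state, and puts
the readout within one grid step — about a response latency — of the
target.

**Integration.** Explicit Euler on the micro-time grid, 8 micro-steps per
resampled BOLD sample by default (configurable via `oversample`).  A
halved step changes the BOLD prediction of a smooth problem by well under
1% (tested); impulse inputs are represented as single-bin unit spikes, so
their effect scales with the micro-step by construction.  Initial states
are zero.  A warning is raised when the step exceeds a crude stability
proxy for the neural flow.

## The trial-level comparator

The Rescorla–Wagner reaction-time model tracks a perceived cue invalidity
`v_t = v_{t-1} + α (u_t - v_{t-1})` and predicts
`g_t = u_t (ζ_i + ζ_2 v_{t-1}) + (1-u_t)(ζ_v + ζ_2 (1-v_{t-1}))`: separate
valid/invalid biases plus a shared scaling of the prediction, driven by
the *previous* trial's belief.  Priors: α is estimated on the logit scale
(so 0 < α ≤ 1) with mean 0.5 and the stated sd of 0.5 mapped through the
inverse-logit derivative at the prior mean (sd 2.0 in logit units);
ζ_v, ζ_i, ζ_2 ~ N(0, 1); v0 ~ N(0.5, 1), clipped to [0, 1] at evaluation
(the belief is a probability; the clip point is flagged here because a
transform for v0 is a genuinely open choice).

## Estimation: variational Laplace

All models are fitted by the same engine: Gaussian posteriors over
parameters, conjugate Gamma posteriors over each data channel's noise
precision, and Fisher-scoring Gauss–Newton updates of the posterior mean
with trust-region step halving whenever a candidate step would lower the
free energy.  Candidate steps are scored with the curvature (Jacobian) at
the current mean; the Jacobian — central finite differences, step 1e-5 —
is recomputed only once a step is accepted.  Convergence is declared after
two consecutive iterations without progress (> 0.01 nats) over the best
visited iterate, which is what is returned; the trace of accepted free
energies is non-decreasing up to a documented tolerance of 1e-3 per step.
On a conjugate linear-Gaussian problem the free energy equals the
closed-form log evidence to ~1e-11 (tested at 1e-3).

Noise hyperpriors follow an explained-variance argument: assuming the
model explains between 10% and 90% of a channel's variance brackets the
residual precision, and the Gamma hyperprior is solved (by root-finding on
the shape via the quantile ratio) so its 10th/90th percentiles match that
bracket.  The construction is scale-equivariant: rescaling the data
rescales the prior so the implied explained-variance interval is unchanged.

Parameter-block prior sds (documented package defaults in the spirit of
common DCM practice): A and C 0.5, self-connection latents 0.5, B 4.0
(modulations act on single micro-bins and are therefore large on the
impulse scale), behavioral weights and readout bias 1.0, behavioral decay
N(0.5, 1).  Excluded trials and unobserved (interspersed) BOLD grid points
contribute nothing to any likelihood.

## Model space and selection

Candidates: behavioral readout from bilateral IPS, FEF, TPJ, or all six
regions; a classical DCM (behavioral parameters fixed at 0, four fewer
estimated parameters than a bilateral-readout bDCM); a hybrid that routes
the learning model's RT predictions in as a third input stream gated only
through the direct behavioral gain; and a variant that replaces the binary
invalid-trial stream with the learner's predicted cue invalidity of the
previous trial (centered, like every stream).

Fixed-effects selection sums log evidence over subjects and applies a
softmax under a uniform model prior.  Random-effects selection fits the
variational Dirichlet–multinomial model of per-subject model frequencies
(uniform Dirichlet prior, concentration 1) and reports expected
frequencies and exceedance probabilities — by the closed-form Beta tail
for two models, otherwise by seeded Monte-Carlo with 1e5 Dirichlet draws
(choices the literature leaves open; both documented here).

## Evaluation statistics

R² = 1 − SSres/SStot and MAE over included points only.  Permutation
p-values shuffle the *predictions* without replacement (default 10,000
shuffles; exhaustive enumeration for ≤ 8 points) and report
`(#{at least as good} + 1) / (#shuffles + 1)` with inclusive ties — so the
smallest attainable p is 1/(n+1), and under the null the p-values are
uniform (tested by KS over 500 replicates).  Distribution agreement uses
the two-sample Kolmogorov–Smirnov distance with the asymptotic p-value
(the exact-vs-asymptotic choice is open; asymptotic documented).
Leave-one-trial-out cross-validation removes exactly one trial's
likelihood term per fold — priors and the other trials unchanged — and
accumulates held-out squared errors into PRESS; failed folds are flagged
and excluded, never imputed.

## Synthetic data: what it emulates and what it does not

The design generator reproduces the 5-block × 40-trial cueing run (32
valid / 8 invalid per block, all location × orientation × SOA cells
balanced — 5 repetitions of each of the 8 cells per default block — with
invalid trials spread over cells as evenly as possible and seeded
tie-breaks), SOAs of 0.4/0.6 s, inter-trial intervals drawn from
{2.0, 2.7, 3.2, 3.9, 4.5} s, and inter-block breaks of 11.5 s (midpoint of
the reported 10–13 s range).  Within a trial, the cue follows trial start
by 1.0 s and a 1.5 s response window follows the target.  BOLD is sampled
at TR 2.2 s and preprocessed exactly as real data would be: per-region
linear detrend, one global scale to a maximum of 4, resampling to 1.1 s by
marking interspersed grid points unobserved (never interpolated).  RT
screening drops errors, misses, responses below 0.2 s, and responses above
Q3 + 3·IQR of the correct, responded trials of the same series; excluded
RTs are stored as 0 with their inclusion mask false.

The calibrated six-region ground truth produces reaction times with mean
≈ 0.42 s, sd ≈ 0.10 s, and a validity effect of ≈ +0.10 s — magnitudes a
typical cueing experiment shows.  Couplings are deliberately heterogeneous
(feedforward vs feedback asymmetries, ventral drive weaker) both for
realism and because the output-region question is ill-posed in a perfectly
symmetric network; the spectral abscissa of A is −0.33, so the
between-subject jitter used in the cohort tests cannot destabilize any
subject.  The invalid-trial modulation routes predominantly into IPS
(10.0 vs 1.0 elsewhere) and the readout weight on bilateral IPS is
**negative** (−0.04): with mean-centered input streams the pre-target
neural states sit below their zero temporal mean, so a negative weight is
what maps an invalid-trial neural boost into slower responses.
Observation noise is additive i.i.d. Gaussian per channel, BOLD noise
specified as signal-variance/noise-variance per region.

What the synthetic data does *not* emulate: scanner drift and physiological
noise spectra (noise is white), error/miss generation (all simulated
responses are correct), eye movements, between-run differences, and
hemodynamic variability across regions (the generator uses one HRF).
Passing recovery and identification tests on these data therefore shows
the estimation machinery is correct and the questions identifiable under
the stated conditions — not that real fMRI data are this well behaved.

## Scaled-down study sizes used in tests

One CPU budget dictates the sizes; they are the package's own choices:
parameter recovery uses a bilateral one-area (2-region) network with a
full 200-trial run, BOLD SNR 40, RT noise sd 0.005 s, 10 seeds; the
output-region identification cohort uses 12 subjects × 2 blocks × 20
trials, BOLD SNR 30, RT noise 0.01 s, and all four output-region variants
per subject (48 inversions, ≈ 4 minutes).  Under these conditions
recovery medians land within 10% of truth with every sign correct, and
both FFX and RFX select the true output region unanimously.

## Artificial lesions

A lesion zeroes the target region's incoming fixed and modulatory
connections; its driving inputs are zeroed too by default (a silenced
region should receive nothing), with `zero_driving=False` available since
the original description leaves this ambiguous.  The self-connection is
retained so the silenced state decays to zero rather than lingering.
Simulated (noiseless) behavior of each lesioned model is screened for
degeneracy: non-finite values, or RT variance below 1e-6 s² after the
10th trial (a readout pinned at the sigmoid's floor or ceiling), flag the
run unstable; instability is recorded as data, not raised as an error.

## Known limitations

- Explicit Euler is first-order; very stiff parameterizations need a finer
  `oversample` than the default 8.
- Finite-difference Jacobians cost two integrations per estimated
  parameter per accepted step; six-region fits take seconds, not
  milliseconds.
- The free-energy landscape of the joint model is multimodal; the solver
  is deterministic from the prior mean, so pathological draws can converge
  to local optima.  Model-comparison consumers should inspect the
  `converged` flag and free-energy traces.
- No group-level (hierarchical) estimation and no nonlinear (second-order)
  neural terms, by scope.
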