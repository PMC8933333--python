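# bdcm — joint modeling of BOLD dynamics and reaction times

`bdcm` is a Python toolkit for **behavioral dynamic causal modeling** of
continuous reaction times: a single generative model that explains both
the regional BOLD time series and the trial-wise reaction times recorded
in a spatial-cueing (Posner) experiment.  It is written for computational
neuroimaging researchers who want to ask not just *how brain regions
couple* but *which region's dynamics drive behavior* — and to answer that
question with Bayesian model comparison and in-silico lesions rather than
correlations.

## The model

Hidden neural states `x` of a six-region attention network (bilateral
IPS, FEF, TPJ) follow the bilinear flow

    dx/dt = A x + Σⱼ uⱼ Bⱼ x + C u

driven by a target-onset stream `u₁` and an invalid-target stream `u₂`.
BOLD is generated per region through the four-state balloon/Windkessel
cascade, `y = g(z, φ) + ε`.  The behavioral extension adds a response
state with the discrete dynamics

    r[k+1] = (A_r x + Σⱼ uⱼ B_rj x + C_r u) − α_r · r[k]

read out through a steep bounded sigmoid `s(r) = 3 / (1 + e^(−100(ρ + r)))`,
so predicted reaction times always lie strictly between 0 and 3 s.  With
the behavioral parameters fixed at zero the model reduces exactly to a
classical DCM; a trial-level Rescorla–Wagner model of reaction times
(`v_t = v_{t−1} + α δ_t`) serves as the purely behavioral comparator.

Everything is estimated by variational Laplace (Gaussian posteriors,
Gamma noise precisions, free-energy model evidence), and model selection
across subjects is available as fixed effects (summed evidence) and
random effects (Dirichlet model frequencies with exceedance
probabilities).  No empirical dataset ships with the package: a
first-class synthetic-data module generates the full design — cue
validity 80/20, SOAs 0.4/0.6 s, ITIs from {2.0, 2.7, 3.2, 3.9, 4.5} s,
five 40-trial blocks — and simulates BOLD + RT data from a calibrated
ground truth for recovery and identification studies.

## Worked example

Simulate a small two-region run, fit the learning model and the joint
model, score the reaction-time fit, and lesion the fitted network:

```bash
cat > demo.yaml <<'YAML'
seed: 3
design:  {n_blocks: 1, trials_per_block: 20}
model:   {regions: [A-L, A-R], output_regions: [A-L]}
inversion: {max_iter: 16}
YAML

bdcm simulate --config demo.yaml --out-dir sim
# simulated 20 trials -> sim
bdcm fit-rw --events sim/events.tsv --config demo.yaml --out rw
# free energy 17.68 -> rw
bdcm fit --model bdcm --events sim/events.tsv --bold sim/bold.tsv \
         --config demo.yaml --out fit-bdcm
# bdcm: F=-225.63 (7 iterations, converged=True)
```

The free energies are log model evidences (up to a bound): the learning
model fits only the 20 reaction times, the joint model additionally fits
two regions × 98 BOLD samples, hence the very different scales — they
become comparable per data channel, which is what the `compare`
subcommand operates on.  Scoring the joint model's RT predictions against
the simulated observations:

```bash
bdcm evaluate --observed rt_obs.tsv --predicted rt_pred.tsv \
              --n-perm 2000 --seed 3 --out eval
# R2=0.8834867347879096 MAE=0.0135 p(R2)=0.0004998 p(MAE)=0.0004998
```

The model explains 88% of the RT variance with a mean absolute error of
14 ms; both statistics beat all 2,000 prediction shuffles, so the
permutation p-values sit at their floor of 1/2001.  Finally,

```bash
bdcm lesion --params fit-bdcm/fitted_params.yaml \
            --events sim/events.tsv --config demo.yaml --out les
```

writes one row per lesion with simulated validity effects per target
location; here lesioning `A-L` — the only readout region — flatlines the
simulated responses, and the row is flagged unstable
(`instability_reason=flatline`) rather than reported as a spurious zero
effect.

Other subcommands: `fit` for the classical-DCM and learning-hybrid
variants, `compare` for FFX/RFX model selection from an evidence table,
`crossval` for leave-one-trial-out PRESS, `describe-model` for parameter
counts, and `run-all` for the whole pipeline end to end.

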