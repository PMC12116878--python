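# Methods

This note documents the models, the synthetic-data generator, the
inference machinery, and the numerical and design choices behind
`prefbandit`, in the package's own terms.

## The task and the models

A participant completes two task sets with disjoint stimuli.  Each set
is a 105-trial preference-judgment phase (7 shapes; each of the 21
unordered pairs once per block, 5 blocks; no feedback), a 150-trial
gambling phase (3 fixed pairs × 50 randomized presentations; each pair
holds a 0.70 and a 0.30 Bernoulli reward stimulus, drawn independently
per stimulus per trial), and a 5-point preference rating of the shapes.
One set assigns the preference-phase favourite the 0.70 schedule
("preferred stimulus high probability task"), the other set's favourite
gets 0.30; set order is counterbalanced across participants.

Gambling behavior is modelled by delta-rule Q-learning with softmax
choice.  Only the chosen option's value updates,
`Q ← Q + α(r − Q)`; the choice probability is the logistic of
`β(Q_chosen − Q_rejected)`.  Rewards in {0, 1} with initial values in
[0, 1] make every update a convex combination, so Q remains in [0, 1] by
closure — no clipping or constraint handling is required during
estimation, and the implementation relies on this rather than enforcing
the box during the value recursion.

The four candidate models differ only in the initial values.  Each
gambling stimulus belongs to a class — the IDM favourite (`high`), the
least-chosen (`low`), or first-seen-in-gambling (`novel`) — and each
model maps classes to free η parameters: RL1 one shared η; RL2 η₁ for
the favourite, η₂ for everything else; RL3 η₁ for favourite and novel,
η₂ for the least-liked; RL4 three distinct slots.  Tying the slots of
any richer model reproduces RL1 exactly, and the tests exploit this
nesting.

Values are seeded per gambling task; the two tasks use disjoint stimuli,
so their value tables never interact, and one (α, β, η…) set is shared
across a participant's two tasks.

## Parameter bounds and the inverse-temperature cap

α and every η live in [0, 1].  The inverse temperature is bounded by a
configurable cap `beta_max`.  The design text this paradigm follows
prints the bound 0 ≤ β ≤ 1, but that cap limits every two-option choice
probability to at most ≈ 0.73 (since |ΔQ| ≤ 1), while the paradigm's
reported first-encounter choice proportions (~0.83 at an initial-value
gap of ~0.3) imply β ≈ 4–5.  We therefore treat the printed bound as a
typographical slip: the package default is `beta_max = 5`, and the
generator's default β = 4 (0.8 × cap) reproduces a first-trial choice
probability of σ(4 × 0.3) ≈ 0.77 at the default η gap.  The tight bound
remains available everywhere by passing `beta_max = 1.0`; no code change
is needed in either direction.  Under the tight bound, initial-value
parameters are close to unidentifiable (even maximum-likelihood
estimates correlate with truth at only ≈ 0.2) and the four models are
practically indistinguishable — which is itself informative about the
paradigm's design envelope.

## Synthetic-data generator

The generator's job is to produce studies with the paradigm's exact
statistical structure, with ground truth retained for recovery checks.

**Preference phase.** Choices follow a logistic rule on latent
preference strengths with sensitivity 2.0 (default).  Latents are a
participant-specific random permutation of seven evenly spaced levels
(`linspace(−3, 3, 7) × latent_step`, default step 1.1) — a graded
preference hierarchy rather than iid draws.  The spacing is calibrated
so that the empirically labelled favourite/least-liked coincide with the
latent extremes for ≥ 95% of simulated participants, and the full
frequency ranking reproduces the latent ranking about as often; iid
normal latents cannot achieve this because near-ties among seven draws
are common.  Optional choice-induced drift (chosen +δ, rejected −δ) is
available as a generative option only and defaults to off; it is never
an inference target.

**Labelling.** The gambling pairs are built from the *empirical*
chosen-frequency extremes, exactly as an experimenter would assign them,
not from the latent truth; the intended extremes are kept in
`truth.json` for validation.  Frequency ties are broken
lexicographically in simulation sweeps (and are a hard error in the
analysis path unless opted in).

**Pairing rule.** The favourite and least-liked are each paired with a
previously unseen partner at the complementary reward probability; the
third pair is two unseen stimuli at 0.70/0.30.  The paradigm does not
fully itemise the pairs' second members; this rule is the documented
assumption, and the four stimuli entering rating/value contrasts are the
two preference-labelled ones plus the two *novel-pair* members (the
partners are excluded).

**Gambling phase.** Choices are generated from the model; per trial both
pair members' rewards are drawn independently at their probabilities,
but only the chosen one's realisation is revealed and learned from.
Per-participant generating parameters default to α ~ U(0.1, 0.6), β
fixed at 4.0, η slots (0.7, 0.4, …).

**Ratings.** `rating = round(clip(0.8·z + 2.0·Q_final + 2.0 + ε, 1, 5))`
with ε ~ N(0, 0.5): a monotone blend of latent preference and final
learned value, so the design's two qualitative rating patterns
(favourite rated highest regardless of reward condition; novel 0.70 >
novel 0.30) emerge and can be switched off by zeroing either weight.

**What the generator does not emulate.** Reaction times, fatigue,
attention lapses, perseveration/choice kernels, forgetting,
counterfactual updating, and any stimulus-specific visual appeal at
first exposure.  Passing tests therefore certify the pipeline under the
model's own assumptions, not that real data satisfy them.

## Inference

**Priors.** Uniform over each parameter's box bounds (the design states
bounds only).

**Sampler.** Random-walk Metropolis with a joint Gaussian proposal,
per-parameter step 0.12 × prior width times a global multiplier adapted
toward ~30% acceptance during warm-up (windows of 100 proposals,
multiplier frozen for the kept draws).  Defaults: 4 chains × 2,500 kept
draws after 1,000 warm-up.  The kernel is numba-compiled and fully
determined by its integer seed.  Convergence is summarised by
split-chain R-hat; any fit with max R-hat > 1.05 is flagged in its
outputs (a logged warning, a `flagged` column), never silently dropped.
Roughly a fifth of single-participant fits flag at default lengths with
R-hat in 1.05–1.10; their posterior means remain serviceable for
recovery summaries, and the flag is the honest record.

**Fitting units.** Parameter estimation (for value trajectories) is per
participant: posterior means under τ = 1.  Model *comparison* pools all
participants' gambling data under one shared parameter set by default.
The reason is structural: with per-participant WBICs summed, an extra
initial-value parameter pays its complexity penalty once per participant
while earning only a comparable amount of evidence per participant — on
data generated at the default η gap of 0.3 the mean per-participant
WBIC difference between the one-η and two-η models is measured at
−0.01 ± 0.24, i.e. exactly zero, making selection a coin flip at any
study size.  Pooling charges the penalty once; thirty pooled
participants yield a WBIC gap of ≈ 18 in favour of the generating
two-η model, the same order as published comparisons of this design.
`fitting_unit="per_participant"` restores summed per-participant WBICs.

**WBIC.** A single tempered run at τ = 1/log n (n = trials entering the
likelihood for the fitting unit: 300 per participant, or the pooled
total), not thermodynamic integration; WBIC is the mean over tempered
draws of the negative total log-likelihood.  On one-parameter conjugate
Bernoulli toys (n = 20–500) it tracks the quadrature negative log
marginal likelihood within ±0.2; the documented oracle band in the tests
is 1.0.

**Bayes factors.** `BF_ab = exp(WBIC_b − WBIC_a)`, reported on the ≥ 1
side with the direction attached, binned per Kass–Raftery.

**Recovery.** Parameter recovery simulates one participant (2 tasks ×
150 trials) per true parameter set and refits at τ = 1; the default
truth grid spans α, η ~ U(0.05, 0.95) with β fixed at the generating
4.0, the canonical full-support design for recovery studies.  β is
deliberately not varied by default (fixed truths give an undefined
correlation, which is reported as NaN with a note).  Model recovery
simulates replicate *studies* (datasets of several participants with
per-participant α) per generating model and selects by pooled WBIC; in
the test suite, 20 datasets × 15 participants per generating model with
shortened chains (2 × 1,200 + 600) keep the run inside a desktop budget,
and the diagonal dominates (19–20/20 per model; tied-η data correctly
falls back to the one-η model).

## Behavioral statistics

"Correct" is choosing a pair's 0.70 member — the expected-reward
maximiser and hence the normative reading of "pick the correct shape".
Paired and one-sample t-tests come with Cohen's d (mean difference over
the SD of differences); repeated-measures ANOVAs (2×2 on correct rates,
2×2×2 on initial/final values) are computed via statsmodels' AnovaRM
with partial η² derived from F and the degrees of freedom.  All factors
have two levels, so sphericity corrections are vacuous and not applied.
Simple effects are reported as squared paired-t statistics with
participant-level degrees of freedom.  Rating contrasts are all pairwise
paired t-tests among the four key stimuli, Holm-corrected within task
condition.  Degenerate inputs (all-equal cells, zero-variance
differences) return exact zero/infinite statistics with a
`zero_variance` flag instead of raising.

For the end-to-end "qualitative pattern" checks, the value-stage
pattern (preference seeding present in initial values, absent in final
values) is judged at the .01 level on both task conditions' ANOVAs —
the significance convention the corresponding published value contrasts
use.  Judging the *absence* half at .05 across two ANOVAs would fail
~1 replicate in 5 by multiplicity alone even under a perfect null, and
the final-stage initial-condition residue (which decays as (1−α)^k) is
a real but tiny effect that stricter thresholds correctly read as
"absent".

## Orchestration and determinism

`RunConfig` (YAML-loadable) carries the design constants — 42
participants, 105/21/5 preference schedule, 50 presentations per pair,
0.70/0.30 — plus sampler and recovery sizes.  Each pipeline stage draws
its randomness from a stream spawned off the master seed, so stages are
reproducible independently; `manifest.json` records per-stage parameters
and SHA-256 hashes of every artifact.  Identical configs produce
byte-identical CSVs.

Trial indices are 1-based in files and in the record types; array
encodings used by the likelihood kernel are 0-based internally.

## Problem sizes used in the checked examples

Chosen-frequency Monte-Carlo oracle: 2,000 simulated participants; IDM
rank-order recovery: 400; label-recovery invariant: 300 task sets;
parameter recovery: 50 datasets at default sampler settings; model
recovery: 20 datasets × 15 participants per generating model (shortened
chains); qualitative-effect replication: 20 studies × 42 participants;
type-I calibration: 1,000 null replicates.  These sizes are the
package's choices for routine verification; all scale up by argument.

## Known limitations

- The pooled comparison mode ignores parameter heterogeneity across
  participants; a hierarchical prior would be the principled middle
  ground and is out of scope.
- WBIC's O(√log n) error means small Bayes factors (log-BF within ~1–2)
  are at the resolution limit of the single-tempered-run estimator.
- The random-walk sampler is adequate for these 3–5 parameter posteriors
  but flags borderline R-hat on a minority of single-participant fits;
  a gradient-based sampler can be swapped in behind the same interface.
- Absolute WBIC values depend on the pooling convention and priors and
  are not comparable across conventions; only differences within one
  convention are meaningful.
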