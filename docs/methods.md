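# Methods

## Generative model

Each simulated child carries demographic attributes (sex, five race groups
A–E, insurance in {public, private, other}; default marginals ~52% male,
race and insurance mixes typical of a large paediatric health system), a
birth year drawn uniformly on a configurable range (default 2014–2022), a
within-year birth offset U(0, 1), and a latent standard-normal risk score
z.

**Event times.** The diagnosis age E follows a discrete-time hazard model
on yearly bins k = 1..K:

    h(k | x) = expit( logit(h0_k) + Σ β_a·1[attribute a]
                      + τ·(yob − yob_min) + γ·z )

with a uniform within-bin jitter turning the sampled bin into a continuous
age.  If no bin fires, E = ∞ ("never within the horizon"); an optional
explicit immune fraction exists for stress tests.  The yearly jitter makes
the DTNN's generative assumptions exactly recoverable in parameter-recovery
tests.  The logit link is approximately proportional-hazards when the h0_k
are small, which is the regime used for the Cox-recovery check (h0 = 0.05,
β = 0.5 gives a continuous-time log-hazard ratio of ≈ 0.48).

**Censoring.** C = min(C_admin, C_drop): administrative censoring
C_admin = extraction_year − (birth_year + offset) anchored at a single
extraction date (default mid-2023), which makes follow-up a deterministic
function of birth year; dropout C_drop ~ Exponential(rate) models loss to
follow-up (default rates 0.05–0.10/yr per scenario; no external anchor for
this value exists, so it was chosen once as a plausible paediatric
attrition level).  T = min(E, C), S = 1[E ≤ C].

**Code sequences.** Codes arrive as a Poisson process at
`mean_codes_per_year` over (0, T).  A fraction of the vocabulary
(`risk_code_fraction`, default 0.3 of 200 tokens) are "risk codes"; each
emitted code is a risk code with probability
expit(logit(0.3) + η) where η is the same linear predictor that drives the
hazard — this is the channel through which the models can learn risk from
the sequence alone.  With `emit_attribute_codes`, one token each for sex,
race, insurance and a birth-era token (`ERA_<year>`) is prepended at age 0:
the simulation analogue of the demographic and secular drift that real
medical vocabularies carry implicitly.  Without such tokens no model could
express the birth-year–linked behaviour under study.

**What the generator does not emulate.** Real code semantics and
co-occurrence structure, visit clustering, informative dropout (dropout is
independent of risk), competing risks, or measurement error in diagnosis
timing.  Passing tests therefore demonstrate the *mechanisms* of censoring
bias and their remedies, not clinical performance levels.

## Filtering and leakage control

`FilterSpec` removes patients diagnosed or censored at or before the
prediction age, optionally applies a birth-year cap, and optionally a
minimum follow-up: by default only *censored* patients below the follow-up
threshold are removed — observed early diagnoses are real labels and
removing them would discard exactly what the classifier trains on; a
config switch (`drop_early_events`) removes all of them for the stricter
reading.  `truncate_features` keeps codes with age < prediction cutoff AND
age < E, so nothing recorded at or after the (latent) diagnosis leaks into
the features.

## Models

All heads share one encoder: embedding lookup (padding and
out-of-vocabulary indices fixed at the zero vector) → per-token fully
connected layer + ReLU → mean pooling over non-padding positions (an
all-padding sequence pools to the zero vector; a config switch divides by
the fixed sequence length instead) → fully connected layer + ReLU → linear
head.  Sequences are truncated to the most recent `max_sequence_length`
events before the cutoff.  Networks are plain numpy with hand-written
gradients, optimised by Adam with decoupled weight decay (decay on weight
matrices only).

* **DTNN**: softmax over the TimeGrid's bins plus one beyond-horizon bin.
  Loss: −log p(t_bin) for events; −log(mass strictly after t_bin) for
  censored observations (the beyond-horizon bin's own mass for patients
  censored past the horizon).  Masses are clamped at 1e-12 inside logs.
* **BC**: one log-odds output, binary cross-entropy against S; its
  probability is constant in evaluation time by construction.
* **DCPH**: one log-hazard-ratio output, Breslow-tie Cox negative partial
  log-likelihood computed within each minibatch (batches without events are
  skipped); absolute risks via the Breslow baseline cumulative hazard
  fitted on the training split, carried forward flat beyond the last event
  time.

**Embeddings.** CBOW with negative sampling (unigram^0.75, window 5, 5
negatives) is implemented and can initialise a frozen embedding layer.  For
the packaged scenarios the embeddings are randomly initialised and trained
with the encoder: on the small synthetic vocabulary CBOW converges to
near-collinear vectors (pairwise cosine ≈ 0.99 even between era tokens),
which erases the token-identity information the experiments depend on.
Frozen pretrained embeddings remain the right choice for large real
vocabularies and are available through `EncoderConfig`.

**Hyperparameters.** Grid search over learning rate × weight decay with
early stopping on validation loss; the candidate with the lowest validation
loss is returned together with the full per-epoch log.  Library defaults:
lr {1e-4, 1e-3, 1e-2}, decay {0, 1e-5, 1e-4}, patience 10.  The packaged
scenarios use a single-point grid (5e-3, 1e-4), batch 256, ≤60 epochs,
patience 10 — at the simulated sample sizes a wider grid changes little and
the single point keeps a full five-setup scenario under a few minutes on
one CPU.

## Time discretisation

`TimeGrid.regular(left, horizon, width)` builds half-open bins
(edge_{k−1}, edge_k] from the prediction-age cutoff to the horizon, plus
the implicit beyond-horizon category; cumulative incidence is a step
function attributing a bin's mass when the bin completes.  Default width is
1 year.  The packaged scenarios use 0.25-year bins: under the censoring
convention above, a patient censored inside bin k counts as surviving all
of bin k, so within-bin administrative censoring biases binned incidence
downward in proportion to bin width (measured on the late-event scenario:
marginal incidence 0.29 at yearly bins vs 0.34 at quarter-year bins vs
0.36 for the continuous-time Kaplan-Meier vs 0.38 latent truth — the
residual KM gap reflects censoring that is marginally informative through
the birth-year trend, which only a conditional model removes).

## Evaluation conventions

* **AUC_t / AP_t**: cases S=1 ∧ T ≤ t; controls T > t; patients censored
  at or before t (including exactly at t) are excluded.  Mann-Whitney with
  ties at 1/2; AP as mean precision at case ranks in descending-score
  order (ties broken by index; scores are continuous in practice).
* **Harrell's C**: comparable pairs T_i < T_j with S_i = 1; score ties 1/2.
* **Censoring concordance**: Harrell-style concordance on the censored
  subset, treating censoring time as the outcome and the predicted
  non-event probability as a risk-like score — a pair is concordant when
  the earlier-censored patient received the higher non-event probability.
  0.5 = no dependence of predictions on follow-up length.  Note that a
  *correct* model is expected to sit slightly below 0.5 here: among
  censored patients, higher-risk individuals are over-represented at short
  censoring times (they only remain censored if censored early), so true
  risk is negatively associated with follow-up within the censored subset.
* **Kaplan-Meier**: right-continuous product-limit S(t) = P(T > t) with
  Greenwood standard errors (used by the 3·SE calibration checks).
* **Calibration**: 10 quantile bins of predicted probability, bins under
  20 patients merged with their neighbour; observed incidence per bin is
  1 − S_KM(t) within the bin.
* **Bootstrap**: percentile intervals over patient resamples (default 100
  resamples, 95%); resamples on which a metric is undefined are redrawn and
  logged; the point estimate always comes from the unresampled data.
  Calibration-in-the-large is tested through the paired per-patient
  difference (prediction − latent outcome), whose bootstrap interval
  accounts for both prediction spread and label variance.

## Experiment design

A scenario fixes the cohort configuration, the prediction-age cutoff, the
bin width, the evaluation times and the five canonical setups — BC under
the base birth-year cap, a stricter cap (two years earlier), and a
minimum-follow-up filter, plus DTNN and DCPH under the base cap.  The test
split is drawn once after the base filter and shared by all setups, so
metric differences are attributable to training-time choices.  All
randomness flows from one root seed split into named substreams
(simulate / split / train / bootstrap) recorded in the report manifest;
reruns are bit-identical.

The four packaged scenarios mirror the timing structure of common
paediatric prediction targets (mean diagnosis ages ~1.5, 2.0, 3.7 and 6.2
years; feature cutoffs at 4 months, 3 months, 15 months and 3 years), with
per-year hazard vectors chosen to land on those means.  Problem sizes used
in the test suite and acceptance runs: 12,000 patients for the
heavy-censoring comparison, 8,000 for the semisynthetic experiment, 20,000
for parameter recovery, 4,000 for the no-censoring equivalence — sizes at
which the mechanisms under study are well separated from their bootstrap
noise while a full run stays in the minutes range on one CPU.

**Semisynthetic censoring.** The training and validation splits' censoring
times are rescaled by max_age / max(C) (so the maximum censoring age
equals max_age exactly), observed times and indicators recomputed, the
prediction-age filter re-applied, and BC/DTNN retrained; evaluation stays
on the untouched original test split and is restricted to times ≤ max_age
(beyond it the comparison would be unfair to the rescaled models).
`find_semisynthetic_max_age` inverts the monotone relationship between
max_age and the fraction of observed events retained, so "rescale until
half the labels are lost" is a constructive condition.

## Known limitations

* The discrete-time censoring convention biases binned incidence downward
  under heavy within-bin censoring; choose bin widths small relative to
  the censoring density (see above).
* The censoring concordance of a *well-specified* model deviates below 0.5
  by an amount growing with the model's real discrimination; it is a
  diagnostic for the direction and size of follow-up dependence, not a
  quantity a good model drives to exactly 0.5.
* With administrative censoring, horizon incidence for the latest birth
  years is not identified from observed data; per-era model estimates
  there are partly extrapolation, and weak prevalence trends (≈1pp/year or
  less at these sample sizes) are below the resolvable noise.
* Early stopping on validation loss can halt before the encoder fully
  exploits weak secondary features (e.g. era tokens), so the strength —
  not the direction — of the classifier's follow-up dependence varies
  across data draws.
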