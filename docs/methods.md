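# Methods

## The problem

Under tonic pain (sustained thermal stimulation), people can learn
actions that temporarily terminate the pain ("escape" or relief
learning).  This package models two such paradigms, fits a family of
candidate learning models to simulated choices and skin conductance
responses (SCRs), compares them at the group level, and asks which
model-derived uncertainty signal best explains trial-by-trial pain
ratings.  The scientific question it operationalises is whether a
Pearce–Hall *associability* signal — a running average of recent
absolute prediction errors that both scales the learning rate and
indexes attention — modulates ongoing pain.

## Task models

**Static paradigm** (`exp1`).  Two fractal cues, two actions.  One cue
("easy") gives relief with probability 0.8 for one press and 0.2 for
the other; the other cue ("hard") gives 0.6/0.4.  Three instrumental
sessions of 20 trials (10 easy, 10 hard, order shuffled) are each
yoked to a Pavlovian session that replays the identical cue/outcome
sequence with instructed presses.  Three post-outcome ratings per
session are scheduled near the beginning, middle and end (defaults
trials 2, 10, 18; configurable).  A rating is a pain rating (0–10)
after no relief and a relief rating after relief.

**Dynamic paradigm** (`exp2`).  Three cues shown simultaneously; the
subject picks one.  Each cue's relief probability follows an
independent bounded random walk: per trial the probability moves
±0.1 and is clipped at the bounds [0.2, 0.8]; the start is uniform in
the bounds.  Eight sessions of 24 trials; ten pre-outcome pain
ratings per session at random trials.  Clipping (rather than
reflection) and a per-trial update cadence are the simplest rules
consistent with "slowly varying, bounded" dynamics.

## Learning models

All models see binary outcomes r ∈ {0, 1} (1 = relief) and start each
session from the same initial state: values Q0 = V0 = 0, associability
α0 = 1, HMM relief belief 0.5.

* **WSLS** — fixed pseudo-values per cue: +p_cue for the previously
  chosen action after relief, −p_cue otherwise, with all signs flipped
  after no relief; choice by softmax with τ fixed at 1, so p1, p2 act
  as effect sizes.  First encounter of a cue is uniform.
* **TD** — Q(s, a) ← Q(s, a) + α (r − Q(s, a)); softmax over actions
  (static paradigm) or over the three cue-values (dynamic paradigm).
* **RW** — the state-level analogue V(s) ← V(s) + α (r − V(s)); no
  choice rule (used for SCR fitting).
* **Hybrid (Pearce–Hall)** — V(s) ← V(s) + κ·α_t(s)·δ with
  α_t(s) ← η |δ| + (1 − η) α_t(s); state and action variants.  With
  η = 0 and α0 = 1 the state variant reduces exactly to RW with rate κ.
* **HMM** — per cue, a two-state chain (relief state vs no-relief
  state) with symmetric transition probability β and observation
  likelihood 0.5·(1 ± c) for relief outcomes and 0.5·(1 ∓ d) for
  no-relief.  Each trial every cue's belief passes through the
  transition; only the chosen cue's belief is reweighted by the
  observed outcome (outcomes of unchosen cues are not observed).
  Relief probability per cue is σ(ΔS + m) with ΔS the belief
  difference and m a shift fixed at 0 by default (optionally fitted);
  choices are a softmax over these probabilities; uncertainty is the
  natural-log entropy of the chosen cue's two-state belief (≤ ln 2),
  recorded both pre-outcome (used as the rating predictor, matching
  the pre-outcome rating time) and post-outcome.
* **HGF** — a three-level binary hierarchical Gaussian filter per cue:
  level 2 tracks the log-odds of relief (coupled to level-3
  log-volatility through κ, with tonic component ω), level 3 evolves
  with variance θ.  Only the chosen cue's means update; all cues'
  variances inflate each trial by the volatility prediction.  Initial
  states μ2 = 0 (belief 0.5), σ2 = 1, μ3 = 1, σ3 = 1.  The filter's
  known instability at high volatility (non-positive level-3
  precision) raises a flagged numerical error; fitting treats such
  evaluations as large penalties.

## Fitting

Parameters live on a Gaussian latent scale (sigmoid-transformed to
[0, 1], exp to (0, ∞), identity when unbounded) with priors N(0, 1)
for choice fits and N(0, 0.05²) on evolution parameters for SCR fits;
the HGF's ω has latent prior mean −2.  Evolution parameters and
initial states are shared across sessions; observation parameters
(inverse temperature τ for choice fits, offset b for SCR fits) are
instantiated per session.  Subjects are fitted independently.

Optimisation is multistart Nelder–Mead from the prior mean plus prior
draws (tolerance 1e-6 by default; the cohort drivers use 2 starts and
tolerance 1e-4 — empirically sufficient for these smooth, low-
dimensional posteriors and what keeps a 20-subject, 4-model cohort
fit to a few minutes).  Model evidence is the Laplace approximation
F = −nll(θ̂) + (d/2) ln 2π − ½ ln det H with H the central
finite-difference Hessian (step 1e-4 latent units; non-positive
eigenvalues floored at 1e-8 with a warning).  MAP + Laplace replaces
the full variational scheme of common toolboxes; it is deterministic,
testable against conjugate closed forms, and asymptotically
equivalent for model-selection purposes.  Absolute free energies are
therefore not comparable to variational implementations — rank order
and group-level selection are the supported surface.

**SCR fitting.**  Sessions in which more than 20% of trials have
amplitude below 0.02 are excluded (strict inequality); surviving
amplitudes are log-transformed within subject, and the first two
trials of each session are excluded from fitting (startle).  The
observation model is g(x) = Predictor + b per source, with the
predictor the model's pre-outcome state value or associability,
unscaled.  Bilateral recordings are fitted simultaneously as two data
sources with per-source offsets, using the right (non-stimulated)
side's exclusion decisions for both.  Offsets are per session (one-b-
per-source available via the session structure); noise variance is
profiled per source (σ̂² = RSS/n, solved jointly with the offset MAP by
coordinate iteration), and the Laplace Hessian is taken over the full
(evolution + offsets) latent vector with the variance at its profile.

## Model comparison

Random-effects BMS with a uniform Dirichlet prior (concentration 1
per model): variational responsibilities and concentrations iterated
to 1e-8.  Exceedance probabilities by seeded Monte-Carlo over the
posterior Dirichlet (default 1e6 draws; K = 2 has a Beta closed form
used as the test oracle).  The Bayes omnibus risk compares the free
energy of the random-frequency model, F1 (variational bound including
the Dirichlet KL), with the exact evidence of the equal-frequency null
F0 = Σ_n [logsumexp_k lme_nk − ln K]; BOR = 1/(1 + exp(F1 − F0)) and
PXP_k = (1 − BOR)·XP_k + BOR/K.

## Pain-rating analysis

Per subject, ratings are regressed on Relief (trials since the last
relief outcome; counts from session start before any relief — the
regressor must be defined on every rated trial), log(Trial) within
session, and one uncertainty predictor: hybrid associability, HMM
entropy, TD surprise (|δ| of the *previous* trial, 0 at session
start), or none.  Predictors are computed over all trials from
group-mean parameters; only rated trials enter the fit.  The literal
regression has no intercept and that remains the default for fitting
observed data; generated ratings include an explicit intercept
(default 7) so they sit in a realistic 0–10 range, and the recovery
studies therefore fit with an intercept added symmetrically to all
four designs — without it, any near-constant predictor stream (HMM
entropy ≈ ln 2) acts as an intercept surrogate and wins spuriously.

Model comparison over rating regressions uses the BIC approximation
to the log evidence (logL − (p/2) ln n) rather than the raw ML log
likelihood: with raw logL a nested null design can never attain the
highest evidence (OLS likelihood is monotone in added columns), which
would make the null structurally unselectable.  Raw logL remains
available (`evidence="loglik"`).  Subjects with more than 90%
identical ratings are excluded.

Static-paradigm statistics: per-subject Spearman correlations of pain
ratings with associability or prediction error, Fisher-z transformed
(|ρ| clipped at 1 − 1e-12) and tested against zero by one-sample t;
paired t-tests for instrumental-vs-Pavlovian contrasts (the two-level
repeated-measures F equals the squared paired t and is computed that
way).  Degenerate inputs are guarded: zero-variance series exclude the
subject with a report entry; identical condition means define t = 0.

The axiomatic binning splits trials by outcome and then into 2 or 3
equal-size bins of ascending TD-predicted value (stable sort breaks
ties), for inspection of prediction-error signatures.

## Synthetic-data generator

Agents act generatively (softmax sampling) against the task
contingencies.  Cohort defaults are the study conditions: sample size
20, TD learning rates ~ N(0.5, 0.1) truncated to [0.05, 0.95],
inverse temperature 3.  SCRs are generated on the log-amplitude scale
(fitting consumes log SCRs) as predictor + b + N(0, 0.1²), bilateral
with shared predictor and per-source offsets for the dynamic paradigm
— the common predictor makes the two sides correlate strongly, as
bilateral SCRs do.  Ratings use β = (−0.1, 0.1, −2.0) with intercept 7
and unit noise, truncated to [0, 10]; the uncertainty coefficient is
sized so a single subject's regression carries a t ≈ 2–3 for that
term, comparable to the group-level effects reported for this kind of
rating data.  No rounding by default (a flag enables integer ratings).

What the generator does *not* emulate: SCR habituation and startle
dynamics (first-trial amplitudes are statistically identical to the
rest, so the first-two-trials exclusion is exercised but not
stressed), omitted or missed responses, reaction times, inter-trial-
interval effects, and rating drift unrelated to the design terms.
Passing recovery tests therefore show internal consistency of the
pipeline under its own generative assumptions, not that real data
satisfy them.

## Reproducibility and problem sizes

Every stochastic step takes an explicit seed; per-subject seeds are
derived through `numpy.random.SeedSequence` and recorded in the
ground-truth table, and a double run of the simulation is
byte-identical.  The cohort drivers default to 20 subjects (the
recovery benchmark script replicates smaller cohorts, 12 subjects ×
3 cohorts, as its default reporting size).  Study-data ingestion is
adapter-based because the source archives' internal layout is
unknown until first contact; the canonical-TSV adapter documents the
interface.

## Known limitations

* Free energies are Laplace approximations; absolute values differ
  from variational implementations.
* The HGF variant (which levels update for unchosen cues) is one of
  several defensible choices; variance-inflation-only for unchosen
  cues is implemented.
* The HMM shift parameter m is fixed at 0 by default; fitting it is
  supported but untested against data.
* Whether the softmax for HMM/HGF should act on beliefs or
  log-beliefs is undetermined; the belief scale is used.
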