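# Methods

This note documents the models, algorithms, defaults, and design choices
behind `voicetest`, and what the synthetic-data pipeline does and does not
establish about real data.

## Acoustic voice space

A speaker is summarized by mean f0 (Hz), formant dispersion
(FD = mean successive difference of F1–F4 = (F4 − F1)/3, Hz) and mean HNR
(dB). Within a gender stratum each dimension is z-scored (sample SD, n − 1
denominator); Euclidean distance in the resulting 3D space is the acoustic
similarity metric. Choices that were genuinely open:

* **f0 scale.** f0 is standardized on the raw Hz scale by default; a
  `log_f0` switch standardizes log-Hz instead. Either choice is recorded in
  `standardization_params` so coordinates are auditable and reproducible.
* **Stratification.** Spaces are built per gender because triplets are
  gender-matched (targets and foils in a trial share gender); pooling
  across genders would let the large between-gender f0 gap dominate the
  metric.
* **Level normalization.** `rms_normalize` scales a waveform so that
  `20·log10(RMS/ref)` hits the target level; the reference defaults to
  2×10⁻⁵, the convention under which 60 dB is a standard comfortable
  presentation level. Stimulus truncation to 250/750 ms applies a 10 ms
  raised-cosine offset ramp to avoid clicks (configurable to a hard cut).
* **Feature extraction.** Pitch/formant/HNR tracking is delegated to a
  pluggable backend object; the package defines only the aggregation
  contract (voiced-frame mean f0, mean F1–F4 with FD derived, mean HNR).
  The CSV feature-table path is fully functional without any backend.

## Triplet search, stratification, assignment

All C(n, 3) same-stratum triples are scanned; a triple qualifies as
near-equilateral when its defect `(max side − min side)/mean side` is at
most the tolerance (default 0.10; zero-area triples never qualify). The
default was chosen so that realistic simulated spaces yield non-empty
similarity strata; it is configurable, as are the size boundaries that
split qualifying triplets into high/medium/low similarity (default:
empirical tertiles of qualifying sizes). Targets are the voices belonging
to the most triplets (ties broken lexicographically by speaker id, making
the pipeline deterministic without a seed). A backtracking search then
assigns each target one triplet per similarity level for the testing phase
plus one medium-similarity learning triplet, under the global constraint
that every foil appears in exactly one assigned triplet; among feasible
candidates it prefers smaller equilaterality defect (a heuristic — any
foil-disjoint assignment is admissible). An independent validator re-checks
foil-disjointness and level-completeness after every search. The end-to-end
simulation preset uses tolerance 0.35, the level at which 40-speaker
Gaussian strata reliably support a feasible assignment.

## Blueprint

The three-phase structure: a learning phase of alternating familiarization
(three sentences by one target) and immediate 3AFC recognition trials, run
in two cycles with fresh immediate-trial sentences in cycle 2 — so each
target accrues exactly five distinct sentences; a passive repetition
playlist (per target one familiarization and one immediate sentence); and a
testing phase crossing similarity (high/medium/low) × duration
(250/750 ms/full) per target, randomized once and then fixed. Sentences are
allocated uniformly at random without replacement under the constraints,
seeded. Target positions are balanced by constrained shuffle (per-position
counts within ±1 of uniform per phase). Each target gets one fresh test
sentence per similarity level, reused across its three durations; with 8
targets this uses 3 + 16 + 24 = 43 of the 50-sentence pool.

**Stimulus counting rule.** `count_stimuli` counts distinct
(speaker, sentence, duration) presentations per phase: the full design
gives 72 learning stimuli (8 targets × 5 sentences + 16 learning foils × 2
sentences) and 216 testing stimuli (72 trials × 3 voices), 288 in total;
the 26-item shortened design gives 78 testing stimuli and 150 in total.
Practice/dummy stimuli (12 before learning, 6 before testing) are carried
as metadata, reported separately, and excluded from all analyses. Break
scheduling is presentation metadata only; no experiment runtime is
implemented.

The validator reports violations rather than raising; position balance is
checked only on full assemblies, since an item-selected subset inherits
whatever positions its surviving trials carry.

## IRT engine

Marginal maximum likelihood via EM on a fixed quadrature grid (default 61
equally spaced nodes on [−6, 6]; prior weights are the normalized normal
density on the nodes). Identification follows the conventional practice:

* **Rasch**: common discrimination fixed at 1, latent SD estimated,
  latent mean 0 — free parameters J + 1;
* **2PL**: latent prior fixed standard normal, per-item discriminations
  free (clipped to [0.05, 5] to prevent divergence on quasi-separated
  items) — free parameters 2J.

Rasch with latent SD s is exactly a 2PL with all discriminations equal to
s, so the models are nested and the likelihood-ratio test has J − 1
degrees of freedom. The M-step solves each item's weighted logistic
regression by safeguarded Newton; the latent-distribution parameters are
updated by directly maximizing the discretized prior term, which keeps the
EM monotone — the marginal log-likelihood is asserted non-decreasing every
iteration. Convergence: max absolute parameter change < 1e−5, at most 500
iterations (non-convergence returns a result flagged provisional).
Starting values are deterministic (logits of observed accuracies); there is
no random initialization. Items with no response variation are flagged
inestimable and excluded with a warning. Missing responses (omissions) are
excluded from the likelihood cell-wise, never imputed or scored incorrect.

Standard errors come from the observed information matrix of the marginal
log-likelihood (central-difference Hessian); the latent SD is
differentiated on the log scale with a delta-method back-transform.
AIC/BIC use the free-parameter counts above with BIC's `ln(n persons)`.

**EAP and reliability.** Abilities are posterior means on the quadrature
grid with posterior SDs as standard errors; a person with no scored
responses falls back to the prior mean and SD. Empirical marginal
reliability is `var(θ̂)/(var(θ̂) + mean(SE²))`. Under the Rasch model the
sum score is sufficient for ability, so equal sum scores over equal scored
items map to equal EAP estimates (tested).

**Item fit.** Infit (information-weighted) and outfit (unweighted) mean
squares of residuals against EAP abilities, plus a binned
observed-vs-expected chi-square (equal-count ability bins, merged below 5
persons). Flag bounds default to [0.7, 1.3]. Because point-estimate
abilities are shrunken and partly driven by the item under test, infit
runs slightly below 1 on well-fitting data (≈0.93 at 20 items, n = 500);
the bounds accommodate this known bias and are configurable.

**DIF.** Two-group Rasch DIF. Omnibus: LR comparison of group-equal
difficulties (non-reference group latent mean freed, shared latent SD)
against group-specific difficulties (group means fixed at 0, shared SD);
df = J − 1. Per item: Wald tests of the difficulty difference from
separate per-group fits linked by the all-items anchor (equal mean
difficulty), with SEs combined from the per-group observed-information
matrices; the small covariance contributed by the anchoring itself
(order 1/J) is neglected. Simulated calibration: omnibus type-I ≈ 5%, and
a one-logit shift at n = 250 per group is flagged in well over 80% of
replicates (both asserted in the acceptance suite).

## Stepwise item selection

The loop mirrors conformity-driven test shortening: (1) drop items with
observed mean accuracy below the 3AFC chance level 1/3 (scored trials
only); (2) fit Rasch and 2PL, and while the LR test prefers the 2PL at
α = 0.05, drop the worst item under the 2PL and refit; (3) after the
switch to Rasch, drop the worst ill-fitting item until all retained items
pass the fit bounds; (4) a DIF screen excludes flagged items. Open choices,
made here and logged in the trace so the path is auditable:

* "worst under the 2PL" = largest |discrimination − Rasch common slope|
  (the Rasch latent SD, which is the comparable common slope), then worst
  infit deviation, then item id;
* "worst under Rasch" = largest infit/outfit deviation among items outside
  the bounds;
* per-item DIF p-values are Benjamini–Hochberg adjusted across items at
  0.05 before exclusion;
* elimination aborts (with partial trace) below 10 retained items.

`finalize` refits Rasch on the final set, reports difficulties with SEs,
the information curve, the EAP-based reliability (recomputed from the
emitted ability estimates, so internally consistent by construction), and
the BIC adjudication against a 2PL refit on the same items.

## Simulation

`simulate_voice_features` draws gender-clustered features (defaults:
male f0 ~ N(115, 15) Hz, female f0 ~ N(210, 20) Hz, F1 ~ N(500, 40) Hz
with formant spacings ~ N(1000, 80) Hz — hence FD ≈ N(1000, 80/√3) —
HNR ~ N(15, 3) dB). These are configurable stand-ins producing distinct
male/female clusters and realistic formant ranges, not measurements.
`simulate_responses` draws from `P = c + (1 − c)·logistic(a(θ − b))` with
θ ~ N(mean, SD²); `c = 1/3` reproduces the 3AFC guessing floor. Omissions
are inserted as missing responses with log-normal RTs shifted above the
4000 ms window; scored trials get log-normal RTs capped below it — only
the cutoff semantics matter downstream, the RT shape is invented. Group
labels and per-(item, group) difficulty shifts inject DIF. The
`make_fixture` presets bundle voices + blueprint + responses at the three
development sizes (72 items × 232 persons; 26 × 454; 22 × 454).

What the simulations do **not** emulate: real acoustic measurement error,
local dependence between trials sharing a triplet or sentence,
multidimensional or method-factor structure, respondent inattention other
than omission, and learning/fatigue over the session. Passing tests
therefore establish correctness and calibration of the machinery under the
stated generating models, not validity claims about any real cohort.

## Scoring and norms

Trials with RT ≥ 4000 ms (inclusive boundary) are excluded as omission
errors before computing proportion correct over scored trials; trial
accounting (scored + omitted = presented) is conserved per person. Cohort
accuracy is compared to chance (1/3) by a one-sample t test. Scores at
least 2 SDs below/above a norm mean (boundaries inclusive) are flagged as
potential phonagnosia / potential super-recognition; the report embeds the
caveat that these are screening signals, not diagnoses, and both overall
and group-specific norms can be used for the screen since the appropriate
reference is itself an open question. The packaged norm table carries the
published validation-cohort descriptives (overall M 0.51, SD 0.18; by
gender and three age bands); the printed age bands share the 31-year
boundary, resolved here to the younger band; ages above the normed range
map to the nearest band with a warning, ages below 18 are unsupported.
Both the sum score/proportion correct and the EAP ability are emitted;
under the Rasch model they order persons identically (sum-score
sufficiency), and the EAP scale is the recommended metric.

Digit span (divergent-validity task): six sequences per length from four
digits upward; the score is the largest length L such that every length
4..L has at least five of six correct, honoring the abort rule (an
incomplete trial count is allowed only at the final, aborted length);
failure already at length four yields the below-floor sentinel 3.

## Problem sizes and numerical notes

The test and acceptance suites run entirely on synthetic data at these
sizes, chosen as representative desk-scale conditions: difficulty recovery
at n = 500 persons × 22 items (RMSE ≤ 0.2 after centering); LR-test and
DIF-omnibus type-I calibration over 50 seeded replicates each (n = 500,
20 items); DIF power over 15 replicates (unit shift, 250 per group);
selection behavior over 9–10 replicates (24 items, n = 500). Dense-grid
trapezoid integration over the continuous prior reproduces the EM's
discretized marginal log-likelihood to ≈1e−9 at unit latent SD — far
inside the asserted 1e−4 — because Riemann sums of Gaussian-tailed
integrands converge spectrally; the agreement degrades if the latent SD
approaches the quadrature range, which is why fits report the grid they
used. All randomness is routed through `numpy.random.default_rng` seeds;
identical seeds give byte-identical blueprints, fixtures, and traces.

## Known limitations

* No 3PL/4PL estimation and no multidimensional models; the guessing floor
  exists only on the generating side, which is precisely what makes the
  misspecification scenarios informative.
* No MCMC/Bayesian estimation; SEs are asymptotic observed-information.
* The stepwise elimination order and the DIF anchoring are reasonable
  documented choices, not the only defensible ones; the trace exists so a
  different analyst can audit or re-run with other settings.
* Audio handling is limited to RMS scaling and truncation; no DSP feature
  extraction is implemented in-package.
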