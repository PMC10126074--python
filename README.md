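# voicetest

A toolkit for constructing, calibrating, and scoring a three-alternative
forced-choice (3AFC) voice learning and memory test.

Standardized tests of voice-identity learning ask a listener to memorize a
set of unfamiliar voices from spoken sentences and later to pick each
learned voice out of a triplet that includes two unfamiliar foils. Building
such a test well requires machinery from two fields at once:

* **voice acoustics** — each speaker is summarized by mean fundamental
  frequency (f0, Hz), formant dispersion (FD = (F4 − F1)/3, Hz) and
  harmonics-to-noise ratio (HNR, dB), and embedded in a z-standardized 3D
  space. Trial difficulty is controlled by choosing triplets of same-gender
  voices that span (near-)equilateral triangles in this space: small
  triangles mean acoustically similar, hence hard, trials;
* **item response theory** — responses are calibrated with Rasch and 2PL
  models fit by marginal maximum likelihood, `P(correct) =
  logistic(a_j(θ − b_j))`, and the item pool is pruned stepwise until the
  parsimonious Rasch model fits: below-chance items out first, then
  ill-fitting items under whichever model the likelihood-ratio test
  prefers, and finally items showing differential item functioning (DIF)
  across gender or age groups. Ability is estimated by the expected a
  posteriori (EAP) method; precision is summarized by the empirical
  marginal reliability `var(θ̂) / (var(θ̂) + mean(SE²))` and the test
  information function `I(θ) = Σ a_j² P(1−P)`.

The package is aimed at researchers who design or adapt voice-memory
instruments and need every stage — stimulus geometry, three-phase test
blueprint, psychometric calibration, item selection, scoring and norms —
reproducible from code. Because real respondent data are rarely shareable,
a seeded simulation module generates gender-clustered voice features and
Rasch/2PL response matrices (with configurable guessing floor, DIF shifts
and omission behavior), so every stage is exercisable end to end.

## Worked example

```python
import numpy as np
from voicetest import irt
from voicetest.simulate import RespondentModel, simulate_responses

b_true = np.random.default_rng(1).uniform(-2, 2, 22)
responses = simulate_responses(RespondentModel(difficulty=b_true), 500, seed=2)

rasch = irt.fit_rasch(responses)
two_pl = irt.fit_2pl(responses, compute_se=False)
lr = irt.lr_test(rasch, two_pl)
abilities = irt.eap_abilities(rasch, responses)
print(f"LR test 2PL vs Rasch: chi2({lr.df}) = {lr.chi2:.2f}, p = {lr.p:.3f}")
print(f"empirical marginal reliability: {irt.empirical_reliability(abilities):.3f}")
```

prints (seeds as above):

```
LR test 2PL vs Rasch: chi2(21) = 20.30, p = 0.503
empirical marginal reliability: 0.809
```

The non-significant likelihood-ratio test says the per-item discriminations
of the 2PL buy nothing over the common-slope Rasch model on data that were
in fact generated from a Rasch model, and a reliability of 0.81 is what 22
informative items on a well-matched ability distribution deliver.
`examples/` contains one narrative script per capability: voice space and
triplet assignment, blueprint assembly and validation, IRT calibration,
stepwise item selection, and scoring/norms.

A thin CLI mirrors the library (`voicetest features|triplets|blueprint|
simulate|fit|select|score`); run `voicetest --help`.

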