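"""Score respondents: omission exclusion, chance comparison, extreme flags.

Simulates a cohort on a 22-item test with a 2% omission rate, scores each
person (RT >= 4000 ms trials removed), tests the cohort against the 1/3
chance level, and screens for scores 2 SDs beyond the packaged norms.
Also scores a digit-span trial log.
"""

import numpy as np
import pandas as pd

from voicetest import scoring
from voicetest.simulate import RespondentModel, simulate_responses

model = RespondentModel(difficulty=np.linspace(-2, 2, 22), omission_prob=0.02)
responses = simulate_responses(model, 200, seed=5)

report = scoring.score_responses(responses, norms=scoring.DEFAULT_NORMS["overall"])
print(f"cohort: n = {report.cohort['n_persons']}, "
      f"omission rate {report.cohort['overall_omission_rate']:.3f}, "
      f"mean accuracy {report.cohort['mean_prop_correct']:.3f}")

scores = report.per_person["prop_correct"].dropna()
t, df, p = scoring.t_vs_chance(scores, alternative="greater")
print(f"vs chance (1/3): t({df}) = {t:.2f}, p = {p:.2g}")

flagged = report.flagged()
print(f"extreme scores (>= 2 SD from norm mean 0.51): {len(flagged)} of {len(scores)}")
print(report.caveat)

norms = scoring.norm_lookup(age=31, gender="f")
print(f"age-31 female norms: band {norms['age_band'].group} "
      f"(M {norms['age_band'].mean}, SD {norms['age_band'].sd})")

span_log = pd.DataFrame(
    [{"sequence_length": l, "trial_index": i, "correct": int(i < k)}
     for l, k in {4: 6, 5: 5, 6: 5, 7: 4}.items() for i in range(6)]
)
print(f"digit span score: {scoring.digit_span_score(span_log)}")
# Score 6: lengths 4-6 each reached >= 5/6 correct, length 7 did not.
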