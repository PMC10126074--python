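"""Respondent scoring, chance comparison, norms, and extreme-score flags.

Scoring removes omission errors (no response within the 4000 ms window;
the boundary is inclusive, RT >= 4000 ms) before computing each person's
proportion correct over scored trials.  Cohort accuracy is compared to the
3AFC chance level (1/3) with a one-sample t test.  Individual scores at
least 2 SDs below (above) a norm mean are flagged as potential phonagnosia
(potential super-recognition); the flags are screening signals only —
clinical conclusions require comprehensive follow-up testing.

The packaged default norms carry the published validation-cohort
descriptives (proportion correct on the final 22-item test) for the
overall sample, gender groups, and three age bands.

Also included: the auditory digit-span scoring rule used as the divergent
validity measure (maximal sequence length with >= 5 of 6 sequences correct,
lengths increasing from four digits, test aborted once a length fails).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .irt import ResponseMatrix

__all__ = [
    "ScoreReport",
    "NormRow",
    "NormTable",
    "DEFAULT_NORMS",
    "score_responses",
    "t_vs_chance",
    "flag_extremes",
    "norm_lookup",
    "digit_span_score",
    "DIGIT_SPAN_FLOOR",
]

CHANCE_3AFC = 1.0 / 3.0
RT_CUTOFF_MS = 4000.0

#: Sentinel for digit-span performance below the four-digit entry level.
DIGIT_SPAN_FLOOR = 3

FLAG_TYPICAL = "typical"
FLAG_LOW = "potential_phonagnosia"
FLAG_HIGH = "potential_super_recognizer"

SCREENING_CAVEAT = (
    "Extreme-score flags are screening signals only; clinical conclusions "
    "about phonagnosia or super-recognition require an in-depth examination "
    "with comprehensive test batteries."
)


@dataclass(frozen=True)
class NormRow:
    group: str
    mean: float
    sd: float
    n: int | None = None
    score_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("norm SD must be positive")


@dataclass
class NormTable:
    """Normative descriptives per group (overall, gender, age bands)."""

    rows: dict[str, NormRow]
    age_bands: tuple[tuple[int, int, str], ...] = (
        (18, 31, "age_18_31"),
        (31, 45, "age_31_45"),
        (46, 74, "age_46_74"),
    )

    def __getitem__(self, group: str) -> NormRow:
        return self.rows[group]


#: Validation-cohort descriptives (proportion correct, final 22-item test).
DEFAULT_NORMS = NormTable(
    rows={
        "overall": NormRow("overall", 0.51, 0.18, 454, (0.05, 0.95)),
        "female": NormRow("female", 0.54, 0.17, 156, (0.11, 0.91)),
        "male": NormRow("male", 0.50, 0.18, 296, (0.05, 0.95)),
        "age_18_31": NormRow("age_18_31", 0.48, 0.17, 163, (0.05, 0.91)),
        "age_31_45": NormRow("age_31_45", 0.51, 0.17, 186, (0.13, 0.91)),
        "age_46_74": NormRow("age_46_74", 0.57, 0.17, 105, (0.12, 0.95)),
    }
)


@dataclass
class ScoreReport:
    per_person: pd.DataFrame  # person_id, n_total, n_scored, n_omitted, omission_rate, prop_correct, flag
    cohort: dict
    caveat: str = SCREENING_CAVEAT

    def flagged(self) -> pd.DataFrame:
        return self.per_person[self.per_person["flag"] != FLAG_TYPICAL]


def score_responses(
    responses: ResponseMatrix,
    rt_cutoff_ms: float = RT_CUTOFF_MS,
    norms: NormRow | None = None,
) -> ScoreReport:
    """Per-person proportion correct after omission exclusion.

    Trials with RT at or above the cutoff are excluded as omission errors
    before scoring (when no RTs are recorded, already-missing entries count
    as the omissions).  Persons with zero scored trials get a missing
    proportion and a warning entry in the cohort summary.  When a norm row
    is supplied, each person is flagged via :func:`flag_extremes`.
    """
    scored = responses.with_omissions_excluded(rt_cutoff_ms)
    n_total = np.full(scored.n_persons, scored.n_items, dtype=float)
    if responses.rt_ms is None:
        # without RTs, a missing correctness entry is the omission record
        presented = np.full_like(scored.correct, True, dtype=bool)
    else:
        presented = np.isfinite(responses.rt_ms) | np.isfinite(responses.correct)
        n_total = presented.sum(axis=1).astype(float)
    mask = scored.scored_mask()
    n_scored = mask.sum(axis=1).astype(float)
    n_omitted = n_total - n_scored
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(n_scored > 0, np.nansum(scored.correct, axis=1) / np.maximum(n_scored, 1), np.nan)
        omission_rate = np.where(n_total > 0, n_omitted / np.maximum(n_total, 1), 0.0)

    flags = [
        flag_extremes(p, norms) if norms is not None and np.isfinite(p) else FLAG_TYPICAL
        for p in prop
    ]
    per_person = pd.DataFrame(
        {
            "person_id": scored.person_ids,
            "n_total": n_total.astype(int),
            "n_scored": n_scored.astype(int),
            "n_omitted": n_omitted.astype(int),
            "omission_rate": omission_rate,
            "prop_correct": prop,
            "flag": flags,
        }
    )
    unscoreable = per_person.loc[~np.isfinite(prop), "person_id"].tolist()
    valid = prop[np.isfinite(prop)]
    cohort = {
        "n_persons": scored.n_persons,
        "n_unscoreable": len(unscoreable),
        "unscoreable_person_ids": unscoreable,
        "overall_omission_rate": float(n_omitted.sum() / max(n_total.sum(), 1)),
        "mean_prop_correct": float(valid.mean()) if valid.size else np.nan,
        "sd_prop_correct": float(valid.std(ddof=1)) if valid.size > 1 else np.nan,
        "norms_used": norms.group if norms is not None else None,
    }
    return ScoreReport(per_person=per_person, cohort=cohort)


def t_vs_chance(
    scores, chance: float = CHANCE_3AFC, alternative: str = "two-sided"
):
    """One-sample t test of mean proportion correct against chance (1/3).

    Returns ``(t, df, p)``.  ``alternative`` may be "two-sided", "greater",
    or "less".
    """
    x = np.asarray(scores, float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("need >= 2 scores")
    if np.std(x, ddof=1) == 0:
        if np.allclose(x, chance):
            return 0.0, x.size - 1, 1.0
        raise ValueError("zero variance in scores; t statistic undefined")
    res = stats.ttest_1samp(x, popmean=chance, alternative=alternative)
    return float(res.statistic), int(x.size - 1), float(res.pvalue)


def flag_extremes(score: float, norms: NormRow) -> str:
    """Flag scores at least 2 SDs below/above the norm mean (inclusive)."""
    if score <= norms.mean - 2 * norms.sd:
        return FLAG_LOW
    if score >= norms.mean + 2 * norms.sd:
        return FLAG_HIGH
    return FLAG_TYPICAL


def norm_lookup(
    age: float,
    gender: str | None = None,
    table: NormTable = DEFAULT_NORMS,
) -> dict:
    """Return the applicable norm rows for a person.

    Always includes the overall row; adds the gender row (when given) and
    the age-band row.  The printed bands share the age-31 boundary; age 31
    is assigned to the younger band.  Ages above the supported range map to
    the nearest band with an out-of-norm warning field; ages below 18 are
    unsupported.
    """
    if age < 18:
        raise ValueError("norms cover ages 18 and above only")
    out: dict = {"overall": table["overall"], "warnings": []}
    if gender is not None:
        key = {"f": "female", "m": "male", "female": "female", "male": "male"}.get(gender.lower())
        if key is None:
            out["warnings"].append(f"no gender norms for {gender!r}")
        else:
            out["gender"] = table[key]
    band_key = None
    for lo, hi, key in table.age_bands:
        if lo <= age <= hi:
            band_key = key
            break  # shared boundaries resolve to the younger band
    if band_key is None:
        band_key = table.age_bands[-1][2]
        out["warnings"].append(
            f"age {age} outside normed range; nearest band {band_key} used"
        )
    out["age_band"] = table[band_key]
    return out


def digit_span_score(trials: pd.DataFrame, criterion: int = 5, per_length: int = 6) -> int:
    """Score the auditory digit-span task.

    ``trials`` needs columns ``sequence_length`` and ``correct`` (0/1).
    Sequence lengths run contiguously from four digits; each length has six
    trials (fewer allowed only at an aborted final length).  The score is
    the largest length L such that every length from 4 through L has at
    least five of six sequences correct.  Failing already at length four
    returns the below-floor sentinel ``3``.
    """
    counts = trials.groupby("sequence_length")["correct"].agg(["sum", "count"])
    lengths = sorted(counts.index)
    if not lengths or lengths[0] != 4:
        raise ValueError("digit-span trials must start at sequence length 4")
    if lengths != list(range(4, lengths[-1] + 1)):
        raise ValueError(f"sequence lengths must be contiguous from 4, got {lengths}")
    score = DIGIT_SPAN_FLOOR
    for i, length in enumerate(lengths):
        n = int(counts.loc[length, "count"])
        if n > per_length:
            raise ValueError(f"more than {per_length} trials at length {length}")
        if n < per_length and i != len(lengths) - 1:
            raise ValueError(
                f"incomplete trial count ({n}) at non-final length {length}"
            )
        if int(counts.loc[length, "sum"]) >= criterion:
            score = length
        else:
            break  # stopping rule: the test aborts after a failed length
    return score
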