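"""Seeded generators for synthetic voices and simulated respondents.

Every pipeline stage is testable without external data: voice features are
drawn from gender-clustered normal distributions, and 3AFC responses are
drawn from Rasch/2PL item response models with an optional guessing floor
(1/3, the 3AFC chance level — the canonical misspecification scenario for
a Rasch analysis of forced-choice data), group-specific difficulty shifts
(DIF), and omission behavior (missing responses carrying reaction times at
or above the 4000 ms response window).

The default feature distributions are configurable stand-ins chosen to
produce distinct male/female f0 clusters and realistic formant/HNR ranges;
they are documented as stand-ins, not as measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import blueprint as bp
from . import triplets as tp
from .features import VoiceFeatures, build_voice_space
from .irt import ResponseMatrix

__all__ = [
    "FeatureDistributions",
    "RespondentModel",
    "simulate_voice_features",
    "simulate_responses",
    "make_fixture",
    "DESIGN_PRESETS",
]


@dataclass(frozen=True)
class FeatureDistributions:
    """Per-gender sampling distributions for the acoustic features.

    f0 is normal per gender; formants are drawn as F1 plus strictly
    positive spacings so they are always increasing; HNR is normal and
    shared across genders.
    """

    f0_mean: dict = field(default_factory=lambda: {"m": 115.0, "f": 210.0})
    f0_sd: dict = field(default_factory=lambda: {"m": 15.0, "f": 20.0})
    f1_mean: float = 500.0
    f1_sd: float = 40.0
    spacing_mean: float = 1000.0  # mean gap between successive formants -> FD
    spacing_sd: float = 80.0
    hnr_mean: float = 15.0
    hnr_sd: float = 3.0

    def validate(self) -> None:
        for g in self.f0_mean:
            if self.f0_sd[g] <= 0 or self.f0_mean[g] <= 0:
                raise ValueError(f"invalid f0 distribution for gender {g!r}")
        if min(self.f1_sd, self.spacing_sd, self.hnr_sd) <= 0 or self.spacing_mean <= 0:
            raise ValueError("scale parameters must be positive")


def simulate_voice_features(
    n_per_gender: int = 40,
    params: FeatureDistributions | None = None,
    seed: int = 0,
) -> list[VoiceFeatures]:
    """Draw a gender-clustered synthetic speaker pool (deterministic per seed).

    Defaults give 40 speakers per gender, matching a stimulus-recording
    database large enough for triplet search.
    """
    if n_per_gender < 3:
        raise ValueError("need >= 3 speakers per gender stratum")
    params = params or FeatureDistributions()
    params.validate()
    rng = np.random.default_rng(seed)
    out: list[VoiceFeatures] = []
    for gender in sorted(params.f0_mean):
        for i in range(n_per_gender):
            f0 = 0.0
            while f0 <= 0:
                f0 = rng.normal(params.f0_mean[gender], params.f0_sd[gender])
            f1 = max(rng.normal(params.f1_mean, params.f1_sd), 150.0)
            spacings = np.maximum(
                rng.normal(params.spacing_mean, params.spacing_sd, size=3), 50.0
            )
            formants = tuple(f1 + np.concatenate([[0.0], np.cumsum(spacings)]))
            out.append(
                VoiceFeatures(
                    speaker_id=f"{gender}{i + 1:02d}",
                    gender=gender,
                    f0_hz=float(f0),
                    fd_hz=float(np.mean(spacings)),
                    hnr_db=float(rng.normal(params.hnr_mean, params.hnr_sd)),
                    formants_hz=formants,  # type: ignore[arg-type]
                )
            )
    return out


@dataclass
class RespondentModel:
    """Generating model for simulated 3AFC respondents.

    ``P(correct) = c + (1 - c) * logistic(a_j * (theta - b_j))`` with
    ability ``theta ~ N(ability_mean, ability_sd)``.  ``guessing = 1/3``
    reproduces the 3AFC floor; ``guessing = 0`` gives clean Rasch/2PL data.
    DIF is injected as additive difficulty shifts for one group.  Omitted
    trials are recorded as missing with an RT at or above 4000 ms; scored
    trials get log-normal RTs below the window.
    """

    difficulty: np.ndarray
    discrimination: np.ndarray | None = None  # default: all 1 (Rasch)
    guessing: float | np.ndarray = 0.0
    ability_mean: float = 0.0
    ability_sd: float = 1.0
    group_proportions: dict | None = None  # e.g. {"f": .5, "m": .5}
    group_name: str = "group"
    dif_shifts: dict = field(default_factory=dict)  # {(item_index, group): delta_b}
    omission_prob: float = 0.0
    rt_log_mean: float = np.log(1500.0)
    rt_log_sd: float = 0.35
    rt_cutoff_ms: float = 4000.0

    def validate(self) -> None:
        c = np.asarray(self.guessing, float)
        if np.any(c < 0) or np.any(c >= 1):
            raise ValueError("guessing floor must lie in [0, 1)")
        if self.ability_sd <= 0:
            raise ValueError("ability SD must be positive")
        if not 0 <= self.omission_prob <= 1:
            raise ValueError("omission probability must lie in [0, 1]")
        if self.group_proportions is not None:
            p = np.array(list(self.group_proportions.values()), float)
            if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
                raise ValueError("group proportions must be non-negative and sum to 1")


def simulate_responses(
    model: RespondentModel,
    n_persons: int,
    seed: int = 0,
    item_ids=None,
) -> ResponseMatrix:
    """Draw a persons x items response matrix (deterministic per seed)."""
    model.validate()
    rng = np.random.default_rng(seed)
    b = np.asarray(model.difficulty, float)
    J = b.size
    a = np.ones(J) if model.discrimination is None else np.asarray(model.discrimination, float)
    c = np.broadcast_to(np.asarray(model.guessing, float), (J,))
    theta = rng.normal(model.ability_mean, model.ability_sd, size=n_persons)

    groups: dict[str, np.ndarray] = {}
    b_person = np.tile(b, (n_persons, 1))
    if model.group_proportions is not None:
        names = sorted(model.group_proportions)
        probs = [model.group_proportions[g] for g in names]
        labels = rng.choice(names, size=n_persons, p=probs)
        groups[model.group_name] = labels
        for (item_index, group), delta in model.dif_shifts.items():
            b_person[labels == group, item_index] += delta

    P = c[None, :] + (1.0 - c[None, :]) / (
        1.0 + np.exp(-a[None, :] * (theta[:, None] - b_person))
    )
    correct = (rng.random((n_persons, J)) < P).astype(float)

    rt = np.exp(rng.normal(model.rt_log_mean, model.rt_log_sd, size=(n_persons, J)))
    rt = np.minimum(rt, model.rt_cutoff_ms - 1.0)
    omitted = rng.random((n_persons, J)) < model.omission_prob
    correct[omitted] = np.nan
    rt[omitted] = model.rt_cutoff_ms + np.exp(
        rng.normal(np.log(500.0), 0.5, size=int(omitted.sum()))
    )

    if item_ids is None:
        item_ids = tuple(f"i{j + 1:02d}" for j in range(J))
    person_ids = tuple(f"p{i + 1:04d}" for i in range(n_persons))
    return ResponseMatrix(person_ids, tuple(item_ids), correct, rt, groups)


#: End-to-end fixture presets sized like the three development stages:
#: the 72-item calibration run, the 26-item validation run, and the final
#: 22-item instrument.
DESIGN_PRESETS = {
    "item-selection": {"n_items": 72, "n_persons": 232},
    "validation": {"n_items": 26, "n_persons": 454},
    "final": {"n_items": 22, "n_persons": 454},
}


def make_fixture(preset: str = "item-selection", seed: int = 0) -> dict:
    """Build a full synthetic bundle: voice space, blueprint, responses.

    The blueprint always assembles the full 72-trial factorial design;
    for the shorter presets a random item subset of the required size is
    retained (mimicking post-selection shortening).  Responses are drawn
    from a Rasch model with difficulties spread over [-2, 2], a small
    omission rate, and a gender grouping.
    """
    if preset not in DESIGN_PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(DESIGN_PRESETS)}")
    spec = DESIGN_PRESETS[preset]
    rng = np.random.default_rng(seed)

    feats = simulate_voice_features(40, seed=seed)
    spaces = {g: build_voice_space(feats, stratum=g) for g in ("f", "m")}
    assignment = None
    for g, space in spaces.items():
        trips = tp.stratify_triplets(tp.find_equilateral_triplets(space, tolerance=0.35))
        targets = tp.select_targets(trips, n_per_stratum=4)
        part = tp.assign_triplets(targets, trips)
        assignment = part if assignment is None else assignment.merge(part)

    design = bp.assemble_blueprint(assignment, seed=seed)
    if spec["n_items"] < len(design.test_trials):
        all_ids = [t.item_id for t in design.test_trials]
        keep = sorted(rng.choice(len(all_ids), size=spec["n_items"], replace=False))
        design = bp.subset_blueprint(design, [all_ids[k] for k in keep])

    item_ids = [t.item_id for t in design.test_trials]
    b = rng.uniform(-2.0, 2.0, size=len(item_ids))
    model = RespondentModel(
        difficulty=b,
        omission_prob=0.015,
        group_proportions={"f": 0.5, "m": 0.5},
        group_name="gender",
    )
    responses = simulate_responses(
        model, spec["n_persons"], seed=seed + 1, item_ids=item_ids
    )
    return {
        "features": feats,
        "spaces": spaces,
        "assignment": assignment,
        "blueprint": design,
        "responses": responses,
        "generating_difficulty": b,
        "preset": preset,
        "seed": seed,
    }
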