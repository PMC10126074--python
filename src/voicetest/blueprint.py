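"""Assembly and validation of the three-phase 3AFC test structure.

The test has a learning phase (familiarization trials alternating with
immediate 3AFC recognition trials, run twice), a passive repetition phase,
and a testing phase of 3AFC trials crossing acoustic similarity (high,
medium, low) with presentation duration (250 ms, 750 ms, full length) for
every learned target.

Constraints carried by the blueprint:

* sentence contents of familiarization trials are identical across targets
  within a cycle; immediate-trial sentences are fresh per trial, with new
  ones in cycle 2 — so each target accrues exactly five distinct sentences
  during learning (3 familiarization + 2 immediate);
* no sentence appears in both the learning and the testing phase, and no
  (speaker, sentence) pair repeats between phases;
* testing-phase foils never appeared during learning;
* target positions within 3AFC trials are balanced (per-position counts
  within +-1 of uniform per phase);
* the testing-phase order is randomized once and then fixed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .triplets import SIMILARITY_LEVELS, TripletAssignment

__all__ = [
    "FamiliarizationTrial",
    "RecognitionTrial",
    "TestBlueprint",
    "ValidationReport",
    "BlueprintAssemblyError",
    "assemble_learning_phase",
    "assemble_test_phase",
    "assemble_blueprint",
    "validate_blueprint",
    "count_stimuli",
    "subset_blueprint",
    "truncate_stimulus",
]

DURATIONS = (250, 750, "full")
RESPONSE_WINDOW_MS = 4000

#: Practice/dummy stimulus counts preceding each response phase; carried as
#: metadata only and excluded from all analyses.
PRACTICE_STIMULI = {"learning": 12, "testing": 6}


class BlueprintAssemblyError(RuntimeError):
    pass


@dataclass(frozen=True)
class FamiliarizationTrial:
    speaker_id: str
    sentence_ids: tuple[str, str, str]
    cycle: int

    def __post_init__(self) -> None:
        if len(set(self.sentence_ids)) != 3:
            raise ValueError("familiarization needs 3 distinct sentences")


@dataclass(frozen=True)
class RecognitionTrial:
    phase: str  # "immediate" or "test"
    voices: tuple[str, str, str]
    target_position: int  # 1..3
    sentence_id: str
    duration: int | str  # ms, or "full"
    similarity: str
    item_id: str
    order_index: int
    cycle: int | None = None
    response_window_ms: int = RESPONSE_WINDOW_MS

    def __post_init__(self) -> None:
        if self.phase not in ("immediate", "test"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if not 1 <= self.target_position <= 3:
            raise ValueError("target_position must be 1..3")
        if len(set(self.voices)) != 3:
            raise ValueError("3AFC trial needs 3 distinct voices")
        if self.duration != "full" and self.duration not in (250, 750):
            raise ValueError(f"unsupported duration {self.duration!r}")

    @property
    def target_id(self) -> str:
        return self.voices[self.target_position - 1]

    @property
    def foil_ids(self) -> tuple[str, str]:
        return tuple(v for i, v in enumerate(self.voices) if i != self.target_position - 1)  # type: ignore[return-value]


@dataclass
class TestBlueprint:
    learning_trials: list  # FamiliarizationTrial | RecognitionTrial, in order
    repetition_playlist: list[tuple[str, str]]  # (speaker_id, sentence_id)
    test_trials: list[RecognitionTrial]
    sentence_pool: tuple[str, ...]
    seed: int
    practice: dict = field(default_factory=lambda: dict(PRACTICE_STIMULI))
    expect_full_crossing: bool = True

    @property
    def targets(self) -> list[str]:
        seen: list[str] = []
        for t in self.learning_trials:
            if isinstance(t, FamiliarizationTrial) and t.speaker_id not in seen:
                seen.append(t.speaker_id)
        return seen

    def learning_sentences(self) -> set[str]:
        out: set[str] = set()
        for t in self.learning_trials:
            if isinstance(t, FamiliarizationTrial):
                out |= set(t.sentence_ids)
            else:
                out.add(t.sentence_id)
        return out

    def learning_voices(self) -> set[str]:
        out: set[str] = set()
        for t in self.learning_trials:
            if isinstance(t, FamiliarizationTrial):
                out.add(t.speaker_id)
            else:
                out |= set(t.voices)
        return out

    def to_dict(self) -> dict:
        def trial_dict(t):
            d = asdict(t)
            d["kind"] = type(t).__name__
            return d

        return {
            "seed": self.seed,
            "sentence_pool": list(self.sentence_pool),
            "practice": self.practice,
            "expect_full_crossing": self.expect_full_crossing,
            "learning_trials": [trial_dict(t) for t in self.learning_trials],
            "repetition_playlist": [list(x) for x in self.repetition_playlist],
            "test_trials": [trial_dict(t) for t in self.test_trials],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "TestBlueprint":
        def parse(td: dict):
            td = dict(td)
            kind = td.pop("kind")
            if kind == "FamiliarizationTrial":
                td["sentence_ids"] = tuple(td["sentence_ids"])
                return FamiliarizationTrial(**td)
            td["voices"] = tuple(td["voices"])
            return RecognitionTrial(**td)

        return cls(
            learning_trials=[parse(t) for t in d["learning_trials"]],
            repetition_playlist=[tuple(x) for x in d["repetition_playlist"]],
            test_trials=[parse(t) for t in d["test_trials"]],
            sentence_pool=tuple(d["sentence_pool"]),
            seed=d["seed"],
            practice=dict(d.get("practice", PRACTICE_STIMULI)),
            expect_full_crossing=d.get("expect_full_crossing", True),
        )


def default_sentence_pool(n: int = 50) -> tuple[str, ...]:
    """Abstract sentence ids standing in for the 50-pseudo-sentence pool."""
    return tuple(f"s{i:02d}" for i in range(1, n + 1))


def _balanced_positions(n: int, rng: np.random.Generator) -> list[int]:
    """n target positions in 1..3, each count within +-1 of n/3, shuffled."""
    base = [1, 2, 3] * (n // 3)
    extra = list(rng.permutation([1, 2, 3])[: n % 3])
    positions = base + [int(p) for p in extra]
    rng.shuffle(positions)
    return positions


def _order_voices(target: str, foils: Sequence[str], position: int, rng: np.random.Generator):
    foils = list(foils)
    rng.shuffle(foils)
    voices = foils[:]
    voices.insert(position - 1, target)
    return tuple(voices)


def assemble_learning_phase(
    assignment: TripletAssignment,
    sentence_pool: Sequence[str],
    seed: int,
):
    """Build the alternating familiarization / immediate-recognition trials.

    Two cycles over a randomized target order.  Cycle-2 familiarization
    reuses the cycle-1 sentences (sentence contents of learning trials are
    identical across speakers); cycle-2 immediate trials use new sentences.
    Also draws the repetition playlist: per target one familiarization and
    one immediate sentence.

    Returns ``(learning_trials, repetition_playlist, used_sentences)``.
    """
    rng = np.random.default_rng(seed)
    targets = list(assignment.targets)
    n_needed = 3 + 2 * len(targets)
    if len(sentence_pool) < n_needed:
        raise BlueprintAssemblyError(
            f"sentence pool exhausted: learning needs {n_needed}, pool has {len(sentence_pool)}"
        )
    pool = list(sentence_pool)
    draw_order = list(rng.permutation(len(pool)))
    cursor = iter(draw_order)

    def draw(k: int) -> list[str]:
        return [pool[next(cursor)] for _ in range(k)]

    fam_sentences = tuple(draw(3))
    target_order = [targets[i] for i in rng.permutation(len(targets))]
    immediate_positions = _balanced_positions(2 * len(targets), rng)

    trials: list = []
    immediate_sentences: dict[str, list[str]] = {t: [] for t in targets}
    pos_idx = 0
    order_index = 0
    for cycle in (1, 2):
        for target in target_order:
            trials.append(FamiliarizationTrial(target, fam_sentences, cycle))
            sentence = draw(1)[0]
            immediate_sentences[target].append(sentence)
            position = immediate_positions[pos_idx]
            pos_idx += 1
            foils = sorted(assignment.learning[target].foil_ids)
            trials.append(
                RecognitionTrial(
                    phase="immediate",
                    voices=_order_voices(target, foils, position, rng),
                    target_position=position,
                    sentence_id=sentence,
                    duration="full",
                    similarity="medium",
                    item_id=f"imm|{target}|c{cycle}",
                    order_index=order_index,
                    cycle=cycle,
                )
            )
            order_index += 1

    repetition = []
    for target in target_order:
        fam_pick = fam_sentences[int(rng.integers(3))]
        imm_pick = immediate_sentences[target][int(rng.integers(2))]
        repetition.extend([(target, fam_pick), (target, imm_pick)])

    used = set(fam_sentences) | {s for ss in immediate_sentences.values() for s in ss}
    return trials, repetition, used


def assemble_test_phase(
    assignment: TripletAssignment,
    sentence_pool: Sequence[str],
    used_sentences: set[str],
    seed: int,
    durations: Sequence = DURATIONS,
):
    """Build the testing-phase trials: full similarity x duration factorial.

    Each target gets one fresh sentence per similarity level (never heard
    during learning), presented at every duration with that level's triplet.
    The trial order is randomized once and then fixed; target positions are
    balanced across the phase.
    """
    rng = np.random.default_rng(seed + 1)
    targets = list(assignment.targets)
    available = [s for s in sentence_pool if s not in used_sentences]
    n_needed = len(targets) * len(SIMILARITY_LEVELS)
    if len(available) < n_needed:
        raise BlueprintAssemblyError(
            f"insufficient unused sentences for testing: need {n_needed}, have {len(available)}"
        )
    picks = [available[i] for i in rng.permutation(len(available))[:n_needed]]
    sentence_for: dict[tuple[str, str], str] = {}
    k = 0
    for target in targets:
        for lvl in SIMILARITY_LEVELS:
            sentence_for[(target, lvl)] = picks[k]
            k += 1

    cells = [
        (target, lvl, dur)
        for target in targets
        for lvl in SIMILARITY_LEVELS
        for dur in durations
    ]
    order = rng.permutation(len(cells))
    positions = _balanced_positions(len(cells), rng)
    trials = []
    for order_index, (cell_idx, position) in enumerate(zip(order, positions)):
        target, lvl, dur = cells[cell_idx]
        foils = sorted(assignment.test[target][lvl].foil_ids)
        trials.append(
            RecognitionTrial(
                phase="test",
                voices=_order_voices(target, foils, position, rng),
                target_position=position,
                sentence_id=sentence_for[(target, lvl)],
                duration=dur,
                similarity=lvl,
                item_id=f"{target}|{lvl}|{dur}",
                order_index=order_index,
            )
        )
    return trials


def assemble_blueprint(
    assignment: TripletAssignment,
    sentence_pool: Sequence[str] | None = None,
    seed: int = 0,
) -> TestBlueprint:
    """Assemble the complete three-phase blueprint (deterministic per seed)."""
    if sentence_pool is None:
        sentence_pool = default_sentence_pool()
    learning, repetition, used = assemble_learning_phase(assignment, sentence_pool, seed)
    test = assemble_test_phase(assignment, sentence_pool, used, seed)
    return TestBlueprint(
        learning_trials=learning,
        repetition_playlist=repetition,
        test_trials=test,
        sentence_pool=tuple(sentence_pool),
        seed=seed,
    )


@dataclass
class ValidationReport:
    violations: list[tuple[str, str]] = field(default_factory=list)

    def add(self, code: str, message: str) -> None:
        self.violations.append((code, message))

    @property
    def valid(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        if self.valid:
            return "blueprint valid (0 violations)"
        lines = [f"{code}: {msg}" for code, msg in self.violations]
        return "\n".join([f"blueprint INVALID ({len(lines)} violations)"] + lines)


def _position_balance_ok(trials: list[RecognitionTrial]) -> bool:
    if not trials:
        return True
    counts = np.bincount([t.target_position for t in trials], minlength=4)[1:4]
    return counts.max() - counts.min() <= 1


def validate_blueprint(blueprint: TestBlueprint) -> ValidationReport:
    """Independent checker for every structural constraint.

    Reports violations instead of raising; an empty violation list means
    the blueprint is valid.
    """
    report = ValidationReport()
    learning_sentences = blueprint.learning_sentences()
    learning_voices = blueprint.learning_voices()
    targets = set(blueprint.targets)

    if not blueprint.test_trials:
        report.add("no_test_trials", "test phase is empty")

    # learning-phase structure
    fam_by_cycle: dict[int, set[tuple[str, ...]]] = {}
    sentences_per_target: dict[str, set[str]] = {t: set() for t in targets}
    for t in blueprint.learning_trials:
        if isinstance(t, FamiliarizationTrial):
            fam_by_cycle.setdefault(t.cycle, set()).add(tuple(sorted(t.sentence_ids)))
            sentences_per_target.setdefault(t.speaker_id, set()).update(t.sentence_ids)
        else:
            if t.similarity != "medium":
                report.add("immediate_similarity", f"{t.item_id}: immediate trial not medium similarity")
            if t.duration != "full":
                report.add("immediate_duration", f"{t.item_id}: immediate trial not full duration")
            if t.target_id not in targets:
                report.add("unknown_target", f"{t.item_id}: target {t.target_id} never familiarized")
            sentences_per_target.setdefault(t.target_id, set()).add(t.sentence_id)
    for cycle, sets in fam_by_cycle.items():
        if len(sets) > 1:
            report.add(
                "familiarization_sentences",
                f"cycle {cycle}: familiarization sentence sets differ across speakers",
            )
    for target in sorted(targets):
        n = len(sentences_per_target.get(target, set()))
        if n != 5:
            report.add(
                "learning_sentence_count",
                f"target {target}: {n} distinct learning sentences (expected 5)",
            )

    immediate = [t for t in blueprint.learning_trials if isinstance(t, RecognitionTrial)]
    if not _position_balance_ok(immediate):
        report.add("position_balance", "immediate-trial target positions not within +-1 of uniform")
    # position balance is a design-time guarantee of the full assembly; an
    # item-selected subset inherits whatever positions its trials carry
    if blueprint.expect_full_crossing and not _position_balance_ok(blueprint.test_trials):
        report.add("position_balance", "test-trial target positions not within +-1 of uniform")

    seen_pairs = {
        (t.speaker_id, s)
        for t in blueprint.learning_trials
        if isinstance(t, FamiliarizationTrial)
        for s in t.sentence_ids
    } | {(v, t.sentence_id) for t in immediate for v in t.voices}

    crossing: dict[str, list[tuple[str, object]]] = {t: [] for t in targets}
    for t in blueprint.test_trials:
        if t.sentence_id in learning_sentences:
            report.add("sentence_reuse", f"{t.item_id}: sentence {t.sentence_id} already used in learning")
        for foil in t.foil_ids:
            if foil in learning_voices:
                report.add("foil_novelty", f"{t.item_id}: foil {foil} appeared in the learning phase")
        if sum(v in targets for v in t.voices) != 1:
            report.add("target_count", f"{t.item_id}: trial must contain exactly one target")
        for v in t.voices:
            if (v, t.sentence_id) in seen_pairs:
                report.add("pair_repeat", f"{t.item_id}: (speaker {v}, sentence {t.sentence_id}) repeats from learning")
        if t.target_id in crossing:
            crossing[t.target_id].append((t.similarity, t.duration))

    if blueprint.expect_full_crossing:
        full = sorted((lvl, str(d)) for lvl in SIMILARITY_LEVELS for d in DURATIONS)
        for target in sorted(targets):
            got = sorted((lvl, str(d)) for lvl, d in crossing.get(target, []))
            if got != full:
                report.add("factor_crossing", f"target {target}: test cells do not form the 3x3 factorial")

    # repetition playlist: 2 sentences per target, one familiarization + one immediate
    fam_set = set().union(*fam_by_cycle.get(1, [frozenset()])) if fam_by_cycle else set()
    imm_by_target: dict[str, set[str]] = {}
    for t in immediate:
        imm_by_target.setdefault(t.target_id, set()).add(t.sentence_id)
    rep_by_target: dict[str, list[str]] = {}
    for speaker, sentence in blueprint.repetition_playlist:
        rep_by_target.setdefault(speaker, []).append(sentence)
    for target in sorted(targets):
        rep = rep_by_target.get(target, [])
        if len(rep) != 2:
            report.add("repetition_count", f"target {target}: {len(rep)} repetition sentences (expected 2)")
            continue
        if not (set(rep) & set(fam_set)) or not (set(rep) & imm_by_target.get(target, set())):
            report.add(
                "repetition_source",
                f"target {target}: repetition must take one familiarization and one immediate sentence",
            )

    return report


def count_stimuli(blueprint: TestBlueprint) -> dict:
    """Count distinct (speaker, sentence, duration) presentations per phase.

    Every voice heard in a trial is one stimulus; repeated presentations of
    the same speaker-sentence-duration combination (e.g. cycle-2
    familiarization reusing cycle-1 sentences) count once.  Practice/dummy
    stimuli are reported separately and excluded from the experimental total.
    """
    learning: set[tuple] = set()
    for t in blueprint.learning_trials:
        if isinstance(t, FamiliarizationTrial):
            learning.update((t.speaker_id, s, "full") for s in t.sentence_ids)
        else:
            learning.update((v, t.sentence_id, t.duration) for v in t.voices)
    testing: set[tuple] = set()
    for t in blueprint.test_trials:
        testing.update((v, t.sentence_id, t.duration) for v in t.voices)
    return {
        "learning_stimuli": len(learning),
        "testing_stimuli": len(testing),
        "total_experimental": len(learning) + len(testing),
        "learning_trials": len(blueprint.learning_trials),
        "immediate_trials": sum(
            isinstance(t, RecognitionTrial) for t in blueprint.learning_trials
        ),
        "test_trials": len(blueprint.test_trials),
        "repetition_presentations": len(blueprint.repetition_playlist),
        "practice_stimuli": dict(blueprint.practice),
    }


def subset_blueprint(blueprint: TestBlueprint, retained_item_ids: Sequence[str]) -> TestBlueprint:
    """Keep only the given test items, preserving the fixed original order.

    Learning and repetition phases are untouched.  Used after item
    selection to derive the shortened test versions.
    """
    known = {t.item_id for t in blueprint.test_trials}
    unknown = set(retained_item_ids) - known
    if unknown:
        raise KeyError(f"unknown test item ids: {sorted(unknown)}")
    retained = set(retained_item_ids)
    kept = [t for t in blueprint.test_trials if t.item_id in retained]
    return TestBlueprint(
        learning_trials=list(blueprint.learning_trials),
        repetition_playlist=list(blueprint.repetition_playlist),
        test_trials=kept,
        sentence_pool=blueprint.sentence_pool,
        seed=blueprint.seed,
        practice=dict(blueprint.practice),
        expect_full_crossing=len(kept) == len(blueprint.test_trials)
        and blueprint.expect_full_crossing,
    )


def truncate_stimulus(
    waveform: np.ndarray,
    rate: int,
    duration,
    onset_sample: int = 0,
    ramp_ms: float = 10.0,
) -> np.ndarray:
    """Cut a stimulus to 250/750 ms from voice onset, or return it whole.

    A raised-cosine offset ramp (default 10 ms) avoids clicks at the cut;
    ``ramp_ms=0`` gives a hard cut.  ``duration="full"`` returns the input
    unchanged.
    """
    x = np.asarray(waveform, dtype=float)
    if duration == "full":
        return x.copy()
    if not 0 <= onset_sample < len(x):
        raise ValueError("onset outside waveform")
    n = int(round(duration * rate / 1000.0))
    if onset_sample + n > len(x):
        raise ValueError(
            f"{duration} ms from onset exceeds the {1000 * (len(x) - onset_sample) / rate:.0f} ms remaining"
        )
    seg = x[onset_sample : onset_sample + n].copy()
    n_ramp = min(int(round(ramp_ms * rate / 1000.0)), len(seg))
    if n_ramp > 0:
        ramp = 0.5 * (1 + np.cos(np.linspace(0, np.pi, n_ramp)))
        seg[-n_ramp:] *= ramp
    return seg
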