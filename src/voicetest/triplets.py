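"""Equilateral voice-triplet search, similarity stratification, and assignment.

A 3AFC trial presents one target and two foil voices.  Within a trial no
voice should stand out acoustically, so candidate triplets are triples of
same-gender voices whose pairwise distances in the standardized voice
space are (approximately) equal — equilateral triangles.  Triangle size
stratifies trials into similarity levels: small triangles mean acoustically
close, hence highly similar and hard; large triangles mean low similarity
and easy.

Learning targets are the voices that participate in most triplets (to
maximize foil combinations); each target then receives one triplet per
similarity level for the testing phase and one additional medium triplet
for the immediate recognition trials of the learning phase, under the
global constraint that every foil belongs to exactly one assigned triplet.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .features import VoiceSpace

__all__ = [
    "Triplet",
    "TripletAssignment",
    "InfeasibleAssignmentError",
    "SIMILARITY_LEVELS",
    "pairwise_distances",
    "find_equilateral_triplets",
    "stratify_triplets",
    "select_targets",
    "assign_triplets",
    "validate_assignment",
]

SIMILARITY_LEVELS = ("high", "medium", "low")

#: Default ceiling on (max side - min side) / mean side for a triangle to
#: count as equilateral.  Configurable; chosen to yield non-empty similarity
#: strata on realistic simulated voice spaces.
DEFAULT_TOLERANCE = 0.10


class InfeasibleAssignmentError(RuntimeError):
    """No foil-disjoint triplet assignment exists for the given candidates."""


@dataclass(frozen=True)
class Triplet:
    target_id: str
    foil_ids: frozenset[str]
    side_lengths: tuple[float, float, float]
    size: float
    max_relative_deviation: float
    similarity: str | None = None

    def __post_init__(self) -> None:
        members = {self.target_id} | self.foil_ids
        if len(members) != 3:
            raise ValueError("triplet needs 3 distinct members")
        if any(s <= 0 for s in self.side_lengths):
            raise ValueError("side lengths must be positive")
        if self.similarity is not None and self.similarity not in SIMILARITY_LEVELS:
            raise ValueError(f"unknown similarity {self.similarity!r}")

    @property
    def member_ids(self) -> frozenset[str]:
        return frozenset({self.target_id}) | self.foil_ids

    def with_target(self, target_id: str) -> "Triplet":
        """Re-root the triplet on one of its members as the target."""
        if target_id not in self.member_ids:
            raise ValueError(f"{target_id} not in triplet")
        return Triplet(
            target_id,
            self.member_ids - {target_id},
            self.side_lengths,
            self.size,
            self.max_relative_deviation,
            self.similarity,
        )

    def with_similarity(self, similarity: str) -> "Triplet":
        return Triplet(
            self.target_id,
            self.foil_ids,
            self.side_lengths,
            self.size,
            self.max_relative_deviation,
            similarity,
        )

    def to_dict(self) -> dict:
        return {
            "target_id": self.target_id,
            "foil_ids": sorted(self.foil_ids),
            "side_lengths": list(self.side_lengths),
            "size": self.size,
            "max_relative_deviation": self.max_relative_deviation,
            "similarity": self.similarity,
        }


def pairwise_distances(space: VoiceSpace) -> np.ndarray:
    """Symmetric Euclidean distance matrix over the space's speakers."""
    return squareform(pdist(space.coords, metric="euclidean"))


def find_equilateral_triplets(
    space: VoiceSpace, tolerance: float = DEFAULT_TOLERANCE
) -> list[Triplet]:
    """Exhaustively scan all C(n, 3) triples for near-equilateral triangles.

    A triple qualifies when its equilaterality defect
    ``(max side - min side) / mean side`` is at most ``tolerance``.
    Degenerate (zero-area) triples — collinear or coincident points — never
    qualify regardless of tolerance.
    The rooting of the returned :class:`Triplet` on the lexicographically
    smallest member is provisional; targets are chosen later.  Output order
    is deterministic (sorted member ids).
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    dist = pairwise_distances(space)
    ids = space.speaker_ids
    order = sorted(range(len(ids)), key=lambda i: ids[i])
    out: list[Triplet] = []
    for i, j, k in itertools.combinations(order, 3):
        sides = (dist[i, j], dist[i, k], dist[j, k])
        mean_side = sum(sides) / 3.0
        longest = max(sides)
        # degenerate (zero-area) triangles never qualify
        if mean_side <= 0 or longest >= (sum(sides) - longest) * (1 - 1e-12):
            continue
        defect = (longest - min(sides)) / mean_side
        if defect <= tolerance:
            out.append(
                Triplet(
                    target_id=ids[i],
                    foil_ids=frozenset({ids[j], ids[k]}),
                    side_lengths=sides,
                    size=mean_side,
                    max_relative_deviation=defect,
                )
            )
    return out


def stratify_triplets(
    triplets: list[Triplet], boundaries: tuple[float, float] | None = None
) -> list[Triplet]:
    """Label triplets high/medium/low similarity by triangle size.

    ``boundaries = (b1, b2)``: size < b1 → high similarity (small triangle),
    b1 <= size < b2 → medium, size >= b2 → low.  By default the boundaries
    are the empirical tertiles of the qualifying triplet sizes.
    """
    if not triplets:
        return []
    if boundaries is None:
        sizes = np.array([t.size for t in triplets])
        boundaries = tuple(np.quantile(sizes, [1 / 3, 2 / 3]))  # type: ignore[assignment]
    b1, b2 = boundaries  # type: ignore[misc]
    if not b1 < b2:
        raise ValueError(f"boundaries must be strictly increasing, got {boundaries}")
    out = []
    for t in triplets:
        label = "high" if t.size < b1 else ("medium" if t.size < b2 else "low")
        out.append(t.with_similarity(label))
    return out


def select_targets(triplets: list[Triplet], n_per_stratum: int = 4) -> list[str]:
    """Pick the voices that are members of the most triplets.

    Membership counts all appearances (as target or foil).  Ties break
    toward the lexicographically smallest speaker id, making selection
    deterministic.
    """
    counts: dict[str, int] = {}
    for t in triplets:
        for sid in t.member_ids:
            counts[sid] = counts.get(sid, 0) + 1
    if len(counts) < n_per_stratum:
        raise ValueError(
            f"only {len(counts)} candidate voices for {n_per_stratum} targets"
        )
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [sid for sid, _ in ranked[:n_per_stratum]]


@dataclass
class TripletAssignment:
    """Per-target triplets for one or more gender strata.

    ``test[target]`` maps similarity level → Triplet; ``learning[target]``
    is the extra medium-similarity triplet for immediate recognition trials.
    Across the whole assignment every foil id appears in exactly one triplet.
    """

    test: dict[str, dict[str, Triplet]] = field(default_factory=dict)
    learning: dict[str, Triplet] = field(default_factory=dict)

    @property
    def targets(self) -> list[str]:
        return list(self.test.keys())

    def all_triplets(self) -> list[Triplet]:
        out = []
        for target in self.test:
            out.extend(self.test[target][lvl] for lvl in SIMILARITY_LEVELS)
            out.append(self.learning[target])
        return out

    def learning_foils(self) -> set[str]:
        return set().union(*(t.foil_ids for t in self.learning.values())) if self.learning else set()

    def test_foils(self) -> set[str]:
        out: set[str] = set()
        for target in self.test:
            for lvl in SIMILARITY_LEVELS:
                out |= self.test[target][lvl].foil_ids
        return out

    def merge(self, other: "TripletAssignment") -> "TripletAssignment":
        """Combine assignments from disjoint strata."""
        if set(self.test) & set(other.test):
            raise ValueError("overlapping targets")
        merged = TripletAssignment(dict(self.test), dict(self.learning))
        merged.test.update(other.test)
        merged.learning.update(other.learning)
        validate_assignment(merged)
        return merged

    def to_dict(self) -> dict:
        return {
            "targets": self.targets,
            "test": {
                tgt: {lvl: t.to_dict() for lvl, t in by_level.items()}
                for tgt, by_level in self.test.items()
            },
            "learning": {tgt: t.to_dict() for tgt, t in self.learning.items()},
        }


def validate_assignment(assignment: TripletAssignment) -> None:
    """Independent check of foil-disjointness and level-completeness."""
    seen_foils: set[str] = set()
    targets = set(assignment.targets)
    for target, by_level in assignment.test.items():
        if set(by_level) != set(SIMILARITY_LEVELS):
            raise InfeasibleAssignmentError(
                f"target {target} missing similarity levels {set(SIMILARITY_LEVELS) - set(by_level)}"
            )
        if target not in assignment.learning:
            raise InfeasibleAssignmentError(f"target {target} has no learning triplet")
        slots = [by_level[lvl] for lvl in SIMILARITY_LEVELS] + [assignment.learning[target]]
        if assignment.learning[target].similarity != "medium":
            raise InfeasibleAssignmentError(
                f"learning triplet for {target} must have medium similarity"
            )
        for trip in slots:
            if trip.target_id != target:
                raise InfeasibleAssignmentError(f"triplet not rooted on {target}")
            for foil in trip.foil_ids:
                if foil in seen_foils or foil in targets:
                    raise InfeasibleAssignmentError(
                        f"foil {foil} reused across triplets"
                    )
            seen_foils |= trip.foil_ids


def assign_triplets(
    targets: list[str], triplets: list[Triplet]
) -> TripletAssignment:
    """Backtracking search for a foil-disjoint assignment.

    For each target the search fills four slots — (high, medium, low) test
    triplets plus a medium learning triplet — drawing from the stratified
    candidate list, never reusing a foil and never using another target as
    a foil.  Among feasible candidates, triplets with smaller equilaterality
    defect are preferred (then lexicographic foils), so the result is
    deterministic given the input order.

    Raises
    ------
    InfeasibleAssignmentError
        Naming the first target/level with no remaining candidate.
    """
    target_set = set(targets)
    # candidates[target][level], re-rooted on the target, best defect first
    candidates: dict[str, dict[str, list[Triplet]]] = {
        t: {lvl: [] for lvl in SIMILARITY_LEVELS} for t in targets
    }
    for trip in triplets:
        if trip.similarity is None:
            raise ValueError("triplets must be stratified before assignment")
        for member in trip.member_ids:
            if member in target_set and not (trip.member_ids - {member}) & target_set:
                candidates[member][trip.similarity].append(trip.with_target(member))
    for by_level in candidates.values():
        for lvl in SIMILARITY_LEVELS:
            by_level[lvl].sort(
                key=lambda t: (t.max_relative_deviation, tuple(sorted(t.foil_ids)))
            )

    # slot list: per target the three test levels then the learning (medium)
    slots: list[tuple[str, str, bool]] = []
    for target in targets:
        for lvl in SIMILARITY_LEVELS:
            slots.append((target, lvl, False))
        slots.append((target, "medium", True))

    chosen: list[Triplet] = []
    used_foils: set[str] = set()

    def backtrack(i: int) -> bool:
        if i == len(slots):
            return True
        target, lvl, _is_learning = slots[i]
        for cand in candidates[target][lvl]:
            if cand.foil_ids & used_foils:
                continue
            if any(cand is c or (c.target_id == target and c.foil_ids == cand.foil_ids) for c in chosen):
                continue
            chosen.append(cand)
            used_foils.update(cand.foil_ids)
            if backtrack(i + 1):
                return True
            chosen.pop()
            used_foils.difference_update(cand.foil_ids)
        return False

    if not backtrack(0):
        # re-run shallowly to name the first unsatisfiable slot
        for target, lvl, is_learning in slots:
            if not candidates[target][lvl]:
                kind = "learning" if is_learning else "test"
                raise InfeasibleAssignmentError(
                    f"no candidate {lvl}-similarity triplet for target {target} ({kind} slot)"
                )
        raise InfeasibleAssignmentError(
            "no foil-disjoint assignment exists for the given candidate triplets"
        )

    assignment = TripletAssignment()
    idx = 0
    for target in targets:
        by_level = {}
        for lvl in SIMILARITY_LEVELS:
            by_level[lvl] = chosen[idx]
            idx += 1
        assignment.test[target] = by_level
        assignment.learning[target] = chosen[idx]
        idx += 1
    validate_assignment(assignment)
    return assignment
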