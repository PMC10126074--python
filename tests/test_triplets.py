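import itertools
import math

import numpy as np
import pytest

from voicetest.features import VoiceSpace
from voicetest.triplets import (
    InfeasibleAssignmentError,
    Triplet,
    TripletAssignment,
    assign_triplets,
    find_equilateral_triplets,
    pairwise_distances,
    select_targets,
    stratify_triplets,
    validate_assignment,
)


def space_from(coords, stratum="f", prefix="v"):
    coords = np.asarray(coords, dtype=float)
    ids = tuple(f"{prefix}{i:02d}" for i in range(len(coords)))
    return VoiceSpace(stratum, ids, coords)


def random_space(n, seed):
    rng = np.random.default_rng(seed)
    return space_from(rng.normal(size=(n, 3)))


class TestPairwiseDistances:
    def test_3_4_5(self):
        d = pairwise_distances(space_from([(0, 0, 0), (3, 4, 0), (0, 0, 1)]))
        assert d[0, 1] == pytest.approx(5.0)

    def test_matches_elementwise_recompute(self):
        space = random_space(6, seed=0)
        d = pairwise_distances(space)
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)
        for i, j in itertools.combinations(range(6), 2):
            assert d[i, j] == pytest.approx(math.dist(space.coords[i], space.coords[j]))


class TestFindEquilateral:
    def test_exact_equilateral(self):
        space = space_from([(0, 0, 0), (1, 0, 0), (0.5, math.sqrt(3) / 2, 0)])
        out = find_equilateral_triplets(space, tolerance=0.01)
        assert len(out) == 1
        assert out[0].max_relative_deviation == pytest.approx(0.0, abs=1e-12)
        assert out[0].size == pytest.approx(1.0)

    def test_collinear_points_excluded(self):
        space = space_from([(0, 0, 0), (1, 0, 0), (2, 0, 0)])
        assert find_equilateral_triplets(space, tolerance=0.9) == []

    def test_matches_bruteforce_enumeration(self):
        space = random_space(10, seed=1)
        tolerance = 0.1
        found = {
            frozenset(t.member_ids): t for t in find_equilateral_triplets(space, tolerance)
        }
        expected = {}
        for i, j, k in itertools.combinations(range(10), 3):
            sides = sorted(
                [
                    math.dist(space.coords[i], space.coords[j]),
                    math.dist(space.coords[i], space.coords[k]),
                    math.dist(space.coords[j], space.coords[k]),
                ]
            )
            defect = (sides[2] - sides[0]) / (sum(sides) / 3)
            if defect <= tolerance:
                key = frozenset({space.speaker_ids[i], space.speaker_ids[j], space.speaker_ids[k]})
                expected[key] = (sum(sides) / 3, defect)
        assert set(found) == set(expected)
        for key, (size, defect) in expected.items():
            assert found[key].size == pytest.approx(size)
            assert found[key].max_relative_deviation == pytest.approx(defect)

    def test_speaker_order_invariance(self):
        space = random_space(8, seed=2)
        perm = np.random.default_rng(3).permutation(8)
        permuted = VoiceSpace(
            space.stratum,
            tuple(space.speaker_ids[p] for p in perm),
            space.coords[perm],
        )
        a = {frozenset(t.member_ids) for t in find_equilateral_triplets(space, 0.2)}
        b = {frozenset(t.member_ids) for t in find_equilateral_triplets(permuted, 0.2)}
        assert a == b

    def test_tolerance_monotonicity(self):
        space = random_space(12, seed=4)
        small = {frozenset(t.member_ids) for t in find_equilateral_triplets(space, 0.05)}
        for tol in (0.1, 0.2, 0.4):
            bigger = {frozenset(t.member_ids) for t in find_equilateral_triplets(space, tol)}
            assert small <= bigger
            small = bigger


def make_triplet(target, foils, size, similarity=None, defect=0.0):
    return Triplet(
        target_id=target,
        foil_ids=frozenset(foils),
        side_lengths=(size, size, size),
        size=size,
        max_relative_deviation=defect,
        similarity=similarity,
    )


class TestStratify:
    def test_direct_rule(self):
        trips = [make_triplet("a", ("b", "c"), s) for s in (0.5, 1.0, 2.0)]
        labelled = stratify_triplets(trips, boundaries=(0.8, 1.5))
        assert [t.similarity for t in labelled] == ["high", "medium", "low"]

    def test_default_tertiles_nonempty(self):
        rng = np.random.default_rng(5)
        trips = [
            make_triplet("a", (f"b{i}", f"c{i}"), s)
            for i, s in enumerate(rng.uniform(0.2, 3.0, 30))
        ]
        labels = {t.similarity for t in stratify_triplets(trips)}
        assert labels == {"high", "medium", "low"}

    def test_single_class(self):
        trips = [make_triplet("a", (f"b{i}", f"c{i}"), 1.0) for i in range(3)]
        labelled = stratify_triplets(trips, boundaries=(0.5, 2.0))
        assert all(t.similarity == "medium" for t in labelled)

    def test_bad_boundaries(self):
        with pytest.raises(ValueError):
            stratify_triplets([make_triplet("a", ("b", "c"), 1.0)], boundaries=(2.0, 1.0))


class TestSelectTargets:
    def test_dominant_voice_selected_first(self):
        trips = [make_triplet("z9", (f"a{i}", f"b{i}"), 1.0) for i in range(4)]
        assert select_targets(trips, 1) == ["z9"]

    def test_counting_oracle(self):
        rng = np.random.default_rng(6)
        ids = [f"v{i}" for i in range(12)]
        trips = []
        for _ in range(40):
            a, b, c = rng.choice(ids, 3, replace=False)
            trips.append(make_triplet(a, (b, c), 1.0))
        counts = {}
        for t in trips:
            for m in t.member_ids:
                counts[m] = counts.get(m, 0) + 1
        picked = select_targets(trips, 4)
        ranked = sorted(counts, key=lambda s: (-counts[s], s))
        assert picked == ranked[:4]

    def test_lexicographic_tiebreak(self):
        trips = [make_triplet("b1", ("x1", "x2"), 1.0), make_triplet("a1", ("y1", "y2"), 1.0)]
        assert select_targets(trips, 1) == ["a1"]

    def test_too_few_candidates(self):
        with pytest.raises(ValueError):
            select_targets([make_triplet("a", ("b", "c"), 1.0)], 5)


class TestAssign:
    def _disjoint_instance(self):
        trips = []
        for t, target in enumerate(("tA", "tB")):
            for s, lvl in enumerate(("high", "medium", "low")):
                trips.append(
                    make_triplet(target, (f"f{t}{s}a", f"f{t}{s}b"), 0.5 + s, lvl)
                )
            trips.append(make_triplet(target, (f"f{t}La", f"f{t}Lb"), 1.0, "medium"))
        return trips

    def test_trivially_feasible(self):
        assignment = assign_triplets(["tA", "tB"], self._disjoint_instance())
        validate_assignment(assignment)  # raises on violation
        assert set(assignment.targets) == {"tA", "tB"}
        foils = [f for t in assignment.all_triplets() for f in t.foil_ids]
        assert len(foils) == len(set(foils)) == 16

    def test_forced_conflict_infeasible(self):
        # one target, single medium triplet shares a foil with the only high one
        trips = [
            make_triplet("t", ("x", "y"), 0.5, "high"),
            make_triplet("t", ("x", "z"), 1.0, "medium"),
            make_triplet("t", ("p", "q"), 2.0, "low"),
        ]
        with pytest.raises(InfeasibleAssignmentError):
            assign_triplets(["t"], trips)

    def test_matches_exhaustive_feasibility(self):
        # 2 targets, a pool of candidate triplets with overlapping foils:
        # backtracking verdict must agree with exhaustive slot enumeration
        rng = np.random.default_rng(7)
        foil_pool = [f"f{i}" for i in range(12)]
        for trial in range(30):
            trips = []
            for target in ("tA", "tB"):
                for lvl in ("high", "medium", "low"):
                    for _ in range(rng.integers(1, 3)):
                        pair = rng.choice(foil_pool, 2, replace=False)
                        trips.append(make_triplet(target, tuple(pair), 1.0, lvl))
            # exhaustive: every combination of one triplet per slot
            slots = []
            for target in ("tA", "tB"):
                for lvl in ("high", "medium", "low"):
                    slots.append([t for t in trips if t.target_id == target and t.similarity == lvl])
                slots.append([t for t in trips if t.target_id == target and t.similarity == "medium"])
            feasible = False
            for combo in itertools.product(*slots):
                foils = [f for t in combo for f in t.foil_ids]
                if len(foils) == len(set(foils)):
                    feasible = True
                    break
            try:
                assignment = assign_triplets(["tA", "tB"], trips)
                validate_assignment(assignment)
                got = True
            except InfeasibleAssignmentError:
                got = False
            assert got == feasible, f"trial {trial}: backtracking={got}, exhaustive={feasible}"

    def test_requires_stratified_triplets(self):
        with pytest.raises(ValueError, match="stratified"):
            assign_triplets(["t"], [make_triplet("t", ("a", "b"), 1.0)])

    def test_merge_rejects_shared_foils(self):
        a = assign_triplets(["tA", "tB"], self._disjoint_instance())
        with pytest.raises((InfeasibleAssignmentError, ValueError)):
            a.merge(a)

    def test_validate_catches_missing_level(self):
        assignment = TripletAssignment(
            test={"t": {"high": make_triplet("t", ("a", "b"), 1.0, "high")}},
            learning={"t": make_triplet("t", ("c", "d"), 1.0, "medium")},
        )
        with pytest.raises(InfeasibleAssignmentError, match="missing similarity"):
            validate_assignment(assignment)
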