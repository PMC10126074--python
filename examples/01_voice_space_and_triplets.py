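"""Build a standardized voice space and find equilateral voice triplets.

Simulates a gender-clustered speaker pool, embeds the female stratum in
the 3D (f0, formant dispersion, HNR) space, searches for near-equilateral
triples, and assigns foil-disjoint triplets to the most-connected targets.
"""

from voicetest import triplets as tp
from voicetest.features import build_voice_space
from voicetest.simulate import simulate_voice_features

features = simulate_voice_features(n_per_gender=40, seed=1)
space = build_voice_space(features, stratum="f")
print(f"voice space: {space.n_speakers} speakers, dims {space.standardization_params['dimensions']}")

found = tp.find_equilateral_triplets(space, tolerance=0.35)
labelled = tp.stratify_triplets(found)
by_level = {lvl: sum(t.similarity == lvl for t in labelled) for lvl in tp.SIMILARITY_LEVELS}
print(f"{len(found)} near-equilateral triplets; per similarity level: {by_level}")

targets = tp.select_targets(labelled, n_per_stratum=4)
assignment = tp.assign_triplets(targets, labelled)
print(f"targets (most triplet memberships): {targets}")
for target in targets:
    trip = assignment.test[target]["high"]
    print(
        f"  {target}: high-similarity triplet foils {sorted(trip.foil_ids)}, "
        f"side {trip.size:.2f} SD units, defect {trip.max_relative_deviation:.3f}"
    )
# Small triangles mean acoustically close voices -> hard trials; every foil
# above appears in exactly one triplet across the whole assignment.
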