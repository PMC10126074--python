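"""Assemble and validate the three-phase test blueprint.

Builds the full 72-trial design (8 targets x 3 similarity levels x 3
durations), checks every structural constraint, and prints the stimulus
accounting; then shortens it to a 26-item version.
"""

from voicetest import blueprint as bp
from voicetest.simulate import make_fixture

bundle = make_fixture("item-selection", seed=1)
design = bundle["blueprint"]

report = bp.validate_blueprint(design)
print(report)

counts = bp.count_stimuli(design)
print(f"learning stimuli: {counts['learning_stimuli']}")       # 8x5 targets + 16x2 foils = 72
print(f"testing stimuli:  {counts['testing_stimuli']}")        # 72 trials x 3 voices = 216
print(f"experimental total: {counts['total_experimental']}")   # 288
print(f"test trials: {counts['test_trials']} (positions balanced, order fixed once)")

retained = [t.item_id for t in design.test_trials[:26]]
short = bp.subset_blueprint(design, retained)
print(f"26-item version: {bp.count_stimuli(short)['total_experimental']} stimuli "
      f"({bp.count_stimuli(short)['testing_stimuli']} in testing)")
# Sentences never repeat between learning and testing, and no testing-phase
# foil was heard during learning, so the test measures voice learning proper.
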