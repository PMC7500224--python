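"""Generate the three paradigm designs and audit their constraints.

Prints the trial counts each paradigm guarantees (240 baseline + 20 per
critical condition for cognitive switching; 24 switch + 96 repeat per task
for affective switching; 109 trials with 10 reversals in 6-15-trial
segments for feedback-based switching) and the validator's verdicts.
"""

from psyflex import generate_design, segment_lengths, validate_design

for paradigm in ("cognitive", "affective", "feedback"):
    design = generate_design(paradigm, seed=1)
    counts = {str(k): int(v) for k, v
              in design.trials["condition"].value_counts().items()}
    print(f"\n{paradigm}: {len(design)} trials")
    print(f"  condition counts: {counts}")
    if design.segment_boundaries:
        lens = segment_lengths(design)
        print(f"  {len(lens)} segments, lengths {min(lens)}-{max(lens)}")
    checks = validate_design(design)
    n_ok = sum(c.passed for c in checks)
    print(f"  validator: {n_ok}/{len(checks)} checks passed")
    for c in checks:
        if not c.passed:
            print(f"    FAILED {c.name}: {c.detail}")
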