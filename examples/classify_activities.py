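"""Full pipeline: simulate a labelled stream, classify it, score the result.

Builds a schedule of standing, walking and jumping segments, generates the
nine-site stream, classifies every 0.2 s window with the default thresholds
(A = 1000 sensor units, walk for 3-6 active sensors, jump for 7+), and
prints the window-level confusion matrix and per-class recognition rates.
"""

from wearmotion import (
    ActivityLabel,
    classify_stream,
    confusion_from_decisions,
    generate_activity_stream,
    recognition_rates,
)

schedule = [
    (ActivityLabel.STAND, 10.0),
    (ActivityLabel.WALK, 10.0),
    (ActivityLabel.JUMP, 10.0),
    (ActivityLabel.WALK, 10.0),
]
stream = generate_activity_stream(schedule, dt=0.2, seed=42)
decisions = classify_stream(stream)

# ground truth per window: the label attached to the first sample of each tick
truth_by_tick = {s.t: s.label for s in stream.samples}
truth = [truth_by_tick[d.t_start] for d in decisions]
predicted = [d.label for d in decisions]

cm = confusion_from_decisions(truth, predicted)
rep = recognition_rates(cm)

print(f"{len(decisions)} windows over {len(schedule)} activity segments")
print("confusion matrix (rows true, cols predicted; stand/walk/jump):")
for row in cm.counts.tolist():
    print("  ", row)
for label, rate in rep.rates.items():
    print(f"recognition rate {label.value:5s}: {rate:6.2f} %")
print(f"average recognition rate : {rep.mean:6.2f} %")
print("Each window's active-sensor count falls in a disjoint band per")
print("activity (0 standing, 6 walking, 9 jumping), so the noiseless")
print("synthetic streams classify perfectly.")
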