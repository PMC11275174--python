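"""Recognition-rate arithmetic on a benchmark confusion table.

Feeds the confusion counts of a 600-trial-per-class wearable recognition
study into the rate calculator and prints per-class rates, the unweighted
class-mean, and the pooled accuracy — which differ, because the class-mean
averages rates while pooling averages trials.
"""

from wearmotion import (
    ActivityLabel,
    ConfusionMatrix,
    k_class_mean,
    pooled_accuracy,
    recognition_rates,
)

counts = [
    [590, 8, 2],   # stand: 590 of 600 correct
    [17, 580, 3],  # walk
    [6, 26, 568],  # jump
]
cm = ConfusionMatrix(counts)
rep = recognition_rates(cm)

for label, rate in rep.rates.items():
    total = cm.totals[list(ActivityLabel).index(label)]
    correct = cm.row(label)[list(ActivityLabel).index(label)]
    print(f"{label.value:5s}: {correct}/{total} correct -> {rate:5.2f} %")
print(f"three-class mean (mean of rates) : {rep.mean:5.2f} %")
two = k_class_mean([rep.rates[ActivityLabel.STAND], rep.rates[ActivityLabel.WALK]])
print(f"two-class mean (stand, walk)     : {two:5.2f} %")
print(f"pooled accuracy (1738/1800)      : {pooled_accuracy(cm):5.2f} %")
print("Rates are percent-correct per class, rounded half-up at two decimals;")
print("the headline average is the unweighted mean of the per-class rates.")
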