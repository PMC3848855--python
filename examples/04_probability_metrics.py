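"""Confusion-matrix probability metrics: accuracy, APM and CPM.

Uses a 4-class worked example of 202 test decisions. The APM answers
"given the true class, what does the classifier call it?"; the CPM
answers the clinically relevant inverse, "given the call, what is the
true class?".
"""

import numpy as np

from acsclass import (
    ConfusionMatrix,
    compute_apm,
    compute_cpm,
    empirical_priors,
    overall_accuracy,
)

cm = ConfusionMatrix(
    [
        [1, 0, 1, 11],
        [0, 49, 1, 5],
        [0, 6, 12, 11],
        [3, 0, 7, 95],
    ]
)
print(f"overall accuracy: {100 * overall_accuracy(cm):.2f}%")

apm = compute_apm(cm)
print("APM (rows: actual, cols: predicted):")
print(np.round(apm.probs, 2))

priors = empirical_priors(cm.row_sums())
cpm = compute_cpm(apm, priors)
print("CPM under the empirical priors (columns sum to 1):")
print(np.round(cpm.probs, 2))
# e.g. APM row 2: 89% of true class-2 cases are called class 2; CPM
# column 2 then gives the probability each call of class 2 is right.
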