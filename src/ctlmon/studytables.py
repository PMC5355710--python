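"""Reference results of the original seven-participant aCAMS operator study.

These printed values (confusion matrices of the two best-documented
participants, per-participant test accuracies, model orders and the
adaptive-automation run summaries) serve two purposes: they are worked
examples for the evaluation engine, and calibration targets for the
synthetic operator profiles.  Matrices follow the package convention:
rows = predicted class, columns = target class.
"""

from __future__ import annotations

import numpy as np

#: 5x5 confusion matrices on the 540-epoch test session
CONFUSION = {
    ("A", "lssvm1"): np.array(
        [
            [168, 1, 0, 0, 0],
            [10, 162, 86, 51, 4],
            [0, 14, 8, 30, 6],
            [0, 0, 0, 0, 0],
            [0, 0, 0, 0, 0],
        ]
    ),
    ("A", "lssvm2"): np.array(
        [
            [177, 1, 0, 0, 0],
            [1, 174, 17, 0, 0],
            [0, 2, 75, 50, 0],
            [0, 0, 2, 30, 7],
            [0, 0, 0, 1, 3],
        ]
    ),
    ("B", "lssvm1"): np.array(
        [
            [134, 6, 0, 0, 0],
            [43, 156, 56, 53, 15],
            [0, 2, 26, 28, 3],
            [0, 0, 6, 7, 5],
            [0, 0, 0, 0, 0],
        ]
    ),
    ("B", "lssvm2"): np.array(
        [
            [177, 2, 0, 0, 0],
            [0, 161, 26, 0, 0],
            [0, 1, 48, 40, 1],
            [0, 0, 14, 47, 19],
            [0, 0, 0, 1, 3],
        ]
    ),
}

#: per-participant 5-class test accuracy by classifier
ACCURACY_TABLE = {
    "participant": ["A", "B", "C", "D", "E", "F", "G"],
    "nb": [0.6444, 0.7037, 0.5463, 0.6185, 0.5722, 0.4870, 0.4093],
    "knn": [0.6870, 0.6333, 0.6759, 0.6482, 0.6074, 0.5426, 0.4926],
    "lssvm1": [0.6259, 0.5982, 0.4815, 0.4722, 0.5093, 0.5111, 0.4778],
    "lssvm2": [0.8500, 0.8074, 0.7667, 0.7315, 0.8611, 0.7370, 0.8593],
}

#: selected NARX orders (d1, d2) per participant
MODEL_ORDERS = {
    "A": (3, 5), "B": (1, 5), "C": (2, 4), "D": (1, 5),
    "E": (1, 7), "F": (2, 6), "G": (2, 8),
}

#: AA summaries, proportional + threshold controller: participant ->
#: (n_mean, c_mean, y_mean) without and with AA
AA_PROPORTIONAL = {
    "A": ((2.7, 2.3, 0.6749), (2.0, 1.7, 0.7849)),
    "B": ((2.7, 2.2, 0.6714), (2.0, 1.8, 0.7761)),
    "C": ((2.7, 2.6, 0.6660), (2.0, 2.0, 0.7606)),
    "D": ((2.7, 2.8, 0.6979), (2.1, 2.3, 0.7704)),
    "E": ((2.7, 2.5, 0.6593), (2.1, 2.0, 0.7508)),
    "F": ((2.7, 2.9, 0.6170), (1.7, 2.2, 0.7261)),
    "G": ((2.7, 1.8, 0.6502), (1.9, 1.5, 0.7468)),
}

#: AA summaries, rule-based controller
AA_RULE_BASED = {
    "A": ((2.7, 2.2, 0.6789), (1.7, 1.5, 0.8339)),
    "B": ((2.7, 2.3, 0.6659), (1.7, 1.6, 0.8224)),
    "C": ((2.7, 2.7, 0.6603), (1.7, 1.8, 0.7946)),
    "D": ((2.7, 2.7, 0.7051), (1.7, 1.9, 0.8239)),
    "E": ((2.7, 2.5, 0.6538), (1.7, 1.7, 0.8135)),
    "F": ((2.7, 2.9, 0.6197), (1.5, 2.0, 0.7583)),
    "G": ((2.7, 1.8, 0.6592), (1.8, 1.4, 0.7779)),
}
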