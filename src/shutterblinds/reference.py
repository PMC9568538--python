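"""Published reference counts for the two pain-expression archives.

The UNBC-McMaster Shoulder Pain Expression Archive and the DISFA database
are access-restricted, but the pooled tenfold-CV confusion matrices and
the class frequencies reported for the shutter-blinds pipeline on them are
public numbers.  They serve as inputs to the metric layer (reproducing the
reported metric values from the reported counts) and as regression anchors
for the evaluation code.  Rows are true classes, columns predictions, in
the order PSPI=0, PSPI=1, 2<=PSPI<=3, PSPI>3.
"""

import numpy as np

from .facs import PAIN_CLASS_LABELS

__all__ = [
    "UNBC_CONFUSION",
    "DISFA_CONFUSION",
    "UNBC_CLASS_COUNTS",
    "UNBC_BALANCED_TARGETS",
    "DISFA_CLASS_COUNTS",
    "DISFA_BALANCED_TARGETS",
    "CLASS_LABELS",
]

CLASS_LABELS = PAIN_CLASS_LABELS

#: Pooled 10-fold CV confusion matrix reported on the balanced UNBC-McMaster set.
UNBC_CONFUSION = np.array(
    [
        [2342, 67, 59, 15],
        [11, 2798, 99, 1],
        [9, 94, 3598, 62],
        [8, 4, 52, 1633],
    ],
    dtype=np.int64,
)

#: Pooled 10-fold CV confusion matrix reported on the balanced DISFA set.
DISFA_CONFUSION = np.array(
    [
        [8528, 405, 80, 12],
        [132, 9606, 227, 8],
        [19, 338, 9765, 187],
        [4, 11, 121, 9739],
    ],
    dtype=np.int64,
)

#: Raw per-group frame counts of the UNBC-McMaster archive (before balancing).
UNBC_CLASS_COUNTS = (40029, 2909, 3763, 1697)
#: Per-group counts after random under-sampling of the "no pain" group.
UNBC_BALANCED_TARGETS = (2483, 2909, 3763, 1697)

#: Raw per-group frame counts of the DISFA archive (before balancing).
DISFA_CLASS_COUNTS = (90309, 9973, 20641, 9875)
#: Per-group counts after under-sampling the first and third groups.
DISFA_BALANCED_TARGETS = (9025, 9973, 10309, 9875)
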