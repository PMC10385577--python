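"""Published clinical reference tables for the tongue-surface pipeline.

The original clinical evaluation of this pipeline trained a VGG16 patch
classifier on 7782 expert-labeled tongue crops and evaluated point-mapping
segmentation on 80 whole-tongue photographs.  The photographs themselves
are not deposited, but the printed summary tables are, and they serve two
purposes here: the evaluator can replay them (e.g. derive the per-class
metric table from the printed confusion matrix), and they anchor
regression tests of the metric formulas.

All structures follow the canonical class order ABNORMAL, NORMAL, OTHER.
"""

from __future__ import annotations

import numpy as np

#: VGG16 confusion matrix on the clinical patch test set
#: (rows = actual, columns = predicted; class order abnormal/normal/other).
VGG16_CONFUSION = np.array([
    [476, 5, 2],
    [23, 458, 1],
    [10, 1, 252],
])

#: ResNet-50 and Xception matrices from the same evaluation.
RESNET50_CONFUSION = np.array([
    [473, 6, 4],
    [15, 463, 4],
    [7, 2, 254],
])
XCEPTION_CONFUSION = np.array([
    [462, 13, 8],
    [8, 473, 1],
    [9, 2, 252],
])

#: Patch dataset sizes: {class: (total, train, valid, test)}.
DATASET_COUNTS = {
    "abnormal": (3220, 2254, 483, 483),
    "normal": (2813, 1881, 449, 483),
    "other": (1749, 1223, 263, 263),
    "total": (7782, 5358, 1195, 1229),
}

#: Published per-class patch metrics (precision, recall, f1, accuracy, auc).
PATCH_METRICS = {
    "abnormal": (0.935, 0.986, 0.960, 0.967, 0.996),
    "normal": (0.987, 0.950, 0.968, 0.976, 0.998),
    "other": (0.988, 0.958, 0.973, 0.989, 0.998),
}

#: Published point-mapping summary over the 80 whole-tongue test
#: photographs: {class: (precision, recall, f1, iou, ap)}.
POINTMAP_METRICS = {
    "abnormal": (0.717, 0.737, 0.727, 0.695, 0.842),
    "normal": (0.650, 0.641, 0.645, 0.590, 0.706),
    "other": (0.851, 0.975, 0.909, 0.831, 1.000),
    "mean": (0.739, 0.784, 0.760, 0.705, 0.849),
}
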