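"""Published reference tables from the Northern Mozambique mapping campaign.

The 2020/2021 growing-season campaign mapped seven land-cover classes over
~380,000 km^2 of smallholder landscape at 4.77 m from monthly mosaics and
validated the map with a stratified sample of 1,875 pixels. Its published
area-weighted confusion matrix and training-sample bookkeeping are shipped
here as plain data so the validation estimators can be exercised against
real printed numbers without any download.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import (ACTIVE_CROPLAND, CLASS_NAMES, CLOSED_WOODLAND, HERBACEOUS,
                   OPEN_WOODLAND, SHORT_FALLOW, UNVEGETATED, WATER)

# Area-weighted confusion matrix of the final 7-class map: rows = mapped
# class, columns = reference class, cells = estimated proportion of the
# study area. Class order: active cropland, short-term fallow, herbaceous
# vegetation, open woodland, closed woodland, unvegetated, water.
MOZAMBIQUE_CONFUSION_PROPORTIONS = np.array([
    [0.1578, 0.0116, 0.0266, 0.0205, 0.0,    0.0055, 0.0],
    [0.002,  0.0437, 0.0035, 0.0013, 0.0,    0.0,    0.0],
    [0.0019, 0.0058, 0.0691, 0.0006, 0.0006, 0.001,  0.0],
    [0.0,    0.0039, 0.0097, 0.3558, 0.0,    0.001,  0.0],
    [0.0,    0.0008, 0.003,  0.0129, 0.2389, 0.0,    0.0],
    [0.0002, 0.0007, 0.0004, 0.0,    0.0,    0.0143, 0.0003],
    [0.0,    0.0,    0.0001, 0.0,    0.0,    0.0,    0.0066],
])

MOZAMBIQUE_CLASS_CODES = np.array([
    ACTIVE_CROPLAND, SHORT_FALLOW, HERBACEOUS, OPEN_WOODLAND,
    CLOSED_WOODLAND, UNVEGETATED, WATER,
])

# Training-sample bookkeeping of the two-stage active-learning campaign:
# final counts after fallow-targeted and margin-targeted augmentation,
# with the initial random-sample counts in parentheses in the source.
MOZAMBIQUE_TRAINING_COUNTS = pd.DataFrame({
    "class_code": MOZAMBIQUE_CLASS_CODES,
    "class_name": [CLASS_NAMES[c] for c in MOZAMBIQUE_CLASS_CODES],
    "final": [677, 301, 370, 650, 601, 226, 53],
    "initial": [582, 209, 239, 532, 514, 168, 51],
})

# Validation design of the campaign: target SE of overall accuracy 1%,
# assumed user's accuracies 0.75 for every class, 200 samples per class
# floor with the remainder allocated proportionally to mapped class shares.
MOZAMBIQUE_DESIGN = {
    "se_target": 0.01,
    "ua_assumed": 0.75,
    "per_class_floor": 200,
    "n_classes": 7,
}

#: Three-class merge used in the campaign's summary accuracy:
#: active cropland and short-term fallow kept, everything else non-crop.
CROPLAND_MERGE = {
    ACTIVE_CROPLAND: 1,
    SHORT_FALLOW: 2,
    HERBACEOUS: 3,
    OPEN_WOODLAND: 3,
    CLOSED_WOODLAND: 3,
    UNVEGETATED: 3,
    WATER: 3,
}


def mozambique_error_matrix():
    """The published campaign matrix as an :class:`ErrorMatrixEstimate`."""
    from .validation import error_matrix_from_proportions

    return error_matrix_from_proportions(MOZAMBIQUE_CONFUSION_PROPORTIONS,
                                         class_codes=MOZAMBIQUE_CLASS_CODES)
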