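"""Planted-structure synthetic study for validating the subset search.

A 36-item bank in which the target construct's 18-item pool contains five
"planted" strong indicators (loading 0.80) among thirteen weak ones
(loading 0.45, each with a 0.25 cross-loading on the other factor); the
opposite construct has eighteen ordinary indicators (loading 0.70).  On data
from this population the best 5-item subset is known by construction to be
discoverable, so exhaustive enumeration over all C(18,5) = 8568 subsets
provides an exact oracle for the ant colony search.
"""

from __future__ import annotations

import numpy as np

from .bank import ItemBank, ItemMeta
from .simulate import DEFAULT_THRESHOLDS, PopulationModel

#: ids of the planted strong indicators in the avoidance pool
PLANTED_IDS = (1, 2, 3, 4, 5)
AVOIDANCE_POOL = tuple(range(1, 19))
ANXIETY_POOL = tuple(range(19, 37))


def planted_bank() -> ItemBank:
    items = [
        ItemMeta(id=i, construct="avoidance", partner_wording="my_partner")
        for i in AVOIDANCE_POOL
    ] + [
        ItemMeta(id=i, construct="anxiety", partner_wording="my_partner")
        for i in ANXIETY_POOL
    ]
    return ItemBank(tuple(items))


def planted_model(
    good_loading: float = 0.80,
    weak_loading: float = 0.45,
    cross_loading: float = 0.25,
    opposite_loading: float = 0.70,
) -> PopulationModel:
    loadings = np.zeros((36, 2))
    for row, iid in enumerate(AVOIDANCE_POOL + ANXIETY_POOL):
        if iid in PLANTED_IDS:
            loadings[row, 0] = good_loading
        elif iid in AVOIDANCE_POOL:
            loadings[row] = (weak_loading, cross_loading)
        else:
            loadings[row, 1] = opposite_loading
    return PopulationModel(
        item_ids=AVOIDANCE_POOL + ANXIETY_POOL,
        loadings=loadings,
        thresholds=np.array(DEFAULT_THRESHOLDS),
    )
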