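"""The German Experiences in Close Relationships scales (ECR-G-36 / ECR-G-10).

This module ships the item-bank metadata of the 36-item German ECR long form,
the published 10-item short-form solution (five avoidance and five anxiety
items), the short form's published item statistics and fit results, and a
synthetic population model with the matching factorial structure.

The ECR measures the two adult-attachment dimensions, avoidance (discomfort
with closeness and intimacy) and anxiety (fear of abandonment and need for
reassurance), with 18 items each on a 7-point Likert scale (1 = disagree
strongly, 7 = agree strongly).  Odd item numbers belong to the avoidance
scale and even numbers to the anxiety scale.

Only published quantities are reproduced here (item numbers, wording classes,
short-form loadings and item statistics, fit rows).  Everything the source
instrument does not pin down numerically — which anxiety items open with a
worry stem, the loadings of the 26 items outside the short form, thresholds —
is a documented synthetic choice, flagged as such.
"""

from __future__ import annotations

import numpy as np

from .bank import ItemBank, ItemMeta
from .simulate import DEFAULT_THRESHOLDS, CriterionSpec, PopulationModel

#: ids whose wording refers ambiguously to "a partner" / "partners";
#: removed by content-based pre-selection
AMBIGUOUS_PARTNER_IDS = frozenset({1, 3, 9, 12, 13, 21, 23, 29, 31, 32, 34})

#: the published short-form solutions (long-form ids)
AVOIDANCE_SOLUTION = (7, 15, 25, 27, 35)
ANXIETY_SOLUTION = (8, 18, 20, 24, 30)

#: short-form presentation order: position 1..10 -> long-form id
#: (avoidance on odd positions, anxiety on even positions, ascending ids —
#: the assignment of ids to positions is a package convention)
SHORT_FORM_ORDER = {
    1: 7, 2: 8, 3: 15, 4: 18, 5: 25, 6: 20, 7: 27, 8: 24, 9: 35, 10: 30,
}

#: short-form positions whose responses must be recoded (x -> 8 - x)
SHORT_FORM_REVERSED_POSITIONS = (1, 3, 7, 9)

#: reverse-keyed long-form ids (synthetic beyond the four short-form items;
#: all on the avoidance scale, as is typical for this instrument)
REVERSE_KEYED_IDS = frozenset({3, 7, 9, 15, 27, 29, 31, 35})

#: anxiety items assigned the "I worry" stem in the fixture — a synthetic,
#: clearly-labeled choice (the published solution items stay unflagged)
WORRY_PREFIX_IDS = frozenset({2, 6, 14, 22, 26, 34})

#: items 2 and 22 share almost identical wording (one twin pair)
TWIN_GROUPS = {1: (2, 22)}

#: item whose content (periods of being single) is hard to answer for people
#: in long-term relationships; banned from short-form solutions
BANNED_IDS = frozenset({28})

#: published short-form item statistics, by position 1..10:
#: mean, SD, corrected item-total correlation, loading on the avoidance
#: factor, loading on the anxiety factor (rotated two-factor solution)
SHORT_FORM_ITEM_STATS = {
    1: (1.78, 1.01, 0.66, 0.81, 0.00),
    2: (3.55, 1.91, 0.51, 0.04, 0.73),
    3: (2.11, 1.28, 0.58, 0.75, -0.16),
    4: (3.14, 1.77, 0.46, 0.08, 0.67),
    5: (1.67, 1.26, 0.35, 0.51, 0.01),
    6: (2.90, 1.60, 0.53, 0.07, 0.72),
    7: (2.04, 1.25, 0.62, 0.79, 0.04),
    8: (4.25, 1.77, 0.48, -0.05, 0.67),
    9: (1.96, 1.30, 0.60, 0.78, 0.07),
    10: (5.32, 1.58, 0.49, -0.21, 0.69),
}

#: published eigenvalues of the 10-item correlation matrix (validation study)
SHORT_FORM_EIGENVALUES = (
    2.79, 2.43, 0.90, 0.74, 0.70, 0.68, 0.53, 0.50, 0.40, 0.34,
)

#: published development-study fit rows: (sample n, scale, df, chi-square)
STUDY1_FIT_ROWS = (
    (788, "avoidance", 5, 5.88),
    (788, "anxiety", 5, 10.10),
    (220, "avoidance", 5, 5.23),
    (220, "anxiety", 5, 7.57),
    (462, "avoidance", 5, 10.90),
    (462, "anxiety", 5, 17.80),
)

#: published external-criterion correlations of the short form
#: (validation study): criterion -> (r with avoidance, r with anxiety)
EXTERNAL_CRITERIA = (
    CriterionSpec("relationship_satisfaction", -0.48, -0.18),
    CriterionSpec("sexual_satisfaction", -0.47, -0.02),
    CriterionSpec("satisfaction_with_life", -0.26, -0.12),
    CriterionSpec("self_esteem", -0.19, -0.30),
)


def build_ecr_bank() -> ItemBank:
    """The shipped ECR-G-36 item bank (18 items per construct)."""
    wording_cycle = ("a_partner", "partners")
    ambiguous = sorted(AMBIGUOUS_PARTNER_IDS)
    items = []
    for iid in range(1, 37):
        construct = "avoidance" if iid % 2 == 1 else "anxiety"
        if iid in AMBIGUOUS_PARTNER_IDS:
            wording = wording_cycle[ambiguous.index(iid) % 2]
        elif iid in (2, 28):
            # item 2 is worded generally (no specific relationship);
            # item 28 refers to periods without a partner
            wording = "none"
        else:
            wording = "my_partner"
        items.append(
            ItemMeta(
                id=iid,
                construct=construct,
                reverse_keyed=iid in REVERSE_KEYED_IDS,
                partner_wording=wording,
                worry_prefix=iid in WORRY_PREFIX_IDS,
                twin_group=next(
                    (g for g, m in TWIN_GROUPS.items() if iid in m), None
                ),
            )
        )
    return ItemBank(tuple(items))


def _short_form_loadings() -> dict[int, tuple[float, float]]:
    """Long-form id -> (avoidance, anxiety) loading, from the published
    rotated two-factor solution of the ten short-form items."""
    out = {}
    for pos, (_, _, _, a1, a2) in SHORT_FORM_ITEM_STATS.items():
        out[SHORT_FORM_ORDER[pos]] = (a1, a2)
    return out


def default_population_model(
    factor_correlation: float = 0.0,
    twin_extra_corr: float = 0.30,
    missing_rate: float = 0.0,
) -> PopulationModel:
    """Synthetic 36-item population model with the ECR-G factorial structure.

    The ten short-form items carry their published loadings (including small
    cross-loadings).  The 26 remaining items take documented fixed values:
    the eleven ambiguous-wording items load 0.40–0.48 (weak indicators, so
    stepwise elimination sheds them early) and the other fifteen load
    0.55–0.75, in deterministic cycles.  These 26 values are synthetic — the
    source instrument does not publish per-item loadings for them.
    """
    selected = _short_form_loadings()
    low_cycle = (0.40, 0.42, 0.44, 0.46, 0.48)
    mid_cycle = (0.55, 0.60, 0.65, 0.70, 0.75)
    item_ids = tuple(range(1, 37))
    loadings = np.zeros((36, 2))
    n_low = n_mid = 0
    for row, iid in enumerate(item_ids):
        axis = 0 if iid % 2 == 1 else 1
        if iid in selected:
            loadings[row] = selected[iid]
        elif iid in AMBIGUOUS_PARTNER_IDS:
            loadings[row, axis] = low_cycle[n_low % len(low_cycle)]
            n_low += 1
        else:
            loadings[row, axis] = mid_cycle[n_mid % len(mid_cycle)]
            n_mid += 1
    return PopulationModel(
        item_ids=item_ids,
        loadings=loadings,
        factor_correlation=factor_correlation,
        thresholds=np.array(DEFAULT_THRESHOLDS),
        twin_groups=TWIN_GROUPS,
        twin_extra_corr=twin_extra_corr,
        missing_rate=missing_rate,
        reverse_keyed=REVERSE_KEYED_IDS,
    )


def short_form_population_model() -> PopulationModel:
    """Population model restricted to the ten short-form items.

    Items are ordered by short-form position 1..10; positions 1, 3, 7, 9 are
    reverse keyed.  Loadings are the published rotated solution.
    """
    positions = tuple(range(1, 11))
    loadings = np.array(
        [
            (SHORT_FORM_ITEM_STATS[p][3], SHORT_FORM_ITEM_STATS[p][4])
            for p in positions
        ]
    )
    return PopulationModel(
        item_ids=positions,
        loadings=loadings,
        thresholds=np.array(DEFAULT_THRESHOLDS),
        reverse_keyed=frozenset(SHORT_FORM_REVERSED_POSITIONS),
    )
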