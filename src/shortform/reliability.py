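"""Reliability estimation and scale scoring.

Two reliability coefficients are used side by side: McDonald's omega, the
factor saturation of a unidimensional model,

.. math:: \\omega = (\\Sigma\\lambda)^2 / ((\\Sigma\\lambda)^2 + \\Sigma\\theta),

computed from CFA estimates, and Cronbach's alpha,

.. math:: \\alpha = \\frac{k}{k-1}\\Bigl(1 -
          \\frac{\\sum_i s_i^2}{s_{total}^2}\\Bigr),

computed directly from the observed responses.  Scale scores are means of
the answered items (1–7 scale) after reverse-key recoding, with a minimum
number of answered items required per scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .bank import ItemBank

#: short-form position layout: avoidance on odd, anxiety on even positions
SHORT_AVOIDANCE_POSITIONS = (1, 3, 5, 7, 9)
SHORT_ANXIETY_POSITIONS = (2, 4, 6, 8, 10)
SHORT_REVERSED_POSITIONS = (1, 3, 7, 9)


def recode(values):
    """Reverse-key recoding on the 1–7 scale: ``x -> 8 - x``."""
    return 8 - values


def cronbach_alpha(
    responses: pd.DataFrame, reverse_keyed: Iterable = ()
) -> float:
    """Cronbach's alpha on listwise-complete rows of one scale's items.

    ``reverse_keyed`` columns are recoded (``x -> 8 - x``) before computing
    item and total variances.
    """
    if responses.shape[1] < 2:
        raise ValueError("alpha needs at least 2 items")
    data = responses.dropna().astype(float)
    if len(data) < 2:
        raise ValueError("alpha needs at least 2 complete rows")
    data = data.copy()
    for col in reverse_keyed:
        data[col] = recode(data[col])
    k = data.shape[1]
    item_var = data.var(axis=0, ddof=1)
    total_var = data.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("zero total-score variance")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


def mcdonald_omega(
    loadings: Sequence[float], residuals: Sequence[float]
) -> float:
    """McDonald's omega from standardized unidimensional CFA estimates."""
    lam = np.asarray(loadings, dtype=float)
    theta = np.asarray(residuals, dtype=float)
    if lam.size == 0:
        raise ValueError("empty loading vector")
    if lam.size != theta.size:
        raise ValueError("loadings and residuals differ in length")
    common = lam.sum() ** 2
    denom = common + theta.sum()
    if denom <= 0:
        raise ValueError("non-positive total variance in omega")
    return float(common / denom)


def item_total_corrected(
    responses: pd.DataFrame, reverse_keyed: Iterable = ()
) -> pd.Series:
    """Corrected item-total correlations (item vs. sum of the other items)."""
    if responses.shape[1] < 3:
        raise ValueError("corrected item-total correlations need >= 3 items")
    data = responses.dropna().astype(float).copy()
    if len(data) < 3:
        raise ValueError("need at least 3 complete rows")
    for col in reverse_keyed:
        data[col] = recode(data[col])
    total = data.sum(axis=1)
    out = {}
    for col in data.columns:
        rest = total - data[col]
        if data[col].std(ddof=1) == 0 or rest.std(ddof=1) == 0:
            raise ValueError(f"zero variance for item {col!r}")
        out[col] = float(np.corrcoef(data[col], rest)[0, 1])
    return pd.Series(out, name="r_it")


@dataclass
class ReliabilityReport:
    """Scale-level reliability and item descriptives."""

    omega: Optional[float]
    alpha: float
    item_total: pd.Series
    means: pd.Series
    sds: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"M": self.means, "SD": self.sds, "r_it": self.item_total}
        )


def scale_report(
    responses: pd.DataFrame,
    reverse_keyed: Iterable = (),
    omega: Optional[float] = None,
) -> ReliabilityReport:
    """Descriptives + alpha for one scale; omega is supplied from a CFA fit.

    Item means and SDs are reported on the observed scale (before recoding),
    matching how item statistics are conventionally tabulated.
    """
    data = responses.astype(float)
    return ReliabilityReport(
        omega=omega,
        alpha=cronbach_alpha(data, reverse_keyed),
        item_total=item_total_corrected(data, reverse_keyed),
        means=data.mean(),
        sds=data.std(ddof=1),
    )


def _validate_likert(data: pd.DataFrame) -> None:
    values = data.to_numpy(dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size and ((finite < 1) | (finite > 7)).any():
        raise ValueError("responses must lie in 1..7 (or be missing)")


def _mean_with_minimum(block: pd.DataFrame, min_answered: int) -> pd.Series:
    answered = block.notna().sum(axis=1)
    scores = block.mean(axis=1)
    return scores.where(answered >= min_answered)


def score_short_form(
    responses: pd.DataFrame, min_answered: int = 4
) -> pd.DataFrame:
    """Score the 10-item short form.

    Columns must be the short-form positions 1..10.  Positions 1, 3, 7 and 9
    are recoded (``x -> 8 - x``); avoidance is the mean of the odd positions
    and anxiety the mean of the even positions.  A scale score is missing
    when fewer than ``min_answered`` of its five items were answered.
    """
    expected = set(range(1, 11))
    if set(responses.columns) != expected:
        raise ValueError("short-form responses need columns 1..10 (positions)")
    data = responses.astype(float).copy()
    _validate_likert(data)
    for pos in SHORT_REVERSED_POSITIONS:
        data[pos] = recode(data[pos])
    return pd.DataFrame(
        {
            "avoidance": _mean_with_minimum(
                data[list(SHORT_AVOIDANCE_POSITIONS)], min_answered
            ),
            "anxiety": _mean_with_minimum(
                data[list(SHORT_ANXIETY_POSITIONS)], min_answered
            ),
        }
    )


def score_long_form(
    responses: pd.DataFrame, bank: ItemBank, min_answered: int = 15
) -> pd.DataFrame:
    """Score the 36-item long form (mean of 18 items per scale).

    Reverse keys come from the bank metadata.  ``min_answered`` (default
    15 of 18) mirrors the short form's at-least-4-of-5 rule.
    """
    data = responses.astype(float).copy()
    _validate_likert(data)
    for iid in bank.reverse_keyed_ids:
        if iid in data.columns:
            data[iid] = recode(data[iid])
    out = {}
    for construct in ("avoidance", "anxiety"):
        ids = [i for i in bank.construct_ids(construct) if i in data.columns]
        if not ids:
            raise ValueError(f"no {construct} items present in responses")
        out[construct] = _mean_with_minimum(data[ids], min_answered)
    return pd.DataFrame(out)
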