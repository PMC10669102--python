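"""Simulation of Likert response data from a two-factor congeneric model.

Participant data behind published attachment questionnaires are typically not
shareable, so the pipeline is exercised on synthetic data with the same
statistical structure: two (near-)orthogonal latent factors, standardized
loadings per item, optional residual correlation between near-duplicate twin
items, graded 7-point responses obtained by thresholding a standard-normal
continuous response, reverse-keyed items emitted on the observed (reversed)
scale, and missing-completely-at-random entries.

The generative model for item :math:`i` is

.. math:: y_i = \\lambda_{ai} F_a + \\lambda_{xi} F_x + \\delta_i e_i,

with ``Var(y_i) = 1``, ``(F_a, F_x)`` bivariate standard normal with
correlation :math:`\\varphi`, and residuals :math:`e` standard normal with
correlation ``twin_extra_corr`` inside each twin group.  Likert categories are
``c`` iff the continuous value falls in ``(t_{c-1}, t_c]`` for ordered
thresholds ``t``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

#: default category thresholds (z-scale), equally spaced and symmetric
DEFAULT_THRESHOLDS = (-1.5, -0.9, -0.3, 0.3, 0.9, 1.5)

FACTORS = ("avoidance", "anxiety")


@dataclass
class PopulationModel:
    """Population parameters of the two-factor congeneric response model.

    Parameters
    ----------
    item_ids
        Item labels, aligned with the rows of ``loadings``.
    loadings
        ``(p, 2)`` array of standardized loadings on (avoidance, anxiety).
    factor_correlation
        Latent correlation between the two factors (0 for orthogonal scales).
    thresholds
        Six ordered cut points shared by all items, or a ``(p, 6)`` array of
        per-item cut points, mapping the standard-normal response to
        categories 1..7.
    twin_groups
        Mapping group label -> item ids whose residuals share
        ``twin_extra_corr``.
    missing_rate
        Probability that an observed entry is missing (MCAR).
    reverse_keyed
        Ids emitted on the reversed scale (observed value ``8 - x``), so that
        scoring has to recode them.
    """

    item_ids: tuple
    loadings: np.ndarray
    factor_correlation: float = 0.0
    thresholds: np.ndarray = field(
        default_factory=lambda: np.array(DEFAULT_THRESHOLDS)
    )
    twin_groups: Mapping[int, Sequence[int]] = field(default_factory=dict)
    twin_extra_corr: float = 0.0
    missing_rate: float = 0.0
    reverse_keyed: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.item_ids = tuple(self.item_ids)
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.reverse_keyed = frozenset(self.reverse_keyed)
        p = len(self.item_ids)
        if self.loadings.shape != (p, 2):
            raise ValueError(
                f"loadings must have shape ({p}, 2), got {self.loadings.shape}"
            )
        if not -1.0 <= self.factor_correlation <= 1.0:
            raise ValueError("factor_correlation must lie in [-1, 1]")
        thr = self.thresholds
        if thr.ndim == 1:
            thr = thr[None, :]
        if thr.shape[1] != 6:
            raise ValueError("thresholds must provide 6 cut points per item")
        if not np.all(np.diff(thr, axis=1) > 0):
            raise ValueError("thresholds must be strictly increasing")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        communality = (self.loadings**2).sum(axis=1)
        if np.any(communality > 1.0 + 1e-12):
            bad = [self.item_ids[i] for i in np.flatnonzero(communality > 1)]
            raise ValueError(f"communality exceeds 1 for items {bad}")
        if np.any(self.uniquenesses() < -1e-12):
            bad = [
                self.item_ids[i]
                for i in np.flatnonzero(self.uniquenesses() < 0)
            ]
            raise ValueError(f"non-positive uniqueness for items {bad}")
        unknown = self.reverse_keyed - set(self.item_ids)
        if unknown:
            raise ValueError(f"reverse_keyed ids not in model: {sorted(unknown)}")
        for group, members in self.twin_groups.items():
            missing = set(members) - set(self.item_ids)
            if missing:
                raise ValueError(
                    f"twin group {group} references unknown items {sorted(missing)}"
                )

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    def phi(self) -> np.ndarray:
        return np.array(
            [[1.0, self.factor_correlation], [self.factor_correlation, 1.0]]
        )

    def uniquenesses(self) -> np.ndarray:
        """Residual variances δ² giving each item unit total variance."""
        lam = self.loadings
        common = np.einsum("if,fg,ig->i", lam, self.phi(), lam)
        return 1.0 - common

    def item_thresholds(self) -> np.ndarray:
        thr = self.thresholds
        if thr.ndim == 1:
            thr = np.broadcast_to(thr, (self.n_items, 6))
        return np.asarray(thr)

    def residual_correlation(self) -> np.ndarray:
        """Residual correlation matrix: identity plus twin blocks."""
        psi = np.eye(self.n_items)
        index = {iid: k for k, iid in enumerate(self.item_ids)}
        for members in self.twin_groups.values():
            idx = [index[m] for m in members]
            for a in idx:
                for b in idx:
                    if a != b:
                        psi[a, b] = self.twin_extra_corr
        return psi

    def implied_covariance(self) -> np.ndarray:
        """Model-implied covariance (= correlation) of the continuous items."""
        lam = self.loadings
        delta = np.sqrt(self.uniquenesses())
        sigma = lam @ self.phi() @ lam.T
        sigma += np.outer(delta, delta) * self.residual_correlation()
        return sigma


@dataclass(frozen=True)
class CriterionSpec:
    """Target correlations of an external criterion with the two factors."""

    name: str
    r_avoidance: float
    r_anxiety: float

    def __post_init__(self) -> None:
        if self.r_avoidance**2 + self.r_anxiety**2 > 1.0 + 1e-12:
            raise ValueError(
                f"criterion {self.name!r}: r_avoidance² + r_anxiety² > 1 "
                "(no unit-variance criterion can have these correlations)"
            )


@dataclass
class StudyData:
    """A simulated study: observed Likert responses plus generating scores.

    The true factor scores (and the pre-discretization continuous responses)
    are exported so that generation contracts can be verified exactly.
    """

    responses: pd.DataFrame
    factors: pd.DataFrame
    continuous: pd.DataFrame


def simulate_continuous(
    model: PopulationModel, n: int, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw ``n`` continuous response vectors and their true factor scores."""
    if n < 2:
        raise ValueError("need n >= 2 participants")
    rng = np.random.default_rng(seed)
    chol_phi = np.linalg.cholesky(model.phi())
    factors = rng.standard_normal((n, 2)) @ chol_phi.T
    resid_corr = model.residual_correlation()
    chol_res = np.linalg.cholesky(resid_corr)
    resid = rng.standard_normal((n, model.n_items)) @ chol_res.T
    delta = np.sqrt(model.uniquenesses())
    values = factors @ model.loadings.T + resid * delta
    cont = pd.DataFrame(values, columns=list(model.item_ids))
    fac = pd.DataFrame(factors, columns=list(FACTORS))
    return cont, fac


def discretize_likert(
    continuous: pd.DataFrame, thresholds: np.ndarray
) -> pd.DataFrame:
    """Map continuous responses to Likert categories 1..7.

    Category ``c`` iff the value lies in ``(t_{c-1}, t_c]`` with
    ``t_0 = -inf`` and ``t_7 = +inf``.
    """
    thr = np.asarray(thresholds, dtype=float)
    if thr.ndim == 1:
        thr = np.broadcast_to(thr, (continuous.shape[1], 6))
    if thr.shape != (continuous.shape[1], 6):
        raise ValueError("thresholds do not match the number of items")
    if not np.all(np.diff(thr, axis=1) > 0):
        raise ValueError("thresholds must be strictly increasing")
    values = continuous.to_numpy()
    cats = np.empty_like(values, dtype=np.int64)
    for j in range(values.shape[1]):
        cats[:, j] = np.searchsorted(thr[j], values[:, j], side="left") + 1
    return pd.DataFrame(cats, columns=continuous.columns, index=continuous.index)


def simulate_study(model: PopulationModel, n: int, seed: int) -> StudyData:
    """Simulate a full study: Likert responses with reverse keying and MCAR.

    Reverse-keyed items are emitted on the observed scale (``8 - x``), so any
    downstream scoring must recode them.  Missingness is applied after
    discretization at ``model.missing_rate``.
    """
    cont, fac = simulate_continuous(model, n, seed)
    responses = discretize_likert(cont, model.item_thresholds()).astype(float)
    for iid in model.reverse_keyed:
        responses[iid] = 8.0 - responses[iid]
    if model.missing_rate > 0:
        # separate stream so the response draw is unaffected by the rate
        rng = np.random.default_rng((int(seed), 0x5F3759))
        mask = rng.random(responses.shape) < model.missing_rate
        responses = responses.mask(mask)
    return StudyData(responses=responses, factors=fac, continuous=cont)


def simulate_criteria(
    factors: pd.DataFrame,
    specs: Sequence[CriterionSpec],
    seed: int,
    factor_correlation: float = 0.0,
) -> pd.DataFrame:
    """Generate unit-variance criterion columns with target factor correlations.

    Each criterion is ``C = β_a F_a + β_x F_x + σ ε`` with ``β = Φ⁻¹ r`` and
    ``σ² = 1 − rᵀ Φ⁻¹ r``; its population correlations with the factors are
    exactly the requested ``(r_avoidance, r_anxiety)``.
    """
    rng = np.random.default_rng(seed)
    phi = np.array([[1.0, factor_correlation], [factor_correlation, 1.0]])
    phi_inv = np.linalg.inv(phi)
    fmat = factors[list(FACTORS)].to_numpy()
    out = {}
    for spec in specs:
        r = np.array([spec.r_avoidance, spec.r_anxiety])
        beta = phi_inv @ r
        sigma2 = 1.0 - r @ phi_inv @ r
        if sigma2 < -1e-12:
            raise ValueError(
                f"criterion {spec.name!r} infeasible for factor correlation "
                f"{factor_correlation}: implied residual variance {sigma2:.3f} < 0"
            )
        noise = rng.standard_normal(len(fmat))
        out[spec.name] = fmat @ beta + np.sqrt(max(sigma2, 0.0)) * noise
    return pd.DataFrame(out, index=factors.index)


def write_responses(responses: pd.DataFrame, path) -> None:
    """Write a response matrix as CSV (participant column + one column per id)."""
    frame = responses.copy()
    frame.insert(0, "participant", np.arange(1, len(frame) + 1))
    frame.to_csv(path, index=False)


def read_responses(path) -> pd.DataFrame:
    """Read a response-matrix CSV written by :func:`write_responses`."""
    frame = pd.read_csv(path)
    if "participant" in frame.columns:
        frame = frame.drop(columns="participant")
    cols = []
    for c in frame.columns:
        try:
            cols.append(int(c))
        except (TypeError, ValueError):
            cols.append(c)
    frame.columns = cols
    return frame
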