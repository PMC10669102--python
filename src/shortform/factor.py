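"""Maximum-likelihood confirmatory and exploratory factor analysis.

The CFA here fits congeneric measurement models (each item loads on exactly
one factor, factor variances fixed to 1, factor covariances free) by
minimizing the normal-theory ML discrepancy

.. math::

    F_{ML} = \\ln|\\Sigma(\\theta)| + \\mathrm{tr}(S\\,\\Sigma(\\theta)^{-1})
             - \\ln|S| - p,

with :math:`\\chi^2 = (n-1) F_{ML}` at the minimum.  Because congeneric
models are scale invariant (every item has a free loading and a free residual
variance), the discrepancy is identical whether the covariance or the
correlation matrix is analyzed; the fit is carried out on the correlation
matrix so estimates come out standardized.

Fit indices follow the usual definitions: CFI against the independence
baseline (diagonal :math:`\\Sigma`, for which
:math:`\\chi^2_b = -(n-1)\\ln|R|`), RMSEA
:math:`= \\sqrt{\\max(\\chi^2 - df, 0)/(df\\,(n-1))}` with a 90% interval from
the noncentral-:math:`\\chi^2` distribution, and AIC/BIC on the
:math:`\\chi^2 - 2\\,df` / :math:`\\chi^2 - \\ln(n)\\,df` scale used for
model comparison across candidate item pools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import permutations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats


# --------------------------------------------------------------------------
# sample moments


@dataclass
class SampleMoments:
    """Covariance/correlation moments of a (listwise-complete) sample."""

    cov: np.ndarray
    corr: np.ndarray
    n: int
    item_ids: tuple

    @property
    def p(self) -> int:
        return len(self.item_ids)

    def subset(self, item_ids: Sequence) -> "SampleMoments":
        idx = [self.item_ids.index(i) for i in item_ids]
        return SampleMoments(
            cov=self.cov[np.ix_(idx, idx)],
            corr=self.corr[np.ix_(idx, idx)],
            n=self.n,
            item_ids=tuple(item_ids),
        )


def sample_moments(responses: pd.DataFrame) -> SampleMoments:
    """Unbiased covariance and correlation on listwise-complete rows."""
    complete = responses.dropna()
    n = len(complete)
    if n < 2:
        raise ValueError("fewer than 2 complete rows after listwise deletion")
    values = complete.to_numpy(dtype=float)
    variances = values.var(axis=0, ddof=1)
    dead = np.flatnonzero(variances <= 0)
    if dead.size:
        names = [responses.columns[i] for i in dead]
        raise ValueError(f"zero-variance item(s): {names}")
    cov = np.cov(values, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    sd = np.sqrt(np.diag(cov))
    corr = cov / np.outer(sd, sd)
    np.fill_diagonal(corr, 1.0)
    return SampleMoments(
        cov=cov, corr=corr, n=n, item_ids=tuple(responses.columns)
    )


# --------------------------------------------------------------------------
# CFA


@dataclass(frozen=True)
class CFASpec:
    """Simple-structure CFA pattern: item id -> factor name.

    Factor variances are fixed to 1 (free loadings); factor covariances are
    free.  Every factor needs at least three indicators for identification.
    """

    pattern: tuple[tuple[object, str], ...]

    @staticmethod
    def from_mapping(mapping: Mapping) -> "CFASpec":
        return CFASpec(tuple(mapping.items()))

    @staticmethod
    def unidimensional(item_ids: Sequence, factor: str = "f1") -> "CFASpec":
        return CFASpec(tuple((i, factor) for i in item_ids))

    @property
    def item_ids(self) -> tuple:
        return tuple(i for i, _ in self.pattern)

    @property
    def factors(self) -> tuple[str, ...]:
        seen: list[str] = []
        for _, f in self.pattern:
            if f not in seen:
                seen.append(f)
        return tuple(seen)

    def __post_init__(self) -> None:
        counts: dict[str, int] = {}
        for _, f in self.pattern:
            counts[f] = counts.get(f, 0) + 1
        thin = sorted(f for f, c in counts.items() if c < 3)
        if thin:
            raise ValueError(
                f"factor(s) {thin} have fewer than 3 indicators (not identified)"
            )

    def n_free_parameters(self) -> int:
        p = len(self.pattern)
        m = len(self.factors)
        return 2 * p + m * (m - 1) // 2

    def degrees_of_freedom(self) -> int:
        p = len(self.pattern)
        return p * (p + 1) // 2 - self.n_free_parameters()


@dataclass
class CFAFit:
    """A fitted measurement model with standardized estimates and fit indices."""

    spec: CFASpec
    loadings: pd.Series
    residuals: pd.Series
    factor_cov: pd.DataFrame
    discrepancy: float
    chi_square: float
    df: int
    p_value: float
    baseline_chi_square: float
    baseline_df: int
    cfi: float
    rmsea: float
    rmsea_ci: tuple[float, float]
    aic: float
    bic: float
    n: int
    converged: bool
    heywood: bool
    diagnostics: dict = field(default_factory=dict)


def _pattern_arrays(spec: CFASpec):
    factors = spec.factors
    fac_index = {f: k for k, f in enumerate(factors)}
    assign = np.array([fac_index[f] for _, f in spec.pattern])
    return factors, assign


def _objective(x, S, assign, m, p, tri):
    lam_v = x[:p]
    theta = x[p : 2 * p]
    psi_v = x[2 * p :]
    Lam = np.zeros((p, m))
    Lam[np.arange(p), assign] = lam_v
    Phi = np.eye(m)
    if m > 1:
        Phi[tri] = psi_v
        Phi[(tri[1], tri[0])] = psi_v
    Sigma = Lam @ Phi @ Lam.T
    Sigma[np.diag_indices(p)] += theta
    try:
        c, low = np.linalg.cholesky(Sigma), True
    except np.linalg.LinAlgError:
        return 1e10, np.zeros_like(x)
    logdet = 2.0 * np.log(np.diag(c)).sum()
    Sinv_S = np.linalg.solve(Sigma, S)
    sign_s, logdet_s = np.linalg.slogdet(S)
    F = logdet + np.trace(Sinv_S) - logdet_s - p
    # dF = tr(G dSigma), G = Sigma^-1 (Sigma - S) Sigma^-1
    Sigma_inv = np.linalg.inv(Sigma)
    G = Sigma_inv - Sigma_inv @ S @ Sigma_inv
    GLP = G @ Lam @ Phi
    grad = np.empty_like(x)
    grad[:p] = 2.0 * GLP[np.arange(p), assign]
    grad[p : 2 * p] = np.diag(G)
    if m > 1:
        LGL = Lam.T @ G @ Lam
        grad[2 * p :] = 2.0 * LGL[tri]
    return F, grad


def fit_cfa(
    moments: SampleMoments,
    spec: CFASpec,
    start: Optional[np.ndarray] = None,
    max_iter: int = 1000,
) -> CFAFit:
    """Fit a congeneric CFA by maximum likelihood.

    Non-convergence and Heywood cases (negative residual variances) are
    reported through the ``converged`` / ``heywood`` flags rather than
    raised, so that optimization loops can treat them as rejections.
    """
    item_ids = spec.item_ids
    missing = set(item_ids) - set(moments.item_ids)
    if missing:
        raise KeyError(f"items {sorted(missing, key=str)} not in moments")
    sub = moments.subset(item_ids)
    R = sub.corr
    p = sub.p
    factors, assign = _pattern_arrays(spec)
    m = len(factors)
    tri = np.triu_indices(m, k=1)
    if start is None:
        x0 = np.concatenate(
            [np.full(p, 0.7), np.full(p, 0.51), np.zeros(m * (m - 1) // 2)]
        )
    else:
        x0 = np.asarray(start, dtype=float)
    res = optimize.minimize(
        _objective,
        x0,
        args=(R, assign, m, p, tri),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-9},
    )
    lam = res.x[:p].copy()
    theta = res.x[p : 2 * p].copy()
    psi = np.eye(m)
    if m > 1:
        psi[tri] = res.x[2 * p :]
        psi[(tri[1], tri[0])] = res.x[2 * p :]
    # fix factor signs: make each factor's loading sum nonnegative
    for k in range(m):
        mask = assign == k
        if lam[mask].sum() < 0:
            lam[mask] *= -1
            psi[k, :] *= -1
            psi[:, k] *= -1
            psi[k, k] = 1.0
    # standardize to unit model-implied item variances
    Lam = np.zeros((p, m))
    Lam[np.arange(p), assign] = lam
    implied_var = np.einsum("if,fg,ig->i", Lam, psi, Lam) + theta
    scale = np.sqrt(np.abs(implied_var))
    scale[scale == 0] = 1.0
    lam_std = lam / scale
    theta_std = theta / scale**2

    F = float(res.fun)
    n = sub.n
    chi2_val = max((n - 1) * F, 0.0)
    df = spec.degrees_of_freedom()
    p_value = float(stats.chi2.sf(chi2_val, df)) if df > 0 else float("nan")
    chi2_b, df_b = baseline_chi2(sub)
    cfi_val = cfi(chi2_val, df, chi2_b, df_b)
    if df >= 1:
        rmsea_val = rmsea(chi2_val, df, n)
        ci = rmsea_ci(chi2_val, df, n)
    else:  # saturated model: misfit per df is undefined, report 0
        rmsea_val = 0.0
        ci = (0.0, 0.0)
    heywood = bool(np.any(theta < 0))
    grad_norm = float(np.max(np.abs(res.jac)))
    converged = bool(res.success) and F < 1e9
    return CFAFit(
        spec=spec,
        loadings=pd.Series(lam_std, index=list(item_ids), name="loading"),
        residuals=pd.Series(theta_std, index=list(item_ids), name="residual"),
        factor_cov=pd.DataFrame(psi, index=list(factors), columns=list(factors)),
        discrepancy=F,
        chi_square=chi2_val,
        df=df,
        p_value=p_value,
        baseline_chi_square=chi2_b,
        baseline_df=df_b,
        cfi=cfi_val,
        rmsea=rmsea_val,
        rmsea_ci=ci,
        aic=chi2_val - 2 * df,
        bic=chi2_val - np.log(n) * df,
        n=n,
        converged=converged,
        heywood=heywood,
        diagnostics={"grad_norm": grad_norm, "n_iter": res.nit,
                     "message": str(res.message)},
    )


def baseline_chi2(moments: SampleMoments) -> tuple[float, int]:
    """Independence-model chi-square and df (CFI baseline).

    With a diagonal baseline covariance the ML discrepancy reduces to
    ``-ln|R|``, so ``chi2_b = -(n-1) ln|R|`` and ``df_b = p(p-1)/2``.
    """
    sign, logdet = np.linalg.slogdet(moments.corr)
    if sign <= 0:
        raise ValueError("singular correlation matrix")
    p = moments.p
    return float(-(moments.n - 1) * logdet), p * (p - 1) // 2


def cfi(chi_square: float, df: int, chi2_b: float, df_b: int) -> float:
    """Comparative fit index against the independence baseline."""
    num = max(chi_square - df, 0.0)
    den = max(chi2_b - df_b, chi_square - df, 0.0)
    if den == 0.0:
        return 1.0
    return 1.0 - num / den


def rmsea(chi_square: float, df: int, n: int) -> float:
    """Root mean square error of approximation."""
    if df < 1 or n < 2:
        raise ValueError("need df >= 1 and n >= 2")
    return float(np.sqrt(max(chi_square - df, 0.0) / (df * (n - 1))))


def _solve_noncentrality(chi_square: float, df: int, target: float) -> float:
    """Noncentrality lambda with ncx2.cdf(chi2; df, lambda) == target."""
    if stats.chi2.cdf(chi_square, df) <= target:
        return 0.0
    lo, hi = 1e-9, max(4.0 * chi_square, 1.0)
    while stats.ncx2.cdf(chi_square, df, hi) > target:
        hi *= 2.0
        if hi > 1e8:  # pragma: no cover - numerical guard
            break
    return float(
        optimize.brentq(
            lambda nc: stats.ncx2.cdf(chi_square, df, nc) - target, lo, hi,
            xtol=1e-10,
        )
    )


def rmsea_ci(
    chi_square: float, df: int, n: int, level: float = 0.90
) -> tuple[float, float]:
    """Noncentrality-based RMSEA confidence interval (default 90%)."""
    if df < 1 or n < 2:
        raise ValueError("need df >= 1 and n >= 2")
    upper_tail = (1.0 + level) / 2.0  # 0.95 for a 90% interval
    lower_tail = (1.0 - level) / 2.0
    nc_lo = _solve_noncentrality(chi_square, df, upper_tail)
    nc_hi = _solve_noncentrality(chi_square, df, lower_tail)
    denom = df * (n - 1)
    return (float(np.sqrt(nc_lo / denom)), float(np.sqrt(nc_hi / denom)))


# --------------------------------------------------------------------------
# EFA


@dataclass
class EFAResult:
    eigenvalues: np.ndarray
    loadings: pd.DataFrame
    rotation: str
    n_factors: int
    converged: bool

    def explained_variance(self, k: Optional[int] = None) -> float:
        """Percent variance explained by the first ``k`` components."""
        k = self.n_factors if k is None else k
        return explained_variance(self.eigenvalues, k)


def explained_variance(eigenvalues: Sequence[float], k: int) -> float:
    """Percent of total variance carried by the ``k`` largest eigenvalues."""
    ev = np.sort(np.asarray(eigenvalues, dtype=float))[::-1]
    if not 1 <= k <= len(ev):
        raise ValueError(f"k must be in 1..{len(ev)}")
    return float(ev[:k].sum() / len(ev) * 100.0)


def efa(
    moments: SampleMoments,
    n_factors: int = 2,
    rotation: str = "varimax",
) -> EFAResult:
    """ML exploratory factor analysis with rotation.

    Eigenvalues are those of the correlation matrix (descending); loadings
    come from maximum-likelihood extraction followed by the requested
    rotation (orthogonal varimax by default, oblique methods by name).
    """
    from statsmodels.multivariate.factor import Factor
    from statsmodels.multivariate.factor_rotation import rotate_factors

    R = moments.corr
    eigenvalues = np.sort(np.linalg.eigvalsh(R))[::-1]
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = Factor(
                corr=R, n_factor=n_factors, method="ml", nobs=moments.n
            )
            fit = model.fit()
        raw = np.asarray(fit.loadings)[:, :n_factors]
    except Exception as exc:  # extraction failure -> flagged, not raised
        return EFAResult(
            eigenvalues=eigenvalues,
            loadings=pd.DataFrame(
                np.full((moments.p, n_factors), np.nan),
                index=list(moments.item_ids),
            ),
            rotation=rotation,
            n_factors=n_factors,
            converged=False,
        )
    if n_factors > 1 and rotation is not None:
        rotated, _ = rotate_factors(raw, rotation)
    else:
        rotated = raw
    # sign convention: each factor's loading sum nonnegative
    signs = np.where(rotated.sum(axis=0) < 0, -1.0, 1.0)
    rotated = rotated * signs
    loadings = pd.DataFrame(
        rotated,
        index=list(moments.item_ids),
        columns=[f"factor{k + 1}" for k in range(n_factors)],
    )
    return EFAResult(
        eigenvalues=eigenvalues,
        loadings=loadings,
        rotation=rotation,
        n_factors=n_factors,
        converged=converged,
    )


def align_loadings(
    loadings: pd.DataFrame | np.ndarray, reference: np.ndarray
) -> np.ndarray:
    """Match a loading matrix to a reference pattern.

    Resolves the column-permutation and sign indeterminacy of factor
    solutions by choosing the permutation/sign combination minimizing the
    sum of squared differences from ``reference``.
    """
    L = np.asarray(loadings, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if L.shape != ref.shape:
        raise ValueError("shape mismatch between loadings and reference")
    k = L.shape[1]
    best, best_err = None, np.inf
    for perm in permutations(range(k)):
        P = L[:, list(perm)]
        for signs in np.ndindex(*([2] * k)):
            s = np.where(np.array(signs) == 1, -1.0, 1.0)
            cand = P * s
            err = float(((cand - ref) ** 2).sum())
            if err < best_err:
                best, best_err = cand, err
    return best
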