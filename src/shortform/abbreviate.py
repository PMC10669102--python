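"""Short-form item selection: composite criterion, ACO, SCOFA, brute force.

A candidate 5-item subset of one construct's pool is judged on four
qualities, each mapped through a steep logistic centred at its cutoff so
that small shortfalls just below the cutoff are penalized sharply:

* model fit — unidimensional CFA on the subset; the fit component is the
  mean of the logistic scores of CFI (cutoff 0.95, higher better) and
  RMSEA (cutoff 0.05, lower better);
* reliability — McDonald's omega from the same CFA (cutoff 0.70);
* convergence — correlation of the subset mean score with the construct's
  full 18-item scale score (cutoff 0.80);
* independence — |correlation| of the subset mean score with the *opposite*
  construct's full scale score (cutoff 0.10, lower better).

The total criterion is the (weighted) sum of the four components, each in
(0, 1).  The ant colony search samples subsets with probability proportional
to per-item pheromone, evaporates pheromone multiplicatively each iteration,
and deposits on the iteration-best subset; an exhaustive enumeration over all
k-subsets serves as the oracle at tractable pool sizes.  SCOFA (stepwise
CFA) instead prunes the pool one lowest-loading item at a time and tracks
information criteria to suggest an optimal length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .bank import ItemBank
from .factor import CFASpec, fit_cfa, sample_moments
from .reliability import mcdonald_omega, recode


# --------------------------------------------------------------------------
# composite criterion


def logistic_component(
    x: float, cutoff: float, direction: str, slope: float = 100.0
) -> float:
    """Logistic quality score in (0, 1), equal to 0.5 at the cutoff.

    ``direction`` is ``"higher"`` when larger raw values are better (CFI,
    omega, convergence r) and ``"lower"`` when smaller values are better
    (RMSEA, |independence r|).
    """
    if slope <= 0:
        raise ValueError("slope must be positive")
    if direction == "higher":
        d = x - cutoff
    elif direction == "lower":
        d = cutoff - x
    else:
        raise ValueError("direction must be 'higher' or 'lower'")
    z = np.clip(slope * d, -500.0, 500.0)
    return float(1.0 / (1.0 + np.exp(-z)))


@dataclass(frozen=True)
class CriterionConfig:
    """Cutoffs, logistic slope, and component weights of the criterion."""

    cfi_cutoff: float = 0.95
    rmsea_cutoff: float = 0.05
    omega_cutoff: float = 0.70
    convergence_cutoff: float = 0.80
    independence_cutoff: float = 0.10
    slope: float = 100.0
    weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if len(self.weights) != 4:
            raise ValueError("weights must have 4 entries")


@dataclass(frozen=True)
class CriterionValue:
    """The four logit-transformed components and their weighted sum."""

    fit_component: float
    reliability_component: float
    convergence_component: float
    independence_component: float
    total: float
    cfi: float
    rmsea: float
    omega: float
    r_long: float
    r_opposite: float
    converged: bool = True

    @staticmethod
    def rejected(reason: str = "") -> "CriterionValue":
        return CriterionValue(
            0.0, 0.0, 0.0, 0.0, 0.0,
            float("nan"), float("nan"), float("nan"),
            float("nan"), float("nan"), converged=False,
        )


def _pairwise_corr(a: pd.Series, b: pd.Series) -> float:
    mask = a.notna() & b.notna()
    if mask.sum() < 3:
        raise ValueError("fewer than 3 complete pairs")
    x, y = a[mask], b[mask]
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise ValueError("zero variance in correlation input")
    return float(np.corrcoef(x, y)[0, 1])


class SubsetEvaluator:
    """Evaluates candidate subsets of one construct's item pool.

    Holds the (reverse-key recoded) response data, the two full-scale
    reference scores, and a cache so repeated evaluations of the same subset
    are bit-identical and free.  The evaluator is a pure function of
    (subset, data, config).
    """

    def __init__(
        self,
        responses: pd.DataFrame,
        bank: ItemBank,
        construct: str,
        config: CriterionConfig = CriterionConfig(),
        long_min_answered: int = 15,
    ):
        if construct not in ("avoidance", "anxiety"):
            raise ValueError(f"unknown construct {construct!r}")
        self.construct = construct
        self.opposite = "anxiety" if construct == "avoidance" else "avoidance"
        self.config = config
        data = responses.astype(float).copy()
        for iid in bank.reverse_keyed_ids:
            if iid in data.columns:
                data[iid] = recode(data[iid])
        self.data = data
        own_ids = [i for i in bank.construct_ids(construct) if i in data.columns]
        opp_ids = [i for i in bank.construct_ids(self.opposite) if i in data.columns]
        self.long_score = self._mean_score(own_ids, long_min_answered)
        self.opposite_score = self._mean_score(opp_ids, long_min_answered)
        self._cache: dict[frozenset, CriterionValue] = {}
        self.n_evaluations = 0  # CFA fits actually performed

    def _mean_score(self, ids, min_answered) -> pd.Series:
        block = self.data[list(ids)]
        answered = block.notna().sum(axis=1)
        return block.mean(axis=1).where(answered >= min(min_answered, len(ids)))

    def __call__(self, subset) -> CriterionValue:
        key = frozenset(subset)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        value = self._evaluate(tuple(sorted(subset)))
        self._cache[key] = value
        return value

    def _evaluate(self, subset: tuple) -> CriterionValue:
        cfg = self.config
        self.n_evaluations += 1
        try:
            moments = sample_moments(self.data[list(subset)])
            fit = fit_cfa(moments, CFASpec.unidimensional(subset))
            if not fit.converged:
                return CriterionValue.rejected("CFA did not converge")
            omega = mcdonald_omega(fit.loadings, fit.residuals)
            short_score = self.data[list(subset)].mean(axis=1)
            r_long = _pairwise_corr(short_score, self.long_score)
            r_opp = _pairwise_corr(short_score, self.opposite_score)
        except (ValueError, np.linalg.LinAlgError, KeyError):
            return CriterionValue.rejected("evaluation error")
        fit_comp = 0.5 * (
            logistic_component(fit.cfi, cfg.cfi_cutoff, "higher", cfg.slope)
            + logistic_component(fit.rmsea, cfg.rmsea_cutoff, "lower", cfg.slope)
        )
        rel_comp = logistic_component(omega, cfg.omega_cutoff, "higher", cfg.slope)
        conv_comp = logistic_component(
            r_long, cfg.convergence_cutoff, "higher", cfg.slope
        )
        indep_comp = logistic_component(
            abs(r_opp), cfg.independence_cutoff, "lower", cfg.slope
        )
        w = cfg.weights
        total = (
            w[0] * fit_comp + w[1] * rel_comp + w[2] * conv_comp + w[3] * indep_comp
        )
        return CriterionValue(
            fit_component=fit_comp,
            reliability_component=rel_comp,
            convergence_component=conv_comp,
            independence_component=indep_comp,
            total=float(total),
            cfi=fit.cfi,
            rmsea=fit.rmsea,
            omega=omega,
            r_long=r_long,
            r_opposite=r_opp,
            converged=True,
        )


# --------------------------------------------------------------------------
# ant colony optimization


@dataclass(frozen=True)
class ACOConfig:
    """Ant-colony settings: 80 ants, evaporation 0.9, patience 50, 15 runs."""

    n_ants: int = 80
    evaporation: float = 0.9
    patience: int = 50
    k: int = 5
    n_runs: int = 15
    tau_init: float = 1.0
    tau_min: float = 0.01
    deposit_scale: float = 0.1
    max_iterations: int = 10_000

    def __post_init__(self) -> None:
        if not 0.0 < self.evaporation < 1.0:
            raise ValueError("evaporation must lie in (0, 1)")
        for name in ("n_ants", "patience", "k", "n_runs", "max_iterations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tau_init <= 0 or self.tau_min <= 0 or self.deposit_scale <= 0:
            raise ValueError("pheromone parameters must be positive")


@dataclass
class ACORun:
    """One ant-colony run: global best, per-iteration log, bookkeeping."""

    best_subset: tuple
    best_value: CriterionValue
    log: pd.DataFrame  # iteration, iteration_best, global_best
    iterations: int
    seed: int
    pheromone: pd.Series


def aco_run(
    pool: Sequence,
    evaluator: Callable[[Sequence], CriterionValue],
    config: ACOConfig = ACOConfig(),
    seed: int = 0,
) -> ACORun:
    """Run one ant colony search for the best k-subset of ``pool``.

    Each ant draws ``k`` distinct items sequentially with probability
    proportional to pheromone.  After every iteration all pheromone
    evaporates by the configured factor, the iteration-best subset's items
    receive a deposit proportional to its criterion total, and pheromone is
    floored at ``tau_min`` so no item becomes unreachable.  The search stops
    after ``patience`` iterations without improvement of the global best.
    """
    pool = tuple(pool)
    if len(pool) == 0:
        raise ValueError("empty item pool")
    if len(pool) < config.k:
        raise ValueError("pool smaller than subset size k")
    rng = np.random.default_rng(seed)
    tau = np.full(len(pool), config.tau_init, dtype=float)
    best_subset: Optional[tuple] = None
    best_value: Optional[CriterionValue] = None
    stall = 0
    records = []
    iteration = 0
    while iteration < config.max_iterations:
        iteration += 1
        iter_best: Optional[tuple] = None
        iter_best_value: Optional[CriterionValue] = None
        probs = tau / tau.sum()
        for _ in range(config.n_ants):
            idx = rng.choice(len(pool), size=config.k, replace=False, p=probs)
            subset = tuple(sorted(pool[i] for i in idx))
            value = evaluator(subset)
            if iter_best_value is None or value.total > iter_best_value.total:
                iter_best, iter_best_value = subset, value
        improved = best_value is None or iter_best_value.total > best_value.total
        if improved:
            best_subset, best_value = iter_best, iter_best_value
            stall = 0
        else:
            stall += 1
        tau *= config.evaporation
        deposit = config.deposit_scale * iter_best_value.total
        members = set(iter_best)
        for i, item in enumerate(pool):
            if item in members:
                tau[i] += deposit
        np.clip(tau, config.tau_min, None, out=tau)
        records.append(
            {
                "iteration": iteration,
                "iteration_best": iter_best_value.total,
                "global_best": best_value.total,
            }
        )
        if stall >= config.patience:
            break
    return ACORun(
        best_subset=best_subset,
        best_value=best_value,
        log=pd.DataFrame.from_records(records),
        iterations=iteration,
        seed=seed,
        pheromone=pd.Series(tau, index=list(pool), name="pheromone"),
    )


@dataclass
class ACOMultiResult:
    best_subset: tuple
    best_value: CriterionValue
    runs: list[ACORun]
    frequency: pd.Series  # how often each run-best subset occurred


def aco_multi(
    pool: Sequence,
    evaluator: Callable[[Sequence], CriterionValue],
    config: ACOConfig = ACOConfig(),
    seed: int = 0,
) -> ACOMultiResult:
    """Repeat the ant colony search ``n_runs`` times with derived seeds.

    Returns the best run-best overall; exact ties on the criterion total are
    broken toward the lexicographically smallest item-id set.
    """
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=config.n_runs)
    runs = [aco_run(pool, evaluator, config, int(s)) for s in run_seeds]
    best = min(runs, key=lambda r: (-r.best_value.total, r.best_subset))
    counts = pd.Series(
        [tuple(r.best_subset) for r in runs], dtype=object
    ).value_counts()
    return ACOMultiResult(
        best_subset=best.best_subset,
        best_value=best.best_value,
        runs=runs,
        frequency=counts,
    )


# --------------------------------------------------------------------------
# exhaustive oracle


@dataclass
class BruteForceResult:
    best_subset: tuple
    best_value: CriterionValue
    ranking: list[tuple[tuple, float]]  # (subset, total), best first
    n_evaluated: int


def brute_force_best(
    pool: Sequence,
    evaluator: Callable[[Sequence], CriterionValue],
    k: int,
    budget: int = 20_000,
) -> BruteForceResult:
    """Enumerate and evaluate every k-subset (the exact-search oracle)."""
    pool = tuple(sorted(pool))
    n_subsets = math.comb(len(pool), k)
    if n_subsets > budget:
        raise ValueError(
            f"{n_subsets} subsets exceed the enumeration budget {budget}; "
            "use the ant colony search instead"
        )
    scored = []
    for subset in combinations(pool, k):
        value = evaluator(subset)
        scored.append((subset, value.total))
    scored.sort(key=lambda t: (-t[1], t[0]))
    best_subset = scored[0][0]
    return BruteForceResult(
        best_subset=best_subset,
        best_value=evaluator(best_subset),
        ranking=scored,
        n_evaluated=n_subsets,
    )


def filter_admissible(
    ranking: Sequence[tuple[tuple, float]],
    bank: ItemBank,
    rules=None,
) -> list[tuple[tuple, float]]:
    """Drop ranked solutions that violate the content rules (post-hoc filter)."""
    from .bank import DEFAULT_RULES, content_admissible

    rules = DEFAULT_RULES if rules is None else rules
    return [
        (subset, total)
        for subset, total in ranking
        if content_admissible(subset, bank, rules)[0]
    ]


# --------------------------------------------------------------------------
# stepwise CFA (SCOFA)


@dataclass
class ScofaStep:
    items: tuple
    aic: float
    bic: float
    loadings: pd.Series
    converged: bool
    dropped: object  # item removed after this step (None on the last step)


@dataclass
class ScofaResult:
    steps: list[ScofaStep]
    suggested_length: int
    elimination_order: tuple  # first-dropped first

    def trajectory(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pool_size": [len(s.items) for s in self.steps],
                "aic": [s.aic for s in self.steps],
                "bic": [s.bic for s in self.steps],
                "converged": [s.converged for s in self.steps],
                "dropped": [s.dropped for s in self.steps],
            }
        )


def scofa(
    responses: pd.DataFrame,
    pool: Sequence,
    bank: Optional[ItemBank] = None,
    min_items: int = 3,
) -> ScofaResult:
    """Stepwise CFA: drop the lowest-loading item until ``min_items`` remain.

    At every step a unidimensional CFA is fitted on the current pool and the
    information criteria (AIC/BIC on the chi-square scale) are recorded; the
    suggested short-form length is the pool size with minimal AIC.  If a step
    fails to converge it is flagged and the drop decision falls back on the
    previous step's loadings.  Loading ties break toward the smaller item id.
    """
    pool = tuple(sorted(pool))
    if len(pool) < min_items:
        raise ValueError(f"pool must contain at least {min_items} items")
    data = responses.astype(float).copy()
    if bank is not None:
        for iid in bank.reverse_keyed_ids:
            if iid in data.columns:
                data[iid] = recode(data[iid])
    current = list(pool)
    steps: list[ScofaStep] = []
    dropped_order: list = []
    prev_loadings: Optional[pd.Series] = None
    while True:
        moments = sample_moments(data[current])
        fit = fit_cfa(moments, CFASpec.unidimensional(current))
        loadings = fit.loadings if fit.converged else None
        if loadings is None and prev_loadings is not None:
            loadings = prev_loadings[prev_loadings.index.isin(current)]
        if loadings is None:
            loadings = fit.loadings  # no better information available
        if len(current) <= min_items:
            steps.append(
                ScofaStep(
                    items=tuple(current),
                    aic=fit.aic,
                    bic=fit.bic,
                    loadings=fit.loadings,
                    converged=fit.converged,
                    dropped=None,
                )
            )
            break
        drop = min(loadings.index, key=lambda i: (loadings[i], i))
        steps.append(
            ScofaStep(
                items=tuple(current),
                aic=fit.aic,
                bic=fit.bic,
                loadings=fit.loadings,
                converged=fit.converged,
                dropped=drop,
            )
        )
        dropped_order.append(drop)
        current.remove(drop)
        prev_loadings = loadings
    best = min(steps, key=lambda s: (s.aic, len(s.items)))
    return ScofaResult(
        steps=steps,
        suggested_length=len(best.items),
        elimination_order=tuple(dropped_order),
    )
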