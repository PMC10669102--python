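"""External-criterion correlations and cross-sample replication reports.

Validation of a fixed short-form solution proceeds in two ways: correlating
the short scales with external criterion variables (convergent/discriminant
validity), and re-evaluating the fixed solution in further samples without
re-optimizing (does the solution still meet the fit, reliability,
convergence, and independence cutoffs?).  Significance is flagged with the
conventional unadjusted stars (* p<0.05, ** p<0.01, *** p<0.001).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bank import ItemBank
from .factor import CFASpec, fit_cfa, sample_moments
from .reliability import cronbach_alpha, mcdonald_omega, recode


def pearson_r(x: Sequence, y: Sequence) -> tuple[float, float, int]:
    """Pearson correlation on pairwise-complete observations.

    Returns ``(r, p, n)`` with the two-sided p-value from the t
    distribution on ``n - 2`` degrees of freedom.
    """
    xs = pd.Series(np.asarray(x, dtype=float))
    ys = pd.Series(np.asarray(y, dtype=float))
    if len(xs) != len(ys):
        raise ValueError("x and y differ in length")
    mask = xs.notna() & ys.notna()
    n = int(mask.sum())
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    xv, yv = xs[mask].to_numpy(), ys[mask].to_numpy()
    if xv.std(ddof=1) == 0 or yv.std(ddof=1) == 0:
        raise ValueError("zero variance in correlation input")
    r, p = stats.pearsonr(xv, yv)
    return float(r), float(p), n


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def correlate_with_criteria(
    scores: pd.DataFrame, criteria: pd.DataFrame
) -> pd.DataFrame:
    """Correlate avoidance/anxiety scores with each criterion column.

    ``scores`` must provide ``avoidance`` and ``anxiety`` columns aligned
    (by index) with the criterion table.  One row per criterion with r,
    p-value, and pairwise-complete n for each scale.
    """
    if not {"avoidance", "anxiety"} <= set(scores.columns):
        raise ValueError("scores need 'avoidance' and 'anxiety' columns")
    criteria = criteria.reindex(scores.index)
    rows = []
    for name in criteria.columns:
        r_a, p_a, n_a = pearson_r(scores["avoidance"], criteria[name])
        r_x, p_x, n_x = pearson_r(scores["anxiety"], criteria[name])
        rows.append(
            {
                "criterion": name,
                "r_avoidance": r_a,
                "p_avoidance": p_a,
                "n_avoidance": n_a,
                "r_anxiety": r_x,
                "p_anxiety": p_x,
                "n_anxiety": n_x,
            }
        )
    return pd.DataFrame(rows).set_index("criterion")


def render_correlation_table(table: pd.DataFrame) -> str:
    """Human-readable criterion-correlation table with significance stars."""
    lines = [f"{'Criterion':<28}{'Avoidance':>12}  {'Anxiety':>12}"]
    for name, row in table.iterrows():
        a = f"{row['r_avoidance']:+.2f}{significance_stars(row['p_avoidance']):<3}"
        x = f"{row['r_anxiety']:+.2f}{significance_stars(row['p_anxiety']):<3}"
        lines.append(f"{str(name):<28}{a:>12}  {x:>12}")
    return "\n".join(lines)


@dataclass
class ReplicationReport:
    """Per-sample evaluation of a fixed two-subscale solution."""

    table: pd.DataFrame
    errors: dict

    def render(self) -> str:
        cols = [
            "sample", "scale", "n", "df", "chi_square", "p_value",
            "rmsea", "rmsea_lo", "rmsea_hi", "cfi", "omega", "alpha",
            "r_long", "r_opposite",
        ]
        frame = self.table[cols].copy()
        for c in cols[4:]:
            frame[c] = frame[c].map(lambda v: f"{v:.2f}")
        return frame.to_string(index=False)


def replicate_solution(
    solution: Mapping[str, Sequence],
    samples: Sequence[pd.DataFrame],
    bank: ItemBank,
    sample_names: Optional[Sequence[str]] = None,
    long_min_answered: int = 15,
) -> ReplicationReport:
    """Evaluate fixed avoidance/anxiety subscales in each sample.

    For every sample and scale: unidimensional CFA fit indices, omega,
    alpha, correlation with the corresponding full-length scale, and
    correlation with the opposite full-length scale.  Failures are recorded
    per sample; the report stays partial rather than aborting.
    """
    if sample_names is None:
        sample_names = [f"sample{i + 1}" for i in range(len(samples))]
    rows = []
    errors: dict = {}
    for name, responses in zip(sample_names, samples):
        try:
            data = responses.astype(float).copy()
            for iid in bank.reverse_keyed_ids:
                if iid in data.columns:
                    data[iid] = recode(data[iid])
            long_scores = {}
            for construct in ("avoidance", "anxiety"):
                ids = [
                    i for i in bank.construct_ids(construct)
                    if i in data.columns
                ]
                block = data[ids]
                answered = block.notna().sum(axis=1)
                long_scores[construct] = block.mean(axis=1).where(
                    answered >= min(long_min_answered, len(ids))
                )
            for construct, items in solution.items():
                items = list(items)
                moments = sample_moments(data[items])
                fit = fit_cfa(moments, CFASpec.unidimensional(items))
                omega = mcdonald_omega(fit.loadings, fit.residuals)
                alpha = cronbach_alpha(data[items])
                short_score = data[items].mean(axis=1)
                opposite = (
                    "anxiety" if construct == "avoidance" else "avoidance"
                )
                r_long, _, _ = pearson_r(short_score, long_scores[construct])
                r_opp, _, _ = pearson_r(short_score, long_scores[opposite])
                rows.append(
                    {
                        "sample": name,
                        "scale": construct,
                        "n": fit.n,
                        "df": fit.df,
                        "chi_square": fit.chi_square,
                        "p_value": fit.p_value,
                        "rmsea": fit.rmsea,
                        "rmsea_lo": fit.rmsea_ci[0],
                        "rmsea_hi": fit.rmsea_ci[1],
                        "cfi": fit.cfi,
                        "omega": omega,
                        "alpha": alpha,
                        "r_long": r_long,
                        "r_opposite": r_opp,
                        "converged": fit.converged,
                        "independence_met": abs(r_opp) < 0.10,
                    }
                )
        except (ValueError, KeyError, np.linalg.LinAlgError) as exc:
            errors[name] = str(exc)
    table = pd.DataFrame(rows)
    return ReplicationReport(table=table, errors=errors)
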