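"""ML CFA/EFA: moments, discrepancy minimization, fit indices, recovery."""

import numpy as np
import pandas as pd
import pytest

import shortform as sf
from shortform.factor import CFASpec, SampleMoments


def moments_from_corr(R, n):
    R = np.asarray(R, dtype=float)
    return SampleMoments(
        cov=R.copy(), corr=R.copy(), n=n, item_ids=tuple(range(1, len(R) + 1))
    )


def congeneric_corr(lam):
    lam = np.asarray(lam, dtype=float)
    R = np.outer(lam, lam)
    np.fill_diagonal(R, 1.0)
    return R


class TestSampleMoments:
    def test_hand_computed_covariance(self):
        resp = pd.DataFrame({1: [1.0, 3.0], 2: [2.0, 4.0]})
        mom = sf.sample_moments(resp)
        assert np.allclose(mom.cov, 2.0)
        assert mom.n == 2

    def test_constant_column_raises(self):
        resp = pd.DataFrame({1: [1.0, 1.0, 1.0], 2: [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="zero-variance"):
            sf.sample_moments(resp)

    def test_listwise_deletion_counts(self):
        resp = pd.DataFrame(
            {1: [1, 2, 3, np.nan, 5], 2: [2, 1, 4, 5, np.nan]}, dtype=float
        )
        assert sf.sample_moments(resp).n == 3

    def test_complete_data_keeps_all_rows(self, study788):
        mom = sf.sample_moments(study788.responses)
        assert mom.n == 788


class TestFitCFA:
    def test_perfect_fit_identity(self):
        R = congeneric_corr([0.7] * 5)
        fit = sf.fit_cfa(moments_from_corr(R, 500), CFASpec.unidimensional(range(1, 6)))
        assert fit.converged and not fit.heywood
        assert fit.chi_square < 1e-6
        assert fit.cfi == 1.0
        assert fit.rmsea == 0.0
        assert np.allclose(fit.loadings, 0.7, atol=1e-4)
        assert np.allclose(fit.residuals, 0.51, atol=1e-4)

    def test_perfect_fit_heterogeneous_loadings(self):
        lam = [0.81, 0.73, 0.51, 0.67, 0.79, 0.6]
        R = congeneric_corr(lam)
        fit = sf.fit_cfa(moments_from_corr(R, 1000), CFASpec.unidimensional(range(1, 7)))
        assert fit.chi_square < 1e-6
        assert np.allclose(fit.loadings, lam, atol=1e-4)

    def test_three_indicator_closed_form(self):
        """df=0 solution matches the exact spanned loadings to 1e-6."""
        lam = np.array([0.8, 0.7, 0.6])
        R = congeneric_corr(lam)
        fit = sf.fit_cfa(moments_from_corr(R, 200), CFASpec.unidimensional(range(1, 4)))
        r12, r13, r23 = R[0, 1], R[0, 2], R[1, 2]
        closed = np.array([
            np.sqrt(r12 * r13 / r23),
            np.sqrt(r12 * r23 / r13),
            np.sqrt(r13 * r23 / r12),
        ])
        assert np.allclose(fit.loadings, closed, atol=1e-6)

    def test_single_factor_df(self):
        assert CFASpec.unidimensional(range(5)).degrees_of_freedom() == 5

    def test_two_factor_df(self):
        spec = CFASpec.from_mapping(
            {i: ("a" if i <= 5 else "b") for i in range(1, 11)}
        )
        assert spec.degrees_of_freedom() == 34

    def test_under_identified_factor_rejected(self):
        with pytest.raises(ValueError, match="3 indicators"):
            CFASpec.from_mapping({1: "a", 2: "a", 3: "a", 4: "b", 5: "b"})

    def test_chi_square_invariant_to_item_order(self, study788, bank):
        items = list(sf.ecr.AVOIDANCE_SOLUTION)
        resp = study788.responses
        fit1 = sf.fit_cfa(
            sf.sample_moments(resp[items]), CFASpec.unidimensional(items)
        )
        rev = items[::-1]
        fit2 = sf.fit_cfa(
            sf.sample_moments(resp[rev]), CFASpec.unidimensional(rev)
        )
        assert fit1.chi_square == pytest.approx(fit2.chi_square, abs=1e-6)
        assert fit1.loadings.sort_index().round(8).equals(
            fit2.loadings.sort_index().round(8)
        )

    def test_indices_consistent_with_recomputation(self, study788):
        items = list(sf.ecr.ANXIETY_SOLUTION)
        fit = sf.fit_cfa(
            sf.sample_moments(study788.responses[items]),
            CFASpec.unidimensional(items),
        )
        assert fit.rmsea == pytest.approx(
            sf.rmsea(fit.chi_square, fit.df, fit.n), abs=1e-12
        )
        assert fit.cfi == pytest.approx(
            sf.cfi(fit.chi_square, fit.df,
                   fit.baseline_chi_square, fit.baseline_df),
            abs=1e-12,
        )

    def test_heywood_case_flagged_not_raised(self):
        # item 1 correlates more strongly than unit communality allows:
        # the exact solution has loading sqrt(.85*.85/.55) > 1, residual < 0
        R = np.array([
            [1.0, 0.85, 0.85],
            [0.85, 1.0, 0.55],
            [0.85, 0.55, 1.0],
        ])
        fit = sf.fit_cfa(moments_from_corr(R, 100), CFASpec.unidimensional(range(1, 4)))
        assert fit.heywood
        assert fit.residuals.iloc[0] < 0


class TestBaseline:
    def test_identity_correlation_gives_zero(self):
        chi2_b, df_b = sf.baseline_chi2(moments_from_corr(np.eye(4), 100))
        assert chi2_b == pytest.approx(0.0, abs=1e-10)
        assert df_b == 6

    def test_df_formula(self):
        _, df_b = sf.baseline_chi2(moments_from_corr(np.eye(5), 50))
        assert df_b == 10

    def test_hand_computed_two_item_case(self):
        R = np.array([[1.0, 0.6], [0.6, 1.0]])
        chi2_b, df_b = sf.baseline_chi2(moments_from_corr(R, 101))
        assert chi2_b == pytest.approx(-100 * np.log(0.64), abs=1e-8)
        assert chi2_b == pytest.approx(44.63, abs=0.01)
        assert df_b == 1


class TestFitIndices:
    def test_cfi_saturated(self):
        assert sf.cfi(5.0, 5, 100.0, 10) == 1.0

    def test_cfi_no_better_than_baseline(self):
        assert sf.cfi(510.0, 10, 505.0, 5) == 0.0

    def test_cfi_arithmetic(self):
        assert sf.cfi(10.10, 5, 505.0, 5) == pytest.approx(1 - 5.10 / 500)

    def test_rmsea_published_rows(self):
        assert sf.rmsea(10.10, 5, 788) == pytest.approx(0.036, abs=0.0005)
        assert sf.rmsea(17.80, 5, 462) == pytest.approx(0.0745, abs=0.0005)

    def test_rmsea_zero_when_chi2_below_df(self):
        assert sf.rmsea(3.0, 5, 200) == 0.0

    def test_rmsea_ci_brackets_point_estimate(self):
        lo, hi = sf.rmsea_ci(17.80, 5, 462)
        point = sf.rmsea(17.80, 5, 462)
        assert lo <= point <= hi
        # published interval for this row is 0.04-0.11 at two decimals
        assert round(lo, 2) == 0.04 and round(hi, 2) == 0.11

    def test_rmsea_ci_collapses_for_tiny_chi2(self):
        lo, hi = sf.rmsea_ci(0.5, 5, 500)
        assert lo == 0.0 and hi == 0.0


class TestEFA:
    def test_identity_correlation(self):
        res = sf.efa(moments_from_corr(np.eye(10), 300), n_factors=2)
        assert np.allclose(res.eigenvalues, 1.0)
        assert res.explained_variance(2) == pytest.approx(20.0)

    def test_eigenvalues_sum_to_item_count(self, study788):
        mom = sf.sample_moments(study788.responses)
        res = sf.efa(mom, n_factors=2)
        assert res.eigenvalues.sum() == pytest.approx(36.0, abs=1e-8)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)

    def test_two_factor_recovery(self, short_model, short_recoded_5000):
        mom = sf.sample_moments(short_recoded_5000)
        res = sf.efa(mom, n_factors=2, rotation="varimax")
        aligned = sf.align_loadings(res.loadings, short_model.loadings)
        assert np.abs(aligned - short_model.loadings).max() < 0.10
        # simple structure: largest loading of each item on its own factor
        own = np.abs(short_model.loadings).argmax(axis=1)
        assert (np.abs(aligned).argmax(axis=1) == own).all()


def test_explained_variance_worked_example():
    ev = (2.79, 2.43, 0.90, 0.74, 0.70, 0.68, 0.53, 0.50, 0.40, 0.34)
    assert sf.explained_variance(ev, 2) == pytest.approx(52.2, abs=0.05)


def test_explained_variance_rejects_bad_k():
    with pytest.raises(ValueError):
        sf.explained_variance((1.0, 1.0), 3)
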