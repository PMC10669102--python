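"""Composite criterion, ant colony search, exhaustive oracle, SCOFA."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import shortform as sf
from shortform import planted
from shortform.abbreviate import ACOConfig, CriterionConfig, CriterionValue


class TestLogistic:
    def test_half_at_cutoff(self):
        assert sf.logistic_component(0.95, 0.95, "higher") == 0.5

    def test_cfi_example(self):
        val = sf.logistic_component(0.99, 0.95, "higher", 100)
        assert val == pytest.approx(1 / (1 + np.exp(-4)), abs=1e-12)

    def test_rmsea_example(self):
        val = sf.logistic_component(0.07, 0.05, "lower", 100)
        assert val == pytest.approx(1 / (1 + np.exp(2)), abs=1e-12)

    def test_monotone_in_quality(self):
        higher = [sf.logistic_component(x, 0.7, "higher") for x in (0.6, 0.7, 0.8)]
        lower = [sf.logistic_component(x, 0.05, "lower") for x in (0.02, 0.05, 0.1)]
        assert higher == sorted(higher)
        assert lower == sorted(lower, reverse=True)

    def test_invalid_slope(self):
        with pytest.raises(ValueError):
            sf.logistic_component(0.5, 0.5, "higher", slope=0)


class TestEvaluator:
    def test_published_solution_meets_all_cutoffs(self, bank, study788):
        evaluator = sf.SubsetEvaluator(study788.responses, bank, "avoidance")
        value = evaluator(sf.ecr.AVOIDANCE_SOLUTION)
        assert value.converged
        assert value.cfi > 0.95
        assert value.rmsea < 0.05
        assert value.omega > 0.70
        assert value.r_long > 0.80
        assert abs(value.r_opposite) < 0.10

    def test_constant_subset_rejected_with_zero_total(self, bank, study788):
        resp = study788.responses.copy()
        for iid in (5, 11, 17, 19, 23):
            resp[iid] = 4.0
        evaluator = sf.SubsetEvaluator(resp, bank, "avoidance")
        value = evaluator((5, 11, 17, 23, 25))
        assert not value.converged and value.total == 0.0

    def test_repeated_calls_bit_identical(self, planted_evaluator):
        a = planted_evaluator((1, 2, 3, 4, 5))
        b = planted_evaluator((5, 4, 3, 2, 1))
        assert a == b

    def test_total_monotone_in_each_index(self):
        """Improving any one raw index strictly increases the total."""
        cfg = CriterionConfig()

        def total(cfi, rmsea, omega, r_long, r_opp):
            comps = [
                0.5 * (
                    sf.logistic_component(cfi, cfg.cfi_cutoff, "higher")
                    + sf.logistic_component(rmsea, cfg.rmsea_cutoff, "lower")
                ),
                sf.logistic_component(omega, cfg.omega_cutoff, "higher"),
                sf.logistic_component(r_long, cfg.convergence_cutoff, "higher"),
                sf.logistic_component(abs(r_opp), cfg.independence_cutoff, "lower"),
            ]
            return sum(comps)

        base = (0.96, 0.04, 0.75, 0.85, 0.05)
        t0 = total(*base)
        better = [
            (0.97, 0.04, 0.75, 0.85, 0.05),
            (0.96, 0.03, 0.75, 0.85, 0.05),
            (0.96, 0.04, 0.78, 0.85, 0.05),
            (0.96, 0.04, 0.75, 0.88, 0.05),
            (0.96, 0.04, 0.75, 0.85, 0.02),
        ]
        for args in better:
            assert total(*args) > t0


class TestACO:
    def test_pool_equal_k_returns_that_subset(self, planted_evaluator):
        run = sf.aco_run(
            (1, 2, 3, 4, 5), planted_evaluator, ACOConfig(patience=1), seed=0
        )
        assert tuple(run.best_subset) == (1, 2, 3, 4, 5)

    def test_evaporation_arithmetic(self):
        calls = []

        def flat(subset):
            calls.append(tuple(subset))
            return CriterionValue.rejected()  # total 0 -> zero deposit

        run = sf.aco_run(
            tuple(range(10)), flat,
            ACOConfig(n_ants=4, patience=5, k=3, max_iterations=1), seed=1,
        )
        # one evaporation step from tau_init=1.0, no deposit
        assert np.allclose(run.pheromone.to_numpy(), 0.9)

    def test_global_best_monotone_nondecreasing(self, planted_evaluator):
        run = sf.aco_run(
            planted.AVOIDANCE_POOL, planted_evaluator,
            ACOConfig(patience=10), seed=3,
        )
        gb = run.log["global_best"].to_numpy()
        assert (np.diff(gb) >= 0).all()
        assert (run.log["iteration_best"] <= run.log["global_best"] + 1e-12).all()

    def test_same_seed_reproducible(self, planted_evaluator):
        cfg = ACOConfig(patience=5, n_runs=2)
        a = sf.aco_multi(planted.AVOIDANCE_POOL, planted_evaluator, cfg, seed=9)
        b = sf.aco_multi(planted.AVOIDANCE_POOL, planted_evaluator, cfg, seed=9)
        assert tuple(a.best_subset) == tuple(b.best_subset)
        assert a.best_value == b.best_value
        assert [r.best_subset for r in a.runs] == [r.best_subset for r in b.runs]

    def test_single_run_matches_aco_run(self, planted_evaluator):
        cfg = ACOConfig(patience=5, n_runs=1)
        multi = sf.aco_multi(planted.AVOIDANCE_POOL, planted_evaluator, cfg, seed=4)
        seed = multi.runs[0].seed
        single = sf.aco_run(planted.AVOIDANCE_POOL, planted_evaluator,
                            cfg, seed=seed)
        assert tuple(single.best_subset) == tuple(multi.best_subset)

    def test_empty_pool_rejected(self, planted_evaluator):
        with pytest.raises(ValueError):
            sf.aco_run((), planted_evaluator, ACOConfig(), seed=0)

    def test_uniform_sampling_with_equal_pheromone(self):
        """With flat pheromone and zero-total solutions (no deposit), the
        sampler draws k-subsets uniformly: chi-square goodness of fit over
        all C(6,3)=20 subsets."""
        counts = {}

        def recorder(subset):
            key = tuple(sorted(subset))
            counts[key] = counts.get(key, 0) + 1
            return CriterionValue.rejected()

        sf.aco_run(
            tuple(range(6)), recorder,
            ACOConfig(n_ants=2500, patience=39, k=3, tau_min=1e-9),
            seed=7,
        )
        total = sum(counts.values())
        assert total == 2500 * 40
        assert set(counts) == set(
            tuple(sorted(c)) for c in combinations(range(6), 3)
        )
        observed = np.array(list(counts.values()))
        expected = total / 20
        chi2_stat = ((observed - expected) ** 2 / expected).sum()
        p = stats.chi2.sf(chi2_stat, 19)
        assert p > 0.001


class TestBruteForce:
    def test_enumeration_count_small_pool(self, planted_evaluator):
        res = sf.brute_force_best((1, 2, 3, 4, 5, 6), planted_evaluator, k=5)
        assert res.n_evaluated == 6
        assert len(res.ranking) == 6

    def test_budget_exceeded(self, planted_evaluator):
        with pytest.raises(ValueError, match="budget"):
            sf.brute_force_best(
                planted.AVOIDANCE_POOL, planted_evaluator, k=5, budget=100
            )
        assert math.comb(18, 5) == 8568

    def test_ranking_sorted_and_dominates_aco(self, planted_evaluator):
        res = sf.brute_force_best((1, 2, 3, 4, 5, 6, 7), planted_evaluator, k=5)
        totals = [t for _, t in res.ranking]
        assert totals == sorted(totals, reverse=True)
        run = sf.aco_run(
            (1, 2, 3, 4, 5, 6, 7), planted_evaluator,
            ACOConfig(patience=5), seed=11,
        )
        assert run.best_value.total <= res.best_value.total + 1e-12


class TestFilterAdmissible:
    def test_filters_rule_violations(self, bank):
        ranking = [((2, 22, 18, 20, 24), 3.9), ((8, 18, 20, 24, 30), 3.5),
                   ((28, 2, 4, 6, 10), 3.2)]
        kept = sf.filter_admissible(ranking, bank)
        assert kept == [((8, 18, 20, 24, 30), 3.5)]


class TestScofa:
    def test_zero_loading_item_dropped_first(self):
        lam = np.column_stack([[0.8, 0.8, 0.8, 0.8, 0.0], np.zeros(5)])
        model = sf.PopulationModel(item_ids=(1, 2, 3, 4, 5), loadings=lam)
        cont, _ = sf.simulate_continuous(model, 2_000, seed=13)
        res = sf.scofa(cont, (1, 2, 3, 4, 5))
        assert res.elimination_order[0] == 5

    def test_pool_of_three_single_step(self, planted_study):
        res = sf.scofa(planted_study.responses, (1, 2, 3))
        assert len(res.steps) == 1
        assert res.suggested_length == 3
        assert res.elimination_order == ()

    def test_weak_wording_items_eliminated_early(self, bank, study788):
        """On the ECR fixture the eleven ambiguous-wording avoidance/anxiety
        items carry the lowest loadings, so stepwise elimination sheds the
        ones in each pool before any strong item."""
        ambiguous = {1, 3, 9, 12, 13, 21, 23, 29, 31, 32, 34}
        for construct in ("avoidance", "anxiety"):
            pool = bank.construct_ids(construct)
            weak = [i for i in pool if i in ambiguous]
            res = sf.scofa(study788.responses, pool, bank)
            first_dropped = set(res.elimination_order[: len(weak)])
            assert first_dropped == set(weak)

    def test_trajectory_runs_down_to_three(self, bank, study788):
        pool = bank.construct_ids("anxiety")
        res = sf.scofa(study788.responses, pool, bank)
        sizes = res.trajectory()["pool_size"].tolist()
        assert sizes == list(range(18, 2, -1))
        assert 3 <= res.suggested_length <= 18
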