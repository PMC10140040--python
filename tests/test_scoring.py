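"""Combined-action scoring: closed-form examples, properties, oracle parity."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coaction.io import ExpressionMatrix, GeneListPair
from coaction.phenotype import ScaledPhenotype, scale_iap
from coaction.scoring import (
    CONFIGURATIONS,
    MEDIAN_SEM_FACTOR,
    combined_action_score,
    expected_additive,
    median_deviation,
    score_all_pairs,
    score_stratification,
    stratify_pair,
)
from helpers_oracle import oracle_pair_score


def _expr(data: dict[str, list[float]], samples=None) -> ExpressionMatrix:
    df = pd.DataFrame(data).T
    df.columns = samples or [f"S{i}" for i in range(df.shape[1])]
    return ExpressionMatrix(df)


def _scaled(values, samples=None) -> ScaledPhenotype:
    samples = samples or [f"S{i}" for i in range(len(values))]
    return scale_iap(pd.Series(values, index=samples, name="iap"))


class TestStratify:
    def test_four_corner_labels(self):
        expr = _expr({"A": [1, 1, 5, 5], "B": [1, 5, 1, 5]})
        strat = stratify_pair(expr, ("A", "B"), min_group_size=1)
        assert list(strat.labels) == ["LL", "LH", "HL", "HH"]

    def test_value_at_median_is_low(self):
        # median of A is 3; the sample sitting exactly there labels L
        expr = _expr({"A": [1, 3, 5], "B": [1, 2, 9]})
        strat = stratify_pair(expr, ("A", "B"), min_group_size=0)
        assert strat.labels[1][0] == "L"

    def test_counts_match_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        a = rng.normal(3.5, 1, 8)
        b = rng.normal(2.0, 1, 8)
        expr = _expr({"A": a, "B": b})
        strat = stratify_pair(expr, ("A", "B"), min_group_size=0)
        ma, mb = np.median(a), np.median(b)
        expected = {
            q: sum(
                1
                for x, y in zip(a, b)
                if ("H" if x > ma else "L") + ("H" if y > mb else "L") == q
            )
            for q in ("LL", "LH", "HL", "HH")
        }
        assert strat.quadrant_sizes == expected

    def test_undersized_quadrant_flags_unscorable(self):
        expr = _expr({"A": [1, 1, 5, 5], "B": [1, 5, 1, 5]})
        strat = stratify_pair(expr, ("A", "B"), min_group_size=2)
        assert not strat.scorable

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(7)
        a = rng.lognormal(2, 1, 30)
        b = rng.lognormal(2, 1, 30)
        s1 = stratify_pair(_expr({"A": a, "B": b}), ("A", "B"), 1)
        s2 = stratify_pair(
            _expr({"A": np.log(a), "B": np.sqrt(b)}), ("A", "B"), 1
        )
        assert list(s1.labels) == list(s2.labels)

    def test_missing_expression_excluded(self):
        expr = _expr({"A": [1, 2, np.nan, 4], "B": [4, 3, 2, 1]})
        strat = stratify_pair(expr, ("A", "B"), min_group_size=0)
        assert strat.labels[2] == ""
        assert sum(strat.quadrant_sizes.values()) == 3


class TestMedianDeviation:
    def _strat(self):
        expr = _expr({"A": np.r_[np.ones(10), 5 * np.ones(10)],
                      "B": np.r_[np.tile([1, 5], 10)]})
        return stratify_pair(expr, ("A", "B"), min_group_size=1)

    def test_raw_difference_of_medians(self):
        strat = self._strat()
        # constant-ish quadrants: sems ~ tiny, M = difference of medians
        iap = np.where(strat.labels == "HH", 0.5, 0.2)
        iap = iap + np.linspace(0, 1e-9, iap.size)  # break exact ties in sd
        dev = median_deviation(iap, strat, "HH", "LL")
        assert dev.M == pytest.approx(0.3, abs=1e-6)

    def test_thresholding_zeroes_small_deviations(self):
        strat = self._strat()
        rng = np.random.default_rng(0)
        iap = rng.normal(0.5, 0.3, strat.labels.size)
        dev = median_deviation(iap, strat, "HH", "LL")
        if abs(dev.M_raw) < dev.sem_M:
            assert dev.M == 0.0
        else:
            assert dev.M == dev.M_raw

    def test_sem_quadrature(self):
        # 3-4-5: sem_M = sqrt(sem_q^2 + sem_b^2)
        assert math.hypot(0.3, 0.4) == pytest.approx(0.5)
        strat = self._strat()
        iap = np.random.default_rng(1).normal(0, 1, strat.labels.size)
        dev = median_deviation(iap, strat, "HH", "LL")
        assert dev.sem_M == pytest.approx(
            math.hypot(dev.sem_quadrant, dev.sem_baseline)
        )

    def test_sem_is_normal_theory_estimator(self):
        strat = self._strat()
        iap = np.random.default_rng(2).normal(0, 1, strat.labels.size)
        dev = median_deviation(iap, strat, "HH", "LL")
        vals = iap[strat.mask("HH")]
        expected = MEDIAN_SEM_FACTOR * np.std(vals, ddof=1) / np.sqrt(vals.size)
        assert dev.sem_quadrant == pytest.approx(expected, rel=1e-12)


class TestExpectedAdditive:
    @pytest.mark.parametrize(
        "m1,m2,model,expected",
        [
            (0.2, 0.3, "HSA", 0.3),
            (0.2, 0.3, "bliss", 0.44),
            (0.0, 0.7, "bliss", 0.7),
            (0.0, -0.4, "bliss", -0.4),
            (-0.2, -0.3, "HSA", -0.2),
        ],
    )
    def test_reference_models(self, m1, m2, model, expected):
        assert expected_additive(m1, m2, model) == pytest.approx(expected)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            expected_additive(0.1, 0.2, "loewe")

    @given(
        m1=st.floats(0, 1, allow_nan=False),
        m2=st.floats(0, 1, allow_nan=False),
    )
    @settings(max_examples=200, derandomize=True)
    def test_hsa_below_bliss_on_unit_interval(self, m1, m2):
        assert expected_additive(m1, m2, "HSA") <= expected_additive(
            m1, m2, "bliss"
        ) + 1e-15


class TestCombinedActionScore:
    def test_planted_act_act_pair_wins_with_positive_score(self, planted_cohort):
        iap = scale_iap(planted_cohort.phenotypes.column("planted_iap"))
        res = combined_action_score(planted_cohort.expr, iap, ("TAPG", "ICPG"))
        assert res.config == "act_act"
        assert res.S is not None and res.S > 0
        assert res.sign == 1

    def test_sign_conflict_reports_missing(self):
        # IAP high only in the two single quadrants, in opposite directions
        expr = _expr({
            "A": np.r_[np.ones(20), 5 * np.ones(20)],
            "B": np.tile([1, 5], 20),
        })
        strat = stratify_pair(expr, ("A", "B"), min_group_size=1)
        rng = np.random.default_rng(3)
        iap = rng.normal(0, 0.01, 40)
        iap[strat.mask("HL")] += 5.0
        iap[strat.mask("LH")] -= 5.0
        res = score_stratification(iap, strat, "HSA")
        # act_act config: M1 (HL) and M2 (LH) have opposite signs -> missing
        from coaction.scoring import CONFIG_BY_ID, config_score
        r_aa = config_score(iap, strat, CONFIG_BY_ID["act_act"], "HSA")
        assert r_aa.S is None

    def test_constant_iap_rejected_at_scaling(self):
        with pytest.raises(Exception):
            _scaled([0.5] * 40)

    def test_symmetry_under_pair_swap(self, random_cohort):
        for seed in range(10):
            expr, iap = random_cohort(n_samples=48, seed=seed)
            r_ab = combined_action_score(expr, iap, ("G0", "G1"), min_group_size=1)
            r_ba = combined_action_score(expr, iap, ("G1", "G0"), min_group_size=1)
            assert (r_ab.S is None) == (r_ba.S is None)
            if r_ab.S is not None:
                assert r_ab.S == pytest.approx(r_ba.S, rel=1e-12)

    def test_bliss_never_exceeds_hsa_for_nonnegative_deviations(
        self, random_cohort
    ):
        for seed in range(20):
            expr, iap = random_cohort(n_samples=44, seed=100 + seed)
            h = combined_action_score(expr, iap, ("G0", "G1"), "HSA", 1)
            b = combined_action_score(expr, iap, ("G0", "G1"), "bliss", 1)
            if (
                h.S is not None and b.S is not None
                and h.config == b.config and h.sign == 1
                and h.M1 is not None and h.M1 >= 0 and h.M2 >= 0
            ):
                assert b.S <= h.S + 1e-12

    def test_sample_order_permutation_invariance(self, random_cohort):
        expr, iap = random_cohort(n_samples=40, seed=9)
        rng = np.random.default_rng(0)
        perm = rng.permutation(expr.samples)
        expr_p = ExpressionMatrix(expr.data[perm])
        iap_p = ScaledPhenotype(
            iap.name, iap.values[perm], iap.sigma, iap.branch
        )
        a = combined_action_score(expr, iap, ("G0", "G1"), min_group_size=1)
        b = combined_action_score(expr_p, iap_p, ("G0", "G1"), min_group_size=1)
        assert a.S == pytest.approx(b.S, rel=1e-12)
        assert a.config == b.config


class TestOracleEquivalence:
    """Pipeline scores equal an independent first-principles recomputation."""

    @pytest.mark.parametrize("model", ["HSA", "bliss"])
    def test_random_instances_match_brute_force(self, model):
        rng = np.random.default_rng(2024)
        checked = 0
        for _ in range(120):
            n = int(rng.integers(20, 61))
            v1 = rng.lognormal(2, 1, n)
            v2 = rng.lognormal(2, 1, n)
            iap_raw = rng.normal(0, 1, n)
            samples = [f"S{i}" for i in range(n)]
            expr = ExpressionMatrix(
                pd.DataFrame([v1, v2], index=["A", "B"], columns=samples)
            )
            iap = scale_iap(pd.Series(iap_raw, index=samples, name="x"))
            res = combined_action_score(expr, iap, ("A", "B"), model, 1)
            oracle = oracle_pair_score(
                list(v1), list(v2), list(iap.values.to_numpy()), model
            )
            if oracle is None:
                assert res.S is None
            else:
                assert res.S == pytest.approx(oracle[1], rel=1e-12, abs=1e-15)
                if res.S != 0.0:
                    assert res.config == oracle[0]
                checked += 1
        assert checked > 50  # most instances produce a definite score


class TestScoreAllPairs:
    def test_pair_count_and_order(self, random_cohort):
        expr, iap = random_cohort(n_samples=40, n_genes=5, seed=1)
        lists = GeneListPair.from_lists(
            ["G0", "G1", "G2"], ["G3", "G4"], expr
        )
        res = score_all_pairs(expr, iap, lists, min_group_size=1)
        assert [r.pair for r in res] == [
            ("G0", "G3"), ("G0", "G4"), ("G1", "G3"),
            ("G1", "G4"), ("G2", "G3"), ("G2", "G4"),
        ]

    def test_shared_gene_skips_self_pair(self, random_cohort):
        expr, iap = random_cohort(n_samples=40, n_genes=6, seed=2)
        lists = GeneListPair.from_lists(
            ["G0", "G1", "G2"], ["G2", "G3", "G4"], expr
        )
        res = score_all_pairs(expr, iap, lists, min_group_size=1)
        assert len(res) == 8
        assert ("G2", "G2") not in [r.pair for r in res]
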