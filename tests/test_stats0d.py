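"""Scalar-statistics tests: normality gate, comparison designs with the
Bonferroni alpha ladder, and the correlation machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from slipgait.stats0d import (
    compare_conditions,
    correlate,
    family_alpha,
    normality_gate,
)


class TestNormalityGate:
    def test_normal_samples_usually_pass(self):
        rng = np.random.default_rng(1)
        passed = sum(normality_gate(rng.normal(size=50)) for _ in range(50))
        assert passed >= 45

    def test_lognormal_samples_usually_fail(self):
        rng = np.random.default_rng(2)
        failed = sum(
            not normality_gate(np.exp(rng.normal(size=50))) for _ in range(50)
        )
        assert failed >= 45

    def test_constant_vector_flagged_not_eligible(self):
        assert normality_gate([2.0, 2.0, 2.0, 2.0]) is False

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            normality_gate([1.0, 2.0])


class TestFamilyAlpha:
    @pytest.mark.parametrize(
        "fam, alpha", [(5, 0.01), (7, 0.007), (8, 0.0063), (9, 0.0056),
                       (10, 0.005), (45, 0.0011)]
    )
    def test_printed_ladder(self, fam, alpha):
        assert family_alpha(fam) == alpha

    def test_generic_bonferroni_otherwise(self):
        assert family_alpha(4) == pytest.approx(0.0125)

    def test_rejects_empty_family(self):
        with pytest.raises(ValueError):
            family_alpha(0)


class TestCompareConditions:
    def test_identical_conditions_not_significant_no_posthocs(self):
        vals = np.arange(10, dtype=float)
        table = pd.DataFrame({"A": vals, "B": vals, "C": vals})
        res = compare_conditions(table, "friedman")
        assert len(res) == 1  # omnibus only
        assert not res[0].significant

    def test_large_shift_detected_with_high_power(self):
        """n = 17, three-within-SD shift: omnibus + post-hoc significant in
        at least 95 % of seeded replicates."""
        rng = np.random.default_rng(3)
        n_rep, hits = 20, 0
        for _ in range(n_rep):
            base = rng.normal(size=17)
            table = pd.DataFrame({"A": base, "B": base + 3.0 +
                                  rng.normal(size=17)})
            res = compare_conditions(table, "wilcoxon_posthoc", family_size=1)
            if all(t.significant for t in res):
                hits += 1
        assert hits >= int(0.95 * n_rep)

    def test_permuted_labels_lose_significance_at_nominal_rate(self):
        rng = np.random.default_rng(4)
        n_rep, false_pos = 60, 0
        for _ in range(n_rep):
            table = pd.DataFrame(rng.normal(size=(15, 3)),
                                 columns=["A", "B", "C"])
            res = compare_conditions(table, "friedman")
            if res[0].significant:
                false_pos += 1
        assert false_pos / n_rep <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_mixed_anova_reports_sources(self):
        rng = np.random.default_rng(5)
        table = pd.DataFrame(rng.normal(size=(12, 3)),
                             columns=["A", "B", "C"])
        table["age_group"] = ["YA"] * 6 + ["OA"] * 6
        res = compare_conditions(table, "mixed_anova", between="age_group")
        sources = {t.contrast for t in res if t.test == "mixed_anova"}
        assert {"age_group", "condition", "Interaction"} <= sources

    def test_missing_cells_rejected(self):
        table = pd.DataFrame({"A": [1.0, 2.0], "B": [1.0, np.nan]})
        with pytest.raises(ValueError):
            compare_conditions(table, "friedman")


class TestCorrelate:
    def test_exact_linear_relation_gives_pearson_one(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=30)
        res = correlate(x, 2 * x + 1)
        assert res.method == "pearson"
        assert res.coefficient == pytest.approx(1.0)

    def test_monotone_transform_of_skewed_data_selects_spearman(self):
        rng = np.random.default_rng(7)
        x = np.exp(rng.normal(size=40))  # heavily skewed
        res = correlate(x, x**3)
        assert res.method == "spearman"
        assert res.coefficient == pytest.approx(1.0)

    def test_pearson_on_ranks_equals_spearman(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        rho = sps.spearmanr(x, y).statistic
        r_ranks = sps.pearsonr(sps.rankdata(x), sps.rankdata(y)).statistic
        assert rho == pytest.approx(r_ranks, abs=1e-12)

    def test_capped_participants_excluded_and_counted(self):
        x = np.arange(10, dtype=float)
        y = 2 * x
        capped = np.zeros(10, dtype=bool)
        capped[:3] = True
        res = correlate(x, y, exclude_capped=True, capped_mask=capped)
        assert res.n == 7 and res.excluded_capped == 3

    def test_null_type_one_error_near_nominal(self):
        """Independent x, y at n = 34: about 5 % of replicates reach
        p <= 0.05, for whichever method the gate selects."""
        rng = np.random.default_rng(9)
        n_rep, sig = 400, 0
        for _ in range(n_rep):
            res = correlate(rng.normal(size=34), rng.normal(size=34))
            if res.p_value <= 0.05:
                sig += 1
        rate = sig / n_rep
        mc = 2 * np.sqrt(0.05 * 0.95 / n_rep)
        assert 0.05 - mc <= rate <= 0.05 + mc + 0.01

    def test_constant_variable_rejected(self):
        with pytest.raises(ValueError):
            correlate(np.ones(10), np.arange(10.0))

    def test_too_few_pairs_after_exclusion_rejected(self):
        with pytest.raises(ValueError):
            correlate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0],
                      exclude_capped=True,
                      capped_mask=[True, True, False])
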