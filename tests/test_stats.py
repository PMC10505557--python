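"""Assumption gate, group comparisons and compact letter displays."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import lignoporo as lp
from lignoporo.errors import DomainError
from lignoporo.stats import _pairwise_tukey, verify_letters


class TestAssumptionGate:
    def test_normal_groups_pass_at_h0_rate(self):
        # under H0 each of (k Shapiro + 1 Bartlett) tests rejects ~5%, so the
        # parametric rate is ~0.95^4 = 0.815 for k=3; assert a binomial band
        hits = 0
        for seed in range(100):
            data = lp.gen_grouped_measurements(
                [(g, "normal", 0.0, 1.0, 20) for g in "abc"], seed=seed
            )
            hits += lp.assumption_gate(data).path == "parametric"
        assert 70 <= hits <= 93

    def test_lognormal_group_forces_nonparametric(self):
        hits = 0
        for seed in range(100):
            data = lp.gen_grouped_measurements(
                [("a", "normal", 0.0, 1.0, 30), ("b", "lognormal", 0.0, 1.0, 30)],
                seed=seed,
            )
            hits += lp.assumption_gate(data).path == "nonparametric"
        assert hits > 50

    def test_constant_group_warns_and_forces_nonparametric(self):
        data = lp.GroupedMeasurements.from_dict(
            {"a": [1.0, 1.0, 1.0], "b": [2.0, 2.1, 1.9]}
        )
        gate = lp.assumption_gate(data)
        assert gate.path == "nonparametric"
        assert gate.warnings

    def test_small_groups_rejected(self):
        data = lp.GroupedMeasurements.from_dict({"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(DomainError):
            lp.assumption_gate(data)

    def test_residual_pooled_shapiro_option(self):
        data = lp.gen_grouped_measurements(
            [(g, "normal", m, 1.0, 15) for g, m in [("a", 0.0), ("b", 5.0)]], seed=4
        )
        gate = lp.assumption_gate(data, shapiro_on="residuals")
        assert set(gate.shapiro_p) == {"residuals"}


class TestCompareGroups:
    def test_identical_groups_single_letter(self):
        rng = np.random.default_rng(0)
        draw = rng.standard_normal(10)
        data = lp.GroupedMeasurements.from_dict({g: list(draw) for g in "abc"})
        res = lp.compare_groups(data, path="parametric")
        assert res.omnibus_p > 0.99
        assert set(res.letters.values()) == {"a"}

    def test_separated_groups_three_letters(self):
        data = lp.gen_grouped_measurements(
            [("a", "normal", 0.0, 1.0, 10), ("b", "normal", 10.0, 1.0, 10),
             ("c", "normal", 20.0, 1.0, 10)],
            seed=3,
        )
        res = lp.compare_groups(data, path="parametric")
        assert len(set(res.letters.values())) == 3
        assert res.omnibus_p < 1e-10

    def test_tukey_two_groups_equals_t_test(self):
        rng = np.random.default_rng(12)
        a, b = rng.normal(0, 1, 10), rng.normal(0.8, 1, 10)
        p_tukey = _pairwise_tukey({"a": a, "b": b}).loc["a", "b"]
        p_t = sps.ttest_ind(a, b).pvalue  # pooled-variance two-sample t
        assert p_tukey == pytest.approx(p_t, abs=1e-6)

    def test_nonparametric_path_runs_kruskal(self):
        data = lp.gen_grouped_measurements(
            [("a", "lognormal", 0.0, 1.0, 12), ("b", "lognormal", 1.5, 1.0, 12)],
            seed=8,
        )
        res = lp.compare_groups(data, path="nonparametric")
        kw = sps.kruskal(*data.group_values().values()).pvalue
        assert res.omnibus_p == pytest.approx(kw)

    def test_single_group_rejected(self):
        data = lp.GroupedMeasurements.from_dict({"a": [1.0, 2.0, 3.0]})
        with pytest.raises(DomainError):
            lp.compare_groups(data)

    def test_model_wrapper_summary(self):
        df = pd.DataFrame({"genotype": ["wt"] * 5 + ["mut"] * 5,
                           "yield": list(range(5)) + list(range(10, 15))})
        res = lp.GroupComparison.from_dataframe(df, "genotype", "yield").fit()
        assert "omnibus" in res.summary()
        assert set(res.letters) == {"wt", "mut"}


class TestLetterGroups:
    def _matrix(self, labels, entries):
        labels = list(labels)
        m = pd.DataFrame(np.ones((len(labels), len(labels))), index=labels, columns=labels)
        for (a, b), p in entries.items():
            m.loc[a, b] = m.loc[b, a] = p
        return m

    def test_all_nonsignificant_single_letter(self):
        letters = lp.letter_groups(self._matrix("abcd", {}), 0.05)
        assert set(letters.values()) == {"a"}

    def test_all_significant_distinct_letters(self):
        labels = "abcd"
        entries = {(x, y): 0.0 for i, x in enumerate(labels) for y in labels[i + 1 :]}
        letters = lp.letter_groups(self._matrix(labels, entries), 0.05)
        assert len(set(letters.values())) == 4

    def test_chain_case_brute_force_verified(self):
        # A~B and B~C but A!=C: the only valid 2-letter display
        m = self._matrix("ABC", {("A", "B"): 0.2, ("B", "C"): 0.2, ("A", "C"): 0.01})
        assert lp.letter_groups(m, 0.05) == {"A": "a", "B": "ab", "C": "b"}

    def test_output_always_consistent_with_matrix(self):
        rng = np.random.default_rng(33)
        labels = list("abcde")
        for _ in range(25):
            m = self._matrix(
                labels,
                {
                    (x, y): float(rng.random())
                    for i, x in enumerate(labels)
                    for y in labels[i + 1 :]
                },
            )
            letters = lp.letter_groups(m, 0.05)
            verify_letters(m.to_numpy(), letters, labels, 0.05)  # raises on defect

    def test_asymmetric_matrix_rejected(self):
        m = self._matrix("ab", {})
        m.iloc[0, 1] = 0.3
        with pytest.raises(DomainError):
            lp.letter_groups(m, 0.05)


class TestFamilywiseError:
    def test_alpha_zero_and_one_limits(self):
        assert lp.type1_error_sim(3, 5, 200, seed=1, alpha=0.0) == 0.0
        assert lp.type1_error_sim(3, 5, 200, seed=1, alpha=1.0) == 1.0

    def test_parametric_shortcut_agrees_with_tukey_matrix(self):
        # any adjusted p < alpha iff the max studentized range exceeds its
        # critical value -- checked against the full matrix decision
        rng = np.random.default_rng(9)
        q_crit = sps.studentized_range.ppf(0.95, 4, 36)
        for _ in range(20):
            values = {f"g{i}": rng.standard_normal(10) for i in range(4)}
            p = _pairwise_tukey(values).to_numpy()
            full = bool((p[np.triu_indices(4, 1)] < 0.05).any())
            arr = np.array(list(values.values()))
            means, mse = arr.mean(1), arr.var(1, ddof=1).mean()
            short = (means.max() - means.min()) / np.sqrt(mse / 10) > q_crit
            assert full == short

    def test_too_few_replicates_rejected(self):
        with pytest.raises(DomainError):
            lp.type1_error_sim(3, 5, 100, seed=1)
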