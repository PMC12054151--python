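"""Module completeness, enrichment score, and BH false-discovery control."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from oralmpg.enrichment import (
    ModuleDefinition,
    bh_adjust,
    binarize_function_table,
    enrich_by_habitat,
    enrichment_test,
    module_complete,
    module_completeness,
)
from oralmpg.simulate import simulate_function_table


def brute_force_bh(p_values):
    """Step-up definition: q_(i) = min_{j >= i} m * p_(j) / j, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for i in range(m - 1, -1, -1):
        running = min(running, m * p[order[i]] / (i + 1))
        q_sorted[i] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


MODULE4 = ModuleDefinition(
    "M1",
    (frozenset({"K1"}), frozenset({"K2"}), frozenset({"K3a", "K3b"}), frozenset({"K4"})),
)


class TestModuleCompleteness:
    def test_three_of_four_steps_is_complete_at_default(self):
        fraction = module_completeness({"K1", "K2", "K4"}, MODULE4)
        assert fraction == 0.75
        assert module_complete({"K1", "K2", "K4"}, MODULE4)

    def test_half_is_incomplete(self):
        assert module_completeness({"K1", "K2"}, MODULE4) == 0.5
        assert not module_complete({"K1", "K2"}, MODULE4)

    def test_any_alternative_satisfies_a_step(self):
        assert module_completeness({"K3b"}, MODULE4) == 0.25

    def test_monotone_in_genome_functions(self, rng):
        universe = ["K1", "K2", "K3a", "K3b", "K4"]
        for _ in range(50):
            base = {k for k in universe if rng.random() < 0.5}
            extra = str(rng.choice(universe))
            assert module_completeness(base | {extra}, MODULE4) >= module_completeness(
                base, MODULE4
            )

    def test_empty_module_rejected(self):
        with pytest.raises(ValueError):
            ModuleDefinition("M0", ())


class TestEnrichmentTest:
    groups = pd.Series({f"a{i}": "A" for i in range(5)} | {f"b{i}": "B" for i in range(5)})

    def test_perfect_separation_scores_n(self):
        presence = pd.Series(
            {f"a{i}": True for i in range(5)} | {f"b{i}": False for i in range(5)}
        )
        res = enrichment_test(presence, self.groups)
        assert res["enrichment_score"] == pytest.approx(10.0)
        assert res["associated_groups"] == frozenset({"A"})

    def test_identical_proportions_null(self):
        presence = pd.Series(
            {f"a{i}": i < 2 for i in range(5)} | {f"b{i}": i < 2 for i in range(5)}
        )
        res = enrichment_test(presence, self.groups)
        assert res["enrichment_score"] == pytest.approx(0.0)
        assert res["p_value"] == pytest.approx(1.0)

    def test_order_invariant(self, rng):
        presence = pd.Series(
            {g: bool(rng.integers(0, 2)) for g in self.groups.index}
        )
        res1 = enrichment_test(presence, self.groups)
        perm = rng.permutation(len(presence))
        res2 = enrichment_test(presence.iloc[perm], self.groups)
        assert res1["enrichment_score"] == pytest.approx(res2["enrichment_score"])
        assert res1["p_value"] == pytest.approx(res2["p_value"])

    def test_exhaustive_two_group_sweep_matches_pearson_chi2(self):
        for n1 in range(1, 13):
            for n2 in range(1, 13):
                groups = pd.Series(
                    ["A"] * n1 + ["B"] * n2,
                    index=[f"g{i}" for i in range(n1 + n2)],
                )
                for a in range(n1 + 1):
                    for b in range(n2 + 1):
                        presence = pd.Series(
                            [True] * a + [False] * (n1 - a) + [True] * b + [False] * (n2 - b),
                            index=groups.index,
                        )
                        res = enrichment_test(presence, groups)
                        if a + b == 0 or a + b == n1 + n2:
                            assert res["enrichment_score"] == 0.0
                            continue
                        ref = chi2_contingency(
                            [[a, n1 - a], [b, n2 - b]], correction=False
                        )
                        assert res["enrichment_score"] == pytest.approx(
                            ref.statistic, abs=1e-10
                        )
                        assert res["p_value"] == pytest.approx(ref.pvalue, abs=1e-10)

    def test_three_groups_use_two_df_chi2(self):
        groups = pd.Series(
            {f"a{i}": "A" for i in range(4)}
            | {f"b{i}": "B" for i in range(4)}
            | {f"c{i}": "C" for i in range(4)}
        )
        presence = pd.Series(
            {f"a{i}": True for i in range(4)}
            | {f"b{i}": i < 2 for i in range(4)}
            | {f"c{i}": False for i in range(4)}
        )
        res = enrichment_test(presence, groups)
        ref = chi2_contingency([[4, 0], [2, 2], [0, 4]], correction=False)
        assert res["enrichment_score"] == pytest.approx(ref.statistic)
        assert res["p_value"] == pytest.approx(ref.pvalue)
        assert ref.dof == 2

    def test_single_group_rejected(self):
        groups = pd.Series({"a": "A", "b": "A"})
        with pytest.raises(ValueError):
            enrichment_test(pd.Series({"a": True, "b": False}), groups)


class TestBHAdjust:
    def test_single_p_identity(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_step_up_hand_computation(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(1000):
            m = int(rng.integers(1, 40))
            p = rng.uniform(0, 1, size=m)
            assert bh_adjust(p) == pytest.approx(brute_force_bh(p), abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestEnrichByHabitat:
    groups = pd.Series(
        {f"a{i}": "A" for i in range(10)} | {f"b{i}": "B" for i in range(10)}
    )

    def test_planted_enrichments_all_flagged(self):
        planted = [(f"PL{i}", "A", 1.0, 0.0) for i in range(5)]
        table = simulate_function_table(
            self.groups, planted, background_functions=500, background_prob=0.5, seed=11
        )
        presence = binarize_function_table(table).reindex(
            self.groups.index, fill_value=False
        )
        out = enrich_by_habitat(presence, self.groups)
        flagged = set(out[out.significant]["id"])
        assert {f"PL{i}" for i in range(5)} <= flagged

    def test_pure_null_controls_false_discoveries(self):
        table = simulate_function_table(
            self.groups, [], background_functions=1000, background_prob=0.5, seed=3
        )
        presence = binarize_function_table(table).reindex(
            self.groups.index, fill_value=False
        )
        out = enrich_by_habitat(presence, self.groups)
        assert out["significant"].mean() <= 0.01

    def test_empty_table(self):
        empty = pd.DataFrame(index=self.groups.index)
        out = enrich_by_habitat(empty, self.groups)
        assert out.empty

    def test_reported_proportions(self):
        presence = pd.DataFrame(
            {"FN": [True] * 10 + [False] * 8 + [True] * 2}, index=self.groups.index
        )
        out = enrich_by_habitat(presence, self.groups).iloc[0]
        assert out["proportion_A"] == pytest.approx(1.0)
        assert out["proportion_B"] == pytest.approx(0.2)
        assert out["associated_groups"] == "A"
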