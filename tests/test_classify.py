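"""Habitat-preference classifier: bipartitions, t and Rao statistics, recovery."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency, ttest_ind

from oralmpg.classify import (
    HabitatMap,
    classify_clade,
    enumerate_bipartitions,
    rao_statistic_for_map,
    t_statistic_for_map,
)


def brute_force_bipartitions(sites):
    """Independent oracle: all unordered 2-set partitions via itertools."""
    sites = sorted(sites)
    seen = set()
    for r in range(1, len(sites)):
        for combo in itertools.combinations(sites, r):
            g1, g2 = frozenset(combo), frozenset(sites) - frozenset(combo)
            seen.add(frozenset([g1, g2]))
    return seen


class TestEnumerateBipartitions:
    @pytest.mark.parametrize("k", range(2, 11))
    def test_count_matches_closed_form_and_brute_force(self, k):
        sites = [f"S{i:02d}" for i in range(k)]
        maps = enumerate_bipartitions(sites)
        assert len(maps) == 2 ** (k - 1) - 1
        as_sets = {frozenset([m.group1, m.group2]) for m in maps}
        assert as_sets == brute_force_bipartitions(sites)
        assert len(as_sets) == len(maps)  # no duplicates

    def test_three_site_listing(self):
        maps = enumerate_bipartitions(["a", "b", "c"])
        splits = {frozenset([m.group1, m.group2]) for m in maps}
        assert splits == {
            frozenset([frozenset("a"), frozenset(["b", "c"])]),
            frozenset([frozenset("b"), frozenset(["a", "c"])]),
            frozenset([frozenset("c"), frozenset(["a", "b"])]),
        }

    def test_two_sites_single_map(self):
        assert len(enumerate_bipartitions(["x", "y"])) == 1

    def test_fewer_than_two_sites_rejected(self):
        with pytest.raises(ValueError):
            enumerate_bipartitions(["only"])

    def test_deterministic_order(self):
        a = enumerate_bipartitions(["TD", "BM", "KG"])
        b = enumerate_bipartitions(["KG", "TD", "BM"])
        assert a == b


def _series(values, sites):
    idx = [f"s{i}" for i in range(len(values))]
    return pd.Series(values, index=idx, dtype=float), pd.Series(sites, index=idx)


class TestTStatistic:
    def test_closed_form_example(self):
        values, sites = _series([1, 2, 3, 4, 5, 6], ["g1"] * 3 + ["g2"] * 3)
        hmap = HabitatMap(frozenset(["g1"]), frozenset(["g2"]))
        # pooled s^2 = 1, se = sqrt(2/3), t = -3/se
        assert t_statistic_for_map(values, sites, hmap) == pytest.approx(-3.674, abs=5e-4)

    def test_equal_distributions_zero(self):
        values, sites = _series([5, 5, 5, 5], ["a", "a", "b", "b"])
        hmap = HabitatMap(frozenset(["a"]), frozenset(["b"]))
        assert t_statistic_for_map(values, sites, hmap) == 0.0

    def test_group_swap_negates(self, rng):
        values, sites = _series(rng.normal(size=10), ["a"] * 5 + ["b"] * 5)
        fwd = t_statistic_for_map(values, sites, HabitatMap(frozenset("a"), frozenset("b")))
        rev = t_statistic_for_map(values, sites, HabitatMap(frozenset("b"), frozenset("a")))
        assert fwd == pytest.approx(-rev)

    def test_matches_scipy_pooled_t_on_random_inputs(self, rng):
        for _ in range(50):
            n1, n2 = rng.integers(2, 12, size=2)
            g1 = rng.normal(0, 1, size=n1)
            g2 = rng.normal(0.5, 2, size=n2)
            values, sites = _series(
                np.concatenate([g1, g2]), ["a"] * n1 + ["b"] * n2
            )
            hmap = HabitatMap(frozenset("a"), frozenset("b"))
            ours = t_statistic_for_map(values, sites, hmap)
            ref = ttest_ind(g1, g2, equal_var=True).statistic
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_perfect_separation_is_signed_infinity(self):
        values, sites = _series([9, 9, 0, 0], ["a", "a", "b", "b"])
        hmap = HabitatMap(frozenset("a"), frozenset("b"))
        assert t_statistic_for_map(values, sites, hmap) == math.inf

    def test_empty_group_is_undefined(self):
        values, sites = _series([1, 2], ["a", "a"])
        hmap = HabitatMap(frozenset("a"), frozenset("b"))
        assert t_statistic_for_map(values, sites, hmap) is None


class TestRaoStatistic:
    def test_known_value(self):
        det, sites = _series([1] * 8 + [0] * 2 + [1] * 2 + [0] * 8, ["a"] * 10 + ["b"] * 10)
        hmap = HabitatMap(frozenset("a"), frozenset("b"))
        assert rao_statistic_for_map(det, sites, hmap) == pytest.approx(7.2)

    def test_equal_prevalence_zero(self):
        det, sites = _series([1] * 5 + [0] * 5 + [1] * 5 + [0] * 5, ["a"] * 10 + ["b"] * 10)
        hmap = HabitatMap(frozenset("a"), frozenset("b"))
        assert rao_statistic_for_map(det, sites, hmap) == 0.0

    @pytest.mark.parametrize("fill", [0, 1])
    def test_degenerate_margin_zero(self, fill):
        det, sites = _series([fill] * 8, ["a"] * 4 + ["b"] * 4)
        hmap = HabitatMap(frozenset("a"), frozenset("b"))
        assert rao_statistic_for_map(det, sites, hmap) == 0.0

    def test_exhaustive_sweep_matches_pearson_chi2(self):
        """Every 2x2 table with group sizes <= 12 agrees with scipy's chi2."""
        hmap = HabitatMap(frozenset("a"), frozenset("b"))
        for n1 in range(1, 13):
            for n2 in range(1, 13):
                for a in range(n1 + 1):
                    for b in range(n2 + 1):
                        det, sites = _series(
                            [1] * a + [0] * (n1 - a) + [1] * b + [0] * (n2 - b),
                            ["a"] * n1 + ["b"] * n2,
                        )
                        ours = rao_statistic_for_map(det, sites, hmap)
                        m1, m0 = a + b, n1 + n2 - a - b
                        if m1 == 0 or m0 == 0:
                            assert ours == 0.0
                            continue
                        table = [[a, n1 - a], [b, n2 - b]]
                        ref = chi2_contingency(table, correction=False).statistic
                        assert ours == pytest.approx(ref, abs=1e-10)


class TestClassifyClade:
    def _community(self, rng, preferred, n_per_site=6, sites=("BM", "KG", "SUPP", "TD")):
        values, site_codes, index = [], [], []
        for site in sites:
            for i in range(n_per_site):
                mu = 20.0 if site in preferred else 0.5
                values.append(rng.gamma(10, mu / 10))
                site_codes.append(site)
                index.append(f"{site}_{i}")
        return (
            pd.Series(values, index=index),
            pd.Series(site_codes, index=index),
        )

    def test_recovers_constructed_preference_both_metrics(self, rng):
        values, sites = self._community(rng, {"TD"})
        res = classify_clade(values, sites, "abundance", site_universe=set(sites))
        assert res.preferred_sites == frozenset({"TD"})
        detections = (values > 10).astype(int)
        res_p = classify_clade(detections, sites, "prevalence", site_universe=set(sites))
        assert res_p.preferred_sites == frozenset({"TD"})

    def test_exchangeable_sites_flagged_no_preference(self):
        idx = [f"s{i}" for i in range(8)]
        values = pd.Series([3.0] * 8, index=idx)
        sites = pd.Series(["BM", "KG", "SUPP", "TD"] * 2, index=idx)
        res = classify_clade(
            values, sites, "abundance", site_universe={"BM", "KG", "SUPP", "TD"},
            min_stat=1e-9,
        )
        assert res.statistic == 0.0
        assert res.preferred_sites == frozenset()

    def test_label_equivariance(self, rng):
        values, sites = self._community(rng, {"TD"})
        relabel = {"BM": "SV", "KG": "TH", "SUPP": "PT", "TD": "SUBP"}
        res1 = classify_clade(values, sites, "abundance", site_universe=set(sites))
        res2 = classify_clade(
            values, sites.map(relabel), "abundance", site_universe=set(relabel.values())
        )
        assert res2.statistic == pytest.approx(res1.statistic)
        assert res2.preferred_sites == frozenset({"SUBP"})

    def test_invariant_to_sample_order(self, rng):
        values, sites = self._community(rng, {"KG"})
        perm = rng.permutation(len(values))
        res1 = classify_clade(values, sites, "abundance", site_universe=set(sites))
        res2 = classify_clade(
            values.iloc[perm], sites.iloc[perm], "abundance", site_universe=set(sites)
        )
        assert res1 == res2

    def test_samples_outside_universe_ignored(self, rng):
        values, sites = self._community(rng, {"TD"})
        extra = pd.Series([999.0], index=["HP_0"])
        extra_site = pd.Series(["HP"], index=["HP_0"])
        res = classify_clade(
            pd.concat([values, extra]), pd.concat([sites, extra_site]),
            "abundance", site_universe=set(sites),
        )
        assert res.preferred_sites == frozenset({"TD"})

    def test_single_site_rejected(self):
        values = pd.Series([1.0, 2.0], index=["a", "b"])
        sites = pd.Series(["TD", "TD"], index=["a", "b"])
        with pytest.raises(ValueError):
            classify_clade(values, sites, "abundance")
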