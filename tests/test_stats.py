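"""Tests of group comparisons, the paired wave test and locus enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import pulsechase as pc
from conftest import make_wave

T15 = np.arange(0, 121, 15.0)


def tidy(groups: dict) -> pd.DataFrame:
    rows = [{"value": v, "group": g} for g, vals in groups.items()
            for v in vals]
    return pd.DataFrame(rows)


class TestGroupCompare:
    def test_identical_groups_give_t_zero_p_one(self):
        res = pc.group_compare(tidy({"a": [2, 2, 2], "b": [2, 2, 2]}),
                               "t_test")
        row = res["omnibus"].iloc[0]
        assert row["statistic"] == 0.0 and row["p"] == 1.0

    def test_t_test_matches_closed_form(self):
        res = pc.group_compare(tidy({"a": [1, 2, 3], "b": [4, 5, 6]}),
                               "t_test")
        row = res["omnibus"].iloc[0]
        # pooled SD = 1, t = -3 / sqrt(2/3), df = 4
        t_expect = -3.0 / math.sqrt(2.0 / 3.0)
        assert row["statistic"] == pytest.approx(t_expect, abs=1e-12)
        assert row["p"] == pytest.approx(2 * sps.t.sf(abs(t_expect), 4),
                                         abs=1e-12)

    def test_kruskal_matches_hand_ranked_oracle(self):
        groups = {"a": [1.0, 3.0, 5.0], "b": [2.0, 4.0, 6.0],
                  "c": [7.0, 8.0, 9.0]}
        res = pc.group_compare(tidy(groups), "kruskal_dunn")
        # brute-force H from explicit ranks (no ties)
        pooled = sorted(v for vals in groups.values() for v in vals)
        rank = {v: i + 1 for i, v in enumerate(pooled)}
        n = len(pooled)
        h = 12.0 / (n * (n + 1)) * sum(
            len(v) * (np.mean([rank[x] for x in v]) - (n + 1) / 2) ** 2
            for v in groups.values())
        assert res["omnibus"]["statistic"].iloc[0] == pytest.approx(h,
                                                                    abs=1e-12)

    def test_posthoc_adjustment_never_decreases_p(self):
        rng = np.random.default_rng(0)
        groups = {g: rng.normal(i, 1, 8) for i, g in enumerate("abcd")}
        for method in ("anova_bonferroni", "kruskal_dunn"):
            post = pc.group_compare(tidy(groups), method)["posthoc"]
            assert (post["p_adjusted"] >= post["p"] - 1e-15).all()
            assert (post["p_adjusted"] <= 1.0).all()

    def test_rank_methods_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(1)
        groups = {g: rng.normal(i, 1, 10) for i, g in enumerate("abc")}
        r1 = pc.group_compare(tidy(groups), "kruskal_dunn")
        warped = {g: np.exp(v) for g, v in groups.items()}
        r2 = pc.group_compare(tidy(warped), "kruskal_dunn")
        assert r1["omnibus"]["statistic"].iloc[0] == pytest.approx(
            r2["omnibus"]["statistic"].iloc[0], abs=1e-10)
        np.testing.assert_allclose(r1["posthoc"]["z"], r2["posthoc"]["z"],
                                   atol=1e-10)

    def test_two_way_anova_detects_interaction(self):
        rng = np.random.default_rng(2)
        rows = []
        for g in ("wt", "mut"):
            for f in ("one", "two"):
                shift = 3.0 if (g == "mut" and f == "two") else 0.0
                for v in rng.normal(shift, 0.5, 10):
                    rows.append({"value": v, "group": g, "factor": f})
        res = pc.group_compare(pd.DataFrame(rows), "two_way_anova")
        tab = res["omnibus"].set_index("term")
        assert tab.loc["group:factor", "p"] < 0.001

    def test_singleton_group_rejected_for_t_test(self):
        with pytest.raises(ValueError):
            pc.group_compare(tidy({"a": [1.0], "b": [2.0, 3.0]}), "t_test")


class TestPairedWaveTest:
    def _waves(self, n, shift_bin=None, shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        waves = []
        for _ in range(n):
            series = {}
            for b in (5.0, 10.0, 15.0):
                base = np.exp(-0.5 * ((T15 - 5 * b) / 30) ** 2)
                base = base + rng.normal(0, 0.02, len(T15))
                if b == shift_bin:
                    base = base + shift
                series[("distal", b)] = base
            waves.append(make_wave(series, T15))
        return waves

    def test_identical_wave_sets_give_p_one(self):
        w = self._waves(5, seed=3)
        res = pc.paired_wave_test(w, w)
        assert (res["p"] == 1.0).all()

    def test_planted_shift_ranks_first(self):
        a = self._waves(10, seed=4)
        b = self._waves(10, shift_bin=10.0, shift=0.3, seed=5)
        res = pc.paired_wave_test(a, b)
        best = res.sort_values("p").iloc[0]
        assert best["bin"] == 10.0
        assert best["p"] < res[res["bin"] != 10.0]["p"].min()

    def test_mismatched_grids_rejected(self):
        a = self._waves(3)
        t_other = np.arange(0, 121, 30.0)
        b = [make_wave({("distal", 5.0): np.ones(len(t_other))}, t_other)]
        with pytest.raises(ValueError, match="mismatched"):
            pc.paired_wave_test(a, b)


def hypergeom_upper_tail_enumeration(n_universe, k_de, n_target, k_obs):
    """Exhaustive P(X >= k) by enumerating all C(N, n) target draws."""
    universe = range(n_universe)
    de = set(range(k_de))
    hits = total = 0
    for draw in itertools.combinations(universe, n_target):
        total += 1
        if len(de & set(draw)) >= k_obs:
            hits += 1
    return hits / total


class TestLocusEnrichment:
    def _genes(self, n):
        return [f"g{i}" for i in range(n)]

    def test_zero_overlap_gives_p_one(self):
        uni = self._genes(10)
        res = pc.locus_enrichment(uni, uni[:3], target_set=uni[5:8])
        assert res.overlap == 0 or res.gene_level_p <= 1.0
        res = pc.locus_enrichment(uni, ["g0", "g1"], target_set=["g5", "g6"])
        assert res.overlap == 0 and res.gene_level_p == 1.0

    def test_matches_combinatorial_value(self):
        # N=10, K=5, n=4, k=4 → C(5,4)·C(5,0)/C(10,4) = 5/210
        uni = self._genes(10)
        res = pc.locus_enrichment(uni, uni[:5], target_set=uni[1:5])
        assert res.overlap == 4
        assert res.gene_level_p == pytest.approx(5 / 210, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(n_universe=st.integers(4, 12), data=st.data())
    def test_matches_exhaustive_enumeration(self, n_universe, data):
        k_de = data.draw(st.integers(1, n_universe))
        n_target = data.draw(st.integers(1, n_universe))
        uni = self._genes(n_universe)
        de = uni[:k_de]
        target = uni[n_universe - n_target:]
        res = pc.locus_enrichment(uni, de, target_set=target)
        expect = hypergeom_upper_tail_enumeration(n_universe, k_de, n_target,
                                                  res.overlap)
        assert res.gene_level_p == pytest.approx(expect, abs=1e-12)

    def test_permutation_p_monotone_in_observed_count(self):
        rng = np.random.default_rng(6)
        uni = self._genes(300)
        loci = {f"L{i}": uni[10 * i:10 * i + 5] for i in range(10)}
        # stronger overlap (all loci hit) vs weaker (few loci hit)
        strong = [loci[f"L{i}"][0] for i in range(10)]
        weak = uni[200:210]
        r_strong = pc.locus_enrichment(uni, strong, loci=loci,
                                       n_permutations=500, seed=1)
        r_weak = pc.locus_enrichment(uni, weak, loci=loci,
                                     n_permutations=500, seed=1)
        assert r_strong.locus_observed > r_weak.locus_observed
        assert r_strong.locus_p <= r_weak.locus_p
        assert r_strong.locus_p >= 1.0 / 501.0

    def test_planted_enrichment_detected(self):
        # genome-scale universe: 22,753 genes, 1,256 DE, 108 loci / 348 genes
        loci_sizes = {f"L{i:03d}": (4 if i < 24 else 3) for i in range(108)}
        detections = 0
        for seed in range(20):
            truth = pc.EnrichmentTruth(universe_size=22753, n_de=1256,
                                       loci=loci_sizes,
                                       planted_fold_enrichment=3.0, seed=seed)
            uni, de, loci = pc.make_enrichment_universe(truth)
            res = pc.locus_enrichment(uni, de, loci=loci,
                                      n_permutations=300, seed=seed)
            detections += res.locus_p < 0.05
        assert detections >= 18  # ≥ 90% detection at fold 3

    def test_input_validation(self):
        with pytest.raises(ValueError, match="empty universe"):
            pc.locus_enrichment([], [], target_set=[])
        with pytest.raises(ValueError, match="loci or a target_set"):
            pc.locus_enrichment(self._genes(5), [])
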