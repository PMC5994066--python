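"""Faith PD, UniFrac (against a brute-force per-edge oracle), rarefaction
and alpha-diversity metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from airway_biogeo._tree import TreeIndex
from airway_biogeo.alpha import (alpha_metrics, build_ensemble, faith_pd,
                                 rarefy_table, RarefiedEnsemble)
from airway_biogeo.core_io import Phylogeny, PipelineConfig

from conftest import make_count_table, random_binary_tree


# ----------------------------------------------------------------------
# brute-force oracles: explicit per-edge descendant-set enumeration


def edges_with_tipsets(tree):
    out = []
    for node in tree.postorder(include_self=False):
        tips = ({node.name} if node.is_tip()
                else {t.name for t in node.tips()})
        out.append((frozenset(tips), float(node.length or 0.0)))
    return out


def faith_pd_bruteforce(tree, present):
    present = set(present)
    return sum(l for tips, l in edges_with_tipsets(tree) if tips & present)


def unweighted_unifrac_bruteforce(tree, set_a, set_b):
    unique = either = 0.0
    for tips, l in edges_with_tipsets(tree):
        in_a, in_b = bool(tips & set_a), bool(tips & set_b)
        if in_a or in_b:
            either += l
            if in_a != in_b:
                unique += l
    return unique / either if either else 0.0


def weighted_unifrac_bruteforce(tree, prop_a: dict, prop_b: dict):
    num = 0.0
    for tips, l in edges_with_tipsets(tree):
        pa = sum(prop_a.get(t, 0.0) for t in tips)
        pb = sum(prop_b.get(t, 0.0) for t in tips)
        num += l * abs(pa - pb)
    depth = {}
    for tip in tree.tips():
        d, node = 0.0, tip
        while node.parent is not None:
            d += node.length or 0.0
            node = node.parent
        depth[tip.name] = d
    denom = sum(d * (prop_a.get(t, 0.0) + prop_b.get(t, 0.0))
                for t, d in depth.items())
    return num / denom if denom else 0.0


# ----------------------------------------------------------------------


class TestFaithPd:
    @pytest.mark.parametrize("present,expected", [
        ({"A"}, 2.0), ({"A", "B"}, 3.0), ({"A", "B", "C", "D"}, 6.0),
    ])
    def test_toy_tree_values(self, toy_phylogeny, present, expected):
        assert faith_pd(present, toy_phylogeny) == pytest.approx(expected)

    def test_unknown_taxon_rejected(self, toy_phylogeny):
        with pytest.raises(KeyError):
            faith_pd({"Z"}, toy_phylogeny)

    def test_empty_set_rejected(self, toy_phylogeny):
        with pytest.raises(ValueError):
            faith_pd(set(), toy_phylogeny)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_monotone_and_total(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_binary_tree(int(rng.integers(3, 14)), rng)
        tips = [t.name for t in tree.tips()]
        ti = TreeIndex(tree, sorted(tips))
        order = list(rng.permutation(tips))
        prev = 0.0
        for k in range(1, len(order) + 1):
            val = ti.faith_pd_set(order[:k])
            assert val >= prev - 1e-12       # adding a taxon never decreases PD
            assert val == pytest.approx(
                faith_pd_bruteforce(tree, order[:k]), abs=1e-12)
            prev = val
        assert prev == pytest.approx(ti.total_branch_length)


class TestUniFracOracle:
    def test_toy_values(self, toy_phylogeny):
        ti = toy_phylogeny.index(["A", "B", "C", "D"])
        pres = np.array([[1, 1, 0, 0], [0, 0, 1, 1], [1, 0, 0, 0]], bool)
        d = ti.unweighted_unifrac(pres)
        assert d[0, 1] == pytest.approx(1.0)       # disjoint clades
        assert d[0, 2] == pytest.approx(1 / 3)     # {A,B} vs {A}
        ab = np.array([[1, 0, 0, 0], [0, 1, 0, 0]], float)
        w = ti.weighted_unifrac_normalized(ab)
        assert w[0, 1] == pytest.approx(0.5)       # all-A vs all-B

    def test_identical_samples_zero(self, toy_phylogeny):
        ti = toy_phylogeny.index(["A", "B", "C", "D"])
        pres = np.array([[1, 0, 1, 0], [1, 0, 1, 0]], bool)
        assert ti.unweighted_unifrac(pres)[0, 1] == pytest.approx(0.0)
        ab = np.array([[3, 0, 5, 0], [3, 0, 5, 0]], float)
        assert ti.weighted_unifrac_normalized(ab)[0, 1] == pytest.approx(0.0)

    def test_agrees_with_bruteforce_on_random_trees(self):
        """Both UniFrac modes equal per-edge enumeration on 200 random
        trees of up to 16 tips, to 1e-12."""
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n_tips = int(rng.integers(3, 17))
            tree = random_binary_tree(n_tips, rng)
            tips = sorted(t.name for t in tree.tips())
            ti = TreeIndex(tree, tips)
            while True:
                pres = rng.uniform(size=(2, n_tips)) < 0.5
                if pres.any(axis=1).all():
                    break
            got = ti.unweighted_unifrac(pres)[0, 1]
            want = unweighted_unifrac_bruteforce(
                tree, {t for t, m in zip(tips, pres[0]) if m},
                {t for t, m in zip(tips, pres[1]) if m})
            assert got == pytest.approx(want, abs=1e-12)

            ab = rng.uniform(0.0, 5.0, size=(2, n_tips)) * pres
            ab[:, 0] += ~pres.any(axis=1)  # guard all-zero rows
            got_w = ti.weighted_unifrac_normalized(ab)[0, 1]
            prop = ab / ab.sum(axis=1, keepdims=True)
            want_w = weighted_unifrac_bruteforce(
                tree, dict(zip(tips, prop[0])), dict(zip(tips, prop[1])))
            assert got_w == pytest.approx(want_w, abs=1e-12)

    def test_unweighted_is_a_metric(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            tree = random_binary_tree(int(rng.integers(4, 12)), rng)
            tips = sorted(t.name for t in tree.tips())
            ti = TreeIndex(tree, tips)
            pres = rng.uniform(size=(6, len(tips))) < 0.6
            pres[:, 0] |= ~pres.any(axis=1)
            d = ti.unweighted_unifrac(pres)
            assert np.allclose(d, d.T)
            assert np.allclose(np.diag(d), 0)
            for i in range(6):
                for j in range(6):
                    for k in range(6):
                        assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


def _two_sample_table():
    return make_count_table(
        {"S1_BB": {"A": 900, "B": 100}, "S2_BB": {"A": 500, "B": 500}},
        [{"sample_id": "S1_BB", "subject_id": "S1", "site": "BB", "group": "AA"},
         {"sample_id": "S2_BB", "subject_id": "S2", "site": "BB", "group": "HC"}])


class TestRarefaction:
    def test_totals_equal_depth(self):
        table = _two_sample_table()
        out = rarefy_table(table, 100, seed=1)
        assert (out.counts.sum(axis=1) == 100).all()
        assert set(out.taxa) <= set(table.taxa)

    def test_sample_at_depth_unchanged(self):
        table = _two_sample_table()
        out = rarefy_table(table, 1000, seed=1)
        assert out.counts.loc["S1_BB"].tolist() == [900, 100]

    def test_below_depth_dropped_with_warning(self):
        table2 = make_count_table(
            {"S1_BB": {"A": 50}, "S2_BB": {"A": 1000}},
            [{"sample_id": "S1_BB", "subject_id": "S1", "site": "BB", "group": "AA"},
             {"sample_id": "S2_BB", "subject_id": "S2", "site": "BB", "group": "HC"}])
        with pytest.warns(UserWarning):
            out2 = rarefy_table(table2, 600, seed=0)
        assert out2.sample_ids == ["S2_BB"]

    def test_all_below_depth_rejected(self):
        with pytest.raises(ValueError):
            rarefy_table(_two_sample_table(), 10_000, seed=0)

    def test_hypergeometric_expectation(self):
        """Mean subsampled count of a 900/1000 taxon at depth 100 matches
        the hypergeometric expectation of 90 within 3 s.e."""
        rng_seeds = range(10_000)
        table = _two_sample_table()
        total = 0
        for seed in rng_seeds:
            total += rarefy_table(table, 100, seed=seed).counts.loc["S1_BB", "A"]
        mean = total / len(rng_seeds)
        # Var of hypergeometric(N=1000, K=900, n=100)
        var = 100 * 0.9 * 0.1 * (900 / 999)
        se = np.sqrt(var / len(rng_seeds))
        assert abs(mean - 90.0) < 3 * se

    def test_deterministic_given_seed(self):
        table = _two_sample_table()
        a = rarefy_table(table, 100, seed=9).counts
        b = rarefy_table(table, 100, seed=9).counts
        assert a.equals(b)


class TestAlphaMetrics:
    def _ensemble(self, counts, toy_phylogeny):
        table = make_count_table(
            counts,
            [{"sample_id": s, "subject_id": s.split("_")[0],
              "site": s.split("_")[1], "group": "AA"} for s in counts])
        depth = int(table.counts.sum(axis=1).iloc[0])
        return RarefiedEnsemble([table], depth, [(0, 0)])

    def test_analytic_shannon(self, toy_phylogeny):
        ens = self._ensemble({"S1_BB": {"A": 2, "B": 1, "C": 1}}, toy_phylogeny)
        out = alpha_metrics(ens, toy_phylogeny)
        assert out.loc["S1_BB", "shannon"] == pytest.approx(1.5)  # bits
        assert out.loc["S1_BB", "richness"] == 3

    def test_uniform_is_even(self, toy_phylogeny):
        ens = self._ensemble({"S1_BB": {"A": 5, "B": 5, "C": 5, "D": 5}},
                             toy_phylogeny)
        out = alpha_metrics(ens, toy_phylogeny)
        assert out.loc["S1_BB", "shannon"] == pytest.approx(2.0)
        assert out.loc["S1_BB", "pielou"] == pytest.approx(1.0)
        assert out.loc["S1_BB", "faith_pd"] == pytest.approx(6.0)

    def test_single_taxon_boundary(self, toy_phylogeny):
        ens = self._ensemble({"S1_BB": {"A": 7}}, toy_phylogeny)
        out = alpha_metrics(ens, toy_phylogeny)
        assert out.loc["S1_BB", "richness"] == 1
        assert out.loc["S1_BB", "shannon"] == pytest.approx(0.0)
        assert np.isnan(out.loc["S1_BB", "pielou"])
        assert out.loc["S1_BB", "faith_pd"] > 0

    def test_shannon_bounded_by_log_richness(self, small_cohort, small_config):
        table, _, phy, _, _ = small_cohort
        ens = build_ensemble(table, small_config)
        out = alpha_metrics(ens, phy)
        assert (out["shannon"] <= np.log2(out["richness"]) + 1e-9).all()

    def test_ensemble_averaging_converges(self, small_cohort):
        """Doubling R changes each averaged metric by less than the
        across-iteration standard error."""
        table, _, phy, _, _ = small_cohort
        cfg_r = PipelineConfig(seed=5, n_rarefactions=8)
        ens = build_ensemble(table, cfg_r)
        from airway_biogeo.alpha import _alpha_one_table
        tindex = phy.index(ens.taxa)
        per = np.stack([_alpha_one_table(t, tindex)["shannon"].values
                        for t in ens.tables])
        half = per[:4].mean(axis=0)
        full = per.mean(axis=0)
        se = per.std(axis=0, ddof=1) / np.sqrt(per.shape[0])
        assert (np.abs(full - half) <= np.maximum(se, 1e-9) * 3).all()
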