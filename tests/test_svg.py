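"""Domain-restricted SVG detection: neighborhoods, tests, filters."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from spagae.datasets import SpatialDataset
from spagae.domains import DomainLabels
from spagae.graph import build_sng
from spagae.svg import (SvgConfig, bh_adjust, detect_svgs, domain_neighbors,
                        expression_percentage, in_domain_fraction,
                        summarize_svgs, wilcoxon_rank_sum)
from spagae.synthetic import SimConfig, simulate_counts, make_lattice


def chain_graph(n=5):
    coords = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
    return build_sng(coords, rad_cutoff=1.5)


def labels_from(labels_arr):
    labels_arr = np.asarray(labels_arr)
    return DomainLabels(labels=labels_arr, K=int(labels_arr.max()),
                        source="latent", bic=float("nan"))


class TestDomainNeighbors:
    def test_chain_rings(self):
        g = chain_graph(5)
        lab = labels_from([2, 2, 1, 2, 2])
        nb = domain_neighbors(g, lab, 1)
        assert set(nb.members) == {2}
        assert set(nb.first_order) == {1, 3}
        assert set(nb.second_order) == {0, 4}

    def test_domain_covering_all_spots(self):
        g = chain_graph(4)
        nb = domain_neighbors(g, labels_from([1, 1, 1, 1]), 1)
        assert nb.first_order.size == 0 and nb.second_order.size == 0

    def test_sets_pairwise_disjoint(self, graph, sim):
        _, truth = sim
        lab = labels_from(truth.true_labels)
        for d in lab.domains:
            nb = domain_neighbors(graph, lab, d)
            assert not set(nb.members) & set(nb.first_order)
            assert not set(nb.members) & set(nb.second_order)
            assert not set(nb.first_order) & set(nb.second_order)

    def test_missing_domain_errors(self):
        g = chain_graph(3)
        with pytest.raises(ValueError, match="no member"):
            domain_neighbors(g, labels_from([1, 1, 2]), 2 + 1)


class TestExpressionPercentage:
    def test_direct_evaluation(self):
        out = expression_percentage(np.array([[2, 3, 5]]))
        np.testing.assert_allclose(out, [[20.0, 30.0, 50.0]])

    def test_rows_sum_to_100_and_scale_invariant(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(4, size=(6, 5)) + 1
        out = expression_percentage(counts)
        np.testing.assert_allclose(out.sum(axis=1), 100.0)
        np.testing.assert_allclose(expression_percentage(counts * 2), out)

    def test_single_gene_all_hundred(self):
        np.testing.assert_allclose(
            expression_percentage(np.array([[7], [1]])), [[100.0], [100.0]])

    def test_zero_total_spot_errors(self):
        with pytest.raises(ValueError, match="zero-total"):
            expression_percentage(np.array([[0, 0]]))


class TestInDomainFraction:
    @pytest.fixture()
    def ds(self):
        counts = np.zeros((5, 2), dtype=int)
        counts[:4, 0] = 1   # gene g0 in 4 of 5 spots
        counts[:, 1] = 1    # gene g1 everywhere
        return SpatialDataset(counts=sp.csr_matrix(counts),
                              coords=np.zeros((5, 2)),
                              spot_ids=[f"s{i}" for i in range(5)],
                              gene_ids=["g0", "g1"])

    def test_everywhere_is_one(self, ds):
        assert in_domain_fraction(ds, np.arange(5), "g1") == 1.0

    def test_four_of_five_fails_strict_rule(self, ds):
        frac = in_domain_fraction(ds, np.arange(5), "g0")
        assert frac == pytest.approx(0.8)
        assert not frac > 0.8

    def test_absent_gene_zero(self, ds):
        ds.counts[:, 0] = 0
        assert in_domain_fraction(ds, np.arange(5), "g0") == 0.0

    def test_global_mode(self, ds):
        # 2 of the 4 expressing spots are members
        assert in_domain_fraction(ds, np.array([0, 1]), "g0",
                                  mode="global") == pytest.approx(0.5)


def rank_sum_enumeration_p(a, b):
    """Two-sided p by full enumeration of rank assignments."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for comb in itertools.combinations(range(len(pooled)), n1):
        us.append(ranks[list(comb)].sum() - n1 * (n1 + 1) / 2)
    us = np.asarray(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(1.0, p)


class TestWilcoxon:
    def test_textbook_exact_case(self):
        assert wilcoxon_rank_sum((1, 2, 3), (4, 5, 6)) == pytest.approx(0.1)

    def test_identical_samples_p_one(self):
        assert wilcoxon_rank_sum([2.0, 2.0], [2.0, 2.0]) == 1.0
        a = np.array([1.0, 2.0, 3.0])
        assert wilcoxon_rank_sum(a, a) == pytest.approx(1.0, abs=0.05)

    @pytest.mark.parametrize("n1,n2", [(1, 1), (2, 3), (3, 3), (4, 4), (5, 5),
                                       (2, 8), (4, 6)])
    def test_matches_enumeration_small_samples(self, n1, n2):
        """Exhaustive agreement with enumeration for pooled n ≤ 10."""
        n = n1 + n2
        values = np.arange(1.0, n + 1.0)
        for comb in itertools.combinations(range(n), n1):
            a = values[list(comb)]
            b = np.delete(values, list(comb))
            assert wilcoxon_rank_sum(a, b) == pytest.approx(
                rank_sum_enumeration_p(a, b), abs=1e-12), (a, b)

    def test_null_pvalues_uniform(self):
        """Large-sample p-values are uniform under the null (KS at 0.01)."""
        from scipy.stats import kstest

        rng = np.random.default_rng(13)
        ps = [wilcoxon_rank_sum(rng.normal(size=200), rng.normal(size=200))
              for _ in range(1000)]
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


def bh_oracle(p):
    """Closed-form step-up: p·m/rank with cumulative minimum."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, p[idx] * m / rank_from_top)
        adj[idx] = running
    return adj


class TestBhAdjust:
    def test_ladder_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=30))
    def test_matches_brute_force(self, pvals):
        np.testing.assert_allclose(bh_adjust(pvals), bh_oracle(pvals),
                                   atol=1e-12)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(14)
        p = rng.uniform(size=100)
        assert np.all(bh_adjust(p) >= p - 1e-15)


# ---------------------------------------------------------------------------
# detect_svgs end-to-end behaviour on planted fixtures


@pytest.fixture(scope="module")
def planted():
    from spagae.preprocess import normalize_log

    cfg = SimConfig(n_rows=14, n_cols=14, n_domains=2, n_genes=40,
                    n_svg_per_domain=4, noise_seed=21)
    coords = make_lattice(cfg.n_rows, cfg.n_cols)
    labels = np.where(coords[:, 1] < coords[:, 1].mean(), 1, 2)
    ds, truth = simulate_counts(coords, labels, cfg)
    ds = normalize_log(ds)
    g = build_sng(coords)
    return ds, truth, g, labels_from(labels)


class TestDetectSvgs:
    def test_planted_genes_detected(self, planted):
        ds, truth, g, lab = planted
        table = detect_svgs(ds, g, lab)
        detected = set(summarize_svgs(table)["gene_id"])
        planted_genes = truth.all_svgs()
        assert len(detected & planted_genes) >= 0.75 * len(planted_genes)

    def test_reported_svgs_satisfy_all_filters(self, planted):
        ds, truth, g, lab = planted
        table = detect_svgs(ds, g, lab)
        hits = table[table["is_svg"]]
        assert len(hits) > 0
        assert (hits["p_adj"] < 0.05).all()
        assert (hits["morans_i"] > 0).all()
        assert (hits["in_domain_frac"] > 0.8).all()
        assert (hits["expr_pct_target"]
                > np.maximum(hits["expr_pct_nbr1"],
                             hits["expr_pct_nbr2"])).all()

    def test_spatially_constant_gene_not_svg(self, planted):
        ds, truth, g, lab = planted
        table = detect_svgs(ds, g, lab)
        background = set(ds.gene_ids) - truth.all_svgs()
        bg_hits = table[table["is_svg"] & table["gene_id"].isin(background)]
        assert len(bg_hits) <= 0.05 * len(background) * 2

    def test_invariant_to_gene_and_spot_order(self, planted):
        ds, truth, g, lab = planted
        table = detect_svgs(ds, g, lab)
        rng = np.random.default_rng(15)
        gperm = rng.permutation(ds.n_genes)
        ds2 = ds.subset(gene_mask=gperm)
        table2 = detect_svgs(ds2, g, lab)
        key = ["gene_id", "domain"]
        merged = table.merge(table2, on=key, suffixes=("_a", "_b"))
        assert len(merged) == len(table)
        np.testing.assert_allclose(merged["p_value_a"], merged["p_value_b"],
                                   equal_nan=True, atol=1e-12)
        assert (merged["is_svg_a"] == merged["is_svg_b"]).all()

    def test_null_replicates_control_false_positives(self):
        """Spatially shuffled genes: p_adj < 0.05 fraction stays at/below α."""
        from spagae.preprocess import normalize_log

        coords = make_lattice(10, 10)
        lab_arr = np.where(coords[:, 1] < coords[:, 1].mean(), 1, 2)
        rates = []
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            counts = rng.poisson(5.0, size=(100, 60))
            ds = SpatialDataset(counts=sp.csr_matrix(counts),
                                coords=coords,
                                spot_ids=[f"s{i}" for i in range(100)],
                                gene_ids=[f"g{j}" for j in range(60)])
            ds = normalize_log(ds)
            g = build_sng(coords)
            table = detect_svgs(ds, g, labels_from(lab_arr))
            sig = (table["p_adj"] < 0.05).sum()
            rates.append(sig / max(table["p_adj"].notna().sum(), 1))
        se = np.std(rates) / np.sqrt(len(rates))
        assert np.mean(rates) <= 0.05 + 2 * se + 1e-9
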