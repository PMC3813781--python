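import itertools
from math import comb

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from agenet import corrnet, temporal
from agenet.corrnet import (
    build_corr_network,
    connectivity_enrichment,
    difference_network,
    fit_power_law,
    pair_combinations,
    read_gmt,
    replicate_combinations,
    resampled_correlation,
    resampled_correlation_matrix,
    write_gmt,
)
from agenet.temporal import ProfileSet, TemporalProfile


def tp(values, gene="g", condition="control"):
    return TemporalProfile(
        gene, condition, (1, 5, 10, 20),
        tuple(np.asarray(v, dtype=float) for v in values),
    )


def hypergeom_fisher_oracle(table):
    """Exhaustive one-sided (greater) Fisher p by summing hypergeometric terms."""
    a, b = table[0]
    c, d = table[1]
    n1, n2 = a + b, c + d
    k = a + c
    total = comb(n1 + n2, k)
    p = 0.0
    for x in range(a, min(n1, k) + 1):
        if k - x <= n2:
            p += comb(n1, x) * comb(n2, k - x) / total
    return p


class TestResampledCorrelation:
    def test_single_replicate_equals_plain_pearson(self):
        x = [[1.0], [3.0], [2.0], [5.0]]
        y = [[2.0], [2.5], [4.0], [6.0]]
        rec = resampled_correlation(tp(x, "a"), tp(y, "b"), n_draws=7, seed=0)
        expected = np.corrcoef([1, 3, 2, 5], [2, 2.5, 4, 6])[0, 1]
        assert rec.r_bar == pytest.approx(expected)

    def test_identical_genes_give_r_one_p_zero(self):
        # noise-free replicates: every joint draw sees the same two profiles
        vals = [[1.0] * 3, [2.0] * 3, [3.3] * 3, [4.0] * 2]
        rec = resampled_correlation(tp(vals, "a"), tp(vals, "b"), n_draws=50, seed=1)
        assert rec.r_bar == pytest.approx(1.0)
        assert rec.p_bar == pytest.approx(0.0, abs=1e-12)

    def test_identical_noisy_genes_near_one(self):
        # replicate noise: draws differ between the two genes, r_bar < 1
        vals = [[1.0, 1.1, 0.9], [2.0, 2.2, 1.9], [3.3, 3.1, 2.9], [4.0, 4.2]]
        rec = resampled_correlation(tp(vals, "a"), tp(vals, "b"), n_draws=50, seed=1)
        assert 0.95 < rec.r_bar < 1.0

    def test_replicate_combination_counts(self):
        vals = [[1.0] * 3, [2.0] * 3, [3.0] * 3, [4.0] * 2]
        profile = tp(vals)
        assert replicate_combinations(profile) == 54
        assert pair_combinations(profile, profile) == 2916

    def test_matrix_version_agrees_with_pairwise(self):
        rng = np.random.default_rng(2)
        blocks = [rng.normal(size=(4, 3)) for _ in range(3)] + [
            rng.normal(size=(4, 2))
        ]
        pset = ProfileSet(
            pd.Index([f"g{i}" for i in range(4)]), "control", (1, 5, 10, 20), blocks
        )
        r_bar, p_bar = resampled_correlation_matrix(pset, n_draws=400, seed=3)
        rec = resampled_correlation(pset.get("g0"), pset.get("g1"), 400, seed=4)
        # independent draw streams: agreement statistical, not exact
        assert r_bar.loc["g0", "g1"] == pytest.approx(rec.r_bar, abs=0.1)
        assert np.allclose(r_bar, r_bar.T)
        assert np.allclose(np.diag(r_bar), 1.0)


class TestCorrNetwork:
    def test_handshake_lemma(self):
        rng = np.random.default_rng(4)
        blocks = [rng.normal(size=(10, 3)) for _ in range(3)] + [
            rng.normal(size=(10, 2))
        ]
        pset = ProfileSet(
            pd.Index([f"g{i}" for i in range(10)]), "control", (1, 5, 10, 20), blocks
        )
        net = build_corr_network(pset, alpha=0.5, n_draws=20, seed=5)
        assert sum(d for _, d in net.degree()) == 2 * net.number_of_edges()

    def test_significant_edges_need_extreme_r(self):
        """With 4 ages, p_bar <= 0.05 forces |r_bar| >= ~0.95 (t-threshold)."""
        rng = np.random.default_rng(6)
        blocks = [rng.normal(size=(15, 3)) for _ in range(3)] + [
            rng.normal(size=(15, 2))
        ]
        pset = ProfileSet(
            pd.Index([f"g{i}" for i in range(15)]), "control", (1, 5, 10, 20), blocks
        )
        net = build_corr_network(pset, alpha=0.05, n_draws=50, seed=7)
        for _, _, d in net.edges(data=True):
            assert abs(d["weight"]) >= 0.9

    def test_all_noise_tiny_alpha_gives_empty_network(self):
        rng = np.random.default_rng(8)
        blocks = [rng.normal(size=(12, 3)) for _ in range(3)] + [
            rng.normal(size=(12, 2))
        ]
        pset = ProfileSet(
            pd.Index([f"g{i}" for i in range(12)]), "control", (1, 5, 10, 20), blocks
        )
        net = build_corr_network(pset, alpha=1e-6, n_draws=30, seed=9)
        assert net.number_of_edges() == 0

    def test_planted_module_recovery(self):
        """Tightly coupled module pairs connect; null pairs mostly do not."""
        rng = np.random.default_rng(10)
        n_mod, n_null = 15, 30
        ages_reps = (3, 3, 3, 2)
        factor = rng.normal(0, 1.5, size=4)  # shared temporal trajectory
        blocks = []
        for a, r in enumerate(ages_reps):
            mod = factor[a] * 0.95 + rng.normal(0, 0.15, size=(n_mod, r))
            null = rng.normal(size=(n_null, r))
            blocks.append(np.vstack([mod, null]))
        genes = pd.Index([f"m{i}" for i in range(n_mod)] +
                         [f"n{i}" for i in range(n_null)])
        pset = ProfileSet(genes, "control", (1, 5, 10, 20), blocks)
        net = build_corr_network(pset, alpha=0.05, n_draws=100, seed=11)
        mod_pairs = list(itertools.combinations([f"m{i}" for i in range(n_mod)], 2))
        null_pairs = list(itertools.combinations([f"n{i}" for i in range(n_null)], 2))
        mod_frac = np.mean([net.has_edge(u, v) for u, v in mod_pairs])
        null_frac = np.mean([net.has_edge(u, v) for u, v in null_pairs])
        assert mod_frac >= 0.8
        assert null_frac <= 0.07


class TestPowerLaw:
    def test_recovers_planted_exponent(self):
        # exact frequencies f(k) = 100 * k^-0.8 realized as a degree multiset
        ks = np.arange(1, 51)
        freqs = np.round(100 * ks ** -0.8).astype(int)
        net = nx.Graph()
        node = 0
        degs = []
        for k, f in zip(ks, freqs):
            degs += [k] * f
        # build an arbitrary graph with this degree histogram via config model
        fit = corrnet.fit_power_law(_graph_with_degrees(degs))
        assert fit.gamma == pytest.approx(-0.8, abs=0.02)

    def test_constant_frequencies_give_zero_slope(self):
        degs = [1] * 10 + [2] * 10 + [3] * 10 + [4] * 10
        fit = corrnet.fit_power_law(_graph_with_degrees(degs))
        assert fit.gamma == pytest.approx(0.0, abs=1e-9)

    def test_scaling_frequencies_changes_intercept_only(self):
        degs = [1] * 40 + [2] * 20 + [3] * 10 + [4] * 5
        fit1 = corrnet.fit_power_law(_graph_with_degrees(degs))
        fit10 = corrnet.fit_power_law(_graph_with_degrees(degs * 10))
        assert fit10.gamma == pytest.approx(fit1.gamma, abs=1e-9)
        assert fit10.log_c == pytest.approx(fit1.log_c + 1.0, abs=1e-9)

    def test_too_few_support_points(self):
        with pytest.raises(ValueError):
            corrnet.fit_power_law(_graph_with_degrees([1, 1, 2, 2]))


def _graph_with_degrees(degs):
    """Any graph whose degree histogram matches ``degs`` (fit uses only that)."""
    if sum(degs) % 2:
        degs = degs + [degs[0]]
    g = nx.configuration_model(degs, seed=0)
    g = nx.Graph(g)  # the fit only sees degrees, parallel-edge loss is fine
    # fall back to an explicit star forest if simplification changed support:
    class _DegreeView:
        def __init__(self, degs):
            self._d = degs

        def degree(self):
            return list(enumerate(self._d))

    return _DegreeView(degs)


class TestDifferenceNetwork:
    @staticmethod
    def _mat(vals, genes):
        return pd.DataFrame(vals, index=genes, columns=genes, dtype=float)

    def test_identity_and_sign_blindness_and_retention(self):
        genes = ["a", "b", "c"]
        rc = self._mat(
            [[1, 0.9, 0.2], [0.9, 1, -0.9], [0.2, -0.9, 1]], genes
        )
        rt = self._mat(
            [[1, 0.9, 0.9], [0.9, 1, 0.9], [0.9, 0.9, 1]], genes
        )
        dn = difference_network(rc, rt, tau=0.5)
        assert not dn.has_edge("a", "b")  # |0.9| - |0.9| = 0
        assert not dn.has_edge("b", "c")  # |0.9| - |-0.9| = 0 (sign-blind)
        assert dn.has_edge("a", "c")
        assert dn["a"]["c"]["weight"] == pytest.approx(0.7)

    def test_identical_matrices_empty(self):
        genes = ["a", "b"]
        r = self._mat([[1, 0.8], [0.8, 1]], genes)
        dn = difference_network(r, r.copy(), tau=0.1)
        assert dn.number_of_edges() == 0
        assert set(dn.nodes) == set(genes)

    def test_antisymmetry_under_condition_swap(self):
        rng = np.random.default_rng(12)
        genes = [f"g{i}" for i in range(6)]
        a = np.clip(rng.uniform(-1, 1, (6, 6)), -1, 1)
        a = (a + a.T) / 2
        b = np.clip(rng.uniform(-1, 1, (6, 6)), -1, 1)
        b = (b + b.T) / 2
        d1 = difference_network(self._mat(a, genes), self._mat(b, genes), tau=0.0)
        d2 = difference_network(self._mat(b, genes), self._mat(a, genes), tau=0.0)
        for u, v, d in d1.edges(data=True):
            assert d2[u][v]["weight"] == pytest.approx(-d["weight"])

    def test_mismatched_gene_sets_raise(self):
        r1 = self._mat([[1, 0], [0, 1]], ["a", "b"])
        r2 = self._mat([[1, 0], [0, 1]], ["a", "c"])
        with pytest.raises(ValueError):
            difference_network(r1, r2)


class TestEnrichment:
    @staticmethod
    def _dn(edges, nodes):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_weighted_edges_from([(u, v, 1.0) for u, v in edges])
        return g

    def test_fisher_matches_hypergeometric_oracle(self):
        from scipy.stats import fisher_exact

        tables = [
            [[9, 1], [20, 80]],
            [[3, 7], [10, 10]],
            [[0, 5], [12, 13]],
            [[5, 0], [0, 25]],
        ]
        for t in tables:
            p_scipy = fisher_exact(t, alternative="greater")[1]
            assert p_scipy == pytest.approx(hypergeom_fisher_oracle(t), rel=1e-9)

    def test_equal_fractions_not_enriched(self):
        # set and background both 50% connected
        nodes = [f"g{i}" for i in range(20)]
        edges = [(nodes[0], nodes[1]), (nodes[2], nodes[3]),
                 (nodes[10], nodes[11]), (nodes[12], nodes[13])]
        dn = self._dn(edges, nodes)
        sets = {"even": set(nodes[:8])}
        result, _ = connectivity_enrichment(dn, sets)
        assert result.iloc[0]["fisher_p"] > 0.3

    def test_small_sets_skipped(self):
        nodes = [f"g{i}" for i in range(10)]
        dn = self._dn([(nodes[0], nodes[1])], nodes)
        result, skipped = connectivity_enrichment(
            dn, {"tiny": set(nodes[:3]), "ok": set(nodes[:5])}, min_set_size=4
        )
        assert "tiny" in skipped
        assert list(result["set_id"]) == ["ok"]

    def test_enriched_module_detected_and_bh_applied(self):
        rng = np.random.default_rng(13)
        nodes = [f"g{i}" for i in range(60)]
        module = nodes[:10]
        edges = list(itertools.combinations(module, 2))
        dn = self._dn(edges, nodes)
        sets = {"module": set(module)}
        for i in range(10):
            sets[f"rand{i}"] = set(rng.choice(nodes, 10, replace=False))
        result, _ = connectivity_enrichment(dn, sets)
        assert result.iloc[0]["set_id"] == "module"
        assert result.iloc[0]["fisher_p"] < 1e-6
        assert (result["q"] >= result["fisher_p"] - 1e-15).all()


def test_gmt_round_trip(tmp_path):
    sets = {"s1": {"a", "b", "c"}, "s2": {"x", "y", "z", "w"}}
    write_gmt(sets, tmp_path / "sets.gmt", descriptions={"s1": "first"})
    back = read_gmt(tmp_path / "sets.gmt")
    assert back == sets
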