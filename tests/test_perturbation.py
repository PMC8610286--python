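import math

import numpy as np
import pytest

from oncolink.rgcn import PredictionRecord
from oncolink.perturbation import (
    binomial_tail,
    centrality_softmax,
    diff_edge_sets,
    diff_networks,
    hub_test,
)


def rec(a, b, ri):
    p = (ri + 100) / 200.0
    return PredictionRecord(gene_a=a, gene_b=b, p=p, ri=ri, label=int(ri >= 0))


class TestDiffNetworks:
    REF = [("A", "B"), ("B", "C"), ("C", "D")]

    def test_identical_networks_give_empty_diff(self):
        preds = [rec(a, b, 100) for a, b in self.REF]
        d = diff_networks(preds, self.REF)
        assert not d.gained_edges and not d.lost_edges

    def test_confidently_negative_reference_edge_is_lost(self):
        preds = [rec("A", "B", -95)]
        d = diff_networks(preds, self.REF)
        assert d.lost_edges == {("A", "B")}
        assert d.k_lost("A") == 1 and d.k_lost("B") == 1
        assert d.k_lost("C") == 0

    def test_abstain_band_contributes_to_neither_side(self):
        preds = [rec("A", "B", -60), rec("A", "D", 60)]
        d = diff_networks(preds, self.REF)
        assert not d.gained_edges and not d.lost_edges

    def test_mixed_six_pair_case_matches_manual_classification(self):
        preds = [
            rec("A", "B", 100),   # reference edge confirmed: neither
            rec("B", "C", -90),   # reference edge denied: lost
            rec("C", "D", 10),    # abstain on reference edge: neither
            rec("A", "C", 95),    # novel and confident: gained
            rec("A", "D", 80),    # novel, exactly at cutoff: gained
            rec("B", "D", -100),  # novel and denied: neither (not in ref)
        ]
        d = diff_networks(preds, self.REF, ri_cutoff=80)
        assert d.gained_edges == {("A", "C"), ("A", "D")}
        assert d.lost_edges == {("B", "C")}
        assert d.k_gained("A") == 2 and d.k_gained("C") == 1
        assert d.k_lost("B") == 1 and d.k_lost("C") == 1

    def test_undirected_normalisation_merges_orientations(self):
        preds = [rec("B", "A", 100)]
        d = diff_networks(preds, [("A", "B")])
        assert not d.gained_edges  # B->A is the same undirected edge

    def test_directed_mode_keeps_orientations_apart(self):
        preds = [rec("B", "A", 100)]
        d = diff_networks(preds, [("A", "B")], directed=True)
        assert d.gained_edges == {("B", "A")}

    @pytest.mark.parametrize("cutoff", [0, -5, 101])
    def test_cutoff_outside_range_errors(self, cutoff):
        with pytest.raises(ValueError, match="ri_cutoff"):
            diff_networks([], self.REF, ri_cutoff=cutoff)

    def test_unscorable_predictions_ignored(self):
        preds = [PredictionRecord("X", "Y", float("nan"), 0, 0, ok=False)]
        d = diff_networks(preds, self.REF)
        assert not d.gained_edges


class TestBinomialTail:
    def test_k_zero_is_exactly_one(self):
        for n, p in [(0, 0.5), (10, 0.01), (1000, 0.999)]:
            assert binomial_tail(0, n, p) == 1.0

    def test_all_successes_fair_coin(self):
        assert binomial_tail(5, 5, 0.5) == pytest.approx(0.03125, abs=1e-15)

    def test_matches_direct_pmf_summation(self):
        # oracle: sum_{i=k}^{n} C(n,i) p^i (1-p)^(n-i)
        want = sum(
            math.comb(10, i) * 0.2**i * 0.8 ** (10 - i) for i in range(3, 11)
        )
        assert want == pytest.approx(0.3222004736)
        assert binomial_tail(3, 10, 0.2) == pytest.approx(want, abs=1e-12)

    def test_telescoping_and_monotonicity(self):
        for n, p in [(20, 0.2), (50, 0.05), (7, 0.9)]:
            tails = [binomial_tail(k, n, p) for k in range(n + 1)]
            assert tails[0] == 1.0
            for k in range(n):
                pmf = math.comb(n, k) * p**k * (1 - p) ** (n - k)
                assert tails[k] - tails[k + 1] == pytest.approx(pmf, abs=1e-12)
                assert tails[k + 1] < tails[k]

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="p must"):
            binomial_tail(1, 5, 0.0)
        with pytest.raises(ValueError, match="k"):
            binomial_tail(6, 5, 0.5)


def star_diff(k, n_extra_nodes=9):
    """Directed diff: gene H holds k of the gained links, one per partner
    (plus one incoming when k exceeds the partner count)."""
    nodes = [f"P{i}" for i in range(n_extra_nodes)]
    edges = [("H", nodes[i]) for i in range(min(k, n_extra_nodes))]
    if k > n_extra_nodes:
        edges += [(nodes[i], "H") for i in range(k - n_extra_nodes)]
    return edges, nodes + ["H"]


class TestHubTest:
    def test_spec_toy_network_k10_is_type1(self):
        # L=10 genes, 10 gained links all at gene H: n=20, p=0.2,
        # raw tail P(B(20,0.2)>=10) = 0.0025948..., x10 Bonferroni = 0.0259
        gained, nodes = star_diff(10)
        d = diff_edge_sets([], gained, directed=True, nodes=nodes)
        res = {r.gene: r for r in hub_test(d, alpha=0.05)}
        h = res["H"]
        assert h.k_gained == 10
        assert h.p_gained == pytest.approx(0.0025948274006740205, rel=1e-10)
        assert h.p_adj_gained == pytest.approx(0.025948274006740205, rel=1e-10)
        assert h.hub_type == "Type1"

    def test_k9_misses_after_bonferroni(self):
        # raw 0.0099818, adjusted 0.0998 > alpha: not a hub
        gained, nodes = star_diff(9)
        extra = [("P0", "P1")]  # tenth link away from H keeps n = 20
        d = diff_edge_sets([], gained + extra, directed=True, nodes=nodes)
        res = {r.gene: r for r in hub_test(d, alpha=0.05)}
        h = res["H"]
        assert h.p_adj_gained == pytest.approx(0.09981786320724303, rel=1e-9)
        assert h.hub_type == "none"

    def test_gene_without_links_is_not_a_hub(self):
        gained, nodes = star_diff(10)
        d = diff_edge_sets([], gained, directed=True, nodes=nodes + ["LONER"])
        res = {r.gene: r for r in hub_test(d)}
        assert res["LONER"].k_gained == 0
        assert res["LONER"].p_gained == 1.0
        assert res["LONER"].hub_type == "none"

    def test_type3_needs_both_classes_significant(self):
        # 12-gene universe: H gains 10 outgoing links and loses its 10
        # incoming reference links; both tails are extreme under
        # Binom(20, 2/12), so H is enriched on both sides
        nodes = [f"P{i}" for i in range(11)] + ["H"]
        gained = [("H", f"P{i}") for i in range(10)]
        ref = [(f"P{i}", "H") for i in range(10)]
        d = diff_edge_sets(ref, gained, directed=True, nodes=nodes)
        res = {r.gene: r for r in hub_test(d)}
        assert res["H"].k_gained == 10 and res["H"].k_lost == 10
        assert res["H"].hub_type == "Type3"
        assert all(r.hub_type == "none" for r in res.values() if r.gene != "H")

    def test_standard_null_model_is_less_conservative(self):
        gained, nodes = star_diff(9)
        extra = [("P0", "P1")]
        d = diff_edge_sets([], gained + extra, directed=True, nodes=nodes)
        doubled = {r.gene: r for r in hub_test(d, null_model="doubled")}
        standard = {r.gene: r for r in hub_test(d, null_model="standard")}
        assert standard["H"].p_gained < doubled["H"].p_gained
        assert standard["H"].hub_type == "Type1"  # p=1/L recovers it

    def test_small_universe_errors(self):
        from oncolink.perturbation import NetworkDiff

        d = NetworkDiff(
            gained={"A": {("A", "B")}},
            lost={},
            gained_edges={("A", "B")},
            lost_edges=set(),
            nodes=("A",),
        )
        with pytest.raises(ValueError, match="at least 2"):
            hub_test(d)

    def test_empty_diff_errors(self):
        d = diff_edge_sets([("A", "B")], [("A", "B")], nodes=["A", "B"])
        with pytest.raises(ValueError, match="empty diff"):
            hub_test(d)


class TestPlantedHubRecovery:
    def test_planted_hubs_recovered_background_clean(self):
        from oncolink.synthetic import (
            SimConfig,
            default_hub_plan,
            gen_perturbed_network,
            gen_reference_net,
        )

        cfg = default_hub_plan(SimConfig(seed=2))
        ref = gen_reference_net(cfg)
        cancer, truth = gen_perturbed_network(ref, cfg)
        d = diff_edge_sets(ref, cancer, directed=True)
        res = {r.gene: r for r in hub_test(d, alpha=0.05)}
        recovered = sum(
            res[g].hub_type == t
            or (t in ("Type1", "Type2") and res[g].hub_type == "Type3")
            for g, t in truth.items()
        )
        false_calls = sum(
            1 for r in res.values() if r.hub_type != "none" and r.gene not in truth
        )
        assert recovered >= 9  # >= 90% of the 10 planted genes
        assert false_calls <= 0.05 * (len(res) - len(truth))

    def test_null_placement_rarely_calls_any_hub(self):
        from dataclasses import replace

        from oncolink.synthetic import (
            SimConfig,
            default_hub_plan,
            gen_perturbed_network,
            gen_reference_net,
        )

        fwe = 0
        n_rep = 100
        for rep in range(n_rep):
            cfg = replace(
                default_hub_plan(SimConfig(seed=30000 + rep)),
                hub_gain_multiplier=1.0,
            )
            ref = gen_reference_net(cfg)
            cancer, _ = gen_perturbed_network(ref, cfg)
            res = hub_test(diff_edge_sets(ref, cancer, directed=True))
            fwe += any(r.hub_type != "none" for r in res)
        assert fwe / n_rep <= 0.05


class TestCentrality:
    def test_regular_graph_is_uniform(self):
        cycle = [(f"N{i}", f"N{(i + 1) % 6}") for i in range(6)]
        c = centrality_softmax(cycle)
        for v in c.values():
            assert v == pytest.approx(1 / 6, abs=1e-9)

    def test_star_centre_strictly_maximal(self):
        star = [("HUB", f"L{i}") for i in range(5)]
        c = centrality_softmax(star)
        assert all(c["HUB"] > c[f"L{i}"] for i in range(5))

    def test_matches_dense_eigendecomposition(self):
        edges = [("A", "B"), ("B", "C"), ("C", "D"), ("A", "C")]
        damping = 0.85
        got = centrality_softmax(edges, damping=damping, tol=1e-14)
        nodes = sorted({g for e in edges for g in e})
        n = len(nodes)
        idx = {g: i for i, g in enumerate(nodes)}
        A = np.zeros((n, n))
        for a, b in edges:
            A[idx[b], idx[a]] = 1
            A[idx[a], idx[b]] = 1
        S = A / A.sum(axis=0, keepdims=True)
        M = damping * S + (1 - damping) / n
        vals, vecs = np.linalg.eig(M)
        lead = vecs[:, np.argmax(vals.real)].real
        lead = lead / lead.sum()
        ex = np.exp(lead - lead.max())
        want = ex / ex.sum()
        for g in nodes:
            assert got[g] == pytest.approx(want[idx[g]], abs=1e-8)

    def test_values_form_probability_distribution(self):
        rng = np.random.default_rng(0)
        edges = [
            (f"N{rng.integers(10)}", f"N{rng.integers(10)}") for _ in range(25)
        ]
        edges = [(a, b) for a, b in edges if a != b]
        c = centrality_softmax(edges)
        assert sum(c.values()) == pytest.approx(1.0, abs=1e-12)

    def test_disconnected_graph_converges_with_damping(self):
        edges = [("A", "B"), ("C", "D")]
        c = centrality_softmax(edges)
        assert sum(c.values()) == pytest.approx(1.0, abs=1e-12)

    def test_no_edges_errors(self):
        with pytest.raises(ValueError, match="at least one edge"):
            centrality_softmax([])
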