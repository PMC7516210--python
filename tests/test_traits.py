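"""Trait causal ODE layer and hierarchical upstream layering."""

import networkx as nx
import numpy as np
import pytest

from segn.inference import decompose, integrate_rk4
from segn.lop import fit_lop_curve
from segn.plasticity import PlasticitySeries
from segn.taxonomy import SignedNetwork
from segn.traits import build_hierarchical_network, fit_trait_system, layer_upstream


class TestLayerUpstream:
    def _net(self, edges, nodes=None):
        g = nx.DiGraph()
        if nodes:
            g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        return SignedNetwork(time=0.0, graph=g)

    def test_chain_layers(self):
        net = self._net([("a", "b"), ("b", "c")])
        layers, unreachable = layer_upstream(net, {"c"})
        assert layers == {"c": 0, "b": 1, "a": 2}
        assert unreachable == set()

    def test_unreachable_flagged(self):
        net = self._net([("a", "b")], nodes=["a", "b", "island"])
        layers, unreachable = layer_upstream(net, {"b"})
        assert unreachable == {"island"}
        assert layers["a"] == 1

    def test_empty_causal_set(self):
        net = self._net([("a", "b")])
        layers, unreachable = layer_upstream(net, set())
        assert layers == {}
        assert unreachable == {"a", "b"}

    def test_causal_genes_must_be_nodes(self):
        with pytest.raises(ValueError):
            layer_upstream(self._net([("a", "b")]), {"zz"})

    def test_random_dag_matches_shortest_path_oracle(self):
        rng = np.random.default_rng(4)
        g = nx.gnp_random_graph(25, 0.12, seed=8, directed=True)
        net = SignedNetwork(time=0.0, graph=g)
        causal = {0, 5, 9}
        layers, unreachable = layer_upstream(net, causal)
        for node in g.nodes:
            dists = []
            for c in causal:
                try:
                    dists.append(nx.shortest_path_length(g, node, c))
                except nx.NetworkXNoPath:
                    pass
            if dists:
                assert layers[node] == min(dists)
            else:
                assert node in unreachable


def _simulated_trait_setup(seed=0):
    """One trait driven by one other trait and one gene module curve."""
    rng = np.random.default_rng(seed)
    times = np.linspace(0, 12, 30)

    def osc(amp, w, phase, decay=0.1):
        return amp * np.exp(-decay * times) * np.sin(w * times + phase)

    gene_vals = {f"gene{k}": osc(8, rng.uniform(0.6, 1.4), rng.uniform(0, 6))
                 for k in range(3)}
    trait2_vals = osc(6, 1.1, 2.0)
    gene_curves = {k: fit_lop_curve(times, v, 10) for k, v in gene_vals.items()}
    t2_curve = fit_lop_curve(times, trait2_vals, 10)

    def field(t, y):
        return np.atleast_1d(
            -0.4 * y[0] + 0.8 * t2_curve(t, extrapolate=True)
            + 0.7 * gene_curves["gene0"](t, extrapolate=True) + 1.0
        )

    t1_vals = integrate_rk4(field, [2.0], times, h=0.02)[:, 0]
    t1_vals = t1_vals + rng.normal(0, 0.05, len(times))
    trait_series = {
        "trait1": PlasticitySeries("trait1", times, t1_vals, kind="trait"),
        "trait2": PlasticitySeries("trait2", times, trait2_vals, kind="trait"),
    }
    trait_curves = {
        "trait1": fit_lop_curve(times, t1_vals, 10),
        "trait2": t2_curve,
    }
    return trait_series, trait_curves, gene_curves


class TestFitTraitSystem:
    def test_recovers_trait_and_gene_drivers(self):
        hits = 0
        for seed in range(10):
            trait_series, trait_curves, gene_curves = _simulated_trait_setup(seed)
            fits = fit_trait_system(trait_series, trait_curves, gene_curves,
                                    refine=False)
            tf = fits["trait1"]
            hits += ("trait2" in tf.trait_regulators
                     and "gene0" in tf.gene_regulators)
        assert hits >= 9

    def test_component_additivity(self):
        trait_series, trait_curves, gene_curves = _simulated_trait_setup(1)
        fits = fit_trait_system(trait_series, trait_curves, gene_curves,
                                refine=False)
        dec = decompose(fits["trait1"].fit)
        assert dec.additivity_gap() < 1e-6

    def test_no_predictors_fully_independent(self):
        times = np.linspace(0, 10, 25)
        vals = 4 * np.exp(-0.3 * times) - 1.0
        rng = np.random.default_rng(2)
        decoys = {f"gene{k}": fit_lop_curve(times, rng.normal(0, 1, 25), 4)
                  for k in range(3)}
        series = {"t1": PlasticitySeries("t1", times, vals, kind="trait")}
        curves = {"t1": fit_lop_curve(times, vals, 8)}
        fits = fit_trait_system(series, curves, decoys, refine=False)
        dec = decompose(fits["t1"].fit)
        np.testing.assert_allclose(dec.p_independent, dec.g_hat, atol=1e-9)

    def test_id_collision_rejected(self):
        times = np.linspace(0, 10, 12)
        c = fit_lop_curve(times, np.sin(times), 4)
        s = {"x": PlasticitySeries("x", times, np.sin(times), kind="trait")}
        with pytest.raises(ValueError, match="collision"):
            fit_trait_system(s, {"x": c}, {"x": c})


def test_build_hierarchical_network_structure():
    trait_series, trait_curves, gene_curves = _simulated_trait_setup(3)
    fits = fit_trait_system(trait_series, trait_curves, gene_curves, refine=False)
    decs = {tid: decompose(tf.fit) for tid, tf in fits.items()}
    g = nx.DiGraph()
    g.add_edges_from([("gene1", "gene0"), ("gene2", "gene1")])
    gene_net = SignedNetwork(time=12.0, graph=g)
    hier = build_hierarchical_network(fits, decs, gene_net, t=12.0)
    # the constructed driver must appear among the causal edges
    assert any(src == "gene0" and tgt == "trait1"
               for src, tgt, _ in hier.causal_edges)
    assert all(tgt in trait_curves for _, tgt, _ in hier.causal_edges)
    # every causal source present in the gene network sits at layer 0
    causal_in_net = {s for s, _, w in hier.causal_edges
                     if w != 0.0 and s in gene_net.graph}
    for src in causal_in_net:
        assert hier.layers[src] == 0
    # all remaining genes either layered by directed distance or flagged
    assert set(gene_net.graph.nodes) == set(hier.layers) | hier.unreachable
    # trait network is over traits only
    assert set(hier.trait_network.graph.nodes) <= set(trait_curves)
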