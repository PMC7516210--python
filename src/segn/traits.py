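"""Trait-level causal ODEs and hierarchical gene-to-trait layering.

Each trait's phenotypic-plasticity dynamics are decomposed into an
independent component, dependent components driven by the other traits,
and dependent components driven by gene (or module) expression curves:

    du_j/dt = R_j(u_j) + sum_{j'} R_jj'(u_j') + sum_i S_ji(g_i).

The same two-stage machinery as the gene network is reused with a pooled
candidate set (other traits + genes), so the trait network, the gene
network, and the gene->trait causal edges form one hierarchical system.
Upstream genes are layered by their shortest directed-path distance to the
genes that enter the causal network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .inference import DecomposedTrajectory, OdeFit, decompose, fit_ode, select_regulators
from .lop import LopCurve
from .plasticity import PlasticitySeries
from .taxonomy import SignedNetwork

__all__ = [
    "TraitOdeFit",
    "HierarchicalNetwork",
    "fit_trait_system",
    "layer_upstream",
    "build_hierarchical_network",
]


@dataclass
class TraitOdeFit:
    """ODE fit for one trait with regulators split by kind."""

    fit: OdeFit
    trait_regulators: list[str]
    gene_regulators: list[str]

    @property
    def trait_id(self) -> str:
        return self.fit.target_id


def fit_trait_system(
    trait_series: dict[str, PlasticitySeries],
    trait_curves: dict[str, LopCurve],
    gene_curves: dict[str, LopCurve],
    d_max: int = 5,
    comp_order: int = 3,
    refine: bool = True,
    n_starts: int = 8,
    seed: int = 1,
) -> dict[str, TraitOdeFit]:
    """Fit the trait ODE system with a pooled trait+gene candidate set.

    Variable selection runs jointly over all other traits and all gene
    (or module mean) curves; the selected subset is then fitted as in the
    gene-level system.  Trait and gene identifiers must not collide.
    """
    overlap = set(trait_curves) & set(gene_curves)
    if overlap:
        raise ValueError(f"trait/gene identifier collision: {sorted(overlap)}")
    fits = {}
    for tid, series in trait_series.items():
        pool = {k: v for k, v in trait_curves.items() if k != tid}
        pool.update(gene_curves)
        selected = select_regulators(trait_curves[tid], pool, d_max=d_max,
                                     comp_order=comp_order, target_series=series)
        fit = fit_ode(
            series, trait_curves[tid],
            {rid: pool[rid] for rid in selected},
            comp_order=comp_order, refine=refine, n_starts=n_starts, seed=seed,
        )
        fits[tid] = TraitOdeFit(
            fit=fit,
            trait_regulators=[r for r in selected if r in trait_curves],
            gene_regulators=[r for r in selected if r in gene_curves],
        )
    return fits


@dataclass
class HierarchicalNetwork:
    """Trait network + gene->trait causal edges + upstream gene layers."""

    trait_network: SignedNetwork | None
    causal_edges: list[tuple[str, str, float]]   # (gene/module, trait, weight)
    layers: dict[str, int] = field(default_factory=dict)
    unreachable: set[str] = field(default_factory=set)


def layer_upstream(gene_network: SignedNetwork | nx.DiGraph, causal_genes) -> tuple[dict[str, int], set[str]]:
    """Layer genes by directed distance to the causal gene set.

    Layer 0 genes are the causal genes themselves (direct edges into a
    trait); layer k genes reach a causal gene in exactly k directed hops.
    Genes with no directed path to the causal set are returned as
    unreachable.  An empty causal set makes every gene unreachable.
    """
    g = gene_network.graph if isinstance(gene_network, SignedNetwork) else gene_network
    causal = set(causal_genes)
    if not causal <= set(g.nodes):
        raise ValueError("causal genes must be network nodes")
    if not causal:
        return {}, set(g.nodes)
    # BFS on the reversed graph gives distance *to* the causal set
    dist = nx.multi_source_dijkstra_path_length(g.reverse(copy=False), causal, weight=None)
    layers = {n: int(d) for n, d in dist.items()}
    unreachable = set(g.nodes) - set(layers)
    return layers, unreachable


def build_hierarchical_network(
    trait_fits: dict[str, TraitOdeFit],
    trait_decompositions: dict[str, DecomposedTrajectory],
    gene_network: SignedNetwork,
    t: float,
) -> HierarchicalNetwork:
    """Assemble the causal layer at time ``t`` from fitted trait ODEs."""
    from .taxonomy import build_network

    trait_only = {
        tid: DecomposedTrajectory(
            target_id=tid, times=dec.times, g_hat=dec.g_hat,
            p_independent=dec.p_independent,
            p_dependent={r: dec.p_dependent[r]
                         for r in trait_fits[tid].trait_regulators},
        )
        for tid, dec in trait_decompositions.items()
    }
    trait_net = build_network(trait_only, t) if trait_only else None

    causal_edges = []
    for tid, tf in trait_fits.items():
        dec = trait_decompositions[tid]
        for gid in tf.gene_regulators:
            causal_edges.append((gid, tid, dec.edge_weight(gid, t)))

    causal_genes = {g for g, _, w in causal_edges if w != 0.0}
    causal_genes &= set(gene_network.graph.nodes)
    layers, unreachable = layer_upstream(gene_network, causal_genes)
    return HierarchicalNetwork(
        trait_network=trait_net,
        causal_edges=causal_edges,
        layers=layers,
        unreachable=unreachable,
    )
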