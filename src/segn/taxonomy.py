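"""Interaction taxonomy and time-stamped signed networks.

The cumulative dependent contributions P_ii'(t) (effect of i' on i) and
P_i'i(t) (effect of i on i') classify each gene pair at a time t into one
of eleven interaction types: symmetric/asymmetric synergism (both
positive, equal or unequal magnitude), directional synergism (one
positive, one zero), altruism/exploitation (one positive, one negative),
symmetric/asymmetric antagonism (both negative), directional antagonism
(one negative, one zero), and coexistence (both zero).  Values within an
epsilon band around zero count as zero; magnitude equality uses a relative
tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import networkx as nx
import numpy as np

from .inference import DecomposedTrajectory

__all__ = ["EdgeClass", "classify_pair", "SignedNetwork", "build_network", "detect_hubs"]


class EdgeClass(str, Enum):
    SYMMETRIC_SYNERGISM = "symmetric_synergism"
    ASYMMETRIC_SYNERGISM = "asymmetric_synergism"
    DIRECTIONAL_SYNERGISM_TOWARD_I = "directional_synergism_toward_i"
    DIRECTIONAL_SYNERGISM_TOWARD_IPRIME = "directional_synergism_toward_iprime"
    ALTRUISM_TOWARD_I = "altruism_toward_i"
    ALTRUISM_TOWARD_IPRIME = "altruism_toward_iprime"
    SYMMETRIC_ANTAGONISM = "symmetric_antagonism"
    ASYMMETRIC_ANTAGONISM = "asymmetric_antagonism"
    DIRECTIONAL_ANTAGONISM_TOWARD_I = "directional_antagonism_toward_i"
    DIRECTIONAL_ANTAGONISM_TOWARD_IPRIME = "directional_antagonism_toward_iprime"
    COEXISTENCE = "coexistence"


def classify_pair(
    p_toward_i: float,
    p_toward_iprime: float,
    epsilon: float = 0.0,
    equal_rel_tol: float = 0.1,
) -> EdgeClass:
    """Map the pair (P_ii'(t), P_i'i(t)) onto the eleven-class taxonomy.

    ``p_toward_i`` is the dependent contribution of i' to i and
    ``p_toward_iprime`` that of i to i'.  ``epsilon >= 0`` is the
    zero band; magnitudes within ``equal_rel_tol`` relative difference
    count as equal for the symmetric/asymmetric split.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    a, b = float(p_toward_i), float(p_toward_iprime)
    sa = 0 if abs(a) <= epsilon else (1 if a > 0 else -1)
    sb = 0 if abs(b) <= epsilon else (1 if b > 0 else -1)

    if sa == 0 and sb == 0:
        return EdgeClass.COEXISTENCE
    if sa == 1 and sb == 1:
        equal = abs(a - b) <= equal_rel_tol * max(abs(a), abs(b))
        return EdgeClass.SYMMETRIC_SYNERGISM if equal else EdgeClass.ASYMMETRIC_SYNERGISM
    if sa == -1 and sb == -1:
        equal = abs(abs(a) - abs(b)) <= equal_rel_tol * max(abs(a), abs(b))
        return EdgeClass.SYMMETRIC_ANTAGONISM if equal else EdgeClass.ASYMMETRIC_ANTAGONISM
    if sa == 1 and sb == 0:
        return EdgeClass.DIRECTIONAL_SYNERGISM_TOWARD_I
    if sa == 0 and sb == 1:
        return EdgeClass.DIRECTIONAL_SYNERGISM_TOWARD_IPRIME
    if sa == -1 and sb == 0:
        return EdgeClass.DIRECTIONAL_ANTAGONISM_TOWARD_I
    if sa == 0 and sb == -1:
        return EdgeClass.DIRECTIONAL_ANTAGONISM_TOWARD_IPRIME
    if sa == 1 and sb == -1:
        return EdgeClass.ALTRUISM_TOWARD_I
    return EdgeClass.ALTRUISM_TOWARD_IPRIME


@dataclass
class SignedNetwork:
    """Directed signed weighted snapshot of the regulatory system at time t."""

    time: float
    graph: nx.DiGraph
    pair_classes: dict[frozenset, EdgeClass] = field(default_factory=dict)
    epsilon: float = 0.0

    @property
    def hubs(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("hub")}

    def edge_table(self):
        """Tidy rows (time, source, target, weight, sign, pair_class)."""
        import pandas as pd

        rows = []
        for u, v, d in self.graph.edges(data=True):
            cls = self.pair_classes.get(frozenset((u, v)), EdgeClass.COEXISTENCE)
            rows.append({
                "time": self.time, "source": u, "target": v,
                "weight": d["weight"], "sign": "+" if d["weight"] > 0 else "-",
                "pair_class": cls.value,
            })
        return pd.DataFrame(rows, columns=["time", "source", "target", "weight",
                                           "sign", "pair_class"])


def build_network(
    decompositions: dict[str, DecomposedTrajectory],
    t: float,
    epsilon: float | None = None,
    epsilon_rel: float = 0.05,
    equal_rel_tol: float = 0.1,
) -> SignedNetwork:
    """Assemble the signed network snapshot at time ``t``.

    An edge i' -> i is drawn when i' is a selected regulator of i and its
    cumulative contribution exceeds the zero band.  ``epsilon`` defaults to
    ``epsilon_rel`` times the largest |P| over all pairs at ``t``.
    """
    nodes = set(decompositions)
    weights: dict[tuple[str, str], float] = {}
    t_ranges = []
    for target, dec in decompositions.items():
        t_ranges.append((dec.times[0], dec.times[-1]))
        for rid, _ in dec.p_dependent.items():
            nodes.add(rid)
            weights[(rid, target)] = dec.edge_weight(rid, t)
    lo = min((a for a, _ in t_ranges), default=0.0)
    hi = max((b for _, b in t_ranges), default=0.0)
    if t < lo - 1e-9 or t > hi + 1e-9:
        raise ValueError(f"snapshot time {t} outside fitted domain [{lo}, {hi}]")

    if epsilon is None:
        max_p = max((abs(w) for w in weights.values()), default=0.0)
        epsilon = epsilon_rel * max_p

    g = nx.DiGraph(time=t, epsilon=epsilon)
    g.add_nodes_from(sorted(nodes))
    for (src, tgt), w in weights.items():
        if abs(w) > epsilon:
            g.add_edge(src, tgt, weight=w, sign="+" if w > 0 else "-")

    classes = {}
    node_list = sorted(nodes)
    for idx, i in enumerate(node_list):
        for iprime in node_list[idx + 1:]:
            p_i = weights.get((iprime, i), 0.0)
            p_ip = weights.get((i, iprime), 0.0)
            classes[frozenset((i, iprime))] = classify_pair(
                p_i, p_ip, epsilon=epsilon, equal_rel_tol=equal_rel_tol
            )

    net = SignedNetwork(time=t, graph=g, pair_classes=classes, epsilon=epsilon)
    for n in detect_hubs(net):
        g.nodes[n]["hub"] = True
    return net


def detect_hubs(network: SignedNetwork) -> set[str]:
    """Nodes whose total (in + out) degree strictly exceeds the network mean."""
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    degrees = dict(g.degree())
    mean_deg = float(np.mean(list(degrees.values())))
    return {n for n, d in degrees.items() if d > mean_deg}
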