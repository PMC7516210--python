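"""Ground-truth regulatory systems and noisy two-treatment observations.

The generator samples a sparse directed network and smooth component
functions, integrates the coupled plasticity ODE forward from a common
pre-treatment baseline, and emits a two-treatment expression dataset whose
treatment difference (DTP) recovers the trajectory up to additive Gaussian
noise.

Default dynamics (one-time design choices, see the methods note):
plasticity runs on the scale of expression-count differences (amplitudes
of order ten).  Intrinsic terms are mean-reverting affine functions
a_i + b_i g_i with drive |a_i| in [2, 10] and slow decay b_i in
[-0.5, -0.15]; initial plasticity magnitudes are randomized over
[3, 8] with random sign, so the stress onset excites every dynamical
mode.  Most edges (70%) are laid down as mutually regulated pairs with
opposite-sign couplings of pair-specific strength — mutual regulation is
the dominant motif between co-expression modules in stress-response
networks — which gives the system damped rotational modes at dispersed
frequencies and the non-monotone, multi-timescale plasticity curves seen
in real time courses.  The remaining edges are one-directional,
c (g + kappa g^2 / 10) with mixed-sign strength |c| drawn log-uniformly
over [0.3, 1.0] — a range spanning marginally detectable to strong
coupling — and curvature |kappa| in [0.3, 0.7] relative to the ten-unit
amplitude scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import integrate_rk4
from .io import ExpressionDataset

__all__ = ["GroundTruth", "simulate_system", "replicate_seeds"]


@dataclass
class GroundTruth:
    """Generating system: graph, component coefficients, noise, trajectories."""

    gene_ids: list[str]
    edges: list[tuple[str, str]]          # (regulator, target), no self-loops
    intrinsic: dict[str, tuple[float, float]]          # a_i, b_i
    couplings: dict[tuple[str, str], tuple[float, float]]   # c, kappa
    delta_sq: float
    times: np.ndarray
    trajectories: np.ndarray              # genes x T, noiseless DTP
    seed: int

    @property
    def m(self) -> int:
        return len(self.gene_ids)

    @property
    def edge_set(self) -> set[tuple[str, str]]:
        return set(self.edges)

    def ordered_pairs(self) -> list[tuple[str, str]]:
        return [(a, b) for a in self.gene_ids for b in self.gene_ids if a != b]


def replicate_seeds(master_seed: int, n: int) -> list[int]:
    """Independent per-replicate seeds derived from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2**31 - 1)) for child in ss.spawn(n)]


AMPLITUDE_SCALE = 10.0   # nominal plasticity amplitude (count-difference units)


def _sample_system(m, n_edges, rng, mutual_frac=0.7):
    """Random sparse regulatory system with stable oscillatory cores.

    Mutually regulated pairs (opposite-sign linear couplings, pair-specific
    frequency) sit upstream in a random topological order; the remaining
    one-directional edges point strictly downstream, so the system is a
    cascade of damped oscillator cores driving a DAG of targets — stable by
    construction while keeping curve shapes diverse and non-monotone.
    """
    order = rng.permutation(m)
    gene_ids = [f"g{i:02d}" for i in range(m)]
    topo = {gene_ids[g]: int(np.where(order == g)[0][0]) for g in range(m)}
    intrinsic = {
        gid: (
            float(rng.choice([-1, 1]) * rng.uniform(2.0, 10.0)),
            float(-rng.uniform(0.15, 0.5)),
        )
        for gid in gene_ids
    }
    n_mutual_pairs = min(int(round(mutual_frac * n_edges / 2.0)), m // 2)
    n_single = n_edges - 2 * n_mutual_pairs

    # pair the 2*n_mutual_pairs earliest genes in topological order
    early = sorted(gene_ids, key=topo.__getitem__)[: 2 * n_mutual_pairs]
    early = [early[k] for k in rng.permutation(len(early))]
    edges, couplings = [], {}
    for p in range(n_mutual_pairs):
        a, b = early[2 * p], early[2 * p + 1]
        sgn = float(rng.choice([-1, 1]))
        w = rng.uniform(0.7, 1.5)
        for (src, tgt), sign in (((a, b), sgn), ((b, a), -sgn)):
            edges.append((src, tgt))
            # linear within-core coupling keeps the rotational mode exact
            couplings[(src, tgt)] = (float(sign * w * rng.uniform(0.7, 1.3)), 0.0)

    # One-directional edges run from oscillator-core genes (the distinct
    # mode generators) strictly downstream.  In-degree is capped at 2 and
    # per-source fan-out kept low, so each target's regulator set stays
    # jointly identifiable from the spectral signature it injects.
    taken = set(edges)
    core = set(early)
    in_deg = {g: 0 for g in gene_ids}
    out_single = {g: 0 for g in gene_ids}
    for _, tgt in edges:
        in_deg[tgt] += 1
    placed = 0
    while placed < n_single:
        for fanout_cap in (1, 2, m):
            downstream = [
                (src, tgt)
                for src in (core or gene_ids) for tgt in gene_ids
                if topo[src] < topo[tgt] and (src, tgt) not in taken
                and in_deg[tgt] < 2 and out_single[src] < fanout_cap
            ]
            if downstream:
                break
        else:
            raise ValueError("cannot place all edges under the degree caps")
        if not downstream:
            raise ValueError("cannot place all edges under the degree caps")
        e = downstream[int(rng.integers(len(downstream)))]
        taken.add(e)
        edges.append(e)
        in_deg[e[1]] += 1
        out_single[e[0]] += 1
        placed += 1
        couplings[e] = (
            float(rng.choice([-1, 1]) * np.exp(rng.uniform(np.log(0.3), np.log(1.0)))),
            float(rng.choice([-1, 1]) * rng.uniform(0.3, 0.7)) / AMPLITUDE_SCALE,
        )
    return gene_ids, edges, intrinsic, couplings


def simulate_system(
    m: int = 33,
    n_edges: int = 45,
    delta_sq: float = 0.01,
    T: int = 30,
    seed: int = 1,
    t_span: tuple[float, float] = (0.0, 12.0),
    baseline: float = 10.0,
    blowup_bound: float = 80.0,
    max_retries: int = 60,
) -> tuple[GroundTruth, ExpressionDataset]:
    """Simulate a ground-truth system and its noisy two-treatment dataset.

    Treatment 1 observes the pre-treatment baseline, treatment 2 observes
    baseline + trajectory; each observation carries Gaussian noise of
    variance ``delta_sq / 2`` so the DTP difference has variance
    ``delta_sq``.  Systems whose trajectories exceed ``blowup_bound`` are
    resampled (up to ``max_retries``).  Identical seeds give identical
    datasets.
    """
    if n_edges > m * (m - 1):
        raise ValueError("n_edges exceeds the number of ordered pairs")
    if delta_sq < 0:
        raise ValueError("delta_sq must be non-negative")
    if T < 2:
        raise ValueError("need at least two time points")
    rng = np.random.default_rng(seed)
    times = np.linspace(t_span[0], t_span[1], T)

    for _ in range(max_retries):
        gene_ids, edges, intrinsic, couplings = _sample_system(m, n_edges, rng)
        index = {g: i for i, g in enumerate(gene_ids)}
        a = np.array([intrinsic[g][0] for g in gene_ids])
        b = np.array([intrinsic[g][1] for g in gene_ids])
        C = np.zeros((m, m))
        K = np.zeros((m, m))
        for (src, tgt), (c, kappa) in couplings.items():
            C[index[tgt], index[src]] = c
            K[index[tgt], index[src]] = kappa

        # initial plasticity bounded away from zero: the stress onset
        # perturbs every gene enough to excite the system's modes
        g_init = (rng.choice([-1, 1], size=m)
                  * rng.uniform(0.3 * AMPLITUDE_SCALE, 0.8 * AMPLITUDE_SCALE, size=m))

        def field(t, g):
            return a + b * g + C @ g + (C * K) @ (g**2)

        try:
            with np.errstate(over="ignore", invalid="ignore"):
                traj = integrate_rk4(field, g_init, times,
                                     h=(times[-1] - times[0]) / (8 * (T - 1)))
        except FloatingPointError:
            continue
        if np.abs(traj).max() <= blowup_bound:
            break
    else:
        raise RuntimeError("could not sample a stable system within the retry cap")

    traj = traj.T  # genes x T
    sd = np.sqrt(delta_sq / 2.0)
    noise1 = rng.normal(0.0, sd, size=(m, T)) if sd > 0 else np.zeros((m, T))
    noise2 = rng.normal(0.0, sd, size=(m, T)) if sd > 0 else np.zeros((m, T))
    obs1 = baseline + noise1
    obs2 = baseline + traj + noise2

    records = []
    data = {}
    for k, obs in ((1, obs1), (2, obs2)):
        for j, t in enumerate(times):
            sid = f"T{k}_t{j:02d}_r1"
            records.append({"sample_id": sid, "treatment": k, "time": float(t),
                            "replicate": 1})
            data[sid] = obs[:, j]
    matrix = pd.DataFrame(data, index=gene_ids)
    dataset = ExpressionDataset(matrix=matrix, samples=pd.DataFrame(records))

    truth = GroundTruth(
        gene_ids=gene_ids, edges=edges, intrinsic=intrinsic, couplings=couplings,
        delta_sq=delta_sq, times=times, trajectories=traj, seed=seed,
    )
    return truth, dataset
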