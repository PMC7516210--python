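"""End-to-end pipeline: configuration, orchestration, exports.

The pipeline chains plasticity computation, functional clustering, sparse
ODE inference, trajectory decomposition, taxonomy/network snapshots,
centrality metrics and (optionally) the trait causal layer, writing plain-
text outputs at every stage.  All randomness hangs off one master seed, so
identical configurations yield identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as segn_io
from .clustering import select_module_count
from .inference import decompose, fit_ode, fit_ode_linear_self, select_regulators
from .lop import LopCurve
from .metrics import centrality_suite
from .plasticity import PlasticitySeries, fit_plasticity_curve
from .taxonomy import build_network
from .traits import build_hierarchical_network, fit_trait_system

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("segn")


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    expression_matrix: str
    sample_sheet: str
    output_dir: str
    trait_matrix: str | None = None
    trait_sheet: str | None = None
    level: str = "module"            # module | gene
    lop_order: int = 4
    comp_order: int = 3
    d_max: int = 5
    epsilon_rel: float = 0.05
    l_min: int = 1
    l_max: int = 6
    emission: str = "skellam"
    snapshot_times: list[float] | None = None
    refine: bool = False
    seed: int = 1
    with_traits: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for label, p in [("expression_matrix", self.expression_matrix),
                         ("sample_sheet", self.sample_sheet)]:
            if not Path(p).exists():
                raise FileNotFoundError(f"{label} not found: {p}")
        if self.with_traits:
            if not (self.trait_matrix and self.trait_sheet):
                raise ValueError("with_traits requires trait_matrix and trait_sheet")
            for p in (self.trait_matrix, self.trait_sheet):
                if not Path(p).exists():
                    raise FileNotFoundError(f"trait input not found: {p}")
        if self.level not in ("module", "gene"):
            raise ValueError("level must be 'module' or 'gene'")
        if not (0 < self.l_min <= self.l_max):
            raise ValueError("need 0 < l_min <= l_max")
        if self.d_max < 0 or self.lop_order < 1 or self.comp_order < 1:
            raise ValueError("numeric config fields out of range")


def _fit_system(series: dict[str, PlasticitySeries], curves: dict[str, LopCurve],
                cfg: RunConfig):
    fits, decs = {}, {}
    for tid, curve in curves.items():
        candidates = {k: v for k, v in curves.items() if k != tid}
        selected = select_regulators(curve, candidates, d_max=cfg.d_max,
                                     comp_order=cfg.comp_order,
                                     target_series=series[tid])
        reg_curves = {r: curves[r] for r in selected}
        if cfg.refine:
            fit = fit_ode(series[tid], curve, reg_curves,
                          comp_order=cfg.comp_order, seed=cfg.seed)
        else:
            fit = fit_ode_linear_self(series[tid], curve, reg_curves,
                                      comp_order=cfg.comp_order)
        fits[tid] = fit
        decs[tid] = decompose(fit)
        log.info("fit %s: regulators=%s sse=%.4g", tid, selected, fit.sse)
    return fits, decs


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns the in-memory result bundle."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(asdict(config)))
    logging.basicConfig(level=logging.INFO)
    log.info("pipeline start: level=%s seed=%d", config.level, config.seed)

    dataset = segn_io.read_expression(config.expression_matrix, config.sample_sheet)
    dtp = dataset.plasticity()
    segn_io.write_plasticity_tsv(dtp, out / "dtp.tsv")
    times = dataset.time_points
    log.info("plasticity: %d genes x %d times", len(dtp), len(times))

    partition = select_module_count(
        dtp, l_range=range(config.l_min, config.l_max + 1),
        lop_order=min(config.lop_order, len(times) - 1),
        emission=config.emission, seed=config.seed,
    )
    segn_io.write_partition_tsv(partition, out / "modules.tsv")
    segn_io.write_module_curves_tsv(partition, times, out / "module_curves.tsv")
    log.info("clustering: L=%d (AIC=%.2f)", partition.n_modules, partition.aic)

    series_by_id = {s.entity_id: s for s in dtp}
    if config.level == "module":
        series, curves = {}, {}
        for l in range(partition.n_modules):
            mid = f"module_{l}"
            members = [s for s in dtp if partition.assignments()[s.entity_id] == l]
            if not members:
                continue
            mean_vals = np.mean([s.values for s in members], axis=0)
            series[mid] = PlasticitySeries(entity_id=mid, times=times,
                                           values=mean_vals, kind="gene")
            curves[mid] = fit_plasticity_curve(
                series[mid], order=min(config.lop_order, len(times) - 1))
    else:
        series = series_by_id
        curves = {
            gid: fit_plasticity_curve(s, order=min(config.lop_order, len(times) - 1))
            for gid, s in series.items()
        }

    fits, decs = _fit_system(series, curves, config)
    segn_io.write_fit_json(fits, out / "ode_fits.json")

    comp_rows = []
    for tid, dec in decs.items():
        for k, t in enumerate(dec.times):
            comp_rows.append((tid, "independent", t, dec.p_independent[k]))
            for rid, p in dec.p_dependent.items():
                comp_rows.append((tid, rid, t, p[k]))
    import pandas as pd

    pd.DataFrame(comp_rows, columns=["target", "source", "time", "value"]).to_csv(
        out / "components.tsv", sep="\t", index=False)

    snap_times = config.snapshot_times or [float(times[-1])]
    networks = {}
    for t in snap_times:
        net = build_network(decs, t, epsilon_rel=config.epsilon_rel)
        networks[t] = net
        tag = f"{t:g}".replace(".", "p")
        segn_io.write_edge_table_tsv(net, out / f"network_t{tag}.tsv")
        segn_io.write_graphml(net, out / f"network_t{tag}.graphml")
        report = centrality_suite(net)
        report.per_node.to_csv(out / f"centrality_t{tag}.tsv", sep="\t",
                               index_label="node")
        log.info("snapshot t=%g: %d edges, hubs=%s", t,
                 net.graph.number_of_edges(), sorted(net.hubs))

    bundle = {"dataset": dataset, "partition": partition, "curves": curves,
              "fits": fits, "decompositions": decs, "networks": networks}

    if config.with_traits:
        trait_ds = segn_io.read_expression(config.trait_matrix, config.trait_sheet,
                                           kind="trait")
        dpp = trait_ds.plasticity()
        segn_io.write_plasticity_tsv(dpp, out / "dpp.tsv")
        trait_series = {s.entity_id: s for s in dpp}
        trait_curves = {
            tid: fit_plasticity_curve(s, order=min(config.lop_order,
                                                   len(s.times) - 1))
            for tid, s in trait_series.items()
        }
        tfits = fit_trait_system(trait_series, trait_curves, curves,
                                 d_max=config.d_max, comp_order=config.comp_order,
                                 refine=config.refine, seed=config.seed)
        tdecs = {tid: decompose(tf.fit) for tid, tf in tfits.items()}
        t_last = snap_times[-1]
        hier = build_hierarchical_network(tfits, tdecs, networks[t_last], t_last)
        pd.DataFrame(
            [(("trait" if g in trait_curves else "gene"), g, tr, w)
             for g, tr, w in hier.causal_edges],
            columns=["source_kind", "source", "target_trait", "weight"],
        ).to_csv(out / "causal_edges.tsv", sep="\t", index=False)
        (out / "layers.json").write_text(json.dumps(
            {"layers": hier.layers, "unreachable": sorted(hier.unreachable)},
            indent=1))
        bundle.update({"trait_fits": tfits, "hierarchical": hier})
        log.info("traits: %d causal edges", len(hier.causal_edges))

    log.info("pipeline done: outputs in %s", out)
    return bundle
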