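"""Readers, writers and the in-memory two-treatment dataset container."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .plasticity import PlasticitySeries, SampleDesign, compute_plasticity

__all__ = [
    "ExpressionDataset",
    "read_expression",
    "write_expression",
    "write_plasticity_tsv",
    "read_plasticity_tsv",
    "write_partition_tsv",
    "write_module_curves_tsv",
    "write_edge_table_tsv",
    "write_graphml",
    "write_fit_json",
]

SHEET_COLUMNS = ["sample_id", "treatment", "time", "replicate"]


@dataclass
class ExpressionDataset:
    """Entity x sample matrix plus its (treatment, time, replicate) sheet."""

    matrix: pd.DataFrame
    samples: pd.DataFrame
    kind: str = "gene"

    def __post_init__(self):
        sheet = self.samples
        missing = [c for c in SHEET_COLUMNS if c not in sheet.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns {missing}")
        sheet = sheet.astype({"sample_id": str, "treatment": int,
                              "time": float, "replicate": int})
        if sheet["sample_id"].duplicated().any():
            dups = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample ids {dups}")
        if not set(sheet["treatment"]) <= {1, 2}:
            raise ValueError("treatments must be coded 1 (control) and 2 (stress)")
        mat_cols = list(map(str, self.matrix.columns))
        sheet_ids = list(sheet["sample_id"])
        unknown = sorted(set(mat_cols) - set(sheet_ids))
        absent = sorted(set(sheet_ids) - set(mat_cols))
        if unknown:
            raise ValueError(f"matrix columns not in sample sheet: {unknown}")
        if absent:
            raise ValueError(f"sample sheet entries missing from matrix: {absent}")
        if not all(np.issubdtype(d, np.number) for d in self.matrix.dtypes):
            bad = [c for c, d in self.matrix.dtypes.items()
                   if not np.issubdtype(d, np.number)]
            raise ValueError(f"non-numeric matrix columns: {bad}")
        self.matrix = self.matrix.copy()
        self.matrix.columns = mat_cols
        self.samples = sheet.reset_index(drop=True)

    @property
    def entity_ids(self) -> list[str]:
        return [str(i) for i in self.matrix.index]

    @property
    def time_points(self) -> np.ndarray:
        return np.array(sorted(self.samples["time"].unique()))

    def design(self) -> SampleDesign:
        reps = self.samples.groupby(["treatment", "time"]).size()
        return SampleDesign(
            entity_ids=tuple(self.entity_ids),
            time_points=tuple(self.time_points),
            replicates={(int(k[0]), float(k[1])): int(v) for k, v in reps.items()},
        )

    def validate_cells(self) -> list[str]:
        """Report (treatment, time) cells missing for the full grid."""
        warnings = []
        have = set(map(tuple, self.samples[["treatment", "time"]].values))
        for k in (1, 2):
            for t in self.time_points:
                if (k, t) not in have:
                    warnings.append(f"no replicates for treatment {k} at time {t}")
        return warnings

    def cell_series(self, entity: str, treatment: int) -> dict[float, list[float]]:
        sheet = self.samples[self.samples["treatment"] == treatment]
        row = self.matrix.loc[entity]
        out: dict[float, list[float]] = {}
        for _, s in sheet.iterrows():
            out.setdefault(float(s["time"]), []).append(float(row[s["sample_id"]]))
        return out

    def plasticity(self) -> list[PlasticitySeries]:
        """Treatment-difference series for every entity."""
        problems = self.validate_cells()
        if problems:
            raise ValueError("; ".join(problems))
        return [
            compute_plasticity(self.cell_series(e, 1), self.cell_series(e, 2),
                               entity_id=e, kind=self.kind)  # type: ignore[arg-type]
            for e in self.entity_ids
        ]


def read_expression(matrix_path, sheet_path, kind: str = "gene") -> ExpressionDataset:
    """Load a TSV/CSV entity-by-sample matrix and its sample sheet."""
    sep_m = "," if str(matrix_path).endswith(".csv") else "\t"
    sep_s = "," if str(sheet_path).endswith(".csv") else "\t"
    matrix = pd.read_csv(matrix_path, sep=sep_m, index_col=0)
    samples = pd.read_csv(sheet_path, sep=sep_s)
    return ExpressionDataset(matrix=matrix, samples=samples, kind=kind)


def write_expression(dataset: ExpressionDataset, matrix_path, sheet_path) -> None:
    dataset.matrix.to_csv(matrix_path, sep="\t", index_label="entity_id")
    dataset.samples.to_csv(sheet_path, sep="\t", index=False)


def write_plasticity_tsv(series: list[PlasticitySeries], path) -> None:
    times = series[0].times
    frame = pd.DataFrame(
        {s.entity_id: s.values for s in series}, index=[f"{t:g}" for t in times]
    ).T
    frame.to_csv(path, sep="\t", index_label="entity_id")


def read_plasticity_tsv(path, kind: str = "gene") -> list[PlasticitySeries]:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    times = np.array([float(c) for c in frame.columns])
    return [
        PlasticitySeries(entity_id=str(idx), times=times,
                         values=frame.loc[idx].to_numpy(float), kind=kind)  # type: ignore[arg-type]
        for idx in frame.index
    ]


def write_partition_tsv(partition, path) -> None:
    rows = pd.DataFrame({
        "gene_id": partition.gene_ids,
        "module_id": partition.labels,
        "max_posterior": partition.posterior.max(axis=1),
    })
    rows.to_csv(path, sep="\t", index=False)


def write_module_curves_tsv(partition, times, path) -> None:
    rows = []
    for l in range(partition.n_modules):
        curve = partition.module_mean_curve(l, times)
        rows.extend(
            {"module_id": l, "time": t, "mean_dtp": v}
            for t, v in zip(times, curve)
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_edge_table_tsv(network, path) -> None:
    network.edge_table().to_csv(path, sep="\t", index=False)


def write_graphml(network, path) -> None:
    g = network.graph.copy()
    for n in g.nodes:
        g.nodes[n].setdefault("hub", False)
    for key in list(g.graph):
        if not isinstance(g.graph[key], (str, int, float, bool)):
            g.graph[key] = str(g.graph[key])
    nx.write_graphml(g, path)


def write_fit_json(fits: dict, path) -> None:
    """Serialize per-target ODE fits (regulators, coefficient blocks, SSE)."""
    payload = {}
    for tid, fit in fits.items():
        payload[tid] = {
            "target": fit.target_id,
            "regulators": list(fit.regulators),
            "theta_independent": fit.q_independent.coefficients.tolist(),
            "theta_dependent": {
                r: f.coefficients.tolist() for r, f in fit.q_dependent.items()
            },
            "g0": fit.g0,
            "sse": None if np.isnan(fit.sse) else fit.sse,
        }
    Path(path).write_text(json.dumps(payload, indent=1))
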