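"""Consensus discriminative features across LOOCV folds.

Only features selected in *every* fold enter the report.  Each consensus
feature's weight in one fold is |hyperplane coefficient| x the trained kernel
weight of its network in that fold, averaged over folds.  Edge weights sum a
pair's consensus weights across the three networks; network totals sum each
network's consensus weights.  Hyperplane coefficients exist only for linear
kernels, so nonlinear runs are refused rather than approximated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import FeatureTable, NETWORK_KINDS
from .evaluation import FoldRecord


@dataclass
class DiscriminativeFeatureReport:
    """Consensus feature weights with per-edge and per-network aggregates."""

    consensus: pd.DataFrame      # feature, network, node_i, node_j, region_i, region_j, mean_weight
    edge_weights: pd.DataFrame   # node_i, node_j, region_i, region_j, weight
    network_totals: dict[str, float]

    @property
    def grand_total(self) -> float:
        return float(self.consensus["mean_weight"].sum())

    def to_csv(self, path) -> None:
        self.consensus.to_csv(path, index=False)

    def write_viewer_files(self, out_dir, n_nodes: int,
                           node_labels) -> tuple[Path, Path]:
        """Node file (label + placeholder coordinates) and n x n edge matrix."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        node_path = out_dir / "nodes.txt"
        with open(node_path, "w") as fh:
            for name in node_labels:
                fh.write(f"0 0 0 1 1 {name}\n")
        mat = np.zeros((n_nodes, n_nodes))
        for _, row in self.edge_weights.iterrows():
            i, j = int(row["node_i"]) - 1, int(row["node_j"]) - 1
            mat[i, j] = mat[j, i] = row["weight"]
        edge_path = out_dir / "edges.txt"
        np.savetxt(edge_path, mat, fmt="%.6g")
        return node_path, edge_path


def consensus_features(folds: list[FoldRecord]) -> np.ndarray:
    """Indices selected in every fold, in canonical (ascending) column order."""
    if not folds:
        raise ValueError("no folds")
    common = set(folds[0].selected_features.tolist())
    for f in folds[1:]:
        common &= set(f.selected_features.tolist())
    return np.array(sorted(common), dtype=int)


def feature_weights(folds: list[FoldRecord],
                    consensus: np.ndarray) -> dict[int, float]:
    """Mean over folds of |w_j| * beta_network(j) for each consensus feature."""
    weights = {int(j): [] for j in consensus}
    for f in folds:
        if f.primal_weights is None:
            raise ValueError(
                "fold lacks hyperplane coefficients; the discriminative-feature "
                "procedure is defined for linear-kernel models only"
            )
        lookup = {}
        for kind, cols in f.selected_per_network.items():
            w = f.primal_weights[kind]
            for local, j in enumerate(cols):
                lookup[int(j)] = abs(float(w[local])) * f.beta[kind]
        for j in weights:
            weights[j].append(lookup[j])
    return {j: float(np.mean(v)) for j, v in weights.items()}


def aggregate(folds: list[FoldRecord],
              table: FeatureTable) -> DiscriminativeFeatureReport:
    """Build the full report: consensus rows, edge sums, network totals."""
    cons = consensus_features(folds)
    fw = feature_weights(folds, cons)
    rows = []
    for j in cons:
        kind, (a, b) = table.provenance[j]
        rows.append({
            "feature": int(j), "network": kind,
            "node_i": a, "node_j": b,
            "region_i": table.node_labels[a - 1],
            "region_j": table.node_labels[b - 1],
            "mean_weight": fw[int(j)],
        })
    consensus_df = pd.DataFrame(
        rows, columns=["feature", "network", "node_i", "node_j",
                       "region_i", "region_j", "mean_weight"])
    if len(consensus_df):
        edge_df = (consensus_df
                   .groupby(["node_i", "node_j", "region_i", "region_j"],
                            as_index=False)["mean_weight"].sum()
                   .rename(columns={"mean_weight": "weight"})
                   .sort_values(["node_i", "node_j"], ignore_index=True))
    else:
        edge_df = pd.DataFrame(columns=["node_i", "node_j", "region_i",
                                        "region_j", "weight"])
    totals = {k: 0.0 for k in NETWORK_KINDS}
    for _, row in consensus_df.iterrows():
        if row["network"] in totals:
            totals[row["network"]] += row["mean_weight"]
        else:
            totals[row["network"]] = totals.get(row["network"], 0.0) + row["mean_weight"]
    return DiscriminativeFeatureReport(
        consensus=consensus_df, edge_weights=edge_df, network_totals=totals)
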