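"""Switching-mechanism gene pairs and network construction/export.

A "switched" pair is positively correlated in one condition and
negatively in the other, with at least moderately strong correlation
(|r| above a threshold, default 0.5) in both. Nodes are annotated with a
differential-expression direction (Welch t-test + Benjamini-Hochberg) and
the network is exportable as SIF, GraphML or plain TSV tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import ttest_ind
from statsmodels.stats.multitest import multipletests

from .io_preprocess import CONDITION_A, CONDITION_B, ExpressionDataset, ExpressionError

logger = logging.getLogger(__name__)

EDGE_COLUMNS = ["geneX", "geneY", "sign", "r_normal", "r_tumor"]
NODE_COLUMNS = ["gene", "direction", "degree"]

INCREASED = "increased"
DECREASED = "decreased"
UNCHANGED = "unchanged"


def detect_switched_pairs(
    records: pd.DataFrame, threshold: float = 0.5, lfdr_max: float | None = None
) -> pd.DataFrame:
    """Filter differential-correlation records down to switched pairs.

    Keeps pairs whose correlations have opposite signs between conditions
    and satisfy ``min(|r1|, |r2|) > threshold`` (strict). When
    ``lfdr_max`` is given, the lfdr filter is applied first. Input order
    is preserved.
    """
    required = {"molecule_X", "molecule_Y", "r1", "r2"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records are missing column(s): {sorted(missing)}")
    sub = records
    if lfdr_max is not None:
        if sub["lfdr"].isna().any():
            raise ValueError("lfdr filter requested but lfdr not computed")
        sub = sub[sub["lfdr"] < lfdr_max]
    keep = (sub["r1"] * sub["r2"] < 0) & (
        np.minimum(sub["r1"].abs(), sub["r2"].abs()) > threshold
    )
    sub = sub[keep]
    edges = pd.DataFrame(
        {
            "geneX": sub["molecule_X"].to_numpy(),
            "geneY": sub["molecule_Y"].to_numpy(),
            "r_normal": sub["r1"].to_numpy(),
            "r_tumor": sub["r2"].to_numpy(),
        }
    )
    edges["sign_normal"] = np.where(edges["r_normal"] > 0, "+", "-")
    edges["sign_tumor"] = np.where(edges["r_tumor"] > 0, "+", "-")
    if "module" in sub.columns:
        edges["module"] = sub["module"].to_numpy()
    return edges.reset_index(drop=True)


def de_direction(ds: ExpressionDataset, alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene regulation direction from a Welch t-test (B vs A) plus BH.

    Direction is ``increased``/``decreased`` by the sign of
    ``mean(tumor) - mean(normal)`` when the BH-adjusted p-value is below
    ``alpha``, otherwise ``unchanged``. Degenerate genes (no variance in
    either group) are ``unchanged`` with a warning.
    """
    a = ds.values[ds.samples_in(CONDITION_A)].to_numpy()
    b = ds.values[ds.samples_in(CONDITION_B)].to_numpy()
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ExpressionError("both conditions need >= 2 samples for a t-test")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = ttest_ind(b, a, axis=1, equal_var=False)
    out = pd.DataFrame(
        {
            "mean_normal": np.nanmean(a, axis=1),
            "mean_tumor": np.nanmean(b, axis=1),
            "t": t,
            "p": p,
        },
        index=ds.gene_ids,
    )
    valid = out["p"].notna()
    if (~valid).any():
        warnings.warn(
            f"{(~valid).sum()} degenerate gene(s) marked '{UNCHANGED}' "
            f"(t-test undefined)"
        )
    out["p_adj"] = np.nan
    if valid.any():
        out.loc[valid, "p_adj"] = multipletests(
            out.loc[valid, "p"].to_numpy(), method="fdr_bh"
        )[1]
    diff = out["mean_tumor"] - out["mean_normal"]
    out["direction"] = np.select(
        [
            valid & (out["p_adj"] < alpha) & (diff > 0),
            valid & (out["p_adj"] < alpha) & (diff < 0),
        ],
        [INCREASED, DECREASED],
        default=UNCHANGED,
    )
    return out


@dataclass
class NetworkTables:
    """Node and edge tables of the switched-pair network."""

    nodes: pd.DataFrame  # gene, direction, degree
    edges: pd.DataFrame  # geneX, geneY, sign, r_normal, r_tumor

    def __post_init__(self) -> None:
        endpoints = set(self.edges["geneX"]) | set(self.edges["geneY"])
        known = set(self.nodes["gene"])
        orphans = endpoints - known
        if orphans:
            raise ValueError(f"edge endpoint(s) missing from node table: {sorted(orphans)}")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def build_network(
    edges: pd.DataFrame, directions: pd.DataFrame | None = None
) -> NetworkTables:
    """Assemble node/edge tables from switched pairs and DE directions.

    The single per-edge sign attribute is taken from the tumor-condition
    correlation.
    """
    edge_table = pd.DataFrame(
        {
            "geneX": edges["geneX"] if len(edges) else pd.Series(dtype=str),
            "geneY": edges["geneY"] if len(edges) else pd.Series(dtype=str),
            "sign": np.where(edges["r_tumor"] > 0, "pos", "neg")
            if len(edges)
            else pd.Series(dtype=str),
            "r_normal": edges["r_normal"] if len(edges) else pd.Series(dtype=float),
            "r_tumor": edges["r_tumor"] if len(edges) else pd.Series(dtype=float),
        }
    )
    genes = sorted(set(edge_table["geneX"]) | set(edge_table["geneY"]))
    degree = pd.concat([edge_table["geneX"], edge_table["geneY"]]).value_counts()
    dir_map = {}
    if directions is not None:
        dir_map = directions["direction"].to_dict()
    nodes = pd.DataFrame(
        {
            "gene": genes,
            "direction": [dir_map.get(g, UNCHANGED) for g in genes],
            "degree": [int(degree.get(g, 0)) for g in genes],
        }
    )
    return NetworkTables(nodes=nodes, edges=edge_table.reset_index(drop=True))


def hub_genes(tables: NetworkTables, k: int | None = None) -> pd.DataFrame:
    """Nodes ranked by degree descending, ties broken lexicographically."""
    ranked = tables.nodes.sort_values(
        by=["degree", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return ranked if k is None else ranked.head(k)


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------

def to_networkx(tables: NetworkTables) -> nx.Graph:
    g = nx.Graph()
    for row in tables.nodes.itertuples(index=False):
        g.add_node(row.gene, direction=row.direction, degree=int(row.degree))
    for row in tables.edges.itertuples(index=False):
        g.add_edge(
            row.geneX,
            row.geneY,
            sign=row.sign,
            r_normal=float(row.r_normal),
            r_tumor=float(row.r_tumor),
        )
    return g


def export_network(tables: NetworkTables, path, fmt: str = "TSV") -> list[Path]:
    """Write the network as SIF, GraphML or TSV node/edge tables.

    For TSV, ``path`` is used as a prefix producing ``<path>.nodes.tsv``
    and ``<path>.edges.tsv``. SIF lines read ``geneX <pos|neg> geneY``.
    """
    fmt = fmt.upper()
    path = Path(path)
    if fmt == "SIF":
        lines = [
            f"{r.geneX}\t{r.sign}\t{r.geneY}" for r in tables.edges.itertuples(index=False)
        ]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
        return [path]
    if fmt == "GRAPHML":
        nx.write_graphml(to_networkx(tables), path)
        return [path]
    if fmt == "TSV":
        nodes_path = path.with_suffix(".nodes.tsv")
        edges_path = path.with_suffix(".edges.tsv")
        tables.nodes.to_csv(nodes_path, sep="\t", index=False)
        tables.edges.to_csv(edges_path, sep="\t", index=False)
        return [nodes_path, edges_path]
    raise ValueError(f"unknown network format {fmt!r}; use SIF, GraphML or TSV")


def read_network(path, fmt: str = "TSV") -> NetworkTables:
    """Re-read a network written by :func:`export_network`."""
    fmt = fmt.upper()
    path = Path(path)
    if fmt == "SIF":
        rows = []
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            gx, sign, gy = line.split("\t")
            rows.append((gx, gy, sign, np.nan, np.nan))
        edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
        genes = sorted(set(edges["geneX"]) | set(edges["geneY"]))
        degree = pd.concat([edges["geneX"], edges["geneY"]]).value_counts()
        nodes = pd.DataFrame(
            {
                "gene": genes,
                "direction": UNCHANGED,
                "degree": [int(degree.get(g, 0)) for g in genes],
            }
        )
        return NetworkTables(nodes=nodes, edges=edges)
    if fmt == "GRAPHML":
        g = nx.read_graphml(path)
        nodes = pd.DataFrame(
            [
                (n, d.get("direction", UNCHANGED), int(d.get("degree", g.degree(n))))
                for n, d in sorted(g.nodes(data=True))
            ],
            columns=NODE_COLUMNS,
        )
        edges = pd.DataFrame(
            [
                (u, v, d["sign"], float(d["r_normal"]), float(d["r_tumor"]))
                for u, v, d in g.edges(data=True)
            ],
            columns=EDGE_COLUMNS,
        )
        return NetworkTables(nodes=nodes, edges=edges)
    if fmt == "TSV":
        nodes = pd.read_csv(path.with_suffix(".nodes.tsv"), sep="\t")
        edges = pd.read_csv(path.with_suffix(".edges.tsv"), sep="\t")
        if edges.empty:
            edges = pd.DataFrame(columns=EDGE_COLUMNS)
        if nodes.empty:
            nodes = pd.DataFrame(columns=NODE_COLUMNS)
        return NetworkTables(nodes=nodes, edges=edges)
    raise ValueError(f"unknown network format {fmt!r}; use SIF, GraphML or TSV")
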