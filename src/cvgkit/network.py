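"""CVG coexpression network: Pearson correlation, highest reciprocal
rank (HRR) edges, connected-component clusters, and export.

HRR(a,b) = max(rank of b among a's correlations, rank of a among b's),
ranks taken over all other genes by descending correlation with
deterministic lexicographic tie-breaking. Small HRR means both genes
place each other among their top correlates; edges with HRR above the
cutoff are discarded, and clusters (components) with fewer than
``min_size`` nodes are removed from the network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)


class NetworkError(ValueError):
    pass


@dataclass(frozen=True)
class NetworkCluster:
    cluster_id: int
    members: frozenset[str]
    edge_count: int

    @property
    def size(self) -> int:
        return len(self.members)


def pcc_matrix(
    matrix: ExpressionMatrix, genes: list[str] | None = None
) -> pd.DataFrame:
    """Pearson correlation across samples for the selected genes.

    Diagonal is 1; genes constant across samples correlate 0 with
    everything (logged). Requires >= 3 samples.
    """
    if matrix.shape[1] < 3:
        raise NetworkError("correlation requires >= 3 samples")
    if genes is None:
        genes = sorted(matrix.gene_ids)
    else:
        missing = [g for g in genes if g not in matrix.data.index]
        if missing:
            raise NetworkError(f"genes absent from matrix: {missing[:5]}")
        genes = sorted(genes)
    x = matrix.data.loc[genes].to_numpy()
    sd = x.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "pcc_matrix: %d constant genes correlate 0 with all others",
            int(constant.sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(x)
    c = np.atleast_2d(c)
    c[~np.isfinite(c)] = 0.0
    np.fill_diagonal(c, 1.0)
    return pd.DataFrame(c, index=genes, columns=genes)


def hrr_edges(pcc: pd.DataFrame, cutoff: int) -> pd.DataFrame:
    """Highest-reciprocal-rank edges from a symmetric correlation frame.

    Returns a frame (gene_a, gene_b, pcc, rank_ab, rank_ba, hrr) with
    gene_a < gene_b and hrr <= cutoff. Rank 1 is the best correlate;
    ties break lexicographically by gene id.
    """
    if pcc.shape[0] != pcc.shape[1] or list(pcc.index) != list(pcc.columns):
        raise NetworkError("pcc must be square with matching index/columns")
    genes = list(pcc.index)
    n = len(genes)
    if n < 2:
        return pd.DataFrame(
            columns=["gene_a", "gene_b", "pcc", "rank_ab", "rank_ba", "hrr"]
        )
    c = pcc.to_numpy()
    # rank[i, j]: position of j in gene i's descending-pcc list (1-based)
    rank = np.zeros((n, n), dtype=int)
    lex = np.argsort(np.array(genes, dtype=object))
    lexpos = np.empty(n, dtype=int)
    lexpos[lex] = np.arange(n)
    for i in range(n):
        others = np.array([j for j in range(n) if j != i])
        keys = np.lexsort((lexpos[others], -c[i, others]))
        for r, idx in enumerate(keys, start=1):
            rank[i, others[idx]] = r
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            h = max(rank[i, j], rank[j, i])
            if h <= cutoff:
                a, b = genes[i], genes[j]
                r_ab, r_ba = rank[i, j], rank[j, i]
                if a > b:
                    a, b = b, a
                    r_ab, r_ba = r_ba, r_ab
                rows.append((a, b, c[i, j], r_ab, r_ba, h))
    out = pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "pcc", "rank_ab", "rank_ba", "hrr"]
    )
    return out.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)


def extract_clusters(edges: pd.DataFrame, min_size: int) -> list[NetworkCluster]:
    """Connected components of the edge graph, pruned below ``min_size``.

    Clusters are numbered by decreasing size (cluster 1 = largest),
    ties broken by lexicographic smallest member.
    """
    if min_size < 1:
        raise NetworkError("min_size must be >= 1")
    g = nx.Graph()
    for a, b in zip(edges["gene_a"], edges["gene_b"]):
        g.add_edge(a, b)
    comps = sorted(
        (sorted(c) for c in nx.connected_components(g)),
        key=lambda c: (-len(c), c[0]),
    )
    clusters = []
    for comp in comps:
        if len(comp) < min_size:
            continue
        sub = g.subgraph(comp)
        clusters.append(
            NetworkCluster(
                cluster_id=len(clusters) + 1,
                members=frozenset(comp),
                edge_count=sub.number_of_edges(),
            )
        )
    return clusters


def cluster_of(clusters: list[NetworkCluster]) -> dict[str, int]:
    return {g: c.cluster_id for c in clusters for g in c.members}


def export_network(
    edges: pd.DataFrame,
    clusters: list[NetworkCluster],
    outdir: str | Path,
    prefix: str = "network",
) -> dict[str, Path]:
    """Write the edge table (TSV), a SIF file and cluster membership.

    Edges incident to pruned (sub-threshold) components carry cluster_id
    0 in the TSV and are omitted from the SIF.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    member = cluster_of(clusters)
    edge_out = edges.copy()
    edge_out["cluster_id"] = [
        member.get(a, 0) for a in edge_out["gene_a"]
    ]
    edge_path = outdir / f"{prefix}_edges.tsv"
    edge_out.to_csv(edge_path, sep="\t", index=False)

    sif_path = outdir / f"{prefix}.sif"
    with open(sif_path, "w") as fh:
        for a, b, cid in zip(
            edge_out["gene_a"], edge_out["gene_b"], edge_out["cluster_id"]
        ):
            if cid > 0:
                fh.write(f"{a}\tco\t{b}\n")

    cluster_path = outdir / f"{prefix}_clusters.tsv"
    rows = [
        {"cluster_id": c.cluster_id, "gene_id": g}
        for c in clusters
        for g in sorted(c.members)
    ]
    pd.DataFrame(rows, columns=["cluster_id", "gene_id"]).to_csv(
        cluster_path, sep="\t", index=False
    )
    return {"edges": edge_path, "sif": sif_path, "clusters": cluster_path}


def read_edges(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df[["gene_a", "gene_b", "pcc", "rank_ab", "rank_ba", "hrr"]]
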