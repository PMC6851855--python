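"""Focal-gene co-expression networks from TPM expression matrices.

The pipeline follows the standard recipe for triad-centered wheat
co-expression analysis: quantile normalization of TPM columns, log2
transformation, selection of the most variable genes, all-pairs Pearson
correlation for a sparse "global" network (only extreme correlations kept),
and a "local" network of genes that rank in the top fraction of
correlations with any of the three focal homoeologs and exceed an absolute
correlation floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GLOBAL_NEG_THRESHOLD = -0.90
GLOBAL_POS_THRESHOLD = 0.98
LOCAL_TOP_FRACTION = 0.01
LOCAL_MIN_ABS_PCC = 0.60


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize sample columns to a common distribution.

    Each column's values are replaced by the across-column mean of the
    order statistics, so afterwards every sample has an identical sorted
    value multiset. Ties within a column receive the mean of the reference
    values spanning their rank range. The transform is idempotent.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    values = matrix.to_numpy(dtype=float)
    if np.any(np.ptp(values, axis=0) == 0.0):
        bad = matrix.columns[np.ptp(values, axis=0) == 0.0]
        raise ValueError(f"uninformative constant sample column(s): {list(bad)}")
    order = np.argsort(values, axis=0, kind="stable")
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    n = values.shape[0]
    for j in range(values.shape[1]):
        # average the reference values over each tied run
        srt = values[order[:, j], j]
        boundaries = np.flatnonzero(np.diff(srt)) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [n]])
        ref_sorted = reference.copy()
        for s, e in zip(starts, ends):
            if e - s > 1:
                ref_sorted[s:e] = reference[s:e].mean()
        out[order[:, j], j] = ref_sorted[np.arange(n)]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def quantile_normalize_log2(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile normalization followed by ``log2(x + 1)``."""
    return np.log2(quantile_normalize(matrix) + 1.0)


def top_variable_genes(
    matrix: pd.DataFrame,
    k: int,
    force_include: Sequence[str] = (),
) -> pd.DataFrame:
    """Keep the ``k`` genes with the highest across-sample SD.

    ``force_include`` genes (typically the focal homoeolog triad) are kept
    even when they fall outside the top ``k``, with a log note.
    """
    if k > matrix.shape[0]:
        raise ValueError("k exceeds number of genes")
    sd = matrix.std(axis=1, ddof=1)
    selected = sd.sort_values(ascending=False, kind="stable").index[:k]
    keep = list(selected)
    for gene in force_include:
        if gene not in set(keep):
            logger.info("top_variable_genes: force-including %s (outside top %d)", gene, k)
            keep.append(gene)
    return matrix.loc[keep]


def pcc(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation of two expression profiles."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("correlation undefined for constant vector")
    return float(np.corrcoef(x, y)[0, 1])


def _drop_constant(matrix: pd.DataFrame) -> pd.DataFrame:
    sd = matrix.std(axis=1, ddof=1)
    constant = sd[sd == 0.0].index
    if len(constant):
        logger.warning(
            "excluding %d constant gene row(s) from correlation: %s",
            len(constant), list(constant)[:5],
        )
        matrix = matrix.drop(index=constant)
    return matrix


def build_global_network(
    matrix: pd.DataFrame,
    k: int | None = None,
    neg_threshold: float = GLOBAL_NEG_THRESHOLD,
    pos_threshold: float = GLOBAL_POS_THRESHOLD,
) -> pd.DataFrame:
    """All-pairs PCC among the top-``k`` variable genes, extreme edges only.

    Edges with PCC below ``neg_threshold`` or above ``pos_threshold`` are
    kept; the wide gap between the thresholds keeps the global layer
    sparse. Returns an edge table (gene_i, gene_j, pcc, sign, layer).
    """
    if k is not None:
        matrix = top_variable_genes(matrix, k)
    matrix = _drop_constant(matrix)
    genes = matrix.index.to_numpy()
    corr = np.corrcoef(matrix.to_numpy(dtype=float))
    iu, ju = np.triu_indices(len(genes), k=1)
    vals = corr[iu, ju]
    keep = (vals < neg_threshold) | (vals > pos_threshold)
    edges = pd.DataFrame(
        {
            "gene_i": genes[iu[keep]],
            "gene_j": genes[ju[keep]],
            "pcc": vals[keep],
        }
    )
    edges["sign"] = np.where(edges["pcc"] >= 0, "+", "-")
    edges["layer"] = "global"
    return edges


def build_local_network(
    matrix: pd.DataFrame,
    focal_genes: Sequence[str],
    top_fraction: float = LOCAL_TOP_FRACTION,
    min_abs_pcc: float = LOCAL_MIN_ABS_PCC,
    ranking: str = "signed",
) -> tuple[set[str], pd.DataFrame]:
    """Local network around the focal homoeolog triad.

    For each focal gene, all other genes are ranked by their PCC with it
    (``ranking="signed"`` ranks by the correlation itself, ``"absolute"``
    by its magnitude). The member set is the union over focal genes of
    genes in the top ``top_fraction`` of that ranking that also exceed
    ``min_abs_pcc`` in absolute value; ties at the quantile boundary are
    all kept. Constant focal genes are skipped with a warning.

    Returns ``(members, edges)`` where edges connect focal genes to members.
    """
    if ranking not in ("signed", "absolute"):
        raise ValueError("ranking must be 'signed' or 'absolute'")
    matrix = _drop_constant(matrix)
    missing = [g for g in focal_genes if g not in matrix.index]
    if missing:
        raise ValueError(f"focal gene(s) not in matrix: {missing}")
    data = matrix.to_numpy(dtype=float)
    genes = matrix.index.to_numpy()
    centered = data - data.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    members: set[str] = set()
    edge_rows = []
    focal_set = set(focal_genes)
    for focal in focal_genes:
        fi = int(np.flatnonzero(genes == focal)[0])
        r = centered @ centered[fi] / (norms * norms[fi])
        others = np.array([g not in focal_set for g in genes])
        scores = r if ranking == "signed" else np.abs(r)
        candidate_scores = scores[others]
        n_top = max(1, int(np.ceil(top_fraction * candidate_scores.size)))
        cutoff = np.sort(candidate_scores)[::-1][n_top - 1]
        in_top = others & (scores >= cutoff)
        chosen = in_top & (np.abs(r) > min_abs_pcc)
        for gi in np.flatnonzero(chosen):
            members.add(str(genes[gi]))
            edge_rows.append(
                {"gene_i": focal, "gene_j": str(genes[gi]), "pcc": float(r[gi])}
            )
    edges = pd.DataFrame(edge_rows, columns=["gene_i", "gene_j", "pcc"])
    if len(edges):
        edges["sign"] = np.where(edges["pcc"] >= 0, "+", "-")
    else:
        edges["sign"] = pd.Series(dtype=str)
    edges["layer"] = "local"
    return members, edges


@dataclass
class CoexprNetwork:
    """Node and edge tables of the combined global + local network."""

    nodes: pd.DataFrame  # gene, focal flag
    edges: pd.DataFrame  # gene_i, gene_j, pcc, sign, layer

    def write_nodes(self, path: str | Path) -> None:
        self.nodes.to_csv(path, sep="\t", index=False)

    def write_edges(self, path: str | Path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)


def build_network(
    tpm: pd.DataFrame,
    focal_genes: Sequence[str],
    k: int = 10_000,
    top_fraction: float = LOCAL_TOP_FRACTION,
    min_abs_pcc: float = LOCAL_MIN_ABS_PCC,
) -> CoexprNetwork:
    """Full pipeline: normalize, select variable genes, build both layers."""
    norm = quantile_normalize_log2(tpm)
    sub = top_variable_genes(norm, min(k, norm.shape[0]), force_include=focal_genes)
    global_edges = build_global_network(sub)
    members, local_edges = build_local_network(
        sub, focal_genes, top_fraction=top_fraction, min_abs_pcc=min_abs_pcc
    )
    edges = pd.concat([global_edges, local_edges], ignore_index=True)
    node_ids = sorted(
        set(edges["gene_i"]) | set(edges["gene_j"]) | set(focal_genes) | members
    )
    nodes = pd.DataFrame(
        {"gene": node_ids, "focal": [g in set(focal_genes) for g in node_ids]}
    )
    return CoexprNetwork(nodes, edges)
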