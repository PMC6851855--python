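"""Homoeolog sequence comparison: K2P distances, NJ trees, bootstrap.

Aligned gene sequences (alignment produced upstream, e.g. with MUSCLE or
MAFFT) are compared under complete deletion of gapped columns: pairwise
Kimura two-parameter distances separate transition and transversion
proportions, neighbor joining (Saitou-Nei) builds the unrooted tree, and
nonparametric bootstrap over alignment columns attaches percent support to
the internal bipartitions of the original tree. Protein alignments get a
simple difference count/percentage.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO
from skbio import TreeNode

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
_VALID = PURINES | PYRIMIDINES


def _is_transition(a: str, b: str) -> bool:
    return (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)


def k2p_distance(seq1: str, seq2: str) -> float:
    """Kimura two-parameter distance between two aligned DNA sequences.

    Columns with a gap or ambiguous base in either sequence are removed
    first (complete deletion). With transition proportion P and
    transversion proportion Q the distance is
    ``-1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)``; saturated pairs for which a
    log argument is non-positive return NaN.
    """
    if len(seq1) != len(seq2):
        raise ValueError("sequences must be aligned to equal length")
    s1, s2 = seq1.upper(), seq2.upper()
    n = transitions = transversions = 0
    for a, b in zip(s1, s2):
        if a not in _VALID or b not in _VALID:
            continue
        n += 1
        if a != b:
            if _is_transition(a, b):
                transitions += 1
            else:
                transversions += 1
    if n == 0:
        raise ValueError("no comparable (ungapped) columns")
    p, q = transitions / n, transversions / n
    w1, w2 = 1.0 - 2.0 * p - q, 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def k2p_matrix(seqs: Mapping[str, str]) -> tuple[list[str], np.ndarray]:
    """Pairwise K2P distance matrix over a set of aligned sequences."""
    ids = list(seqs)
    n = len(ids)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = k2p_distance(seqs[ids[i]], seqs[ids[j]])
            dist[i, j] = dist[j, i] = d
    return ids, dist


def nj_tree(ids: Sequence[str], dist: np.ndarray) -> TreeNode:
    """Neighbor-joining tree (Saitou-Nei) from a distance matrix.

    Ties in the Q criterion are broken by the lowest index pair, so the
    topology is deterministic. Negative branch lengths are clamped to zero
    with the negative length transferred to the sister branch, preserving
    the path length between the joined taxa. The returned tree is unrooted
    (trifurcating root for >= 3 taxa).
    """
    n = len(ids)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    d = np.array(dist, dtype=float)
    if d.shape != (n, n) or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    nodes: list[TreeNode] = [TreeNode(name=str(i_d)) for i_d in ids]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        q = (m - 2) * sub - totals[:, None] - totals[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index pair on ties: argmin of flattened array scans rows first
        flat = int(np.argmin(q))
        i_loc, j_loc = divmod(flat, m)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = d[i, j]
        li = 0.5 * dij + (totals[i_loc] - totals[j_loc]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = _fix_negative(li, lj)
        parent = TreeNode()
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = li, lj
        parent.extend([child_i, child_j])
        # distances from the new node to the remaining taxa
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.vstack([d, new_row])
        new_col = np.append(new_row, 0.0)
        d = np.column_stack([d, new_col])
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    # join the last three nodes at an unrooted trifurcation
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    root = TreeNode()
    for idx, length in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = max(length, 0.0)
        root.append(nodes[idx])
    return root


def _fix_negative(li: float, lj: float) -> tuple[float, float]:
    if li < 0.0:
        lj += li
        li = 0.0
    if lj < 0.0:
        li += lj
        lj = 0.0
    return li, max(lj, 0.0)


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Nontrivial bipartitions of an unrooted tree.

    Each internal edge splits the taxa into two sides; the split is
    canonicalized as the side not containing the alphabetically first
    taxon, so rooted representations of the same unrooted topology agree.
    """
    taxa = frozenset(t.name for t in tree.tips())
    anchor = min(taxa)
    splits: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(taxa) - 2:
            continue
        if anchor in side:
            side = taxa - side
        splits.add(side)
    return splits


def same_topology(tree1: TreeNode, tree2: TreeNode) -> bool:
    """Whether two unrooted trees share the same set of bipartitions."""
    return bipartitions(tree1) == bipartitions(tree2)


def _strip_gap_columns(seqs: Mapping[str, str]) -> dict[str, str]:
    ids = list(seqs)
    arr = np.array([list(seqs[i].upper()) for i in ids])
    ok = np.all(np.isin(arr, list(_VALID)), axis=0)
    return {i: "".join(row) for i, row in zip(ids, arr[:, ok])}


def bootstrap_support(
    seqs: Mapping[str, str],
    n_reps: int = 1000,
    seed: int = 0,
) -> tuple[TreeNode, dict[frozenset, float]]:
    """Bootstrap support for the NJ tree of an aligned sequence set.

    Gapped columns are removed alignment-wide (complete deletion), the NJ
    tree is built from K2P distances, and ``n_reps`` column-resampled
    replicates are rebuilt; each original bipartition's support is the
    percentage of replicates containing it. Support values are attached to
    the internal node names of the returned tree. ``n_reps = 0`` returns
    the tree with no supports.
    """
    stripped = _strip_gap_columns(seqs)
    ids, dist = k2p_matrix(stripped)
    tree = nj_tree(ids, dist)
    splits = bipartitions(tree)
    if n_reps == 0:
        return tree, {}
    length = len(next(iter(stripped.values())))
    arr = {i: np.array(list(s)) for i, s in stripped.items()}
    rng = np.random.default_rng(seed)
    hits = {s: 0 for s in splits}
    for _ in range(n_reps):
        cols = rng.integers(0, length, size=length)
        resampled = {i: "".join(a[cols]) for i, a in arr.items()}
        rep_ids, rep_dist = k2p_matrix(resampled)
        if np.isnan(rep_dist).any():
            continue
        rep_splits = bipartitions(nj_tree(rep_ids, rep_dist))
        for s in splits & rep_splits:
            hits[s] += 1
    support = {s: 100.0 * h / n_reps for s, h in hits.items()}
    _annotate_support(tree, support)
    return tree, support


def _annotate_support(tree: TreeNode, support: dict[frozenset, float]) -> None:
    taxa = frozenset(t.name for t in tree.tips())
    anchor = min(taxa)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = taxa - side
        if side in support:
            node.name = str(int(round(support[side])))


def count_aa_differences(seq1: str, seq2: str) -> tuple[int, float]:
    """Count amino-acid differences between two aligned protein sequences.

    Columns containing a gap in either sequence are excluded; returns the
    count of differing columns and the percentage over compared columns
    (one decimal).
    """
    if len(seq1) != len(seq2):
        raise ValueError("sequences must be aligned to equal length")
    compared = differing = 0
    for a, b in zip(seq1.upper(), seq2.upper()):
        if a in "-." or b in "-." or a == "X" or b == "X":
            continue
        compared += 1
        if a != b:
            differing += 1
    if compared == 0:
        raise ValueError("no comparable columns")
    return differing, round(100.0 * differing / compared, 1)


def read_alignment(path: str | Path) -> dict[str, str]:
    """Read an aligned FASTA into an id -> sequence mapping."""
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) > 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    return seqs


def write_newick(tree: TreeNode, path: str | Path | None = None) -> str:
    """Serialize a tree to Newick (branch lengths + integer support labels)."""
    buf = io.StringIO()
    tree.write(buf, format="newick")
    newick = buf.getvalue().strip()
    if path is not None:
        Path(path).write_text(newick + "\n")
    return newick
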