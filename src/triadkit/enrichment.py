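"""GO term enrichment of a gene set against a genome background.

One-term-at-a-time Fisher exact tests on 2x2 carrier tables, two-tailed by
the probability-mass rule, with Benjamini-Hochberg control of the false
discovery rate and fold-change reporting (proportion of the gene set
annotated with the term over the genome-wide proportion). GO annotations
are consumed as a flat gene-to-term table; no propagation through the GO
graph is performed.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-tailed Fisher exact p-value for a 2x2 count table.

    Two-tailed by the probability-mass rule: the p-value sums the
    hypergeometric probabilities of every table with the observed margins
    whose probability does not exceed that of the observed table. A zero
    margin gives p = 1.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = list(p_values)
    if not p:
        return []
    if any(not 0.0 <= x <= 1.0 for x in p):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def load_annotation(path: str | Path) -> dict[str, set[str]]:
    """Load a two-column (gene, GO id) TSV into a gene -> terms mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"], dtype=str)
    out: dict[str, set[str]] = {}
    for gene, term in zip(df["gene"], df["term"]):
        out.setdefault(gene, set()).add(term)
    return out


def enrich_terms(
    gene_set: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    background: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Fisher-exact enrichment of every term with >=1 gene in the set.

    ``background`` defaults to all annotated genes and must contain the
    gene set. For each term the 2x2 table is (in-set annotated ``a``,
    in-set not ``b``, out-of-set annotated ``c``, out-of-set not ``d``);
    fold change is ``(a / set size) / (term total / background size)``.
    Results are sorted by adjusted p-value ascending.
    """
    genes = set(gene_set)
    bg = set(background) if background is not None else set(annotation)
    if not genes <= bg:
        raise ValueError("gene set must be a subset of the background")
    if not genes:
        return pd.DataFrame(
            columns=["term", "a", "b", "c", "d", "fold_change", "p", "p_adj"]
        )
    term_genes: dict[str, set[str]] = {}
    for gene in bg:
        for term in annotation.get(gene, ()):
            term_genes.setdefault(term, set()).add(gene)
    n_set, n_bg = len(genes), len(bg)
    rows = []
    for term, carriers in sorted(term_genes.items()):
        a = len(carriers & genes)
        if a == 0:
            continue
        total = len(carriers)
        b = n_set - a
        c = total - a
        d = n_bg - n_set - c
        fold = (a / n_set) / (total / n_bg)
        p = fisher_exact_2x2([[a, b], [c, d]])
        rows.append(
            {"term": term, "a": a, "b": b, "c": c, "d": d,
             "fold_change": fold, "p": p}
        )
    result = pd.DataFrame(rows)
    result["p_adj"] = bh_adjust(result["p"])
    return result.sort_values(
        ["p_adj", "p", "term"], kind="stable", ignore_index=True
    )
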