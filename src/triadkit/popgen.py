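"""Diversity, differentiation and haplotype analyses of exome-capture SNPs.

Implements the windowed sweep-scan statistics used to detect domestication
selection around a focal gene: per-SNP nucleotide diversity (unbiased
average pairwise heterozygosity), Hudson-type F_ST between populations
(ratio-of-averages over windows), 2-Mb sliding-window scans, genic
haplotype extraction with frequency tables per population, and Fisher
exact tests of haplotype-frequency differences between populations.

Genotypes are diploid alt-allele dosages (0, 1, 2; -1 missing). Positions
are 1-based as in VCF; query regions use BED conventions (0-based
half-open) and are converted internally.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .enrichment import fisher_exact_2x2

logger = logging.getLogger(__name__)

WINDOW_SIZE = 2_000_000
WINDOW_STEP = 400_000


@dataclass
class SNPMatrix:
    """Biallelic SNP genotypes with population labels.

    ``genotypes`` has one row per SNP (positions strictly increasing) and
    one column per accession.
    """

    chrom: str
    positions: np.ndarray  # 1-based
    genotypes: np.ndarray  # int8, 0/1/2 alt dosage, -1 missing
    accessions: list[str]
    populations: list[str]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.genotypes.shape != (self.positions.size, len(self.accessions)):
            raise ValueError("genotype matrix shape mismatch")
        if len(self.populations) != len(self.accessions):
            raise ValueError("one population label per accession required")

    def pop_columns(self, population: str) -> np.ndarray:
        cols = np.flatnonzero(np.array(self.populations) == population)
        if cols.size == 0:
            raise ValueError(f"no accessions in population {population!r}")
        return cols

    @classmethod
    def from_vcf(cls, vcf_path: str | Path, pops_path: str | Path) -> "SNPMatrix":
        """Read biallelic SNPs from VCF v4.2 plus an accession->population TSV."""
        pops = pd.read_csv(pops_path, sep="\t", dtype=str)
        pop_map = dict(zip(pops["accession"], pops["population"]))
        with pysam.VariantFile(str(vcf_path)) as vcf:
            samples = list(vcf.header.samples)
            chroms: set[str] = set()
            positions = []
            rows = []
            for rec in vcf:
                if rec.alts is None or len(rec.alts) != 1:
                    continue  # biallelic only
                chroms.add(rec.chrom)
                positions.append(rec.pos)
                row = np.empty(len(samples), dtype=np.int8)
                for i, sample in enumerate(samples):
                    gt = rec.samples[sample]["GT"]
                    if gt is None or any(a is None for a in gt):
                        row[i] = -1
                    else:
                        row[i] = sum(gt)
                rows.append(row)
        if len(chroms) != 1:
            raise ValueError("expected a single chromosome per matrix")
        return cls(
            chrom=chroms.pop(),
            positions=np.array(positions),
            genotypes=np.array(rows),
            accessions=samples,
            populations=[pop_map[s] for s in samples],
        )


def site_pi(n_called_copies: int, alt_copies: int) -> float:
    """Unbiased per-site nucleotide diversity ``2p(1-p) * n/(n-1)``.

    ``n_called_copies`` is the number of successfully called allele copies
    at the site (twice the called diploid genotypes); requires n >= 2.
    """
    n = n_called_copies
    if n < 2:
        raise ValueError("need at least 2 called allele copies")
    p = alt_copies / n
    return 2.0 * p * (1.0 - p) * n / (n - 1)


def hudson_fst(
    p1: float, n1: int, p2: float, n2: int
) -> float | None:
    """Hudson-type F_ST at one SNP: ``1 - H_within / H_between``.

    ``H_within`` is the mean of the two unbiased within-population
    heterozygosities and ``H_between = p1(1-p2) + p2(1-p1)``. Sites fixed
    for the same allele in both populations (H_between = 0) carry no
    information and return ``None``; slightly negative estimates are
    reported as computed.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 called allele copies per population")
    h_b = p1 * (1.0 - p2) + p2 * (1.0 - p1)
    if h_b == 0.0:
        return None
    h_w = (
        2.0 * p1 * (1.0 - p1) * n1 / (n1 - 1)
        + 2.0 * p2 * (1.0 - p2) * n2 / (n2 - 1)
    ) / 2.0
    return 1.0 - h_w / h_b


def _site_arrays(geno: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site called allele copies and alt copies for a set of columns."""
    sub = geno[:, cols]
    called = sub >= 0
    n = 2 * called.sum(axis=1)
    alt = np.where(called, sub, 0).sum(axis=1)
    return n.astype(float), alt.astype(float)


def window_scan(
    snp: SNPMatrix,
    window: int = WINDOW_SIZE,
    step: int = WINDOW_STEP,
    chrom_length: int | None = None,
    fst_pair: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Sliding-window scan of per-population pi and pairwise Hudson F_ST.

    Windows are half-open ``[start, start + window)`` at ``step`` spacing
    from 0 to the end of the chromosome (``chrom_length`` defaults to the
    last SNP position). Window pi is the mean of per-site pi over contained
    SNPs; window F_ST is the ratio of averages ``1 - sum(H_w) / sum(H_b)``
    over contained informative SNPs. Windows without usable SNPs report NaN.
    """
    pops = sorted(set(snp.populations))
    if fst_pair is None and len(pops) == 2:
        fst_pair = (pops[0], pops[1])
    length = chrom_length if chrom_length is not None else int(snp.positions.max())
    if window > length:
        logger.warning("window larger than chromosome; single truncated window")

    per_pop: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    pi_site: dict[str, np.ndarray] = {}
    for pop in pops:
        n, alt = _site_arrays(snp.genotypes, snp.pop_columns(pop))
        per_pop[pop] = (n, alt)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
            pi = 2.0 * p * (1.0 - p) * n / np.maximum(n - 1, 1)
        pi[n < 2] = np.nan  # sites without enough called copies drop out
        pi_site[pop] = pi

    hw = hb = None
    if fst_pair is not None:
        (n1, a1), (n2, a2) = per_pop[fst_pair[0]], per_pop[fst_pair[1]]
        with np.errstate(divide="ignore", invalid="ignore"):
            q1 = a1 / np.maximum(n1, 1)
            q2 = a2 / np.maximum(n2, 1)
            hw = (
                2.0 * q1 * (1.0 - q1) * n1 / np.maximum(n1 - 1, 1)
                + 2.0 * q2 * (1.0 - q2) * n2 / np.maximum(n2 - 1, 1)
            ) / 2.0
            hb = q1 * (1.0 - q2) + q2 * (1.0 - q1)
        usable = (n1 >= 2) & (n2 >= 2) & (hb > 0)
        hw = np.where(usable, hw, np.nan)
        hb = np.where(usable, hb, np.nan)

    rows = []
    starts = range(0, max(length - window, 0) + step, step)
    for start in starts:
        end = start + window
        # positions are 1-based; half-open window [start, end) in 0-based bp
        mask = (snp.positions > start) & (snp.positions <= end)
        row: dict = {
            "chrom": snp.chrom,
            "start": start,
            "end": end,
            "n_snps": int(mask.sum()),
        }
        for pop in pops:
            vals = pi_site[pop][mask]
            vals = vals[~np.isnan(vals)]
            row[f"pi_{pop}"] = float(vals.mean()) if vals.size else math.nan
        if fst_pair is not None:
            w = hw[mask]
            b = hb[mask]
            ok = ~np.isnan(b)
            if ok.any() and np.nansum(b[ok]) > 0:
                row["fst"] = float(1.0 - np.nansum(w[ok]) / np.nansum(b[ok]))
            else:
                row["fst"] = math.nan
        rows.append(row)
    return pd.DataFrame(rows)


def extract_haplotypes(
    snp: SNPMatrix,
    region: tuple[int, int],
    gene_id: str = "gene",
) -> pd.DataFrame:
    """Genic haplotype table for one gene region (BED 0-based half-open).

    Accessions with any missing or heterozygous call in the region are
    excluded (accessions are expected to be inbred, so heterozygous genic
    calls indicate unreliable data). Haplotypes are keyed by the genotype
    vector across the region's SNPs and labelled ``H1, H2, ...`` by
    descending pooled frequency. Returns a tidy table with per-population
    counts and frequencies.
    """
    start, end = region
    mask = (snp.positions > start) & (snp.positions <= end)
    if not mask.any():
        raise ValueError("region contains no SNPs")
    sub = snp.genotypes[mask]
    complete = np.all((sub == 0) | (sub == 2), axis=0)
    n_excluded = (~complete).sum()
    if n_excluded:
        logger.info(
            "extract_haplotypes: excluded %d accession(s) with missing or "
            "heterozygous genic calls", n_excluded,
        )
    if not complete.any():
        logger.warning("extract_haplotypes: all accessions excluded")
        return pd.DataFrame(
            columns=["gene", "population", "haplotype", "key", "count", "frequency"]
        )
    keys = ["".join(str(v // 2) for v in sub[:, j]) for j in np.flatnonzero(complete)]
    pops = [snp.populations[j] for j in np.flatnonzero(complete)]
    df = pd.DataFrame({"key": keys, "population": pops})
    pooled = df["key"].value_counts(sort=True)
    labels = {key: f"H{i + 1}" for i, key in enumerate(pooled.index)}
    counts = (
        df.groupby(["population", "key"], as_index=False).size()
        .rename(columns={"size": "count"})
    )
    counts["haplotype"] = counts["key"].map(labels)
    counts["gene"] = gene_id
    totals = counts.groupby("population")["count"].transform("sum")
    counts["frequency"] = counts["count"] / totals
    counts["rank"] = counts["haplotype"].str.slice(1).astype(int)
    counts = counts.sort_values(["population", "rank"], ignore_index=True)
    return counts[["gene", "population", "haplotype", "key", "count", "frequency"]]


def frequencies_from_counts(counts: "dict[str, int]") -> dict[str, float]:
    """Haplotype frequencies from per-haplotype accession counts."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("need at least one counted accession")
    return {hap: n / total for hap, n in counts.items()}


def compare_haplotype_freqs(
    hap_table: pd.DataFrame,
    haplotype: str,
    pop1: str,
    pop2: str,
) -> float:
    """Two-tailed Fisher p for a haplotype's frequency difference.

    Builds the 2x2 carrier/non-carrier x population table from the
    haplotype table and delegates to :func:`fisher_exact_2x2`. A haplotype
    absent from both populations gives p = 1.
    """
    counts = {}
    for pop in (pop1, pop2):
        sub = hap_table[hap_table["population"] == pop]
        if sub.empty:
            raise ValueError(f"population {pop!r} not in haplotype table")
        total = int(sub["count"].sum())
        carriers = int(sub.loc[sub["haplotype"] == haplotype, "count"].sum())
        counts[pop] = (carriers, total - carriers)
    if counts[pop1][0] == 0 and counts[pop2][0] == 0:
        return 1.0
    return fisher_exact_2x2([list(counts[pop1]), list(counts[pop2])])
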