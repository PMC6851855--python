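"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the five input kinds of a hexaploid-wheat CRISPR
knockout study: amplicon reads carrying programmed indel alleles on three
homoeologs, per-plant per-spike grain phenotypes under an additive dosage
model, a TPM expression matrix with a planted co-expression module around a
focal homoeolog triad, and exome-capture-style SNP matrices for a wild and
a domesticated population with a planted selective sweep and discrete genic
haplotypes.

Every generator consumes a :class:`SimConfig` and returns an in-memory
result object holding both the data and a truth table sufficient to score
the downstream caller; ``write_*`` methods emit the standard file formats
(FASTQ Phred+33, FASTA, VCF v4.2, TSV). The same seed always reproduces
byte-identical output.
"""

from __future__ import annotations

import ast
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .amplicon import GENOMES, HomoeologRef, dosage_from_code

TRAITS = ("width", "length", "area", "tgw")

#: trait baselines for the unedited genotype: grain width (mm), length (mm),
#: area (mm^2) and thousand grain weight (g) typical of a spring wheat
#: cultivar
DEFAULT_BASELINES = {"width": 3.67, "length": 6.27, "area": 16.67, "tgw": 42.72}

#: per-homoeolog effect of a homozygous knockout, percent change of each
#: trait relative to wild type; the D-genome copy (highest expressed) has
#: the largest effect, and knockouts widen and shorten the grain while
#: raising TGW
DEFAULT_EFFECTS = {
    "A": {"width": 0.0, "length": 0.0, "area": 0.0, "tgw": 0.0},
    "B": {"width": 1.91, "length": 0.32, "area": 1.50, "tgw": 1.78},
    "D": {"width": 2.18, "length": -2.07, "area": 0.36, "tgw": 2.90},
}

#: between-plant trait standard deviations (same units as the trait)
DEFAULT_NOISE_SD = {"width": 0.087, "length": 0.168, "area": 0.71, "tgw": 2.45}

#: default per-population haplotype frequencies at the focal gene; the wild
#: population segregates three haplotypes while the domesticated population
#: is fixed for the lead haplotype, the signature left by domestication
#: selection
DEFAULT_HAP_FREQS = {
    "wild": {"H1": 0.194, "H2": 0.452, "H3": 0.354},
    "domesticated": {"H1": 1.0},
}


@dataclass
class SimConfig:
    """Configuration shared by all generators.

    Counts are per the natural unit of each generator: ``n_reads`` is reads
    per homoeolog per plant, ``n_plants`` plants in a phenotyping family,
    ``n_genes``/``n_samples`` the expression matrix shape, ``n_wild``/
    ``n_domesticated`` accessions per population. ``effect_sizes`` are
    percent changes for a homozygous knockout, halved per mutant allele
    under the additive dosage model. ``error_rate`` is the per-base
    substitution rate of the read simulator; ``sweep_strength`` in [0, 1]
    scales how far domesticated allele frequencies are pushed toward
    fixation inside ``sweep_span``.
    """

    seed: int = 0
    # amplicon reads
    n_reads: int = 60
    error_rate: float = 0.001
    # phenotypes
    n_plants: int = 116
    spikes_per_plant: int = 3
    effect_sizes: dict = field(default_factory=lambda: {
        g: dict(t) for g, t in DEFAULT_EFFECTS.items()
    })
    baselines: dict = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    spike_sd: dict | None = None  # defaults to noise_sd
    # expression
    n_genes: int = 5000
    n_samples: int = 209
    module_size: int = 50
    module_loading: float = 0.9
    expr_noise_sd: float = 0.3
    # population genetics
    n_wild: int = 34
    n_domesticated: int = 40
    chrom_length: int = 40_000_000
    n_snps: int = 4000
    sweep_span: tuple[int, int] = (10_000_000, 14_000_000)
    sweep_strength: float = 0.9
    gene_region: tuple[int, int] = (11_900_000, 11_905_000)
    n_gene_snps: int = 8
    missing_rate: float = 0.02
    hap_freqs: dict = field(default_factory=lambda: {
        p: dict(h) for p, h in DEFAULT_HAP_FREQS.items()
    })

    def __post_init__(self) -> None:
        for name in ("n_reads", "n_plants", "spikes_per_plant", "n_genes",
                     "n_samples", "module_size", "n_wild", "n_domesticated",
                     "n_snps", "n_gene_snps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("error_rate", "missing_rate", "sweep_strength"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.module_size >= self.n_genes:
            raise ValueError("module_size must be smaller than n_genes")
        if not (0 <= self.sweep_span[0] < self.sweep_span[1] <= self.chrom_length):
            raise ValueError("sweep_span outside simulated chromosome")
        for pop, freqs in self.hap_freqs.items():
            total = sum(freqs.values())
            if not math.isclose(total, 1.0, abs_tol=1e-6):
                raise ValueError(f"haplotype frequencies for {pop} sum to {total}")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        """Load a flat ``key = value`` config file; values are Python literals."""
        kwargs = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            kwargs[key.strip()] = ast.literal_eval(value.strip())
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# amplicon reads


def default_refs(length: int = 240, *, _seed: int = 715) -> list[HomoeologRef]:
    """Three homoeolog amplicon references differing only at diagnostic bases.

    The amplicons share a common backbone; diagnostic bases at three offsets
    upstream of the cut site uniquely separate the A, B and D copies, so a
    primer-anchored read keeps its diagnostic coordinates regardless of
    indels at the cut site. The PAM lies 3 nt downstream of the cut.
    """
    rng = np.random.default_rng(_seed)
    backbone = "".join(rng.choice(list("ACGT"), size=length))
    cut = length // 2
    pam = (cut + 3, cut + 6)
    backbone = backbone[: pam[0]] + backbone[pam[0]] + "GG" + backbone[pam[1]:]
    diag_offsets = (30, 50, 70)
    diag_bases = {"A": ("A", "C", "G"), "B": ("C", "G", "T"), "D": ("G", "T", "A")}
    refs = []
    for genome in GENOMES:
        seq = list(backbone)
        for off, base in zip(diag_offsets, diag_bases[genome]):
            seq[off] = base
        refs.append(
            HomoeologRef(
                genome=genome,
                sequence="".join(seq),
                cut_site=cut,
                pam_span=pam,
                diagnostics=tuple(zip(diag_offsets, diag_bases[genome])),
            )
        )
    return refs


def _apply_allele(ref: HomoeologRef, allele: str) -> str:
    """Build the read sequence carrying one programmed allele.

    Allele strings: ``"WT"``, ``"-n"`` (n bases deleted spanning the cut
    site) or ``"+n:SEQ"`` (SEQ inserted at the cut site).
    """
    seq = ref.sequence
    if allele == "WT":
        return seq
    if allele.startswith("+"):
        n_str, _, ins = allele[1:].partition(":")
        n = int(n_str)
        if len(ins) != n:
            raise ValueError(f"insertion length mismatch in {allele!r}")
        return seq[: ref.cut_site] + ins + seq[ref.cut_site:]
    n = -int(allele)
    start = ref.cut_site - n // 2
    if start < 0 or start + n > len(seq):
        raise ValueError(f"deletion {allele!r} exceeds amplicon bounds")
    return seq[:start] + seq[start + n:]


_BASE_IDX = {b: i for i, b in enumerate("ACGT")}
_BASES = np.array(list("ACGT"))


def _add_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate == 0:
        return seq
    arr = np.array(list(seq))
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


@dataclass
class AmpliconReadSet:
    """Simulated FASTQ reads plus the per-read truth table."""

    reads: list[tuple[str, str]]  # (read_id, sequence)
    truth: pd.DataFrame  # read_id, homoeolog, allele
    refs: list[HomoeologRef]

    def sequences(self) -> list[str]:
        return [seq for _, seq in self.reads]

    def write_fastq(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rid, seq in self.reads:
                fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")

    def write_refs(self, fasta_path: str | Path, targets_path: str | Path) -> None:
        with open(fasta_path, "w") as fh:
            for ref in self.refs:
                fh.write(f">{ref.genome}\n{ref.sequence}\n")
        rows = [
            {
                "genome": ref.genome,
                "cut_site": ref.cut_site,
                "pam_start": ref.pam_span[0],
                "pam_end": ref.pam_span[1],
                "diagnostics": ",".join(f"{o}:{b}" for o, b in ref.diagnostics),
            }
            for ref in self.refs
        ]
        pd.DataFrame(rows).to_csv(targets_path, sep="\t", index=False)

    def write_truth(self, path: str | Path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def gen_amplicon_reads(
    cfg: SimConfig,
    refs: Sequence[HomoeologRef] | None = None,
    allele_freqs: Mapping[str, Sequence[tuple[str, float]]] | None = None,
    plant_id: str = "plant1",
    exact_counts: bool = False,
) -> AmpliconReadSet:
    """Simulate amplicon reads carrying programmed indel alleles.

    ``allele_freqs`` maps each subgenome to ``(allele, frequency)`` pairs
    (frequencies summing to 1); the default is all wild type. ``cfg.n_reads``
    reads are drawn per homoeolog with multinomial allele counts, then
    independent substitution errors are applied at ``cfg.error_rate``. With
    ``exact_counts`` the allele counts realize the programmed frequencies
    exactly (largest-remainder rounding) instead of being sampled, which is
    useful when scoring a caller against the truth table without binomial
    noise.
    """
    refs = list(refs) if refs is not None else default_refs()
    rng = np.random.default_rng(cfg.seed)
    if allele_freqs is None:
        allele_freqs = {g: [("WT", 1.0)] for g in GENOMES}
    reads: list[tuple[str, str]] = []
    truth_rows: list[dict] = []
    for ref in refs:
        spec = list(allele_freqs.get(ref.genome, [("WT", 1.0)]))
        total = sum(f for _, f in spec)
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError(f"allele frequencies for {ref.genome} sum to {total}")
        templates = [_apply_allele(ref, allele) for allele, _ in spec]
        if exact_counts:
            choices = _exact_choices(cfg.n_reads, [f for _, f in spec])
        else:
            choices = rng.choice(len(spec), size=cfg.n_reads, p=[f for _, f in spec])
        for i, k in enumerate(choices):
            rid = f"{plant_id}:{ref.genome}:{i:04d}"
            seq = _add_errors(templates[k], rng, cfg.error_rate)
            reads.append((rid, seq))
            truth_rows.append(
                {"read_id": rid, "homoeolog": ref.genome, "allele": spec[k][0]}
            )
    return AmpliconReadSet(reads, pd.DataFrame(truth_rows), refs)


def _exact_choices(n: int, freqs: Sequence[float]) -> np.ndarray:
    """Allele indices realizing frequencies exactly (largest remainder)."""
    raw = [n * f for f in freqs]
    counts = [int(x) for x in raw]
    short = n - sum(counts)
    by_remainder = sorted(range(len(freqs)), key=lambda k: raw[k] - counts[k],
                          reverse=True)
    for k in by_remainder[:short]:
        counts[k] += 1
    return np.repeat(np.arange(len(freqs)), counts)


#: mutant fractions implied by each zygosity class, used when simulating
#: reads for a plant of known genotype
_ZYG_FRACTION = {0: 0.0, 1: 0.5, 2: 1.0}


def allele_freqs_for_code(
    code: str, allele: str = "-10"
) -> dict[str, list[tuple[str, float]]]:
    """Per-homoeolog allele frequencies implied by a genotype code."""
    freqs: dict[str, list[tuple[str, float]]] = {}
    for genome, dosage in dosage_from_code(code).items():
        f = _ZYG_FRACTION[dosage]
        spec: list[tuple[str, float]] = []
        if f < 1.0:
            spec.append(("WT", 1.0 - f))
        if f > 0.0:
            spec.append((allele, f))
        freqs[genome] = spec
    return freqs


# ---------------------------------------------------------------------------
# phenotypes


@dataclass
class PhenotypeSim:
    """Simulated per-spike phenotype table plus generating truth."""

    table: pd.DataFrame  # plant_id, genotype, spike, width, length, area, tgw
    truth: pd.DataFrame  # genome, trait, effect_pct

    def write_table(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def write_truth(self, path: str | Path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def gen_phenotype_table(
    cfg: SimConfig,
    genotypes: Sequence[str] | None = None,
) -> PhenotypeSim:
    """Simulate grain phenotypes under the additive dosage model.

    Each plant's expected trait value is
    ``baseline * (1 + sum_g effect_g * mutant_alleles_g / 2)`` with
    Gaussian between-plant and between-spike noise; negative draws are
    resampled. ``genotypes`` lists one six-letter code per plant; by
    default ``cfg.n_plants`` plants are split evenly across the four
    genotype classes of a segregating double-knockout family.
    """
    rng = np.random.default_rng(cfg.seed)
    if genotypes is None:
        classes = ["AABBDD", "AAbbDD", "AABBdd", "AAbbdd"]
        genotypes = [classes[i % len(classes)] for i in range(cfg.n_plants)]
    spike_sd = cfg.spike_sd if cfg.spike_sd is not None else cfg.noise_sd
    rows = []
    for p, code in enumerate(genotypes):
        dosage = dosage_from_code(code)
        plant_means = {}
        for trait in TRAITS:
            shift = sum(
                cfg.effect_sizes[g][trait] / 100.0 * dosage[g] / 2.0
                for g in GENOMES
            )
            expected = cfg.baselines[trait] * (1.0 + shift)
            value = expected + rng.normal(0.0, cfg.noise_sd[trait])
            while value <= 0:  # resample impossible negative trait values
                value = expected + rng.normal(0.0, cfg.noise_sd[trait])
            plant_means[trait] = value
        for s in range(cfg.spikes_per_plant):
            row = {"plant_id": f"P{p:04d}", "genotype": code, "spike": s + 1}
            for trait in TRAITS:
                value = plant_means[trait] + rng.normal(0.0, spike_sd[trait])
                while value <= 0:
                    value = plant_means[trait] + rng.normal(0.0, spike_sd[trait])
                row[trait] = value
            rows.append(row)
    truth = pd.DataFrame(
        [
            {"genome": g, "trait": t, "effect_pct": cfg.effect_sizes[g][t]}
            for g in GENOMES
            for t in TRAITS
        ]
    )
    return PhenotypeSim(pd.DataFrame(rows), truth)


# ---------------------------------------------------------------------------
# expression


@dataclass
class ExpressionSim:
    """Simulated TPM matrix (genes x samples) plus module-membership truth."""

    tpm: pd.DataFrame
    truth: pd.DataFrame  # gene_id, module_member
    focal_genes: tuple[str, str, str]

    def write_tpm(self, path: str | Path) -> None:
        self.tpm.to_csv(path, sep="\t")

    def write_truth(self, path: str | Path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


FOCAL_GENES = ("FOCAL_A", "FOCAL_B", "FOCAL_D")


def gen_expression_matrix(cfg: SimConfig) -> ExpressionSim:
    """Simulate a TPM matrix with a planted co-expression module.

    The first ``cfg.module_size`` genes (including the three focal
    homoeologs) follow a shared latent factor with loading
    ``cfg.module_loading`` plus Gaussian noise; background genes are
    independent. Log-scale values are mapped to strictly positive TPMs via
    ``2**(x + 4)``, so the module structure survives the downstream
    log transformation.
    """
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_genes, cfg.n_samples
    latent = rng.normal(size=m)
    log_expr = np.empty((n, m))
    k = cfg.module_size
    log_expr[:k] = (
        cfg.module_loading * latent[None, :]
        + rng.normal(scale=cfg.expr_noise_sd, size=(k, m))
    )
    log_expr[k:] = rng.normal(scale=0.5, size=(n - k, m))
    tpm = np.round(2.0 ** (log_expr + 4.0), 4)
    gene_ids = list(FOCAL_GENES) + [f"gene{i:05d}" for i in range(n - 3)]
    sample_ids = [f"sample{j:03d}" for j in range(m)]
    frame = pd.DataFrame(tpm, index=pd.Index(gene_ids, name="gene"), columns=sample_ids)
    truth = pd.DataFrame(
        {"gene_id": gene_ids, "module_member": [i < k for i in range(n)]}
    )
    return ExpressionSim(frame, truth, FOCAL_GENES)


# ---------------------------------------------------------------------------
# additive trees (for scoring distance-based tree reconstruction)


def gen_additive_distances(
    n_taxa: int, rng: np.random.Generator
) -> tuple[list[str], np.ndarray, set[frozenset]]:
    """Random tree with positive branch lengths and its additive distances.

    Builds a random binary topology by sequential cluster joins with branch
    lengths uniform on (0.1, 1), and returns ``(ids, distance_matrix,
    splits)`` where ``splits`` are the canonical nontrivial bipartitions of
    the generating tree (each split represented by the side not containing
    the alphabetically first taxon). Any consistent distance-based
    reconstruction must recover exactly these splits.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    ids = [f"t{i}" for i in range(n_taxa)]
    clusters: list[set[str]] = [{t} for t in ids]
    extra = {t: 0.0 for t in ids}  # distance from each leaf to its cluster root
    pair_dist: dict[frozenset, float] = {}
    splits: set[frozenset] = set()
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        li = float(rng.uniform(0.1, 1.0))
        lj = float(rng.uniform(0.1, 1.0))
        for a in clusters[i]:
            for b in clusters[j]:
                pair_dist[frozenset((a, b))] = extra[a] + li + extra[b] + lj
        for a in clusters[i]:
            extra[a] += li
        for b in clusters[j]:
            extra[b] += lj
        for side in (clusters[i], clusters[j]):
            if 2 <= len(side) <= n_taxa - 2:
                splits.add(frozenset(side))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [
            clusters[i] | clusters[j]
        ]
    mat = np.zeros((n_taxa, n_taxa))
    for a in range(n_taxa):
        for b in range(a + 1, n_taxa):
            mat[a, b] = mat[b, a] = pair_dist[frozenset((ids[a], ids[b]))]
    taxa = frozenset(ids)
    anchor = min(taxa)
    canon = {
        (taxa - s) if anchor in s else s
        for s in splits
    }
    return ids, mat, {s for s in canon if 2 <= len(s) <= n_taxa - 2}


# ---------------------------------------------------------------------------
# population genetics


@dataclass
class PopgenSim:
    """Simulated SNP genotypes for two populations plus the planted truth.

    ``genotypes`` holds alt-allele dosages (0/2 for inbred accessions, -1
    missing) with one row per SNP and one column per accession.
    """

    chrom: str
    positions: np.ndarray
    genotypes: np.ndarray
    accessions: list[str]
    populations: list[str]
    truth_haplotypes: pd.DataFrame  # accession, population, haplotype
    sweep_span: tuple[int, int]
    gene_region: tuple[int, int]

    def write_vcf(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##contig=<ID={self.chrom},length={self.positions.max() + 1}>\n")
            fh.write(
                '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            )
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.accessions)
                + "\n"
            )
            gt_str = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
            for i, pos in enumerate(self.positions):
                calls = "\t".join(gt_str[int(g)] for g in self.genotypes[i])
                fh.write(
                    f"{self.chrom}\t{pos}\tsnp{i:05d}\tA\tG\t.\tPASS\t.\tGT\t{calls}\n"
                )

    def write_populations(self, path: str | Path) -> None:
        pd.DataFrame(
            {"accession": self.accessions, "population": self.populations}
        ).to_csv(path, sep="\t", index=False)

    def write_truth(self, path: str | Path) -> None:
        self.truth_haplotypes.to_csv(path, sep="\t", index=False)


def gen_popgen_vcf(cfg: SimConfig) -> PopgenSim:
    """Simulate inbred-accession SNP data with a sweep and genic haplotypes.

    Wild-population allele frequencies are uniform on (0.05, 0.95);
    domesticated frequencies equal the wild ones outside ``cfg.sweep_span``
    and are pushed toward the nearest fixation point inside it by
    ``cfg.sweep_strength``. SNPs inside ``cfg.gene_region`` instead encode
    ``len(hap_freqs)`` discrete haplotypes drawn at the programmed
    per-population frequencies. Accessions are homozygous (selfing wheat);
    calls go missing independently at ``cfg.missing_rate``.
    """
    rng = np.random.default_rng(cfg.seed)
    hap_ids = sorted({h for freqs in cfg.hap_freqs.values() for h in freqs})
    n_haps = len(hap_ids)
    if n_haps > 2 ** cfg.n_gene_snps:
        raise ValueError("more haplotypes than distinct genic SNP vectors")

    n_background = cfg.n_snps
    positions = np.sort(
        rng.choice(cfg.chrom_length, size=n_background, replace=False)
    ).astype(np.int64) + 1
    # carve out the gene region for the programmed haplotype SNPs
    g0, g1 = cfg.gene_region
    keep = (positions <= g0) | (positions > g1)
    positions = positions[keep]
    gene_pos = np.sort(
        rng.choice(np.arange(g0 + 1, g1 + 1), size=cfg.n_gene_snps, replace=False)
    )
    all_pos = np.sort(np.concatenate([positions, gene_pos]))
    is_genic = np.isin(all_pos, gene_pos)

    pops = ["wild"] * cfg.n_wild + ["domesticated"] * cfg.n_domesticated
    accessions = [f"acc{i:03d}" for i in range(len(pops))]
    n_acc = len(pops)
    n_snp = all_pos.size

    p_wild = rng.uniform(0.05, 0.95, size=n_snp)
    p_dom = p_wild.copy()
    s0, s1 = cfg.sweep_span
    in_sweep = (all_pos > s0) & (all_pos <= s1)
    target = np.where(p_wild >= 0.5, 1.0, 0.0)
    s = cfg.sweep_strength
    p_dom[in_sweep] = (1 - s) * p_wild[in_sweep] + s * target[in_sweep]

    geno = np.empty((n_snp, n_acc), dtype=np.int8)
    pop_arr = np.array(pops)
    for pop, p in (("wild", p_wild), ("domesticated", p_dom)):
        cols = np.flatnonzero(pop_arr == pop)
        draws = rng.random((n_snp, cols.size)) < p[:, None]
        geno[:, cols] = 2 * draws.astype(np.int8)

    # distinct binary haplotype vectors over the genic SNPs
    hap_vectors: dict[str, np.ndarray] = {}
    seen: set[bytes] = set()
    for hap in hap_ids:
        while True:
            vec = rng.integers(0, 2, size=cfg.n_gene_snps).astype(np.int8)
            if vec.tobytes() not in seen:
                seen.add(vec.tobytes())
                hap_vectors[hap] = vec
                break
    genic_idx = np.flatnonzero(is_genic)
    truth_rows = []
    for j, (acc, pop) in enumerate(zip(accessions, pops)):
        freqs = cfg.hap_freqs[pop]
        names = sorted(freqs)
        hap = names[rng.choice(len(names), p=[freqs[h] for h in names])]
        geno[genic_idx, j] = 2 * hap_vectors[hap]
        truth_rows.append({"accession": acc, "population": pop, "haplotype": hap})

    if cfg.missing_rate > 0:
        miss = rng.random(geno.shape) < cfg.missing_rate
        geno[miss] = -1

    return PopgenSim(
        chrom="chr2A",
        positions=all_pos,
        genotypes=geno,
        accessions=accessions,
        populations=pops,
        truth_haplotypes=pd.DataFrame(truth_rows),
        sweep_span=cfg.sweep_span,
        gene_region=cfg.gene_region,
    )
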