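"""Calling CRISPR editing outcomes from homoeolog amplicon reads.

Hexaploid wheat carries three near-identical copies (homoeologs) of most
genes on its A, B and D subgenomes. Amplicon deep sequencing of a gRNA
target region therefore yields a read mixture that must first be assigned
to a homoeolog using diagnostic bases, before indels at the Cas9 cut site
can be detected, normalized and tabulated into per-allele frequencies and,
finally, per-plant zygosity calls.

Coordinates are 0-based half-open throughout. Reads are assumed to be
primer-anchored, i.e. position 0 of the read corresponds to position 0 of
the amplicon reference.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align, SeqIO

logger = logging.getLogger(__name__)

GENOMES = ("A", "B", "D")

#: default scoring for the global read-vs-amplicon alignment
MATCH_SCORE = 2.0
MISMATCH_SCORE = -2.0
GAP_OPEN = -6.0
GAP_EXTEND = -1.0

#: indels farther than this from the cut site are treated as alignment noise
CUT_WINDOW = 20

# read-fraction thresholds for zygosity calls; the gaps between them are
# deliberate: calls falling inside a gap are reported as ambiguous rather
# than forced to the nearest class
WT_MAX_FRACTION = 0.10
HET_MIN_FRACTION = 0.30
HET_MAX_FRACTION = 0.70
HOM_MIN_FRACTION = 0.90


@dataclass(frozen=True)
class HomoeologRef:
    """One homoeolog amplicon reference with its gRNA target annotation.

    Parameters
    ----------
    genome :
        Subgenome label, one of ``A``, ``B``, ``D``.
    sequence :
        Amplicon sequence, uppercase DNA.
    cut_site :
        0-based offset of the expected Cas9 blunt cut (3 nt upstream of the
        PAM).
    pam_span :
        Half-open interval of the PAM trinucleotide.
    diagnostics :
        ``(offset, base)`` pairs whose bases jointly distinguish this
        homoeolog from the other two.
    cds_frame_offset :
        Reading-frame phase of position 0 of the amplicon (0, 1 or 2).
    """

    genome: str
    sequence: str
    cut_site: int
    pam_span: tuple[int, int]
    diagnostics: tuple[tuple[int, str], ...]
    cds_frame_offset: int = 0

    def __post_init__(self) -> None:
        if self.genome not in GENOMES:
            raise ValueError(f"genome must be one of {GENOMES}, got {self.genome!r}")
        if not 0 <= self.cut_site < len(self.sequence):
            raise ValueError("cut_site outside amplicon")
        for off, base in self.diagnostics:
            if not 0 <= off < len(self.sequence):
                raise ValueError("diagnostic position outside amplicon")
            if self.sequence[off] != base:
                raise ValueError(
                    f"diagnostic base mismatch at {off}: reference has "
                    f"{self.sequence[off]!r}, annotation says {base!r}"
                )


@dataclass(frozen=True)
class IndelCall:
    """Normalized indel observed in a single read.

    ``net_indel`` is the signed sum of indel lengths within the cut-site
    window (insertions positive, deletions negative); 0 with an empty
    ``inserted_seq`` means wild type. ``normalized_start`` is the leftmost
    position after left-shifting each indel through flanking repeats (the
    VCF convention), so the "-10"/"-3" style labels are stable across reads.
    """

    net_indel: int
    inserted_seq: str
    normalized_start: int

    @property
    def is_wt(self) -> bool:
        return self.net_indel == 0 and not self.inserted_seq

    @property
    def frameshift(self) -> bool:
        return self.net_indel % 3 != 0

    def label(self) -> str:
        if self.is_wt:
            return "WT"
        if self.net_indel < 0 and not self.inserted_seq:
            return str(self.net_indel)
        if self.net_indel > 0:
            return f"+{self.net_indel}:{self.inserted_seq}"
        return f"{self.net_indel}:{self.inserted_seq}"


@dataclass(frozen=True)
class EditAllele:
    """One observed allele of a homoeolog, aggregated over reads."""

    net_indel: int
    inserted_seq: str
    normalized_start: int
    read_count: int
    frequency: float

    @property
    def is_wt(self) -> bool:
        return self.net_indel == 0 and not self.inserted_seq

    @property
    def frameshift(self) -> bool:
        return self.net_indel % 3 != 0

    def label(self) -> str:
        return IndelCall(self.net_indel, self.inserted_seq, self.normalized_start).label()


@dataclass
class PlantGenotype:
    """Per-plant editing genotype across the three homoeologs.

    ``code`` is the six-letter genotype string used for hexaploid editing
    studies: one letter pair per subgenome in A, B, D order, uppercase for
    wild-type and lowercase for mutated alleles (heterozygotes written
    uppercase-first, e.g. ``AABbdd``). When any homoeolog call is ambiguous
    the code is withheld (``None``) instead of being coerced.
    """

    zygosity: dict[str, str]
    code: str | None
    functional_copies: int | None

    def __post_init__(self) -> None:
        if self.code is not None:
            n_upper = sum(1 for c in self.code if c.isupper())
            if n_upper != self.functional_copies:
                raise ValueError("functional_copies inconsistent with code")


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    # do not penalize missing read tails (reads may be shorter than amplicon)
    try:
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older Biopython naming
        aligner.query_end_gap_score = 0.0
    return aligner


_ALIGNER = _make_aligner()


def assign_homoeolog(
    read: str,
    refs: Sequence[HomoeologRef],
    min_covered: int = 1,
) -> tuple[str | None, str]:
    """Assign a primer-anchored read to a homoeolog via diagnostic bases.

    Returns ``(genome_label, "ok")`` when every diagnostic position covered
    by the read matches exactly one reference; otherwise ``(None, reason)``
    with reason one of ``"too_short"``, ``"no_match"``, ``"conflict"``.
    """
    matches: list[str] = []
    any_covered = False
    for ref in refs:
        covered = [(off, base) for off, base in ref.diagnostics if off < len(read)]
        if len(covered) < min_covered:
            continue
        any_covered = True
        if all(read[off] == base for off, base in covered):
            matches.append(ref.genome)
    if not any_covered:
        return None, "too_short"
    if len(matches) == 1:
        return matches[0], "ok"
    if len(matches) == 0:
        return None, "no_match"
    return None, "conflict"


def _left_normalize_deletion(ref: str, start: int, length: int) -> int:
    """Shift a deletion left through flanking repeats; returns new start."""
    while start > 0 and ref[start - 1] == ref[start + length - 1]:
        start -= 1
    return start


def _left_normalize_insertion(ref: str, pos: int, seq: str) -> tuple[int, str]:
    """Shift an insertion left through flanking repeats."""
    while pos > 0 and seq and ref[pos - 1] == seq[-1]:
        seq = ref[pos - 1] + seq[:-1]
        pos -= 1
    return pos, seq


def call_indel_allele(
    read: str,
    ref: HomoeologRef,
    cut_window: int = CUT_WINDOW,
    min_identity: float = 0.75,
) -> IndelCall | None:
    """Call the indel allele carried by one read against its homoeolog.

    The read is globally aligned to the amplicon; indels whose (normalized)
    span lies within ``cut_window`` bp of the cut site are summed into the
    net indel; indels farther away are alignment noise and ignored. Reads
    whose alignment identity falls below ``min_identity`` are discarded
    (returns ``None``).
    """
    # fast path: an equal-length read with few mismatches carries only
    # substitutions — no gapped alignment needed (compensating indel pairs
    # would leave a long frame-shifted, high-mismatch stretch instead)
    if len(read) == len(ref.sequence):
        mismatches = sum(1 for a, b in zip(read, ref.sequence) if a != b)
        if mismatches / len(read) <= 0.02:
            return IndelCall(0, "", ref.cut_site)

    aln = _ALIGNER.align(ref.sequence, read)[0]
    tgt_blocks, qry_blocks = aln.aligned
    n_match = 0
    n_cols = 0
    for (ts, te), (qs, qe) in zip(tgt_blocks, qry_blocks):
        n_cols += te - ts
        n_match += sum(
            1 for i in range(te - ts) if ref.sequence[ts + i] == read[qs + i]
        )
    if n_cols == 0 or n_match / max(n_cols, 1) < min_identity:
        return None

    deletions: list[tuple[int, int]] = []  # (normalized start, length)
    insertions: list[tuple[int, str]] = []  # (normalized pos, seq)
    for k in range(1, len(tgt_blocks)):
        prev_te, prev_qe = tgt_blocks[k - 1][1], qry_blocks[k - 1][1]
        ts, qs = tgt_blocks[k][0], qry_blocks[k][0]
        if ts > prev_te:  # gap in read = deletion from reference
            length = ts - prev_te
            start = _left_normalize_deletion(ref.sequence, prev_te, length)
            if _near_cut(start, start + length, ref.cut_site, cut_window):
                deletions.append((start, length))
        if qs > prev_qe:  # gap in reference = insertion in read
            seq = read[prev_qe:qs]
            pos, seq = _left_normalize_insertion(ref.sequence, prev_te, seq)
            if _near_cut(pos, pos, ref.cut_site, cut_window):
                insertions.append((pos, seq))

    if not deletions and not insertions:
        return IndelCall(0, "", ref.cut_site)
    net = sum(len(s) for _, s in insertions) - sum(n for _, n in deletions)
    inserted = "".join(s for _, s in sorted(insertions))
    start = min([p for p, _ in deletions] + [p for p, _ in insertions])
    return IndelCall(net, inserted, start)


def _near_cut(start: int, end: int, cut: int, window: int) -> bool:
    return start <= cut + window and end >= cut - window


@lru_cache(maxsize=200_000)
def _call_indel_cached(read: str, ref: HomoeologRef) -> IndelCall | None:
    """Memoized :func:`call_indel_allele`; amplicon read sets repeat sequences."""
    return call_indel_allele(read, ref)


def summarize_alleles(
    calls: Iterable[IndelCall],
) -> tuple[list[EditAllele], float | None]:
    """Aggregate per-read indel calls into an allele table.

    Alleles are keyed by ``(net_indel, inserted_seq, normalized_start)``;
    frequency is read count over total assigned reads, and the table is
    sorted by frequency descending. Returns ``(alleles, editing_efficiency)``
    where efficiency is the fraction of non-wild-type reads, or ``None``
    when no reads were assigned.
    """
    counts = Counter(
        (c.net_indel, c.inserted_seq, c.normalized_start) for c in calls
    )
    total = sum(counts.values())
    if total == 0:
        return [], None
    alleles = [
        EditAllele(net, ins, start, n, n / total)
        for (net, ins, start), n in counts.items()
    ]
    alleles.sort(key=lambda a: (-a.frequency, a.net_indel, a.inserted_seq))
    efficiency = sum(a.frequency for a in alleles if not a.is_wt)
    return alleles, efficiency


def mutant_fraction(alleles: Sequence[EditAllele]) -> float:
    """Fraction of assigned reads carrying any non-wild-type allele."""
    return sum(a.frequency for a in alleles if not a.is_wt)


def _zygosity_from_fraction(f: float) -> str:
    if f < WT_MAX_FRACTION:
        return "WT"
    if HET_MIN_FRACTION <= f <= HET_MAX_FRACTION:
        return "het"
    if f > HOM_MIN_FRACTION:
        return "hom"
    return "ambiguous"


_ZYG_TO_PAIR = {"WT": "{U}{U}", "het": "{U}{l}", "hom": "{l}{l}"}


def call_plant_genotype(
    allele_tables: Mapping[str, Sequence[EditAllele]],
) -> PlantGenotype:
    """Call per-homoeolog zygosity and the six-letter genotype code.

    The mutant read fraction *f* of each homoeolog maps to a zygosity class
    with deliberate gaps: f < 0.10 wild type, 0.30-0.70 heterozygous,
    f > 0.90 homozygous mutant, anything else ambiguous. If any homoeolog is
    ambiguous the genotype code and functional-copy count are withheld.
    """
    zygosity: dict[str, str] = {}
    for genome in GENOMES:
        alleles = allele_tables.get(genome, [])
        if not alleles:
            zygosity[genome] = "ambiguous"
            continue
        zygosity[genome] = _zygosity_from_fraction(mutant_fraction(alleles))
    if any(z == "ambiguous" for z in zygosity.values()):
        return PlantGenotype(zygosity, None, None)
    code = "".join(
        _ZYG_TO_PAIR[zygosity[g]].format(U=g.upper(), l=g.lower()) for g in GENOMES
    )
    functional = sum(1 for c in code if c.isupper())
    return PlantGenotype(zygosity, code, functional)


def genotype_reads(
    reads: Iterable[str],
    refs: Sequence[HomoeologRef],
) -> tuple[dict[str, list[EditAllele]], dict[str, float | None], PlantGenotype]:
    """Full per-plant pipeline: assign, call indels, tabulate, call genotype.

    Returns ``(allele_tables, efficiencies, genotype)`` keyed by subgenome.
    """
    ref_by_genome = {r.genome: r for r in refs}
    calls: dict[str, list[IndelCall]] = {g: [] for g in GENOMES}
    for read in reads:
        genome, _reason = assign_homoeolog(read, refs)
        if genome is None:
            continue
        call = _call_indel_cached(read, ref_by_genome[genome])
        if call is not None:
            calls[genome].append(call)
    tables: dict[str, list[EditAllele]] = {}
    efficiencies: dict[str, float | None] = {}
    for genome in GENOMES:
        alleles, eff = summarize_alleles(calls[genome])
        tables[genome] = alleles
        efficiencies[genome] = eff
    return tables, efficiencies, call_plant_genotype(tables)


# ---------------------------------------------------------------------------
# genotype code helpers and file I/O


def dosage_from_code(code: str) -> dict[str, int]:
    """Mutant-allele count (0/1/2) per subgenome from a genotype code."""
    if len(code) != 6:
        raise ValueError(f"genotype code must have 6 letters, got {code!r}")
    out: dict[str, int] = {}
    for i, genome in enumerate(GENOMES):
        pair = code[2 * i : 2 * i + 2]
        if {c.upper() for c in pair} != {genome}:
            raise ValueError(f"unexpected letters {pair!r} for genome {genome}")
        out[genome] = sum(1 for c in pair if c.islower())
    return out


def functional_copies_from_code(code: str) -> int:
    """Number of non-mutated alleles (0-6) encoded by a genotype code."""
    return sum(1 for c in code if c.isupper())


def read_fastq(path: str | Path) -> list[str]:
    """Read sequences from a FASTQ file (Phred+33)."""
    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")]


def load_refs(fasta_path: str | Path, targets_path: str | Path) -> list[HomoeologRef]:
    """Load homoeolog references from FASTA plus a targets TSV.

    The targets table has columns ``genome``, ``cut_site``, ``pam_start``,
    ``pam_end`` and ``diagnostics`` (comma-separated ``offset:base`` pairs);
    FASTA record ids are the genome labels.
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    targets = pd.read_csv(targets_path, sep="\t", dtype={"genome": str})
    refs = []
    for row in targets.itertuples():
        diags = tuple(
            (int(p.split(":")[0]), p.split(":")[1])
            for p in str(row.diagnostics).split(",")
        )
        refs.append(
            HomoeologRef(
                genome=row.genome,
                sequence=seqs[row.genome],
                cut_site=int(row.cut_site),
                pam_span=(int(row.pam_start), int(row.pam_end)),
                diagnostics=diags,
            )
        )
    return refs


def allele_table_frame(tables: Mapping[str, Sequence[EditAllele]]) -> pd.DataFrame:
    """Flatten per-homoeolog allele tables into one tidy DataFrame."""
    rows = [
        {
            "genome": genome,
            "allele": a.label(),
            "net_indel": a.net_indel,
            "inserted_seq": a.inserted_seq,
            "normalized_start": a.normalized_start,
            "count": a.read_count,
            "frequency": a.frequency,
            "frameshift": a.frameshift,
        }
        for genome, alleles in tables.items()
        for a in alleles
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "genome",
            "allele",
            "net_indel",
            "inserted_seq",
            "normalized_start",
            "count",
            "frequency",
            "frameshift",
        ],
    )
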