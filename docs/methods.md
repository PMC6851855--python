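# Methods

This note records the models, defaults and numerical choices behind each
module, and what the synthetic generators do and do not emulate.

## Amplicon genotyping

Reads are assumed primer-anchored: read position 0 equals amplicon
position 0, so diagnostic bases placed upstream of the cut site keep their
coordinates regardless of cut-site indels. A read is assigned to a
homoeolog only when every diagnostic position it covers matches exactly
one reference; conflicting or non-matching reads are left unassigned
rather than guessed.

Indel calling uses a global pairwise alignment (match +2, mismatch −2, gap
open −6, gap extend −1; read end-gaps free, so truncated reads are not
penalized). Each indel is left-shifted through flanking repeats (the VCF
normalization convention) so that repeat-ambiguous deletions always get the
same label. Only indels within ±20 bp of the cut site count toward the
allele; more distant gaps are treated as alignment noise. Equal-length
reads with ≤2% mismatches are called wild type without alignment — a
substitution-only read cannot carry a net indel, and a compensating
insertion/deletion pair would leave a long frame-shifted stretch far above
that mismatch ceiling. Reads below 75% alignment identity are discarded
with a reason code.

Zygosity is called from the mutant read fraction *f* per homoeolog with
deliberate gaps between classes: *f* < 0.10 wild type, 0.30 ≤ *f* ≤ 0.70
heterozygous, *f* > 0.90 homozygous; anything else is ambiguous, and an
ambiguous homoeolog withholds the whole genotype code instead of forcing a
call. The thresholds are a documented choice — read-count-based genotyping
has no canonical cutoffs — and the gaps mean sequencing noise produces
explicit ambiguity, never a silently wrong code.

## Phenotype statistics

Spike measurements are averaged into plant means first; all group
statistics operate on plant means (the plant, not the spike, is the
experimental unit). The *t*-test is pooled-variance Student's (not Welch),
two-tailed, with df = n₁+n₂−2; percent changes are computed from unrounded
group means and printed at two decimals. ANOVA and Tukey HSD use the
standard one-way decomposition and studentized-range distribution via
scipy. Degenerate inputs (zero pooled variance, all-identical
observations) are flagged rather than propagated as NaN surprises. The
dosage trend reports the Spearman correlation of plant trait values
against functional copy number (0–6), whose sign summarizes monotonicity
without assuming linearity. qPCR relative expression is 2^−ΔΔCt with
ΔCt = Ct_target − Ct_reference; without a calibrator the uncalibrated
2^−ΔCt is returned and labelled by a log note.

## Co-expression network

Quantile normalization replaces each sample column's order statistics by
the across-sample mean of order statistics; ties receive the mean of the
reference values across their rank range, which makes the transform
idempotent. The log transform is log2(x+1); the +1 offset keeps zero TPMs
finite and is the conventional choice. The global layer keeps only PCC
< −0.90 or > 0.98 among the top-variable genes; the local layer ranks all
genes by their correlation with each focal homoeolog separately
("top 1%" is interpreted per focal gene over the signed PCC, then the
union is taken — per-gene absolute ranking is available via
`ranking="absolute"`), intersected with |PCC| > 0.60. Ties at the 1%
boundary are all kept. Constant gene rows have undefined correlation and
are excluded with a warning; constant sample columns are an error.

## GO enrichment

The 2×2 table per term is (in-set annotated, in-set not, out-of-set
annotated, out-of-set not) over a background that defaults to all
annotated genes. Fold change is the in-set term proportion over the
genome-wide proportion. Only terms with at least one in-set gene are
tested — testing never-observed terms only inflates the correction burden.
The two-tailed p-value follows the probability-mass rule (all tables with
the observed margins whose probability does not exceed the observed
one). No propagation to GO ancestor terms is performed; annotations are
consumed exactly as given, which is a known limitation when annotation
depth differs between gene sets.

## Population genetics

Per-site diversity uses the unbiased estimator 2p̂(1−p̂)·n/(n−1) with n the
called allele copies at the site. F_ST is Hudson-type, 1 − H_w/H_b, with
H_w the mean unbiased within-population heterozygosity and
H_b = p̂₁(1−p̂₂) + p̂₂(1−p̂₁); windows combine sites as a ratio of averages
(ΣH_w / ΣH_b), the standard recommendation for window scans because it is
robust to low-information sites. Sites fixed for the same allele in both
populations are uninformative and excluded; slightly negative estimates are
reported as computed. Windows are 2 Mb sliding at a 400-kb step by default
(the step is configurable; overlapping windows give smooth profiles).

Haplotype extraction keys accessions by their genotype vector over the
genic SNPs. Accessions with any missing or heterozygous genic call are
excluded — the panels emulated here are inbred selfing wheat, so a
heterozygous call indicates unreliable data; this exclusion is why
per-population haplotype totals can be smaller than the panel size.
Haplotype labels H1, H2, … follow descending pooled frequency.
Cross-population comparisons build carrier/non-carrier 2×2 tables and use
the same Fisher test as the enrichment module. The composite-likelihood
sweep scan (XP-CLR) used alongside π/F_ST in this literature is a prior
published method and is deliberately not reimplemented; the scan reports
π and F_ST only.

## Phylogenetics

K2P distances are computed under complete deletion (columns with a gap or
ambiguous base in either sequence removed; pairwise for distance matrices,
alignment-wide before bootstrapping). Saturated pairs (log argument ≤ 0)
return NaN rather than an arbitrary large distance. Neighbor joining
follows Saitou–Nei with the Q criterion; ties break to the lowest-index
pair so results are deterministic. Negative branch lengths are clamped to
zero with the deficit transferred to the sister branch, preserving the
joined pair's path length. Bootstrap support is the percentage of
column-resampled replicates containing each original bipartition;
replicates whose resampled distances saturate are skipped (counting
against support, a conservative choice). Agreement with library NJ is at
the topology level; branch-length and tie-handling details may differ from
other implementations.

## Synthetic data

The generators define the study conditions for all tests:

- **Reads**: three 240-bp homoeolog amplicons differing only at three
  diagnostic bases upstream of the cut site; programmed alleles ("WT",
  "−n", "+n:SEQ") at per-homoeolog frequencies; independent substitution
  errors at 0.001/bp by default (indel sequencing errors are off so the
  truth stays unambiguous); 60 reads per homoeolog per plant. The
  `exact_counts` mode realizes programmed frequencies exactly
  (largest-remainder rounding), which is what truth-scoring runs use: it
  separates caller error from binomial sampling noise.
- **Phenotypes**: trait = baseline × (1 + Σ_g effect_g·dosage_g/2) + plant
  noise + spike noise, all Gaussian, negatives resampled. Baselines
  (width 3.67 mm, length 6.27 mm, area 16.67 mm², TGW 42.72 g) and
  homozygous-knockout effects (B: +1.91% width, +0.32% length, +1.50%
  area, +1.78% TGW; D: +2.18%, −2.07%, +0.36%, +2.90%) are the observed
  single-genome knockout magnitudes for this gene family; plant-level SDs
  are back-computed from the reported standard errors (SE·√n). Per-spike
  variance components are not reported anywhere, so spike SD defaults to
  the plant SD; three spikes per plant.
- **Expression**: 5,000 genes × 209 samples by default. The real
  compendium this emulates has >100k gene models; 5,000 keeps the
  all-pairs correlation tractable while leaving the top-1% rule a
  meaningful filter (50 genes per focal homoeolog). The 50-gene module
  (including the three focal homoeologs) follows one latent factor with
  loading 0.9 and noise SD 0.3 (pairwise PCC ≈ 0.9); background genes are
  independent. Log-scale values map to TPMs via 2^(x+4), strictly
  positive and monotone so module structure survives the log transform.
  The generator does not emulate mean–variance coupling, batch structure
  or isoform mixtures, so passing tests show threshold logic and ranking
  are correct, not that the thresholds are optimal for real RNA-seq.
- **SNP panels**: 34 wild + 40 domesticated inbred accessions (genotypes
  0/2, homozygous), ~4,000 SNPs on a 40-Mb chromosome. Wild allele
  frequencies are uniform on (0.05, 0.95); inside the 10–14 Mb sweep the
  domesticated frequencies are pushed 90% of the way to the nearest
  fixation point. A 5-kb focal gene region inside the sweep carries
  discrete haplotypes at programmed per-population frequencies (wild
  0.194/0.452/0.354 across three haplotypes; domesticated fixed for the
  lead haplotype — the observed pattern at a domestication-selected
  locus). Calls go missing independently at 2%. There is no coalescent
  model, recombination map or linkage disequilibrium beyond the planted
  structure, so sweep-recovery tests validate the scan statistics, not
  demographic realism.
- **Additive trees**: random topologies with branch lengths uniform on
  (0.1, 1) and their exact path-length distance matrices, used to check
  the consistency of distance-based reconstruction.

Same seed ⇒ byte-identical outputs for every generator.

## Problem sizes in the acceptance script

`scripts/acceptance.py` uses 200 genotyped plants, 50 phenotype
replicates, one 5,000-gene expression run, 20 SNP-panel seeds and 200
additive trees — sizes chosen so the whole script completes in well under
a minute while every rate it reports is estimated from enough replicates
to be stable at the tolerances that matter.
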