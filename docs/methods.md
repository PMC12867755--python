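# Methods

This note documents the models, algorithms and design choices behind
`ectosrna`, in the spirit of the methods documentation of packages such as
msprime or statsmodels: what is computed, under which assumptions, with
which defaults, and what the synthetic benchmarks do and do not show.

## Coordinates and formats

All internal coordinates are 0-based half-open `[start, end)`. GFF3
(1-based inclusive) is converted at the I/O boundary only; import and
export compose to the identity. Mapped sRNA reads are exchanged as BED6
with the read sequence in the name column and the number of genomic
placements in the score column; because mapping allowed zero mismatches,
a read's sequence always equals the strand-aware genome substring at its
interval, and reads containing N are rejected on import. Multi-mapping
reads are represented once per placement; `n_loci` records the total
placement count.

## Hairpin miRNA discovery

A putative miRNA gene is an inverted-repeat locus whose sRNA reads show
the miRNA/miRNA\* duplex pattern with mature predominance.

*Palindrome seeds.* "Palindromic region" is interpreted as an exact,
gap-free, even-length substring equal to its own reverse complement — a
zero-loop inverted repeat. The threshold "> 8 bp" is read as length ≥ 9,
hence ≥ 10 for even-length hits. The scanner performs center expansion
over all 2-base seed pairs, vectorized with numpy, reporting each maximal
palindrome (not extensible by one base on both sides); windows containing
N never qualify. Exactness at seed stage is safe because the next stage
widens the context: real hairpin loops and arm mismatches are captured by
the window, not the seed. Whether the original curation tolerated
mismatched seeds is unknown; exact seeds are this package's choice.

*Candidate windows.* Each palindrome midpoint is extended by 70 bp in
both directions (clipped at contig ends). Overlapping windows merge into
a single region retaining all source hits, so one hairpin is never
annotated twice.

*Coverage.* A region is kept when its maximum per-base read depth,
strand-agnostic over all placements, strictly exceeds 20×. Maximum
per-base depth is the quantity a curator sees in a genome browser; the
alternative reading (total read count per region) is rejected because it
conflates depth with window width.

*Pattern classification.* On a single strand the region's reads are
clustered greedily by 5′ end: repeatedly take the most frequent 5′
position (leftmost on ties) and absorb reads within `max_cluster_slop`
(default 3 nt). Acceptance requires: the two heaviest clusters jointly
hold ≥ `major_frac` (default 0.8) of the strand's reads across their
duplex footprint (minor stray clusters from neighbouring regions merged
into the same window are thereby tolerated, while siRNA-like scatter is
not); each cluster's most common sequence exceeds `unique_frac` (0.5) of
its reads ("a unique miRNA and miRNA\*"); the two dominant sequences are
antisense partners — best ungapped offset alignment of one against the
reverse complement of the other with identity ≥ 0.8 and at most 4 nt
unaligned overhang; the star cluster has ≥ `min_star_reads` (2) reads and
the mature (deeper) cluster at least `min_predominance` (2.0) times the
star count. Failures carry one of five reason codes: `single_cluster`,
`diffuse_reads`, `no_arm_pairing`, `no_predominance`,
`insufficient_star`. The numeric thresholds codify qualitative curation
criteria and are config-exposed; no published values exist for them.
The canonical 2-nt 3′-overhang duplex geometry is produced by the
simulator but is not a rejection criterion of the classifier, since the
curation criteria do not state it.

*Duplicates.* Loci with identical mature sequence at distinct coordinates
are all retained as separate gene models; exact coordinate duplicates
collapse to one.

Raising `min_cov` or `min_predominance` can only shrink the accepted set
(tested); annotating the reverse-complemented genome with strand-flipped
reads yields coordinate-mirrored loci (tested).

## Library profiling

Size spectra count read lengths and, per length, the 5′ base of the read
in read orientation (T reported as U). Genomic origin is assigned by
≥ 1 bp strand-agnostic overlap with precedence miRNA > TE > exon >
intron > intergenic; precedence is this package's choice where the
upstream convention is unstated — miRNA first matches the separate miRNA
tally, TE before gene matches a TE-focused narrative. Multi-mapping reads
contribute at every placement, consistent with multi-mapper inclusion in
counting. Presence categories (total-only / RISC-only / both / none) use
a ≥ 1 read threshold, config-exposed.

## DESL analysis

*Features.* Genes and miRNA loci enter as-is. On each strand separately,
the gaps not covered by a same-strand gene or locus are tiled
left-to-right into 5-kb bins; the terminal partial bin keeps its natural
length (discarding it would silently drop loci). Bins are named
`<upstream_id>_<k><strand>` with the nearest same-strand feature ending
at or before the gap as upstream id and `<contig>_START` as sentinel; the
strand suffix keeps ids unique when the same upstream feature flanks gaps
on both strand tilings. Genes plus bins partition every base exactly once
per strand, so total assigned counts equal the number of read placements
passing the length filter (tested).

*Counting.* Sense-strand only; reads shorter than 15 nt excluded; each
placement counted; a read overlapping two same-strand features is
assigned to the larger overlap, ties to the leftmost. The tie rule is
deterministic by construction because upstream tools vary here.

*Differential test.* A deliberately minimal NB Wald test, validated by
calibration rather than by matching any external implementation:

- size factors by median-of-ratios (geometric-mean reference over
  features positive in all samples);
- per-feature dispersion α (Var = μ + αμ²) by pooled method-of-moments on
  normalized counts, clipped to [1e-6, 10];
- a mean–dispersion trend α(μ) = a₀ + a₁/μ fitted by least squares
  (coefficients clipped ≥ 0);
- moderated shrinkage in log space: the trend acts as a prior worth
  `prior_df` = 10 degrees of freedom, the per-feature estimate gets
  weight df_res/(df_res + prior_df) with df_res = n₁ + n₂ − 2;
- Wald statistic on log normalized group means with a 0.5 stabilizer and
  delta-method variance μ_g·Σ(1/s_j)/n_g² + αμ_g²/n_g, referred to a
  t distribution with df_res + prior_df degrees of freedom;
- two-sided p-values, BH-adjusted over tested features; all-zero
  features are excluded from testing and from the BH denominator.

With 3 vs 3 replicates at the generator's default conditions this design
achieves a null raw-p < 0.05 rate near 0.05 (the test suite requires
[0.03, 0.07]) and > 90% recall of planted |log₂FC| = 2 effects at
p_adj < 0.05; both are recomputed by `scripts/acceptance.py`. The prior
df and the t reference were chosen to meet exactly this calibration —
they are part of the test's design, documented here, not per-dataset
tuning knobs.

DESL calling uses p_adj < 0.05 with no fold-change floor by default
(config-exposed; the upstream criterion says only "statistically
significant"). DEG calling uses p_adj < 0.001 and |log₂FC| ≥ 1. No upper
read-length bound is applied in counting beyond the library's own
size-selection window.

*Enrichment.* The miRNA-vs-background DESL comparison is a 2×2 Pearson
χ² without continuity correction (counts are large); on the printed locus
counts (36/59 Tarver, 101/295 putative, 911/78512 overall) both p-values
underflow below 2.2 × 10⁻¹⁶.

## Target prediction

Targeting is antisense: a hit at CDS offset j requires Hamming distance
≤ 3 between the miRNA and the reverse complement of the CDS window —
full length, ungapped, no G:U wobble credit (the simplest reading of
"three mismatches"; gaps and wobble tolerance are unknowable from the
stated criterion). All qualifying offsets are reported; summaries count
distinct genes per miRNA and distinct miRNAs per gene over the full id
universes. Expression response uses a two-sided rank-sum test: exact
enumeration of all C(n₁+n₂, n₁) rank splits when both samples have ≤ 10
observations (midranks enter the enumeration, so identical samples give
p = 1), otherwise the tie-corrected normal approximation.

## Statistics

Goodness-of-fit: Pearson χ² with df = classes − 1, per-class
contributions (O − E)²/E, and the (1 − α) critical value; no continuity
correction anywhere (the 21:17 segregation table gives χ² = 8/19 = 0.421
exactly, p = 0.516). Distribution functions come from scipy; BH
adjustment from statsmodels; both are cross-checked in the test suite
against independent brute-force definitions and permutation nulls.

## Synthetic data: what it emulates, and what it does not

The generator plants the statistical structure the analyses assume:

- genome: by default 2 contigs × 200 kb of i.i.d. uniform sequence with
  40 non-overlapping genes (2–4 exons, introns of 80–300 bp), 20 TEs
  (400–1500 bp) and 10 miRNA hairpins. Hairpins are 21-nt arms around a
  15-nt loop, with the genomic 3′ arm the exact reverse complement of the
  5′ arm. The loop carries a self-reverse-complement core (plus one
  filler base for odd loop lengths) so every hairpin contains a gap-free
  ≥ 14 bp palindrome and is detectable by the seed scan.
- libraries: read lengths follow a distribution with mode 0.58 at 21 nt;
  21-nt background reads start with U with probability 0.9 (enforced by
  position resampling, so reads always match the genome exactly);
  mature reads always start with U (arm bases are set accordingly).
  Origin sampling uses miRNA 0.3%, TE 33%, exon 20%, intron 10%,
  intergenic 36.7% for the total library and miRNA 4%, TE 5%, exon 15%,
  intron 28%, intergenic 48% for the RISC library — calibrated to the
  reported ~0.3% vs ~4% miRNA fractions and TE depletion; the exact RISC
  reweighting factors are otherwise unpublished and config-exposed.
  miRNA loci emit only the mature/star duplex: the star is the opposite
  arm shifted 2 nt downstream in transcript direction, giving canonical
  2-nt 3′ overhangs, with mature:star odds 5. Background reads are kept
  out of hairpin ± 90 bp.
- counts: NB with Var = μ + αμ² (α = 0.1, μ = 100 for every feature so
  planted effects sit at a known mean); a fraction 0.1 of features get
  their group-2 mean scaled by 2^(±2) with random sign, recorded in the
  truth set.

Default library depth is 200,000 reads — a deliberately scaled-down
library (real ones run tens of millions) chosen so that each planted
locus receives ≥ 50 reads at the realistic 0.3% miRNA fraction and the
full pipeline remains interactive.

Features real data has that the simulator does not: sequencing errors and
adapter artifacts; isomiR 5′/3′ heterogeneity and hairpin-loop or
degradation reads at miRNA loci; multi-mapping read placements;
nucleotide composition bias; overlapping or nested annotation; dispersion
that varies across features. Consequently, passing the recovery
benchmarks shows the pipeline implements its stated rules correctly and
is well calibrated under its model — not that discovery precision or FDR
will be 1.0 / nominal on real libraries, where diffuse loci, isomiRs and
repeat-derived reads make classification genuinely harder.

## Degenerate inputs and numerical conventions

Empty read libraries raise; an empty palindrome scan returns an empty
list. Features with all-zero counts are reported with NaN p-values.
Cluster-mode ties break leftmost; feature-assignment ties break leftmost;
the greedy cluster ordering is deterministic. p-values are kept at full
precision; 3-decimal rounding is presentation only. All randomness flows
from a single integer seed through `numpy.random.default_rng` with fixed
stream offsets per stage (genome 0, total library 1, RISC library 2,
counts 3), so every artifact is a pure function of `(config, seed)`.

## Known limitations

No RNA secondary-structure validation of hairpins (a thermodynamic check
would reduce false positives on real data); no isomiR quantification; no
homology-based miRNA family assignment; target prediction scans CDS only
(no 3′ UTRs) and uses no seed-region weighting; the differential test is
not a DESeq2 reimplementation and will not numerically match it; BAM
input is not parsed directly — convert alignments to the documented BED6
dialect first.
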