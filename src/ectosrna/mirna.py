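"""Palindrome-seeded putative miRNA gene discovery.

The discovery pipeline codifies a hairpin-annotation strategy: collect all
maximal reverse-complement palindromes above a length threshold, extend each
palindrome midpoint by a fixed window to both sides, keep windows whose
per-base sRNA read depth exceeds a coverage threshold, and accept a window
as a miRNA locus only when its reads show the canonical miRNA/miRNA*
pattern — exactly two positional read clusters, each dominated by a unique
sequence, the two dominant sequences complementary arm partners, with clear
mature-read predominance. Duplicated loci at different genomic positions
are retained as individual gene models.

"Palindrome" here means an exact, gap-free, even-length substring equal to
its own reverse complement (a zero-loop inverted repeat); the window
extension then captures realistic loops and arms. The default minimum
palindrome length of 9 keeps every even-length hit of >= 10 bp.
"""

from __future__ import annotations

from bisect import bisect_left
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .core import GenomicFeature, MappedRead, MiRNALocus, SequenceRecord, revcomp

REJECTION_REASONS = (
    "single_cluster",
    "diffuse_reads",
    "no_arm_pairing",
    "no_predominance",
    "insufficient_star",
)

_COMP_TABLE = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGT", b"TGCA"):
    _COMP_TABLE[_a] = _b


@dataclass(frozen=True)
class PalindromeHit:
    """A maximal even-length reverse-complement palindrome."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if (self.end - self.start) % 2 != 0 or self.end <= self.start:
            raise ValueError("palindrome interval must be even-length and non-empty")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def mid(self) -> int:
        return self.start + self.length // 2


@dataclass(frozen=True)
class CandidateRegion:
    """A window around one or more palindrome midpoints."""

    contig: str
    start: int
    end: int
    hits: Tuple[PalindromeHit, ...] = ()


@dataclass(frozen=True)
class Rejection:
    """A candidate region that failed locus classification."""

    region: CandidateRegion
    reason: str


@dataclass
class DiscoveryParams:
    """Tunable thresholds of the discovery pipeline."""

    min_palindrome_len: int = 9
    extension: int = 70
    min_cov: int = 20
    min_star_reads: int = 2
    max_cluster_slop: int = 3
    min_predominance: float = 2.0
    #: dominant-sequence fraction required for a cluster to count as "unique"
    unique_frac: float = 0.5
    #: fraction of same-strand reads the two major clusters must jointly hold
    major_frac: float = 0.8
    #: minimum identity of the mature/star duplex over their best overlap
    pairing_min_identity: float = 0.8
    #: maximum unaligned overhang allowed when pairing arm sequences
    pairing_max_end_slack: int = 4


def find_palindromes(seq: str, min_len: int = 9) -> List[PalindromeHit]:
    """All maximal even-length reverse-complement palindromes of length >= min_len.

    Maximality means the palindrome cannot be extended by one base on both
    sides. Windows containing N never qualify. Contig is left empty; callers
    attach it.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    n = len(seq)
    if n < 2:
        return []
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    comp = _COMP_TABLE[arr]  # complement codes; N maps to 0, matching nothing
    centers = np.nonzero(arr[:-1] == comp[1:])[0]
    if centers.size == 0:
        return []
    radius = np.ones(centers.size, dtype=np.int64)
    active = np.arange(centers.size)
    r = 1
    while active.size:
        c = centers[active]
        inside = (c - r >= 0) & (c + 1 + r < n)
        active = active[inside]
        c = centers[active]
        grown = arr[c - r] == comp[c + 1 + r]
        active = active[grown]
        radius[active] = r + 1
        r += 1
    hits = []
    for c, h in zip(centers, radius):
        if 2 * h >= min_len:
            hits.append(PalindromeHit("", int(c - h + 1), int(c + 1 + h)))
    return hits


def build_candidates(
    hits: Sequence[PalindromeHit],
    extension: int = 70,
    contig_len: Optional[int] = None,
) -> List[CandidateRegion]:
    """Extend each palindrome midpoint by ``extension`` to both sides.

    Windows are clipped to ``[0, contig_len)`` and overlapping windows from
    distinct hits merge into a single region retaining all source hits.
    """
    regions: List[CandidateRegion] = []
    for hit in sorted(hits, key=lambda h: (h.contig, h.start)):
        lo = max(0, hit.mid - extension)
        hi = hit.mid + extension
        if contig_len is not None:
            hi = min(hi, contig_len)
        if regions and regions[-1].contig == hit.contig and lo <= regions[-1].end:
            prev = regions[-1]
            regions[-1] = CandidateRegion(
                prev.contig, prev.start, max(prev.end, hi), prev.hits + (hit,)
            )
        else:
            regions.append(CandidateRegion(hit.contig, lo, hi, (hit,)))
    return regions


def _depth_arrays(
    reads: Sequence[MappedRead], contig_lengths: Dict[str, int]
) -> Dict[str, np.ndarray]:
    diffs = {c: np.zeros(l + 1, dtype=np.int64) for c, l in contig_lengths.items()}
    for r in reads:
        if r.contig in diffs:
            diffs[r.contig][r.start] += 1
            diffs[r.contig][min(r.end, len(diffs[r.contig]) - 1)] -= 1
    return {c: np.cumsum(d[:-1]) for c, d in diffs.items()}


def coverage_filter(
    regions: Sequence[CandidateRegion],
    reads: Sequence[MappedRead],
    min_cov: int = 20,
    contig_lengths: Optional[Dict[str, int]] = None,
) -> List[CandidateRegion]:
    """Keep regions whose maximum per-base read depth strictly exceeds min_cov.

    Depth is strand-agnostic; every read placement contributes.
    """
    if contig_lengths is None:
        contig_lengths = {}
        for r in regions:
            contig_lengths[r.contig] = max(contig_lengths.get(r.contig, 0), r.end)
        for r in reads:
            contig_lengths[r.contig] = max(contig_lengths.get(r.contig, 0), r.end)
    depth = _depth_arrays(reads, contig_lengths)
    kept = []
    for region in regions:
        d = depth.get(region.contig)
        if d is None or region.start >= d.size:
            continue
        if d[region.start : region.end].max(initial=0) > min_cov:
            kept.append(region)
    return kept


def _cluster_by_five_prime(
    reads: Sequence[MappedRead], slop: int
) -> List[List[MappedRead]]:
    """Greedy modal clustering of reads by 5' end position.

    Repeatedly takes the most frequent 5' position (leftmost on ties) and
    absorbs all reads whose 5' ends lie within ``slop`` of it.
    """
    by_pos: Dict[int, List[MappedRead]] = {}
    for r in reads:
        by_pos.setdefault(r.five_prime, []).append(r)
    clusters: List[List[MappedRead]] = []
    while by_pos:
        mode = max(by_pos, key=lambda p: (len(by_pos[p]), -p))
        members: List[MappedRead] = []
        for p in [p for p in by_pos if abs(p - mode) <= slop]:
            members.extend(by_pos.pop(p))
        clusters.append(members)
    clusters.sort(key=len, reverse=True)
    return clusters


def _duplex_identity(a: str, b: str, max_end_slack: int) -> float:
    """Best ungapped identity between ``a`` and revcomp(``b``).

    Scans all offsets whose unaligned overhang is within ``max_end_slack``
    and returns the highest fraction of matching positions over the
    overlap.
    """
    rb = revcomp(b)
    best = 0.0
    for offset in range(-max_end_slack, max_end_slack + 1):
        lo_a = max(0, offset)
        lo_b = max(0, -offset)
        span = min(len(a) - lo_a, len(rb) - lo_b)
        if span < min(len(a), len(rb)) - max_end_slack:
            continue
        matches = sum(
            1 for i in range(span) if a[lo_a + i] == rb[lo_b + i]
        )
        best = max(best, matches / span)
    return best


def classify_locus(
    region: CandidateRegion,
    reads: Sequence[MappedRead],
    params: Optional[DiscoveryParams] = None,
) -> Union[MiRNALocus, Rejection]:
    """Accept a candidate region as a miRNA locus or reject with a reason.

    Acceptance requires, on a single strand: two positional read clusters
    (5' ends within ``max_cluster_slop`` of each cluster mode) jointly
    holding at least ``major_frac`` of the strand's reads over their
    duplex footprint, each dominated by one read sequence, whose dominant
    sequences are
    complementary arm partners; the deeper (mature) cluster must have at
    least ``min_predominance`` times the star cluster's reads, and the star
    cluster at least ``min_star_reads`` reads. Rejection reasons:
    single_cluster, diffuse_reads, no_arm_pairing, no_predominance,
    insufficient_star.
    """
    params = params or DiscoveryParams()
    overlapping = [
        r for r in reads
        if r.contig == region.contig and r.start < region.end and r.end > region.start
    ]
    best_locus: Optional[MiRNALocus] = None
    reject_reason: Optional[str] = None
    reject_weight = -1

    for strand in ("+", "-"):
        sub = [r for r in overlapping if r.strand == strand]
        if not sub:
            continue

        def _note(reason: str) -> None:
            nonlocal reject_reason, reject_weight
            if len(sub) > reject_weight:
                reject_reason, reject_weight = reason, len(sub)

        clusters = _cluster_by_five_prime(sub, params.max_cluster_slop)
        if len(clusters) == 1:
            _note("single_cluster")
            continue
        # the miRNA/miRNA* pattern: two clusters dominating their duplex
        # footprint; reads elsewhere in the window (merged neighbouring
        # palindromes) do not count against them
        top2 = clusters[0:2]
        span_lo = min(r.start for c in top2 for r in c)
        span_hi = max(r.end for c in top2 for r in c)
        in_span = sum(1 for r in sub if r.start < span_hi and r.end > span_lo)
        if (len(top2[0]) + len(top2[1])) / in_span < params.major_frac:
            _note("diffuse_reads")
            continue
        clusters = top2
        dominant: List[MappedRead] = []
        counts: List[int] = []
        unique_ok = True
        for cluster in clusters:
            seq_counts = Counter(r.seq for r in cluster)
            top_seq, top_n = seq_counts.most_common(1)[0]
            if top_n / len(cluster) <= params.unique_frac:
                unique_ok = False
                break
            dominant.append(next(r for r in cluster if r.seq == top_seq))
            counts.append(len(cluster))
        if not unique_ok:
            _note("diffuse_reads")
            continue
        identity = _duplex_identity(
            dominant[0].seq, dominant[1].seq, params.pairing_max_end_slack
        )
        same_position = (dominant[0].start, dominant[0].end) == (
            dominant[1].start, dominant[1].end,
        )
        if identity < params.pairing_min_identity or same_position:
            _note("no_arm_pairing")
            continue
        mature_i = 0 if counts[0] >= counts[1] else 1
        star_i = 1 - mature_i
        if counts[star_i] < params.min_star_reads:
            _note("insufficient_star")
            continue
        if counts[mature_i] < params.min_predominance * counts[star_i]:
            _note("no_predominance")
            continue
        left_i = 0 if dominant[0].start <= dominant[1].start else 1
        right_i = 1 - left_i
        arm5 = (dominant[left_i].start, dominant[left_i].end)
        arm3 = (dominant[right_i].start, dominant[right_i].end)
        if arm5[1] > arm3[0]:
            _note("no_arm_pairing")  # arms must be disjoint
            continue
        mature_is_left = mature_i == left_i
        mature_arm = (
            "5p" if mature_is_left == (strand == "+") else "3p"
        )
        locus = MiRNALocus(
            locus_id="",
            contig=region.contig,
            strand=strand,
            arm5=arm5,
            arm3=arm3,
            mature_arm=mature_arm,
            mature_seq=dominant[mature_i].seq,
            star_seq=dominant[star_i].seq,
            mature_count=counts[mature_i],
            star_count=counts[star_i],
        )
        if best_locus is None or locus.mature_count > best_locus.mature_count:
            best_locus = locus

    if best_locus is not None:
        return best_locus
    return Rejection(region, reject_reason or "diffuse_reads")


def deduplicate_loci(loci: Sequence[MiRNALocus]) -> List[MiRNALocus]:
    """Collapse exact coordinate duplicates; keep same-sequence loci at
    distinct positions as individual gene models."""
    seen = set()
    out = []
    for locus in sorted(loci, key=lambda l: (l.contig, l.start, l.end, l.strand)):
        key = (locus.contig, locus.start, locus.end, locus.strand)
        if key not in seen:
            seen.add(key)
            out.append(locus)
    return out


def annotate_genome(
    genome: Sequence[SequenceRecord],
    reads: Sequence[MappedRead],
    params: Optional[DiscoveryParams] = None,
) -> Tuple[List[MiRNALocus], List[Rejection]]:
    """Full discovery pipeline: palindromes -> windows -> coverage -> pattern.

    Returns accepted loci (deduplicated, with ids assigned in genomic
    order) and the rejected candidates with reason codes. Deterministic
    for fixed inputs.
    """
    params = params or DiscoveryParams()
    contig_lengths = {rec.id: len(rec.seq) for rec in genome}
    regions: List[CandidateRegion] = []
    for rec in genome:
        hits = [
            PalindromeHit(rec.id, h.start, h.end)
            for h in find_palindromes(rec.seq, params.min_palindrome_len)
        ]
        regions.extend(build_candidates(hits, params.extension, len(rec.seq)))
    regions = coverage_filter(regions, reads, params.min_cov, contig_lengths)

    # bin reads per region via sorted starts (reads are short)
    reads_sorted = sorted(reads, key=lambda r: (r.contig, r.start))
    starts_by_contig: Dict[str, List[int]] = {}
    reads_by_contig: Dict[str, List[MappedRead]] = {}
    max_len = max((len(r) for r in reads), default=0)
    for r in reads_sorted:
        starts_by_contig.setdefault(r.contig, []).append(r.start)
        reads_by_contig.setdefault(r.contig, []).append(r)

    loci: List[MiRNALocus] = []
    rejections: List[Rejection] = []
    for region in regions:
        starts = starts_by_contig.get(region.contig, [])
        creads = reads_by_contig.get(region.contig, [])
        lo = bisect_left(starts, region.start - max_len)
        hi = bisect_left(starts, region.end)
        window = [r for r in creads[lo:hi] if r.end > region.start]
        result = classify_locus(region, window, params)
        if isinstance(result, MiRNALocus):
            loci.append(result)
        else:
            rejections.append(result)

    loci = deduplicate_loci(loci)
    out = []
    for i, locus in enumerate(loci):
        out.append(
            MiRNALocus(
                locus_id=f"pmir{i + 1:04d}",
                contig=locus.contig,
                strand=locus.strand,
                arm5=locus.arm5,
                arm3=locus.arm3,
                mature_arm=locus.mature_arm,
                mature_seq=locus.mature_seq,
                star_seq=locus.star_seq,
                mature_count=locus.mature_count,
                star_count=locus.star_count,
                provenance="putative",
            )
        )
    return out, rejections
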