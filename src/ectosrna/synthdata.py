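"""Synthetic genomes, sRNA libraries and count matrices with planted truth.

The generator emulates the statistical structure of a brown-algal small-RNA
study so every downstream stage runs offline: a multi-chromosome genome with
non-overlapping genes (exons/introns), transposable elements and intergenic
space; planted inverted-repeat miRNA hairpins producing mature/star read
duplexes with mature predominance and canonical 2-nt 3' overhangs; total
sRNA libraries with a 21-nt length mode and a strong 5'-uridine bias; a
RISC-bound library with miRNA-derived reads enriched (~4% vs ~0.3%) and
TE-derived reads depleted; and negative-binomial count matrices with planted
differential loci.

All outputs are pure functions of ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._intervals import complement_intervals, merge_intervals
from .core import GenomicFeature, MappedRead, MiRNALocus, SequenceRecord, revcomp

_BASES = "ACGT"
_CATEGORY_ORDER = ("miRNA", "TE", "exon", "intron", "intergenic")


class SizingError(ValueError):
    """Requested features cannot be placed without overlap."""


@dataclass
class SimConfig:
    """Study-condition parameters of the simulator.

    Defaults encode the conditions the analyses assume: a 21-nt sRNA size
    mode, ~90% 5'U at 21 nt, mature:star read odds of 5, miRNA reads at
    ~0.3% of a total library vs ~4% of a RISC library with TE depletion,
    and NB counts with variance mean + alpha*mean^2.
    """

    seed: int = 0
    n_contigs: int = 2
    contig_len: int = 200_000
    n_genes: int = 40
    n_tes: int = 20
    n_mirnas: int = 10
    arm_len: int = 21
    loop_len: int = 15
    mature_star_ratio: float = 5.0
    size_dist: Dict[int, float] = field(
        default_factory=lambda: {19: 0.04, 20: 0.16, 21: 0.58, 22: 0.15, 23: 0.07}
    )
    p5U: float = 0.9
    library_depth: int = 200_000
    origin_probs_total: Dict[str, float] = field(
        default_factory=lambda: {
            "miRNA": 0.003, "TE": 0.33, "exon": 0.20, "intron": 0.10, "intergenic": 0.367,
        }
    )
    origin_probs_risc: Dict[str, float] = field(
        default_factory=lambda: {
            "miRNA": 0.04, "TE": 0.05, "exon": 0.15, "intron": 0.28, "intergenic": 0.48,
        }
    )
    #: background reads are kept out of hairpin +- this pad: planted miRNA
    #: loci emit only the mature/star duplex (no degradation reads).
    mirna_exclusion_pad: int = 90
    nb_mean: float = 100.0
    nb_dispersion: float = 0.1
    frac_de: float = 0.1
    lfc_de: float = 2.0

    def __post_init__(self) -> None:
        if not (0 <= self.p5U <= 1):
            raise ValueError("p5U must be in [0, 1]")
        if not (0 <= self.frac_de <= 1):
            raise ValueError("frac_de must be in [0, 1]")
        if abs(sum(self.size_dist.values()) - 1.0) > 1e-9:
            raise ValueError("size_dist must sum to 1")
        for name, probs in (
            ("origin_probs_total", self.origin_probs_total),
            ("origin_probs_risc", self.origin_probs_risc),
        ):
            if set(probs) != set(_CATEGORY_ORDER):
                raise ValueError(f"{name} must have keys {_CATEGORY_ORDER}")
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        for attr in ("n_contigs", "contig_len", "n_genes", "n_tes", "n_mirnas",
                     "arm_len", "loop_len", "library_depth"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")
        if self.mature_star_ratio <= 0:
            raise ValueError("mature_star_ratio must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")


@dataclass
class TruthSet:
    """Ground truth of a simulation: planted loci and differential features."""

    loci: List[MiRNALocus] = field(default_factory=list)
    #: feature_id -> true signed log2 fold change of planted DE features
    de_lfc: Dict[str, float] = field(default_factory=dict)
    contig_lengths: Dict[str, int] = field(default_factory=dict)
    #: locus_id -> {"mature": (contig, start, end, strand, seq), "star": ...}
    read_templates: Dict[str, Dict[str, Tuple[str, int, int, str, str]]] = field(
        default_factory=dict
    )


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    codes = rng.integers(0, 4, n, dtype=np.uint8)
    return _BASE_BYTES[codes].tobytes().decode("ascii")


def _place(
    rng: np.random.Generator,
    occupied: List[Tuple[int, int]],
    length: int,
    contig_len: int,
    pad: int = 150,
    attempts: int = 2000,
) -> int:
    """Find a start for a feature of ``length`` avoiding occupied +- pad."""
    if length + 2 * pad >= contig_len:
        raise SizingError(f"feature of length {length} cannot fit contig of {contig_len}")
    for _ in range(attempts):
        start = int(rng.integers(pad, contig_len - length - pad))
        if all(start - pad >= e or start + length + pad <= s for s, e in occupied):
            occupied.append((start, start + length))
            return start
    raise SizingError(
        f"could not place feature of length {length} after {attempts} attempts; "
        "reduce feature counts or enlarge contigs"
    )


def _build_hairpin(
    rng: np.random.Generator, arm_len: int, loop_len: int, mature_arm: str
) -> Tuple[str, str]:
    """Return (arm5 sequence, loop sequence) for one planted hairpin.

    The loop carries a self-reverse-complement core so the hairpin contains
    a gap-free even palindrome detectable by the seed scan. The base of the
    arm that becomes the mature read's 5' end is forced to U(T), matching
    the AGO1-clade loading preference.
    """
    arm5 = list(_rand_seq(rng, arm_len))
    if mature_arm == "5p":
        arm5[0] = "T"  # mature 5' base is arm5[0] on either strand
    else:
        arm5[-1] = "A"  # mature 5' base is comp(arm5[-1])
    arm5_s = "".join(arm5)
    half = _rand_seq(rng, loop_len // 2)
    loop = half + revcomp(half)
    if loop_len % 2 == 1:
        avoid = revcomp(arm5_s[-1])
        filler = _BASES[int(rng.integers(0, 4))]
        while filler == avoid:
            filler = _BASES[int(rng.integers(0, 4))]
        loop += filler
    return arm5_s, loop


def make_genome(
    config: SimConfig,
) -> Tuple[List[SequenceRecord], List[GenomicFeature], TruthSet]:
    """Generate a genome with annotated genes, TEs and planted miRNA hairpins.

    Returns contig records, the gene/exon/intron/TE annotation, and a
    :class:`TruthSet` whose ``loci`` hold the planted hairpins (with mature
    and star read templates). Hairpins are placed in intergenic space;
    ``arm3`` is the exact reverse complement of ``arm5``.
    """
    rng = np.random.default_rng([config.seed, 0])
    contig_names = [f"chr{i + 1}" for i in range(config.n_contigs)]
    seqs: Dict[str, List[str]] = {
        name: list(_rand_seq(rng, config.contig_len)) for name in contig_names
    }
    occupied: Dict[str, List[Tuple[int, int]]] = {name: [] for name in contig_names}
    features: List[GenomicFeature] = []
    truth = TruthSet(contig_lengths={n: config.contig_len for n in contig_names})

    # genes with alternating exon/intron structure
    for i in range(config.n_genes):
        contig = contig_names[i % config.n_contigs]
        n_exons = int(rng.integers(2, 5))
        exon_lens = rng.integers(150, 601, n_exons)
        intron_lens = rng.integers(80, 301, n_exons - 1)
        glen = int(exon_lens.sum() + intron_lens.sum())
        start = _place(rng, occupied[contig], glen, config.contig_len)
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"gene{i + 1:04d}"
        features.append(GenomicFeature(contig, start, start + glen, strand, gid, "gene"))
        pos = start
        for k in range(n_exons):
            e = pos + int(exon_lens[k])
            features.append(
                GenomicFeature(contig, pos, e, strand, f"{gid}.e{k + 1}", "exon", gid)
            )
            pos = e
            if k < n_exons - 1:
                e = pos + int(intron_lens[k])
                features.append(
                    GenomicFeature(contig, pos, e, strand, f"{gid}.i{k + 1}", "intron", gid)
                )
                pos = e

    for i in range(config.n_tes):
        contig = contig_names[i % config.n_contigs]
        tlen = int(rng.integers(400, 1501))
        start = _place(rng, occupied[contig], tlen, config.contig_len)
        strand = "+" if rng.random() < 0.5 else "-"
        features.append(
            GenomicFeature(contig, start, start + tlen, strand, f"te{i + 1:04d}", "TE")
        )

    hp_len = 2 * config.arm_len + config.loop_len
    for i in range(config.n_mirnas):
        contig = contig_names[i % config.n_contigs]
        strand = "+" if rng.random() < 0.5 else "-"
        mature_arm = "5p" if rng.random() < 0.5 else "3p"
        arm5_seq, loop = _build_hairpin(rng, config.arm_len, config.loop_len, mature_arm)
        hairpin = arm5_seq + loop + revcomp(arm5_seq)
        start = _place(rng, occupied[contig], hp_len, config.contig_len)
        seqs[contig][start : start + hp_len] = list(hairpin)
        a5 = (start, start + config.arm_len)
        a3 = (start + config.arm_len + config.loop_len, start + hp_len)
        lid = f"mir{i + 1:04d}"
        mature_iv, star_base = (
            (a5, a3) if (strand == "+") == (mature_arm == "5p") else (a3, a5)
        )
        shift = 2 if strand == "+" else -2
        star_iv = (star_base[0] + shift, star_base[1] + shift)
        contig_seq = "".join(seqs[contig])

        def _extract(iv: Tuple[int, int]) -> str:
            s = contig_seq[iv[0] : iv[1]]
            return s if strand == "+" else revcomp(s)

        locus = MiRNALocus(
            locus_id=lid, contig=contig, strand=strand, arm5=a5, arm3=a3,
            mature_arm=mature_arm, mature_seq=_extract(mature_iv),
            star_seq=_extract(star_iv), provenance="putative",
        )
        truth.loci.append(locus)
        truth.read_templates[lid] = {
            "mature": (contig, mature_iv[0], mature_iv[1], strand, locus.mature_seq),
            "star": (contig, star_iv[0], star_iv[1], strand, locus.star_seq),
        }

    records = [SequenceRecord(name, "".join(seqs[name])) for name in contig_names]
    return records, features, truth


def _category_intervals(
    features: Sequence[GenomicFeature],
    truth: TruthSet,
    config: SimConfig,
) -> Dict[str, List[Tuple[str, int, int]]]:
    """Sampling intervals per origin category (contig, start, end)."""
    out: Dict[str, List[Tuple[str, int, int]]] = {c: [] for c in _CATEGORY_ORDER}
    for f in features:
        if f.category in ("TE", "exon", "intron"):
            out[f.category].append((f.contig, f.start, f.end))
    # intergenic = complement of all annotation and hairpin exclusion zones
    blocked: Dict[str, List[Tuple[int, int]]] = {c: [] for c in truth.contig_lengths}
    for f in features:
        if f.category in ("gene", "TE"):
            blocked[f.contig].append((f.start, f.end))
    pad = config.mirna_exclusion_pad
    for locus in truth.loci:
        blocked[locus.contig].append((locus.start - pad, locus.end + pad))
    max_len = max(self_len for self_len in config.size_dist) if config.size_dist else 25
    for contig, length in truth.contig_lengths.items():
        for s, e in complement_intervals(blocked[contig], length):
            if e - s >= max_len + 10:
                out["intergenic"].append((contig, s, e))
    return out


def simulate_reads(
    genome: Sequence[SequenceRecord],
    features: Sequence[GenomicFeature],
    truth: TruthSet,
    config: SimConfig,
    library: str = "total",
    return_labels: bool = False,
):
    """Simulate one mapped sRNA library ("total" or "risc").

    Read lengths follow ``size_dist``; among 21-nt background reads the
    5' base is U(T) with probability ``p5U`` (enforced by resampling start
    positions, so every read's sequence still equals the strand-aware
    genome substring at its interval — zero-mismatch mapping). miRNA-locus
    reads are the mature or star template with mature:star odds
    ``mature_star_ratio``. The RISC library reweights origin sampling to
    deplete TE reads and enrich miRNA reads.

    With ``return_labels=True`` also returns the per-read origin category
    labels (a numpy array aligned with the read list).
    """
    if library not in ("total", "risc"):
        raise ValueError("library must be 'total' or 'risc'")
    if config.library_depth <= 0:
        raise ValueError("library_depth must be positive")
    rng = np.random.default_rng([config.seed, 1 if library == "total" else 2])
    contig_str = {rec.id: rec.seq for rec in genome}
    probs = (
        config.origin_probs_total if library == "total" else config.origin_probs_risc
    ).copy()
    if not truth.loci:
        probs["intergenic"] += probs.pop("miRNA")
        probs["miRNA"] = 0.0
    vec = np.array([probs[c] for c in _CATEGORY_ORDER])
    n_cat = rng.multinomial(config.library_depth, vec)
    intervals = _category_intervals(features, truth, config)

    lengths_dist = sorted(config.size_dist)
    length_p = np.array([config.size_dist[l] for l in lengths_dist])

    reads: List[MappedRead] = []
    labels: List[str] = []

    # --- miRNA locus reads: mature or star templates
    n_mi = int(n_cat[0])
    if n_mi:
        locus_idx = rng.integers(0, len(truth.loci), n_mi)
        p_mature = config.mature_star_ratio / (1.0 + config.mature_star_ratio)
        is_mature = rng.random(n_mi) < p_mature
        for li, mat in zip(locus_idx, is_mature):
            locus = truth.loci[int(li)]
            contig, s, e, strand, seq = truth.read_templates[locus.locus_id][
                "mature" if mat else "star"
            ]
            reads.append(MappedRead(contig, s, e, strand, seq))
            labels.append("miRNA")

    # --- background reads sampled inside category intervals
    for cat, n_reads in zip(_CATEGORY_ORDER[1:], n_cat[1:]):
        n_reads = int(n_reads)
        if n_reads == 0:
            continue
        ivs = intervals[cat]
        if not ivs:
            raise SizingError(f"no intervals available for category {cat!r}")
        iv_lens = np.array([e - s for _, s, e in ivs], dtype=float)
        iv_p = iv_lens / iv_lens.sum()
        iv_choice = rng.choice(len(ivs), size=n_reads, p=iv_p)
        read_lens = rng.choice(lengths_dist, size=n_reads, p=length_p)
        strands = np.where(rng.random(n_reads) < 0.5, "+", "-")
        want_u = (read_lens == 21) & (rng.random(n_reads) < config.p5U)
        check_u = read_lens == 21  # constrain both U and non-U starts
        starts = np.empty(n_reads, dtype=np.int64)
        pending = np.arange(n_reads)
        for _ in range(300):
            if pending.size == 0:
                break
            for j in pending:
                c, s, e = ivs[int(iv_choice[j])]
                hi = e - int(read_lens[j])
                starts[j] = int(rng.integers(s, hi + 1)) if hi > s else s
            # keep only 21-nt reads whose 5' base violates the U constraint
            still = []
            for j in pending:
                if not check_u[j]:
                    continue
                c, _, _ = ivs[int(iv_choice[j])]
                if strands[j] == "+":
                    first = contig_str[c][starts[j]]
                    is_t = first == "T"
                else:
                    first = contig_str[c][starts[j] + int(read_lens[j]) - 1]
                    is_t = first == "A"
                if is_t != bool(want_u[j]):
                    still.append(j)
            pending = np.array(still, dtype=np.int64)
        for j in range(n_reads):
            c, _, _ = ivs[int(iv_choice[j])]
            s = int(starts[j])
            e = s + int(read_lens[j])
            seq = contig_str[c][s:e]
            if strands[j] == "-":
                seq = revcomp(seq)
            reads.append(MappedRead(c, s, e, str(strands[j]), seq))
            labels.append(cat)

    if return_labels:
        return reads, np.array(labels)
    return reads


def simulate_counts(
    features: Sequence,
    config: SimConfig,
    n_samples_per_group: int,
) -> Tuple[pd.DataFrame, TruthSet]:
    """Simulate an NB count matrix with planted differential features.

    ``features`` may be GenomicFeatures or plain feature-id strings. Counts
    are NB with variance ``mean + alpha * mean**2``; a fraction ``frac_de``
    of features get their group-2 mean scaled by ``2**(+-lfc_de)`` (sign
    random, recorded in the returned TruthSet). Columns are named
    ``g1_s*``/``g2_s*`` to encode the two groups.
    """
    if n_samples_per_group < 2:
        raise ValueError("need >= 2 samples per group")
    ids = [f.feature_id if hasattr(f, "feature_id") else str(f) for f in features]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate feature ids")
    rng = np.random.default_rng([config.seed, 3])
    n = len(ids)
    de_mask = rng.random(n) < config.frac_de
    signs = rng.choice([-1.0, 1.0], size=n)
    lfc = np.where(de_mask, config.lfc_de * signs, 0.0)
    mean1 = np.full(n, config.nb_mean)
    mean2 = config.nb_mean * np.power(2.0, lfc)

    def _draw(mean: np.ndarray, k: int) -> np.ndarray:
        if config.nb_dispersion <= 1e-12:
            return rng.poisson(mean[:, None], size=(n, k))
        r = 1.0 / config.nb_dispersion
        p = r / (r + mean)
        return rng.negative_binomial(r, p[:, None], size=(n, k))

    m = n_samples_per_group
    counts = np.concatenate([_draw(mean1, m), _draw(mean2, m)], axis=1)
    cols = [f"g1_s{j + 1}" for j in range(m)] + [f"g2_s{j + 1}" for j in range(m)]
    matrix = pd.DataFrame(counts, index=pd.Index(ids, name="feature_id"), columns=cols)
    truth = TruthSet(de_lfc={i: float(l) for i, l, d in zip(ids, lfc, de_mask) if d})
    return matrix, truth


def sample_groups(matrix: pd.DataFrame) -> List[str]:
    """Recover group labels from ``simulate_counts`` column names."""
    return [c.split("_")[0] for c in matrix.columns]
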