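"""Differentially expressed sRNA locus (DESL) analysis.

Feature construction (genes + miRNA loci + stranded 5-kb intergenic bins
covering every base on each strand), strand-specific read counting with a
minimum read length and multi-mapper inclusion, a minimal negative-binomial
Wald test with Benjamini-Hochberg correction, DESL calling, DESL/DEG
overlap, and the miRNA-vs-background DESL enrichment chi-square.

The differential test is deliberately minimal: median-of-ratios size
factors, per-feature method-of-moments dispersion shrunk toward a fitted
mean-dispersion trend, and a Wald z-statistic on the log normalized group
means. It is validated by calibration properties (type-I rate, power on
planted effects), not by matching any particular external implementation.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from ._intervals import complement_intervals
from .core import GenomicFeature, MappedRead, MiRNALocus
from .stats import bh_adjust, chisq_2x2

DEFAULT_BIN_SIZE = 5000
DEFAULT_MIN_READ_LEN = 15  # featureCounts-style minimum fragment length

#: DEG thresholds for the mRNA differential-expression path
DEG_PADJ = 0.001
DEG_LFC = 1.0


def build_features(
    annotation: Sequence[GenomicFeature],
    mirna_loci: Sequence[MiRNALocus],
    contig_lengths: Dict[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
) -> List[GenomicFeature]:
    """Genes + miRNA loci + stranded intergenic bins tiling each strand.

    On each strand, gaps not covered by a same-strand gene or miRNA locus
    are tiled left-to-right in ``bin_size`` pieces; the terminal partial
    bin keeps its natural length. Bins are named
    ``<upstream_id>_<k><strand>`` where the upstream id is the nearest
    same-strand feature ending at or before the gap (sentinel
    ``<contig>_START`` when none) and k counts bins ascending within the
    gap. Together with the genes this covers every base once per strand.
    """
    genes = [f for f in annotation if f.category == "gene"]
    locus_feats = [
        l.as_feature() if isinstance(l, MiRNALocus) else l for l in mirna_loci
    ]
    for f in genes + locus_feats:
        if f.contig not in contig_lengths:
            raise ValueError(f"contig {f.contig!r} missing from contig_lengths")
    out: List[GenomicFeature] = list(genes) + locus_feats
    for contig, length in contig_lengths.items():
        for strand in ("+", "-"):
            blocking = sorted(
                (f for f in genes + locus_feats
                 if f.contig == contig and f.strand == strand),
                key=lambda f: f.start,
            )
            gaps = complement_intervals([(f.start, f.end) for f in blocking], length)
            ends = [f.end for f in blocking]
            for gap_start, gap_end in gaps:
                upstream = None
                for f in blocking:
                    if f.end <= gap_start:
                        upstream = f.feature_id
                    else:
                        break
                prefix = upstream if upstream is not None else f"{contig}_START"
                k = 0
                pos = gap_start
                while pos < gap_end:
                    k += 1
                    end = min(pos + bin_size, gap_end)
                    out.append(
                        GenomicFeature(
                            contig, pos, end, strand,
                            f"{prefix}_{k}{strand}", "intergenic_bin",
                        )
                    )
                    pos = end
    return out


def count_features(
    features: Sequence[GenomicFeature],
    reads_by_sample: Dict[str, Sequence[MappedRead]],
    min_read_len: int = DEFAULT_MIN_READ_LEN,
) -> pd.DataFrame:
    """Strand-specific feature counting of mapped sRNA reads.

    A read contributes only to features on its own strand; reads shorter
    than ``min_read_len`` are excluded; multi-mapping reads count at every
    placement (each read record is one placement). A read overlapping two
    same-strand features goes to the one with the larger overlap, ties to
    the leftmost. Returns a features x samples integer DataFrame.
    """
    ids = [f.feature_id for f in features]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate feature ids")
    # sorted feature arrays per (contig, strand)
    index: Dict[Tuple[str, str], Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for key in {(f.contig, f.strand) for f in features}:
        feats = sorted(
            ((f.start, f.end, i) for i, f in enumerate(features)
             if (f.contig, f.strand) == key),
        )
        index[key] = (
            np.array([s for s, _, _ in feats], dtype=np.int64),
            np.array([e for _, e, _ in feats], dtype=np.int64),
            np.array([i for _, _, i in feats], dtype=np.int64),
        )

    matrix = np.zeros((len(ids), len(reads_by_sample)), dtype=np.int64)
    for col, (sample, reads) in enumerate(reads_by_sample.items()):
        for r in reads:
            if len(r) < min_read_len:
                continue
            key = (r.contig, r.strand)
            if key not in index:
                continue
            starts, ends, rows = index[key]
            j = int(np.searchsorted(starts, r.start, side="right")) - 1
            best_row, best_ov = -1, 0
            for cand in (j, j + 1, j + 2):
                if 0 <= cand < starts.size:
                    ov = min(int(ends[cand]), r.end) - max(int(starts[cand]), r.start)
                    if ov > best_ov:
                        best_ov, best_row = ov, int(rows[cand])
            if best_row >= 0:
                matrix[best_row, col] += 1
    return pd.DataFrame(
        matrix, index=pd.Index(ids, name="feature_id"), columns=list(reads_by_sample)
    )


def size_factors(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors (one per sample).

    The reference is the per-feature geometric mean over samples, using
    only features with all-positive counts; each sample's factor is the
    median ratio of its counts to the reference.
    """
    counts = matrix.to_numpy(dtype=float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no feature has positive counts in every sample")
    sub = counts[positive]
    log_ref = np.log(sub).mean(axis=1)
    factors = np.exp(np.median(np.log(sub) - log_ref[:, None], axis=0))
    return pd.Series(factors, index=matrix.columns, name="size_factor")


def _dispersion_trend(mu: np.ndarray, alpha_mom: np.ndarray) -> np.ndarray:
    """Fit alpha ~ a0 + a1/mu by least squares (coefficients clipped >= 0)."""
    ok = (mu > 0) & np.isfinite(alpha_mom)
    if ok.sum() < 2:
        return np.full_like(mu, max(float(np.nanmedian(alpha_mom)), 1e-6))
    x = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
    coef, *_ = np.linalg.lstsq(x, alpha_mom[ok], rcond=None)
    a0, a1 = max(coef[0], 0.0), max(coef[1], 0.0)
    if a0 == 0.0 and a1 == 0.0:
        a0 = max(float(np.median(alpha_mom[ok])), 1e-6)
    return a0 + a1 / np.maximum(mu, 1e-8)


def nb_test(
    matrix: pd.DataFrame,
    groups: Sequence[str],
    padj_threshold: float = 0.05,
    lfc_threshold: float = 0.0,
    prior_df: float = 10.0,
) -> pd.DataFrame:
    """Minimal per-feature negative-binomial Wald test between two groups.

    Counts are normalized by median-of-ratios size factors; the NB
    dispersion (variance = mu + alpha*mu^2) is estimated per feature by
    pooled method-of-moments and shrunk in log space toward an
    a0 + a1/mu trend. Shrinkage is moderated: the trend acts as a prior
    worth ``prior_df`` degrees of freedom, so the per-feature estimate
    gets weight df_res / (df_res + prior_df) with df_res = n1 + n2 - 2,
    and the Wald statistic on the log normalized group means (0.5
    stabilizer) is referred to a t distribution with df_res + prior_df
    degrees of freedom. P-values are two-sided, BH-adjusted across tested
    features. Features with all-zero counts are excluded from testing and
    from the BH denominator.

    Returns a DataFrame indexed by feature with columns baseMean, log2FC
    (group2/group1), pvalue, padj, significant.
    """
    groups = np.asarray([str(g) for g in groups])
    if groups.size != matrix.shape[1]:
        raise ValueError("groups length must match sample count")
    levels = list(dict.fromkeys(groups))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    m1 = groups == levels[0]
    m2 = groups == levels[1]
    n1, n2 = int(m1.sum()), int(m2.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 replicates for dispersion estimation")

    sf = size_factors(matrix).to_numpy()
    counts = matrix.to_numpy(dtype=float)
    y = counts / sf[None, :]
    tested = counts.sum(axis=1) > 0

    mu1 = y[:, m1].mean(axis=1)
    mu2 = y[:, m2].mean(axis=1)
    base_mean = y.mean(axis=1)
    var1 = y[:, m1].var(axis=1, ddof=1)
    var2 = y[:, m2].var(axis=1, ddof=1)
    var_pooled = ((n1 - 1) * var1 + (n2 - 1) * var2) / (n1 + n2 - 2)
    mu_bar = (mu1 + mu2) / 2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = (var_pooled - mu_bar) / np.square(mu_bar)
    alpha_mom = np.clip(np.nan_to_num(alpha_mom, nan=0.0), 1e-6, 10.0)
    alpha_trend = np.clip(_dispersion_trend(mu_bar[tested], alpha_mom[tested]), 1e-6, 10.0)
    df_res = n1 + n2 - 2
    w = df_res / (df_res + prior_df)
    alpha = np.full(matrix.shape[0], np.nan)
    alpha[tested] = np.exp(
        w * np.log(alpha_mom[tested]) + (1 - w) * np.log(alpha_trend)
    )

    lfc = np.log2((mu2 + 0.5) / (mu1 + 0.5))
    inv1 = float((1.0 / sf[m1]).sum())
    inv2 = float((1.0 / sf[m2]).sum())
    var_mu1 = mu1 * inv1 / n1**2 + alpha * np.square(mu1) / n1
    var_mu2 = mu2 * inv2 / n2**2 + alpha * np.square(mu2) / n2
    vlog = var_mu1 / np.square(mu1 + 0.5) + var_mu2 / np.square(mu2 + 0.5)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.log(mu2 + 0.5) - np.log(mu1 + 0.5)) / np.sqrt(vlog)
    z = np.nan_to_num(z, nan=0.0, posinf=0.0, neginf=0.0)
    from scipy.stats import t as t_dist

    pvalue = np.where(tested, 2.0 * t_dist.sf(np.abs(z), df_res + prior_df), np.nan)
    padj = np.full(matrix.shape[0], np.nan)
    if tested.any():
        padj[tested] = bh_adjust(pvalue[tested])
    significant = (
        (padj < padj_threshold) & (np.abs(lfc) >= lfc_threshold) & tested
    )
    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FC": lfc,
            "pvalue": pvalue,
            "padj": padj,
            "significant": np.where(np.isnan(padj), False, significant),
        },
        index=matrix.index,
    )


def call_desl(
    diff: pd.DataFrame,
    padj_threshold: float = 0.05,
    lfc_threshold: float = 0.0,
) -> Set[str]:
    """Feature ids with padj below threshold and |log2FC| at or above floor."""
    if diff.empty:
        return set()
    mask = (diff["padj"] < padj_threshold) & (diff["log2FC"].abs() >= lfc_threshold)
    return set(diff.index[mask.fillna(False)])


def call_degs(diff: pd.DataFrame) -> Set[str]:
    """Differentially expressed genes: padj < 0.001 and |log2FC| >= 1."""
    return call_desl(diff, DEG_PADJ, DEG_LFC)


def desl_deg_overlap(
    desl_ids: Iterable[str], deg_ids: Iterable[str]
) -> Tuple[int, List[str]]:
    """Intersection of DESL and DEG id sets (count, sorted identities)."""
    overlap = sorted(set(desl_ids) & set(deg_ids))
    return len(overlap), overlap


def mirna_enrichment_test(
    n_desl_mirna: int, n_mirna: int, n_desl_total: int, n_total: int
) -> Tuple[float, float]:
    """2x2 chi-square: DESL rate among miRNA loci vs all other loci.

    No continuity correction. Inputs must satisfy the subset relations
    (miRNA DESLs within both the miRNA set and the DESL set).
    """
    if not (0 <= n_desl_mirna <= min(n_mirna, n_desl_total)):
        raise ValueError("inconsistent counts: n_desl_mirna exceeds a margin")
    if n_mirna > n_total or n_desl_total > n_total:
        raise ValueError("inconsistent counts: subset totals exceed n_total")
    a = n_desl_mirna
    b = n_mirna - n_desl_mirna
    c = n_desl_total - n_desl_mirna
    d = (n_total - n_mirna) - c
    if d < 0:
        raise ValueError("inconsistent counts: negative background cell")
    return chisq_2x2(a, b, c, d)
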