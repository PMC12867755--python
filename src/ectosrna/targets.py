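"""miRNA target prediction by bounded-mismatch antisense complementarity.

A miRNA targets a coding sequence at offset j when the Hamming distance
between the miRNA and the reverse complement of the CDS window
[j, j + len) is at most ``max_mismatches`` — full-length, ungapped, no
G:U wobble credit. Summaries count distinct genes per miRNA and distinct
miRNAs per gene over the full id universes; expression response compares
target-set expression between conditions with a rank-sum test (exact
enumeration for small samples).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .core import SequenceRecord, revcomp
from .stats import ranksum

DEFAULT_MAX_MISMATCHES = 3
MIRNA_LEN_RANGE = (18, 24)


@dataclass(frozen=True)
class TargetHit:
    """One complementary window of a miRNA in a coding sequence."""

    mirna_id: str
    gene_id: str
    cds_offset: int
    mismatches: int


@dataclass(frozen=True)
class TargetSummary:
    """Target-count summary over the full miRNA and gene universes."""

    n_mirnas: int
    n_genes: int
    frac_mirna_ge1: float
    frac_mirna_ge2: float
    frac_mirna_ge5: float
    frac_genes_untargeted: float
    frac_genes_single: float
    frac_genes_multi: float


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def predict_targets(
    mirnas: Sequence[SequenceRecord],
    cds: Sequence[SequenceRecord],
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> List[TargetHit]:
    """Scan every CDS for antisense matches of every miRNA.

    Reports all qualifying offsets per (miRNA, gene). A miRNA longer than
    a CDS yields no hits there. miRNA sequences must be 18-24 nt over
    {A,C,G,T}; CDS may contain N (windows with N never match).
    """
    lo, hi = MIRNA_LEN_RANGE
    for m in mirnas:
        if not (lo <= len(m.seq) <= hi):
            raise ValueError(
                f"miRNA {m.id!r} length {len(m.seq)} outside [{lo}, {hi}]"
            )
        if "N" in m.seq.upper():
            raise ValueError(f"miRNA {m.id!r} contains N")
    hits: List[TargetHit] = []
    patterns = [(m.id, _encode(revcomp(m.seq))) for m in mirnas]
    for gene in cds:
        arr = _encode(gene.seq)
        for mirna_id, pat in patterns:
            k = pat.size
            if arr.size < k:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(arr, k)
            mm = (windows != pat[None, :]).sum(axis=1)
            for off in np.nonzero(mm <= max_mismatches)[0]:
                hits.append(TargetHit(mirna_id, gene.id, int(off), int(mm[off])))
    return hits


def summarize_targets(
    hits: Sequence[TargetHit],
    all_mirna_ids: Iterable[str],
    all_gene_ids: Iterable[str],
) -> TargetSummary:
    """Distinct-gene counts per miRNA and distinct-miRNA counts per gene.

    Multiple windows in one gene count as a single targeted gene.
    Fractions are over the full id universes; the three gene fractions
    partition to 1.
    """
    mirna_ids = list(dict.fromkeys(all_mirna_ids))
    gene_ids = list(dict.fromkeys(all_gene_ids))
    genes_per_mirna: Dict[str, Set[str]] = {m: set() for m in mirna_ids}
    mirnas_per_gene: Dict[str, Set[str]] = {g: set() for g in gene_ids}
    for h in hits:
        if h.mirna_id not in genes_per_mirna or h.gene_id not in mirnas_per_gene:
            raise ValueError(f"hit references unknown id: {h}")
        genes_per_mirna[h.mirna_id].add(h.gene_id)
        mirnas_per_gene[h.gene_id].add(h.mirna_id)
    nm, ng = len(mirna_ids), len(gene_ids)
    mirna_counts = np.array([len(v) for v in genes_per_mirna.values()])
    gene_counts = np.array([len(v) for v in mirnas_per_gene.values()])
    return TargetSummary(
        n_mirnas=nm,
        n_genes=ng,
        frac_mirna_ge1=float((mirna_counts >= 1).mean()) if nm else 0.0,
        frac_mirna_ge2=float((mirna_counts >= 2).mean()) if nm else 0.0,
        frac_mirna_ge5=float((mirna_counts >= 5).mean()) if nm else 0.0,
        frac_genes_untargeted=float((gene_counts == 0).mean()) if ng else 1.0,
        frac_genes_single=float((gene_counts == 1).mean()) if ng else 0.0,
        frac_genes_multi=float((gene_counts > 1).mean()) if ng else 0.0,
    )


def expression_response(
    target_gene_ids: Iterable[str],
    expr: pd.DataFrame,
    condition_pairs: Sequence[Tuple[Sequence[str], Sequence[str]]],
) -> Dict[Tuple[str, str], Tuple[float, float]]:
    """Rank-sum comparison of target-set expression between conditions.

    ``expr`` is a normalized genes x samples table; each condition in a
    pair is a list of sample columns whose per-gene mean expression over
    the target set forms one sample for the two-sided rank-sum test
    (exact enumeration when both sample sizes are <= 10, normal
    approximation with tie correction otherwise). Returns
    {(name_a, name_b): (statistic, p)} keyed by comma-joined column names.
    """
    targets = [g for g in dict.fromkeys(target_gene_ids) if g in expr.index]
    if len(targets) < 2:
        raise ValueError("target set must contain >= 2 genes present in expr")
    sub = expr.loc[targets]
    out: Dict[Tuple[str, str], Tuple[float, float]] = {}
    for cols_a, cols_b in condition_pairs:
        x = sub[list(cols_a)].mean(axis=1).to_numpy()
        y = sub[list(cols_b)].mean(axis=1).to_numpy()
        key = (",".join(cols_a), ",".join(cols_b))
        out[key] = ranksum(x, y)
    return out


def desl_mirna_target_response(
    desl_mirnas: Iterable[str],
    hits: Sequence[TargetHit],
    diff: pd.DataFrame,
) -> pd.DataFrame:
    """Join DESL miRNAs with their targets' differential-expression results.

    One row per (miRNA, target gene) with the gene's log2FC and padj where
    available (NaN otherwise). Empty inputs give an empty table.
    """
    desl_set = set(desl_mirnas)
    rows = []
    seen = set()
    for h in hits:
        if h.mirna_id not in desl_set or (h.mirna_id, h.gene_id) in seen:
            continue
        seen.add((h.mirna_id, h.gene_id))
        if h.gene_id in diff.index:
            lfc = float(diff.loc[h.gene_id, "log2FC"])
            padj = float(diff.loc[h.gene_id, "padj"])
        else:
            lfc, padj = float("nan"), float("nan")
        rows.append(
            {"mirna_id": h.mirna_id, "gene_id": h.gene_id,
             "target_log2FC": lfc, "target_padj": padj}
        )
    return pd.DataFrame(rows, columns=["mirna_id", "gene_id", "target_log2FC", "target_padj"])
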