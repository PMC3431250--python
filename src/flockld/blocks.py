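"""Gabriel-rule haplotype-block detection and per-chromosome summaries.

A SNP pair is in *strong LD* when the one-sided upper 95% confidence bound on
|D'| exceeds 0.98 and the lower bound exceeds 0.70; it shows *strong evidence
of historical recombination* when the upper bound is below 0.90; otherwise it
is uninformative.  A candidate span qualifies as a block when its outermost
pair is in strong LD and at least 95% of its informative pairs are too.
Candidates are accepted greedily by decreasing physical span (ties leftmost),
skipping overlaps.

Only the core Gabriel criterion is implemented; size-stratified sub-rules
found in some GUI implementations are deliberately omitted (thresholds are
configurable instead).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .datamodel import MarkerMap
from .ld import CIBound


class PairClass(Enum):
    STRONG_LD = "strong_ld"
    RECOMB = "recomb"
    UNINFORMATIVE = "uninformative"


@dataclass
class Block:
    chrom: int
    first: int  # marker index within the chromosome, inclusive
    last: int
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def span_kb(self) -> float:
        return (self.end_bp - self.start_bp) / 1000.0


def classify_pair(
    ci: CIBound,
    strong_cu: float = 0.98,
    strong_cl: float = 0.70,
    recomb_cu: float = 0.90,
) -> PairClass:
    """Gabriel classification of one pair from its |D'| confidence bounds."""
    if ci.CU > strong_cu and ci.CL > strong_cl:
        return PairClass.STRONG_LD
    if ci.CU < recomb_cu:
        return PairClass.RECOMB
    return PairClass.UNINFORMATIVE


def classify_matrix(
    CL: np.ndarray, CU: np.ndarray,
    strong_cu: float = 0.98, strong_cl: float = 0.70, recomb_cu: float = 0.90,
) -> np.ndarray:
    """Vectorized classification: +1 strong LD, -1 recombination, 0 neither.

    NaN bounds (undefined pairs) classify as 0 (uninformative).
    """
    out = np.zeros(np.shape(CL), dtype=np.int8)
    strong = (CU > strong_cu) & (CL > strong_cl)
    recomb = CU < recomb_cu
    out[np.where(strong)] = 1
    out[np.where(recomb & ~strong)] = -1
    return out


def gabriel_blocks(
    classes: np.ndarray,
    bp: np.ndarray,
    chrom: int = 0,
    min_strong_fraction: float = 0.95,
    max_span_kb: float | None = None,
) -> list[Block]:
    """Call blocks on one chromosome from a pair-classification matrix.

    ``classes[i, j]`` (+1 strong LD, -1 recombination, 0 uninformative) for
    marker indices ``i < j`` in map order; ``bp`` are the marker positions.
    A span ``[i..j]`` is a candidate iff ``classes[i, j] == +1`` and, among
    the informative pairs within the span, the strong-LD fraction is at least
    ``min_strong_fraction``.  Greedy acceptance by decreasing bp span, ties
    leftmost, skipping spans that overlap an accepted block.
    """
    m = len(bp)
    if classes.shape != (m, m):
        raise ValueError("classification matrix shape mismatch")
    C = np.asarray(classes, dtype=np.int64)
    # 2-D prefix sums over the upper triangle -> O(1) strong/informative counts
    strong = np.triu(C == 1, k=1).astype(np.int64)
    inform = np.triu(C != 0, k=1).astype(np.int64)
    Ps = strong.cumsum(axis=0).cumsum(axis=1)
    Pi = inform.cumsum(axis=0).cumsum(axis=1)

    def rect(P: np.ndarray, i: int, j: int) -> int:
        # number of marked pairs (a, b) with i <= a < b <= j
        total = P[j, j]
        left = P[j, i - 1] if i > 0 else 0
        top = P[i - 1, j] if i > 0 else 0
        corner = P[i - 1, i - 1] if i > 0 else 0
        return total - left - top + corner

    candidates: list[tuple[int, int, int]] = []  # (span_bp, i, j)
    for i in range(m - 1):
        for j in range(i + 1, m):
            if C[i, j] != 1:
                continue
            span = int(bp[j] - bp[i])
            if max_span_kb is not None and span / 1000.0 > max_span_kb:
                continue
            n_inf = rect(Pi, i, j)
            n_str = rect(Ps, i, j)
            if n_inf > 0 and n_str / n_inf >= min_strong_fraction:
                candidates.append((span, i, j))
    # decreasing span; ties leftmost
    candidates.sort(key=lambda t: (-t[0], t[1]))
    taken = np.zeros(m, dtype=bool)
    blocks: list[Block] = []
    for span, i, j in candidates:
        if taken[i : j + 1].any():
            continue
        taken[i : j + 1] = True
        blocks.append(
            Block(chrom, i, j, int(bp[i]), int(bp[j]), j - i + 1)
        )
    blocks.sort(key=lambda b: b.first)
    return blocks


def call_blocks_from_bounds(
    CL: np.ndarray,
    CU: np.ndarray,
    bp: np.ndarray,
    chrom: int = 0,
    min_strong_fraction: float = 0.95,
    max_span_kb: float | None = None,
    **thresholds,
) -> list[Block]:
    """Classify a bound matrix then call blocks (convenience wrapper)."""
    classes = classify_matrix(CL, CU, **thresholds)
    return gabriel_blocks(classes, bp, chrom, min_strong_fraction, max_span_kb)


def blocks_to_frame(blocks: list[Block], markers: MarkerMap | None = None) -> pd.DataFrame:
    rows = []
    for b in blocks:
        row = {
            "chrom": b.chrom,
            "start_bp": b.start_bp,
            "end_bp": b.end_bp,
            "n_snps": b.n_snps,
            "span_kb": b.span_kb,
        }
        if markers is not None:
            idx = markers.chrom_indices(b.chrom)
            row["snps"] = ",".join(markers.ids[idx[b.first : b.last + 1]])
        rows.append(row)
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "n_snps", "span_kb"] + (["snps"] if markers is not None else []))


def block_summary(
    blocks: list[Block],
    markers: MarkerMap,
    chrom_lengths_bp: dict[int, int] | None = None,
) -> pd.DataFrame:
    """Per-chromosome block table plus an ``all`` total row.

    Columns: block count, total/min/max span (kb), percent of chromosome
    length covered by blocks (omitted with a warning if lengths are missing),
    SNPs inside blocks and their percentage of all mapped SNPs.
    """
    import warnings

    have_len = chrom_lengths_bp is not None
    if not have_len:
        warnings.warn("chromosome lengths missing; % length column omitted")
    rows = []
    chroms = [int(c) for c in markers.chromosomes()]
    for c in chroms:
        cblocks = [b for b in blocks if b.chrom == c]
        n_snps_chrom = len(markers.chrom_indices(c))
        snps_in = sum(b.n_snps for b in cblocks)
        spans = [b.span_kb for b in cblocks]
        row = {
            "chrom": c,
            "n_blocks": len(cblocks),
            "total_kb": float(np.sum(spans)) if spans else 0.0,
            "min_kb": float(np.min(spans)) if spans else np.nan,
            "max_kb": float(np.max(spans)) if spans else np.nan,
            "n_snps_in_blocks": snps_in,
            "pct_snps_in_blocks": 100.0 * snps_in / n_snps_chrom if n_snps_chrom else np.nan,
        }
        if have_len:
            L = chrom_lengths_bp.get(c)
            row["pct_length_in_blocks"] = (
                100.0 * sum(b.end_bp - b.start_bp for b in cblocks) / L if L else np.nan
            )
        rows.append(row)
    total_snps = len(markers)
    spans = [b.span_kb for b in blocks]
    total = {
        "chrom": "all",
        "n_blocks": len(blocks),
        "total_kb": float(np.sum(spans)) if spans else 0.0,
        "min_kb": float(np.min(spans)) if spans else np.nan,
        "max_kb": float(np.max(spans)) if spans else np.nan,
        "n_snps_in_blocks": sum(b.n_snps for b in blocks),
        "pct_snps_in_blocks": 100.0 * sum(b.n_snps for b in blocks) / total_snps
        if total_snps
        else np.nan,
    }
    if have_len:
        tot_len = sum(v for v in chrom_lengths_bp.values())
        total["pct_length_in_blocks"] = (
            100.0 * sum(b.end_bp - b.start_bp for b in blocks) / tot_len if tot_len else np.nan
        )
    rows.append(total)
    return pd.DataFrame(rows)
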