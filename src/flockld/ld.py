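"""Pairwise linkage disequilibrium from phased haplotypes.

Statistics are computed by direct haplotype counting (no EM from genotypes).
For a pair of biallelic loci with joint haplotype counts
``(n_AB, n_Ab, n_aB, n_ab)`` over the haplotypes non-missing at both sites:

.. math::

    D = p_{AB} - p_A p_B, \\qquad
    D' = |D| / D_{max}, \\qquad
    r^2 = D^2 / (p_A(1-p_A)\\,p_B(1-p_B))

with ``Dmax = min(p_A(1-p_B), (1-p_A)p_B)`` when ``D > 0`` and
``min(p_A p_B, (1-p_A)(1-p_B))`` otherwise.  ``r^2 <= D'^2`` always.

Confidence bounds on ``|D'|`` (used by the block caller) come from the
normalized multinomial likelihood on a ``|D'|`` grid with allele frequencies
held at their MLEs — the construction used for Gabriel-style block calling.

Pairs where either locus is monomorphic in the jointly observed haplotypes
are *undefined* and excluded from all summaries (never scored as zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import MISSING, DataError, HaplotypeSet

#: Physical-distance bin edges (bp) for the decay table:
#: 10/20/40/60/100/200/500 kb, 1/2/5/10/20/50 Mb, then open-ended.
DECAY_BIN_EDGES_BP: tuple[int, ...] = (
    0,
    10_000,
    20_000,
    40_000,
    60_000,
    100_000,
    200_000,
    500_000,
    1_000_000,
    2_000_000,
    5_000_000,
    10_000_000,
    20_000_000,
    50_000_000,
)

DECAY_BIN_LABELS: tuple[str, ...] = (
    "<10kb",
    "10-20kb",
    "20-40kb",
    "40-60kb",
    "60-100kb",
    "100-200kb",
    "200-500kb",
    "500kb-1Mb",
    "1-2Mb",
    "2-5Mb",
    "5-10Mb",
    "10-20Mb",
    "20-50Mb",
    ">50Mb",
)


@dataclass
class PairLD:
    """LD statistics for one SNP pair."""

    snp_i: str
    snp_j: str
    n_AB: int
    n_Ab: int
    n_aB: int
    n_ab: int
    p_A: float
    p_B: float
    D: float
    Dmax: float
    Dprime: float
    r2: float
    dist_bp: int = 0
    c: float = float("nan")  # genetic distance, Morgans

    @property
    def n(self) -> int:
        return self.n_AB + self.n_Ab + self.n_aB + self.n_ab


@dataclass
class CIBound:
    """One-sided confidence bounds on |D'|."""

    CL: float
    CU: float

    def __post_init__(self) -> None:
        if self.CL > self.CU + 1e-12:
            raise DataError("CL must not exceed CU")


def pair_ld(counts: tuple[int, int, int, int], snp_i: str = "i", snp_j: str = "j") -> PairLD:
    """LD statistics from four haplotype counts ``(n_AB, n_Ab, n_aB, n_ab)``.

    Raises :class:`DataError` if the total count is < 2 or either locus is
    monomorphic in the pair sample (the statistics are undefined there).
    """
    n_AB, n_Ab, n_aB, n_ab = (int(c) for c in counts)
    if min(n_AB, n_Ab, n_aB, n_ab) < 0:
        raise DataError("negative haplotype count")
    n = n_AB + n_Ab + n_aB + n_ab
    if n < 2:
        raise DataError("need at least 2 haplotypes")
    p_A = (n_AB + n_Ab) / n
    p_B = (n_AB + n_aB) / n
    if p_A in (0.0, 1.0) or p_B in (0.0, 1.0):
        raise DataError("monomorphic locus: LD undefined")
    p_AB = n_AB / n
    D = p_AB - p_A * p_B
    if D > 0:
        Dmax = min(p_A * (1 - p_B), (1 - p_A) * p_B)
    else:
        Dmax = min(p_A * p_B, (1 - p_A) * (1 - p_B))
    Dprime = 0.0 if D == 0 else abs(D) / Dmax
    r2 = D * D / (p_A * (1 - p_A) * p_B * (1 - p_B))
    return PairLD(snp_i, snp_j, n_AB, n_Ab, n_aB, n_ab, p_A, p_B, D, Dmax, Dprime, r2)


def _dprime_grid_weights(
    counts: tuple[int, int, int, int], grid: np.ndarray
) -> np.ndarray:
    """Normalized multinomial likelihood of the counts over a |D'| grid."""
    stats = pair_ld(counts)
    sgn = 1.0 if stats.D >= 0 else -1.0
    p_A, p_B = stats.p_A, stats.p_B
    p_AB = p_A * p_B + sgn * grid * stats.Dmax
    probs = np.stack(
        [p_AB, p_A - p_AB, p_B - p_AB, 1 - p_A - p_B + p_AB], axis=-1
    )
    probs = np.clip(probs, 0.0, 1.0)
    cnt = np.array(counts, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(cnt > 0, cnt * np.log(np.where(probs > 0, probs, 1.0)), 0.0)
        ll = np.where((cnt > 0) & (probs <= 0), -np.inf, ll).sum(axis=-1)
    ll -= ll.max()
    w = np.exp(ll)
    return w / w.sum()


def dprime_ci(counts: tuple[int, int, int, int], grid_step: float = 0.001) -> CIBound:
    """Likelihood-based one-sided confidence bounds on |D'|.

    The multinomial likelihood is evaluated on a regular |D'| grid (allele
    frequencies fixed at their MLEs), normalized to a unit mass, and the
    bounds read off the cumulative mass: ``CL`` is the largest grid value
    with at most 5% of the mass strictly below it, ``CU`` the smallest with
    at least 95% at or below it.
    """
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    w = _dprime_grid_weights(counts, grid)
    cum = np.cumsum(w)
    below = cum - w  # mass strictly below each grid point
    CL = float(grid[np.flatnonzero(below <= 0.05 + 1e-12).max()])
    CU = float(grid[np.flatnonzero(cum >= 0.95 - 1e-12).min()])
    return CIBound(CL, CU)


def dprime_ci_batch(
    counts: np.ndarray, grid_step: float = 0.001, chunk: int = 2048
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`dprime_ci` over an ``(n_pairs, 4)`` count array."""
    counts = np.asarray(counts, dtype=float)
    n_pairs = counts.shape[0]
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    CL = np.empty(n_pairs)
    CU = np.empty(n_pairs)
    for lo in range(0, n_pairs, chunk):
        blk = counts[lo : lo + chunk]
        n = blk.sum(axis=1, keepdims=True)
        p_A = (blk[:, 0:1] + blk[:, 1:2]) / n
        p_B = (blk[:, 0:1] + blk[:, 2:3]) / n
        D = blk[:, 0:1] / n - p_A * p_B
        Dmax = np.where(
            D > 0,
            np.minimum(p_A * (1 - p_B), (1 - p_A) * p_B),
            np.minimum(p_A * p_B, (1 - p_A) * (1 - p_B)),
        )
        sgn = np.where(D >= 0, 1.0, -1.0)
        p_AB = p_A * p_B + sgn * grid[None, :] * Dmax  # (b, G)
        hap = np.stack(
            [p_AB, p_A - p_AB, p_B - p_AB, 1 - p_A - p_B + p_AB], axis=2
        )  # (b, G, 4)
        hap = np.clip(hap, 0.0, 1.0)
        cnt = blk[:, None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.where(
                cnt > 0,
                cnt * np.log(np.where(hap > 0, hap, 1.0)),
                0.0,
            )
            ll = np.where((cnt > 0) & (hap <= 0), -np.inf, ll).sum(axis=2)
        ll -= ll.max(axis=1, keepdims=True)
        w = np.exp(ll)
        w /= w.sum(axis=1, keepdims=True)
        cum = np.cumsum(w, axis=1)
        below = cum - w
        CL[lo : lo + chunk] = grid[
            (below <= 0.05 + 1e-12).cumsum(axis=1).argmax(axis=1)
        ]
        CU[lo : lo + chunk] = grid[(cum >= 0.95 - 1e-12).argmax(axis=1)]
    return CL, CU


def _pairwise_matrices(H: np.ndarray):
    """All-pairs LD matrices from a haplotype block ``H`` (rows = haplotypes).

    Returns ``(N, Dprime, r2, defined)`` where ``N[i, j]`` is the number of
    jointly non-missing haplotypes and ``defined`` marks pairs where both
    loci are polymorphic in that joint sample.
    """
    V = (H != MISSING).astype(np.float64)
    X = np.where(H == 1, 1.0, 0.0) * V
    N = V.T @ V
    C11 = X.T @ X
    S = X.T @ V  # S[i, j] = # of 1s at locus i among rows observed at both i and j
    with np.errstate(divide="ignore", invalid="ignore"):
        p = S / N           # freq of locus i within pair (i, j)
        q = S.T / N         # freq of locus j within pair (i, j)
        D = C11 / N - p * q
        varprod = p * (1 - p) * q * (1 - q)
        r2 = np.where(varprod > 0, D * D / varprod, np.nan)
        Dmax = np.where(
            D > 0, np.minimum(p * (1 - q), (1 - p) * q), np.minimum(p * q, (1 - p) * (1 - q))
        )
        Dp = np.where(Dmax > 0, np.abs(D) / Dmax, np.nan)
        Dp = np.where((D == 0) & (varprod > 0), 0.0, Dp)
    defined = (N >= 2) & (varprod > 0)
    return N, Dp, r2, defined


def pair_counts(H: np.ndarray, i: int, j: int) -> tuple[int, int, int, int]:
    """Joint haplotype counts ``(n_11, n_10, n_01, n_00)`` for loci i, j.

    The "A"/"B" labels are the allele coded 1 at each locus.
    """
    a, b = H[:, i], H[:, j]
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    return (
        int(((a == 1) & (b == 1)).sum()),
        int(((a == 1) & (b == 0)).sum()),
        int(((a == 0) & (b == 1)).sum()),
        int(((a == 0) & (b == 0)).sum()),
    )


def chromosome_pair_table(
    h: HaplotypeSet, chrom: int, max_dist_bp: int | None = None
) -> pd.DataFrame:
    """All defined within-chromosome SNP pairs with D', r2 and distance.

    Memory scales with the square of one chromosome's SNP count; chromosomes
    are processed independently by callers.
    """
    idx = h.markers.chrom_indices(chrom)
    sub = h.H[:, idx]
    _, Dp, r2, defined = _pairwise_matrices(sub)
    iu, ju = np.triu_indices(len(idx), k=1)
    ok = defined[iu, ju]
    dist = np.abs(h.markers.bp[idx[ju]] - h.markers.bp[idx[iu]])
    if max_dist_bp is not None:
        ok = ok & (dist <= max_dist_bp)
    iu, ju = iu[ok], ju[ok]
    return pd.DataFrame(
        {
            "chrom": chrom,
            "snp_i": h.markers.ids[idx[iu]],
            "snp_j": h.markers.ids[idx[ju]],
            "dist_bp": np.abs(h.markers.bp[idx[ju]] - h.markers.bp[idx[iu]]),
            "dprime": Dp[iu, ju],
            "r2": r2[iu, ju],
        }
    )


def syntenic_pair_table(h: HaplotypeSet) -> pd.DataFrame:
    """Concatenated :func:`chromosome_pair_table` over all chromosomes."""
    parts = [chromosome_pair_table(h, int(c)) for c in h.markers.chromosomes()]
    return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()


def ld_decay_table(
    pairs: pd.DataFrame, edges_bp: tuple[int, ...] = DECAY_BIN_EDGES_BP
) -> pd.DataFrame:
    """Decay summary over half-open physical-distance bins ``[lower, upper)``.

    Input must be syntenic pairs with columns ``dist_bp``, ``dprime``, ``r2``.
    Per bin: pair count plus mean/SD/min/max of D' and r².  Bin counts sum to
    the number of input pairs (conservation).
    """
    edges = list(edges_bp) + [np.inf]
    cats = pd.cut(pairs["dist_bp"], bins=edges, right=False, labels=False)
    rows = []
    for b in range(len(edges) - 1):
        sel = pairs[cats == b]
        label = (
            DECAY_BIN_LABELS[b]
            if edges_bp == DECAY_BIN_EDGES_BP
            else f"[{edges[b]},{edges[b + 1]})"
        )
        row = {"bin": label, "lower_bp": edges[b], "n_pairs": len(sel)}
        for stat in ("dprime", "r2"):
            v = sel[stat].to_numpy()
            row[f"{stat}_mean"] = v.mean() if len(v) else np.nan
            row[f"{stat}_sd"] = v.std(ddof=1) if len(v) > 1 else np.nan
            row[f"{stat}_min"] = v.min() if len(v) else np.nan
            row[f"{stat}_max"] = v.max() if len(v) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def r2_by_mb_bin(pairs: pd.DataFrame, bin_mb: float = 1.0) -> pd.DataFrame:
    """Mean r² in consecutive ``bin_mb``-wide physical-distance intervals."""
    width = bin_mb * 1e6
    idx = np.floor(pairs["dist_bp"].to_numpy() / width).astype(int)
    df = pd.DataFrame({"bin": idx, "r2": pairs["r2"].to_numpy()})
    out = df.groupby("bin")["r2"].agg(["count", "mean"]).reset_index()
    out["midpoint_mb"] = (out["bin"] + 0.5) * bin_mb
    return out.rename(columns={"count": "n_pairs", "mean": "r2_mean"})


def half_length_r2(
    bin_means: np.ndarray, midpoints_mb: np.ndarray | None = None
) -> tuple[float, float]:
    """Distance at which binned mean r² first decays to half its maximum.

    ``bin_means`` are mean r² over consecutive 1-Mb intervals (midpoints
    default to 0.5, 1.5, ... Mb).  The maximum must sit in the first bin; the
    crossing distance is linearly interpolated between the midpoints of the
    two bins straddling half the maximum.  Returns ``(half_value, distance_mb)``.
    """
    means = np.asarray(bin_means, dtype=float)
    if len(means) < 2:
        raise DataError("need at least 2 bins")
    if midpoints_mb is None:
        midpoints_mb = np.arange(len(means)) + 0.5
    midpoints_mb = np.asarray(midpoints_mb, dtype=float)
    if means.argmax() != 0:
        raise DataError("maximum mean r2 not in the first bin")
    half = means[0] / 2.0
    for k in range(1, len(means)):
        if means[k] <= half:
            if means[k] == half:
                return half, float(midpoints_mb[k])
            frac = (half - means[k - 1]) / (means[k] - means[k - 1])
            return half, float(midpoints_mb[k - 1] + frac * (midpoints_mb[k] - midpoints_mb[k - 1]))
    raise DataError("no decay: curve never falls to half its maximum")


def nonsyntenic_ld(
    h: HaplotypeSet, fraction: float = 0.05, seed: int = 0
) -> dict:
    """Background LD between chromosomes from a random SNP subsample.

    Samples ``ceil(fraction * m_c)`` SNPs per chromosome without replacement
    (seeded), computes D'/r² for every between-chromosome pair among the
    sampled SNPs, and returns summary statistics.  The mean non-syntenic r²
    estimates the association expected by chance, ~1/n for n haplotypes.
    """
    chroms = h.markers.chromosomes()
    if len(chroms) < 2:
        raise DataError("need at least 2 chromosomes")
    rng = np.random.default_rng(seed)
    sampled: list[np.ndarray] = []
    for c in chroms:
        idx = h.markers.chrom_indices(int(c))
        k = math.ceil(fraction * len(idx))
        sampled.append(np.sort(rng.choice(idx, size=k, replace=False)))
    all_idx = np.concatenate(sampled)
    sub = h.H[:, all_idx]
    _, Dp, r2, defined = _pairwise_matrices(sub)
    chrom_of = h.markers.chrom[all_idx]
    iu, ju = np.triu_indices(len(all_idx), k=1)
    ok = (chrom_of[iu] != chrom_of[ju]) & defined[iu, ju]
    r2v = r2[iu[ok], ju[ok]]
    dpv = Dp[iu[ok], ju[ok]]
    return {
        "n_pairs": int(ok.sum()),
        "n_snps_sampled": int(len(all_idx)),
        "r2_mean": float(r2v.mean()),
        "r2_sd": float(r2v.std(ddof=1)),
        "r2_min": float(r2v.min()),
        "r2_max": float(r2v.max()),
        "dprime_mean": float(dpv.mean()),
        "dprime_sd": float(dpv.std(ddof=1)),
        "dprime_min": float(dpv.min()),
        "dprime_max": float(dpv.max()),
    }
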