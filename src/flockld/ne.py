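"""Historical effective population size from the decay of r² with distance.

Under drift-recombination equilibrium the expected squared allele correlation
between loci separated by ``c`` Morgans in a sample of ``n`` chromosomes is

.. math::

    E[r^2] \\approx \\frac{1}{1 + 4 N_e c} + \\frac{1}{n}

(Sved's relation plus the finite-sample term), so each genetic distance
``c`` carries information about the effective size roughly ``T = 1/(2c)``
generations ago.  Inverting the relation on binned pairs gives a trajectory
of past ``N_e``.

Physical distances are converted to Morgans through one of three modes:
a flat 1 cM/Mb, a single genome-average cM/Mb rate, or per-chromosome rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .datamodel import DataError

#: Default T grid (generations ago) for trajectory reporting.
DEFAULT_TIME_POINTS: tuple[float, ...] = (1, 5, 10, 15, 25, 50, 75, 100, 150, 200, 250)


class ConversionMode(Enum):
    UNIFORM_1 = "uniform_1"      # 1 cM ~ 1 Mb everywhere
    GENOME_AVG = "genome_avg"    # one genome-wide cM/Mb rate
    PER_CHROM = "per_chrom"      # chromosome-specific cM/Mb rates


@dataclass
class GeneticMap:
    """bp -> Morgans conversion policy."""

    mode: ConversionMode = ConversionMode.UNIFORM_1
    genome_rate_cm_per_mb: float = 1.0
    chrom_rates_cm_per_mb: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.genome_rate_cm_per_mb <= 0:
            raise DataError("genome rate must be positive")
        if any(r <= 0 for r in self.chrom_rates_cm_per_mb.values()):
            raise DataError("chromosome rates must be positive")

    def rate(self, chrom: int) -> float:
        """cM/Mb rate applying to ``chrom`` under the current mode."""
        if self.mode is ConversionMode.UNIFORM_1:
            return 1.0
        if self.mode is ConversionMode.GENOME_AVG:
            return self.genome_rate_cm_per_mb
        try:
            return self.chrom_rates_cm_per_mb[int(chrom)]
        except KeyError:
            raise DataError(f"no cM/Mb rate for chromosome {chrom}") from None


def bp_to_morgans(dist_bp, chrom, gmap: GeneticMap):
    """Convert physical distance to Morgans: ``c = bp * rate / 1e8``.

    (rate in cM/Mb: bp/1e6 -> Mb, * rate -> cM, /100 -> Morgans.)
    Accepts scalars or arrays; ``chrom`` may be an array in PER_CHROM mode.
    """
    dist_bp = np.asarray(dist_bp, dtype=float)
    if np.any(dist_bp < 0):
        raise DataError("negative distance")
    if gmap.mode is ConversionMode.PER_CHROM and np.ndim(chrom) > 0:
        rates = np.array([gmap.rate(c) for c in np.asarray(chrom).ravel()])
        rates = rates.reshape(np.shape(chrom))
    else:
        rates = gmap.rate(int(np.asarray(chrom).flat[0]) if np.ndim(chrom) else int(chrom))
    out = dist_bp * rates / 1e8
    return float(out) if out.ndim == 0 else out


def expected_r2(ne: float, c: float, n: int) -> float:
    """Forward model: Sved expectation plus sample-size term."""
    return 1.0 / (1.0 + 4.0 * ne * c) + 1.0 / n


def ne_point(r2_mean: float, c_mean: float, n: int) -> float | None:
    """Invert the expectation for one bin: ``Ne = (1/(r2 - 1/n) - 1)/(4c)``.

    Returns ``None`` (undefined) when ``r2_mean <= 1/n`` — the adjusted LD is
    non-positive and carries no information about Ne.
    """
    if c_mean <= 0:
        raise DataError("c_mean must be positive")
    if n < 2:
        raise DataError("need n >= 2 haplotypes")
    adj = r2_mean - 1.0 / n
    if adj <= 0:
        return None
    ne = (1.0 / adj - 1.0) / (4.0 * c_mean)
    return ne if ne > 0 else None


@dataclass
class NeEstimate:
    T: float            # generations ago, 1/(2 c_mean)
    c_mean: float       # Morgans
    r2_mean: float
    n: int
    ne: float | None
    mode: str
    n_pairs: int


def bin_pairs_by_c(
    c: np.ndarray, r2: np.ndarray, bin_size: int = 1000
) -> pd.DataFrame:
    """Stack pairs sorted by genetic distance into bins of ``bin_size`` pairs.

    The final partial bin is dropped.  Returns per-bin mean c, mean r², and
    T = 1/(2 c_mean).
    """
    c = np.asarray(c, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if len(c) < bin_size:
        raise DataError(f"need at least {bin_size} pairs, got {len(c)}")
    order = np.argsort(c, kind="stable")
    n_bins = len(c) // bin_size
    cs = c[order][: n_bins * bin_size].reshape(n_bins, bin_size)
    rs = r2[order][: n_bins * bin_size].reshape(n_bins, bin_size)
    c_mean = cs.mean(axis=1)
    return pd.DataFrame(
        {
            "c_mean": c_mean,
            "r2_mean": rs.mean(axis=1),
            "T": 1.0 / (2.0 * c_mean),
            "n_pairs": bin_size,
        }
    )


def ne_trajectory(
    pairs: pd.DataFrame,
    gmap: GeneticMap,
    n: int,
    bin_size: int = 1000,
    time_points: tuple[float, ...] = DEFAULT_TIME_POINTS,
) -> list[NeEstimate]:
    """Past-Ne estimates at requested time points from a syntenic pair table.

    ``pairs`` needs columns ``chrom``, ``dist_bp``, ``r2``.  Pairs are
    converted to genetic distance under ``gmap``, sorted ascending by c and
    stacked into ``bin_size``-pair bins; each bin yields (c̄, r̄², T, Ne).
    Each requested time point reports the bin with the nearest T (ties: the
    smaller c̄, i.e. the larger T).
    """
    if any(t <= 0 for t in time_points):
        raise DataError("time points must be positive")
    c = bp_to_morgans(pairs["dist_bp"].to_numpy(), pairs["chrom"].to_numpy(), gmap)
    keep = c > 0
    bins = bin_pairs_by_c(c[keep], pairs["r2"].to_numpy()[keep], bin_size)
    out: list[NeEstimate] = []
    for t in time_points:
        k = int(np.argmin(np.abs(bins["T"].to_numpy() - t)))
        # tie toward smaller c_mean = larger T: argmin returns the first of
        # equals and bins are sorted ascending in c (descending in T)
        row = bins.iloc[k]
        out.append(
            NeEstimate(
                T=float(row["T"]),
                c_mean=float(row["c_mean"]),
                r2_mean=float(row["r2_mean"]),
                n=n,
                ne=ne_point(float(row["r2_mean"]), float(row["c_mean"]), n),
                mode=gmap.mode.value,
                n_pairs=int(row["n_pairs"]),
            )
        )
    return out


def trajectory_frame(
    estimates: list[NeEstimate],
    requested_T: tuple[float, ...] = DEFAULT_TIME_POINTS,
    generation_interval_years: float | None = None,
) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "requested_T": list(requested_T),
            "T": [e.T for e in estimates],
            "c_mean": [e.c_mean for e in estimates],
            "r2_mean": [e.r2_mean for e in estimates],
            "n": [e.n for e in estimates],
            "ne": [np.nan if e.ne is None else e.ne for e in estimates],
            "mode": [e.mode for e in estimates],
        }
    )
    if generation_interval_years is not None:
        df["years_ago"] = df["T"] * generation_interval_years
    return df
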