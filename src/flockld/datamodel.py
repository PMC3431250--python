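"""Core domain types for half-sib SNP-panel analyses.

Conventions shared by every module:

* Coordinates are 1-based inclusive base pairs (PLINK ``.map`` style); pair
  distances are plain ``|bp_i - bp_j|``.
* Genotypes are allele dosages ``x in {0, 1, 2}`` counting copies of a
  designated reference allele; missing data is the sentinel :data:`MISSING`
  (stored as int8 ``-1``) and must be masked out before any arithmetic.
* Haplotype alleles are ``{0, 1}`` with the same missing sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing dosage / allele.  Always compare against this name;
#: the numeric value never participates in arithmetic.
MISSING: int = -1

#: Parental-origin tags for haplotypes.
PATERNAL, MATERNAL, UNKNOWN = "P", "M", "U"


class DataError(ValueError):
    """Raised when an input file or container violates its contract."""


@dataclass
class MarkerMap:
    """Physical (and optionally genetic) map of SNPs.

    Parameters
    ----------
    ids
        SNP identifiers, unique genome-wide.
    chrom
        Autosome label per SNP (positive integer).
    bp
        1-based physical position per SNP; strictly increasing and unique
        within each chromosome.
    cm
        Optional genetic position in centimorgans.
    """

    ids: np.ndarray
    chrom: np.ndarray
    bp: np.ndarray
    cm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=np.int64)
        self.bp = np.asarray(self.bp, dtype=np.int64)
        if self.cm is not None:
            self.cm = np.asarray(self.cm, dtype=float)
            if self.cm.shape != self.ids.shape:
                raise DataError("cM column length mismatch")
        if not (len(self.ids) == len(self.chrom) == len(self.bp)):
            raise DataError("marker map column length mismatch")
        if len(np.unique(self.ids)) != len(self.ids):
            raise DataError("duplicate SNP identifiers in map")
        if np.any(self.chrom <= 0):
            raise DataError("chromosome labels must be positive integers")
        if np.any(self.bp <= 0):
            raise DataError("bp positions must be positive (1-based)")
        for c in np.unique(self.chrom):
            pos = self.bp[self.chrom == c]
            if np.any(np.diff(pos) <= 0):
                raise DataError(
                    f"positions on chromosome {c} not strictly increasing/unique"
                )

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_markers(self) -> int:
        return len(self.ids)

    def chromosomes(self) -> np.ndarray:
        """Chromosome labels present, ascending."""
        return np.unique(self.chrom)

    def chrom_indices(self, c: int) -> np.ndarray:
        """Column indices of the SNPs on chromosome ``c`` (map order)."""
        return np.flatnonzero(self.chrom == c)

    def subset(self, idx: np.ndarray) -> "MarkerMap":
        idx = np.asarray(idx)
        return MarkerMap(
            self.ids[idx],
            self.chrom[idx],
            self.bp[idx],
            None if self.cm is None else self.cm[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        d = {"chrom": self.chrom, "id": self.ids, "bp": self.bp}
        if self.cm is not None:
            d["cm"] = self.cm
        return pd.DataFrame(d)


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix over ``{0, 1, 2, MISSING}``."""

    individuals: list[str]
    markers: MarkerMap
    X: np.ndarray  # int8, shape (n_individuals, n_markers)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.int8)
        if self.X.ndim != 2:
            raise DataError("dosage matrix must be 2-D")
        if self.X.shape != (len(self.individuals), len(self.markers)):
            raise DataError(
                f"dosage matrix shape {self.X.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.markers)} markers"
            )
        bad = ~np.isin(self.X, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DataError(
                f"invalid dosage {self.X[i, j]} for {self.individuals[i]} "
                f"at {self.markers.ids[j]}"
            )
        if len(set(self.individuals)) != len(self.individuals):
            raise DataError("duplicate individual identifiers")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def observed(self) -> np.ndarray:
        """Boolean mask of non-missing entries."""
        return self.X != MISSING

    def allele_freq(self) -> np.ndarray:
        """Reference-allele frequency per SNP among non-missing genotypes.

        Monomorphic-by-missingness columns (no calls) yield ``nan``.
        """
        obs = self.observed()
        called = obs.sum(axis=0)
        dose = np.where(obs, self.X, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(called > 0, dose / (2.0 * called), np.nan)

    def subset(
        self,
        individuals_idx: np.ndarray | None = None,
        markers_idx: np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        ii = (
            np.arange(self.n_individuals)
            if individuals_idx is None
            else np.asarray(individuals_idx)
        )
        jj = (
            np.arange(self.n_markers)
            if markers_idx is None
            else np.asarray(markers_idx)
        )
        return GenotypeMatrix(
            [self.individuals[i] for i in ii],
            self.markers.subset(jj),
            self.X[np.ix_(ii, jj)],
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.individuals), self.markers, self.X.copy())


@dataclass
class HaplotypeSet:
    """Phased chromosome copies: one row per haplotype over ``{0, 1, MISSING}``.

    ``carriers`` holds ``(individual_id, origin)`` per row, origin one of
    ``P`` (paternal), ``M`` (maternal), ``U`` (unknown).  ``n`` — the number
    of haplotype rows — is the chromosome sample size used by the LD-based
    Ne estimator.
    """

    H: np.ndarray  # int8, shape (n_haplotypes, n_markers)
    carriers: list[tuple[str, str]]
    markers: MarkerMap

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=np.int8)
        if self.H.ndim != 2:
            raise DataError("haplotype matrix must be 2-D")
        if self.H.shape[0] != len(self.carriers):
            raise DataError("carrier list does not match haplotype rows")
        if self.H.shape[1] != len(self.markers):
            raise DataError(
                f"haplotype columns ({self.H.shape[1]}) do not match "
                f"marker count ({len(self.markers)})"
            )
        bad = ~np.isin(self.H, (0, 1, MISSING))
        if bad.any():
            raise DataError("haplotype alleles must be 0/1/missing")
        counts: dict[str, int] = {}
        for ind, origin in self.carriers:
            counts[ind] = counts.get(ind, 0) + 1
            if origin not in (PATERNAL, MATERNAL, UNKNOWN):
                raise DataError(f"bad origin tag {origin!r} for {ind}")
        over = [k for k, v in counts.items() if v > 2]
        if over:
            raise DataError(f"more than 2 haplotypes for individual(s) {over}")

    @property
    def n(self) -> int:
        """Number of haplotypes (chromosome sample size)."""
        return self.H.shape[0]

    @property
    def n_markers(self) -> int:
        return self.H.shape[1]

    def subset_markers(self, idx: np.ndarray) -> "HaplotypeSet":
        idx = np.asarray(idx)
        return HaplotypeSet(self.H[:, idx], list(self.carriers), self.markers.subset(idx))


@dataclass
class Pedigree:
    """Directed acyclic parent map with birth years.

    ``records`` is a DataFrame with columns ``id, sire, dam, birth_year``;
    unknown parents are ``None``.  Parents named but without their own row
    are treated as declared founders.
    """

    records: pd.DataFrame
    _order: list[str] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        req = ["id", "sire", "dam", "birth_year"]
        if list(self.records.columns[:4]) != req:
            raise DataError(f"pedigree columns must be {req}")
        ids = self.records["id"].tolist()
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids)[pd.Series(ids).duplicated()].iloc[0]
            raise DataError(f"duplicate individual id in pedigree: {dup}")
        self._order = self._toposort()
        self._check_birth_years()

    def _toposort(self) -> list[str]:
        # Kahn's algorithm over the parent->offspring DAG; cycle reported on
        # failure by walking parent links from a stuck node.
        parents = self.parent_map()
        known = set(parents)
        indeg = {
            i: sum(1 for p in ps if p is not None and p in known)
            for i, ps in parents.items()
        }
        queue = sorted(i for i, d in indeg.items() if d == 0)
        children: dict[str, list[str]] = {}
        for i, ps in parents.items():
            for p in ps:
                if p is not None and p in known:
                    children.setdefault(p, []).append(i)
        order: list[str] = []
        while queue:
            node = queue.pop()
            order.append(node)
            for ch in children.get(node, ()):
                indeg[ch] -= 1
                if indeg[ch] == 0:
                    queue.append(ch)
        if len(order) != len(parents):
            stuck = next(i for i, d in indeg.items() if d > 0 and i not in set(order))
            cycle = [stuck]
            seen = {stuck}
            node = stuck
            while True:
                node = next(
                    p for p in parents[node] if p is not None and indeg.get(p, 0) > 0
                )
                if node in seen:
                    cycle.append(node)
                    break
                cycle.append(node)
                seen.add(node)
            raise DataError(f"pedigree cycle detected: {' -> '.join(cycle)}")
        return order

    def _check_birth_years(self) -> None:
        by = dict(zip(self.records["id"], self.records["birth_year"]))
        for _, row in self.records.iterrows():
            y = row["birth_year"]
            if y is None or pd.isna(y):
                continue
            for p in (row["sire"], row["dam"]):
                py = by.get(p)
                if p is not None and py is not None and not pd.isna(py) and y < py:
                    raise DataError(
                        f"{row['id']} born {y} before parent {p} born {py}"
                    )

    def parent_map(self) -> dict[str, tuple[str | None, str | None]]:
        return {
            row["id"]: (row["sire"], row["dam"])
            for _, row in self.records.iterrows()
        }

    def topological_order(self) -> list[str]:
        """Ids sorted parents-before-offspring."""
        return list(self._order)

    def founders(self) -> list[str]:
        return [
            row["id"]
            for _, row in self.records.iterrows()
            if row["sire"] is None and row["dam"] is None
        ]

    def birth_years(self) -> dict[str, int | None]:
        return dict(zip(self.records["id"], self.records["birth_year"]))

    def sire_of(self) -> dict[str, str | None]:
        return dict(zip(self.records["id"], self.records["sire"]))

    def __len__(self) -> int:
        return len(self.records)
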