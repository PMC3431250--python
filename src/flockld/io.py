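"""Readers and writers for PLINK-style text genotypes, pedigree and haplotype TSVs.

Dialects
--------
``.map``   four whitespace-separated columns: chrom, snp id, cM, bp.
``.ped``   six leading columns (family, id, sire, dam, sex, phenotype) then two
           allele columns per SNP; ``0`` marks a missing allele.
pedigree   TSV with header ``id  sire  dam  birth_year``; ``0`` or empty field
           means unknown.
haplotype  TSV, one row per chromosome copy: carrier id, origin (P/M/U), then
           one ``0``/``1``/``.`` symbol per SNP.

Writers emit the same dialects byte-stably for a fixed input ordering, so a
write/read round trip is exact.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .datamodel import (
    MISSING,
    DataError,
    GenotypeMatrix,
    HaplotypeSet,
    MarkerMap,
    Pedigree,
)

_AUTOSOME_MAX = 90  # labels above this (or X/Y/MT/0) are treated as non-autosomal


def _parse_chrom(tok: str) -> int | None:
    """Numeric autosome label, or None for sex/unmapped/unknown chromosomes."""
    t = tok.strip().upper()
    if t in {"X", "Y", "XY", "MT", "M", "0", ""}:
        return None
    try:
        c = int(t)
    except ValueError:
        return None
    return c if 0 < c <= _AUTOSOME_MAX else None


def read_map(path: str | os.PathLike, drop_non_autosomal: bool = True):
    """Read a 4-column ``.map`` file.

    Returns ``(MarkerMap, kept_column_indices, n_dropped)`` where the indices
    refer to the original file order (needed to slice the matching ``.ped``
    allele columns when sex-chromosome or unmapped rows are dropped).
    """
    rows = []
    with open(path) as fh:
        for k, line in enumerate(fh):
            if not line.strip():
                continue
            toks = line.split()
            if len(toks) != 4:
                raise DataError(f"{path}: map line {k + 1} has {len(toks)} columns, expected 4")
            rows.append((toks[0], toks[1], float(toks[2]), int(toks[3]), k))
    chroms = [_parse_chrom(r[0]) for r in rows]
    if drop_non_autosomal:
        keep = [i for i, c in enumerate(chroms) if c is not None]
    else:
        keep = list(range(len(rows)))
    n_dropped = len(rows) - len(keep)
    mm = MarkerMap(
        ids=np.array([rows[i][1] for i in keep], dtype=object),
        chrom=np.array([chroms[i] for i in keep], dtype=np.int64),
        bp=np.array([rows[i][3] for i in keep], dtype=np.int64),
        cm=np.array([rows[i][2] for i in keep], dtype=float),
    )
    return mm, np.array([rows[i][4] for i in keep], dtype=np.int64), n_dropped


def read_genotypes(
    ped_path: str | os.PathLike,
    map_path: str | os.PathLike,
    ref_allele: str | None = None,
) -> GenotypeMatrix:
    """Read PLINK-style text ``.ped``/``.map`` into a :class:`GenotypeMatrix`.

    Dosages count copies of the first allele observed per SNP (re-polarize to
    the minor allele downstream if needed); pass ``ref_allele`` to count a
    fixed symbol instead (as written by :func:`write_genotypes`, giving an
    exact round trip).  A half-missing genotype (one allele ``0``) is fully
    missing.  Non-autosomal map rows are dropped with their allele columns.
    """
    markers, keep_cols, _ = read_map(map_path)
    n_total_snps = None
    individuals: list[str] = []
    geno_rows: list[np.ndarray] = []
    # first allele seen per (kept) SNP defines the reference; second defines alt
    ref = np.array([ref_allele] * len(markers), dtype=object)
    alt = np.array([None] * len(markers), dtype=object)

    with open(map_path) as fh:
        n_total_snps = sum(1 for line in fh if line.strip())

    with open(ped_path) as fh:
        for k, line in enumerate(fh):
            if not line.strip():
                continue
            toks = line.split()
            if len(toks) != 6 + 2 * n_total_snps:
                raise DataError(
                    f"{ped_path}: row {k + 1} has {len(toks)} fields, expected "
                    f"{6 + 2 * n_total_snps} for {n_total_snps} SNPs"
                )
            individuals.append(toks[1])
            alleles = np.array(toks[6:], dtype=object).reshape(-1, 2)[keep_cols]
            row = np.empty(len(markers), dtype=np.int8)
            for j, (a1, a2) in enumerate(alleles):
                if a1 == "0" or a2 == "0":
                    row[j] = MISSING
                    continue
                dose = 0
                for a in (a1, a2):
                    if ref[j] is None:
                        ref[j] = a
                    if a == ref[j]:
                        dose += 1
                    elif alt[j] is None:
                        alt[j] = a
                    elif a != alt[j]:
                        raise DataError(
                            f"SNP {markers.ids[j]} has more than 2 alleles "
                            f"({ref[j]}, {alt[j]}, {a})"
                        )
                row[j] = dose
            geno_rows.append(row)
    if not geno_rows:
        raise DataError(f"{ped_path}: no genotype rows")
    return GenotypeMatrix(individuals, markers, np.vstack(geno_rows))


def write_genotypes(
    g: GenotypeMatrix,
    ped_path: str | os.PathLike,
    map_path: str | os.PathLike,
    ref_allele: str = "A",
    alt_allele: str = "B",
) -> None:
    """Write ``.ped``/``.map`` using symbolic alleles (dosage counts `ref_allele`)."""
    with open(map_path, "w") as fh:
        for j in range(g.n_markers):
            cm = float(g.markers.cm[j]) if g.markers.cm is not None else 0.0
            fh.write(f"{g.markers.chrom[j]}\t{g.markers.ids[j]}\t{cm!r}\t{g.markers.bp[j]}\n")
    pair = {
        0: f"{alt_allele} {alt_allele}",
        1: f"{ref_allele} {alt_allele}",
        2: f"{ref_allele} {ref_allele}",
        MISSING: "0 0",
    }
    with open(ped_path, "w") as fh:
        for i, ind in enumerate(g.individuals):
            cells = " ".join(pair[int(x)] for x in g.X[i])
            fh.write(f"FAM {ind} 0 0 0 -9 {cells}\n")


def _parse_parent(tok: str) -> str | None:
    t = tok.strip()
    return None if t in {"0", ""} else t


def read_pedigree(path: str | os.PathLike) -> Pedigree:
    """Read a pedigree TSV (header ``id sire dam birth_year``)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    need = {"id", "sire", "dam", "birth_year"}
    if not need.issubset(df.columns):
        raise DataError(f"{path}: pedigree header must contain {sorted(need)}")
    records = pd.DataFrame(
        {
            "id": df["id"].astype(str),
            "sire": [_parse_parent(s) for s in df["sire"]],
            "dam": [_parse_parent(d) for d in df["dam"]],
            "birth_year": [
                int(y) if str(y).strip() not in {"", "0"} else None
                for y in df["birth_year"]
            ],
        }
    )
    return Pedigree(records)


def write_pedigree(ped: Pedigree, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("id\tsire\tdam\tbirth_year\n")
        for _, row in ped.records.iterrows():
            s = row["sire"] or "0"
            d = row["dam"] or "0"
            y = "" if row["birth_year"] is None else str(row["birth_year"])
            fh.write(f"{row['id']}\t{s}\t{d}\t{y}\n")


_HAP_SYM = {"0": 0, "1": 1, ".": MISSING}
_HAP_INV = {0: "0", 1: "1", MISSING: "."}


def read_haplotypes(path: str | os.PathLike, markers: MarkerMap) -> HaplotypeSet:
    """Read a haplotype TSV against a supplied marker map."""
    carriers: list[tuple[str, str]] = []
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for k, line in enumerate(fh):
            if not line.strip():
                continue
            toks = line.rstrip("\n").split("\t")
            if len(toks) != 2 + len(markers):
                raise DataError(
                    f"{path}: row {k + 1} has {len(toks) - 2} allele columns, "
                    f"map has {len(markers)} SNPs"
                )
            carriers.append((toks[0], toks[1]))
            try:
                rows.append(np.array([_HAP_SYM[t] for t in toks[2:]], dtype=np.int8))
            except KeyError as e:
                raise DataError(f"{path}: row {k + 1}: bad allele symbol {e}") from e
    return HaplotypeSet(np.vstack(rows), carriers, markers)


def write_haplotypes(h: HaplotypeSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for (ind, origin), row in zip(h.carriers, h.H):
            fh.write(f"{ind}\t{origin}\t" + "\t".join(_HAP_INV[int(a)] for a in row) + "\n")
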