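"""Pedigree and marker-based inbreeding coefficients.

Pedigree inbreeding ``F_PED`` is the diagonal of the additive relationship
matrix minus one, computed per individual with the Meuwissen–Luo ancestor-
tracing algorithm (equivalent to Wright's path counting; founders assumed
unrelated and non-inbred, unknown parents treated as unique founders).

Marker-based coefficients follow the three GCTA ``--ibc`` estimators.  With
dosage ``x``, reference-allele frequency ``p`` and ``m`` the number of
non-missing SNPs for the individual:

.. math::

    \\hat F_1 = \\frac1m \\sum \\frac{(x - 2p)^2}{2p(1-p)} - 1
    \\qquad\\text{(variance of the additive genotype)}

    \\hat F_2 = \\frac1m \\sum \\Big[1 - \\frac{x(2-x)}{2p(1-p)}\\Big]
    \\qquad\\text{(excess homozygosity)}

    \\hat F_3 = \\frac1m \\sum \\frac{x^2 - (1+2p)x + 2p^2}{2p(1-p)}
    \\qquad\\text{(correlation between uniting gametes)}

Frequencies default to the analyzed sample (the study population is its own
base population), so individual estimates can be negative; negative values
are clamped to zero in *reporting* only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import MISSING, DataError, GenotypeMatrix, Pedigree


def f_pedigree(ped: Pedigree) -> pd.Series:
    """Meuwissen–Luo inbreeding coefficient per individual.

    For each animal the algorithm traces its ancestor list youngest-first,
    accumulating the squared within-family segregation contributions
    ``L_ij^2 d_j`` that make up the relationship-matrix diagonal
    ``A_ii = 1 + F_i``.
    """
    order = ped.topological_order()
    parents = ped.parent_map()
    pos = {ind: k for k, ind in enumerate(order)}
    F: dict[str, float] = {}
    # d_j: variance of the Mendelian sampling term of j given its parents
    d: dict[str, float] = {}

    for ind in order:
        s, dm = parents[ind]
        Fs = F.get(s, 0.0) if s is not None else None
        Fd = F.get(dm, 0.0) if dm is not None else None
        if s is not None and dm is not None:
            d[ind] = 0.5 - 0.25 * (Fs + Fd)
        elif s is not None:
            d[ind] = 0.75 - 0.25 * Fs
        elif dm is not None:
            d[ind] = 0.75 - 0.25 * Fd
        else:
            d[ind] = 1.0

        if s is None and dm is None:
            F[ind] = 0.0
            continue
        # trace ancestors of ind, youngest first; L accumulates the row of
        # the Cholesky factor restricted to ind's ancestor set
        L = {ind: 1.0}
        a_ii = 0.0
        heap = {pos[ind]}
        while heap:
            k = max(heap)
            heap.discard(k)
            node = order[k]
            coeff = L.pop(node)
            a_ii += coeff * coeff * d[node]
            for par in parents.get(node, (None, None)):
                if par is not None:
                    L[par] = L.get(par, 0.0) + 0.5 * coeff
                    heap.add(pos[par])
        F[ind] = a_ii - 1.0
    return pd.Series({ind: F[ind] for ind in ped.records["id"]}, name="F_PED")


def f_markers(
    g: GenotypeMatrix, freqs: np.ndarray | None = None
) -> pd.DataFrame:
    """GCTA-style marker inbreeding estimators F1, F2, F3 per individual.

    ``freqs`` are per-SNP reference-allele frequencies; by default estimated
    from the sample itself.  SNPs with ``p`` of 0 or 1 (or undefined) are
    excluded with a warning; each individual's denominator ``m`` counts only
    its own non-missing SNPs.
    """
    import warnings

    p = g.allele_freq() if freqs is None else np.asarray(freqs, dtype=float)
    if p.shape != (g.n_markers,):
        raise DataError("frequency vector length mismatch")
    usable = np.isfinite(p) & (p > 0) & (p < 1)
    if not usable.all():
        warnings.warn(
            f"{int((~usable).sum())} SNP(s) with p in {{0,1}} or undefined excluded"
        )
    p = p[usable]
    X = g.X[:, usable]
    obs = X != MISSING
    x = np.where(obs, X, 0).astype(float)
    denom = 2.0 * p * (1.0 - p)

    t1 = (x - 2.0 * p) ** 2 / denom          # additive-variance score
    t2 = 1.0 - x * (2.0 - x) / denom         # excess-homozygosity score
    t3 = (x * x - (1.0 + 2.0 * p) * x + 2.0 * p * p) / denom

    m = obs.sum(axis=1).astype(float)
    if np.any(m == 0):
        raise DataError("individual with no called genotypes")
    F1 = np.where(obs, t1, 0.0).sum(axis=1) / m - 1.0
    F2 = np.where(obs, t2, 0.0).sum(axis=1) / m
    F3 = np.where(obs, t3, 0.0).sum(axis=1) / m
    return pd.DataFrame(
        {"id": g.individuals, "F1": F1, "F2": F2, "F3": F3}
    ).set_index("id")


def inbreeding_table(
    g: GenotypeMatrix, ped: Pedigree, freqs: np.ndarray | None = None
) -> pd.DataFrame:
    """Joined per-individual table: F_PED, F1, F2, F3, birth_year."""
    fm = f_markers(g, freqs)
    fp = f_pedigree(ped)
    by = ped.birth_years()
    fm["F_PED"] = [fp.get(i, np.nan) for i in fm.index]
    fm["birth_year"] = [by.get(i) for i in fm.index]
    return fm[["birth_year", "F_PED", "F1", "F2", "F3"]]


def inbreeding_trend(
    records: pd.DataFrame,
    clamp_negative: bool = True,
    threshold: float = 0.0625,
) -> pd.DataFrame:
    """Per-birth-year means of each F metric, plus the fraction above 0.0625.

    With ``clamp_negative`` (default) negative estimates are treated as 0 in
    the mean, matching the convention of reporting only positive inbreeding;
    stored estimates are never modified.  The 0.0625 threshold is the
    first-cousin-mating level conventionally flagged as high.
    """
    metrics = [c for c in ("F_PED", "F1", "F2", "F3") if c in records.columns]
    df = records.dropna(subset=["birth_year"])
    rows = []
    for year, grp in df.groupby("birth_year"):
        row: dict = {"birth_year": int(year), "n": len(grp)}
        for mcol in metrics:
            v = grp[mcol].to_numpy(dtype=float)
            v = v[np.isfinite(v)]
            vv = np.maximum(v, 0.0) if clamp_negative else v
            row[f"{mcol}_mean"] = vv.mean() if len(vv) else np.nan
            row[f"{mcol}_frac_over_{threshold:g}"] = (
                (v > threshold).mean() if len(v) else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows).sort_values("birth_year").reset_index(drop=True)
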