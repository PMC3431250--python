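"""Two-stage genotype quality control, Mendelian cleaning and sire-based imputation.

The QC protocol is the standard SNP-array one for a half-sib daughter design:

1. per-individual call-rate filter (individuals with more than ``max_missing``
   missing genotypes removed) — applied before any marker filter so as many
   markers as possible survive;
2. per-marker filters, applied sequentially: call rate, minor allele
   frequency, Hardy-Weinberg exact test;
3. Mendelian cleaning of sire-daughter opposing-homozygote conflicts;
4. deterministic iterative imputation of missing daughter genotypes from the
   sire genotype plus current population allele frequencies.

Every removal is recorded in a :class:`QCLedger` whose step arithmetic
(remaining = previous remaining - removed) is asserted on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .datamodel import MISSING, DataError, GenotypeMatrix, Pedigree


@dataclass
class LedgerStep:
    step: str
    threshold: float | str
    removed: int
    remaining: int


@dataclass
class QCLedger:
    """Ordered record of QC steps with conservation checking."""

    unit: str  # "individuals" or "markers"
    initial: int
    steps: list[LedgerStep] = field(default_factory=list)

    def add(self, step: str, threshold: float | str, removed: int) -> None:
        prev = self.steps[-1].remaining if self.steps else self.initial
        remaining = prev - removed
        if removed < 0 or remaining < 0:
            raise DataError(f"ledger arithmetic violated at step {step!r}")
        self.steps.append(LedgerStep(step, threshold, removed, remaining))

    @property
    def remaining(self) -> int:
        return self.steps[-1].remaining if self.steps else self.initial

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "unit": self.unit,
                    "step": s.step,
                    "threshold": s.threshold,
                    "removed": s.removed,
                    "remaining": s.remaining,
                }
                for s in self.steps
            ]
        )

    def to_dict(self) -> dict:
        return {
            "unit": self.unit,
            "initial": self.initial,
            "steps": [vars(s) for s in self.steps],
        }


@dataclass
class MarkerStats:
    """Per-SNP summary statistics on the current matrix."""

    ids: np.ndarray
    call_rate: np.ndarray
    p: np.ndarray  # reference-allele frequency
    maf: np.ndarray
    het: np.ndarray  # observed heterozygosity
    hwe_p: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "call_rate": self.call_rate,
                "p_ref": self.p,
                "maf": self.maf,
                "het": self.het,
                "hwe_p": self.hwe_p,
            }
        )


def filter_individuals(
    g: GenotypeMatrix, max_missing: float = 0.10
) -> tuple[GenotypeMatrix, QCLedger]:
    """Remove individuals with missing fraction strictly above ``max_missing``."""
    if not (0 < max_missing < 1):
        raise DataError("max_missing must be in (0,1)")
    if g.n_individuals == 0 or g.n_markers == 0:
        raise DataError("empty genotype matrix")
    miss_frac = (~g.observed()).mean(axis=1)
    keep = np.flatnonzero(miss_frac <= max_missing)
    ledger = QCLedger("individuals", g.n_individuals)
    ledger.add("individual_missingness", max_missing, g.n_individuals - len(keep))
    return g.subset(individuals_idx=keep), ledger


def hwe_exact_pvalue(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg test p-value.

    Conditional on the sample size and allele count, enumerates every possible
    heterozygote count and sums the probabilities of all configurations no
    more likely than the observed one (Wigginton-style exact test, two-sided
    by probability mass).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise DataError("negative genotype count")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise DataError("all genotype counts zero")
    n_A = 2 * n_AA + n_Aa
    n_rare = min(n_A, 2 * n - n_A)
    # possible het counts share the parity of the rare-allele count
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hom_rare = (n_rare - hets) // 2
    hom_common = n - hets - hom_rare
    logp = (
        gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hom_common + 1)
        + hets * np.log(2.0)
    )
    logp -= gammaln(2 * n + 1) - gammaln(n_rare + 1) - gammaln(2 * n - n_rare + 1)
    probs = np.exp(logp)
    probs /= probs.sum()  # guard accumulated rounding
    obs = probs[np.flatnonzero(hets == n_Aa)[0]]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def marker_stats(g: GenotypeMatrix) -> MarkerStats:
    """Call rate, allele frequency, MAF, heterozygosity and HWE p per SNP."""
    obs = g.observed()
    called = obs.sum(axis=0)
    n_ind = g.n_individuals
    call_rate = called / n_ind
    p = g.allele_freq()
    maf = np.minimum(p, 1 - p)
    het = np.where(called > 0, np.where(obs, g.X == 1, False).sum(axis=0) / np.maximum(called, 1), np.nan)
    hwe = np.ones(g.n_markers)
    for j in range(g.n_markers):
        col = g.X[obs[:, j], j]
        if len(col) == 0:
            hwe[j] = np.nan
            continue
        hwe[j] = hwe_exact_pvalue(
            int((col == 2).sum()), int((col == 1).sum()), int((col == 0).sum())
        )
    return MarkerStats(g.markers.ids, call_rate, p, maf, het, hwe)


def hwe_chisq_pvalue(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """One-degree-of-freedom chi-squared HWE test (offered as an alternative)."""
    from scipy.stats import chi2

    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise DataError("all genotype counts zero")
    p = (2 * n_AA + n_Aa) / (2 * n)
    q = 1 - p
    if p == 0 or q == 0:
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_AA, n_Aa, n_aa])
    stat = ((obs - exp) ** 2 / exp).sum()
    return float(chi2.sf(stat, df=1))


def marker_qc(
    g: GenotypeMatrix,
    min_call: float = 0.95,
    min_maf: float = 0.05,
    hwe_alpha: float = 1e-5,
    hwe_test: str = "exact",
) -> tuple[GenotypeMatrix, MarkerStats, QCLedger]:
    """Sequential per-marker QC: call rate, then MAF, then HWE.

    A SNP removed at one step is not re-tested at the next, so the ledger
    decomposes the total removed count by cause.  Thresholds are inclusive:
    retained SNPs have call rate >= ``min_call``, MAF >= ``min_maf`` and HWE
    p-value > ``hwe_alpha``.
    """
    if hwe_test not in ("exact", "chisq"):
        raise DataError("hwe_test must be 'exact' or 'chisq'")
    ledger = QCLedger("markers", g.n_markers)
    obs = g.observed()
    call_rate = obs.sum(axis=0) / g.n_individuals
    alive = call_rate >= min_call
    ledger.add("call_rate", min_call, int((~alive).sum()))

    p = g.allele_freq()
    maf = np.minimum(p, 1 - p)
    drop_maf = alive & ~(maf >= min_maf)  # NaN-freq SNPs fail too
    ledger.add("maf", min_maf, int(drop_maf.sum()))
    alive &= ~drop_maf

    hwe_fn = hwe_exact_pvalue if hwe_test == "exact" else hwe_chisq_pvalue
    drop_hwe = np.zeros_like(alive)
    for j in np.flatnonzero(alive):
        col = g.X[obs[:, j], j]
        pval = hwe_fn(int((col == 2).sum()), int((col == 1).sum()), int((col == 0).sum()))
        if not pval > hwe_alpha:
            drop_hwe[j] = True
    ledger.add("hwe", hwe_alpha, int(drop_hwe.sum()))
    alive &= ~drop_hwe

    out = g.subset(markers_idx=np.flatnonzero(alive))
    return out, marker_stats(out), ledger


def _sire_daughter_index(
    g: GenotypeMatrix, ped: Pedigree
) -> list[tuple[int, np.ndarray]]:
    """(sire_row, daughter_rows) for each genotyped sire with genotyped daughters."""
    row_of = {ind: i for i, ind in enumerate(g.individuals)}
    sire_of = ped.sire_of()
    fam: dict[str, list[int]] = {}
    for ind, i in row_of.items():
        s = sire_of.get(ind)
        if s is not None and s in row_of:
            fam.setdefault(s, []).append(i)
    return [(row_of[s], np.array(d)) for s, d in sorted(fam.items())]


def mendelian_clean(
    g: GenotypeMatrix, ped: Pedigree, max_sire_conflict_fraction: float = 0.05
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Blank sire-daughter opposing-homozygote conflicts.

    A conflict is a SNP where sire and daughter are homozygous for opposite
    alleles (dosages 0 vs 2).  The daughter's genotype is set missing; if one
    sire conflicts with more than ``max_sire_conflict_fraction`` of his
    genotyped daughters at a SNP, the sire genotype is blanked instead and
    the daughters kept.  Returns the cleaned matrix and a per-(SNP, sire)
    conflict report.
    """
    out = g.copy()
    report_rows = []
    for sire_row, d_rows in _sire_daughter_index(g, ped):
        sire_g = g.X[sire_row]
        dg = g.X[d_rows]
        conflict = ((sire_g == 2) & (dg == 0)) | ((sire_g == 0) & (dg == 2))
        n_conf = conflict.sum(axis=0)
        genotyped = (dg != MISSING).sum(axis=0)
        for j in np.flatnonzero(n_conf):
            frac = n_conf[j] / genotyped[j]
            if frac > max_sire_conflict_fraction:
                out.X[sire_row, j] = MISSING
                resolution = "sire_blanked"
            else:
                out.X[d_rows[conflict[:, j]], j] = MISSING
                resolution = "daughters_blanked"
            report_rows.append(
                {
                    "snp": g.markers.ids[j],
                    "sire": g.individuals[sire_row],
                    "n_conflicts": int(n_conf[j]),
                    "n_genotyped_daughters": int(genotyped[j]),
                    "resolution": resolution,
                }
            )
    report = pd.DataFrame(
        report_rows,
        columns=["snp", "sire", "n_conflicts", "n_genotyped_daughters", "resolution"],
    )
    return out, report


def impute_from_sire(
    g: GenotypeMatrix,
    ped: Pedigree,
    iterations: int = 10,
    accept_prob: float = 0.95,
) -> GenotypeMatrix:
    """Deterministic sire + population-frequency imputation of missing daughters.

    For a missing daughter genotype with a genotyped sire, the paternal allele
    distribution comes from the sire genotype (homozygote: certain;
    heterozygote: 1/2 each) and the maternal allele from the current
    population reference-allele frequency ``p``.  The genotype posterior is
    the convolution of the two; the modal genotype is written only when its
    posterior probability reaches ``accept_prob`` — the threshold guards
    against over-imputing the most frequent allele.  After each full pass the
    frequencies are re-estimated from the updated matrix and the pass is
    repeated ``iterations`` times.  Observed genotypes are never overwritten.
    """
    if not accept_prob > 0.5:
        raise DataError("accept_prob must exceed 0.5 (ties would be admitted)")
    out = g.copy()
    families = _sire_daughter_index(g, ped)
    originally_missing = out.X == MISSING
    for _ in range(iterations):
        p = out.allele_freq()  # re-estimated from observed + imputed so far
        changed = False
        for sire_row, d_rows in families:
            sire_g = out.X[sire_row]
            for j in np.flatnonzero(sire_g != MISSING):
                pj = p[j]
                if np.isnan(pj):
                    continue
                targets = d_rows[out.X[d_rows, j] == MISSING]
                if len(targets) == 0:
                    continue
                if sire_g[j] == 2:
                    pat = np.array([0.0, 1.0])  # P(paternal allele = [alt, ref])
                elif sire_g[j] == 0:
                    pat = np.array([1.0, 0.0])
                else:
                    pat = np.array([0.5, 0.5])
                mat = np.array([1 - pj, pj])
                post = np.array(
                    [
                        pat[0] * mat[0],                      # dosage 0
                        pat[0] * mat[1] + pat[1] * mat[0],    # dosage 1
                        pat[1] * mat[1],                      # dosage 2
                    ]
                )
                mode = int(post.argmax())
                if post[mode] >= accept_prob:
                    out.X[targets, j] = mode
                    changed = True
        if not changed:
            break
    # contract: only originally-missing cells may differ from the input
    assert np.array_equal(out.X[~originally_missing], g.X[~originally_missing])
    return out
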