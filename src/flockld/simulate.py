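"""Forward-in-time Wright–Fisher simulator with recombination and half-sib sampling.

The simulator stands in for an undeposited SNP-array dataset: it produces a
population with a configurable (piecewise-constant, possibly declining)
effective-size trajectory, array-like ascertainment (MAF floor), a half-sib
family structure (few sires, many daughters out of distinct dams), plus the
complete truth needed to validate every pipeline stage — true phase, true
pedigree, the per-meiosis transmitted alleles, and the realized Ne history.

Model
-----
Discrete non-overlapping generations of ``N(t)`` diploids; each offspring
draws two parents uniformly with replacement.  Founders start in linkage
equilibrium with allele frequencies uniform on [0.1, 0.9]; there is no
mutation afterwards, so polymorphism comes from founder variation and drift
(array SNPs are pre-ascertained sites, and this keeps allele bookkeeping
exact).  Gametes recombine as a no-interference crossover process on the
genetic map, implemented marker-to-marker with Haldane switch probabilities
``r = (1 - exp(-2d))/2`` for adjacent-interval distance ``d`` Morgans — the
exact marker-resolution marginal of Poisson-count, uniformly-placed
crossovers.  A burn-in of ``4 x N`` generations before the trajectory epoch
lets LD reach drift-recombination equilibrium.  Everything is deterministic
given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import (
    MATERNAL,
    MISSING,
    PATERNAL,
    DataError,
    GenotypeMatrix,
    HaplotypeSet,
    MarkerMap,
    Pedigree,
)

import pandas as pd


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic population.

    Defaults are desk-scale: 4 chromosomes x 500 SNPs x 100 cM at N <= 200,
    a declining trajectory, and a 16-sire half-sib design scaled down to 8
    sires x 40 daughters.  ``bp_per_cm`` fixes the physical map at 1 Mb/cM so
    physical and genetic distance are proportional unless overridden.
    """

    ne_trajectory: tuple[tuple[int, int], ...] = ((0, 150), (50, 100), (100, 60), (150, 60))
    n_chromosomes: int = 4
    snps_per_chromosome: int = 500
    candidate_snp_factor: int = 4
    chromosome_length_cm: float = 100.0
    n_sires: int = 8
    daughters_per_sire: int = 40
    missing_rate: float = 0.01
    genotype_error_rate: float = 0.001
    ascertainment_maf: float = 0.05
    bp_per_cm: int = 1_000_000
    burnin_factor: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.ne_trajectory:
            raise DataError("ne_trajectory must be non-empty")
        gens = [g for g, _ in self.ne_trajectory]
        if gens != sorted(gens) or len(set(gens)) != len(gens):
            raise DataError("trajectory generations must be strictly increasing")
        if gens[0] != 0:
            raise DataError("trajectory must start at generation 0")
        if any(n <= 1 for _, n in self.ne_trajectory):
            raise DataError("population sizes must exceed 1")
        for r in (self.missing_rate, self.genotype_error_rate):
            if not 0 <= r < 1:
                raise DataError("rates must be in [0, 1)")
        if min(self.n_chromosomes, self.snps_per_chromosome, self.n_sires,
               self.daughters_per_sire) <= 0:
            raise DataError("counts must be positive")

    @property
    def epoch_length(self) -> int:
        return self.ne_trajectory[-1][0] + 1

    def n_at(self, t: int) -> int:
        """Diploid size at trajectory generation ``t`` (piecewise-constant)."""
        n = self.ne_trajectory[0][1]
        for g, size in self.ne_trajectory:
            if t >= g:
                n = size
        return n


@dataclass
class SimTruth:
    """Full truth emitted by :func:`simulate_population`."""

    config: SimConfig
    markers: MarkerMap
    haplotypes: np.ndarray        # final generation, shape (2N, m), int8
    true_ne: pd.DataFrame         # columns: generation (0 = oldest), N
    founder_freqs: np.ndarray

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0] // 2


def _marker_map(cfg: SimConfig) -> MarkerMap:
    # candidate loci: the simulator seeds more sites than the target panel
    # because drift (no mutation) fixes a large share during burn-in; the
    # MAF ascertainment step later thins survivors to the panel size, the
    # way a real array is designed from a larger discovery set
    m = cfg.snps_per_chromosome * cfg.candidate_snp_factor
    ids, chroms, bps, cms = [], [], [], []
    for c in range(1, cfg.n_chromosomes + 1):
        # SNPs evenly spaced; first at one spacing from the origin
        spacing_cm = cfg.chromosome_length_cm / m
        for j in range(m):
            cm = (j + 1) * spacing_cm
            ids.append(f"snp_{c}_{j + 1}")
            chroms.append(c)
            bps.append(int(round(cm * cfg.bp_per_cm)))
            cms.append(cm)
    return MarkerMap(
        np.array(ids, dtype=object),
        np.array(chroms),
        np.array(bps),
        np.array(cms, dtype=float),
    )


def _recomb_probs(markers: MarkerMap) -> list[np.ndarray]:
    """Adjacent-interval Haldane switch probabilities per chromosome."""
    probs = []
    for c in markers.chromosomes():
        idx = markers.chrom_indices(int(c))
        d_morgan = np.diff(markers.cm[idx]) / 100.0
        probs.append(0.5 * (1.0 - np.exp(-2.0 * d_morgan)))
    return probs


def _meiose(
    parents_H: np.ndarray,
    parent_idx: np.ndarray,
    chrom_slices: list[np.ndarray],
    rprobs: list[np.ndarray],
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized meiosis: one gamete per entry of ``parent_idx``.

    ``parents_H`` has two consecutive rows per parent (2i, 2i+1).  For each
    gamete and chromosome a random starting strand is chosen and strand
    switches occur between adjacent markers with the Haldane probabilities.
    """
    k = len(parent_idx)
    m_total = parents_H.shape[1]
    gametes = np.empty((k, m_total), dtype=np.int8)
    h0 = parents_H[2 * parent_idx]
    h1 = parents_H[2 * parent_idx + 1]
    for idx, rp in zip(chrom_slices, rprobs):
        m = len(idx)
        switch = np.empty((k, m), dtype=bool)
        switch[:, 0] = rng.random(k) < 0.5          # random starting strand
        switch[:, 1:] = rng.random((k, m - 1)) < rp
        strand = np.cumsum(switch, axis=1) & 1       # 0/1 strand per marker
        sub0, sub1 = h0[:, idx], h1[:, idx]
        gametes[:, idx] = np.where(strand == 0, sub0, sub1)
    return gametes


def simulate_population(cfg: SimConfig) -> SimTruth:
    """Run burn-in plus the trajectory epoch; return the final generation.

    Burn-in lasts ``burnin_factor x N(0)`` generations at the oldest size so
    linkage disequilibrium equilibrates before the epoch of interest.
    """
    rng = np.random.default_rng(cfg.seed)
    markers = _marker_map(cfg)
    chrom_slices = [markers.chrom_indices(int(c)) for c in markers.chromosomes()]
    rprobs = _recomb_probs(markers)
    m_total = len(markers)

    founder_freqs = rng.uniform(0.1, 0.9, size=m_total)
    n0 = cfg.ne_trajectory[0][1]
    H = (rng.random((2 * n0, m_total)) < founder_freqs).astype(np.int8)

    burnin = cfg.burnin_factor * n0
    sizes = [n0] * burnin + [cfg.n_at(t) for t in range(cfg.epoch_length)]
    ne_rows = []
    for step, n_next in enumerate(sizes):
        n_cur = H.shape[0] // 2
        sire_idx = rng.integers(0, n_cur, size=n_next)
        dam_idx = rng.integers(0, n_cur, size=n_next)
        pat = _meiose(H, sire_idx, chrom_slices, rprobs, rng)
        mat = _meiose(H, dam_idx, chrom_slices, rprobs, rng)
        H = np.empty((2 * n_next, m_total), dtype=np.int8)
        H[0::2] = pat
        H[1::2] = mat
        if step >= burnin:
            ne_rows.append({"generation": step - burnin, "N": n_next})
    return SimTruth(cfg, markers, H, pd.DataFrame(ne_rows), founder_freqs)


@dataclass
class HalfSibSample:
    """Genotyped half-sib study sample with its truth."""

    genotypes: GenotypeMatrix      # sires + daughters (dams not genotyped)
    pedigree: Pedigree
    true_phase: HaplotypeSet       # sires' and daughters' true haplotypes
    kept_markers: np.ndarray       # indices into the simulated marker map
    candidate_maf: np.ndarray      # pre-ascertainment MAF of every candidate
    transmissions: pd.DataFrame    # per-meiosis record: offspring, parent, role


def sample_halfsib(truth: SimTruth, cfg: SimConfig | None = None) -> HalfSibSample:
    """Draw the half-sib daughter design from the final generation.

    ``n_sires`` individuals become sires; each is mated to
    ``daughters_per_sire`` distinct dams (one daughter per dam; dams are not
    genotyped, matching the study design).  SNPs whose MAF in the genotyped
    sample falls below ``ascertainment_maf`` are dropped, emulating array
    ascertainment.  Daughter haplotypes are true meioses from the simulated
    parents, so the emitted phase and transmission record are exact.
    """
    cfg = cfg or truth.config
    rng = np.random.default_rng(cfg.seed + 1)
    n_pop = truth.n_individuals
    if n_pop < max(2, cfg.n_sires):
        raise DataError(
            f"final generation has {n_pop} individuals; need at least "
            f"{max(2, cfg.n_sires)} for {cfg.n_sires} sires"
        )
    sires = rng.permutation(n_pop)[: cfg.n_sires]
    # The genotyped census is one generation below the last modeled one and
    # much larger than N (as in a commercial flock): dams are fresh,
    # distinct offspring of random final-generation parents.
    need_dams = cfg.n_sires * cfg.daughters_per_sire

    markers = truth.markers
    chrom_slices = [markers.chrom_indices(int(c)) for c in markers.chromosomes()]
    rprobs = _recomb_probs(markers)

    ids: list[str] = []
    hap_rows: list[np.ndarray] = []
    carriers: list[tuple[str, str]] = []
    ped_rows: list[dict] = []
    trans_rows: list[dict] = []

    sire_names = [f"sire_{k + 1}" for k in range(cfg.n_sires)]
    for name, pidx in zip(sire_names, sires):
        ids.append(name)
        hap_rows.append(truth.haplotypes[2 * pidx])
        carriers.append((name, PATERNAL))
        hap_rows.append(truth.haplotypes[2 * pidx + 1])
        carriers.append((name, MATERNAL))
        ped_rows.append({"id": name, "sire": None, "dam": None, "birth_year": 2000})

    # dam genomes: one meiosis from each of two random final-gen parents
    dam_p1 = rng.integers(0, n_pop, size=need_dams)
    dam_p2 = rng.integers(0, n_pop, size=need_dams)
    dam_H = np.empty((2 * need_dams, len(markers)), dtype=np.int8)
    dam_H[0::2] = _meiose(truth.haplotypes, dam_p1, chrom_slices, rprobs, rng)
    dam_H[1::2] = _meiose(truth.haplotypes, dam_p2, chrom_slices, rprobs, rng)

    d = 0
    for k, sidx in enumerate(sires):
        sname = sire_names[k]
        for _ in range(cfg.daughters_per_sire):
            dname = f"d_{k + 1}_{d + 1}"
            didx = d
            d += 1
            pat = _meiose(truth.haplotypes, np.array([sidx]), chrom_slices, rprobs, rng)[0]
            mat = _meiose(dam_H, np.array([didx]), chrom_slices, rprobs, rng)[0]
            ids.append(dname)
            hap_rows.append(pat)
            carriers.append((dname, PATERNAL))
            hap_rows.append(mat)
            carriers.append((dname, MATERNAL))
            ped_rows.append(
                {"id": dname, "sire": sname, "dam": None, "birth_year": 2005}
            )
            trans_rows.append({"offspring": dname, "parent": sname, "role": "sire"})
    H = np.vstack(hap_rows)
    X = (H[0::2] + H[1::2]).astype(np.int8)

    # array ascertainment on the genotyped sample, then even thinning of the
    # surviving candidates down to the target panel size per chromosome
    freq = X.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)
    keep = np.flatnonzero(maf >= cfg.ascertainment_maf)
    thinned: list[np.ndarray] = []
    for c in markers.chromosomes():
        on_c = keep[markers.chrom[keep] == c]
        if len(on_c) > cfg.snps_per_chromosome:
            sel = np.linspace(0, len(on_c) - 1, cfg.snps_per_chromosome).round().astype(int)
            on_c = on_c[np.unique(sel)]
        thinned.append(on_c)
    keep = np.concatenate(thinned)
    kept_map = markers.subset(keep)

    g = GenotypeMatrix(ids, kept_map, X[:, keep])
    phase = HaplotypeSet(H[:, keep], carriers, kept_map)
    ped = Pedigree(pd.DataFrame(ped_rows, columns=["id", "sire", "dam", "birth_year"]))
    return HalfSibSample(g, ped, phase, keep, maf, pd.DataFrame(trans_rows))


def degrade(
    g: GenotypeMatrix, missing_rate: float, error_rate: float, seed: int
) -> GenotypeMatrix:
    """Apply missingness then genotyping error, independently per entry.

    Each entry is set missing with ``missing_rate``; each surviving entry is
    replaced with a uniformly-chosen *different* dosage with ``error_rate``.
    Deterministic given the seed.
    """
    for r in (missing_rate, error_rate):
        if not 0 <= r <= 1:
            raise DataError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = g.copy()
    drop = rng.random(out.X.shape) < missing_rate
    out.X[drop] = MISSING
    if error_rate > 0:
        err = (rng.random(out.X.shape) < error_rate) & ~drop & (out.X != MISSING)
        # uniform among the two other dosages
        shift = rng.integers(1, 3, size=out.X.shape)
        out.X[err] = ((out.X[err] + shift[err]) % 3).astype(np.int8)
    return out
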