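"""QC: filters, the exact HWE test vs a brute-force oracle, Mendelian
cleaning and sire imputation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flockld.datamodel import MISSING, DataError, GenotypeMatrix
from flockld.qc import (
    filter_individuals,
    hwe_exact_pvalue,
    impute_from_sire,
    marker_qc,
    marker_stats,
    mendelian_clean,
)

from .conftest import make_pedigree, toy_markers


def geno(X) -> GenotypeMatrix:
    X = np.asarray(X, dtype=np.int8)
    return GenotypeMatrix(
        [f"i{k}" for k in range(X.shape[0])], toy_markers(X.shape[1]), X
    )


def hwe_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Independent enumeration oracle: probability of each genotype table
    conditional on n and the allele count, via exact rational weights."""
    n = n_AA + n_Aa + n_aa
    n_A = 2 * n_AA + n_Aa
    configs = []
    for het in range(n + 1):
        aa2 = n_A - het  # 2 * n_AA
        if aa2 < 0 or aa2 % 2:
            continue
        nAA = aa2 // 2
        naa = n - nAA - het
        if naa < 0:
            continue
        w = (
            math.factorial(n)
            // (math.factorial(nAA) * math.factorial(het) * math.factorial(naa))
            * 2**het
        )
        configs.append((het, w))
    total = sum(w for _, w in configs)
    obs_w = dict(configs)[n_Aa]
    return sum(w for _, w in configs if w <= obs_w) / total


class TestHWEExact:
    @pytest.mark.parametrize(
        "counts,expected",
        [((1, 0, 1), 1 / 3), ((0, 2, 0), 1.0), ((5, 0, 0), 1.0)],
    )
    def test_small_cases(self, counts, expected):
        assert hwe_exact_pvalue(*counts) == pytest.approx(expected)

    def test_matches_enumeration_oracle_exhaustively(self):
        """Every genotype table with n <= 25 agrees with the oracle."""
        for n in range(1, 26):
            for n_AA in range(n + 1):
                for n_Aa in range(n - n_AA + 1):
                    n_aa = n - n_AA - n_Aa
                    got = hwe_exact_pvalue(n_AA, n_Aa, n_aa)
                    want = hwe_oracle(n_AA, n_Aa, n_aa)
                    assert got == pytest.approx(want, rel=1e-9), (n_AA, n_Aa, n_aa)

    def test_all_zero_rejected(self):
        with pytest.raises(DataError):
            hwe_exact_pvalue(0, 0, 0)


class TestFilterIndividuals:
    def test_boundary_is_strictly_greater(self):
        X = np.ones((3, 100), dtype=np.int8)
        X[0, :11] = MISSING  # 11% -> removed
        X[1, :10] = MISSING  # exactly 10% -> retained
        g, ledger = filter_individuals(geno(X), 0.10)
        assert g.individuals == ["i1", "i2"]
        assert ledger.steps[0].removed == 1

    def test_no_missing_removes_none(self):
        g, ledger = filter_individuals(geno(np.ones((4, 10))), 0.10)
        assert ledger.steps[0].removed == 0
        assert ledger.remaining == 4


class TestMarkerQC:
    def build_panel(self):
        """10 SNPs: 2 low call rate, 3 low MAF, 1 HWE-failing, 4 clean."""
        rng = np.random.default_rng(5)
        n = 60
        cols = []
        # 4 clean SNPs near HWE with maf ~0.4
        for _ in range(4):
            cols.append(rng.choice([0, 1, 2], size=n, p=[0.36, 0.48, 0.16]))
        # 2 low call-rate (50% missing), otherwise clean
        for _ in range(2):
            c = rng.choice([0, 1, 2], size=n, p=[0.36, 0.48, 0.16])
            c[: n // 2] = MISSING
            cols.append(c)
        # 3 low MAF (one alt allele in the whole sample)
        for _ in range(3):
            c = np.zeros(n)
            c[0] = 1
            cols.append(c)
        # 1 extreme HWE failure: all heterozygous
        cols.append(np.ones(n))
        X = np.stack(cols, axis=1).astype(np.int8)
        return geno(X)

    def test_sequential_ledger(self):
        g, stats, ledger = marker_qc(self.build_panel())
        removed = [s.removed for s in ledger.steps]
        assert removed == [2, 3, 1]
        assert ledger.remaining == 4
        assert g.n_markers == 4
        # conservation at every step
        prev = ledger.initial
        for s in ledger.steps:
            assert s.remaining == prev - s.removed
            prev = s.remaining

    def test_maf_boundary_inclusive(self):
        # 10 individuals, exactly one het in ten -> maf 0.05 retained
        X = np.zeros((10, 1), dtype=np.int8)
        X[0, 0] = 1
        g, _, ledger = marker_qc(geno(X), min_call=0.5, min_maf=0.05, hwe_alpha=1e-5)
        assert g.n_markers == 1

    def test_low_call_not_counted_at_maf_step(self):
        X = np.zeros((10, 1), dtype=np.int8)  # maf 0 AND low call
        X[:6, 0] = MISSING
        _, _, ledger = marker_qc(geno(X))
        assert [s.removed for s in ledger.steps] == [1, 0, 0]


class TestMendelianClean:
    def ped_for(self, n):
        return make_pedigree(
            [("S", None, None, 2000)]
            + [(f"d{k}", "S", None, 2001) for k in range(n)]
        )

    def setup_method(self):
        self.ped = self.ped_for(10)

    def matrix(self, sire, daughters):
        X = np.array([[sire]] + [[d] for d in daughters], dtype=np.int8)
        g = GenotypeMatrix(
            ["S"] + [f"d{k}" for k in range(len(daughters))], toy_markers(1), X
        )
        return g

    def test_opposing_homozygote_blanks_daughter(self):
        # 1 conflict among 40 daughters: below the sire-majority fraction
        g = self.matrix(2, [0] + [2] * 39)
        out, report = mendelian_clean(g, self.ped_for(40))
        assert out.X[1, 0] == MISSING
        assert out.X[0, 0] == 2
        assert report.iloc[0]["resolution"] == "daughters_blanked"

    def test_shared_allele_no_conflict(self):
        g = self.matrix(2, [1] * 10)
        out, report = mendelian_clean(g, self.ped)
        assert len(report) == 0
        assert np.array_equal(out.X, g.X)

    def test_majority_conflict_blanks_sire(self):
        g = self.matrix(2, [0] * 10)
        out, report = mendelian_clean(g, self.ped)
        assert out.X[0, 0] == MISSING
        assert np.all(out.X[1:, 0] == 0)
        assert report.iloc[0]["resolution"] == "sire_blanked"


class TestImputeFromSire:
    def run_one(self, sire_dose, other_doses, accept=0.95):
        """One missing daughter + filler individuals fixing the frequency."""
        ped = make_pedigree(
            [("S", None, None, 2000), ("d0", "S", None, 2001)]
        )
        X = np.array([[sire_dose], [MISSING]] + [[d] for d in other_doses], dtype=np.int8)
        g = GenotypeMatrix(
            ["S", "d0"] + [f"f{k}" for k in range(len(other_doses))],
            toy_markers(1),
            X,
        )
        return impute_from_sire(g, ped, accept_prob=accept).X[1, 0]

    def test_high_frequency_imputes(self):
        # sire hom ref, p(ref) ~ 0.99 -> posterior 0.99 for dosage 2
        fillers = [2] * 49 + [1]  # p = (1 + 2 + 98) / 102
        assert self.run_one(2, fillers) == 2

    def test_moderate_frequency_stays_missing(self):
        fillers = [2] * 8 + [1, 1]  # p(ref) = 0.9 over sire+fillers
        assert self.run_one(2, fillers) == MISSING

    def test_het_sire_uninformative(self):
        fillers = [1] * 10  # p = 0.5
        assert self.run_one(1, fillers) == MISSING

    def test_accept_prob_must_exceed_half(self):
        ped = make_pedigree([("S", None, None, 2000), ("d0", "S", None, 2001)])
        g = GenotypeMatrix(["S", "d0"], toy_markers(1), np.array([[2], [MISSING]], dtype=np.int8))
        with pytest.raises(DataError):
            impute_from_sire(g, ped, accept_prob=0.5)

    def test_never_overwrites_observed(self, small_halfsib):
        cfg, sample = small_halfsib
        from flockld.simulate import degrade

        g = degrade(sample.genotypes, 0.05, 0.0, seed=4)
        out = impute_from_sire(g, sample.pedigree)
        obs = g.X != MISSING
        assert np.array_equal(out.X[obs], g.X[obs])
        # imputed dosages are Mendelian-consistent with the sire
        sire_of = sample.pedigree.sire_of()
        row = {ind: i for i, ind in enumerate(g.individuals)}
        imputed = (g.X == MISSING) & (out.X != MISSING)
        for ind, s in sire_of.items():
            if s is None or s not in row:
                continue
            for j in np.flatnonzero(imputed[row[ind]]):
                sd, dd = out.X[row[s], j], out.X[row[ind], j]
                if sd == 2:
                    assert dd >= 1
                elif sd == 0:
                    assert dd <= 1

    def test_imputation_calibration(self, small_halfsib):
        """Accuracy of imputed genotypes >= accept_prob on simulated truth."""
        cfg, sample = small_halfsib
        from flockld.simulate import degrade

        g_true = sample.genotypes
        g = degrade(g_true, 0.10, 0.0, seed=9)
        out = impute_from_sire(g, sample.pedigree, accept_prob=0.80)
        filled = (g.X == MISSING) & (out.X != MISSING)
        assert filled.sum() > 100
        acc = (out.X[filled] == g_true.X[filled]).mean()
        assert acc >= 0.75  # accept_prob minus sampling slack


class TestMarkerStatsInvariants:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_maf_bounds_and_call_count(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.choice([0, 1, 2, MISSING], size=(12, 8), p=[0.3, 0.3, 0.3, 0.1])
        g = geno(X)
        st_ = marker_stats(g)
        ok = ~np.isnan(st_.maf)
        assert np.all(st_.maf[ok] <= 0.5 + 1e-12)
        assert np.all(st_.maf[ok] >= 0)
        counts = st_.call_rate * g.n_individuals
        assert np.allclose(counts, np.round(counts))
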