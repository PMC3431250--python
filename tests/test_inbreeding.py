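"""Pedigree F (Meuwissen-Luo vs kinship recursion oracle) and marker F."""

import numpy as np
import pandas as pd
import pytest

from flockld.datamodel import MISSING, GenotypeMatrix
from flockld.inbreeding import f_markers, f_pedigree, inbreeding_trend

from .conftest import make_pedigree, toy_markers


def kinship_oracle_F(ped):
    """Inbreeding via the classic recursive coancestry (Malécot kinship):
    f(a,b) for a younger = (f(sa,b)+f(da,b))/2, f(a,a) = (1+f(sa,da))/2,
    unknown parents contribute 0.  Independent of the Meuwissen-Luo route."""
    parents = ped.parent_map()
    order = {ind: k for k, ind in enumerate(ped.topological_order())}
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def f(a, b):
        if a is None or b is None:
            return 0.0
        if a == b:
            sa, da = parents[a]
            return 0.5 * (1.0 + f(*_sorted(sa, da)))
        # recurse on the younger of the two
        if order.get(a, -1) < order.get(b, -1):
            a, b = b, a
        sa, da = parents.get(a, (None, None))
        return 0.5 * (f(*_sorted(sa, b)) + f(*_sorted(da, b)))

    def _sorted(x, y):
        if x is None or y is None:
            return x, y
        return (x, y) if order.get(x, -1) <= order.get(y, -1) or x == y else (y, x)

    return {ind: f(*_sorted(*parents[ind])) for ind in parents}


class TestPedigreeF:
    def test_parent_offspring_mating(self):
        ped = make_pedigree(
            [
                ("A", None, None, None),
                ("B", None, None, None),
                ("C", "A", "B", None),
                ("D", "A", "C", None),
            ]
        )
        assert f_pedigree(ped)["D"] == pytest.approx(0.25)

    def test_half_sib_mating(self):
        ped = make_pedigree(
            [
                ("S", None, None, None),
                ("D1", None, None, None),
                ("D2", None, None, None),
                ("H1", "S", "D1", None),
                ("H2", "S", "D2", None),
                ("X", "H1", "H2", None),
            ]
        )
        assert f_pedigree(ped)["X"] == pytest.approx(0.125)

    def test_first_cousin_mating(self):
        ped = make_pedigree(
            [
                ("GA", None, None, None),
                ("GB", None, None, None),
                ("P1", "GA", "GB", None),
                ("P2", "GA", "GB", None),
                ("M1", None, None, None),
                ("M2", None, None, None),
                ("C1", "P1", "M1", None),
                ("C2", "P2", "M2", None),
                ("K", "C1", "C2", None),
            ]
        )
        assert f_pedigree(ped)["K"] == pytest.approx(0.0625)

    def test_founders_and_outbred_zero(self):
        ped = make_pedigree(
            [
                ("A", None, None, None),
                ("B", None, None, None),
                ("C", "A", "B", None),
            ]
        )
        F = f_pedigree(ped)
        assert F["A"] == 0 and F["B"] == 0 and F["C"] == 0

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_kinship_oracle_on_random_pedigrees(self, seed):
        """Random pedigrees of <= 12 individuals, exact agreement."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 13))
        rows = []
        ids = [f"x{k}" for k in range(n)]
        for k, ind in enumerate(ids):
            if k < 2 or rng.random() < 0.25:
                rows.append((ind, None, None, None))
            else:
                s, d = rng.choice(k, size=2, replace=True)
                rows.append(
                    (
                        ind,
                        ids[int(s)],
                        ids[int(d)] if d != s else None,
                        None,
                    )
                )
        ped = make_pedigree(rows)
        got = f_pedigree(ped)
        want = kinship_oracle_F(ped)
        for ind in ids:
            assert got[ind] == pytest.approx(want[ind], abs=1e-12), ind


class TestMarkerF:
    def test_all_het_gives_minus_one(self):
        g = GenotypeMatrix(["i"], toy_markers(5), np.ones((1, 5), dtype=np.int8))
        F = f_markers(g, np.full(5, 0.5))
        assert F.loc["i", "F1"] == pytest.approx(-1)
        assert F.loc["i", "F2"] == pytest.approx(-1)
        assert F.loc["i", "F3"] == pytest.approx(-1)

    def test_all_hom_ref_gives_one(self):
        g = GenotypeMatrix(["i"], toy_markers(5), np.full((1, 5), 2, dtype=np.int8))
        F = f_markers(g, np.full(5, 0.5))
        for m in ("F1", "F2", "F3"):
            assert F.loc["i", m] == pytest.approx(1)

    def test_hand_arithmetic_two_snps(self):
        g = GenotypeMatrix(["i"], toy_markers(2), np.array([[0, 1]], dtype=np.int8))
        F = f_markers(g, np.array([0.5, 0.25]))
        assert F.loc["i", "F1"] == pytest.approx(1 / 3)
        assert F.loc["i", "F2"] == pytest.approx(-1 / 3)
        assert F.loc["i", "F3"] == pytest.approx(0.0)

    def test_fixed_snps_excluded_with_warning(self):
        g = GenotypeMatrix(
            ["i"], toy_markers(2), np.array([[2, 1]], dtype=np.int8)
        )
        with pytest.warns(UserWarning, match="excluded"):
            F = f_markers(g, np.array([1.0, 0.5]))
        assert F.loc["i", "F2"] == pytest.approx(-1)  # only the p=0.5 SNP used

    def test_missing_skipped_with_per_individual_m(self):
        X = np.array([[1, MISSING, 1]], dtype=np.int8)
        g = GenotypeMatrix(["i"], toy_markers(3), X)
        F = f_markers(g, np.full(3, 0.5))
        assert F.loc["i", "F2"] == pytest.approx(-1)

    def test_outbred_hwe_population_means_near_zero(self):
        """With true p supplied, estimator means over unrelated HWE
        individuals are 0 within 3 SE."""
        rng = np.random.default_rng(12)
        n, m = 300, 400
        p = rng.uniform(0.1, 0.9, size=m)
        X = (rng.random((n, m)) < p).astype(np.int8) + (
            rng.random((n, m)) < p
        ).astype(np.int8)
        g = GenotypeMatrix([f"i{k}" for k in range(n)], toy_markers(m), X)
        F = f_markers(g, p)
        for col in ("F1", "F2", "F3"):
            se = F[col].std(ddof=1) / np.sqrt(n)
            assert abs(F[col].mean()) < 3 * se + 1e-3

    def test_selfed_lines_recover_true_F(self):
        """After s selfing generations F = 1 - 0.5^s; all three estimators
        are unbiased within 3 SE when true p is supplied."""
        rng = np.random.default_rng(34)
        m = 600
        p = rng.uniform(0.2, 0.8, size=m)
        for s, f_true in ((1, 0.5), (2, 0.75)):
            n = 200
            X = np.empty((n, m), dtype=np.int8)
            for i in range(n):
                # draw the two alleles IBD with prob f_true, else independent
                ibd = rng.random(m) < f_true
                a1 = (rng.random(m) < p).astype(np.int8)
                a2 = np.where(ibd, a1, (rng.random(m) < p).astype(np.int8))
                X[i] = a1 + a2
            g = GenotypeMatrix([f"i{k}" for k in range(n)], toy_markers(m), X)
            F = f_markers(g, p)
            for col in ("F1", "F2", "F3"):
                se = F[col].std(ddof=1) / np.sqrt(n)
                assert F[col].mean() == pytest.approx(f_true, abs=3 * se + 1e-3), (s, col)

    def test_correlation_ordering_on_halfsib_data(self, small_halfsib):
        """corr(F2, F3) >= corr(F1, F2) on half-sib structured genotypes."""
        _, sample = small_halfsib
        F = f_markers(sample.genotypes)
        c23 = F["F2"].corr(F["F3"])
        c12 = F["F1"].corr(F["F2"])
        assert c23 >= c12


class TestTrend:
    def records(self):
        return pd.DataFrame(
            {
                "birth_year": [2001, 2001, 2002, 2002, 2002],
                "F1": [-0.02, 0.02, 0.05, 0.07, 0.10],
            }
        )

    def test_clamped_mean(self):
        t = inbreeding_trend(self.records())
        assert t.loc[t["birth_year"] == 2001, "F1_mean"].item() == pytest.approx(0.01)

    def test_unclamped_mean(self):
        t = inbreeding_trend(self.records(), clamp_negative=False)
        assert t.loc[t["birth_year"] == 2001, "F1_mean"].item() == pytest.approx(0.0)

    def test_fraction_over_threshold(self):
        t = inbreeding_trend(self.records())
        assert t.loc[t["birth_year"] == 2002, "F1_frac_over_0.0625"].item() == pytest.approx(2 / 3)
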