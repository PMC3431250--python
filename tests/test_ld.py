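"""Pairwise LD statistics, confidence bounds, decay binning, half-length
and non-syntenic background."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flockld.datamodel import MISSING, DataError, HaplotypeSet
from flockld.ld import (
    DECAY_BIN_EDGES_BP,
    dprime_ci,
    dprime_ci_batch,
    half_length_r2,
    ld_decay_table,
    nonsyntenic_ld,
    pair_counts,
    pair_ld,
    r2_by_mb_bin,
    syntenic_pair_table,
)

from .conftest import population_haplotypes, toy_markers

counts_strategy = st.tuples(
    st.integers(0, 60), st.integers(0, 60), st.integers(0, 60), st.integers(0, 60)
)


def polymorphic(c):
    n = sum(c)
    if n < 2:
        return False
    pA = (c[0] + c[1]) / n
    pB = (c[0] + c[2]) / n
    return 0 < pA < 1 and 0 < pB < 1


class TestPairLD:
    def test_hand_arithmetic(self):
        p = pair_ld((4, 1, 1, 4))
        assert p.D == pytest.approx(0.15)
        assert p.Dmax == pytest.approx(0.25)
        assert p.Dprime == pytest.approx(0.6)
        assert p.r2 == pytest.approx(0.36)

    def test_perfect_association(self):
        p = pair_ld((5, 0, 0, 5))
        assert p.Dprime == pytest.approx(1.0)
        assert p.r2 == pytest.approx(1.0)

    def test_independence(self):
        p = pair_ld((1, 1, 1, 1))
        assert p.D == 0 and p.Dprime == 0 and p.r2 == 0

    def test_monomorphic_rejected(self):
        with pytest.raises(DataError, match="monomorphic"):
            pair_ld((5, 5, 0, 0))

    @given(counts_strategy)
    @settings(max_examples=300, deadline=None)
    def test_r2_bounded_by_dprime_squared(self, c):
        if not polymorphic(c):
            return
        p = pair_ld(c)
        assert p.r2 <= p.Dprime**2 + 1e-9

    @given(counts_strategy)
    @settings(max_examples=150, deadline=None)
    def test_allele_relabeling_invariance(self, c):
        if not polymorphic(c):
            return
        p = pair_ld(c)
        # swap alleles at the first locus: (AB, Ab) <-> (aB, ab)
        q = pair_ld((c[2], c[3], c[0], c[1]))
        assert q.Dprime == pytest.approx(p.Dprime, abs=1e-12)
        assert q.r2 == pytest.approx(p.r2, abs=1e-12)
        assert abs(q.D) == pytest.approx(abs(p.D), abs=1e-12)
        # swap at the second locus too
        r = pair_ld((c[1], c[0], c[3], c[2]))
        assert r.Dprime == pytest.approx(p.Dprime, abs=1e-12)
        assert r.r2 == pytest.approx(p.r2, abs=1e-12)


def ci_oracle(counts, step=1e-4):
    """Fine-grid likelihood oracle for the |D'| bounds."""
    stats = pair_ld(counts)
    grid = np.arange(0.0, 1.0 + step / 2, step)
    sgn = 1.0 if stats.D >= 0 else -1.0
    pAB = stats.p_A * stats.p_B + sgn * grid * stats.Dmax
    probs = np.stack(
        [pAB, stats.p_A - pAB, stats.p_B - pAB, 1 - stats.p_A - stats.p_B + pAB],
        axis=1,
    ).clip(0, 1)
    ll = np.zeros(len(grid))
    for k, cnt in enumerate(counts):
        if cnt:
            with np.errstate(divide="ignore"):
                ll += np.where(probs[:, k] > 0, cnt * np.log(probs[:, k]), -np.inf)
    w = np.exp(ll - ll.max())
    w /= w.sum()
    cum = np.cumsum(w)
    CL = grid[np.flatnonzero(cum - w <= 0.05).max()]
    CU = grid[np.flatnonzero(cum >= 0.95).min()]
    return CL, CU


class TestDprimeCI:
    def test_strong_ld_pair(self):
        ci = dprime_ci((50, 0, 0, 50))
        assert ci.CL >= 0.70
        assert ci.CU >= 0.98

    def test_independent_pair(self):
        ci = dprime_ci((25, 25, 25, 25))
        assert ci.CU < 0.90

    def test_tiny_counts_wide(self):
        ci = dprime_ci((2, 1, 1, 2))
        assert ci.CU - ci.CL > 0.5

    @pytest.mark.parametrize(
        "counts", [(50, 0, 0, 50), (25, 25, 25, 25), (2, 1, 1, 2), (30, 5, 8, 40)]
    )
    def test_matches_fine_grid_oracle(self, counts):
        ci = dprime_ci(counts)
        CL, CU = ci_oracle(counts)
        assert ci.CL == pytest.approx(CL, abs=2e-3)
        assert ci.CU == pytest.approx(CU, abs=2e-3)

    @given(counts_strategy)
    @settings(max_examples=60, deadline=None)
    def test_batch_equals_scalar(self, c):
        if not polymorphic(c):
            return
        ci = dprime_ci(c)
        CL, CU = dprime_ci_batch(np.array([c], dtype=float))
        assert CL[0] == pytest.approx(ci.CL, abs=1e-12)
        assert CU[0] == pytest.approx(ci.CU, abs=1e-12)

    def test_bounds_bracket_mle_when_well_populated(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            c = tuple(int(x) for x in rng.integers(100, 400, size=4))
            p = pair_ld(c)
            ci = dprime_ci(c)
            assert ci.CL - 0.005 <= p.Dprime <= ci.CU + 0.005


class TestDecayTable:
    def test_bin_placement(self):
        pairs = pd.DataFrame(
            {
                "dist_bp": [5_000, 15_000, 15_000_000],
                "dprime": [0.5, 0.5, 0.5],
                "r2": [0.2, 0.2, 0.2],
            }
        )
        t = ld_decay_table(pairs)
        assert t.loc[t["bin"] == "<10kb", "n_pairs"].item() == 1
        assert t.loc[t["bin"] == "10-20kb", "n_pairs"].item() == 1
        assert t.loc[t["bin"] == "10-20Mb", "n_pairs"].item() == 1

    def test_boundary_half_open(self):
        pairs = pd.DataFrame({"dist_bp": [10_000], "dprime": [0.1], "r2": [0.1]})
        t = ld_decay_table(pairs)
        assert t.loc[t["bin"] == "10-20kb", "n_pairs"].item() == 1
        assert t.loc[t["bin"] == "<10kb", "n_pairs"].item() == 0

    def test_means_and_conservation(self):
        rng = np.random.default_rng(7)
        dist = rng.integers(1, 60_000_000, size=500)
        pairs = pd.DataFrame(
            {"dist_bp": dist, "dprime": rng.random(500), "r2": rng.random(500)}
        )
        t = ld_decay_table(pairs)
        assert t["n_pairs"].sum() == 500
        # cross-check one bin by hand
        lo, hi = 2_000_000, 5_000_000
        sel = pairs[(pairs["dist_bp"] >= lo) & (pairs["dist_bp"] < hi)]
        row = t[t["bin"] == "2-5Mb"].iloc[0]
        assert row["n_pairs"] == len(sel)
        assert row["r2_mean"] == pytest.approx(sel["r2"].mean())
        assert row["dprime_sd"] == pytest.approx(sel["dprime"].std(ddof=1))


class TestHalfLength:
    def test_exact_hit(self):
        v, d = half_length_r2([0.4, 0.3, 0.2, 0.1])
        assert v == pytest.approx(0.2)
        assert d == pytest.approx(2.5)

    def test_interpolated(self):
        v, d = half_length_r2([0.4, 0.1])
        assert d == pytest.approx(0.5 + (0.2 - 0.4) / (0.1 - 0.4) * 1.0)

    def test_no_decay_error(self):
        with pytest.raises(DataError, match="no decay"):
            half_length_r2([0.3, 0.3])


class TestPairCountsMissing:
    def test_missing_rows_excluded(self):
        mm = toy_markers(2)
        H = np.array(
            [[1, 1], [1, MISSING], [0, 0], [MISSING, 1], [1, 0]], dtype=np.int8
        )
        assert pair_counts(H, 0, 1) == (1, 1, 0, 1)

    def test_table_matches_per_pair_counting(self, small_halfsib):
        """Vectorized pair table agrees with explicit counting + pair_ld."""
        _, sample = small_halfsib
        h = sample.true_phase
        tab = syntenic_pair_table(h)
        idx = {s: k for k, s in enumerate(h.markers.ids)}
        for _, row in tab.sample(25, random_state=3).iterrows():
            c = pair_counts(h.H, idx[row["snp_i"]], idx[row["snp_j"]])
            p = pair_ld(c)
            assert row["r2"] == pytest.approx(p.r2, abs=1e-9)
            assert row["dprime"] == pytest.approx(p.Dprime, abs=1e-9)


class TestNonsyntenic:
    def test_sample_count_and_determinism(self, small_halfsib):
        _, sample = small_halfsib
        h = sample.true_phase
        a = nonsyntenic_ld(h, 0.05, seed=42)
        b = nonsyntenic_ld(h, 0.05, seed=42)
        assert a == b
        per_chrom = [
            int(np.ceil(0.05 * len(h.markers.chrom_indices(int(c)))))
            for c in h.markers.chromosomes()
        ]
        assert a["n_snps_sampled"] == sum(per_chrom)

    def test_background_matches_sampling_theory(self):
        """Mean between-chromosome r2 ~ 1/n when the drift floor 1/(3N) is
        negligible (large N, short history)."""
        from flockld.simulate import SimConfig, simulate_population

        cfg = SimConfig(
            ne_trajectory=((0, 1000), (10, 1000)),
            n_chromosomes=4,
            snps_per_chromosome=60,
            candidate_snp_factor=1,
            burnin_factor=0,  # unlinked LD equilibrates within ~10 generations
            seed=21,
        )
        truth = simulate_population(cfg)
        h = population_haplotypes(truth)
        rng = np.random.default_rng(5)
        rows = rng.choice(h.n, size=60, replace=False)
        sub = HaplotypeSet(h.H[rows], [h.carriers[r] for r in rows], h.markers)
        res = nonsyntenic_ld(sub, fraction=0.25, seed=33)
        n = sub.n
        se = res["r2_sd"] / np.sqrt(res["n_pairs"])
        assert res["r2_mean"] == pytest.approx(1.0 / n, abs=3 * se)
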