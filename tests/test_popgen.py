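import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_block
from oracles import hudson_fst_brute, pi_brute, tajimas_d_brute, watterson_brute

from polyte.core import GenotypePanel, PolyteError, PopulationAssignment
from polyte.popgen import (
    pairwise_fst,
    pairwise_pi,
    rod,
    tajima_constants,
    tajimas_d,
    tajimas_d_from_counts,
    watterson_theta,
    windowed_scan,
)


class TestPairwisePi:
    def test_identical_haplotypes_zero(self):
        block = make_block([[0, 1], [0, 1]])
        assert pairwise_pi(block)[0] == 0.0

    def test_three_haplotypes_enumeration(self):
        # {00, 01, 11}: pair diffs 1, 2, 1 -> mean 4/3
        block = make_block([[0, 0], [0, 1], [1, 1]])
        pi_raw, pi_bp = pairwise_pi(block)
        assert pi_raw == pytest.approx(4 / 3, abs=1e-12)
        assert pi_bp == pytest.approx((4 / 3) / 1000)

    def test_single_site_frequency_form(self):
        # alleles {0,0,1,1}: 4 of 6 pairs differ -> 2/3 = 2*(1/4)*(4/3)
        block = make_block([[0], [0], [1], [1]])
        assert pairwise_pi(block)[0] == pytest.approx(2 / 3, abs=1e-12)

    def test_requires_two_haplotypes(self):
        with pytest.raises(PolyteError):
            pairwise_pi(make_block([[0, 1]]))


class TestWatterson:
    def test_zero_sites(self):
        assert watterson_theta(0, 5) == 0.0

    def test_s5_n4(self):
        assert watterson_theta(5, 4) == pytest.approx(30 / 11, abs=1e-12)

    def test_s1_n2(self):
        assert watterson_theta(1, 2) == pytest.approx(1.0)

    def test_matches_rational_oracle(self):
        for S, n in [(3, 7), (10, 12), (1, 2), (17, 5)]:
            assert watterson_theta(S, n) == pytest.approx(watterson_brute(S, n), abs=1e-12)

    def test_rejects_n1(self):
        with pytest.raises(PolyteError):
            watterson_theta(3, 1)


class TestTajimasD:
    def test_no_segregating_sites_undefined(self):
        assert math.isnan(tajimas_d_from_counts(0.0, 0, 10))

    def test_small_n_undefined(self):
        assert math.isnan(tajimas_d_from_counts(1.0, 2, 3))

    def test_zero_when_pi_equals_theta(self):
        # n=4: 8 singleton columns (pi 1/2 each) + 3 doubleton columns
        # (pi 2/3 each) give pi_raw = 6 = 11 / a1(4) = theta_w exactly
        cols = [[1, 0, 0, 0]] * 8 + [[1, 1, 0, 0]] * 3
        m = np.array(cols, dtype=np.uint8).T
        block = make_block(m, positions=np.arange(11))
        pi_raw = pairwise_pi(block)[0]
        theta = watterson_theta(block.S, block.n)
        assert pi_raw == pytest.approx(6.0, abs=1e-12)
        assert theta == pytest.approx(6.0, abs=1e-12)
        assert tajimas_d(block) == pytest.approx(0.0, abs=1e-9)
        # exact-zero contract when the numerator is exactly zero
        assert tajimas_d_from_counts(theta, block.S, block.n) == 0.0

    def test_three_singletons_negative(self):
        m = np.zeros((4, 3), dtype=np.uint8)
        m[0, 0] = m[1, 1] = m[2, 2] = 1
        block = make_block(m)
        pi_raw = pairwise_pi(block)[0]
        assert pi_raw == pytest.approx(1.5)
        assert watterson_theta(3, 4) == pytest.approx(18 / 11)
        assert tajimas_d(block) < 0
        assert tajimas_d(block) == pytest.approx(tajimas_d_brute(m), abs=1e-12)

    def test_constants_harmonic(self):
        const = tajima_constants(10)
        assert const.a1 == pytest.approx(sum(1 / i for i in range(1, 10)))
        assert const.e1 > 0 and const.e2 > 0

    @settings(max_examples=60, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        S = int(rng.integers(1, 31))
        m = (rng.random((n, S)) < rng.uniform(0.1, 0.9)).astype(np.uint8)
        block = make_block(m, positions=np.arange(S))
        assert pairwise_pi(block)[0] == pytest.approx(pi_brute(m), abs=1e-9)
        d_pkg = tajimas_d(block)
        d_ref = tajimas_d_brute(m)
        if math.isnan(d_ref):
            assert math.isnan(d_pkg)
        else:
            assert d_pkg == pytest.approx(d_ref, abs=1e-9)


class TestFst:
    def test_fixed_difference_is_one(self):
        a = make_block([[0], [0]], prune=False)
        b = make_block([[1], [1]], prune=False)
        assert pairwise_fst(a, b) == pytest.approx(1.0)

    def test_symmetric_polymorphism_is_minus_one(self):
        a = make_block([[0], [1]])
        b = make_block([[0], [1]])
        assert pairwise_fst(a, b) == pytest.approx(-1.0)

    def test_shared_monomorphic_undefined(self):
        a = make_block([[0], [0]], prune=False)
        b = make_block([[0], [0]], prune=False)
        assert math.isnan(pairwise_fst(a, b))

    def test_label_swap_symmetry(self, rng):
        a = make_block((rng.random((5, 8)) < 0.3).astype(np.uint8), positions=np.arange(8))
        b = make_block((rng.random((7, 8)) < 0.6).astype(np.uint8), positions=np.arange(8))
        assert pairwise_fst(a, b) == pytest.approx(pairwise_fst(b, a), abs=1e-12)

    def test_matches_pair_enumeration_oracle(self, rng):
        for _ in range(20):
            a = (rng.random((4, 6)) < rng.uniform(0.2, 0.8)).astype(np.uint8)
            b = (rng.random((5, 6)) < rng.uniform(0.2, 0.8)).astype(np.uint8)
            ref = hudson_fst_brute(a, b)
            block_a = make_block(a, positions=np.arange(6), prune=False)
            block_b = make_block(b, positions=np.arange(6), prune=False)
            got = pairwise_fst(block_a, block_b)
            if math.isnan(ref):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(ref, abs=1e-9)

    def test_wc_estimator_fixed_difference(self):
        a = make_block([[0], [0], [0]], prune=False)
        b = make_block([[1], [1], [1]], prune=False)
        assert pairwise_fst(a, b, estimator="wc") == pytest.approx(1.0)


class TestRod:
    def test_equal_pi_zero(self):
        assert rod(0.004, 0.004) == 0.0

    def test_target_zero_one(self):
        assert rod(0.0, 0.004) == 1.0

    def test_half(self):
        assert rod(0.002, 0.004) == pytest.approx(0.5)

    def test_ref_zero_undefined(self):
        assert math.isnan(rod(0.001, 0.0))

    def test_strictly_decreasing_in_target(self):
        grid = np.linspace(0.0, 0.01, 25)
        values = [rod(pi_t, 0.01) for pi_t in grid]
        assert all(x > y for x, y in zip(values, values[1:]))


class TestWindowedScan:
    def _panel(self, positions, counts, samples):
        return GenotypePanel(
            chrom="chr1",
            positions=np.asarray(positions),
            counts=np.asarray(counts, dtype=np.int8),
            samples=samples,
        )

    def _pops(self, samples):
        half = len(samples) // 2
        return PopulationAssignment.from_pairs(
            [(s, "A") for s in samples[:half]] + [(s, "B") for s in samples[half:]]
        )

    def test_even_window_placement(self, rng):
        # 10 SNPs evenly spaced over 25,000 bp -> 5 windows x 2 SNPs
        positions = np.arange(10) * 2500 + 100
        counts = (rng.random((6, 10)) < 0.5).astype(np.int8) + (
            rng.random((6, 10)) < 0.5
        ).astype(np.int8)
        samples = [f"s{i}" for i in range(6)]
        win, _ = windowed_scan(
            self._panel(positions, counts, samples),
            self._pops(samples),
            window_bp=5000,
            step_bp=5000,
            maf_min=0.0,
            span_end=25_000,
        )
        per_window = win.groupby("start")["n_sites"].max()
        assert len(per_window) == 5

    def test_empty_window_row_present_undefined(self):
        samples = ["s0", "s1", "s2", "s3"]
        counts = [[1, 0], [0, 1], [1, 1], [0, 0]]
        win, _ = windowed_scan(
            self._panel([100, 8000], counts, samples),
            self._pops(samples),
            window_bp=5000,
            step_bp=5000,
            maf_min=0.0,
            span_end=15_000,
        )
        empty = win[win.start == 10_000]
        assert len(empty) == 2  # one row per population
        assert empty["pi_bp"].isna().all()
        assert empty["tajima_d"].isna().all()

    def test_empty_panel_rejected(self):
        samples = ["s0", "s1"]
        panel = GenotypePanel(
            chrom="chr1",
            positions=np.array([], dtype=np.int64),
            counts=np.zeros((2, 0), dtype=np.int8),
            samples=samples,
        )
        with pytest.raises(PolyteError):
            windowed_scan(panel, self._pops(samples))

    def test_maf_filter_drops_rare_sites(self):
        samples = [f"s{i}" for i in range(10)]
        counts = np.zeros((10, 2), dtype=np.int8)
        counts[0, 0] = 1  # freq 1/20 = 0.05
        counts[::2, 1] = 2  # freq 0.5, segregating within each population
        win, _ = windowed_scan(
            self._panel([10, 20], counts, samples),
            self._pops(samples),
            window_bp=100,
            step_bp=100,
            maf_min=0.06,
            span_end=100,
        )
        assert win["n_sites"].max() == 1

    def test_neutral_panel_mean_d_near_zero(self):
        from polyte.simulate import simulate_neutral_window

        rng = np.random.default_rng(7)
        ds = []
        for _ in range(500):
            block = simulate_neutral_window(10, 5.0, 1000, seed=rng)
            if block.S:
                ds.append(tajimas_d(block))
        mean = np.mean(ds)
        se = np.std(ds) / np.sqrt(len(ds))
        assert abs(mean) < 3 * se + 0.05
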