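import itertools

import numpy as np
import pandas as pd
import pytest

from pavpop import selection, synthdata
from pavpop.errors import DataError, ParameterError
from tests.conftest import make_haps


def brute_force_pi(alleles: np.ndarray, length: float) -> float:
    """Mean pairwise difference count over all haplotype pairs, per bp."""
    n = alleles.shape[0]
    diffs = [
        np.sum(alleles[i] != alleles[j]) for i, j in itertools.combinations(range(n), 2)
    ]
    return float(np.mean(diffs)) / length


class TestWindowPi:
    def test_single_polymorphic_site(self):
        # n=2 with differing alleles over a 10-bp window
        pi = selection.window_pi(
            np.array([5]), np.array([1.0]), np.array([2.0]), (0, 10)
        )
        assert pi == pytest.approx(0.1)

    def test_empty_window(self):
        pi = selection.window_pi(np.array([]), np.array([]), np.array([]), (0, 100))
        assert pi == 0.0

    def test_matches_brute_force_pairwise_oracle(self, rng):
        for _ in range(20):
            n_hap = int(rng.integers(2, 21))
            n_sites = int(rng.integers(1, 51))
            L = 1000
            alleles = (rng.random((n_hap, n_sites)) < rng.uniform(0.1, 0.9)).astype(
                np.uint8
            )
            positions = np.sort(
                rng.choice(np.arange(1, L + 1), size=n_sites, replace=False)
            )
            derived = alleles.sum(axis=0).astype(float)
            n = np.full(n_sites, float(n_hap))
            got = selection.window_pi(positions, derived, n, (0, L))
            assert got == pytest.approx(brute_force_pi(alleles, L), abs=1e-12)


class TestTajima:
    def test_constants_n2_closed_form(self):
        c = selection.tajima_constants(2)
        assert (c.a1, c.a2) == (1.0, 1.0)
        assert c.c1 == pytest.approx(0.0)
        assert c.e1 == pytest.approx(0.0)
        assert c.e2 == pytest.approx(0.0)

    def test_constants_n10_against_harmonic_sums(self):
        c = selection.tajima_constants(10)
        assert c.a1 == pytest.approx(sum(1 / i for i in range(1, 10)), abs=1e-12)
        assert c.a1 == pytest.approx(2.828968, abs=1e-6)
        assert c.e1 == pytest.approx(0.019061, abs=1e-6)
        assert c.e2 == pytest.approx(0.004949, abs=1e-6)

    def test_d_zero_when_pi_equals_watterson(self):
        c = selection.tajima_constants(10)
        assert selection.tajima_d(16, 16 / c.a1, 10) == pytest.approx(0.0, abs=1e-12)

    def test_d_undefined_for_no_segregating_sites(self):
        assert selection.tajima_d(0, 0.0, 10) is None

    def test_worked_value(self):
        assert selection.tajima_d(16, 3.0, 10) == pytest.approx(-2.1737, abs=1e-4)

    def test_small_sample_rejected(self):
        with pytest.raises(ParameterError):
            selection.tajima_d(5, 1.0, 3)

    def test_neutral_coalescent_mean_d_near_zero(self):
        from pavpop import sweep

        n = 20
        dem = sweep.Demography.constant(n)
        L, S, pi = sweep.simulate_batch(dem, 10.0, 1000, np.random.default_rng(17))
        ds = [
            selection.tajima_d(int(s), float(p), n)
            for s, p in zip(S, pi)
            if s > 0
        ]
        assert -0.3 < np.mean(ds) < 0.3


class TestEhh:
    def test_equals_one_at_core(self):
        haps = make_haps(np.array([[1, 0], [1, 1], [1, 0], [1, 1]]))
        pos, vals = selection.ehh(haps, 0, 1, "right")
        assert vals[0] == 1.0

    def test_two_by_two_split(self):
        # 4 carriers split 2+2 at the next marker -> 2*C(2,2)/C(4,2) = 1/3
        haps = make_haps(np.array([[1, 0], [1, 0], [1, 1], [1, 1]]))
        _, vals = selection.ehh(haps, 0, 1, "right")
        assert vals[1] == pytest.approx(1 / 3)

    def test_identical_carriers_stay_at_one(self):
        block = np.tile(np.array([1, 0, 1, 1, 0], dtype=np.uint8), (4, 1))
        haps = make_haps(np.vstack([block, 1 - block]))
        _, vals = selection.ehh(haps, 0, 1, "right")
        assert (vals == 1.0).all()

    def test_monotone_non_increasing(self, rng):
        alleles = (rng.random((30, 40)) < 0.5).astype(np.uint8)
        alleles[:, 20] = (np.arange(30) < 15).astype(np.uint8)
        for direction in ("left", "right"):
            _, vals = selection.ehh(haps := make_haps(alleles), 20, 1, direction)
            assert (np.diff(vals) <= 1e-12).all()

    def test_single_carrier_rejected(self):
        haps = make_haps(np.array([[1, 0], [0, 1], [0, 0]]))
        with pytest.raises(DataError):
            selection.ehh(haps, 0, 1)


class TestIhs:
    def test_mirror_symmetry_gives_zero(self):
        # derived carriers are an exact structural copy of ancestral
        # carriers; EHH decays 1 -> 1/3 -> 0 on both sides for both alleles
        block = np.array(
            [[0, 0, 0, 0, 0], [0, 1, 0, 1, 0], [1, 0, 0, 0, 1], [1, 1, 0, 1, 1]],
            dtype=np.uint8,
        )
        derived = block.copy()
        derived[:, 2] = 1
        haps = make_haps(np.vstack([block, derived]))
        rec = selection.ihs_unstandardized(haps, 2)
        assert rec is not None
        assert rec.ihs == pytest.approx(0.0, abs=1e-12)

    def test_planted_sweep_gives_negative_ihs(self):
        haps, truth = synthdata.gen_sweep_haplotypes(
            n_hap=100, n_snps=300, seed=21, core_freq=0.4
        )
        rec = selection.ihs_unstandardized(haps, truth["core_index"])
        assert rec is not None
        assert rec.ihh_derived > rec.ihh_ancestral
        assert rec.ihs < 0

    def test_degenerate_cutoff_rejected(self):
        haps = make_haps(np.array([[1, 0], [1, 1], [0, 0], [0, 1]]))
        with pytest.raises(ParameterError):
            selection.ihs_unstandardized(haps, 0, cutoff=1.0)

    def test_monomorphic_core_rejected(self):
        haps = make_haps(np.array([[1, 0], [1, 1], [1, 0], [1, 1]]))
        with pytest.raises(DataError):
            selection.ihs_unstandardized(haps, 0)


class TestStandardizeIhs:
    @staticmethod
    def _records(rng, n, freq_fn):
        return [
            selection.IhsRecord(i, i * 100, freq_fn(i), 1.0, 1.0, float(rng.normal()))
            for i in range(n)
        ]

    def test_single_bin_centres_and_scales(self, rng):
        recs = self._records(rng, 200, lambda i: 0.5)
        out = selection.standardize_ihs(recs, n_bins=1)
        z = np.array([r.ihs_std for r in out])
        assert abs(z.mean()) < 1e-12
        assert z.std() == pytest.approx(1.0, abs=1e-12)

    def test_bins_centred_separately(self, rng):
        recs = self._records(rng, 400, lambda i: 0.2 if i % 2 else 0.8)
        for r in recs:
            if r.derived_freq > 0.5:
                r.ihs += 5.0  # shift one frequency class
        out = selection.standardize_ihs(recs, n_bins=2, min_bin_size=20)
        for lo, hi in [(0.0, 0.5), (0.5, 1.0)]:
            z = np.array([r.ihs_std for r in out if lo < r.derived_freq <= hi])
            assert abs(z.mean()) < 1e-10
            assert z.std() == pytest.approx(1.0, abs=1e-10)

    def test_small_bins_merged(self, rng):
        recs = self._records(rng, 30, lambda i: i / 30)
        out = selection.standardize_ihs(recs, n_bins=50, min_bin_size=20)
        z = np.array([r.ihs_std for r in out])
        assert np.isfinite(z).all()

    def test_neutral_extreme_fraction_matches_normal_tail(self, rng):
        # independent neutral sites: |standardized iHS| > 2 should occur at
        # roughly the two-sided normal tail rate
        alleles = (rng.random((200, 1200)) < rng.uniform(0.1, 0.9, 1200)).astype(
            np.uint8
        )
        haps = make_haps(alleles)
        recs = selection.ihs_scan(haps, min_maf=0.1)
        recs = selection.standardize_ihs(recs)
        z = np.array([r.ihs_std for r in recs])
        assert len(z) > 500
        assert np.mean(np.abs(z) > 2) == pytest.approx(0.046, abs=0.02)


class TestScanWindows:
    def test_fraction_extreme(self):
        pos = np.arange(1, 11) * 1000
        vals = np.array([3.0] * 4 + [0.0] * 6)
        win = selection.scan_windows(pos, vals, 10_000, 10_000, min_snps=1)
        assert win.loc[0, "value"] == pytest.approx(0.4)

    def test_sparse_window_is_null(self):
        win = selection.scan_windows(
            np.array([500]), np.array([1.0]), 1000, 1000, min_snps=10
        )
        assert np.isnan(win.loc[0, "value"])

    def test_each_snp_in_window_over_step_windows(self):
        pos = np.arange(200_001, 400_000, 5_000)
        vals = np.zeros(len(pos))
        win = selection.scan_windows(pos, vals, 100_000, 10_000, min_snps=1)
        for p in pos:
            covering = ((win["start"] < p) & (p <= win["end"])).sum()
            assert covering == 100_000 // 10_000


class TestOutlierWindows:
    def _frame(self, values):
        return pd.DataFrame(
            {
                "start": np.arange(len(values)) * 10,
                "end": np.arange(1, len(values) + 1) * 10,
                "n_snps": 10,
                "value": values,
            }
        )

    def test_single_minimum_flagged(self, rng):
        values = rng.normal(size=100)
        values[42] = values.min() - 5
        out = selection.outlier_windows(self._frame(values), "lower", 0.01)
        assert out["outlier"].sum() == 1
        assert bool(out.loc[42, "outlier"])

    def test_all_tied_all_flagged(self):
        out = selection.outlier_windows(self._frame(np.ones(50)), "lower", 0.02)
        assert out["outlier"].all()

    def test_planted_sweep_core_window_in_upper_tail(self):
        haps, truth = synthdata.gen_sweep_haplotypes(
            n_hap=150, n_snps=400, seed=33, core_freq=0.4
        )
        recs = selection.standardize_ihs(selection.ihs_scan(haps))
        pos = np.array([r.position for r in recs])
        z = np.array([r.ihs_std for r in recs])
        win = selection.scan_windows(pos, z, 100_000, 10_000, min_snps=5)
        out = selection.outlier_windows(win, "upper", 0.02)
        core = truth["core_position"]
        core_windows = out[(out["start"] < core) & (core <= out["end"])]
        assert core_windows["outlier"].any()
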