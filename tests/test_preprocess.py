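import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scentpipe.gcms_io import RawChromatogram
from scentpipe.preprocess import (
    BinnedChromatogram,
    PreprocessConfig,
    baseline_drift_correct,
    compute_tic,
    mirex_normalize,
    quantile_noise_correct,
    round_mz,
    run_preprocess,
    segment_time,
)
from conftest import gaussian_chrom


class TestRoundMz:
    def test_merges_neighbouring_fractional_channels(self):
        c = RawChromatogram(
            times=np.array([0.0, 1.0]),
            mz_raw=np.array([23.6, 23.7]),
            intensity=np.array([[1.0, 2.0], [3.0, 4.0]]),
        )
        b = round_mz(c)
        np.testing.assert_array_equal(b.mz, [24])
        np.testing.assert_array_equal(b.intensity, [[3.0], [7.0]])

    def test_integer_axis_is_identity(self, tiny_chrom):
        c = RawChromatogram(
            times=tiny_chrom.times,
            mz_raw=np.array([50.0, 51.0]),
            intensity=tiny_chrom.intensity,
        )
        b = round_mz(c)
        np.testing.assert_array_equal(b.mz, [50, 51])
        np.testing.assert_array_equal(b.intensity, c.intensity)

    def test_half_rounds_up(self):
        c = RawChromatogram(
            times=np.array([0.0]), mz_raw=np.array([23.5]),
            intensity=np.array([[7.0]]),
        )
        assert round_mz(c).mz.tolist() == [24]

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_conserves_total_ion_count(self, seed):
        rng = np.random.default_rng(seed)
        n_t, n_m = rng.integers(1, 8), rng.integers(1, 12)
        c = RawChromatogram(
            times=np.sort(rng.uniform(0, 10, n_t)) + np.arange(n_t) * 1e-3,
            mz_raw=np.sort(rng.uniform(20, 40, n_m)) + np.arange(n_m) * 1e-6,
            intensity=rng.integers(0, 1000, (n_t, n_m)).astype(float),
        )
        assert round_mz(c).intensity.sum() == c.intensity.sum()


class TestComputeTic:
    @pytest.mark.parametrize(
        "matrix,expected",
        [
            ([[1, 2], [3, 4]], [3, 7]),
            ([[0, 0], [0, 0]], [0, 0]),
            ([[5], [9]], [5, 9]),
        ],
    )
    def test_sums_channels(self, matrix, expected):
        c = BinnedChromatogram(
            times=np.arange(len(matrix), dtype=float),
            mz=np.arange(50, 50 + len(matrix[0])),
            intensity=np.array(matrix, dtype=float),
        )
        np.testing.assert_array_equal(compute_tic(c).total, expected)


class TestSegmentTime:
    def test_default_run_gives_28_segments(self):
        g = segment_time(41.0, 1.5)
        assert g.n_segments == 28
        assert round(g.dt, 1) == 1.5

    def test_small_run(self):
        g = segment_time(3.0, 1.5)
        assert g.boundaries == ((0.0, 1.5), (1.5, 3.0))

    def test_boundaries_tile_run(self):
        g = segment_time(41.0, 1.5)
        assert g.boundaries[0][0] == 0.0
        assert g.boundaries[-1][1] == pytest.approx(41.0)
        for (_, hi), (lo, _) in zip(g.boundaries, g.boundaries[1:]):
            assert hi == pytest.approx(lo)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            segment_time(0.0, 1.5)
        with pytest.raises(ValueError):
            segment_time(41.0, -1.0)


def _brute_force_quantile(values, q):
    """Sorted linear interpolation at rank (n-1)q, written independently."""
    v = sorted(values)
    pos = (len(v) - 1) * q
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    return v[lo] + (pos - lo) * (v[hi] - v[lo])


class TestQuantileNoiseCorrect:
    def test_worked_subtraction_rule(self):
        # a cell whose 15th percentile is 400: 1000 -> 600 and 390 -> 0
        values = np.full(20, 400.0)
        values[-2:] = [1000.0, 390.0]
        c = BinnedChromatogram(
            times=np.linspace(0, 1.4, 20), mz=np.array([50]),
            intensity=values[:, None],
        )
        g = segment_time(1.4, 1.5)
        out = quantile_noise_correct(c, g).intensity[:, 0]
        assert out[-2] == pytest.approx(600.0)
        assert out[-1] == 0.0

    def test_constant_cell_zeroed(self):
        c = BinnedChromatogram(
            times=np.linspace(0, 1, 10), mz=np.array([50]),
            intensity=np.full((10, 1), 42.0),
        )
        out = quantile_noise_correct(c, segment_time(1.0, 1.5))
        assert np.all(out.intensity == 0)

    def test_matches_brute_force_quantile_oracle(self):
        values = np.arange(0.0, 2000.0, 100.0)  # 0, 100, ..., 1900
        c = BinnedChromatogram(
            times=np.linspace(0, 1, 20), mz=np.array([50]),
            intensity=values[:, None],
        )
        out = quantile_noise_correct(c, segment_time(1.0, 1.5), q=0.15)
        thresh = _brute_force_quantile(values, 0.15)
        np.testing.assert_allclose(
            out.intensity[:, 0], np.maximum(values - thresh, 0)
        )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_contract_nonnegative_zero_quantile_idempotent_ordered(self, seed):
        rng = np.random.default_rng(seed)
        n_t = 60
        c = BinnedChromatogram(
            times=np.linspace(0, 6, n_t), mz=np.arange(50, 54),
            intensity=rng.gamma(2.0, 100.0, (n_t, 4)),
        )
        g = segment_time(6.0, 1.5)
        out = quantile_noise_correct(c, g, q=0.15)
        assert np.all(out.intensity >= 0)
        # the q-quantile of every corrected cell is 0 (floor-rank form is
        # exact; the interpolated form is bounded by the gap between the
        # order statistics flanking the quantile)
        gap_bound = np.zeros(4)
        for lo, hi in g.boundaries:
            mask = (c.times >= lo) & (c.times < hi if hi < 6 else c.times <= hi)
            cell = out.intensity[mask]
            np.testing.assert_array_equal(
                np.quantile(cell, 0.15, axis=0, method="lower"), 0.0
            )
            orig = np.sort(c.intensity[mask], axis=0)
            pos = (mask.sum() - 1) * 0.15
            gap = orig[int(np.ceil(pos))] - orig[int(np.floor(pos))]
            assert np.all(np.quantile(cell, 0.15, axis=0) <= gap + 1e-9)
            gap_bound = np.maximum(gap_bound, gap)
        # idempotent up to the interpolation residue of the quantile
        out2 = quantile_noise_correct(out, g, q=0.15)
        assert np.abs(out2.intensity - out.intensity).max() <= gap_bound.max() + 1e-9
        # within-cell ordering preserved wherever both values survive
        for lo, hi in g.boundaries:
            mask = (c.times >= lo) & (c.times < hi if hi < 6 else c.times <= hi)
            orig, corr = c.intensity[mask], out.intensity[mask]
            pos = (corr[:-1] > 0) & (corr[1:] > 0)
            assert np.all(
                np.sign(np.diff(orig, axis=0))[pos]
                == np.sign(np.diff(corr, axis=0))[pos]
            )


class TestBaselineDriftCorrect:
    def test_pure_polynomial_removed(self):
        times = np.linspace(0, 10, 200)
        base = 100 + 20 * times + 3 * times**2
        c = BinnedChromatogram(
            times=times, mz=np.array([50]), intensity=base[:, None],
        )
        out = baseline_drift_correct(c, degree=2)
        assert np.max(np.abs(out.intensity)) < 1e-6 * base.max()

    def test_peak_height_recovered_over_linear_ramp(self):
        times = np.linspace(0, 10, 400)
        h = 500.0
        ramp = 10 + 5 * times
        peak = h * np.exp(-0.5 * ((times - 5.0) / 0.2) ** 2)
        c = BinnedChromatogram(
            times=times, mz=np.array([50]), intensity=(ramp + peak)[:, None],
        )
        out = baseline_drift_correct(c, degree=1)
        assert out.intensity.max() == pytest.approx(h, rel=0.05)

    def test_all_zero_input_unchanged(self):
        c = BinnedChromatogram(
            times=np.linspace(0, 1, 50), mz=np.array([50]),
            intensity=np.zeros((50, 1)),
        )
        out = baseline_drift_correct(c)
        assert np.all(out.intensity == 0)


class TestMirexNormalize:
    def _with_mirex(self, area_scale):
        c = gaussian_chrom(
            n_t=2000, n_mz=4, peaks=[(29.6, 0.05, 2, 1000.0 * area_scale)],
        )
        return round_mz(c)

    def test_samples_scaled_to_common_reference(self):
        areas = []
        for s in (2.0, 4.0):
            out, area, detected = mirex_normalize(self._with_mirex(s), reference=1.0)
            assert detected
            _, post_area, _ = mirex_normalize(out, reference=1.0)
            areas.append(post_area)
        assert areas[0] == pytest.approx(areas[1], rel=1e-9)
        assert areas[0] == pytest.approx(1.0, rel=1e-9)

    def test_sample_at_reference_unchanged(self):
        c = self._with_mirex(1.0)
        _, area, _ = mirex_normalize(c, reference=1.0)
        out, _, _ = mirex_normalize(c, reference=area)
        np.testing.assert_allclose(out.intensity, c.intensity, rtol=1e-12)

    def test_dropout_flagged_not_scaled(self):
        c = round_mz(gaussian_chrom(n_t=2000, n_mz=4, noise_sd=5.0, seed=3))
        out, area, detected = mirex_normalize(c, reference=1e6)
        assert not detected
        np.testing.assert_array_equal(out.intensity, c.intensity)


class TestRunPreprocess:
    def test_all_stages_disabled_is_identity(self, tiny_chrom):
        cfg = PreprocessConfig(stages=("round",))
        out, _ = run_preprocess(tiny_chrom, cfg)
        assert out.intensity.sum() == tiny_chrom.intensity.sum()

    def test_stack_removes_stripe_and_drift_and_anchors_mirex(self):
        times = np.linspace(0, 41, 1500)
        drift = 30 * (times / 41.0)
        c = gaussian_chrom(
            n_t=1500, n_mz=6,
            peaks=[(10.0, 0.15, 1, 2000.0), (29.6, 0.05, 4, 5000.0)],
            drift=drift,
        )
        # persistent stripe artifact on channel 3
        c.intensity[(times > 5) & (times < 35), 3] += 80.0
        out, info = run_preprocess(c, PreprocessConfig())
        assert info["mirex_detected"]
        # stripe channel flattened to ~0 in its plateau
        plateau = (times > 6) & (times < 34)
        assert np.median(out.intensity[plateau, 3]) < 1e-3 * out.intensity.max()
        _, post_area, _ = mirex_normalize(out)
        assert post_area == pytest.approx(1.0, rel=1e-6)

    def test_near_idempotent(self):
        c = gaussian_chrom(
            n_t=1500, n_mz=6,
            peaks=[(10.0, 0.15, 1, 2000.0), (29.6, 0.05, 4, 5000.0)],
            noise_sd=3.0,
        )
        cfg = PreprocessConfig()
        once, _ = run_preprocess(c, cfg)
        twice, _ = run_preprocess(once, cfg)
        denom = np.abs(once.intensity).max()
        assert np.abs(twice.intensity - once.intensity).max() < 0.01 * denom
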