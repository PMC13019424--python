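"""Spectrum model, I/O and preprocessing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acylquant import (Spectrum, SpectrumSet, WavenumberGrid, WindowSet,
                       band_area, correct_baseline, extract_windows,
                       load_spectra, normalize_ester_band, preprocess,
                       resample, save_spectra, subtract_background)
from acylquant.synth import Composition, NoiseParams, mix


def make_spec(grid, fn, sid="s"):
    return Spectrum(grid, fn(grid.values), sid)


class TestGridAndTypes:
    def test_default_grid_is_1151_points(self, grid):
        assert len(grid) == 1151
        assert grid.values[0] == 650.0 and grid.values[-1] == 1800.0

    @pytest.mark.parametrize("values", [[1, 1, 2], [3, 2, 1], [1, np.nan, 2], [5]])
    def test_invalid_grids_rejected(self, values):
        with pytest.raises(ValueError):
            WavenumberGrid(np.array(values, dtype=float))

    def test_spectrum_length_must_match_grid(self, grid):
        with pytest.raises(ValueError):
            Spectrum(grid, np.zeros(len(grid) - 1))

    def test_set_requires_unique_ids_and_shared_grid(self, grid):
        a = Spectrum(grid, np.zeros(len(grid)), "a")
        with pytest.raises(ValueError):
            SpectrumSet.from_spectra([a, a.copy()])
        other = WavenumberGrid(np.arange(650.0, 1800.0, 2.0))
        b = Spectrum(other, np.zeros(len(other)), "b")
        with pytest.raises(ValueError):
            SpectrumSet.from_spectra([a, b])


class TestWindowSet:
    def test_parse_and_render_table_dialect(self):
        text = "1800-1700,1500-1380,1200-1110,930-650"
        ws = WindowSet.from_string(text)
        assert ws.to_string() == text
        assert ws.intervals[0] == (1700.0, 1800.0)

    def test_sorted_descending_and_non_overlap(self):
        ws = WindowSet([(650, 930), (1700, 1800)])
        assert [hi for _, hi in ws.intervals] == [1800.0, 930.0]
        with pytest.raises(ValueError):
            WindowSet([(650, 1000), (900, 1100)])

    @pytest.mark.parametrize("bad", ["", "1700-1800", "a-b", "1800:1700"])
    def test_bad_strings_rejected(self, bad):
        with pytest.raises(ValueError):
            WindowSet.from_string(bad)


class TestResample:
    def test_identity_grid_returns_equal_intensities(self, grid):
        s = make_spec(grid, lambda v: np.sin(v / 50))
        out = resample(s, grid)
        assert np.array_equal(out.intensity, s.intensity)
        assert out.id == s.id

    def test_linear_interpolation_closed_form(self, grid):
        s = make_spec(grid, lambda v: 2.0 * v)
        g = WavenumberGrid(np.array([700.5, 701.5]))
        out = resample(s, g)
        assert out.intensity == pytest.approx([1401.0, 1403.0], abs=1e-12)

    def test_out_of_span_raises(self, grid):
        s = make_spec(grid, lambda v: v)
        with pytest.raises(ValueError):
            resample(s, WavenumberGrid(np.array([1790.0, 1850.0])))


class TestSubtractBackground:
    def test_self_subtraction_zeroes(self, grid):
        s = make_spec(grid, lambda v: np.cos(v / 100) + 2)
        assert np.all(subtract_background(s, s, 1.0).intensity == 0)

    def test_zero_scale_is_identity(self, grid):
        s = make_spec(grid, lambda v: v**0.5)
        bg = make_spec(grid, lambda v: np.ones_like(v))
        assert np.array_equal(subtract_background(s, bg, 0.0).intensity, s.intensity)

    def test_elementwise_arithmetic(self):
        g = WavenumberGrid(np.array([650.0, 651.0]))
        s = Spectrum(g, np.array([3.0, 3.0]))
        bg = Spectrum(g, np.array([1.0, 2.0]))
        assert subtract_background(s, bg, 2.0).intensity == pytest.approx([1.0, -1.0])

    def test_grid_mismatch_raises(self, grid):
        s = make_spec(grid, lambda v: v)
        g2 = WavenumberGrid(grid.values[:-1])
        with pytest.raises(ValueError):
            subtract_background(s, Spectrum(g2, np.zeros(len(g2))), 1.0)


class TestBaseline:
    def test_pure_polynomial_is_its_own_baseline(self, grid):
        v = grid.values
        s = make_spec(grid, lambda v: 1e-3 * (v - 1200) ** 2 + 0.5)
        corrected, baseline = correct_baseline(s, order=2, n_iter=5)
        assert np.max(np.abs(corrected.intensity)) < 1e-6 * np.max(s.intensity)

    def test_constant_recovered(self, grid):
        s = make_spec(grid, lambda v: np.full_like(v, 7.0))
        corrected, baseline = correct_baseline(s, order=0, n_iter=3)
        assert baseline.intensity == pytest.approx(7.0, rel=1e-9)
        assert np.max(np.abs(corrected.intensity)) < 1e-8

    def test_peaks_plus_cubic_recovered_within_1pct_rms(self, grid):
        v = grid.values
        t = (v - v[0]) / (v[-1] - v[0])
        cubic = 2.0 + 1.5 * t - 2.0 * t**2 + 1.0 * t**3
        peaks = sum(
            5.0 * np.exp(-0.5 * ((v - c) / 8.0) ** 2) for c in (900, 1300, 1650)
        )
        s = Spectrum(grid, cubic + peaks, "synthetic")
        _, baseline = correct_baseline(s, order=3, n_iter=30)
        rms_err = np.sqrt(np.mean((baseline.intensity - cubic) ** 2))
        assert rms_err < 0.01 * np.sqrt(np.mean(cubic**2))

    def test_order_too_high_raises(self):
        g = WavenumberGrid(np.array([650.0, 651.0, 652.0]))
        with pytest.raises(ValueError):
            correct_baseline(Spectrum(g, np.ones(3)), order=3, n_iter=1)


class TestBandArea:
    def test_rectangle(self, grid):
        s = make_spec(grid, lambda v: np.full_like(v, 2.0))
        assert band_area(s, (1720, 1770)) == pytest.approx(100.0)

    def test_zero_spectrum(self, grid):
        s = make_spec(grid, lambda v: np.zeros_like(v))
        assert band_area(s, (1720, 1770)) == 0.0

    def test_triangle_closed_form(self, grid):
        v = grid.values
        y = np.clip(1.0 - np.abs(v - 1000.0) / 5.0, 0.0, None)
        assert band_area(Spectrum(grid, y), (995, 1005)) == pytest.approx(5.0)

    def test_too_few_points_raises(self, grid):
        s = make_spec(grid, lambda v: v)
        with pytest.raises(ValueError):
            band_area(s, (1000.2, 1000.8))


class TestNormalize:
    def test_constant_band(self, grid):
        s = make_spec(grid, lambda v: np.full_like(v, 2.0))
        out = normalize_ester_band(s)
        assert band_area(out, (1720, 1770)) == pytest.approx(1.0, rel=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.floats(min_value=1e-6, max_value=1e6))
    def test_scale_invariance(self, a):
        grid = WavenumberGrid.default()
        s = make_spec(grid, lambda v: np.exp(-((v - 1740) / 20.0) ** 2) + 0.1)
        n1 = normalize_ester_band(s)
        n2 = normalize_ester_band(s.copy(intensity=a * s.intensity))
        np.testing.assert_allclose(n1.intensity, n2.intensity, rtol=1e-12)

    def test_idempotent(self, grid):
        s = make_spec(grid, lambda v: np.exp(-((v - 1740) / 15.0) ** 2) + 0.05)
        once = normalize_ester_band(s)
        twice = normalize_ester_band(once)
        np.testing.assert_allclose(once.intensity, twice.intensity, rtol=1e-12)

    def test_nonpositive_area_raises(self, grid):
        s = make_spec(grid, lambda v: -np.ones_like(v))
        with pytest.raises(ValueError):
            normalize_ester_band(s)


class TestExtractWindows:
    def test_full_grid_window_returns_raw_matrix(self, grid, fame_pures):
        ss = SpectrumSet.from_spectra(fame_pures.values())
        M, cmap = extract_windows(ss, WindowSet([(650, 1800)]))
        assert M.shape == (5, 1151)
        assert sorted(cmap.tolist()) == grid.values.tolist()
        np.testing.assert_array_equal(np.sort(M, axis=1), np.sort(ss.intensities, axis=1))

    def test_published_myristate_windows_channel_count(self, grid, fame_pures):
        ss = SpectrumSet.from_spectra(fame_pures.values())
        ws = WindowSet.from_string("1800-1700,1500-1380,1200-1110,930-650")
        M, cmap = extract_windows(ss, ws)
        assert M.shape[1] == 101 + 121 + 91 + 281 == 594
        assert len(cmap) == 594

    def test_row_per_spectrum(self, grid):
        a = make_spec(grid, lambda v: v, "a")
        b = make_spec(grid, lambda v: 2 * v, "b")
        ss = SpectrumSet.from_spectra([a, b])
        M, _ = extract_windows(ss, WindowSet([(700, 800)]))
        assert M.shape[0] == 2

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.integers(min_value=650, max_value=1800),
                    min_size=2, max_size=8, unique=True))
    def test_channel_count_matches_analytic(self, edges):
        """Channels in closed intervals equal the analytic grid-point count."""
        edges = sorted(edges)
        intervals = [(float(lo), float(hi))
                     for lo, hi in zip(edges[::2], edges[1::2]) if lo < hi]
        if not intervals:
            return
        grid = WavenumberGrid.default()
        ss = SpectrumSet.from_spectra([Spectrum(grid, np.zeros(1151), "z")])
        M, _ = extract_windows(ss, WindowSet(intervals))
        expect = sum(int(hi) - int(lo) + 1 for lo, hi in intervals)
        assert M.shape[1] == expect


class TestCSVRoundtrip:
    def test_roundtrip_preserves_values(self, grid, tmp_path):
        rng = np.random.default_rng(7)
        ss = SpectrumSet.from_spectra(
            [Spectrum(grid, rng.uniform(0, 10, 1151), f"s{i}") for i in range(3)]
        )
        path = tmp_path / "spectra.csv"
        save_spectra(ss, path)
        back = load_spectra(path)
        assert back.ids == ss.ids
        np.testing.assert_allclose(back.grid.values, grid.values, rtol=1e-12)
        np.testing.assert_allclose(back.intensities, ss.intensities, rtol=1e-11)

    def test_duplicate_wavenumber_rows_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("wavenumber_cm1,a\n650,1\n650,2\n651,3\n")
        with pytest.raises(ValueError):
            load_spectra(path)

    def test_shape_bookkeeping(self, tmp_path, grid):
        import pandas as pd

        df = pd.DataFrame({"wavenumber_cm1": grid.values})
        for i in range(5):
            df[f"s{i}"] = float(i)
        path = tmp_path / "wide.csv"
        df.to_csv(path, index=False)
        ss = load_spectra(path)
        assert len(ss) == 5 and len(ss.grid) == 1151

    def test_ragged_columns_rejected(self, tmp_path):
        path = tmp_path / "ragged.csv"
        path.write_text("wavenumber_cm1,a,b\n650,1,2\n651,3,\n652,4,5\n")
        with pytest.raises(ValueError):
            load_spectra(path)


class TestPreprocessChain:
    def test_chain_idempotent_after_first_normalize(self, grid, fame_pures):
        params = NoiseParams(sigma_rel=0.005, drift_order=2,
                             drift_amp_rel=0.05, seed=11)
        c = Composition({"MA": 30.0, "OA": 50.0, "LA": 20.0})
        raw = SpectrumSet.from_spectra([mix(c, fame_pures, params, id="m")])
        once = preprocess(raw, baseline_order=3)
        twice = preprocess(once, baseline_order=3)
        np.testing.assert_allclose(
            twice.intensities, once.intensities, rtol=0,
            atol=1e-9 * np.max(np.abs(once.intensities)),
        )

    def test_normalized_band_area_is_unit(self, grid, fame_pures):
        pre = preprocess(SpectrumSet.from_spectra(fame_pures.values()))
        for s in pre:
            assert band_area(s, (1720, 1770)) == pytest.approx(1.0, rel=1e-12)
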