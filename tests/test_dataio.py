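"""Streak conversion, preprocessing, time-axis construction, file I/O."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cryphot.dataio import (
    ChirpModel,
    StreakTriplet,
    TAMatrix,
    build_time_axis,
    chirp_correct,
    read_matrix,
    subtract_pre_t0,
    ta_from_streak,
    write_matrix,
)
from cryphot.globalfit import IRF, KineticBasis, solve_dads
from cryphot import synthdata


def small_matrix(values, times=None, wavelengths=None, **kw):
    values = np.asarray(values, dtype=float)
    nw, nt = values.shape
    return TAMatrix(
        wavelengths=wavelengths if wavelengths is not None else np.arange(400.0, 400.0 + nw),
        times=times if times is not None else np.arange(nt, dtype=float),
        values=values,
        **kw,
    )


class TestStreakConversion:
    def test_no_pump_effect_gives_zero(self):
        wl, t = np.array([450.0, 460.0]), np.array([0.0, 1.0, 2.0])
        lamp = np.full((2, 3), 5000.0)
        trip = StreakTriplet(wl, t, d_fl=lamp + 10, d_0=np.full((2, 3), 10.0),
                             d_f=lamp + 10)
        ta = ta_from_streak(trip)
        assert np.allclose(ta.values, 0.0)
        assert ta.mask is None

    def test_decadic_log_identity(self):
        # transmitted fraction 0.1 -> 1 OD
        wl, t = np.array([450.0, 460.0]), np.array([0.0, 1.0])
        d0 = np.full((2, 2), 7.0)
        df_ = d0 + 1000.0
        dfl = d0 + 100.0
        ta = ta_from_streak(StreakTriplet(wl, t, dfl, d0, df_))
        assert np.allclose(ta.values, 1.0)

    def test_round_trip_machine_precision(self):
        rng = np.random.default_rng(11)
        truth = synthdata.ms_truth(seed=1)
        m = synthdata.generate_regime(truth, "magic")
        lamp = 1e4 * (1.0 + 0.3 * rng.random(m.wavelengths.size))
        trip = synthdata.streak_from_ta(m, lamp=lamp, dark=55.0)
        back = ta_from_streak(trip)
        assert np.abs(back.values - m.values).max() < 1e-10

    def test_invalid_cells_masked_not_fabricated(self):
        wl, t = np.array([450.0, 460.0]), np.array([0.0, 1.0])
        d0 = np.full((2, 2), 10.0)
        dfl = d0 + np.array([[100.0, -5.0], [100.0, 100.0]])  # one cell <= d0
        ta = ta_from_streak(StreakTriplet(wl, t, np.clip(dfl, 0, None), d0, d0 + 1000.0))
        assert ta.mask is not None and ta.mask[0, 1]
        assert not ta.mask[1, 1]

    def test_shape_mismatch_rejected(self):
        wl, t = np.array([450.0, 460.0]), np.array([0.0, 1.0])
        with pytest.raises(ValueError, match="shape"):
            StreakTriplet(wl, t, np.zeros((2, 3)), np.zeros((2, 2)), np.zeros((2, 2)))


class TestPreT0Subtraction:
    def test_constant_offset_removed_exactly_and_idempotent(self):
        t = np.linspace(-1.0, 5.0, 30)
        offs = np.array([0.3, -0.2, 1.5])
        m = small_matrix(np.tile(offs[:, None], (1, 30)), times=t)
        out = subtract_pre_t0(m, -0.1)
        assert np.allclose(out.values, 0.0)
        again = subtract_pre_t0(out, -0.1)
        assert np.array_equal(again.values, out.values)

    def test_scatter_spectrum_removed_signal_untouched(self):
        truth = synthdata.ps_truth(seed=3, snr=0, with_chirp=False, with_scatter=True)
        clean = synthdata.ps_truth(seed=3, snr=0, with_chirp=False, with_scatter=False)
        m = synthdata.generate_regime(truth, "magic")
        m0 = synthdata.generate_regime(clean, "magic")
        out = subtract_pre_t0(m, -0.5e-12)
        pre = out.times < -0.5e-12
        assert np.abs(out.values[:, pre].mean(axis=1)).max() < 1e-14
        assert np.abs(out.values - m0.values).max() < 1e-12

    def test_all_zero_identity(self):
        m = small_matrix(np.zeros((2, 10)), times=np.linspace(-2, 2, 10))
        assert np.allclose(subtract_pre_t0(m, 0.0).values, 0.0)

    def test_requires_pre_t0_points(self):
        m = small_matrix(np.zeros((2, 10)), times=np.linspace(0.5, 2, 10))
        with pytest.raises(ValueError, match=">= 3"):
            subtract_pre_t0(m, 0.0)


class TestChirpCorrection:
    def test_zero_chirp_is_identity(self, ps_matrix_clean):
        c = ChirpModel(coefficients=[0.0], time_unit="s")
        out = chirp_correct(ps_matrix_clean, c)
        assert np.array_equal(out.values, ps_matrix_clean.values)

    def test_known_chirp_round_trip(self):
        truth = synthdata.ps_truth(seed=5, snr=0, with_chirp=True, with_scatter=False)
        clean = synthdata.ps_truth(seed=5, snr=0, with_chirp=False, with_scatter=False)
        m = synthdata.generate_regime(truth, "magic")
        m0 = synthdata.generate_regime(clean, "magic")
        out = chirp_correct(m, truth.chirp)
        ok = ~out.effective_mask()
        peak = np.abs(m0.values).max()
        assert np.abs((out.values - m0.values)[ok]).max() < 0.01 * peak

    def test_artefact_alignment_after_correction(self):
        # a coherent-artefact-like impulse at t0(lambda) must align at one
        # common time zero after correction
        wl = np.linspace(400.0, 700.0, 31)
        t = np.linspace(-1e-12, 1e-12, 201)
        chirp = ChirpModel(coefficients=[0.0, 1.2e-15], reference_nm=550.0,
                           time_unit="s")
        t0 = chirp.t0(wl)
        sigma = 60e-15
        vals = np.exp(-((t[None, :] - t0[:, None]) ** 2) / (2 * sigma**2))
        m = TAMatrix(wl, t, vals, time_unit="s")
        out = chirp_correct(m, chirp)
        step = t[1] - t[0]
        peaks = out.times[np.argmax(np.where(out.effective_mask(), -1, out.values), axis=1)]
        assert np.ptp(peaks) <= step + 1e-18

    def test_out_of_axis_shifts_masked(self):
        wl = np.array([400.0, 500.0])
        t = np.linspace(0.0, 1.0, 11)
        chirp = ChirpModel(coefficients=[0.5], time_unit="s")  # shift by half axis
        m = TAMatrix(wl, t, np.ones((2, 11)), time_unit="s")
        out = chirp_correct(m, chirp)
        assert out.mask is not None and out.mask.any()


class TestTimeAxis:
    def test_quasi_log_axis_equal_decade_weights(self):
        axis = build_time_axis(-1e-12, 1e-12, 3e-9, 500)
        assert axis.size >= 499 and np.all(np.diff(axis) > 0)
        counts = [
            np.sum((axis > lo) & (axis <= hi))
            for lo, hi in [(1e-12, 1e-11), (1e-11, 1e-10), (1e-10, 1e-9)]
        ]
        assert max(counts) - min(counts) <= 1

    def test_tiny_axis(self):
        axis = build_time_axis(0.0, 1.0, 10.0, 3)
        assert axis[0] == 0.0 and axis[-1] == 10.0
        assert np.all(np.diff(axis) > 0)

    @given(
        t_switch=st.floats(1e-13, 1e-9),
        decades=st.floats(0.5, 4.0),
        n=st.integers(10, 600),
    )
    def test_axis_unique_ascending(self, t_switch, decades, n):
        axis = build_time_axis(-t_switch, t_switch, t_switch * 10**decades, n)
        assert np.all(np.diff(axis) > 0)
        assert np.unique(axis).size == axis.size

    def test_non_monotone_request_rejected(self):
        with pytest.raises(ValueError):
            build_time_axis(1.0, 0.5, 10.0, 100)


class TestMaskPropagation:
    def test_masked_cells_never_enter_fits(self):
        truth = synthdata.ms_truth(seed=2)
        m = synthdata.generate_regime(truth, "magic")
        basis = KineticBasis.from_lifetimes([0.187, 60.0])
        _, chi2_ref, _ = solve_dads(m, basis, None)

        mask = np.zeros_like(m.values, dtype=bool)
        mask[::3, ::5] = True
        m_masked = m.copy()
        m_masked.mask = mask
        _, chi2_masked, _ = solve_dads(m_masked, basis, None)

        poisoned = m_masked.copy()
        poisoned.values = np.where(mask, 1e30, poisoned.values)
        _, chi2_poisoned, _ = solve_dads(poisoned, basis, None)
        assert chi2_poisoned == pytest.approx(chi2_masked, rel=1e-12)
        assert chi2_masked != pytest.approx(chi2_ref, rel=1e-12)


class TestFileIO:
    @pytest.mark.parametrize("ext", ["csv", "tsv", "h5"])
    def test_round_trip(self, tmp_path, ext):
        truth = synthdata.ms_truth(seed=4)
        m = synthdata.generate_regime(truth, "magic")
        m.mask = np.zeros_like(m.values, dtype=bool)
        m.mask[0, :3] = True
        path = str(tmp_path / f"m.{ext}")
        write_matrix(m, path)
        back = read_matrix(path)
        ok = ~m.mask
        assert np.allclose(back.values[ok], m.values[ok], atol=1e-9)
        assert np.allclose(back.wavelengths, m.wavelengths)
        assert np.allclose(back.times, m.times)
        assert np.array_equal(back.effective_mask(), m.mask)
        assert back.time_unit == m.time_unit
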