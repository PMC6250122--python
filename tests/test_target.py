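"""Compartmental models, DADS -> SAS, spectral arithmetic, RPR."""

import numpy as np
import pytest

from cryphot.dataio import TAMatrix
from cryphot.globalfit import GlobalFit, IRF, KineticBasis, conv_exp
from cryphot.target import (
    KineticModel,
    SpeciesSpectrum,
    add_ground_state,
    concentrations,
    estimate_rpr,
    residual_flavin_correlation,
    sas_from_dads,
    strip_flavin,
)
from cryphot import synthdata


IRF_PS = IRF.from_fwhm(100e-15)


class TestConcentrations:
    def test_fast_feed_slow_drain_populates_intermediate_fully(self):
        k1, k2 = 1e4, 1e-2  # k1 >> k2
        model = KineticModel(
            ["A", "B", "C"], [("A", "B", k1), ("B", "C", k2)], [1, 0, 0]
        )
        t = np.linspace(0, 1.0, 200)
        C = concentrations(model, None, IRF(mu=0.0, sigma=1e-5), t)
        assert C[:, 1].max() == pytest.approx(1.0, abs=1e-3)

    def test_twenty_percent_recombination_gives_eighty_percent_plateau(self):
        k1, k2 = 1.0 / 848e-15, 1.0 / 46e-12
        model = KineticModel(
            ["exc", "RP1", "RP23"],
            [("exc", "RP1", k1), ("RP1", None, 0.2 * k2), ("RP1", "RP23", 0.8 * k2)],
            [1, 0, 0],
        )
        t = np.array([1e-9, 2e-9, 3e-9])
        C = concentrations(model, None, IRF_PS, t)
        assert np.allclose(C[:, 2], 0.8, atol=1e-6)

    def test_no_kinetics_gives_irf_broadened_step(self):
        model = KineticModel(["only"], [], [1.0])
        t = np.linspace(-1.0, 3.0, 100)
        irf = IRF(mu=0.2, sigma=0.3)
        C = concentrations(model, None, irf, t)
        assert np.allclose(C[:, 0], conv_exp(t, 0.0, irf), rtol=1e-12)

    def test_eigenrate_mismatch_raises_listing_both(self):
        model = KineticModel(["A", "B"], [("A", "B", 5.0)], [1, 0])
        wrong = KineticBasis(np.array([2.0, 0.0]))
        with pytest.raises(ValueError, match="do not match"):
            concentrations(model, wrong, None, np.linspace(0, 1, 10))

    def test_population_conservation_under_closed_model(self):
        # explicit ground compartment: total population equals the
        # IRF-broadened excitation step at every delay
        k1, k2 = 1.0 / 848e-15, 1.0 / 46e-12
        model = KineticModel(
            ["exc", "RP1", "RP23", "ground"],
            [("exc", "RP1", k1), ("RP1", "ground", 0.2 * k2),
             ("RP1", "RP23", 0.8 * k2)],
            [1, 0, 0, 0],
        )
        t = np.geomspace(1e-14, 3e-9, 200)
        C = concentrations(model, None, IRF_PS, t)
        total = C.sum(axis=1)
        assert np.abs(total - conv_exp(t, 0.0, IRF_PS)).max() < 1e-9


class TestSasFromDads:
    def fit_ps(self, truth):
        m = synthdata.generate_regime(truth, "magic")
        return GlobalFit(
            m, lifetimes_init=[1e-12, 40e-12, np.inf], irf=IRF_PS,
            fit_irf_mu=False,
        ).fit(multistarts=1)

    def test_identity_model_returns_dads(self):
        truth = synthdata.ps_truth(seed=2, snr=0, with_chirp=False,
                                   with_scatter=False)
        res = self.fit_ps(truth)
        sas = sas_from_dads(res, KineticModel.identity(res.basis.rates))
        assert np.allclose(sas.sas, res.dads, atol=1e-12)
        assert sas.chi2 == res.chi2

    def test_branched_scheme_recovers_generator_spectra(self):
        truth = synthdata.ps_truth(seed=3, snr=0, with_chirp=False,
                                   with_scatter=False)
        res = self.fit_ps(truth)
        model = KineticModel(
            truth.model.compartments, truth.model.transitions, truth.model.p0,
        )
        sas = sas_from_dads(res, model, rate_rtol=1e-3)
        for i, name in enumerate(model.compartments):
            expected = truth.amplitude * truth.diff_spectra[name]
            rms = np.sqrt(np.mean((sas.sas[i] - expected) ** 2))
            assert rms < 0.01 * np.abs(expected).max()

    def test_chi2_identical_through_model_application(self):
        truth = synthdata.ps_truth(seed=4, snr=30, with_chirp=False,
                                   with_scatter=False)
        res = self.fit_ps(truth)
        k1, k2 = np.sort(res.basis.rates)[::-1][:2]
        model = KineticModel(
            ["exc", "RP1", "RP23"],
            [("exc", "RP1", k1), ("RP1", None, 0.2 * k2), ("RP1", "RP23", 0.8 * k2)],
            [1, 0, 0],
        )
        sas = sas_from_dads(res, model, rate_rtol=1e-3)
        assert sas.chi2 == res.chi2  # exact equality, not approx

    def test_reconstruction_preserved(self):
        truth = synthdata.ps_truth(seed=5, snr=30, with_chirp=False,
                                   with_scatter=False)
        res = self.fit_ps(truth)
        model = KineticModel(
            truth.model.compartments, truth.model.transitions, truth.model.p0
        )
        sas = sas_from_dads(res, model, rate_rtol=1e-3)
        # F B == C SAS by construction: A maps one onto the other exactly
        assert np.allclose(sas.amplitude_map @ sas.sas, res.dads, atol=1e-12)

    def test_wrong_compartment_count_rejected(self):
        truth = synthdata.ps_truth(seed=2, snr=0, with_chirp=False,
                                   with_scatter=False)
        res = self.fit_ps(truth)
        model = KineticModel(["A", "B"], [("A", "B", res.basis.rates[0])], [1, 0])
        with pytest.raises(ValueError):
            sas_from_dads(res, model)

    def test_noisy_replicates_recover_spectra_within_one_percent_rms(self):
        rms_rel = []
        for seed in range(6):
            truth = synthdata.ps_truth(seed=300 + seed, snr=30,
                                       with_chirp=False, with_scatter=False)
            res = self.fit_ps(truth)
            model = KineticModel(
                truth.model.compartments, truth.model.transitions, truth.model.p0
            )
            sas = sas_from_dads(res, model, rate_rtol=0.3)
            i = model.compartments.index("RP23")
            expected = truth.amplitude * truth.diff_spectra["RP23"]
            rms_rel.append(
                np.sqrt(np.mean((sas.sas[i] - expected) ** 2))
                / np.abs(expected).max()
            )
        assert np.mean(rms_rel) < 0.01


class TestGroundStateAddition:
    def test_zero_fraction_is_identity(self, species, grid):
        ground = SpeciesSpectrum("FAD_ox", grid, species["FAD_ox"])
        s = species["FAD_anion"] - species["FAD_ox"]
        out, frac = add_ground_state(s, ground, fraction=0.0)
        assert np.array_equal(out, s)
        assert frac == 0.0

    def test_recovers_generating_excited_amount(self, species, grid):
        ground = SpeciesSpectrum("FAD_ox", grid, species["FAD_ox"])
        c_true = 0.0173
        sum_dads = c_true * (
            synthdata.EXCITED_STATE_BANDS.evaluate(grid) - species["FAD_ox"]
        )
        out, frac = add_ground_state(sum_dads, ground)
        assert frac == pytest.approx(c_true, rel=0.02)
        band = (grid >= 430) & (grid <= 490)
        assert out[band].min() >= -1e-12

    def test_mismatched_grids_rejected(self, species, grid):
        ground = SpeciesSpectrum("FAD_ox", grid, species["FAD_ox"])
        with pytest.raises(ValueError):
            add_ground_state(np.zeros(grid.size - 1), ground)


class TestStripFlavin:
    def test_known_mixture_recovers_coefficient(self, species, grid):
        # tryptophan radical band placed red of the flavin window, i.e.
        # flat inside it - the assumption the stripping procedure relies on
        fdiff = species["FAD_anion"] - species["FAD_ox"]
        trp = synthdata.BandModel([(640.0, 80.0, 0.5)]).evaluate(grid)
        mixture = 0.8 * fdiff + trp
        stripped, alpha = strip_flavin(mixture, fdiff, grid)
        assert alpha == pytest.approx(0.80, abs=0.01)
        window = (grid >= 430) & (grid <= 500)
        assert np.abs(stripped - trp)[window].max() < 0.02
        # stripping must remove the flavin shape from the window: the
        # residual correlation collapses relative to the raw mixture
        before = residual_flavin_correlation(mixture, fdiff, grid)
        after = residual_flavin_correlation(stripped, fdiff, grid)
        assert abs(before) > 0.99
        assert abs(after) < abs(before)
        # with a residual that is genuinely flat in the window the
        # diagnostic reads (numerically) zero
        flat_strip, _ = strip_flavin(0.8 * fdiff, fdiff, grid)
        assert residual_flavin_correlation(flat_strip, fdiff, grid) == 0.0

    def test_orthogonal_input_gives_zero(self, grid):
        fdiff = np.where((grid >= 430) & (grid <= 470), 1.0, 0.0)
        probe = np.where((grid >= 472) & (grid <= 500), 1.0, 0.0)
        _, alpha = strip_flavin(probe, fdiff, grid)
        assert alpha == pytest.approx(0.0, abs=1e-12)

    def test_self_input_fully_stripped(self, species, grid):
        fdiff = species["FAD_anion"] - species["FAD_ox"]
        stripped, alpha = strip_flavin(fdiff.copy(), fdiff, grid)
        assert alpha == pytest.approx(1.0, rel=1e-12)
        assert np.abs(stripped).max() < 1e-12

    def test_empty_flavin_signal_in_window_rejected(self, grid):
        flat = np.zeros(grid.size)
        with pytest.raises(ValueError, match="~0 inside"):
            strip_flavin(np.ones(grid.size), flat, grid)


class TestEstimateRpr:
    @pytest.mark.parametrize("alpha,expected", [(0.8, 0.2), (1.0, 0.0), (1.1, 0.0)])
    def test_complement_and_clipping(self, alpha, expected):
        assert estimate_rpr(alpha) == pytest.approx(expected)

    def test_out_of_tolerance_rejected(self):
        with pytest.raises(ValueError):
            estimate_rpr(1.5)
        with pytest.raises(ValueError):
            estimate_rpr(-0.1)

    def test_end_to_end_recovery_on_branched_synthetic_data(self):
        from cryphot.workflows import ps_recovery

        out = ps_recovery(seed=11, multistarts=2)
        assert out["rpr"] == pytest.approx(0.20, abs=0.03)
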