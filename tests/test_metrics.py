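"""Goodness-of-fit panel and CPE characterization statistics."""

import math

import numpy as np
import pytest

from dentimp import (
    CPE,
    ImpedanceSpectrum,
    characterize_cpe,
    cpe_impedance,
    fit_metrics,
    model_impedance,
    phase_error_stats,
    relative_error_stats,
    valsa_impedance,
)
from dentimp.datasets import recurrent_fit_params
from dentimp.valsa import load_reference_network


def _spectrum(re, im, f=None):
    re = np.asarray(re, dtype=float)
    if f is None:
        f = np.arange(1.0, re.size + 1)
    return ImpedanceSpectrum(f, re + 1j * np.asarray(im, dtype=float))


def reference_panel(o, s):
    """Independent re-implementation with a different summation order."""
    n = len(o)
    o_bar = math.fsum(o) / n
    sq = [(oi - si) ** 2 for oi, si in zip(o, s)]
    ab = [abs(oi - si) for oi, si in zip(o, s)]
    mae = math.fsum(sorted(ab)) / n
    rmse = math.sqrt(math.fsum(sorted(sq)) / n)
    nse = 1.0 - math.fsum(sorted(sq)) / math.fsum(sorted((oi - o_bar) ** 2 for oi in o))
    wia = 1.0 - math.fsum(sorted(sq)) / math.fsum(
        sorted((abs(si - o_bar) + abs(oi - o_bar)) ** 2 for oi, si in zip(o, s))
    )
    lce = 1.0 - math.fsum(sorted(ab)) / math.fsum(sorted(abs(oi - o_bar) for oi in o))
    mo = o_bar
    ms = math.fsum(s) / n
    cov = math.fsum((oi - mo) * (si - ms) for oi, si in zip(o, s))
    r2 = cov**2 / (
        math.fsum((oi - mo) ** 2 for oi in o) * math.fsum((si - ms) ** 2 for si in s)
    )
    return mae, rmse, r2, nse, wia, lce


class TestRelativeErrorStats:
    def test_identical_spectra_give_zero(self, young_spectrum):
        for comp in ("re", "neg_imag", "magnitude"):
            stats = relative_error_stats(young_spectrum, young_spectrum, comp)
            assert stats.max == stats.mean == stats.median == stats.sd == 0.0

    def test_hand_computed_toy_vectors(self):
        ref = _spectrum([100.0, 200.0, 300.0], [-1.0, -1.0, -1.0])
        tst = _spectrum([101.0, 198.0, 300.0], [-1.0, -1.0, -1.0])
        stats = relative_error_stats(ref, tst, "re")
        errors = [1.0, 1.0, 0.0]
        assert stats.max == pytest.approx(1.0)
        assert stats.mean == pytest.approx(2.0 / 3.0)
        assert stats.median == pytest.approx(1.0)
        assert stats.sd == pytest.approx(np.std(errors, ddof=1))

    def test_grid_mismatch_rejected(self, young_spectrum, coarse_grid):
        from dentimp import reconstruct_reference

        other = reconstruct_reference("young", coarse_grid)
        with pytest.raises(ValueError, match="grid"):
            relative_error_stats(young_spectrum, other, "re")

    def test_unknown_component_rejected(self, young_spectrum):
        with pytest.raises(ValueError, match="component"):
            relative_error_stats(young_spectrum, young_spectrum, "imag")


class TestPhaseErrorStats:
    def test_constant_offset(self):
        f = np.array([1.0, 10.0, 100.0])
        ref = ImpedanceSpectrum.from_polar(f, np.ones(3), np.full(3, -45.0))
        tst = ImpedanceSpectrum.from_polar(f, np.ones(3), np.full(3, -44.5))
        stats = phase_error_stats(ref, tst)
        assert stats.max == pytest.approx(0.5)
        assert stats.mean == pytest.approx(0.5)
        assert stats.sd == pytest.approx(0.0, abs=1e-12)


class TestFitMetricsPanel:
    def test_perfect_agreement(self, young_spectrum):
        panel = fit_metrics(young_spectrum, young_spectrum)
        for comp in (panel.real, panel.imag):
            assert comp.mae == 0.0 and comp.rmse == 0.0
            for stat in (comp.r2, comp.nse, comp.wia, comp.lce):
                assert stat == pytest.approx(1.0, abs=1e-12)

    def test_toy_vectors_against_reference_implementation(self):
        o = [1.0, 2.0, 3.0]
        s = [1.1, 2.0, 2.9]
        ref = _spectrum(o, [-v for v in o])
        tst = _spectrum(s, [-v for v in s])
        panel = fit_metrics(ref, tst)
        mae, rmse, r2, nse, wia, lce = reference_panel(o, s)
        assert panel.real.mae == pytest.approx(mae, rel=1e-12)
        assert panel.real.rmse == pytest.approx(rmse, rel=1e-12)
        assert panel.real.r2 == pytest.approx(r2, rel=1e-12)
        assert panel.real.nse == pytest.approx(nse, rel=1e-12)
        assert panel.real.wia == pytest.approx(wia, rel=1e-12)
        assert panel.real.lce == pytest.approx(lce, rel=1e-12)

    def test_random_vectors_against_reference_implementation(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 60))
            o = rng.normal(0, 10, n)
            s = o + rng.normal(0, 1, n)
            panel = fit_metrics(_spectrum(o, -np.abs(o) - 1), _spectrum(s, -np.abs(o) - 1))
            mae, rmse, r2, nse, wia, lce = reference_panel(list(o), list(s))
            assert panel.real.mae == pytest.approx(mae, rel=1e-9)
            assert panel.real.rmse == pytest.approx(rmse, rel=1e-9)
            assert panel.real.r2 == pytest.approx(r2, rel=1e-9)
            assert panel.real.nse == pytest.approx(nse, rel=1e-9)
            assert panel.real.wia == pytest.approx(wia, rel=1e-9)
            assert panel.real.lce == pytest.approx(lce, rel=1e-9)
            assert panel.real.rmse >= panel.real.mae  # Jensen

    def test_zero_variance_reference_rejected(self):
        flat = _spectrum([5.0, 5.0, 5.0], [-1.0, -2.0, -3.0])
        other = _spectrum([5.0, 6.0, 7.0], [-1.0, -2.0, -3.0])
        with pytest.raises(ValueError, match="variance"):
            fit_metrics(flat, other)

    def test_ideal_recurrent_refit_panel_is_printed_zeros_and_ones(
        self, young_spectrum, old_spectrum, study_grid
    ):
        # the recurrent re-fit reproduces the Cole reconstruction so closely
        # that every panel entry prints as 0 or 1
        for group, ref in (("young", young_spectrum), ("old", old_spectrum)):
            test = model_impedance(recurrent_fit_params(group), study_grid)
            stats = relative_error_stats(ref, test, "re")
            assert stats.max < 0.05
            panel = fit_metrics(ref, test)
            for comp in (panel.real, panel.imag):
                assert comp.r2 == pytest.approx(1.0, abs=1e-6)
                assert comp.nse == pytest.approx(1.0, abs=1e-6)
                assert comp.wia == pytest.approx(1.0, abs=1e-6)
                assert comp.lce == pytest.approx(1.0, abs=1e-3)


class TestEmulatorRegression:
    """The printed error panel of the EIA-component circuits."""

    def test_young_max_relative_errors(self, young_spectrum, young_emulated):
        assert relative_error_stats(
            young_spectrum, young_emulated, "re"
        ).max == pytest.approx(1.047, abs=5e-3)
        assert relative_error_stats(
            young_spectrum, young_emulated, "neg_imag"
        ).max == pytest.approx(1.822, abs=5e-3)

    def test_old_max_relative_errors(self, old_spectrum, old_emulated):
        assert relative_error_stats(
            old_spectrum, old_emulated, "re"
        ).max == pytest.approx(0.905, abs=5e-3)
        assert relative_error_stats(
            old_spectrum, old_emulated, "neg_imag"
        ).max == pytest.approx(1.578, abs=5e-3)

    def test_young_panel_mae_rmse(self, young_spectrum, young_emulated):
        panel = fit_metrics(young_spectrum, young_emulated)
        assert panel.real.mae == pytest.approx(19.261, abs=5e-3)
        assert panel.real.rmse == pytest.approx(41.744, abs=5e-3)
        assert panel.imag.mae == pytest.approx(15.734, abs=5e-3)
        assert panel.imag.rmse == pytest.approx(31.781, abs=5e-3)


class TestCharacterizeCPE:
    def test_ideal_cpe_self_characterization(self, study_grid):
        target = CPE(0.5, 15.6e-6)
        spectrum = ImpedanceSpectrum(
            study_grid.frequencies, cpe_impedance(target, study_grid.omega)
        )
        ch = characterize_cpe(spectrum, target)
        assert ch.order_mean == pytest.approx(0.5, abs=1e-12)
        assert ch.order_sd == pytest.approx(0.0, abs=1e-12)
        assert ch.pseudo_cap_mean == pytest.approx(15.6e-6, rel=1e-9)
        assert ch.magnitude_error.max == pytest.approx(0.0, abs=1e-9)
        assert ch.phase_error.max == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize(
        "group, element, c_target, mag_max, phase_max, order_cov",
        [
            ("young", "cpe_s", 15.6e-6, 1.150, 0.623, 0.644),
            ("young", "cpe_d", 30.1e-6, 1.188, 0.556, 0.700),
            ("old", "cpe_s", 13.5e-6, 1.075, 0.606, 0.631),
            ("old", "cpe_d", 169e-6, 1.188, 0.526, 0.597),
        ],
    )
    def test_reference_network_characterization(
        self, study_grid, group, element, c_target, mag_max, phase_max, order_cov
    ):
        net = load_reference_network(group, element)
        spectrum = valsa_impedance(net, study_grid)
        ch = characterize_cpe(spectrum, CPE(0.5, c_target))
        assert ch.order_mean == pytest.approx(0.5, abs=2e-3)
        assert ch.magnitude_error.max == pytest.approx(mag_max, abs=5e-3)
        assert ch.phase_error.max == pytest.approx(phase_max, abs=5e-3)
        assert ch.order_cov == pytest.approx(order_cov, abs=0.05)
        assert ch.pseudo_cap_mean == pytest.approx(c_target, rel=0.05)
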