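"""Overlap integral, Förster distance, efficiency relations and unmixing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdfret import fret
from cdfret import synthetic as syn
from cdfret.spectra import Spectrum
from .conftest import gaussian_spectrum


class TestOverlapIntegral:
    def test_disjoint_bands_give_zero(self):
        donor = gaussian_spectrum(400.0, 3.0, lo=350.0, hi=650.0)
        acceptor = gaussian_spectrum(600.0, 3.0, lo=350.0, hi=650.0,
                                     kind="molar_absorptivity")
        j = fret.overlap_integral(donor, acceptor)
        assert j.j_nm4 == pytest.approx(0.0, abs=1e-3)

    def test_matches_fine_grid_brute_force(self, donor_band, acceptor_band):
        j = fret.overlap_integral(donor_band, acceptor_band)
        # independent oracle: direct quadrature of the analytic integrand
        # at 0.01 nm step, donor area-normalized
        lam = np.arange(350.0, 650.0 + 0.005, 0.01)
        fd = 100.0 * np.exp(-((lam - 456.0) ** 2) / (2 * 25.0**2))
        eps = 1.2e4 * np.exp(-((lam - 445.0) ** 2) / (2 * 20.0**2))
        oracle = np.trapezoid(fd * eps * lam**4, lam) / np.trapezoid(fd, lam)
        assert j.j_nm4 == pytest.approx(oracle, rel=1e-3)

    def test_invariant_to_donor_amplitude(self, donor_band, acceptor_band):
        scaled = donor_band.with_values(donor_band.values * 37.5)
        j1 = fret.overlap_integral(donor_band, acceptor_band)
        j2 = fret.overlap_integral(scaled, acceptor_band)
        assert j2.j_nm4 == pytest.approx(j1.j_nm4, rel=1e-12)

    def test_linear_in_acceptor_absorptivity(self, donor_band, acceptor_band):
        doubled = acceptor_band.with_values(acceptor_band.values * 2)
        j1 = fret.overlap_integral(donor_band, acceptor_band)
        j2 = fret.overlap_integral(donor_band, doubled)
        assert j2.j_nm4 == pytest.approx(2 * j1.j_nm4, rel=1e-12)

    def test_narrow_coincident_bands_approach_delta_limit(self):
        # as both widths shrink, J -> eps0 * lambda0^4
        lam0, eps0 = 500.0, 1.0e4
        donor = gaussian_spectrum(lam0, 0.1, lo=480.0, hi=520.0, step=0.01)
        acceptor = gaussian_spectrum(lam0, 2.0, amplitude=eps0, lo=480.0,
                                     hi=520.0, step=0.01,
                                     kind="molar_absorptivity")
        j = fret.overlap_integral(donor, acceptor)
        assert j.j_nm4 == pytest.approx(eps0 * lam0**4, rel=0.01)

    def test_rejects_absorbance_kind(self, donor_band):
        bad = gaussian_spectrum(445.0, 20.0, kind="absorbance")
        with pytest.raises(ValueError, match="molar absorptivity"):
            fret.overlap_integral(donor_band, bad)

    def test_disjoint_supports_raise(self):
        donor = gaussian_spectrum(400.0, 10.0, lo=350.0, hi=450.0)
        acceptor = gaussian_spectrum(550.0, 10.0, lo=500.0, hi=650.0,
                                     kind="molar_absorptivity")
        with pytest.raises(ValueError, match="disjoint"):
            fret.overlap_integral(donor, acceptor)


class TestForsterDistance:
    def test_hand_evaluated_reference_point(self):
        # kappa2 = 2/3, eta = 1.336, phi = 0.54, J = 1.30e14 M^-1 cm^-1 nm^4
        r0 = fret.forster_distance_from_nm4(1.30e14, phi=0.54)
        assert r0 == pytest.approx(3.3, abs=0.05)

    def test_phi_to_zero_limit(self):
        # R0 scales as phi^(1/6), so it vanishes as phi -> 0
        assert fret.forster_distance_from_nm4(1e14, phi=1e-18) < 1e-2

    def test_sixth_root_scaling_in_phi(self):
        r1 = fret.forster_distance_from_nm4(1e14, phi=0.3)
        r2 = fret.forster_distance_from_nm4(1e14, phi=0.6)
        assert r2 / r1 == pytest.approx(2 ** (1 / 6), rel=1e-12)

    def test_rejects_nonpositive_inputs(self):
        with pytest.raises(ValueError):
            fret.forster_distance(-1e-14, phi=0.5)
        with pytest.raises(ValueError):
            fret.forster_distance(1e-14, phi=0.0)

    @settings(deadline=None, max_examples=40)
    @given(log_j=st.floats(12.0, 16.0), phi=st.floats(0.05, 1.0),
           kappa2=st.floats(0.1, 4.0))
    def test_dual_unit_cross_check(self, log_j, phi, kappa2):
        """cm-scale and Å-scale formulations agree within 1% over 4 decades."""
        j_nm4 = 10.0**log_j
        r0_cm_form = fret.forster_distance(j_nm4 * fret.NM4_TO_CM3,
                                           kappa2=kappa2, phi=phi)
        r0_angstrom_form = 0.211 * (kappa2 * 1.336**-4 * phi * j_nm4) ** (1 / 6)
        assert r0_cm_form == pytest.approx(r0_angstrom_form / 10.0, rel=0.01)


class TestEfficiencyFromFluorescence:
    def test_no_quench_is_zero(self):
        assert fret.efficiency_from_fluorescence(5.0, 5.0) == 0.0

    @pytest.mark.parametrize("frac,expected", [(0.09, 0.91), (0.16, 0.84)])
    def test_strong_quench_values(self, frac, expected):
        assert fret.efficiency_from_fluorescence(frac * 10.0, 10.0) == \
            pytest.approx(expected)

    def test_small_violation_clips_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            e = fret.efficiency_from_fluorescence(10.1, 10.0)
        assert e == 0.0
        assert "clipping" in caplog.text

    def test_large_violation_raises(self):
        with pytest.raises(ValueError, match="units"):
            fret.efficiency_from_fluorescence(11.0, 10.0)

    def test_zero_donor_reference_raises(self):
        with pytest.raises(ValueError):
            fret.efficiency_from_fluorescence(1.0, 0.0)


class TestEfficiencyDistanceRelation:
    def test_r_equals_r0_single_acceptor_is_half(self):
        assert fret.efficiency_from_distance(3.3, 3.3, 1) == pytest.approx(0.5)

    def test_hand_arithmetic_point(self):
        # 3.3^6 / (3.3^6 + 1.8^6) = 0.9743...
        assert fret.efficiency_from_distance(1.8, 3.3, 1) == pytest.approx(
            3.3**6 / (3.3**6 + 1.8**6), rel=1e-12)
        assert fret.efficiency_from_distance(1.8, 3.3, 1) == pytest.approx(
            0.9743, abs=5e-4)

    def test_many_acceptors_limit(self):
        assert fret.efficiency_from_distance(5.0, 3.3, 1e9) == pytest.approx(
            1.0, abs=1e-6)

    def test_monotone_in_r_n_r0(self):
        rs = np.linspace(1.0, 8.0, 30)
        es = [fret.efficiency_from_distance(r, 3.3, 1) for r in rs]
        assert np.all(np.diff(es) < 0)
        ns = np.arange(1, 20)
        es = [fret.efficiency_from_distance(3.0, 3.3, n) for n in ns]
        assert np.all(np.diff(es) > 0)

    def test_inversion_point(self):
        assert fret.distance_from_efficiency(0.5, 3.3, 1) == pytest.approx(3.3)
        assert fret.distance_from_efficiency(0.91, 3.3, 1) == pytest.approx(
            2.24, abs=0.01)

    @settings(deadline=None, max_examples=60)
    @given(e=st.floats(1e-6, 1 - 1e-6), n=st.integers(1, 50),
           r0=st.floats(0.5, 10.0))
    def test_round_trip_to_machine_precision(self, e, n, r0):
        r = fret.distance_from_efficiency(e, r0, n)
        assert fret.efficiency_from_distance(r, r0, n) == pytest.approx(
            e, rel=1e-12)

    def test_degenerate_efficiency_raises(self):
        for e in (0.0, 1.0):
            with pytest.raises(ValueError):
                fret.distance_from_efficiency(e, 3.3, 1)


class TestUnmix:
    def test_exact_mixture_recovered(self, donor_band):
        acceptor = gaussian_spectrum(521.0, 30.0, amplitude=100.0)
        mix = Spectrum(donor_band.wavelengths,
                       0.3 * donor_band.values + 0.7 * acceptor.values)
        res = fret.unmix(mix, donor_band, acceptor)
        assert res.donor_coeff == pytest.approx(0.3, abs=1e-9)
        assert res.acceptor_coeff == pytest.approx(0.7, abs=1e-9)
        assert res.residual_rms < 1e-9

    def test_donor_only_composite(self, donor_band):
        acceptor = gaussian_spectrum(521.0, 30.0, amplitude=100.0)
        res = fret.unmix(donor_band, donor_band, acceptor)
        assert res.donor_coeff == pytest.approx(1.0, abs=1e-9)
        assert res.acceptor_coeff == pytest.approx(0.0, abs=1e-9)

    def test_collinear_references_rejected(self, donor_band):
        near_copy = donor_band.with_values(donor_band.values * 2.0)
        with pytest.raises(ValueError, match="collinear"):
            fret.unmix(donor_band, donor_band, near_copy)

    def test_random_noisy_mixtures_within_3pct_rms(self, donor_band):
        acceptor = gaussian_spectrum(521.0, 30.0, amplitude=100.0)
        rng = np.random.default_rng(42)
        truths, estimates = [], []
        for _ in range(100):
            a, b = rng.uniform(0.05, 1.0, size=2)
            clean = a * donor_band.values + b * acceptor.values
            noisy = clean * (1 + rng.normal(0, 0.01, clean.size))
            res = fret.unmix(Spectrum(donor_band.wavelengths, noisy),
                             donor_band, acceptor)
            truths.append([a, b])
            estimates.append([res.donor_coeff, res.acceptor_coeff])
        truths = np.asarray(truths)
        estimates = np.asarray(estimates)
        rms_err = np.sqrt(np.mean((estimates - truths) ** 2, axis=0))
        assert np.all(rms_err / np.mean(truths, axis=0) < 0.03)


class TestSelectExcitation:
    def test_reddest_band_wins_for_445nm_acceptor(self, acceptor_band):
        cfg = syn.get_preset("low_donor")
        candidates = {x: syn.make_donor_emission(cfg, x)
                      for x in (320.0, 340.0, 360.0)}
        assert fret.select_excitation(candidates, acceptor_band) == 360.0

    def test_single_candidate(self, donor_band, acceptor_band):
        assert fret.select_excitation({340.0: donor_band}, acceptor_band) == 340.0

    def test_tie_breaks_to_lowest_excitation(self, donor_band, acceptor_band):
        assert fret.select_excitation(
            {340.0: donor_band, 320.0: donor_band}, acceptor_band) == 320.0

    def test_empty_candidates_raise(self, acceptor_band):
        with pytest.raises(ValueError):
            fret.select_excitation({}, acceptor_band)


class TestRegimeCheck:
    def test_reported_distance_pair_is_in_regime(self):
        ok, ratio = fret.check_regime(1.8, 3.3)
        assert ok
        assert ratio == pytest.approx(1.8 / 3.3)

    def test_boundary_is_strict(self):
        ok, _ = fret.check_regime(0.5 * 3.3, 3.3)
        assert not ok

    def test_r_equal_r0(self):
        ok, ratio = fret.check_regime(3.3, 3.3)
        assert ok and ratio == 1.0


class TestFretParamsConsistency:
    def test_reported_triple_is_flagged_inconsistent(self):
        # E = 0.91 with R0 = 3.3 nm would need r = 2.24 nm at n = 1;
        # r = 1.8 nm is not jointly consistent for any n >= 1
        params = fret.FretParams(efficiency=0.91, r0_nm=3.3, r_nm=1.8,
                                 n_acceptors=1)
        assert params.is_consistent() is False

    def test_self_consistent_triple_passes(self):
        e = fret.efficiency_from_distance(2.24, 3.3, 1)
        params = fret.FretParams(efficiency=e, r0_nm=3.3, r_nm=2.24,
                                 n_acceptors=1)
        assert params.is_consistent() is True

    def test_missing_fields_return_none(self):
        assert fret.FretParams(efficiency=0.5).is_consistent() is None


class TestTitrationAnalysis:
    def test_noise_free_recovery_of_planted_efficiency(self):
        cfg = syn.get_preset("low_donor", noise_sigma=0.0)
        analysis = fret.analyze_titration(syn.simulate_titration(cfg))
        assert analysis.efficiency == pytest.approx(0.91, abs=1e-6)
        assert analysis.binding.K == pytest.approx(2.7e4, rel=1e-6)

    def test_apparent_efficiency_saturates_toward_planted(self):
        cfg = syn.get_preset("low_donor", noise_sigma=0.0)
        analysis = fret.analyze_titration(syn.simulate_titration(cfg))
        app = analysis.apparent_efficiency
        assert np.all(np.diff(app) > 0)
        assert app[-1] < cfg.planted_E
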