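import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit

from groovedyn import biophys as bp
from groovedyn import synthetic_data as sd
from groovedyn.biophys import (Spectrum1D, cest_summary, ddg_from_pka,
                               fit_dissociation, fit_lorentzian_mixture,
                               fit_melt_bigaussian, fit_steady_state,
                               kon_from_koff_kd, lorentzian)


class TestEnergetics:
    def test_histidine_burial_destabilization(self):
        # pKa drop from 6.1 (free) to 4.9 (bound) at 298.15 K
        ddg = ddg_from_pka(4.9, 6.1, 298.15)
        assert round(ddg, 1) == 1.6

    def test_equal_pka_zero(self):
        assert ddg_from_pka(6.0, 6.0) == 0.0

    def test_unit_shift_arithmetic(self):
        assert ddg_from_pka(5.0, 6.0, 298.15) == pytest.approx(
            2.303 * 1.987 * 298.15 / 1000, rel=1e-9)
        assert ddg_from_pka(5.0, 6.0) == pytest.approx(1.364, abs=5e-4)


class TestKon:
    def test_printed_rates(self):
        assert kon_from_koff_kd(0.039, 62e-6) == pytest.approx(629, rel=0.01)
        assert kon_from_koff_kd(1.0, 1.0) == 1.0

    def test_zero_kd_rejected(self):
        with pytest.raises(ZeroDivisionError):
            kon_from_koff_kd(0.1, 0.0)

    def test_mass_action_round_trip(self):
        """kon/koff chosen, equilibrium simulated, fitted KD returns
        koff/kon."""
        kon_true, koff_true = 1e4, 0.05
        KD_true = koff_true / kon_true
        b_tot = 1e-9  # trace ligand: no titrant depletion

        def equilibrate(a_tot):
            def rhs(t, y):
                ab = y[0]
                return [kon_true * (a_tot - ab) * (b_tot - ab)
                        - koff_true * ab]
            sol = solve_ivp(rhs, [0, 5000], [0.0], rtol=1e-10, atol=1e-15)
            return sol.y[0, -1] / b_tot  # fractional saturation

        conc = np.geomspace(KD_true / 10, KD_true * 10, 8)
        resp = np.array([equilibrate(c) for c in conc])
        KD_fit, Rmax, _ = fit_steady_state(conc, resp)
        assert KD_fit == pytest.approx(KD_true, rel=1e-3)


class TestDissociation:
    def test_noiseless_exact(self):
        t = np.linspace(0, 60, 100)
        y = 2.0 * np.exp(-0.05 * t) + 0.3
        fit = fit_dissociation(t, y)
        assert fit.koff[0] == pytest.approx(0.05, abs=1e-9)

    def test_printed_rate_recovery_under_noise(self):
        rates = []
        for seed in range(100):
            t, y, _ = sd.gen_binding_data("dissociation", seed=seed,
                                          noise=0.01)
            rates.append(fit_dissociation(t, y).koff[0])
        assert np.median(rates) == pytest.approx(0.039, rel=0.10)

    def test_biphasic_noiseless(self):
        t = np.linspace(0, 300, 400)
        y = 1.0 * np.exp(-0.1 * t) + 1.0 * np.exp(-0.01 * t)
        fit = fit_dissociation(t, y, n_phases=2)
        assert fit.koff[0] == pytest.approx(0.1, rel=0.01)
        assert fit.koff[1] == pytest.approx(0.01, rel=0.01)

    def test_biphasic_beats_monophasic_on_biphasic_data(self):
        t, y, _ = sd.gen_binding_data("dissociation", seed=3, noise=0.005,
                                      koff=0.1, koff2=0.01, amp2=1.0)
        mono = fit_dissociation(t, y, n_phases=1)
        bi = fit_dissociation(t, y, n_phases=2)
        assert bi.residual_norm < mono.residual_norm

    def test_rising_signal_flagged(self):
        t = np.linspace(0, 10, 50)
        fit = fit_dissociation(t, np.linspace(0, 1, 50))
        assert fit.warnings

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_dissociation([0, 1, 2], [3, 2, 1])


class TestSteadyState:
    def test_noiseless_exact(self):
        c = np.geomspace(1e-6, 1e-3, 8)
        KD, Rmax = 62e-6, 120.0
        r = Rmax * c / (KD + c)
        KD_fit, Rmax_fit, _ = fit_steady_state(c, r)
        assert KD_fit == pytest.approx(KD, rel=1e-6)
        assert Rmax_fit == pytest.approx(Rmax, rel=1e-6)

    def test_half_saturation_property(self):
        c = np.geomspace(1e-6, 1e-3, 10)
        KD, Rmax = 5e-5, 80.0
        KD_fit, Rmax_fit, _ = fit_steady_state(c, Rmax * c / (KD + c))
        assert Rmax_fit * KD_fit / (KD_fit + KD_fit) == pytest.approx(
            Rmax_fit / 2)

    def test_noise_recovery_median(self):
        kds = []
        for seed in range(100):
            c, r, _ = sd.gen_binding_data("isotherm", seed=seed, noise=0.02)
            kds.append(fit_steady_state(c, r)[0])
        assert np.median(kds) == pytest.approx(62e-6, rel=0.05)

    def test_extrapolation_warning(self):
        c = np.geomspace(1e-8, 1e-6, 6)
        KD = 1e-2
        with pytest.warns(UserWarning, match="extrapolation"):
            fit_steady_state(c, 10 * c / (KD + c))


class TestMelt:
    def test_single_transition_noiseless(self):
        T, y, _ = sd.gen_binding_data("melt", seed=0, noise=0.0, Tm1=65.0)
        tm1, _, params = fit_melt_bigaussian(T, y)
        assert tm1 == pytest.approx(65.0, abs=1e-3)
        assert params["single_transition"]

    def test_two_transitions_noiseless(self):
        T, y, _ = sd.gen_binding_data("melt", seed=0, noise=0.0,
                                      Tm1=55.0, Tm2=70.0)
        tm1, tm2, _ = fit_melt_bigaussian(T, y)
        assert sorted([tm1, tm2]) == pytest.approx([55.0, 70.0], abs=0.1)

    def test_noise_recovery(self):
        tms = []
        for seed in range(50):
            T, y, _ = sd.gen_binding_data("melt", seed=seed, noise=0.03,
                                          Tm1=55.0, Tm2=70.0)
            tm1, tm2, _ = fit_melt_bigaussian(T, y)
            tms.append(sorted([tm1, tm2]))
        med = np.median(tms, axis=0)
        assert med[0] == pytest.approx(55.0, abs=0.5)
        assert med[1] == pytest.approx(70.0, abs=0.5)


class TestLorentzianMixture:
    def test_single_component_noiseless(self):
        x = np.linspace(-130, -120, 3000)
        spec = Spectrum1D(x, lorentzian(x, -125.18, 0.4, 2.0))
        comp, = fit_lorentzian_mixture(spec, 1)
        assert comp.center == pytest.approx(-125.18, abs=1e-6)
        assert comp.fwhm == pytest.approx(0.4, rel=1e-6)
        assert comp.area_fraction == pytest.approx(1.0)

    def test_three_state_area_split_recovered(self):
        fracs = []
        for seed in range(25):
            spec, _ = sd.gen_spectrum(seed=seed, snr=20)
            comps = fit_lorentzian_mixture(spec, 3, seed=seed)
            fracs.append([c.area_fraction for c in comps])
        med = np.median(fracs, axis=0) * 100
        assert med[0] == pytest.approx(8.0, abs=3.0)
        assert med[1] == pytest.approx(77.0, abs=3.0)
        assert med[2] == pytest.approx(15.0, abs=3.0)

    def test_overlapping_pair_matches_grid_search(self):
        x = np.linspace(-127, -123, 4000)
        truth = [(-125.3, 0.5, 1.0), (-124.9, 0.5, 0.8)]
        y = sum(lorentzian(x, *p) for p in truth)
        spec = Spectrum1D(x, y)
        comps = fit_lorentzian_mixture(spec, 2, seed=0)
        # dense grid search over the two centers, widths/areas by linear
        # refit
        best = (np.inf, None)
        for c1 in np.arange(-125.6, -125.0, 0.02):
            for c2 in np.arange(-125.2, -124.6, 0.02):
                def model(x, w1, a1, w2, a2):
                    return (lorentzian(x, c1, abs(w1), a1)
                            + lorentzian(x, c2, abs(w2), a2))
                try:
                    popt, _ = curve_fit(model, x, y,
                                        p0=[0.5, 1.0, 0.5, 1.0],
                                        maxfev=5000)
                except RuntimeError:
                    continue
                res = np.linalg.norm(y - model(x, *popt))
                if res < best[0]:
                    best = (res, (c1, c2))
        fit_res = np.linalg.norm(
            y - sum(lorentzian(x, c.center, c.fwhm, c.area) for c in comps))
        assert fit_res <= best[0] + 1e-6

    def test_area_fractions_sum_to_one(self):
        spec, _ = sd.gen_spectrum(seed=9, snr=20)
        comps = fit_lorentzian_mixture(spec, 3, seed=9)
        assert sum(c.area_fraction for c in comps) == pytest.approx(1.0,
                                                                    abs=1e-6)


class TestCEST:
    def test_no_transfer_empty_graph(self):
        n = 3
        tr = np.zeros((n, n))
        np.fill_diagonal(tr, 0.95)
        ref, fam, comps, _ = sd.gen_cest_family(transfer=tr, snr=100,
                                                seed=0)
        peaks = fit_lorentzian_mixture(ref, 3, seed=0)
        res = cest_summary(fam, ref, peaks)
        assert res.edges == []
        assert sorted(res.isolated) == [0, 1, 2]

    def test_full_exchange_fully_connected(self):
        ref, fam, comps, _ = sd.gen_cest_family(snr=100, seed=1)
        peaks = fit_lorentzian_mixture(ref, 3, seed=1)
        res = cest_summary(fam, ref, peaks)
        assert len(res.edges) == 6
        assert res.isolated == []
        d = np.diag(res.reduction)
        assert np.all(d > 0.8)

    def test_non_exchanging_peak_isolated(self):
        tr = np.full((3, 3), 0.5)
        np.fill_diagonal(tr, 0.95)
        tr[2, :2] = 0.0
        tr[:2, 2] = 0.0
        ref, fam, comps, _ = sd.gen_cest_family(transfer=tr, snr=100,
                                                seed=2)
        peaks = fit_lorentzian_mixture(ref, 3, seed=2)
        res = cest_summary(fam, ref, peaks)
        assert 2 in res.isolated
        assert (0, 1) in res.edges and (1, 0) in res.edges

    def test_contamination_warning_near_untargeted_peak(self):
        # peaks 0.6 ppm apart: irradiating between them saturates both
        comps = [(-125.6, 0.2, 0.5), (-125.0, 0.2, 0.5)]
        ref, fam, _, _ = sd.gen_cest_family(components=comps, snr=100,
                                            seed=3)
        peaks = fit_lorentzian_mixture(ref, 2, seed=3)
        bad = {-125.35: next(iter(fam.values()))}
        with pytest.warns(UserWarning, match="contamination"):
            cest_summary(bad, ref, peaks)
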