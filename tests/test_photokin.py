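"""Kinetic fitting and oxidant inversion arithmetic."""

import numpy as np
import pytest

from photoxkit.constants import RateConstantTable
from photoxkit.photokin import (
    KineticFitError,
    ProbeTimeSeries,
    fit_first_order,
    fit_formation_rate,
    hydroxyl,
    singlet_oxygen,
    triplet_hdo,
    triplet_tmp,
)
from photoxkit.pipeline import recover_oxidants
from photoxkit.synthio import ProbeDesign, SynthConfig, gen_dataset

CONST = RateConstantTable()
HOURS5 = np.linspace(0, 5 * 3600, 7)


def decay_series(k, c0=1e-5, t=HOURS5, probe="FFA", rep=0):
    return ProbeTimeSeries("X", probe, t, c0 * np.exp(-k * t), rep, c0, "probe")


class TestFirstOrder:
    def test_exact_exponential(self):
        fit = fit_first_order(decay_series(1e-4))
        assert fit.value == pytest.approx(1e-4, rel=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_series_zero_rate(self):
        s = ProbeTimeSeries("X", "FFA", HOURS5, np.full(7, 1e-5), 0, 1e-5, "probe")
        fit = fit_first_order(s)
        assert fit.value == 0.0

    def test_nonpositive_points_excluded_with_warning(self):
        c = 1e-5 * np.exp(-1e-4 * HOURS5)
        c[-1] = 0.0
        s = ProbeTimeSeries("X", "FFA", HOURS5, c, 0, 1e-5, "probe")
        with pytest.warns(UserWarning, match="non-positive"):
            fit = fit_first_order(s)
        assert fit.value == pytest.approx(1e-4, rel=1e-10)
        assert fit.n_points == 6

    def test_too_few_points_raises(self):
        s = ProbeTimeSeries("X", "FFA", np.array([0.0, 60.0, 120.0]),
                            np.array([1e-5, 0.0, 0.0]), 0, 1e-5, "probe")
        with pytest.warns(UserWarning):
            with pytest.raises(KineticFitError):
                fit_first_order(s)

    def test_noisy_replicates_recover_truth_within_two_se(self):
        # Monte-Carlo: 2% noise, 3 replicates, true k = 5e-5 s^-1
        rng = np.random.default_rng(42)
        true_k = 5e-5
        recovered = []
        for _ in range(200):
            reps = []
            for r in range(3):
                c = 1e-5 * np.exp(-true_k * HOURS5)
                c = c * (1 + rng.normal(0, 0.02, size=c.shape))
                reps.append(ProbeTimeSeries("X", "FFA", HOURS5, np.clip(c, 0, None), r, 1e-5, "probe"))
            recovered.append(fit_first_order(reps).value)
        mean = np.mean(recovered)
        se = np.std(recovered, ddof=1) / np.sqrt(len(recovered))
        assert abs(mean - true_k) < 2 * se + 1e-9 * true_k


class TestFormationRate:
    def test_exact_line(self):
        s = ProbeTimeSeries("X", "benzene-phenol", HOURS5, 1e-11 * HOURS5, 0, 2e-3, "product")
        fit = fit_formation_rate(s, precursor_initial_M=2e-3)
        assert fit.value == pytest.approx(1e-11, rel=1e-10)

    def test_zero_product(self):
        s = ProbeTimeSeries("X", "benzene-phenol", HOURS5, np.zeros(7), 0, 2e-3, "product")
        assert fit_formation_rate(s, 2e-3).value == 0.0

    def test_saturating_curve_early_window(self):
        # P(t) = a (1 - exp(-b t)): initial slope a*b; early window keeps
        # points with P < 10% of the precursor, i.e. small b*t
        a, b, c0 = 5e-6, 1e-5, 2e-4
        t = np.linspace(0, 3600, 13)
        p = a * (1 - np.exp(-b * t))
        s = ProbeTimeSeries("X", "benzene-phenol", t, p, 0, c0, "product")
        fit = fit_formation_rate(s, precursor_initial_M=c0)
        assert fit.value == pytest.approx(a * b, rel=0.03)

    def test_too_few_points_raises(self):
        s = ProbeTimeSeries("X", "benzene-phenol", np.array([0.0, 100.0]),
                            np.array([0.0, 1e-9]), 0, 2e-3, "product")
        with pytest.raises(KineticFitError):
            fit_formation_rate(s, 2e-3)


class TestChannelArithmetic:
    def test_singlet_oxygen_chain(self):
        fit = fit_first_order(decay_series(1e-4))
        res = singlet_oxygen(fit, CONST, ra=2.2e-6)
        assert res.riss_M == pytest.approx(1e-12, rel=1e-10)
        assert res.production_M_s == pytest.approx(1e-12 * 2.2e5, rel=1e-10)
        assert res.phi == pytest.approx(0.10, rel=1e-10)

    def test_singlet_oxygen_requires_positive_ra(self):
        fit = fit_first_order(decay_series(1e-4))
        with pytest.raises(ValueError):
            singlet_oxygen(fit, CONST, ra=0.0)

    def test_hydroxyl_production_from_phenol_yield(self):
        t = HOURS5
        s = ProbeTimeSeries("X", "benzene-phenol", t, 5.3e-12 * t, 0, 2e-3, "product")
        fit = fit_formation_rate(s, 2e-3)
        res = hydroxyl(fit, CONST, benzene_conc_M=2e-3, ra=1e-6)
        assert res.production_M_s == pytest.approx(1e-11, rel=1e-9)
        assert res.riss_M == pytest.approx(1e-11 / (7.8e9 * 2e-3), rel=1e-9)

    def test_hydroxyl_zero_rate_all_zero(self):
        s = ProbeTimeSeries("X", "benzene-phenol", HOURS5, np.zeros(7), 0, 2e-3, "product")
        res = hydroxyl(fit_formation_rate(s, 2e-3), CONST, 2e-3, ra=1e-6)
        assert res.production_M_s == 0 and res.riss_M == 0 and res.phi == 0

    def test_hydroxyl_warns_outside_scavenging_design(self):
        s = ProbeTimeSeries("X", "benzene-phenol", HOURS5, 1e-12 * HOURS5, 0, 2e-3, "product")
        fit = fit_formation_rate(s, 2e-3)
        with pytest.warns(UserWarning, match="scavenging"):
            hydroxyl(fit, CONST, benzene_conc_M=1e-5, ra=1e-6)

    def _oxidant(self, channel, riss, se=0.0):
        from photoxkit.photokin import OxidantResult

        return OxidantResult("X", channel, riss, 0.0, 1e-6, 0.0, riss_stderr=se)

    def test_tmp_without_companions_is_uncorrected(self):
        fit = fit_first_order(decay_series(3e-4, probe="TMP"))
        res = triplet_tmp(fit, self._oxidant("hydroxyl", 0.0),
                          self._oxidant("singlet_oxygen", 0.0), CONST, ra=1e-6)
        assert res.riss_M == pytest.approx(3e-4 / 3e9, rel=1e-10)
        assert not res.flags

    def test_tmp_exact_cancellation_zero_without_flag(self):
        oh = self._oxidant("hydroxyl", 1e-16)
        so = self._oxidant("singlet_oxygen", 1e-12)
        k_obs = CONST.k_tmp_oh * 1e-16 + CONST.k_tmp_singlet_oxygen * 1e-12
        fit = fit_first_order(decay_series(k_obs, probe="TMP"))
        res = triplet_tmp(fit, oh, so, CONST, ra=1e-6)
        assert res.riss_M == pytest.approx(0.0, abs=1e-18)
        assert "negative_corrected_rate_floored" not in res.flags

    def test_tmp_negative_corrected_rate_floored_and_flagged(self):
        oh = self._oxidant("hydroxyl", 1e-14)  # correction exceeds k_obs
        so = self._oxidant("singlet_oxygen", 1e-11)
        fit = fit_first_order(decay_series(1e-5, probe="TMP"))
        res = triplet_tmp(fit, oh, so, CONST, ra=1e-6)
        assert res.riss_M == 0.0
        assert "negative_corrected_rate_floored" in res.flags

    def test_missing_companions_raise(self):
        fit = fit_first_order(decay_series(1e-4, probe="TMP"))
        with pytest.raises(ValueError):
            triplet_tmp(fit, None, None, CONST, ra=1e-6)


class TestTripletHDO:
    def hdo_series(self, rate, t=np.linspace(0, 1200, 7), h0=1e-4):
        return [ProbeTimeSeries("X", "HDO", t, rate * t, 0, h0, "product")]

    def test_hyperbola_double_reciprocal_exact(self):
        # R = R_max [HDO] / (K + [HDO]) makes 1/R linear in 1/[HDO]:
        # the intercept recovers R_max exactly
        r_max, k_half = 2e-10, 1e-4
        by_conc = {
            h0: self.hdo_series(r_max * h0 / (k_half + h0), h0=h0)
            for h0 in (2.5e-5, 5e-5, 1e-4, 2e-4, 5e-4)
        }
        res = triplet_hdo(by_conc, CONST, ra=1e-6)
        assert res.production_M_s == pytest.approx(r_max / CONST.f_iso, rel=1e-9)
        assert res.riss_M == pytest.approx(r_max / CONST.f_iso / CONST.k_triplet_quench, rel=1e-9)

    def test_saturated_rates_give_common_rate(self):
        by_conc = {h0: self.hdo_series(3e-10, h0=h0) for h0 in (5e-5, 1e-4, 5e-4)}
        res = triplet_hdo(by_conc, CONST, ra=1e-6)
        assert res.production_M_s == pytest.approx(3e-10 / CONST.f_iso, rel=1e-9)

    def test_nonpositive_intercept_flagged(self):
        # rates rising faster than proportionally => negative 1/R intercept
        concs = np.array([1e-4, 2e-4, 4e-4])
        x = 1.0 / concs
        y = -1e9 + 5e5 * x  # all y > 0 but intercept < 0
        by_conc = {c: self.hdo_series(1.0 / yi, h0=c) for c, yi in zip(concs, y)}
        res = triplet_hdo(by_conc, CONST, ra=1e-6)
        assert "extrapolation_failure_nonpositive_intercept" in res.flags
        assert np.isnan(res.phi)

    def test_requires_three_levels(self):
        by_conc = {1e-4: self.hdo_series(1e-10), 2e-4: self.hdo_series(1.5e-10)}
        with pytest.raises(ValueError):
            triplet_hdo(by_conc, CONST, ra=1e-6)


class TestRoundTripAndInvariance:
    def test_noiseless_recovery_all_channels(self, noiseless_dataset):
        recovered = recover_oxidants(noiseless_dataset)
        for sid in noiseless_dataset.sample_ids():
            t = noiseless_dataset.truth[sid]
            for ch, res in recovered[sid].items():
                tol = 0.005 if ch == "triplet_hdo" else 0.001
                assert res.phi == pytest.approx(t.phi[ch], rel=tol), (sid, ch)
                assert res.riss_M == pytest.approx(t.riss[ch], rel=tol), (sid, ch)

    def test_phi_invariant_to_probe_concentration(self):
        # doubling FFA and TMP initial concentrations must not move phi
        base = SynthConfig(n_fractions=1, series=("COM",), include_bulk=False)
        doubled = SynthConfig(
            n_fractions=1, series=("COM",), include_bulk=False,
            design=ProbeDesign(ffa_initial_M=2e-5, tmp_initial_M=2e-5),
        )
        r1 = recover_oxidants(gen_dataset(base, seed=1))
        r2 = recover_oxidants(gen_dataset(doubled, seed=1))
        for ch in ("singlet_oxygen", "triplet_tmp"):
            assert r1["C1"][ch].phi == pytest.approx(r2["C1"][ch].phi, rel=1e-9)

    def test_replicate_uncertainty_propagates(self):
        cfg = SynthConfig(n_fractions=1, series=("COM",), include_bulk=False,
                          design=ProbeDesign(noise_sd=0.02))
        rec = recover_oxidants(gen_dataset(cfg, seed=3))
        res = rec["C1"]["singlet_oxygen"]
        assert res.riss_stderr > 0
        assert res.phi_stderr > 0
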