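"""Synthetic-data generator: truths, trends, determinism, and oracles."""

import numpy as np
import pytest
from scipy import stats

from photoxkit.constants import RateConstantTable
from photoxkit.synthio import (
    CHANNELS,
    ProbeDesign,
    SampleTruth,
    SynthConfig,
    SyntheticDataset,
    TrendConfig,
    gen_component_library,
    gen_dataset,
    gen_eem,
    gen_probe_series,
    gen_sample_set,
)


class TestComponentLibrary:
    def test_six_nonneg_peak_normalized_components(self, library):
        assert library.n_components == 6
        assert np.all(library.ex_profiles >= 0) and np.all(library.em_profiles >= 0)
        np.testing.assert_allclose(library.ex_profiles.max(axis=1), 1.0, rtol=0, atol=0)
        np.testing.assert_allclose(library.em_profiles.max(axis=1), 1.0, rtol=0, atol=0)

    def test_deterministic(self):
        a = gen_component_library(seed=5)
        b = gen_component_library(seed=5)
        np.testing.assert_array_equal(a.ex_profiles, b.ex_profiles)
        np.testing.assert_array_equal(a.em_profiles, b.em_profiles)

    def test_pairwise_congruence_below_095(self, library):
        # direct dot-product oracle on the joint ex (x) em profile
        for i in range(6):
            for j in range(i + 1, 6):
                pi = np.outer(library.ex_profiles[i], library.em_profiles[i]).ravel()
                pj = np.outer(library.ex_profiles[j], library.em_profiles[j]).ravel()
                cong = pi @ pj / (np.linalg.norm(pi) * np.linalg.norm(pj))
                assert cong < 0.95, (library.names[i], library.names[j], cong)
                assert cong == pytest.approx(library.joint_congruence(i, j), rel=1e-12)

    def test_short_grid_rejected(self):
        with pytest.raises(ValueError):
            gen_component_library(ex_grid=np.array([300.0, 310.0, 320.0]))


class TestSampleSet:
    def test_sample_count_two_series(self):
        samples, truth = gen_sample_set(n_fractions=6, series=("COM", "EPS"))
        assert len(samples) == 14  # 2 bulk + 12 fractions
        assert set(samples["sample_id"]) == set(truth.ids())

    def test_zero_slope_gives_equal_phi(self):
        trend = TrendConfig(phi_log_slope=0.0)
        _, truth = gen_sample_set(n_fractions=4, series=("COM",), trend_config=trend)
        phis = [truth[f"C{i}"].phi["singlet_oxygen"] for i in range(1, 5)]
        assert np.ptp(phis) == 0

    def test_phi_anticorrelates_perfectly_with_fraction(self):
        _, truth = gen_sample_set(n_fractions=6, series=("COM",))
        for ch in CHANNELS:
            phis = [truth[f"C{i}"].phi[ch] for i in range(1, 7)]
            rho = stats.spearmanr(phis, range(1, 7)).statistic
            assert rho == pytest.approx(-1.0)
            assert np.all(np.diff(phis) <= 0)  # non-increasing with MW

    def test_phi_bounds_and_positive_riss(self):
        _, truth = gen_sample_set()
        for sid in truth.ids():
            t = truth[sid]
            for ch in CHANNELS:
                assert 0 <= t.phi[ch] <= 0.2
                assert t.riss[ch] > 0
            assert t.ra > 0

    def test_riss_truths_decrease_with_mw(self):
        # the study conditions: both phi and [RI]_ss fall across MW fractions
        _, truth = gen_sample_set(n_fractions=6, series=("COM", "EPS"))
        for prefix in ("C", "E"):
            for ch in CHANNELS:
                riss = [truth[f"{prefix}{i}"].riss[ch] for i in range(1, 7)]
                assert np.all(np.diff(riss) < 0), (prefix, ch)

    def test_composition_trends(self):
        samples, _ = gen_sample_set(n_fractions=6, series=("COM",))
        fr = samples[samples["fraction"] > 0].sort_values("fraction")
        assert np.all(np.diff(fr["protein_mg_l"]) > 0)  # protein rises with MW
        assert np.all(np.diff(fr["polysaccharide_mg_l"]) < 0)

    def test_nonpositive_doc_rejected(self):
        with pytest.raises(ValueError):
            TrendConfig(doc_mg_l=0.0)


class TestGenEEM:
    def test_zero_scores_zero_matrix(self, library):
        eem = gen_eem(np.zeros(6), library)
        assert not eem.intensity.any()

    def test_single_component_rank_one(self, library):
        scores = np.zeros(6)
        scores[2] = 1.0
        eem = gen_eem(scores, library)
        expect = np.outer(library.ex_profiles[2], library.em_profiles[2])
        np.testing.assert_allclose(eem.intensity, expect, rtol=0, atol=0)

    def test_mixture_matches_brute_force_sum(self, library):
        scores = np.array([1.0, 2.0, 0, 0, 0, 0])
        eem = gen_eem(scores, library)
        # brute-force double loop over every grid point
        for i in range(0, library.ex_grid.size, 7):
            for j in range(0, library.em_grid.size, 13):
                expect = sum(
                    scores[f] * library.ex_profiles[f, i] * library.em_profiles[f, j]
                    for f in range(6)
                )
                assert eem.intensity[i, j] == pytest.approx(expect, rel=1e-12)

    def test_negative_score_rejected(self, library):
        with pytest.raises(ValueError):
            gen_eem([-1, 0, 0, 0, 0, 0], library)

    def test_noise_seeded_and_clipped(self, library):
        scores = np.full(6, 10.0)
        a = gen_eem(scores, library, noise_sd=0.05, seed=3)
        b = gen_eem(scores, library, noise_sd=0.05, seed=3)
        c = gen_eem(scores, library, noise_sd=0.05, seed=4)
        np.testing.assert_array_equal(a.intensity, b.intensity)
        assert not np.array_equal(a.intensity, c.intensity)
        assert np.all(a.intensity >= 0)

    def test_scatter_ridge_injection(self, library):
        scores = np.full(6, 10.0)
        plain = gen_eem(scores, library)
        ridged = gen_eem(scores, library, scatter_halfwidths_nm=(10, 10), scatter_amplitude=2.0)
        ex = library.ex_grid[:, None]
        em = library.em_grid[None, :]
        on_ridge = (np.abs(em - ex) <= 10) | (np.abs(em - 2 * ex) <= 10)
        np.testing.assert_array_equal(ridged.intensity[~on_ridge], plain.intensity[~on_ridge])
        assert np.all(ridged.intensity[on_ridge] > plain.intensity[on_ridge])


class TestProbeSeries:
    def _truth(self, riss, production, ra=1e-6):
        return SampleTruth(
            sample_id="X",
            scores=np.ones(6),
            phi={ch: production.get(ch, 0.0) / ra for ch in CHANNELS},
            production={ch: production.get(ch, 0.0) for ch in CHANNELS},
            riss={ch: riss.get(ch, 0.0) for ch in CHANNELS},
            ra=ra,
            index_targets={},
        )

    def test_ffa_decay_rate_implied_by_truth(self):
        # [1O2*]_ss = 1e-12 M and k_FFA = 1e8 give k_obs = 1e-4 s^-1
        truth = self._truth({"singlet_oxygen": 1e-12}, {})
        design = ProbeDesign(n_replicates=1)
        out = gen_probe_series(truth, "FFA", design, RateConstantTable())
        s = out["series"][0]
        expect = design.ffa_initial_M * np.exp(-1e-4 * s.times_s)
        np.testing.assert_allclose(s.concentrations_M, expect, rtol=1e-12)

    def test_tmp_constant_without_oxidants(self):
        truth = self._truth({}, {})
        out = gen_probe_series(truth, "TMP", ProbeDesign(n_replicates=1), RateConstantTable())
        assert np.ptp(out["series"][0].concentrations_M) == 0

    def test_noiseless_replicates_identical(self):
        truth = self._truth({"singlet_oxygen": 1e-12}, {})
        out = gen_probe_series(truth, "FFA", ProbeDesign(n_replicates=3), RateConstantTable())
        a, b, c = (s.concentrations_M for s in out["series"])
        np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(b, c)

    def test_unknown_probe_rejected(self):
        truth = self._truth({}, {})
        with pytest.raises(ValueError):
            gen_probe_series(truth, "rose-bengal", ProbeDesign(), RateConstantTable())

    def test_hdo_levels_cover_design_range(self, noiseless_dataset):
        by_conc = noiseless_dataset.hdo_by_conc("C1")
        levels = sorted(by_conc)
        assert len(levels) >= 3
        assert levels[-1] / levels[0] >= 4


class TestDatasetDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = SynthConfig(n_fractions=2, series=("COM",),
                          design=ProbeDesign(noise_sd=0.02), eem_noise_sd=0.01)
        a = gen_dataset(cfg, seed=9)
        b = gen_dataset(cfg, seed=9)
        for sid in a.sample_ids():
            np.testing.assert_array_equal(a.eems[sid].intensity, b.eems[sid].intensity)
            for probe in ("FFA", "TMP"):
                np.testing.assert_array_equal(
                    a.kinetics[(sid, probe)]["series"][0].concentrations_M,
                    b.kinetics[(sid, probe)]["series"][0].concentrations_M,
                )

    def test_different_seed_same_truth_different_noise(self):
        cfg = SynthConfig(n_fractions=2, series=("COM",),
                          design=ProbeDesign(noise_sd=0.02), eem_noise_sd=0.01)
        a = gen_dataset(cfg, seed=1)
        b = gen_dataset(cfg, seed=2)
        for sid in a.sample_ids():
            ta, tb = a.truth[sid], b.truth[sid]
            assert ta.phi == tb.phi and ta.riss == tb.riss and ta.ra == tb.ra
            assert not np.array_equal(a.eems[sid].intensity, b.eems[sid].intensity)

    def test_all_generated_values_nonnegative(self, noiseless_dataset):
        ds = noiseless_dataset
        for sid in ds.sample_ids():
            assert np.all(ds.eems[sid].intensity >= 0)
            for probe in ("FFA", "TMP", "benzene-phenol", "HDO"):
                for s in ds.kinetics[(sid, probe)]["series"]:
                    assert np.all(s.concentrations_M >= 0)


class TestDatasetIO:
    def test_write_read_round_trip(self, tmp_path, noiseless_dataset):
        out = tmp_path / "ds"
        noiseless_dataset.write(out)
        back = SyntheticDataset.read(out)
        assert back.sample_ids() == noiseless_dataset.sample_ids()
        for sid in ("C0", "E3"):
            np.testing.assert_allclose(
                back.absorbance[sid].absorbance,
                noiseless_dataset.absorbance[sid].absorbance,
                rtol=0, atol=0,
            )
            np.testing.assert_allclose(
                back.eems[sid].intensity, noiseless_dataset.eems[sid].intensity,
                rtol=0, atol=0,
            )
            sa = back.kinetics[(sid, "FFA")]["series"]
            sb = noiseless_dataset.kinetics[(sid, "FFA")]["series"]
            assert len(sa) == len(sb)
            np.testing.assert_allclose(
                sa[0].concentrations_M, sb[0].concentrations_M, rtol=0, atol=0
            )
            ta, tb = back.truth[sid], noiseless_dataset.truth[sid]
            assert ta.phi == pytest.approx(tb.phi)
            assert ta.riss == pytest.approx(tb.riss)

    def test_every_referenced_sample_exists(self, noiseless_dataset):
        ids = set(noiseless_dataset.sample_ids())
        assert set(noiseless_dataset.absorbance) == ids
        assert set(noiseless_dataset.eems) == ids
        assert {sid for sid, _ in noiseless_dataset.kinetics} == ids
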