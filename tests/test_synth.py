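"""Synthetic hemisphere ground truth and the BOLD forward model."""

import numpy as np
import pandas as pd
import pytest

from fstloc import glm, stimuli, synth


class TestHemisphere:
    def test_region_sizes_and_orderings(self, hemisphere):
        t = hemisphere.tuning
        assert int(hemisphere.region_mask("hMTMST").sum()) == 296
        assert int(hemisphere.region_mask("pFST").sum()) == 95
        by = t.groupby("region")
        assert by.gain2d.mean()["hMTMST"] > by.gain2d.mean()["pFST"]
        assert by.opponency.mean()["hMTMST"] > by.opponency.mean()["pFST"]
        assert (
            by.prf_sigma.mean()["pFST"]
            > by.prf_sigma.mean()["hMTMST"]
            > by.prf_sigma.mean()["V1like"]
        )
        assert (
            by.t1.mean()["hMTMST"] < by.t1.mean()["pFST"] < by.t1.mean()["background"]
        )

    def test_pfst_anterior_or_inferior(self, hemisphere):
        r_mt, c_mt = hemisphere.centroid("hMTMST")
        r_f, c_f = hemisphere.centroid("pFST")
        assert c_f > c_mt or r_f > r_mt

    def test_deterministic_given_seed(self):
        a = synth.make_hemisphere(seed=42)
        b = synth.make_hemisphere(seed=42)
        pd.testing.assert_frame_equal(a.tuning, b.tuning)
        assert np.array_equal(a.atlas_label, b.atlas_label)

    def test_zero_atlas_jitter_is_identity(self):
        cfg = synth.HemisphereConfig(atlas_jitter=0)
        h = synth.make_hemisphere(cfg, seed=1)
        assert np.array_equal(h.atlas_label, h.region_label)
        from fstloc import roi

        assert roi.dice(h.atlas_mask("pFST"), h.region_mask("pFST")) == 1.0

    def test_overlapping_regions_rejected(self):
        regions = synth.default_regions()
        regions[2].row0 = regions[1].row0
        regions[2].col0 = regions[1].col0
        with pytest.raises(ValueError, match="overlap"):
            synth.make_hemisphere(synth.HemisphereConfig(regions=regions), seed=0)

    def test_region_exceeding_grid_rejected(self):
        regions = synth.default_regions()
        regions[2].col0 = 60
        with pytest.raises(ValueError, match="grid"):
            synth.make_hemisphere(synth.HemisphereConfig(regions=regions), seed=0)


class TestNeuralResponse:
    @pytest.fixture()
    def tuning(self):
        return {
            "gain2d": 1.0,
            "gain3d": 2.0,
            "coh_selectivity": 0.5,
            "opponency": 0.4,
        }

    def test_opponency_scaling(self, tuning):
        sched = stimuli.build_opponent_schedule(5, 4)
        resp = synth.neural_response(tuning, sched)
        # unpaired drives gain2d; paired is suppressed by the opponency index
        assert resp[:5].tolist() == [1.0] * 5
        assert resp[5:10] == pytest.approx([0.6] * 5)

    @pytest.mark.parametrize("opp,paired_amp", [(0.0, 1.0), (1.0, 0.0)])
    def test_opponency_extremes(self, tuning, opp, paired_amp):
        tuning["opponency"] = opp
        sched = stimuli.build_opponent_schedule(5, 2)
        resp = synth.neural_response(tuning, sched)
        assert resp[5:10] == pytest.approx([paired_amp] * 5)

    def test_3d_selectivity(self, tuning):
        sched = stimuli.build_3d_schedule(5, 1, blank_s=5)
        resp = synth.neural_response(tuning, sched)
        assert resp[:5].tolist() == [2.0] * 5  # coherent
        assert resp[5:10] == pytest.approx([1.0] * 5)  # scrambled, coh_sel 0.5
        assert resp[10:].tolist() == [0.0] * 5  # blank

    def test_unknown_label_rejected(self, tuning):
        sched = stimuli.BlockSchedule([stimuli.Block("warp", 0, 5)], 5.0)
        with pytest.raises(ValueError):
            synth.neural_response(tuning, sched)


class TestPRFResponse:
    def test_full_field_contained_gaussian_is_one(self):
        ap = stimuli.ApertureMovie(
            grid=np.ones((1, 64, 64), dtype=bool), radius=12.2, kind="bar"
        )
        r = synth.prf_neural_response(
            {"prf_x0": 0.0, "prf_y0": 0.0, "prf_sigma": 1.0}, ap
        )
        assert r[0] == pytest.approx(1.0, abs=0.01)

    def test_empty_mask_is_zero(self):
        ap = stimuli.ApertureMovie(
            grid=np.zeros((1, 64, 64), dtype=bool), radius=12.2, kind="bar"
        )
        r = synth.prf_neural_response(
            {"prf_x0": 0.0, "prf_y0": 0.0, "prf_sigma": 2.0}, ap
        )
        assert r[0] == 0.0

    def test_half_field_is_half(self):
        grid = np.zeros((1, 64, 64), dtype=bool)
        grid[:, :, 32:] = True  # x > 0 half-plane
        ap = stimuli.ApertureMovie(grid=grid, radius=12.2, kind="bar")
        r = synth.prf_neural_response(
            {"prf_x0": 0.0, "prf_y0": 0.0, "prf_sigma": 1.0}, ap
        )
        assert r[0] == pytest.approx(0.5, abs=0.02)

    def test_nonpositive_sigma_rejected(self):
        ap = stimuli.ApertureMovie(
            grid=np.ones((1, 64, 64), dtype=bool), radius=12.2, kind="bar"
        )
        with pytest.raises(ValueError):
            synth.prf_neural_response(
                {"prf_x0": 0.0, "prf_y0": 0.0, "prf_sigma": 0.0}, ap
            )


class TestSimulateBold:
    def test_zero_everything_gives_zero(self):
        out = synth.simulate_bold(np.zeros(50), noise_sd=0.0)
        assert np.all(out == 0.0)

    def test_noiseless_equals_convolved_input(self, hrf_kernel):
        neural = np.zeros(80)
        neural[10:25] = 1.5
        out = synth.simulate_bold(neural, noise_sd=0.0, hrf_kernel=hrf_kernel)
        expected = np.convolve(neural, hrf_kernel)[:80]
        assert np.allclose(out, expected)

    def test_noise_sd_calibrated(self, hrf_kernel):
        neural = np.zeros(10_000)
        clean = synth.simulate_bold(neural, 0.0, hrf_kernel=hrf_kernel)
        noisy = synth.simulate_bold(neural, 1.0, seed=9, hrf_kernel=hrf_kernel)
        resid_sd = (noisy - clean).std()
        assert abs(resid_sd - 1.0) < 0.05

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            synth.simulate_bold(np.zeros(10), noise_sd=-0.1)

    def test_simulated_run_finite_and_shaped(self, hemisphere):
        sched = stimuli.build_opponent_schedule(5, 4)
        ts = synth.simulate_run(hemisphere, sched, noise_sd=0.5, seed=1)
        assert ts.values.shape == (hemisphere.n_vertices, sched.n_timepoints)
        assert np.all(np.isfinite(ts.values))
        # psc conversion undoes the raw wrapping
        psc = glm.to_psc(ts)
        assert np.allclose(psc.values.mean(axis=1), 0.0, atol=1e-10)


class TestCohort:
    def test_cohort_size_and_effect_directions(self):
        cohort = synth.cohort_measures(n_subjects=3, seed=0)
        assert len(cohort) == 6
        m = cohort[0]["measures"]
        assert m["opponency"]["hMTMST"].mean() > m["opponency"]["pFST"].mean()
        assert m["motion3d"]["pFST"].mean() > m["motion3d"]["hMTMST"].mean()

    def test_null_cohort_has_no_designed_gap(self):
        cohort = synth.cohort_measures(n_subjects=9, seed=1, null=True)
        gaps = [
            h["measures"]["opponency"]["hMTMST"].mean()
            - h["measures"]["opponency"]["pFST"].mean()
            for h in cohort
        ]
        assert abs(np.mean(gaps)) < 0.1
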