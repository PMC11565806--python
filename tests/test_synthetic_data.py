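"""Cohort generator, probe/event designs and the forward intensity model."""

import numpy as np
import pytest
from scipy import stats

from fnirsinc import quality_metrics as qm, synthetic_data as sd


class TestGenerateParticipants:
    def test_deterministic_under_seed(self):
        cfg = sd.SimulationConfig(seed=42)
        a = sd.generate_participants(5, cfg)
        b = sd.generate_participants(5, cfg)
        for pa, pb in zip(a, b):
            assert pa == pb

    def test_side_hair_density_moment(self):
        cfg = sd.SimulationConfig(seed=11)
        cohort = sd.generate_participants(1000, cfg)
        vals = [p.trichoscopy["side"].avg_num_hairs for p in cohort]
        mean, sd_ = 160.7, 41.3
        assert abs(np.mean(vals) - mean) < 3 * sd_ / np.sqrt(1000)

    def test_pigment_moment_matches_truncated_normal(self):
        # the draw truncates the parent N(25.3, 18.1) to the observed
        # range [4.7, 90]; the expected mean is the truncated-normal mean
        cfg = sd.SimulationConfig(seed=12)
        cohort = sd.generate_participants(1000, cfg)
        vals = [p.skin_pigmentation for p in cohort]
        mean, s = 25.3, 18.1
        a, b = (4.7 - mean) / s, (90.0 - mean) / s
        expected = stats.truncnorm.mean(a, b, loc=mean, scale=s)
        expected_sd = stats.truncnorm.std(a, b, loc=mean, scale=s)
        assert abs(np.mean(vals) - expected) < 3 * expected_sd / np.sqrt(1000)

    def test_pigment_color_dependence(self):
        cfg = sd.SimulationConfig(seed=13, pigment_color_dependence=0.5)
        cohort = sd.generate_participants(2000, cfg)
        pig = [p.skin_pigmentation for p in cohort]
        col = [p.hair_color for p in cohort]
        r = np.corrcoef(pig, col)[0, 1]
        assert abs(r - 0.5) < 0.1

    def test_profile_invariants(self, cohort):
        for p in cohort:
            for block in p.trichoscopy.values():
                assert block.thin_pct + block.middle_pct + block.thick_pct \
                    == pytest.approx(100.0, abs=0.5)
                assert block.single_fu_pct + block.double_fu_pct \
                    + block.triple_fu_pct == pytest.approx(100.0, abs=0.5)
                assert block.cumulative_thickness == pytest.approx(
                    block.avg_num_hairs * block.avg_shaft_thickness * 1e-3,
                    abs=1e-6)
                assert 42.0 <= block.avg_shaft_thickness <= 88.0
            assert 4.7 <= p.skin_pigmentation <= 90.0
            if p.hair_color == 0:
                assert p.hair_type == 0 and p.hair_texture == 0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sd.generate_participants(0)
        with pytest.raises(ValueError, match="prior"):
            sd.generate_participants(3, hair_color_prior=(0.5, 0.5, 0.5, 0, 0))


class TestGenerateProbe:
    def test_roi_channel_counts(self, probe):
        for hemi in ("left", "right"):
            assert len(probe.channel_indices("forehead", "long", hemi)) == 4
            assert len(probe.channel_indices("forehead", "short", hemi)) == 1
            assert len(probe.channel_indices("side", "long", hemi)) == 10
            assert len(probe.channel_indices("side", "short", hemi)) == 2
            assert len(probe.channel_indices("back", "long", hemi)) == 4
            assert len(probe.channel_indices("back", "short", hemi)) == 1

    def test_total_channels_per_hemisphere(self, probe):
        for hemi in ("left", "right"):
            assert len(probe.channel_indices(hemisphere=hemi)) == 22

    def test_separations(self, probe):
        for ch in probe.channels:
            expected = 8.0 if ch.kind == "short" else 30.0
            assert ch.separation_mm == pytest.approx(expected, abs=2.0)

    def test_channels_reference_existing_optodes(self, probe):
        srcs = {o.label for o in probe.sources}
        dets = {o.label for o in probe.detectors}
        for ch in probe.channels:
            assert ch.source in srcs and ch.detector in dets


class TestGenerateEvents:
    def test_trial_counts_and_gaps(self):
        stim = sd.generate_events(15, seed=3)
        assert len(stim.events) == 30
        assert len(stim.onsets("left")) == 15
        assert len(stim.onsets("right")) == 15
        onsets = np.sort(stim.onsets())
        assert np.all(np.diff(onsets) >= 10.0)   # 5 s stim + >= 5 s ISI
        for _, dur, _ in stim.events:
            assert dur == 5.0

    def test_single_trial_no_overlap(self):
        stim = sd.generate_events(1, seed=0)
        assert len(stim.events) == 2
        (t1, d1, _), (t2, _, _) = sorted(stim.events)
        assert t2 >= t1 + d1

    def test_order_randomized(self):
        orders = {tuple(c for _, _, c in sorted(sd.generate_events(
            15, seed=s).events)) for s in range(5)}
        assert len(orders) > 1


class TestAttenuationExponent:
    def test_zero_at_minima(self, sim_config):
        prof = _profile(pigment=4.7, color=0, hair_type=0, thickness=42.0)
        for region in ("forehead", "side", "back"):
            assert sd.attenuation_exponent(prof, region, sim_config) == \
                pytest.approx(0.0)

    def test_monotone_in_pigmentation(self, sim_config):
        lo = _profile(pigment=20.0)
        hi = _profile(pigment=60.0)
        for region in ("forehead", "side", "back"):
            assert sd.attenuation_exponent(hi, region, sim_config) > \
                sd.attenuation_exponent(lo, region, sim_config)

    def test_forehead_independent_of_hair(self, sim_config):
        a = _profile(color=1, hair_type=1, thickness=45.0)
        b = _profile(color=4, hair_type=4, thickness=85.0)
        assert sd.attenuation_exponent(a, "forehead", sim_config) == \
            sd.attenuation_exponent(b, "forehead", sim_config)
        assert sd.attenuation_exponent(b, "side", sim_config) > \
            sd.attenuation_exponent(a, "side", sim_config)

    def test_unknown_region_rejected(self, sim_config):
        with pytest.raises(ValueError):
            sd.attenuation_exponent(_profile(), "occiput", sim_config)


class TestGenerateRecording:
    def test_perfect_coupling_unit_sci(self, probe, clean_config):
        cfg = clean_config
        cfg = sd.SimulationConfig(
            seed=0, noise_floor_raw=0.0, cardiac_rel_amplitude=0.01,
            systemic_rel_amplitude=0.0, wavelength_gains=(1.0, 1.0),
            channel_log10_sd=0.0, coupling_weights={})
        prof = _profile()
        rec = sd.generate_recording(prof, probe, 30.0, 10.2, config=cfg)
        i = probe.channel_indices("forehead", "long", "right")[0]
        assert qm.scalp_coupling_index(rec, i) == pytest.approx(1.0,
                                                                abs=1e-9)

    def test_noise_only_null_sci(self, probe):
        cfg = sd.SimulationConfig(seed=0, cardiac_rel_amplitude=0.0,
                                  systemic_rel_amplitude=0.0)
        prof = _profile()
        hits = total = 0
        for seed in range(30):
            rec = sd.generate_recording(prof, probe, 180.0, 10.2,
                                        config=cfg, seed=seed)
            for i in probe.channel_indices("side", "long", "right")[:3]:
                total += 1
                if abs(qm.scalp_coupling_index(rec, i)) < 0.1:
                    hits += 1
        assert hits / total >= 0.95

    def test_clean_baseline_mean(self, probe, clean_config):
        prof = _profile(pigment=4.7, color=0, hair_type=0, thickness=42.0)
        rec = sd.generate_recording(prof, probe, 20.0, 10.2,
                                    config=clean_config)
        i = probe.channel_indices("side", "long", "right")[0]
        assert qm.uncorrected_signal_mean(rec, i) == pytest.approx(0.33,
                                                                   rel=1e-9)

    def test_mean_intensity_monotone_in_attenuation(self, probe,
                                                    clean_config):
        lo = _profile(pigment=10.0, color=1, thickness=50.0)
        hi = _profile(pigment=80.0, color=4, thickness=80.0)
        r_lo = sd.generate_recording(lo, probe, 15.0, 10.2,
                                     config=clean_config)
        r_hi = sd.generate_recording(hi, probe, 15.0, 10.2,
                                     config=clean_config)
        for i in range(probe.n_channels):
            assert qm.uncorrected_signal_mean(r_hi, i) <= \
                qm.uncorrected_signal_mean(r_lo, i)

    def test_determinism(self, probe, sim_config):
        prof = _profile()
        a = sd.generate_recording(prof, probe, 12.0, 10.2, config=sim_config,
                                  seed=5)
        b = sd.generate_recording(prof, probe, 12.0, 10.2, config=sim_config,
                                  seed=5)
        assert np.array_equal(a.data, b.data)

    def test_auto_scaled_power_decouples_usm_from_csm(self, probe):
        cfg = sd.SimulationConfig(seed=0, source_power_policy="auto-scaled",
                                  noise_floor_raw=0.0,
                                  cardiac_rel_amplitude=0.0,
                                  systemic_rel_amplitude=0.0,
                                  wavelength_gains=(1.0, 1.0),
                                  channel_log10_sd=0.0,
                                  auto_power_base_pct=1.0)
        lo = _profile(pigment=10.0, color=1, thickness=50.0)
        hi = _profile(pigment=40.0, color=2, thickness=65.0)
        r_lo = sd.generate_recording(lo, probe, 15.0, 10.2, config=cfg)
        r_hi = sd.generate_recording(hi, probe, 15.0, 10.2, config=cfg)
        i = probe.channel_indices("side", "long", "right")[0]
        usm_ratio = qm.uncorrected_signal_mean(r_hi, i) / \
            qm.uncorrected_signal_mean(r_lo, i)
        csm_diff = qm.corrected_signal_mean(r_hi, i) - \
            qm.corrected_signal_mean(r_lo, i)
        # power compensation hides most of the loss in the raw mean,
        # power correction restores it in the corrected mean
        assert usm_ratio > 0.9
        assert csm_diff < -0.5

    def test_invalid_durations(self, probe, sim_config):
        with pytest.raises(ValueError):
            sd.generate_recording(_profile(), probe, -1.0, 10.2,
                                  config=sim_config)
        with pytest.raises(ValueError):
            sd.generate_recording(_profile(), probe, 10.0, 0.0,
                                  config=sim_config)


class TestCappingPair:
    def test_side_back_improve_forehead_unchanged(self, probe):
        cfg = sd.SimulationConfig(seed=21)
        profs = sd.generate_participants(12, cfg)
        d_sci, d_usm_fh = [], []
        for i, prof in enumerate(profs):
            r1, r2 = sd.generate_capping_pair(prof, probe, cfg,
                                              duration_s=40, seed=300 + i)
            assert r1.run_label == "rest_fast_cap"
            assert r2.run_label == "rest_proper_cap"
            q1 = qm.channel_quality_table(r1, prof.id)
            q2 = qm.channel_quality_table(r2, prof.id)
            side = q1["roi"] == "side"
            d_sci.append(q2[side]["sci"].mean() - q1[side]["sci"].mean())
            fh = q1["roi"] == "forehead"
            d_usm_fh.append((q2[fh]["usm"].mean() - q1[fh]["usm"].mean())
                            / q1[fh]["usm"].mean())
        assert np.mean(d_sci) > 0
        assert abs(np.mean(d_usm_fh)) < 0.05

    def test_no_degradation_is_exchangeable(self, probe):
        cfg = sd.SimulationConfig(seed=22, fast_capping_attenuation=0.0,
                                  fast_capping_coupling_penalty=0.0)
        prof = sd.generate_participants(1, cfg)[0]
        diffs = []
        for s in range(10):
            r1, r2 = sd.generate_capping_pair(prof, probe, cfg,
                                              duration_s=30, seed=s)
            q1 = qm.channel_quality_table(r1, "p")
            q2 = qm.channel_quality_table(r2, "p")
            diffs.append(q2["usm"].mean() - q1["usm"].mean())
        # null case: differences scatter around zero
        assert abs(np.mean(diffs)) < 3 * np.std(diffs) / np.sqrt(len(diffs)) \
            + 1e-12


def _profile(pigment=25.0, color=3, hair_type=2, texture=2, thickness=62.0):
    if color == 0:
        hair_type = texture = 0
    block = sd.TrichoscopyBlock(
        avg_num_hairs=160.0, avg_shaft_thickness=thickness, thin_pct=6.5,
        middle_pct=20.9, thick_pct=72.6, single_fu_pct=31.0,
        double_fu_pct=43.4, triple_fu_pct=25.6, n_follicular_units=80.0,
        sinclair_scale=2.5)
    return sd.ParticipantProfile(
        id="sub-test", age=30.0, sex="female", head_circumference_cm=57.0,
        nasion_inion_cm=35.0, ear_to_ear_cm=36.0, skin_pigmentation=pigment,
        skin_type=2, hair_color=color, hair_type=hair_type,
        hair_texture=texture,
        trichoscopy={"side": block, "back": block})
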