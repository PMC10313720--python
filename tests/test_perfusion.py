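"""Blood-flow estimators: TAC extraction, trigger logic, MSM and FPA maps."""

import numpy as np
import pytest

from ctfpa import (
    Curve,
    DynamicSeries,
    FPAConfig,
    MSMConfig,
    ROIMask,
    TriggerNeverFiredError,
    WindowExceededError,
    compute_tp,
    extract_tac,
    find_tbase,
    find_tmax,
    fpa_map,
    injection_duration,
    map_stats,
    msm_map,
    select_second_frame,
)
from ctfpa.perfusion import PerfusionMap
from ctfpa.timing import _pancreatic_compartment


def _series(values_per_frame, shape=(4, 4), times=None):
    """Uniform-valued frames on a small grid."""
    values = np.asarray(values_per_frame, dtype=float)
    times = np.arange(values.size) * 1.5 if times is None else times
    vox = np.broadcast_to(values[:, None, None], (values.size, *shape)).copy()
    return DynamicSeries(vox, times)


class TestExtractTac:
    def test_uniform_series(self):
        series = _series([100.0] * 5)
        roi = ROIMask(np.ones((4, 4), dtype=bool), "all")
        curve = extract_tac(series, roi)
        assert np.all(curve.values == 100.0)

    def test_single_voxel_mask_returns_exact_time_course(self, rng):
        vox = rng.normal(60, 10, (6, 3, 3))
        series = DynamicSeries(vox, np.arange(6.0))
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 2] = True
        curve = extract_tac(series, ROIMask(mask, "one"))
        np.testing.assert_array_equal(curve.values, vox[:, 1, 2])

    def test_checkerboard_average(self):
        vox = np.zeros((3, 4, 4))
        vox[:, ::2, ::2] = 80.0
        vox[:, 1::2, 1::2] = 80.0
        vox[:, ::2, 1::2] = 120.0
        vox[:, 1::2, ::2] = 120.0
        series = DynamicSeries(vox, np.arange(3.0))
        curve = extract_tac(series, ROIMask(np.ones((4, 4), dtype=bool), "all"))
        np.testing.assert_allclose(curve.values, 100.0)

    def test_baseline_from_pre_trigger_frames(self):
        series = _series([50.0, 52.0, 130.0, 200.0])
        roi = ROIMask(np.ones((4, 4), dtype=bool), "all")
        curve = extract_tac(series, roi, trigger_threshold=120.0)
        assert curve.baseline == pytest.approx(51.0)
        tissue = extract_tac(series, roi, baseline_frames=2)
        assert tissue.baseline == pytest.approx(51.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            ROIMask(np.zeros((4, 4), dtype=bool), "empty")


class TestTriggerAndPeak:
    def test_first_strict_exceedance(self):
        curve = Curve(np.arange(4.0), [50.0, 100.0, 130.0, 200.0])
        assert find_tbase(curve, 120.0) == 2

    def test_boundary_value_exceeds(self):
        curve = Curve(np.arange(3.0), [121.0, 50.0, 60.0])
        assert find_tbase(curve, 120.0) == 0

    def test_equal_value_does_not_fire(self):
        curve = Curve(np.arange(3.0), [120.0, 120.0, 121.0])
        assert find_tbase(curve, 120.0) == 2

    def test_never_fired(self):
        curve = Curve(np.arange(3.0), [50.0, 60.0, 70.0])
        with pytest.raises(TriggerNeverFiredError):
            find_tbase(curve, 120.0)

    def test_peak_and_tie_break(self):
        assert find_tmax(Curve(np.arange(4.0), [0.0, 10.0, 300.0, 250.0])) == 2
        assert find_tmax(Curve(np.arange(4.0), [7.0, 7.0, 7.0, 7.0])) == 0

    def test_brute_force_agreement(self, rng):
        """find_tbase / find_tmax match linear scans on 1000 random curves."""
        for _ in range(1000):
            vals = rng.uniform(0, 300, size=rng.integers(3, 40))
            curve = Curve(np.arange(vals.size, dtype=float), vals)
            expected_max = max(range(vals.size), key=lambda i: (vals[i], -i))
            assert find_tmax(curve) == expected_max
            thr = float(rng.uniform(50, 250))
            hits = [i for i, v in enumerate(vals) if v > thr]
            if hits:
                assert find_tbase(curve, thr) == hits[0]
            else:
                with pytest.raises(TriggerNeverFiredError):
                    find_tbase(curve, thr)


class TestTimingArithmetic:
    @pytest.mark.parametrize(
        "t_i,d,expected", [(16.0, 13.5, 21.5), (16.0, 0.0, 8.0), (2.0, 0.0, 1.0)]
    )
    def test_bolus_centre(self, t_i, d, expected):
        assert compute_tp(t_i, d) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "volume,rate,expected", [(80.0, 5.0, 16.0), (0.0, 5.0, 0.0), (40.0, 4.0, 10.0)]
    )
    def test_injection_duration(self, volume, rate, expected):
        assert injection_duration(volume, rate) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            injection_duration(80.0, 0.0)
        with pytest.raises(ValueError):
            compute_tp(-1.0, 0.0)
        with pytest.raises(ValueError):
            compute_tp(16.0, -0.5)


class TestSelectSecondFrame:
    @pytest.fixture()
    def aif(self):
        times = 13.0 + 1.5 * np.arange(34)
        vals = np.full(34, 50.0)
        vals[2:] = np.concatenate([np.linspace(130, 400, 6), np.linspace(390, 100, 26)])
        return Curve(times, vals, baseline=50.0)

    def test_fpa1_returns_peak(self, aif):
        idx = select_second_frame(aif, FPAConfig(variant="fpa1"))
        assert idx == find_tmax(aif)
        assert idx > find_tbase(aif, 120.0)

    def test_fpa2_nearest_frame(self, aif):
        """t_base at 16 s, t_p = 8 s: target 24 s picks the 23.5 s frame."""
        cfg = FPAConfig(variant="fpa2", t_i=16.0, dispersion_d=0.0)
        idx = select_second_frame(aif, cfg)
        target = aif.times[find_tbase(aif, 120.0)] + 8.0
        expected = int(np.argmin(np.abs(aif.times - target)))
        assert idx == expected == 7

    def test_fpa2_tie_goes_to_earlier_frame(self):
        times = np.arange(0.0, 30.0, 1.5)
        vals = np.where(times >= 3.0, 200.0, 50.0)
        aif = Curve(times, vals, baseline=50.0)
        # t_base at 3.0 s; t_p = 8.25 targets 11.25 s, equidistant from 10.5 and 12.0
        cfg = FPAConfig(variant="fpa2", t_i=16.0, dispersion_d=0.25)
        assert select_second_frame(aif, cfg) == 7  # 10.5 s

    def test_window_exceeded(self, aif):
        cfg = FPAConfig(variant="fpa2", t_i=16.0, dispersion_d=60.0)
        with pytest.raises(WindowExceededError):
            select_second_frame(aif, cfg)


class TestMsmMap:
    def test_constant_voxels_give_zero(self):
        series = _series([70.0] * 6)
        aif = Curve(series.times, np.linspace(50, 300, 6), baseline=50.0)
        pmap = msm_map(series, aif)
        assert np.all(pmap.bf == 0.0)

    def test_linear_ramp_closed_form(self):
        """2 HU/s ramp with a 200 HU AIF reference gives 60 ml/100 ml/min."""
        times = np.arange(10.0)
        series = _series(2.0 * times, times=times)
        aif = Curve(times, 50.0 + np.concatenate([[0.0], np.full(9, 200.0)]), baseline=50.0)
        pmap = msm_map(series, aif, MSMConfig(slope_window=3, rho_t=1.0))
        np.testing.assert_allclose(pmap.bf, 6000.0 * 2.0 / 200.0, rtol=1e-9)
        assert pmap.bf.flat[0] == pytest.approx(60.0)

    def test_rho_t_scales_inversely(self):
        times = np.arange(10.0)
        series = _series(2.0 * times, times=times)
        aif = Curve(times, 50.0 + np.full(10, 200.0), baseline=50.0)
        p1 = msm_map(series, aif, MSMConfig(rho_t=1.0))
        p2 = msm_map(series, aif, MSMConfig(rho_t=1.05))
        np.testing.assert_allclose(p2.bf, p1.bf / 1.05, rtol=1e-12)

    def test_noise_free_recovery_within_5_percent(self, clean_subject):
        pmap = msm_map(clean_subject.series, clean_subject.aif_true)
        for tissue, bf_true in clean_subject.ground_truth.items():
            vals = pmap.bf[clean_subject.masks[f"{tissue}_polygonal"].mask]
            assert np.abs(vals / bf_true - 1.0).max() < 0.05

    def test_absolute_reference_mode(self, clean_subject):
        enh = msm_map(clean_subject.series, clean_subject.aif_true,
                      MSMConfig(aif_reference="enhancement"))
        absolute = msm_map(clean_subject.series, clean_subject.aif_true,
                           MSMConfig(aif_reference="absolute"))
        ratio = clean_subject.aif_true.enhancement.max() / clean_subject.aif_true.values.max()
        np.testing.assert_allclose(absolute.bf, enh.bf * ratio, rtol=1e-9)


class TestFpaMap:
    def test_zero_enhancement_gives_zero_map(self):
        series = _series([60.0] * 10, times=13.0 + 1.5 * np.arange(10))
        vals = np.concatenate([[50.0, 50.0], np.linspace(130, 300, 8)])
        aif = Curve(series.times, vals, baseline=50.0)
        comp = ROIMask(np.ones((4, 4), dtype=bool), "comp")
        pmap = fpa_map(series, aif, FPAConfig(variant="fpa1"), comp)
        assert np.all(pmap.bf == 0.0)

    def test_closed_form_average_perfusion(self):
        """dHU_avg 30 HU over an AIF-enhancement integral of 3000 HU.s -> 60.

        A voxel at half the average change maps to 30 ml/100 ml/min.
        """
        times = np.arange(0.0, 31.0, 1.5)
        n = times.size
        vox = np.zeros((n, 2, 1))
        i0, i1 = 1, n - 1
        span = times[i1] - times[i0]
        vox[i1:, 0, 0] = 45.0  # dHU 45
        vox[i1:, 1, 0] = 15.0  # dHU 15 -> avg 30
        series = DynamicSeries(vox, times)
        enh = 3000.0 / span  # constant enhancement whose integral is 3000 HU.s
        aif_vals = np.full(n, 40.0)
        aif_vals[i0:] = 40.0 + enh
        aif = Curve(times, aif_vals, baseline=40.0)
        cfg = FPAConfig(trigger_threshold=41.0, variant="fpa2", t_i=2 * (span - 0.1))
        comp = ROIMask(np.ones((2, 1), dtype=bool), "comp")
        pmap = fpa_map(series, aif, cfg, comp)
        assert pmap.timing == (i0, i1)
        assert pmap.provenance["p_avg"] == pytest.approx(60.0, rel=1e-9)
        assert pmap.bf[0, 0] == pytest.approx(90.0, rel=1e-9)
        assert pmap.bf[1, 0] == pytest.approx(30.0, rel=1e-9)

    def test_noise_free_recovery(self, clean_subject):
        """With no outflow before the second scan, FPA1 recovers flow exactly."""
        comp = _pancreatic_compartment(clean_subject)
        pmap = fpa_map(clean_subject.series, clean_subject.aif_true,
                       FPAConfig(variant="fpa1"), comp)
        for tissue, bf_true in clean_subject.ground_truth.items():
            mean, _ = map_stats(pmap, clean_subject.masks[f"{tissue}_circular"])
            assert mean == pytest.approx(bf_true, rel=1e-9)

    def test_compartment_mean_equals_p_avg(self, noisy_subject):
        comp = _pancreatic_compartment(noisy_subject)
        pmap = fpa_map(noisy_subject.series, noisy_subject.aif_true,
                       FPAConfig(variant="fpa2", dispersion_d=6.0), comp)
        # the raw (pre-flooring) compartment mean obeys the normalisation identity
        assert pmap.provenance["compartment_mean_raw"] == pytest.approx(
            pmap.provenance["p_avg"], abs=1e-9
        )
        # flooring never increases magnitudes
        assert np.all(pmap.bf >= 0.0)

    def test_baseline_shift_invariance(self, noisy_subject):
        comp = _pancreatic_compartment(noisy_subject)
        cfg = FPAConfig(variant="fpa2", dispersion_d=3.0)
        base = fpa_map(noisy_subject.series, noisy_subject.aif_true, cfg, comp)
        shifted_series = DynamicSeries(noisy_subject.series.voxels + 25.0,
                                       noisy_subject.series.times)
        shifted = fpa_map(shifted_series, noisy_subject.aif_true, cfg, comp)
        np.testing.assert_allclose(shifted.bf, base.bf, atol=1e-10)

    def test_scales_with_inverse_aif_amplitude(self, clean_subject):
        comp = _pancreatic_compartment(clean_subject)
        cfg = FPAConfig(variant="fpa2", dispersion_d=3.0)
        aif = clean_subject.aif_true
        doubled = Curve(aif.times, aif.baseline + 2.0 * aif.enhancement, baseline=aif.baseline)
        base = fpa_map(clean_subject.series, aif, cfg, comp)
        halved = fpa_map(clean_subject.series, doubled, cfg, comp)
        np.testing.assert_allclose(halved.bf, base.bf / 2.0, rtol=1e-9)

    def test_flooring_only_affects_negative_voxels(self, rng):
        times = 13.0 + 1.5 * np.arange(6)
        vox = rng.normal(0.0, 5.0, (6, 8, 8)) + 50.0
        series = DynamicSeries(vox, times)
        vals = np.concatenate([[50.0], np.linspace(200, 300, 5)])
        aif = Curve(times, vals, baseline=50.0)
        comp = ROIMask(np.ones((8, 8), dtype=bool), "comp")
        pmap = fpa_map(series, aif, FPAConfig(variant="fpa1"), comp)
        dhu = vox[-1] - vox[1]
        assert pmap.n_floored == int((dhu < 0).sum())
        assert np.all(pmap.bf >= 0.0)
        assert np.all(pmap.bf[dhu >= 0] > 0.0)

    def test_negative_map_construction_rejected(self):
        with pytest.raises(ValueError):
            PerfusionMap(bf=np.array([[-1.0]]), method="MSM")


class TestMapStats:
    def test_uniform_map(self):
        pmap = PerfusionMap(bf=np.full((5, 5), 42.0), method="MSM")
        roi = ROIMask(np.ones((5, 5), dtype=bool), "all")
        assert map_stats(pmap, roi) == (42.0, 0.0)

    def test_two_voxel_hand_arithmetic(self):
        bf = np.zeros((2, 2))
        bf[0, 0], bf[0, 1] = 10.0, 30.0
        mask = np.zeros((2, 2), dtype=bool)
        mask[0, :] = True
        mean, sd = map_stats(PerfusionMap(bf=bf, method="MSM"), ROIMask(mask, "pair"))
        assert mean == pytest.approx(20.0)
        assert sd == pytest.approx(np.sqrt(200.0))  # sample SD, 14.142...

    def test_matches_naive_loop(self, rng):
        for _ in range(20):
            bf = rng.uniform(0, 150, (10, 10))
            mask = rng.uniform(size=(10, 10)) < 0.4
            if mask.sum() < 2:
                continue
            mean, sd = map_stats(PerfusionMap(bf=bf, method="MSM"), ROIMask(mask, "r"))
            vals = [bf[i, j] for i in range(10) for j in range(10) if mask[i, j]]
            loop_mean = sum(vals) / len(vals)
            loop_sd = (sum((v - loop_mean) ** 2 for v in vals) / (len(vals) - 1)) ** 0.5
            assert mean == pytest.approx(loop_mean, abs=1e-9)
            assert sd == pytest.approx(loop_sd, abs=1e-9)
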