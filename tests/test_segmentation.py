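"""Split-half mapping, thresholds and iterative refinement."""

import numpy as np
import pytest

import pulsevessel as pv
from pulsevessel.cardiac import CardiacWaveform, PhaseAssignment
from pulsevessel.errors import EmptyRegionError, PulseVesselError
from pulsevessel.segmentation import CorrelationMap, _rowwise_pearson


def _wave(values):
    v = np.asarray(values, float)
    return CardiacWaveform(
        n_bins=v.size, bin_means=v, bin_counts=np.ones(v.size, int)
    )


def _uniform_phases(n_slices, n_t, seed=0):
    r = np.random.default_rng(seed)
    return PhaseAssignment(
        phases=r.uniform(size=(n_slices, n_t)),
        valid=np.ones((n_slices, n_t), dtype=bool),
    )


def _noise_bold(shape, n_t, seed=0, tr=0.5):
    r = np.random.default_rng(seed)
    return pv.Bold4D(r.normal(size=(*shape, n_t)), (2.5, 2.5, 2.5), tr)


class TestSplitHalves:
    def test_sizes_and_disjointness(self, rng):
        a, b = pv.split_halves(490, rng)
        assert a.size == 245 and b.size == 245
        assert np.intersect1d(a, b).size == 0
        assert np.array_equal(np.sort(np.concatenate([a, b])), np.arange(490))

    def test_odd_count_floor_rule(self, rng):
        a, b = pv.split_halves(5, rng)
        assert a.size == 2 and b.size == 3

    def test_same_seed_identical(self):
        a1, b1 = pv.split_halves(100, np.random.default_rng(42))
        a2, b2 = pv.split_halves(100, np.random.default_rng(42))
        assert np.array_equal(a1, a2) and np.array_equal(b1, b2)


class TestWaveformCorrelation:
    def test_self_correlation_is_one(self, rng):
        w = _wave(rng.normal(size=20))
        assert pv.waveform_correlation(w, w) == pytest.approx(1.0)

    def test_sign_flip(self, rng):
        v = rng.normal(size=20)
        assert pv.waveform_correlation(_wave(v), _wave(-v)) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        r = pv.waveform_correlation(_wave([1, 2, 3, 4]), _wave([1, 3, 2, 4]))
        assert r == pytest.approx(0.8)

    def test_zero_variance_is_nan(self, rng):
        assert np.isnan(
            pv.waveform_correlation(_wave(np.ones(8)), _wave(rng.normal(size=8)))
        )

    def test_matches_brute_force_pearson(self, rng):
        """(N-1)-normalized standardization equals plain Pearson."""
        for _ in range(200):
            x, y = rng.normal(size=(2, 20))
            num = np.sum((x - x.mean()) * (y - y.mean()))
            den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
            assert pv.waveform_correlation(_wave(x), _wave(y)) == pytest.approx(
                num / den, abs=1e-12
            )


class TestSplitHalfMap:
    def test_noise_voxels_centered_on_zero(self):
        bold = _noise_bold((8, 8, 4), 400, seed=3)
        phases = _uniform_phases(4, 400, seed=4)
        mask = pv.Mask3D(np.ones((8, 8, 4), bool), "brain")
        m = pv.split_half_corr_map(
            bold, phases, mask, n_repeats=30, rng=np.random.default_rng(5)
        )
        vals = m.values[np.isfinite(m.values)]
        se = vals.std() / np.sqrt(vals.size)
        assert abs(vals.mean()) < 3 * se + 0.01

    def test_vessel_voxels_exceed_point_six(self, phantom, prepped_bold, phantom_phases):
        m = pv.split_half_corr_map(
            prepped_bold,
            phantom_phases,
            phantom.truth_artery,
            n_repeats=20,
            rng=np.random.default_rng(0),
        )
        vals = m.values[phantom.truth_artery.data]
        assert np.nanmean(vals) > 0.6

    def test_repeat_averaging_reduces_variance(self):
        # averaging over splits removes split-randomness but not the
        # data-dependent component, so the shrinkage saturates well below
        # the independent-repeats factor; ~2x is what the estimator gives
        bold = _noise_bold((10, 10, 2), 400, seed=9)
        phases = _uniform_phases(2, 400, seed=10)
        mask = pv.Mask3D(np.ones((10, 10, 2), bool), "brain")
        m1 = pv.split_half_corr_map(bold, phases, mask, n_repeats=1,
                                    rng=np.random.default_rng(1))
        m100 = pv.split_half_corr_map(bold, phases, mask, n_repeats=100,
                                      rng=np.random.default_rng(1))
        v1 = np.nanvar(m1.values)
        v100 = np.nanvar(m100.values)
        assert v100 < v1 / 1.5

    def test_amplitude_monotonicity(self):
        """Stronger pulsatility never lowers a vessel's mean split-half
        correlation (fixed seed, amplitude grid)."""
        means = []
        for amp in (0.0, 0.5, 1.0, 2.0):
            bundle = pv.generate_phantom(
                pv.default_config(pulsatility_amplitude=amp, n_volumes=200)
            )
            trimmed = pv.trim_initial_volumes(bundle.bold, 10)
            prepped = pv.highpass_filter(trimmed, brain_mask=bundle.truth_artery)
            peaks = pv.detect_peaks(bundle.physio)
            phases = pv.assign_phase(prepped.acquisition_times(), peaks)
            m = pv.split_half_corr_map(
                prepped, phases, bundle.truth_artery,
                n_repeats=15, rng=np.random.default_rng(2),
            )
            means.append(np.nanmean(m.values[bundle.truth_artery.data]))
        assert all(b >= a - 0.02 for a, b in zip(means, means[1:]))
        assert means[-1] > means[0] + 0.3


class TestThresholds:
    def test_constant_map_threshold_is_the_constant(self):
        values = np.full((8, 8, 8), 0.2)
        cm = CorrelationMap(values, kind="split_half_mean")
        brain = pv.Mask3D(np.ones((8, 8, 8), bool), "brain")
        assert pv.preliminary_threshold(cm, brain) == pytest.approx(0.2)

    def test_standard_normal_gives_about_three(self, rng):
        # correlation-like values rescaled: use N(0, 0.1) and check mean+3sd
        vals = rng.normal(0.0, 0.1, size=(20, 20, 20)).clip(-1, 1)
        cm = CorrelationMap(vals, kind="split_half_mean")
        brain = pv.Mask3D(np.ones((20, 20, 20), bool), "brain")
        assert pv.preliminary_threshold(cm, brain) == pytest.approx(0.3, abs=0.02)

    def test_nan_policy(self, rng):
        vals = np.full((10, 10, 10), np.nan)
        vals[:5] = 0.1
        cm = CorrelationMap(vals, kind="split_half_mean")
        brain = pv.Mask3D(np.ones((10, 10, 10), bool), "brain")
        assert pv.preliminary_threshold(cm, brain) == pytest.approx(0.1)

    def test_too_few_defined_voxels(self):
        vals = np.full((4, 4, 4), np.nan)
        vals[0, 0, 0] = 0.5
        cm = CorrelationMap(vals, kind="split_half_mean")
        with pytest.raises(PulseVesselError, match="too few"):
            pv.preliminary_threshold(cm, pv.Mask3D(np.ones((4, 4, 4), bool), "brain"))

    def test_preliminary_region_rules(self, rng):
        vals = rng.uniform(-0.2, 0.5, size=(8, 8, 8))
        cm = CorrelationMap(vals, kind="split_half_mean")
        roi = pv.Mask3D(np.ones((8, 8, 8), bool), "general_artery")
        with pytest.raises(EmptyRegionError, match="empty preliminary region"):
            pv.preliminary_region(cm, roi, threshold=1.0)
        full = pv.preliminary_region(cm, roi, threshold=-2.0)
        assert full.n_voxels == 8 * 8 * 8

    def test_background_quantile_uniform(self, rng):
        vals = rng.uniform(0, 1, size=(20, 20, 20))
        cm = CorrelationMap(vals, kind="template")
        brain = pv.Mask3D(np.ones((20, 20, 20), bool), "brain")
        q = pv.background_quantile(cm, brain, [], 0.99)
        assert q == pytest.approx(0.99, abs=0.01)

    def test_background_quantile_median_of_three(self):
        vals = np.full((5, 5, 5), np.nan)
        vals.flat[:125] = np.resize([0.01, 0.02, 0.03], 125)
        cm = CorrelationMap(vals, kind="template")
        brain = pv.Mask3D(np.ones((5, 5, 5), bool), "brain")
        assert pv.background_quantile(cm, brain, [], 0.5) == pytest.approx(0.02)

    def test_exclusion_removes_high_population(self, rng):
        # two populations with a known background quantile once the
        # high-valued ROI is excluded
        vals = rng.uniform(0, 0.2, size=(12, 12, 12))
        roi = np.zeros((12, 12, 12), bool)
        roi[:4] = True
        vals[roi] = rng.uniform(0.8, 1.0, size=roi.sum())
        cm = CorrelationMap(vals, kind="template")
        brain = pv.Mask3D(np.ones((12, 12, 12), bool), "brain")
        q = pv.background_quantile(
            cm, brain, [pv.Mask3D(roi, "general_artery")], 0.99
        )
        assert q < 0.2


class TestRegionWaveform:
    def test_single_voxel_equals_bin_waveform_demeaned(self, rng):
        bold = _noise_bold((3, 3, 2), 300, seed=11)
        phases = _uniform_phases(2, 300, seed=12)
        mask = np.zeros((3, 3, 2), bool)
        mask[1, 2, 1] = True
        regional = pv.region_mean_waveform(bold, phases, pv.Mask3D(mask), n_bins=10)
        pa = PhaseAssignment(phases.phases[1], phases.valid[1])
        single = pv.bin_waveform(bold.data[1, 2, 1], pa, n_bins=10)
        expect = single.bin_means - np.average(
            single.bin_means, weights=single.bin_counts
        )
        assert np.allclose(regional.bin_means, expect, atol=1e-10)

    def test_duplicate_voxels_match_single(self):
        r = np.random.default_rng(13)
        series = r.normal(size=300)
        data = np.stack([series, series])[:, None, None, :]
        bold = pv.Bold4D(data, (2.5, 2.5, 2.5), 0.5)
        phases = _uniform_phases(1, 300, seed=14)
        both = pv.region_mean_waveform(
            bold, phases, pv.Mask3D(np.ones((2, 1, 1), bool)), n_bins=10
        )
        one = pv.region_mean_waveform(
            bold, phases, pv.Mask3D(np.array([[[True]], [[False]]])), n_bins=10
        )
        assert np.allclose(both.bin_means, one.bin_means)

    def test_recovers_generator_waveform(self, phantom, prepped_bold, phantom_phases):
        wave = pv.region_mean_waveform(
            prepped_bold, phantom_phases, phantom.truth_artery, n_bins=20
        )
        r = np.corrcoef(wave.bin_means, phantom.generator_waveform.bin_means)[0, 1]
        assert r > 0.98

    def test_empty_mask_errors(self):
        bold = _noise_bold((2, 2, 2), 100)
        with pytest.raises(EmptyRegionError):
            pv.region_mean_waveform(
                bold, _uniform_phases(2, 100), pv.Mask3D(np.zeros((2, 2, 2), bool))
            )


class TestTemplateMap:
    def test_matching_and_antiphase_voxels(self):
        template_vals = np.sin(2 * np.pi * (np.arange(20) + 0.5) / 20)
        r = np.random.default_rng(15)
        phases = _uniform_phases(1, 4000, seed=16)
        sig = np.interp(
            phases.phases[0], (np.arange(20) + 0.5) / 20, template_vals
        )
        data = np.stack([sig, -sig])[:, None, None, :]
        bold = pv.Bold4D(data, (2.5, 2.5, 2.5), 0.5)
        cm = pv.template_corr_map(
            bold, phases, _wave(template_vals), pv.Mask3D(np.ones((2, 1, 1), bool))
        )
        assert cm.values[0, 0, 0] > 0.99
        assert cm.values[1, 0, 0] < -0.99

    def test_rejects_over_interpolated_template(self):
        wave = CardiacWaveform(
            n_bins=10,
            bin_means=np.arange(10.0),
            bin_counts=np.array([1] * 4 + [0] * 6),
        )
        bold = _noise_bold((2, 2, 2), 100)
        with pytest.raises(PulseVesselError, match="template"):
            pv.template_corr_map(
                bold, _uniform_phases(2, 100), wave,
                pv.Mask3D(np.ones((2, 2, 2), bool)),
            )

    def test_rowwise_pearson_matches_corrcoef(self, rng):
        w = rng.normal(size=(50, 20))
        v = rng.normal(size=20)
        expected = [np.corrcoef(row, v)[0, 1] for row in w]
        assert np.allclose(_rowwise_pearson(w, v), expected, atol=1e-12)


class TestRefinement:
    def test_masks_subset_of_general_rois(self, phantom, pipeline_result):
        res = pipeline_result
        assert not np.any(res.artery.mask.data & ~phantom.general_artery_roi.data)
        assert not np.any(
            res.sss.mask.data
            & ~(phantom.general_sss_roi.data & phantom.brain_mask.data)
        )

    def test_converged_volume_trace(self, pipeline_result):
        for seg in (pipeline_result.artery, pipeline_result.sss):
            assert seg.converged
            assert len(seg.iterations) <= 20
            if len(seg.iterations) >= 2:
                v_prev, v_last = seg.iterations[-2][0], seg.iterations[-1][0]
                assert abs(v_last - v_prev) / v_prev < 0.01
            for vol, _thr, n in seg.iterations:
                assert vol == pytest.approx(n * 2.5**3 / 1000.0)

    def test_roi_without_pulsatile_voxels_errors(self, phantom, prepped_bold,
                                                 phantom_phases):
        # a general ROI placed in pure background yields an empty segmentation
        dead_roi = np.zeros(phantom.bold.spatial_shape, bool)
        dead_roi[2:6, 2:6, 2:6] = True
        dead_roi &= phantom.brain_mask.data
        rois = {
            "artery": pv.Mask3D(dead_roi, "general_artery"),
            "sss": phantom.general_sss_roi,
        }
        template = pv.region_mean_waveform(
            prepped_bold, phantom_phases, phantom.truth_artery, 20
        )
        with pytest.raises(EmptyRegionError):
            pv.refine_segmentation(
                prepped_bold, phantom_phases, "artery", rois,
                phantom.brain_mask, template,
            )


class TestOrchestration:
    def test_end_to_end_report(self, phantom, pipeline_result):
        res = pipeline_result
        assert res.qc.ppg_pass
        assert res.split_half_map.kind == "split_half_mean"
        assert res.preliminary_mask.n_voxels > 0
        assert res.artery.converged and res.sss.converged

    def test_artery_only_run_warns(self, phantom):
        res = pv.segment_vessels(
            phantom.bold, phantom.physio, phantom.brain_mask,
            phantom.general_artery_roi, None,
            config=pv.SegmentationConfig(seed=2, n_repeats=10),
        )
        assert res.sss is None
        assert any("SSS" in w for w in res.warnings)

    def test_strict_qc_gate(self, phantom, rng):
        bad_physio = pv.PhysioTrace(rng.normal(size=4000), fs=8.0)
        with pytest.raises(pv.QualityControlError):
            pv.segment_vessels(
                phantom.bold, bad_physio, phantom.brain_mask,
                phantom.general_artery_roi, phantom.general_sss_roi,
                config=pv.SegmentationConfig(seed=2, strict_qc=True),
            )
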