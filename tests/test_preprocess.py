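import numpy as np
import pytest

import pmkit
from pmkit import (MarkerDataset, PreprocessConfig, center_weight_normalize,
                   com_recenter, gap_fill, inverse_transform_coordinates,
                   lowpass_filter, mirror_trial, transform_coordinates)
from pmkit.preprocess import DegenerateTrialError
from pmkit import synthgen as sg
from conftest import make_planted_model


def _rank1_trial(T=200, N=9, gap=None, seed=0):
    """All columns scalar multiples of one sinusoid (plus offsets)."""
    rng = np.random.default_rng(seed)
    t = np.arange(T) / 100.0
    a = np.sin(2 * np.pi * 1.5 * t)
    loadings = rng.uniform(0.5, 2.0, N)
    offsets = rng.uniform(-5, 5, N)
    data = np.outer(a, loadings) + offsets
    labels = [f"m{j}" for j in range(N // 3)]
    truth = data.copy()
    mask = np.zeros_like(data, bool)
    if gap is not None:
        col, start, length = gap
        mask[start:start + length, col] = True
        data = data.copy()
        data[mask] = np.nan
    return MarkerDataset("s", "t", 100.0, labels, data, mask), truth


class TestGapFill:
    def test_identity_without_gaps(self, small_trial):
        assert gap_fill(small_trial) is small_trial

    def test_rank1_gap_recovered(self):
        trial, truth = _rank1_trial(gap=(2, 50, 10))
        filled = gap_fill(trial, rank=1)
        scale = np.max(np.abs(truth))
        np.testing.assert_allclose(filled.data, truth, atol=1e-6 * scale)
        assert not filled.missing_mask.any()

    def test_observed_cells_untouched(self):
        trial, truth = _rank1_trial(gap=(4, 100, 20))
        obs = ~trial.missing_mask
        filled = gap_fill(trial, rank=1)
        np.testing.assert_array_equal(filled.data[obs], trial.data[obs])

    def test_edge_gap(self):
        trial, truth = _rank1_trial(gap=(1, 0, 8))
        filled = gap_fill(trial, rank=1)
        scale = np.max(np.abs(truth))
        np.testing.assert_allclose(filled.data, truth, atol=1e-4 * scale)

    def test_fully_missing_column_rejected(self):
        trial, _ = _rank1_trial(T=50, gap=(0, 0, 50))
        with pytest.raises(DegenerateTrialError, match="fully missing"):
            gap_fill(trial, rank=1)

    def test_auto_rank_on_planted_model(self):
        model = make_planted_model(noise_sd=0.0)
        gappy = sg.generate_gappy_trial(model, [("LKNE", 100, 15)])
        truth = sg.generate_trial(model)
        filled = gap_fill(gappy)
        scale = np.max(np.abs(truth.data - truth.data.mean(axis=0)))
        assert np.max(np.abs(filled.data - truth.data)) < 1e-4 * scale


class TestMirror:
    def test_involution(self, planted_model):
        trial = sg.generate_trial(planted_model)
        swap = sg.humanoid_swap_map()
        twice = mirror_trial(mirror_trial(trial, "x", swap), "x", swap)
        np.testing.assert_array_equal(twice.data, trial.data)

    def test_single_marker_axis_negation(self):
        ds = MarkerDataset("s", "t", 100.0, ["m"],
                           np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]]))
        out = mirror_trial(ds, "y", {})
        np.testing.assert_array_equal(out.data,
                                      [[1.0, -2.0, 3.0], [1.0, -2.0, 3.0]])

    def test_symmetric_posture_is_fixed_point(self, humanoid_labels,
                                              humanoid_base):
        # static bilaterally symmetric posture: mirroring about x changes
        # nothing once left/right markers are swapped
        data = np.tile(humanoid_base, (5, 1))
        ds = MarkerDataset("s", "t", 100.0, humanoid_labels, data)
        out = mirror_trial(ds, "x", sg.humanoid_swap_map())
        np.testing.assert_array_equal(out.data, ds.data)

    def test_unknown_swap_label_rejected(self, small_trial):
        with pytest.raises(ValueError):
            mirror_trial(small_trial, "x", {"m1": "nope"})


class TestTransformCoordinates:
    def test_fixed_point_spherical(self):
        data = np.tile([1.0, 0.0, 0.0], (5, 1))
        ds = MarkerDataset("s", "t", 100.0, ["m"], data)
        out = transform_coordinates(ds, "spherical", origin=(0, 0, 0))
        np.testing.assert_allclose(out.data, np.tile([1.0, 0.0, 0.0], (5, 1)),
                                   atol=1e-12)

    @pytest.mark.parametrize("system", ["spherical", "cylindrical"])
    def test_round_trip(self, system, planted_model):
        trial = sg.generate_trial(planted_model)
        fwd = transform_coordinates(trial, system, origin=(0, 0, 0))
        back = inverse_transform_coordinates(fwd, system, origin=(0, 0, 0))
        np.testing.assert_allclose(back.data, trial.data, atol=1e-9)

    def test_arc_constant_radius(self):
        arc = sg.generate_arc_trial(radius=2.0, arc_degrees=120, frames=300)
        out = transform_coordinates(arc, "cylindrical", origin=(0, 0, 0))
        rho = out.data[:, 0]
        assert np.max(np.abs(rho - 2.0)) < 1e-9

    def test_azimuth_unwrapped(self):
        # 300 degree arc crosses the -pi branch cut; unwrap removes the jump
        arc = sg.generate_arc_trial(radius=1.0, arc_degrees=300, frames=400)
        out = transform_coordinates(arc, "cylindrical", origin=(0, 0, 0))
        az = out.data[:, 1]
        assert np.max(np.abs(np.diff(az))) < 0.1

    def test_origin_degeneracy_reported(self):
        data = np.zeros((4, 3))
        ds = MarkerDataset("s", "t", 100.0, ["m"], data)
        with pytest.raises(ValueError, match="frame 0"):
            transform_coordinates(ds, "spherical", origin=(0, 0, 0))


class TestLowpassFilter:
    def test_dc_passes_exactly(self):
        data = np.full((500, 3), 7.5)
        ds = MarkerDataset("s", "t", 100.0, ["m"], data)
        out = lowpass_filter(ds, cutoff=7.0)
        np.testing.assert_allclose(out.data, data, atol=1e-9)

    def test_stopband_attenuation(self):
        # oracle: amplitude via least-squares regression on sin/cos basis
        T, fs = 2000, 100.0
        t = np.arange(T) / fs
        lo = np.sin(2 * np.pi * 1.0 * t)
        hi = np.sin(2 * np.pi * 30.0 * t)
        data = np.column_stack([lo + hi, lo + hi, lo + hi])
        ds = MarkerDataset("s", "t", fs, ["m"], data)
        out = lowpass_filter(ds, cutoff=7.0)

        def amp(x, f):
            basis = np.column_stack([np.sin(2 * np.pi * f * t),
                                     np.cos(2 * np.pi * f * t)])
            coef, *_ = np.linalg.lstsq(basis, x, rcond=None)
            return np.hypot(*coef)

        assert amp(out.data[:, 0], 30.0) < 0.01
        assert amp(out.data[:, 0], 1.0) == pytest.approx(1.0, rel=0.01)

    def test_zero_phase(self):
        T, fs = 1000, 100.0
        t = np.arange(T) / fs
        x = np.sin(2 * np.pi * 1.0 * t)
        ds = MarkerDataset("s", "t", fs, ["m"],
                           np.column_stack([x, x, x]))
        y = lowpass_filter(ds, cutoff=7.0).data[:, 0]
        xc = np.correlate(y - y.mean(), x - x.mean(), mode="full")
        assert np.argmax(xc) == T - 1  # zero lag

    def test_cutoff_above_nyquist_rejected(self, small_trial):
        with pytest.raises(ValueError):
            lowpass_filter(small_trial, cutoff=60.0)

    def test_gaps_rejected(self):
        data = np.random.default_rng(0).normal(size=(100, 3))
        data[5, 0] = np.nan
        ds = MarkerDataset("s", "t", 100.0, ["m"], data)
        with pytest.raises(ValueError, match="gaps"):
            lowpass_filter(ds, cutoff=7.0)

    def test_too_short_rejected(self):
        ds = MarkerDataset("s", "t", 100.0, ["m"], np.zeros((10, 3)))
        with pytest.raises(ValueError, match="warm-up"):
            lowpass_filter(ds, cutoff=7.0)


class TestCenterWeightNormalize:
    def test_plain_centering(self):
        ds = MarkerDataset("s", "t", 100.0, ["m"],
                           np.array([[1.0, 3.0, 0.0], [3.0, 5.0, 0.0]]))
        out = center_weight_normalize(ds, PreprocessConfig())
        np.testing.assert_allclose(out.matrix[:, :2],
                                   [[-1.0, -1.0], [1.0, 1.0]])
        np.testing.assert_allclose(out.center_offset, [2.0, 4.0, 0.0])
        assert out.norm_factor == 1.0

    def test_med_analytic(self):
        ds = MarkerDataset("s", "t", 100.0, ["m"],
                           np.array([[3.0, 4.0, 0.0], [-3.0, -4.0, 0.0]]))
        out = center_weight_normalize(
            ds, PreprocessConfig(normalization="med"))
        assert out.norm_factor == pytest.approx(5.0)
        np.testing.assert_allclose(out.matrix[:, :2],
                                   [[0.6, 0.8], [-0.6, -0.8]])

    def test_med_row_norm_mean_is_one(self, planted_model):
        trial = sg.generate_trial(planted_model)
        out = center_weight_normalize(
            trial, PreprocessConfig(normalization="med"))
        assert np.mean(np.linalg.norm(out.matrix, axis=1)) == \
            pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("c", [0.3, 2.0, 1234.0])
    def test_med_scale_invariance(self, c, planted_model):
        trial = sg.generate_trial(planted_model)
        cfg = PreprocessConfig(normalization="med")
        base = center_weight_normalize(trial, cfg).matrix
        scaled = center_weight_normalize(trial.copy(data=trial.data * c),
                                         cfg).matrix
        np.testing.assert_allclose(scaled, base, atol=1e-9)

    def test_weighting_applied(self):
        ds = MarkerDataset("s", "t", 100.0, ["m1", "m2"],
                           np.array([[1.0, 0, 0, 1.0, 0, 0],
                                     [3.0, 0, 0, 3.0, 0, 0]]))
        mm = pmkit.build_mass_model({"m1": 0.25, "m2": 0.75}, ["m1", "m2"])
        out = center_weight_normalize(ds, PreprocessConfig(weighting=mm))
        np.testing.assert_allclose(out.matrix[:, 0], [-0.25, 0.25])
        np.testing.assert_allclose(out.matrix[:, 3], [-0.75, 0.75])

    def test_height_normalization(self):
        ds = MarkerDataset("s", "t", 100.0, ["m"],
                           np.array([[10.0, 0, 0], [-10.0, 0, 0]]))
        out = center_weight_normalize(
            ds, PreprocessConfig(normalization="height",
                                 subject_height=1800.0))
        assert out.norm_factor == 1800.0
        np.testing.assert_allclose(out.matrix[:, 0], [10 / 1800, -10 / 1800])

    def test_motionless_med_rejected(self):
        ds = MarkerDataset("s", "t", 100.0, ["m"], np.ones((5, 3)))
        with pytest.raises(DegenerateTrialError):
            center_weight_normalize(ds, PreprocessConfig(normalization="med"))

    def test_centering_idempotent(self, planted_model):
        trial = sg.generate_trial(planted_model)
        once = center_weight_normalize(trial, PreprocessConfig())
        again = center_weight_normalize(
            trial.copy(data=once.matrix), PreprocessConfig())
        np.testing.assert_allclose(again.matrix, once.matrix, atol=1e-12)


class TestComRecenter:
    def _mass(self, labels):
        return pmkit.build_mass_model(
            {m: 1.0 / len(labels) for m in labels}, labels)

    def test_translation_invariance(self, planted_model):
        trial = sg.generate_trial(planted_model)
        mass = self._mass(trial.marker_labels)
        shifted = trial.copy(data=trial.data + np.tile([123.0, -4.0, 9.0],
                                                       trial.n_markers))
        np.testing.assert_allclose(com_recenter(shifted, mass).data,
                                   com_recenter(trial, mass).data,
                                   atol=1e-9)

    def test_single_marker_goes_to_zero(self):
        ds = MarkerDataset("s", "t", 100.0, ["m"],
                           np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]))
        mass = pmkit.build_mass_model({"m": 1.0}, ["m"])
        np.testing.assert_allclose(com_recenter(ds, mass).data, 0.0)

    def test_weighted_mean_is_zero(self, planted_model):
        trial = sg.generate_trial(planted_model)
        rng = np.random.default_rng(9)
        frac = rng.uniform(0.01, 0.05, trial.n_markers)
        frac /= frac.sum()
        mass = pmkit.build_mass_model(
            dict(zip(trial.marker_labels, frac)), trial.marker_labels)
        out = com_recenter(trial, mass)
        xyz = out.data.reshape(out.n_frames, out.n_markers, 3)
        com = (xyz * mass.marker_weights[None, :, None]).sum(axis=1)
        assert np.max(np.abs(com)) < 1e-12 * np.max(np.abs(trial.data))

    def test_zero_total_weight_rejected(self, small_trial):
        mass = pmkit.build_mass_model({}, small_trial.marker_labels)
        with pytest.raises(ValueError):
            com_recenter(small_trial, mass)


class TestPipeline:
    def test_provenance_records_steps(self, planted_model):
        trial = sg.generate_trial(planted_model)
        cfg = PreprocessConfig(filter_cutoff=7.0, normalization="med")
        out = pmkit.run_pipeline(trial, cfg)
        steps = [p["step"] for p in out.provenance]
        assert steps == ["lowpass_filter", "center_weight_normalize"]

    def test_remaining_gaps_rejected(self, planted_model):
        gappy = sg.generate_gappy_trial(planted_model, [("LSHO", 10, 5)])
        with pytest.raises(ValueError, match="gaps"):
            pmkit.run_pipeline(gappy, PreprocessConfig())

    def test_gapfill_enabled(self, planted_model):
        gappy = sg.generate_gappy_trial(planted_model, [("LSHO", 10, 5)])
        out = pmkit.run_pipeline(
            gappy, PreprocessConfig(do_gapfill=True, gapfill_rank=3))
        assert out.provenance[0]["step"] == "gap_fill"

    def test_config_validation(self):
        cfg = PreprocessConfig(filter_cutoff=60.0)
        with pytest.raises(ValueError):
            cfg.validate(sampling_rate=100.0)
        cfg2 = PreprocessConfig(normalization="height")
        with pytest.raises(ValueError):
            cfg2.validate(sampling_rate=100.0)
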