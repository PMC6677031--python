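"""Synthetic-cohort generator: determinism, closed-form structure and
round-trips through the downstream quantifiers."""

import warnings

import numpy as np
import pandas as pd
import pytest

from tapmark.fc import compute_fc_matrix, fisher_z
from tapmark.kinematics import process_recording
from tapmark.pipeline import make_fixtures
from tapmark.simulate import (
    CohortConfig,
    ConfigError,
    default_fc_targets,
    generate_cohort,
    generate_roi_timeseries,
    generate_tap_waveform,
    generate_voi_counts,
)
from tapmark.spect import uptake_from_counts


def _tiny_config(seed=3):
    return make_fixtures("tiny", seed=seed)


class TestCohort:
    def test_group_counts(self, tiny_cohort):
        counts = tiny_cohort.subjects["group"].value_counts()
        assert counts.to_dict() == {"HC": 3, "RBD-N": 3, "RBD-MMI": 3}
        assert len(tiny_cohort.waveforms) == 9 * 2
        assert tiny_cohort.voi_counts["subject_id"].nunique() == 9
        assert len(tiny_cohort.roi_timeseries) == 9

    def test_seed_determinism(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = generate_cohort(_tiny_config())
            b = generate_cohort(_tiny_config())
        pd.testing.assert_frame_equal(a.subjects, b.subjects)
        pd.testing.assert_frame_equal(a.voi_counts, b.voi_counts)
        for key in a.waveforms:
            assert np.array_equal(a.waveforms[key].distance, b.waveforms[key].distance)
        for sid in a.roi_timeseries:
            assert np.array_equal(a.roi_timeseries[sid].data, b.roi_timeseries[sid].data)

    def test_different_seed_differs(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = generate_cohort(_tiny_config(seed=3))
            b = generate_cohort(_tiny_config(seed=4))
        assert not a.subjects.drop(columns=["subject_id", "group", "sex"]).equals(
            b.subjects.drop(columns=["subject_id", "group", "sex"])
        )

    def test_zero_group_size_rejected(self):
        cfg = _tiny_config()
        cfg.n_per_group = {"HC": 0, "RBD-N": 3, "RBD-MMI": 3}
        with pytest.raises(ConfigError, match="n_per_group"):
            generate_cohort(cfg)

    def test_bad_group_labels_rejected(self):
        cfg = _tiny_config()
        cfg.n_per_group = {"HC": 3, "PD": 3}
        with pytest.raises(ConfigError, match="group labels"):
            cfg.validate()

    def test_config_json_roundtrip(self):
        cfg = _tiny_config()
        restored = CohortConfig.from_json(cfg.to_json())
        assert restored.n_per_group == cfg.n_per_group
        assert restored.sbr_mean_by_group_region_side == cfg.sbr_mean_by_group_region_side
        for g in cfg.fc_target_matrix_by_group:
            assert np.allclose(
                restored.fc_target_matrix_by_group[g], cfg.fc_target_matrix_by_group[g]
            )

    def test_group_effect_monotonicity(self):
        # lowering a group's amplitude mean cannot raise its extracted mean
        def mean_amp(level, seed):
            cfg = _tiny_config(seed=seed)
            cfg.amplitude_mean_by_group_side = {
                g: {"R": level if g == "RBD-MMI" else 60.0, "L": 60.0}
                for g in cfg.n_per_group
            }
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cohort = generate_cohort(cfg)
            vals = [
                process_recording(rec)[1]["mean_amplitude"]
                for (sid, hand), rec in cohort.waveforms.items()
                if hand == "R" and sid.startswith("RM")
            ]
            return np.mean(vals)

        lo = np.mean([mean_amp(35.0, s) for s in range(10)])
        hi = np.mean([mean_amp(60.0, s) for s in range(10)])
        assert lo < hi


class TestTapWaveform:
    def test_exact_excursion_without_noise(self):
        rec = generate_tap_waveform(60.0, 3.0, 15.0, slope=0.0, noise_sd=0.0)
        assert np.ptp(rec.distance) == pytest.approx(60.0, abs=1e-9)

    def test_cycle_count_closed_form(self):
        rec = generate_tap_waveform(60.0, 3.0, 15.0, noise_sd=0.0)
        # one upward midline crossing per cycle -> duration * frequency = 45
        above = (rec.distance > 30.0).astype(int)
        upward = int(np.sum(np.diff(above) == 1))
        assert upward == 45

    def test_slope_shrinks_successive_cycles(self):
        rec = generate_tap_waveform(60.0, 2.0, 5.0, slope=-1.0, noise_sd=0.0)
        fs, f = 200.0, 2.0
        for k in range(9):
            seg = rec.distance[int(k * fs / f) : int((k + 1) * fs / f) + 1]
            assert np.ptp(seg) == pytest.approx(60.0 - k, abs=0.05)

    def test_distance_never_negative(self):
        rec = generate_tap_waveform(10.0, 3.0, 5.0, noise_sd=5.0, seed=0)
        assert (rec.distance >= 0).all()

    @pytest.mark.parametrize("bad", [{"amplitude": -1.0}, {"duration": 0.0}])
    def test_invalid_arguments_rejected(self, bad):
        kwargs = {"amplitude": 60.0, "frequency": 3.0, "duration": 15.0, **bad}
        with pytest.raises(ValueError):
            generate_tap_waveform(**kwargs)


class TestVoiCounts:
    SBR = {
        ("caudate", "R"): 1.0, ("caudate", "L"): 1.0,
        ("ant_putamen", "R"): 0.5, ("ant_putamen", "L"): 0.0,
        ("post_putamen", "R"): 2.0, ("post_putamen", "L"): 1.5,
    }

    def test_zero_noise_inversion_is_exact(self):
        counts = generate_voi_counts(self.SBR, 1000.0, noise_sd=0.0)
        uptake = uptake_from_counts(counts)
        for (region, side), sbr in self.SBR.items():
            got = uptake[(uptake.region == region) & (uptake.side == side)]["sbr"].iloc[0]
            assert got == pytest.approx(sbr, abs=1e-12)

    def test_sbr_one_doubles_counts(self):
        counts = generate_voi_counts(self.SBR, 1000.0, noise_sd=0.0)
        row = counts[(counts.region == "caudate") & (counts.side == "R")]
        assert row["mean_count"].iloc[0] == pytest.approx(2000.0)

    def test_noise_sd_recovered_monte_carlo(self, rng):
        vals = []
        for _ in range(5000):
            counts = generate_voi_counts(self.SBR, 1000.0, noise_sd=0.1, seed=rng)
            row = counts[(counts.region == "caudate") & (counts.side == "R")]
            vals.append(row["mean_count"].iloc[0] / 1000.0 - 1.0 - 1.0)
        assert np.std(vals) == pytest.approx(0.1, rel=0.05)

    def test_nonpositive_cerebellar_count_rejected(self):
        with pytest.raises(ValueError, match="cerebellar"):
            generate_voi_counts(self.SBR, 0.0)


class TestRoiTimeseries:
    def test_identity_target_off_diagonals_small(self, rng):
        labels = tuple(f"r{i}" for i in range(6))
        ts = generate_roi_timeseries(np.eye(6), 2000, seed=rng, roi_labels=labels)
        r = np.corrcoef(ts.data, rowvar=False)
        off = r[np.triu_indices(6, 1)]
        assert np.abs(off).max() < 5.0 / np.sqrt(2000)

    def test_fisher_z_calibration(self, rng):
        target = np.array([[1.0, 0.5], [0.5, 1.0]])
        zs = []
        for _ in range(1000):
            ts = generate_roi_timeseries(target, 180, seed=rng, roi_labels=("a", "b"))
            zs.append(fisher_z(np.corrcoef(ts.data, rowvar=False)[0, 1]))
        se = 1.0 / np.sqrt(177) / np.sqrt(1000)
        assert abs(np.mean(zs) - np.arctanh(0.5)) < 3 * se + 0.5 / (2 * 179)

    def test_duplicated_roi_perfectly_correlated(self, rng):
        target = np.ones((2, 2))
        ts = generate_roi_timeseries(target, 50, seed=rng, roi_labels=("a", "a_copy"))
        assert np.allclose(ts.data[:, 0], ts.data[:, 1])
        res = compute_fc_matrix(ts)
        assert res.r_matrix[0, 1] == pytest.approx(1.0)

    def test_non_psd_target_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="eigenvalue"):
            generate_roi_timeseries(bad, 50, roi_labels=("a", "b"))

    def test_default_targets_are_valid_correlations(self):
        for g, m in default_fc_targets().items():
            assert np.allclose(m, m.T)
            assert np.allclose(np.diag(m), 1.0)
            assert np.linalg.eigvalsh(m).min() > 0
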