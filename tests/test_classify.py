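"""Normative 2-SD model and the mild-motor-impairment rule."""



import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tapmark.classify import (
    NormativeTappingResults,
    classify_cohort,
    classify_subject,
    fit_normative_model,
)

PARAM_SIDE = [(p, s) for p in ("amplitude", "open_speed", "close_speed") for s in ("R", "L")]


def make_summaries(values_by_subject, slopes=-0.2):
    """Build a summary table; values_by_subject maps sid -> dict of
    (param, side) -> value (defaults filled with HC-like numbers)."""
    defaults = {"amplitude": 60.0, "open_speed": 0.55, "close_speed": 0.55}
    col = {"amplitude": "mean_amplitude", "open_speed": "mean_peak_open_speed",
           "close_speed": "mean_peak_close_speed"}
    slope_col = {"amplitude": "slope_amplitude", "open_speed": "slope_open_speed",
                 "close_speed": "slope_close_speed"}
    rows = []
    for sid, overrides in values_by_subject.items():
        for side in ("R", "L"):
            row = {"subject_id": sid, "hand": side, "n_cycles": 40}
            for p in ("amplitude", "open_speed", "close_speed"):
                row[col[p]] = overrides.get((p, side), defaults[p])
                row[slope_col[p]] = overrides.get((f"slope_{p}", side), slopes)
            rows.append(row)
    return pd.DataFrame(rows)


def hc_reference(n=10, spread=1.0, seed=0):
    rng = np.random.default_rng(seed)
    values = {}
    for i in range(n):
        overrides = {}
        for p, s in PARAM_SIDE:
            base = 60.0 if p == "amplitude" else 0.55
            sd = 10.0 if p == "amplitude" else 0.08
            overrides[(p, s)] = base + spread * sd * rng.standard_normal()
            overrides[(f"slope_{p}", s)] = -0.2 + 0.1 * rng.standard_normal()
        values[f"HC{i:03d}"] = overrides
    return make_summaries(values)


class TestNormativeFit:
    def test_hand_computed_mean_sd_cutoff(self):
        summ = make_summaries(
            {
                "H1": {("amplitude", "R"): 50.0, ("amplitude", "L"): 55.0},
                "H2": {("amplitude", "R"): 60.0, ("amplitude", "L"): 60.0},
                "H3": {("amplitude", "R"): 70.0, ("amplitude", "L"): 65.0},
            }
        )
        # other parameters constant -> perturb them to avoid degeneracy
        for i, c in enumerate(
            ["mean_peak_open_speed", "mean_peak_close_speed", "slope_amplitude",
             "slope_open_speed", "slope_close_speed"]
        ):
            summ[c] = summ[c] + 0.01 * np.arange(len(summ)) * (i + 1)
        res = fit_normative_model(summ)
        row = res.params.loc[("amplitude", "R")]
        assert row["value_mean"] == pytest.approx(60.0)
        assert row["value_sd"] == pytest.approx(10.0)  # sample SD, n-1
        assert row["value_cutoff"] == pytest.approx(40.0)

    def test_slope_cutoff_two_sd_below_mean(self):
        # published HC right-amplitude slope statistics imply cutoff -0.73
        params = pd.DataFrame(
            {
                "value_mean": 60.0, "value_sd": 10.0, "value_cutoff": 40.0,
                "slope_mean": -0.17, "slope_sd": 0.28,
                "slope_cutoff": -0.17 - 2 * 0.28,
            },
            index=pd.MultiIndex.from_tuples(PARAM_SIDE, names=["parameter", "side"]),
        )
        res = NormativeTappingResults(params=params, n_hc=20)
        assert res.params.loc[("amplitude", "R"), "slope_cutoff"] == pytest.approx(-0.73)

    def test_zero_variance_rejected(self):
        summ = make_summaries({f"H{i}": {} for i in range(4)})  # all identical
        with pytest.raises(ValueError, match="zero variance"):
            fit_normative_model(summ)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            fit_normative_model(hc_reference(n=2))

    def test_missing_hand_excluded_with_warning(self):
        summ = hc_reference(n=5)
        summ = summ[~((summ.subject_id == "HC000") & (summ.hand == "L"))]
        with pytest.warns(RuntimeWarning, match="missing hand"):
            res = fit_normative_model(summ)
        assert res.n_hc == 4

    def test_json_roundtrip(self, tmp_path):
        res = fit_normative_model(hc_reference())
        path = tmp_path / "model.json"
        res.to_json(path)
        restored = NormativeTappingResults.from_json(path.read_text())
        pd.testing.assert_frame_equal(
            restored.params.sort_index(), res.params.sort_index(), check_like=True
        )
        assert restored.n_hc == res.n_hc


@pytest.fixture(scope="module")
def model():
    return fit_normative_model(hc_reference())


class TestClassification:

    def test_values_at_means_not_flagged(self, model):
        means = {
            (p, s): model.params.loc[(p, s), "value_mean"] for p, s in PARAM_SIDE
        }
        summ = make_summaries({"X": means})
        out = model.classify(summ)
        assert not out["is_mmi"].iloc[0]
        assert out["n_flags"].iloc[0] == 0

    def test_single_low_parameter_flags(self, model):
        stats = model.params.loc[("amplitude", "R")]
        low = {("amplitude", "R"): stats["value_mean"] - 2.5 * stats["value_sd"]}
        low.update({(p, s): model.params.loc[(p, s), "value_mean"]
                    for p, s in PARAM_SIDE if (p, s) != ("amplitude", "R")})
        out = model.classify(make_summaries({"X": low}))
        assert out["is_mmi"].iloc[0]
        assert out["n_flags"].iloc[0] == 1
        assert out["flag_amplitude_R"].iloc[0]

    def test_exact_cutoff_is_not_flagged(self, model):
        cutoffs = {(p, s): model.params.loc[(p, s), "value_cutoff"] for p, s in PARAM_SIDE}
        out = model.classify(make_summaries({"X": cutoffs}))
        assert not out["is_mmi"].iloc[0]
        assert out["n_flags"].iloc[0] == 0

    def test_decrement_criterion_independent_of_values(self, model):
        means = {(p, s): model.params.loc[(p, s), "value_mean"] for p, s in PARAM_SIDE}
        steep = dict(means)
        steep[("slope_amplitude", "R")] = (
            model.params.loc[("amplitude", "R"), "slope_cutoff"] - 0.5
        )
        out = model.classify(make_summaries({"X": steep}))
        assert not out["is_mmi"].iloc[0]
        assert out["has_progressive_decrement"].iloc[0]

    def test_missing_hand_rejected(self, model):
        summ = make_summaries({"X": {}})
        with pytest.raises(ValueError, match="one summary per hand"):
            classify_subject(summ.iloc[0].to_dict(), summ.iloc[0].to_dict(), model)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        start=st.floats(min_value=30.0, max_value=90.0),
        drop=st.floats(min_value=0.0, max_value=60.0),
        which=st.integers(min_value=0, max_value=5),
    )
    def test_monotonicity_decreasing_never_unflags(self, start, drop, which):
        model = fit_normative_model(hc_reference())
        p, s = PARAM_SIDE[which]
        scale = 1.0 if p == "amplitude" else 0.01

        def mmi_at(value):
            vals = {(pp, ss): model.params.loc[(pp, ss), "value_mean"] for pp, ss in PARAM_SIDE}
            vals[(p, s)] = value * scale
            return bool(model.classify(make_summaries({"X": vals}))["is_mmi"].iloc[0])

        assert not (mmi_at(start) and not mmi_at(start - drop))


class TestCohortClassification:
    def test_constructed_low_subjects_detected(self):
        hc = hc_reference(n=10)
        model = fit_normative_model(hc)
        patients = {}
        for i in range(5):  # amplitude drawn 3 SD below the HC mean
            stats = model.params.loc[("amplitude", "R")]
            patients[f"P{i}"] = {("amplitude", "R"): stats["value_mean"] - 3 * stats["value_sd"]}
        for i in range(5, 8):
            patients[f"P{i}"] = {
                (p, s): model.params.loc[(p, s), "value_mean"] for p, s in PARAM_SIDE
            }
        summ = pd.concat([hc, make_summaries(patients)], ignore_index=True)
        subjects = pd.DataFrame(
            {
                "subject_id": summ["subject_id"].unique(),
                "group": ["HC"] * 10 + ["RBD"] * 8,
            }
        )
        table, _ = classify_cohort(summ, subjects)
        assert table["is_mmi"].sum() >= 5
        flagged = set(table[table.is_mmi]["subject_id"])
        assert {f"P{i}" for i in range(5)} <= flagged

    def test_no_patients_gives_empty_table(self):
        hc = hc_reference()
        subjects = pd.DataFrame(
            {"subject_id": hc["subject_id"].unique(), "group": "HC"}
        )
        table, res = classify_cohort(hc, subjects)
        assert table.empty
        assert res.n_hc == 10

    def test_no_hc_rejected(self):
        summ = hc_reference()
        subjects = pd.DataFrame({"subject_id": summ["subject_id"].unique(), "group": "RBD"})
        with pytest.raises(ValueError, match="no HC"):
            classify_cohort(summ, subjects)
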