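"""Synthetic cohort generator.

Emulates the data structure of a three-group study — healthy controls
(HC), RBD patients with normal motor function (RBD-N) and RBD patients
with mild motor impairment (RBD-MMI) — so every downstream analysis stage
is testable without subject-level data:

- demographics and clinical scores drawn around published group-level
  statistics (truncated normals; integer UPDRS items as Binomial(4, m/4));
- 15-s finger-tapping distance waveforms as raised-cosine tap trains with
  group-dependent amplitude, speed scaling and per-cycle decrement slope;
- striatal/cerebellar VOI mean counts realizing configured specific
  binding ratios with a graded, asymmetric reduction in the patient groups;
- multivariate-Gaussian ROI time series whose correlation structure
  differs by group in specific sensorimotor pairs.

Everything is a pure function of (config, seed): identical inputs give
bit-identical cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._rng import stage_rng
from .fc import DEFAULT_ROI_LABELS, RoiTimeSeries
from .kinematics import TapRecording
from .spect import CEREBELLUM, SIDES, STRIATAL_REGIONS

GROUPS = ("HC", "RBD-N", "RBD-MMI")
_GROUP_PREFIX = {"HC": "HC", "RBD-N": "RN", "RBD-MMI": "RM"}


class ConfigError(ValueError):
    """Invalid cohort configuration; message names the offending field."""


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

#: Demographics and clinical scores: per-group (mean, SD) or special entries.
DEFAULT_DEMOGRAPHICS: dict[str, Any] = {
    "age": {"HC": (70.7, 3.6), "RBD-N": (70.8, 4.0), "RBD-MMI": (72.2, 4.6)},
    "male_fraction": {"HC": 11 / 20, "RBD-N": 8 / 15, "RBD-MMI": 0.5},
    "scores": {
        # score -> group -> (mean, sd); truncation bounds applied per score
        "edinburgh_handedness": {"HC": (93.7, 19.5), "RBD-N": (95.8, 6.6), "RBD-MMI": (92.5, 11.6)},
        "mmse": {"HC": (28.7, 1.7), "RBD-N": (28.6, 1.2), "RBD-MMI": (29.3, 0.9)},
        "hads": {"HC": (5.2, 5.0), "RBD-N": (9.1, 4.8), "RBD-MMI": (12.6, 8.0)},
        "hads_anxiety": {"HC": (1.9, 2.3), "RBD-N": (3.5, 2.5), "RBD-MMI": (5.2, 5.9)},
        "hads_depression": {"HC": (3.3, 3.0), "RBD-N": (5.0, 3.6), "RBD-MMI": (7.3, 3.8)},
        "odor_identification": {"HC": (6.8, 1.5), "RBD-N": (4.8, 1.7), "RBD-MMI": (4.2, 2.4)},
        "rbdsq_j": {"HC": (1.3, 1.8), "RBD-N": (8.0, 2.5), "RBD-MMI": (9.1, 1.8)},
        "epworth": {"HC": (3.8, 2.6), "RBD-N": (5.8, 2.9), "RBD-MMI": (4.5, 3.5)},
        "pittsburgh": {"HC": (3.0, 2.5), "RBD-N": (5.0, 2.1), "RBD-MMI": (6.3, 3.8)},
    },
    "disease_duration": {"RBD-N": (4.7, 3.0), "RBD-MMI": (5.6, 3.9)},  # RBD groups only
    # UPDRS-III motor items (0-4 integers): per-group mean, drawn Binomial(4, m/4)
    "updrs_items": {
        "speech": {"HC": 0.0, "RBD-N": 0.06, "RBD-MMI": 0.12},
        "facial_expression": {"HC": 0.0, "RBD-N": 0.06, "RBD-MMI": 0.0},
        "tremor_at_rest": {"HC": 0.0, "RBD-N": 0.0, "RBD-MMI": 0.0},
        "action_tremor": {"HC": 0.05, "RBD-N": 0.06, "RBD-MMI": 0.12},
        "rigidity": {"HC": 0.2, "RBD-N": 0.33, "RBD-MMI": 0.25},
        "rt_finger_tapping": {"HC": 0.05, "RBD-N": 0.13, "RBD-MMI": 0.62},
        "lt_finger_tapping": {"HC": 0.05, "RBD-N": 0.0, "RBD-MMI": 0.50},
        "hand_movements": {"HC": 0.10, "RBD-N": 0.13, "RBD-MMI": 0.25},
        "rapid_alternating": {"HC": 0.0, "RBD-N": 0.13, "RBD-MMI": 0.0},
        "leg_agility": {"HC": 0.0, "RBD-N": 0.13, "RBD-MMI": 0.12},
        "arising_from_chair": {"HC": 0.0, "RBD-N": 0.0, "RBD-MMI": 0.0},
        "posture": {"HC": 0.0, "RBD-N": 0.06, "RBD-MMI": 0.0},
        "gait": {"HC": 0.0, "RBD-N": 0.0, "RBD-MMI": 0.0},
        "postural_stability": {"HC": 0.0, "RBD-N": 0.06, "RBD-MMI": 0.0},
        "body_bradykinesia": {"HC": 0.05, "RBD-N": 0.13, "RBD-MMI": 0.12},
    },
    # Polysomnography (RBD groups only): variable -> group -> (mean, sd)
    "psg": {
        "total_sleep_time_min": {"RBD-N": (405.7, 66.1), "RBD-MMI": (408.9, 71.3)},
        "sleep_efficiency_pct": {"RBD-N": (77.3, 11.9), "RBD-MMI": (78.9, 11.9)},
        "sleep_onset_latency_min": {"RBD-N": (11.1, 7.3), "RBD-MMI": (12.0, 5.5)},
        "rem_latency_min": {"RBD-N": (95.5, 45.8), "RBD-MMI": (84.3, 74.8)},
        "n1_pct": {"RBD-N": (23.0, 21.5), "RBD-MMI": (15.1, 6.1)},
        "n2_pct": {"RBD-N": (57.0, 14.4), "RBD-MMI": (57.9, 10.6)},
        "n3_pct": {"RBD-N": (2.4, 3.4), "RBD-MMI": (3.5, 3.5)},
        "rem_pct": {"RBD-N": (26.5, 31.5), "RBD-MMI": (21.3, 8.1)},
        "rem_without_atonia_pct": {"RBD-N": (50.1, 23.7), "RBD-MMI": (47.9, 22.2)},
        "arousal_index": {"RBD-N": (14.0, 6.4), "RBD-MMI": (14.4, 3.6)},
        "plm_index": {"RBD-N": (21.4, 21.1), "RBD-MMI": (11.8, 16.9)},
        "apnea_hypopnea_index": {"RBD-N": (5.5, 6.7), "RBD-MMI": (4.9, 5.4)},
    },
    "head_motion_fd": {"HC": (0.23, 0.14), "RBD-N": (0.22, 0.11), "RBD-MMI": (0.16, 0.076)},
}

#: Healthy-elderly reference SBR levels (no printed absolute values exist;
#: chosen at typical FP-CIT magnitudes) and per-group percent reductions.
_HC_SBR = {"caudate": 4.5, "ant_putamen": 4.2, "post_putamen": 4.0}
_SBR_REDUCTION_PCT = {
    "HC": {},
    "RBD-N": {
        ("post_putamen", "R"): 4.1,
        ("post_putamen", "L"): 3.8,
        ("ant_putamen", "R"): 4.6,
        ("ant_putamen", "L"): 1.0,
        ("caudate", "R"): 0.0,
        ("caudate", "L"): 0.0,
    },
    "RBD-MMI": {
        ("post_putamen", "R"): 30.2,
        ("post_putamen", "L"): 19.5,
        ("ant_putamen", "R"): 22.0,
        ("ant_putamen", "L"): 20.1,
        ("caudate", "R"): 15.8,
        ("caudate", "L"): 17.0,
    },
}


def default_sbr_means() -> dict[str, dict[tuple, float]]:
    """Per-group, per-(region, side) mean SBR implementing the graded,
    asymmetric reduction pattern (posterior putamen > anterior putamen >
    caudate, right side more affected in RBD-MMI)."""
    out: dict[str, dict[tuple, float]] = {}
    for group in GROUPS:
        red = _SBR_REDUCTION_PCT[group]
        out[group] = {
            (region, side): _HC_SBR[region] * (1.0 - red.get((region, side), 0.0) / 100.0)
            for region in STRIATAL_REGIONS
            for side in SIDES
        }
    return out


#: FC effect pairs (unordered) -> per-group target correlation.
_FC_EFFECT_PAIRS = {
    # reduced striatum-SPL coupling in both patient groups
    ("R_ant_putamen", "R_SPL"): {"HC": 0.40, "RBD-N": 0.10, "RBD-MMI": 0.10},
    ("L_ant_putamen", "R_SPL"): {"HC": 0.40, "RBD-N": 0.10, "RBD-MMI": 0.10},
    ("L_caudate", "R_SPL"): {"HC": 0.40, "RBD-N": 0.10, "RBD-MMI": 0.10},
    # elevated cerebellar lobule VIII - sensorimotor cortex coupling in RBD-MMI
    ("R_cereb_VIII", "R_S1"): {"HC": 0.25, "RBD-N": 0.10, "RBD-MMI": 0.40},
    ("L_cereb_VIII", "R_S1"): {"HC": 0.25, "RBD-N": 0.10, "RBD-MMI": 0.40},
    ("L_cereb_VIII", "L_S1"): {"HC": 0.25, "RBD-N": 0.10, "RBD-MMI": 0.40},
    ("L_cereb_VIII", "R_PM"): {"HC": 0.25, "RBD-N": 0.10, "RBD-MMI": 0.40},
}


def default_fc_targets(
    roi_labels: tuple = DEFAULT_ROI_LABELS, base_r: float = 0.10
) -> dict[str, np.ndarray]:
    """Per-group target ROI correlation matrices.

    A weak compound-symmetry background (``base_r``) plus the group-specific
    effect pairs at desk-detectable effect size (delta-r = 0.3).
    """
    idx = {lab: i for i, lab in enumerate(roi_labels)}
    out = {}
    for group in GROUPS:
        m = np.full((len(roi_labels), len(roi_labels)), base_r)
        np.fill_diagonal(m, 1.0)
        for (a, b), levels in _FC_EFFECT_PAIRS.items():
            if a in idx and b in idx:
                m[idx[a], idx[b]] = m[idx[b], idx[a]] = levels[group]
        out[group] = m
    return out


@dataclass
class CohortConfig:
    """All knobs of the synthetic study.

    Defaults are the study conditions: group sizes 20/15/8 (HC, RBD-N,
    RBD-MMI), 15-s taps at ~3 Hz sampled at 200 Hz, the published percent
    SBR reductions, and connectivity effects of delta-r = 0.3.
    """

    n_per_group: dict = field(
        default_factory=lambda: {"HC": 20, "RBD-N": 15, "RBD-MMI": 8}
    )
    seed: int = 0
    # --- tapping ---
    sampling_rate: float = 200.0
    tap_duration: float = 15.0
    tap_frequency_mean: float = 3.0
    tap_frequency_sd: float = 0.3
    amplitude_mean_by_group_side: dict = field(
        default_factory=lambda: {
            "HC": {"R": 60.0, "L": 58.0},
            "RBD-N": {"R": 55.0, "L": 53.0},
            "RBD-MMI": {"R": 38.0, "L": 36.0},
        }
    )
    amplitude_between_sd: float = 8.0
    open_speed_scale: dict = field(
        default_factory=lambda: {"HC": 1.0, "RBD-N": 1.0, "RBD-MMI": 0.85}
    )
    close_speed_scale: dict = field(
        default_factory=lambda: {"HC": 1.0, "RBD-N": 1.0, "RBD-MMI": 0.70}
    )
    slope_mean_by_group: dict = field(
        default_factory=lambda: {"HC": -0.24, "RBD-N": -0.28, "RBD-MMI": -0.32}
    )
    slope_sd_by_group: dict = field(
        default_factory=lambda: {"HC": 0.30, "RBD-N": 0.32, "RBD-MMI": 0.35}
    )
    noise_sd_distance: float = 0.5
    # --- SPECT ---
    sbr_mean_by_group_region_side: dict = field(default_factory=default_sbr_means)
    sbr_between_sd: float = 0.4
    sbr_noise_sd: float = 0.1
    cerebellar_count_mean: float = 1000.0
    cerebellar_count_sd: float = 100.0
    # --- rsfMRI ---
    roi_labels: tuple = DEFAULT_ROI_LABELS
    fc_target_matrix_by_group: dict = field(default_factory=default_fc_targets)
    n_volumes: int = 180
    tr: float = 2.5
    # --- demographics ---
    demographics_spec: dict = field(default_factory=lambda: DEFAULT_DEMOGRAPHICS)

    def validate(self) -> None:
        if set(self.n_per_group) != set(GROUPS):
            raise ConfigError(f"n_per_group: group labels must be exactly {GROUPS}")
        for g, n in self.n_per_group.items():
            if not isinstance(n, (int, np.integer)) or n <= 0:
                raise ConfigError(f"n_per_group[{g!r}]: must be a positive integer, got {n!r}")
        if self.sampling_rate < 50:
            raise ConfigError("sampling_rate: must be >= 50 Hz")
        if not (0.5 < self.tap_frequency_mean < 8):
            raise ConfigError("tap_frequency_mean: must lie in (0.5, 8) Hz")
        if self.tap_duration <= 0:
            raise ConfigError("tap_duration: must be positive")
        for name in (
            "tap_frequency_sd",
            "amplitude_between_sd",
            "noise_sd_distance",
            "sbr_between_sd",
            "sbr_noise_sd",
            "cerebellar_count_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name}: must be >= 0")
        if self.cerebellar_count_mean <= 0:
            raise ConfigError("cerebellar_count_mean: must be positive")
        if self.n_volumes < 10:
            raise ConfigError("n_volumes: must be >= 10")
        if self.tr <= 0:
            raise ConfigError("tr: must be positive")
        for g in GROUPS:
            m = np.asarray(self.fc_target_matrix_by_group[g], dtype=float)
            if m.shape != (len(self.roi_labels),) * 2:
                raise ConfigError(f"fc_target_matrix_by_group[{g!r}]: wrong shape")
            if not np.allclose(m, m.T):
                raise ConfigError(f"fc_target_matrix_by_group[{g!r}]: not symmetric")
            if not np.allclose(np.diag(m), 1.0):
                raise ConfigError(f"fc_target_matrix_by_group[{g!r}]: diagonal must be 1")
            w = np.linalg.eigvalsh(m)
            if w.min() < -1e-8:
                raise ConfigError(
                    f"fc_target_matrix_by_group[{g!r}]: not positive semidefinite "
                    f"(eigenvalue {w.min():.3g})"
                )

    def to_json(self, path=None) -> str:
        def _stringify_keys(d):
            if isinstance(d, dict):
                return {
                    ("|".join(k) if isinstance(k, tuple) else k): _stringify_keys(v)
                    for k, v in d.items()
                }
            return d

        payload = {
            k: _stringify_keys(v)
            for k, v in self.__dict__.items()
            if k not in ("fc_target_matrix_by_group", "roi_labels")
        }
        payload["roi_labels"] = list(self.roi_labels)
        payload["fc_target_matrix_by_group"] = {
            g: np.asarray(m).tolist() for g, m in self.fc_target_matrix_by_group.items()
        }
        text = json.dumps(payload, indent=2, sort_keys=True, default=_jsonify)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source: str) -> "CohortConfig":
        payload = json.loads(source)
        payload["roi_labels"] = tuple(payload["roi_labels"])
        payload["fc_target_matrix_by_group"] = {
            g: np.asarray(m, dtype=float)
            for g, m in payload["fc_target_matrix_by_group"].items()
        }
        for key in ("amplitude_mean_by_group_side", "sbr_mean_by_group_region_side"):
            if key in payload:
                payload[key] = _rekey(payload[key])
        return cls(**payload)


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return obj
    raise TypeError(f"cannot serialize {type(obj)}")


def _rekey(d):
    """JSON round-trip helper: tuple keys are serialized as 'a|b' strings."""
    out = {}
    for k, v in d.items():
        if isinstance(v, dict):
            out[k] = {
                (tuple(kk.split("|")) if isinstance(kk, str) and "|" in kk else kk): vv
                for kk, vv in v.items()
            }
        else:
            out[k] = v
    return out


# ---------------------------------------------------------------------------
# Elementary generators
# ---------------------------------------------------------------------------


def generate_tap_waveform(
    amplitude: float,
    frequency: float,
    duration: float,
    slope: float = 0.0,
    noise_sd: float = 0.0,
    open_close_asymmetry: float = 1.0,
    sampling_rate: float = 200.0,
    seed=None,
    subject_id: str = "sim",
    hand: str = "R",
    amplitude_floor: float = 1.0,
) -> TapRecording:
    """Raised-cosine tap train.

    The k-th cycle (k = 0, 1, ...) has peak-to-trough excursion
    ``max(amplitude + slope*k, amplitude_floor)``.  Within a cycle of
    period ``T = 1/frequency`` the opening phase occupies
    ``a/(1+a) * T`` and the closing phase ``1/(1+a) * T`` where
    ``a = open_close_asymmetry``, so peak close speed is ``a`` times peak
    open speed; for a = 1 both equal the sinusoid-implied ``A*pi*f``.
    Additive Gaussian noise (``noise_sd`` mm) is clipped so distance never
    goes negative.  The trace samples the closed interval [0, duration].
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if not (0.5 < frequency < 8):
        raise ValueError("frequency must lie in (0.5, 8) Hz")
    if open_close_asymmetry <= 0:
        raise ValueError("open_close_asymmetry must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * sampling_rate)) + 1
    t = np.arange(n) / sampling_rate
    T = 1.0 / frequency
    a = open_close_asymmetry
    t_open = T * a / (1.0 + a)
    cycle = np.floor(t / T + 1e-12).astype(int)
    phase = t - cycle * T
    A = np.maximum(amplitude + slope * cycle, amplitude_floor)
    d = np.where(
        phase < t_open,
        A / 2.0 * (1.0 - np.cos(np.pi * phase / t_open)),
        A / 2.0 * (1.0 + np.cos(np.pi * (phase - t_open) / (T - t_open))),
    )
    if noise_sd > 0:
        d = d + rng.normal(0.0, noise_sd, size=n)
    np.clip(d, 0.0, None, out=d)
    return TapRecording(subject_id=subject_id, hand=hand, sampling_rate=sampling_rate, distance=d)


def generate_voi_counts(
    sbr_by_region_side: dict,
    cerebellar_count: float,
    noise_sd: float = 0.0,
    seed=None,
    subject_id: str = "sim",
) -> pd.DataFrame:
    """VOI mean-count table realizing the given SBR values.

    ``striatal_count = cerebellar_count * (1 + SBR + eps)`` with
    ``eps ~ N(0, noise_sd)``; with ``noise_sd = 0`` recomputing SBR from
    the table returns the configured values exactly.
    """
    if cerebellar_count <= 0:
        raise ValueError("cerebellar_count must be positive")
    for key, v in sbr_by_region_side.items():
        if v <= -1:
            raise ValueError(f"target SBR for {key} must be > -1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for region in STRIATAL_REGIONS:
        for side in SIDES:
            sbr = sbr_by_region_side[(region, side)]
            eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            rows.append(
                {
                    "subject_id": subject_id,
                    "region": region,
                    "side": side,
                    "mean_count": cerebellar_count * (1.0 + sbr + eps),
                }
            )
    rows.append(
        {"subject_id": subject_id, "region": CEREBELLUM, "side": "NA", "mean_count": cerebellar_count}
    )
    return pd.DataFrame(rows)


def generate_roi_timeseries(
    target_correlation: np.ndarray,
    n_volumes: int,
    seed=None,
    roi_labels: tuple = DEFAULT_ROI_LABELS,
    tr: float = 2.5,
    subject_id: str = "sim",
) -> RoiTimeSeries:
    """Zero-mean multivariate Gaussian draws with the target correlation.

    The target must be symmetric, unit-diagonal and positive semidefinite
    (singular targets, e.g. a duplicated ROI at r = 1, are allowed).
    """
    m = np.asarray(target_correlation, dtype=float)
    if m.shape != (len(roi_labels),) * 2:
        raise ValueError("target matrix shape must match roi_labels")
    if not np.allclose(m, m.T):
        raise ValueError("target matrix must be symmetric")
    w, V = np.linalg.eigh(m)
    if w.min() < -1e-8:
        raise ValueError(f"target matrix not positive semidefinite (eigenvalue {w.min():.3g})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    factor = V * np.sqrt(np.clip(w, 0.0, None))
    data = rng.standard_normal((int(n_volumes), m.shape[0])) @ factor.T
    return RoiTimeSeries(subject_id=subject_id, roi_labels=roi_labels, tr=tr, data=data)


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    """A complete synthetic study bundle."""

    config: CohortConfig
    subjects: pd.DataFrame
    waveforms: dict  # (subject_id, hand) -> TapRecording
    voi_counts: pd.DataFrame  # long table over all subjects
    roi_timeseries: dict  # subject_id -> RoiTimeSeries


def _truncnorm(rng, mean, sd, lo=-np.inf, hi=np.inf, size=None):
    if sd <= 0:
        return np.full(size, float(mean)) if size else float(mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full synthetic study for ``config`` (deterministic in
    ``config.seed``)."""
    config.validate()
    spec = config.demographics_spec
    subject_rows = []
    waveforms: dict = {}
    voi_tables = []
    roi_ts: dict = {}
    subj_index = 0
    for group in GROUPS:
        for i in range(config.n_per_group[group]):
            sid = f"{_GROUP_PREFIX[group]}{i + 1:03d}"
            row: dict = {"subject_id": sid, "group": group}

            rng_d = stage_rng(config.seed, "demographics", subj_index)
            row["age"] = round(float(_truncnorm(rng_d, *spec["age"][group], lo=40, hi=95)), 1)
            row["sex"] = "M" if rng_d.random() < spec["male_fraction"][group] else "F"
            for score, per_group in spec["scores"].items():
                mean, sd = per_group[group]
                hi = {"mmse": 30, "edinburgh_handedness": 100}.get(score, np.inf)
                lo = {"edinburgh_handedness": -100}.get(score, 0.0)
                row[score] = round(float(_truncnorm(rng_d, mean, sd, lo=lo, hi=hi)), 1)
            if group in spec["disease_duration"]:
                row["disease_duration"] = round(
                    float(_truncnorm(rng_d, *spec["disease_duration"][group], lo=0.1)), 1
                )
            else:
                row["disease_duration"] = np.nan
            total = 0
            for item, per_group in spec["updrs_items"].items():
                m = min(max(per_group[group], 0.0), 4.0)
                val = int(rng_d.binomial(4, m / 4.0))
                row[f"updrs3_{item}"] = val
                total += val
            row["updrs3_total"] = total
            for var, per_group in spec["psg"].items():
                if group in per_group:
                    hi = 100.0 if var.endswith("_pct") else np.inf
                    row[var] = round(float(_truncnorm(rng_d, *per_group[group], lo=0.0, hi=hi)), 1)
                else:
                    row[var] = np.nan
            row["head_motion_fd"] = round(
                float(_truncnorm(rng_d, *spec["head_motion_fd"][group], lo=0.0)), 3
            )

            rng_t = stage_rng(config.seed, "tapping", subj_index)
            s_o = config.open_speed_scale[group]
            s_c = config.close_speed_scale[group]
            for hand in ("R", "L"):
                amp = float(
                    _truncnorm(
                        rng_t,
                        config.amplitude_mean_by_group_side[group][hand],
                        config.amplitude_between_sd,
                        lo=10.0,
                    )
                )
                freq = float(
                    _truncnorm(
                        rng_t, config.tap_frequency_mean, config.tap_frequency_sd, lo=1.0, hi=6.0
                    )
                )
                slope = float(
                    rng_t.normal(
                        config.slope_mean_by_group[group], config.slope_sd_by_group[group]
                    )
                )
                # time-warp so peak open/close speeds are s_o*A*pi*f and s_c*A*pi*f
                f_wave = 2.0 * freq * s_o * s_c / (s_o + s_c)
                waveforms[(sid, hand)] = generate_tap_waveform(
                    amplitude=amp,
                    frequency=f_wave,
                    duration=config.tap_duration,
                    slope=slope,
                    noise_sd=config.noise_sd_distance,
                    open_close_asymmetry=s_c / s_o,
                    sampling_rate=config.sampling_rate,
                    seed=rng_t,
                    subject_id=sid,
                    hand=hand,
                )

            rng_s = stage_rng(config.seed, "spect", subj_index)
            cereb = float(
                _truncnorm(
                    rng_s, config.cerebellar_count_mean, config.cerebellar_count_sd, lo=100.0
                )
            )
            sbr_subj = {
                key: max(mean + rng_s.normal(0.0, config.sbr_between_sd), -0.9)
                if config.sbr_between_sd > 0
                else mean
                for key, mean in config.sbr_mean_by_group_region_side[group].items()
            }
            voi_tables.append(
                generate_voi_counts(
                    sbr_subj, cereb, noise_sd=config.sbr_noise_sd, seed=rng_s, subject_id=sid
                )
            )

            rng_f = stage_rng(config.seed, "fmri", subj_index)
            roi_ts[sid] = generate_roi_timeseries(
                config.fc_target_matrix_by_group[group],
                config.n_volumes,
                seed=rng_f,
                roi_labels=config.roi_labels,
                tr=config.tr,
                subject_id=sid,
            )

            subject_rows.append(row)
            subj_index += 1

    return Cohort(
        config=config,
        subjects=pd.DataFrame(subject_rows),
        waveforms=waveforms,
        voi_counts=pd.concat(voi_tables, ignore_index=True),
        roi_timeseries=roi_ts,
    )
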