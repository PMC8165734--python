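"""Synthetic thermal-trial generator with known ground truth.

Emulates a paired stress-exposure experiment filmed with a radiometric
camera at 2 Hz: each trial spans a 3.5-minute undisturbed baseline followed
by 3.5 minutes of either handling (stress) or continued rest (control), with
time 0 at the enclosure opening.  Two facial regions respond with different
magnitudes: the bill cools by ~2.6 degC after handling while the eye region
cools by only ~0.4 degC.  The head wanders in yaw through a bounded smooth
random walk; yaw departure from facing the camera depresses the *apparent*
eye-region temperature by up to ~0.4 degC (an angle-of-incidence emissivity
artifact) but leaves the bill unaffected.  During handling the head is held
roughly perpendicular to the camera (yaw near 0).

Every output is a pure function of (config, seed).  The generator can emit
plain records (for the statistics), landmark projections (for the pose
solver), and full raw-count frames via the forward radiometric model (for
the end-to-end pipeline).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .extraction import RegionMask
from .pose import CameraModel, HeadModel3D, LandmarkObservation, default_head_template, \
    euler_to_rotation, project_points
from .radiometry import RadiometricCalibration, ThermalFrame, forward_radiance

__all__ = [
    "SimulationConfig",
    "SimulatedTrial",
    "ar1_noise",
    "temperature_trajectory",
    "pose_track",
    "apparent_temperature",
    "project_model",
    "render_frames",
    "simulate_records",
    "simulate_trial",
]

REGIONS = ("eye", "bill")


@dataclass(frozen=True)
class SimulationConfig:
    """Full generative specification of a synthetic experiment.

    Defaults encode the emulated study conditions: 9 stress / 5 control
    individuals, 2 Hz for 7 minutes (3.5 baseline + 3.5 treatment),
    baselines 35.0 / 31.5 degC (eye / bill), post-handling declines 0.4 /
    2.6 degC reached within 60 s, frame-level AR1 noise with rho = 0.889,
    individual baseline SD 0.35 degC, and a yaw-dependent apparent-
    temperature bias of 0.4 degC amplitude at the eye region only over the
    observed yaw span of roughly -88 to +61 degrees.
    """

    n_stress: int = 9
    n_control: int = 5
    trial_length_s: float = 420.0
    frame_rate_hz: float = 2.0
    baseline_eye_C: float = 35.0
    baseline_bill_C: float = 31.5
    decline_eye_C: float = 0.4
    decline_bill_C: float = 2.6
    decline_rise_s: float = 60.0
    ar1_rho: float = 0.889
    resid_sd_C: float = 0.30
    indiv_intercept_sd_C: float = 0.35
    indiv_slope_sd_eye_C: float = 0.1
    indiv_slope_sd_bill_C: float = 0.8
    yaw_bias_amplitude_eye_C: float = 0.4
    yaw_bias_amplitude_bill_C: float = 0.0
    yaw_range_deg: tuple[float, float] = (-88.0, 61.0)
    yaw_step_sd_deg: float = 3.0
    pitch_roll_step_sd_deg: float = 0.4
    pitch_roll_limit_deg: float = 12.0
    handled_yaw_sd_deg: float = 2.0
    landmark_noise_px: float = 0.5
    landmark_dropout_prob: float = 0.15
    qc_fail_frame_prob: float = 0.01
    frame_width: int = 640
    frame_height: int = 480
    head_distance_mm: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (-1.0 < self.ar1_rho < 1.0):
            raise ValueError("ar1_rho must lie in (-1, 1)")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        for name in ("resid_sd_C", "indiv_intercept_sd_C", "indiv_slope_sd_eye_C",
                     "indiv_slope_sd_bill_C"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def replace(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps (s); time 0 is the enclosure opening, mid-trial."""
        n = int(round(self.trial_length_s * self.frame_rate_hz))
        return (np.arange(n) - n // 2) / self.frame_rate_hz

    def baseline(self, region: str) -> float:
        return self.baseline_eye_C if region == "eye" else self.baseline_bill_C

    def decline(self, region: str) -> float:
        return self.decline_eye_C if region == "eye" else self.decline_bill_C

    def slope_sd(self, region: str) -> float:
        return self.indiv_slope_sd_eye_C if region == "eye" else self.indiv_slope_sd_bill_C

    def yaw_bias_amplitude(self, region: str) -> float:
        return (self.yaw_bias_amplitude_eye_C if region == "eye"
                else self.yaw_bias_amplitude_bill_C)


@dataclass
class SimulatedTrial:
    """One individual's trial: truth, pose track, landmarks and (optionally) frames."""

    individual_id: str
    treatment: str
    times: np.ndarray
    true_temps: dict            # region -> true degC series
    apparent_temps: dict        # region -> yaw-biased degC series
    pose: pd.DataFrame          # frame_id, time_s, pitch/yaw/roll (truth)
    landmarks: list             # LandmarkObservation per frame
    qc_fail_frames: set         # frame_ids generated to fail pose QC
    frames: list | None = None  # ThermalFrame sequence when rendered
    masks: dict | None = None   # region -> RegionMask


def ar1_noise(n: int, rho: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR1 series with marginal SD ``sd`` and lag-1 correlation ``rho``."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1.0 - rho * rho)
    e = rng.normal(0.0, innov_sd, n)
    e[0] = rng.normal(0.0, sd)
    out = np.empty(n)
    acc = e[0]
    out[0] = acc
    for i in range(1, n):
        acc = rho * acc + e[i]
        out[i] = acc
    return out


def _decline_shape(t: np.ndarray, rise_s: float) -> np.ndarray:
    """Smooth monotone 0 -> 1 transition over [0, rise_s] (smoothstep), then plateau."""
    u = np.clip(t / rise_s, 0.0, 1.0)
    g = 3 * u**2 - 2 * u**3
    g[t < 0] = 0.0
    return g


def temperature_trajectory(region: str, treatment: str, indiv_intercept: float,
                           indiv_slope: float, config: SimulationConfig,
                           rng: np.random.Generator) -> np.ndarray:
    """True surface-temperature series (degC) for one individual and region.

    baseline + individual intercept, plus (stress only) a smooth monotone
    decline reaching ``decline + indiv_slope`` within ``decline_rise_s`` and
    persisting, plus AR1 Gaussian noise.
    """
    t = config.times
    temp = np.full(t.shape, config.baseline(region) + indiv_intercept)
    if treatment == "stress":
        amplitude = config.decline(region) + indiv_slope
        temp -= amplitude * _decline_shape(t, config.decline_rise_s)
    temp += ar1_noise(len(t), config.ar1_rho, config.resid_sd_C, rng)
    return temp


def _reflect(x: float, lo: float, hi: float) -> float:
    width = hi - lo
    if width <= 0:
        return lo
    y = (x - lo) % (2 * width)
    return lo + (y if y <= width else 2 * width - y)


def pose_track(config: SimulationConfig, rng: np.random.Generator,
               treatment: str = "control") -> pd.DataFrame:
    """Per-frame (pitch, yaw, roll): a bounded smooth random walk.

    Yaw reflects at the configured range bounds.  In stress trials, frames
    after time 0 hold the head roughly perpendicular to the camera (yaw
    jittering near 0) to emulate restraint during handling.
    """
    t = config.times
    lo, hi = config.yaw_range_deg
    yaw = np.empty(len(t))
    yaw[0] = rng.uniform(lo, hi)
    for i in range(1, len(t)):
        yaw[i] = _reflect(yaw[i - 1] + rng.normal(0, config.yaw_step_sd_deg), lo, hi)
    if treatment == "stress":
        handled = t >= 0
        yaw[handled] = np.clip(
            rng.normal(0.0, config.handled_yaw_sd_deg, handled.sum()), lo, hi
        )
    lim = config.pitch_roll_limit_deg
    pitch = np.empty(len(t))
    roll = np.empty(len(t))
    pitch[0] = rng.uniform(-lim / 2, lim / 2)
    roll[0] = rng.uniform(-lim / 2, lim / 2)
    for i in range(1, len(t)):
        pitch[i] = _reflect(pitch[i - 1] + rng.normal(0, config.pitch_roll_step_sd_deg), -lim, lim)
        roll[i] = _reflect(roll[i - 1] + rng.normal(0, config.pitch_roll_step_sd_deg), -lim, lim)
    return pd.DataFrame({"time_s": t, "pitch_deg": pitch, "yaw_deg": yaw, "roll_deg": roll})


def yaw_bias(yaw_deg, region: str, config: SimulationConfig) -> np.ndarray:
    """Apparent-temperature depression (degC) as a function of yaw.

    The bias grows monotonically with the angular departure from facing the
    camera (yaw = -90), following a 1 - cos(incidence) law rescaled so that
    the difference between the two extremes of the configured yaw range
    equals the region's bias amplitude.
    """
    yaw = np.asarray(yaw_deg, dtype=float)
    amp = config.yaw_bias_amplitude(region)
    if amp == 0:
        return np.zeros_like(yaw)
    lo, hi = config.yaw_range_deg
    inc = np.deg2rad(yaw + 90.0)      # 0 when facing the camera
    inc_lo, inc_hi = np.deg2rad(lo + 90.0), np.deg2rad(hi + 90.0)
    g = 1.0 - np.cos(inc)
    g_lo, g_hi = 1.0 - np.cos(inc_lo), 1.0 - np.cos(inc_hi)
    return amp * (g - g_lo) / (g_hi - g_lo)


def apparent_temperature(true_C, yaw_deg, region: str,
                         config: SimulationConfig) -> np.ndarray:
    """Observed temperature before radiometric encoding: true - bias(yaw)."""
    return np.asarray(true_C, dtype=float) - yaw_bias(yaw_deg, region, config)


def project_model(pose_row, model: HeadModel3D, camera: CameraModel,
                  noise_px: float, rng: np.random.Generator,
                  *, frame_id: str = "f0", translation=None,
                  dropout_prob: float = 0.0) -> LandmarkObservation:
    """Project the head template under a pose into noisy pixel landmarks.

    ``pose_row`` carries pitch/yaw/roll in degrees.  Optional random
    occlusion drops landmarks (never below 4 per frame).
    """
    r = euler_to_rotation(pose_row["pitch_deg"], pose_row["yaw_deg"], pose_row["roll_deg"])
    if translation is None:
        translation = np.array([0.0, 0.0, 500.0])
    labels = list(model.points)
    pts = model.array(labels)
    uv = project_points(pts, r, np.asarray(translation, float), camera)
    if noise_px > 0:
        uv = uv + rng.normal(0.0, noise_px, uv.shape)
    keep = np.ones(len(labels), dtype=bool)
    if dropout_prob > 0:
        keep = rng.random(len(labels)) > dropout_prob
        while keep.sum() < 4:
            keep[rng.integers(len(labels))] = True
    lm = {lab: (float(u), float(v)) for lab, (u, v), k in zip(labels, uv, keep) if k}
    return LandmarkObservation(frame_id=frame_id, landmarks=lm)


def _region_masks(config: SimulationConfig) -> dict:
    """Static ground-truth ROI masks scaled to the frame size.

    At the native 640x480 resolution the eye mask covers ~2200 px and the
    bill mask ~2000 px, matching the emulated study's region sizes.
    """
    h, w = config.frame_height, config.frame_width
    scale = (h * w) / (480 * 640)
    masks = {}
    yy, xx = np.mgrid[0:h, 0:w]
    # eye: ellipse left-of-centre; bill: rectangle right-of-centre
    r_eye = np.sqrt(2200.0 * scale / np.pi)
    cy, cx = h * 0.4, w * 0.35
    masks["eye"] = RegionMask("eye", (yy - cy) ** 2 + (xx - cx) ** 2 <= r_eye**2)
    n_bill = max(int(round(2000 * scale)), 4)
    bw = max(int(np.sqrt(n_bill * 2)), 2)
    bh = max(n_bill // bw, 1)
    y0, x0 = int(h * 0.55), int(w * 0.6)
    bill = np.zeros((h, w), dtype=bool)
    bill[y0:y0 + bh, x0:x0 + bw] = True
    masks["bill"] = RegionMask("bill", bill)
    return masks


def render_frames(trial: SimulatedTrial, calib: RadiometricCalibration,
                  config: SimulationConfig, rng: np.random.Generator):
    """Encode a trial's apparent temperatures into raw-count frames + masks.

    Background pixels sit at ambient; within each ROI the temperature field
    peaks exactly at the trajectory value (a central hot spot with a mild
    falloff elsewhere), so max-extraction over the emitted mask recovers the
    trajectory up to count quantization.
    """
    masks = _region_masks(config)
    ambient = calib.atmosphere_temp_C
    h, w = config.frame_height, config.frame_width
    base = np.full((h, w), ambient)
    frames = []
    falloff = {}
    for region, rm in masks.items():
        idx = np.flatnonzero(rm.mask.ravel())
        fall = np.full(idx.shape, 0.8)
        fall[len(idx) // 2] = 0.0   # peak pixel carries the exact value
        falloff[region] = (idx, fall)
    for i, t in enumerate(trial.times):
        temp = base.copy()
        flat = temp.ravel()
        for region, rm in masks.items():
            idx, fall = falloff[region]
            flat[idx] = trial.apparent_temps[region][i] - fall
        counts = forward_radiance(temp + 273.15, calib)
        counts = np.round(counts).astype(np.int32)
        frames.append(ThermalFrame(counts=counts, timestamp=float(t),
                                   frame_id=f"{trial.individual_id}_{trial.treatment}_{i:05d}",
                                   trial_id=f"{trial.individual_id}_{trial.treatment}"))
    trial.frames = frames
    trial.masks = masks
    return frames, masks


def simulate_trial(individual_id: str, treatment: str, config: SimulationConfig,
                   rng: np.random.Generator, *, with_landmarks: bool = True,
                   camera: CameraModel | None = None,
                   template: HeadModel3D | None = None,
                   indiv_intercept: float = 0.0,
                   indiv_slopes: dict | None = None) -> SimulatedTrial:
    """Generate one individual's trial (no frame rendering by default)."""
    t = config.times
    slopes = indiv_slopes or {r: 0.0 for r in REGIONS}
    pose = pose_track(config, rng, treatment)
    true_temps, apparent = {}, {}
    for region in REGIONS:
        series = temperature_trajectory(region, treatment, indiv_intercept,
                                        slopes[region], config, rng)
        true_temps[region] = series
        apparent[region] = apparent_temperature(series, pose["yaw_deg"].to_numpy(),
                                                region, config)
    frame_ids = [f"{individual_id}_{treatment}_{i:05d}" for i in range(len(t))]
    pose = pose.assign(frame_id=frame_ids)
    landmarks: list[LandmarkObservation] = []
    qc_fail: set[str] = set()
    if with_landmarks:
        camera = camera or CameraModel(width=config.frame_width, height=config.frame_height,
                                       cx=config.frame_width / 2, cy=config.frame_height / 2)
        template = template or default_head_template()
        translation = np.array([0.0, 0.0, config.head_distance_mm])
        for i, fid in enumerate(frame_ids):
            fail = rng.random() < config.qc_fail_frame_prob
            noise = 40.0 if fail else config.landmark_noise_px
            obs = project_model(pose.iloc[i], template, camera, noise, rng,
                                frame_id=fid, translation=translation,
                                dropout_prob=config.landmark_dropout_prob)
            landmarks.append(obs)
            if fail:
                qc_fail.add(fid)
    return SimulatedTrial(
        individual_id=individual_id, treatment=treatment, times=t,
        true_temps=true_temps, apparent_temps=apparent, pose=pose,
        landmarks=landmarks, qc_fail_frames=qc_fail,
    )


def _individual_effects(config: SimulationConfig, rng: np.random.Generator,
                        individuals: list[str]) -> dict:
    out = {}
    for ind in individuals:
        out[ind] = {
            "intercept": rng.normal(0.0, config.indiv_intercept_sd_C),
            "slopes": {r: rng.normal(0.0, config.slope_sd(r)) for r in REGIONS},
        }
    return out


def simulate_records(config: SimulationConfig, *, include_yaw: bool = True,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Frame-level records table for the whole experiment (no rendering).

    The returned yaw is the ground-truth head yaw (what a perfect pose
    pipeline would attach); ``temp_max_C`` is the apparent (yaw-biased)
    temperature.  Columns match the extraction-module record schema.
    """
    rng = rng or np.random.default_rng(config.seed)
    individuals = ([f"S{i:02d}" for i in range(config.n_stress)]
                   + [f"C{i:02d}" for i in range(config.n_control)])
    treatments = (["stress"] * config.n_stress + ["control"] * config.n_control)
    effects = _individual_effects(config, rng, individuals)
    rows = []
    for ind, treat in zip(individuals, treatments):
        trial = simulate_trial(ind, treat, config, rng, with_landmarks=False,
                               indiv_intercept=effects[ind]["intercept"],
                               indiv_slopes=effects[ind]["slopes"])
        for region in REGIONS:
            rows.append(pd.DataFrame({
                "individual_id": ind,
                "treatment": treat,
                "region": region,
                "time_s": trial.times,
                "temp_max_C": trial.apparent_temps[region],
                "yaw_deg": trial.pose["yaw_deg"].to_numpy() if include_yaw else np.nan,
                "window_averaged": False,
            }))
    return pd.concat(rows, ignore_index=True)


def simulate_experiment(config: SimulationConfig, *, render: bool = False,
                        calib: RadiometricCalibration | None = None) -> list[SimulatedTrial]:
    """All trials of the experiment, with landmarks (and frames if ``render``)."""
    rng = np.random.default_rng(config.seed)
    individuals = ([f"S{i:02d}" for i in range(config.n_stress)]
                   + [f"C{i:02d}" for i in range(config.n_control)])
    treatments = (["stress"] * config.n_stress + ["control"] * config.n_control)
    effects = _individual_effects(config, rng, individuals)
    trials = []
    calib = calib or RadiometricCalibration()
    for ind, treat in zip(individuals, treatments):
        trial = simulate_trial(ind, treat, config, rng,
                               indiv_intercept=effects[ind]["intercept"],
                               indiv_slopes=effects[ind]["slopes"])
        if render:
            render_frames(trial, calib, config, rng)
        trials.append(trial)
    return trials


def write_trial_directory(trials: list[SimulatedTrial], out_dir: str | Path,
                          config: SimulationConfig,
                          calib: RadiometricCalibration | None = None,
                          *, write_frames: bool = False) -> None:
    """Emit the on-disk layout: frames/ (TIFF), landmarks.csv, masks/, manifest.csv, truth.json."""
    import dataclasses
    import json

    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lm_rows, manifest_rows, truth = [], [], {"config": dataclasses.asdict(config), "trials": {}}
    for trial in trials:
        key = f"{trial.individual_id}_{trial.treatment}"
        truth["trials"][key] = {
            "qc_fail_frames": sorted(trial.qc_fail_frames),
            "n_frames": len(trial.times),
        }
        for obs in trial.landmarks:
            for lab, (u, v) in obs.landmarks.items():
                lm_rows.append((obs.frame_id, lab, u, v))
        for i, t in enumerate(trial.times):
            fid = f"{trial.individual_id}_{trial.treatment}_{i:05d}"
            manifest_rows.append((fid, trial.individual_id, trial.treatment, float(t)))
        if write_frames and trial.frames is not None:
            fdir = out / "frames"
            fdir.mkdir(exist_ok=True)
            for fr in trial.frames:
                tifffile.imwrite(fdir / f"{fr.frame_id}.tif",
                                 fr.counts.astype(np.uint16))
        if trial.masks is not None:
            mdir = out / "masks"
            mdir.mkdir(exist_ok=True)
            for region, rm in trial.masks.items():
                np.savetxt(mdir / f"{key}_{region}.csv", rm.mask.astype(int),
                           fmt="%d", delimiter=",")
    pd.DataFrame(lm_rows, columns=["frame_id", "label", "u_px", "v_px"]).to_csv(
        out / "landmarks.csv", index=False)
    pd.DataFrame(manifest_rows,
                 columns=["frame_id", "individual_id", "treatment", "time_s"]).to_csv(
        out / "manifest.csv", index=False)
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
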