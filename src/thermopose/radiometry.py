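"""Radiometric conversion between raw thermal-camera counts and surface temperature.

Long-wave thermal cameras report a digital signal that is (approximately) linear
in received radiance.  The sensor signal attributable to a blackbody at
temperature ``T`` follows the camera-specific Planck parameterization

    S(T) = R1 / (R2 * (exp(B / T) - F)) - O

with calibration constants ``R1, R2, B, O, F`` stored by the manufacturer.  The
total scene signal mixes three sources: object emission (weight ``eps * tau``),
reflected ambient radiation (``(1 - eps) * tau``) and atmospheric path emission
(``1 - tau``), where ``eps`` is the object emissivity and ``tau`` the
atmospheric transmittance over the camera-object path.  Inverting this model
recovers object surface temperature from raw counts.

All user-facing temperatures are degrees Celsius; internals are kelvin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "AtmosphericConstants",
    "RadiometricCalibration",
    "ThermalFrame",
    "atmospheric_transmittance",
    "planck_signal",
    "invert_planck",
    "forward_radiance",
    "raw_to_temperature",
    "convert_frame",
    "load_calibration",
    "read_frame",
    "write_temperature_matrix",
]

KELVIN_OFFSET = 273.15

#: Valid object-temperature domain for the forward model (K).
T_MIN_K = 233.0
T_MAX_K = 373.0


@dataclass(frozen=True)
class AtmosphericConstants:
    """Coefficients of the two-term exponential atmospheric attenuation model.

    Defaults are the standard long-wave values used across the radiometric
    literature for FLIR-class cameras.
    """

    alpha1: float = 0.006569
    alpha2: float = 0.01262
    beta1: float = -0.002276
    beta2: float = -0.00667
    x: float = 1.9


@dataclass(frozen=True)
class RadiometricCalibration:
    """Planck calibration constants plus scene parameters.

    Planck-constant defaults are typical uncooled long-wave microbolometer
    values, suitable for synthetic work; real-camera constants (extractable
    from radiometric image metadata) must be supplied by the user.

    Scene defaults mirror a controlled indoor trial: emissivity 0.95 for bare
    facial tissue, 18 degC ambient at 40% relative humidity, reflected source
    assumed equal to ambient, 0.5 m camera distance.
    """

    planck_R1: float = 21106.77
    planck_R2: float = 0.012545
    planck_B: float = 1501.0
    planck_O: float = -7340.0
    planck_F: float = 1.0
    emissivity: float = 0.95
    reflected_temp_C: float = 18.0
    atmosphere_temp_C: float = 18.0
    relative_humidity: float = 0.40
    object_distance_m: float = 0.5
    atm_constants: AtmosphericConstants = field(default_factory=AtmosphericConstants)

    def __post_init__(self) -> None:
        if not (0.0 < self.emissivity <= 1.0):
            raise ValueError(f"emissivity must lie in (0, 1], got {self.emissivity}")
        if not (0.0 <= self.relative_humidity <= 1.0):
            raise ValueError(
                f"relative_humidity must lie in [0, 1], got {self.relative_humidity}"
            )
        if self.object_distance_m < 0:
            raise ValueError(f"object_distance_m must be >= 0, got {self.object_distance_m}")
        if self.planck_B <= 0 or self.planck_R2 <= 0:
            raise ValueError("planck_B and planck_R2 must be positive")

    @property
    def reflected_temp_K(self) -> float:
        return self.reflected_temp_C + KELVIN_OFFSET

    @property
    def atmosphere_temp_K(self) -> float:
        return self.atmosphere_temp_C + KELVIN_OFFSET

    def replace(self, **kwargs) -> "RadiometricCalibration":
        return replace(self, **kwargs)


@dataclass
class ThermalFrame:
    """One raw thermal image: a matrix of sensor counts with identity metadata."""

    counts: np.ndarray
    timestamp: float
    frame_id: str
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if not np.all(np.isfinite(self.counts)):
            raise ValueError(f"frame {self.frame_id}: non-finite counts")
        if np.any(self.counts < 0):
            raise ValueError(f"frame {self.frame_id}: negative counts")


def planck_signal(temp_K, calib: RadiometricCalibration):
    """Blackbody sensor signal S(T) for the camera's Planck constants."""
    t = np.asarray(temp_K, dtype=float)
    return calib.planck_R1 / (calib.planck_R2 * (np.exp(calib.planck_B / t) - calib.planck_F)) - calib.planck_O


def invert_planck(signal, calib: RadiometricCalibration):
    """Temperature (K) whose blackbody signal equals ``signal``.

    Invalid signals (log argument <= 1, i.e. no physical temperature) map to NaN.
    """
    s = np.asarray(signal, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        arg = calib.planck_R1 / (calib.planck_R2 * (s + calib.planck_O)) + calib.planck_F
        ok = np.isfinite(arg) & (arg > 1.0)
        out = np.where(ok, calib.planck_B / np.log(np.where(ok, arg, 2.0)), np.nan)
    return out


def atmospheric_transmittance(calib: RadiometricCalibration) -> float:
    """Atmospheric transmittance tau over the camera-object path.

    Uses the standard two-exponential model in sqrt(distance) with water-vapour
    content derived from air temperature (degC) and relative humidity:

        omega = RH * exp(1.5587 + 0.06939*T - 0.00027816*T^2 + 0.00000068455*T^3)
        tau   = X*exp(-sqrt(d)*(a1 + b1*sqrt(omega)))
              + (1-X)*exp(-sqrt(d)*(a2 + b2*sqrt(omega)))

    Returns a value clamped to (0, 1]; d = 0 gives exactly 1.
    """
    c = calib.atm_constants
    t_c = calib.atmosphere_temp_C
    omega = calib.relative_humidity * np.exp(
        1.5587 + 0.06939 * t_c - 0.00027816 * t_c**2 + 0.00000068455 * t_c**3
    )
    sqd = np.sqrt(calib.object_distance_m)
    sqw = np.sqrt(omega)
    tau = c.x * np.exp(-sqd * (c.alpha1 + c.beta1 * sqw)) + (1.0 - c.x) * np.exp(
        -sqd * (c.alpha2 + c.beta2 * sqw)
    )
    return float(min(max(tau, np.finfo(float).tiny), 1.0))


def forward_radiance(temp_obj_K, calib: RadiometricCalibration):
    """Total scene signal (counts, real-valued) for an object at ``temp_obj_K``.

    post: eps*tau*S(T_obj) + (1-eps)*tau*S(T_refl) + (1-tau)*S(T_atm);
    strictly increasing in the object temperature.
    """
    t = np.asarray(temp_obj_K, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("object temperature must be finite")
    if np.any(t < T_MIN_K) or np.any(t > T_MAX_K):
        raise ValueError(
            f"object temperature outside supported range [{T_MIN_K}, {T_MAX_K}] K"
        )
    eps = calib.emissivity
    tau = atmospheric_transmittance(calib)
    s_obj = planck_signal(t, calib)
    s_refl = planck_signal(calib.reflected_temp_K, calib)
    s_atm = planck_signal(calib.atmosphere_temp_K, calib)
    return eps * tau * s_obj + (1.0 - eps) * tau * s_refl + (1.0 - tau) * s_atm


def raw_to_temperature(total_signal, calib: RadiometricCalibration, *, frame_id: str = ""):
    """Object surface temperature (degC) from total scene signal (counts).

    Subtracts the reflected and path contributions, rescales by emissivity and
    transmittance, then inverts the Planck signal model.  A signal invalid for
    the calibration (logarithm argument <= 1, i.e. object signal at or below
    the Planck offset) raises a domain error for scalar input; array input
    propagates NaN (see :func:`convert_frame`).
    """
    s_total = np.asarray(total_signal, dtype=float)
    scalar = s_total.ndim == 0
    eps = calib.emissivity
    tau = atmospheric_transmittance(calib)
    s_refl = planck_signal(calib.reflected_temp_K, calib)
    s_atm = planck_signal(calib.atmosphere_temp_K, calib)
    s_obj = (s_total - (1.0 - eps) * tau * s_refl - (1.0 - tau) * s_atm) / (eps * tau)
    temp_K = invert_planck(s_obj, calib)
    if scalar and not np.isfinite(temp_K):
        where = f" in frame {frame_id}" if frame_id else ""
        raise ValueError(
            f"signal {float(s_total):g} invalid for this calibration{where}: "
            "Planck inversion has no real solution"
        )
    temp_C = temp_K - KELVIN_OFFSET
    return float(temp_C) if scalar else temp_C


def convert_frame(frame: ThermalFrame, calib: RadiometricCalibration):
    """Convert a raw frame to a temperature matrix (degC), same shape.

    Pixels whose signal is invalid for the calibration become NaN; their count
    is returned alongside the matrix rather than aborting the conversion.

    Returns
    -------
    (temps, n_invalid) : (ndarray, int)
    """
    temps = raw_to_temperature(frame.counts.astype(float), calib)
    n_invalid = int(np.count_nonzero(~np.isfinite(temps)))
    return temps, n_invalid


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

_CALIB_KEYS = {
    "planck_R1", "planck_R2", "planck_B", "planck_O", "planck_F",
    "emissivity", "reflected_temp_C", "atmosphere_temp_C",
    "relative_humidity", "object_distance_m",
}


def load_calibration(path: str | Path) -> RadiometricCalibration:
    """Read a flat key-value calibration block (YAML/JSON mapping)."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping of calibration keys")
    unknown = set(raw) - _CALIB_KEYS - {"atm_constants"}
    if unknown:
        raise ValueError(f"{path}: unknown calibration keys {sorted(unknown)}")
    atm = raw.pop("atm_constants", None)
    kwargs = {k: float(v) for k, v in raw.items()}
    if atm is not None:
        kwargs["atm_constants"] = AtmosphericConstants(**{k: float(v) for k, v in atm.items()})
    return RadiometricCalibration(**kwargs)


def read_frame(path: str | Path, timestamp: float, frame_id: str, trial_id: str = "") -> ThermalFrame:
    """Load one raw frame from a 16-bit TIFF or a CSV count matrix."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        counts = tifffile.imread(path)
    else:
        counts = np.loadtxt(path, delimiter=",")
    return ThermalFrame(counts=counts, timestamp=timestamp, frame_id=frame_id, trial_id=trial_id)


def write_temperature_matrix(temps: np.ndarray, path: str | Path, *, log: dict | None = None) -> None:
    """Write a temperature matrix as 32-bit float TIFF or CSV, with optional JSON log."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, temps.astype(np.float32))
    else:
        np.savetxt(path, temps, delimiter=",", fmt="%.4f")
    if log is not None:
        path.with_suffix(".json").write_text(json.dumps(log, indent=2))
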