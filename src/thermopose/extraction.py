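"""Region-level temperature extraction and windowing.

From converted temperature matrices, extract per-frame maxima over region
masks (eye region, bill), attach trial metadata and head pose, and average
the series in non-overlapping 10-second windows to reduce temporal
autocorrelation before modelling.

The regional *maximum* is used instead of the mean so that an imperfect
region outline (cool feathered pixels included by mistake) does not bias the
reading: the hottest bare-tissue pixel is robust to perimeter errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RegionMask",
    "max_region_temperature",
    "window_average",
    "assemble_records",
    "DEFAULT_WINDOW_S",
]

DEFAULT_WINDOW_S = 10.0

RECORD_COLUMNS = [
    "individual_id", "treatment", "region", "time_s",
    "temp_max_C", "yaw_deg", "window_averaged",
]


@dataclass
class RegionMask:
    """Boolean pixel mask for one region of interest."""

    region: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.region not in ("eye", "bill"):
            raise ValueError(f"region must be 'eye' or 'bill', got {self.region!r}")
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(f"{self.region} mask is empty")

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


def max_region_temperature(temp_matrix: np.ndarray, mask: RegionMask) -> float:
    """Maximum temperature (degC) over the masked, non-NaN pixels.

    Returns NaN (with a warning) when every masked pixel is invalid.
    """
    temp_matrix = np.asarray(temp_matrix, dtype=float)
    if temp_matrix.shape != mask.mask.shape:
        raise ValueError(
            f"shape mismatch: frame {temp_matrix.shape} vs mask {mask.mask.shape}"
        )
    vals = temp_matrix[mask.mask]
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        warnings.warn(f"{mask.region}: all masked pixels invalid; returning NaN")
        return float("nan")
    return float(finite.max())


def window_average(records: pd.DataFrame, width_s: float = DEFAULT_WINDOW_S) -> pd.DataFrame:
    """Average records in non-overlapping windows aligned at time 0.

    Windows are half-open ``[t, t + width_s)`` anchored at time 0 and
    extended symmetrically to negative times, so a window never straddles
    the treatment onset.  Within each (individual, treatment, region) series
    the window mean temperature, mean yaw over yaw-bearing frames, and the
    window-midpoint time are reported.  Partial windows are averaged over
    the frames available and flagged via ``n_frames``.
    """
    if width_s <= 0:
        raise ValueError("window width must be positive")
    df = records.copy()
    idx = np.floor(df["time_s"].to_numpy(float) / width_s).astype(int)
    df["_win"] = idx
    keys = ["individual_id", "treatment", "region", "_win"]
    grouped = df.groupby(keys, sort=True)
    out = grouped.agg(
        temp_max_C=("temp_max_C", "mean"),
        yaw_deg=("yaw_deg", "mean") if "yaw_deg" in df.columns else ("temp_max_C", "size"),
        n_frames=("temp_max_C", "size"),
    ).reset_index()
    if "yaw_deg" not in records.columns:
        out["yaw_deg"] = np.nan
    out["time_s"] = (out["_win"] + 0.5) * width_s
    out["window_averaged"] = True
    out = out.drop(columns="_win")
    return out[RECORD_COLUMNS + ["n_frames"]]


def assemble_records(temps: pd.DataFrame, poses: pd.DataFrame | None,
                     manifest: pd.DataFrame) -> pd.DataFrame:
    """Join per-frame region temperatures with pose yaw and trial metadata.

    Parameters
    ----------
    temps : DataFrame
        Columns ``frame_id``, ``region``, ``temp_max_C``.
    poses : DataFrame, optional
        Columns ``frame_id``, ``yaw_deg``, ``retained`` (pose output CSV).
        Frames without a retained pose keep the temperature record but carry
        missing yaw, so models without the yaw term use every frame while
        yaw-adjusted models use the pose-bearing subset.
    manifest : DataFrame
        Columns ``frame_id``, ``individual_id``, ``treatment``, ``time_s``.

    Raises
    ------
    ValueError
        Duplicate frame ids within a region, or in the manifest.
    """
    if manifest["frame_id"].duplicated().any():
        raise ValueError("duplicate frame_id in manifest")
    if temps.duplicated(subset=["frame_id", "region"]).any():
        raise ValueError("duplicate (frame_id, region) in temperature table")
    merged = temps.merge(manifest, on="frame_id", how="inner")
    if merged.empty:
        warnings.warn("no overlapping frame ids between temperatures and manifest")
    if poses is not None and not poses.empty:
        if poses["frame_id"].duplicated().any():
            raise ValueError("duplicate frame_id in pose table")
        usable = poses.loc[poses["retained"], ["frame_id", "yaw_deg"]]
        merged = merged.merge(usable, on="frame_id", how="left")
    else:
        merged["yaw_deg"] = np.nan
    merged["window_averaged"] = False
    return merged[RECORD_COLUMNS + ["frame_id"]].sort_values(
        ["individual_id", "treatment", "region", "time_s"]
    ).reset_index(drop=True)
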