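"""Per-cell trace extraction and featurization.

A cell's trace is its relative nuclear localization over time: mean reporter
intensity over the nuclear pixels divided by the mean reporter intensity over
a perinuclear cytoplasmic ring averaged across the pre-stimulus frames
(background subtracted from both).  From each trace the module computes the
standard readouts: an active/inactive call, peak amplitude, time-to-peak,
peak width at half maximum, and a count of secondary activations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .segment import Track

__all__ = [
    "Trace",
    "TraceFeatures",
    "TraceExtractionError",
    "FeatureConfig",
    "extract_trace",
    "classify_active",
    "peak_features",
    "count_secondary_peaks",
    "features_table",
    "traces_table",
]

log = logging.getLogger(__name__)


class TraceExtractionError(ValueError):
    """A cell whose trace cannot be computed (e.g. no pre-stimulus cytoplasm)."""


@dataclass(frozen=True)
class Trace:
    """Normalized nuclear-localization time course of one cell.

    ``time`` is minutes relative to stimulation (t = 0 at the stimulation
    frame); ``valid`` flags frames where the cell was detected.
    """

    track_id: int
    time: np.ndarray
    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        v = np.asarray(self.values, dtype=float)
        ok = np.asarray(self.valid, dtype=bool)
        if not (t.shape == v.shape == ok.shape):
            raise ValueError("time, values and valid must have identical shapes")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "valid", ok)


@dataclass(frozen=True)
class TraceFeatures:
    active: bool
    baseline: float
    peak_amp: float
    time_to_peak: float
    peak_width: float
    width_censored: bool
    n_secondary: int


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable thresholds of the featurization stage.

    ``activity_theta``/``activity_frames``: a cell is active if its trace
    exceeds baseline + theta for at least that many consecutive valid
    post-stimulus frames (automated surrogate for manual activity curation).
    ``half_level_from_baseline`` switches the half-max level from the
    (post-stimulus min + max)/2 convention to (baseline + max)/2.
    """

    activity_theta: float = 0.2
    activity_frames: int = 3
    secondary_rel_height: float = 0.5
    secondary_min_separation: float = 60.0
    half_level_from_baseline: bool = False
    background: float | None = None  # None = estimate from image corners


# ---------------------------------------------------------------------------
# Extraction


def _corner_background(img: np.ndarray, size: int = 8) -> float:
    """Median intensity over the four image corners (background estimate)."""
    h, w = img.shape
    s = min(size, h // 2, w // 2)
    patches = [img[:s, :s], img[:s, -s:], img[-s:, :s], img[-s:, -s:]]
    return float(np.median(np.concatenate([p.ravel() for p in patches])))


def extract_trace(
    reporter: np.ndarray,
    track: Track,
    labels: np.ndarray,
    rings: np.ndarray,
    stim_frame: int,
    dt: float,
    background: float | None = None,
) -> Trace:
    """Measure one cell's normalized nuclear-localization trace.

    Parameters
    ----------
    reporter : (T, H, W) reporter-channel stack.
    track : the cell's track; frames without a detection become invalid.
    labels, rings : (T, H, W) nuclear label stack and matching cytoplasmic
        ring label stack (same label ids).
    stim_frame : index of the stimulation frame (t = 0).
    dt : frame interval in minutes.
    background : constant background level; if None it is estimated per frame
        from the image corners.

    Raises
    ------
    TraceExtractionError
        If no pre-stimulus frame yields a positive cytoplasmic mean.
    """
    n_frames = reporter.shape[0]
    time = (np.arange(n_frames) - stim_frame) * dt
    values = np.full(n_frames, np.nan)
    valid = np.zeros(n_frames, dtype=bool)

    nuc_means = np.full(n_frames, np.nan)
    ring_means = np.full(n_frames, np.nan)
    for frame, label, _, _ in track.rows:
        frame_img = reporter[frame]
        bg = _corner_background(frame_img) if background is None else background
        nuc_mask = labels[frame] == label
        ring_mask = rings[frame] == label
        if not nuc_mask.any():
            continue
        nuc_means[frame] = frame_img[nuc_mask].mean() - bg
        if ring_mask.any():
            ring_means[frame] = frame_img[ring_mask].mean() - bg

    pre = (np.arange(n_frames) < stim_frame) & np.isfinite(ring_means)
    if not pre.any() or np.nanmean(ring_means[pre]) <= 0:
        raise TraceExtractionError(
            f"track {track.track_id}: no valid pre-stimulus cytoplasmic signal"
        )
    cyto_pre = float(np.mean(ring_means[pre]))

    ok = np.isfinite(nuc_means)
    values[ok] = nuc_means[ok] / cyto_pre
    valid = ok & (values > 0)
    values[~valid] = np.nan
    return Trace(track_id=track.track_id, time=time, values=values, valid=valid)


# ---------------------------------------------------------------------------
# Featurization


def _baseline(trace: Trace) -> float:
    pre = (trace.time < 0) & trace.valid
    if not pre.any():
        raise ValueError("trace has no valid pre-stimulus frame")
    return float(trace.values[pre].mean())


def classify_active(
    trace: Trace, theta: float = 0.2, m: int = 3
) -> bool:
    """Activity call: >= m consecutive valid post-stimulus frames above
    baseline + theta (sustained nuclear brightening)."""
    base = _baseline(trace)
    post = trace.time >= 0
    run = 0
    for v, ok in zip(trace.values[post], trace.valid[post]):
        if ok and v >= base + theta:
            run += 1
            if run >= m:
                return True
        else:
            run = 0
    return False


def _cross_time(t0: float, v0: float, t1: float, v1: float, level: float) -> float:
    """Linear-interpolated time at which the segment crosses ``level``."""
    if v1 == v0:
        return t0
    return t0 + (level - v0) * (t1 - t0) / (v1 - v0)


def peak_features(trace: Trace, half_level_from_baseline: bool = False) -> TraceFeatures:
    """Peak amplitude, time-to-peak and width at half maximum of one trace.

    The peak is the maximum over valid post-stimulus frames (first occurrence
    on ties).  The half level is midway between the post-stimulus minimum and
    maximum (or between baseline and maximum when
    ``half_level_from_baseline``); the width is the length of the contiguous
    interval around the peak during which the linearly interpolated trace
    stays above that level.  If the trace never falls below the half level
    after the peak the width is right-censored at the last valid frame and
    flagged.
    """
    base = _baseline(trace)
    sel = (trace.time >= 0) & trace.valid
    if sel.sum() < 2:
        raise ValueError("trace needs >= 2 valid post-stimulus frames")
    t = trace.time[sel]
    v = trace.values[sel]

    i_max = int(np.argmax(v))  # argmax returns the first maximum
    peak_amp = float(v[i_max])
    time_to_peak = float(t[i_max])
    ref_min = base if half_level_from_baseline else float(v.min())
    half = (ref_min + peak_amp) / 2.0

    # walk left from the peak to the first sample below the half level
    left = t[0]
    for i in range(i_max, 0, -1):
        if v[i - 1] < half:
            left = _cross_time(t[i - 1], v[i - 1], t[i], v[i], half)
            break

    right = t[-1]
    censored = True
    for i in range(i_max, len(v) - 1):
        if v[i + 1] < half:
            right = _cross_time(t[i], v[i], t[i + 1], v[i + 1], half)
            censored = False
            break

    return TraceFeatures(
        active=True,
        baseline=base,
        peak_amp=peak_amp,
        time_to_peak=time_to_peak,
        peak_width=float(right - left),
        width_censored=censored,
        n_secondary=0,
    )


def count_secondary_peaks(
    trace: Trace,
    rel_height: float = 0.5,
    min_separation: float = 60.0,
    half_level_from_baseline: bool = False,
) -> int:
    """Count secondary activations: local maxima outside the primary peak's
    half-max interval, with prominence >= rel_height * (peak_amp - baseline)
    and at least ``min_separation`` minutes from the primary peak."""
    feats = peak_features(trace, half_level_from_baseline=half_level_from_baseline)
    sel = (trace.time >= 0) & trace.valid
    t = trace.time[sel]
    v = trace.values[sel]
    prominence = rel_height * (feats.peak_amp - feats.baseline)
    if prominence <= 0:
        return 0
    idx, _ = find_peaks(v, prominence=prominence)
    half_lo = feats.time_to_peak - feats.peak_width  # conservative primary window
    half_hi = feats.time_to_peak + feats.peak_width
    count = 0
    for i in idx:
        ti = t[i]
        if abs(ti - feats.time_to_peak) < min_separation:
            continue
        if half_lo <= ti <= half_hi:
            continue
        count += 1
    return count


# ---------------------------------------------------------------------------
# Tabular interfaces


def features_table(traces: list[Trace], cfg: FeatureConfig = FeatureConfig()) -> pd.DataFrame:
    """One row of features per cell; inactive cells get NaN peak features."""
    rows = []
    for trace in traces:
        try:
            active = classify_active(trace, cfg.activity_theta, cfg.activity_frames)
            if active:
                f = peak_features(trace, cfg.half_level_from_baseline)
                f = replace(
                    f,
                    n_secondary=count_secondary_peaks(
                        trace,
                        cfg.secondary_rel_height,
                        cfg.secondary_min_separation,
                        cfg.half_level_from_baseline,
                    ),
                )
            else:
                f = TraceFeatures(
                    active=False,
                    baseline=_baseline(trace),
                    peak_amp=np.nan,
                    time_to_peak=np.nan,
                    peak_width=np.nan,
                    width_censored=False,
                    n_secondary=0,
                )
        except ValueError as exc:
            log.warning("excluding track %s: %s", trace.track_id, exc)
            continue
        rows.append(
            {
                "track_id": trace.track_id,
                "active": f.active,
                "baseline": f.baseline,
                "peak_amp": f.peak_amp,
                "time_to_peak": f.time_to_peak,
                "peak_width": f.peak_width,
                "width_censored": f.width_censored,
                "n_secondary": f.n_secondary,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "track_id",
            "active",
            "baseline",
            "peak_amp",
            "time_to_peak",
            "peak_width",
            "width_censored",
            "n_secondary",
        ],
    )


def traces_table(traces: list[Trace]) -> pd.DataFrame:
    """Long-format table: one row per cell x frame."""
    frames = []
    for trace in traces:
        frames.append(
            pd.DataFrame(
                {
                    "track_id": trace.track_id,
                    "time_min": trace.time,
                    "intensity": trace.values,
                    "valid": trace.valid,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["track_id", "time_min", "intensity", "valid"])
    return pd.concat(frames, ignore_index=True)
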