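"""Trajectory preprocessing, responder calling, and dynamic-feature extraction.

Every downstream analysis (mutual information, classification, correlation,
dose-response) consumes the per-cell feature table produced here.  The core
catalog covers the named trajectory descriptors — activation/deactivation
speed, amplitude, oscillatory content, duration, early-vs-late balance and
total activity — plus sixteen half-hour activity integrals spanning 0–8 h.
Time features are in minutes from stimulus onset (t = 0); amplitude features
inherit the trajectory's units.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .trajectories import ActivityTrajectory

logger = logging.getLogger(__name__)

CORE_FEATURES = (
    "time_to_half_max_activity",
    "time_to_max",
    "max_amplitude",
    "max_derivative",
    "min_derivative",
    "first_peak_width_at_half_prominence",
    "total_duration",
    "total_activity",
    "time_to_half_total_activity",
    "dominant_frequency",
    "n_peaks",
    "early_late_ratio",
)

N_INTERVALS = 16            # half-hour integrals over 0-8 h
INTERVAL_MIN = 30.0

#: absolute fallback when the baseline window has zero variance (A.U.)
BASELINE_SD_FLOOR = 1e-3


def interval_feature_names(n_intervals: int = N_INTERVALS) -> list[str]:
    return [f"integral_{i * 0.5:g}_{(i + 1) * 0.5:g}h" for i in range(n_intervals)]


def catalog_names(n_intervals: int = N_INTERVALS) -> list[str]:
    return list(CORE_FEATURES) + interval_feature_names(n_intervals)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def _smooth(y: np.ndarray, window: int = 5) -> np.ndarray:
    if window <= 1 or y.size < window:
        return y
    kernel = np.ones(window) / window
    pad = window // 2
    ypad = np.pad(y, pad, mode="edge")
    return np.convolve(ypad, kernel, mode="valid")[: y.size]


def preprocess(trajs: list[ActivityTrajectory],
               mock_trajs: list[ActivityTrajectory] | None = None,
               min_mocks: int = 8,
               smooth_window: int = 5) -> list[ActivityTrajectory]:
    """Per-cell baseline deduction plus mock-derived drift correction.

    Each channel has the mean of its baseline (negative-time) frames
    subtracted.  If at least ``min_mocks`` mock trajectories are supplied, a
    drift curve (their framewise mean, smoothed) is subtracted from every
    trajectory; with fewer mocks the drift step is skipped with a warning.
    """
    out = []
    drift = None
    if mock_trajs:
        if len(mock_trajs) >= min_mocks:
            drift = {}
            for ch in ("p38", "nfkb"):
                stack = np.stack([_baseline_deduct(m).channel(ch) for m in mock_trajs])
                drift[ch] = _smooth(stack.mean(axis=0), smooth_window)
        else:
            warnings.warn(
                f"only {len(mock_trajs)} mock trajectories (< {min_mocks}); "
                "drift correction skipped", stacklevel=2)
    for traj in trajs:
        t = _baseline_deduct(traj)
        if drift is not None:
            t = t.with_channels(t.p38 - drift["p38"], t.nfkb - drift["nfkb"])
        out.append(t)
    return out


def _baseline_deduct(traj: ActivityTrajectory) -> ActivityTrajectory:
    base = traj.baseline_mask
    if not base.any():
        raise ValueError(f"cell {traj.cell_id}: no baseline frames (negative times)")
    return traj.with_channels(traj.p38 - np.nanmean(traj.p38[base]),
                              traj.nfkb - np.nanmean(traj.nfkb[base]))


# ---------------------------------------------------------------------------
# quality filtering
# ---------------------------------------------------------------------------

DEFAULT_QUALITY_RULES = {
    "full_duration": True,     # no missing frames over the whole course
    "max_abs_activity": 50.0,  # extreme-activity cap, either channel
    "min_baseline_frames": 3,
}


@dataclass
class QualityReport:
    n_input: int
    removed_by_rule: dict
    retained: int

    @property
    def retained_fraction(self) -> float:
        return self.retained / self.n_input if self.n_input else 0.0


def quality_filter(trajs: list[ActivityTrajectory],
                   rules: dict | None = None) -> tuple[list[ActivityTrajectory], QualityReport]:
    """Drop cells violating any configured rule; report per-rule counts.

    A cell removed by an earlier rule is not re-counted under later ones.
    """
    rules = {**DEFAULT_QUALITY_RULES, **(rules or {})}
    removed = {name: 0 for name in ("full_duration", "max_abs_activity",
                                    "min_baseline_frames")}
    kept = []
    for traj in trajs:
        if rules.get("full_duration", True) and (
                np.isnan(traj.p38).any() or np.isnan(traj.nfkb).any()):
            removed["full_duration"] += 1
            continue
        cap = rules.get("max_abs_activity")
        if cap is not None and (np.nanmax(np.abs(traj.p38)) > cap
                                or np.nanmax(np.abs(traj.nfkb)) > cap):
            removed["max_abs_activity"] += 1
            continue
        if int(traj.baseline_mask.sum()) < rules.get("min_baseline_frames", 3):
            removed["min_baseline_frames"] += 1
            continue
        kept.append(traj)
    if trajs and not kept:
        raise ValueError("quality filter removed every cell; review rule thresholds")
    return kept, QualityReport(len(trajs), removed, len(kept))


# ---------------------------------------------------------------------------
# responder calling
# ---------------------------------------------------------------------------

def responder_threshold(traj: ActivityTrajectory, pathway: str, k_sd: float = 3.0) -> float:
    base = traj.channel(pathway)[traj.baseline_mask]
    if base.size < 3:
        raise ValueError(f"cell {traj.cell_id}: need >= 3 baseline frames")
    sd = float(np.nanstd(base, ddof=1))
    if sd == 0.0:
        # routine for noise-free simulated baselines, hence debug level
        logger.debug("cell %s: zero baseline SD; using floor %.0e",
                     traj.cell_id, BASELINE_SD_FLOOR)
        sd = BASELINE_SD_FLOOR
    return k_sd * sd


def call_responder(traj: ActivityTrajectory, pathway: str = "p38", k_sd: float = 3.0,
                   n_consecutive: int = 3, window_min: float = 60.0) -> bool:
    """True iff activity exceeds ``k_sd`` x baseline SD for ``n_consecutive``
    consecutive frames within ``window_min`` of stimulation."""
    thr = responder_threshold(traj, pathway, k_sd)
    sel = (traj.time_min >= 0) & (traj.time_min <= window_min)
    above = traj.channel(pathway)[sel] > thr
    run = 0
    for a in above:
        run = run + 1 if a else 0
        if run >= n_consecutive:
            return True
    return False


def responder_fraction(trajs: list[ActivityTrajectory], pathway: str = "p38",
                       **kwargs) -> float:
    if not trajs:
        raise ValueError("empty trajectory set")
    return float(np.mean([call_responder(t, pathway, **kwargs) for t in trajs]))


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

def _first_crossing_time(t: np.ndarray, y: np.ndarray, level: float) -> float:
    """First linearly interpolated upward crossing of ``level``."""
    above = y >= level
    if not above.any():
        return np.nan
    i = int(np.argmax(above))
    if i == 0:
        return float(t[0])
    t0, t1, y0, y1 = t[i - 1], t[i], y[i - 1], y[i]
    if y1 == y0:
        return float(t1)
    return float(t0 + (level - y0) * (t1 - t0) / (y1 - y0))


def _series_features(t: np.ndarray, y: np.ndarray, threshold: float,
                     frame: float, n_intervals: int) -> dict:
    out: dict[str, float] = {}
    ymax = float(np.max(y))
    imax = int(np.argmax(y))
    out["max_amplitude"] = ymax
    out["time_to_max"] = float(t[imax])
    out["time_to_half_max_activity"] = _first_crossing_time(t, y, ymax / 2.0)

    dy = np.gradient(y, t)  # central differences, one-sided at the ends
    out["max_derivative"] = float(dy.max())
    out["min_derivative"] = float(dy.min())

    above = y > threshold
    out["total_duration"] = float(above.sum() * frame)

    total = float(np.trapezoid(y, t))
    out["total_activity"] = float(sum(
        _interval_integral(t, y, i * INTERVAL_MIN, (i + 1) * INTERVAL_MIN)
        for i in range(n_intervals)))
    cum = np.concatenate([[0.0], np.cumsum(np.diff(t) * (y[1:] + y[:-1]) / 2.0)])
    out["time_to_half_total_activity"] = (
        _first_crossing_time(t, cum, total / 2.0) if total > 0 else np.nan)

    # first-peak width at half prominence
    peaks, props = find_peaks(y, height=threshold, distance=2,
                              prominence=0, width=0, rel_height=0.5)
    out["n_peaks"] = float(len(peaks))
    if len(peaks):
        out["first_peak_width_at_half_prominence"] = float(props["widths"][0] * frame)
    else:
        out["first_peak_width_at_half_prominence"] = np.nan

    # dominant frequency of the detrended 0-4 h segment, zero bin excluded
    seg = (t >= 0) & (t <= 240.0)
    ys = y[seg]
    if ys.size >= 8:
        ys = ys - np.polyval(np.polyfit(t[seg], ys, 1), t[seg])
        power = np.abs(np.fft.rfft(ys)) ** 2
        freqs = np.fft.rfftfreq(ys.size, d=frame)
        out["dominant_frequency"] = float(freqs[1:][np.argmax(power[1:])])
    else:
        out["dominant_frequency"] = np.nan

    early = _interval_integral(t, y, 0.0, 120.0)
    late = _interval_integral(t, y, 120.0, 480.0)
    out["early_late_ratio"] = float(early / late) if late != 0 else np.nan

    for i, name in enumerate(interval_feature_names(n_intervals)):
        out[name] = _interval_integral(t, y, i * INTERVAL_MIN, (i + 1) * INTERVAL_MIN)
    return out


def _interval_integral(t: np.ndarray, y: np.ndarray, t0: float, t1: float) -> float:
    """Trapezoidal integral of the linearly interpolated series on [t0, t1].

    Returns NaN when the grid does not span the interval."""
    if t0 < t[0] or t1 > t[-1]:
        return np.nan
    tt = np.unique(np.concatenate([[t0, t1], t[(t > t0) & (t < t1)]]))
    yy = np.interp(tt, t, y)
    return float(np.trapezoid(yy, tt))


def extract_features(trajs: list[ActivityTrajectory],
                     pathways: tuple = ("p38", "nfkb"),
                     n_intervals: int = N_INTERVALS,
                     k_sd: float = 3.0) -> pd.DataFrame:
    """Per-cell feature table: metadata columns + pathway-prefixed features.

    The responder threshold (``k_sd`` x baseline SD per cell and channel) is
    used for the duration/peak-count features.  Features whose span exceeds
    the grid are recorded as NaN, never raised.
    """
    rows = []
    for traj in trajs:
        post = traj.post_mask
        t = traj.time_min[post]
        row = {"cell_id": traj.cell_id, "condition": traj.stimulus,
               "dose": traj.dose, "replicate": traj.replicate}
        for ch in pathways:
            thr = responder_threshold(traj, ch, k_sd)
            feats = _series_features(t, traj.channel(ch)[post], thr,
                                     traj.frame_min, n_intervals)
            row.update({f"{ch}_{k}": v for k, v in feats.items()})
        rows.append(row)
    return pd.DataFrame(rows)


METADATA_COLUMNS = ("cell_id", "condition", "dose", "replicate")


def feature_columns(table: pd.DataFrame, pathway: str | None = None) -> list[str]:
    cols = [c for c in table.columns if c not in METADATA_COLUMNS]
    if pathway is not None:
        cols = [c for c in cols if c.startswith(pathway + "_")]
    return cols
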