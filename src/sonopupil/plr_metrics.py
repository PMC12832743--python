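"""Pupillary-light-reflex metrics from a diameter-time trace.

Six scalar metrics summarise one acquisition:

- INIT: mean pre-stimulus diameter (mm),
- END: minimum diameter after constriction onset (mm),
- DELTA: constriction ratio (INIT - END) / INIT,
- LAT: latency from light onset to constriction onset (s),
- ACV: average constriction velocity, (INIT - END) over the onset-to-minimum
  interval (mm/s),
- ADV: average dilation velocity, measured as a secant from the minimum to a
  configurable fraction of amplitude recovery (mm/s).

Commercial pupillometers do not publish their exact onset or velocity
windows, so the operational definitions here are explicit and configurable
(:class:`MetricsConfig`): the trace is median-smoothed, constriction onset is
the first post-stimulus crossing of ``INIT - max(k * baseline SD, min_drop)``
that keeps falling for a few frames, optionally refined by back-extrapolating
the early descent to the baseline level to remove frame-quantisation bias.
Undefined quantities (e.g. latency of a flat trace) are reported as NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.isotonic import isotonic_regression

__all__ = [
    "PLRMetrics",
    "MetricsConfig",
    "SessionResult",
    "compute_metrics",
    "average_session",
    "quality_control",
    "metrics_to_frame",
    "write_metrics_csv",
]

METRIC_NAMES = ("init", "end", "delta", "lat", "acv", "adv")


@dataclass(frozen=True)
class PLRMetrics:
    """The six PLR metrics for one acquisition (NaN marks undefined)."""

    init: float  # mm
    end: float   # mm
    delta: float  # fraction
    lat: float   # s
    acv: float   # mm/s
    adv: float   # mm/s

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def scaled(self, c: float) -> "PLRMetrics":
        """Multiply the linear (mm / mm/s) fields by ``c``; delta and lat are
        scale-free and unchanged."""
        return PLRMetrics(
            init=self.init * c, end=self.end * c, delta=self.delta,
            lat=self.lat, acv=self.acv * c, adv=self.adv * c,
        )


@dataclass(frozen=True)
class MetricsConfig:
    """Operational parameters for metric extraction.

    ``baseline_window`` (s) is the pre-stimulus span averaged for INIT.
    Constriction onset requires the smoothed trace to drop below
    ``INIT - max(onset_k_sigma * baseline SD, onset_min_drop)`` and keep
    falling for ``onset_persistence`` frames.  ``refine_onset`` then
    back-extrapolates a line fitted to the early descent up to the baseline
    level, which removes the systematic one-to-two frame delay of the raw
    threshold crossing.  ``recovery_fraction_for_adv`` sets the amplitude
    recovery point ending the ADV window.  With ``velocity_fit`` enabled the
    velocities are the slopes of lines fitted over the central constriction
    and recovery segments — identical to the endpoint secants for a linear
    reflex but insensitive to pixel quantisation; the secants are the
    fallback when too few fit points exist.
    """

    baseline_window: float = 0.8       # s
    smoothing_window: int = 5          # frames, odd
    onset_k_sigma: float = 3.0
    onset_min_drop: float = 0.05       # mm
    onset_persistence: int = 3         # frames
    recovery_fraction_for_adv: float = 0.5
    refine_onset: bool = True
    velocity_fit: bool = True

    def __post_init__(self) -> None:
        if self.baseline_window <= 0:
            raise ValueError("baseline_window must be positive")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd and >= 1")
        if self.onset_persistence < 1:
            raise ValueError("onset_persistence must be >= 1")
        if not 0 < self.recovery_fraction_for_adv <= 1:
            raise ValueError("recovery_fraction_for_adv must lie in (0, 1]")


@dataclass
class SessionResult:
    """Triplicate (or k-fold) acquisitions for one eye plus their average."""

    eye_id: str
    modality: str                      # "auto_upa" or "ipa"
    per_acquisition: list[PLRMetrics]
    averaged: PLRMetrics
    qc_pass: bool = True
    qc_reasons: list[str] | None = None


def _phase_line(
    tt: np.ndarray, yy: np.ndarray, lo: float, hi: float, increasing: bool
) -> tuple[float, float] | None:
    """Fit diameter vs time over one monotone reflex phase; return (slope,
    intercept) or None.

    Chord diameters are quantised to whole pixels, so a phase appears as a
    noisy staircase.  The samples are first made monotone by isotonic
    regression (pool-adjacent-violators), which removes noise flickers; each
    pooled block is then collapsed to its (mean time, level) point — an
    unbiased sample of the underlying line when the true phase is linear.
    The first and last blocks (adjacent plateaus: baseline, minimum or the
    converged tail) are dropped, remaining blocks are windowed to diameters
    in [lo, hi], and a line is fitted when at least two blocks survive.
    """
    y = isotonic_regression(np.asarray(yy, dtype=float), increasing=increasing)
    # contiguous equal-value runs = isotonic blocks (tolerance absorbs float
    # jitter in pixel-quantised diameters)
    edges = np.flatnonzero(np.abs(np.diff(y)) > 1e-9)
    starts = np.r_[0, edges + 1]
    stops = np.r_[edges, y.size - 1]
    t_mid = np.array([(tt[a] + tt[b]) / 2.0 for a, b in zip(starts, stops)])
    vals = y[starts]
    if vals.size < 4:  # need interior blocks besides the two endpoint plateaus
        return None
    t_mid, vals = t_mid[1:-1], vals[1:-1]
    keep = (vals >= lo) & (vals <= hi)
    if keep.sum() < 2:
        return None
    slope, intercept = np.polyfit(t_mid[keep], vals[keep], 1)
    return float(slope), float(intercept)


def _smooth(diams: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or diams.size == 0:
        return diams.copy()
    w = min(window, diams.size if diams.size % 2 else diams.size - 1)
    if w < 1:
        return diams.copy()
    return ndimage.median_filter(diams, size=w, mode="nearest")


def compute_metrics(trace, config: MetricsConfig = MetricsConfig()) -> PLRMetrics:
    """Extract the six PLR metrics from a :class:`~sonopupil.segmentation.DiameterTrace`.

    Raises ``ValueError`` when fewer than 3 valid baseline frames or no valid
    post-stimulus frame exist (a QC-level failure rather than a metric).
    """
    valid = np.asarray(trace.valid_flags, dtype=bool)
    times = np.asarray(trace.times, dtype=float)[valid]
    diams = np.asarray(trace.diameters, dtype=float)[valid]
    onset_t = float(trace.stimulus_onset)

    base_sel = (times >= onset_t - config.baseline_window) & (times < onset_t)
    if base_sel.sum() < 3:
        raise ValueError("fewer than 3 valid baseline frames before the stimulus")
    if not np.any(times >= onset_t):
        raise ValueError("no valid post-stimulus frames")

    s = _smooth(diams, config.smoothing_window)
    init = float(np.mean(s[base_sel]))
    base_sd = float(np.std(s[base_sel], ddof=1))

    drop = max(config.onset_k_sigma * base_sd, config.onset_min_drop)
    thresh = init - drop
    post = np.flatnonzero(times >= onset_t)

    cross = None
    for i in post:
        if s[i] >= thresh:
            continue
        j_hi = min(i + config.onset_persistence, s.size - 1)
        window = s[i + 1 : j_hi + 1]
        if window.size == 0 or (np.all(window <= s[i]) and window.min() < s[i]):
            cross = int(i)
            break

    if cross is None:
        # Null response: no measurable constriction onset.
        tail = s[post]
        k_min = int(post[np.argmin(tail)])
        end = float(s[k_min])
        return PLRMetrics(
            init=init, end=end, delta=(init - end) / init,
            lat=math.nan, acv=math.nan, adv=math.nan,
        )

    # END: earliest minimum of the smoothed trace at/after the crossing.
    after = np.flatnonzero(times >= times[cross])
    k_min = int(after[np.argmin(s[after])])
    end = float(s[k_min])
    t_min = float(times[k_min])
    amp = init - end

    # Walk back from the crossing along the monotone descent.
    j = cross
    first_post = int(post[0])
    while j > first_post and s[j - 1] > s[j]:
        j -= 1
    t_on = float(times[j])

    if config.refine_onset and amp > 0:
        # Back-extrapolate the early descent to the baseline level.
        lo, hi = init - 0.6 * amp, init - 0.05 * amp
        seg = [k for k in range(j, k_min + 1) if lo <= s[k] <= hi]
        if len(seg) >= 2:
            tt, dd = times[seg], s[seg]
            slope, intercept = np.polyfit(tt, dd, 1)
            if slope < 0:
                t_fit = (init - intercept) / slope
                t_on = float(np.clip(t_fit, onset_t, times[cross]))

    lat = t_on - onset_t

    # Phase-line fits (velocity + END refinement).  The windows are relative
    # to the preliminary amplitude; the descent line covers the central
    # constriction, the recovery line the rise up to the ADV endpoint.
    des_line = rec_line = None
    if config.velocity_fit and amp > 0:
        des_line = _phase_line(
            times[j : k_min + 1], s[j : k_min + 1],
            lo=end + 0.15 * amp, hi=end + 0.85 * amp, increasing=False,
        )
        rec_hi = end + min(config.recovery_fraction_for_adv + 0.05, 1.0) * amp
        # when the trace flattens within the recording, keep the window top
        # clear of the plateau level, else its noise blocks flatten the fit
        conv = float(np.median(s[times >= times[-1] - 0.5]))
        if conv > end:
            rec_hi = min(rec_hi, conv - 0.25 * (conv - end))
        # truncate before the converged tail: stop at the first sample
        # reaching the window top (or the first attainment of the post-min
        # maximum); the truncated block is dropped inside _phase_line anyway
        tail = s[k_min:]
        over = np.flatnonzero(tail >= rec_hi)
        k_stop = k_min + (int(over[0]) if over.size else int(np.argmax(tail == tail.max())))
        rec_line = _phase_line(
            times[k_min : k_stop + 1], s[k_min : k_stop + 1],
            lo=end + 0.10 * amp, hi=rec_hi, increasing=True,
        )
        if des_line and rec_line and des_line[0] < 0 and rec_line[0] > 0:
            # END refined to the descent/recovery line intersection, which
            # undoes the smoothing overshoot at a sharp V-minimum.  The
            # smoothed minimum can only overestimate END, so the refinement
            # is accepted only just below it.
            (m1, c1), (m2, c2) = des_line, rec_line
            t_x = (c2 - c1) / (m1 - m2)
            end_x = m1 * t_x + c1
            if end - 0.2 <= end_x <= end and t_on < t_x <= t_min + 0.2:
                end = float(end_x)
                amp = init - end

    acv = amp / (t_min - t_on) if t_min > t_on else math.nan
    if des_line is not None and des_line[0] < 0:
        acv = -des_line[0]

    # ADV: minimum -> first time the trace regains the configured fraction of
    # the amplitude (or the last valid frame if never reached).
    target = end + config.recovery_fraction_for_adv * amp
    rec = np.flatnonzero((times > t_min) & (s >= target))
    k_rec = int(rec[0]) if rec.size else s.size - 1
    t_rec = float(times[k_rec])
    adv = (float(s[k_rec]) - end) / (t_rec - t_min) if t_rec > t_min else math.nan
    if rec_line is not None and rec_line[0] > 0:
        adv = rec_line[0]

    return PLRMetrics(init=init, end=end, delta=amp / init, lat=lat, acv=acv, adv=adv)


def average_session(per_acquisition: Sequence[PLRMetrics]) -> PLRMetrics:
    """Field-wise arithmetic mean over acquisitions.

    A field is averaged over the acquisitions where it is defined and is NaN
    in the result only if undefined in all of them.
    """
    if len(per_acquisition) == 0:
        raise ValueError("average_session needs at least one acquisition")
    out = {}
    for name in METRIC_NAMES:
        vals = np.array([getattr(m, name) for m in per_acquisition], dtype=float)
        defined = vals[np.isfinite(vals)]
        out[name] = float(defined.mean()) if defined.size else math.nan
    return PLRMetrics(**out)


def quality_control(trace, config: MetricsConfig = MetricsConfig()) -> tuple[bool, list[str]]:
    """Signal-adequacy checks mirroring on-device acquisition prompts.

    Fails (with named reasons) when the recording is shorter than one second
    past the stimulus (``too_short``), fewer than 80% of frames segmented
    (``valid_fraction``), fewer than 3 valid baseline frames
    (``insufficient_baseline``), or the baseline diameter has a coefficient
    of variation above 5% (``baseline_cv``).
    """
    reasons: list[str] = []
    times = np.asarray(trace.times, dtype=float)
    valid = np.asarray(trace.valid_flags, dtype=bool)
    diams = np.asarray(trace.diameters, dtype=float)

    if times.size == 0 or times[-1] < trace.stimulus_onset + 1.0:
        reasons.append("too_short")
    if times.size and valid.mean() < 0.8:
        reasons.append("valid_fraction")
    if times.size:
        base = valid & (times >= trace.stimulus_onset - config.baseline_window) & (
            times < trace.stimulus_onset
        )
        if base.sum() < 3:
            reasons.append("insufficient_baseline")
        else:
            b = diams[base]
            if b.mean() > 0 and b.std(ddof=1) / b.mean() > 0.05:
                reasons.append("baseline_cv")
    return (len(reasons) == 0, reasons)


# ---------------------------------------------------------------------------
# tabular export

def metrics_to_frame(sessions: Iterable[SessionResult]) -> pd.DataFrame:
    """Long-format table: one row per acquisition plus one averaged row."""
    rows = []
    for ses in sessions:
        for k, m in enumerate(ses.per_acquisition):
            rows.append(
                {"eye_id": ses.eye_id, "modality": ses.modality,
                 "acquisition": k + 1, "qc_pass": ses.qc_pass,
                 **{f"{n}{u}": m.as_dict()[n] for n, u in _COL_UNITS}}
            )
        rows.append(
            {"eye_id": ses.eye_id, "modality": ses.modality,
             "acquisition": "mean", "qc_pass": ses.qc_pass,
             **{f"{n}{u}": ses.averaged.as_dict()[n] for n, u in _COL_UNITS}}
        )
    return pd.DataFrame(rows)


_COL_UNITS = [
    ("init", "_mm"), ("end", "_mm"), ("delta", ""),
    ("lat", "_s"), ("acv", "_mm_s"), ("adv", "_mm_s"),
]


def write_metrics_csv(sessions: Iterable[SessionResult], path: str | Path) -> Path:
    path = Path(path)
    metrics_to_frame(sessions).to_csv(path, index=False, float_format="%.10g")
    return path
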