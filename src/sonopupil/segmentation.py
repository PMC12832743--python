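"""Per-frame pupil segmentation and diameter-trace extraction.

The pipeline mirrors how automated B-mode pupillometry localises the pupil in
a tangential transpalpebral view: intensity thresholding inside the bright
iris echo band, morphological opening/closing to clean speckle, connected
component selection with frame-to-frame centroid tracking, and the pupil
diameter measured as the maximal horizontal chord through the component
centroid.

The iris-band region of interest is found automatically from the row-mean
intensity profile: among the contiguous bright row bands, the one containing
the most sub-threshold (anechoic) pixels is taken to hold the pupil gap.
This keeps the dark acoustic background outside the band from competing with
the pupil.  On frames without band structure (e.g. uniform test images) the
whole frame is the ROI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "SegmentationConfig",
    "PupilMask",
    "DiameterTrace",
    "segment_frame",
    "chord_diameter",
    "extract_trace",
    "write_trace_csv",
    "read_trace_csv",
]


@dataclass(frozen=True)
class SegmentationConfig:
    threshold_method: str = "otsu"     # "otsu" | "fixed"
    fixed_threshold: float = 0.3       # grayscale, used when method == "fixed"
    opening_radius_px: int = 1
    closing_radius_px: int = 2
    min_component_area_px: int = 30
    boundary_smoothing_window: int = 1  # odd; 1 disables
    tracking_search_radius_px: int = 20
    band_fraction: float = 0.5         # row-mean fraction defining bright bands
    min_contrast: float = 0.1          # below this ROI range -> no pupil

    def __post_init__(self) -> None:
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if self.opening_radius_px < 0 or self.closing_radius_px < 0:
            raise ValueError("morphology radii must be >= 0")
        if self.min_component_area_px < 1:
            raise ValueError("min_component_area_px must be >= 1")
        if self.boundary_smoothing_window < 1 or self.boundary_smoothing_window % 2 == 0:
            raise ValueError("boundary_smoothing_window must be odd and >= 1")


@dataclass
class PupilMask:
    mask: np.ndarray             # H x W bool
    centroid_row_px: float
    centroid_col_px: float
    area_px: int
    valid: bool

    @classmethod
    def invalid(cls, shape: tuple[int, int]) -> "PupilMask":
        return cls(np.zeros(shape, dtype=bool), math.nan, math.nan, 0, False)


@dataclass
class DiameterTrace:
    """Per-frame pupil diameter (mm) vs time (s) with validity flags."""

    times: np.ndarray
    diameters: np.ndarray
    valid_flags: np.ndarray
    stimulus_onset: float
    loop_id: str = "loop"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.diameters = np.asarray(self.diameters, dtype=float)
        self.valid_flags = np.asarray(self.valid_flags, dtype=bool)
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


def _disk(radius: int) -> np.ndarray:
    if radius <= 0:
        return np.ones((1, 1), dtype=bool)
    r = np.arange(-radius, radius + 1)
    return (r[:, None] ** 2 + r[None, :] ** 2) <= radius**2


def _find_band(frame: np.ndarray, config: SegmentationConfig) -> tuple[int, int] | None:
    """Row range [r0, r1) of the bright band most likely holding the pupil gap.

    Row brightness is scored by the 90th percentile across columns, so a wide
    anechoic gap cannot drag its own band below the cutoff.  Candidate bands
    are contiguous runs of rows scoring above ``band_fraction`` of the
    maximum; among them the band with the most dark pixels (below its own
    Otsu split) wins.  Returns None when the frame has no usable contrast.
    """
    profile = np.percentile(frame, 90, axis=1)
    m = profile.max()
    if m <= 0 or (frame.max() - frame.min()) < config.min_contrast:
        return None
    bright = profile >= config.band_fraction * m
    labels, n = ndimage.label(bright)
    best, best_dark = None, -1
    for lab in range(1, n + 1):
        rows = np.flatnonzero(labels == lab)
        if rows.size < 3:
            continue
        band = frame[rows[0] : rows[-1] + 1]
        if band.max() - band.min() < config.min_contrast:
            dark = 0
        else:
            dark = int((band < threshold_otsu(band)).sum())
        if dark > best_dark:
            best, best_dark = (int(rows[0]), int(rows[-1] + 1)), dark
    return best


def segment_frame(
    frame: np.ndarray,
    config: SegmentationConfig = SegmentationConfig(),
    prior_centroid: tuple[float, float] | None = None,
) -> PupilMask:
    """Segment the pupil (dark region) in one grayscale frame.

    Thresholds dark pixels inside the detected iris band, cleans the binary
    mask with opening then closing, discards small components, and selects
    the component nearest ``prior_centroid`` (largest if no prior).  Ties on
    distance break by larger area, then smaller row index.  Degenerate frames
    yield ``valid=False`` rather than raising.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or frame.size == 0:
        return PupilMask.invalid(frame.shape if frame.ndim == 2 else (0, 0))

    band = _find_band(frame, config)
    if band is None:
        return PupilMask.invalid(frame.shape)
    r0, r1 = band
    roi = frame[r0:r1]

    if config.threshold_method == "fixed":
        thr = config.fixed_threshold
    else:
        if roi.max() - roi.min() < config.min_contrast:
            return PupilMask.invalid(frame.shape)
        thr = threshold_otsu(roi)

    dark = np.zeros(frame.shape, dtype=bool)
    dark[r0:r1] = roi < thr
    if not dark.any():
        return PupilMask.invalid(frame.shape)

    if config.opening_radius_px > 0:
        dark = ndimage.binary_opening(dark, structure=_disk(config.opening_radius_px))
    if config.closing_radius_px > 0:
        dark = ndimage.binary_closing(dark, structure=_disk(config.closing_radius_px))
    if not dark.any():
        return PupilMask.invalid(frame.shape)

    labels, n = ndimage.label(dark)
    if n == 0:
        return PupilMask.invalid(frame.shape)
    idx = np.arange(1, n + 1)
    areas = ndimage.sum_labels(np.ones_like(labels), labels, idx)
    keep = idx[areas >= config.min_component_area_px]
    if keep.size == 0:
        return PupilMask.invalid(frame.shape)
    centroids = ndimage.center_of_mass(dark, labels, keep)
    areas = areas[keep - 1]

    if prior_centroid is not None:
        pr, pc = prior_centroid
        dists = np.array([math.hypot(cr - pr, cc - pc) for cr, cc in centroids])
        within = dists <= config.tracking_search_radius_px
        pool = np.flatnonzero(within) if within.any() else np.arange(keep.size)
        if within.any():
            # nearest; ties -> larger area -> smaller centroid row
            order = sorted(
                pool, key=lambda k: (dists[k], -areas[k], centroids[k][0])
            )
        else:  # tracking lost: re-acquire on the largest component
            order = sorted(pool, key=lambda k: (-areas[k], centroids[k][0]))
        sel = order[0]
    else:
        sel = int(np.lexsort((np.array([c[0] for c in centroids]), -areas))[0])

    mask = labels == keep[sel]
    if config.boundary_smoothing_window > 1:
        w = config.boundary_smoothing_window
        mask = ndimage.median_filter(mask, size=(w, w))
        if not mask.any():
            return PupilMask.invalid(frame.shape)
        cr, cc = ndimage.center_of_mass(mask)
        return PupilMask(mask, float(cr), float(cc), int(mask.sum()), True)
    cr, cc = centroids[sel]
    return PupilMask(mask, float(cr), float(cc), int(areas[sel]), True)


def chord_diameter(mask: PupilMask, pixel_spacing: float) -> float:
    """Maximal horizontal chord through the pupil centroid, in mm.

    On the mask row nearest the centroid row, the contiguous run of pupil
    pixels containing (or nearest to) the centroid column is measured
    inclusively; its length times the pixel spacing is the diameter.
    Invalid masks give NaN.
    """
    if not mask.valid:
        return math.nan
    row = int(np.clip(round(mask.centroid_row_px), 0, mask.mask.shape[0] - 1))
    cols = np.flatnonzero(mask.mask[row])
    if cols.size == 0:
        return math.nan
    breaks = np.flatnonzero(np.diff(cols) > 1)
    starts = np.r_[0, breaks + 1]
    stops = np.r_[breaks, cols.size - 1]
    runs = [(cols[a], cols[b]) for a, b in zip(starts, stops)]
    cc = mask.centroid_col_px

    def run_dist(run: tuple[int, int]) -> float:
        lo, hi = run
        if lo <= cc <= hi:
            return 0.0
        return min(abs(cc - lo), abs(cc - hi))

    lo, hi = min(runs, key=run_dist)
    return float((hi - lo + 1) * pixel_spacing)


def extract_trace(loop, config: SegmentationConfig = SegmentationConfig()) -> DiameterTrace:
    """Segment a cine loop frame by frame into a diameter-time trace.

    Each frame's centroid seeds the next frame's component selection (edge
    tracking); per-frame failures set ``valid_flags`` False rather than
    aborting the trace.
    """
    T = loop.frames.shape[0]
    diams = np.full(T, math.nan)
    valid = np.zeros(T, dtype=bool)
    prior: tuple[float, float] | None = None
    for k in range(T):
        m = segment_frame(loop.frames[k], config, prior_centroid=prior)
        if m.valid:
            d = chord_diameter(m, loop.pixel_spacing)
            if math.isfinite(d) and d > 0:
                diams[k] = d
                valid[k] = True
                prior = (m.centroid_row_px, m.centroid_col_px)
    return DiameterTrace(
        times=np.arange(T) / loop.frame_rate,
        diameters=diams,
        valid_flags=valid,
        stimulus_onset=loop.stimulus_onset,
        loop_id=loop.loop_id,
    )


# ---------------------------------------------------------------------------
# trace CSV I/O (columns: loop_id, frame_index, time_s, diameter_mm, valid)

def write_trace_csv(trace: DiameterTrace, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "loop_id": trace.loop_id,
            "frame_index": np.arange(trace.times.size),
            "time_s": trace.times,
            "diameter_mm": trace.diameters,
            "valid": trace.valid_flags.astype(int),
            "stimulus_onset_s": trace.stimulus_onset,
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def read_trace_csv(path: str | Path) -> list[DiameterTrace]:
    """Read one or more traces (grouped by ``loop_id``) from a CSV file."""
    df = pd.read_csv(path)
    traces = []
    for loop_id, g in df.groupby("loop_id", sort=False):
        g = g.sort_values("frame_index")
        traces.append(
            DiameterTrace(
                times=g["time_s"].to_numpy(),
                diameters=g["diameter_mm"].to_numpy(),
                valid_flags=g["valid"].to_numpy().astype(bool),
                stimulus_onset=float(g["stimulus_onset_s"].iloc[0]),
                loop_id=str(loop_id),
            )
        )
    return traces
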