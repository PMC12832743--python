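"""Synthetic transpalpebral B-mode cine loops with a known pupillary light reflex.

The generator emulates the tangential ocular view used in transpalpebral
ultrasound pupillometry: a bright eyelid echo band near the transducer, a
bright iris echo band deeper in the frame, and an anechoic (dark) gap in the
iris band whose horizontal width tracks the pupil diameter.  The diameter
follows a parametric pupillary-light-reflex (PLR) waveform — baseline,
latency after the light stimulus, constriction to a minimum, then partial
redilation — so every rendered loop carries exact, analytically known
ground-truth metrics.

Speckle is modelled as multiplicative gamma noise with unit mean (shape
parameter ``speckle_shape``; larger is cleaner, ``None`` disables it),
followed by a Gaussian point-spread blur.  This is deliberately not a
full radio-frequency ultrasound simulation: the downstream segmentation
only needs a dark region with a measurable horizontal extent, and the
gamma/blur model is sufficient to stress thresholding and morphology.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

from .plr_metrics import PLRMetrics

__all__ = [
    "PLRWaveform",
    "SceneConfig",
    "CineLoop",
    "GroundTruth",
    "waveform_diameter",
    "true_metrics",
    "render_cine",
    "write_cine",
    "read_cine",
]


@dataclass(frozen=True)
class PLRWaveform:
    """Parametric pupil diameter-versus-time curve for one light stimulus.

    Parameters
    ----------
    baseline_diameter : float
        Pre-stimulus pupil diameter in mm (the true INIT).
    min_diameter : float
        Diameter at maximal constriction in mm (the true END).
    latency : float
        Time from light onset to the onset of constriction in s (true LAT).
    constriction_duration : float
        Duration of the constriction phase in s.
    recovery_fraction : float
        Fraction of the constriction amplitude regained by the end of the
        recovery phase, in [0, 1].
    recovery_duration : float
        Duration of the redilation phase in s.
    shape : {"piecewise_linear", "exponential"}
        Segment shape.  Exponential segments are normalised so the minimum
        diameter is attained exactly at the end of the constriction phase,
        keeping the closed-form ground truth exact.
    tau_constrict, tau_dilate : float
        Time constants (s) of the exponential segments; ignored in
        piecewise-linear mode.
    """

    baseline_diameter: float
    min_diameter: float
    latency: float
    constriction_duration: float
    recovery_fraction: float = 0.6
    recovery_duration: float = 1.2
    shape: str = "piecewise_linear"
    tau_constrict: float = 0.4
    tau_dilate: float = 0.8

    def __post_init__(self) -> None:
        if not self.min_diameter < self.baseline_diameter:
            raise ValueError("min_diameter must be strictly below baseline_diameter")
        if self.latency < 0:
            raise ValueError("latency must be non-negative")
        if self.constriction_duration <= 0:
            raise ValueError("constriction_duration must be positive")
        if not 0.0 <= self.recovery_fraction <= 1.0:
            raise ValueError("recovery_fraction must lie in [0, 1]")
        if self.recovery_duration < 0:
            raise ValueError("recovery_duration must be non-negative")
        if self.shape not in ("piecewise_linear", "exponential"):
            raise ValueError(f"unknown waveform shape {self.shape!r}")
        if self.shape == "exponential" and (self.tau_constrict <= 0 or self.tau_dilate <= 0):
            raise ValueError("exponential mode needs positive time constants")

    @property
    def amplitude(self) -> float:
        """Constriction amplitude in mm."""
        return self.baseline_diameter - self.min_diameter


def waveform_diameter(waveform: PLRWaveform, t, stimulus_onset: float):
    """Pupil diameter (mm) at time ``t`` (s) for a stimulus at ``stimulus_onset``.

    Accepts a scalar or array of times and returns the same shape.  The curve
    is baseline until ``stimulus_onset + latency``, descends to
    ``min_diameter`` over ``constriction_duration``, recovers
    ``recovery_fraction`` of the amplitude over ``recovery_duration``, and is
    constant thereafter.
    """
    w = waveform
    t = np.asarray(t, dtype=float)
    t0 = stimulus_onset + w.latency        # constriction onset
    t1 = t0 + w.constriction_duration      # maximal constriction
    t2 = t1 + w.recovery_duration          # recovery endpoint
    amp = w.amplitude
    rec_amp = w.recovery_fraction * amp

    d = np.full(t.shape, w.baseline_diameter, dtype=float)

    con = (t >= t0) & (t < t1)
    rec = (t >= t1) & (t < t2)
    post = t >= t2

    if w.shape == "piecewise_linear":
        d[con] = w.baseline_diameter - amp * (t[con] - t0) / w.constriction_duration
        if w.recovery_duration > 0:
            d[rec] = w.min_diameter + rec_amp * (t[rec] - t1) / w.recovery_duration
    else:
        # Normalised exponentials: the segment reaches its endpoint exactly,
        # so END/ACV ground truth stays in closed form.
        kc = -np.expm1(-w.constriction_duration / w.tau_constrict)
        d[con] = w.baseline_diameter - amp * (-np.expm1(-(t[con] - t0) / w.tau_constrict)) / kc
        if w.recovery_duration > 0:
            kd = -np.expm1(-w.recovery_duration / w.tau_dilate)
            d[rec] = w.min_diameter + rec_amp * (-np.expm1(-(t[rec] - t1) / w.tau_dilate)) / kd
    d[post] = w.min_diameter + rec_amp
    return d if d.ndim else float(d)


def true_metrics(waveform: PLRWaveform) -> PLRMetrics:
    """Closed-form PLR metrics implied by a waveform (no simulation).

    INIT and END are the baseline and minimum diameters, DELTA their relative
    difference, LAT the latency, ACV the endpoint secant over the constriction
    phase and ADV the endpoint secant over the recovery phase.  ADV is
    undefined (NaN) when there is no recovery phase.
    """
    w = waveform
    amp = w.amplitude
    if w.recovery_duration > 0 and w.recovery_fraction > 0:
        adv = (w.recovery_fraction * amp) / w.recovery_duration
    else:
        adv = math.nan
    return PLRMetrics(
        init=w.baseline_diameter,
        end=w.min_diameter,
        delta=amp / w.baseline_diameter,
        lat=w.latency,
        acv=amp / w.constriction_duration,
        adv=adv,
    )


@dataclass(frozen=True)
class SceneConfig:
    """Geometry, timing, intensity and noise settings for a rendered loop.

    Intensities are on the [0, 1] grayscale of the rendered frames; the
    pupil gap must be darker than the iris band for segmentation to be
    well-posed.  ``speckle_shape=None`` disables speckle; ``blur_sigma_px=0``
    disables the point-spread blur.
    """

    frame_height_px: int = 96
    frame_width_px: int = 128
    pixel_spacing: float = 0.1   # mm/px
    frame_rate: float = 30.0     # Hz
    duration: float = 5.0        # s
    stimulus_onset: float = 1.0  # s
    eyelid_band_thickness_px: int = 10
    iris_band_thickness_px: int = 24
    pupil_center_row_px: int = 56
    pupil_center_col_px: int = 64
    iris_intensity: float = 0.75
    eyelid_intensity: float = 0.85
    background_intensity: float = 0.30
    pupil_intensity: float = 0.05
    speckle_shape: float | None = 4.0
    blur_sigma_px: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        if self.duration * self.frame_rate < 10:
            raise ValueError("need at least 10 frames (duration x frame_rate)")
        if not self.pupil_intensity < self.iris_intensity:
            raise ValueError("pupil_intensity must be below iris_intensity")
        if not 0 <= self.stimulus_onset < self.duration:
            raise ValueError("stimulus_onset must lie within the recording")
        if self.speckle_shape is not None and self.speckle_shape <= 0:
            raise ValueError("speckle_shape must be positive or None")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))


@dataclass
class CineLoop:
    """A timed stack of grayscale frames with spatial/temporal calibration."""

    frames: np.ndarray          # T x H x W, float in [0, 1]
    frame_rate: float           # Hz
    pixel_spacing: float        # mm/px
    stimulus_onset: float       # s
    loop_id: str = "loop"

    def __post_init__(self) -> None:
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a non-empty T x H x W stack")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.frames.shape[0]) / self.frame_rate

    @property
    def duration(self) -> float:
        return self.frames.shape[0] / self.frame_rate


@dataclass
class GroundTruth:
    waveform: PLRWaveform
    true_metrics: PLRMetrics
    pupil_center_row_px: int
    pupil_center_col_px: int


def _speckle_enabled(scene: SceneConfig) -> bool:
    return scene.speckle_shape is not None and math.isfinite(scene.speckle_shape)


def render_template(waveform: PLRWaveform, scene: SceneConfig) -> np.ndarray:
    """Noise-free T x H x W tissue template (no speckle, no blur)."""
    H, W, T = scene.frame_height_px, scene.frame_width_px, scene.n_frames
    times = np.arange(T) / scene.frame_rate
    diam = waveform_diameter(waveform, times, scene.stimulus_onset)
    gap_px = np.rint(diam / scene.pixel_spacing).astype(int)

    r0 = scene.pupil_center_row_px - scene.iris_band_thickness_px // 2
    r1 = r0 + scene.iris_band_thickness_px
    if r0 < scene.eyelid_band_thickness_px or r1 > H:
        raise ValueError("iris band does not fit below the eyelid band")
    starts = scene.pupil_center_col_px - gap_px // 2
    stops = starts + gap_px
    if starts.min() < 0 or stops.max() > W:
        raise ValueError("pupil gap wider than the frame; enlarge the scene")

    frames = np.full((T, H, W), scene.background_intensity, dtype=np.float64)
    frames[:, : scene.eyelid_band_thickness_px, :] = scene.eyelid_intensity
    frames[:, r0:r1, :] = scene.iris_intensity
    for k in range(T):
        frames[k, r0:r1, starts[k] : stops[k]] = scene.pupil_intensity
    return frames


def render_cine(waveform: PLRWaveform, scene: SceneConfig) -> tuple[CineLoop, GroundTruth]:
    """Render a cine loop: template x gamma speckle -> Gaussian blur -> clip.

    The same ``scene.rng_seed`` gives bit-identical output.
    """
    frames = render_template(waveform, scene)
    if _speckle_enabled(scene):
        rng = np.random.default_rng(scene.rng_seed)
        k = float(scene.speckle_shape)
        frames = frames * rng.gamma(k, 1.0 / k, size=frames.shape)
    if scene.blur_sigma_px > 0:
        frames = ndimage.gaussian_filter(
            frames, sigma=(0.0, scene.blur_sigma_px, scene.blur_sigma_px)
        )
    np.clip(frames, 0.0, 1.0, out=frames)
    loop = CineLoop(
        frames=frames.astype(np.float32),
        frame_rate=scene.frame_rate,
        pixel_spacing=scene.pixel_spacing,
        stimulus_onset=scene.stimulus_onset,
        loop_id=f"sim-{scene.rng_seed}",
    )
    gt = GroundTruth(
        waveform=waveform,
        true_metrics=true_metrics(waveform),
        pupil_center_row_px=scene.pupil_center_row_px,
        pupil_center_col_px=scene.pupil_center_col_px,
    )
    return loop, gt


# ---------------------------------------------------------------------------
# file I/O: multi-page TIFF plus a JSON sidecar with calibration + ground truth

def write_cine(
    loop: CineLoop,
    tiff_path: str | Path,
    ground_truth: GroundTruth | None = None,
    scene: SceneConfig | None = None,
    bit_depth: int = 16,
) -> Path:
    """Write a loop as multi-page grayscale TIFF with a ``.json`` sidecar.

    Returns the sidecar path.  The sidecar carries everything needed to
    interpret the pixels (frame rate, pixel spacing, stimulus onset) and,
    when available, the generating waveform and its true metrics.
    """
    tiff_path = Path(tiff_path)
    if bit_depth == 8:
        data = np.round(loop.frames * 255).astype(np.uint8)
    elif bit_depth == 16:
        data = np.round(loop.frames * 65535).astype(np.uint16)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    tifffile.imwrite(tiff_path, data, photometric="minisblack")

    meta: dict = {
        "loop_id": loop.loop_id,
        "frame_rate": loop.frame_rate,
        "pixel_spacing": loop.pixel_spacing,
        "stimulus_onset": loop.stimulus_onset,
        "bit_depth": bit_depth,
    }
    if scene is not None:
        meta["scene"] = dataclasses.asdict(scene)
        meta["seed"] = scene.rng_seed
    if ground_truth is not None:
        meta["waveform"] = dataclasses.asdict(ground_truth.waveform)
        meta["true_metrics"] = dataclasses.asdict(ground_truth.true_metrics)
        meta["pupil_center_row_px"] = ground_truth.pupil_center_row_px
        meta["pupil_center_col_px"] = ground_truth.pupil_center_col_px
    sidecar = tiff_path.with_suffix(".json")
    sidecar.write_text(json.dumps(meta, indent=2))
    return sidecar


def read_cine(tiff_path: str | Path, sidecar_path: str | Path | None = None) -> CineLoop:
    """Read a multi-page TIFF + sidecar back into a :class:`CineLoop`."""
    tiff_path = Path(tiff_path)
    if sidecar_path is None:
        sidecar_path = tiff_path.with_suffix(".json")
    meta = json.loads(Path(sidecar_path).read_text())
    data = tifffile.imread(tiff_path)
    if data.ndim == 2:
        data = data[None]
    scale = 255.0 if data.dtype == np.uint8 else 65535.0
    frames = data.astype(np.float32) / scale
    return CineLoop(
        frames=frames,
        frame_rate=float(meta["frame_rate"]),
        pixel_spacing=float(meta["pixel_spacing"]),
        stimulus_onset=float(meta["stimulus_onset"]),
        loop_id=str(meta.get("loop_id", tiff_path.stem)),
    )
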