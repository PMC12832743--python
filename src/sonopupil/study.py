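"""End-to-end study emulator: simulate -> segment -> metrics -> statistics.

Reproduces the design of a paired method-comparison study at the bedside:
a cohort of patients contributes two eyes each; every eye receives three
consecutive ultrasound cine acquisitions which are segmented, converted to
PLR metrics, and averaged; a second (reference, infrared-style) modality is
emulated as the analytic ground-truth metrics plus configurable per-metric
offsets and noise; and a reliability arm re-acquires each eye with a second
emulated observer (independent speckle and small probe-placement shifts).

Outputs are an agreement report (one Bland-Altman/regression row per
metric), a reliability report (inter-observer ICC(2,1) on per-observer
session means, intra-observer ICC(3,1) on within-observer repeats), the full
per-acquisition metric table, and a manifest recording the seed and a config
hash.  Identical config + seed gives byte-identical CSV output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agreement import ReliabilityTable, agreement_table, icc
from .plr_metrics import (
    METRIC_NAMES,
    MetricsConfig,
    PLRMetrics,
    SessionResult,
    average_session,
    compute_metrics,
    quality_control,
)
from .segmentation import SegmentationConfig, extract_trace
from .synthesis import PLRWaveform, SceneConfig, render_cine, true_metrics

__all__ = ["StudyConfig", "run_study", "default_study_config"]

log = logging.getLogger("sonopupil.study")

#: population distributions for the per-eye waveform parameters:
#: (mean, sd, lower clip, upper clip).  Baseline diameter and constriction
#: ratio match a typical adult ICU cohort; latency and the velocity targets
#: are expressed on the reference (infrared) modality's scale.
_DEFAULT_POPULATION = {
    "baseline_mm": (4.05, 0.57, 2.8, 5.8),
    "delta": (0.25, 0.05, 0.10, 0.42),
    "latency_s": (0.28, 0.027, 0.15, 0.45),
    "acv_mm_s": (1.46, 0.30, 0.7, 2.6),
    "adv_mm_s": (0.78, 0.17, 0.35, 1.4),
}

#: reference-modality measurement noise SD per metric (device repeatability).
_DEFAULT_B_NOISE = {
    "init": 0.03, "end": 0.03, "delta": 0.005,
    "lat": 0.015, "acv": 0.04, "adv": 0.04,
}


@dataclass
class StudyConfig:
    n_patients: int = 20
    eyes_per_patient: int = 2
    acquisitions_per_eye: int = 3
    #: additive offsets applied to the emulated reference modality (B);
    #: the reported bias is A - B, so an offset of -x here appears as +x bias.
    modality_b_offsets: dict = field(default_factory=lambda: {m: 0.0 for m in METRIC_NAMES})
    modality_b_noise_sd: dict = field(default_factory=lambda: dict(_DEFAULT_B_NOISE))
    waveform_population: dict = field(default_factory=lambda: dict(_DEFAULT_POPULATION))
    recovery_fraction: float = 0.85
    scene: SceneConfig = field(default_factory=SceneConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    include_reliability: bool = True
    observer_shift_px: int = 2       # probe-placement jitter for observer 2
    rng_seed: int = 7

    def __post_init__(self) -> None:
        if min(self.n_patients, self.eyes_per_patient, self.acquisitions_per_eye) < 1:
            raise ValueError("counts must be >= 1")

    def to_json(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(type(o))
        return json.dumps(dataclasses.asdict(self), default=enc, indent=2, sort_keys=True)


def default_study_config(**overrides) -> StudyConfig:
    return dataclasses.replace(StudyConfig(), **overrides) if overrides else StudyConfig()


def _truncated_normal(rng: np.random.Generator, mean, sd, lo, hi) -> float:
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def _sample_waveform(rng: np.random.Generator, config: StudyConfig) -> PLRWaveform:
    pop = config.waveform_population
    base = _truncated_normal(rng, *pop["baseline_mm"])
    delta = _truncated_normal(rng, *pop["delta"])
    lat = _truncated_normal(rng, *pop["latency_s"])
    acv = _truncated_normal(rng, *pop["acv_mm_s"])
    adv = _truncated_normal(rng, *pop["adv_mm_s"])
    amp = base * delta
    constriction = float(np.clip(amp / acv, 0.2, 2.0))
    recovery = float(np.clip(config.recovery_fraction * amp / adv, 0.3, 2.5))
    return PLRWaveform(
        baseline_diameter=base,
        min_diameter=base - amp,
        latency=lat,
        constriction_duration=constriction,
        recovery_fraction=config.recovery_fraction,
        recovery_duration=recovery,
    )


def _measure_acquisition(
    waveform: PLRWaveform, scene: SceneConfig, config: StudyConfig
) -> tuple[PLRMetrics, bool, list[str]]:
    loop, _ = render_cine(waveform, scene)
    trace = extract_trace(loop, config.segmentation)
    ok, reasons = quality_control(trace, config.metrics)
    if not ok:
        log.warning("QC failure on %s: %s", loop.loop_id, ",".join(reasons))
    return compute_metrics(trace, config.metrics), ok, reasons


def _measure_session(
    waveform: PLRWaveform, eye_id: str, seeds, center_shift: tuple[int, int], config: StudyConfig
) -> SessionResult:
    per_acq, qc_ok, qc_reasons = [], True, []
    for seed in seeds:
        scene = dataclasses.replace(
            config.scene,
            rng_seed=int(seed),
            pupil_center_row_px=config.scene.pupil_center_row_px + center_shift[0],
            pupil_center_col_px=config.scene.pupil_center_col_px + center_shift[1],
        )
        m, ok, reasons = _measure_acquisition(waveform, scene, config)
        per_acq.append(m)
        qc_ok &= ok
        qc_reasons.extend(reasons)
    return SessionResult(
        eye_id=eye_id, modality="auto_upa", per_acquisition=per_acq,
        averaged=average_session(per_acq), qc_pass=qc_ok, qc_reasons=qc_reasons,
    )


def _emulate_reference(
    truth: PLRMetrics, rng: np.random.Generator, config: StudyConfig
) -> PLRMetrics:
    vals = {}
    for name in METRIC_NAMES:
        t = getattr(truth, name)
        off = config.modality_b_offsets.get(name, 0.0)
        sd = config.modality_b_noise_sd.get(name, 0.0)
        vals[name] = t + off + (rng.normal(0.0, sd) if sd > 0 else 0.0)
    return PLRMetrics(**vals)


def run_study(config: StudyConfig, outdir: str | Path) -> dict:
    """Run the full emulated study and write its report bundle to ``outdir``.

    Returns a dict with the agreement table, reliability table, metrics
    table and manifest (also written as CSV/JSON files).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.rng_seed)
    pop_rng = np.random.default_rng(ss.spawn(1)[0])
    ref_rng = np.random.default_rng(ss.spawn(1)[0])
    acq_seeds = np.random.default_rng(ss.spawn(1)[0]).integers(
        0, 2**31 - 1,
        size=(config.n_patients * config.eyes_per_patient, 2, config.acquisitions_per_eye),
    )
    shift_rng = np.random.default_rng(ss.spawn(1)[0])

    rows = []
    intra: dict[str, list[list[float]]] = {m: [] for m in METRIC_NAMES}
    inter: dict[str, list[list[float]]] = {m: [] for m in METRIC_NAMES}
    eye_idx = 0
    for p in range(config.n_patients):
        for e in range(config.eyes_per_patient):
            side = "R" if e == 0 else ("L" if e == 1 else f"E{e}")
            eye_id = f"P{p + 1:02d}{side}"
            waveform = _sample_waveform(pop_rng, config)
            truth = true_metrics(waveform)
            try:
                ses1 = _measure_session(
                    waveform, eye_id, acq_seeds[eye_idx, 0], (0, 0), config
                )
            except ValueError as exc:
                raise RuntimeError(f"measurement failed for eye {eye_id}: {exc}") from exc
            ref = _emulate_reference(truth, ref_rng, config)
            rows.append({"eye_id": eye_id, "modality": "auto_upa",
                         **ses1.averaged.as_dict(), "qc_pass": ses1.qc_pass})
            rows.append({"eye_id": eye_id, "modality": "ipa",
                         **ref.as_dict(), "qc_pass": True})

            if config.include_reliability:
                shift = tuple(
                    shift_rng.integers(-config.observer_shift_px, config.observer_shift_px + 1, 2)
                )
                try:
                    ses2 = _measure_session(
                        waveform, eye_id, acq_seeds[eye_idx, 1], shift, config
                    )
                except ValueError as exc:
                    raise RuntimeError(
                        f"observer-2 measurement failed for eye {eye_id}: {exc}"
                    ) from exc
                for m in METRIC_NAMES:
                    inter[m].append(
                        [getattr(ses1.averaged, m), getattr(ses2.averaged, m)]
                    )
                    intra[m].append([getattr(a, m) for a in ses1.per_acquisition])
            eye_idx += 1
            log.info("eye %s done (%d/%d)", eye_id, eye_idx,
                     config.n_patients * config.eyes_per_patient)

    metrics_df = pd.DataFrame(rows)
    agreement = agreement_table(metrics_df, METRIC_NAMES)

    rel_rows = []
    if config.include_reliability:
        for m in METRIC_NAMES:
            for form, data, design in (
                ("icc_2_1", inter[m], "inter_observer"),
                ("icc_3_1", intra[m], "intra_observer"),
            ):
                arr = np.asarray(data, dtype=float)
                ok = np.all(np.isfinite(arr), axis=1)
                arr = arr[ok]
                if arr.shape[0] < 2:
                    rel_rows.append({"metric_name": m, "form": form,
                                     "design": design, "icc": math.nan, "n": int(arr.shape[0])})
                    continue
                res = icc(ReliabilityTable(m, arr, design=design), form)
                rel_rows.append({"metric_name": m, "form": form, "design": design,
                                 "icc": res.icc, "n": int(arr.shape[0])})
    reliability = pd.DataFrame(rel_rows)

    cfg_json = config.to_json()
    manifest = {
        "seed": config.rng_seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "sonopupil_version": __version__,
        "n_eyes": config.n_patients * config.eyes_per_patient,
    }

    metrics_df.to_csv(outdir / "metrics.csv", index=False, float_format="%.10g")
    agreement.to_csv(outdir / "agreement.csv", index=False, float_format="%.10g")
    reliability.to_csv(outdir / "reliability.csv", index=False, float_format="%.10g")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (outdir / "config.json").write_text(cfg_json)

    return {"metrics": metrics_df, "agreement": agreement,
            "reliability": reliability, "manifest": manifest}
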