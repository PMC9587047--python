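"""End-to-end orchestration: recordings -> per-segment indices -> dose models.

Restraint chain, per individual:
  ventilatory channel -> bandpass 1–10 Hz -> 5-s segments -> z-score ->
      {Burg/AIC peak frequency; peak detection -> 10 Hz tachogram -> CV}
  ECG channel -> bandpass 5–120 Hz -> 5-s segments -> z-score ->
      {peak count / 5 s (heart rate); tachogram CV}

Free-swimming chain, per individual:
  tracking -> nearest electrode per 5-s window -> stitched single channel ->
      same ventilatory chain; plus average swimming speed per window.

Segments that fail any stage (degenerate, flat spectrum, too few peaks)
are marked invalid and excluded listwise per metric — never imputed — so
row counts are exact: 5 individuals x 24 five-second segments = 120 rows
per dose, dropping to 96 when one individual fails the 72-h survival
criterion.  The surviving cohort is then fed to the mixed-model selection,
with piecewise (0–1, 1–100 mg/L) sections for the non-monotone indices
(heartbeat CV, swimming speed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import arspectrum, conditioning, events, kinematics, mixedmodel
from .conditioning import FilterSpec
from .errors import ConfigError, GillwaveError
from .events import PeakDetectionSpec
from .io import CohortMetadata, Recording, filter_cohort
from .kinematics import ElectrodeGrid, Trajectory

log = logging.getLogger("gillwave")


@dataclass
class PipelineConfig:
    """Run configuration with the study's analysis conditions as defaults."""

    condition: str = "restraint"
    filter_order: int = 3
    vent_low_hz: float = 1.0
    vent_high_hz: float = 10.0
    ecg_low_hz: float = 5.0
    ecg_high_hz: float = 120.0
    segment_length_s: float = 5.0
    ar_p_min: int = 10
    ar_p_max: int = 50
    peak_band_low_hz: float = 1.0
    peak_band_high_hz: float = 10.0
    peak_grid_hz: float = 0.01
    vent_min_height: float = 0.5
    vent_min_interval_s: float = 0.1
    ecg_min_height: float = 0.1
    ecg_min_interval_s: float = 0.2
    ecg_polarity: int = 1
    tachogram_rate_hz: float = 10.0
    cv_use_resampled: bool = True
    selection_window_s: float = 5.0
    selection_aggregator: str = "mean"
    speed_window_s: float = 5.0
    log_base: str = "e"
    seed: int = 0
    input_dir: str = "."
    output_dir: str = "out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load and validate a YAML configuration; unknown keys are rejected."""
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.condition not in ("restraint", "free_swimming"):
            raise ConfigError(f"condition must be restraint|free_swimming, got {cfg.condition!r}")
        for name in ("segment_length_s", "tachogram_rate_hz", "selection_window_s"):
            if getattr(cfg, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        return cfg

    def vent_filter(self) -> FilterSpec:
        return FilterSpec(self.filter_order, self.vent_low_hz, self.vent_high_hz)

    def ecg_filter(self) -> FilterSpec:
        return FilterSpec(self.filter_order, self.ecg_low_hz, self.ecg_high_hz)

    def vent_peaks(self) -> PeakDetectionSpec:
        return PeakDetectionSpec(self.vent_min_height, self.vent_min_interval_s)

    def ecg_peaks(self) -> PeakDetectionSpec:
        return PeakDetectionSpec(
            self.ecg_min_height, self.ecg_min_interval_s, self.ecg_polarity
        )


@dataclass
class PipelineResult:
    """Per-segment index table plus selected mixed-model fits."""

    segments: pd.DataFrame
    fits: dict[str, mixedmodel.LMMFit] = field(default_factory=dict)
    aic_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    report: pd.DataFrame | None = None
    n_invalid: int = 0


def _vent_rows(x: np.ndarray, rate_hz: float, cfg: PipelineConfig, prov: dict) -> list[dict]:
    filtered = conditioning.bandpass(x, rate_hz, cfg.vent_filter())
    rows = []
    for seg in conditioning.segment_signal(filtered, rate_hz, cfg.segment_length_s, prov):
        base = dict(prov, segment=seg.index)
        try:
            z = conditioning.standardize(seg)
        except GillwaveError as exc:
            log.debug("segment %s invalid before analysis: %s", seg.index, exc)
            rows.append(dict(base, metric="peak_frequency", value=np.nan))
            rows.append(dict(base, metric="cv_vent", value=np.nan))
            continue
        try:
            pf = arspectrum.segment_peak_frequency(
                z.values, rate_hz, cfg.ar_p_min, cfg.ar_p_max,
                (cfg.peak_band_low_hz, cfg.peak_band_high_hz), cfg.peak_grid_hz,
            )
        except GillwaveError as exc:
            log.debug("peak frequency invalid for segment %s: %s", seg.index, exc)
            pf = np.nan
        rows.append(dict(base, metric="peak_frequency", value=pf))
        try:
            cv = events.segment_interval_cv(
                z, cfg.vent_peaks(), cfg.tachogram_rate_hz,
                use_resampled=cfg.cv_use_resampled,
            )
        except GillwaveError as exc:
            log.debug("ventilatory CV invalid for segment %s: %s", seg.index, exc)
            cv = np.nan
        rows.append(dict(base, metric="cv_vent", value=cv))
    return rows


def _ecg_rows(x: np.ndarray, rate_hz: float, cfg: PipelineConfig, prov: dict) -> list[dict]:
    filtered = conditioning.bandpass(x, rate_hz, cfg.ecg_filter())
    rows = []
    for seg in conditioning.segment_signal(filtered, rate_hz, cfg.segment_length_s, prov):
        base = dict(prov, segment=seg.index)
        try:
            z = conditioning.standardize(seg)
        except GillwaveError:
            rows.append(dict(base, metric="heart_rate", value=np.nan))
            rows.append(dict(base, metric="cv_heart", value=np.nan))
            continue
        ev = events.detect_peaks(z, cfg.ecg_peaks())
        rows.append(
            dict(base, metric="heart_rate", value=events.heart_rate(ev, cfg.segment_length_s))
        )
        try:
            cv = events.segment_interval_cv(
                z, cfg.ecg_peaks(), cfg.tachogram_rate_hz,
                use_resampled=cfg.cv_use_resampled,
            )
        except GillwaveError:
            cv = np.nan
        rows.append(dict(base, metric="cv_heart", value=cv))
    return rows


def _attach_meta(rows: list[dict], meta: CohortMetadata) -> None:
    for r in rows:
        r["individual_id"] = meta.individual_id
        r["concentration_mg_per_l"] = meta.concentration_mg_per_l
        r["condition"] = meta.condition


def _model_stage(
    segments: pd.DataFrame,
    monotone_metrics: tuple[str, ...],
    piecewise_metrics: tuple[str, ...],
) -> tuple[dict, dict]:
    fits: dict[str, mixedmodel.LMMFit] = {}
    aics: dict[str, pd.DataFrame] = {}
    for metric in monotone_metrics + piecewise_metrics:
        sub = segments[(segments["metric"] == metric) & segments["value"].notna()]
        if sub.empty:
            continue
        if metric in piecewise_metrics:
            for (lo, hi), (fit, aic) in mixedmodel.piecewise_fit(sub).items():
                key = f"{metric}[{lo:g}-{hi:g}]"
                fits[key], aics[key] = fit, aic
        else:
            fits[metric], aics[metric] = mixedmodel.select_model_aic(sub)
    return fits, aics


def run_restraint(
    recordings: Mapping[str, Any],
    meta: list[CohortMetadata],
    cfg: PipelineConfig | None = None,
) -> PipelineResult:
    """Restraint-condition analysis for a cohort of recordings.

    ``recordings`` maps individual_id either to a single Recording carrying
    both a ventilatory and an ecg channel (possible only when they share a
    rate) or, as in the experiments where the optical ventilatory signal
    runs at 100 fps and the ECG at 1 kHz, to a mapping
    ``{"ventilatory": Recording, "ecg": Recording}``.  Individuals failing
    the 72-h survival criterion are dropped before anything else.
    """
    cfg = cfg or PipelineConfig(condition="restraint")
    rows: list[dict] = []
    for m in filter_cohort(meta):
        rec = recordings[m.individual_id]
        if isinstance(rec, Recording):
            vent_rec = ecg_rec = rec
        else:
            vent_rec, ecg_rec = rec["ventilatory"], rec["ecg"]
        prov = {}
        vr = _vent_rows(vent_rec.channel("ventilatory"), vent_rec.rate_hz, cfg, prov)
        er = _ecg_rows(ecg_rec.channel("ecg"), ecg_rec.rate_hz, cfg, prov)
        _attach_meta(vr + er, m)
        rows.extend(vr + er)
    segments = pd.DataFrame(rows)
    if segments.empty:
        raise GillwaveError("restraint run produced no segments")
    n_invalid = int(segments["value"].isna().sum())
    segments = segments[segments["value"].notna()].reset_index(drop=True)
    fits, aics = _model_stage(
        segments, ("peak_frequency", "cv_vent", "heart_rate"), ("cv_heart",)
    )
    return PipelineResult(segments, fits, aics, mixedmodel.report(fits), n_invalid)


def run_freeswim(
    recordings: Mapping[str, Recording],
    trajectories: Mapping[str, Trajectory],
    meta: list[CohortMetadata],
    cfg: PipelineConfig | None = None,
    grid: ElectrodeGrid | None = None,
) -> PipelineResult:
    """Free-swimming analysis: electrode selection, ventilation, and speed."""
    cfg = cfg or PipelineConfig(condition="free_swimming")
    grid = grid or kinematics.default_grid()
    rows: list[dict] = []
    for m in filter_cohort(meta):
        rec = recordings[m.individual_id]
        traj = trajectories[m.individual_id]
        sel = kinematics.nearest_electrode(
            traj, grid, cfg.selection_window_s,
            duration_s=rec.duration_s, aggregator=cfg.selection_aggregator,
        )
        stitched = kinematics.stitch_channel(rec, sel)
        vr = _vent_rows(stitched.samples[0], stitched.rate_hz, cfg, {})
        speeds = kinematics.average_speed(traj, cfg.speed_window_s, duration_s=rec.duration_s)
        sr = [dict(segment=w, metric="avg_speed", value=v) for w, v in enumerate(speeds)]
        _attach_meta(vr + sr, m)
        rows.extend(vr + sr)
    segments = pd.DataFrame(rows)
    if segments.empty:
        raise GillwaveError("free-swimming run produced no segments")
    n_invalid = int(segments["value"].isna().sum())
    segments = segments[segments["value"].notna()].reset_index(drop=True)
    fits, aics = _model_stage(segments, ("peak_frequency", "cv_vent"), ("avg_speed",))
    return PipelineResult(segments, fits, aics, mixedmodel.report(fits), n_invalid)


def write_outputs(result: PipelineResult, out_dir: str | Path, cfg: PipelineConfig) -> None:
    """Write segments.csv, lmm_report.csv and a provenance sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.segments.to_csv(out / "segments.csv", index=False)
    if result.report is not None:
        result.report.to_csv(out / "lmm_report.csv", index=False)
    import hashlib

    cfg_dict = asdict(cfg)
    cfg_hash = hashlib.sha256(json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest()[:16]
    prov = {
        "config": cfg_dict,
        "config_sha256_16": cfg_hash,
        "seed": cfg.seed,
        "n_invalid_segments": result.n_invalid,
        "versions": _versions(),
    }
    with open(out / "provenance.json", "w") as f:
        json.dump(prov, f, indent=2)


def _versions() -> dict[str, str]:
    import scipy
    import statsmodels

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
    }
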