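"""Synthetic ground-truth generators for every pipeline stage.

These generators emulate the study's data at its actual conditions —
quasi-periodic ventilatory oscillations in the 1–10 Hz band, ECG-like
R-wave trains at 1–4 beats/s, fish trajectories in the 210 x 140 mm arena,
126-channel array recordings with distance-dependent attenuation, and
cohort index tables drawn from the candidate mixed-model structures —
and return the exact ground truth (event times, frequencies, parameters)
so estimator accuracy can be measured, not assumed.

Event timing uses Gamma renewal processes: successive intervals are i.i.d.
Gamma with the requested mean and coefficient of variation (shape = 1/CV^2),
which keeps intervals positive at any CV.  All generators are
seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SpecError
from .io import ARRAY_RATE_HZ, ECG_RATE_HZ, Recording
from .kinematics import TANK_H_MM, TANK_W_MM, ElectrodeGrid, Trajectory
from .mixedmodel import DOSES_MG_PER_L, LMMSpec, log_concentration


def _renewal_times(rng, mean_interval: float, cv: float, duration: float) -> np.ndarray:
    """Event times of a Gamma renewal process covering [~0, duration]."""
    n_guess = int(np.ceil(duration / mean_interval)) + 10
    times = []
    t = 0.0
    while t <= duration + 2 * mean_interval:
        if cv <= 0:
            iv = np.full(n_guess, mean_interval)
        else:
            shape = 1.0 / cv**2
            iv = rng.gamma(shape, mean_interval / shape, size=n_guess)
        for v in iv:
            t += v
            times.append(t)
            if t > duration + 2 * mean_interval:
                break
    return np.asarray(times)


@dataclass(frozen=True)
class VentilatorySimSpec:
    """Quasi-periodic ventilatory oscillation (1–6 Hz range in the data)."""

    mean_freq_hz: float = 3.0
    interval_cv: float = 0.1
    waveform: str = "sinusoidal"  # or "pulse"
    noise_sd: float = 0.05
    duration_s: float = 120.0
    rate_hz: float = ARRAY_RATE_HZ
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_freq_hz > self.rate_hz / 4:
            raise SpecError("mean frequency must be below Nyquist/4")
        if self.interval_cv < 0 or self.noise_sd < 0:
            raise SpecError("interval_cv and noise_sd must be nonnegative")
        if self.waveform not in ("sinusoidal", "pulse"):
            raise SpecError(f"unknown waveform {self.waveform!r}")


def gen_ventilatory(spec: VentilatorySimSpec) -> tuple[Recording, dict]:
    """Generate a ventilatory signal plus ground truth.

    Intervals between opercular cycles are Gamma-renewal with the requested
    mean rate and CV.  The sinusoidal waveform accumulates one cycle of
    phase per interval (cosine, so maxima sit exactly at event times); the
    pulse waveform renders a Gaussian bump at each event.  Truth dict keys:
    ``event_times_s``, ``mean_freq_hz``, ``interval_cv``.
    """
    rng = np.random.default_rng(spec.seed)
    mean_iv = 1.0 / spec.mean_freq_hz
    # one event before t=0 so the phase is defined from the first sample
    ev = _renewal_times(rng, mean_iv, spec.interval_cv, spec.duration_s) - mean_iv
    t = np.arange(int(round(spec.duration_s * spec.rate_hz))) / spec.rate_hz
    if spec.waveform == "sinusoidal":
        phase = 2 * np.pi * np.interp(t, ev, np.arange(len(ev), dtype=float))
        x = np.cos(phase)
    else:
        x = np.zeros_like(t)
        width = 0.1 * mean_iv
        for e in ev[(ev > -5 * width) & (ev < spec.duration_s + 5 * width)]:
            lo = max(0, int((e - 5 * width) * spec.rate_hz))
            hi = min(len(t), int((e + 5 * width) * spec.rate_hz) + 1)
            x[lo:hi] += np.exp(-0.5 * ((t[lo:hi] - e) / width) ** 2)
    x = x + spec.noise_sd * rng.standard_normal(len(t))
    truth = {
        "event_times_s": ev[(ev >= 0) & (ev <= spec.duration_s)],
        "mean_freq_hz": spec.mean_freq_hz,
        "interval_cv": spec.interval_cv,
    }
    return Recording(x[None, :], spec.rate_hz, ["ventilatory"]), truth


@dataclass(frozen=True)
class EcgSimSpec:
    """ECG-like R-wave train (heart rate 1–4 beats/s in the data)."""

    rate_bps: float = 2.26
    beat_cv: float = 0.1
    r_wave_width_s: float = 0.02
    noise_sd: float = 0.01
    duration_s: float = 120.0
    rate_hz: float = ECG_RATE_HZ
    seed: int = 0
    phase_s: float = 0.0  # offset of the first beat

    def __post_init__(self) -> None:
        if self.r_wave_width_s >= (1.0 / self.rate_bps) / 4:
            raise SpecError("R-wave width must be < mean beat interval / 4")


def gen_ecg(spec: EcgSimSpec) -> tuple[Recording, dict]:
    """Generate an ECG-like recording plus true beat times.

    Beat times follow a Gamma renewal process; each beat is rendered as a
    narrow Ricker (Mexican-hat) template: a sharp positive R deflection
    flanked by shallow negative lobes.  The template is zero-mean and its
    energy sits well inside the 5–120 Hz ECG passband, so bandpass
    conditioning leaves the morphology essentially unchanged.
    """
    rng = np.random.default_rng(spec.seed)
    mean_iv = 1.0 / spec.rate_bps
    ev = _renewal_times(rng, mean_iv, spec.beat_cv, spec.duration_s) - mean_iv + spec.phase_s
    ev = ev[(ev >= 0) & (ev <= spec.duration_s)]
    t = np.arange(int(round(spec.duration_s * spec.rate_hz))) / spec.rate_hz
    x = np.zeros_like(t)
    w = spec.r_wave_width_s / 2.0  # Ricker scale; central lobe ~ r_wave_width_s wide
    for e in ev:
        lo = max(0, int((e - 8 * w) * spec.rate_hz))
        hi = min(len(t), int((e + 8 * w) * spec.rate_hz) + 1)
        dt = (t[lo:hi] - e) / w
        x[lo:hi] += (1.0 - dt**2) * np.exp(-0.5 * dt**2)
    x = x + spec.noise_sd * rng.standard_normal(len(t))
    truth = {"beat_times_s": ev, "rate_bps": spec.rate_bps, "beat_cv": spec.beat_cv}
    return Recording(x[None, :], spec.rate_hz, ["ecg"]), truth


def gen_trajectory(
    duration_s: float = 120.0,
    frame_rate_hz: float = 29.97,
    tank_dims_mm: tuple[float, float] = (TANK_W_MM, TANK_H_MM),
    mean_speed_mm_s: float = 27.7,
    heading_sd: float = 1.5,
    seed: int = 0,
) -> Trajectory:
    """Reflected correlated random walk inside the tank.

    The heading follows an Ornstein–Uhlenbeck-like diffusion
    (``heading_sd`` rad/sqrt(s)) at constant speed ``mean_speed_mm_s``;
    positions reflect off the walls, so the path length per unit time —
    what :func:`~gillwave.kinematics.average_speed` measures — equals the
    commanded speed up to frame discretization.
    """
    rng = np.random.default_rng(seed)
    w, h = tank_dims_mm
    n = int(round(duration_s * frame_rate_hz)) + 1
    dt = 1.0 / frame_rate_hz
    theta = rng.uniform(0, 2 * np.pi)
    x, y = np.empty(n), np.empty(n)
    x[0], y[0] = w / 2, h / 2
    for i in range(1, n):
        theta += heading_sd * np.sqrt(dt) * rng.standard_normal()
        nx = x[i - 1] + mean_speed_mm_s * dt * np.cos(theta)
        ny = y[i - 1] + mean_speed_mm_s * dt * np.sin(theta)
        # reflect at the walls
        if nx < 0:
            nx = -nx
            theta = np.pi - theta
        elif nx > w:
            nx = 2 * w - nx
            theta = np.pi - theta
        if ny < 0:
            ny = -ny
            theta = -theta
        elif ny > h:
            ny = 2 * h - ny
            theta = -theta
        x[i], y[i] = nx, ny
    return Trajectory(np.arange(n) * dt, x, y, frame_rate_hz=frame_rate_hz)


def gen_array_recording(
    traj: Trajectory,
    source: Recording,
    grid: ElectrodeGrid,
    attenuation_scale_mm: float = 30.0,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> Recording:
    """Project a source signal onto the electrode array.

    Channel i receives ``source(t) * exp(-d_i(t) / attenuation_scale_mm)``
    plus white noise, with d_i(t) the fish–electrode distance (trajectory
    linearly interpolated to the signal rate).  Exponential decay is a
    deliberately simple monotone attenuation: nearest-electrode selection
    only requires that closer means stronger.
    """
    rng = np.random.default_rng(seed)
    t = source.times_s
    fx = np.interp(t, traj.times_s, traj.x_mm)
    fy = np.interp(t, traj.times_s, traj.y_mm)
    src = source.samples[0]
    ex, ey = grid.positions_mm.T
    d = np.hypot(fx[None, :] - ex[:, None], fy[None, :] - ey[:, None])
    samples = src[None, :] * np.exp(-d / attenuation_scale_mm)
    samples += noise_sd * rng.standard_normal(samples.shape)
    return Recording(
        samples, source.rate_hz, ["array"] * grid.n_electrodes, source.start_time_s
    )


@dataclass(frozen=True)
class CohortSimSpec:
    """Cohort index table drawn from one of the candidate LMM structures.

    Defaults reproduce the restraint peak-frequency conditions: slope
    0.333 Hz per unit ln-concentration, intercept 3.36 Hz, and a single
    reported random-intercept SD of 0.384 under the concentration +
    (concentration, individual) structure (model 6).  The one SD is placed
    on the (concentration, individual) term with the concentration-level
    component at zero — the configuration a fit reports as a single SD,
    the dose-level variance sitting at the boundary.  5 individuals per
    dose, 24 segments each.
    """

    beta0: float = 3.36
    beta1: float = 0.333
    sd_by_C: float = 0.0
    sd_by_j: float = 0.0
    sd_by_Cj: float = 0.384
    residual_sd: float = 0.8
    doses: tuple[float, ...] = DOSES_MG_PER_L
    n_individuals_per_dose: int = 5
    n_segments: int = 24
    generating_model_id: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        terms = LMMSpec(self.generating_model_id).random_terms
        active = {"C": self.sd_by_C, "j": self.sd_by_j, "Cj": self.sd_by_Cj}
        for name, sd in active.items():
            if sd < 0:
                raise SpecError("random-effect SDs must be nonnegative")
            if name not in terms and sd != 0:
                raise SpecError(
                    f"sd_by_{name}={sd} but model {self.generating_model_id} "
                    f"has no {name} term (set it to 0)"
                )


def gen_cohort_indices(spec: CohortSimSpec) -> tuple[pd.DataFrame, dict]:
    """Draw a per-segment index table from the generating mixed model.

    Returns a tidy table with columns ``individual_id``,
    ``concentration_mg_per_l``, ``segment``, ``value`` (one row per dose x
    individual x segment; 5 x 24 x 4 doses = 480 rows, 120 per dose at the
    defaults) and the truth dict of generating parameters and drawn
    random intercepts.
    """
    rng = np.random.default_rng(spec.seed)
    terms = LMMSpec(spec.generating_model_id).random_terms
    b_C = {d: (spec.sd_by_C * rng.standard_normal() if "C" in terms else 0.0) for d in spec.doses}
    rows = []
    b_j: dict[str, float] = {}
    b_Cj: dict[str, float] = {}
    for d in spec.doses:
        C = log_concentration(d)
        for i in range(spec.n_individuals_per_dose):
            ind = f"d{d:g}_i{i}"
            b_j[ind] = spec.sd_by_j * rng.standard_normal() if "j" in terms else 0.0
            b_Cj[ind] = spec.sd_by_Cj * rng.standard_normal() if "Cj" in terms else 0.0
            eps = spec.residual_sd * rng.standard_normal(spec.n_segments)
            vals = spec.beta1 * C + spec.beta0 + b_C[d] + b_j[ind] + b_Cj[ind] + eps
            for s, v in enumerate(vals):
                rows.append(
                    {
                        "individual_id": ind,
                        "concentration_mg_per_l": d,
                        "segment": s,
                        "value": v,
                    }
                )
    table = pd.DataFrame(rows)
    truth = {
        "beta0": spec.beta0,
        "beta1": spec.beta1,
        "sd_by_C": spec.sd_by_C,
        "sd_by_j": spec.sd_by_j,
        "sd_by_Cj": spec.sd_by_Cj,
        "residual_sd": spec.residual_sd,
        "b_C": b_C,
        "b_j": b_j,
        "b_Cj": b_Cj,
        "generating_model_id": spec.generating_model_id,
    }
    return table, truth


def gen_restraint_cohort(
    seed: int = 0,
    duration_s: float = 120.0,
    n_per_dose: int = 5,
    doses: tuple[float, ...] = DOSES_MG_PER_L,
    exclude_one_50: bool = True,
    vent_beta: tuple[float, float] = (3.36, 0.333),
    vent_sd: float = 0.384,
    hr_beta: tuple[float, float] = (2.26, -0.0529),
    hr_sd: float = 0.15,
    vent_interval_cv: float = 0.1,
    beat_cv: float = 0.2,
):
    """Synthesize a full restraint cohort at the study design.

    Per-individual true ventilatory frequency and heart rate are drawn from
    dose-effect lines at the published restraint scales (ventilation: 3.36 +
    0.333 C with individual SD 0.384; heart rate: 2.26 - 0.0529 C), clipped
    to the observed physiological ranges (ventilation 1-6 Hz, heart rate
    1-4 beats/s).  Each individual gets a 100 fps optical ventilatory
    recording and a 1 kHz ECG.  When ``exclude_one_50`` is set, one
    individual of the 50 mg/L group is flagged as not surviving 72 h,
    mirroring the study's exclusion (96 instead of 120 segments for that
    dose).

    Returns ``(recordings, metadata, truth)`` where recordings maps
    individual_id to ``{"ventilatory": Recording, "ecg": Recording}``.
    """
    from .io import RESTRAINT_VIDEO_FPS, CohortMetadata

    rng = np.random.default_rng(seed)
    recordings: dict = {}
    meta: list = []
    truth: dict = {"individuals": {}}
    for d in doses:
        C = log_concentration(d)
        for i in range(n_per_dose):
            iid = f"r{d:g}_{i}"
            f_vent = float(np.clip(vent_beta[0] + vent_beta[1] * C + vent_sd * rng.standard_normal(), 1.2, 6.0))
            hr = float(np.clip(hr_beta[0] + hr_beta[1] * C + hr_sd * rng.standard_normal(), 1.2, 3.8))
            vrec, vtruth = gen_ventilatory(
                VentilatorySimSpec(
                    mean_freq_hz=f_vent, interval_cv=vent_interval_cv,
                    duration_s=duration_s, rate_hz=RESTRAINT_VIDEO_FPS,
                    seed=int(rng.integers(2**31)),
                )
            )
            erec, etruth = gen_ecg(
                EcgSimSpec(
                    rate_bps=hr, beat_cv=beat_cv, duration_s=duration_s,
                    seed=int(rng.integers(2**31)),
                )
            )
            recordings[iid] = {"ventilatory": vrec, "ecg": erec}
            survived = not (exclude_one_50 and d == 50.0 and i == n_per_dose - 1)
            meta.append(CohortMetadata(iid, d, "restraint", survived_72h=survived))
            truth["individuals"][iid] = {
                "vent_freq_hz": f_vent, "heart_rate_bps": hr,
                "vent_truth": vtruth, "ecg_truth": etruth,
            }
    truth["vent_beta"] = vent_beta
    truth["hr_beta"] = hr_beta
    return recordings, meta, truth


def gen_freeswim_cohort(
    seed: int = 0,
    duration_s: float = 120.0,
    n_per_dose: int = 5,
    doses: tuple[float, ...] = DOSES_MG_PER_L,
    vent_beta: tuple[float, float] = (2.41, 0.160),
    vent_sd: float = 0.0409,
    speed_by_dose: tuple[float, ...] = (10.1, 23.7, 3.95, 2.0),
    speed_sd: float = 7.53,
    vent_interval_cv: float = 0.05,
    attenuation_scale_mm: float = 30.0,
    noise_sd: float = 0.05,
    grid: ElectrodeGrid | None = None,
):
    """Synthesize a full free-swimming cohort at the study design.

    Each individual gets a correlated-random-walk trajectory whose mean
    speed follows the published rise-then-fall dose profile: the 0-1 mg/L
    section line gives 10.1 and 23.7 mm/s at doses 0 and 1 (stimulant
    effect), and the 1-100 mg/L line (27.7 - 6.04 C) gives ~3.95 mm/s at
    50 mg/L and a floor of 2 mm/s at 100 mg/L (anxiogenic slowing, the
    line itself dropping below zero there).  Ventilation uses a
    quasi-periodic source
    at the free-swimming dose-effect scale (2.41 + 0.160 C), and a
    126-channel array recording with exponential distance attenuation.

    Returns ``(recordings, trajectories, metadata, truth)``.
    """
    from .io import CohortMetadata
    from .kinematics import default_grid as _default_grid

    rng = np.random.default_rng(seed)
    grid = grid or _default_grid()
    recordings: dict = {}
    trajectories: dict = {}
    meta: list = []
    truth: dict = {"individuals": {}}
    for d, sp in zip(doses, speed_by_dose):
        C = log_concentration(d)
        for i in range(n_per_dose):
            iid = f"f{d:g}_{i}"
            f_vent = float(np.clip(vent_beta[0] + vent_beta[1] * C + vent_sd * rng.standard_normal(), 1.2, 6.0))
            speed = float(np.clip(sp + speed_sd * rng.standard_normal(), 2.0, 60.0))
            traj = gen_trajectory(
                duration_s=duration_s, mean_speed_mm_s=speed,
                seed=int(rng.integers(2**31)),
            )
            src, vtruth = gen_ventilatory(
                VentilatorySimSpec(
                    mean_freq_hz=f_vent, interval_cv=vent_interval_cv,
                    duration_s=duration_s, seed=int(rng.integers(2**31)),
                )
            )
            rec = gen_array_recording(
                traj, src, grid, attenuation_scale_mm=attenuation_scale_mm,
                noise_sd=noise_sd, seed=int(rng.integers(2**31)),
            )
            recordings[iid] = rec
            trajectories[iid] = traj
            meta.append(CohortMetadata(iid, d, "free_swimming"))
            truth["individuals"][iid] = {
                "vent_freq_hz": f_vent, "mean_speed_mm_s": speed, "vent_truth": vtruth,
            }
    truth["vent_beta"] = vent_beta
    truth["speed_by_dose"] = dict(zip(doses, speed_by_dose))
    return recordings, trajectories, meta, truth
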