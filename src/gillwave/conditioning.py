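"""Bandpass filtering, segmentation, and amplitude standardization.

Every signal entering the analysis passes through the same three-step
conditioning chain: a zero-phase 3rd-order Butterworth bandpass (1–10 Hz
for ventilatory signals, 5–120 Hz for ECG), division into consecutive
non-overlapping 5-s segments, and per-segment z-scoring.  Zero-phase
(forward–backward) filtering is used so that peak times, which feed the
interval-variability statistics, are not displaced by filter group delay;
the effective magnitude response is the square of the single-pass design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import signal as _signal

from .errors import DegenerateSegmentError, SpecError

DEFAULT_FILTER_ORDER = 3
DEFAULT_SEGMENT_S = 5.0


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth bandpass specification (order, passband edges in Hz)."""

    order: int = DEFAULT_FILTER_ORDER
    low_hz: float = 1.0
    high_hz: float = 10.0

    def __post_init__(self) -> None:
        if self.order < 1:
            raise SpecError("filter order must be >= 1")
        if not 0 < self.low_hz < self.high_hz:
            raise SpecError("need 0 < low_hz < high_hz")

    def validate_for_rate(self, rate_hz: float) -> None:
        if self.high_hz >= rate_hz / 2:
            raise SpecError(
                f"high cutoff {self.high_hz} Hz >= Nyquist ({rate_hz / 2} Hz); "
                "e.g. the 120 Hz ECG cutoff needs a 1 kHz sampling rate"
            )


#: ventilatory passband (both optical under restraint and array channels)
VENTILATORY_FILTER = FilterSpec(order=3, low_hz=1.0, high_hz=10.0)
#: ECG passband (retains the sharp R wave, drops baseline wander)
ECG_FILTER = FilterSpec(order=3, low_hz=5.0, high_hz=120.0)


@dataclass
class Segment:
    """One fixed-length window of one conditioned channel.

    ``provenance`` carries (individual_id, concentration, condition, role)
    so that per-segment indices can be assembled into the cohort table.
    """

    values: np.ndarray
    rate_hz: float
    index: int = 0
    length_s: float = DEFAULT_SEGMENT_S
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = round(self.length_s * self.rate_hz)
        if len(self.values) != expected:
            raise SpecError(
                f"segment has {len(self.values)} samples, expected {expected} "
                f"({self.length_s} s at {self.rate_hz} Hz)"
            )

    @property
    def start_time_s(self) -> float:
        return self.index * self.length_s


def bandpass(x: np.ndarray, rate_hz: float, spec: FilterSpec) -> np.ndarray:
    """Zero-phase Butterworth bandpass; output length equals input length."""
    x = np.asarray(x, dtype=float)
    spec.validate_for_rate(rate_hz)
    min_len = 3 * (2 * spec.order + 1)
    if len(x) <= min_len:
        raise SpecError(f"signal too short to filter stably (need > {min_len} samples)")
    sos = _signal.butter(
        spec.order, [spec.low_hz, spec.high_hz], btype="bandpass", fs=rate_hz, output="sos"
    )
    return _signal.sosfiltfilt(sos, x)


def segment_signal(
    x: np.ndarray,
    rate_hz: float,
    length_s: float = DEFAULT_SEGMENT_S,
    provenance: dict[str, Any] | None = None,
) -> list[Segment]:
    """Divide a signal into consecutive non-overlapping fixed-length windows.

    Windows start at t = 0; an incomplete trailing window is discarded
    (120 s at any rate with 5-s windows yields exactly 24 segments).
    Returns an empty list if the signal is shorter than one window.
    """
    x = np.asarray(x, dtype=float)
    n_win = int(round(length_s * rate_hz))
    k = len(x) // n_win
    prov = provenance or {}
    return [
        Segment(
            values=x[i * n_win : (i + 1) * n_win],
            rate_hz=rate_hz,
            index=i,
            length_s=length_s,
            provenance=dict(prov),
        )
        for i in range(k)
    ]


def standardize(seg: Segment) -> Segment:
    """Z-score a segment (mean 0, sample SD 1).

    Raises
    ------
    DegenerateSegmentError
        If the segment is (near-)constant; the pipeline marks such segments
        invalid rather than propagating NaNs.
    """
    sd = float(np.std(seg.values, ddof=1))
    if sd <= 1e-12:
        raise DegenerateSegmentError(
            f"segment {seg.index} is (near-)constant, cannot standardize"
        )
    z = (seg.values - seg.values.mean()) / sd
    return Segment(
        values=z,
        rate_hz=seg.rate_hz,
        index=seg.index,
        length_s=seg.length_s,
        provenance=dict(seg.provenance),
    )
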