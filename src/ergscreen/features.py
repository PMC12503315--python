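"""Component amplitude extraction from averaged ERG waveforms.

Measurement conventions on a baseline-corrected trace (baseline = 0):

* a-wave: baseline to the negative trough inside the a-window
  (reported as a non-negative magnitude);
* b-wave: a-trough to the positive peak inside the b-window;
* c-wave (scotopic only): baseline to the peak after the b-peak;
* FO-like wave (scotopic only): c-peak to the subsequent trough.

Extrema are located on the raw averaged samples without smoothing;
ties break to the earliest time point. Search windows are closed
intervals in ms post-stimulus and are user-configurable — defaults are
package choices consistent with standard mouse ERG timing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .waveform_io import ERGTrace

__all__ = [
    "ComponentWindows",
    "ComponentAmplitudes",
    "DEFAULT_WINDOWS",
    "SCOTOPIC_PARAMETERS",
    "PHOTOPIC_PARAMETERS",
    "extract_components",
    "extract_cohort_components",
    "measure_latencies",
]

SCOTOPIC_PARAMETERS = ("a", "b", "c", "fo")
PHOTOPIC_PARAMETERS = ("a", "b")


class ExtractionError(ValueError):
    """A component window is empty after landmark-ordering constraints."""


@dataclass(frozen=True)
class ComponentWindows:
    """Closed search intervals [start_ms, end_ms] post-stimulus."""

    scotopic: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "a": (3.0, 60.0),
            "b": (15.0, 250.0),
            "c": (400.0, 3500.0),
            "fo": (400.0, 5000.0),
        }
    )
    photopic: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "a": (3.0, 30.0),
            "b": (15.0, 100.0),
        }
    )

    def for_condition(self, condition: str) -> Mapping[str, tuple[float, float]]:
        return getattr(self, condition)


DEFAULT_WINDOWS = ComponentWindows()


@dataclass
class ComponentAmplitudes:
    """Extracted amplitudes (µV) and landmark times (ms) for one unit."""

    mouse_id: str
    eye: str
    condition: str
    amplitudes: dict[str, float]
    landmarks_ms: dict[str, float]

    def to_rows(self) -> list[dict]:
        params = (
            SCOTOPIC_PARAMETERS if self.condition == "scotopic"
            else PHOTOPIC_PARAMETERS
        )
        return [
            {
                "mouse_id": self.mouse_id,
                "eye": self.eye,
                "condition": self.condition,
                "parameter": p,
                "amplitude_uV": self.amplitudes.get(p, np.nan),
                "landmark_ms": self.landmarks_ms.get(p, np.nan),
            }
            for p in params
        ]


def _window_extremum(
    times: np.ndarray,
    samples: np.ndarray,
    window: tuple[float, float],
    after_ms: float | None,
    find: str,
) -> tuple[float, float]:
    """Return (time_ms, value) of the windowed min/max; earliest tie wins."""
    mask = (times >= window[0] - 1e-9) & (times <= window[1] + 1e-9)
    if after_ms is not None:
        mask &= times > after_ms
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ExtractionError(
            f"empty {find} window {window} after t > {after_ms}"
        )
    sub = samples[idx]
    local = int(np.argmin(sub) if find == "min" else np.argmax(sub))
    j = idx[local]
    return float(times[j]), float(samples[j])


def extract_components(
    avg_trace: ERGTrace,
    windows: ComponentWindows = DEFAULT_WINDOWS,
) -> ComponentAmplitudes:
    """Extract component amplitudes from a baseline-corrected average.

    A component whose search window is empty after the landmark-ordering
    constraints is recorded as missing (NaN) rather than failing the
    whole trace.
    """
    times = avg_trace.times_ms()
    samples = avg_trace.samples
    win = windows.for_condition(avg_trace.condition)

    amplitudes: dict[str, float] = {}
    landmarks: dict[str, float] = {}

    # a-wave: baseline to trough; clipped at 0 if the trace never dips
    t_a, v_a = _window_extremum(times, samples, win["a"], None, "min")
    amplitudes["a"] = max(0.0, -v_a)
    landmarks["a"] = t_a

    # b-wave: a-trough to peak, searched after the trough
    try:
        t_b, v_b = _window_extremum(times, samples, win["b"], t_a, "max")
        amplitudes["b"] = max(0.0, v_b - v_a)
        landmarks["b"] = t_b
    except ExtractionError:
        amplitudes["b"] = np.nan
        landmarks["b"] = np.nan
        t_b = None

    if avg_trace.condition == "scotopic":
        # c-wave: baseline to peak after the b-peak
        t_c = v_c = None
        try:
            if t_b is None:
                raise ExtractionError("no b-peak landmark")
            t_c, v_c = _window_extremum(times, samples, win["c"], t_b, "max")
            amplitudes["c"] = v_c
            landmarks["c"] = t_c
        except ExtractionError:
            amplitudes["c"] = np.nan
            landmarks["c"] = np.nan
        # FO-like: c-peak to subsequent trough
        try:
            if t_c is None:
                raise ExtractionError("no c-peak landmark")
            t_fo, v_fo = _window_extremum(times, samples, win["fo"], t_c, "min")
            amplitudes["fo"] = max(0.0, v_c - v_fo)
            landmarks["fo"] = t_fo
        except ExtractionError:
            amplitudes["fo"] = np.nan
            landmarks["fo"] = np.nan

    return ComponentAmplitudes(
        mouse_id=avg_trace.mouse_id,
        eye=avg_trace.eye,
        condition=avg_trace.condition,
        amplitudes=amplitudes,
        landmarks_ms=landmarks,
    )


def extract_cohort_components(
    averaged_traces: Sequence[ERGTrace],
    windows: ComponentWindows = DEFAULT_WINDOWS,
) -> pd.DataFrame:
    """Tidy amplitude table for a collection of averaged traces.

    Columns: mouse_id, eye, condition, parameter, amplitude_uV,
    landmark_ms.
    """
    rows: list[dict] = []
    for trace in averaged_traces:
        rows.extend(extract_components(trace, windows).to_rows())
    return pd.DataFrame(
        rows,
        columns=[
            "mouse_id", "eye", "condition", "parameter",
            "amplitude_uV", "landmark_ms",
        ],
    )


def measure_latencies(
    avg_trace: ERGTrace,
    windows: ComponentWindows = DEFAULT_WINDOWS,
) -> pd.DataFrame:
    """Landmark times for one averaged trace.

    Provided for completeness; latencies are excluded from the
    screening statistics.
    """
    comp = extract_components(avg_trace, windows)
    return pd.DataFrame(
        [
            {
                "mouse_id": comp.mouse_id,
                "eye": comp.eye,
                "condition": comp.condition,
                "parameter": p,
                "landmark_ms": t,
            }
            for p, t in comp.landmarks_ms.items()
        ]
    )
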