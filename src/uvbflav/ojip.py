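"""JIP-test analysis of fast fluorescence (OJIP) transients.

Landmarks of the fast rise: O is the minimum fluorescence of the
trace, K the fluorescence at 300 µs, J at 2 ms, P the maximum.  Two
double normalizations are computed per replicate:

    Vt = (Ft - F_O) / (F_P - F_O)     (O-P, "relative variable fluorescence")
    Wt = (Ft - F_O) / (F_J - F_O)     (O-J)

and treatment-minus-control difference kinetics

    dVt = mean Vt(treatment) - mean Vt(control)
    dWt = mean Wt(treatment) - mean Wt(control)

whose reads at 2 ms (delta-J, from dVt) and 300 µs (delta-K, from
dWt) diagnose acceptor-side QA(-) accumulation and donor-side
(oxygen-evolving complex) impairment respectively.

Landmark reads and grid alignment interpolate linearly in log10(time),
matching the logarithmic sampling of fast-kinetics fluorometers.
Group curves are means of per-replicate normalized curves (normalize
first, average second).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .trace import FluorTrace

T_K = 3e-4  # K step, 300 microseconds
T_J = 2e-3  # J step, 2 milliseconds


@dataclass(frozen=True)
class OjipLandmarks:
    """O/K/J/P landmark fluorescence values of one transient."""

    trace_id: str
    F_O: float
    F_K: float
    F_J: float
    F_P: float

    @property
    def is_valid(self) -> bool:
        """A transient with no variable fluorescence (F_P == F_O) is degenerate."""
        return self.F_P > self.F_O

    @property
    def v_j(self) -> float:
        """Relative variable fluorescence at the J step."""
        if not self.is_valid:
            raise ValueError("degenerate transient: F_P == F_O")
        return (self.F_J - self.F_O) / (self.F_P - self.F_O)


@dataclass
class NormalizedCurve:
    """A Vt or Wt curve on its time grid."""

    trace_id: str
    time_s: np.ndarray
    values: np.ndarray
    kind: str  # "Vt" or "Wt"

    def at(self, t: float) -> float:
        return _log_interp(self.time_s, self.values, t)


@dataclass
class DeltaCurve:
    """Treatment-minus-control difference of mean normalized curves."""

    time_s: np.ndarray
    values: np.ndarray
    kind: str  # "dVt" or "dWt"
    delta_j: float | None  # dVt at 2 ms (None for dWt curves)
    delta_k: float | None  # dWt at 300 us (None for dVt curves)

    def at(self, t: float) -> float:
        return _log_interp(self.time_s, self.values, t)


def _log_interp(time_s: np.ndarray, values: np.ndarray, t: float) -> float:
    """Linear interpolation in log10(time)."""
    if not (time_s[0] <= t <= time_s[-1]):
        raise ValueError(f"time {t} s outside the trace grid")
    return float(np.interp(np.log10(t), np.log10(time_s), values))


def extract_landmarks(trace: FluorTrace) -> OjipLandmarks:
    """Read O (minimum), K (300 µs), J (2 ms) and P (maximum).

    The trace must cover [300 µs, 2 ms] with at least 10 points; K and
    J are interpolated at their exact times (exact grid samples are
    returned unchanged by the interpolation).
    """
    if trace.time_s.size < 10:
        raise ValueError("trace too short: need >= 10 points")
    if not np.all(np.isfinite(trace.fluorescence)):
        raise ValueError("non-finite fluorescence values")
    if trace.time_s[0] > T_K or trace.time_s[-1] < T_J:
        raise ValueError("trace must cover [300 us, 2 ms]")
    return OjipLandmarks(
        trace_id=trace.sample_id,
        F_O=float(trace.fluorescence.min()),
        F_K=_log_interp(trace.time_s, trace.fluorescence, T_K),
        F_J=_log_interp(trace.time_s, trace.fluorescence, T_J),
        F_P=float(trace.fluorescence.max()),
    )


def landmark_table(traces: Sequence[FluorTrace]) -> pd.DataFrame:
    rows = []
    for tr in traces:
        lm = extract_landmarks(tr)
        rows.append(
            {
                "sample_id": tr.sample_id,
                "group": tr.group,
                "F_O": lm.F_O,
                "F_K": lm.F_K,
                "F_J": lm.F_J,
                "F_P": lm.F_P,
                "V_J": lm.v_j if lm.is_valid else np.nan,
                "valid": lm.is_valid,
            }
        )
    return pd.DataFrame(rows)


def normalize_vt(trace: FluorTrace, landmarks: OjipLandmarks | None = None) -> NormalizedCurve:
    """O-P double normalization: Vt = (Ft - F_O)/(F_P - F_O).

    Affine-invariant in the raw fluorescence; Vt(O) = 0, Vt(P) = 1.
    """
    lm = landmarks or extract_landmarks(trace)
    if lm.F_P == lm.F_O:
        raise ValueError("degenerate transient: F_P == F_O")
    return NormalizedCurve(
        trace_id=trace.sample_id,
        time_s=trace.time_s.copy(),
        values=(trace.fluorescence - lm.F_O) / (lm.F_P - lm.F_O),
        kind="Vt",
    )


def normalize_wt(trace: FluorTrace, landmarks: OjipLandmarks | None = None) -> NormalizedCurve:
    """O-J double normalization: Wt = (Ft - F_O)/(F_J - F_O); Wt(2 ms) = 1."""
    lm = landmarks or extract_landmarks(trace)
    if lm.F_J == lm.F_O:
        raise ValueError("degenerate transient: F_J == F_O")
    return NormalizedCurve(
        trace_id=trace.sample_id,
        time_s=trace.time_s.copy(),
        values=(trace.fluorescence - lm.F_O) / (lm.F_J - lm.F_O),
        kind="Wt",
    )


def _mean_curve(traces: Sequence[FluorTrace], kind: str, grid: np.ndarray) -> np.ndarray:
    normalize = normalize_vt if kind == "Vt" else normalize_wt
    stack = []
    for tr in traces:
        curve = normalize(tr)
        if curve.time_s.shape == grid.shape and np.allclose(curve.time_s, grid):
            stack.append(curve.values)
        else:
            if grid[0] < curve.time_s[0] or grid[-1] > curve.time_s[-1]:
                raise ValueError("trace grids do not cover a common range")
            stack.append(
                np.interp(np.log10(grid), np.log10(curve.time_s), curve.values)
            )
    return np.mean(stack, axis=0)


def delta_curves(
    treatment: Sequence[FluorTrace],
    control: Sequence[FluorTrace],
    kind: str = "Vt",
) -> DeltaCurve:
    """Difference kinetics: mean normalized treatment curve minus control.

    ``kind`` selects the normalization ("Vt" or "Wt").  Replicates are
    normalized individually, averaged per group on the control grid
    (log-time linear resampling when grids differ), then subtracted.
    delta_j (for Vt) is the difference at 2 ms; delta_k (for Wt) at
    300 µs.  Antisymmetric under swapping treatment and control.
    """
    if kind not in ("Vt", "Wt"):
        raise ValueError("kind must be 'Vt' or 'Wt'")
    if not treatment or not control:
        raise ValueError("both groups must be nonempty")
    grid = control[0].time_s.copy()
    diff = _mean_curve(treatment, kind, grid) - _mean_curve(control, kind, grid)
    delta_j = _log_interp(grid, diff, T_J) if kind == "Vt" else None
    delta_k = _log_interp(grid, diff, T_K) if kind == "Wt" else None
    return DeltaCurve(
        time_s=grid,
        values=diff,
        kind="d" + kind,
        delta_j=delta_j,
        delta_k=delta_k,
    )
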