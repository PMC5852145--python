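"""Raw-trace preprocessing: 1 Hz decimation, step-artifact repair, noise s.d.

Raw growth-cone recordings carry three kinds of noise: single-sample spikes,
step-like offsets from the recording apparatus, and small white observation
noise.  Spikes are removed implicitly by decimating to the 1 s grid, steps by
linear complementation across an annotated (or detected) window, and the white
component is quantified per series as sigma_i for use in the likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "RawTrace",
    "MpTimeSeries",
    "StepArtifact",
    "downsample_to_1hz",
    "correct_step_artifacts",
    "detect_step_artifacts",
    "smooth_trace",
    "estimate_noise_sd",
    "preprocess_trace",
]

DEFAULT_SMOOTH_WINDOW = 31


@dataclass
class RawTrace:
    times: np.ndarray
    values: np.ndarray
    series_id: str = ""
    condition_label: str = "control"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if len(self.times) >= 2 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class MpTimeSeries:
    """Preprocessed potential trace on a uniform 1 s grid."""

    series_id: str
    condition_label: str
    values: np.ndarray
    sigma_i: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def T_i(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.T_i, dtype=float)

    def replace(self, **kw) -> "MpTimeSeries":
        return replace(self, **kw)


@dataclass(frozen=True)
class StepArtifact:
    onset_index: int
    end_index: int
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.onset_index >= self.end_index:
            raise ValueError("onset_index must be < end_index")


def downsample_to_1hz(raw: RawTrace) -> MpTimeSeries:
    """Decimate to one sample per integer second (nearest raw sample).

    Single-sample spikes falling between grid seconds are dropped by
    construction rather than filtered.
    """
    if len(raw.times) < 2 or raw.times[-1] - raw.times[0] < 2.0:
        raise ValueError("raw trace must span at least 2 s")
    t0 = np.ceil(raw.times[0])
    grid = np.arange(t0, np.floor(raw.times[-1]) + 0.5, 1.0)
    idx = np.searchsorted(raw.times, grid)
    idx = np.clip(idx, 1, len(raw.times) - 1)
    left_closer = (grid - raw.times[idx - 1]) <= (raw.times[idx] - grid)
    nearest = np.where(left_closer, idx - 1, idx)
    return MpTimeSeries(
        series_id=raw.series_id,
        condition_label=raw.condition_label,
        values=raw.values[nearest],
    )


def detect_step_artifacts(
    series: MpTimeSeries,
    jump_mv: float = 5.0,
    mad_factor: float = 6.0,
    persist_s: int = 10,
) -> list[StepArtifact]:
    """Flag indices whose first difference is an outlier with a lasting offset.

    A jump qualifies when |dV| exceeds max(jump_mv, mad_factor * MAD of all
    first differences) and the median level over the following persist_s
    seconds stays displaced by more than half the jump.
    """
    v = series.values
    if len(v) < persist_s + 2:
        return []
    dv = np.diff(v)
    mad = np.median(np.abs(dv - np.median(dv)))
    thresh = max(jump_mv, mad_factor * 1.4826 * mad)
    out: list[StepArtifact] = []
    last_end = -1
    for j in np.flatnonzero(np.abs(dv) > thresh):
        if j <= last_end or j + 1 + persist_s > len(v):
            continue
        before = np.median(v[max(0, j - persist_s): j + 1])
        after = np.median(v[j + 1: j + 1 + persist_s])
        if abs(after - before) > 0.5 * abs(dv[j]):
            out.append(StepArtifact(onset_index=int(j), end_index=int(j + 1), offset=float(dv[j])))
            last_end = j + 1
    return out


def _step_height(v: np.ndarray, before: np.ndarray, after: np.ndarray) -> float:
    """Level change across a transition, from a joint piecewise fit.

    Regresses the side-window samples on a shared quadratic trend plus an
    after-dummy; the dummy coefficient is the step height.  Pooling both
    sides under one trend keeps the estimator variance far below that of
    extrapolating separate side fits, and the quadratic term absorbs signal
    curvature during transients.
    """
    if len(before) == 0 or len(after) == 0:
        return 0.0
    idx = np.concatenate([before, after])
    if len(idx) < 4:
        return float(v[after[0]] - v[before[-1]])
    t = idx.astype(float) - idx.mean()
    X = np.column_stack([
        np.ones(len(idx)),
        t,
        t * t,
        np.concatenate([np.zeros(len(before)), np.ones(len(after))]),
    ])
    coef, *_ = np.linalg.lstsq(X, v[idx], rcond=None)
    return float(coef[3])


def correct_step_artifacts(
    series: MpTimeSeries,
    annotations: list[StepArtifact] | None = None,
    auto_detect: bool = False,
    side_points: int = 60,
) -> MpTimeSeries:
    """Remove step artifacts by complementing each window with a straight line.

    Each annotation window [onset, end] should span one level transition.  The
    step height is estimated from side_points samples on each side of the
    window (see _step_height) — single-sample endpoint differences would
    shift the whole tail by an observation-noise-sized error.  The height is
    subtracted from everything at and after ``end`` and the window interior
    is bridged by the line joining the corrected endpoints.  Applying the
    same annotations twice is a no-op.
    """
    if annotations is None:
        annotations = detect_step_artifacts(series) if auto_detect else []
    if not annotations:
        return series.replace(values=series.values.copy())
    anns = sorted(annotations, key=lambda a: a.onset_index)
    for a, b in zip(anns, anns[1:]):
        if b.onset_index < a.end_index:
            raise ValueError("overlapping step-artifact annotations")
    v = series.values.copy()
    n = len(v)
    for k, a in enumerate(anns):
        if a.onset_index < 0 or a.end_index >= n:
            raise ValueError("annotation outside series range")
        # side windows must not reach into a neighboring transition
        lo = max(0, a.onset_index - side_points + 1)
        if k > 0:
            lo = max(lo, anns[k - 1].end_index + 1)
        hi = min(n, a.end_index + side_points)
        if k + 1 < len(anns):
            hi = min(hi, anns[k + 1].onset_index)
        before = np.arange(lo, a.onset_index + 1)
        after = np.arange(a.end_index, hi)
        h = _step_height(v, before, after)
        v[a.end_index:] -= h
        span = a.end_index - a.onset_index
        if span > 1:
            interior = np.arange(a.onset_index + 1, a.end_index)
            frac = (interior - a.onset_index) / span
            v[interior] = v[a.onset_index] + frac * (v[a.end_index] - v[a.onset_index])
    return series.replace(values=v)


def smooth_trace(series: MpTimeSeries, window_s: int = DEFAULT_SMOOTH_WINDOW) -> np.ndarray:
    """Centered moving average; the window shrinks symmetrically at the edges."""
    if window_s < 3 or window_s % 2 == 0:
        raise ValueError("window_s must be an odd integer >= 3")
    v = series.values
    n = len(v)
    if window_s > n:
        raise ValueError("smoothing window larger than series")
    half = window_s // 2
    csum = np.concatenate([[0.0], np.cumsum(v)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half, n - 1)
    # shrink symmetrically so the window stays centered near the edges
    reach = np.minimum(np.arange(n) - lo, hi - np.arange(n))
    lo = np.arange(n) - reach
    hi = np.arange(n) + reach
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def estimate_noise_sd(series: MpTimeSeries, window_s: int = DEFAULT_SMOOTH_WINDOW) -> float:
    """Observation-noise s.d. from residuals against the smoothed trace."""
    resid = series.values - smooth_trace(series, window_s)
    return float(np.std(resid, ddof=1))


def preprocess_trace(
    raw: RawTrace,
    annotations: list[StepArtifact] | None = None,
    auto_detect_steps: bool = True,
    window_s: int = DEFAULT_SMOOTH_WINDOW,
) -> MpTimeSeries:
    """Full pipeline: decimate, repair steps, attach sigma_i."""
    series = downsample_to_1hz(raw)
    series = correct_step_artifacts(series, annotations, auto_detect=auto_detect_steps)
    return series.replace(sigma_i=estimate_noise_sd(series, window_s))
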