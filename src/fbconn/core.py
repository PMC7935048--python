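"""Activity-domain to connectivity-domain transforms.

Sliding-window Pearson correlation (SWPC) estimates time-varying
connectivity between two series by correlating them inside a rectangular
window of length ``2*half_width + 1`` centred on each time point.  Writing
the windowed correlation as a convolution of a rectangular kernel with the
per-sample normalized product trajectory

    w(t) = z_x(t) * z_y(t),   z(t) = (x(t) - mu(t)) / sigma(t),

where ``mu``/``sigma`` are windowed moments, shows that SWPC is a low-pass
filter acting on ``w``.  This module computes the windowed moments, the
trajectory ``w(t)`` for every component pair, SWPC itself (both the exact
per-window Pearson form and the moving-average convolution form), and the
static whole-recording connectivity matrix.

Conventions
-----------
* Time indexing is 0-based.  A trajectory sample at index ``t`` corresponds
  to activity sample ``t + half_width``; multiply by the sampling interval
  (``tr_seconds``) to convert to seconds.
* Edge policy is valid-support truncation: no padding of the activity
  series, so a window of length ``L = 2*half_width + 1`` over ``T`` samples
  yields ``T - L + 1`` trajectory samples.
* Component pairs are ordered lexicographically, ``(i, j)`` with ``i < j``.
* A window with zero variance yields a missing value (NaN) at that sample
  and a logged warning, never a hard failure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("fbconn")

__all__ = [
    "ComponentTimeSeries",
    "WindowSpec",
    "WindowedMoments",
    "PairProductTrajectory",
    "SwpcTrajectory",
    "StaticFncMatrix",
    "pair_order",
    "pair_labels",
    "windowed_moments",
    "pair_product_trajectory",
    "swpc",
    "swpc_via_convolution",
    "static_fnc",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowSpec:
    """Rectangular window of length ``2*half_width + 1`` samples."""

    half_width: int

    def __post_init__(self) -> None:
        if int(self.half_width) != self.half_width or self.half_width < 1:
            raise ValueError(f"half_width must be a positive integer, got {self.half_width!r}")
        object.__setattr__(self, "half_width", int(self.half_width))

    @property
    def window_length(self) -> int:
        return 2 * self.half_width + 1

    @classmethod
    def from_window_length(cls, length: int) -> "WindowSpec":
        if length % 2 == 0 or length < 3:
            raise ValueError(
                f"window length must be odd and >= 3 so it centres on a sample; got {length}"
            )
        return cls(half_width=(length - 1) // 2)


@dataclass
class ComponentTimeSeries:
    """One subject's time x component activity matrix with sampling interval."""

    values: np.ndarray          # shape (T, C)
    tr_seconds: float
    component_ids: list[str] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"values must be a 2-D time x component matrix, got shape {self.values.shape}")
        if self.values.shape[0] < 2:
            raise ValueError(f"need at least 2 time points, got {self.values.shape[0]}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("component time series contain non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError(f"tr_seconds must be positive, got {self.tr_seconds}")
        if not self.component_ids:
            self.component_ids = [f"c{i}" for i in range(self.values.shape[1])]
        if len(self.component_ids) != self.values.shape[1]:
            raise ValueError("component_ids length does not match number of columns")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_components(self) -> int:
        return self.values.shape[1]

    @property
    def sampling_hz(self) -> float:
        return 1.0 / self.tr_seconds


@dataclass
class WindowedMoments:
    """Per-sample windowed mean and (population-form) standard deviation."""

    mean: np.ndarray
    sd: np.ndarray
    window: WindowSpec
    valid_range: tuple[int, int]    # inclusive activity-sample indices


@dataclass
class PairProductTrajectory:
    """w(t) for every component pair: the raw connectivity-domain signal."""

    values: np.ndarray              # shape (T - 2*half_width, P)
    pair_index: list[tuple[int, int]]
    window: WindowSpec
    time_offset: int                # trajectory sample t -> activity sample t + time_offset
    tr_seconds: float
    component_ids: list[str] = field(default_factory=list)
    subject_id: str = ""

    @property
    def n_pairs(self) -> int:
        return self.values.shape[1]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def sampling_hz(self) -> float:
        return 1.0 / self.tr_seconds

    def times_seconds(self) -> np.ndarray:
        return (np.arange(self.n_samples) + self.time_offset) * self.tr_seconds


@dataclass
class SwpcTrajectory:
    """Sliding-window Pearson correlation trajectories for every pair."""

    values: np.ndarray
    pair_index: list[tuple[int, int]]
    window: WindowSpec
    method: str                     # "direct" | "convolution"
    time_offset: int
    tr_seconds: float
    component_ids: list[str] = field(default_factory=list)
    subject_id: str = ""

    @property
    def n_pairs(self) -> int:
        return self.values.shape[1]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def times_seconds(self) -> np.ndarray:
        return (np.arange(self.n_samples) + self.time_offset) * self.tr_seconds


@dataclass
class StaticFncMatrix:
    """Whole-recording Pearson correlation matrix (static FNC)."""

    values: np.ndarray              # symmetric C x C, unit diagonal
    component_ids: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Pair ordering
# ---------------------------------------------------------------------------

def pair_order(n_components: int) -> list[tuple[int, int]]:
    """Deterministic pair ordering: (i, j), i < j, lexicographic."""
    iu, ju = np.triu_indices(n_components, k=1)
    return list(zip(iu.tolist(), ju.tolist()))


def pair_labels(component_ids: list[str]) -> list[str]:
    return [f"{component_ids[i]}_{component_ids[j]}" for i, j in pair_order(len(component_ids))]


# ---------------------------------------------------------------------------
# Windowed moments
# ---------------------------------------------------------------------------

def _check_window(win: WindowSpec, n_timepoints: int) -> None:
    if win.window_length > n_timepoints:
        raise ValueError(
            f"window of {win.window_length} samples does not fit a series of "
            f"{n_timepoints} samples"
        )


def _moving_average(x: np.ndarray, length: int) -> np.ndarray:
    """Valid-mode moving average along axis 0 (exact direct summation)."""
    kernel = np.ones(length) / length
    if x.ndim == 1:
        return np.convolve(x, kernel, mode="valid")
    return np.apply_along_axis(lambda col: np.convolve(col, kernel, mode="valid"), 0, x)


def windowed_moments(x: np.ndarray, win: WindowSpec) -> WindowedMoments:
    """Windowed sample mean and standard deviation of a 1-D series.

    The mean at activity sample ``t`` averages ``x`` over ``[t - hw, t + hw]``;
    the standard deviation is the square root of the windowed average squared
    deviation (population form, divisor ``2*hw + 1``).  Both are defined only
    on the valid range ``[hw, T - 1 - hw]``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("windowed_moments expects a 1-D series")
    _check_window(win, x.shape[0])
    length = win.window_length
    # centring by the global mean keeps the two-pass variance formula from
    # cancelling catastrophically (a constant series must give sd exactly 0)
    shift = x.mean()
    xc = x - shift
    mean_c = _moving_average(xc, length)
    m2 = _moving_average(xc * xc, length)
    var = np.maximum(m2 - mean_c * mean_c, 0.0)
    return WindowedMoments(
        mean=mean_c + shift,
        sd=np.sqrt(var),
        window=win,
        valid_range=(win.half_width, x.shape[0] - 1 - win.half_width),
    )


# ---------------------------------------------------------------------------
# Pair product trajectory w(t)
# ---------------------------------------------------------------------------

def pair_product_trajectory(X: ComponentTimeSeries, win: WindowSpec) -> PairProductTrajectory:
    """Per-sample normalized product w(t) for every component pair.

    Each component is z-scored per sample against its own windowed moments;
    ``w`` for pair (i, j) is the product of the two z-scores.  Samples whose
    window has zero variance yield NaN (with a warning); a constant component
    therefore produces all-NaN trajectories for its pairs.
    """
    if X.n_components < 2:
        raise ValueError("need at least 2 components to form pairs")
    _check_window(win, X.n_timepoints)
    hw = win.half_width
    T = X.n_timepoints

    length = win.window_length
    shift = X.values.mean(axis=0)
    xc = X.values - shift
    mean_c = _moving_average(xc, length)
    m2 = _moving_average(xc * xc, length)
    sd = np.sqrt(np.maximum(m2 - mean_c * mean_c, 0.0))
    mean = mean_c + shift

    centre = X.values[hw:T - hw]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (centre - mean) / sd, np.nan)

    n_degenerate = int(np.sum(sd == 0))
    if n_degenerate:
        logger.warning(
            "pair_product_trajectory: %d zero-variance window(s) for subject %r; "
            "emitting missing values", n_degenerate, X.subject_id,
        )

    pairs = pair_order(X.n_components)
    iu, ju = np.triu_indices(X.n_components, k=1)
    w = z[:, iu] * z[:, ju]
    return PairProductTrajectory(
        values=w,
        pair_index=pairs,
        window=win,
        time_offset=hw,
        tr_seconds=X.tr_seconds,
        component_ids=list(X.component_ids),
        subject_id=X.subject_id,
    )


# ---------------------------------------------------------------------------
# SWPC
# ---------------------------------------------------------------------------

def swpc(X: ComponentTimeSeries, win: WindowSpec) -> SwpcTrajectory:
    """Exact sliding-window Pearson correlation for every component pair.

    Each output sample is the sample Pearson correlation of the two series
    inside the window centred at that sample, guaranteed to lie in [-1, 1].
    Windows in which either series is constant yield NaN with a warning.
    """
    _check_window(win, X.n_timepoints)
    hw = win.half_width
    length = win.window_length
    vals = X.values - X.values.mean(axis=0)     # shift-invariant; tames cancellation
    pairs = pair_order(X.n_components)
    iu, ju = np.triu_indices(X.n_components, k=1)

    s1 = _moving_average(vals, length) * length
    s2 = _moving_average(vals * vals, length) * length
    sxy = _moving_average(vals[:, iu] * vals[:, ju], length) * length

    num = length * sxy - s1[:, iu] * s1[:, ju]
    varx = length * s2 - s1 * s1
    varx = np.maximum(varx, 0.0)
    den = np.sqrt(varx[:, iu] * varx[:, ju])

    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(den > 0, num / den, np.nan)
    n_degenerate = int(np.sum(den == 0))
    if n_degenerate:
        logger.warning(
            "swpc: %d zero-variance window(s) for subject %r; emitting missing values",
            n_degenerate, X.subject_id,
        )
    r = np.clip(r, -1.0, 1.0)
    return SwpcTrajectory(
        values=r,
        pair_index=pairs,
        window=win,
        method="direct",
        time_offset=hw,
        tr_seconds=X.tr_seconds,
        component_ids=list(X.component_ids),
        subject_id=X.subject_id,
    )


def swpc_via_convolution(w: PairProductTrajectory) -> SwpcTrajectory:
    """SWPC approximation as a normalized rectangular convolution of w(t).

    The rectangular kernel is normalized by ``1/(2*hw + 1)`` so the output is
    on the correlation scale.  Because ``w`` already lost ``hw`` samples at
    each edge, the valid support shrinks by a further ``hw`` per edge: the
    output sample at index ``t`` corresponds to activity sample ``t + 2*hw``.
    Missing values in ``w`` propagate through every window they touch.
    """
    hw = w.window.half_width
    _check_window(w.window, w.n_samples)
    out = _moving_average(w.values, w.window.window_length)
    return SwpcTrajectory(
        values=out,
        pair_index=list(w.pair_index),
        window=w.window,
        method="convolution",
        time_offset=w.time_offset + hw,
        tr_seconds=w.tr_seconds,
        component_ids=list(w.component_ids),
        subject_id=w.subject_id,
    )


# ---------------------------------------------------------------------------
# Static FNC
# ---------------------------------------------------------------------------

def static_fnc(X: ComponentTimeSeries) -> StaticFncMatrix:
    """Whole-recording Pearson correlation matrix across components."""
    if X.n_timepoints < 3:
        raise ValueError("static FNC needs at least 3 time points")
    sd = X.values.std(axis=0)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(X.values, rowvar=False)
    if np.any(degenerate):
        logger.warning(
            "static_fnc: %d zero-variance component(s) for subject %r; "
            "their rows/columns are missing", int(degenerate.sum()), X.subject_id,
        )
        corr[degenerate, :] = np.nan
        corr[:, degenerate] = np.nan
    ok = ~degenerate
    corr[np.ix_(ok, ok)] = np.clip(corr[np.ix_(ok, ok)], -1.0, 1.0)
    np.fill_diagonal(corr, np.where(degenerate, np.nan, 1.0))
    return StaticFncMatrix(values=corr, component_ids=list(X.component_ids))
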