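"""Raw plate-reader trace preprocessing.

Pipeline: absorbance -> concentration (Beer-Lambert), moving-average
smoothing, Ramer-Douglas-Peucker (RDP) thinning to a fixed point budget, and
optional lag-phase trimming. Traces are (time [min], NADH [mM]) series.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "EXTINCTION_COEFFICIENTS",
    "DEFAULT_PATHLENGTH_CM",
    "RawTrace",
    "Dataset",
    "DatasetSeries",
    "abs_to_conc",
    "moving_average",
    "rdp_thin",
    "auto_thin",
    "trim_lag_phase",
]

logger = logging.getLogger(__name__)

#: NADH extinction coefficients in 1/(mM cm) by wavelength (nm). The 340 nm
#: value is the canonical NADH coefficient; 390/400 nm extend the dynamic
#: range of the assay and were determined empirically.
EXTINCTION_COEFFICIENTS = {340: 6.220, 390: 0.4276, 400: 0.1205}

#: Optical pathlength of a 60 uL reaction in a 384-well plate (cm).
DEFAULT_PATHLENGTH_CM = 0.623


@dataclass(frozen=True)
class RawTrace:
    """An ordered time series of absorbance (AU) or concentration (mM)."""

    times: np.ndarray  # minutes, strictly increasing
    values: np.ndarray
    wavelength: Optional[int] = None  # nm; None once converted to mM
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1 or len(times) != len(values):
            raise ValueError("times and values must be 1-D and equal length")
        if len(times) >= 2 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class Dataset:
    """A filtered concentration trace plus its assay setup.

    ``init`` maps species ids to initial concentrations (mM); ``enzyme_conc``
    maps enzyme-level parameter names (e.g. ``E_fdh``) to concentrations.
    ``lag_min`` is the dead time between reaction start and the first
    measurement, in minutes (0 until estimated). ``observed`` names the
    measured species (NADH).
    """

    id: str
    trace: RawTrace
    init: dict
    enzyme_conc: dict = field(default_factory=dict)
    lag_min: float = 0.0
    observed: str = "Q"

    def model_times(self) -> np.ndarray:
        """Measurement times on the model clock (reaction start = 0)."""
        return self.trace.times + self.lag_min


@dataclass
class DatasetSeries:
    """A group of datasets fitted together under one kinetic model."""

    datasets: list
    model_tag: str
    kdq_range: Optional[tuple] = None  # (lo, hi) in 1/min

    def __post_init__(self) -> None:
        if not self.datasets:
            raise ValueError("a dataset series must contain at least one dataset")

    def __len__(self) -> int:
        return len(self.datasets)

    def __iter__(self):
        return iter(self.datasets)


def abs_to_conc(absorbance, wavelength: int, pathlength: float = DEFAULT_PATHLENGTH_CM):
    """Convert absorbance to NADH concentration (mM) via Beer-Lambert.

    conc = A / (epsilon(lambda) * pathlength), with epsilon in 1/(mM cm).
    """
    if wavelength not in EXTINCTION_COEFFICIENTS:
        raise ValueError(
            f"unknown wavelength {wavelength} nm; expected one of "
            f"{sorted(EXTINCTION_COEFFICIENTS)}"
        )
    if pathlength <= 0:
        raise ValueError(f"pathlength must be > 0 cm, got {pathlength!r}")
    a = np.asarray(absorbance, dtype=float)
    if np.any(~np.isfinite(a)) or np.any(a < 0):
        raise ValueError("absorbance must be finite and >= 0")
    out = a / (EXTINCTION_COEFFICIENTS[wavelength] * pathlength)
    return float(out) if np.isscalar(absorbance) else out


def moving_average(trace: RawTrace, window: int = 10) -> RawTrace:
    """Smooth a trace with a centered moving average, truncated at the ends.

    Point ``i`` is replaced by the mean over indices
    ``[i - floor((w-1)/2), i + floor(w/2)]`` intersected with the trace.
    Times are unchanged.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    n = len(trace)
    if window > n:
        raise ValueError(f"window {window} exceeds trace length {n}")
    if window == 1:
        return trace
    left = (window - 1) // 2
    right = window // 2
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - left)
        hi = min(n, i + right + 1)
        out[i] = trace.values[lo:hi].mean()
    return replace(trace, values=out)


def _minmax_scale(x: np.ndarray) -> np.ndarray:
    span = x.max() - x.min()
    if span == 0:
        return np.zeros_like(x)
    return (x - x.min()) / span


def _perp_distances(t: np.ndarray, v: np.ndarray, i0: int, i1: int) -> np.ndarray:
    """Perpendicular distance of points i0+1..i1-1 from the chord (i0, i1)."""
    p0 = np.array([t[i0], v[i0]])
    p1 = np.array([t[i1], v[i1]])
    chord = p1 - p0
    norm = np.hypot(*chord)
    pts = np.stack([t[i0 + 1:i1], v[i0 + 1:i1]], axis=1) - p0
    if norm == 0:
        return np.hypot(pts[:, 0], pts[:, 1])
    # |cross product| / |chord|
    return np.abs(pts[:, 0] * chord[1] - pts[:, 1] * chord[0]) / norm


def rdp_mask(times: np.ndarray, values: np.ndarray, epsilon: float) -> np.ndarray:
    """Boolean keep-mask of the RDP simplification of (times, values)."""
    n = len(times)
    keep = np.zeros(n, dtype=bool)
    keep[0] = keep[-1] = True
    stack = [(0, n - 1)]
    while stack:
        i0, i1 = stack.pop()
        if i1 - i0 < 2:
            continue
        d = _perp_distances(times, values, i0, i1)
        j = int(np.argmax(d))
        if d[j] > epsilon:
            split = i0 + 1 + j
            keep[split] = True
            stack.append((i0, split))
            stack.append((split, i1))
    return keep


def rdp_thin(trace: RawTrace, epsilon: float, normalize: bool = True) -> RawTrace:
    """Ramer-Douglas-Peucker polyline simplification of a trace.

    Keeps both endpoints; recursively keeps the point of maximum perpendicular
    distance from the chord whenever it exceeds ``epsilon``. With
    ``normalize`` (default) distances are measured after per-axis min-max
    scaling of the trace, making ``epsilon`` dimensionless; time and
    concentration otherwise carry incommensurate units.
    """
    if epsilon < 0:
        raise ValueError(f"epsilon must be >= 0, got {epsilon!r}")
    if len(trace) < 2:
        raise ValueError("RDP needs at least 2 points")
    if normalize:
        t, v = _minmax_scale(trace.times), _minmax_scale(trace.values)
    else:
        t, v = trace.times, trace.values
    keep = rdp_mask(t, v, epsilon)
    return replace(trace, times=trace.times[keep], values=trace.values[keep])


def auto_thin(
    trace: RawTrace,
    target: tuple = (95, 105),
    max_iter: int = 60,
    normalize: bool = True,
) -> RawTrace:
    """Thin a trace to the configured point budget by searching epsilon.

    Bisects on log10(epsilon) — the retained count is monotone non-increasing
    in epsilon — until the RDP output size lands in ``[lo, hi]``. Inputs
    already at or below the budget are passed through unchanged.
    """
    lo, hi = target
    if lo > hi:
        raise ValueError(f"target range is empty: {target}")
    n = len(trace)
    if n <= hi:
        if n < lo:
            warnings.warn(
                f"trace has {n} points, below the target budget [{lo}, {hi}]; "
                "returned unchanged"
            )
        logger.info("auto_thin: %d points already within budget, passthrough", n)
        return trace
    # log10(eps) bracket: tiny eps keeps ~all points, eps > sqrt(2) keeps 2
    log_lo, log_hi = -12.0, 1.0
    counts = {}

    def count_at(log_eps: float) -> int:
        if log_eps not in counts:
            counts[log_eps] = len(rdp_thin(trace, 10.0 ** log_eps, normalize=normalize))
        return counts[log_eps]

    for _ in range(max_iter):
        mid = 0.5 * (log_lo + log_hi)
        c = count_at(mid)
        if lo <= c <= hi:
            return rdp_thin(trace, 10.0 ** mid, normalize=normalize)
        if c > hi:
            log_lo = mid  # too many points -> need larger epsilon
        else:
            log_hi = mid
    achieved = sorted(counts.values())
    nearest = min(achieved, key=lambda c: min(abs(c - lo), abs(c - hi)))
    raise RuntimeError(
        f"auto_thin failed to reach [{lo}, {hi}] points in {max_iter} iterations; "
        f"nearest achievable count was {nearest}"
    )


def trim_lag_phase(trace: RawTrace, cut, nadh_init: Optional[float] = None) -> RawTrace:
    """Drop the points before ``cut`` and re-zero the time axis.

    ``cut`` is a time (float, minutes) or an index (int). Used to remove the
    temperature-equilibration lag phase of sigmoidal NADH traces; when
    ``nadh_init`` is given, the nominal initial NADH concentration is recorded
    in the trace metadata for the downstream initial condition.
    """
    if isinstance(cut, (int, np.integer)) and not isinstance(cut, bool):
        idx = int(cut)
        if idx < 0 or idx >= len(trace):
            raise ValueError(f"cut index {idx} outside trace of length {len(trace)}")
    else:
        t = float(cut)
        if t > trace.times[-1]:
            raise ValueError(f"cut time {t} beyond final time {trace.times[-1]}")
        idx = int(np.searchsorted(trace.times, t, side="left"))
    if idx >= len(trace) - 1:
        raise ValueError("cut would leave fewer than 2 points")
    offset = trace.times[idx]
    meta = dict(trace.meta)
    meta["trim_offset_min"] = float(offset)
    if nadh_init is not None:
        meta["nadh_init_mM"] = float(nadh_init)
    return replace(
        trace,
        times=trace.times[idx:] - offset,
        values=trace.values[idx:],
        meta=meta,
    )
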