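"""First-order Haar structure function for irregular time series.

The Haar fluctuation at timescale ``tau`` is the absolute difference
between the mean of the second half and the mean of the first half of a
window of width ``tau``; the structure function ``S(tau)`` averages this
over windows laid across the record.  The algorithm is interpolation-free,
which makes it robust to the irregular sampling of sediment records down to
timescales near the series resolution, and fluctuations keep the units of
the input series (here: unitless sqrt-proportion composites).

Windowing conventions (declared, since structure-function practice varies):

* windows start at the first sample time and advance by ``tau/2``
  (50% overlap) while they fit inside the record;
* half-windows are the half-open intervals ``[t0, t0+tau/2)`` and
  ``[t0+tau/2, t0+tau)``;
* a window is accepted when both halves contain at least
  ``min_samples_per_half`` samples (default 1); half-window means are
  unweighted;
* scales with no accepted window are omitted from the result.

No Gaussian calibration constant is applied; all comparisons are
internally consistent.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError

#: Shared global grid for aggregation: 10 scales per decade, 10 yr – 20 ka.
GLOBAL_GRID_BOUNDS = (10.0, 20000.0)
POINTS_PER_DECADE = 10


@dataclass
class HaarSF:
    """S(tau) over log-spaced timescales with per-scale sample counts."""

    scales: np.ndarray        # yr, ascending
    fluctuations: np.ndarray  # S(tau) >= 0
    n_windows: np.ndarray     # accepted windows per scale
    n_records: np.ndarray | None = None  # aggregates only
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales, dtype=float)
        self.fluctuations = np.asarray(self.fluctuations, dtype=float)
        self.n_windows = np.asarray(self.n_windows)
        if np.any(np.diff(self.scales) <= 0):
            raise ValueError("scales must be strictly ascending")
        if np.any(self.fluctuations < 0):
            raise ValueError("fluctuations must be non-negative")


def default_scale_grid(times: np.ndarray) -> np.ndarray:
    """Log-spaced grid, 10 points per decade, from 2x median spacing to the span."""
    times = np.asarray(times, dtype=float)
    if times.size < 4:
        raise InsufficientDataError("need >= 4 samples for a scale grid")
    lo = 2.0 * float(np.median(np.diff(times)))
    hi = float(times[-1] - times[0])
    if hi <= lo:
        return np.array([hi])
    n_points = max(2, int(round(POINTS_PER_DECADE * np.log10(hi / lo))) + 1)
    return np.geomspace(lo, hi, n_points)


def global_scale_grid(
    lo: float = GLOBAL_GRID_BOUNDS[0], hi: float = GLOBAL_GRID_BOUNDS[1]
) -> np.ndarray:
    """Anchored global grid (10^(k/10) yr) used to re-bin HSFs for aggregation."""
    k_lo = int(np.ceil(POINTS_PER_DECADE * np.log10(lo) - 1e-9))
    k_hi = int(np.floor(POINTS_PER_DECADE * np.log10(hi) + 1e-9))
    return 10.0 ** (np.arange(k_lo, k_hi + 1) / POINTS_PER_DECADE)


def haar_sf(
    times: np.ndarray,
    values: np.ndarray,
    scale_grid: np.ndarray | None = None,
    min_samples_per_half: int = 1,
) -> HaarSF:
    """First-order Haar structure function of one irregular series."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size < 4:
        raise InsufficientDataError(f"need >= 4 samples, got {times.size}")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if scale_grid is None:
        scale_grid = default_scale_grid(times)
    t0, t_last = times[0], times[-1]
    span = t_last - t0
    csum = np.concatenate([[0.0], np.cumsum(values)])

    out_scales, out_fluct, out_nwin = [], [], []
    for tau in np.asarray(scale_grid, dtype=float):
        if tau <= 0 or tau > span:
            continue
        n_starts = int(np.floor((span - tau) / (tau / 2.0) + 1e-9)) + 1
        starts = t0 + (tau / 2.0) * np.arange(n_starts)
        left = np.searchsorted(times, starts, side="left")
        mid = np.searchsorted(times, starts + tau / 2.0, side="left")
        right = np.searchsorted(times, starts + tau, side="left")
        n1 = mid - left
        n2 = right - mid
        ok = (n1 >= min_samples_per_half) & (n2 >= min_samples_per_half)
        if not ok.any():
            continue
        m1 = (csum[mid[ok]] - csum[left[ok]]) / n1[ok]
        m2 = (csum[right[ok]] - csum[mid[ok]]) / n2[ok]
        out_scales.append(tau)
        out_fluct.append(float(np.mean(np.abs(m2 - m1))))
        out_nwin.append(int(ok.sum()))
    if not out_scales:
        raise InsufficientDataError("no scale admitted an occupied window")
    return HaarSF(
        scales=np.array(out_scales),
        fluctuations=np.array(out_fluct),
        n_windows=np.array(out_nwin),
    )


def _rebin_to_grid(hsf: HaarSF, grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map each scale of an HSF to its nearest log-scale bin of ``grid``.

    Returns (per-bin S values, per-bin n_windows); bins with no
    contribution hold NaN / 0.  Multiple scales landing in one bin are
    averaged with n_windows weights.
    """
    log_grid = np.log(grid)
    vals = np.full(grid.size, np.nan)
    wsum = np.zeros(grid.size)
    acc = np.zeros(grid.size)
    for tau, s, nw in zip(hsf.scales, hsf.fluctuations, hsf.n_windows):
        i = int(np.argmin(np.abs(log_grid - np.log(tau))))
        acc[i] += s * nw
        wsum[i] += nw
    nz = wsum > 0
    vals[nz] = acc[nz] / wsum[nz]
    return vals, wsum


def aggregate_hsf(
    hsf_list: list[HaarSF],
    n_max: int = 100,
    grid: np.ndarray | None = None,
) -> HaarSF:
    """Average many HSFs on a shared grid with quantile-based confidence bounds.

    Per scale, the aggregate is the mean of the available per-record S(tau)
    and the confidence half-width is the central-68% inter-quantile
    half-range of those estimates divided by ``sqrt(min(n, n_max))``.
    Capping n at ``n_max`` accounts for the limited spatial degrees of
    freedom of environmental records.
    """
    if not hsf_list:
        raise ValueError("aggregate_hsf needs at least one HSF")
    if grid is None:
        grid = global_scale_grid()
    stack = np.vstack([_rebin_to_grid(h, grid)[0] for h in hsf_list])
    n_rec = np.sum(np.isfinite(stack), axis=0)
    keep = n_rec >= 1
    means = np.nanmean(stack[:, keep], axis=0)
    q16 = np.nanpercentile(stack[:, keep], 16, axis=0)
    q84 = np.nanpercentile(stack[:, keep], 84, axis=0)
    half = (q84 - q16) / 2.0 / np.sqrt(np.minimum(n_rec[keep], n_max))
    total_windows = np.nansum(
        np.vstack([_rebin_to_grid(h, grid)[1] for h in hsf_list]), axis=0
    )[keep]
    return HaarSF(
        scales=grid[keep],
        fluctuations=means,
        n_windows=total_windows.astype(int),
        n_records=n_rec[keep],
        ci_low=means - half,
        ci_high=means + half,
    )
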