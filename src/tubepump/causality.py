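"""Resistance-gated bivariate Granger causality.

The causal relation between the wall-movement pressure-gradient proxy
and the volumetric flow rate is tested only inside the heartbeat phase
window of low viscous resistance (normalized resistance below a
threshold, default 0.1), where the pressure term — rather than the
near-closure resistance — governs the flow. The test is the classical
nested-OLS F-test: the restricted model regresses y on its own p lags,
the unrestricted model adds the p lags of x.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (
    DegenerateInputError,
    InsufficientDataError,
    RankDeficiencyError,
)

__all__ = [
    "GrangerResult",
    "low_resistance_window",
    "granger_test",
    "causality_table",
]


@dataclass
class GrangerResult:
    """One direction x lag cell of the causality table."""

    direction: str  # pressure_to_flow | flow_to_pressure | x_to_y | y_to_x
    lag: int
    lag_ms: float
    f_stat: float
    p_value: float
    n_effective: int
    significant_at: tuple[float, ...] = ()


def low_resistance_window(
    resistance_norm: np.ndarray,
    threshold: float = 0.1,
    min_samples: int | None = None,
    max_lag: int = 3,
    circular: bool = True,
) -> tuple[np.ndarray, list[tuple[int, int]], np.ndarray]:
    """Low-resistance gate: mask, contiguous segments, longest segment indices.

    Segments are maximal runs of ``Rnorm < threshold``; with ``circular``
    (one folded cycle) a run may wrap around the cycle end. Lagged
    regression needs contiguous samples, so only the longest run is used
    downstream. Raises :class:`InsufficientDataError` when the longest
    run cannot support the maximal requested lag (fewer than
    ``3 * max_lag + 2`` samples).
    """
    rn = np.asarray(resistance_norm, dtype=float)
    mask = rn < threshold
    n = len(rn)
    if min_samples is None:
        min_samples = 3 * max_lag + 2
    if not mask.any():
        raise InsufficientDataError("no samples below the resistance threshold")
    if mask.all():
        return mask, [(0, n)], np.arange(n)

    ext = np.concatenate([mask, mask]) if circular else mask
    segments: list[tuple[int, int]] = []
    start = None
    for i, v in enumerate(ext):
        if v and start is None:
            start = i
        elif not v and start is not None:
            if start < n:
                segments.append((start, min(i - start, n)))
            start = None
    if start is not None and start < n:
        segments.append((start, min(len(ext) - start, n)))
    # drop duplicates from the doubled array (runs fully in the second copy)
    segments = [(s % n, ln) for s, ln in segments]
    if circular and mask[0] and mask[-1]:
        # the run at index 0 is the tail of the wrap-around run
        segments = [(s, ln) for s, ln in segments if s != 0]
    seen = set()
    uniq = []
    for s, ln in segments:
        if s not in seen:
            uniq.append((s, ln))
            seen.add(s)
    best_start, best_len = max(uniq, key=lambda t: t[1])
    if best_len < min_samples:
        raise InsufficientDataError(
            f"longest low-resistance run has {best_len} samples; "
            f"need at least {min_samples} for lag {max_lag}"
        )
    idx = (best_start + np.arange(best_len)) % n
    return mask, uniq, idx


def _lag_matrix(series: np.ndarray, lag: int) -> np.ndarray:
    """Columns [s_{t-1}, ..., s_{t-lag}] for t = lag..T-1."""
    return np.column_stack([series[lag - k : len(series) - k] for k in range(1, lag + 1)])


def granger_test(
    x: np.ndarray,
    y: np.ndarray,
    lag: int,
    volume_rate_hz: float = 100.0,
    use_f: bool = True,
) -> GrangerResult:
    """Does x Granger-cause y at the given lag order?

    Both series are de-meaned; the restricted model is
    ``y_t ~ y_{t-1..t-p}``, the unrestricted adds ``x_{t-1..t-p}``.
    ``F = [(RSS_r - RSS_u)/p] / [RSS_u/(T - 2p - 1)]`` with ``T``
    usable observations, referred to ``F(p, T - 2p - 1)``; with
    ``use_f=False`` the large-sample chi-square form is used instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DegenerateInputError("x and y must be equal-length 1D series")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DegenerateInputError("series must be finite (gate out masked samples first)")
    n = len(x)
    if lag < 1:
        raise DegenerateInputError("lag must be >= 1")
    if n < 3 * lag + 2:
        raise InsufficientDataError(f"need at least {3 * lag + 2} samples for lag {lag}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero-variance series")
    x = x - x.mean()
    y = y - y.mean()

    t_eff = n - lag
    yt = y[lag:]
    xr = np.column_stack([np.ones(t_eff), _lag_matrix(y, lag)])
    xu = np.column_stack([xr, _lag_matrix(x, lag)])
    if np.linalg.matrix_rank(xu) < xu.shape[1]:
        raise RankDeficiencyError("perfectly collinear lagged regressors")

    beta_r, _, _, _ = np.linalg.lstsq(xr, yt, rcond=None)
    beta_u, _, _, _ = np.linalg.lstsq(xu, yt, rcond=None)
    rss_r = float(np.sum((yt - xr @ beta_r) ** 2))
    rss_u = float(np.sum((yt - xu @ beta_u) ** 2))
    df_denom = t_eff - 2 * lag - 1
    if df_denom <= 0:
        raise InsufficientDataError("not enough observations for the denominator df")
    if rss_u <= 0:
        raise DegenerateInputError("unrestricted model fits exactly; test undefined")
    f = ((rss_r - rss_u) / lag) / (rss_u / df_denom)
    f = max(f, 0.0)
    if use_f:
        p = float(stats.f.sf(f, lag, df_denom))
    else:
        p = float(stats.chi2.sf(f * lag, lag))
    sig = tuple(a for a in (0.05, 0.01) if p <= a)
    return GrangerResult(
        direction="x_to_y",
        lag=lag,
        lag_ms=lag * 1000.0 / volume_rate_hz,
        f_stat=float(f),
        p_value=p,
        n_effective=t_eff,
        significant_at=sig,
    )


def causality_table(
    g: np.ndarray,
    v: np.ndarray,
    window_idx: np.ndarray | None = None,
    lags: tuple[int, ...] = (1, 2, 3),
    volume_rate_hz: float = 100.0,
    use_f: bool = True,
) -> list[GrangerResult]:
    """Both causal directions at each lag, on the gated window.

    ``window_idx`` selects the contiguous low-resistance samples (e.g.
    from :func:`low_resistance_window`); one :class:`GrangerResult` per
    direction per lag, with significance flagged at 0.05 and 0.01.
    """
    g = np.asarray(g, dtype=float)
    v = np.asarray(v, dtype=float)
    if window_idx is not None:
        g = g[window_idx]
        v = v[window_idx]
    results = []
    for lag in lags:
        fwd = granger_test(g, v, lag, volume_rate_hz=volume_rate_hz, use_f=use_f)
        fwd.direction = "pressure_to_flow"
        rev = granger_test(v, g, lag, volume_rate_hz=volume_rate_hz, use_f=use_f)
        rev.direction = "flow_to_pressure"
        results.extend([fwd, rev])
    return results
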