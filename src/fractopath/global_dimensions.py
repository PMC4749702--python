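"""Global Renyi dimensions D0, D1, D2 of a binary raster.

The capacity dimension D0 is the slope of ``log N(eps)`` versus
``log (1/eps)``, where ``N(eps)`` is the number of eps-sized grid boxes
containing at least one foreground pixel.  The information dimension D1
replaces ``log N`` with the box-occupancy entropy ``-sum p log p`` (p = box
pixel count / total foreground pixels).  The correlation dimension D2 is the
slope of ``log C(eps)`` versus ``log eps``, where
``C(eps) = 2 g_eps / (M (M-1))`` and ``g_eps`` counts pixel pairs closer than
``eps`` (Euclidean distance between pixel centers).

All three are estimated over a finite scale scan and an ordinary
least-squares fit; for self-similar test objects with known dimension the
estimates agree with the analytic value to within the fit tolerance of the
scale schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from ._fit import ols_slope
from .errors import DegenerateInputError, InsufficientScalesError

__all__ = [
    "BoxCountSeries",
    "DimensionEstimate",
    "default_scales",
    "box_count",
    "capacity_dimension",
    "information_dimension",
    "pair_counts",
    "correlation_dimension",
    "best_fit_range",
]


def default_scales(shape: tuple[int, int]) -> np.ndarray:
    """Powers of 2 from 2 px up to ``min(height, width) / 4``.

    Avoids saturated large boxes while leaving at least four scales on images
    of a few hundred pixels per side.
    """
    limit = min(shape) // 4
    if limit < 2:
        raise ValueError(f"image too small for a scale scan: shape {shape}")
    eps = []
    e = 2
    while e <= limit:
        eps.append(e)
        e *= 2
    return np.asarray(eps, dtype=np.int64)


@dataclass
class BoxCountSeries:
    """Per-scale occupancy statistics of a fixed-grid box scan.

    Attributes
    ----------
    eps : array of box sizes (pixels).
    n_boxes : occupied-box counts N(eps).
    info_sums : per-eps occupancy entropy ``-sum p ln p`` (nats).
    n_pixels : total foreground pixel count M.
    pair_counts : optional per-eps close-pair counts g_eps (filled by
        :func:`pair_counts`).
    """

    eps: np.ndarray
    n_boxes: np.ndarray
    info_sums: np.ndarray
    n_pixels: int
    pair_counts: np.ndarray | None = None


@dataclass
class DimensionEstimate:
    """A fitted scaling exponent with its regression diagnostics."""

    value: float
    stderr: float
    r_squared: float
    fit_range: tuple[float, float]
    n_scales: int
    kind: str = field(default="D0")


def _box_masses(img: np.ndarray, eps: int) -> np.ndarray:
    """Pixel counts of each eps x eps grid cell (origin (0,0), edges clipped)."""
    h, w = img.shape
    rows = np.arange(0, h, eps)
    cols = np.arange(0, w, eps)
    sums = np.add.reduceat(img.astype(np.int64), rows, axis=0)
    sums = np.add.reduceat(sums, cols, axis=1)
    return sums


def box_count(
    img: np.ndarray,
    eps_list: np.ndarray | None = None,
    multi_offset: bool = False,
) -> BoxCountSeries:
    """Fixed-grid box scan of a binary image.

    Parameters
    ----------
    img
        2-D boolean raster.
    eps_list
        Box sizes; defaults to :func:`default_scales`.
    multi_offset
        When true, ``n_boxes`` at each scale is the minimum over four grid
        origins (0,0), (e/2,0), (0,e/2), (e/2,e/2) — a diagnostic for grid
        placement sensitivity.  Occupancy probabilities (and hence D1) always
        use the (0,0) origin for determinism.

    Raises
    ------
    DegenerateInputError
        If the image has no foreground pixels.
    """
    img = np.asarray(img, dtype=bool)
    m = int(img.sum())
    if m == 0:
        raise DegenerateInputError("empty foreground: box counts undefined")
    if eps_list is None:
        eps_list = default_scales(img.shape)
    eps_list = np.asarray(eps_list, dtype=np.int64)
    if np.any(eps_list < 1) or np.any(eps_list > min(img.shape)):
        raise ValueError("each eps must satisfy 1 <= eps <= min(height, width)")

    n_boxes = np.empty(eps_list.size, dtype=np.int64)
    info = np.empty(eps_list.size, dtype=np.float64)
    for i, e in enumerate(eps_list):
        masses = _box_masses(img, int(e))
        occ = masses[masses > 0]
        n = occ.size
        if multi_offset and e >= 2:
            half = int(e) // 2
            for dr, dc in ((half, 0), (0, half), (half, half)):
                shifted = _box_masses(img[dr:, dc:], int(e))
                n = min(n, int((shifted > 0).sum()))
        n_boxes[i] = n
        p = occ / m
        info[i] = float(-(p * np.log(p)).sum())
    return BoxCountSeries(eps=eps_list, n_boxes=n_boxes, info_sums=info, n_pixels=m)


def _select(series_eps: np.ndarray, fit_range) -> np.ndarray:
    if fit_range is None:
        return np.ones(series_eps.size, dtype=bool)
    lo, hi = fit_range
    return (series_eps >= lo) & (series_eps <= hi)


def capacity_dimension(
    series: BoxCountSeries, fit_range: tuple[float, float] | None = None
) -> DimensionEstimate:
    """D0: OLS slope of ``log N(eps)`` versus ``log(1/eps)``."""
    keep = _select(series.eps, fit_range)
    if keep.sum() < 3:
        raise InsufficientScalesError("need >= 3 scales inside the fit range")
    eps = series.eps[keep].astype(np.float64)
    x = np.log(1.0 / eps)
    y = np.log(series.n_boxes[keep].astype(np.float64))
    slope, _, stderr, r2 = ols_slope(x, y)
    return DimensionEstimate(
        value=slope,
        stderr=stderr,
        r_squared=r2,
        fit_range=(float(eps.min()), float(eps.max())),
        n_scales=int(keep.sum()),
        kind="D0",
    )


def information_dimension(
    series: BoxCountSeries, fit_range: tuple[float, float] | None = None
) -> DimensionEstimate:
    """D1: OLS slope of the box-occupancy entropy versus ``log(1/eps)``."""
    keep = _select(series.eps, fit_range)
    if keep.sum() < 3:
        raise InsufficientScalesError("need >= 3 scales inside the fit range")
    eps = series.eps[keep].astype(np.float64)
    x = np.log(1.0 / eps)
    y = series.info_sums[keep]
    slope, _, stderr, r2 = ols_slope(x, y)
    return DimensionEstimate(
        value=slope,
        stderr=stderr,
        r_squared=r2,
        fit_range=(float(eps.min()), float(eps.max())),
        n_scales=int(keep.sum()),
        kind="D1",
    )


def _foreground_coords(img: np.ndarray) -> np.ndarray:
    return np.argwhere(np.asarray(img, dtype=bool)).astype(np.float64)


def pair_counts(
    img: np.ndarray,
    eps_list: np.ndarray,
    max_pairs: int = 2_000_000,
    seed: int = 0,
) -> tuple[np.ndarray, int]:
    """Close-pair counts g_eps on the exact pixel set.

    All pairs are enumerated when ``M (M-1) / 2 <= max_pairs``; otherwise a
    seeded uniform subsample of pixels is used so the pair budget is met.
    Distances are Euclidean between 0-based (row, col) pixel centers; a pair
    counts toward g_eps when its distance is strictly below eps.

    Returns ``(g, m_used)`` where ``m_used`` is the number of pixels entering
    the enumeration.
    """
    coords = _foreground_coords(img)
    m = coords.shape[0]
    if m < 2:
        raise DegenerateInputError("need at least two foreground pixels")
    if m * (m - 1) // 2 > max_pairs:
        m_used = int((1 + np.sqrt(1 + 8 * max_pairs)) // 2)
        rng = np.random.default_rng(seed)
        coords = coords[rng.choice(m, size=m_used, replace=False)]
    else:
        m_used = m
    d = pdist(coords)
    eps_arr = np.asarray(eps_list, dtype=np.float64)
    g = np.array([(d < e).sum() for e in eps_arr], dtype=np.int64)
    return g, m_used


def correlation_dimension(
    img: np.ndarray,
    eps_list: np.ndarray | None = None,
    max_pairs: int = 2_000_000,
    seed: int = 0,
) -> DimensionEstimate:
    """D2: OLS slope of ``log C(eps)`` versus ``log eps``.

    ``C(eps) = 2 g_eps / (M (M-1))`` is the correlation sum.  Scales with
    ``g_eps = 0`` carry no information and are dropped before the fit.
    """
    img = np.asarray(img, dtype=bool)
    if eps_list is None:
        eps_list = default_scales(img.shape)
    eps_arr = np.asarray(eps_list, dtype=np.float64)
    g, m_used = pair_counts(img, eps_arr, max_pairs=max_pairs, seed=seed)
    keep = g > 0
    if keep.sum() < 3:
        raise InsufficientScalesError("fewer than 3 scales with nonzero pair counts")
    c = 2.0 * g[keep] / (m_used * (m_used - 1))
    x = np.log(eps_arr[keep])
    y = np.log(c)
    slope, _, stderr, r2 = ols_slope(x, y)
    return DimensionEstimate(
        value=slope,
        stderr=stderr,
        r_squared=r2,
        fit_range=(float(eps_arr[keep].min()), float(eps_arr[keep].max())),
        n_scales=int(keep.sum()),
        kind="D2",
    )


def best_fit_range(
    series: BoxCountSeries, min_scales: int = 4
) -> tuple[float, float]:
    """Contiguous scale sub-range maximizing the D0 fit's r².

    A plateau-detection helper: scans every contiguous window of at least
    ``min_scales`` scales and returns the (eps_min, eps_max) of the window
    whose capacity fit has the highest r².
    """
    n = series.eps.size
    if n < min_scales:
        raise InsufficientScalesError(f"need >= {min_scales} scales")
    best = None
    for i in range(n):
        for j in range(i + min_scales, n + 1):
            sub = (float(series.eps[i]), float(series.eps[j - 1]))
            lo, hi = min(sub), max(sub)
            est = capacity_dimension(series, fit_range=(lo, hi))
            if best is None or est.r_squared > best[0]:
                best = (est.r_squared, (lo, hi))
    return best[1]
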