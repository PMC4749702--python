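"""Local fractal dimension (LFD) and local connected fractal dimension (LCFD).

Both assign a scaling exponent to each foreground pixel P: foreground pixels
are counted inside square windows of growing odd side ``s`` centered at P,
and the slope of ``log N(s)`` versus ``log s`` is fitted by least squares.
The LFD counts every foreground pixel in the window; the LCFD counts only the
pixels of the 8-connected component of P within the window, making it a local
measure of intercellular connectivity rather than of mere density.

Windows are clipped at the image border.  Pixels whose largest window loses
more than half of its area to clipping are excluded from the map (their
slopes would be biased low); LCFD additionally requires the seed pixel's full
8-neighborhood to lie inside the image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError

__all__ = ["LocalDimensionMap", "MapSummary", "lfd_map", "lcfd_map", "summarize_map"]

#: Default window sides: geometric growth, five fit points.
DEFAULT_WINDOWS = (3, 5, 9, 17, 33)

_EIGHT = np.ones((3, 3), dtype=np.int8)  # 8-connectivity structuring element


@dataclass
class LocalDimensionMap:
    """Per-pixel local slopes.

    Attributes
    ----------
    values : slope estimates, one per retained foreground pixel.
    coords : (n, 2) row/col coordinates of those pixels.
    window_sizes : odd window sides used.
    kind : ``"LFD"`` or ``"LCFD"``.
    sampled : True when the foreground was subsampled to meet a pixel budget.
    n_excluded : pixels dropped by the border rule (or LCFD eligibility).
    """

    values: np.ndarray
    coords: np.ndarray
    window_sizes: tuple[int, ...]
    kind: str
    sampled: bool = False
    n_excluded: int = 0


@dataclass
class MapSummary:
    mean: float
    median: float
    sd: float
    cv: float
    n: int


def _check_windows(window_sizes) -> tuple[int, ...]:
    ws = tuple(int(s) for s in window_sizes)
    if len(ws) < 2:
        raise ValueError("need at least two window sizes to fit a slope")
    if any(s < 3 or s % 2 == 0 for s in ws):
        raise ValueError(f"window sizes must be odd and >= 3, got {ws}")
    return tuple(sorted(ws))


def _slopes(log_s: np.ndarray, log_n: np.ndarray) -> np.ndarray:
    """Vectorized per-row OLS slope of log N against log s."""
    x = log_s - log_s.mean()
    denom = float((x**2).sum())
    y = log_n - log_n.mean(axis=1, keepdims=True)
    return (y @ x) / denom


def _border_keep(
    coords: np.ndarray, shape: tuple[int, int], s_max: int
) -> np.ndarray:
    """Mask of pixels whose largest window keeps > 50% of its area."""
    half = s_max // 2
    r, c = coords[:, 0], coords[:, 1]
    h, w = shape
    rows = np.minimum(r + half, h - 1) - np.maximum(r - half, 0) + 1
    cols = np.minimum(c + half, w - 1) - np.maximum(c - half, 0) + 1
    return rows * cols >= 0.5 * s_max * s_max


def lfd_map(
    img: np.ndarray,
    window_sizes=DEFAULT_WINDOWS,
    max_pixels: int | None = None,
    seed: int = 0,
) -> LocalDimensionMap:
    """Local fractal dimension map of a binary image.

    ``N(s)`` for a pixel is the count of all foreground pixels inside the
    clipped ``s x s`` window centered on it; the map value is the OLS slope
    of ``log N(s)`` on ``log s``.  When ``max_pixels`` is given and the
    foreground is larger, a seeded uniform subsample of pixels is evaluated
    and the result is flagged ``sampled``.
    """
    img = np.asarray(img, dtype=bool)
    ws = _check_windows(window_sizes)
    coords = np.argwhere(img)
    if coords.shape[0] == 0:
        raise DegenerateInputError("empty foreground")

    keep = _border_keep(coords, img.shape, ws[-1])
    n_excluded = int((~keep).sum())
    coords = coords[keep]
    if coords.shape[0] == 0:
        raise DegenerateInputError(
            "all foreground pixels excluded by the border rule"
        )

    sampled = False
    if max_pixels is not None and coords.shape[0] > max_pixels:
        rng = np.random.default_rng(seed)
        coords = coords[rng.choice(coords.shape[0], size=max_pixels, replace=False)]
        sampled = True

    # Integral image: window sums in O(1) per pixel per scale.
    sat = np.zeros((img.shape[0] + 1, img.shape[1] + 1), dtype=np.int64)
    sat[1:, 1:] = np.cumsum(np.cumsum(img.astype(np.int64), axis=0), axis=1)
    h, w = img.shape
    r, c = coords[:, 0], coords[:, 1]
    counts = np.empty((coords.shape[0], len(ws)), dtype=np.float64)
    for j, s in enumerate(ws):
        half = s // 2
        r0 = np.maximum(r - half, 0)
        r1 = np.minimum(r + half, h - 1) + 1
        c0 = np.maximum(c - half, 0)
        c1 = np.minimum(c + half, w - 1) + 1
        counts[:, j] = sat[r1, c1] - sat[r0, c1] - sat[r1, c0] + sat[r0, c0]
    values = _slopes(np.log(np.asarray(ws, dtype=np.float64)), np.log(counts))
    return LocalDimensionMap(
        values=values,
        coords=coords,
        window_sizes=ws,
        kind="LFD",
        sampled=sampled,
        n_excluded=n_excluded,
    )


def lcfd_map(
    img: np.ndarray,
    window_sizes=DEFAULT_WINDOWS,
    max_pixels: int | None = 5000,
    seed: int = 0,
) -> LocalDimensionMap:
    """Local connected fractal dimension map.

    Like :func:`lfd_map` but ``N(s)`` counts only the 8-connected component
    of the seed pixel within each window, so disconnected neighbors do not
    contribute.  Eligible seeds are foreground pixels whose 8-neighborhood is
    fully inside the image.  The per-pixel component labeling is O(s²) per
    scale, hence the default pixel budget.
    """
    img = np.asarray(img, dtype=bool)
    ws = _check_windows(window_sizes)
    coords = np.argwhere(img)
    if coords.shape[0] == 0:
        raise DegenerateInputError("empty foreground")

    h, w = img.shape
    inner = (
        (coords[:, 0] >= 1)
        & (coords[:, 0] <= h - 2)
        & (coords[:, 1] >= 1)
        & (coords[:, 1] <= w - 2)
    )
    keep = inner & _border_keep(coords, img.shape, ws[-1])
    n_excluded = int((~keep).sum())
    coords = coords[keep]
    if coords.shape[0] == 0:
        raise DegenerateInputError("no eligible seed pixels for the LCFD")

    sampled = False
    if max_pixels is not None and coords.shape[0] > max_pixels:
        rng = np.random.default_rng(seed)
        coords = coords[rng.choice(coords.shape[0], size=max_pixels, replace=False)]
        sampled = True

    log_s = np.log(np.asarray(ws, dtype=np.float64))
    counts = np.empty((coords.shape[0], len(ws)), dtype=np.float64)
    for i, (r, c) in enumerate(coords):
        for j, s in enumerate(ws):
            half = s // 2
            r0, r1 = max(r - half, 0), min(r + half, h - 1) + 1
            c0, c1 = max(c - half, 0), min(c + half, w - 1) + 1
            window = img[r0:r1, c0:c1]
            labels, _ = ndimage.label(window, structure=_EIGHT)
            counts[i, j] = (labels == labels[r - r0, c - c0]).sum()
    values = _slopes(log_s, np.log(counts))
    return LocalDimensionMap(
        values=values,
        coords=coords,
        window_sizes=ws,
        kind="LCFD",
        sampled=sampled,
        n_excluded=n_excluded,
    )


def connected_window_counts(
    img: np.ndarray, pixel: tuple[int, int], window_sizes=DEFAULT_WINDOWS
) -> np.ndarray:
    """N(s) of the seed pixel's 8-connected component per window (diagnostic)."""
    img = np.asarray(img, dtype=bool)
    ws = _check_windows(window_sizes)
    h, w = img.shape
    r, c = pixel
    if not img[r, c]:
        raise ValueError("seed pixel is not foreground")
    out = np.empty(len(ws), dtype=np.int64)
    for j, s in enumerate(ws):
        half = s // 2
        r0, r1 = max(r - half, 0), min(r + half, h - 1) + 1
        c0, c1 = max(c - half, 0), min(c + half, w - 1) + 1
        window = img[r0:r1, c0:c1]
        labels, _ = ndimage.label(window, structure=_EIGHT)
        out[j] = int((labels == labels[r - r0, c - c0]).sum())
    return out


def summarize_map(m: LocalDimensionMap) -> MapSummary:
    """Mean, median, population SD and CV (= SD/mean) of a local map."""
    v = np.asarray(m.values, dtype=np.float64)
    if v.size == 0:
        raise DegenerateInputError("empty local dimension map")
    mean = float(v.mean())
    sd = float(v.std(ddof=0))
    cv = sd / mean if mean > 0 else float("nan")
    return MapSummary(
        mean=mean, median=float(np.median(v)), sd=sd, cv=cv, n=int(v.size)
    )
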