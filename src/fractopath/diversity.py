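"""Diversity measures: Shannon entropy and lacunarity.

Entropy here is the base-2 Shannon entropy of the *adjacent-pixel-difference*
distribution: absolute gray (or binary) differences of all horizontally and
vertically adjacent pixel pairs are pooled into an empirical symbol
distribution.  A uniform image, or any image in which every adjacent pair
differs by the same amount (a checkerboard), has entropy 0.  On binary
images the alphabet has at most two symbols, so H <= 1 bit.

The entropy-versus-scale series fits the box-occupancy entropy H(eps) as a
linear function of log eps; its negated slope is an alternative estimator of
the information dimension D1.

Lacunarity λ(r) is the squared coefficient of variation of the box-mass
distribution at box size r — a measure of gappiness: clumped patterns with
large irregular gaps have high λ, translation-invariant patterns have λ = 0.
The default sampling scheme is the gliding box (stride 1, boxes overlap); a
fixed non-overlapping grid is available for cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._fit import ols_slope
from .errors import DegenerateInputError, InsufficientScalesError
from .global_dimensions import _box_masses, default_scales

__all__ = [
    "EntropyResult",
    "EntropyScaleSeries",
    "LacunarityResult",
    "shannon_entropy",
    "entropy_scale_series",
    "lacunarity",
]


@dataclass
class EntropyResult:
    """Entropy of the adjacent-difference distribution.

    ``symbols``/``p`` give the observed difference values and their empirical
    probabilities; ``n_pairs`` is the number of adjacent pairs pooled.
    """

    h: float
    symbols: np.ndarray
    p: np.ndarray
    n_pairs: int


@dataclass
class EntropyScaleSeries:
    """Box-occupancy entropy per scale and its linear fit in log eps.

    ``slope`` is the dimension D (the negated regression slope, so that
    H(eps) = intercept - D * log2(eps)); ``intercept`` is the entropy H_D
    extrapolated to eps = 1.
    """

    eps: np.ndarray
    h_of_eps: np.ndarray
    slope: float
    intercept: float
    stderr: float
    r_squared: float


@dataclass
class LacunarityResult:
    """Per-scale lacunarity and the per-image mean.

    ``per_scale`` rows are (r, lambda(r), mu(r), sigma(r)); ``lambda_mean``
    is the unweighted mean of lambda(r) over the scanned r values.
    """

    per_scale: list[tuple[int, float, float, float]]
    lambda_mean: float
    mode: str


def shannon_entropy(img: np.ndarray) -> EntropyResult:
    """Base-2 entropy of pooled horizontal+vertical adjacent differences."""
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D raster")
    if arr.dtype == bool:
        arr = arr.astype(np.int16)
    else:
        arr = arr.astype(np.int16)
    h_diff = np.abs(np.diff(arr, axis=1)).ravel()
    v_diff = np.abs(np.diff(arr, axis=0)).ravel()
    diffs = np.concatenate([h_diff, v_diff])
    if diffs.size == 0:
        raise DegenerateInputError("image has no adjacent pixel pairs")
    symbols, counts = np.unique(diffs, return_counts=True)
    p = counts / counts.sum()
    h = float(-(p * np.log2(p)).sum()) + 0.0  # normalize -0.0
    return EntropyResult(h=h, symbols=symbols, p=p, n_pairs=int(diffs.size))


def entropy_scale_series(
    img: np.ndarray, eps_list: np.ndarray | None = None
) -> EntropyScaleSeries:
    """Box-occupancy entropy H(eps) and its slope in log2(eps).

    For each scale the image is tiled by eps-sized grid cells and the base-2
    entropy of the occupancy distribution (cell mass / total foreground) is
    computed; H(eps) is then fitted as a linear function of log2 eps.  The
    negated slope estimates the information dimension D1.
    """
    img = np.asarray(img, dtype=bool)
    m = int(img.sum())
    if m == 0:
        raise DegenerateInputError("empty foreground")
    if eps_list is None:
        eps_list = default_scales(img.shape)
    eps_arr = np.asarray(eps_list, dtype=np.int64)
    if eps_arr.size < 3:
        raise InsufficientScalesError("need >= 3 scales")
    h_vals = np.empty(eps_arr.size, dtype=np.float64)
    for i, e in enumerate(eps_arr):
        masses = _box_masses(img, int(e))
        p = masses[masses > 0] / m
        h_vals[i] = float(-(p * np.log2(p)).sum())
    raw_slope, intercept, stderr, r2 = ols_slope(np.log2(eps_arr), h_vals)
    return EntropyScaleSeries(
        eps=eps_arr,
        h_of_eps=h_vals,
        slope=-raw_slope,
        intercept=intercept,
        stderr=stderr,
        r_squared=r2,
    )


def _gliding_masses(img: np.ndarray, r: int) -> np.ndarray:
    """Masses of every r x r box at stride 1 (overlapping)."""
    sat = np.zeros((img.shape[0] + 1, img.shape[1] + 1), dtype=np.int64)
    sat[1:, 1:] = np.cumsum(np.cumsum(img.astype(np.int64), axis=0), axis=1)
    return (
        sat[r:, r:] - sat[:-r, r:] - sat[r:, :-r] + sat[:-r, :-r]
    ).ravel()


def lacunarity(
    img: np.ndarray,
    r_list: np.ndarray | None = None,
    mode: str = "gliding",
) -> LacunarityResult:
    """Lacunarity λ(r) = (sigma/mu)² of the box-mass distribution.

    Parameters
    ----------
    img
        2-D boolean raster with at least one foreground pixel.
    r_list
        Box sizes; defaults to powers of 2 from 2 to ``min(dim)/4``.
    mode
        ``"gliding"`` (default): every box position at stride 1, overlapping.
        ``"grid"``: non-overlapping tiling of complete r x r tiles only.

    Notes
    -----
    Empty boxes count toward the mass distribution (mass 0).  In grid mode a
    scale whose complete tiles miss all foreground is reported as NaN and
    excluded from ``lambda_mean``.
    """
    img = np.asarray(img, dtype=bool)
    if img.sum() == 0:
        raise DegenerateInputError("empty foreground")
    if mode not in ("gliding", "grid"):
        raise ValueError(f"unknown lacunarity mode: {mode!r}")
    if r_list is None:
        r_list = default_scales(img.shape)
    r_arr = np.asarray(r_list, dtype=np.int64)
    if np.any(r_arr < 1) or np.any(r_arr > min(img.shape)):
        raise ValueError("each r must satisfy 1 <= r <= min(height, width)")

    per_scale: list[tuple[int, float, float, float]] = []
    for r in r_arr:
        r = int(r)
        if mode == "gliding":
            masses = _gliding_masses(img, r)
        else:
            h, w = img.shape
            trimmed = img[: (h // r) * r, : (w // r) * r]
            if trimmed.size == 0:
                per_scale.append((r, float("nan"), 0.0, 0.0))
                continue
            masses = _box_masses(trimmed, r).ravel()
        mu = float(masses.mean())
        sigma = float(masses.std(ddof=0))
        lam = (sigma / mu) ** 2 if mu > 0 else float("nan")
        per_scale.append((r, lam, mu, sigma))
    lams = np.array([row[1] for row in per_scale], dtype=np.float64)
    if np.all(np.isnan(lams)):
        raise DegenerateInputError("no scale produced a defined lacunarity")
    return LacunarityResult(
        per_scale=per_scale, lambda_mean=float(np.nanmean(lams)), mode=mode
    )
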