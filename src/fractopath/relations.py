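"""Inter-measure linear relations and the multifractal ordering check.

Across a cohort, lacunarity falls linearly with the capacity dimension and
entropy rises linearly with the information dimension; the entropy-lacunarity
relation is tri-linear with fixed breakpoints at H = 0.7 and H = 0.9.  The
reference coefficients (module constants below) are the published cohort
fits; :func:`fit_linear` and :func:`fit_trilinear_h_lambda` re-estimate them
on any feature table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateInputError

__all__ = [
    "LinearFit",
    "PiecewiseFit",
    "fit_linear",
    "fit_trilinear_h_lambda",
    "multifractal_check",
    "D0_LAMBDA_COEFFS",
    "D1_ENTROPY_COEFFS",
    "H_LAMBDA_SEGMENTS",
    "H_BREAKPOINTS",
]

#: Reference cohort fit, lambda = 2.0701 - 0.8145 * D0  (intercept, slope).
D0_LAMBDA_COEFFS = (2.0701, -0.8145)
#: Reference cohort fit, H = -1.4280 + 1.3511 * D1  (intercept, slope).
D1_ENTROPY_COEFFS = (-1.4280, 1.3511)
#: Tri-linear lambda(H) segments, (intercept, slope) for H<=0.7, 0.7<H<0.9, H>=0.9.
H_LAMBDA_SEGMENTS = ((1.0301, -0.3057), (1.1625, -0.5224), (1.7503, -1.199))
#: Fixed tri-linear breakpoints on the H axis (bits).
H_BREAKPOINTS = (0.7, 0.9)


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r: float
    n: int
    domain: tuple[float, float] | None = None


@dataclass
class PiecewiseFit:
    """Three independent segment fits with fixed breakpoints.

    ``segments[i]`` is a :class:`LinearFit` or ``None`` when the segment's
    domain held fewer than two distinct predictor values.
    """

    segments: tuple[LinearFit | None, LinearFit | None, LinearFit | None]
    breakpoints: tuple[float, float] = H_BREAKPOINTS


def fit_linear(x, y, domain: tuple[float, float] | None = None) -> LinearFit:
    """Ordinary least squares of y on x with Pearson r.

    A constant response is fitted as a flat line with r = 0 by convention; a
    constant predictor is degenerate and raises.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 2:
        raise ValueError("need at least two paired points")
    if np.ptp(x) == 0.0:
        raise DegenerateInputError("constant predictor: slope undefined")
    if np.ptp(y) == 0.0:
        return LinearFit(
            slope=0.0, intercept=float(y[0]), r=0.0, n=int(x.size), domain=domain
        )
    res = stats.linregress(x, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        n=int(x.size),
        domain=domain,
    )


def fit_trilinear_h_lambda(h, lam) -> PiecewiseFit:
    """Independent OLS of lambda on H within the three fixed H segments.

    Boundary points H = 0.7 go to the lower segment and H = 0.9 to the upper
    one; the middle interval is open on both sides.  Segments with fewer than
    two distinct H values are flagged empty (``None``).
    """
    h = np.asarray(h, dtype=np.float64)
    lam = np.asarray(lam, dtype=np.float64)
    if h.size != lam.size:
        raise ValueError("h and lam must be paired")
    b0, b1 = H_BREAKPOINTS
    masks = (h <= b0, (h > b0) & (h < b1), h >= b1)
    domains = ((-np.inf, b0), (b0, b1), (b1, np.inf))
    segments = []
    for mask, dom in zip(masks, domains):
        xs, ys = h[mask], lam[mask]
        if xs.size >= 2 and np.ptp(xs) > 0.0:
            segments.append(fit_linear(xs, ys, domain=dom))
        else:
            segments.append(None)
    if all(s is None for s in segments):
        raise ValueError("all tri-linear segments are empty")
    return PiecewiseFit(segments=tuple(segments))


def multifractal_check(
    d0: float, d1: float, d2: float, tol: float = 0.0
) -> tuple[bool, tuple[float, float]]:
    """Check the multifractal ordering D0 >= D1 >= D2 within a tolerance.

    Returns ``(ok, (d0 - d1, d1 - d2))``; ``ok`` is true when both margins
    are above ``-tol``, so monofractal estimates (equal dimensions up to
    estimator noise) pass at a small positive tolerance.
    """
    vals = (float(d0), float(d1), float(d2))
    if not all(np.isfinite(vals)):
        raise ValueError("dimensions must be finite")
    m1, m2 = vals[0] - vals[1], vals[1] - vals[2]
    return (m1 >= -tol and m2 >= -tol), (m1, m2)
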