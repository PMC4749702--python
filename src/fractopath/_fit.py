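"""Shared least-squares helpers for log-log slope fits."""

from __future__ import annotations

import numpy as np
from scipy import stats


def ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """OLS fit of ``y`` on ``x``.

    Returns ``(slope, intercept, stderr, r_squared)``.  A constant ``y`` is a
    legitimate degenerate case for dimension fits (e.g. a single pixel at all
    scales): slope 0, stderr 0, r² defined as 1 (the flat line is exact).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 2:
        raise ValueError("need at least two paired points")
    if np.ptp(y) == 0.0:
        return 0.0, float(y[0]), 0.0, 1.0
    res = stats.linregress(x, y)
    return (
        float(res.slope),
        float(res.intercept),
        float(res.stderr),
        float(res.rvalue) ** 2,
    )
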