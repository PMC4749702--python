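"""Synthetic fixtures: fractal images with known dimensions, gland-like vs
infiltrative nuclei patterns, and tabular cohorts with the reference class
structure.

Three families of generators make every pipeline stage testable without
patient data:

* analytic fractals — the Sierpinski carpet (D0 = log 8 / log 3), a random
  percolation fractal with tunable expected dimension ``log(b^2 p) / log b``,
  and a point-sampled binomial multiplicative cascade whose Renyi dimensions
  strictly decrease (a genuine multifractal);
* tissue-like binary maps — sparse rings of nucleus-sized dots emulating
  gland cross-sections (epithelial nuclei around lumina) versus uniformly or
  clumpily scattered dots emulating cellular infiltrates, with equal-density
  pairing so morphology, not density, drives measured differences;
* feature cohorts — per-class draws of (D0, D1, D2, LFD, CV-LFD, LCFD,
  CV-LCFD, H, lambda) using the reference per-class means/SDs, with D0
  truncated to its class cut-off interval so class membership is exact by
  construction, and lambda/H optionally generated from the reference linear
  couplings on D0/D1 plus Gaussian noise.

Every generator takes an explicit seed and is bit-for-bit reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, PackingError, SpecError
from .relations import D0_LAMBDA_COEFFS, D1_ENTROPY_COEFFS
from .stratification import PAPER_D0_CUTOFFS

__all__ = [
    "TABLE_STATS",
    "CLASS_SIZES",
    "CLASS_GLEASON",
    "PatternSpec",
    "CohortSpec",
    "make_sierpinski",
    "make_percolation",
    "make_cascade",
    "make_tissue_pattern",
    "make_cohort",
]

#: Reference per-class (mean, sd) of each measure for classes C1..C7 and BPH.
TABLE_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "d0": {
        "BPH": (1.5038, 0.0902),
        "C1": (1.4836, 0.0490),
        "C2": (1.5659, 0.0125),
        "C3": (1.6035, 0.0125),
        "C4": (1.6383, 0.0066),
        "C5": (1.6684, 0.0138),
        "C6": (1.7318, 0.0199),
        "C7": (1.7986, 0.0241),
    },
    "d1": {
        "BPH": (1.5222, 0.0936),
        "C1": (1.5114, 0.0445),
        "C2": (1.5673, 0.0250),
        "C3": (1.6081, 0.0247),
        "C4": (1.6474, 0.0232),
        "C5": (1.6703, 0.0260),
        "C6": (1.7282, 0.0221),
        "C7": (1.7651, 0.0237),
    },
    "d2": {
        "BPH": (1.5342, 0.0734),
        "C1": (1.5525, 0.0977),
        "C2": (1.6426, 0.0634),
        "C3": (1.6657, 0.0586),
        "C4": (1.7046, 0.0641),
        "C5": (1.7069, 0.0511),
        "C6": (1.7575, 0.0357),
        "C7": (1.8107, 0.0452),
    },
    "lfd_mean": {
        "BPH": (1.6310, 0.0792),
        "C1": (1.5109, 0.1447),
        "C2": (1.5396, 0.2129),
        "C3": (1.6529, 0.1497),
        "C4": (1.6992, 0.1342),
        "C5": (1.6897, 0.1236),
        "C6": (1.7644, 0.0821),
        "C7": (1.8225, 0.0552),
    },
    "lfd_cv": {
        "BPH": (0.0939, 0.0357),
        "C1": (0.0631, 0.0253),
        "C2": (0.0582, 0.0507),
        "C3": (0.0594, 0.0453),
        "C4": (0.0761, 0.0522),
        "C5": (0.0817, 0.0502),
        "C6": (0.0780, 0.0356),
        "C7": (0.0450, 0.0144),
    },
    "lcfd_mean": {
        "BPH": (1.4507, 0.2063),
        "C1": (1.4908, 0.1353),
        "C2": (1.5716, 0.1665),
        "C3": (1.6106, 0.2110),
        "C4": (1.5663, 0.2639),
        "C5": (1.6310, 0.1935),
        "C6": (1.7051, 0.1313),
        "C7": (1.7212, 0.1432),
    },
    "lcfd_cv": {
        "BPH": (0.1916, 0.0514),
        "C1": (0.1403, 0.0473),
        "C2": (0.1421, 0.0526),
        "C3": (0.1074, 0.0671),
        "C4": (0.1462, 0.0831),
        "C5": (0.1002, 0.0687),
        "C6": (0.1085, 0.0543),
        "C7": (0.1154, 0.0609),
    },
    "h": {
        "BPH": (0.5760, 0.1234),
        "C1": (0.5638, 0.1072),
        "C2": (0.6946, 0.0376),
        "C3": (0.7594, 0.0337),
        "C4": (0.7866, 0.0533),
        "C5": (0.8457, 0.0219),
        "C6": (0.9361, 0.0253),
        "C7": (0.9500, 0.0661),
    },
    "lam": {
        "BPH": (0.8516, 0.0524),
        "C1": (0.8597, 0.0370),
        "C2": (0.8125, 0.0215),
        "C3": (0.7656, 0.0309),
        "C4": (0.7527, 0.0367),
        "C5": (0.7205, 0.0183),
        "C6": (0.6284, 0.0405),
        "C7": (0.6108, 0.0843),
    },
}

#: Reference test-set sizes per complexity class (208 carcinomas in total).
CLASS_SIZES = {"C1": 60, "C2": 20, "C3": 37, "C4": 16, "C5": 23, "C6": 29, "C7": 23}

#: Structural grade most represented in each complexity class.
CLASS_GLEASON = {
    "C1": "3+3",
    "C2": "3+4",
    "C3": "4+3",
    "C4": "4+4",
    "C5": "4+5",
    "C6": "5+4",
    "C7": "5+5",
}

CLASSES = tuple(CLASS_SIZES)


# --------------------------------------------------------------------------
# analytic fractal fixtures
# --------------------------------------------------------------------------

def make_sierpinski(depth: int) -> np.ndarray:
    """Sierpinski carpet of side 3**depth with exactly 8**depth foreground cells."""
    if not 1 <= int(depth) <= 6:
        raise ValueError(f"depth must be in [1, 6], got {depth}")
    base = np.ones((3, 3), dtype=bool)
    base[1, 1] = False
    img = base.copy()
    for _ in range(int(depth) - 1):
        img = np.kron(img, base)
    return img


def make_percolation(b: int, levels: int, p: float, seed: int) -> np.ndarray:
    """Random curdling fractal on a b x b subdivision.

    Each surviving cell splits into b^2 subcells, each retained independently
    with probability p; the expected dimension is ``log(b^2 p) / log b`` when
    ``b^2 p > 1``.  Side length is ``b**levels``.
    """
    if b < 2 or levels < 1 or not 0.0 <= p <= 1.0:
        raise ValueError("need b >= 2, levels >= 1, p in [0, 1]")
    rng = np.random.default_rng(seed)
    img = np.ones((1, 1), dtype=bool)
    for _ in range(int(levels)):
        img = np.kron(img, np.ones((b, b), dtype=bool))
        img &= rng.random(img.shape) < p
    return img


def make_cascade(
    levels: int = 8,
    weights: tuple[float, float, float, float] = (0.4, 0.3, 0.2, 0.1),
    n_points: int = 8000,
    seed: int = 0,
) -> np.ndarray:
    """Point-sampled binomial multiplicative cascade (a multifractal fixture).

    A 2^levels square measure is built by recursively splitting each cell's
    mass over its four children with the given weights (randomly permuted per
    parent), then ``n_points`` pixels are drawn i.i.d. from that measure.
    The measure has strictly decreasing Renyi dimensions (for the default
    weights D0 = 2, D1 ~= 1.846, D2 ~= 1.737), and the sampled raster
    reproduces the ordering D0 >= D1 >= D2 when the scale scan stays above
    the mean inter-point spacing (use eps >= 8 at the defaults); finer scales
    are dominated by the finite sampling, which biases D0/D1 down and D2 up.
    """
    w = np.asarray(weights, dtype=np.float64)
    if w.size != 4 or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must be four non-negatives summing to 1")
    if levels < 2 or n_points < 1:
        raise ValueError("need levels >= 2 and n_points >= 1")
    rng = np.random.default_rng(seed)
    measure = np.ones((1, 1), dtype=np.float64)
    for _ in range(int(levels)):
        h, wd = measure.shape
        out = np.empty((2 * h, 2 * wd), dtype=np.float64)
        perms = rng.permuted(np.tile(w, (h * wd, 1)), axis=1).reshape(h, wd, 4)
        out[0::2, 0::2] = measure * perms[:, :, 0]
        out[0::2, 1::2] = measure * perms[:, :, 1]
        out[1::2, 0::2] = measure * perms[:, :, 2]
        out[1::2, 1::2] = measure * perms[:, :, 3]
        measure = out
    flat = measure.ravel()
    cells = rng.choice(flat.size, size=int(n_points), replace=True, p=flat / flat.sum())
    img = np.zeros(flat.size, dtype=bool)
    img[cells] = True
    return img.reshape(measure.shape)


# --------------------------------------------------------------------------
# tissue-like binary maps
# --------------------------------------------------------------------------

@dataclass
class PatternSpec:
    """Parameters of a synthetic nuclei map.

    ``kind`` selects the morphology: ``gland`` (non-overlapping rings of
    nucleus dots around empty lumina), ``infiltrate`` (scattered dots,
    optionally clumped), or the degenerate fixtures ``filled`` / ``line`` /
    ``point``.  ``target_foreground`` (infiltrate only) keeps adding dots
    until the foreground count reaches the target, enabling density-matched
    gland/infiltrate pairs.
    """

    kind: str = "gland"
    size: tuple[int, int] = (432, 648)
    seed: int = 0
    n_glands: int = 12
    gland_radius: float = 28.0
    ring_thickness: float = 7.0
    jitter: float = 2.0
    dot_radius: int = 3
    n_dots: int = 4000
    clumping: float = 0.0
    target_foreground: int | None = None


def _disc_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    r = np.arange(-radius, radius + 1)
    dy, dx = np.meshgrid(r, r, indexing="ij")
    keep = dy**2 + dx**2 <= radius**2
    return dy[keep], dx[keep]


def _stamp_dots(
    img: np.ndarray, centers: np.ndarray, dot_radius: int
) -> None:
    dy, dx = _disc_offsets(dot_radius)
    h, w = img.shape
    for cy, cx in centers:
        yy = np.clip(np.round(cy + dy).astype(int), 0, h - 1)
        xx = np.clip(np.round(cx + dx).astype(int), 0, w - 1)
        img[yy, xx] = True


def _gland_pattern(spec: PatternSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.size
    outer = spec.gland_radius + spec.ring_thickness / 2 + spec.dot_radius
    if 2 * outer >= min(h, w):
        raise PackingError("gland radius too large for the canvas")
    centers: list[tuple[float, float]] = []
    min_sep = 2 * outer + 2.0
    tries = 0
    while len(centers) < spec.n_glands:
        tries += 1
        if tries > 20000:
            raise PackingError(
                f"cannot pack {spec.n_glands} glands of outer radius {outer:.0f} "
                f"onto a {h}x{w} canvas"
            )
        cy = rng.uniform(outer, h - outer)
        cx = rng.uniform(outer, w - outer)
        if all((cy - y) ** 2 + (cx - x) ** 2 >= min_sep**2 for y, x in centers):
            centers.append((cy, cx))
    img = np.zeros((h, w), dtype=bool)
    for cy, cx in centers:
        # nuclei spaced roughly one dot diameter apart along the ring
        n_nuclei = max(8, int(2 * np.pi * spec.gland_radius / (2.2 * spec.dot_radius)))
        theta = rng.uniform(0, 2 * np.pi) + np.linspace(
            0, 2 * np.pi, n_nuclei, endpoint=False
        )
        radii = spec.gland_radius + rng.normal(0, spec.jitter, size=n_nuclei)
        dots = np.column_stack(
            [cy + radii * np.sin(theta), cx + radii * np.cos(theta)]
        )
        _stamp_dots(img, dots, spec.dot_radius)
    return img


def _infiltrate_pattern(spec: PatternSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.size
    img = np.zeros((h, w), dtype=bool)
    margin = spec.dot_radius
    placed: list[tuple[float, float]] = []

    def place_one() -> None:
        if placed and spec.clumping > 0 and rng.random() < spec.clumping:
            base = placed[rng.integers(len(placed))]
            cy = np.clip(base[0] + rng.normal(0, 4 * spec.dot_radius), margin, h - margin)
            cx = np.clip(base[1] + rng.normal(0, 4 * spec.dot_radius), margin, w - margin)
        else:
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
        placed.append((cy, cx))
        _stamp_dots(img, np.array([[cy, cx]]), spec.dot_radius)

    if spec.target_foreground is not None:
        cap = 50 * max(spec.target_foreground // max(_disc_offsets(spec.dot_radius)[0].size, 1), 1)
        while img.sum() < spec.target_foreground and len(placed) < cap:
            place_one()
    else:
        for _ in range(spec.n_dots):
            place_one()
    return img


def make_tissue_pattern(spec: PatternSpec) -> np.ndarray:
    """Binary nuclei map for one of the synthetic morphologies."""
    h, w = spec.size
    if h < 8 or w < 8:
        raise ValueError("canvas too small")
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "gland":
        return _gland_pattern(spec, rng)
    if spec.kind == "infiltrate":
        return _infiltrate_pattern(spec, rng)
    if spec.kind == "filled":
        return np.ones((h, w), dtype=bool)
    if spec.kind == "line":
        img = np.zeros((h, w), dtype=bool)
        img[h // 2, :] = True
        return img
    if spec.kind == "point":
        img = np.zeros((h, w), dtype=bool)
        img[h // 2, w // 2] = True
        return img
    raise ValueError(f"unknown pattern kind: {spec.kind!r}")


# --------------------------------------------------------------------------
# tabular cohorts
# --------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Parameters of a synthetic feature cohort.

    Per-class D0 is drawn from a truncated normal confined to the class's
    cut-off interval (reference means/SDs pre-truncation), so class
    membership is exact by construction.  D1 tracks D0 with a small
    independent noise (``d1_noise``), keeping corr(D0, D1) >= 0.95.  With
    coupling on, lambda is generated from the reference linear relation on D0
    and H from the relation on D1, each plus Gaussian noise; with coupling
    off they are plain normal draws from the class statistics.
    """

    seed: int
    n_per_class: dict[str, int] = field(default_factory=lambda: dict(CLASS_SIZES))
    class_stats: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in TABLE_STATS.items()}
    )
    cutoffs: tuple[float, ...] = PAPER_D0_CUTOFFS
    d0_bounds: tuple[float, float] = (1.40, 1.95)
    couple_lambda: bool = True
    couple_h: bool = True
    noise_lambda: float = 0.02
    noise_h: float = 0.025
    d1_noise: float = 0.005
    include_bph: bool = False
    n_bph: int = 20


def _class_intervals(spec: CohortSpec) -> dict[str, tuple[float, float]]:
    lo, hi = spec.d0_bounds
    cuts = tuple(spec.cutoffs)
    if any(b <= a for a, b in zip(cuts, cuts[1:])):
        raise SpecError("cutoffs must be strictly increasing")
    if not lo < cuts[0] or not cuts[-1] < hi:
        raise SpecError("d0_bounds must bracket the cutoffs")
    edges = (lo,) + cuts + (hi,)
    return {c: (edges[i], edges[i + 1]) for i, c in enumerate(CLASSES)}


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int
) -> np.ndarray:
    if sd <= 0:
        mid = min(max(mean, lo), hi)
        return np.full(n, mid)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Synthetic labeled feature table, one row per case.

    Columns: case_id, complexity_class, gleason_label, d0, d1, d2, lfd_mean,
    lfd_cv, lcfd_mean, lcfd_cv, h, lam.
    """
    intervals = _class_intervals(spec)
    for cls, n in spec.n_per_class.items():
        if cls not in intervals:
            raise SpecError(f"unknown class {cls!r}")
        if n < 0:
            raise SpecError("class sizes must be >= 0")
        lo, hi = intervals[cls]
        mean = spec.class_stats["d0"][cls][0]
        if not (lo - 0.2) < mean < (hi + 0.2):
            raise SpecError(
                f"class {cls} D0 mean {mean} inconsistent with interval ({lo}, {hi}]"
            )
    rng = np.random.default_rng(spec.seed)
    rows: list[dict] = []
    eq8_b, eq8_m = D0_LAMBDA_COEFFS
    eq9_b, eq9_m = D1_ENTROPY_COEFFS
    groups = list(spec.n_per_class.items())
    if spec.include_bph:
        groups.append(("BPH", spec.n_bph))
    for cls, n in groups:
        if n == 0:
            continue
        if cls == "BPH":
            m_d0, s_d0 = spec.class_stats["d0"]["BPH"]
            d0 = rng.normal(m_d0, s_d0, size=n)
        else:
            lo, hi = intervals[cls]
            m_d0, s_d0 = spec.class_stats["d0"][cls]
            d0 = _truncated_normal(rng, m_d0, s_d0, lo, np.nextafter(hi, lo), n)
        m_d1 = spec.class_stats["d1"][cls][0]
        d1 = d0 + (m_d1 - m_d0) + rng.normal(0, spec.d1_noise, size=n)
        if spec.couple_lambda:
            lam = eq8_b + eq8_m * d0 + rng.normal(0, spec.noise_lambda, size=n)
        else:
            lam = rng.normal(*spec.class_stats["lam"][cls], size=n)
        if spec.couple_h:
            h = eq9_b + eq9_m * d1 + rng.normal(0, spec.noise_h, size=n)
        else:
            h = rng.normal(*spec.class_stats["h"][cls], size=n)
        d2 = rng.normal(*spec.class_stats["d2"][cls], size=n)
        lfd = rng.normal(*spec.class_stats["lfd_mean"][cls], size=n)
        lfd_cv = np.abs(rng.normal(*spec.class_stats["lfd_cv"][cls], size=n))
        lcfd = rng.normal(*spec.class_stats["lcfd_mean"][cls], size=n)
        lcfd_cv = np.abs(rng.normal(*spec.class_stats["lcfd_cv"][cls], size=n))
        for i in range(n):
            rows.append(
                {
                    "case_id": f"{cls}-{i + 1:03d}",
                    "complexity_class": cls,
                    "gleason_label": CLASS_GLEASON.get(cls, "BPH"),
                    "d0": d0[i],
                    "d1": d1[i],
                    "d2": d2[i],
                    "lfd_mean": lfd[i],
                    "lfd_cv": lfd_cv[i],
                    "lcfd_mean": lcfd[i],
                    "lcfd_cv": lcfd_cv[i],
                    "h": h[i],
                    "lam": lam[i],
                }
            )
    if not rows:
        raise DegenerateInputError("cohort spec produced no cases")
    return pd.DataFrame(rows)
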