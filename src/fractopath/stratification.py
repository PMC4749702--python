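"""ROC analysis, complexity-class stratification, and aggressiveness tiers.

Carcinomas are stratified into ordered complexity classes C1..C7 by cut-off
values of the capacity dimension D0 (or, equivalently, D1).  A cut-off
between two adjacent ordered groups is found by ROC analysis (Youden index,
ties resolved toward the midpoint of the separating score interval);
re-stratification iterates cut-off estimation and single-step reassignment of
cases lying outside their group's interval until a fixed point is reached, at
which every class is a disjoint D0 interval and every adjacent-class AUC is
exactly 1.0.

The published cut-offs (``PAPER_D0_CUTOFFS``) ship as a fixed boundary set so
cases can be classified without re-estimation, and the two conjunctive
aggressiveness criteria over (D0, LFD, LCFD, H, lambda) assign each case a
low / intermediate / high tier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import LabelError

__all__ = [
    "PAPER_D0_CUTOFFS",
    "ROCResult",
    "ClassBoundaries",
    "RestratifyResult",
    "roc",
    "restratify",
    "classify_d0",
    "paper_boundaries",
    "aggressiveness",
    "LOW_TIER",
    "HIGH_TIER",
]

#: Published D0 cut-offs separating C1|C2, C2|C3, ... C6|C7.
PAPER_D0_CUTOFFS = (1.5450, 1.5820, 1.6270, 1.6490, 1.6980, 1.7640)

#: Low-aggressiveness tier: all five must hold.
LOW_TIER = {"d0_lt": 1.5820, "lfd_lt": 1.3, "lcfd_gt": 1.5, "h_lt": 0.7, "lam_gt": 0.8}
#: High-aggressiveness tier: all five must hold.
HIGH_TIER = {
    "d0_gt": 1.6980,
    "lfd_gt": 1.7644,
    "lcfd_gt": 1.7051,
    "h_gt": 0.9,
    "lam_lt": 0.7,
}


@dataclass
class ROCResult:
    """Full ROC curve between two score groups.

    ``thresholds`` are candidate cut-offs (midpoints between adjacent unique
    scores, plus sentinels below/above the range); a case is called positive
    when its score is strictly above the cut-off.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    optimal_cutoff: float
    p_value: float


@dataclass
class ClassBoundaries:
    """Ordered cut-offs defining interval classes on one classifier."""

    classifier: str
    cutoffs: tuple[float, ...]
    provenance: str = "estimated"
    class_names: tuple[str, ...] = field(default=())

    def __post_init__(self):
        cuts = tuple(float(c) for c in self.cutoffs)
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ValueError("cutoffs must be strictly increasing")
        self.cutoffs = cuts
        if not self.class_names:
            self.class_names = tuple(f"C{i + 1}" for i in range(len(cuts) + 1))
        elif len(self.class_names) != len(cuts) + 1:
            raise ValueError("need one more class name than cutoffs")


@dataclass
class RestratifyResult:
    boundaries: ClassBoundaries
    assignments: np.ndarray
    n_iterations: int
    n_reassigned: int
    collapsed_classes: tuple[str, ...] = ()


def paper_boundaries(classifier: str = "d0") -> ClassBoundaries:
    """The published seven-class boundary set, loadable without estimation."""
    return ClassBoundaries(
        classifier=classifier, cutoffs=PAPER_D0_CUTOFFS, provenance="fixed"
    )


def roc(scores, labels) -> ROCResult:
    """ROC curve, AUC, Youden cut-off and rank-sum p-value.

    ``labels`` is binary; the positive group is label 1 (or True).  The AUC
    is the pairwise-comparison probability with ties counted 1/2, identical
    to the trapezoid area under the empirical curve.  The optimal cut-off
    maximizes sensitivity + specificity - 1; among tied candidates the median
    midpoint is taken, so a perfectly separating cut-off lands in the middle
    of the separating gap.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    if scores.size != labels.size:
        raise ValueError("scores and labels must be paired")
    pos = scores[labels]
    neg = scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise LabelError("both label groups must be non-empty")

    # AUC with ties counted 1/2 via average ranks.
    ranks = stats.rankdata(scores)
    auc = (ranks[labels].sum() - pos.size * (pos.size + 1) / 2) / (
        pos.size * neg.size
    )

    # Normal approximation to the rank-sum statistic (reporting only).
    try:
        p_value = float(
            stats.mannwhitneyu(
                pos, neg, alternative="two-sided", method="asymptotic"
            ).pvalue
        )
    except ValueError:  # all scores identical
        p_value = 1.0

    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    cands = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    sens = np.array([(pos > t).mean() for t in cands])
    spec = np.array([(neg <= t).mean() for t in cands])
    youden = sens + spec - 1.0
    best = youden == youden.max()
    optimal = float(np.median(cands[best]))
    return ROCResult(
        thresholds=cands,
        sensitivity=sens,
        specificity=spec,
        auc=float(auc),
        optimal_cutoff=optimal,
        p_value=p_value,
    )


def _as_class_indices(labels) -> tuple[np.ndarray, list[str]]:
    """Map ordered labels (ints or 'C1'-style names) to 0-based indices."""
    labels = np.asarray(labels)
    if labels.dtype.kind in "iu":
        uniq = np.unique(labels)
        names = [f"C{int(u)}" for u in uniq]
        idx = np.searchsorted(uniq, labels)
        return idx, names
    names = sorted(set(str(x) for x in labels), key=lambda s: (len(s), s))
    lookup = {n: i for i, n in enumerate(names)}
    return np.array([lookup[str(x)] for x in labels]), names


def restratify(
    values, initial_labels, classifier: str = "d0", max_iter: int = 500
) -> RestratifyResult:
    """Iterative re-stratification of cases into interval-consistent classes.

    Starting from ordered initial group labels, each iteration (a) finds the
    ROC (Youden) cut-off between every adjacent pair of classes, (b) moves
    every case whose classifier value falls outside its class's cut-off
    interval one class toward the side it violates, and (c) recomputes, until
    no case moves.  At the fixed point, classes are disjoint intervals of the
    classifier, so every adjacent-class AUC equals 1.0 with sensitivity and
    specificity 1.0.

    Classes emptied during iteration are dropped (reported in
    ``collapsed_classes``) and the boundary list shrinks accordingly.
    """
    values = np.asarray(values, dtype=np.float64)
    idx, names = _as_class_indices(initial_labels)
    if values.size != idx.size:
        raise ValueError("values and labels must be paired")
    if len(names) < 2:
        raise LabelError("need at least two ordered initial groups")

    active = sorted(set(idx.tolist()))
    if len(active) < 2:
        raise LabelError("need at least two non-empty initial groups")
    collapsed: list[str] = []
    n_reassigned = 0
    n_iter = 0
    cutoffs: list[float] = []
    for n_iter in range(1, max_iter + 1):
        cutoffs = []
        for lo, hi in zip(active, active[1:]):
            r = roc(
                np.concatenate([values[idx == lo], values[idx == hi]]),
                np.concatenate(
                    [np.zeros((idx == lo).sum()), np.ones((idx == hi).sum())]
                ),
            )
            cutoffs.append(r.optimal_cutoff)
        moved = 0
        new_idx = idx.copy()
        pos_of = {cls: k for k, cls in enumerate(active)}
        for i in range(values.size):
            k = pos_of[idx[i]]
            if k > 0 and values[i] <= cutoffs[k - 1]:
                new_idx[i] = active[k - 1]
                moved += 1
            elif k < len(active) - 1 and values[i] > cutoffs[k]:
                new_idx[i] = active[k + 1]
                moved += 1
        idx = new_idx
        n_reassigned += moved
        surviving = sorted(set(idx.tolist()))
        if len(surviving) < len(active):
            collapsed.extend(names[c] for c in active if c not in surviving)
            active = surviving
            if len(active) < 2:
                raise LabelError("re-stratification collapsed to a single class")
            continue
        if moved == 0:
            break
    else:
        raise RuntimeError(f"re-stratification did not converge in {max_iter} steps")

    boundaries = ClassBoundaries(
        classifier=classifier,
        cutoffs=tuple(cutoffs),
        provenance="estimated",
        class_names=tuple(names[c] for c in active),
    )
    assignments = np.array([names[c] for c in idx])
    return RestratifyResult(
        boundaries=boundaries,
        assignments=assignments,
        n_iterations=n_iter,
        n_reassigned=n_reassigned,
        collapsed_classes=tuple(collapsed),
    )


def classify_d0(value, boundaries: ClassBoundaries | None = None):
    """Assign classifier values to interval classes.

    Values equal to a cut-off go to the lower class; values above the last
    cut-off go to the top class.  Accepts a scalar (returns one class name)
    or an array (returns an array of names).  Defaults to the published
    boundaries.
    """
    if boundaries is None:
        boundaries = paper_boundaries()
    arr = np.asarray(value, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("classifier values must be finite")
    pos = np.searchsorted(np.asarray(boundaries.cutoffs), arr, side="left")
    names = np.asarray(boundaries.class_names)
    out = names[pos]
    return out.item() if np.isscalar(value) or arr.ndim == 0 else out


def aggressiveness(fv) -> str:
    """Three-tier aggressiveness call from one case's five measures.

    ``fv`` is a mapping (dict, pandas Series, ...) with keys ``d0``,
    ``lfd_mean``, ``lcfd_mean``, ``h``, ``lam``.  Low requires all of
    D0 < 1.5820, LFD < 1.3, LCFD > 1.5, H < 0.7, lambda > 0.8; high requires
    all of D0 > 1.6980, LFD > 1.7644, LCFD > 1.7051, H > 0.9, lambda < 0.7;
    anything else is intermediate.
    """
    try:
        d0 = float(fv["d0"])
        lfd = float(fv["lfd_mean"])
        lcfd = float(fv["lcfd_mean"])
        h = float(fv["h"])
        lam = float(fv["lam"])
    except (KeyError, TypeError) as exc:
        raise ValueError(f"missing measure for aggressiveness call: {exc}") from exc
    vals = (d0, lfd, lcfd, h, lam)
    if not all(np.isfinite(vals)):
        raise ValueError("all five measures must be finite")
    low = (
        d0 < LOW_TIER["d0_lt"]
        and lfd < LOW_TIER["lfd_lt"]
        and lcfd > LOW_TIER["lcfd_gt"]
        and h < LOW_TIER["h_lt"]
        and lam > LOW_TIER["lam_gt"]
    )
    high = (
        d0 > HIGH_TIER["d0_gt"]
        and lfd > HIGH_TIER["lfd_gt"]
        and lcfd > HIGH_TIER["lcfd_gt"]
        and h > HIGH_TIER["h_gt"]
        and lam < HIGH_TIER["lam_lt"]
    )
    if low:
        return "low"
    if high:
        return "high"
    return "intermediate"
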