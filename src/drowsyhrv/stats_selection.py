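"""ROC-area feature ranking and independent two-sample t-tests.

The area under the empirical ROC curve (equivalently the normalised
Mann-Whitney U statistic) measures how well one feature separates the
drowsy group (positive class) from the alert group: 0.5 means complete
overlap, 1.0 perfect separation with drowsy values higher, 0.0 perfect
separation with drowsy values lower.  Areas of at least 0.7 — or at most
0.3, since a reliably *lower* feature is just as usable — mark a feature
as acceptable for classification, so ranking uses the distance
``|area - 0.5|``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import numpy as np
from scipy import stats as sps

__all__ = [
    "ROCResult",
    "TTestResult",
    "roc_area",
    "rank_features",
    "ttest_independent",
]

ACCEPTABLE_HIGH = 0.7
ACCEPTABLE_LOW = 0.3
ALPHA = 0.05


@dataclass(frozen=True)
class ROCResult:
    feature_name: str
    roc_area: float
    direction: Literal["drowsy_higher", "drowsy_lower"]
    acceptable: bool

    @property
    def distance(self) -> float:
        """Distance from the uninformative area 0.5 (the ranking key)."""
        return abs(self.roc_area - 0.5)


@dataclass(frozen=True)
class TTestResult:
    feature_name: str
    t_statistic: float
    p_two_tailed: float
    significant: bool


def roc_area(values: np.ndarray, labels: np.ndarray,
             feature_name: str = "") -> ROCResult:
    """Area under the empirical ROC curve, drowsy (+1) as positive class.

    Computed by the rank-sum (Mann-Whitney) formulation with ties
    credited one half: the fraction of (drowsy, alert) value pairs the
    drowsy member wins.  Labels are +1 (drowsy) / -1 (alert); both
    classes must be non-empty.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    pos = values[labels == 1]
    neg = values[labels == -1]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be non-empty")
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    u = float(np.sum(ranks[:pos.size])) - pos.size * (pos.size + 1) / 2.0
    area = u / (pos.size * neg.size)
    return ROCResult(
        feature_name=feature_name,
        roc_area=area,
        direction="drowsy_higher" if area >= 0.5 else "drowsy_lower",
        acceptable=area >= ACCEPTABLE_HIGH or area <= ACCEPTABLE_LOW,
    )


def rank_features(table: Mapping[str, Iterable[float]] | "np.ndarray",
                  labels: np.ndarray) -> list[ROCResult]:
    """Rank features by how far their ROC area sits from 0.5.

    ``table`` maps feature name to values (one per sample).  Sorted by
    ``|area - 0.5|`` descending; ties broken by feature name for a
    stable, reproducible ordering.
    """
    results = [roc_area(np.asarray(vals, dtype=float), labels, name)
               for name, vals in table.items()]
    return sorted(results, key=lambda r: (-r.distance, r.feature_name))


def ttest_independent(group_a: np.ndarray, group_b: np.ndarray,
                      feature_name: str = "",
                      equal_var: bool = True) -> TTestResult:
    """Independent two-sample t-test (pooled variance by default).

    ``equal_var=False`` selects the Welch variant.  Significance is
    judged two-tailed at alpha = 0.05.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
        raise ValueError("zero pooled variance: t statistic undefined")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(feature_name=feature_name, t_statistic=float(t),
                       p_two_tailed=float(p), significant=bool(p < ALPHA))
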