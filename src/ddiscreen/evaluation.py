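"""Classification metrics and inter-algorithm agreement.

Signal sets are scored against a truth set over a fixed triple universe
(confusion counts, then accuracy / precision / recall / specificity /
Youden's index / F-measure / NPV), and compared with each other via
Cohen's kappa plus the chance-uncorrected positive and negative
proportionate agreements.

Ratios with a zero denominator are reported as ``None`` (undefined),
never coerced to 0 or 1.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence, Set
from dataclasses import dataclass
from typing import Optional

from .contingency import ContingencyTable4x2, TripleKey
from .signals import Z975

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "AgreementResult",
    "confusion",
    "metrics",
    "agreement",
    "stratify_by_reports",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN of a signal set against a truth set."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def detected(self) -> int:
        """Number of triples the detector flagged (TP + FP)."""
        return self.tp + self.fp


@dataclass(frozen=True)
class MetricSet:
    """The seven classification indicators; ``None`` marks an undefined ratio."""

    accuracy: Optional[float]
    precision_ppv: Optional[float]
    recall_sensitivity: Optional[float]
    specificity: Optional[float]
    youden_index: Optional[float]
    f_measure: Optional[float]
    npv: Optional[float]

    FIELDS = (
        "accuracy",
        "precision_ppv",
        "recall_sensitivity",
        "specificity",
        "youden_index",
        "f_measure",
        "npv",
    )

    def rounded(self, ndigits: int = 3) -> dict[str, Optional[float]]:
        """Values rounded half-to-even at the reporting precision."""
        return {
            name: (None if v is None else round(v, ndigits))
            for name, v in ((f, getattr(self, f)) for f in self.FIELDS)
        }


def _ratio(num: float, den: float) -> Optional[float]:
    return None if den == 0 else num / den


def confusion(
    predicted: Set[TripleKey],
    truth: Set[TripleKey],
    universe: Iterable[TripleKey],
) -> ConfusionCounts:
    """Confusion counts of ``predicted`` against ``truth`` over ``universe``."""
    universe_set = set(universe)
    stray = (set(predicted) | set(truth)) - universe_set
    if stray:
        raise ValueError(f"{len(stray)} triple(s) outside the universe, e.g. {sorted(stray)[0]}")
    tp = len(set(predicted) & set(truth))
    fp = len(set(predicted) - set(truth))
    fn = len(set(truth) - set(predicted))
    tn = len(universe_set) - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(c: ConfusionCounts) -> MetricSet:
    """All seven indicators from unrounded ratios.

    accuracy = (TP+TN)/total; precision = TP/(TP+FP);
    recall = TP/(TP+FN); specificity = TN/(FP+TN);
    Youden = recall + specificity - 1; F = 2PR/(P+R);
    NPV = TN/(TN+FN).
    """
    if c.total == 0:
        raise ValueError("confusion counts are all zero")
    accuracy = _ratio(c.tp + c.tn, c.total)
    precision = _ratio(c.tp, c.tp + c.fp)
    recall = _ratio(c.tp, c.tp + c.fn)
    specificity = _ratio(c.tn, c.fp + c.tn)
    youden = None if recall is None or specificity is None else recall + specificity - 1.0
    if precision is None or recall is None or precision + recall == 0:
        f_measure = None
    else:
        f_measure = 2.0 * recall * precision / (recall + precision)
    npv = _ratio(c.tn, c.tn + c.fn)
    return MetricSet(
        accuracy=accuracy,
        precision_ppv=precision,
        recall_sensitivity=recall,
        specificity=specificity,
        youden_index=youden,
        f_measure=f_measure,
        npv=npv,
    )


@dataclass(frozen=True)
class AgreementResult:
    """Cohen's kappa (with 95% CI) and proportionate agreements.

    ``table`` holds the 2x2 agreement counts (a, b, c, d) = (both flag,
    only A flags, only B flags, neither flags).
    """

    kappa: Optional[float]
    kappa_ci_lower: Optional[float]
    kappa_ci_upper: Optional[float]
    p_positive: Optional[float]
    p_negative: Optional[float]
    table: tuple[int, int, int, int]


def _kappa_variance(a: int, b: int, c: int, d: int, po: float, pe: float) -> float:
    # Large-sample variance of the kappa estimate (Fleiss-Cohen-Everitt),
    # specialised to two categories.
    n = a + b + c + d
    p = [[a / n, b / n], [c / n, d / n]]
    row = [p[0][0] + p[0][1], p[1][0] + p[1][1]]
    col = [p[0][0] + p[1][0], p[0][1] + p[1][1]]
    term1 = sum(
        p[i][i] * ((1 - pe) - (row[i] + col[i]) * (1 - po)) ** 2 for i in range(2)
    )
    term2 = (1 - po) ** 2 * sum(
        p[i][j] * (col[i] + row[j]) ** 2 for i in range(2) for j in range(2) if i != j
    )
    term3 = (po * pe - 2 * pe + po) ** 2
    return (term1 + term2 - term3) / (n * (1 - pe) ** 4)


def agreement(
    set_a: Set[TripleKey],
    set_b: Set[TripleKey],
    universe: Iterable[TripleKey],
    z: float = Z975,
) -> AgreementResult:
    """Cohen's kappa and positive/negative proportionate agreement.

    kappa = (po - pe) / (1 - pe) with po the observed agreement and pe
    the chance agreement from the marginals; the CI uses the asymptotic
    standard error.  With degenerate marginals (pe = 1), kappa is 1 for
    perfect agreement and undefined otherwise.
    """
    universe_set = set(universe)
    stray = (set(set_a) | set(set_b)) - universe_set
    if stray:
        raise ValueError(f"{len(stray)} triple(s) outside the universe, e.g. {sorted(stray)[0]}")
    n = len(universe_set)
    if n == 0:
        raise ValueError("empty universe")
    a = len(set(set_a) & set(set_b))
    b = len(set(set_a) - set(set_b))
    c = len(set(set_b) - set(set_a))
    d = n - a - b - c

    po = (a + d) / n
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / n**2
    if pe == 1.0:
        kappa = 1.0 if po == 1.0 else None
        lower = upper = kappa
    else:
        kappa = (po - pe) / (1.0 - pe)
        se = math.sqrt(max(_kappa_variance(a, b, c, d, po, pe), 0.0))
        lower, upper = kappa - z * se, kappa + z * se

    p_positive = _ratio(2 * a, 2 * a + b + c)
    p_negative = _ratio(2 * d, 2 * d + b + c)
    return AgreementResult(
        kappa=kappa,
        kappa_ci_lower=lower,
        kappa_ci_upper=upper,
        p_positive=p_positive,
        p_negative=p_negative,
        table=(a, b, c, d),
    )


def stratify_by_reports(
    signal_sets: Mapping[str, Set[TripleKey]],
    tables: Mapping[TripleKey, ContingencyTable4x2],
    min_n111: int,
) -> tuple[list[TripleKey], dict[str, set[TripleKey]]]:
    """Restrict the universe and every signal set to triples with n111 >= floor.

    Returns the filtered universe (sorted) and the filtered signal sets;
    confusion/agreement are then computed on the restricted universe.
    """
    if min_n111 < 0:
        raise ValueError("min_n111 must be >= 0")
    universe = sorted(t for t, tab in tables.items() if tab.n111 >= min_n111)
    keep = set(universe)
    filtered = {name: set(s) & keep for name, s in signal_sets.items()}
    return universe, filtered
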