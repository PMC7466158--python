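"""Signal statistics and detection verdicts for drug-drug interaction screening.

Detectors operate on a :class:`~ddiscreen.contingency.ContingencyTable4x2`
and return a :class:`SignalVerdict` carrying the statistic values, the
interval bound used for the decision, and the boolean verdict.

Implemented detectors:

* subset reporting odds ratio (ROR), under either the *previous*
  criterion (signal in at least one directional subset) or the *new*
  criterion (signal required in both directional subsets);
* the Omega shrinkage measure (log2 shrinkage observed/expected ratio
  for three-way co-reporting, signal when the lower credibility bound
  Omega025 exceeds 0);
* three component interaction models — additive (risk difference),
  multiplicative (ratio of risk ratios) and a Yates-corrected one-sided
  chi-square — whose intersection forms the surrogate ("hypothetical")
  truth set used for evaluation.

All decision thresholds use strict inequalities: a bound landing exactly
on the threshold is not a signal.
"""

from __future__ import annotations

import enum
import math
from collections.abc import Iterable, Mapping, Set
from dataclasses import dataclass, field, replace
from typing import Optional

from .contingency import ContingencyTable4x2, Perspective, SubsetView, TripleKey, subset_view

__all__ = [
    "Z975",
    "Algorithm",
    "SubsetCriterion",
    "RorConfig",
    "RorResult",
    "SubsetRorDetail",
    "OmegaResult",
    "AdditiveResult",
    "MultiplicativeResult",
    "ChiSquareResult",
    "SignalVerdict",
    "ror",
    "subset_signal",
    "omega_signal",
    "g11_from_f",
    "additive_signal",
    "multiplicative_signal",
    "chi_square_signal",
    "hypothetical_truth",
    "detect_all",
]

#: 97.5th percentile of the standard normal, fixed to double precision so
#: that results are bit-reproducible across platforms.
Z975 = 1.959964

#: Upper 5% critical value of the chi-square distribution with 1 df.
CHI2_CRIT_1DF = 3.841

#: f-cells exactly equal to 1 are clamped below 1 before the odds
#: transform (the odds of 1 is infinite).
_F_CLAMP = 1.0 - 1e-12


class Algorithm(enum.Enum):
    SUBSET_PREVIOUS = "subset-previous"
    SUBSET_NEW = "subset-new"
    OMEGA = "omega"
    ADDITIVE = "additive"
    MULTIPLICATIVE = "multiplicative"
    CHI_SQUARE = "chi-square"
    TRUTH = "truth"


class SubsetCriterion(enum.Enum):
    """Previous: signal in either directional subset.  New: in both."""

    PREVIOUS = "previous"
    NEW = "new"


# ---------------------------------------------------------------------------
# subset ROR
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RorConfig:
    """Decision rule for a single-subset ROR signal.

    A subset signals when the ROR is computable, its lower confidence
    bound exceeds ``threshold``, and N11 >= ``min_n11``.  ``haldane``
    adds 0.5 to all four cells (exploratory; off by default so zero-cell
    subsets are simply not computable).
    """

    threshold: float = 1.0
    min_n11: int = 0
    haldane: bool = False
    z: float = Z975


DEFAULT_ROR_CONFIG = RorConfig()


@dataclass(frozen=True)
class RorResult:
    """Point estimate and 95% CI of the reporting odds ratio."""

    ror: float
    ci_lower: float
    ci_upper: float
    computable: bool

    @classmethod
    def not_computable(cls) -> "RorResult":
        return cls(math.nan, math.nan, math.nan, False)


def ror(subset: SubsetView, config: RorConfig = DEFAULT_ROR_CONFIG) -> RorResult:
    """Reporting odds ratio of a 2x2 subset with its 95% confidence interval.

    ROR = (N11/N10) / (N01/N00); the CI is computed on the log scale with
    standard error sqrt(1/N11 + 1/N10 + 1/N01 + 1/N00).  Any zero cell
    makes the estimate non-computable unless the Haldane-Anscombe
    correction is enabled.
    """
    counts = subset.counts()
    if any(c < 0 for c in counts):
        raise ValueError(f"negative count in subset: {counts}")
    n11, n10, n01, n00 = (float(c) for c in counts)
    if config.haldane:
        n11, n10, n01, n00 = n11 + 0.5, n10 + 0.5, n01 + 0.5, n00 + 0.5
    if min(n11, n10, n01, n00) == 0:
        return RorResult.not_computable()
    estimate = (n11 * n00) / (n10 * n01)
    se = math.sqrt(1 / n11 + 1 / n10 + 1 / n01 + 1 / n00)
    log_ror = math.log(estimate)
    return RorResult(
        ror=estimate,
        ci_lower=math.exp(log_ror - config.z * se),
        ci_upper=math.exp(log_ror + config.z * se),
        computable=True,
    )


@dataclass(frozen=True)
class SubsetRorDetail:
    """Both directional subset RORs plus the per-subset signal booleans."""

    within_d1: RorResult
    within_d2: RorResult
    signal_d1: bool
    signal_d2: bool


@dataclass(frozen=True)
class SignalVerdict:
    """One detector's verdict on one triple."""

    algorithm: Algorithm
    signal: bool
    detail: object = None
    triple: Optional[TripleKey] = None


def _single_subset_signal(result: RorResult, n11: int, config: RorConfig) -> bool:
    return bool(
        result.computable
        and result.ci_lower > config.threshold
        and n11 >= config.min_n11
    )


def subset_signal(
    table: ContingencyTable4x2,
    criterion: SubsetCriterion,
    config: RorConfig = DEFAULT_ROR_CONFIG,
    triple: Optional[TripleKey] = None,
) -> SignalVerdict:
    """Subset-ROR interaction verdict under the previous or new criterion.

    Let s1 be the drug-2 signal within drug-1 users and s2 the drug-1
    signal within drug-2 users.  PREVIOUS declares an interaction signal
    when s1 OR s2; NEW requires s1 AND s2.
    """
    view1 = subset_view(table, Perspective.WITHIN_D1_USERS)
    view2 = subset_view(table, Perspective.WITHIN_D2_USERS)
    r1 = ror(view1, config)
    r2 = ror(view2, config)
    s1 = _single_subset_signal(r1, view1.N11, config)
    s2 = _single_subset_signal(r2, view2.N11, config)
    if criterion is SubsetCriterion.PREVIOUS:
        signal = s1 or s2
        algorithm = Algorithm.SUBSET_PREVIOUS
    elif criterion is SubsetCriterion.NEW:
        signal = s1 and s2
        algorithm = Algorithm.SUBSET_NEW
    else:
        raise ValueError(f"invalid criterion: {criterion!r}")
    return SignalVerdict(
        algorithm=algorithm,
        signal=signal,
        detail=SubsetRorDetail(r1, r2, s1, s2),
        triple=triple,
    )


# ---------------------------------------------------------------------------
# Omega shrinkage measure
# ---------------------------------------------------------------------------

def _odds(x: float) -> float:
    return x / (1.0 - x)


def g11_from_f(f00: float, f10: float, f01: float) -> float:
    """Expected event proportion under co-exposure, on the odds scale.

    odds(g11) = max(o(f00), o(f10)) + max(o(f00), o(f01)) - o(f00) with
    o(x) = x/(1-x).  Reduces to g11 = max(f00, f01) when f10 < f00 and
    to g11 = max(f00, f10) when f01 < f00 (the odds transform is
    monotone).  Inputs equal to 1 are clamped just below 1.
    """
    f00c = min(f00, _F_CLAMP)
    f10c = min(f10, _F_CLAMP)
    f01c = min(f01, _F_CLAMP)
    odds_g11 = max(_odds(f00c), _odds(f10c)) + max(_odds(f00c), _odds(f01c)) - _odds(f00c)
    return 1.0 - 1.0 / (odds_g11 + 1.0)


@dataclass(frozen=True)
class OmegaResult:
    """Omega shrinkage measure components for one triple."""

    f00: float
    f10: float
    f01: float
    f11: float
    g11: float
    e111: float
    omega: float
    omega025: float
    signal: bool
    computable: bool = True
    clamped: bool = False

    @classmethod
    def not_computable(cls) -> "OmegaResult":
        nan = math.nan
        return cls(nan, nan, nan, nan, nan, nan, nan, nan, False, False, False)


def omega_signal(
    table: ContingencyTable4x2, triple: Optional[TripleKey] = None
) -> SignalVerdict:
    """Omega shrinkage measure verdict: signal iff Omega025 > 0.

    Omega = log2((n111 + 0.5) / (E111 + 0.5)) with E111 = g11 * n11p, and
    Omega025 = Omega - z / (ln 2 * sqrt(n111)).  Requires all four row
    marginals positive; n111 = 0 yields Omega025 = -inf (never a signal).
    """
    if min(table.n11p, table.n10p, table.n01p, table.n00p) == 0:
        return SignalVerdict(Algorithm.OMEGA, False, OmegaResult.not_computable(), triple)
    f00 = table.n001 / table.n00p
    f10 = table.n101 / table.n10p
    f01 = table.n011 / table.n01p
    f11 = table.n111 / table.n11p
    clamped = max(f00, f10, f01) >= 1.0
    g11 = g11_from_f(f00, f10, f01)
    e111 = g11 * table.n11p
    omega = math.log2((table.n111 + 0.5) / (e111 + 0.5))
    if table.n111 > 0:
        omega025 = omega - Z975 / (math.log(2.0) * math.sqrt(table.n111))
    else:
        omega025 = -math.inf
    result = OmegaResult(
        f00=f00, f10=f10, f01=f01, f11=f11,
        g11=g11, e111=e111,
        omega=omega, omega025=omega025,
        signal=omega025 > 0.0,
        computable=True,
        clamped=clamped,
    )
    return SignalVerdict(Algorithm.OMEGA, result.signal, result, triple)


# ---------------------------------------------------------------------------
# component interaction models (surrogate-truth constituents)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AdditiveResult:
    """Excess risk beyond additivity with its one-sided lower bound."""

    delta: float
    se: float
    lower: float
    signal: bool
    computable: bool = True

    @classmethod
    def not_computable(cls) -> "AdditiveResult":
        return cls(math.nan, math.nan, math.nan, False, False)


def additive_signal(
    table: ContingencyTable4x2, z: float = Z975, triple: Optional[TripleKey] = None
) -> SignalVerdict:
    """Additive-model verdict: risk difference beyond additivity.

    delta = f11 - f10 - f01 + f00 with binomial variance
    sum_ij fij (1 - fij) / nij+; signal iff delta - z * sqrt(var) > 0.
    """
    if min(table.n11p, table.n10p, table.n01p, table.n00p) == 0:
        return SignalVerdict(Algorithm.ADDITIVE, False, AdditiveResult.not_computable(), triple)
    f11 = table.n111 / table.n11p
    f10 = table.n101 / table.n10p
    f01 = table.n011 / table.n01p
    f00 = table.n001 / table.n00p
    delta = f11 - f10 - f01 + f00
    var = (
        f11 * (1 - f11) / table.n11p
        + f10 * (1 - f10) / table.n10p
        + f01 * (1 - f01) / table.n01p
        + f00 * (1 - f00) / table.n00p
    )
    se = math.sqrt(var)
    lower = delta - z * se
    result = AdditiveResult(delta=delta, se=se, lower=lower, signal=lower > 0.0)
    return SignalVerdict(Algorithm.ADDITIVE, result.signal, result, triple)


@dataclass(frozen=True)
class MultiplicativeResult:
    """Ratio of risk ratios with its log-scale 95% CI."""

    ratio: float
    ci_lower: float
    ci_upper: float
    signal: bool
    computable: bool = True

    @classmethod
    def not_computable(cls) -> "MultiplicativeResult":
        return cls(math.nan, math.nan, math.nan, False, False)


def multiplicative_signal(
    table: ContingencyTable4x2, z: float = Z975, triple: Optional[TripleKey] = None
) -> SignalVerdict:
    """Multiplicative-model verdict: ratio of risk ratios above 1.

    R = (f11 * f00) / (f10 * f01); log-scale variance
    sum_ij (1 - fij) / (nij+ * fij); signal iff the lower CI bound of R
    exceeds 1.  Any zero f-cell makes the test non-computable.
    """
    if min(table.n11p, table.n10p, table.n01p, table.n00p) == 0:
        return SignalVerdict(
            Algorithm.MULTIPLICATIVE, False, MultiplicativeResult.not_computable(), triple
        )
    f11 = table.n111 / table.n11p
    f10 = table.n101 / table.n10p
    f01 = table.n011 / table.n01p
    f00 = table.n001 / table.n00p
    if min(f11, f10, f01, f00) == 0.0:
        return SignalVerdict(
            Algorithm.MULTIPLICATIVE, False, MultiplicativeResult.not_computable(), triple
        )
    ratio = (f11 * f00) / (f10 * f01)
    var = (
        (1 - f11) / (table.n11p * f11)
        + (1 - f10) / (table.n10p * f10)
        + (1 - f01) / (table.n01p * f01)
        + (1 - f00) / (table.n00p * f00)
    )
    se = math.sqrt(var)
    log_ratio = math.log(ratio)
    result = MultiplicativeResult(
        ratio=ratio,
        ci_lower=math.exp(log_ratio - z * se),
        ci_upper=math.exp(log_ratio + z * se),
        signal=math.exp(log_ratio - z * se) > 1.0,
    )
    return SignalVerdict(Algorithm.MULTIPLICATIVE, result.signal, result, triple)


@dataclass(frozen=True)
class ChiSquareResult:
    """Yates-corrected one-sided chi-square against the multiplicative null."""

    statistic: float
    expected: float
    signal: bool
    computable: bool = True

    @classmethod
    def not_computable(cls) -> "ChiSquareResult":
        return cls(math.nan, math.nan, False, False)


def chi_square_signal(
    table: ContingencyTable4x2,
    critical: float = CHI2_CRIT_1DF,
    triple: Optional[TripleKey] = None,
) -> SignalVerdict:
    """Chi-square verdict: Yates-corrected excess of n111 over its expectation.

    e = n11p * f10 * f01 / f00 (clamped to [0, n11p]); the statistic is
    (|n111 - e| - 0.5)^2 * (1/e + 1/(n11p - e)); signal iff the statistic
    exceeds the 1-df critical value AND n111 > e (one-sided guard).
    """
    if min(table.n11p, table.n10p, table.n01p, table.n00p) == 0 or table.n001 == 0:
        return SignalVerdict(
            Algorithm.CHI_SQUARE, False, ChiSquareResult.not_computable(), triple
        )
    f10 = table.n101 / table.n10p
    f01 = table.n011 / table.n01p
    f00 = table.n001 / table.n00p
    expected = min(max(table.n11p * f10 * f01 / f00, 0.0), float(table.n11p))
    if expected <= 0.0 or expected >= table.n11p:
        return SignalVerdict(
            Algorithm.CHI_SQUARE, False, ChiSquareResult.not_computable(), triple
        )
    deviation = max(abs(table.n111 - expected) - 0.5, 0.0)
    statistic = deviation**2 * (1.0 / expected + 1.0 / (table.n11p - expected))
    signal = statistic > critical and table.n111 > expected
    result = ChiSquareResult(statistic=statistic, expected=expected, signal=signal)
    return SignalVerdict(Algorithm.CHI_SQUARE, signal, result, triple)


# ---------------------------------------------------------------------------
# surrogate truth
# ---------------------------------------------------------------------------

VerdictMap = Mapping[TripleKey, SignalVerdict]


def _signal_set(verdicts: "VerdictMap | Set[TripleKey]") -> Set[TripleKey]:
    if isinstance(verdicts, Mapping):
        return {t for t, v in verdicts.items() if v.signal}
    return set(verdicts)


def hypothetical_truth(
    additive: "VerdictMap | Set[TripleKey]",
    multiplicative: "VerdictMap | Set[TripleKey]",
    chi_square: "VerdictMap | Set[TripleKey]",
) -> set[TripleKey]:
    """Surrogate truth: triples flagged by all three component models.

    Accepts either verdict mappings (whose key sets — the universes —
    must coincide) or plain signal sets.
    """
    maps = [v for v in (additive, multiplicative, chi_square) if isinstance(v, Mapping)]
    if maps:
        universes = [set(m.keys()) for m in maps]
        if any(u != universes[0] for u in universes[1:]):
            raise ValueError("verdict sets were computed over different triple universes")
    sets = [_signal_set(v) for v in (additive, multiplicative, chi_square)]
    return set(sets[0]) & set(sets[1]) & set(sets[2])


# ---------------------------------------------------------------------------
# batch driver
# ---------------------------------------------------------------------------

def detect_all(
    tables: Mapping[TripleKey, ContingencyTable4x2],
    algorithm: Algorithm,
    ror_config: RorConfig = DEFAULT_ROR_CONFIG,
) -> dict[TripleKey, SignalVerdict]:
    """Run one detector over every triple; TRUTH intersects the three models."""
    if algorithm is Algorithm.TRUTH:
        parts = {
            alg: detect_all(tables, alg)
            for alg in (Algorithm.ADDITIVE, Algorithm.MULTIPLICATIVE, Algorithm.CHI_SQUARE)
        }
        truth = hypothetical_truth(*parts.values())
        return {
            t: SignalVerdict(Algorithm.TRUTH, t in truth, None, t) for t in tables
        }

    out: dict[TripleKey, SignalVerdict] = {}
    for t, table in tables.items():
        if algorithm is Algorithm.SUBSET_PREVIOUS:
            out[t] = subset_signal(table, SubsetCriterion.PREVIOUS, ror_config, t)
        elif algorithm is Algorithm.SUBSET_NEW:
            out[t] = subset_signal(table, SubsetCriterion.NEW, ror_config, t)
        elif algorithm is Algorithm.OMEGA:
            out[t] = omega_signal(table, t)
        elif algorithm is Algorithm.ADDITIVE:
            out[t] = additive_signal(table, triple=t)
        elif algorithm is Algorithm.MULTIPLICATIVE:
            out[t] = multiplicative_signal(table, triple=t)
        elif algorithm is Algorithm.CHI_SQUARE:
            out[t] = chi_square_signal(table, triple=t)
        else:
            raise ValueError(f"unknown algorithm: {algorithm!r}")
    return out
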