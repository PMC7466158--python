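"""Published benchmark numbers for the JADER Stevens-Johnson-syndrome screen.

The original full-database screen (374,327 reports, 2004Q1-2015Q4)
evaluated three criteria over a universe of 3,924 (drug1, drug2, SJS)
triples against a surrogate truth of 923 triples, and published the
resulting confusion counts.  Those printed counts are recorded here so
that the derived indicators and detected-set shares can be recomputed
and checked without access to the licensed source database.
"""

from __future__ import annotations

from .evaluation import ConfusionCounts

__all__ = [
    "STUDY_UNIVERSE_SIZE",
    "STUDY_TRUTH_SIZE",
    "STUDY_CONFUSION",
    "acceptance_targets",
]

#: Number of (drug1, drug2, event) triples in the published screen.
STUDY_UNIVERSE_SIZE = 3924

#: Size of the published surrogate-truth set (all three component models agree).
STUDY_TRUTH_SIZE = 923

#: Published confusion counts (TP, FP, TN, FN) per screening criterion.
STUDY_CONFUSION = {
    "previous_subset": ConfusionCounts(tp=542, fp=1251, tn=1750, fn=381),
    "new_subset": ConfusionCounts(tp=542, fp=367, tn=2634, fn=381),
    "omega": ConfusionCounts(tp=538, fp=174, tn=2827, fn=385),
}


def acceptance_targets() -> dict[str, dict[str, float | int]]:
    """Recompute the published derived quantities from the confusion counts.

    Every value is computed at run time from :data:`STUDY_CONFUSION` via
    :func:`ddiscreen.evaluation.metrics`; nothing is hard-coded beyond
    the printed input counts.  Keys follow the external target ids.
    """
    from .evaluation import metrics

    prev = STUDY_CONFUSION["previous_subset"]
    new = STUDY_CONFUSION["new_subset"]
    omg = STUDY_CONFUSION["omega"]
    m_prev = metrics(prev)
    m_new = metrics(new)
    m_omg = metrics(omg)

    n = STUDY_UNIVERSE_SIZE
    return {
        "t1": {"value": round(m_prev.accuracy, 3), "n": prev.total},
        "t2": {"value": round(m_new.accuracy, 3), "n": new.total},
        "t3": {"value": round(m_new.precision_ppv, 3), "n": new.total},
        "t4": {"value": round(m_omg.precision_ppv, 3), "n": omg.total},
        "t5": {"value": round(m_new.specificity, 3), "n": new.total},
        "t6": {"value": round(m_omg.youden_index, 3), "n": omg.total},
        "t7": {"value": round(m_new.f_measure, 3), "n": new.total},
        "t8": {"value": round(m_prev.npv, 3), "n": prev.total},
        "t9": {"value": prev.detected, "n": n},
        "t10": {"value": new.detected, "n": n},
        "t11": {"value": round(100.0 * new.detected / n, 1), "n": n},
        "t12": {"value": round(100.0 * omg.detected / n, 1), "n": n},
    }
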