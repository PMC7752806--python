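"""Questionnaire scoring and group assignment.

Instruments and rules:

* PCL-5 (PTSD Checklist for DSM-5): 20 items, 0-4 each, total 0-80;
  provisional PTSD+ at total >= 33.  Cluster scores follow the DSM-5 item
  blocks: B (intrusion) items 1-5, C (avoidance) 6-7, D (negative
  mood/cognition) 8-14, E (arousal/reactivity) 15-20.
* PHQ-8: 8 items, 0-3 each, total 0-24.  Aggregate scoring bands: None 0-4,
  Mild 5-9, Moderate 10-14, Moderately Severe 15-20, Severe >20; total >=
  10 flags clinically significant depression.  Symptom scoring requires
  depressed mood or anhedonia "more than half the days" (response >= 2)
  plus at least five of eight symptoms at that frequency.
* AMBI (Adult Measure of Behavioural Inhibition): 16 items, 0-2 each,
  total 0-32; behaviourally inhibited at total > 15.5.
* Head-injury screen: mTBI+ requires an injury event with altered
  consciousness and loss of consciousness absent or <= 30 min (the
  conventional mild-severity bound); an approximation of the full clinical
  screen, swappable via the ``loc_limit_min`` argument.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import pandas as pd

from .synthdata import SubjectRecord, TbiScreen

__all__ = [
    "PhqCategory",
    "ScoredSubject",
    "score_pcl5",
    "score_phq8",
    "score_ambi",
    "classify_mtbi",
    "score_subject",
    "score_cohort",
    "PCL_CUTOFF",
    "AMBI_CUTOFF",
]

PCL_CUTOFF = 33
AMBI_CUTOFF = 15.5
PHQ_AGGREGATE_CUTOFF = 10

# DSM-5 symptom-cluster item blocks (1-based, inclusive)
PCL_CLUSTERS = {"b": (1, 5), "c": (6, 7), "d": (8, 14), "e": (15, 20)}


class PhqCategory(str, enum.Enum):
    NONE = "None"
    MILD = "Mild"
    MODERATE = "Moderate"
    MODERATELY_SEVERE = "ModeratelySevere"
    SEVERE = "Severe"


@dataclass(frozen=True)
class ScoredSubject:
    subject_id: str
    pcl_total: int
    pcl_cluster_b: int
    pcl_cluster_c: int
    pcl_cluster_d: int
    pcl_cluster_e: int
    ptsd_positive: bool
    phq_total: int
    phq_category: PhqCategory
    mdd_symptom_positive: bool
    mdd_aggregate_positive: bool
    ambi_total: int
    bi_positive: bool
    mtbi_positive: bool


def _check_items(items, n, lo, hi, name):
    items = list(items)
    if len(items) != n:
        raise ValueError(f"{name} requires exactly {n} items, got {len(items)}")
    for v in items:
        if not (isinstance(v, (int,)) or float(v).is_integer()) or not lo <= v <= hi:
            raise ValueError(f"{name} items must be integers in {lo}..{hi}")
    return [int(v) for v in items]


def score_pcl5(items) -> tuple[int, int, int, int, int, bool]:
    """Return (total, cluster_b, cluster_c, cluster_d, cluster_e, ptsd_positive)."""
    items = _check_items(items, 20, 0, 4, "PCL-5")
    clusters = {
        k: sum(items[lo - 1 : hi]) for k, (lo, hi) in PCL_CLUSTERS.items()
    }
    total = sum(items)
    return (
        total,
        clusters["b"],
        clusters["c"],
        clusters["d"],
        clusters["e"],
        total >= PCL_CUTOFF,
    )


def phq_category(total: int) -> PhqCategory:
    if total <= 4:
        return PhqCategory.NONE
    if total <= 9:
        return PhqCategory.MILD
    if total <= 14:
        return PhqCategory.MODERATE
    if total <= 20:
        return PhqCategory.MODERATELY_SEVERE
    return PhqCategory.SEVERE


def score_phq8(items) -> tuple[int, PhqCategory, bool, bool]:
    """Return (total, category, mdd_symptom_positive, mdd_aggregate_positive).

    Items 1 and 2 are the anchor symptoms (depressed mood, anhedonia);
    a response >= 2 codes "more than half the days".
    """
    items = _check_items(items, 8, 0, 3, "PHQ-8")
    total = sum(items)
    frequent = sum(1 for v in items if v >= 2)
    symptom = (items[0] >= 2 or items[1] >= 2) and frequent >= 5
    return total, phq_category(total), symptom, total >= PHQ_AGGREGATE_CUTOFF


def score_ambi(items) -> tuple[int, bool]:
    """Return (total, bi_positive); BI at total > 15.5."""
    items = _check_items(items, 16, 0, 2, "AMBI")
    total = sum(items)
    return total, total > AMBI_CUTOFF


def classify_mtbi(screen: TbiScreen, loc_limit_min: float = 30.0) -> bool:
    """Mild-TBI predicate over the head-injury screen."""
    if screen.event is None or screen.alteration_of_consciousness is None:
        raise ValueError("screen must state event and alteration of consciousness")
    if not screen.event or not screen.alteration_of_consciousness:
        return False
    if screen.loc_duration_min is None:
        return True
    return screen.loc_duration_min <= loc_limit_min


def score_subject(subject: SubjectRecord) -> ScoredSubject:
    total, b, c, d, e, ptsd = score_pcl5(subject.pcl5_items)
    phq_total, cat, sym, agg = score_phq8(subject.phq8_items)
    ambi_total, bi = score_ambi(subject.ambi_items)
    return ScoredSubject(
        subject_id=subject.subject_id,
        pcl_total=total,
        pcl_cluster_b=b,
        pcl_cluster_c=c,
        pcl_cluster_d=d,
        pcl_cluster_e=e,
        ptsd_positive=ptsd,
        phq_total=phq_total,
        phq_category=cat,
        mdd_symptom_positive=sym,
        mdd_aggregate_positive=agg,
        ambi_total=ambi_total,
        bi_positive=bi,
        mtbi_positive=classify_mtbi(subject.tbi_screen),
    )


def score_cohort(cohort: list[SubjectRecord]) -> pd.DataFrame:
    """Scored table, one row per subject, joined with age and group labels."""
    rows = []
    for s in cohort:
        sc = score_subject(s)
        rows.append(
            {
                "subject_id": sc.subject_id,
                "age": s.age,
                "sex": s.sex,
                "pcl_total": sc.pcl_total,
                "pcl_cluster_b": sc.pcl_cluster_b,
                "pcl_cluster_c": sc.pcl_cluster_c,
                "pcl_cluster_d": sc.pcl_cluster_d,
                "pcl_cluster_e": sc.pcl_cluster_e,
                "ptsd_positive": sc.ptsd_positive,
                "phq_total": sc.phq_total,
                "phq_category": sc.phq_category.value,
                "mdd_symptom_positive": sc.mdd_symptom_positive,
                "mdd_aggregate_positive": sc.mdd_aggregate_positive,
                "ambi_total": sc.ambi_total,
                "bi_positive": sc.bi_positive,
                "mtbi_positive": sc.mtbi_positive,
            }
        )
    return pd.DataFrame(rows)
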