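"""Per-patient aggregation and cohort-level statistics.

Patient summaries count CTCs and CTECs over validated events (events whose
chromosome-8 hybridization failed are excluded from every count), and
cohort summaries report per-group positivity percentages, medians of the
per-patient CTC+CTEC totals, and a tie-corrected Kruskal-Wallis H test
across disease groups.

Rounding conventions: percentages half-up to 1 decimal, medians half-up to
2 decimals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .atlas import Category, Classification, classify_event
from .events import CellEvent, ValidationError, WbcReference, is_ctc, is_ctec, ploidy_call

log = logging.getLogger(__name__)

__all__ = [
    "GroupSummary",
    "KruskalResult",
    "PatientSummary",
    "aggregate_patient",
    "group_summary",
    "kruskal_wallis",
    "positivity_rate",
    "round_half_up",
    "summarize_cohort",
]


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding (0.05 at 1 digit -> 0.1), unlike banker's."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class PatientSummary:
    patient_id: str
    disease_group: str
    n_ctc: int = 0
    n_ctec: int = 0
    n_crc_leaves: int = 0
    subtype_histogram: dict = field(default_factory=dict)

    @property
    def n_total_ctc_ctec(self) -> int:
        return self.n_ctc + self.n_ctec

    @property
    def ctc_positive(self) -> bool:
        return self.n_ctc > 0


@dataclass
class GroupSummary:
    disease_group: str
    n_patients: int
    n_positive: int
    positivity_pct: float
    median_total: float

    def __post_init__(self) -> None:
        if not (0 <= self.n_positive <= self.n_patients):
            raise ValidationError("n_positive must be within [0, n_patients]")


def aggregate_patient(
    events: Sequence[CellEvent],
    ref: WbcReference | None = None,
    *,
    patient_id: str | None = None,
    disease_group: str = "synthetic",
    aneuploid_min3: bool = False,
    classifications: Sequence[Classification] | None = None,
) -> PatientSummary:
    """Summarize one patient's events.

    ``classifications`` may be supplied to avoid re-classifying (must be
    parallel to ``events``); otherwise each event is classified here.
    An empty event list yields an all-zero summary (requires ``patient_id``).
    """
    ids = {ev.patient_id for ev in events}
    if len(ids) > 1:
        raise ValidationError(f"mixed patient_ids in one aggregation: {sorted(ids)}")
    if events:
        patient_id = events[0].patient_id
        disease_group = events[0].disease_group
    elif patient_id is None:
        raise ValidationError("empty event list needs an explicit patient_id")

    summary = PatientSummary(patient_id, disease_group)
    if classifications is None:
        classifications = [classify_event(ev, ref) for ev in events]
    elif len(classifications) != len(events):
        raise ValidationError("classifications not parallel to events")

    for ev, cls in zip(events, classifications):
        if cls.category is Category.QC_FAIL:
            continue
        ploidy = ploidy_call(ev.cep8_spots)
        if is_ctc(ev, ploidy, aneuploid_min3=aneuploid_min3):
            summary.n_ctc += 1
        if is_ctec(ev, ploidy, aneuploid_min3=aneuploid_min3):
            summary.n_ctec += 1
        if cls.category is Category.ATLAS_LEAF:
            summary.n_crc_leaves += 1
            key = cls.leaf.canonical_string
            summary.subtype_histogram[key] = summary.subtype_histogram.get(key, 0) + 1
    return summary


def summarize_cohort(
    events: Sequence[CellEvent],
    ref: WbcReference | None = None,
    *,
    aneuploid_min3: bool = False,
    first_sample_only: bool = True,
) -> list[PatientSummary]:
    """Group events by patient and aggregate each.

    When a patient has several samples, only the lexicographically first
    sample is counted by default (one summary per patient, not per sample).
    """
    by_patient: dict[str, list[CellEvent]] = {}
    for ev in events:
        by_patient.setdefault(ev.patient_id, []).append(ev)
    out = []
    for pid in sorted(by_patient):
        evs = by_patient[pid]
        if first_sample_only:
            first = min(ev.sample_id for ev in evs)
            evs = [ev for ev in evs if ev.sample_id == first]
        out.append(aggregate_patient(evs, ref, aneuploid_min3=aneuploid_min3))
    return out


def positivity_rate(summaries: Sequence[PatientSummary]) -> float:
    """Percent of patients with at least one CTC, half-up to 1 decimal."""
    if not summaries:
        raise ValidationError("empty summary list")
    frac = sum(s.ctc_positive for s in summaries) / len(summaries)
    return round_half_up(100.0 * frac, 1)


class KruskalResult(NamedTuple):
    H: float
    df: int
    p: float


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KruskalResult:
    """Kruskal-Wallis H test with tie correction and chi-square p-value.

    Mid-ranks over the pooled sample; H = 12/(N(N+1)) * sum n_i (rbar_i -
    (N+1)/2)^2, divided by C = 1 - sum(t^3 - t)/(N^3 - N) over tie groups.
    """
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValidationError("all groups must be non-empty")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n = pooled.size
    ranks = sps.rankdata(pooled)  # mid-ranks
    sizes = [len(g) for g in groups]
    h = 0.0
    start = 0
    for ni in sizes:
        rbar = float(np.mean(ranks[start : start + ni]))
        h += ni * (rbar - (n + 1) / 2.0) ** 2
        start += ni
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - float(np.sum(counts**3 - counts)) / (n**3 - n)
    if correction == 0.0:
        raise ValidationError("all pooled values identical; H undefined")
    h /= correction
    df = len(groups) - 1
    return KruskalResult(float(h), df, float(sps.chi2.sf(h, df)))


def group_summary(
    summaries: Sequence[PatientSummary],
) -> tuple[list[GroupSummary], Optional[KruskalResult]]:
    """Per-group positivity and median totals, plus cohort-wide KW.

    The KW test is skipped (returns ``None``, with a log notice) for a
    single group or when every total is identical.
    """
    if not summaries:
        raise ValidationError("empty summary list")
    by_group: dict[str, list[PatientSummary]] = {}
    for s in summaries:
        by_group.setdefault(s.disease_group, []).append(s)

    rows = []
    for group in sorted(by_group):
        members = by_group[group]
        totals = [s.n_total_ctc_ctec for s in members]
        rows.append(
            GroupSummary(
                disease_group=group,
                n_patients=len(members),
                n_positive=sum(s.ctc_positive for s in members),
                positivity_pct=positivity_rate(members),
                median_total=round_half_up(float(np.median(totals)), 2),
            )
        )

    kw: Optional[KruskalResult] = None
    if len(by_group) >= 2:
        grouped = [
            [s.n_total_ctc_ctec for s in by_group[g]] for g in sorted(by_group)
        ]
        try:
            kw = kruskal_wallis(grouped)
        except ValidationError as exc:
            log.warning("Kruskal-Wallis skipped: %s", exc)
    else:
        log.info("single group: Kruskal-Wallis skipped")
    return rows, kw
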