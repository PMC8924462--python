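"""Chromosome-8 / chromosome-12 dual-probe co-detection analysis.

Combines the two per-cell ploidy calls into a discrete pattern, aggregates
CD45- dual-probe events per patient, and computes the probe-comparison
statistics: the patient-level fraction in which the chromosome-8 probe alone
would miss an aneuploid cell (chr8 diploid, chr12 aneuploid), and a paired
comparison of per-patient aneuploid-cell totals between the two probes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats as sps

from .events import CellEvent, Ploidy, ValidationError, is_aneuploid, ploidy_call

__all__ = [
    "DegenerateTestError",
    "DualPloidyPattern",
    "MissingProbeError",
    "PatternKind",
    "ProbeComparison",
    "ProbePatientSummary",
    "build_probe_summaries",
    "dual_pattern",
    "probe_totals_comparison",
    "single_probe_fn_rate",
]


class MissingProbeError(ValidationError):
    """Signals a single-probe event (no chromosome-12 count); caller skips."""


class DegenerateTestError(ValueError):
    """Paired differences have zero variance with nonzero mean."""


class PatternKind(str, enum.Enum):
    ANEU8_DI12 = "aneu8_di12"
    DI8_ANEU12 = "di8_aneu12"
    ANEU8_ANEU12 = "aneu8_aneu12"
    DI8_DI12 = "di8_di12"
    QC = "qc"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class DualPloidyPattern:
    chr8: Ploidy
    chr12: Ploidy
    pattern: PatternKind


def dual_pattern(
    cep8_spots: int,
    cep12_spots: int | None,
    *,
    aneuploid_min3: bool = False,
) -> DualPloidyPattern:
    """Combine the two spot counts into a dual-ploidy pattern.

    ``qc`` whenever either probe failed (0 spots); otherwise the four-way
    aneuploid/diploid cross of the two calls.
    """
    if cep12_spots is None:
        raise MissingProbeError("single-probe event: cep12_spots missing")
    chr8 = ploidy_call(cep8_spots)
    chr12 = ploidy_call(cep12_spots)
    if chr8 is Ploidy.QC_FAIL or chr12 is Ploidy.QC_FAIL:
        kind = PatternKind.QC
    else:
        a8 = is_aneuploid(chr8, aneuploid_min3=aneuploid_min3)
        a12 = is_aneuploid(chr12, aneuploid_min3=aneuploid_min3)
        kind = {
            (True, True): PatternKind.ANEU8_ANEU12,
            (True, False): PatternKind.ANEU8_DI12,
            (False, True): PatternKind.DI8_ANEU12,
            (False, False): PatternKind.DI8_DI12,
        }[(a8, a12)]
    return DualPloidyPattern(chr8, chr12, kind)


@dataclass
class ProbePatientSummary:
    """Per-patient dual-probe aggregate over CD45- co-detected cells."""

    patient_id: str
    n_aneu8: int = 0
    n_aneu12: int = 0
    has_di8_aneu12: bool = False

    def __post_init__(self) -> None:
        if self.n_aneu8 < 0 or self.n_aneu12 < 0:
            raise ValidationError("probe counts must be >= 0")


def build_probe_summaries(
    events: Sequence[CellEvent], *, aneuploid_min3: bool = False
) -> list[ProbePatientSummary]:
    """Aggregate dual-probe events per patient.

    Every patient with at least one dual-probe event gets a summary (the
    denominator of the false-negative rate), but only CD45- events carrying
    both probe counts contribute to the aneuploid totals and the
    chr8-diploid/chr12-aneuploid flag; the flag requires chr8 to be exactly
    diploid (a failed chr8 hybridization does not count).
    """
    by_patient: dict[str, ProbePatientSummary] = {}
    for ev in events:
        if ev.cep12_spots is None:
            continue
        summ = by_patient.setdefault(ev.patient_id, ProbePatientSummary(ev.patient_id))
        if ev.cd45:
            continue
        pat = dual_pattern(ev.cep8_spots, ev.cep12_spots, aneuploid_min3=aneuploid_min3)
        if pat.chr8 is not Ploidy.QC_FAIL and is_aneuploid(
            pat.chr8, aneuploid_min3=aneuploid_min3
        ):
            summ.n_aneu8 += 1
        if pat.chr12 is not Ploidy.QC_FAIL and is_aneuploid(
            pat.chr12, aneuploid_min3=aneuploid_min3
        ):
            summ.n_aneu12 += 1
        if pat.chr8 is Ploidy.DIPLOID and pat.pattern is PatternKind.DI8_ANEU12:
            summ.has_di8_aneu12 = True
    return [by_patient[pid] for pid in by_patient]


def single_probe_fn_rate(summaries: Sequence[ProbePatientSummary]) -> float:
    """Fraction of patients with >= 1 chr8-diploid/chr12-aneuploid cell."""
    if not summaries:
        raise ValidationError("empty summary list")
    ids = [s.patient_id for s in summaries]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate patient_ids in probe summaries")
    return sum(s.has_di8_aneu12 for s in summaries) / len(summaries)


class ProbeComparison(NamedTuple):
    median8: float
    median12: float
    t: float
    p: float


def probe_totals_comparison(
    summaries: Sequence[ProbePatientSummary], *, paired: bool = True
) -> ProbeComparison:
    """Medians of the two per-patient aneuploid totals plus a two-tailed
    t-test on them (paired by default; Welch unpaired via ``paired=False``).
    """
    if len(summaries) < 2:
        raise ValidationError("need >= 2 patients for a probe comparison")
    a8 = np.array([s.n_aneu8 for s in summaries], dtype=float)
    a12 = np.array([s.n_aneu12 for s in summaries], dtype=float)
    median8 = float(np.median(a8))
    median12 = float(np.median(a12))
    if paired:
        diffs = a8 - a12
        if np.ptp(diffs) == 0:
            if diffs[0] == 0:
                return ProbeComparison(median8, median12, 0.0, 1.0)
            raise DegenerateTestError(
                "paired differences are constant and nonzero; t undefined"
            )
        res = sps.ttest_rel(a8, a12)
    else:
        res = sps.ttest_ind(a8, a12, equal_var=False)
    return ProbeComparison(median8, median12, float(res.statistic), float(res.pvalue))
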