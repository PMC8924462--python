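"""Core domain model for circulating-rare-cell events.

A :class:`CellEvent` is one detected nucleated cell with its per-channel
staining calls (CD45, a panel marker, CD31, Vimentin, optionally CD133), a
size measurement (diameter in micrometres and/or an explicit size class) and
FISH spot counts for the chromosome-8 probe and, optionally, the
chromosome-12 probe.

This module also provides the three primitive gates every downstream step is
built on: spot-count ploidy calling (:func:`ploidy_call`), size gating
against a mean white-blood-cell diameter (:func:`classify_size`) and the
CTC/CTEC phenotype predicates (:func:`is_ctc`, :func:`is_ctec`).

Conventions:

* 0 spots is a hybridization failure (``qc_fail``), never haploid.
* "aneuploid" means any called ploidy other than diploid; ``qc_fail`` is
  never aneuploid. A stricter gate requiring >= 3 spots is available via
  ``aneuploid_min3=True`` for sensitivity analyses.
* Vimentin does not veto CTC/CTEC membership; the Vim- variants are kept as
  the "classical" annotation instead of a hard filter.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "CellEvent",
    "Panel",
    "Ploidy",
    "SizeClass",
    "ValidationError",
    "WbcReference",
    "classify_size",
    "is_aneuploid",
    "is_ctc",
    "is_ctec",
    "ploidy_call",
]


class ValidationError(ValueError):
    """Raised when an input record or argument violates a model invariant."""


class Ploidy(str, enum.Enum):
    """Categorical chromosome-copy class called from a FISH spot count."""

    HAPLOID = "haploid"
    DIPLOID = "diploid"
    TRIPLOID = "triploid"
    TETRAPLOID = "tetraploid"
    MULTIPLOID = "multiploid"  # >= 5 signals
    QC_FAIL = "qc_fail"  # 0 signals: hybridization failure

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Panel(str, enum.Enum):
    """Which antibody panel filled the interchangeable marker channel."""

    TUMOR = "tumor_panel"
    STEM = "stem_panel"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class SizeClass(str, enum.Enum):
    SMALL = "small"
    LARGE = "large"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class WbcReference:
    """Mean white-blood-cell diameter used as the small/large boundary."""

    mean_wbc_diameter_um: float = 10.0

    def __post_init__(self) -> None:
        if not (self.mean_wbc_diameter_um > 0):
            raise ValidationError(
                f"mean_wbc_diameter_um must be > 0, got {self.mean_wbc_diameter_um}"
            )


@dataclass
class CellEvent:
    """One detected nucleated cell.

    All staining calls are boolean; DAPI positivity (a nucleus) is implicit
    because the platform only emits nucleated events. ``pm`` is the call on
    the interchangeable panel-marker channel (EpCAM/CK18/PD-L1/AFP/HER2/
    CA19-9 on the tumor panel, CD133 on the stem panel).
    """

    patient_id: str
    sample_id: str
    disease_group: str
    event_id: str
    cep8_spots: int
    cd45: bool = False
    pm: bool = False
    cd31: bool = False
    vim: bool = False
    cd133: bool = False
    panel: Panel = Panel.TUMOR
    panel_marker_name: str = "EpCAM"
    cluster_id: Optional[str] = None
    diameter_um: Optional[float] = None
    size_class: Optional[SizeClass] = None
    cep12_spots: Optional[int] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if isinstance(self.panel, str) and not isinstance(self.panel, Panel):
            self.panel = Panel(self.panel)
        if isinstance(self.size_class, str) and not isinstance(self.size_class, SizeClass):
            self.size_class = SizeClass(self.size_class)
        self.validate()

    def validate(self) -> None:
        if self.diameter_um is None and self.size_class is None:
            raise ValidationError(
                f"event {self.event_id!r}: needs diameter_um or size_class"
            )
        if self.diameter_um is not None and not (self.diameter_um > 0):
            raise ValidationError(
                f"event {self.event_id!r}: diameter_um must be > 0"
            )
        _check_spots(self.cep8_spots, "cep8_spots", self.event_id)
        if self.cep12_spots is not None:
            _check_spots(self.cep12_spots, "cep12_spots", self.event_id)
        if self.panel is Panel.STEM and self.panel_marker_name != "CD133":
            raise ValidationError(
                f"event {self.event_id!r}: stem_panel implies panel_marker_name "
                f"'CD133', got {self.panel_marker_name!r}"
            )

    @property
    def cd133_positive(self) -> bool:
        """CD133 call from either the dedicated column or the stem panel."""
        return self.cd133 or (self.panel is Panel.STEM and self.pm)

    @property
    def any_lineage_marker(self) -> bool:
        """Any of the PM/CD31/Vim channels positive."""
        return self.pm or self.cd31 or self.vim


def _check_spots(value, name: str, event_id: str = "?") -> None:
    if isinstance(value, bool) or not isinstance(value, (int, np.integer)):
        raise ValidationError(f"event {event_id!r}: {name} must be an integer")
    if value < 0:
        raise ValidationError(f"event {event_id!r}: {name} must be >= 0")


_PLOIDY_BY_COUNT = {
    0: Ploidy.QC_FAIL,
    1: Ploidy.HAPLOID,
    2: Ploidy.DIPLOID,
    3: Ploidy.TRIPLOID,
    4: Ploidy.TETRAPLOID,
}


def ploidy_call(spots: int) -> Ploidy:
    """Call a categorical ploidy class from a FISH spot count.

    0 -> qc_fail, 1 -> haploid, 2 -> diploid, 3 -> triploid,
    4 -> tetraploid, >=5 -> multiploid.
    """
    _check_spots(spots, "spots")
    return _PLOIDY_BY_COUNT.get(int(spots), Ploidy.MULTIPLOID)


def is_aneuploid(ploidy: Ploidy, *, aneuploid_min3: bool = False) -> bool:
    """Whether a ploidy call counts as aneuploid.

    Default: anything but diploid and qc_fail (haploid included). With
    ``aneuploid_min3`` only >= 3 copies (triploid/tetraploid/multiploid)
    qualify.
    """
    if aneuploid_min3:
        return ploidy in (Ploidy.TRIPLOID, Ploidy.TETRAPLOID, Ploidy.MULTIPLOID)
    return ploidy not in (Ploidy.DIPLOID, Ploidy.QC_FAIL)


def classify_size(event: CellEvent, ref: WbcReference | None = None) -> SizeClass:
    """Small/large gate against the mean WBC diameter.

    An explicit ``size_class`` takes precedence over ``diameter_um``.
    Ties go to small (cells at the WBC boundary are small).
    """
    if event.size_class is not None:
        return event.size_class
    if event.diameter_um is None:
        raise ValidationError(
            f"event {event.event_id!r}: needs diameter_um or size_class"
        )
    ref = ref or WbcReference()
    if event.diameter_um <= ref.mean_wbc_diameter_um:
        return SizeClass.SMALL
    return SizeClass.LARGE


def is_ctc(
    event: CellEvent,
    ploidy: Ploidy | None = None,
    *,
    aneuploid_min3: bool = False,
) -> bool:
    """Circulating tumor cell predicate.

    CD45-/CD31- tumor-panel event that is either tumor-marker positive or
    chromosome-8 aneuploid. Vimentin status is not restrictive.
    """
    if ploidy is None:
        ploidy = ploidy_call(event.cep8_spots)
    return (
        not event.cd45
        and not event.cd31
        and event.panel is Panel.TUMOR
        and (event.pm or is_aneuploid(ploidy, aneuploid_min3=aneuploid_min3))
    )


def is_ctec(
    event: CellEvent,
    ploidy: Ploidy | None = None,
    *,
    aneuploid_min3: bool = False,
) -> bool:
    """Circulating tumor-derived endothelial cell predicate.

    CD45-/CD31+ event with aneuploid chromosome 8; the panel marker is free
    and Vimentin is not restrictive.
    """
    if ploidy is None:
        ploidy = ploidy_call(event.cep8_spots)
    return (
        not event.cd45
        and event.cd31
        and is_aneuploid(ploidy, aneuploid_min3=aneuploid_min3)
    )
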