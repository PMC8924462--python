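"""Subtype atlas enumeration and per-event classification.

The atlas is the 71-leaf label set obtained by crossing cell size, ploidy
class and the (PM, CD31, Vim) marker combination:

* aneuploid branch: {small, large} x {haploid, triploid, tetraploid,
  multiploid} x all 8 marker combinations  -> 64 leaves
* diploid branch: size-agnostic, any of the 7 combinations with at least
  one positive marker -> 7 leaves

Diploid marker-negative CD45- events are not rare cells (``diploid_null``),
CD45+ events are routed to ``normal_wbc`` or ``hematologic_crc``, and
0-spot events to ``qc_fail``.

Classification order follows the platform's gating: for small cells the
hemocyte marker (CD45) takes priority over everything else; for large cells
ploidy is characterized first and the same CD45 rules are applied after.
Because every gate is a deterministic function of the full feature set, the
two orders yield the same mapping; both are kept explicit in
:func:`classify_event` for readability.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Optional, Sequence

from .events import (
    CellEvent,
    Ploidy,
    SizeClass,
    ValidationError,
    WbcReference,
    classify_size,
    is_aneuploid,
    is_ctc,
    is_ctec,
    ploidy_call,
)

__all__ = [
    "ANNOTATION_FLAGS",
    "Category",
    "Classification",
    "MARKER_COMBOS",
    "SubtypeLabel",
    "annotate_clusters",
    "atlas_table",
    "classify_event",
    "enumerate_atlas",
    "parse_canonical",
]

#: (pm, cd31, vim) combinations in fixed descending-bit order.
MARKER_COMBOS: tuple[tuple[bool, bool, bool], ...] = tuple(
    (pm, cd31, vim)
    for pm in (True, False)
    for cd31 in (True, False)
    for vim in (True, False)
)

ANEUPLOID_AXES: tuple[Ploidy, ...] = (
    Ploidy.HAPLOID,
    Ploidy.TRIPLOID,
    Ploidy.TETRAPLOID,
    Ploidy.MULTIPLOID,
)

ANNOTATION_FLAGS = frozenset(
    {
        "classical_CTC",
        "classical_CTEC",
        "EMT_CTC",
        "mesenchymal_CTEC",
        "fusion_cluster",
        "CTM_member",
        "stem_like",
        "endothelial_progenitor_like",
        "naked_nuclei",
    }
)


def _sign(b: bool) -> str:
    return "+" if b else "-"


@dataclass(frozen=True)
class SubtypeLabel:
    """One leaf of the atlas: size axis x ploidy axis x marker combination."""

    size_axis: str  # "small" | "large" | "any"
    ploidy_axis: Ploidy
    pm: bool
    cd31: bool
    vim: bool

    def __post_init__(self) -> None:
        if self.size_axis not in ("small", "large", "any"):
            raise ValidationError(f"bad size_axis {self.size_axis!r}")
        if self.ploidy_axis is Ploidy.QC_FAIL:
            raise ValidationError("qc_fail is not an atlas axis")
        if self.ploidy_axis is Ploidy.DIPLOID:
            if self.size_axis != "any":
                raise ValidationError("diploid leaves are size-agnostic")
            if not (self.pm or self.cd31 or self.vim):
                raise ValidationError("diploid leaves need >=1 positive marker")
        elif self.size_axis == "any":
            raise ValidationError("aneuploid leaves need an explicit size")

    @property
    def marker_combo(self) -> tuple[bool, bool, bool]:
        return (self.pm, self.cd31, self.vim)

    @property
    def canonical_string(self) -> str:
        return (
            f"{self.size_axis}|{self.ploidy_axis.value}|"
            f"PM{_sign(self.pm)}CD31{_sign(self.cd31)}Vim{_sign(self.vim)}"
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.canonical_string


_CANONICAL_RE = re.compile(
    r"^(small|large|any)\|(haploid|diploid|triploid|tetraploid|multiploid)\|"
    r"PM([+-])CD31([+-])Vim([+-])$"
)


def parse_canonical(text: str) -> SubtypeLabel:
    """Inverse of :attr:`SubtypeLabel.canonical_string`."""
    m = _CANONICAL_RE.match(text)
    if not m:
        raise ValidationError(f"not a canonical subtype string: {text!r}")
    size, ploidy, pm, cd31, vim = m.groups()
    return SubtypeLabel(size, Ploidy(ploidy), pm == "+", cd31 == "+", vim == "+")


@lru_cache(maxsize=1)
def enumerate_atlas() -> tuple[SubtypeLabel, ...]:
    """All 71 leaves in deterministic order (aneuploid branch first)."""
    leaves: list[SubtypeLabel] = []
    for size in ("small", "large"):
        for ploidy in ANEUPLOID_AXES:
            for pm, cd31, vim in MARKER_COMBOS:
                leaves.append(SubtypeLabel(size, ploidy, pm, cd31, vim))
    for pm, cd31, vim in MARKER_COMBOS:
        if pm or cd31 or vim:
            leaves.append(SubtypeLabel("any", Ploidy.DIPLOID, pm, cd31, vim))
    return tuple(leaves)


def atlas_table() -> list[dict]:
    """Atlas as plain rows (for export and alternative factorizations)."""
    return [
        {
            "index": i,
            "size_axis": leaf.size_axis,
            "ploidy_axis": leaf.ploidy_axis.value,
            "pm": int(leaf.pm),
            "cd31": int(leaf.cd31),
            "vim": int(leaf.vim),
            "canonical_string": leaf.canonical_string,
        }
        for i, leaf in enumerate(enumerate_atlas())
    ]


class Category(str, enum.Enum):
    ATLAS_LEAF = "atlas_leaf"
    NORMAL_WBC = "normal_wbc"
    HEMATOLOGIC_CRC = "hematologic_crc"
    DIPLOID_NULL = "diploid_null"
    QC_FAIL = "qc_fail"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class Classification:
    category: Category
    leaf: Optional[SubtypeLabel] = None
    annotations: set = field(default_factory=set)
    size: Optional[SizeClass] = None  # observed size, kept for reporting

    def __post_init__(self) -> None:
        if (self.leaf is not None) != (self.category is Category.ATLAS_LEAF):
            raise ValidationError("leaf present iff category is atlas_leaf")
        unknown = set(self.annotations) - ANNOTATION_FLAGS
        if unknown:
            raise ValidationError(f"unknown annotation flags: {sorted(unknown)}")


def _annotations_for(event: CellEvent, ploidy: Ploidy) -> set:
    aneu = is_aneuploid(ploidy)
    flags: set = set()
    if is_ctc(event, ploidy):
        flags.add("EMT_CTC" if event.vim else "classical_CTC")
    if is_ctec(event, ploidy):
        flags.add("mesenchymal_CTEC" if event.vim else "classical_CTEC")
    if not event.cd45 and aneu:
        if event.cd133_positive:
            flags.add("stem_like")
            if event.cd31:
                flags.add("endothelial_progenitor_like")
        if not event.any_lineage_marker:
            flags.add("naked_nuclei")
        if event.pm and event.cd31 and event.vim and event.cluster_id is not None:
            flags.add("fusion_cluster")
    return flags


def classify_event(
    event: CellEvent, ref: WbcReference | None = None
) -> Classification:
    """Map one event to exactly one category (and leaf, if it is a rare cell).

    Gate order: small cells are CD45-gated first; large cells are
    ploidy-characterized first, then CD45-gated with the same rules.
    CD45+ events with any lineage marker or aneuploidy are hematologic rare
    cells; plain CD45+ diploid events are residual leukocytes. Remaining
    CD45- events land on an atlas leaf (aneuploid, or diploid with >= 1
    marker), ``diploid_null`` or ``qc_fail``.
    """
    size = classify_size(event, ref)
    ploidy = ploidy_call(event.cep8_spots)
    annotations = _annotations_for(event, ploidy)

    # For large cells ploidy is characterized before the hemocyte gate, for
    # small cells after; both gates are deterministic functions of the full
    # feature set, so one shared evaluation covers both orders.
    result = _cd45_gate(event, ploidy) or _cd45neg_gate(event, size, ploidy)
    result.annotations = annotations
    result.size = size
    return result


def _cd45_gate(event: CellEvent, ploidy: Ploidy) -> Optional[Classification]:
    if not event.cd45:
        return None
    if event.any_lineage_marker or is_aneuploid(ploidy):
        return Classification(Category.HEMATOLOGIC_CRC)
    # diploid or qc_fail with no markers: residual leukocyte either way,
    # the hemocyte gate outranks the FISH channel.
    return Classification(Category.NORMAL_WBC)


def _cd45neg_gate(
    event: CellEvent, size: SizeClass, ploidy: Ploidy
) -> Classification:
    if ploidy is Ploidy.QC_FAIL:
        return Classification(Category.QC_FAIL)
    if is_aneuploid(ploidy):
        leaf = SubtypeLabel(size.value, ploidy, event.pm, event.cd31, event.vim)
        return Classification(Category.ATLAS_LEAF, leaf=leaf)
    if event.any_lineage_marker:
        leaf = SubtypeLabel("any", Ploidy.DIPLOID, event.pm, event.cd31, event.vim)
        return Classification(Category.ATLAS_LEAF, leaf=leaf)
    return Classification(Category.DIPLOID_NULL)


def annotate_clusters(
    events: Sequence[CellEvent], classifications: Sequence[Classification]
) -> list[Classification]:
    """Add cluster-level annotation flags; returns a new parallel list.

    A cluster is >= 2 events sharing a ``cluster_id``. Every member of a
    cluster containing at least one rare-cell member (atlas leaf or
    hematologic) gains ``CTM_member``. Member-level flags (fusion cluster,
    endothelial progenitor, naked nuclei) are applied to cluster members
    irrespective of whether they were already set at classification time.
    """
    if len(events) != len(classifications):
        raise ValidationError(
            f"parallel lists differ in length: {len(events)} events vs "
            f"{len(classifications)} classifications"
        )
    out = [replace(c, annotations=set(c.annotations)) for c in classifications]

    members: dict[str, list[int]] = {}
    for i, ev in enumerate(events):
        if ev.cluster_id is not None:
            members.setdefault(ev.cluster_id, []).append(i)

    rare = (Category.ATLAS_LEAF, Category.HEMATOLOGIC_CRC)
    for idx in members.values():
        if len(idx) < 2:
            continue
        if not any(out[i].category in rare for i in idx):
            continue
        for i in idx:
            out[i].annotations.add("CTM_member")
            ev = events[i]
            ploidy = ploidy_call(ev.cep8_spots)
            if not ev.cd45 and is_aneuploid(ploidy):
                if ev.pm and ev.cd31 and ev.vim:
                    out[i].annotations.add("fusion_cluster")
                if ev.cd133_positive and ev.cd31:
                    out[i].annotations.add("endothelial_progenitor_like")
                if not ev.any_lineage_marker:
                    out[i].annotations.add("naked_nuclei")
    return out
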