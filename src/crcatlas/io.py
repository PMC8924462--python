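"""Tab-separated table readers/writers and the run configuration.

Event tables use a fixed 16-column header; booleans are serialized as 0/1
and missing optional values as empty strings. Unknown columns are preserved
on read (in ``CellEvent.extra``) and appended after the standard columns on
write. Malformed rows are reported with their 1-based line numbers.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict, field
from typing import Iterable, Optional, Sequence

import yaml

from .atlas import Classification
from .cohort import GroupSummary, PatientSummary
from .dualprobe import ProbePatientSummary
from .events import CellEvent, Panel, SizeClass, ValidationError

__all__ = [
    "EVENT_COLUMNS",
    "EventTableError",
    "RunConfig",
    "read_events",
    "read_patient_summaries",
    "write_events",
    "write_group_summaries",
    "write_labeled_events",
    "write_patient_summaries",
    "write_probe_summaries",
]

EVENT_COLUMNS = [
    "patient_id",
    "sample_id",
    "disease_group",
    "event_id",
    "cluster_id",
    "panel",
    "panel_marker_name",
    "cd45",
    "pm",
    "cd31",
    "vim",
    "cd133",
    "diameter_um",
    "size_class",
    "cep8_spots",
    "cep12_spots",
]


class EventTableError(ValidationError):
    """Malformed event table (bad header or unparseable rows)."""


def _parse_bool(text: str, column: str) -> bool:
    if text in ("0", "1"):
        return text == "1"
    raise ValueError(f"{column} must be 0 or 1, got {text!r}")


def _parse_int(text: str, column: str) -> int:
    try:
        return int(text)
    except ValueError:
        raise ValueError(f"{column} must be an integer, got {text!r}") from None


def _row_to_event(row: dict) -> CellEvent:
    diameter = row["diameter_um"]
    size_class = row["size_class"]
    cep12 = row["cep12_spots"]
    cluster = row["cluster_id"]
    extra = {k: v for k, v in row.items() if k not in EVENT_COLUMNS}
    return CellEvent(
        patient_id=row["patient_id"],
        sample_id=row["sample_id"],
        disease_group=row["disease_group"],
        event_id=row["event_id"],
        cluster_id=cluster if cluster != "" else None,
        panel=Panel(row["panel"]),
        panel_marker_name=row["panel_marker_name"],
        cd45=_parse_bool(row["cd45"], "cd45"),
        pm=_parse_bool(row["pm"], "pm"),
        cd31=_parse_bool(row["cd31"], "cd31"),
        vim=_parse_bool(row["vim"], "vim"),
        cd133=_parse_bool(row["cd133"], "cd133"),
        diameter_um=float(diameter) if diameter != "" else None,
        size_class=SizeClass(size_class) if size_class != "" else None,
        cep8_spots=_parse_int(row["cep8_spots"], "cep8_spots"),
        cep12_spots=_parse_int(cep12, "cep12_spots") if cep12 != "" else None,
        extra=extra,
    )


def read_events(path) -> list[CellEvent]:
    """Read an event TSV; raises :class:`EventTableError` naming the missing
    column or listing malformed rows with line numbers."""
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise EventTableError(f"{path}: empty file") from None
        missing = [c for c in EVENT_COLUMNS if c not in header]
        if missing:
            raise EventTableError(
                f"{path}: missing mandatory column(s): {', '.join(missing)}"
            )
        events: list[CellEvent] = []
        errors: list[str] = []
        for lineno, values in enumerate(reader, start=2):
            if not values or (len(values) == 1 and values[0] == ""):
                continue
            if len(values) != len(header):
                errors.append(
                    f"line {lineno}: expected {len(header)} fields, got {len(values)}"
                )
                continue
            row = dict(zip(header, values))
            try:
                events.append(_row_to_event(row))
            except (ValueError, ValidationError) as exc:
                errors.append(f"line {lineno}: {exc}")
    if errors:
        raise EventTableError(f"{path}: {len(errors)} malformed row(s): " + "; ".join(errors))
    return events


def _b(x: bool) -> str:
    return "1" if x else "0"


def _event_row(ev: CellEvent, extra_cols: Sequence[str]) -> list[str]:
    row = [
        ev.patient_id,
        ev.sample_id,
        ev.disease_group,
        ev.event_id,
        ev.cluster_id or "",
        ev.panel.value,
        ev.panel_marker_name,
        _b(ev.cd45),
        _b(ev.pm),
        _b(ev.cd31),
        _b(ev.vim),
        _b(ev.cd133),
        "" if ev.diameter_um is None else format(ev.diameter_um, "g"),
        "" if ev.size_class is None else ev.size_class.value,
        str(ev.cep8_spots),
        "" if ev.cep12_spots is None else str(ev.cep12_spots),
    ]
    row.extend(ev.extra.get(c, "") for c in extra_cols)
    return row


def _extra_columns(events: Iterable[CellEvent]) -> list[str]:
    cols: list[str] = []
    for ev in events:
        for k in ev.extra:
            if k not in cols:
                cols.append(k)
    return cols


def _open_writer(path):
    fh = open(path, "w", encoding="utf-8", newline="")
    return fh, csv.writer(fh, delimiter="\t", lineterminator="\n")


def write_events(events: Sequence[CellEvent], path) -> None:
    extra_cols = _extra_columns(events)
    fh, writer = _open_writer(path)
    with fh:
        writer.writerow(EVENT_COLUMNS + extra_cols)
        for ev in events:
            writer.writerow(_event_row(ev, extra_cols))


def write_labeled_events(
    events: Sequence[CellEvent],
    classifications: Sequence[Classification],
    path,
) -> None:
    """Event TSV plus category, leaf_canonical and annotations columns."""
    if len(events) != len(classifications):
        raise ValidationError("events and classifications must be parallel")
    extra_cols = _extra_columns(events)
    fh, writer = _open_writer(path)
    with fh:
        writer.writerow(
            EVENT_COLUMNS + extra_cols + ["category", "leaf_canonical", "annotations"]
        )
        for ev, cls in zip(events, classifications):
            writer.writerow(
                _event_row(ev, extra_cols)
                + [
                    cls.category.value,
                    cls.leaf.canonical_string if cls.leaf else "",
                    ";".join(sorted(cls.annotations)),
                ]
            )


def write_patient_summaries(summaries: Sequence[PatientSummary], path) -> None:
    fh, writer = _open_writer(path)
    with fh:
        writer.writerow(
            [
                "patient_id",
                "disease_group",
                "n_ctc",
                "n_ctec",
                "n_total_ctc_ctec",
                "n_crc_leaves",
                "ctc_positive",
                "subtype_histogram",
            ]
        )
        for s in summaries:
            hist = ";".join(f"{k}:{v}" for k, v in sorted(s.subtype_histogram.items()))
            writer.writerow(
                [
                    s.patient_id,
                    s.disease_group,
                    str(s.n_ctc),
                    str(s.n_ctec),
                    str(s.n_total_ctc_ctec),
                    str(s.n_crc_leaves),
                    _b(s.ctc_positive),
                    hist,
                ]
            )


def read_patient_summaries(path) -> list[PatientSummary]:
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        out = []
        for row in reader:
            hist = {}
            if row.get("subtype_histogram"):
                for part in row["subtype_histogram"].split(";"):
                    key, _, count = part.rpartition(":")
                    hist[key] = int(count)
            out.append(
                PatientSummary(
                    patient_id=row["patient_id"],
                    disease_group=row["disease_group"],
                    n_ctc=int(row["n_ctc"]),
                    n_ctec=int(row["n_ctec"]),
                    n_crc_leaves=int(row["n_crc_leaves"]),
                    subtype_histogram=hist,
                )
            )
    return out


def write_group_summaries(rows: Sequence[GroupSummary], path) -> None:
    fh, writer = _open_writer(path)
    with fh:
        writer.writerow(
            ["disease_group", "n_patients", "n_positive", "positivity_pct", "median_total"]
        )
        for r in rows:
            writer.writerow(
                [
                    r.disease_group,
                    str(r.n_patients),
                    str(r.n_positive),
                    format(r.positivity_pct, ".1f"),
                    format(r.median_total, ".2f"),
                ]
            )


def write_probe_summaries(summaries: Sequence[ProbePatientSummary], path) -> None:
    fh, writer = _open_writer(path)
    with fh:
        writer.writerow(["patient_id", "n_aneu8", "n_aneu12", "has_di8_aneu12"])
        for s in summaries:
            writer.writerow(
                [s.patient_id, str(s.n_aneu8), str(s.n_aneu12), _b(s.has_di8_aneu12)]
            )


@dataclass
class RunConfig:
    """End-to-end pipeline configuration; round-trips through JSON/YAML."""

    wbc_reference_um: float = 10.0
    aneuploid_min3: bool = False
    paired_ttest: bool = True
    seed: int = 0
    n_patients_per_group: dict = field(default_factory=dict)
    params_path: Optional[str] = None
    events_path: Optional[str] = None
    output_dir: str = "."

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = open(path, encoding="utf-8").read()
        data = (
            yaml.safe_load(text)
            if str(path).endswith((".yaml", ".yml"))
            else json.loads(text)
        )
        return cls(**data)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            if str(path).endswith((".yaml", ".yml")):
                yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
            else:
                json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
                fh.write("\n")
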