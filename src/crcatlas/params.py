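"""Cohort generator parameters and the bundled reference cohort table.

:func:`load_reference_cohort` reads the packaged per-group patient counts
(31 disease groups; total patients and CTC-positive patients per group).
:func:`default_cohort_params` turns that table into per-group generator
parameters: each group keeps its observed positivity, groups with a known
reported median get that median as the simulation target, and everything
else falls back to a neutral default. A dedicated ``co_detection`` group
carries the dual-probe settings.

Marker-combination and ploidy-class frequencies are invented defaults that
encode only the qualitative pattern (endothelial-involved combinations
common, epithelial-marker-positive ones rare, a triple-negative "naked"
fraction); they are placeholders, not measured frequencies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Mapping

import yaml

from .events import ValidationError

__all__ = [
    "CohortParams",
    "GroupParams",
    "default_cohort_params",
    "load_params",
    "load_reference_cohort",
    "save_params",
]

#: order matches atlas.MARKER_COMBOS: (pm, cd31, vim) descending bits
#: +++, ++-, +-+, +--, -++, -+-, --+, ---
DEFAULT_MARKER_COMBO_FREQS = (0.02, 0.03, 0.02, 0.03, 0.20, 0.30, 0.25, 0.15)

#: haploid, diploid, triploid, tetraploid, multiploid
DEFAULT_PLOIDY_FREQS = (0.05, 0.10, 0.30, 0.20, 0.35)

#: diploid-free variant for co-detection cohorts (every CD45- cell is
#: chr8-aneuploid, so the chr8 totals track the drawn counts directly)
CODETECTION_PLOIDY_FREQS = (0.05, 0.0, 0.35, 0.20, 0.40)

#: groups with a reported cohort median for the per-patient CTC+CTEC total
REPORTED_MEDIANS = {
    "Infectious diseases": 22.0,
    "Pancreatic cancer": 19.0,
    "Gastric cancer": 14.0,
    "Colorectal cancer": 15.0,
    "Ampulla cancer": 15.0,
    "Maxillofacial tumors": 7.0,
}

DEFAULT_TARGET_MEDIAN = 10.0

#: dual-probe trial settings: per-patient chr8-aneuploid median 12, and a
#: 57.27% patient-level probability of carrying >= 1 chr8-diploid/
#: chr12-aneuploid cell
CODETECTION_GROUP = "co_detection"
CODETECTION_POSITIVITY = 0.95
CODETECTION_MEDIAN = 12.0
CODETECTION_P_DI8_ANEU12 = 0.5727


def _check_fraction(name: str, x: float) -> None:
    if not (0.0 <= x <= 1.0):
        raise ValidationError(f"{name} must be in [0, 1], got {x}")


def _check_simplex(name: str, v: tuple[float, ...], k: int) -> None:
    if len(v) != k:
        raise ValidationError(f"{name} must have {k} entries, got {len(v)}")
    if any(x < 0 for x in v):
        raise ValidationError(f"{name} entries must be >= 0")
    if abs(sum(v) - 1.0) > 1e-9:
        raise ValidationError(f"{name} must sum to 1, got {sum(v)!r}")


@dataclass
class GroupParams:
    """Generator parameters for one disease group."""

    positivity: float
    target_median: float
    dispersion: float = 1.5
    marker_combo_freqs: tuple = DEFAULT_MARKER_COMBO_FREQS
    ploidy_freqs: tuple = DEFAULT_PLOIDY_FREQS
    p_di8_aneu12: float = 0.0
    wbc_background: float = 2.0
    co_detection: bool = False
    ctc_fraction: float = 0.45  # expected CTC share of the CTC+CTEC total

    def __post_init__(self) -> None:
        self.marker_combo_freqs = tuple(self.marker_combo_freqs)
        self.ploidy_freqs = tuple(self.ploidy_freqs)
        self.validate()

    def validate(self) -> None:
        _check_fraction("positivity", self.positivity)
        _check_fraction("p_di8_aneu12", self.p_di8_aneu12)
        _check_fraction("ctc_fraction", self.ctc_fraction)
        if self.target_median < 0:
            raise ValidationError("target_median must be >= 0")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be > 0")
        if self.wbc_background < 0:
            raise ValidationError("wbc_background must be >= 0")
        _check_simplex("marker_combo_freqs", self.marker_combo_freqs, 8)
        _check_simplex("ploidy_freqs", self.ploidy_freqs, 5)


@dataclass
class CohortParams:
    """Per-disease-group generator parameters."""

    groups: dict = field(default_factory=dict)  # name -> GroupParams

    def __post_init__(self) -> None:
        for name, gp in list(self.groups.items()):
            if isinstance(gp, Mapping):
                self.groups[name] = GroupParams(**gp)

    def group(self, name: str) -> GroupParams:
        try:
            return self.groups[name]
        except KeyError:
            raise ValidationError(f"no parameters for group {name!r}") from None

    def to_dict(self) -> dict:
        return {
            "groups": {
                name: {
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in asdict(gp).items()
                }
                for name, gp in self.groups.items()
            }
        }


def load_reference_cohort() -> list[dict]:
    """Bundled per-group patient counts (31 disease groups)."""
    text = (
        resources.files("crcatlas").joinpath("data/reference_cohort.tsv").read_text()
    )
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    rows = []
    for ln in lines[1:]:
        vals = ln.split("\t")
        row = dict(zip(header, vals))
        row["n_patients"] = int(row["n_patients"])
        row["n_ctc_positive"] = int(row["n_ctc_positive"])
        rows.append(row)
    return rows


def default_cohort_params() -> CohortParams:
    """Shipped parameter table covering all reference groups plus the
    dual-probe ``co_detection`` group and a generic ``synthetic`` group."""
    groups: dict[str, GroupParams] = {}
    for row in load_reference_cohort():
        name = row["disease_group"]
        groups[name] = GroupParams(
            positivity=row["n_ctc_positive"] / row["n_patients"],
            target_median=REPORTED_MEDIANS.get(name, DEFAULT_TARGET_MEDIAN),
            # groups with a pinned median get a less heavy tail so 200-patient
            # cohort medians concentrate on the target
            dispersion=2.5 if name in REPORTED_MEDIANS else 1.5,
        )
    groups[CODETECTION_GROUP] = GroupParams(
        positivity=CODETECTION_POSITIVITY,
        target_median=CODETECTION_MEDIAN,
        dispersion=2.5,
        ploidy_freqs=CODETECTION_PLOIDY_FREQS,
        p_di8_aneu12=CODETECTION_P_DI8_ANEU12,
        co_detection=True,
    )
    groups["synthetic"] = GroupParams(
        positivity=0.9, target_median=DEFAULT_TARGET_MEDIAN
    )
    return CohortParams(groups=groups)


def load_params(path) -> CohortParams:
    """Read a JSON or YAML parameter document (mirrors field names)."""
    text = open(path, encoding="utf-8").read()
    data = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) else json.loads(text)
    if "groups" not in data:
        raise ValidationError("parameter document must have a 'groups' mapping")
    return CohortParams(groups=data["groups"])


def save_params(params: CohortParams, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(params.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
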