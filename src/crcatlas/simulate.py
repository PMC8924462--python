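"""Seeded synthetic cohort generator.

Per-patient CTC+CTEC totals follow a hurdle model: zero with probability
``1 - positivity``, otherwise ``1 + NegBin(size=dispersion, mean=mu)``, with
``mu`` fitted by a deterministic grid search so the analytic mixture median
hits the configured target. Drawn totals are then materialized as cell
events that the classification pipeline provably recovers: every generated
"CTC event" satisfies the CTC predicate and every "CTEC event" the CTEC
predicate, and a patient is CTC-positive exactly when the drawn total is
positive (at least one CTC is allocated to every positive patient).

Determinism: each patient gets an independent substream
``SeedSequence(seed, spawn_key=(crc32(group), patient_index))``, so tables
are byte-identical for identical (params, n, seed) regardless of group
iteration order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .events import CellEvent, Panel, ValidationError
from .atlas import MARKER_COMBOS
from .params import CohortParams, GroupParams

__all__ = ["HurdleCountModel", "InfeasibleModelError", "fit_count_model", "generate_cohort"]

#: spot-count support per ploidy index (haploid..multiploid)
_PLOIDY_SPOTS = ((1,), (2,), (3,), (4,), (5, 6, 7, 8))

_ANEUPLOID_SPOT_CHOICES = (1, 3, 4, 5, 6, 7, 8)


class InfeasibleModelError(ValidationError):
    """No hurdle model can reach the requested (positivity, median) pair."""


@dataclass(frozen=True)
class HurdleCountModel:
    """Zero-inflated shifted negative-binomial count model."""

    positivity: float
    mu: float
    dispersion: float

    @property
    def _nb_p(self) -> float:
        return self.dispersion / (self.dispersion + self.mu)

    def median(self) -> int:
        """Analytic mixture median (smallest m with CDF(m) >= 0.5)."""
        if self.positivity <= 0.5:
            return 0
        q = (0.5 - (1.0 - self.positivity)) / self.positivity
        return int(sps.nbinom.ppf(q, self.dispersion, self._nb_p)) + 1

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.positivity == 0.0:
            return np.zeros(size, dtype=np.int64)
        positive = rng.random(size) < self.positivity
        counts = np.zeros(size, dtype=np.int64)
        n_pos = int(positive.sum())
        if n_pos:
            counts[positive] = 1 + rng.negative_binomial(
                self.dispersion, self._nb_p, size=n_pos
            )
        return counts

    def sample_one(self, rng: np.random.Generator) -> int:
        return int(self.sample(rng, 1)[0])


def fit_count_model(
    positivity: float, target_median: float, dispersion: float = 1.5
) -> HurdleCountModel:
    """Fit ``mu`` so the analytic mixture median equals round(target_median).

    The median is a step function of ``mu``; a deterministic geometric grid
    is scanned and, among the feasible values, the one that balances the
    mixture CDF around 0.5 at the target (so empirical cohort medians
    concentrate on it rather than drifting to a neighbour) is returned.
    """
    if not (0.0 <= positivity <= 1.0):
        raise ValidationError(f"positivity must be in [0, 1], got {positivity}")
    if target_median < 0:
        raise ValidationError("target_median must be >= 0")
    if dispersion <= 0:
        raise ValidationError("dispersion must be > 0")

    m = int(round(target_median))
    if m == 0:
        if positivity > 0.5:
            raise InfeasibleModelError(
                "positivity > 0.5 forces a positive median; target 0 infeasible"
            )
        return HurdleCountModel(positivity, 1.0, dispersion)
    if positivity <= 0.5:
        raise InfeasibleModelError(
            f"positivity {positivity} <= 0.5 pins the mixture median at 0; "
            f"target {target_median} is unreachable"
        )

    q = (0.5 - (1.0 - positivity)) / positivity
    grid = np.geomspace(0.05, 5.0e4, 6000)
    p_nb = dispersion / (dispersion + grid)
    medians = sps.nbinom.ppf(q, dispersion, p_nb) + 1
    feasible = medians == m
    if not feasible.any():
        raise InfeasibleModelError(
            f"no mu on the search grid reaches median {m} "
            f"(positivity={positivity}, dispersion={dispersion})"
        )
    # mixture CDF just below/at the target; balance them around 0.5
    cdf_lo = (1.0 - positivity) + positivity * sps.nbinom.cdf(m - 2, dispersion, p_nb)
    cdf_hi = (1.0 - positivity) + positivity * sps.nbinom.cdf(m - 1, dispersion, p_nb)
    imbalance = np.where(feasible, np.abs(cdf_lo + cdf_hi - 1.0), np.inf)
    mu = float(grid[int(np.argmin(imbalance))])
    return HurdleCountModel(positivity, mu, dispersion)


def _conditional_combo(
    rng: np.random.Generator,
    freqs: tuple,
    keep: list[int],
) -> tuple[bool, bool, bool]:
    w = np.asarray([freqs[i] for i in keep], dtype=float)
    if w.sum() <= 0:
        w = np.ones(len(keep))
    idx = keep[rng.choice(len(keep), p=w / w.sum())]
    return MARKER_COMBOS[idx]

_CTC_COMBOS = [i for i, (_, cd31, _) in enumerate(MARKER_COMBOS) if not cd31]
_CTC_PM_COMBOS = [i for i, (pm, cd31, _) in enumerate(MARKER_COMBOS) if pm and not cd31]
_CTEC_COMBOS = [i for i, (_, cd31, _) in enumerate(MARKER_COMBOS) if cd31]


def _diameter(rng: np.random.Generator) -> float:
    # 40% small (at or below the 10 um WBC boundary), 60% large
    if rng.random() < 0.4:
        return float(np.round(rng.uniform(6.0, 10.0), 2))
    return float(np.round(rng.uniform(10.5, 22.0), 2))


def _sample_ploidy_spots(
    rng: np.random.Generator, ploidy_freqs: tuple, *, exclude_diploid: bool
) -> int:
    w = np.asarray(ploidy_freqs, dtype=float)
    if exclude_diploid:
        w = w.copy()
        w[1] = 0.0
    if w.sum() <= 0:
        raise ValidationError("ploidy_freqs leave no admissible class")
    k = int(rng.choice(5, p=w / w.sum()))
    return int(rng.choice(_PLOIDY_SPOTS[k]))


def _chr12_spots(rng: np.random.Generator, cep8_spots: int) -> int:
    # concordant-aneuploid with probability 0.6 when chr8 is aneuploid,
    # otherwise diploid; chr8-diploid cells stay chr12-diploid (discordance
    # is injected separately at the patient level)
    if cep8_spots != 2 and rng.random() < 0.6:
        return int(rng.choice(_ANEUPLOID_SPOT_CHOICES))
    return 2


def _patient_events(
    rng: np.random.Generator,
    gp: GroupParams,
    group: str,
    patient_id: str,
    total: int,
) -> list[CellEvent]:
    events: list[CellEvent] = []
    co = gp.co_detection

    n_ctc = 0
    if total > 0:
        # every positive patient gets >= 1 CTC so CTC-positivity tracks the
        # hurdle draw exactly
        n_ctc = 1 + int(rng.binomial(total - 1, gp.ctc_fraction)) if total > 1 else 1
    n_ctec = total - n_ctc

    def _append(kind: str, pm: bool, cd31: bool, vim: bool, cep8: int) -> None:
        cep12 = _chr12_spots(rng, cep8) if co else None
        events.append(
            CellEvent(
                patient_id=patient_id,
                sample_id="s1",
                disease_group=group,
                event_id=f"{patient_id}-e{len(events):04d}",
                cep8_spots=cep8,
                cd45=(kind == "wbc"),
                pm=pm,
                cd31=cd31,
                vim=vim,
                panel=Panel.TUMOR,
                panel_marker_name="EpCAM",
                diameter_um=_diameter(rng),
                cep12_spots=cep12,
            )
        )

    for _ in range(n_ctc):
        cep8 = _sample_ploidy_spots(rng, gp.ploidy_freqs, exclude_diploid=False)
        keep = _CTC_PM_COMBOS if cep8 == 2 else _CTC_COMBOS
        pm, cd31, vim = _conditional_combo(rng, gp.marker_combo_freqs, keep)
        _append("ctc", pm, cd31, vim, cep8)
    for _ in range(n_ctec):
        cep8 = _sample_ploidy_spots(rng, gp.ploidy_freqs, exclude_diploid=True)
        pm, cd31, vim = _conditional_combo(rng, gp.marker_combo_freqs, _CTEC_COMBOS)
        _append("ctec", pm, cd31, vim, cep8)

    if co and rng.random() < gp.p_di8_aneu12:
        # discordant sentinel: CD45-, marker-negative, chr8 diploid, chr12
        # aneuploid -- invisible to CTC/CTEC counting but caught by the
        # dual-probe summary
        events.append(
            CellEvent(
                patient_id=patient_id,
                sample_id="s1",
                disease_group=group,
                event_id=f"{patient_id}-e{len(events):04d}",
                cep8_spots=2,
                cd45=False,
                pm=False,
                cd31=False,
                vim=False,
                diameter_um=_diameter(rng),
                cep12_spots=int(rng.choice(_ANEUPLOID_SPOT_CHOICES)),
            )
        )

    n_wbc = int(rng.poisson(gp.wbc_background))
    if not events and n_wbc == 0:
        n_wbc = 1  # every drawn blood sample carries >= 1 residual WBC, so
        # every patient appears in the table (keeps cohort medians honest)
    for _ in range(n_wbc):
        _append("wbc", False, False, False, 2)
    return events


def generate_cohort(
    params: CohortParams,
    n_patients_per_group: dict,
    seed: int,
) -> list[CellEvent]:
    """Generate a per-cell event table for the requested group sizes.

    Deterministic for identical (params, n, seed); groups are emitted in
    sorted name order, patients in index order.
    """
    if seed is None:
        raise ValidationError("seed is required")
    entropy = int(seed) & 0xFFFFFFFFFFFFFFFF
    events: list[CellEvent] = []
    for group in sorted(n_patients_per_group):
        n = int(n_patients_per_group[group])
        if n < 0:
            raise ValidationError(f"negative patient count for {group!r}")
        gp = params.group(group)
        model = fit_count_model(gp.positivity, gp.target_median, gp.dispersion)
        tag = zlib.crc32(group.encode("utf-8"))
        for i in range(n):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy, spawn_key=(tag, i))
            )
            patient_id = f"{group.replace(' ', '_')}_p{i:05d}"
            total = model.sample_one(rng)
            events.extend(_patient_events(rng, gp, group, patient_id, total))
    return events
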