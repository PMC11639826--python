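"""Deleterious-mutation filtering, binary pathway profiles and TMB strata.

A patient's mutational profile is re-expressed as a binary 11-vector over
the canonical signaling pathways: a pathway is "mutated" (bit set) when the
patient carries at least one deleterious mutation in any member gene of
that pathway. Deleterious means flagged pathogenic by COSMIC and/or ClinVar
(the flags are inputs; see :mod:`psncohort.io`).

Patients are stratified by tumor mutation burden at a strict cutoff
(high TMB means ``tmb > cutoff``, default 10 Mut/Mb) and by smoking status
(current or former smokers form the S class, never-smokers the NS class).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .io import (
    PATHWAY_ORDER,
    Cohort,
    MutationRecord,
    PathwayCatalog,
    PatientRecord,
    SmokingStatus,
)

__all__ = [
    "PathwayProfile",
    "StratificationConfig",
    "PatientStratum",
    "StratificationError",
    "filter_deleterious",
    "build_pathway_profiles",
    "stratify",
    "pathway_summary",
    "round_half_up",
]

logger = logging.getLogger(__name__)


class StratificationError(ValueError):
    """A patient cannot be assigned to a stratum."""


@dataclass(frozen=True)
class PathwayProfile:
    """Binary mutated-pathway vector for one patient, canonical order."""

    patient_id: str
    x: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.x) != len(PATHWAY_ORDER):
            raise ValueError(
                f"profile for {self.patient_id!r} has length {len(self.x)}, "
                f"expected {len(PATHWAY_ORDER)}"
            )
        if any(v not in (0, 1) for v in self.x):
            raise ValueError(f"profile for {self.patient_id!r} is not binary: {self.x}")

    def __getitem__(self, pathway: str) -> int:
        return self.x[PATHWAY_ORDER.index(pathway)]


@dataclass(frozen=True)
class StratificationConfig:
    """TMB cutoff and which smoking statuses count as smokers.

    The TMB comparison is strict: a patient at exactly the cutoff is low-TMB
    (">10 Mut/Mb" defines the high class).
    """

    tmb_cutoff: float = 10.0
    smoker_classes: frozenset[SmokingStatus] = frozenset(
        {SmokingStatus.FORMER, SmokingStatus.CURRENT}
    )
    #: combine the two pathogenicity flags with "any" (OR) or "all" (AND)
    pathogenicity_rule: Literal["any", "all"] = "any"

    def __post_init__(self) -> None:
        if self.tmb_cutoff <= 0:
            raise ValueError(f"tmb_cutoff must be positive, got {self.tmb_cutoff}")


@dataclass(frozen=True)
class PatientStratum:
    patient_id: str
    tmb_class: Literal["H", "L"]
    smoking_class: Literal["S", "NS"]

    @property
    def subgroup(self) -> str:
        return f"{self.smoking_class}/{self.tmb_class}"


def filter_deleterious(
    mutations: Iterable[MutationRecord], *, rule: Literal["any", "all"] = "any"
) -> list[MutationRecord]:
    """Keep mutations flagged pathogenic, preserving input order.

    ``rule="any"`` (default) keeps a record when either database flags it
    pathogenic; ``rule="all"`` requires both flags.
    """
    if rule == "any":
        return [m for m in mutations if m.cosmic_pathogenic or m.clinvar_pathogenic]
    if rule == "all":
        return [m for m in mutations if m.cosmic_pathogenic and m.clinvar_pathogenic]
    raise ValueError(f"unknown pathogenicity rule {rule!r}")


def build_pathway_profiles(
    cohort: Cohort,
    *,
    deleterious_only: bool = True,
    rule: Literal["any", "all"] = "any",
) -> list[PathwayProfile]:
    """One binary pathway profile per patient, in cohort patient order.

    A single gene belonging to two pathways sets both bits. Mutations in
    genes absent from every pathway are ignored for profiling (logged at
    debug level). Patients with no qualifying mutation get the all-zero
    profile. Duplicate mutation rows and row order do not affect the result.
    """
    mutations = (
        filter_deleterious(cohort.mutations, rule=rule)
        if deleterious_only
        else list(cohort.mutations)
    )
    bits: dict[str, set[int]] = {p.patient_id: set() for p in cohort.patients}
    index = {name: i for i, name in enumerate(PATHWAY_ORDER)}
    for m in mutations:
        hit = cohort.catalog.pathways_of(m.gene)
        if not hit:
            logger.debug(
                "gene %s (patient %s) is in no catalog pathway; ignored",
                m.gene,
                m.patient_id,
            )
            continue
        bits[m.patient_id].update(index[p] for p in hit)
    return [
        PathwayProfile(
            patient_id=p.patient_id,
            x=tuple(1 if i in bits[p.patient_id] else 0 for i in range(len(PATHWAY_ORDER))),
        )
        for p in cohort.patients
    ]


def stratify(
    patients: Sequence[PatientRecord],
    cfg: StratificationConfig = StratificationConfig(),
) -> list[PatientStratum]:
    """Assign each patient a TMB class (H/L, strict cutoff) and smoking class."""
    strata = []
    for p in patients:
        if p.tmb is None:
            raise StratificationError(f"patient {p.patient_id!r} has no TMB value")
        strata.append(
            PatientStratum(
                patient_id=p.patient_id,
                tmb_class="H" if p.tmb > cfg.tmb_cutoff else "L",
                smoking_class="S" if p.smoking_status in cfg.smoker_classes else "NS",
            )
        )
    return strata


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round with ties away from zero, matching clinical-table formatting."""
    factor = 10.0**decimals
    return float(np.floor(np.abs(value) * factor + 0.5) / factor * np.sign(value))


def pathway_summary(
    profiles: Sequence[PathwayProfile], strata: Sequence[PatientStratum]
) -> pd.DataFrame:
    """Mutated-patient counts and percentages per pathway and smoking class.

    Returns a DataFrame indexed by pathway with columns ``S_count``,
    ``S_pct``, ``NS_count``, ``NS_pct``; percentages are rounded half-up to
    one decimal. An empty class yields missing percentages.
    """
    prof_ids = {p.patient_id for p in profiles}
    strat_ids = {s.patient_id for s in strata}
    if prof_ids != strat_ids:
        raise ValueError(
            "profiles and strata must cover the same patients; "
            f"difference: {sorted(prof_ids ^ strat_ids)[:5]}"
        )
    klass = {s.patient_id: s.smoking_class for s in strata}
    x = np.array([p.x for p in profiles], dtype=int)
    is_s = np.array([klass[p.patient_id] == "S" for p in profiles])

    out = {}
    for label, mask in (("S", is_s), ("NS", ~is_s)):
        size = int(mask.sum())
        counts = x[mask].sum(axis=0) if size else np.zeros(len(PATHWAY_ORDER), dtype=int)
        pcts = [
            round_half_up(100.0 * c / size, 1) if size else np.nan for c in counts
        ]
        out[f"{label}_count"] = counts.astype(int)
        out[f"{label}_pct"] = pcts
    return pd.DataFrame(out, index=list(PATHWAY_ORDER)).rename_axis("pathway")
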