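"""Community characterization: pathway profiles, TMB contrasts, enrichment.

Once the patient similarity network has been partitioned, each community is
described by the percentage of its members mutated in each of the 11
pathways, compared for TMB level across communities (Kruskal-Wallis), and
tested for over-representation of high-TMB patients (hypergeometric upper
tail against the stratum the network was built on). Community pathway
profiles from different cohorts are compared with Spearman correlation,
whose p-value at profile length 11 is evaluated against a Monte-Carlo
permutation null rather than the rough t approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .enrichment import EnrichmentResult, hypergeom_upper_tail
from .io import PATHWAY_ORDER, PatientRecord
from .network import CommunityPartition
from .profiling import PathwayProfile, PatientStratum

__all__ = [
    "CommunityProfile",
    "GroupComparison",
    "ProfileCorrelation",
    "community_profiles",
    "compare_tmb",
    "htmb_enrichment",
    "profile_correlation",
]

#: permutations for the Monte-Carlo Spearman null (accuracy ~3 decimals)
SPEARMAN_PERMUTATIONS = 1_000_000
SPEARMAN_SEED = 20241126  # fixed so reported p-values are reproducible


@dataclass(frozen=True)
class CommunityProfile:
    """Percentage of community members mutated per pathway (canonical order)."""

    label: int
    size: int
    pct_mutated: tuple[float, ...]

    def __getitem__(self, pathway: str) -> float:
        return self.pct_mutated[PATHWAY_ORDER.index(pathway)]


@dataclass(frozen=True)
class GroupComparison:
    """Tie-corrected Kruskal-Wallis H across groups with chi-square p."""

    statistic: float
    p_value: float
    group_sizes: tuple[int, ...]
    degenerate: bool = False


@dataclass(frozen=True)
class ProfileCorrelation:
    """Spearman correlation between two community pathway profiles."""

    rho: float
    p_value: float
    n_permutations: int


def community_profiles(
    partition: CommunityPartition, profiles: Sequence[PathwayProfile]
) -> list[CommunityProfile]:
    """Per-community mutated-pathway percentage vectors."""
    by_id = {p.patient_id: p for p in profiles}
    if set(by_id) != set(partition.assignment):
        raise ValueError(
            "partition and profiles must cover identical patients; difference: "
            f"{sorted(set(by_id) ^ set(partition.assignment))[:5]}"
        )
    out = []
    for label in sorted(set(partition.assignment.values())):
        members = partition.members(label)
        x = np.array([by_id[pid].x for pid in members], dtype=float)
        pct = 100.0 * x.mean(axis=0)
        out.append(
            CommunityProfile(label=label, size=len(members), pct_mutated=tuple(pct))
        )
    return out


def compare_tmb(
    partition: CommunityPartition, patients: Sequence[PatientRecord]
) -> GroupComparison:
    """Kruskal-Wallis comparison of TMB across communities.

    All-identical TMB values make the tie correction degenerate; that case
    is reported as H = 0, p = 1 with the degeneracy flag set.
    """
    tmb = {p.patient_id: p.tmb for p in patients}
    missing = [pid for pid in partition.assignment if pid not in tmb]
    if missing:
        raise ValueError(f"patients without TMB in partition: {missing[:5]}")
    labels = sorted(set(partition.assignment.values()))
    if len(labels) < 2:
        raise ValueError("need at least two communities to compare TMB")
    groups = [[tmb[pid] for pid in partition.members(c)] for c in labels]
    if any(len(g) == 0 for g in groups):
        raise ValueError("every community must be non-empty")
    sizes = tuple(len(g) for g in groups)
    flat = [v for g in groups for v in g]
    if len(set(flat)) == 1:
        return GroupComparison(
            statistic=0.0, p_value=1.0, group_sizes=sizes, degenerate=True
        )
    h, p = stats.kruskal(*groups)
    return GroupComparison(statistic=float(h), p_value=float(p), group_sizes=sizes)


def htmb_enrichment(
    partition: CommunityPartition,
    strata: Sequence[PatientStratum],
    community: int,
) -> EnrichmentResult:
    """Is a community over-represented in high-TMB patients?

    The background is the full stratum cohort the network was built on
    (all patients in the partition).
    """
    by_id = {s.patient_id: s for s in strata}
    members = partition.members(community)
    if not members:
        raise ValueError(f"community {community} does not exist in the partition")
    cohort_ids = list(partition.assignment)
    missing = [pid for pid in cohort_ids if pid not in by_id]
    if missing:
        raise ValueError(f"patients without strata: {missing[:5]}")
    N = len(cohort_ids)
    K = sum(1 for pid in cohort_ids if by_id[pid].tmb_class == "H")
    n = len(members)
    k = sum(1 for pid in members if by_id[pid].tmb_class == "H")
    p = hypergeom_upper_tail(N, K, n, k)
    return EnrichmentResult(
        pathway="htmb", N=N, K=K, n=n, k=k, p_value=p, q_value=p
    )


def _rankdata(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v, method="average")


def profile_correlation(
    a: CommunityProfile | Sequence[float],
    b: CommunityProfile | Sequence[float],
    *,
    n_permutations: int = SPEARMAN_PERMUTATIONS,
    seed: int = SPEARMAN_SEED,
) -> ProfileCorrelation:
    """Spearman correlation between two pathway-percentage profiles.

    rho uses average ranks for ties. The two-sided p-value is estimated
    from ``n_permutations`` random permutations of one profile (with the
    +1 correction, so the estimate is never exactly zero); at profile
    length 11 the t approximation is unreliable and is not used.
    """
    va = np.asarray(a.pct_mutated if isinstance(a, CommunityProfile) else a, float)
    vb = np.asarray(b.pct_mutated if isinstance(b, CommunityProfile) else b, float)
    if va.shape != vb.shape or va.ndim != 1:
        raise ValueError("profiles must be 1-d vectors of equal length")
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ValueError(
            "Spearman correlation undefined: one profile has zero variance"
        )
    ra, rb = _rankdata(va), _rankdata(vb)
    ra_c = ra - ra.mean()
    rb_c = rb - rb.mean()
    denom_a = np.sqrt((ra_c**2).sum())
    denom_b = np.sqrt((rb_c**2).sum())
    rho = float((ra_c * rb_c).sum() / (denom_a * denom_b))

    rng = np.random.default_rng(seed)
    perms = rng.permuted(
        np.tile(rb_c, (n_permutations, 1)), axis=1
    )
    null = perms @ ra_c / (denom_a * denom_b)
    extreme = int(np.count_nonzero(np.abs(null) >= abs(rho) - 1e-12))
    p = (extreme + 1) / (n_permutations + 1)
    return ProfileCorrelation(rho=rho, p_value=float(p), n_permutations=n_permutations)
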