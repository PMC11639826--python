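"""Hypergeometric pathway enrichment with Benjamini–Hochberg FDR control.

For a subgroup of ``n`` patients drawn from a background of ``N`` patients
of whom ``K`` carry a mutated pathway, the over-representation p-value is
the upper tail of the hypergeometric distribution,

    P(X >= k) = sum_{j=k}^{min(n,K)} C(K,j) C(N-K, n-j) / C(N,n),

computed here with exact integer arithmetic (suffix sums of ``math.comb``
terms converted through :class:`fractions.Fraction`), so the result is the
correctly rounded double for any cohort size used at desk scale. The family
of tests adjusted together is always the 11 pathways of a single subgroup
versus-background comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .io import PATHWAY_ORDER
from .profiling import PathwayProfile, PatientStratum

__all__ = [
    "EnrichmentResult",
    "hypergeom_upper_tail",
    "bh_adjust",
    "enrich_pathways",
    "enrichment_table",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """One pathway's 2x2 over-representation test within a comparison family."""

    pathway: str
    N: int
    K: int
    n: int
    k: int
    p_value: float
    q_value: float


@lru_cache(maxsize=262144)
def _suffix_numerators(N: int, K: int, n: int) -> tuple[int, ...]:
    """suffix[k] = sum_{j>=k} C(K,j) C(N-K, n-j), for k = 0..min(n,K)+1."""
    kmax = min(n, K)
    terms = [math.comb(K, j) * math.comb(N - K, n - j) for j in range(kmax + 1)]
    suffix = [0] * (kmax + 2)
    for j in range(kmax, -1, -1):
        suffix[j] = suffix[j + 1] + terms[j]
    return tuple(suffix)


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact upper-tail hypergeometric probability P(X >= k).

    Parameters follow the urn convention: ``N`` background size, ``K``
    marked in the background, ``n`` subgroup size, ``k`` marked in the
    subgroup. ``k = 0`` returns exactly 1.0.
    """
    for name, v in (("N", N), ("K", K), ("n", n), ("k", k)):
        if not isinstance(v, (int, np.integer)) or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    if K > N or n > N:
        raise ValueError(f"need K <= N and n <= N; got N={N}, K={K}, n={n}")
    if k > min(n, K):
        raise ValueError(f"need k <= min(n, K) = {min(n, K)}; got k={k}")
    suffix = _suffix_numerators(int(N), int(K), int(n))
    return float(Fraction(suffix[int(k)], math.comb(int(N), int(n))))


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values, in input order.

    ``q_(i) = min_{j >= i} p_(j) * m / j`` over the sorted p-values,
    capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a non-empty 1-d sequence")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def enrich_pathways(
    profiles: Sequence[PathwayProfile],
    strata: Sequence[PatientStratum],
    subgroup: Callable[[PatientStratum], bool],
    background: Callable[[PatientStratum], bool],
) -> list[EnrichmentResult]:
    """Test all 11 pathways for over-representation of mutations in a subgroup.

    ``subgroup`` and ``background`` are predicates over patient strata; the
    subgroup must be contained in the background. FDR adjustment spans the
    11 pathways of this one comparison and nothing else.
    """
    by_id = {s.patient_id: s for s in strata}
    missing = [p.patient_id for p in profiles if p.patient_id not in by_id]
    if missing:
        raise ValueError(f"profiles without strata: {missing[:5]}")
    bg = [p for p in profiles if background(by_id[p.patient_id])]
    sub = [p for p in profiles if subgroup(by_id[p.patient_id])]
    if not bg or not sub:
        raise ValueError("subgroup and background must both be non-empty")
    bg_ids = {p.patient_id for p in bg}
    stray = [p.patient_id for p in sub if p.patient_id not in bg_ids]
    if stray:
        raise ValueError(
            f"subgroup is not contained in background; e.g. {stray[:5]}"
        )
    N, n = len(bg), len(sub)
    bg_x = np.array([p.x for p in bg], dtype=int)
    sub_x = np.array([p.x for p in sub], dtype=int)
    Ks = bg_x.sum(axis=0)
    ks = sub_x.sum(axis=0)
    p_values = [
        hypergeom_upper_tail(N, int(K), n, int(k)) for K, k in zip(Ks, ks)
    ]
    q_values = bh_adjust(p_values)
    return [
        EnrichmentResult(
            pathway=path,
            N=N,
            K=int(K),
            n=n,
            k=int(k),
            p_value=p,
            q_value=float(q),
        )
        for path, K, k, p, q in zip(PATHWAY_ORDER, Ks, ks, p_values, q_values)
    ]


def enrichment_table(results: Sequence[EnrichmentResult], alpha: float = 0.05) -> pd.DataFrame:
    """Tabulate enrichment results with a significance flag at ``alpha``."""
    return pd.DataFrame(
        {
            "pathway": [r.pathway for r in results],
            "N": [r.N for r in results],
            "K": [r.K for r in results],
            "n": [r.n for r in results],
            "k": [r.k for r in results],
            "p_value": [r.p_value for r in results],
            "q_value": [r.q_value for r in results],
            "significant": [r.q_value < alpha for r in results],
        }
    ).set_index("pathway")
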