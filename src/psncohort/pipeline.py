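"""End-to-end analysis: profiles, strata, enrichment, networks, communities.

The full run reproduces the study's analysis order: deleterious filtering
and pathway profiling, TMB/smoking stratification, the stratum summary
table, the four reported enrichment comparisons (high-TMB vs the whole
cohort, never-smokers vs the whole cohort, S/H vs smokers, NS/H vs
never-smokers), one patient similarity network per smoking stratum with
Louvain communities, and per-community characterization (pathway profile,
TMB contrast, high-TMB enrichment, OS/PFS log-rank, response rates).
Every stochastic step's seed is logged in machine-parseable key=value
lines and recorded in the report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import characterization as char
from . import enrichment as enr
from . import network as net
from . import outcomes as out
from .io import Cohort, write_network
from .network import CommunityPartition, KernelParams, SimilarityNetwork
from .profiling import (
    PathwayProfile,
    PatientStratum,
    StratificationConfig,
    build_pathway_profiles,
    pathway_summary,
    stratify,
)

__all__ = ["RunConfig", "AnalysisReport", "run_full_analysis"]

logger = logging.getLogger(__name__)

#: strata with fewer patients than this get no similarity network
MIN_NETWORK_SIZE = 3


@dataclass(frozen=True)
class RunConfig:
    """All knobs of a full analysis run."""

    stratification: StratificationConfig = StratificationConfig()
    kernel: KernelParams = KernelParams()
    resolution: float = 1.0
    louvain_seed: int = 0
    n_restarts: int = 100
    alpha: float = 0.05
    out_dir: Path | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


@dataclass
class StratumAnalysis:
    """Network + communities + characterization for one smoking stratum."""

    stratum: str
    network: SimilarityNetwork
    partition: CommunityPartition
    has_structure: bool
    structure_diagnostics: dict
    community_profiles: list[char.CommunityProfile]
    tmb_comparison: char.GroupComparison | None
    htmb_enrichment: list[enr.EnrichmentResult]
    os_logrank: out.LogRankResult | None
    community_orr: dict[int, float]
    community_median_tmb: dict[int, float]


@dataclass
class AnalysisReport:
    summary: "object"  # pandas DataFrame, Table-2-style layout
    enrichments: Mapping[str, list[enr.EnrichmentResult]]
    strata: list[PatientStratum]
    profiles: list[PathwayProfile]
    networks: dict[str, StratumAnalysis]
    config: RunConfig

    def to_json_dict(self) -> dict:
        """Timestamp-free, JSON-serializable view of the report."""
        def enr_rows(results):
            return [
                {
                    "pathway": r.pathway,
                    "N": r.N,
                    "K": r.K,
                    "n": r.n,
                    "k": r.k,
                    "p_value": r.p_value,
                    "q_value": r.q_value,
                }
                for r in results
            ]

        networks = {}
        for name, sa in self.networks.items():
            networks[name] = {
                "n_patients": len(sa.network.patient_ids),
                "n_communities": sa.partition.n_communities,
                "modularity": sa.partition.modularity,
                "has_structure": sa.has_structure,
                "structure_diagnostics": sa.structure_diagnostics,
                "community_sizes": [
                    p.size for p in sa.community_profiles
                ],
                "community_profiles": [
                    {"label": p.label, "size": p.size, "pct_mutated": list(p.pct_mutated)}
                    for p in sa.community_profiles
                ],
                "tmb_kruskal": (
                    None
                    if sa.tmb_comparison is None
                    else {
                        "statistic": sa.tmb_comparison.statistic,
                        "p_value": sa.tmb_comparison.p_value,
                        "degenerate": sa.tmb_comparison.degenerate,
                    }
                ),
                "htmb_enrichment": enr_rows(sa.htmb_enrichment),
                "os_logrank": (
                    None
                    if sa.os_logrank is None
                    else {
                        "statistic": sa.os_logrank.statistic,
                        "p_value": sa.os_logrank.p_value,
                        "df": sa.os_logrank.df,
                    }
                ),
                "community_orr": {str(k): v for k, v in sa.community_orr.items()},
                "community_median_tmb": {
                    str(k): v for k, v in sa.community_median_tmb.items()
                },
            }
        return {
            "pathway_summary": json.loads(self.summary.to_json(orient="index")),
            "enrichments": {k: enr_rows(v) for k, v in self.enrichments.items()},
            "networks": networks,
            "config": {
                "tmb_cutoff": self.config.stratification.tmb_cutoff,
                "kernel_k": self.config.kernel.k_neighbors,
                "kernel_mu": self.config.kernel.mu,
                "resolution": self.config.resolution,
                "louvain_seed": self.config.louvain_seed,
                "n_restarts": self.config.n_restarts,
                "alpha": self.config.alpha,
            },
        }


def _enrichment_families(profiles, strata):
    """The four published comparison families (subgroup, background)."""
    return {
        "H_vs_cohort": (lambda s: s.tmb_class == "H", lambda s: True),
        "NS_vs_cohort": (lambda s: s.smoking_class == "NS", lambda s: True),
        "SH_vs_S": (
            lambda s: s.subgroup == "S/H",
            lambda s: s.smoking_class == "S",
        ),
        "NSH_vs_NS": (
            lambda s: s.subgroup == "NS/H",
            lambda s: s.smoking_class == "NS",
        ),
    }


def run_full_analysis(cohort: Cohort, cfg: RunConfig = RunConfig()) -> AnalysisReport:
    """Execute the whole analysis on one cohort; deterministic given cfg."""
    logger.info("stage=profiling n_patients=%d", len(cohort.patients))
    profiles = build_pathway_profiles(
        cohort, rule=cfg.stratification.pathogenicity_rule
    )
    strata = stratify(cohort.patients, cfg.stratification)
    summary = pathway_summary(profiles, strata)

    enrichments = {}
    for name, (sub, bg) in _enrichment_families(profiles, strata).items():
        try:
            enrichments[name] = enr.enrich_pathways(profiles, strata, sub, bg)
            logger.info("stage=enrichment family=%s", name)
        except ValueError as exc:  # e.g. empty subgroup in a tiny cohort
            logger.warning("stage=enrichment family=%s skipped: %s", name, exc)

    by_id = {p.patient_id: p for p in cohort.patients}
    strata_by_id = {s.patient_id: s for s in strata}
    networks: dict[str, StratumAnalysis] = {}
    for label in ("S", "NS"):
        members = [p for p in profiles if strata_by_id[p.patient_id].smoking_class == label]
        if len(members) < MIN_NETWORK_SIZE:
            logger.warning(
                "stage=network stratum=%s skipped n=%d (< %d patients)",
                label,
                len(members),
                MIN_NETWORK_SIZE,
            )
            continue
        logger.info(
            "stage=network stratum=%s n=%d k=%d mu=%g seed=%d restarts=%d",
            label,
            len(members),
            min(cfg.kernel.k_neighbors, len(members) - 1),
            cfg.kernel.mu,
            cfg.louvain_seed,
            cfg.n_restarts,
        )
        network = net.build_network(members, cfg.kernel)
        partition = net.detect_communities(
            network,
            resolution=cfg.resolution,
            seed=cfg.louvain_seed,
            n_restarts=cfg.n_restarts,
        )
        ok, diagnostics = net.has_community_structure(partition)
        comm_profiles = char.community_profiles(partition, members)
        member_patients = [by_id[p.patient_id] for p in members]
        member_strata = [strata_by_id[p.patient_id] for p in members]

        tmb_cmp = None
        os_lr = None
        if partition.n_communities >= 2:
            tmb_cmp = char.compare_tmb(partition, member_patients)
            groups = [
                out.os_records([by_id[pid] for pid in partition.members(c)])
                for c in sorted(set(partition.assignment.values()))
            ]
            os_lr = out.logrank_test(groups)
        htmb = [
            char.htmb_enrichment(partition, member_strata, c)
            for c in sorted(set(partition.assignment.values()))
        ]
        orr = {}
        med_tmb = {}
        for c in sorted(set(partition.assignment.values())):
            pts = [by_id[pid] for pid in partition.members(c)]
            orr[c] = out.response_rates(pts).orr_pct
            med_tmb[c] = float(np.median([p.tmb for p in pts]))
        networks[label] = StratumAnalysis(
            stratum=label,
            network=network,
            partition=partition,
            has_structure=ok,
            structure_diagnostics=diagnostics,
            community_profiles=comm_profiles,
            tmb_comparison=tmb_cmp,
            htmb_enrichment=htmb,
            os_logrank=os_lr,
            community_orr=orr,
            community_median_tmb=med_tmb,
        )

    report = AnalysisReport(
        summary=summary,
        enrichments=enrichments,
        strata=strata,
        profiles=profiles,
        networks=networks,
        config=cfg,
    )
    if cfg.out_dir is not None:
        _write_report(report, Path(cfg.out_dir), strata)
    return report


def _write_report(report: AnalysisReport, out_dir: Path, strata) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    report.summary.to_csv(out_dir / "pathway_summary.tsv", sep="\t")
    for name, results in report.enrichments.items():
        enr.enrichment_table(results, report.config.alpha).to_csv(
            out_dir / f"enrichment_{name}.tsv", sep="\t"
        )
    for label, sa in report.networks.items():
        write_network(
            sa.network,
            out_dir / f"network_{label}.graphml",
            partition=sa.partition,
            strata=strata,
        )
        with open(out_dir / f"partition_{label}.tsv", "w", encoding="utf-8") as fh:
            fh.write(f"# modularity_Q={sa.partition.modularity:.10f}\n")
            fh.write("patient_id\tcommunity\n")
            for pid in sa.network.patient_ids:
                fh.write(f"{pid}\t{sa.partition.assignment[pid]}\n")
    with open(out_dir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report.to_json_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
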