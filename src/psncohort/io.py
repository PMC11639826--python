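"""Reading and writing of cohort input files and network artifacts.

Input formats
-------------
* mutation table — MAF-lite TSV with columns ``patient_id``, ``gene``,
  ``variant_label``, ``cosmic_pathogenic``, ``clinvar_pathogenic``.
  Pathogenicity database lookups are frozen into the two boolean flag
  columns so that runs are reproducible and need no network access.
* clinical table — TSV with columns ``patient_id``, ``smoking_status``,
  ``tmb`` (Mut/Mb), ``pdl1_pct``, ``os_months``, ``os_event``,
  ``pfs_months``, ``pfs_event``, ``best_response`` (RECIST v1.1 category).
* gene sets — standard GMT (name, description, tab-separated gene symbols),
  one line per pathway; exactly the 11 canonical signaling pathways must
  be present.

All tables are tab-separated UTF-8; ``.`` or an empty cell means missing.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "PATHWAY_ORDER",
    "SmokingStatus",
    "BestResponse",
    "MutationRecord",
    "PatientRecord",
    "PathwayCatalog",
    "Cohort",
    "SchemaError",
    "ValidationError",
    "CatalogError",
    "read_mutations",
    "read_clinical",
    "read_gmt",
    "write_mutations",
    "write_clinical",
    "write_gmt",
    "write_network",
    "read_edge_list",
    "default_catalog",
]

#: Canonical pathway order; indexes every profile vector, summary table and plot.
PATHWAY_ORDER: tuple[str, ...] = (
    "cell_cycle",
    "hippo",
    "myc",
    "notch",
    "oxidative_stress_nrf2",
    "pi3k",
    "rtk_ras_map",
    "tgf_beta",
    "p53",
    "beta_catenin_wnt",
    "ddr",
)

_MISSING = {"", "."}
_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


class SchemaError(ValueError):
    """A required column is absent or a cell cannot be parsed."""


class ValidationError(ValueError):
    """A parsed record violates a domain invariant."""


class CatalogError(ValueError):
    """The gene-set file does not define exactly the 11 canonical pathways."""


class SmokingStatus(str, Enum):
    NEVER = "never"
    FORMER = "former"
    CURRENT = "current"


class BestResponse(str, Enum):
    CR = "CR"
    PR = "PR"
    SD = "SD"
    PD = "PD"
    NE = "NE"


@dataclass(frozen=True)
class MutationRecord:
    """One somatic call with frozen pathogenicity flags."""

    patient_id: str
    gene: str
    variant_label: str = ""
    cosmic_pathogenic: bool = False
    clinvar_pathogenic: bool = False

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValidationError("mutation record with empty patient_id")
        gene = self.gene.strip().upper()
        if not gene:
            raise ValidationError(
                f"mutation record for {self.patient_id!r} with empty gene symbol"
            )
        object.__setattr__(self, "gene", gene)


@dataclass(frozen=True)
class PatientRecord:
    """Clinical covariates and outcome endpoints for one patient.

    ``pfs_months <= os_months`` is deliberately NOT enforced: real data may
    violate it through assessment scheduling. Only non-negativity is checked.
    """

    patient_id: str
    smoking_status: SmokingStatus
    tmb: float
    os_months: float
    os_event: bool
    pfs_months: float
    pfs_event: bool
    best_response: BestResponse
    pdl1_pct: float | None = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValidationError("patient record with empty patient_id")
        for name in ("tmb", "os_months", "pfs_months"):
            value = getattr(self, name)
            if value is None or value < 0:
                raise ValidationError(
                    f"patient {self.patient_id!r}: {name} must be a non-negative number, got {value!r}"
                )
        if self.pdl1_pct is not None and not 0 <= self.pdl1_pct <= 100:
            raise ValidationError(
                f"patient {self.patient_id!r}: pdl1_pct outside [0, 100]: {self.pdl1_pct!r}"
            )


@dataclass(frozen=True)
class PathwayCatalog:
    """The 11 curated signaling pathways and their member gene sets.

    Order is fixed to :data:`PATHWAY_ORDER`; a gene may belong to more than
    one pathway.
    """

    gene_sets: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        names = tuple(self.gene_sets)
        if names != PATHWAY_ORDER:
            raise CatalogError(
                f"catalog must contain exactly the canonical pathways in order; got {names}"
            )
        for name, genes in self.gene_sets.items():
            if not genes:
                raise CatalogError(f"pathway {name!r} has an empty gene set")

    @property
    def pathways(self) -> tuple[str, ...]:
        return PATHWAY_ORDER

    def __getitem__(self, pathway: str) -> frozenset[str]:
        return self.gene_sets[pathway]

    def pathways_of(self, gene: str) -> tuple[str, ...]:
        """All pathways that contain ``gene`` (possibly none)."""
        return tuple(p for p in PATHWAY_ORDER if gene in self.gene_sets[p])


@dataclass(frozen=True)
class Cohort:
    """Patients, their somatic calls and the pathway catalog, bundled."""

    patients: tuple[PatientRecord, ...]
    mutations: tuple[MutationRecord, ...]
    catalog: PathwayCatalog

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate patient ids: {dupes}")
        known = set(ids)
        orphans = sorted({m.patient_id for m in self.mutations} - known)
        if orphans:
            raise ValidationError(
                f"mutations reference unknown patient ids: {orphans[:5]}"
            )

    @property
    def patient_ids(self) -> tuple[str, ...]:
        return tuple(p.patient_id for p in self.patients)


# ---------------------------------------------------------------------------
# parsing helpers


def _parse_bool(raw: str, *, column: str, line: int) -> bool:
    token = raw.strip().lower()
    if token in _TRUE:
        return True
    if token in _FALSE:
        return False
    raise SchemaError(
        f"line {line}: cannot parse {column}={raw!r} as a boolean "
        "(expected true/false, 1/0 or yes/no)"
    )


def _parse_float(raw: str, *, column: str, line: int) -> float | None:
    token = raw.strip()
    if token in _MISSING:
        return None
    try:
        return float(token)
    except ValueError:
        raise SchemaError(
            f"line {line}: cannot parse {column}={raw!r} as a number"
        ) from None


def _check_columns(header: Sequence[str], required: Iterable[str], path: Path) -> None:
    missing = [c for c in required if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def _rows(path: Path):
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, no header row")
        yield reader.fieldnames
        yield from enumerate(reader, start=2)


# ---------------------------------------------------------------------------
# readers


def read_mutations(path: str | Path) -> list[MutationRecord]:
    """Read a MAF-lite mutation TSV, preserving row order.

    Gene symbols are upper-cased and whitespace-trimmed; boolean flag columns
    accept true/false, 1/0 and yes/no case-insensitively.
    """
    path = Path(path)
    rows = _rows(path)
    header = next(rows)
    _check_columns(
        header, ("patient_id", "gene", "cosmic_pathogenic", "clinvar_pathogenic"), path
    )
    records = []
    for line, row in rows:
        records.append(
            MutationRecord(
                patient_id=row["patient_id"].strip(),
                gene=row["gene"],
                variant_label=(row.get("variant_label") or "").strip(),
                cosmic_pathogenic=_parse_bool(
                    row["cosmic_pathogenic"], column="cosmic_pathogenic", line=line
                ),
                clinvar_pathogenic=_parse_bool(
                    row["clinvar_pathogenic"], column="clinvar_pathogenic", line=line
                ),
            )
        )
    return records


def read_clinical(path: str | Path) -> list[PatientRecord]:
    """Read the clinical TSV into validated :class:`PatientRecord` objects."""
    path = Path(path)
    rows = _rows(path)
    header = next(rows)
    _check_columns(
        header,
        (
            "patient_id",
            "smoking_status",
            "tmb",
            "os_months",
            "os_event",
            "pfs_months",
            "pfs_event",
            "best_response",
        ),
        path,
    )
    records = []
    for line, row in rows:
        pid = row["patient_id"].strip()
        status_raw = row["smoking_status"].strip().lower()
        try:
            status = SmokingStatus(status_raw)
        except ValueError:
            raise ValidationError(
                f"patient {pid!r}: unknown smoking_status {row['smoking_status']!r}"
            ) from None
        response_raw = (row.get("best_response") or "").strip().upper()
        if response_raw in {r.upper() for r in _MISSING} or not response_raw:
            response = BestResponse.NE
        else:
            try:
                response = BestResponse(response_raw)
            except ValueError:
                raise ValidationError(
                    f"patient {pid!r}: unknown best_response {row['best_response']!r}"
                ) from None
        tmb = _parse_float(row["tmb"], column="tmb", line=line)
        if tmb is None:
            raise ValidationError(f"patient {pid!r}: missing tmb")
        records.append(
            PatientRecord(
                patient_id=pid,
                smoking_status=status,
                tmb=tmb,
                pdl1_pct=_parse_float(
                    row.get("pdl1_pct", "."), column="pdl1_pct", line=line
                ),
                os_months=_parse_float(row["os_months"], column="os_months", line=line),
                os_event=_parse_bool(row["os_event"], column="os_event", line=line),
                pfs_months=_parse_float(
                    row["pfs_months"], column="pfs_months", line=line
                ),
                pfs_event=_parse_bool(row["pfs_event"], column="pfs_event", line=line),
                best_response=response,
            )
        )
    return records


_ALIAS = {
    # tolerated GMT spellings, case-insensitive, mapped to canonical names
    "cellcycle": "cell_cycle",
    "cell_cycle": "cell_cycle",
    "hippo": "hippo",
    "myc": "myc",
    "notch": "notch",
    "oxidative_stress_nrf2": "oxidative_stress_nrf2",
    "oxidativestressnrf2": "oxidative_stress_nrf2",
    "nrf2": "oxidative_stress_nrf2",
    "pi3k": "pi3k",
    "rtk_ras_map": "rtk_ras_map",
    "rtkrasmap": "rtk_ras_map",
    "tgf_beta": "tgf_beta",
    "tgfbeta": "tgf_beta",
    "p53": "p53",
    "beta_catenin_wnt": "beta_catenin_wnt",
    "betacateninwnt": "beta_catenin_wnt",
    "wnt": "beta_catenin_wnt",
    "ddr": "ddr",
}


def _canonical_pathway(raw: str) -> str | None:
    key = "".join(ch for ch in raw.strip().lower() if ch.isalnum() or ch == "_")
    if key in _ALIAS:
        return _ALIAS[key]
    return _ALIAS.get(key.replace("_", ""))


def read_gmt(path: str | Path) -> PathwayCatalog:
    """Read pathway gene sets from a GMT file into the canonical catalog.

    Pathway names are matched case-insensitively against the canonical list
    and the result is re-ordered canonically; duplicate genes within a line
    are deduplicated.
    """
    path = Path(path)
    found: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise CatalogError(
                    f"{path}: GMT line needs name, description and >=1 gene: {line!r}"
                )
            name = _canonical_pathway(parts[0])
            if name is None:
                raise CatalogError(f"{path}: unrecognized pathway name {parts[0]!r}")
            if name in found:
                raise CatalogError(f"{path}: duplicate pathway {name!r}")
            genes = frozenset(g.strip().upper() for g in parts[2:] if g.strip())
            found[name] = genes
    missing = [p for p in PATHWAY_ORDER if p not in found]
    extra = [p for p in found if p not in PATHWAY_ORDER]
    if missing or extra:
        raise CatalogError(
            f"{path}: catalog mismatch; missing={missing or 'none'} extra={extra or 'none'}"
        )
    return PathwayCatalog(gene_sets={p: found[p] for p in PATHWAY_ORDER})


# ---------------------------------------------------------------------------
# writers


def write_mutations(records: Sequence[MutationRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["patient_id", "gene", "variant_label", "cosmic_pathogenic", "clinvar_pathogenic"]
        )
        for r in records:
            w.writerow(
                [
                    r.patient_id,
                    r.gene,
                    r.variant_label,
                    str(r.cosmic_pathogenic).lower(),
                    str(r.clinvar_pathogenic).lower(),
                ]
            )


def write_clinical(records: Sequence[PatientRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            [
                "patient_id",
                "smoking_status",
                "tmb",
                "pdl1_pct",
                "os_months",
                "os_event",
                "pfs_months",
                "pfs_event",
                "best_response",
            ]
        )
        for r in records:
            w.writerow(
                [
                    r.patient_id,
                    r.smoking_status.value,
                    repr(r.tmb),
                    "." if r.pdl1_pct is None else repr(r.pdl1_pct),
                    repr(r.os_months),
                    str(r.os_event).lower(),
                    repr(r.pfs_months),
                    str(r.pfs_event).lower(),
                    r.best_response.value,
                ]
            )


def write_gmt(catalog: PathwayCatalog, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in PATHWAY_ORDER:
            genes = sorted(catalog[name])
            fh.write("\t".join([name, "na", *genes]) + "\n")


def write_network(net, path: str | Path, *, partition=None, strata=None) -> None:
    """Write a similarity network as GraphML plus a 3-column edge list.

    ``path`` names the GraphML file; an edge-list variant with the same stem
    and ``.edges.tsv`` suffix is written next to it. Node attributes include
    patient_id, tmb, tmb_class, smoking_status and community when the
    corresponding metadata is provided.
    """
    if len(net.patient_ids) == 0:
        raise ValueError("refusing to write an empty network")
    path = Path(path)
    strata_by_id = {s.patient_id: s for s in strata} if strata else {}
    assignment = dict(partition.assignment) if partition is not None else {}

    g = nx.Graph()
    for idx, pid in enumerate(net.patient_ids):
        attrs = {"patient_id": pid}
        stratum = strata_by_id.get(pid)
        if stratum is not None:
            attrs["tmb_class"] = stratum.tmb_class
            attrs["smoking_status"] = stratum.smoking_class
        if pid in assignment:
            attrs["community"] = int(assignment[pid])
        g.add_node(idx, **attrs)
    n = len(net.patient_ids)
    for i in range(n):
        for j in range(i + 1, n):
            if net.W[i, j] > 0:
                g.add_edge(i, j, weight=float(net.W[i, j]))
    nx.write_graphml(g, path)

    edge_path = path.with_suffix(".edges.tsv")
    with open(edge_path, "w", encoding="utf-8") as fh:
        fh.write("i\tj\tweight\n")
        for i in range(n):
            for j in range(i + 1, n):
                if net.W[i, j] > 0:
                    fh.write(
                        f"{net.patient_ids[i]}\t{net.patient_ids[j]}\t{net.W[i, j]:.12f}\n"
                    )


def read_edge_list(path: str | Path) -> list[tuple[str, str, float]]:
    """Read back the 3-column edge list written by :func:`write_network`."""
    edges = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("i\tj\tweight"):
            raise SchemaError(f"{path}: not an edge-list file")
        for line in fh:
            i, j, w = line.rstrip("\n").split("\t")
            edges.append((i, j, float(w)))
    return edges


# ---------------------------------------------------------------------------
# default catalog


def default_catalog() -> PathwayCatalog:
    """A best-effort stand-in catalog of member genes per pathway.

    The authoritative gene lists are an input (GMT); this built-in catalog
    exists so the synthetic generator and examples run out of the box. Gene
    sets are intentionally disjoint here, although overlapping membership is
    fully supported by the profile builder.
    """
    sets = {
        "cell_cycle": {"CDKN2A", "CDKN2B", "CCND1", "CCNE1", "CDK4", "CDK6", "RB1"},
        "hippo": {"NF2", "LATS1", "LATS2", "SAV1", "TAOK1", "FAT1"},
        "myc": {"MYC", "MYCN", "MYCL", "MAX", "MXD1", "MNT"},
        "notch": {"NOTCH1", "NOTCH2", "NOTCH3", "NOTCH4", "FBXW7", "SPEN"},
        "oxidative_stress_nrf2": {"NFE2L2", "KEAP1", "CUL3"},
        "pi3k": {"PIK3CA", "PIK3R1", "PTEN", "AKT1", "MTOR", "TSC1", "TSC2", "STK11"},
        "rtk_ras_map": {
            "EGFR", "KRAS", "NRAS", "HRAS", "BRAF", "MET", "ALK",
            "ERBB2", "RET", "ROS1", "NF1", "MAP2K1",
        },
        "tgf_beta": {"TGFBR1", "TGFBR2", "SMAD2", "SMAD3", "SMAD4", "ACVR2A"},
        "p53": {"TP53", "MDM2", "MDM4"},
        "beta_catenin_wnt": {"CTNNB1", "APC", "AXIN1", "AXIN2", "RNF43", "TCF7L2"},
        "ddr": {
            "BRCA1", "BRCA2", "ATM", "ATR", "CHEK1", "CHEK2", "PALB2",
            "RAD51", "FANCA", "MLH1", "MSH2", "MSH6", "POLE", "ERCC2",
        },
    }
    return PathwayCatalog(gene_sets={p: frozenset(sets[p]) for p in PATHWAY_ORDER})
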