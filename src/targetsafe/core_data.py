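"""Domain model for drug-target genetic-safety analysis.

The unit of analysis is the drug x organ-system pair. Phenotypes (drug
indications, clinical-trial side effects, and the Mendelian / GWAS phenotypes
of the genes encoding a drug's targets) are all expressed in a fixed
vocabulary of 21 MedDRA system-organ-class (SOC) categories. Each drug x SOC
pair carries:

* whether the drug was ever pursued for an indication in that organ system,
* whether a clinical side effect was recorded in that organ system, and
* the genetic support of the drug's targets for that organ system, coded
  per evidence source as MATCH (some target gene has a phenotype in the SOC),
  MISMATCH (some target gene is informative, but none in the SOC), or
  NO_INFO (no target gene has any phenotype for that source).

This module provides the record types, TSV catalog I/O, the genetic-support
encoding, and the construction of the flattened observation table that every
downstream analysis (enrichment, permutation, regression, cross-validation)
consumes.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

#: The 21 organ-system categories, in fixed report order.
SOC_LABELS: tuple[str, ...] = (
    "Blood", "Heart", "Congenital", "Ear", "Endocrine", "Eye",
    "Gastrointestinal", "Hepatobiliary", "Immune", "Infection", "Metabolism",
    "Musculoskeletal", "Neoplasm", "Nervous", "Pregnancy", "Mental",
    "Urologic", "Reproductive", "Respiratory", "Skin", "Vascular",
)

SOC_INDEX: dict[str, int] = {s: i for i, s in enumerate(SOC_LABELS)}

N_SOC = len(SOC_LABELS)

MODALITIES = ("small_molecule", "biological")
ROUTES = ("enteral", "parenteral", "topical", "other")
EXPRESSION_BREADTHS = ("all", "mixed", "enriched", "none_detected")

GENETIC_SOURCES = ("mendelian", "gwas")


class Support(str, Enum):
    """Three-level genetic support of a drug's targets for one organ system."""

    MATCH = "MATCH"
    MISMATCH = "MISMATCH"
    NO_INFO = "NO_INFO"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def validate_socs(socs: Iterable[str], context: str = "") -> frozenset[str]:
    """Return ``socs`` as a frozenset, rejecting labels outside the vocabulary."""
    out = frozenset(socs)
    bad = out - set(SOC_LABELS)
    if bad:
        where = f" in {context}" if context else ""
        raise ValueError(f"unknown SOC label(s) {sorted(bad)}{where}")
    return out


@dataclass(frozen=True)
class GeneRecord:
    """A drug-target gene with its human-genetic phenotype annotations."""

    gene_id: str
    mendelian_socs: frozenset[str] = frozenset()
    gwas_socs: frozenset[str] = frozenset()
    constrained: bool = False  # pLI >= 0.9 proxy
    expression_breadth: str = "none_detected"

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be nonempty")
        object.__setattr__(self, "mendelian_socs",
                           validate_socs(self.mendelian_socs, self.gene_id))
        object.__setattr__(self, "gwas_socs",
                           validate_socs(self.gwas_socs, self.gene_id))
        if self.expression_breadth not in EXPRESSION_BREADTHS:
            raise ValueError(
                f"unknown expression_breadth {self.expression_breadth!r} "
                f"for gene {self.gene_id}")

    def socs(self, source: str) -> frozenset[str]:
        if source == "mendelian":
            return self.mendelian_socs
        if source == "gwas":
            return self.gwas_socs
        raise ValueError(f"unknown genetic source {source!r}")

    @property
    def informative(self) -> bool:
        """True if the gene has any phenotype from either source."""
        return bool(self.mendelian_socs or self.gwas_socs)


@dataclass(frozen=True)
class DrugRecord:
    """A drug with its target genes, modality, routes, indications and side effects."""

    drug_id: str
    targets: frozenset[str]
    modality: str = "small_molecule"
    routes: frozenset[str] = frozenset()
    indications: frozenset[str] = frozenset()
    side_effects: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.drug_id:
            raise ValueError("drug_id must be nonempty")
        object.__setattr__(self, "targets", frozenset(self.targets))
        if not self.targets:
            raise ValueError(f"drug {self.drug_id} has no targets")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r} for {self.drug_id}")
        routes = frozenset(self.routes)
        bad = routes - set(ROUTES)
        if bad:
            raise ValueError(f"unknown route(s) {sorted(bad)} for {self.drug_id}")
        object.__setattr__(self, "routes", routes)
        object.__setattr__(self, "indications",
                           validate_socs(self.indications, self.drug_id))
        object.__setattr__(self, "side_effects",
                           validate_socs(self.side_effects, self.drug_id))


GeneCatalog = dict[str, GeneRecord]
DrugCatalog = dict[str, DrugRecord]


@dataclass(frozen=True)
class Observation:
    """One drug x SOC pair, the unit of the enrichment analysis."""

    drug_id: str
    soc: str
    on_indication: bool
    side_effect: bool
    mendelian: Support
    gwas: Support
    any_support: bool
    all_targets_informative: bool


@dataclass
class ObservationSet:
    """Flattened drug x SOC observation table.

    ``df`` has one row per retained pair with columns ``drug_id``, ``soc``,
    ``on_indication``, ``side_effect``, ``mendelian``, ``gwas``,
    ``any_support``, ``all_targets_informative``.
    """

    df: pd.DataFrame
    mode: str = "all"

    def __post_init__(self) -> None:
        if self.mode not in ("all", "off_indication"):
            raise ValueError(f"unknown observation mode {self.mode!r}")
        if self.mode == "off_indication" and bool(self.df["on_indication"].any()):
            raise ValueError("off_indication set contains on-indication rows")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def observations(self) -> list[Observation]:
        return [
            Observation(r.drug_id, r.soc, bool(r.on_indication),
                        bool(r.side_effect), Support(r.mendelian),
                        Support(r.gwas), bool(r.any_support),
                        bool(r.all_targets_informative))
            for r in self.df.itertuples(index=False)
        ]


# ---------------------------------------------------------------------------
# Genetic-support encoding
# ---------------------------------------------------------------------------

def derive_genetic_support(drug: DrugRecord, genes: GeneCatalog, soc: str,
                           source: str) -> Support:
    """Support level of ``drug``'s target set for organ system ``soc``.

    MATCH if any target gene has ``soc`` in its phenotype set for ``source``;
    otherwise MISMATCH if any target gene has a nonempty phenotype set for
    that source; otherwise NO_INFO.
    """
    if soc not in SOC_INDEX:
        raise ValueError(f"unknown SOC label {soc!r}")
    informative = False
    for gid in drug.targets:
        try:
            gene = genes[gid]
        except KeyError:
            raise KeyError(
                f"target gene {gid!r} of drug {drug.drug_id} not in catalog"
            ) from None
        socs = gene.socs(source)
        if soc in socs:
            return Support.MATCH
        if socs:
            informative = True
    return Support.MISMATCH if informative else Support.NO_INFO


# ---------------------------------------------------------------------------
# Array view of the catalogs (vectorized path used throughout)
# ---------------------------------------------------------------------------

@dataclass
class CatalogArrays:
    """Boolean-matrix view of a pair of catalogs, in stable sorted id order."""

    gene_ids: list[str]
    drug_ids: list[str]
    mend: np.ndarray        # (G, 21) gene has Mendelian phenotype in SOC
    gwas: np.ndarray        # (G, 21)
    targets: np.ndarray     # (D, G) drug targets gene
    indications: np.ndarray  # (D, 21)
    side_effects: np.ndarray  # (D, 21)


def catalogs_to_arrays(drugs: DrugCatalog, genes: GeneCatalog) -> CatalogArrays:
    gene_ids = sorted(genes)
    drug_ids = sorted(drugs)
    gidx = {g: i for i, g in enumerate(gene_ids)}
    G, D = len(gene_ids), len(drug_ids)
    mend = np.zeros((G, N_SOC), dtype=bool)
    gwa = np.zeros((G, N_SOC), dtype=bool)
    for i, g in enumerate(gene_ids):
        rec = genes[g]
        for s in rec.mendelian_socs:
            mend[i, SOC_INDEX[s]] = True
        for s in rec.gwas_socs:
            gwa[i, SOC_INDEX[s]] = True
    tmat = np.zeros((D, G), dtype=bool)
    ind = np.zeros((D, N_SOC), dtype=bool)
    se = np.zeros((D, N_SOC), dtype=bool)
    for j, d in enumerate(drug_ids):
        rec = drugs[d]
        for g in rec.targets:
            if g not in gidx:
                raise KeyError(f"target gene {g!r} of drug {d} not in catalog")
            tmat[j, gidx[g]] = True
        for s in rec.indications:
            ind[j, SOC_INDEX[s]] = True
        for s in rec.side_effects:
            se[j, SOC_INDEX[s]] = True
    return CatalogArrays(gene_ids, drug_ids, mend, gwa, tmat, ind, se)


def _support_matrices(arr: CatalogArrays, pheno: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(match, informative) boolean (D, 21) / (D,) matrices for one source."""
    match = arr.targets @ pheno          # bool matmul: OR of ANDs
    informative = arr.targets @ pheno.any(axis=1)
    return match, informative


def build_observations(drugs: DrugCatalog, genes: GeneCatalog,
                       mode: str = "all") -> ObservationSet:
    """Flatten the catalogs into one row per drug x SOC pair.

    ``mode="off_indication"`` drops every pair where the SOC is among the
    drug's pursued indications, removing potential exaggerated-pharmacology
    effects in the organ of intended action.
    """
    if mode not in ("all", "off_indication"):
        raise ValueError(f"unknown observation mode {mode!r}")
    arr = catalogs_to_arrays(drugs, genes)
    D = len(arr.drug_ids)
    m_match, m_info = _support_matrices(arr, arr.mend)
    g_match, g_info = _support_matrices(arr, arr.gwas)

    def levels(match: np.ndarray, info: np.ndarray) -> np.ndarray:
        lev = np.where(match, Support.MATCH.value,
                       np.where(info[:, None], Support.MISMATCH.value,
                                Support.NO_INFO.value))
        return lev

    gene_informative = arr.mend.any(axis=1) | arr.gwas.any(axis=1)
    # every target informative <=> no target hits an uninformative gene
    all_info = ~(arr.targets @ ~gene_informative)

    df = pd.DataFrame({
        "drug_id": np.repeat(arr.drug_ids, N_SOC),
        "soc": np.tile(SOC_LABELS, D),
        "on_indication": arr.indications.ravel(),
        "side_effect": arr.side_effects.ravel(),
        "mendelian": levels(m_match, m_info).ravel(),
        "gwas": levels(g_match, g_info).ravel(),
        "any_support": (m_match | g_match).ravel(),
        "all_targets_informative": np.repeat(all_info, N_SOC),
    })
    if mode == "off_indication":
        df = df.loc[~df["on_indication"]].reset_index(drop=True)
    return ObservationSet(df=df, mode=mode)


# ---------------------------------------------------------------------------
# Raw side-effect term filtering (applied upstream of SOC aggregation)
# ---------------------------------------------------------------------------

def remove_common_side_effects(
    drugs: DrugCatalog | Iterable[str],
    raw_side_effect_terms: Mapping[str, set[str]],
    threshold: float = 0.10,
) -> tuple[dict[str, set[str]], list[str]]:
    """Drop raw side-effect terms observed for at least ``threshold`` of drugs.

    Very common terms (headache, nausea, ...) are unlikely to be
    target-mediated and would otherwise dominate the organ-system
    aggregation. Returns the filtered per-drug term sets and the sorted list
    of removed terms.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    drug_ids = list(drugs)
    n = len(drug_ids)
    counts: dict[str, int] = {}
    for did in drug_ids:
        for term in raw_side_effect_terms.get(did, ()):
            counts[term] = counts.get(term, 0) + 1
    removed = sorted(t for t, c in counts.items() if c >= threshold * n)
    removed_set = set(removed)
    filtered = {
        did: set(raw_side_effect_terms.get(did, ())) - removed_set
        for did in drug_ids
    }
    return filtered, removed


# ---------------------------------------------------------------------------
# TSV catalog I/O
# ---------------------------------------------------------------------------

_GENE_COLS = ["gene_id", "mendelian_socs", "gwas_socs", "constrained",
              "expression_breadth"]
_DRUG_COLS = ["drug_id", "targets", "modality", "routes", "indications",
              "side_effects"]
_OBS_COLS = ["drug_id", "soc", "on_indication", "side_effect",
             "mendelian_support", "gwas_support", "all_targets_informative"]


def _split(cell: object) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return frozenset()
    text = str(cell).strip()
    if not text:
        return frozenset()
    return frozenset(p for p in text.split(";") if p)


def _join(items: Iterable[str]) -> str:
    return ";".join(sorted(items))


def _read_tsv(path, cols: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != cols:
        raise ValueError(f"{path}: expected header {cols}, got {list(df.columns)}")
    return df


def load_gene_table(path) -> GeneCatalog:
    """Read a gene catalog from TSV (see package docs for the schema)."""
    df = _read_tsv(path, _GENE_COLS)
    catalog: GeneCatalog = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.gene_id in catalog:
            raise ValueError(f"{path}:{i}: duplicate gene_id {row.gene_id!r}")
        try:
            rec = GeneRecord(
                gene_id=row.gene_id,
                mendelian_socs=_split(row.mendelian_socs),
                gwas_socs=_split(row.gwas_socs),
                constrained=row.constrained == "1",
                expression_breadth=row.expression_breadth,
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{i}: {exc}") from None
        if row.constrained not in ("0", "1"):
            raise ValueError(f"{path}:{i}: constrained must be 0 or 1")
        catalog[rec.gene_id] = rec
    return catalog


def write_gene_table(catalog: GeneCatalog, path) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "mendelian_socs": _join(g.mendelian_socs),
            "gwas_socs": _join(g.gwas_socs),
            "constrained": int(g.constrained),
            "expression_breadth": g.expression_breadth,
        }
        for g in (catalog[k] for k in sorted(catalog))
    ]
    pd.DataFrame(rows, columns=_GENE_COLS).to_csv(path, sep="\t", index=False)


def load_drug_table(path, genes: GeneCatalog | None = None) -> DrugCatalog:
    """Read a drug catalog from TSV; validate target ids against ``genes`` if given."""
    df = _read_tsv(path, _DRUG_COLS)
    catalog: DrugCatalog = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.drug_id in catalog:
            raise ValueError(f"{path}:{i}: duplicate drug_id {row.drug_id!r}")
        try:
            rec = DrugRecord(
                drug_id=row.drug_id,
                targets=_split(row.targets),
                modality=row.modality,
                routes=_split(row.routes),
                indications=_split(row.indications),
                side_effects=_split(row.side_effects),
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{i}: {exc}") from None
        if genes is not None:
            missing = rec.targets - set(genes)
            if missing:
                raise ValueError(
                    f"{path}:{i}: unknown target gene(s) {sorted(missing)}")
        catalog[rec.drug_id] = rec
    return catalog


def write_drug_table(catalog: DrugCatalog, path) -> None:
    rows = [
        {
            "drug_id": d.drug_id,
            "targets": _join(d.targets),
            "modality": d.modality,
            "routes": _join(d.routes),
            "indications": _join(d.indications),
            "side_effects": _join(d.side_effects),
        }
        for d in (catalog[k] for k in sorted(catalog))
    ]
    pd.DataFrame(rows, columns=_DRUG_COLS).to_csv(path, sep="\t", index=False)


def load_observation_table(path, mode: str = "all") -> ObservationSet:
    """Read a pre-flattened drug x SOC observation table (supplementary layout)."""
    df = _read_tsv(path, _OBS_COLS)
    bad = set(df["soc"]) - set(SOC_LABELS)
    if bad:
        raise ValueError(f"{path}: unknown SOC label(s) {sorted(bad)}")
    for col in ("mendelian_support", "gwas_support"):
        bad_lev = set(df[col]) - {s.value for s in Support}
        if bad_lev:
            raise ValueError(f"{path}: invalid {col} value(s) {sorted(bad_lev)}")
    out = pd.DataFrame({
        "drug_id": df["drug_id"],
        "soc": df["soc"],
        "on_indication": df["on_indication"].astype(int).astype(bool),
        "side_effect": df["side_effect"].astype(int).astype(bool),
        "mendelian": df["mendelian_support"],
        "gwas": df["gwas_support"],
        "all_targets_informative":
            df["all_targets_informative"].astype(int).astype(bool),
    })
    out["any_support"] = ((out["mendelian"] == Support.MATCH.value)
                          | (out["gwas"] == Support.MATCH.value))
    out = out[["drug_id", "soc", "on_indication", "side_effect", "mendelian",
               "gwas", "any_support", "all_targets_informative"]]
    if mode == "off_indication":
        out = out.loc[~out["on_indication"]].reset_index(drop=True)
    return ObservationSet(df=out, mode=mode)


def write_observation_table(obs: ObservationSet, path) -> None:
    df = obs.df
    out = pd.DataFrame({
        "drug_id": df["drug_id"],
        "soc": df["soc"],
        "on_indication": df["on_indication"].astype(int),
        "side_effect": df["side_effect"].astype(int),
        "mendelian_support": df["mendelian"],
        "gwas_support": df["gwas"],
        "all_targets_informative": df["all_targets_informative"].astype(int),
    })
    out.to_csv(path, sep="\t", index=False)
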