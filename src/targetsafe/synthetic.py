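"""Synthetic gene/drug catalogs with the statistical structure of the study.

The generator draws a cohort of target genes with Mendelian and GWAS
phenotype annotations, a cohort of drugs targeting those genes (with shared
target sets, so grouped cross-validation is non-trivial), and per drug x SOC
side effects from a single logistic model:

    logit P(SE) = alpha_s + beta_genetic * [any target matches SOC]
                + beta_indication * [SOC among indications]
                + covariate terms (modality, routes, constraint, expression)

Indication-genetics confounding is induced by seeding a drug's indications
from its targets' phenotype organ systems with probability ``confounding`` —
mirroring how rational drug discovery makes indications correlate with
target genetics even when genetics has no causal side-effect role.

Defaults emulate the study's scale: 1819 drugs, 1046 targeted genes, per-SOC
baseline side-effect rates equal to the published no-support rates, a
genetic log-odds of ln(1.55) (the published off-indication, less-confounded
enrichment), and roughly half of the genes uninformative per source.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core_data import (
    EXPRESSION_BREADTHS,
    N_SOC,
    ROUTES,
    SOC_INDEX,
    SOC_LABELS,
    DrugCatalog,
    DrugRecord,
    GeneCatalog,
    GeneRecord,
)
from .reference_data import PUBLISHED_BASELINE_RATES

DEFAULT_BASELINE_LOGIT: dict[str, float] = {
    soc: math.log(r / (1 - r)) for soc, r in PUBLISHED_BASELINE_RATES.items()
}

#: Drug/gene covariate log-odds on the side-effect scale (deliberately small;
#: the covariates are confounder stand-ins, not the object of the simulation).
DEFAULT_COVARIATE_EFFECTS: dict[str, float] = {
    "modality_biological": -0.20,
    "route_enteral": 0.00,
    "route_parenteral": 0.10,
    "route_topical": -0.10,
    "route_other": 0.00,
    "constrained": 0.10,
    "expr_all": 0.20,
    "expr_mixed": 0.10,
    "expr_enriched": 0.00,
}


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort; defaults emulate the study."""

    n_drugs: int = 1819
    n_genes: int = 1046
    #: fixed int k, or an inclusive (lo, hi) range, of targets per drug
    targets_per_drug: int | tuple[int, int] = (1, 3)
    #: probability a drug reuses a previously drawn drug's whole target set
    target_sharing: float = 0.4
    #: per-SOC intercept alpha_s (log-odds of a side effect absent all effects)
    baseline_logit: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_LOGIT))
    #: log-OR added when the drug has any-source genetic support for the SOC
    beta_genetic: float = math.log(1.55)
    #: log-OR added when the SOC is among the drug's indications
    beta_indication: float = math.log(2.0)
    #: probability an indication is seeded from target phenotype organ systems
    confounding: float = 0.25
    frac_no_mendelian: float = 0.50
    frac_no_gwas: float = 0.55
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_drugs < 0 or self.n_genes < 0:
            raise ValueError("n_drugs and n_genes must be nonnegative")
        for name in ("target_sharing", "confounding", "frac_no_mendelian",
                     "frac_no_gwas"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if isinstance(self.targets_per_drug, int):
            if self.targets_per_drug < 1:
                raise ValueError("targets_per_drug must be >= 1")
        else:
            try:
                lo, hi = self.targets_per_drug
            except (TypeError, ValueError):
                raise ValueError(
                    "targets_per_drug must be an int or a (lo, hi) pair"
                ) from None
            if not (1 <= lo <= hi):
                raise ValueError("targets_per_drug range must satisfy 1 <= lo <= hi")
        missing = set(self.baseline_logit) ^ set(SOC_LABELS)
        if missing:
            raise ValueError(f"baseline_logit must cover exactly the vocabulary; "
                             f"difference {sorted(missing)}")


def _draw_soc_set(rng: np.random.Generator) -> frozenset[str]:
    k = 1 + rng.poisson(1.5)
    k = min(k, N_SOC)
    return frozenset(rng.choice(SOC_LABELS, size=k, replace=False))


def _generate_genes(config: SimConfig, rng: np.random.Generator) -> GeneCatalog:
    width = max(4, len(str(config.n_genes)))
    genes: GeneCatalog = {}
    for i in range(config.n_genes):
        mend = (frozenset() if rng.random() < config.frac_no_mendelian
                else _draw_soc_set(rng))
        gwa = (frozenset() if rng.random() < config.frac_no_gwas
               else _draw_soc_set(rng))
        rec = GeneRecord(
            gene_id=f"G{i + 1:0{width}d}",
            mendelian_socs=mend,
            gwas_socs=gwa,
            constrained=bool(rng.random() < 0.3),
            expression_breadth=str(rng.choice(
                EXPRESSION_BREADTHS, p=[0.35, 0.30, 0.25, 0.10])),
        )
        genes[rec.gene_id] = rec
    return genes


def _n_targets(config: SimConfig, rng: np.random.Generator) -> int:
    if isinstance(config.targets_per_drug, int):
        return min(config.targets_per_drug, config.n_genes)
    lo, hi = config.targets_per_drug
    return int(rng.integers(lo, min(hi, config.n_genes) + 1))


def generate(config: SimConfig) -> tuple[GeneCatalog, DrugCatalog]:
    """Draw a (gene catalog, drug catalog) pair; deterministic given the seed.

    The random stream is consumed in a fixed documented order: gene
    annotations first, then per-drug structure (targets, modality, routes,
    indications), then the side-effect draws.
    """
    rng = np.random.default_rng(config.seed)
    genes = _generate_genes(config, rng)
    gene_ids = sorted(genes)

    if config.n_drugs == 0:
        return genes, {}
    if config.n_genes == 0:
        raise ValueError("cannot generate drugs without genes")

    # per-gene phenotype matrices for support lookups
    mend = np.zeros((len(gene_ids), N_SOC), dtype=bool)
    gwa = np.zeros((len(gene_ids), N_SOC), dtype=bool)
    for i, g in enumerate(gene_ids):
        for s in genes[g].mendelian_socs:
            mend[i, SOC_INDEX[s]] = True
        for s in genes[g].gwas_socs:
            gwa[i, SOC_INDEX[s]] = True
    gidx = {g: i for i, g in enumerate(gene_ids)}

    width = max(4, len(str(config.n_drugs)))
    skeletons: list[dict] = []
    for j in range(config.n_drugs):
        if skeletons and rng.random() < config.target_sharing:
            targets = skeletons[int(rng.integers(len(skeletons)))]["targets"]
        else:
            k = _n_targets(config, rng)
            targets = frozenset(rng.choice(gene_ids, size=k, replace=False))
        modality = "biological" if rng.random() < 0.25 else "small_molecule"
        routes = {str(rng.choice(ROUTES, p=[0.55, 0.30, 0.10, 0.05]))}
        if rng.random() < 0.15:
            routes.add(str(rng.choice(ROUTES)))
        pheno_union = [
            SOC_LABELS[s]
            for s in np.flatnonzero(
                np.any([mend[gidx[g]] | gwa[gidx[g]] for g in targets], axis=0))
        ]
        n_ind = 1 if rng.random() < 0.6 else 2
        indications: set[str] = set()
        for _ in range(n_ind):
            if pheno_union and rng.random() < config.confounding:
                indications.add(str(rng.choice(pheno_union)))
            else:
                indications.add(str(rng.choice(SOC_LABELS)))
        skeletons.append({
            "drug_id": f"D{j + 1:0{width}d}",
            "targets": targets,
            "modality": modality,
            "routes": frozenset(routes),
            "indications": frozenset(indications),
        })

    alpha = np.array([config.baseline_logit[s] for s in SOC_LABELS])
    eff = config.covariate_effects
    drugs: DrugCatalog = {}
    for sk in skeletons:
        tidx = [gidx[g] for g in sk["targets"]]
        any_match = mend[tidx].any(axis=0) | gwa[tidx].any(axis=0)
        on_ind = np.zeros(N_SOC, dtype=bool)
        for s in sk["indications"]:
            on_ind[SOC_INDEX[s]] = True
        cov = 0.0
        if sk["modality"] == "biological":
            cov += eff.get("modality_biological", 0.0)
        for r in sk["routes"]:
            cov += eff.get(f"route_{r}", 0.0)
        if any(genes[g].constrained for g in sk["targets"]):
            cov += eff.get("constrained", 0.0)
        for breadth in ("all", "mixed", "enriched"):
            if any(genes[g].expression_breadth == breadth for g in sk["targets"]):
                cov += eff.get(f"expr_{breadth}", 0.0)
        logit = (alpha + config.beta_genetic * any_match
                 + config.beta_indication * on_ind + cov)
        p = 1.0 / (1.0 + np.exp(-logit))
        se_flags = rng.random(N_SOC) < p
        side_effects = frozenset(SOC_LABELS[s] for s in np.flatnonzero(se_flags))
        rec = DrugRecord(drug_id=sk["drug_id"], targets=sk["targets"],
                         modality=sk["modality"], routes=sk["routes"],
                         indications=sk["indications"],
                         side_effects=side_effects)
        drugs[rec.drug_id] = rec
    return genes, drugs


def fixture_small() -> tuple[GeneCatalog, DrugCatalog]:
    """A hand-classifiable 5-gene, 6-drug fixture used across module tests.

    Contains two drugs sharing a target set (d1, d2), a multi-target drug
    with one uninformative target (d3), and a fully uninformative gene (g4).
    """
    genes = {
        g.gene_id: g for g in (
            GeneRecord("g1", frozenset({"Heart", "Blood"}), frozenset(),
                       constrained=True, expression_breadth="enriched"),
            GeneRecord("g2", frozenset(), frozenset({"Heart"}),
                       constrained=False, expression_breadth="all"),
            GeneRecord("g3", frozenset({"Nervous"}),
                       frozenset({"Nervous", "Mental"}),
                       constrained=False, expression_breadth="mixed"),
            GeneRecord("g4", frozenset(), frozenset(),
                       constrained=False, expression_breadth="none_detected"),
            GeneRecord("g5", frozenset({"Skin"}), frozenset({"Immune"}),
                       constrained=True, expression_breadth="mixed"),
        )
    }
    drugs = {
        d.drug_id: d for d in (
            DrugRecord("d1", frozenset({"g1"}), "small_molecule",
                       frozenset({"enteral"}), frozenset({"Heart"}),
                       frozenset({"Heart", "Skin"})),
            DrugRecord("d2", frozenset({"g1"}), "biological",
                       frozenset({"parenteral"}), frozenset({"Vascular"}),
                       frozenset({"Blood"})),
            DrugRecord("d3", frozenset({"g2", "g4"}), "small_molecule",
                       frozenset({"enteral", "topical"}), frozenset({"Nervous"}),
                       frozenset({"Heart"})),
            DrugRecord("d4", frozenset({"g3"}), "small_molecule",
                       frozenset({"enteral"}), frozenset({"Mental"}),
                       frozenset({"Nervous", "Mental"})),
            DrugRecord("d5", frozenset({"g4"}), "biological",
                       frozenset({"parenteral"}), frozenset({"Immune"}),
                       frozenset({"Infection"})),
            DrugRecord("d6", frozenset({"g5", "g1"}), "small_molecule",
                       frozenset({"topical"}), frozenset({"Skin"}),
                       frozenset({"Heart"})),
        )
    }
    return genes, drugs
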