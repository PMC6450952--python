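"""Structured permutation nulls for the enrichment statistic.

Raw enrichment can be inflated by dataset composition (which genes are
informative, which drugs report many side effects). Two structured
randomizations probe this: permuting the assignment of phenotype sets to
genes (keeping the fraction of uninformative genes and the Mendelian/GWAS
co-occurrence intact) and permuting whole side-effect profiles among drugs
(keeping per-drug profile sizes and per-SOC totals intact). Each yields a
Monte-Carlo null distribution for any scalar statistic of the observation
table and an add-one empirical P.
"""

from __future__ import annotations

import logging
from collections.abc import Callable, Iterable
from dataclasses import dataclass, replace

import numpy as np

from .core_data import (
    DrugCatalog,
    GeneCatalog,
    ObservationSet,
    build_observations,
)
from .enrichment import enrichment_analysis

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    null_values: np.ndarray
    empirical_p: float
    n_perm: int
    seed: int

    def __post_init__(self) -> None:
        if not (0 < self.empirical_p <= 1):
            raise ValueError("empirical_p must be in (0, 1]")


def empirical_p_value(observed: float, null_values: Iterable[float]) -> float:
    """Add-one Monte-Carlo P: (#{null >= observed} + 1) / (n + 1).

    Never returns 0; with 999 permutations the floor is 0.001, matching the
    "P < 0.001" reporting convention.
    """
    null = np.asarray(list(null_values), dtype=float)
    r = int(np.sum(null >= observed))
    return (r + 1) / (len(null) + 1)


def permute_gene_phenotypes(
    genes: GeneCatalog,
    source: str = "both",
    rng_seed: int | np.random.Generator = 0,
    within: Iterable[str] | None = None,
) -> GeneCatalog:
    """Reassign phenotype sets to gene ids by a uniform permutation.

    ``source`` selects what travels: "mendelian" or "gwas" permutes that
    source's sets alone; "both" moves each gene's (Mendelian, GWAS) pair as a
    unit, preserving the cross-source co-occurrence structure. Empty sets are
    permuted like any other, so the fraction of uninformative genes is
    preserved exactly. ``within`` optionally restricts the permutation to a
    subset of gene ids (e.g. the genes actually appearing as drug targets).
    """
    if source not in ("mendelian", "gwas", "both"):
        raise ValueError(f"unknown source {source!r}")
    if not genes:
        raise ValueError("empty gene catalog")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    ids = sorted(genes) if within is None else sorted(set(within) & set(genes))
    perm = rng.permutation(len(ids))
    out = dict(genes)
    for i, gid in enumerate(ids):
        donor = genes[ids[perm[i]]]
        rec = out[gid]
        if source in ("mendelian", "both"):
            rec = replace(rec, mendelian_socs=donor.mendelian_socs)
        if source in ("gwas", "both"):
            rec = replace(rec, gwas_socs=donor.gwas_socs)
        out[gid] = rec
    return out


def permute_drug_side_effects(
    drugs: DrugCatalog,
    rng_seed: int | np.random.Generator = 0,
) -> DrugCatalog:
    """Reassign whole side-effect SOC profiles among drugs uniformly.

    Targets, indications, modality and routes are untouched; the multiset of
    side-effect profiles (hence every per-SOC side-effect total) is preserved.
    """
    if not drugs:
        raise ValueError("empty drug catalog")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    ids = sorted(drugs)
    perm = rng.permutation(len(ids))
    return {
        did: replace(drugs[did], side_effects=drugs[ids[perm[i]]].side_effects)
        for i, did in enumerate(ids)
    }


def pooled_or_statistic(observations: ObservationSet) -> float:
    """Default statistic: the pooled any-support enrichment odds ratio."""
    return enrichment_analysis(observations, per_soc=False,
                               support_source="any").odds_ratio


def target_gene_ids(drugs: DrugCatalog) -> set[str]:
    out: set[str] = set()
    for rec in drugs.values():
        out |= rec.targets
    return out


def permutation_test(
    genes: GeneCatalog,
    drugs: DrugCatalog,
    statistic: Callable[[ObservationSet], float] = pooled_or_statistic,
    mode: str = "genetics",
    n_perm: int = 999,
    seed: int = 0,
    observation_mode: str = "all",
) -> PermutationResult:
    """Monte-Carlo permutation test of an observation-table statistic.

    ``mode="genetics"`` permutes gene -> phenotype-set assignment (jointly
    over both sources, within the genes that appear as drug targets);
    ``mode="side_effects"`` permutes drug -> side-effect profiles.
    Observations are rebuilt for every replicate. Replicates on which the
    statistic fails (raises, or returns a non-finite value) are dropped and
    logged; more than 10% failures is an error.
    """
    if mode not in ("genetics", "side_effects"):
        raise ValueError(f"unknown permutation mode {mode!r}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = statistic(build_observations(drugs, genes, mode=observation_mode))
    targets = target_gene_ids(drugs)
    streams = np.random.SeedSequence(seed).spawn(n_perm)
    null_values: list[float] = []
    n_failed = 0
    for ss in streams:
        rng = np.random.default_rng(ss)
        if mode == "genetics":
            g, d = permute_gene_phenotypes(genes, "both", rng, within=targets), drugs
        else:
            g, d = genes, permute_drug_side_effects(drugs, rng)
        try:
            value = statistic(build_observations(d, g, mode=observation_mode))
        except Exception as exc:  # noqa: BLE001 - replicate-level fault barrier
            logger.warning("permutation replicate failed: %s", exc)
            n_failed += 1
            continue
        if not np.isfinite(value):
            logger.warning("permutation replicate produced non-finite statistic")
            n_failed += 1
            continue
        null_values.append(float(value))
    if n_failed > 0.10 * n_perm:
        raise RuntimeError(
            f"{n_failed}/{n_perm} permutation replicates failed")
    null = np.asarray(null_values)
    return PermutationResult(
        observed=float(observed),
        null_values=null,
        empirical_p=empirical_p_value(observed, null),
        n_perm=len(null),
        seed=seed,
    )
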