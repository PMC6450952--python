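"""Report rendering and the end-to-end pipeline driver.

`render_table1` formats per-organ-system enrichment results the way the
published per-SOC table prints them (counts, rates at one decimal percent,
OR at two decimals, Fisher P at three significant figures, plus a Total row
of cell-wise sums). `run_pipeline` strings the stages together — simulate or
load, enrichment (pooled, per-SOC, de-risk), permutation tests, per-SOC
models, and cross-validation — writing TSV/JSON artifacts and a manifest
sufficient to reproduce the run.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .core_data import (
    SOC_LABELS,
    build_observations,
    load_drug_table,
    load_gene_table,
    load_observation_table,
    write_drug_table,
    write_gene_table,
    write_observation_table,
)
from .crossval import genetics_null_cv, loto_cv
from .enrichment import (
    ContingencyTable,
    EnrichmentResult,
    derisk_analysis,
    diagnostic_metrics,
    enrichment_analysis,
    result_from_table,
)
from .permutation import permutation_test
from .regression import eligible_categories, fit_logistic, build_design
from .synthetic import SimConfig, generate

logger = logging.getLogger(__name__)

_TABLE1_HEADER = [
    "phenotype_category", "support_se", "support_no_se", "no_support_se",
    "no_support_no_se", "rate_support", "rate_no_support", "odds_ratio", "p",
]


def _fmt_rate(x: float) -> str:
    return "NA" if math.isnan(x) else f"{100 * x:.1f}%"


def _fmt_or(x: float) -> str:
    return "NA" if math.isnan(x) else f"{x:.2f}"


def render_table1(results: dict[str, EnrichmentResult]) -> str:
    """TSV replica of the per-organ-system enrichment table, plus a Total row."""
    missing = set(SOC_LABELS) - set(results)
    if missing:
        raise ValueError(f"missing categories: {sorted(missing)}")
    lines = ["\t".join(_TABLE1_HEADER)]
    total = ContingencyTable(0, 0, 0, 0)
    for soc in SOC_LABELS:
        r = results[soc]
        t = r.table
        total = total + t
        lines.append("\t".join([
            soc, str(t.a), str(t.b), str(t.c), str(t.d),
            _fmt_rate(r.rate_support), _fmt_rate(r.rate_no_support),
            _fmt_or(r.odds_ratio), f"{r.p_two_tailed:.3g}",
        ]))
    rt = result_from_table(total)
    lines.append("\t".join([
        "Total", str(total.a), str(total.b), str(total.c), str(total.d),
        _fmt_rate(rt.rate_support), _fmt_rate(rt.rate_no_support),
        _fmt_or(rt.odds_ratio), f"{rt.p_two_tailed:.3g}",
    ]))
    return "\n".join(lines) + "\n"


@dataclass
class RunConfig:
    """Pipeline configuration: exactly one input source must be set."""

    gene_table: str | None = None
    drug_table: str | None = None
    flat_table: str | None = None
    simulate: SimConfig | None = None
    mode: str = "all"               # "all" | "off_indication"
    seed: int = 0
    out_dir: str = "results"
    n_perm: int = 199
    run_models: bool = True
    run_crossval: bool = True
    cv_n_perm: int = 0              # 0 disables the permuted-genetics null
    min_count: int = 100

    def __post_init__(self) -> None:
        sources = [self.flat_table is not None,
                   self.gene_table is not None or self.drug_table is not None,
                   self.simulate is not None]
        if sum(sources) != 1:
            raise ValueError("exactly one of flat_table, gene+drug tables, "
                             "or simulate must be specified")
        if (self.gene_table is None) != (self.drug_table is None):
            raise ValueError("gene_table and drug_table must be given together")


def _result_to_dict(r: EnrichmentResult) -> dict:
    return {
        "table": [r.table.a, r.table.b, r.table.c, r.table.d],
        "rate_support": r.rate_support,
        "rate_no_support": r.rate_no_support,
        "odds_ratio": r.odds_ratio,
        "ci_low": r.ci_low, "ci_high": r.ci_high,
        "p_two_tailed": r.p_two_tailed,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write artifacts under ``config.out_dir``.

    Returns the report bundle (also written as JSON). All randomness flows
    from ``config.seed``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": {
        k: (asdict(v) if isinstance(v, SimConfig) else v)
        for k, v in asdict(config).items()
    }, "seed": config.seed}

    genes = drugs = None
    if config.simulate is not None:
        logger.info("stage simulate")
        genes, drugs = generate(config.simulate)
        write_gene_table(genes, out / "genes.tsv")
        write_drug_table(drugs, out / "drugs.tsv")
        obs = build_observations(drugs, genes, mode=config.mode)
    elif config.flat_table is not None:
        logger.info("stage load flat table")
        obs = load_observation_table(config.flat_table, mode=config.mode)
    else:
        logger.info("stage load catalogs")
        genes = load_gene_table(config.gene_table)
        drugs = load_drug_table(config.drug_table, genes)
        obs = build_observations(drugs, genes, mode=config.mode)
    write_observation_table(obs, out / "observations.tsv")

    logger.info("stage enrich")
    pooled = enrichment_analysis(obs, per_soc=False)
    per_soc = enrichment_analysis(obs, per_soc=True)
    (out / "table1.tsv").write_text(render_table1(per_soc))
    bundle["pooled_enrichment"] = _result_to_dict(pooled)
    try:
        bundle["derisk"] = _result_to_dict(derisk_analysis(obs))
    except ValueError as exc:
        bundle["derisk"] = {"error": str(exc)}
    dm = diagnostic_metrics(pooled.table)
    bundle["diagnostics"] = {
        "sensitivity": dm.sensitivity, "specificity": dm.specificity,
        "lr_plus": dm.lr_plus, "ilr_minus": dm.ilr_minus,
    }

    if genes is not None and drugs is not None:
        logger.info("stage permtest")
        for mode in ("genetics", "side_effects"):
            pt = permutation_test(genes, drugs, mode=mode,
                                  n_perm=config.n_perm, seed=config.seed,
                                  observation_mode=config.mode)
            bundle[f"permutation_{mode}"] = {
                "observed": pt.observed,
                "empirical_p": pt.empirical_p,
                "null_mean": float(pt.null_values.mean()),
                "n_perm": pt.n_perm,
            }

        eligible = eligible_categories(drugs, min_count=config.min_count)
        bundle["eligible_categories"] = eligible
        if config.run_models:
            logger.info("stage model (%d categories)", len(eligible))
            model_rows = {}
            for soc in eligible:
                design = build_design(
                    drugs, genes, soc,
                    exclude_on_indication=config.mode == "off_indication")
                fit = fit_logistic(design)
                model_rows[soc] = {
                    term: {
                        "coef": float(fit.params.loc[term, "coef"]),
                        "odds_ratio": float(fit.params.loc[term, "odds_ratio"]),
                        "p": float(fit.params.loc[term, "p"]),
                    }
                    for term in ("mend_match", "mend_mismatch",
                                 "gwas_match", "gwas_mismatch")
                }
            bundle["models"] = model_rows
        if config.run_crossval:
            logger.info("stage crossval")
            cv_rows = {}
            for soc in eligible:
                try:
                    full = loto_cv(drugs, genes, soc, "full")
                    nogen = loto_cv(drugs, genes, soc, "no_genetics")
                except ValueError as exc:
                    cv_rows[soc] = {"error": str(exc)}
                    continue
                row = {"auc_full": full.auc, "auc_no_genetics": nogen.auc,
                       "n_skipped": full.n_skipped}
                if config.cv_n_perm:
                    null = genetics_null_cv(drugs, genes, soc,
                                            n_perm=config.cv_n_perm,
                                            seed=config.seed)
                    row["empirical_p"] = null.empirical_p
                cv_rows[soc] = row
            bundle["crossval"] = cv_rows

    (out / "report.json").write_text(json.dumps(bundle, indent=2, sort_keys=True))
    logger.info("wrote %s", out / "report.json")
    return bundle
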