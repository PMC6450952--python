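#!/usr/bin/env python
"""Enrichment and permutation analysis of the synthetic cohort.

Reads the catalogs written by 01_simulate_cohort.py (or regenerates them),
computes pooled / per-source / off-indication enrichment and the de-risk
split, and runs the two structured permutation tests (genetics and
side-effect profiles). Confounded indications make the all-pairs OR exceed
the generative off-indication effect, mirroring the attenuation seen when
on-indication pairs are excluded.
"""

import argparse
import json
from pathlib import Path

from targetsafe.core_data import (
    build_observations,
    load_drug_table,
    load_gene_table,
)
from targetsafe.enrichment import derisk_analysis, enrichment_analysis
from targetsafe.permutation import permutation_test
from targetsafe.reporting import render_table1
from targetsafe.synthetic import SimConfig, generate


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--n-perm", type=int, default=199)
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    if (args.cohort / "genes.tsv").exists():
        genes = load_gene_table(args.cohort / "genes.tsv")
        drugs = load_drug_table(args.cohort / "drugs.tsv", genes)
        print(f"loaded cohort from {args.cohort}")
    else:
        genes, drugs = generate(SimConfig(seed=args.seed))
        print("cohort files not found; regenerated from seed")

    obs_all = build_observations(drugs, genes, "all")
    obs_off = build_observations(drugs, genes, "off_indication")

    summary = {}
    for label, obs in (("all", obs_all), ("off_indication", obs_off)):
        for source in ("any", "mendelian", "gwas"):
            r = enrichment_analysis(obs, support_source=source)
            summary[f"{label}_{source}_or"] = round(r.odds_ratio, 3)
        summary[f"{label}_n_pairs"] = len(obs)
    derisk = derisk_analysis(obs_all)
    summary["derisk_or"] = round(derisk.odds_ratio, 3)
    summary["derisk_p"] = derisk.p_two_tailed

    per_soc = enrichment_analysis(obs_all, per_soc=True)
    (args.out / "synthetic_table1.tsv").write_text(render_table1(per_soc))

    for mode in ("genetics", "side_effects"):
        pt = permutation_test(genes, drugs, mode=mode, n_perm=args.n_perm,
                              seed=args.seed)
        summary[f"perm_{mode}_observed_or"] = round(pt.observed, 3)
        summary[f"perm_{mode}_null_mean_or"] = round(
            float(pt.null_values.mean()), 3)
        summary[f"perm_{mode}_empirical_p"] = pt.empirical_p

    (args.out / "synthetic_enrichment.json").write_text(
        json.dumps(summary, indent=2))

    print(f"pooled any-source OR: all {summary['all_any_or']} "
          f"({summary['all_n_pairs']} pairs) vs off-indication "
          f"{summary['off_indication_any_or']} "
          f"({summary['off_indication_n_pairs']} pairs)")
    print(f"de-risk split OR {summary['derisk_or']} "
          f"(P {summary['derisk_p']:.3g}) — fully-annotated-but-mismatched "
          f"target sets carry lower side-effect risk")
    for mode in ("genetics", "side_effects"):
        print(f"permuted {mode}: null mean OR "
              f"{summary[f'perm_{mode}_null_mean_or']}, observed "
              f"{summary[f'perm_{mode}_observed_or']}, empirical P "
              f"{summary[f'perm_{mode}_empirical_p']:.3g}")


if __name__ == "__main__":
    main()
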