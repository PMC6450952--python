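#!/usr/bin/env python
"""Recompute the published per-organ enrichment table from its counts.

Feeds the bundled per-SOC 2x2 contingency counts through the package's
odds-ratio and Fisher machinery, writes a formatted replica of the
published table, and summarizes the pooled association, diagnostic metrics,
and the >=100-drug model-eligibility rule.
"""

import argparse
import json
from pathlib import Path

from targetsafe.enrichment import (
    ContingencyTable,
    result_from_table,
    diagnostic_metrics,
)
from targetsafe.reference_data import (
    PUBLISHED_SOC_COUNTS,
    PUBLISHED_TOTAL_COUNTS,
)
from targetsafe.regression import eligible_categories_from_counts
from targetsafe.reporting import render_table1


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    results = {soc: result_from_table(ContingencyTable(*cells))
               for soc, cells in PUBLISHED_SOC_COUNTS.items()}
    (args.out / "table1_replica.tsv").write_text(render_table1(results))

    total = ContingencyTable(*PUBLISHED_TOTAL_COUNTS)
    pooled = result_from_table(total)
    m = diagnostic_metrics(total)
    se_counts = {s: c[0] + c[2] for s, c in PUBLISHED_SOC_COUNTS.items()}
    eligible = eligible_categories_from_counts(se_counts)
    summary = {
        "pooled_odds_ratio": round(pooled.odds_ratio, 2),
        "pooled_ci": [round(pooled.ci_low, 2), round(pooled.ci_high, 2)],
        "pooled_fisher_p": pooled.p_two_tailed,
        "rate_with_support_pct": round(100 * pooled.rate_support, 1),
        "rate_without_support_pct": round(100 * pooled.rate_no_support, 1),
        "sensitivity_pct": round(100 * m.sensitivity, 1),
        "specificity_pct": round(100 * m.specificity, 1),
        "lr_plus": round(m.lr_plus, 2),
        "ilr_minus": round(m.ilr_minus, 2),
        "eligible_categories": eligible,
    }
    (args.out / "published_summary.json").write_text(
        json.dumps(summary, indent=2))

    print(f"wrote {args.out / 'table1_replica.tsv'}")
    print(f"pooled: OR {summary['pooled_odds_ratio']} "
          f"(95% CI {summary['pooled_ci'][0]}-{summary['pooled_ci'][1]}), "
          f"rates {summary['rate_with_support_pct']}% vs "
          f"{summary['rate_without_support_pct']}%")
    print(f"genetic support as a screen: sensitivity "
          f"{summary['sensitivity_pct']}%, specificity "
          f"{summary['specificity_pct']}%, LR+ {summary['lr_plus']}, "
          f"iLR- {summary['ilr_minus']}")
    print(f"{len(eligible)}/21 organ systems eligible for modeling "
          f"(excluded: {sorted(set(se_counts) - set(eligible))})")


if __name__ == "__main__":
    main()
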