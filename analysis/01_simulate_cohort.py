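#!/usr/bin/env python
"""Draw the default synthetic cohort and write its catalogs.

Generates 1819 drugs over 1046 target genes with study-like structure
(shared target sets, indication-genetics confounding, published per-organ
baseline side-effect rates) and writes the gene/drug catalogs, the flattened
drug x SOC observation table, and a config sidecar under results/.
"""

import argparse
import json
from dataclasses import asdict
from pathlib import Path

from targetsafe.core_data import (
    build_observations,
    write_drug_table,
    write_gene_table,
    write_observation_table,
)
from targetsafe.synthetic import SimConfig, generate


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/cohort"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    config = SimConfig(seed=args.seed)
    genes, drugs = generate(config)
    obs = build_observations(drugs, genes)

    write_gene_table(genes, args.out / "genes.tsv")
    write_drug_table(drugs, args.out / "drugs.tsv")
    write_observation_table(obs, args.out / "observations.tsv")
    (args.out / "config.json").write_text(
        json.dumps(asdict(config), indent=2, default=str))

    n_informative = sum(1 for g in genes.values() if g.informative)
    n_supported_drugs = len(set(
        obs.df.loc[obs.df.any_support, "drug_id"]))
    print(f"wrote {len(drugs)} drugs x 21 organ systems "
          f"= {len(obs)} observations to {args.out}")
    print(f"{n_informative}/{len(genes)} genes informative; "
          f"{n_supported_drugs}/{len(drugs)} drugs with >=1 supported pair")


if __name__ == "__main__":
    main()
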