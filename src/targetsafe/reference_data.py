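"""Published per-organ-system contingency counts.

The 2019 retrospective study of 1819 drugs underlying this package printed,
for each of the 21 organ-system categories, the 2x2 classification of drugs
by (targets have a genetic phenotype in the organ system) x (a clinical-trial
side effect was recorded in that organ system), together with the resulting
side-effect rates, odds ratios and Fisher P values. Those printed counts are
bundled here as reference inputs: they let the enrichment statistics, the
diagnostic-metric summary, and the model-eligibility rule be recomputed and
checked against the published figures without access to the underlying
commercial databases.

Counts are (a, b, c, d) = (support & SE, support & no SE, no support & SE,
no support & no SE); a + b + c + d = 1819 in every row.
"""

from __future__ import annotations

import pandas as pd

from .core_data import SOC_LABELS

#: Per-SOC (a, b, c, d) drug counts, keyed in fixed vocabulary order.
PUBLISHED_SOC_COUNTS: dict[str, tuple[int, int, int, int]] = {
    "Blood": (96, 269, 234, 1220),
    "Heart": (145, 176, 451, 1047),
    "Congenital": (17, 572, 22, 1208),
    "Ear": (5, 112, 74, 1628),
    "Endocrine": (97, 252, 177, 1293),
    "Eye": (56, 256, 193, 1314),
    "Gastrointestinal": (155, 276, 497, 891),
    "Hepatobiliary": (20, 153, 160, 1486),
    "Immune": (113, 335, 251, 1120),
    "Infection": (64, 104, 536, 1115),
    "Metabolism": (228, 400, 280, 911),
    "Musculoskeletal": (217, 435, 322, 845),
    "Neoplasm": (48, 305, 122, 1344),
    "Nervous": (343, 421, 401, 654),
    "Pregnancy": (7, 268, 35, 1509),
    "Mental": (208, 350, 255, 1006),
    "Urologic": (75, 245, 220, 1279),
    "Reproductive": (75, 199, 186, 1359),
    "Respiratory": (140, 211, 464, 1004),
    "Skin": (122, 224, 413, 1060),
    "Vascular": (281, 299, 436, 803),
}

#: Published odds ratios (2 decimals) per SOC, for cross-checking.
PUBLISHED_SOC_OR: dict[str, float] = {
    "Blood": 1.86, "Heart": 1.91, "Congenital": 1.63, "Ear": 0.98,
    "Endocrine": 2.81, "Eye": 1.49, "Gastrointestinal": 1.01,
    "Hepatobiliary": 1.21, "Immune": 1.51, "Infection": 1.28,
    "Metabolism": 1.85, "Musculoskeletal": 1.31, "Neoplasm": 1.73,
    "Nervous": 1.33, "Pregnancy": 1.13, "Mental": 2.34, "Urologic": 1.78,
    "Reproductive": 2.75, "Respiratory": 1.44, "Skin": 1.40, "Vascular": 1.73,
}

#: Published two-tailed Fisher P values, as printed (strings preserve precision).
PUBLISHED_SOC_P: dict[str, str] = {
    "Blood": "1.34E-05", "Heart": "3.92E-07", "Congenital": "0.165",
    "Ear": "1.00", "Endocrine": "3.71E-12", "Eye": "0.0186",
    "Gastrointestinal": "0.954", "Hepatobiliary": "0.423",
    "Immune": "1.76E-03", "Infection": "0.144", "Metabolism": "1.34E-08",
    "Musculoskeletal": "0.0118", "Neoplasm": "3.10E-03", "Nervous": "3.73E-03",
    "Pregnancy": "0.827", "Mental": "5.16E-14", "Urologic": "2.20E-04",
    "Reproductive": "5.75E-10", "Respiratory": "3.68E-03", "Skin": "8.75E-03",
    "Vascular": "8.31E-08",
}

#: Column-wise total of the 21 rows (all drug x SOC pairs pooled).
PUBLISHED_TOTAL_COUNTS: tuple[int, int, int, int] = (2512, 5862, 5729, 24096)

#: Baseline (no-genetic-support) side-effect rate per SOC, c / (c + d).
PUBLISHED_BASELINE_RATES: dict[str, float] = {
    soc: c / (c + d) for soc, (a, b, c, d) in PUBLISHED_SOC_COUNTS.items()
}


def published_counts_frame() -> pd.DataFrame:
    """The per-SOC counts as a DataFrame indexed by SOC in vocabulary order."""
    df = pd.DataFrame.from_dict(PUBLISHED_SOC_COUNTS, orient="index",
                                columns=["a", "b", "c", "d"])
    return df.loc[list(SOC_LABELS)]
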