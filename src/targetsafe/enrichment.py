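"""Enrichment statistics for genetic support vs observed side effects.

Every statistic here reduces to a 2x2 contingency table over drug x SOC
observations: rows are genetic support (exposed / unexposed under some
predicate), columns are side-effect status. The table feeds

* the raw odds ratio with a Woolf (log-scale normal) confidence interval,
* Fisher's exact test (two-tailed by the probability-mass convention, or
  one-tailed for directional arm comparisons), and
* screening-style diagnostic metrics (sensitivity, specificity, LR+, iLR-).
"""

from __future__ import annotations

import math
from collections.abc import Callable
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import SOC_LABELS, ObservationSet, Support

Z_95 = 1.959964


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: (a, b) exposed with/without side effect, (c, d) unexposed."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"cell {name} must be a nonnegative integer")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])

    def __add__(self, other: "ContingencyTable") -> "ContingencyTable":
        return ContingencyTable(self.a + other.a, self.b + other.b,
                                self.c + other.c, self.d + other.d)


@dataclass(frozen=True)
class EnrichmentResult:
    table: ContingencyTable
    rate_support: float
    rate_no_support: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_two_tailed: float


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Genetic support viewed as a screening test for the side effect."""

    sensitivity: float
    specificity: float
    lr_plus: float
    ilr_minus: float


def fisher_exact_two_tailed(table: ContingencyTable) -> float:
    """Two-tailed Fisher exact P (probability-mass convention).

    Sums, over all tables with the observed margins, the hypergeometric
    probabilities of outcomes whose point probability does not exceed the
    observed one (within a small relative tolerance). Degenerate margins
    give P = 1.
    """
    if min(table.a + table.b, table.c + table.d,
           table.a + table.c, table.b + table.d) == 0:
        return 1.0
    return float(stats.fisher_exact(table.as_array(), alternative="two-sided")[1])


def fisher_exact_one_tailed_greater(table: ContingencyTable) -> float:
    """P(A >= a) under the hypergeometric null with the observed margins."""
    if min(table.a + table.b, table.c + table.d,
           table.a + table.c, table.b + table.d) == 0:
        return 1.0
    return float(stats.fisher_exact(table.as_array(), alternative="greater")[1])


def odds_ratio_ci(table: ContingencyTable,
                  z: float = Z_95,
                  haldane: bool = False) -> tuple[float, float, float]:
    """Sample odds ratio (a*d)/(b*c) with a Woolf log-scale CI.

    With a zero cell the raw OR is 0 or +inf and the CI is undefined (NaN);
    ``haldane=True`` instead adds 0.5 to every cell for CI display only
    (the point estimate stays raw).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if b * c == 0 and a * d == 0:
        return math.nan, math.nan, math.nan
    if b * c == 0:
        or_ = math.inf
    elif a * d == 0:
        or_ = 0.0
    else:
        or_ = (a * d) / (b * c)
    if min(a, b, c, d) == 0:
        if not haldane:
            return or_, math.nan, math.nan
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log((a * d) / (b * c))
    return or_, math.exp(log_or - z * se), math.exp(log_or + z * se)


def result_from_table(table: ContingencyTable) -> EnrichmentResult:
    or_, lo, hi = odds_ratio_ci(table)
    rate_s = table.a / (table.a + table.b) if table.a + table.b else math.nan
    rate_n = table.c / (table.c + table.d) if table.c + table.d else math.nan
    return EnrichmentResult(
        table=table, rate_support=rate_s, rate_no_support=rate_n,
        odds_ratio=or_, ci_low=lo, ci_high=hi,
        p_two_tailed=fisher_exact_two_tailed(table),
    )


def tabulate(observations: ObservationSet,
             support: Callable[[pd.DataFrame], pd.Series] | pd.Series,
             soc_filter: str | None = None) -> ContingencyTable:
    """Count observations into a 2x2 table by (support predicate, side effect).

    ``support`` is either a boolean Series aligned to ``observations.df`` or a
    callable producing one from the frame.
    """
    df = observations.df
    exposed = support(df) if callable(support) else support
    exposed = np.asarray(exposed, dtype=bool)
    se = df["side_effect"].to_numpy(dtype=bool)
    if soc_filter is not None:
        keep = (df["soc"] == soc_filter).to_numpy()
        exposed, se = exposed[keep], se[keep]
    a = int((exposed & se).sum())
    b = int((exposed & ~se).sum())
    c = int((~exposed & se).sum())
    d = int((~exposed & ~se).sum())
    return ContingencyTable(a, b, c, d)


SUPPORT_PREDICATES: dict[str, Callable[[pd.DataFrame], pd.Series]] = {
    "any": lambda df: df["any_support"],
    "mendelian": lambda df: df["mendelian"] == Support.MATCH.value,
    "gwas": lambda df: df["gwas"] == Support.MATCH.value,
}


def enrichment_analysis(
    observations: ObservationSet,
    per_soc: bool = False,
    support_source: str = "any",
) -> EnrichmentResult | dict[str, EnrichmentResult]:
    """Pooled (or per organ system) side-effect enrichment by genetic support."""
    if support_source not in SUPPORT_PREDICATES:
        raise ValueError(f"unknown support source {support_source!r}")
    if len(observations) == 0 and not per_soc:
        raise ValueError("empty observation set")
    pred = SUPPORT_PREDICATES[support_source]
    if not per_soc:
        return result_from_table(tabulate(observations, pred))
    return {
        soc: result_from_table(tabulate(observations, pred, soc_filter=soc))
        for soc in SOC_LABELS
    }


def derisk_analysis(observations: ObservationSet) -> EnrichmentResult:
    """Among unsupported pairs, does full target information lower SE risk?

    Restricts to observations with no genetic support and compares side-effect
    rates between pairs where every target gene is informative (phenotypes
    exist, but none match the organ system — an explicit genetic "all clear")
    and pairs with at least one uninformative target (absence of evidence).
    OR < 1 means the explicit mismatch de-risks the organ system.
    """
    df = observations.df
    unsupported = df.loc[~df["any_support"]]
    exposed = unsupported["all_targets_informative"].to_numpy(dtype=bool)
    if not exposed.any():
        raise ValueError("empty stratum: no fully-informative unsupported pairs")
    if exposed.all():
        raise ValueError("empty stratum: no partly-uninformative unsupported pairs")
    sub = ObservationSet(df=unsupported.reset_index(drop=True),
                         mode=observations.mode)
    return result_from_table(
        tabulate(sub, sub.df["all_targets_informative"].astype(bool)))


def diagnostic_metrics(table: ContingencyTable) -> DiagnosticMetrics:
    """Sensitivity/specificity/likelihood ratios of support as a SE predictor."""
    if table.a + table.c == 0 or table.b + table.d == 0:
        raise ValueError("diagnostic metrics need both outcome margins nonzero")
    sens = table.a / (table.a + table.c)
    spec = table.d / (table.b + table.d)
    lr_plus = sens / (1 - spec) if spec < 1 else math.inf
    ilr_minus = spec / (1 - sens) if sens < 1 else math.inf
    return DiagnosticMetrics(sens, spec, lr_plus, ilr_minus)


def arm_association_filter(
    treatment: tuple[int, int],
    placebo: tuple[int, int],
    alpha: float = 0.05,
) -> tuple[bool, float]:
    """Keep an adverse event iff it is significantly more common on treatment.

    ``treatment`` and ``placebo`` are (events, arm size). The one-tailed
    Fisher test asks whether the event is enriched in the treatment arm; the
    event is kept when P < alpha and the treatment rate exceeds placebo.
    """
    (et, nt), (ep, np_) = treatment, placebo
    if nt == 0 or np_ == 0:
        raise ValueError("empty trial arm")
    if not (0 <= et <= nt and 0 <= ep <= np_):
        raise ValueError("events exceed arm size")
    table = ContingencyTable(et, nt - et, ep, np_ - ep)
    p = fisher_exact_one_tailed_greater(table)
    keep = p < alpha and (et / nt) > (ep / np_)
    return keep, p
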