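"""Leave-one-target-set-out cross-validation with leakage exclusion.

Drugs sharing target genes share genetic information, so ordinary CV leaks:
a held-out drug's genetics can be learned from a training drug with the same
target. Here each unique target set forms one fold; its test set is every
drug with exactly that target set and its training set excludes any drug
sharing *any* gene with it. Pooled out-of-fold predictions give a single
ROC AUC. The contribution of genetics is read off by comparing the full
model's AUC against (a) the same model without genetics columns and (b) a
null AUC distribution from refitting under permuted gene-phenotype
assignments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .core_data import DrugCatalog, GeneCatalog
from .permutation import (
    PermutationResult,
    empirical_p_value,
    permute_gene_phenotypes,
    target_gene_ids,
)
from .regression import GENETICS_COLUMNS, build_design, fit_predict_logistic

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVFold:
    target_set: frozenset[str]
    test_drugs: frozenset[str]
    train_drugs: frozenset[str]
    skipped: bool = False
    reason: str = ""


@dataclass
class CVResult:
    predictions: pd.DataFrame  # drug_id, score, label
    auc: float
    folds: list[CVFold]
    n_skipped: int
    variant: str


def target_set_partition(drugs: DrugCatalog) -> list[CVFold]:
    """One fold per unique target set, with the sharing-exclusion rule.

    Training drugs are exactly those sharing no gene with the fold's target
    set. Folds whose training set is empty are marked skipped (single-class
    training responses are only detectable later, per organ system).
    """
    if not drugs:
        raise ValueError("empty drug catalog")
    by_set: dict[frozenset[str], set[str]] = {}
    for did, rec in drugs.items():
        by_set.setdefault(rec.targets, set()).add(did)
    folds = []
    for tset in sorted(by_set, key=sorted):
        test = frozenset(by_set[tset])
        train = frozenset(
            did for did, rec in drugs.items() if not (rec.targets & tset))
        skipped = len(train) == 0
        folds.append(CVFold(
            target_set=tset, test_drugs=test, train_drugs=train,
            skipped=skipped, reason="empty training set" if skipped else ""))
    return folds


def _assert_no_leakage(fold: CVFold, drugs: DrugCatalog) -> None:
    train_targets: set[str] = set()
    for did in fold.train_drugs:
        train_targets |= drugs[did].targets
    leaked = fold.target_set & train_targets
    if leaked:
        raise AssertionError(
            f"genetic leakage: fold {sorted(fold.target_set)} shares "
            f"{sorted(leaked)} with its training set")


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC (ties counted 1/2) of ``scores`` against binary labels."""
    labels = np.asarray(labels)
    if labels.min() == labels.max():
        raise ValueError("AUC undefined: single-class labels")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def loto_cv(
    drugs: DrugCatalog,
    genes: GeneCatalog,
    soc: str,
    variant: str = "full",
    exclude_on_indication: bool = True,
    folds: list[CVFold] | None = None,
) -> CVResult:
    """Leave-one-target-set-out CV of the per-SOC logistic model.

    ``variant="no_genetics"`` drops the four genetic-support indicator
    columns before fitting. The fold partition depends only on target sets,
    so a precomputed one may be passed (e.g. to hold it fixed across
    permutation replicates).
    """
    if variant not in ("full", "no_genetics"):
        raise ValueError(f"unknown variant {variant!r}")
    design = build_design(drugs, genes, soc,
                          exclude_on_indication=exclude_on_indication)
    if variant == "no_genetics":
        design = design.drop_columns(GENETICS_COLUMNS)
    X = design.predictors.to_numpy(dtype=float)
    y = design.response
    row_of = {did: i for i, did in enumerate(design.drug_ids)}
    # warm start every per-fold Newton fit from the full-data solution
    from .regression import _irls
    warm = _irls(np.hstack([np.ones((len(X), 1)), X]), y,
                 np.zeros(X.shape[1] + 1))

    if folds is None:
        folds = target_set_partition(drugs)
    out_folds: list[CVFold] = []
    ids: list[str] = []
    scores: list[float] = []
    labels: list[int] = []
    n_skipped = 0
    for fold in folds:
        if fold.skipped:
            out_folds.append(fold)
            n_skipped += 1
            continue
        test_rows = [row_of[d] for d in sorted(fold.test_drugs) if d in row_of]
        train_rows = [row_of[d] for d in sorted(fold.train_drugs) if d in row_of]
        if not test_rows:
            # every drug with this target set is on-indication-excluded
            out_folds.append(fold)
            continue
        ytr = y[train_rows]
        if len(train_rows) == 0 or ytr.min() == ytr.max():
            fold = CVFold(fold.target_set, fold.test_drugs, fold.train_drugs,
                          skipped=True, reason="single-class training response")
            out_folds.append(fold)
            n_skipped += 1
            continue
        _assert_no_leakage(fold, drugs)
        preds = fit_predict_logistic(X[train_rows], ytr, X[test_rows],
                                     warm_start=warm)
        for r, p in zip(test_rows, preds):
            ids.append(design.drug_ids[r])
            scores.append(float(p))
            labels.append(int(y[r]))
        out_folds.append(fold)
    if not ids:
        raise ValueError("all folds skipped; no out-of-fold predictions")
    predictions = pd.DataFrame({"drug_id": ids, "score": scores,
                                "label": labels})
    return CVResult(predictions=predictions,
                    auc=roc_auc(predictions["score"], predictions["label"]),
                    folds=out_folds, n_skipped=n_skipped, variant=variant)


def genetics_null_cv(
    drugs: DrugCatalog,
    genes: GeneCatalog,
    soc: str,
    n_perm: int = 1000,
    seed: int = 0,
    exclude_on_indication: bool = True,
) -> PermutationResult:
    """Permutation null for the CV AUC of the full model.

    Each replicate permutes the gene -> phenotype-set assignment (jointly
    over both sources, within the drug-target genes), reruns the full CV on
    the fixed fold partition, and records its AUC; the empirical P is the
    add-one tail frequency of null AUCs at or above the observed one.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    folds = target_set_partition(drugs)
    observed = loto_cv(drugs, genes, soc, "full",
                       exclude_on_indication=exclude_on_indication,
                       folds=folds).auc
    targets = target_gene_ids(drugs)
    null_values: list[float] = []
    n_failed = 0
    for ss in np.random.SeedSequence(seed).spawn(n_perm):
        permuted = permute_gene_phenotypes(
            genes, "both", np.random.default_rng(ss), within=targets)
        try:
            null_values.append(
                loto_cv(drugs, permuted, soc, "full",
                        exclude_on_indication=exclude_on_indication,
                        folds=folds).auc)
        except Exception as exc:  # noqa: BLE001 - replicate-level fault barrier
            logger.warning("null CV replicate failed: %s", exc)
            n_failed += 1
    if n_failed > 0.10 * n_perm:
        raise RuntimeError(f"{n_failed}/{n_perm} null CV replicates failed")
    null = np.asarray(null_values)
    return PermutationResult(
        observed=float(observed), null_values=null,
        empirical_p=empirical_p_value(observed, null),
        n_perm=len(null), seed=seed)
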