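"""Per-organ-system logistic side-effect models.

For a chosen organ system the response is whether each drug elicited a side
effect there; predictors are the drug's indications (20 indicators, Neoplasm
excluded), modality, delivery routes, target expression breadth, target
constraint, and the three-level genetic support per evidence source
(MATCH / MISMATCH indicators, NO_INFO baseline). Two fits are provided: the
full maximum-likelihood logistic model (Wald inference) and an L1-penalized
(lasso) fit with a glmnet-style repeated-cross-validation penalty selection:
lambda* = (mean lambda.min + mean lambda.1se) / 2 over repeated 10-fold
AUC curves.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .core_data import (
    ROUTES,
    SOC_LABELS,
    DrugCatalog,
    GeneCatalog,
    Support,
    derive_genetic_support,
)
from .enrichment import Z_95

logger = logging.getLogger(__name__)

#: Indication indicator columns: every SOC except Neoplasm (oncology trials
#: were excluded upstream, so a Neoplasm indication carries no information).
INDICATION_SOCS: tuple[str, ...] = tuple(s for s in SOC_LABELS if s != "Neoplasm")

GENETICS_COLUMNS = ("mend_match", "mend_mismatch", "gwas_match", "gwas_mismatch")
EXPRESSION_COLUMNS = ("expr_all", "expr_mixed", "expr_enriched")


@dataclass
class DesignMatrix:
    """Response vector and named predictor matrix for one organ-system model."""

    response: np.ndarray
    predictors: pd.DataFrame
    soc: str | None = None
    off_indication: bool = False
    drug_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.response) != len(self.predictors):
            raise ValueError("response and predictor lengths differ")
        if self.predictors.columns.duplicated().any():
            raise ValueError("duplicate predictor column names")

    def drop_columns(self, columns) -> "DesignMatrix":
        keep = [c for c in self.predictors.columns if c not in set(columns)]
        return DesignMatrix(self.response, self.predictors[keep], self.soc,
                            self.off_indication, self.drug_ids)


@dataclass
class ModelFit:
    """Per-predictor estimates; ``params`` is indexed by predictor name."""

    params: pd.DataFrame   # columns: coef, se, p, odds_ratio, ci_low, ci_high, selected
    intercept: float
    converged: bool
    lam: float | None = None

    def predict(self, predictors: pd.DataFrame) -> np.ndarray:
        beta = self.params["coef"].reindex(predictors.columns).to_numpy()
        return expit(self.intercept + predictors.to_numpy(dtype=float) @ beta)


def eligible_categories(drugs: DrugCatalog, min_count: int = 100) -> list[str]:
    """Organ systems with at least ``min_count`` drugs eliciting a side effect."""
    counts = {soc: 0 for soc in SOC_LABELS}
    for rec in drugs.values():
        for soc in rec.side_effects:
            counts[soc] += 1
    return [soc for soc in SOC_LABELS if counts[soc] >= min_count]


def eligible_categories_from_counts(se_counts: Mapping[str, int],
                                    min_count: int = 100) -> list[str]:
    """Same rule applied to precomputed per-SOC side-effect drug counts."""
    return [soc for soc in SOC_LABELS if se_counts.get(soc, 0) >= min_count]


def build_design(
    drugs: DrugCatalog,
    genes: GeneCatalog,
    soc: str,
    exclude_on_indication: bool = False,
    expression_matrix: pd.DataFrame | None = None,
) -> DesignMatrix:
    """One row per drug predicting a side effect in ``soc``.

    ``exclude_on_indication`` drops drugs indicated in the modeled organ
    system. ``expression_matrix`` (gene x tissue, log2 TPM) switches the
    expression encoding from breadth indicators to per-tissue means over the
    drug's targets.
    """
    if soc not in SOC_LABELS:
        raise ValueError(f"unknown SOC label {soc!r}")
    rows = []
    response = []
    ids = []
    for did in sorted(drugs):
        rec = drugs[did]
        if exclude_on_indication and soc in rec.indications:
            continue
        row: dict[str, float] = {}
        for s in INDICATION_SOCS:
            row[f"ind_{s}"] = float(s in rec.indications)
        row["modality_biological"] = float(rec.modality == "biological")
        for r in ROUTES:
            row[f"route_{r}"] = float(r in rec.routes)
        if expression_matrix is None:
            for breadth in ("all", "mixed", "enriched"):
                row[f"expr_{breadth}"] = float(any(
                    genes[g].expression_breadth == breadth for g in rec.targets))
        else:
            vals = expression_matrix.loc[sorted(rec.targets)]
            for tissue, v in vals.mean(axis=0).items():
                row[f"tissue_{tissue}"] = float(v)
        row["constrained"] = float(any(
            genes[g].constrained for g in rec.targets))
        mend = derive_genetic_support(rec, genes, soc, "mendelian")
        gwa = derive_genetic_support(rec, genes, soc, "gwas")
        row["mend_match"] = float(mend is Support.MATCH)
        row["mend_mismatch"] = float(mend is Support.MISMATCH)
        row["gwas_match"] = float(gwa is Support.MATCH)
        row["gwas_mismatch"] = float(gwa is Support.MISMATCH)
        rows.append(row)
        response.append(float(soc in rec.side_effects))
        ids.append(did)
    if not rows:
        raise ValueError(f"no drugs left for SOC {soc!r} "
                         f"(exclude_on_indication={exclude_on_indication})")
    y = np.asarray(response)
    if y.min() == y.max():
        raise ValueError(f"constant response for SOC {soc!r}: "
                         f"{int(y.sum())}/{len(y)} positive")
    X = pd.DataFrame(rows, index=ids)
    return DesignMatrix(response=y, predictors=X, soc=soc,
                        off_indication=exclude_on_indication, drug_ids=ids)


def build_pooled_design(drugs: DrugCatalog, genes: GeneCatalog,
                        mode: str = "all") -> DesignMatrix:
    """Observation-level design over all drug x SOC pairs.

    Mirrors the generative structure of the synthetic cohort: per-SOC
    intercept offsets (dummies against the first vocabulary SOC), an
    on-indication indicator, the genetic-support indicators, and the shared
    drug/target covariates. Useful for pooled effect estimation, e.g.
    recovering a single genetic log-OR across organ systems.
    """
    from .core_data import build_observations

    obs = build_observations(drugs, genes, mode=mode).df
    X = pd.DataFrame(index=obs.index)
    for s in SOC_LABELS[1:]:
        X[f"soc_{s}"] = (obs["soc"] == s).astype(float)
    X["on_indication"] = obs["on_indication"].astype(float)
    X["mend_match"] = (obs["mendelian"] == Support.MATCH.value).astype(float)
    X["mend_mismatch"] = (obs["mendelian"] == Support.MISMATCH.value).astype(float)
    X["gwas_match"] = (obs["gwas"] == Support.MATCH.value).astype(float)
    X["gwas_mismatch"] = (obs["gwas"] == Support.MISMATCH.value).astype(float)
    cov = {}
    for did in sorted(drugs):
        rec = drugs[did]
        row = {"modality_biological": float(rec.modality == "biological"),
               "constrained": float(any(genes[g].constrained
                                        for g in rec.targets))}
        for r in ROUTES:
            row[f"route_{r}"] = float(r in rec.routes)
        for breadth in ("all", "mixed", "enriched"):
            row[f"expr_{breadth}"] = float(any(
                genes[g].expression_breadth == breadth for g in rec.targets))
        cov[did] = row
    cov_df = pd.DataFrame.from_dict(cov, orient="index")
    X = pd.concat([X, cov_df.loc[obs["drug_id"]].set_index(obs.index)], axis=1)
    y = obs["side_effect"].to_numpy(dtype=float)
    return DesignMatrix(response=y, predictors=X, soc=None,
                        off_indication=mode == "off_indication",
                        drug_ids=list(obs["drug_id"]))


def fit_logistic(design: DesignMatrix) -> ModelFit:
    """Unpenalized maximum-likelihood logistic fit with Wald inference."""
    y = design.response
    if y.min() == y.max():
        raise ValueError("response is constant")
    X = design.predictors
    if len(X) <= X.shape[1]:
        warnings.warn("fewer rows than predictors; estimates may be unstable",
                      stacklevel=2)
    Xc = sm.add_constant(X.astype(float), has_constant="add")
    model = sm.GLM(y, Xc, family=sm.families.Binomial())
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = model.fit(maxiter=200)
        except Exception:
            # fall back to a gradient optimizer that tolerates separation
            res = sm.Logit(y, Xc).fit(method="lbfgs", maxiter=500, disp=False)
            converged = False
    if any("separat" in str(w.message).lower() for w in caught):
        warnings.warn("possible perfect separation; coefficients unreliable",
                      stacklevel=2)
        converged = False
    converged = converged and bool(getattr(res, "converged", True))
    coefs = res.params
    ses = res.bse
    pvals = res.pvalues
    names = [c for c in Xc.columns if c != "const"]
    params = pd.DataFrame({
        "coef": coefs.reindex(names),
        "se": ses.reindex(names),
        "p": pvals.reindex(names),
    })
    params["odds_ratio"] = np.exp(params["coef"])
    params["ci_low"] = np.exp(params["coef"] - Z_95 * params["se"])
    params["ci_high"] = np.exp(params["coef"] + Z_95 * params["se"])
    params["selected"] = True
    return ModelFit(params=params, intercept=float(coefs["const"]),
                    converged=converged)


def fit_lasso(design: DesignMatrix, lam: float, tol: float = 1e-8,
              max_iter: int = 100_000) -> ModelFit:
    """L1-penalized logistic fit at penalty ``lam`` (intercept unpenalized).

    Objective (glmnet convention): mean negative log-likelihood plus
    ``lam * ||beta||_1``; predictors are used unstandardized (all-indicator
    designs share a scale).
    """
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    if lam == 0:
        fit = fit_logistic(design)
        fit.lam = 0.0
        return fit
    y = design.response
    if y.min() == y.max():
        raise ValueError("response is constant")
    X = design.predictors.to_numpy(dtype=float)
    n = len(y)
    clf = LogisticRegression(l1_ratio=1.0, C=1.0 / (n * lam), solver="saga",
                             tol=tol, max_iter=max_iter, fit_intercept=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, y)
    coef = clf.coef_.ravel()
    params = pd.DataFrame({
        "coef": coef,
        "se": np.nan,
        "p": np.nan,
        "odds_ratio": np.exp(coef),
        "ci_low": np.nan,
        "ci_high": np.nan,
        "selected": np.abs(coef) > 1e-10,
    }, index=list(design.predictors.columns))
    return ModelFit(params=params, intercept=float(clf.intercept_[0]),
                    converged=True, lam=lam)


def lambda_grid(design: DesignMatrix, n_lambda: int = 100,
                min_ratio: float = 1e-4) -> np.ndarray:
    """Descending log-spaced grid from the smallest all-zero penalty."""
    X = design.predictors.to_numpy(dtype=float)
    y = design.response
    lam_max = float(np.abs(X.T @ (y - y.mean())).max() / len(y))
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def _path_fold_auc(X: np.ndarray, y: np.ndarray, train: np.ndarray,
                   test: np.ndarray, grid: np.ndarray,
                   cv_tol: float) -> np.ndarray:
    """Test AUC along the (descending) lambda path for one CV fold."""
    n_tr = len(train)
    clf = LogisticRegression(l1_ratio=1.0, solver="saga", tol=cv_tol,
                             max_iter=20_000, warm_start=True)
    aucs = np.empty(len(grid))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for i, lam in enumerate(grid):
            clf.C = 1.0 / (n_tr * lam)
            clf.fit(X[train], y[train])
            scores = clf.decision_function(X[test])
            aucs[i] = roc_auc_score(y[test], scores)
    return aucs


def select_lambda(
    design: DesignMatrix,
    n_repeats: int = 100,
    n_folds: int = 10,
    seed: int = 0,
    n_lambda: int = 100,
    cv_tol: float = 1e-4,
) -> tuple[float, pd.DataFrame]:
    """Repeated-CV penalty selection.

    Per repeat, ``n_folds``-fold stratified CV yields a mean AUC curve over
    the lambda grid; ``lambda_min`` maximizes it and ``lambda_1se`` is the
    largest lambda whose mean AUC is within one across-fold standard error
    of the maximum. The returned ``lambda_star`` is the average of the mean
    ``lambda_min`` and the mean ``lambda_1se`` over repeats.
    """
    X = design.predictors.to_numpy(dtype=float)
    y = design.response
    if min((y == 1).sum(), (y == 0).sum()) < n_folds:
        raise ValueError("too few observations per class for stratified folds")
    grid = lambda_grid(design, n_lambda=n_lambda)
    master = np.random.SeedSequence(seed)
    records = []
    for rep, ss in enumerate(master.spawn(n_repeats)):
        state_iter = iter(ss.generate_state(16))
        for attempt in range(16):
            skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                                  random_state=int(next(state_iter)) % (2**32))
            fold_aucs = []
            try:
                for train, test in skf.split(X, y):
                    if y[test].min() == y[test].max():
                        raise ValueError("single-class test fold")
                    fold_aucs.append(
                        _path_fold_auc(X, y, train, test, grid, cv_tol))
            except ValueError as exc:
                logger.warning("repeat %d attempt %d refolded: %s",
                               rep, attempt, exc)
                continue
            break
        else:
            raise RuntimeError(f"could not build valid folds for repeat {rep}")
        curves = np.vstack(fold_aucs)             # (folds, lambdas)
        mean_auc = curves.mean(axis=0)
        i_min = int(np.argmax(mean_auc))
        se_max = curves[:, i_min].std(ddof=1) / np.sqrt(n_folds)
        within = np.flatnonzero(mean_auc >= mean_auc[i_min] - se_max)
        # grid is descending, so the largest qualifying lambda is the first
        records.append({"lambda_min": grid[i_min],
                        "lambda_1se": grid[within[0]]})
    per_run = pd.DataFrame(records)
    lambda_star = float((per_run["lambda_min"].mean()
                         + per_run["lambda_1se"].mean()) / 2)
    return lambda_star, per_run


def _irls(X1: np.ndarray, y: np.ndarray, beta0: np.ndarray,
          max_iter: int = 30, tol: float = 1e-8) -> np.ndarray:
    """Newton-Raphson (IRLS) for logistic ML with step halving.

    ``X1`` includes the intercept column. A tiny ridge jitter keeps the
    Hessian solvable for collinear or constant columns; under separation the
    step-halving loop stalls gracefully at large finite coefficients.
    """
    beta = beta0.copy()
    eta = X1 @ beta
    ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
    for _ in range(max_iter):
        p = expit(eta)
        grad = X1.T @ (y - p)
        w = np.maximum(p * (1 - p), 1e-10)
        hess = (X1 * w[:, None]).T @ X1
        hess.flat[:: hess.shape[0] + 1] += 1e-9
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            raise RuntimeError("singular Hessian in IRLS") from None
        for _ in range(20):
            cand = beta + step
            eta_c = X1 @ cand
            ll_c = float(y @ eta_c - np.logaddexp(0.0, eta_c).sum())
            if np.isfinite(ll_c) and ll_c >= ll - 1e-12:
                break
            step = step / 2
        else:
            return beta
        moved = float(np.max(np.abs(cand - beta)))
        beta, eta, ll = cand, eta_c, ll_c
        if moved < tol:
            break
    return beta


def fit_predict_logistic(X_train: np.ndarray, y_train: np.ndarray,
                         X_test: np.ndarray,
                         warm_start: np.ndarray | None = None) -> np.ndarray:
    """Fast unpenalized logistic fit-and-predict used inside CV loops.

    ``warm_start`` (intercept-first coefficient vector, e.g. from a fit on
    the full data) cuts Newton iterations for near-identical training sets.
    Falls back to scikit-learn's LBFGS solver if the Newton path fails.
    """
    X1 = np.hstack([np.ones((len(X_train), 1)), X_train])
    beta0 = (warm_start.copy() if warm_start is not None
             else np.zeros(X1.shape[1]))
    try:
        beta = _irls(X1, y_train, beta0)
        if not np.all(np.isfinite(beta)):
            raise RuntimeError("non-finite coefficients")
    except RuntimeError:
        clf = LogisticRegression(C=np.inf, solver="lbfgs", tol=1e-6,
                                 max_iter=1000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf.fit(X_train, y_train)
            return clf.predict_proba(X_test)[:, 1]
    return expit(beta[0] + X_test @ beta[1:])
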