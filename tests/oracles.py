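"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — exact rational enumeration and
direct objective minimization — and shares no code with the package paths
it validates.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit


def hypergeom_pmf_exact(a: int, r1: int, r2: int, c1: int) -> Fraction:
    """P(A = a) for a 2x2 table with row sums (r1, r2) and first column sum c1."""
    n = r1 + r2
    return Fraction(comb(r1, a) * comb(r2, c1 - a), comb(n, c1))


def _support(r1: int, r2: int, c1: int) -> range:
    return range(max(0, c1 - r2), min(r1, c1) + 1)


def fisher_enum_two_tailed(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-tailed Fisher P by full enumeration (probability-mass convention)."""
    r1, r2, c1 = a + b, c + d, a + c
    if min(r1, r2, c1, b + d) == 0:
        return Fraction(1)
    p_obs = hypergeom_pmf_exact(a, r1, r2, c1)
    total = Fraction(0)
    for k in _support(r1, r2, c1):
        pk = hypergeom_pmf_exact(k, r1, r2, c1)
        # scipy applies a tiny relative tolerance when comparing point masses
        if pk <= p_obs * (1 + Fraction(1, 10**7)):
            total += pk
    return total


def fisher_enum_one_tailed_greater(a: int, b: int, c: int, d: int) -> Fraction:
    """P(A >= a) by enumeration of the upper tail."""
    r1, r2, c1 = a + b, c + d, a + c
    if min(r1, r2, c1, b + d) == 0:
        return Fraction(1)
    return sum((hypergeom_pmf_exact(k, r1, r2, c1)
                for k in _support(r1, r2, c1) if k >= a), Fraction(0))


def auc_concordance_exact(scores, labels) -> Fraction:
    """Mann-Whitney AUC as an exact rational pairwise concordance count."""
    pos = [Fraction(float(s)) for s, l in zip(scores, labels) if l]
    neg = [Fraction(float(s)) for s, l in zip(scores, labels) if not l]
    num = Fraction(0)
    for p in pos:
        for q in neg:
            if p > q:
                num += 1
            elif p == q:
                num += Fraction(1, 2)
    return num / (len(pos) * len(neg))


def logistic_nll(beta: np.ndarray, X1: np.ndarray, y: np.ndarray) -> float:
    eta = X1 @ beta
    return float(np.logaddexp(0.0, eta).sum() - y @ eta)


def fit_logistic_oracle(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Generic convex-optimizer ML fit; returns (coefficients incl. intercept, NLL)."""
    X1 = np.hstack([np.ones((len(X), 1)), X])
    res = minimize(logistic_nll, np.zeros(X1.shape[1]), args=(X1, y),
                   method="BFGS", options={"gtol": 1e-10, "maxiter": 5000})
    return res.x, logistic_nll(res.x, X1, y)


def fit_lasso_oracle(X: np.ndarray, y: np.ndarray, lam: float,
                     n_iter: int = 200_000, tol: float = 1e-12) -> np.ndarray:
    """Proximal-gradient (ISTA) minimizer of mean logistic NLL + lam*||beta||_1.

    Intercept-first coefficient vector; the intercept is unpenalized.
    """
    n = len(y)
    X1 = np.hstack([np.ones((n, 1)), X])
    L = np.linalg.eigvalsh(X1.T @ X1 / n).max() / 4 + 1e-12  # Lipschitz bound
    beta = np.zeros(X1.shape[1])
    for _ in range(n_iter):
        p = expit(X1 @ beta)
        grad = X1.T @ (p - y) / n
        z = beta - grad / L
        new = np.sign(z) * np.maximum(np.abs(z) - lam / L, 0.0)
        new[0] = z[0]  # unpenalized intercept
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    return beta


def lasso_objective(beta: np.ndarray, X: np.ndarray, y: np.ndarray,
                    lam: float) -> float:
    X1 = np.hstack([np.ones((len(y), 1)), X])
    return logistic_nll(beta, X1, y) / len(y) + lam * np.abs(beta[1:]).sum()
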