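"""Independent brute-force oracles used by the test suite.

Each function recomputes a quantity from first principles, sharing no code
with the package implementation it checks:

* soft-margin linear SVM solved as the dual quadratic program (SLSQP);
* recursive feature elimination re-run on top of that QP solver;
* Grubbs statistic/decision, Bonferroni-adjusted outlier p-values and
  variance inflation factors by direct formula / textbook regression.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.optimize import minimize


def svm_dual_weights(X, y, C=1.0):
    """Linear soft-margin SVM weights from the dual QP.

    Maximize sum(a) - 1/2 a' Q a  s.t.  0 <= a <= C,  a . y = 0, with
    Q_ij = y_i y_j x_i . x_j; then w = sum_i a_i y_i x_i.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    assert len(classes) == 2
    ypm = np.where(y == classes[1], 1.0, -1.0)
    n = len(ypm)
    Q = (ypm[:, None] * ypm[None, :]) * (X @ X.T)

    def obj(a):
        return 0.5 * a @ Q @ a - a.sum()

    def jac(a):
        return Q @ a - 1.0

    res = minimize(
        obj,
        np.zeros(n),
        jac=jac,
        method="SLSQP",
        bounds=[(0.0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ ypm, "jac": lambda a: ypm}],
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    return (res.x * ypm) @ X


def rfe_elimination_order(X, y, C=1.0, standardize=True):
    """Recursive elimination order (worst first, survivor last) via the QP.

    Mirrors the squared-weight criterion and the lowest-index tie-break,
    but every SVM is solved by :func:`svm_dual_weights`.
    """
    X = np.asarray(X, dtype=float)
    if standardize:
        sd = X.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        X = (X - X.mean(axis=0)) / sd
    surviving = list(range(X.shape[1]))
    order = []
    while len(surviving) > 1:
        w = svm_dual_weights(X[:, surviving], y, C=C)
        crit = w**2
        crit[crit < 1e-10] = 0.0  # solver noise around an exact zero weight
        g = int(np.lexsort((np.arange(len(crit)), crit))[0])
        order.append(surviving.pop(g))
    order.extend(surviving)
    return order


def grubbs_decision(x, alpha=0.05):
    """(statistic, critical value, flagged index or None) for one pass."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    dev = np.abs(x - x.mean())
    i = int(np.argmax(dev))
    g = dev[i] / x.std(ddof=1)
    t2 = stats.t.ppf(1 - alpha / (2 * n), n - 2) ** 2
    crit = ((n - 1) / np.sqrt(n)) * np.sqrt(t2 / (n - 2 + t2))
    return float(g), float(crit), (i if g > crit else None)


def bonferroni_adjusted_pvalues(x):
    """Bonferroni-adjusted outlier p-values via the leave-one-out t-test.

    For each i, the externally studentized residual of the intercept-only
    model equals (x_i - mean_{-i}) / (s_{-i} sqrt(1 + 1/(n-1))) -- computed
    here literally by deleting observation i.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    out = np.empty(n)
    for i in range(n):
        rest = np.delete(x, i)
        t_i = (x[i] - rest.mean()) / (rest.std(ddof=1) * np.sqrt(1 + 1.0 / (n - 1)))
        out[i] = min(1.0, n * 2 * stats.t.sf(abs(t_i), n - 2))
    return out


def vif_direct(X):
    """VIF of every column via explicit OLS fits with intercept."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    vifs = np.empty(p)
    for i in range(p):
        y = X[:, i]
        others = np.column_stack([np.ones(n), np.delete(X, i, axis=1)])
        beta, _, _, _ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        tss = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - resid @ resid / tss if tss > 0 else 1.0
        vifs[i] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return vifs


def lda_predict_pooled(X_train, y_train, X_test, ridge=0.0):
    """Classical equal-prior LDA from the pooled within-class covariance."""
    X_train = np.asarray(X_train, float)
    classes = np.unique(y_train)
    assert len(classes) == 2
    x0, x1 = X_train[y_train == classes[0]], X_train[y_train == classes[1]]
    mu0, mu1 = x0.mean(axis=0), x1.mean(axis=0)
    s = ((x0 - mu0).T @ (x0 - mu0) + (x1 - mu1).T @ (x1 - mu1)) / (
        len(X_train) - 2
    )
    s = s + ridge * np.eye(s.shape[0])
    w = np.linalg.solve(s, mu1 - mu0)
    thresh = 0.5 * (mu0 + mu1) @ w
    return np.where(np.asarray(X_test, float) @ w > thresh, classes[1], classes[0])
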