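"""Paired nonparametric comparisons and simple regression controls.

Conventions for the Wilcoxon signed-rank test follow the R idiom
(``wilcox.test`` plus the ``rcompanion`` helpers): zero differences are
dropped before ranking, |d| are ranked with mid-ranks for ties, W is the
sum of ranks of positive differences, Z uses the tie-corrected variance
without continuity correction, and the matched-pairs rank-biserial
correlation is rc = 2·W/(n(n+1)/2) − 1.  Exact two-sided p-values are
computed by full enumeration of the 2ⁿ sign assignments for small n.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from math import sqrt
from typing import Sequence

import numpy as np
from scipy import stats as sps


class PairedStatsError(ValueError):
    pass


@dataclass(frozen=True)
class PairedTestResult:
    W: float
    Z: float
    rc: float
    p_value: float
    n_input: int
    n_effective: int
    method: str  # "exact" or "normal"

    def to_dict(self) -> dict:
        return {"W": self.W, "Z": self.Z, "rc": self.rc, "p_value": self.p_value,
                "n_input": self.n_input, "n_effective": self.n_effective,
                "method": self.method}


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def signed_rank_summary(w: float, n_effective: int,
                        tie_groups: Sequence[int] = ()) -> tuple[float, float]:
    """(Z, rc) from a positive-rank sum W and effective sample size.

    Z = (W − n(n+1)/4)/σ with σ² = n(n+1)(2n+1)/24 − Σt(t³−t)/48 over tied
    groups of size t, no continuity correction; rc = 2W/(n(n+1)/2) − 1.
    Usable as a conventions cross-check when only (W, n) are known.
    """
    n = n_effective
    total = n * (n + 1) / 2
    mu = n * (n + 1) / 4
    var = n * (n + 1) * (2 * n + 1) / 24
    var -= sum(t**3 - t for t in tie_groups) / 48
    z = (w - mu) / sqrt(var) if var > 0 else float("nan")
    rc = 2 * w / total - 1
    return z, rc


def _exact_two_tailed_p(w_obs: float, ranks: np.ndarray) -> float:
    """Enumerate all 2ⁿ sign assignments of the given |d| ranks."""
    n = len(ranks)
    ws = np.zeros(2**n)
    for i, signs in enumerate(product((0, 1), repeat=n)):
        ws[i] = sum(r for r, s in zip(ranks, signs) if s)
    eps = 1e-9
    p_ge = (ws >= w_obs - eps).mean()
    p_le = (ws <= w_obs + eps).mean()
    return min(1.0, 2 * min(p_ge, p_le))


def wilcoxon_paired(x, y, *, exact_threshold: int = 12) -> PairedTestResult:
    """Two-tailed paired Wilcoxon signed-rank test of x vs y.

    Exact enumeration for n_effective ≤ ``exact_threshold``; otherwise a
    normal approximation with tie-corrected variance and no continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise PairedStatsError("x and y must be equal-length 1-D sequences")
    d = x - y
    n_input = d.size
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise PairedStatsError("no nonzero pairs")
    ranks = _midranks(np.abs(d))
    w = float(ranks[d > 0].sum())

    _, counts = np.unique(np.abs(d), return_counts=True)
    z, rc = signed_rank_summary(w, n, tie_groups=[int(c) for c in counts if c > 1])

    if n <= exact_threshold:
        p = _exact_two_tailed_p(w, ranks)
        method = "exact"
    else:
        p = 2 * sps.norm.sf(abs(z))
        method = "normal"
    return PairedTestResult(W=float(w), Z=float(z), rc=float(rc),
                            p_value=float(min(1.0, p)),
                            n_input=n_input, n_effective=n, method=method)


def sign_test(x, y, *, tie_policy: str = "drop") -> float:
    """Two-tailed exact sign test (binomial, success probability ½).

    ``tie_policy``: "drop" (default) discards zero differences;
    "majority" counts them with whichever side is in the majority — a
    replication switch only.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = x - y
    pos = int((d > 0).sum())
    neg = int((d < 0).sum())
    ties = int((d == 0).sum())
    if pos + neg == 0:
        raise PairedStatsError("all differences are ties")
    if tie_policy == "majority" and ties:
        if pos >= neg:
            pos += ties
        else:
            neg += ties
    elif tie_policy != "drop":
        raise PairedStatsError(f"unknown tie policy {tie_policy!r}")
    n = pos + neg
    return float(sps.binomtest(pos, n, 0.5, alternative="two-sided").pvalue)


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks; large-sample p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.shape != y.shape:
        raise PairedStatsError("need ≥3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise PairedStatsError("constant input")
    rs, p = sps.spearmanr(x, y)
    return float(rs), float(p)


def ols_residuals(y, X) -> np.ndarray:
    """Least-squares residuals of y on covariate columns X (intercept added).

    Residuals are orthogonal to every covariate column; rank-deficient
    design matrices are rejected.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if y.shape[0] != X.shape[0]:
        raise PairedStatsError("y and X row counts differ")
    design = sm.add_constant(X, has_constant="add")
    if y.shape[0] < design.shape[1] + 1:
        raise PairedStatsError("too few rows for the number of covariates")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise PairedStatsError("rank-deficient design matrix")
    fit = sm.OLS(y, design).fit()
    return np.asarray(fit.resid)
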