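"""Phylogenetic principal component analysis.

Components are the eigenvectors of the evolutionary covariance (or
correlation) matrix: the cross-species covariance of trait deviations from
the GLS-estimated ancestral mean, whitened by V(lambda)^-1, with lambda
fitted by multivariate maximum likelihood under a matrix-normal model.
Species scores are the (centered, optionally standardized) data projected
onto the eigenvectors; growth-form categories can be passively projected
afterwards as centroids of their member species' scores, without having
influenced the axes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from elevtrait.pgls import LambdaGLS, bm_covariance

__all__ = ["PPCAResult", "phylo_pca", "project_categories"]

_GOLD = (math.sqrt(5.0) - 1.0) / 2.0


@dataclass
class PPCAResult:
    loadings: pd.DataFrame      # variables x components
    scores: pd.DataFrame        # species x components
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    lambda_hat: float
    mode: str                   # "corr" or "cov"
    ancestral_mean: pd.Series
    flags: tuple = ()

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "lambda_hat": self.lambda_hat,
            "eigenvalues": self.eigenvalues.tolist(),
            "percent_variance": self.percent_variance.tolist(),
            "loadings": {c: self.loadings[c].to_dict() for c in self.loadings},
            "scores": {c: self.scores[c].to_dict() for c in self.scores},
            "ancestral_mean": self.ancestral_mean.to_dict(),
            "flags": list(self.flags),
        }


def _matrix_normal_profile(solver: LambdaGLS, X: np.ndarray):
    """Profile log-likelihood over lambda for the matrix-normal model
    X ~ MN(1 a', R kron V(lambda)) with a and R profiled out by ML."""
    n, m = X.shape
    ones = np.ones((n, 1))

    def ll(lam):
        Z, logdetV = solver.whiten(lam, np.column_stack([ones, X]))
        z1, ZX = Z[:, :1], Z[:, 1:]
        # GLS ancestral mean per column
        a = (z1.T @ ZX) / float((z1.T @ z1)[0, 0])
        E = ZX - z1 @ a
        S = E.T @ E
        R = S / n
        sign, logdetR = np.linalg.slogdet(R + 1e-12 * np.eye(m))
        return (-0.5 * n * m * (math.log(2.0 * math.pi) + 1.0)
                - 0.5 * n * logdetR - 0.5 * m * logdetV), a.ravel()

    grid = np.linspace(0.0, 1.0, 21)
    vals = [ll(g)[0] for g in grid]
    i = int(np.argmax(vals))
    a, b = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    x1 = b - _GOLD * (b - a)
    x2 = a + _GOLD * (b - a)
    f1, f2 = ll(x1)[0], ll(x2)[0]
    while b - a > 1e-6:
        if f1 < f2:
            a, x1, f1 = x1, x2, f2
            x2 = a + _GOLD * (b - a)
            f2 = ll(x2)[0]
        else:
            b, x2, f2 = x2, x1, f1
            x1 = b - _GOLD * (b - a)
            f1 = ll(x1)[0]
    lam = 0.5 * (a + b)
    best = ll(lam)[0]
    for endpoint, v in ((0.0, vals[0]), (1.0, vals[-1])):
        if v >= best - 1e-9:
            lam, best = endpoint, v
    return float(lam)


def phylo_pca(
    matrix: pd.DataFrame,
    tree,
    lambda_mode="ML",
    mode: str = "corr",
) -> PPCAResult:
    """Phylogenetic PCA of a species x variables matrix.

    Parameters
    ----------
    matrix : complete-case numeric DataFrame indexed by species (>= 3 rows).
    lambda_mode : "ML" (multivariate maximum likelihood) or a fixed float.
    mode : "corr" (default; variables standardized via the evolutionary
        correlation matrix, appropriate when traits mix units) or "cov".

    The component sign convention is deterministic: the largest-magnitude
    loading of each component is made positive.
    """
    X = matrix.astype(float)
    if X.isna().any().any():
        raise ValueError("matrix must be complete cases (no NaN)")
    n, m = X.shape
    if n < 3:
        raise ValueError("need at least 3 species")
    if mode not in ("corr", "cov"):
        raise ValueError("mode must be 'corr' or 'cov'")

    C = bm_covariance(tree, X.index)
    solver = LambdaGLS(C)
    Xv = X.to_numpy()

    if lambda_mode == "ML":
        lam = _matrix_normal_profile(solver, Xv)
    else:
        lam = float(lambda_mode)
        if not 0.0 <= lam <= 1.0:
            raise ValueError("lambda must be in [0, 1]")

    ones = np.ones((n, 1))
    Z, _ = solver.whiten(lam, np.column_stack([ones, Xv]))
    z1, ZX = Z[:, :1], Z[:, 1:]
    a = ((z1.T @ ZX) / float((z1.T @ z1)[0, 0])).ravel()  # GLS ancestral mean
    Ew = ZX - z1 @ a[None, :]
    R = (Ew.T @ Ew) / (n - 1)                       # evolutionary covariance

    flags = []
    if mode == "corr":
        sd = np.sqrt(np.diag(R))
        if np.any(sd == 0):
            raise ValueError("zero-variance variable in correlation mode")
        A = R / np.outer(sd, sd)
    else:
        A = R

    evals, evecs = np.linalg.eigh(A)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    n_comp = min(n - 1, m)
    if np.any(evals[:n_comp] < -1e-8):
        flags.append("negative_eigenvalues_truncated")
    rank = int(np.sum(evals > max(evals.max(), 0) * 1e-10))
    if rank < n_comp:
        flags.append(f"rank_deficient:{rank}")
        n_comp = rank
    evals = np.maximum(evals[:n_comp], 0.0)
    evecs = evecs[:, :n_comp]

    # deterministic sign convention
    for j in range(n_comp):
        i_max = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[i_max, j] < 0:
            evecs[:, j] = -evecs[:, j]

    centered = Xv - a[None, :]
    if mode == "corr":
        centered = centered / sd[None, :]
    scores = centered @ evecs

    comp_names = [f"PC{j + 1}" for j in range(n_comp)]
    total = evals.sum()
    pct = 100.0 * evals / total if total > 0 else np.zeros(n_comp)
    return PPCAResult(
        loadings=pd.DataFrame(evecs, index=X.columns, columns=comp_names),
        scores=pd.DataFrame(scores, index=X.index, columns=comp_names),
        eigenvalues=evals,
        percent_variance=pct,
        lambda_hat=float(lam),
        mode=mode,
        ancestral_mean=pd.Series(a, index=X.columns),
        flags=tuple(flags),
    )


def project_categories(scores: pd.DataFrame, growth_forms: pd.Series) -> pd.DataFrame:
    """Passive centroids of a categorical label on the first two components.

    The categories play no role in the ordination; each centroid is simply
    the mean score of its member species.  Categories with fewer than two
    members are flagged.
    """
    gf = pd.Series(growth_forms).reindex(scores.index)
    if gf.isna().all() or len(gf.dropna().unique()) == 0:
        raise ValueError("no growth-form categories to project")
    if gf.isna().any():
        raise ValueError("every species needs a growth-form label")
    comps = list(scores.columns[:2])
    rows = []
    for cat, grp in scores.groupby(gf.astype(str), sort=True):
        row = {"growth_form": cat, "n": len(grp)}
        for c in comps:
            row[c] = float(grp[c].mean())
        row["flag"] = "few_members" if len(grp) < 2 else ""
        rows.append(row)
    return pd.DataFrame(rows).set_index("growth_form")
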