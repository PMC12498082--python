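"""Phylogenetic generalized least squares (PGLS) with ML Pagel's lambda.

The residual covariance across species is ``sigma^2 * V(lambda)`` where
``V(lambda)`` keeps the Brownian diagonal of the tree covariance ``C`` and
scales its off-diagonal (shared-branch) entries by ``lambda`` in [0, 1].
``lambda = 0`` means phylogenetic independence, ``lambda = 1`` the full
Brownian expectation.  lambda is estimated by maximizing the profile
log-likelihood (sigma^2 profiled out analytically) with a coarse grid
followed by golden-section refinement, with both endpoints checked
explicitly so boundary optima are reported as exactly 0 or 1.

Model comparison uses ML (not REML) so AIC is valid across different
fixed-effect sets; the parameter count ``k`` includes lambda and sigma^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

__all__ = [
    "bm_covariance", "lambda_transform", "LambdaGLS", "PGLSFit",
    "pgls_fit", "adjusted_r2", "build_design",
]

_GOLD = (math.sqrt(5.0) - 1.0) / 2.0


def normalize_label(label: str) -> str:
    """Canonical species label: stripped, internal whitespace -> underscore."""
    return "_".join(str(label).split())


def bm_covariance(tree, species_order) -> np.ndarray:
    """Brownian covariance matrix of a rooted tree.

    ``C[i, j]`` is the root-to-MRCA path length of tips i and j (the branch
    length the two lineages share); the diagonal holds root-to-tip depths.

    Parameters
    ----------
    tree : dendropy.Tree
        Rooted tree with branch lengths.
    species_order : sequence of str
        Tip labels defining row/column order.

    Raises
    ------
    KeyError
        If any requested species is not a tip of the tree (all offenders
        are listed).
    """
    species_order = [normalize_label(s) for s in species_order]
    n = len(species_order)
    index = {s: i for i, s in enumerate(species_order)}
    if len(index) != n:
        raise ValueError("duplicate species in species_order")

    # node depths from the root
    depth = {}
    for node in tree.preorder_node_iter():
        edge = node.edge.length or 0.0
        depth[node] = (depth[node.parent_node] if node.parent_node else 0.0) + edge

    tip_idx = {}
    for leaf in tree.leaf_node_iter():
        label = normalize_label(leaf.taxon.label if leaf.taxon else leaf.label)
        tip_idx[leaf] = index.get(label)

    missing = set(species_order) - {
        normalize_label(l.taxon.label if l.taxon else l.label)
        for l in tree.leaf_node_iter()
    }
    if missing:
        raise KeyError(f"species missing from tree: {sorted(missing)}")

    C = np.zeros((n, n))
    # postorder: at each internal node, tips in different child subtrees have
    # their MRCA here, so C = depth(node) for those pairs
    leafsets = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = tip_idx[node]
            if i is not None:
                C[i, i] = depth[node]
                leafsets[node] = [i]
            else:
                leafsets[node] = []
            continue
        children = [leafsets[ch] for ch in node.child_nodes()]
        d = depth[node]
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                for i in children[a]:
                    for j in children[b]:
                        C[i, j] = C[j, i] = d
        leafsets[node] = [i for ch in children for i in ch]
    return C


def lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Pagel's lambda transform: off-diagonal entries scaled by ``lam``."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    return V


class LambdaGLS:
    """Whitening engine for the lambda family V(lambda) of one covariance C.

    For ultrametric trees diag(C) is constant, so V(lambda) shares C's
    eigenvectors and whitening reduces to a diagonal rescaling after a single
    eigendecomposition; otherwise a Cholesky factorization is taken per
    lambda.  Both paths produce identical fits.
    """

    def __init__(self, C: np.ndarray):
        C = np.asarray(C, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("C must be square")
        self.C = C
        self.n = C.shape[0]
        d = np.diag(C)
        self.height = float(d.mean())
        self.ultrametric = bool(
            np.allclose(d, self.height, rtol=0.0, atol=1e-8 * max(self.height, 1.0))
        )
        if self.ultrametric:
            evals, Q = np.linalg.eigh(C)
            self._evals = evals
            self._Q = Q

    def whiten(self, lam: float, M: np.ndarray) -> tuple[np.ndarray, float]:
        """Return (L^-1 M, log|V(lam)|) for V = L L^T."""
        if not 0.0 <= lam <= 1.0:
            raise ValueError(f"lambda must be in [0, 1], got {lam}")
        if self.ultrametric:
            w = lam * self._evals + (1.0 - lam) * self.height
            w = np.maximum(w, 1e-12)
            Mt = self._Q.T @ M
            return Mt / np.sqrt(w)[:, None], float(np.log(w).sum())
        V = lambda_transform(self.C, lam)
        L = linalg.cholesky(V, lower=True)
        Z = linalg.solve_triangular(L, M, lower=True)
        return Z, float(2.0 * np.log(np.diag(L)).sum())


@dataclass
class PGLSFit:
    """A fitted phylogenetic regression."""

    response: str
    terms: tuple
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    lambda_hat: float
    sigma2_hat: float
    logL: float
    aic: float
    r2: float
    adj_r2: float
    n: int
    k: int
    n_predictors: int  # non-intercept coefficient count
    species: tuple = ()
    flags: tuple = ()

    def summary(self) -> str:
        rows = pd.DataFrame(
            {"coef": self.params, "se": self.bse, "t": self.tvalues, "p": self.pvalues}
        )
        head = (
            f"PGLS fit: {self.response} ~ {' + '.join(self.terms) or '1'}\n"
            f"n = {self.n}  lambda = {self.lambda_hat:.4f}  "
            f"logL = {self.logL:.3f}  AIC = {self.aic:.3f}  "
            f"R2 = {self.r2:.4f}  adjR2 = {self.adj_r2:.4f}\n"
        )
        return head + rows.to_string()


def build_design(
    table: pd.DataFrame, terms, reference: dict | None = None
) -> tuple[pd.DataFrame, dict]:
    """Expand model terms into a numeric design (no intercept column).

    Continuous columns pass through; categorical/object columns are expanded
    to reference-coded indicator columns named ``term[level]``, the reference
    being the alphabetically first level (overridable per term).  Returns the
    design and a mapping term -> list of design columns, so a categorical
    term can be treated as a single predictor block.
    """
    reference = reference or {}
    cols = {}
    groups: dict[str, list[str]] = {}
    for term in terms:
        if term not in table.columns:
            raise KeyError(f"term {term!r} not in table")
        col = table[term]
        if pd.api.types.is_numeric_dtype(col):
            cols[term] = col.astype(float)
            groups[term] = [term]
        else:
            levels = sorted(col.astype(str).unique())
            ref = reference.get(term, levels[0])
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} absent for {term!r}")
            groups[term] = []
            for lev in levels:
                if lev == ref:
                    continue
                name = f"{term}[{lev}]"
                cols[name] = (col.astype(str) == lev).astype(float)
                groups[term].append(name)
    design = pd.DataFrame(cols, index=table.index)
    return design, groups


def _fixed_lambda_fit(solver: LambdaGLS, lam: float, X: np.ndarray, y: np.ndarray):
    n = solver.n
    Z, logdet = solver.whiten(lam, np.column_stack([X, y]))
    Zx, zy = Z[:, :-1], Z[:, -1]
    beta, *_ = np.linalg.lstsq(Zx, zy, rcond=None)
    resid = zy - Zx @ beta
    rss = float(resid @ resid)
    sigma2_ml = max(rss / n, 1e-300)
    logL = -0.5 * (n * math.log(2.0 * math.pi * sigma2_ml) + n + logdet)
    return beta, rss, sigma2_ml, logL, Zx, zy


def _profile_lambda(solver, X, y, tol: float = 1e-7):
    """Maximize the lambda profile likelihood: 21-point grid, golden-section
    refinement in the bracketing interval, explicit endpoint checks."""

    def ll(lam):
        return _fixed_lambda_fit(solver, lam, X, y)[3]

    grid = np.linspace(0.0, 1.0, 21)
    vals = np.array([ll(g) for g in grid])
    i = int(np.argmax(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    a, b = lo, hi
    x1 = b - _GOLD * (b - a)
    x2 = a + _GOLD * (b - a)
    f1, f2 = ll(x1), ll(x2)
    while b - a > tol:
        if f1 < f2:
            a, x1, f1 = x1, x2, f2
            x2 = a + _GOLD * (b - a)
            f2 = ll(x2)
        else:
            b, x2, f2 = x2, x1, f1
            x1 = b - _GOLD * (b - a)
            f1 = ll(x1)
    lam = 0.5 * (a + b)
    best = ll(lam)
    # endpoint checks: a boundary optimum is reported exactly
    for endpoint in (0.0, 1.0):
        v = vals[0] if endpoint == 0.0 else vals[-1]
        if v >= best - 1e-9:
            lam, best = endpoint, v
    return float(lam), float(best)


def _collinear_columns(X: np.ndarray, names) -> list:
    """Columns that do not increase the design rank, scanned left to right."""
    bad = []
    rank = 0
    for j in range(X.shape[1]):
        r = np.linalg.matrix_rank(X[:, : j + 1])
        if r == rank:
            bad.append(names[j])
        rank = r
    return bad


def pgls_fit(
    y,
    design,
    tree=None,
    lambda_mode="ML",
    *,
    C: np.ndarray | None = None,
    solver: LambdaGLS | None = None,
    response_name: str | None = None,
    terms=None,
) -> PGLSFit:
    """Fit a phylogenetic linear model by GLS with Pagel's lambda.

    Parameters
    ----------
    y : pandas.Series
        Response indexed by species.
    design : pandas.DataFrame
        Numeric predictors indexed by species (no intercept column; one is
        prepended).  Use :func:`build_design` to expand categoricals.
    tree : dendropy.Tree, optional
        Source of the Brownian covariance; alternatively pass ``C`` or a
        prebuilt ``solver`` (the latter is the fast path for subset
        searches that refit many designs over one species set).
    lambda_mode : "ML" or a float in [0, 1]
        Estimate lambda by maximum likelihood, or fix it.
    """
    y = pd.Series(y).astype(float)
    design = pd.DataFrame(design, index=y.index).astype(float)
    species = tuple(y.index.astype(str))
    n = len(y)
    if not np.isfinite(y.to_numpy()).all() or not np.isfinite(design.to_numpy()).all():
        raise ValueError("non-finite values in response or design")

    if solver is None:
        if C is None:
            if tree is None:
                raise ValueError("provide tree, C, or solver")
            C = bm_covariance(tree, species)
        solver = LambdaGLS(C)
    if solver.n != n:
        raise ValueError("covariance size does not match data")

    names = ["Intercept"] + list(design.columns)
    X = np.column_stack([np.ones(n), design.to_numpy()])
    p_coef = X.shape[1]
    if n < p_coef + 2:
        raise ValueError(f"too few species (n={n}) for {p_coef} coefficients")
    if np.linalg.matrix_rank(X) < p_coef:
        bad = _collinear_columns(X, names)
        raise ValueError(f"singular design; collinear columns: {bad}")

    yv = y.to_numpy()
    if lambda_mode == "ML":
        lam, logL = _profile_lambda(solver, X, yv)
    else:
        lam = float(lambda_mode)
        if not 0.0 <= lam <= 1.0:
            raise ValueError(f"lambda must be in [0, 1], got {lam}")
        logL = None

    beta, rss, sigma2_ml, logL, Zx, zy = _fixed_lambda_fit(solver, lam, X, yv)

    dof = n - p_coef
    sigma2_u = rss / dof if dof > 0 else np.nan
    XtX_inv = np.linalg.inv(Zx.T @ Zx)
    bse = np.sqrt(np.maximum(np.diag(XtX_inv) * sigma2_u, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / bse
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)

    # R2 against the intercept-only GLS at the same lambda
    rss0 = _fixed_lambda_fit(solver, lam, X[:, :1], yv)[1]
    r2 = 1.0 - rss / rss0 if rss0 > 0 else 0.0

    p_pred = p_coef - 1
    flags = []
    if n - p_pred - 1 > 0:
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p_pred - 1)
    else:
        adj = float("nan")
        flags.append("adj_r2_undefined")

    k = p_coef + 2  # coefficients + lambda + sigma^2
    fit = PGLSFit(
        response=response_name or getattr(y, "name", None) or "y",
        terms=tuple(terms) if terms is not None else tuple(design.columns),
        params=pd.Series(beta, index=names),
        bse=pd.Series(bse, index=names),
        tvalues=pd.Series(tvals, index=names),
        pvalues=pd.Series(pvals, index=names),
        lambda_hat=float(lam),
        sigma2_hat=float(sigma2_ml),
        logL=float(logL),
        aic=float(-2.0 * logL + 2.0 * k),
        r2=float(r2),
        adj_r2=float(adj),
        n=n,
        k=k,
        n_predictors=p_pred,
        species=species,
        flags=tuple(flags),
    )
    return fit


def adjusted_r2(fit: PGLSFit) -> float:
    """Adjusted R^2 = 1 - (1 - R^2) (n - 1) / (n - p - 1)."""
    n, p = fit.n, fit.n_predictors
    if n - p - 1 <= 0:
        return float("nan")
    return 1.0 - (1.0 - fit.r2) * (n - 1) / (n - p - 1)
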