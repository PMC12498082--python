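"""Sequential category-wise exhaustive-AIC predictor selection.

Predictors are organized into three hierarchical categories — morphology,
anatomy, physiology — reflecting nested levels of plant adaptation.  Within
a category every subset of its predictors (2^m designs, always including
the carried-forward covariates, down to the covariates-only design) is fit
by PGLS with ML Pagel's lambda re-estimated per design.  The winner is the
smallest subset whose AIC lies within ``aic_margin`` (default 2, the
conventional "equivalent support" band) of the enumeration minimum: models
within 2 AIC units have comparable support, and a predictor that only
separates such near-ties has not demonstrated influence on the response, so
it is not carried.  ``aic_margin=0`` gives the strict minimum-AIC rule.
The enumeration minimum itself is reported as ``min_aic``.  Predictors
selected at one stage become covariates for the next, so later categories
are judged on what they add beyond earlier ones.

A predictor's importance is the AIC penalty for living without it: the best
AIC over all enumerated designs that exclude it, minus the best AIC overall
(a re-search, not a single drop-one refit; a ``drop_one`` mode provides the
simpler variant).  Subsets within 2 AIC units of the best are reported as
near-ties, since such models have comparable support and may carry traits
masked by collinearity.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from elevtrait.pgls import LambdaGLS, bm_covariance, build_design, pgls_fit, PGLSFit

__all__ = [
    "CategorySpec", "CategoryResult", "SelectionLedger", "DEFAULT_CATEGORIES",
    "enumerate_subsets", "select_category", "sequential_selection",
]


@dataclass(frozen=True)
class CategorySpec:
    name: str
    predictors: tuple

    def __post_init__(self):
        object.__setattr__(self, "predictors", tuple(self.predictors))


DEFAULT_CATEGORIES = (
    CategorySpec("morphology", ("Height", "growth_form")),
    CategorySpec("anatomy", ("Bark/xylem", "Longevity", "Mechanical tissue",
                             "Storage tissue", "Ring width")),
    CategorySpec("physiology", ("LNC", "LPC", "LCC", "RNC", "RPC",
                                "d15N", "d13C", "Fructan", "Starch",
                                "Free sugar")),
)


def enumerate_subsets(predictors, covariates=()) -> list:
    """All 2^m designs: covariates plus each subset of the predictors.

    Deterministic order: by subset size, then lexicographic.  Raises on
    duplicate names between covariates and predictors.
    """
    predictors = list(predictors)
    covariates = tuple(covariates)
    if len(predictors) > 12:
        raise ValueError("more than 12 predictors (2^m fits) — split the category")
    dup = set(predictors) & set(covariates)
    if dup:
        raise ValueError(f"names duplicated between covariates and predictors: {sorted(dup)}")
    if len(set(predictors)) != len(predictors):
        raise ValueError("duplicate predictor names")
    designs = []
    for size in range(len(predictors) + 1):
        for combo in itertools.combinations(sorted(predictors), size):
            designs.append(covariates + combo)
    return designs


@dataclass
class CategoryResult:
    """Outcome of one category's exhaustive search."""

    name: str
    covariates: tuple
    candidates: tuple
    best_subset: tuple          # selected predictors (excl. covariates)
    best_fit: PGLSFit
    min_aic: float              # minimum AIC over all enumerated designs
    n_designs: int
    n_species: int
    importance: dict            # predictor -> re-search delta-AIC when omitted
    near_ties: list             # [(subset, delta_aic)] with delta < 2 vs min
    skipped: list = field(default_factory=list)


def _fit_design(data, terms, response, solver, groups_cache):
    design, groups = build_design(data, terms)
    return pgls_fit(
        data[response], design, solver=solver, lambda_mode="ML",
        response_name=response, terms=terms,
    )


def select_category(
    data: pd.DataFrame,
    tree,
    category: CategorySpec,
    covariates=(),
    response: str = "optimum",
    importance_mode: str = "re_search",
    aic_margin: float = 2.0,
    solver: LambdaGLS | None = None,
) -> CategoryResult:
    """Exhaustive AIC search over one category's predictor subsets.

    ``data`` must hold the response, all candidate predictors, and the
    covariates, restricted to complete cases (handled by
    :func:`sequential_selection`); a categorical predictor such as growth
    form enters and leaves as one block of indicator columns.
    """
    covariates = tuple(covariates)
    designs = enumerate_subsets(category.predictors, covariates)
    if solver is None:
        solver = LambdaGLS(bm_covariance(tree, data.index))

    fits = {}
    skipped = []
    for terms in designs:
        try:
            fits[terms] = _fit_design(data, terms, response, solver, None)
        except ValueError as exc:
            skipped.append((terms, str(exc)))
    if not fits:
        raise ValueError(f"all designs failed in category {category.name}: {skipped}")

    min_aic = min(f.aic for f in fits.values())
    supported = [t for t in fits if fits[t].aic <= min_aic + aic_margin + 1e-9]
    best_terms = min(
        supported,
        key=lambda t: (len(t) - len(covariates), t[len(covariates):],
                       round(fits[t].aic, 10)),
    )
    best_fit = fits[best_terms]
    best_subset = best_terms[len(covariates):]

    importance = {}
    for pred in best_subset:
        if importance_mode == "re_search":
            rivals = [f.aic for t, f in fits.items() if pred not in t]
        else:  # drop_one
            t = tuple(x for x in best_terms if x != pred)
            rivals = [fits[t].aic] if t in fits else []
        importance[pred] = (min(rivals) - min_aic) if rivals else float("nan")

    near = []
    for terms, fit in fits.items():
        delta = fit.aic - min_aic
        if delta < 2.0:
            near.append((terms[len(covariates):], float(delta)))
    near.sort(key=lambda it: (it[1], len(it[0]), it[0]))

    return CategoryResult(
        name=category.name, covariates=covariates,
        candidates=tuple(category.predictors),
        best_subset=best_subset, best_fit=best_fit, min_aic=float(min_aic),
        n_designs=len(designs), n_species=len(data),
        importance=importance, near_ties=near, skipped=skipped,
    )


@dataclass
class SelectionLedger:
    """Per-stage record of the sequential search."""

    response: str
    stages: list               # list of CategoryResult
    cumulative_adj_r2: list    # adj R2 of each stage's best model
    increments: list           # stage-over-stage change in adj R2

    @property
    def final_terms(self) -> tuple:
        return self.stages[-1].covariates + self.stages[-1].best_subset if self.stages else ()

    def to_dict(self) -> dict:
        out = {"response": self.response, "stages": [], "cumulative_adj_r2":
               self.cumulative_adj_r2, "increments": self.increments}
        for st in self.stages:
            out["stages"].append({
                "name": st.name,
                "covariates": list(st.covariates),
                "candidates": list(st.candidates),
                "best_subset": list(st.best_subset),
                "min_aic": st.min_aic,
                "n_designs": st.n_designs,
                "n_species": st.n_species,
                "importance": st.importance,
                "near_ties": [[list(s), d] for s, d in st.near_ties],
                "skipped": [[list(t), msg] for t, msg in st.skipped],
                "fit": {
                    "terms": list(st.best_fit.terms),
                    "coef": st.best_fit.params.to_dict(),
                    "se": st.best_fit.bse.to_dict(),
                    "pvalues": st.best_fit.pvalues.to_dict(),
                    "lambda_hat": st.best_fit.lambda_hat,
                    "logL": st.best_fit.logL,
                    "aic": st.best_fit.aic,
                    "r2": st.best_fit.r2,
                    "adj_r2": st.best_fit.adj_r2,
                    "n": st.best_fit.n,
                    "k": st.best_fit.k,
                },
            })
        return out

    def to_json(self, path=None, indent=2) -> str:
        text = json.dumps(self.to_dict(), indent=indent, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def report(self) -> str:
        """Human-readable narrative of the selection outcome."""
        lines = [f"Sequential selection for response {self.response!r}"]
        for st, r2, inc in zip(self.stages, self.cumulative_adj_r2, self.increments):
            chosen = ", ".join(st.best_subset) or "(covariates only)"
            lines.append(
                f"  [{st.name}] best subset: {chosen}  "
                f"(n={st.n_species}, {st.n_designs} designs, "
                f"lambda={st.best_fit.lambda_hat:.3f}, "
                f"adjR2={100 * r2:.2f}%, +{100 * inc:.2f}%)"
            )
            for pred, delta in sorted(st.importance.items(), key=lambda kv: -kv[1]):
                lines.append(f"    dAIC when {pred} omitted: {delta:.2f}")
            ties = [s for s, d in st.near_ties if d > 0]
            if ties:
                lines.append(f"    near-ties (dAIC<2): {ties}")
        return "\n".join(lines)


def sequential_selection(
    data: pd.DataFrame,
    tree,
    categories=DEFAULT_CATEGORIES,
    response: str = "optimum",
    importance_mode: str = "re_search",
    aic_margin: float = 2.0,
) -> SelectionLedger:
    """Run the categories in order, carrying selected predictors forward.

    Stage t's covariates are the union of predictors selected at stages
    < t (always retained; candidate designs never drop them).  Complete
    cases are taken per stage over that stage's candidates plus covariates,
    so n can differ between stages and is recorded per stage.
    """
    stages = []
    covariates: tuple = ()
    cum, inc = [], []
    prev_r2 = 0.0
    for cat in categories:
        cols = [response, *covariates, *cat.predictors]
        sub = data[cols].dropna()
        solver = LambdaGLS(bm_covariance(tree, sub.index))
        res = select_category(
            sub, tree, cat, covariates, response=response,
            importance_mode=importance_mode, aic_margin=aic_margin,
            solver=solver,
        )
        stages.append(res)
        covariates = covariates + res.best_subset
        r2 = res.best_fit.adj_r2
        cum.append(float(r2))
        inc.append(float(r2 - prev_r2))
        prev_r2 = r2
    return SelectionLedger(response=response, stages=stages,
                           cumulative_adj_r2=cum, increments=inc)
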