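"""Huisman-Olff-Fresco (HOF) species response curves along elevation.

The five classical model shapes, built from products of logistic terms with
ceiling M (fixed at 1 for presence/absence data, the intercept absorbing
prevalence) and x the elevation standardized to [0, 1]:

    I   flat      y = M / (1 + e^a)
    II  monotone  y = M / (1 + e^(a+bx))
    III plateau   y = M / [(1 + e^(a+bx)) (1 + e^c)]
    IV  symmetric y = M / [(1 + e^(a+bx)) (1 + e^(c-bx))]
    V   skewed    y = M / [(1 + e^(a+bx)) (1 + e^(c-dx))]

Each model is fitted by maximizing the Bernoulli log-likelihood with
multi-start L-BFGS-B (deterministic start grid, warm starts from the best
simpler model so the nested log-likelihood ordering holds).  Model choice is
by AIC with a parsimony margin: among models within ``aic_margin`` (default
2, the conventional "equivalent support" band) of the minimum AIC, the one
with fewest parameters wins; a margin of 0 gives the strict lowest-AIC rule
with ties going to the simpler model.  Without the margin, a spurious
1-degree-of-freedom likelihood gain on featureless data beats the AIC
penalty with probability P(chi2_1 > 2) ~ 0.16, so the flat model would be
rejected far too often.  The
species' elevational optimum is the point of maximum response: closed form
(c - a) / (2b) for model IV, a numeric argmax for model V, the gradient
boundary for monotone fits (flagged), undefined for model I.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "HOFFit", "MODEL_PARAMS", "hof_response", "fit_hof", "fit_hof_models",
    "extract_optimum", "extract_range_limits",
]

MODEL_PARAMS = {"I": ("a",), "II": ("a", "b"), "III": ("a", "b", "c"),
                "IV": ("a", "b", "c"), "V": ("a", "b", "c", "d")}

_PCLIP = 1e-10


@dataclass
class HOFFit:
    """A fitted HOF response model for one species."""

    species: str
    model_type: str
    params: dict
    M: float
    logL: float
    aic: float
    n_records: int
    elev_min: float  # observed gradient span (m), used for back-transform
    elev_max: float
    optimum: float | None = None
    range_min: float | None = None
    range_max: float | None = None
    flags: tuple = ()

    def response(self, elevation) -> np.ndarray:
        """Predicted occurrence probability at elevation (metres)."""
        x = (np.asarray(elevation, dtype=float) - self.elev_min) / (
            self.elev_max - self.elev_min
        )
        return hof_response(x, self.model_type, self.params, self.M)


def hof_response(x, model_type: str, params: dict, M: float = 1.0):
    """Evaluate a HOF curve at standardized elevation x; returns values in (0, M]."""
    if not 0.0 < M <= 1.0:
        raise ValueError(f"M must be in (0, 1], got {M}")
    need = MODEL_PARAMS.get(model_type)
    if need is None:
        raise ValueError(f"unknown model type {model_type!r}")
    missing = [p for p in need if p not in params]
    if missing:
        raise ValueError(f"model {model_type} missing parameters {missing}")
    x = np.asarray(x, dtype=float)
    a = params["a"]
    if model_type == "I":
        return np.full_like(x, M / (1.0 + math.exp(a)))
    b = params["b"]
    u = a + b * x
    f1 = 1.0 / (1.0 + np.exp(np.clip(u, -700, 700)))
    if model_type == "II":
        return M * f1
    c = params["c"]
    if model_type == "III":
        return M * f1 / (1.0 + math.exp(min(c, 700)))
    d = b if model_type == "IV" else params["d"]
    v = c - d * x
    f2 = 1.0 / (1.0 + np.exp(np.clip(v, -700, 700)))
    return M * f1 * f2


def _nll_and_grad(theta, x, y, model_type, M):
    """Bernoulli negative log-likelihood and analytic gradient."""
    n = x.size
    a = theta[0]
    if model_type == "I":
        u = np.full(n, a)
        b = 0.0
    else:
        b = theta[1]
        u = a + b * x
    f1 = 1.0 / (1.0 + np.exp(np.clip(u, -700, 700)))
    if model_type in ("I", "II"):
        f2 = np.ones(n)
        v = None
    elif model_type == "III":
        v = np.full(n, theta[2])
        f2 = 1.0 / (1.0 + np.exp(np.clip(v, -700, 700)))
    else:
        d = b if model_type == "IV" else theta[3]
        v = theta[2] - d * x
        f2 = 1.0 / (1.0 + np.exp(np.clip(v, -700, 700)))
    p = np.clip(M * f1 * f2, _PCLIP, 1.0 - _PCLIP)
    nll = -np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p))

    # dNLL/dp * dp/d{u,v}; dp/du = -p (1 - f1), dp/dv = -p (1 - f2)
    w = (p - y) / (p * (1.0 - p))
    gu = w * (-p * (1.0 - f1))
    grad = np.zeros_like(theta)
    grad[0] = gu.sum()
    if model_type != "I":
        grad[1] = (gu * x).sum()
    if model_type in ("III", "IV", "V"):
        gv = w * (-p * (1.0 - f2))
        grad[2] = gv.sum()
        if model_type == "IV":
            grad[1] += (gv * -x).sum()
        elif model_type == "V":
            grad[3] = (gv * -x).sum()
    return nll, grad


_BOUND_A = (-30.0, 30.0)
_BOUND_B = (-500.0, 500.0)


def _fit_model(x, y, model_type, starts):
    bounds = {"I": [_BOUND_A], "II": [_BOUND_A, _BOUND_B],
              "III": [_BOUND_A, _BOUND_B, _BOUND_A],
              "IV": [_BOUND_A, _BOUND_B, _BOUND_A],
              "V": [_BOUND_A, _BOUND_B, _BOUND_A, _BOUND_B]}[model_type]
    best = None
    for s in starts:
        theta0 = np.clip(np.asarray(s, dtype=float),
                         [b[0] for b in bounds], [b[1] for b in bounds])
        res = optimize.minimize(
            _nll_and_grad, theta0, args=(x, y, model_type, 1.0),
            jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best


def fit_hof_models(x: np.ndarray, y: np.ndarray) -> dict:
    """ML fits of all five models on standardized data.

    Returns {model_type: (params dict, logL)}.  Start grids are
    deterministic; each more complex model is warm-started from the best
    simpler one, so maximized log-likelihoods respect the nesting order
    (V >= IV >= II >= I, III >= II) up to optimizer tolerance.
    """
    n = x.size
    prev = float(y.mean())
    if prev in (0.0, 1.0):
        raise ValueError("fit_hof_models needs both presences and absences")
    a_prev = math.log(1.0 / prev - 1.0)

    fits = {}
    # model I: closed-form MLE
    logL_I = float(n * (prev * math.log(prev) + (1 - prev) * math.log(1 - prev)))
    fits["I"] = ({"a": a_prev}, logL_I)

    a_grid = (-2.0, 0.0, 2.0)
    b_grid = (-20.0, -5.0, 5.0, 20.0)
    starts_II = [(a_prev, 0.0)] + [(a, b) for a in a_grid for b in b_grid]
    res_II = _fit_model(x, y, "II", starts_II)
    fits["II"] = ({"a": res_II.x[0], "b": res_II.x[1]}, -res_II.fun)

    aII, bII = res_II.x
    starts_III = [(aII, bII, -20.0)] + [
        (a, b, c) for a in a_grid for b in b_grid for c in (a, -a)
    ]
    res_III = _fit_model(x, y, "III", starts_III)
    fits["III"] = (dict(zip("abc", res_III.x)), -res_III.fun)

    starts_IV = [(aII, bII, -20.0)] + [
        (a, b, c) for a in a_grid for b in b_grid for c in (a, -a)
    ]
    res_IV = _fit_model(x, y, "IV", starts_IV)
    fits["IV"] = (dict(zip("abc", res_IV.x)), -res_IV.fun)

    aIV, bIV, cIV = res_IV.x
    starts_V = [(aIV, bIV, cIV, bIV)] + [
        (a, b, a, b) for a in a_grid for b in b_grid
    ]
    res_V = _fit_model(x, y, "V", starts_V)
    fits["V"] = (dict(zip("abcd", res_V.x)), -res_V.fun)
    return fits


def fit_hof(
    records,
    species: str | None = None,
    threshold_frac: float = 0.05,
    min_records: int = 30,
    aic_margin: float = 2.0,
) -> HOFFit:
    """Fit the HOF hierarchy to one species' presence/absence records.

    Parameters
    ----------
    records : pandas.DataFrame with columns ``elevation_m`` and ``present``,
        or a (elevations, presences) tuple of arrays.
    species : species label for the report (taken from a ``species`` column
        when present).
    threshold_frac : fraction of the peak response defining range limits.
    aic_margin : parsimony band; the fewest-parameter model within this many
        AIC units of the minimum is selected (0 = strict lowest AIC).

    Returns the selected fit with the optimum and range limits
    back-transformed to metres.
    """
    if isinstance(records, pd.DataFrame):
        elev = records["elevation_m"].to_numpy(dtype=float)
        pres = records["present"].to_numpy(dtype=float)
        if species is None and "species" in records.columns:
            uniq = records["species"].unique()
            if len(uniq) == 1:
                species = str(uniq[0])
    else:
        elev, pres = (np.asarray(v, dtype=float) for v in records)
    species = species or "species"
    n = elev.size
    if n < min_records:
        raise ValueError(
            f"insufficient data for {species}: {n} records (< {min_records})"
        )
    if not set(np.unique(pres)) <= {0.0, 1.0}:
        raise ValueError("presence must be binary 0/1")

    lo, hi = float(elev.min()), float(elev.max())
    if hi <= lo:
        raise ValueError("degenerate elevation span")
    x = (elev - lo) / (hi - lo)
    y = pres

    prev = y.mean()
    if prev in (0.0, 1.0):
        # all-absent or all-present: flat model, degenerate
        p_hat = min(max(prev, _PCLIP), 1.0 - _PCLIP)
        a_hat = math.log(1.0 / p_hat - 1.0)
        logL = float(n * (p_hat * math.log(p_hat) + (1 - p_hat) * math.log(1 - p_hat))) if 0 < prev < 1 else 0.0
        fit = HOFFit(species, "I", {"a": a_hat}, 1.0, logL,
                     -2.0 * logL + 2.0, n, lo, hi, flags=("degenerate",))
        return fit

    fits = fit_hof_models(x, y)

    aics = {mt: -2.0 * fits[mt][1] + 2.0 * len(MODEL_PARAMS[mt]) for mt in fits}
    min_aic = min(aics.values())
    # simplest model with equivalent support; hierarchy order breaks k-ties
    best_type = next(mt for mt in ("I", "II", "III", "IV", "V")
                     if aics[mt] <= min_aic + aic_margin + 1e-9)
    best_aic = aics[best_type]
    params, logL = fits[best_type]

    fit = HOFFit(species, best_type, params, 1.0, float(logL), float(best_aic),
                 n, lo, hi)
    fit.optimum, opt_flags = _optimum(fit)
    fit.flags = fit.flags + opt_flags
    fit.range_min, fit.range_max = extract_range_limits(fit, threshold_frac)
    return fit


def _std_to_m(fit: HOFFit, x: float) -> float:
    return fit.elev_min + x * (fit.elev_max - fit.elev_min)


def _optimum(fit: HOFFit):
    """Optimum in metres plus flags; None when undefined (model I)."""
    p = fit.params
    if fit.model_type == "I":
        return None, ()
    if fit.model_type in ("II", "III"):
        b = p["b"]
        if b == 0.0:
            return None, ("flat_monotone",)
        # response M/(1+e^(a+bx)) decreases in x when b > 0
        x_star = 0.0 if b > 0 else 1.0
        return _std_to_m(fit, x_star), ("boundary",)
    if fit.model_type == "IV":
        b = p["b"]
        if b == 0.0:
            return None, ("flat_unimodal",)
        x_star = (p["c"] - p["a"]) / (2.0 * b)
        flags = ()
        if not 0.0 <= x_star <= 1.0:
            x_star = min(max(x_star, 0.0), 1.0)
            flags = ("optimum_at_boundary",)
        return _std_to_m(fit, x_star), flags
    # model V: 1-m grid argmax refined by golden section
    span = fit.elev_max - fit.elev_min
    grid = np.linspace(0.0, 1.0, max(int(round(span)) + 1, 101))
    vals = hof_response(grid, fit.model_type, p, fit.M)
    i = int(np.argmax(vals))
    a = grid[max(i - 1, 0)]
    b_ = grid[min(i + 1, grid.size - 1)]
    gold = (math.sqrt(5.0) - 1.0) / 2.0
    x1 = b_ - gold * (b_ - a)
    x2 = a + gold * (b_ - a)
    f1 = float(hof_response(x1, fit.model_type, p, fit.M))
    f2 = float(hof_response(x2, fit.model_type, p, fit.M))
    while (b_ - a) * span > 1e-4:
        if f1 < f2:
            a, x1, f1 = x1, x2, f2
            x2 = a + gold * (b_ - a)
            f2 = float(hof_response(x2, fit.model_type, p, fit.M))
        else:
            b_, x2, f2 = x2, x1, f1
            x1 = b_ - gold * (b_ - a)
            f1 = float(hof_response(x1, fit.model_type, p, fit.M))
    x_star = 0.5 * (a + b_)
    flags = ()
    if i in (0, grid.size - 1):
        flags = ("boundary",)
    return _std_to_m(fit, x_star), flags


def extract_optimum(fit: HOFFit):
    """Elevation (m) of maximum response, or None when undefined (model I)."""
    return _optimum(fit)[0]


def extract_range_limits(fit: HOFFit, threshold_frac: float = 0.05):
    """Outermost elevations where the response equals threshold_frac x peak.

    Clipped to the observed gradient; for monotone fits one side is the
    gradient edge.  Model I (flat) has undefined limits.
    """
    if not 0.0 < threshold_frac < 1.0:
        raise ValueError("threshold_frac must be in (0, 1)")
    if fit.model_type == "I":
        return None, None
    span = fit.elev_max - fit.elev_min
    grid = np.linspace(0.0, 1.0, max(int(round(span)) + 1, 1001))
    vals = hof_response(grid, fit.model_type, fit.params, fit.M)
    peak = float(vals.max())
    thr = threshold_frac * peak
    above = vals >= thr
    idx = np.nonzero(above)[0]
    lo_x, hi_x = grid[idx[0]], grid[idx[-1]]

    def refine(x_out, x_in):
        # bisect the crossing between an outside and an inside point
        f = lambda t: float(hof_response(t, fit.model_type, fit.params, fit.M)) - thr
        if f(x_out) >= 0:  # already at gradient edge
            return x_out
        a, b = x_out, x_in
        for _ in range(60):
            m = 0.5 * (a + b)
            if f(m) < 0:
                a = m
            else:
                b = m
        return 0.5 * (a + b)

    lo = refine(grid[max(idx[0] - 1, 0)], lo_x) if idx[0] > 0 else 0.0
    hi = refine(grid[min(idx[-1] + 1, grid.size - 1)], hi_x) if idx[-1] < grid.size - 1 else 1.0
    return _std_to_m(fit, lo), _std_to_m(fit, hi)


def fit_all_species(occurrences: pd.DataFrame, threshold_frac: float = 0.05,
                    min_records: int = 30, aic_margin: float = 2.0) -> pd.DataFrame:
    """Fit HOF models per species of an occurrence table; returns the optima
    table (species, model_type, optimum_m, min_m, max_m, aic, n_records, flags)."""
    rows = []
    for sp, grp in occurrences.groupby("species", sort=True):
        try:
            fit = fit_hof(grp, species=str(sp), threshold_frac=threshold_frac,
                          min_records=min_records, aic_margin=aic_margin)
        except ValueError as exc:
            rows.append({"species": sp, "model_type": None, "optimum_m": np.nan,
                         "min_m": np.nan, "max_m": np.nan, "aic": np.nan,
                         "n_records": len(grp), "flags": f"error:{exc}"})
            continue
        rows.append({
            "species": sp, "model_type": fit.model_type,
            "optimum_m": fit.optimum if fit.optimum is not None else np.nan,
            "min_m": fit.range_min if fit.range_min is not None else np.nan,
            "max_m": fit.range_max if fit.range_max is not None else np.nan,
            "aic": fit.aic, "n_records": fit.n_records,
            "flags": ";".join(fit.flags),
        })
    return pd.DataFrame(rows)
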