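"""Importance analysis of sweep results by range-normalised linear regression.

Each swept parameter and the response (J_RMSE) are normalised to [0, 1] by
subtracting the minimum and dividing by the range, so a main-effect
coefficient is the fractional change in performance from moving that
parameter across its full tested range (holding everything else fixed).
Pairwise interactions are products of the already-normalised predictors.
Coefficient magnitude is the term's "importance"; the conventional threshold
for first-order importance is 0.1.

A separate univariate regression relates performance to mean coactivation
across the sweep (J_RMSE / max(J_RMSE) against the raw coactivation mean).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "PARAMS",
    "RegressionReport",
    "normalize_range",
    "fit_importance",
    "coactivation_regression",
]

PARAMS = ("alpha_d", "c1", "alpha_a", "vmax", "Fmax")

#: Term order used in reports: intercept, main effects, pairwise interactions.
ALL_TERMS = ("Intercept",) + PARAMS + (
    "alpha_d:c1", "alpha_d:alpha_a", "alpha_d:vmax", "alpha_d:Fmax",
    "c1:alpha_a", "c1:vmax", "c1:Fmax",
    "alpha_a:vmax", "alpha_a:Fmax", "vmax:Fmax",
)

FIRST_ORDER_TERMS = ("Intercept", "alpha_a", "vmax", "Fmax", "alpha_d:c1")
INDEPENDENT_TERMS = ("Intercept", "alpha_a", "vmax", "Fmax")

_VARIANTS = {
    "all_terms": ALL_TERMS,
    "first_order_only": FIRST_ORDER_TERMS,
    "first_order_independent_only": INDEPENDENT_TERMS,
}


def normalize_range(x):
    """(x - min) / (max - min); errors on a constant vector."""
    x = np.asarray(x, dtype=float)
    rng = x.max() - x.min()
    if rng == 0:
        raise ValueError("cannot range-normalize a constant vector")
    return (x - x.min()) / rng


@dataclass
class RegressionReport:
    """Fitted importance model: term -> coefficient, plus fit quality."""

    variant: str
    coefficients: dict[str, float]
    r_squared: float
    response: str = "J_RMSE"

    def important_terms(self, threshold: float = 0.1) -> dict[str, float]:
        return {k: v for k, v in self.coefficients.items()
                if abs(v) > threshold}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": list(self.coefficients),
            "importance": list(self.coefficients.values()),
        })


def _design(table: pd.DataFrame, terms) -> pd.DataFrame:
    norm = {p: normalize_range(table[p].to_numpy()) for p in PARAMS}
    cols = {}
    for term in terms:
        if term == "Intercept":
            cols[term] = np.ones(len(table))
        elif ":" in term:
            a, b = term.split(":")
            cols[term] = norm[a] * norm[b]
        else:
            cols[term] = norm[term]
    return pd.DataFrame(cols, index=table.index)


def fit_importance(table: pd.DataFrame, variant: str = "all_terms",
                   response: str = "J_RMSE",
                   renormalize_products: bool = False,
                   normalize_response: bool = True) -> RegressionReport:
    """OLS of range-normalised response on range-normalised predictors.

    ``variant`` selects the term set: 'all_terms' (intercept + 5 mains + 10
    pairwise products), 'first_order_only' (intercept, alpha_a, vmax, Fmax
    and the alpha_d:c1 interaction) or 'first_order_independent_only' (the
    same without the interaction).  ``renormalize_products`` re-scales each
    product column back to [0, 1] (off by default: on a full factorial whose
    normalised levels include 0 and 1 the products already span [0, 1]).
    """
    if variant not in _VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    X = _design(table, _VARIANTS[variant])
    if renormalize_products:
        for term in X.columns:
            if ":" in term:
                X[term] = normalize_range(X[term].to_numpy())
    y = table[response].to_numpy(dtype=float)
    if normalize_response:
        y = normalize_range(y)
    model = sm.OLS(y, X)
    fit = model.fit()
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    coeffs = {term: float(fit.params[term]) for term in X.columns}
    return RegressionReport(variant=variant, coefficients=coeffs,
                            r_squared=float(fit.rsquared), response=response)


def coactivation_regression(table: pd.DataFrame):
    """OLS of J_RMSE / max(J_RMSE) on mean coactivation.

    Returns (slope, intercept, r_squared, p_value).  A negative slope means
    higher coactivation goes with better performance (lower error).
    """
    y = table["J_RMSE"].to_numpy(dtype=float)
    if y.max() == y.min():
        raise ValueError("response has zero variance")
    y = y / y.max()
    x = table["a_c_mean"].to_numpy(dtype=float)
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    return (float(fit.params[1]), float(fit.params[0]),
            float(fit.rsquared), float(fit.pvalues[1]))
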