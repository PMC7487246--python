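"""Classical fixed-effects statistics used throughout the pipeline.

Linear models are ordinary least squares with reference-level dummy
coding (first level alphabetically) for categorical terms, interactions
as products of coded columns, and a Gaussian log-likelihood (ML variance
RSS/n) for information criteria.  Also: AICc, nested-model F tests,
a focal-term marginal R², and the exact two-sided binomial test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
import statsmodels.api as sm


@dataclass
class LinearFit:
    """An OLS fit with the bookkeeping needed for model comparison."""

    response: str
    terms: tuple[str, ...]
    coef: pd.Series
    n: int
    k: int                      # parameter count incl. intercept
    rss: float
    r_squared: float
    log_likelihood: float       # Gaussian, ML variance RSS/n
    term_cols: dict[str, list[str]] = field(repr=False, default_factory=dict)
    design: pd.DataFrame = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)
    pvalues: pd.Series = field(repr=False, default=None)

    def predict(self, design: pd.DataFrame | None = None) -> np.ndarray:
        X = self.design if design is None else design[self.design.columns]
        return X.to_numpy(dtype=float) @ self.coef.to_numpy()


def _is_categorical(series: pd.Series) -> bool:
    return not pd.api.types.is_numeric_dtype(series)


def _code_factor(data: pd.DataFrame, name: str) -> pd.DataFrame:
    """Code one variable: identity for numeric, treatment dummies otherwise.

    Reference level = first level alphabetically (dropped).
    """
    col = data[name]
    if _is_categorical(col):
        levels = sorted(col.astype(str).unique())
        out = pd.DataFrame(index=data.index)
        for lev in levels[1:]:
            out[f"{name}[{lev}]"] = (col.astype(str) == lev).astype(float)
        return out
    return pd.DataFrame({name: col.astype(float)})


def _code_term(data: pd.DataFrame, term: str) -> pd.DataFrame:
    """Code a term; ``a:b`` interactions are products of coded columns."""
    parts = term.split(":")
    coded = [_code_factor(data, p.strip()) for p in parts]
    out = coded[0]
    for nxt in coded[1:]:
        prod = pd.DataFrame(index=data.index)
        for c1 in out.columns:
            for c2 in nxt.columns:
                prod[f"{c1}:{c2}"] = out[c1] * nxt[c2]
        out = prod
    return out


def build_design(data: pd.DataFrame, terms: list[str] | tuple[str, ...]
                 ) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Dummy-coded design matrix with intercept; returns (X, term -> columns)."""
    X = pd.DataFrame({"Intercept": np.ones(len(data))}, index=data.index)
    term_cols = {"Intercept": ["Intercept"]}
    for term in terms:
        coded = _code_term(data, term)
        for c in coded.columns:
            if c in X.columns:
                raise ValueError(f"duplicate design column {c!r} from {term!r}")
            X[c] = coded[c]
        term_cols[term] = list(coded.columns)
    return X, term_cols


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Columns beyond the numerical rank, by pivoted QR."""
    _, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    return [names[i] for i in sorted(piv[rank:])]


def fit_linear(data: pd.DataFrame, response: str,
               terms: list[str] | tuple[str, ...]) -> LinearFit:
    """Fit ``response ~ intercept + terms`` by ordinary least squares.

    Raises ``ValueError`` naming the aliased design columns if the
    dummy-coded design is rank deficient.
    """
    if response not in data.columns:
        raise ValueError(f"response {response!r} not in data")
    clean = data.dropna(subset=[response]).reset_index(drop=True)
    y = clean[response].to_numpy(dtype=float)
    X, term_cols = build_design(clean, terms)
    Xv = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        aliased = _aliased_columns(Xv, list(X.columns))
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    res = sm.OLS(y, Xv).fit()
    coef = pd.Series(res.params, index=X.columns)
    return LinearFit(
        response=response,
        terms=tuple(terms),
        coef=coef,
        n=len(y),
        k=Xv.shape[1],
        rss=float(res.ssr),
        r_squared=float(res.rsquared),
        log_likelihood=float(res.llf),
        term_cols=term_cols,
        design=X,
        y=y,
        pvalues=pd.Series(res.pvalues, index=X.columns),
    )


def aicc(fit: LinearFit) -> float:
    """Small-sample corrected AIC: −2·logL + 2k + 2k(k+1)/(n − k − 1)."""
    n, k = fit.n, fit.k
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined: n={n} <= k+1={k + 1}")
    return -2.0 * fit.log_likelihood + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def compare_nested(null_fit: LinearFit, full_fit: LinearFit
                   ) -> tuple[float, int, int, float]:
    """Extra-sum-of-squares F test of a nested pair of OLS fits.

    Returns ``(F, df1, df2, p)`` with
    F = ((RSS0 − RSS1)/Δk) / (RSS1/(n − k1)).
    """
    if not set(null_fit.terms) <= set(full_fit.terms):
        raise ValueError("models are not nested (null terms not a subset)")
    if null_fit.n != full_fit.n or null_fit.response != full_fit.response:
        raise ValueError("fits are not on the same data/response")
    df1 = full_fit.k - null_fit.k
    if df1 <= 0:
        raise ValueError("full model adds no parameters over the null")
    df2 = full_fit.n - full_fit.k
    f_stat = ((null_fit.rss - full_fit.rss) / df1) / (full_fit.rss / df2)
    p = float(scipy.stats.f.sf(f_stat, df1, df2))
    return float(f_stat), df1, df2, p


def marginal_r2(fit: LinearFit, focal_term: str) -> float:
    """Share of response variance attributable to one fixed term.

    Computed as var(X_focal · β_focal) / var(y) — an all-fixed-effects
    analogue of the marginal R² used for mixed models.  Equals the
    ordinary R² for a single-predictor model.
    """
    if focal_term not in fit.term_cols:
        raise ValueError(f"term {focal_term!r} not in model {fit.terms}")
    cols = fit.term_cols[focal_term]
    comp = fit.design[cols].to_numpy(dtype=float) @ fit.coef[cols].to_numpy()
    var_y = float(np.var(fit.y))
    if var_y == 0:
        raise ValueError("response has zero variance")
    return float(np.var(comp) / var_y)


def exact_binomial(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial test p-value.

    Two-sided by the minimum-likelihood method: the sum of Binomial(n, p0)
    probabilities over all outcomes no more likely than the observed one.
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"invalid binomial outcome k={k}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be in (0, 1)")
    return float(scipy.stats.binomtest(int(k), int(n), p0).pvalue)
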