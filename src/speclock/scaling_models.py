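"""Statistical models linking cline width to divergence time.

Three layers:

* log-space Pearson correlation between width ``w`` and divergence time
  ``T`` (both spanning orders of magnitude, hence the log transform);
* the tension-zone selection coefficient ``s = 8 sigma^2 / w^2`` obtained
  by inverting ``w = sigma * sqrt(8 / s)``, an ad-hoc dispersal correction
  of width;
* gamma GLMs with a log link for width on {T, dispersal category D,
  taxonomic group G}, compared over an exhaustively enumerated candidate
  set by AICc weights, with likelihood-ratio (ANOVA-like) tests on the
  best model's terms.

The gamma shape parameter is profiled out by maximum likelihood given the
fitted mean structure, and counted as a parameter in AICc.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import optimize, special, stats

from .records import DISPERSAL_CATEGORIES, AnalysisRow, SpeclockError

__all__ = [
    "CorrelationResult",
    "SelectionEstimate",
    "GlmFit",
    "pearson_log",
    "selection_coefficient",
    "enumerate_candidates",
    "formula_for",
    "rows_to_frame",
    "fit_gamma_glm",
    "akaike_weights",
    "anova_lr",
]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p_value: float
    scope: str = "all"


def pearson_log(
    widths: Sequence[float],
    times: Sequence[float],
    scope: str = "all",
    transform: str = "log",
) -> CorrelationResult:
    """Pearson correlation of (log w, log T).

    The correlation coefficient is invariant to the base of the logarithm
    and to positive rescaling of either variable.  The two-sided p-value
    comes from the t reference distribution with n - 2 df,
    t = r * sqrt((n - 2) / (1 - r^2)).
    """
    w = np.asarray(widths, dtype=float)
    t = np.asarray(times, dtype=float)
    if w.size != t.size or w.size < 3:
        raise SpeclockError("pearson_log requires n >= 3 paired observations")
    if transform == "log":
        if np.any(w <= 0) or np.any(t <= 0):
            raise SpeclockError("log transform requires strictly positive values")
        w, t = np.log(w), np.log(t)
    if np.ptp(w) == 0 or np.ptp(t) == 0:
        raise SpeclockError("undefined correlation: zero variance in a coordinate")
    r, p = stats.pearsonr(w, t)
    return CorrelationResult(r=float(r), n=int(w.size), p_value=float(p), scope=scope)


@dataclass(frozen=True)
class SelectionEstimate:
    pair_id: str
    s: float
    sigma_used: float


def selection_coefficient(
    width_km: float, dispersal_category: str, pair_id: str = "?"
) -> SelectionEstimate:
    """Selection against hybrids from the tension-zone width relation.

    A tension zone balances dispersal into the zone against selection on
    hybrids, giving w = sigma * sqrt(8 / s); inverted, s = 8 sigma^2 / w^2.
    sigma is the representative (geometric-midpoint) dispersal of the
    pair's category.
    """
    cat = DISPERSAL_CATEGORIES.get(dispersal_category)
    if cat is None:
        raise SpeclockError(
            f"pair {pair_id}: dispersal category {dispersal_category!r} cannot "
            "be resolved to a representative sigma"
        )
    if not width_km > 0:
        raise SpeclockError(f"pair {pair_id}: width must be positive")
    sigma = cat.representative_sigma
    return SelectionEstimate(pair_id=pair_id, s=8.0 * sigma**2 / width_km**2, sigma_used=sigma)


# --- candidate enumeration -------------------------------------------------

_MAIN_ORDER = ("T", "D", "G")


def enumerate_candidates(
    predictors: Sequence[str] = _MAIN_ORDER, interactions: bool = False
) -> list[tuple[str, ...]]:
    """All candidate term sets over the predictors, in canonical order.

    Without interactions: every main-effect subset (2^p formulas, the
    empty tuple being the intercept-only model).  With pairwise
    interactions: every term set obeying marginality — an interaction
    ``X:Y`` only appears alongside both mains — which for three
    predictors yields 18 formulas.  Ordered by size then lexicographically
    in main-effect order.
    """
    preds = [p for p in _MAIN_ORDER if p in predictors]
    if not preds:
        raise SpeclockError("at least one predictor required")
    out: list[tuple[str, ...]] = []
    for k in range(len(preds) + 1):
        for mains in itertools.combinations(preds, k):
            pair_terms = [f"{a}:{b}" for a, b in itertools.combinations(mains, 2)]
            if interactions:
                for j in range(len(pair_terms) + 1):
                    for inter in itertools.combinations(pair_terms, j):
                        out.append(tuple(mains) + inter)
            else:
                out.append(tuple(mains))
    # canonical order: number of terms, then positional order
    def key(terms: tuple[str, ...]):
        return (len(terms), [(_MAIN_ORDER.index(t[0]), t) for t in terms])

    return sorted(set(out), key=key)


_TERM_TO_PATSY = {
    "T": "{T}",
    "D": "C(dispersal_category)",
    "G": "C(group)",
}


def formula_for(terms: Sequence[str], time_scale: str = "log") -> str:
    """Translate a term set like ("T", "D", "T:D") into a patsy formula."""
    tvar = "log_time" if time_scale == "log" else "divergence_time_ma"

    def tr(term: str) -> str:
        return ":".join(_TERM_TO_PATSY[p].format(T=tvar) for p in term.split(":"))

    rhs = " + ".join(tr(t) for t in terms) if terms else "1"
    return f"width_km ~ {rhs}"


def rows_to_frame(rows: Sequence[AnalysisRow]) -> pd.DataFrame:
    """Analysis rows as a DataFrame with the derived ``log_time`` column."""
    df = pd.DataFrame(
        {
            "pair_id": [r.pair_id for r in rows],
            "category_id": [r.category_id for r in rows],
            "width_km": [r.width_km for r in rows],
            "divergence_time_ma": [r.divergence_time_ma for r in rows],
            "group": [r.group for r in rows],
            "dispersal_category": [r.dispersal_category for r in rows],
            "n_markers_max": [r.n_markers_max for r in rows],
        }
    )
    df["log_time"] = np.log(df["divergence_time_ma"])
    return df


# --- gamma GLM -------------------------------------------------------------


@dataclass
class GlmFit:
    terms: tuple[str, ...]
    formula: str
    coefficients: pd.Series
    standard_errors: pd.Series
    shape: float
    loglik: float
    k: int  # parameters incl. intercept and shape
    n: int
    aicc: float
    converged: bool
    akaike_weight: Optional[float] = None
    result: object = field(default=None, repr=False)


def _gamma_profile_loglik(y: np.ndarray, mu: np.ndarray) -> tuple[float, float]:
    """Profile-ML gamma shape and log-likelihood given fitted means.

    Solves d/d(alpha) sum log f(y_i; alpha, mu_i) = 0, i.e.
    log(alpha) - digamma(alpha) = mean(log mu - log y + y/mu - 1).
    """
    c = float(np.mean(np.log(mu) - np.log(y) + y / mu - 1.0))
    if c <= 1e-12:
        # (near-)perfect fit: likelihood unbounded in the shape; cap it
        alpha = 1e12
    else:
        f = lambda a: math.log(a) - special.digamma(a) - c
        alpha = optimize.brentq(f, 1e-10, 1e12)
    ll = float(
        np.sum(
            alpha * np.log(alpha / mu)
            + (alpha - 1.0) * np.log(y)
            - alpha * y / mu
            - special.gammaln(alpha)
        )
    )
    return alpha, ll


def aicc_from_loglik(loglik: float, k: int, n: int) -> float:
    """AICc = -2 loglik + 2k + 2k(k+1)/(n-k-1); undefined when n <= k+1."""
    if n <= k + 1:
        raise SpeclockError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def fit_gamma_glm(
    terms: Sequence[str] | str,
    rows: Sequence[AnalysisRow] | pd.DataFrame,
    time_scale: str = "log",
    tol: float = 1e-8,
    maxiter: int = 100,
) -> GlmFit:
    """Fit a gamma GLM with log link by IRLS and score it by AICc.

    ``terms`` is either a term set from :func:`enumerate_candidates` or a
    ready patsy formula string.  The mean structure is fitted by IRLS
    (relative deviance tolerance ``tol``, at most ``maxiter`` iterations);
    the gamma shape is then profiled by ML and counted in ``k``.
    """
    df = rows if isinstance(rows, pd.DataFrame) else rows_to_frame(rows)
    if np.any(df["width_km"].to_numpy() <= 0):
        raise SpeclockError("gamma GLM requires strictly positive response")
    if isinstance(terms, str):
        formula, term_tuple = terms, (terms,)
    else:
        term_tuple = tuple(terms)
        formula = formula_for(term_tuple, time_scale=time_scale)
    model = smf.glm(formula, data=df, family=sm.families.Gamma(link=sm.families.links.Log()))
    res = model.fit(maxiter=maxiter, tol=tol, scale=None)
    y = model.endog
    mu = np.asarray(res.fittedvalues)
    shape, ll = _gamma_profile_loglik(y, mu)
    k = len(res.params) + 1  # + gamma shape
    n = int(len(y))
    return GlmFit(
        terms=term_tuple,
        formula=formula,
        coefficients=res.params,
        standard_errors=res.bse,
        shape=shape,
        loglik=ll,
        k=k,
        n=n,
        aicc=aicc_from_loglik(ll, k, n),
        converged=bool(getattr(res, "converged", True)),
        result=res,
    )


def akaike_weights(fits: Sequence[GlmFit]) -> list[GlmFit]:
    """Attach AICc (Akaike) weights; non-converged fits are excluded.

    w_i = exp(-Delta_i / 2) / sum_j exp(-Delta_j / 2) with
    Delta_i = AICc_i - min AICc.  Returns fits sorted by ascending AICc
    (best model first).
    """
    ok = [f for f in fits if f.converged]
    if not ok:
        raise SpeclockError("no converged fits to weight")
    if len(ok) < len(fits):
        import warnings

        warnings.warn(f"{len(fits) - len(ok)} non-converged fit(s) excluded from weights")
    aiccs = np.array([f.aicc for f in ok])
    delta = aiccs - aiccs.min()
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    for f, wi in zip(ok, w):
        f.akaike_weight = float(wi)
    return sorted(ok, key=lambda f: f.aicc)


def anova_lr(
    best: GlmFit,
    rows: Sequence[AnalysisRow] | pd.DataFrame,
    time_scale: str = "log",
    typ: str = "II",
) -> pd.DataFrame:
    """Type-II likelihood-ratio tests for each term of the best model.

    For a main effect, any interactions containing it are removed from
    both the comparison and the reduced model (marginality); for an
    interaction the comparison model is the best model itself.  The
    statistic is 2 * (loglik_full - loglik_reduced), chi-square with df =
    number of mean parameters removed.  ``typ="III"`` drops each term from
    the full model directly.
    """
    df = rows if isinstance(rows, pd.DataFrame) else rows_to_frame(rows)
    records = []
    for term in best.terms:
        if typ == "II" and ":" not in term:
            comp_terms = tuple(
                t for t in best.terms if not (":" in t and term in t.split(":"))
            )
        else:
            comp_terms = best.terms
        red_terms = tuple(t for t in comp_terms if t != term)
        full = (
            best
            if comp_terms == best.terms
            else fit_gamma_glm(comp_terms, df, time_scale=time_scale)
        )
        reduced = fit_gamma_glm(red_terms, df, time_scale=time_scale)
        lr = max(0.0, 2.0 * (full.loglik - reduced.loglik))
        ddf = full.k - reduced.k
        p = float(stats.chi2.sf(lr, ddf)) if ddf > 0 else float("nan")
        records.append({"term": term, "df": ddf, "lr_chisq": lr, "p_value": p})
    return pd.DataFrame(records)
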