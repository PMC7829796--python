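"""Linear response models, slope-ratio efficacy and simple correlations.

Each per-plant response (dry weight, cumulative incident light, leaf
length, leaf width) is modeled as a linear function of the far-red and
PPFD photon flux densities at the plant position, starting from the full
candidate set {intercept, FR, PPFD, FR x PPFD} and pruning it by
backwards stepwise elimination: while any removable term has p > alpha,
drop the least significant one and refit (the interaction must leave
before either main effect it involves; the intercept always stays).

When both main-effect slopes survive, their ratio quantifies how much
more effective a unit of far-red photon flux is than a unit of PPFD at
increasing the response:

    percent_more_effective = 100 * (slope_FR / slope_PPFD - 1).

Fitting is ordinary least squares with Gaussian errors and two-sided
t-based p-values (alpha defaults to 0.05); no multiple-testing
correction is applied.  The interaction column is the product of the
mean-centered predictors, so the FR and PPFD coefficients remain the
marginal slopes at the gradient center whether or not the interaction
survives elimination; whenever the interaction is dropped the fit is
the plain uncentered two-slope model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "LinearModelFit",
    "EfficacyResult",
    "CorrelationResult",
    "fit_response_model",
    "efficacy_ratio",
    "correlate",
    "per_unit_slope",
]

CANDIDATE_TERMS = ("fr", "ppfd", "fr:ppfd")

FR_COL = "fr_umol_m2_s"
PPFD_COL = "ppfd_umol_m2_s"


@dataclass(frozen=True)
class LinearModelFit:
    """Final model after backwards elimination (intercept always kept)."""

    response: str
    terms: tuple[str, ...]
    coef: dict
    se: dict
    p_values: dict
    conf_int: dict
    r_squared: float
    n: int
    alpha: float

    def __post_init__(self) -> None:
        for term, p in self.p_values.items():
            if not 0 <= p <= 1:
                raise ValueError(f"p-value for {term} outside [0, 1]")
        if set(self.coef) != {"intercept", *self.terms}:
            raise ValueError("coefficients must match retained terms")


@dataclass(frozen=True)
class EfficacyResult:
    """Slope-ratio efficacy of far-red relative to PPFD."""

    response: str
    slope_fr: float
    slope_ppfd: float
    percent_more_effective: float

    @property
    def percent_rounded(self) -> int:
        """Integer-rounded percentage, the conventional reporting form."""
        return int(round(self.percent_more_effective))


@dataclass(frozen=True)
class CorrelationResult:
    x: str
    y: str
    pearson_r: float
    p_value: float
    slope: float
    intercept: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.pearson_r) > 1 + 1e-12:
            raise ValueError("|r| must be <= 1")


def _design(fr: np.ndarray, ppfd: np.ndarray, terms: tuple[str, ...]) -> pd.DataFrame:
    cols = {"intercept": np.ones_like(fr)}
    if "fr" in terms:
        cols["fr"] = fr
    if "ppfd" in terms:
        cols["ppfd"] = ppfd
    if "fr:ppfd" in terms:
        # centered product: keeps the main effects interpretable as
        # marginal slopes at the gradient center even when the
        # interaction is retained (and decorrelates it from the mains)
        cols["fr:ppfd"] = (fr - fr.mean()) * (ppfd - ppfd.mean())
    return pd.DataFrame(cols)


def fit_response_model(
    table: pd.DataFrame,
    response: str,
    alpha: float = 0.05,
    fr_col: str = FR_COL,
    ppfd_col: str = PPFD_COL,
) -> LinearModelFit:
    """Backwards stepwise OLS of ``response`` on FR, PPFD and their
    interaction.

    Elimination removes, at each step, the removable term with the
    largest p-value above ``alpha`` (a main effect is removable only
    once the interaction is gone).  Exact p-value ties are broken by
    removing the interaction first, then alphabetically.
    """
    y = table[response].to_numpy(dtype=float)
    fr = table[fr_col].to_numpy(dtype=float)
    ppfd = table[ppfd_col].to_numpy(dtype=float)
    terms = list(CANDIDATE_TERMS)
    if len(y) <= len(terms) + 1:
        raise ValueError("need more observations than candidate terms")
    if np.ptp(fr) == 0 or np.ptp(ppfd) == 0:
        raise ValueError("constant predictor: design would be rank deficient")

    sst = float(np.sum((y - y.mean()) ** 2))
    perfect_tol = 1e-12 * max(sst, 1.0)

    while True:
        X = _design(fr, ppfd, tuple(terms))
        res = sm.OLS(y, X).fit()
        if res.ssr <= perfect_tol:
            # numerically exact fit: t-statistics are meaningless, so a
            # term carries evidence only if removing it breaks the fit
            pvals = {}
            for t in terms:
                reduced = tuple(u for u in terms if u != t)
                ssr_r = sm.OLS(y, _design(fr, ppfd, reduced)).fit().ssr
                pvals[t] = 1.0 if ssr_r <= perfect_tol else 0.0
        else:
            # 0/0 t-statistics (NaN p) mean "no evidence the term matters"
            pvals = {t: (1.0 if np.isnan(res.pvalues[t]) else float(res.pvalues[t])) for t in terms}
        removable = [t for t in terms if t == "fr:ppfd" or "fr:ppfd" not in terms]
        drop = [t for t in removable if pvals[t] > alpha]
        if not drop:
            break
        # largest p first; ties: interaction, then alphabetical
        drop.sort(key=lambda t: (-pvals[t], 0 if t == "fr:ppfd" else 1, t))
        terms.remove(drop[0])

    ci = res.conf_int(alpha=0.05)
    names = list(X.columns)
    return LinearModelFit(
        response=response,
        terms=tuple(t for t in names if t != "intercept"),
        coef={t: float(res.params[t]) for t in names},
        se={t: float(res.bse[t]) for t in names},
        p_values={t: (0.0 if np.isinf(res.tvalues[t]) else 1.0 if np.isnan(res.pvalues[t]) else float(res.pvalues[t])) for t in names},
        conf_int={t: (float(ci.loc[t, 0]), float(ci.loc[t, 1])) for t in names},
        r_squared=float(res.rsquared),
        n=int(res.nobs),
        alpha=alpha,
    )


def efficacy_ratio(fit: LinearModelFit) -> EfficacyResult:
    """Far-red vs PPFD slope-ratio efficacy from a fitted model.

    Defined only when both main-effect slopes were retained and the
    PPFD slope is nonzero; rounding happens only at reporting time.
    """
    if "fr" not in fit.terms or "ppfd" not in fit.terms:
        raise ValueError("both FR and PPFD slopes must be retained")
    slope_fr = fit.coef["fr"]
    slope_ppfd = fit.coef["ppfd"]
    if slope_ppfd == 0:
        raise ZeroDivisionError("PPFD slope is zero; efficacy undefined")
    return EfficacyResult(
        response=fit.response,
        slope_fr=slope_fr,
        slope_ppfd=slope_ppfd,
        percent_more_effective=100.0 * (slope_fr / slope_ppfd - 1.0),
    )


def correlate(x, y, x_name: str = "x", y_name: str = "y") -> CorrelationResult:
    """Pearson correlation plus the OLS slope/intercept of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    r, p = sps.pearsonr(x, y)
    lr = sps.linregress(x, y)
    return CorrelationResult(
        x=x_name,
        y=y_name,
        pearson_r=float(r),
        p_value=float(p),
        slope=float(lr.slope),
        intercept=float(lr.intercept),
        n=int(x.size),
    )


def per_unit_slope(
    table: pd.DataFrame, response: str, predictor: str
) -> tuple[float, float]:
    """Simple per-unit OLS slope of ``response`` on one predictor and
    its two-sided p-value (the single-gradient reporting style)."""
    x = table[predictor].to_numpy(dtype=float)
    y = table[response].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    if np.ptp(y) == 0:
        return 0.0, 1.0
    lr = sps.linregress(x, y)
    return float(lr.slope), float(lr.pvalue)
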