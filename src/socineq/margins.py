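"""Adjusted prevalences by income x education via predictive margins.

Fits a survey-weighted logistic regression of the outcome on the full
income-by-education interaction plus region, sex and age group, then
computes the marginal (adjusted) prevalence for each income x education
combination by marginal standardization (g-computation): every record is
counterfactually assigned to the cell, predicted probabilities are averaged
with the survey weights over the observed distribution of the remaining
covariates, and delta-method confidence intervals use the cluster-robust
covariance of the fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import GLMFit, fit_weighted_binomial

__all__ = ["MarginalPrevalence", "fit_interaction_logit", "predictive_margins"]

_Z95 = stats.norm.ppf(0.975)


@dataclass
class MarginalPrevalence:
    income_group: object
    education_group: object
    adjusted_prevalence: float | None
    ci_low: float | None
    ci_high: float | None
    wave: str | None = None
    n_cell: int = 0
    reason: str | None = None  # set when the cell is non-estimable

    @property
    def estimable(self) -> bool:
        return self.adjusted_prevalence is not None


def fit_interaction_logit(
    records: pd.DataFrame,
    *,
    income: str = "income_group",
    education: str = "education_group",
    adjusters: Sequence[str] = ("region", "sex", "age_group"),
    **fit_kw,
) -> GLMFit:
    """Weighted logit fit of outcome ~ income*education + adjusters.

    Empty income x education cells do not abort the fit; the corresponding
    margins are reported as non-estimable by :func:`predictive_margins`.
    Single-level income or education raises (no contrast to estimate).
    """
    for col in (income, education):
        if records[col].nunique() < 2:
            raise ValueError(f"{col!r} has a single level; no contrast")
        if records[col].isna().any():
            raise ValueError(f"missing values in {col!r}")
    terms = [f"{income}*{education}", *adjusters]
    return fit_weighted_binomial(records, terms, link="logit", **fit_kw)


def interaction_wald(fit: GLMFit, sep: str = ":") -> tuple[float, float, int]:
    """Joint Wald chi-square test that all interaction coefficients are zero."""
    names = [n for n in fit.params.index if sep in n]
    if not names:
        raise ValueError("fit contains no interaction terms")
    b = fit.params[names].to_numpy()
    V = fit.cov.loc[names, names].to_numpy()
    stat = float(b @ np.linalg.solve(V, b))
    dof = len(names)
    return stat, float(stats.chi2.sf(stat, dof)), dof


def predictive_margins(
    fit: GLMFit,
    records: pd.DataFrame,
    *,
    income: str = "income_group",
    education: str = "education_group",
    weight: str = "weight",
    wave: str | None = None,
) -> list[MarginalPrevalence]:
    """Adjusted prevalence at each observed income x education combination.

    For cell (i, e): set every record's income to i and education to e,
    push through the fitted model, and average the predicted probabilities
    with the survey weights.  Cells unobserved in the data are returned
    non-estimable with a reason rather than extrapolated.
    """
    if fit.design is None:
        raise ValueError("fit carries no design information")
    w = records[weight].to_numpy(float)
    w = w / w.sum()
    beta = fit.params.to_numpy()
    cov = fit.cov.to_numpy()

    inc_levels = _levels(records[income])
    edu_levels = _levels(records[education])
    observed = records.groupby([income, education], observed=False).size()

    out: list[MarginalPrevalence] = []
    for i in inc_levels:
        for e in edu_levels:
            n_cell = int(observed.get((i, e), 0))
            if n_cell == 0:
                out.append(
                    MarginalPrevalence(
                        i, e, None, None, None, wave=wave, n_cell=0,
                        reason="empty income x education cell",
                    )
                )
                continue
            cf = records.copy()
            cf[income] = _const(records[income], i)
            cf[education] = _const(records[education], e)
            X = fit.design.matrix(cf)[fit.params.index].to_numpy(float)
            p = 1.0 / (1.0 + np.exp(-(X @ beta)))
            m = float(np.sum(w * p))
            grad = (w * p * (1 - p)) @ X
            se = float(np.sqrt(grad @ cov @ grad))
            out.append(
                MarginalPrevalence(
                    i, e,
                    m,
                    max(m - _Z95 * se, 0.0),
                    min(m + _Z95 * se, 1.0),
                    wave=wave,
                    n_cell=n_cell,
                )
            )
    return out


def margins_frame(margins: Sequence[MarginalPrevalence]) -> pd.DataFrame:
    return pd.DataFrame(
        dict(
            income_group=m.income_group,
            education_group=m.education_group,
            adjusted_prevalence=m.adjusted_prevalence,
            ci_low=m.ci_low,
            ci_high=m.ci_high,
            wave=m.wave,
            n_cell=m.n_cell,
            reason=m.reason,
        )
        for m in margins
    )


def _levels(s: pd.Series) -> list:
    if isinstance(s.dtype, pd.CategoricalDtype):
        return [l for l in s.cat.categories if (s == l).any()]
    return sorted(pd.unique(s.dropna()).tolist())


def _const(template: pd.Series, value) -> pd.Series:
    if isinstance(template.dtype, pd.CategoricalDtype):
        return pd.Series(
            pd.Categorical(
                [value] * len(template),
                categories=template.cat.categories,
                ordered=template.cat.ordered,
            ),
            index=template.index,
        )
    return pd.Series([value] * len(template), index=template.index)
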