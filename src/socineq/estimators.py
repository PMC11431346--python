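"""Survey-weighted binomial GLMs and the slope/relative indices of inequality.

The slope index of inequality (SII) is the coefficient of the ridit score in
an identity-link binomial regression of the binary outcome: the model-implied
prevalence difference between the hypothetical top (score 1) and bottom
(score 0) of the socioeconomic distribution.  The relative index of
inequality (RII) is exp(coefficient) from the same regression with a log
link: the top/bottom prevalence ratio.  Both are fitted by iteratively
reweighted least squares with the survey weights entering as analysis
weights, and variance comes from a cluster-robust (sandwich) estimator with
primary sampling units as clusters — the Taylor-linearization variance used
by survey packages.

Identity- and log-link binomial likelihoods are not globally concave over
the feasible region, and fitted probabilities can escape (0, 1) during
iteration; the fitter clamps fitted probabilities to (eps, 1 - eps) with
eps = 1e-8 and step-halves whenever a full IRLS step fails to improve the
deviance.  Non-convergence never yields a silent result: a documented
fallback is used (identity -> weighted linear-probability least squares;
log -> logit fit transformed through marginal standardization) and the
estimate carries a ``converged``/``fallback`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ridit import GroupedDistribution, compute_ridit_scores

__all__ = [
    "Design",
    "GLMFit",
    "InequalityEstimate",
    "fit_weighted_binomial",
    "estimate_sii",
    "estimate_rii",
    "grouped_oracle",
    "expand_grouped",
]

_EPS = 1e-8
_MAX_ITER = 200
_MAX_HALVINGS = 30
_TOL = 1e-12


class DegenerateOutcomeError(ValueError):
    """All outcomes identical: no binomial variation to model."""


class ConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------


class Design:
    """Design-matrix builder for additive terms with simple interactions.

    Terms are column names; categorical columns are dummy-encoded against
    their first (reference) level.  ``a:b`` denotes the interaction columns
    (elementwise products of the two expansions) and ``a*b`` expands to
    ``a + b + a:b``.  Category levels are frozen at construction so that
    matrices built later (e.g. for predictive margins on counterfactual
    data) align column-for-column with the fit.
    """

    def __init__(self, data: pd.DataFrame, terms: Sequence[str]):
        expanded: list[str] = []
        for t in terms:
            if "*" in t:
                a, b = (s.strip() for s in t.split("*", 1))
                expanded += [a, b, f"{a}:{b}"]
            else:
                expanded.append(t.strip())
        self.terms = expanded
        self.levels: dict[str, list] = {}
        for t in expanded:
            for name in t.split(":"):
                if name in self.levels:
                    continue
                col = data[name]
                if isinstance(col.dtype, pd.CategoricalDtype):
                    self.levels[name] = list(col.cat.categories)
                elif col.dtype == object or col.dtype == bool:
                    self.levels[name] = sorted(pd.unique(col.dropna()).tolist())
        self.columns = self._matrix_columns(data)

    def _encode(self, data: pd.DataFrame, name: str) -> pd.DataFrame:
        if name in self.levels:
            levels = self.levels[name]
            out = pd.DataFrame(index=data.index)
            for lev in levels[1:]:  # first level is the reference
                out[f"{name}[{lev}]"] = (data[name] == lev).astype(float)
            return out
        return pd.DataFrame({name: data[name].astype(float)})

    def _term_block(self, data: pd.DataFrame, term: str) -> pd.DataFrame:
        parts = term.split(":")
        block = self._encode(data, parts[0])
        for p in parts[1:]:
            nxt = self._encode(data, p)
            cols = {}
            for c1 in block.columns:
                for c2 in nxt.columns:
                    cols[f"{c1}:{c2}"] = block[c1].to_numpy() * nxt[c2].to_numpy()
            block = pd.DataFrame(cols, index=data.index)
        return block

    def _matrix_columns(self, data: pd.DataFrame) -> list[str]:
        return list(self.matrix(data).columns)

    def matrix(self, data: pd.DataFrame) -> pd.DataFrame:
        blocks = [pd.DataFrame({"Intercept": np.ones(len(data))}, index=data.index)]
        for t in self.terms:
            blocks.append(self._term_block(data, t))
        X = pd.concat(blocks, axis=1)
        return X


# ---------------------------------------------------------------------------
# links
# ---------------------------------------------------------------------------


def _link_funcs(link: str):
    if link == "identity":
        return (lambda mu: mu, lambda eta: eta, lambda mu: np.ones_like(mu))
    if link == "log":
        return (np.log, np.exp, lambda mu: mu)
    if link == "logit":
        return (
            lambda mu: np.log(mu / (1 - mu)),
            lambda eta: 1.0 / (1.0 + np.exp(-eta)),
            lambda mu: mu * (1 - mu),
        )
    raise ValueError(f"unknown link {link!r}")


def _deviance(y, mu, w):
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        t2 = np.where(y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0.0)
    return 2.0 * float(np.sum(w * (t1 + t2)))


# ---------------------------------------------------------------------------
# fit result containers
# ---------------------------------------------------------------------------


@dataclass
class GLMFit:
    """A fitted weighted binomial GLM with robust covariance."""

    params: pd.Series
    cov: pd.DataFrame
    link: str
    converged: bool
    iterations: int
    n_obs: int
    n_clusters: int
    deviance: float
    design: Design | None = None
    fallback: str | None = None

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    def wald(self, name: str, null: float = 0.0):
        """(z, two-sided p) for a single coefficient."""
        z = (self.params[name] - null) / self.bse[name]
        return float(z), float(2 * stats.norm.sf(abs(z)))

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        if self.design is None:
            raise ValueError("fit carries no design; cannot predict")
        X = self.design.matrix(data)[self.params.index].to_numpy(float)
        _, inv, _ = _link_funcs(self.link)
        return np.clip(inv(X @ self.params.to_numpy()), _EPS, 1 - _EPS)


@dataclass
class InequalityEstimate:
    """Point estimate and 95% CI for one inequality index.

    ``estimate`` is on the prevalence-difference scale for the SII and is a
    dimensionless positive ratio for the RII; ``se`` is on the natural scale
    for the SII and on the log (link) scale for the RII.
    """

    index: str  # "SII" | "RII"
    estimate: float
    ci_low: float
    ci_high: float
    se: float
    n: int
    adjusted_for: tuple = ()
    domain: str = "overall"
    wave: str | None = None
    group: str | None = None
    converged: bool = True
    fallback: str | None = None
    fit: GLMFit | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.index == "RII" and self.estimate <= 0:
            raise ValueError("RII must be positive")
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("CI must contain the estimate")


# ---------------------------------------------------------------------------
# the IRLS fitter
# ---------------------------------------------------------------------------


def _irls(y, X, w, link, start=None):
    """Weighted-binomial IRLS with probability clamping and step-halving."""
    glink, ginv, dmu_deta = _link_funcs(link)
    n, p = X.shape
    if start is None:
        ybar = min(max(float(np.average(y, weights=w)), _EPS), 1 - _EPS)
        beta = np.zeros(p)
        beta[0] = glink(np.array([ybar]))[0]
    else:
        beta = np.asarray(start, dtype=float).copy()

    def clamp(mu):
        return np.clip(mu, _EPS, 1 - _EPS)

    mu = clamp(ginv(X @ beta))
    dev = _deviance(y, mu, w)
    converged = False
    it = 0
    for it in range(1, _MAX_ITER + 1):
        eta = glink(mu)
        d = dmu_deta(mu)
        var = mu * (1 - mu)
        wirls = w * d * d / var
        z = eta + (y - mu) / d
        sw = np.sqrt(wirls)
        beta_new, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        step = beta_new - beta
        # step-halve until the deviance does not deteriorate
        lam = 1.0
        for _ in range(_MAX_HALVINGS):
            cand = beta + lam * step
            mu_c = clamp(ginv(X @ cand))
            dev_c = _deviance(y, mu_c, w)
            if np.isfinite(dev_c) and dev_c <= dev + 1e-10:
                break
            lam *= 0.5
        else:
            break  # no improving step: stop iterating
        delta = abs(dev - dev_c)
        beta, mu, dev = cand, mu_c, dev_c
        if delta < _TOL * (abs(dev) + 1.0):
            converged = True
            break
    return beta, mu, dev, converged, it


def _sandwich(y, X, w, mu, link, clusters, strata):
    """Cluster-robust covariance with clusters-1 small-sample correction.

    Bread is the IRLS information X' W X; meat aggregates score
    contributions within clusters (within strata, scores are centred on the
    stratum mean, mirroring Taylor-linearization survey variance).  Without
    cluster identifiers every record is its own cluster, which reduces to a
    heteroskedasticity-robust estimator.
    """
    _, _, dmu_deta = _link_funcs(link)
    d = dmu_deta(mu)
    var = mu * (1 - mu)
    wirls = w * d * d / var
    bread = np.linalg.pinv(X.T @ (X * wirls[:, None]))
    scores = X * (w * (y - mu) * d / var)[:, None]

    if clusters is None:
        clusters = np.arange(len(y))
    cl = pd.factorize(clusters)[0]
    df = pd.DataFrame(scores)
    df["_cl"] = cl
    if strata is not None:
        df["_st"] = pd.factorize(strata)[0]
        cl_sum = df.groupby(["_st", "_cl"], sort=False).sum()
        meat = np.zeros((X.shape[1], X.shape[1]))
        n_clusters = 0
        for _, sub in cl_sum.groupby(level=0, sort=False):
            s = sub.to_numpy(float)
            n_h = s.shape[0]
            n_clusters += n_h
            if n_h < 2:
                meat += s.T @ s
                continue
            c = s - s.mean(axis=0, keepdims=True)
            meat += (n_h / (n_h - 1)) * (c.T @ c)
        cov = bread @ meat @ bread
    else:
        cl_sum = df.groupby("_cl", sort=False).sum().to_numpy(float)
        n_clusters = cl_sum.shape[0]
        if n_clusters < 2:
            raise ValueError("need at least 2 clusters for robust variance")
        meat = cl_sum.T @ cl_sum
        cov = (n_clusters / (n_clusters - 1)) * (bread @ meat @ bread)
    cov = (cov + cov.T) / 2.0
    return cov, n_clusters


def fit_weighted_binomial(
    records: pd.DataFrame,
    terms: Sequence[str],
    *,
    link: str,
    outcome: str = "outcome",
    weight: str = "weight",
    psu: str | None = "psu",
    stratum: str | None = "stratum",
    allow_fallback: bool = True,
) -> GLMFit:
    """Fit ``outcome ~ 1 + terms`` as a weighted binomial GLM.

    Survey weights enter as analysis (frequency-style) weights in the
    likelihood; covariance is the cluster-robust sandwich on PSUs when a
    ``psu`` column is present, otherwise heteroskedasticity-robust.

    On non-convergence a fallback is applied (identity -> linear-probability
    weighted least squares; log -> logit fit with the RII recovered by
    marginal standardization) and recorded in ``fallback``; the result is
    never silent.
    """
    y = records[outcome].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise DegenerateOutcomeError("all outcomes identical; nothing to model")
    w = records[weight].to_numpy(dtype=float)
    if (w <= 0).any():
        raise ValueError("weights must be positive")

    design = Design(records, terms)
    Xdf = design.matrix(records)
    X = Xdf.to_numpy(dtype=float)
    names = list(Xdf.columns)

    clusters = (
        records[psu].to_numpy()
        if psu is not None and psu in records.columns and records[psu].notna().all()
        else None
    )
    strata = (
        records[stratum].to_numpy()
        if stratum is not None
        and stratum in records.columns
        and records[stratum].notna().all()
        and clusters is not None
        else None
    )

    beta, mu, dev, converged, it = _irls(y, X, w, link)
    fallback = None
    if not converged and allow_fallback:
        if link == "identity":
            # linear-probability weighted least squares
            sw = np.sqrt(w)
            beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
            mu = np.clip(X @ beta, _EPS, 1 - _EPS)
            dev = _deviance(y, mu, w)
            fallback = "wls-linear-probability"
        elif link == "log":
            # refit with the always-concave logit likelihood; callers that
            # need a ratio transform it through marginal standardization
            beta, mu, dev, conv2, it2 = _irls(y, X, w, "logit")
            if not conv2:
                raise ConvergenceError("logit fallback failed to converge")
            fit = GLMFit(
                params=pd.Series(beta, index=names),
                cov=pd.DataFrame(
                    _sandwich(y, X, w, mu, "logit", clusters, strata)[0],
                    index=names,
                    columns=names,
                ),
                link="logit",
                converged=True,
                iterations=it + it2,
                n_obs=len(y),
                n_clusters=_n_clusters(clusters, len(y)),
                deviance=dev,
                design=design,
                fallback="logit-margins",
            )
            return fit

    cov, n_clusters = _sandwich(y, X, w, mu, link, clusters, strata)
    return GLMFit(
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        link=link,
        converged=converged,
        iterations=it,
        n_obs=len(y),
        n_clusters=n_clusters,
        deviance=dev,
        design=design,
        fallback=fallback,
    )


def _n_clusters(clusters, n):
    return int(pd.unique(clusters).size) if clusters is not None else n


# ---------------------------------------------------------------------------
# SII / RII
# ---------------------------------------------------------------------------

_Z95 = stats.norm.ppf(0.975)


def _ridit_margin_ratio(fit: GLMFit, records: pd.DataFrame, ridit: str):
    """RII via marginal standardization of a logit fit (fallback path).

    Predicts every record at ridit 1 and at ridit 0, averages with the
    survey weights, and returns the ratio with a delta-method log-scale SE.
    """
    w = records["weight"].to_numpy(float)
    w = w / w.sum()
    beta = fit.params.to_numpy()
    grads = {}
    means = {}
    for val in (1.0, 0.0):
        df = records.copy()
        df[ridit] = val
        X = fit.design.matrix(df)[fit.params.index].to_numpy(float)
        p = 1.0 / (1.0 + np.exp(-(X @ beta)))
        means[val] = float(np.sum(w * p))
        grads[val] = (w * p * (1 - p)) @ X
    ratio = means[1.0] / means[0.0]
    g = grads[1.0] / means[1.0] - grads[0.0] / means[0.0]  # d log-ratio / d beta
    se_log = float(np.sqrt(g @ fit.cov.to_numpy() @ g))
    return ratio, se_log


def _estimate(
    records,
    group,
    index,
    adjusters,
    *,
    ridit="ridit",
    domain="overall",
    wave=None,
    **fit_kw,
) -> InequalityEstimate:
    if ridit not in records.columns:
        raise ValueError(
            f"records carry no {ridit!r} column; attach ridit scores first"
        )
    link = "identity" if index == "SII" else "log"
    terms = [ridit, *adjusters]
    fit = fit_weighted_binomial(records, terms, link=link, **fit_kw)

    if fit.fallback == "logit-margins":
        est, se_log = _ridit_margin_ratio(fit, records, ridit)
        lo = est * np.exp(-_Z95 * se_log)
        hi = est * np.exp(_Z95 * se_log)
        se = se_log
    else:
        b = float(fit.params[ridit])
        se = float(fit.bse[ridit])
        if index == "SII":
            est, lo, hi = b, b - _Z95 * se, b + _Z95 * se
        else:
            est = float(np.exp(b))
            lo, hi = float(np.exp(b - _Z95 * se)), float(np.exp(b + _Z95 * se))
    return InequalityEstimate(
        index=index,
        estimate=float(est),
        ci_low=float(lo),
        ci_high=float(hi),
        se=se,
        n=fit.n_obs,
        adjusted_for=tuple(adjusters),
        domain=domain,
        wave=wave,
        group=group,
        converged=fit.converged,
        fallback=fit.fallback,
        fit=fit,
    )


def estimate_sii(
    records: pd.DataFrame,
    group: str,
    adjusters: Sequence[str] = ("sex", "age_group"),
    **kw,
) -> InequalityEstimate:
    """Slope index of inequality: ridit coefficient, identity-link binomial fit.

    Positive values mean the favorable outcome concentrates among the
    socially advantaged (higher ridit).  95% Wald CI on the natural scale.
    """
    return _estimate(records, group, "SII", tuple(adjusters), **kw)


def estimate_rii(
    records: pd.DataFrame,
    group: str,
    adjusters: Sequence[str] = ("sex", "age_group"),
    **kw,
) -> InequalityEstimate:
    """Relative index of inequality: exp(ridit coefficient), log-link fit.

    Always positive; 1.0 means no relative inequality.  The 95% CI is Wald
    on the log scale, then exponentiated.
    """
    return _estimate(records, group, "RII", tuple(adjusters), **kw)


# ---------------------------------------------------------------------------
# grouped-data oracle
# ---------------------------------------------------------------------------


def expand_grouped(dist: GroupedDistribution) -> pd.DataFrame:
    """Expand a grouped distribution to weighted pseudo-individual records.

    Two records per category (outcome 1 with weight share*prevalence,
    outcome 0 with the complement) — sufficient statistics for any binomial
    GLM on the group structure, so fits on this expansion must agree with
    fits on microdata having identical group aggregates.
    """
    if dist.prevalences is None:
        raise ValueError("distribution carries no prevalences")
    sc = compute_ridit_scores(dist)
    prev = dict(zip(dist.labels, dist.prevalences))
    rows = []
    for lab, share, mid in zip(sc.labels, sc.shares, sc.midpoints):
        p = prev[lab]
        for y, wt in ((1, share * p), (0, share * (1 - p))):
            if wt > 0:
                rows.append(
                    dict(group_label=lab, ridit=mid, outcome=y, weight=wt)
                )
    return pd.DataFrame(rows)


def grouped_oracle(
    dist: GroupedDistribution, index: str, method: str = "glm"
) -> float:
    """Unadjusted SII/RII computed directly from a grouped distribution.

    ``method="glm"`` expands the groups to pseudo-records and runs the same
    weighted binomial fit as the microdata path.  ``method="wls"`` is the
    closed-form share-weighted least-squares slope of the group prevalences
    (log prevalences for the RII) on the ridit midpoints — an independent
    textbook variant useful for cross-checking.
    """
    if index not in ("SII", "RII"):
        raise ValueError("index must be 'SII' or 'RII'")
    if method == "glm":
        df = expand_grouped(dist)
        fit = fit_weighted_binomial(
            df,
            ["ridit"],
            link="identity" if index == "SII" else "log",
            psu=None,
            stratum=None,
        )
        b = float(fit.params["ridit"])
        return b if index == "SII" else float(np.exp(b))
    if method == "wls":
        sc = compute_ridit_scores(dist)
        prev = dict(zip(dist.labels, dist.prevalences))
        m = np.array(sc.midpoints)
        s = np.array(sc.shares)
        p = np.array([prev[l] for l in sc.labels])
        resp = p if index == "SII" else np.log(p)
        mbar = np.average(m, weights=s)
        rbar = np.average(resp, weights=s)
        slope = np.sum(s * (m - mbar) * (resp - rbar)) / np.sum(s * (m - mbar) ** 2)
        return float(slope) if index == "SII" else float(np.exp(slope))
    raise ValueError("method must be 'glm' or 'wls'")
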