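"""Change in SII/RII between two survey waves via a ridit-by-wave interaction.

Both waves are pooled into one weighted binomial GLM containing the ridit
score, a wave indicator, their interaction, and the adjusters.  With
identity link the interaction coefficient is the between-wave difference in
the SII; with log link its exponential is the between-wave RII ratio.  A
positive (SII) or >1 (RII) significant interaction means inequality grew.

By default the adjusters also interact with wave (wave-specific adjuster
effects), which makes the pooled model a saturated reparametrization of the
two per-wave fits: the interaction then equals the contrast of the per-wave
indices exactly.  ``shared_adjusters=True`` constrains adjuster effects to
be common across waves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import GLMFit, InequalityEstimate, fit_weighted_binomial, _estimate

__all__ = ["TrendTest", "test_change", "tabulate"]

_Z95 = stats.norm.ppf(0.975)


@dataclass
class TrendTest:
    """Between-wave change in one inequality index.

    ``interaction`` is the additive SII difference (wave2 - wave1) or the
    multiplicative RII ratio (wave2 / wave1); ``se`` is always on the link
    (coefficient) scale.
    """

    index: str
    interaction: float
    ci_low: float
    ci_high: float
    se: float
    p_value: float
    waves: tuple
    per_wave_estimates: tuple
    domain: str = "overall"
    group: str | None = None
    fit: GLMFit | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.index == "RII" and self.interaction <= 0:
            raise ValueError("RII interaction ratio must be positive")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def test_change(
    records: pd.DataFrame,
    group: str,
    index: str,
    adjusters: Sequence[str] = ("sex", "age_group"),
    *,
    ridit: str = "ridit",
    wave: str = "wave",
    shared_adjusters: bool = False,
    domain: str = "overall",
    **fit_kw,
) -> TrendTest:
    """Wald test of the ridit-by-wave interaction in the pooled model.

    Records must already carry per-wave ridit scores (see
    :func:`socineq.ridit.attach_scores`) and exactly two wave labels.
    """
    if index not in ("SII", "RII"):
        raise ValueError("index must be 'SII' or 'RII'")
    waves = sorted(pd.unique(records[wave]))
    if len(waves) != 2:
        raise ValueError(f"exactly two waves required, got {waves}")
    w1, w2 = waves

    df = records.copy()
    df["_wave2"] = (df[wave] == w2).astype(float)
    terms = [ridit, "_wave2", f"{ridit}:_wave2"]
    for a in adjusters:
        terms.append(a)
        if not shared_adjusters:
            terms.append(f"{a}:_wave2")

    link = "identity" if index == "SII" else "log"
    fit = fit_weighted_binomial(df, terms, link=link, **fit_kw)
    name = f"{ridit}:_wave2"
    coef = float(fit.params[name])
    se = float(fit.bse[name])
    _, p = fit.wald(name)
    if index == "SII":
        est, lo, hi = coef, coef - _Z95 * se, coef + _Z95 * se
    else:
        est = float(np.exp(coef))
        lo, hi = float(np.exp(coef - _Z95 * se)), float(np.exp(coef + _Z95 * se))

    per_wave = tuple(
        _estimate(
            records[records[wave] == wv],
            group,
            index,
            tuple(adjusters),
            ridit=ridit,
            domain=domain,
            wave=str(wv),
            **fit_kw,
        )
        for wv in (w1, w2)
    )
    return TrendTest(
        index=index,
        interaction=est,
        ci_low=lo,
        ci_high=hi,
        se=se,
        p_value=p,
        waves=(str(w1), str(w2)),
        per_wave_estimates=per_wave,
        domain=domain,
        group=group,
        fit=fit,
    )


def _fmt(x: float, ratio: bool) -> str:
    return f"{x:.2f}"


def tabulate(results: Sequence[TrendTest]) -> pd.DataFrame:
    """Tidy results table: one row per (domain, group variable, index).

    Columns hold each wave's estimate with its 95% CI, the interaction term
    (SII difference / RII ratio) with CI, and the Wald p-value — the layout
    of a standard inequality-monitoring summary table.  Estimates are kept
    at full precision; round for display.
    """
    cols = [
        "domain", "group", "index",
        "wave1", "est1", "ci1_low", "ci1_high",
        "wave2", "est2", "ci2_low", "ci2_high",
        "interaction", "int_ci_low", "int_ci_high", "p_value",
    ]
    rows = []
    for t in results:
        e1, e2 = t.per_wave_estimates
        rows.append(
            dict(
                domain=t.domain,
                group=t.group,
                index=t.index,
                wave1=t.waves[0], est1=e1.estimate,
                ci1_low=e1.ci_low, ci1_high=e1.ci_high,
                wave2=t.waves[1], est2=e2.estimate,
                ci2_low=e2.ci_low, ci2_high=e2.ci_high,
                interaction=t.interaction,
                int_ci_low=t.ci_low, int_ci_high=t.ci_high,
                p_value=t.p_value,
            )
        )
    return pd.DataFrame(rows, columns=cols)
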