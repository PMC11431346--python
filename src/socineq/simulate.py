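"""Synthetic survey microdata with known inequality structure.

Generates individual-level records that mimic the structure of a national
household health survey: ordered socioeconomic groups with wave-specific
population shares, a binary outcome whose prevalence follows a known truth
(group prevalences, linear-in-ridit, or log-linear-in-ridit), additive sex
and age effects, primary-sampling-unit clustering with a chosen
intra-cluster correlation, and unequal sampling weights (optionally
informative, i.e. correlated with the socioeconomic group).  Because the
truth is known, every estimator in the package can be validated end to end:
null recovery, parameter recovery, confidence-interval coverage, and
design-effect direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import AGE_LEVELS
from .ridit import GroupedDistribution, compute_ridit_scores

__all__ = ["SimulationDesign", "generate", "true_index"]


class InfeasibleDesignError(ValueError):
    """Some covariate cell implies a probability outside (0, 1)."""


@dataclass(frozen=True)
class SimulationDesign:
    """Specification of a two-wave (or single-wave) synthetic survey.

    Parameters
    ----------
    n : records per wave.
    shares : mapping wave label -> group-share vector (sums to 1).
    truth : per-wave outcome model.  Each wave maps to one of
        ``("linear", a, b)`` — prevalence ``a + b * ridit`` so the true
        SII is ``b``; ``("loglinear", a, b)`` — prevalence
        ``exp(a + b * ridit)`` so the true RII is ``exp(b)``; or
        ``("prevalence", (p1, ..., pK))`` — explicit group prevalences.
    group_labels : ordered category labels, most disadvantaged first.
    sex_effect : additive risk offset for females (vs males).
    age_effects : additive risk offsets per age group (first is reference).
    age_shares : population shares of the age groups.
    n_psu : primary sampling units per wave (0 disables clustering).
    icc : within-PSU outcome correlation in [0, 1); induced through a
        beta-distributed cluster-level deflection of each record's
        probability sharing one uniform draw per PSU.
    psu_segregation : in [0, 1); socioeconomic homogeneity of PSUs.  Each
        PSU gets its own group-share vector drawn from a Dirichlet with
        mean equal to the wave's shares and concentration
        ``shares * (1/seg - 1)`` — census sectors are socially clustered,
        which is what makes cluster sampling inflate the variance of the
        inequality slope, not just of the mean.  0 disables.
    informative_weights : strength g of group-dependent inclusion: the
        sampled group distribution is tilted to shares * (1 + g * k)
        (k = 0-based group index) and each record carries weight
        proportional to the inverse tilt, so weighted analyses recover the
        population shares while unweighted ones drift.  0 disables.
    """

    n: int = 5000
    shares: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {"2013": (0.25, 0.25, 0.25, 0.25)}
    )
    truth: Mapping[str, tuple] = field(
        default_factory=lambda: {"2013": ("linear", 0.5, 0.3)}
    )
    group_labels: Sequence[str] | None = None
    sex_effect: float = 0.0
    age_effects: Sequence[float] = (0.0, 0.0, 0.0, 0.0)
    age_shares: Sequence[float] = (0.15, 0.30, 0.35, 0.20)
    n_psu: int = 0
    icc: float = 0.0
    psu_segregation: float = 0.0
    informative_weights: float = 0.0

    def waves(self) -> list[str]:
        return list(self.shares)


def _cell_probs(design: SimulationDesign, wave: str) -> np.ndarray:
    """True outcome probability per (group, sex, age) cell; validates range."""
    shares = np.asarray(design.shares[wave], float)
    dist = GroupedDistribution(
        tuple(_labels(design)), tuple(shares / shares.sum())
    )
    mid = np.asarray(compute_ridit_scores(dist).midpoints)
    kind, *params = design.truth[wave]
    if kind == "linear":
        a, b = params
        base = a + b * mid
    elif kind == "loglinear":
        a, b = params
        base = np.exp(a + b * mid)
    elif kind == "prevalence":
        base = np.asarray(params[0], float)
        if base.shape != mid.shape:
            raise InfeasibleDesignError("one prevalence per group required")
    else:
        raise ValueError(f"unknown truth kind {kind!r}")
    sex = np.array([0.0, design.sex_effect])
    age = np.asarray(design.age_effects, float)
    cells = base[:, None, None] + sex[None, :, None] + age[None, None, :]
    if (cells <= 0).any() or (cells >= 1).any():
        raise InfeasibleDesignError(
            "design implies cell probabilities outside (0, 1); "
            f"range [{cells.min():.3f}, {cells.max():.3f}]"
        )
    return cells


def _labels(design: SimulationDesign) -> list[str]:
    k = len(next(iter(design.shares.values())))
    if design.group_labels is not None:
        if len(design.group_labels) != k:
            raise ValueError("group_labels length mismatch")
        return list(design.group_labels)
    return [f"G{i + 1}" for i in range(k)]


def true_index(design: SimulationDesign, wave: str, index: str) -> float:
    """The designed SII or RII for a wave (exact for linear/loglinear truth).

    For explicit group-prevalence truth the value is the grouped GLM fit on
    the design's own shares, i.e. what an infinite unadjusted sample would
    recover.
    """
    kind, *params = design.truth[wave]
    if kind == "linear":
        return params[1] if index == "SII" else float("nan")
    if kind == "loglinear":
        return float(np.exp(params[1])) if index == "RII" else float("nan")
    from .estimators import grouped_oracle

    shares = np.asarray(design.shares[wave], float)
    dist = GroupedDistribution(
        tuple(_labels(design)),
        tuple(shares / shares.sum()),
        tuple(params[0]),
    )
    return grouped_oracle(dist, index)


def generate(
    design: SimulationDesign, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Draw one synthetic survey; identical design + seed -> identical data.

    Returns an analysis-ready frame with columns outcome, group (ordered
    categorical), sex, age_group, wave, weight, psu, stratum.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    labels = _labels(design)
    frames = []
    for wave in design.waves():
        cells = _cell_probs(design, wave)
        shares = np.asarray(design.shares[wave], float)
        shares = shares / shares.sum()
        n = design.n
        if design.n_psu > 0:
            psu = rng.integers(0, design.n_psu, size=n)
        else:
            psu = None
        tilt = 1.0 + design.informative_weights * np.arange(len(labels))
        if psu is not None and design.psu_segregation > 0:
            seg = design.psu_segregation
            conc = np.maximum(shares * (1.0 / seg - 1.0), 1e-3)
            psu_shares = rng.dirichlet(conc, size=design.n_psu) * tilt
            psu_shares /= psu_shares.sum(axis=1, keepdims=True)
            g = np.array(
                [rng.choice(len(labels), p=psu_shares[j]) for j in psu]
            )
        else:
            sample_shares = shares * tilt
            g = rng.choice(len(labels), size=n,
                           p=sample_shares / sample_shares.sum())
        sex = rng.choice(2, size=n, p=(0.48, 0.52))
        age = rng.choice(len(AGE_LEVELS), size=n, p=np.asarray(design.age_shares))
        p = cells[g, sex, age]

        if psu is not None:
            if design.icc > 0:
                # shared uniform per PSU pushed through each record's own
                # beta quantile function -> within-PSU correlation ~ icc
                u = rng.uniform(size=design.n_psu)[psu]
                r = (1 - design.icc) / design.icc
                p = stats.beta.ppf(u, np.maximum(p * r, 1e-9),
                                   np.maximum((1 - p) * r, 1e-9))
                p = np.clip(p, 1e-12, 1 - 1e-12)
            psu_lab = np.array([f"{wave}-psu{j:04d}" for j in psu])
        else:
            psu_lab = np.full(n, None, dtype=object)

        y = (rng.uniform(size=n) < p).astype(int)

        if design.informative_weights != 0.0:
            weight = 1.0 / tilt[g]
            weight = weight / weight.mean()
        else:
            weight = np.ones(n)

        frames.append(
            pd.DataFrame(
                {
                    "outcome": y,
                    "group": pd.Categorical.from_codes(
                        g, categories=labels, ordered=True
                    ),
                    "sex": pd.Categorical.from_codes(
                        sex, categories=["male", "female"]
                    ),
                    "age_group": pd.Categorical.from_codes(
                        age, categories=list(AGE_LEVELS), ordered=True
                    ),
                    "wave": wave,
                    "weight": weight,
                    "psu": psu_lab,
                    "stratum": None,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
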