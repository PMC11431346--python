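"""Ridit scoring of ordered socioeconomic groups.

Each ordered category occupies a range of the weighted cumulative population
distribution; its ridit score is the midpoint of that range.  Scores lie in
(0, 1), increase with social position, and their share-weighted mean is 0.5
by construction.  Regressing an outcome on this score yields the slope index
of inequality (identity link) or, after exponentiation, the relative index
of inequality (log link); because the scores are recomputed from each wave's
own weighted distribution, shifts in group sizes between surveys are
reflected in the covariate rather than distorting the index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GroupedDistribution",
    "RiditScores",
    "compute_ridit_scores",
    "attach_scores",
    "score_table",
    "weighted_shares",
]

_SHARE_TOL = 1e-9


class DegenerateDistributionError(ValueError):
    """A single category holds the entire population: no gradient exists."""


@dataclass(frozen=True)
class GroupedDistribution:
    """Ordered categories with weighted population shares.

    Parameters
    ----------
    labels : ordered category labels, most disadvantaged first.
    shares : weighted population proportions; must be >= 0 and sum to 1.
    prevalences : optional per-group outcome prevalences in [0, 1].
    domain : analysis domain the distribution describes (e.g. "Brazil").
    wave : survey wave label.
    flags : data-quality annotations attached by the source loader.
    """

    labels: tuple
    shares: tuple
    prevalences: tuple | None = None
    domain: str = "overall"
    wave: str | None = None
    flags: tuple = field(default_factory=tuple)

    def __post_init__(self):
        labels = tuple(self.labels)
        shares = tuple(float(s) for s in self.shares)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "shares", shares)
        if len(labels) < 2:
            raise ValueError("need at least two ordered categories")
        if len(labels) != len(shares):
            raise ValueError("labels and shares differ in length")
        if len(set(labels)) != len(labels):
            raise ValueError("labels must be distinct")
        if any(s < 0 for s in shares):
            raise ValueError("shares must be non-negative")
        if abs(sum(shares) - 1.0) > _SHARE_TOL:
            raise ValueError(
                f"shares must sum to 1 (got {sum(shares):.12f}); "
                "renormalize before constructing the distribution"
            )
        if self.prevalences is not None:
            prev = tuple(float(p) for p in self.prevalences)
            object.__setattr__(self, "prevalences", prev)
            if len(prev) != len(labels):
                raise ValueError("prevalences length mismatch")
            if any(not (0.0 <= p <= 1.0) for p in prev):
                raise ValueError("prevalences must lie in [0, 1]")

    @property
    def mean_prevalence(self) -> float:
        """Share-weighted mean of the group prevalences."""
        if self.prevalences is None:
            raise ValueError("distribution carries no prevalences")
        return float(np.dot(self.shares, self.prevalences))


@dataclass(frozen=True)
class RiditScores:
    """Cumulative-midpoint scores for an ordered distribution."""

    labels: tuple
    shares: tuple
    midpoints: tuple

    def as_series(self) -> pd.Series:
        return pd.Series(self.midpoints, index=list(self.labels), name="ridit")


def compute_ridit_scores(dist: GroupedDistribution) -> RiditScores:
    """Midpoint of each category's range in the cumulative distribution.

    midpoint_k = sum(shares[:k]) + shares[k] / 2

    Zero-share categories are dropped (with a warning) before scoring:
    their midpoint would coincide with a bin edge and carries no data.
    A distribution concentrated in one category raises
    :class:`DegenerateDistributionError`.
    """
    shares = np.asarray(dist.shares, dtype=float)
    labels = np.asarray(dist.labels, dtype=object)
    if np.max(shares) >= 1.0 - _SHARE_TOL:
        raise DegenerateDistributionError(
            "a single category holds the whole population; "
            "no inequality gradient is estimable"
        )
    keep = shares > 0.0
    if not keep.all():
        dropped = [str(l) for l in labels[~keep]]
        warnings.warn(
            f"dropping zero-share categories before ridit scoring: {dropped}",
            stacklevel=2,
        )
        shares = shares[keep]
        labels = labels[keep]
        shares = shares / shares.sum()
    cum = np.concatenate([[0.0], np.cumsum(shares)])
    midpoints = cum[:-1] + shares / 2.0
    return RiditScores(tuple(labels), tuple(shares), tuple(midpoints))


def weighted_shares(
    values: pd.Series, weights: pd.Series, order: Sequence
) -> np.ndarray:
    """Weighted category proportions in the given order."""
    totals = weights.groupby(values, observed=False).sum()
    totals = totals.reindex(list(order)).fillna(0.0)
    s = totals.to_numpy(dtype=float)
    total = s.sum()
    if total <= 0:
        raise ValueError("total weight is zero")
    return s / total


def _category_order(series: pd.Series) -> list:
    if isinstance(series.dtype, pd.CategoricalDtype):
        if not series.cat.ordered:
            raise ValueError(f"column {series.name!r} must be an ordered categorical")
        return list(series.cat.categories)
    raise ValueError(
        f"column {series.name!r} must be an ordered categorical so the "
        "social ordering is fixed by configuration, not by the data"
    )


def score_table(
    records: pd.DataFrame,
    group: str,
    *,
    weight: str = "weight",
    domain: str | None = None,
    per_wave: bool = True,
    wave: str = "wave",
) -> pd.DataFrame:
    """Tidy audit table of (domain, wave, label, share, midpoint).

    Shares are the weighted category proportions computed within each
    (domain x wave) cell; midpoints are the corresponding ridit scores.
    """
    df = records
    if df[group].isna().any():
        raise ValueError(f"missing values in group column {group!r}")
    order = _category_order(df[group])

    keys: list[str] = []
    if domain is not None:
        keys.append(domain)
    if per_wave:
        keys.append(wave)

    rows = []
    if keys:
        grouped = df.groupby(keys, observed=True, sort=True)
        for key, sub in grouped:
            if not isinstance(key, tuple):
                key = (key,)
            if len(sub) == 0:
                raise ValueError(f"empty cell {dict(zip(keys, key))}")
            shares = weighted_shares(sub[group], sub[weight], order)
            dist = GroupedDistribution(tuple(order), tuple(shares))
            sc = compute_ridit_scores(dist)
            for lab, sh, mp in zip(sc.labels, sc.shares, sc.midpoints):
                row = dict(zip(keys, key))
                row.update(group=group, label=lab, share=sh, midpoint=mp)
                rows.append(row)
    else:
        shares = weighted_shares(df[group], df[weight], order)
        sc = compute_ridit_scores(GroupedDistribution(tuple(order), tuple(shares)))
        for lab, sh, mp in zip(sc.labels, sc.shares, sc.midpoints):
            rows.append(dict(group=group, label=lab, share=sh, midpoint=mp))
    return pd.DataFrame(rows)


def attach_scores(
    records: pd.DataFrame,
    group: str,
    *,
    weight: str = "weight",
    domain: str | None = None,
    per_wave: bool = True,
    wave: str = "wave",
    column: str = "ridit",
) -> pd.DataFrame:
    """Return a copy of ``records`` with a ridit covariate attached.

    Each record receives the midpoint of its category, computed from the
    weighted category distribution within its (domain x wave) cell.  With
    ``per_wave=True`` (default) the distribution is recomputed per wave, so
    score drift reflects changing group sizes between surveys.
    """
    table = score_table(
        records, group, weight=weight, domain=domain, per_wave=per_wave, wave=wave
    )
    keys = [k for k in ([domain] if domain else []) + ([wave] if per_wave else [])]
    out = records.copy()
    lookup = table.set_index(keys + ["label"])["midpoint"] if keys else (
        table.set_index("label")["midpoint"]
    )
    if keys:
        idx = pd.MultiIndex.from_frame(
            pd.concat([out[k] for k in keys] + [out[group]], axis=1)
        )
        out[column] = lookup.reindex(idx).to_numpy()
    else:
        out[column] = out[group].map(lookup).astype(float).to_numpy()
    if out[column].isna().any():
        bad = out.loc[out[column].isna(), group].unique()
        raise ValueError(f"categories without a score (zero share?): {list(bad)}")
    return out
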