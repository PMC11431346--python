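"""Reading and recoding raw survey microdata into analysis-ready records.

Raw household-survey rows carry a 5-level self-rated oral health response,
education attendance/course labels, total household income with the number
of residents, sex, age in years, region, wave, a sampling weight, and
optional PSU/stratum identifiers.  A declarative configuration (YAML/JSON
mapping) drives every recode, so questionnaire dialects are data, not code:

* outcome: "very good"/"good" -> 1; "regular"/"bad"/"very bad" -> 0;
* education: course labels -> years-of-study bins 0-4 / 5-8 / 9-11 / 12+;
* income: per-capita household income (total / residents) expressed in
  multiples of the wave's statutory minimum wage (BRL 678.00 in 2013,
  BRL 998.00 in 2019) and binned 0-1 / 1.1-2 / 2.1-3 / 3.1+.  The printed
  bin labels are rounded displays of the half-open partition
  (0,1], (1,2], (2,3], (3,inf) — exhaustive, no gaps;
* age in years -> groups 18-24 / 25-39 / 40-59 / 60+.

Rows that violate an invariant (non-positive weight, age < 18, missing
income, unmapped label, ...) are routed to a rejects table with a reason
code — complete-case analysis with an explicit tally, never a silent drop.
Accepted + rejected always equals the input row count.
"""

from __future__ import annotations

import copy
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datasets import AGE_LEVELS, EDUCATION_LEVELS, INCOME_LEVELS

__all__ = [
    "DEFAULT_CONFIG",
    "load_config",
    "read_microdata",
    "recode_records",
    "load_analysis",
    "recode_outcome",
    "recode_education",
    "recode_income",
    "recode_age",
    "write_analysis",
    "read_analysis",
]


class ConfigError(ValueError):
    """Fatal configuration problem (e.g. a required column is absent)."""


#: Default variable map for PNS-style microdata exported as delimited text.
DEFAULT_CONFIG: dict = {
    "columns": {
        "respondent_id": "id",
        "outcome_raw": "sroh",
        "education_raw": "course",
        "household_income_total": "hh_income",
        "n_residents": "n_residents",
        "sex": "sex",
        "age_years": "age",
        "region": "region",
        "wave": "wave",
        "weight": "weight",
        "psu": "psu",          # optional
        "stratum": "stratum",  # optional
    },
    "outcome_map": {
        "very good": 1, "good": 1,
        "regular": 0, "bad": 0, "very bad": 0,
    },
    "education_map": {
        "never frequented school": "0-4",
        "nursery": "0-4",
        "preschool": "0-4",
        "youth and adults literacy": "0-4",
        "youth and adults education": "0-4",
        "supplementary elementary education": "0-4",
        "regular course of elementary education": "5-8",
        "regular course of high school": "9-11",
        "eja high school": "9-11",
        "supplementary high school": "9-11",
        "undergraduate": "12+",
        "higher-level specialization": "12+",
        "masters": "12+",
        "phd": "12+",
    },
    # statutory monthly minimum wage (BRL) per survey wave
    "mw_values": {"2013": 678.00, "2019": 998.00},
    # upper edges of the income bins, in minimum wages; intervals are
    # half-open on the left: (0,1], (1,2], (2,3], (3,inf)
    "income_bin_edges": [1.0, 2.0, 3.0],
    "age_bin_edges": [24, 39, 59],  # inclusive upper edges; last bin open
    "waves": ["2013", "2019"],
    "sex_labels": ["male", "female"],
}

_MANDATORY = (
    "outcome_raw", "education_raw", "household_income_total", "n_residents",
    "sex", "age_years", "region", "wave", "weight",
)
_OPTIONAL = ("respondent_id", "psu", "stratum")


def load_config(path: str | Path | None = None) -> dict:
    """Load a variable-map config (YAML or JSON), merged over the defaults."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


# ---------------------------------------------------------------------------
# scalar recoders
# ---------------------------------------------------------------------------


def recode_outcome(label: str, config: dict | None = None) -> int:
    """5-level self-rating -> binary positive outcome (1 = very good/good)."""
    cfg = config or DEFAULT_CONFIG
    key = str(label).strip().lower()
    try:
        return int(cfg["outcome_map"][key])
    except KeyError:
        raise KeyError(f"unmapped outcome label {label!r}") from None


def recode_education(label: str, config: dict | None = None) -> str:
    """Course label -> years-of-study category."""
    cfg = config or DEFAULT_CONFIG
    key = str(label).strip().lower()
    try:
        return cfg["education_map"][key]
    except KeyError:
        raise KeyError(f"unmapped education label {label!r}") from None


def recode_income(
    household_income_total: float,
    n_residents: int,
    mw_value: float,
    config: dict | None = None,
) -> str:
    """Per-capita income in minimum wages -> income category.

    income per capita = total / residents; bins are (0,1], (1,2], (2,3],
    (3, inf) in MW units, with zero income in the lowest bin.
    """
    cfg = config or DEFAULT_CONFIG
    if n_residents < 1:
        raise ValueError("n_residents must be >= 1")
    if mw_value <= 0:
        raise ValueError("mw_value must be positive")
    if household_income_total < 0 or not np.isfinite(household_income_total):
        raise ValueError("income must be a finite non-negative amount")
    mw = (household_income_total / n_residents) / mw_value
    for edge, lab in zip(cfg["income_bin_edges"], INCOME_LEVELS):
        if mw <= edge:
            return lab
    return INCOME_LEVELS[-1]


def recode_age(age_years: int, config: dict | None = None) -> str:
    cfg = config or DEFAULT_CONFIG
    if age_years < 18:
        raise ValueError("adults only: age must be >= 18")
    for edge, lab in zip(cfg["age_bin_edges"], AGE_LEVELS):
        if age_years <= edge:
            return lab
    return AGE_LEVELS[-1]


# ---------------------------------------------------------------------------
# table-level operations
# ---------------------------------------------------------------------------


def _reject(rejects, idx, reason):
    rejects.append({"row": int(idx), "reason": reason})


def read_microdata(
    path: str | Path, config: dict | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a delimited table into validated raw records plus a rejects table.

    The delimiter (comma or tab) is sniffed from the header line.  A missing
    mandatory column is a fatal :class:`ConfigError`; malformed individual
    rows (unparseable weight/age, non-positive weight, age below 18,
    unknown wave) are rejected row-wise with a reason code.
    """
    cfg = config or DEFAULT_CONFIG
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    raw.columns = [c.strip() for c in raw.columns]

    cols = cfg["columns"]
    missing = [
        cols[f] for f in _MANDATORY if cols.get(f) not in raw.columns
    ]
    if missing:
        raise ConfigError(f"missing mandatory column(s): {missing}")

    rename = {
        cols[f]: f
        for f in (*_MANDATORY, *_OPTIONAL)
        if cols.get(f) in raw.columns
    }
    df = raw.rename(columns=rename)[list(rename.values())].copy()
    df.index = range(len(df))

    rejects: list[dict] = []
    ok = pd.Series(True, index=df.index)

    weight = pd.to_numeric(df["weight"].replace("", np.nan), errors="coerce")
    bad = weight.isna()
    for i in df.index[bad & ok]:
        _reject(rejects, i, "unparseable weight")
    ok &= ~bad
    bad = (weight <= 0) & ok
    for i in df.index[bad]:
        _reject(rejects, i, "nonpositive weight")
    ok &= ~bad

    age = pd.to_numeric(df["age_years"].replace("", np.nan), errors="coerce")
    bad = age.isna() & ok
    for i in df.index[bad]:
        _reject(rejects, i, "unparseable age")
    ok &= ~bad
    bad = (age < 18) & ok
    for i in df.index[bad]:
        _reject(rejects, i, "age below 18")
    ok &= ~bad

    nres = pd.to_numeric(df["n_residents"].replace("", np.nan), errors="coerce")
    bad = (nres.isna() | (nres < 1)) & ok
    for i in df.index[bad]:
        _reject(rejects, i, "invalid resident count")
    ok &= ~bad

    waves = [str(w) for w in cfg["waves"]]
    bad = ~df["wave"].astype(str).isin(waves) & ok
    for i in df.index[bad]:
        _reject(rejects, i, "unknown wave")
    ok &= ~bad

    out = df[ok].copy()
    out["weight"] = weight[ok]
    out["age_years"] = age[ok].astype(int)
    out["n_residents"] = nres[ok].astype(int)
    out["wave"] = out["wave"].astype(str)
    rej = pd.DataFrame(rejects, columns=["row", "reason"])
    assert len(out) + len(rej) == len(df)
    return out, rej


def recode_records(
    raw: pd.DataFrame, config: dict | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw records -> analysis records, with per-row rejects and reasons.

    Complete-case: any unmapped label or missing income rejects the row,
    tallied by reason, mirroring survey practice of excluding item
    nonresponse from the analytic sample.
    """
    cfg = config or DEFAULT_CONFIG
    rows: list[dict] = []
    rejects: list[dict] = []
    mw_values = {str(k): float(v) for k, v in cfg["mw_values"].items()}
    for idx, r in raw.iterrows():
        try:
            outcome = recode_outcome(r["outcome_raw"], cfg)
        except KeyError:
            _reject(rejects, idx, "unmapped outcome label")
            continue
        try:
            edu = recode_education(r["education_raw"], cfg)
        except KeyError:
            _reject(rejects, idx, "unmapped education label")
            continue
        inc_raw = str(r["household_income_total"]).strip()
        if inc_raw == "" or inc_raw.lower() in ("na", "nan"):
            _reject(rejects, idx, "missing income")
            continue
        try:
            total = float(inc_raw)
            inc = recode_income(
                total, int(r["n_residents"]), mw_values[str(r["wave"])], cfg
            )
        except (ValueError, KeyError):
            _reject(rejects, idx, "invalid income")
            continue
        sex = str(r["sex"]).strip().lower()
        if sex not in cfg["sex_labels"]:
            _reject(rejects, idx, "unmapped sex label")
            continue
        rows.append(
            {
                "respondent_id": r.get("respondent_id", str(idx)),
                "outcome": outcome,
                "education_group": edu,
                "income_group": inc,
                "sex": sex,
                "age_group": recode_age(int(r["age_years"]), cfg),
                "region": str(r["region"]).strip(),
                "wave": str(r["wave"]),
                "weight": float(r["weight"]),
                "psu": r.get("psu", "") or None,
                "stratum": r.get("stratum", "") or None,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "respondent_id", "outcome", "education_group", "income_group",
            "sex", "age_group", "region", "wave", "weight", "psu", "stratum",
        ],
    )
    if len(df):
        df = _with_categories(df)
    rej = pd.DataFrame(rejects, columns=["row", "reason"])
    return df, rej


def _with_categories(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["education_group"] = pd.Categorical(
        df["education_group"], categories=list(EDUCATION_LEVELS), ordered=True
    )
    df["income_group"] = pd.Categorical(
        df["income_group"], categories=list(INCOME_LEVELS), ordered=True
    )
    df["age_group"] = pd.Categorical(
        df["age_group"], categories=list(AGE_LEVELS), ordered=True
    )
    df["sex"] = pd.Categorical(df["sex"], categories=["male", "female"])
    return df


def load_analysis(
    path: str | Path, config: dict | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """read_microdata + recode_records; rejects from both stages concatenated."""
    raw, rej1 = read_microdata(path, config)
    analysis, rej2 = recode_records(raw, config)
    rejects = pd.concat([rej1, rej2], ignore_index=True)
    return analysis, rejects


def write_analysis(df: pd.DataFrame, path: str | Path) -> None:
    """Write analysis records as CSV; re-reading restores all fields."""
    df.to_csv(path, index=False)


def read_analysis(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"respondent_id": str, "wave": str, "psu": str, "stratum": str},
    )
    df["psu"] = df["psu"].where(df["psu"].notna(), None)
    df["stratum"] = df["stratum"].where(df["stratum"].notna(), None)
    return _with_categories(df)
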