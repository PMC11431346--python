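"""Published reference distributions from the Brazilian National Health Survey.

The 2013 and 2019 PNS (Pesquisa Nacional de Saude) descriptive tables report,
for adults (>= 18 years), the weighted share of each education and per-capita
income group together with the weighted prevalence of positive self-rated
oral health (SROH, "very good"/"good") in that group.  These grouped
distributions are enough to drive every grouped-data computation in this
package — ridit scores, closed-form SII/RII oracles, and consistency checks
against the published overall prevalences (67.50% in 2013, 69.68% in 2019).

Values are stored exactly as printed (percent scale); shares are
renormalized to sum to 1 on load.  The income 2013 column is flagged: its
printed shares sum to 90.38%, an apparent transcription error in the source
table (the 1.1-2 MW share duplicates another cell), so only its renormalized
form is usable and no overall-prevalence consistency should be expected.
"""

from __future__ import annotations

from .ridit import GroupedDistribution

__all__ = [
    "pns_sroh_distribution",
    "EDUCATION_LEVELS",
    "INCOME_LEVELS",
    "AGE_LEVELS",
    "OVERALL_PREVALENCE",
]

EDUCATION_LEVELS = ("0-4", "5-8", "9-11", "12+")
INCOME_LEVELS = ("0-1", "1.1-2", "2.1-3", "3.1+")
AGE_LEVELS = ("18-24", "25-39", "40-59", "60+")

#: Published overall prevalence of positive SROH (percent), by wave.
OVERALL_PREVALENCE = {"2013": 67.50, "2019": 69.68}

# (share %, positive-SROH prevalence %) per group, as printed.
_PNS = {
    ("education", "2013"): {
        "0-4": (21.43, 57.11),
        "5-8": (25.09, 60.61),
        "9-11": (34.30, 70.61),
        "12+": (19.18, 82.55),
    },
    ("education", "2019"): {
        "0-4": (18.11, 61.99),
        "5-8": (23.34, 60.89),
        "9-11": (35.91, 71.41),
        "12+": (22.64, 82.15),
    },
    ("income", "2013"): {
        "0-1": (49.74, 59.98),
        "1.1-2": (19.18, 70.74),
        "2.1-3": (9.34, 75.45),
        "3.1+": (12.12, 84.50),
    },
    ("income", "2019"): {
        "0-1": (51.24, 62.93),
        "1.1-2": (28.16, 73.33),
        "2.1-3": (9.07, 78.37),
        "3.1+": (11.52, 83.90),
    },
}

# Printed income-2013 shares sum to 90.38%, not 100%.
_FLAGGED = {("income", "2013"): "printed shares sum to 90.38%; renormalized"}


def pns_sroh_distribution(group: str, wave: str | int) -> GroupedDistribution:
    """Grouped PNS distribution of positive SROH for ``group`` and ``wave``.

    Parameters
    ----------
    group : ``"education"`` (years of study) or ``"income"``
        (per-capita household income in minimum wages).
    wave : ``2013`` or ``2019``.

    Returns
    -------
    GroupedDistribution with shares renormalized to sum to 1 and
    prevalences on the proportion scale.  Known data-quality issues are
    recorded in ``flags``.
    """
    wave = str(wave)
    key = (group, wave)
    if key not in _PNS:
        raise KeyError(f"no reference distribution for {group!r}, wave {wave!r}")
    table = _PNS[key]
    labels = tuple(table)
    shares = [table[l][0] / 100.0 for l in labels]
    total = sum(shares)
    shares = tuple(s / total for s in shares)
    prevalences = tuple(table[l][1] / 100.0 for l in labels)
    flags = (_FLAGGED[key],) if key in _FLAGGED else ()
    return GroupedDistribution(
        labels=labels,
        shares=shares,
        prevalences=prevalences,
        domain="Brazil",
        wave=wave,
        flags=flags,
    )
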