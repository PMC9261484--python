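"""Packaged transcriptions of the study's printed summary tables.

The source publication deposits no raw per-fish data; what it prints are
summary tables: the pooled prey-composition table (occurrence, numeric
and weight percentages plus per-estuary %IRI and vacuity rates), the
per-estuary/station isotope summaries, and the diet / isotopic-niche
overlap matrices. These transcriptions are the package's reference
inputs: the diet table alone is sufficient to recompute the index of
relative importance, the category and habitat-origin roll-ups, and the
Schoener overlaps, and the summaries parameterize the paper-like
synthetic generator.

Blank cells are missing values (the prey was not observed in that
estuary), not zeros. Censored entries printed as ``<0.01`` are parsed to
half the bound (0.005) by the shared censoring convention.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .data_model import parse_censored

__all__ = ["FIXTURE_NAMES", "load_fixture"]

FIXTURE_NAMES = (
    "table1_design",
    "table2_diet",
    "table2_vacuity",
    "table3_isotopes",
    "table4_overlap",
)

_CENSORED_COLUMNS = {
    "table2_diet": (
        "pctFO", "pctN", "pctW",
        "pct_iri_slack", "pct_iri_wimereux", "pct_iri_liane",
        "pct_iri_canche", "pct_iri_authie", "pct_iri_somme", "pct_iri_total",
    ),
}


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged table transcription by name.

    Parameters
    ----------
    name
        One of ``table1_design`` (sampling design: n per estuary and
        station, length summaries), ``table2_diet`` (32 prey taxa with
        %FO/%N/%W and per-estuary %IRI), ``table2_vacuity`` (per-estuary
        empty-gut percentages), ``table3_isotopes`` (per estuary and
        station δ13C/δ15N means ± SD, hull area TA, corrected ellipse
        area SEAc, trophic position TP) or ``table4_overlap`` (tidy
        Schoener and isotopic niche-region overlap percentages).
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    with resources.files(__package__).joinpath(f"fixtures/{name}.csv").open() as handle:
        table = pd.read_csv(handle, dtype=str, keep_default_na=False)
    for column in table.columns:
        if column in _CENSORED_COLUMNS.get(name, table.columns):
            parsed = table[column].map(parse_censored) if _is_numeric(table[column]) else None
            if parsed is not None:
                table[column] = parsed
    return table


def _is_numeric(series: pd.Series) -> bool:
    for value in series:
        text = str(value).strip()
        if not text:
            continue
        if text.startswith("<"):
            text = text[1:]
        try:
            float(text)
        except ValueError:
            return False
    return True
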