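"""Typed records and delimited-text I/O for trophic-niche datasets.

A dataset is five tidy tables (one record per row):

``fish``
    one sampled fish per row — ``fish_id``, ``estuary``, ``station``,
    ``season``, ``total_length`` (mm), optional ``body_weight`` (g) and
    ``silvering_stage``, and a boolean ``gut_empty``.
``prey_items``
    one counted, weighed gut-content item per row — ``fish_id``,
    ``taxon_name``, ``count`` (individuals), ``weight`` (g).
``taxonomy``
    one prey taxon per row — ``taxon_name``, higher ``category``
    (e.g. Malacostraca), and ``habitat_origin`` from the five-letter
    salinity-habitat vocabulary (M, MB, MBF, F, T).
``isotopes``
    one muscle sample per row — ``fish_id``, ``delta13C`` (‰ vs VPDB),
    ``delta15N`` (‰ vs atmospheric N2), optional ``cn_ratio``.
``baselines``
    baseline δ15N per estuary/station/season with its trophic level
    (``tp_base``, conventionally 1 for primary resources).

Referential integrity and closed vocabularies are enforced when the
:class:`Dataset` is constructed, not when it is used.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "STATIONS",
    "SEASONS",
    "SILVERING_STAGES",
    "HABITAT_ORIGINS",
    "SchemaError",
    "IntegrityError",
    "VocabularyError",
    "parse_censored",
    "Dataset",
    "read_dataset",
    "write_report",
]

STATIONS = ("lower", "middle", "upper")
SEASONS = ("winter", "spring", "summer", "autumn")
SILVERING_STAGES = ("OH", "FII", "FIII", "FIV", "FV", "MII")
HABITAT_ORIGINS = ("M", "MB", "MBF", "F", "T")


class SchemaError(ValueError):
    """A required column is missing or has the wrong type."""


class IntegrityError(ValueError):
    """A cross-table reference points at a record that does not exist."""


class VocabularyError(ValueError):
    """A token is not in the closed vocabulary for its column."""


def parse_censored(value) -> float:
    """Parse a possibly censored numeral such as ``"<0.01"``.

    Censored entries (detection/rounding limits printed as ``<bound``)
    are parsed to half the censoring bound — the midpoint convention.
    Plain numerals pass through unchanged; blanks become NaN.
    """
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return float("nan")
    text = str(value).strip()
    if not text:
        return float("nan")
    if text.startswith("<"):
        return float(text[1:]) / 2.0
    return float(text)


def _canonicalize(series: pd.Series, vocabulary: tuple[str, ...], column: str) -> pd.Series:
    """Map case-insensitive tokens to canonical case; reject unknown ones."""
    lookup = {v.lower(): v for v in vocabulary}
    out = []
    for raw in series:
        if raw is None or (isinstance(raw, float) and math.isnan(raw)):
            out.append(None)
            continue
        token = str(raw).strip()
        if not token:
            out.append(None)
            continue
        try:
            out.append(lookup[token.lower()])
        except KeyError:
            raise VocabularyError(
                f"unknown token {token!r} in column {column!r}; "
                f"expected one of {vocabulary}"
            ) from None
    return pd.Series(out, index=series.index, dtype=object)


_REQUIRED = {
    "fish": ("fish_id", "estuary", "station", "season", "total_length", "gut_empty"),
    "prey_items": ("fish_id", "taxon_name", "count", "weight"),
    "taxonomy": ("taxon_name", "category", "habitat_origin"),
    "isotopes": ("fish_id", "delta13C", "delta15N"),
    "baselines": ("estuary", "station", "season", "delta15N_base"),
}


def _require_columns(df: pd.DataFrame, table: str) -> None:
    for column in _REQUIRED[table]:
        if column not in df.columns:
            raise SchemaError(f"table {table!r} is missing required column {column!r}")


@dataclass
class Dataset:
    """In-memory dataset: five cross-validated tidy tables."""

    fish: pd.DataFrame
    prey: pd.DataFrame
    taxonomy: pd.DataFrame
    isotopes: pd.DataFrame = field(default_factory=pd.DataFrame)
    baselines: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        _require_columns(self.fish, "fish")
        _require_columns(self.prey, "prey_items")
        _require_columns(self.taxonomy, "taxonomy")
        if len(self.isotopes):
            _require_columns(self.isotopes, "isotopes")
        if len(self.baselines):
            _require_columns(self.baselines, "baselines")

        fish = self.fish
        if fish["fish_id"].duplicated().any():
            dup = fish.loc[fish["fish_id"].duplicated(), "fish_id"].iloc[0]
            raise IntegrityError(f"duplicate fish_id {dup!r}")
        if (pd.to_numeric(fish["total_length"]) <= 0).any():
            raise SchemaError("total_length must be positive")
        fish["station"] = _canonicalize(fish["station"], STATIONS, "station")
        fish["season"] = _canonicalize(fish["season"], SEASONS, "season")
        if "silvering_stage" in fish.columns:
            fish["silvering_stage"] = _canonicalize(
                fish["silvering_stage"], SILVERING_STAGES, "silvering_stage"
            )
        fish["gut_empty"] = fish["gut_empty"].map(_parse_bool)

        taxonomy = self.taxonomy
        if taxonomy["taxon_name"].duplicated().any():
            dup = taxonomy.loc[taxonomy["taxon_name"].duplicated(), "taxon_name"].iloc[0]
            raise IntegrityError(f"duplicate taxon_name {dup!r} in taxonomy")
        taxonomy["habitat_origin"] = _canonicalize(
            taxonomy["habitat_origin"], HABITAT_ORIGINS, "habitat_origin"
        )

        prey = self.prey
        known_fish = set(fish["fish_id"])
        for fid in prey["fish_id"]:
            if fid not in known_fish:
                raise IntegrityError(f"prey item references unknown fish_id {fid!r}")
        known_taxa = set(taxonomy["taxon_name"])
        for taxon in prey["taxon_name"]:
            if taxon not in known_taxa:
                raise IntegrityError(f"prey item references unknown taxon {taxon!r}")
        if len(prey):
            if (pd.to_numeric(prey["count"]) < 1).any():
                raise SchemaError("prey count must be >= 1 for a recorded item")
            if (pd.to_numeric(prey["weight"]) < 0).any():
                raise SchemaError("prey weight must be non-negative")
        # a fish flagged gut_empty must carry no prey items
        empty_ids = set(fish.loc[fish["gut_empty"], "fish_id"])
        offending = empty_ids & set(prey["fish_id"])
        if offending:
            raise IntegrityError(
                f"fish {sorted(offending)[0]!r} is flagged gut_empty but has prey items"
            )

        if len(self.isotopes):
            iso = self.isotopes
            for fid in iso["fish_id"]:
                if fid not in known_fish:
                    raise IntegrityError(f"isotope record references unknown fish_id {fid!r}")
            if "cn_ratio" not in iso.columns:
                iso["cn_ratio"] = np.nan
        if len(self.baselines):
            base = self.baselines
            base["station"] = _canonicalize(base["station"], STATIONS, "station")
            base["season"] = _canonicalize(base["season"], SEASONS, "season")
            if "tp_base" not in base.columns:
                base["tp_base"] = 1.0


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in {"true", "1", "yes", "t"}:
        return True
    if text in {"false", "0", "no", "f"}:
        return False
    raise SchemaError(f"cannot interpret {value!r} as a boolean gut_empty flag")


def read_dataset(paths: Mapping[str, str | Path]) -> Dataset:
    """Read a dataset from delimited-text tables.

    Parameters
    ----------
    paths
        Mapping with keys ``fish``, ``prey_items``, ``taxonomy``,
        ``isotopes`` (optional) and ``baselines`` (optional), each a
        path to a comma-separated UTF-8 file with a header row.
    """
    def _read(key: str, required: bool) -> pd.DataFrame:
        if key not in paths or paths[key] is None:
            if required:
                raise SchemaError(f"no path given for required table {key!r}")
            return pd.DataFrame()
        return pd.read_csv(paths[key])

    fish = _read("fish", required=True)
    prey = _read("prey_items", required=True)
    taxonomy = _read("taxonomy", required=True)
    isotopes = _read("isotopes", required=False)
    baselines = _read("baselines", required=False)
    for df in (prey, isotopes, baselines):
        for column in df.columns:
            if df[column].dtype == object and df[column].astype(str).str.startswith("<").any():
                df[column] = df[column].map(parse_censored)
    return Dataset(fish=fish, prey=prey, taxonomy=taxonomy,
                   isotopes=isotopes, baselines=baselines)


def write_dataset(dataset: Dataset, directory: str | Path) -> dict[str, Path]:
    """Write the dataset back to the standard four/five CSV tables."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    tables = {
        "fish": dataset.fish,
        "prey_items": dataset.prey,
        "taxonomy": dataset.taxonomy,
        "isotopes": dataset.isotopes,
        "baselines": dataset.baselines,
    }
    for name, df in tables.items():
        if not len(df):
            continue
        path = directory / f"{name}.csv"
        df.to_csv(path, index=False)
        written[name] = path
    return written


def _format_float(x) -> str:
    if isinstance(x, (float, np.floating)):
        if math.isnan(x):
            return ""
        return f"{x:.6g}"
    return str(x)


def write_report(results, path: str | Path, format: str = "delimited") -> None:
    """Write a stage result byte-stably (sorted keys, 6 significant digits).

    ``results`` may be a DataFrame/Series (``delimited``) or any nesting
    of dicts/lists/scalars (``json``).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "delimited":
        if isinstance(results, pd.Series):
            results = results.rename("value").rename_axis("key").reset_index()
        if not isinstance(results, pd.DataFrame):
            raise TypeError("delimited output requires a DataFrame or Series")
        out = results.copy()
        for column in out.columns:
            out[column] = out[column].map(_format_float)
        out.to_csv(path, index=False)
    elif format == "json":
        path.write_text(json.dumps(_jsonable(results), sort_keys=True, indent=1) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return [_jsonable(rec) for rec in obj.to_dict(orient="records")]
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return float(f"{float(obj):.6g}") if math.isfinite(obj) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj
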