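"""Gut-content analysis: composition percentages, IRI, vacuity, overlap.

The diet of a group of fish is summarized per prey taxon by three
percentages — relative abundance (%N, share of prey individuals),
relative weight (%W, share of prey mass) and frequency of occurrence
(%FO, share of non-empty guts containing the taxon) — combined into the
index of relative importance

    IRI_i = (%N_i + %W_i) × %FO_i

and normalized to %IRI = 100 · IRI_i / Σ_j IRI_j. The parenthesized
(Pinkas) form is used: the occurrence percentage multiplies the sum of
the abundance and weight percentages.

Diet similarity between two groups is the Schoener overlap
α = 1 − ½ Σ_i |P_xi − P_yi| over diet proportions, conventionally called
significant at α ≥ 0.6.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .data_model import Dataset

__all__ = [
    "DietTable",
    "SchoenerResult",
    "prey_percentages",
    "iri_table",
    "category_iri",
    "habitat_composition",
    "vacuity_rate",
    "schoener_overlap",
    "overlap_matrix",
]

SDOI_SIGNIFICANCE = 0.6  # conventional threshold for "significant" diet overlap


@dataclass
class DietTable:
    """Per-group, per-taxon diet composition.

    ``data`` has the grouping columns, ``taxon``, and the percentage
    columns (``pctN``, ``pctW``, ``pctFO``, and after :func:`iri_table`
    also ``iri`` and ``pct_iri``). ``empty_groups`` lists groups whose
    guts were all empty: their metrics are undefined and they carry no
    rows, rather than rows of silent zeros.
    """

    data: pd.DataFrame
    group_keys: list[str]
    empty_groups: list[tuple] = field(default_factory=list)

    def groups(self) -> list[tuple]:
        if not self.group_keys:
            return [()]
        return sorted(set(map(tuple, self.data[self.group_keys].itertuples(index=False))))

    def composition(self, group: tuple | None = None, column: str = "pct_iri") -> pd.Series:
        """Taxon-indexed composition column for one group (or the whole table)."""
        df = self.data
        if group is not None and self.group_keys:
            mask = np.ones(len(df), dtype=bool)
            for key, value in zip(self.group_keys, group):
                mask &= df[key] == value
            df = df[mask]
        return df.set_index("taxon")[column]


class SchoenerResult(NamedTuple):
    alpha: float
    significant: bool


def _grouped_fish(dataset: Dataset, group_by: Sequence[str] | None):
    fish = dataset.fish
    if not group_by:
        return [((), fish)]
    return [
        (key if isinstance(key, tuple) else (key,), sub)
        for key, sub in fish.groupby(list(group_by), sort=True)
    ]


def prey_percentages(dataset: Dataset, group_by: Sequence[str] | None = None) -> DietTable:
    """Per-taxon %N, %W and %FO within each group of fish.

    %FO uses the number of *non-empty* guts in the group as its
    denominator: occurrence is a statement about feeding fish. Groups
    containing only empty guts are listed in ``empty_groups``.
    """
    group_by = list(group_by or [])
    prey = dataset.prey
    rows = []
    empty_groups: list[tuple] = []
    for key, fish_sub in _grouped_fish(dataset, group_by):
        feeding = fish_sub.loc[~fish_sub["gut_empty"], "fish_id"]
        n_feeding = len(feeding)
        if n_feeding == 0:
            empty_groups.append(key)
            continue
        items = prey[prey["fish_id"].isin(set(feeding))]
        if not len(items):
            empty_groups.append(key)
            continue
        counts = items.groupby("taxon_name")["count"].sum()
        weights = items.groupby("taxon_name")["weight"].sum()
        occurrence = items.groupby("taxon_name")["fish_id"].nunique()
        for taxon in counts.index:
            rows.append(
                dict(zip(group_by, key))
                | {
                    "taxon": taxon,
                    "pctN": 100.0 * counts[taxon] / counts.sum(),
                    "pctW": 100.0 * weights[taxon] / weights.sum(),
                    "pctFO": 100.0 * occurrence[taxon] / n_feeding,
                }
            )
    data = pd.DataFrame(rows, columns=group_by + ["taxon", "pctN", "pctW", "pctFO"])
    return DietTable(data=data, group_keys=group_by, empty_groups=empty_groups)


def iri_table(percentages: DietTable | pd.DataFrame) -> DietTable:
    """Add IRI = (%N + %W) × %FO and its normalized %IRI per group."""
    if isinstance(percentages, pd.DataFrame):
        percentages = DietTable(data=percentages.copy(), group_keys=[])
    df = percentages.data.copy()
    for column in ("pctN", "pctW", "pctFO"):
        if column not in df.columns:
            raise KeyError(f"missing column {column!r}; run prey_percentages first")
    df["iri"] = (df["pctN"] + df["pctW"]) * df["pctFO"]
    if percentages.group_keys:
        totals = df.groupby(percentages.group_keys)["iri"].transform("sum")
    else:
        totals = df["iri"].sum()
    if np.any(np.asarray(totals) <= 0):
        raise ValueError("IRI sums to zero within a group; %IRI is undefined")
    df["pct_iri"] = 100.0 * df["iri"] / totals
    return DietTable(data=df, group_keys=percentages.group_keys,
                     empty_groups=list(percentages.empty_groups))


def category_iri(table: DietTable, taxonomy: pd.DataFrame) -> DietTable:
    """Aggregate %IRI over higher taxonomic categories (sum of members)."""
    mapping = taxonomy.set_index("taxon_name")["category"]
    df = table.data.copy()
    unmapped = set(df["taxon"]) - set(mapping.index)
    if unmapped:
        raise KeyError(f"taxa without a category mapping: {sorted(unmapped)}")
    df["category"] = df["taxon"].map(mapping)
    keys = table.group_keys + ["category"]
    out = (
        df.groupby(keys, sort=True)[["iri", "pct_iri"]]
        .sum()
        .reset_index()
        .rename(columns={"category": "taxon"})
    )
    return DietTable(data=out, group_keys=table.group_keys,
                     empty_groups=list(table.empty_groups))


def habitat_composition(table: DietTable, taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Share of %IRI contributed by each prey habitat origin.

    Origins are the salinity-habitat classes (M, MB, MBF, F, T); taxa
    without an assigned origin are kept in an explicit ``unknown`` bin so
    the shares still sum to 100 within each group.
    """
    mapping = taxonomy.set_index("taxon_name")["habitat_origin"]
    df = table.data.copy()
    origin = df["taxon"].map(mapping)
    df["habitat_origin"] = origin.where(origin.notna() & (origin != ""), "unknown")
    keys = table.group_keys + ["habitat_origin"]
    out = df.groupby(keys, sort=True)["pct_iri"].sum().rename("pct").reset_index()
    return out


def vacuity_rate(dataset: Dataset, group_by: Sequence[str] | None = None) -> pd.DataFrame:
    """Percentage of fish with an empty gut, per group."""
    group_by = list(group_by or [])
    rows = []
    for key, fish_sub in _grouped_fish(dataset, group_by):
        if not len(fish_sub):
            raise ValueError(f"empty group {key!r}")
        rows.append(
            dict(zip(group_by, key))
            | {
                "n": len(fish_sub),
                "n_empty": int(fish_sub["gut_empty"].sum()),
                "vacuity_pct": 100.0 * fish_sub["gut_empty"].mean(),
            }
        )
    return pd.DataFrame(rows, columns=group_by + ["n", "n_empty", "vacuity_pct"])


def schoener_overlap(profile_x: pd.Series, profile_y: pd.Series) -> SchoenerResult:
    """Schoener overlap α = 1 − ½ Σ|P_xi − P_yi| between two diet profiles.

    Profiles are aligned on the union of taxa (absent taxon → 0) and
    renormalized to proportions, so inputs may be percentages — including
    printed columns that sum to 99.9 from rounding.
    """
    x = profile_x.fillna(0.0).astype(float)
    y = profile_y.fillna(0.0).astype(float)
    taxa = x.index.union(y.index)
    x = x.reindex(taxa, fill_value=0.0)
    y = y.reindex(taxa, fill_value=0.0)
    if x.sum() <= 0 or y.sum() <= 0:
        raise ValueError("a diet profile sums to zero; overlap is undefined")
    px = x / x.sum()
    py = y / y.sum()
    alpha = float(1.0 - 0.5 * np.abs(px - py).sum())
    alpha = min(max(alpha, 0.0), 1.0)
    return SchoenerResult(alpha=alpha, significant=alpha >= SDOI_SIGNIFICANCE)


def overlap_matrix(
    tables: DietTable | dict[str, pd.Series],
    taxonomy: pd.DataFrame | None = None,
    level: str = "taxon",
) -> pd.DataFrame:
    """Pairwise Schoener overlap between diet groups.

    ``tables`` is either an IRI :class:`DietTable` grouped by one or more
    keys, or a mapping of group label → composition Series. ``level``
    chooses the aggregation: raw taxa or higher categories (the latter
    needs ``taxonomy``). Returns a symmetric DataFrame of proportions in
    [0, 1] with a unit diagonal.
    """
    if isinstance(tables, DietTable):
        work = tables
        if level == "category":
            if taxonomy is None:
                raise ValueError("category-level overlap requires a taxonomy table")
            work = category_iri(work, taxonomy)
        elif level != "taxon":
            raise ValueError(f"unknown aggregation level {level!r}")
        profiles = {
            " / ".join(map(str, group)): work.composition(group)
            for group in work.groups()
        }
    else:
        profiles = dict(tables)
    labels = list(profiles)
    if len(labels) < 2:
        raise ValueError("overlap matrix needs at least two groups")
    values = np.eye(len(labels))
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            alpha = schoener_overlap(profiles[a], profiles[labels[j]]).alpha
            values[i, j] = values[j, i] = alpha
    return pd.DataFrame(values, index=labels, columns=labels)
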