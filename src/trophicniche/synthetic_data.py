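"""Synthetic datasets with the estuary study's structure.

The generator emulates a 6-estuary × 3-salinity-station × 4-season
sampling design. Per fish: the gut is empty with the estuary's vacuity
probability; otherwise a prey-item count vector is drawn
Dirichlet-multinomial around the estuary's diet composition (moderate
inter-fish heterogeneity via the Dirichlet concentration), with
per-individual prey masses lognormal around per-taxon medians — so
weight and numeric compositions differ informatively. Isotope values are
bivariate normal at the fish's estuary × station niche, with δ13C
enriched toward the seaward (lower) station and δ15N likewise highest
seaward, mirroring the study's salinity gradients. Baselines are emitted
noiselessly per estuary × station × season so trophic-position recovery
is limited only by isotope noise.

:func:`paperlike_config` anchors every parameter to the printed summary
tables: per-estuary diet compositions are the %IRI columns of the pooled
prey table, vacuity the printed per-estuary rates, isotope means and
covariances the per-station summaries, and sample sizes the sampling
design table. :class:`GroundTruth` carries the exact quantities the
configuration implies, including the diet percentages expected from the
Dirichlet-multinomial model in closed form, for parameter-recovery
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2, poisson

from .data_model import Dataset, SEASONS, STATIONS
from .fixtures import load_fixture

__all__ = ["SyntheticConfig", "GroundTruth", "generate", "default_config", "paperlike_config"]


@dataclass
class SyntheticConfig:
    """Full parameterization of the synthetic study.

    ``diet_compositions`` maps estuary → probability vector over
    ``taxa``; ``isotope_means``/``isotope_cov`` map (estuary, station) →
    bivariate (δ13C, δ15N) mean and 2×2 covariance; ``n_fish`` is either
    a constant per estuary × station × season cell or a mapping from
    (estuary, station, season). ``dispersion`` is the Dirichlet
    concentration controlling inter-fish diet heterogeneity;
    ``mean_items`` the mean number of prey individuals per non-empty
    gut; ``prey_mass_median``/``prey_mass_sigma`` the per-taxon
    lognormal individual-mass model (grams). ``baseline_offset`` places
    the δ15N baseline that many ‰ below each group's consumer mean.
    """

    taxa: list[str]
    taxonomy: pd.DataFrame
    estuaries: list[str]
    diet_compositions: dict[str, np.ndarray]
    vacuity: dict[str, float]
    isotope_means: dict[tuple[str, str], tuple[float, float]]
    isotope_cov: dict[tuple[str, str], np.ndarray]
    n_fish: Mapping[tuple[str, str, str], int] | int = 5
    prey_mass_median: np.ndarray | None = None
    prey_mass_sigma: float = 0.5
    mean_items: float = 20.0
    dispersion: float = 50.0
    length_mean: float = 450.0
    length_sd: float = 130.0
    baseline_offset: float = 8.5
    stations: tuple[str, ...] = STATIONS
    seasons: tuple[str, ...] = SEASONS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.prey_mass_median is None:
            self.prey_mass_median = np.full(len(self.taxa), 0.1)
        self.prey_mass_median = np.asarray(self.prey_mass_median, dtype=float)
        for estuary, comp in self.diet_compositions.items():
            comp = np.asarray(comp, dtype=float)
            if comp.shape != (len(self.taxa),):
                raise ValueError(f"composition for {estuary!r} has the wrong length")
            if np.any(comp < 0) or not np.isclose(comp.sum(), 1.0):
                raise ValueError(f"composition for {estuary!r} must be proportions summing to 1")
            self.diet_compositions[estuary] = comp
        for key, cov in self.isotope_cov.items():
            cov = np.asarray(cov, dtype=float)
            if np.any(np.linalg.eigvalsh(cov) <= 0):
                raise ValueError(f"isotope covariance for {key!r} is not positive definite")
            self.isotope_cov[key] = cov

    def cell_n(self, estuary: str, station: str, season: str) -> int:
        if isinstance(self.n_fish, Mapping):
            return int(self.n_fish.get((estuary, station, season), 0))
        return int(self.n_fish)


def _expected_fo(composition: np.ndarray, dispersion: float, mean_items: float) -> np.ndarray:
    """P(taxon present in a non-empty gut) under Dirichlet-multinomial.

    Marginally each taxon's count is beta-binomial; the absence
    probability given k items is a ratio of rising factorials, averaged
    over the shifted-Poisson item count K = 1 + Poisson(mean_items − 1).
    """
    lam = max(mean_items - 1.0, 0.0)
    kmax = int(poisson.ppf(1 - 1e-10, lam)) if lam > 0 else 0
    ks = np.arange(0, kmax + 1)
    pk = poisson.pmf(ks, lam) if lam > 0 else np.array([1.0])
    a0 = dispersion
    ai = dispersion * composition
    items = ks[None, :] + 1  # K = k + 1 >= 1
    log_absent = (
        gammaln(a0 - ai[:, None] + items)
        + gammaln(a0)
        - gammaln(a0 + items)
        - gammaln(a0 - ai[:, None])
    )
    with np.errstate(invalid="ignore"):
        absent = np.where(ai[:, None] > 0, np.exp(log_absent), 1.0)
    return 1.0 - absent @ pk


@dataclass
class GroundTruth:
    """Exact quantities implied by a :class:`SyntheticConfig`."""

    compositions: dict[str, pd.Series]
    expected_diet: dict[str, pd.DataFrame]
    niche: dict[tuple[str, str], dict]
    vacuity: dict[str, float]
    baselines: pd.DataFrame

    def niche_overlap(self, group_a, group_b, alpha: float = 0.95,
                      n_mc: int = 100_000, seed=0) -> float:
        """Percent mass of A's generating normal inside B's α niche region."""
        rng = np.random.default_rng(seed)
        a, b = self.niche[group_a], self.niche[group_b]
        x = rng.multivariate_normal(a["mean"], a["cov"], size=n_mc)
        diff = x - np.asarray(b["mean"])
        mahal2 = np.einsum("ni,ij,nj->n", diff, np.linalg.inv(b["cov"]), diff)
        return 100.0 * float((mahal2 <= chi2.ppf(alpha, df=2)).mean())


def _ground_truth(config: SyntheticConfig) -> GroundTruth:
    mean_mass = config.prey_mass_median * np.exp(config.prey_mass_sigma**2 / 2)
    expected_diet = {}
    compositions = {}
    for estuary in config.estuaries:
        comp = config.diet_compositions[estuary]
        pct_n = 100.0 * comp
        w = comp * mean_mass
        pct_w = 100.0 * w / w.sum()
        pct_fo = 100.0 * _expected_fo(comp, config.dispersion, config.mean_items)
        iri = (pct_n + pct_w) * pct_fo
        table = pd.DataFrame(
            {
                "taxon": config.taxa,
                "pctN": pct_n,
                "pctW": pct_w,
                "pctFO": pct_fo,
                "pct_iri": 100.0 * iri / iri.sum(),
            }
        )
        expected_diet[estuary] = table
        compositions[estuary] = pd.Series(comp, index=config.taxa)
    niche = {
        key: {
            "mean": np.asarray(mean, dtype=float),
            "cov": config.isotope_cov[key],
            "sea": float(np.pi * np.sqrt(np.linalg.det(config.isotope_cov[key]))),
        }
        for key, mean in config.isotope_means.items()
    }
    baseline_rows = [
        {
            "estuary": estuary,
            "station": station,
            "season": season,
            "delta15N_base": config.isotope_means[(estuary, station)][1] - config.baseline_offset,
            "tp_base": 1.0,
        }
        for estuary in config.estuaries
        for station in config.stations
        for season in config.seasons
        if (estuary, station) in config.isotope_means
    ]
    return GroundTruth(
        compositions=compositions,
        expected_diet=expected_diet,
        niche=niche,
        vacuity=dict(config.vacuity),
        baselines=pd.DataFrame(baseline_rows),
    )


def generate(config: SyntheticConfig, seed=None) -> tuple[Dataset, GroundTruth]:
    """Draw one dataset from the configuration; reproducible under seed."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    truth = _ground_truth(config)
    fish_rows, prey_rows, iso_rows = [], [], []
    taxa = np.array(config.taxa)
    for estuary in config.estuaries:
        comp = config.diet_compositions[estuary]
        support = np.where(comp > 0)[0]
        alpha = config.dispersion * comp[support]
        for station in config.stations:
            mean = np.asarray(config.isotope_means[(estuary, station)], dtype=float)
            cov = config.isotope_cov[(estuary, station)]
            for season in config.seasons:
                for k in range(config.cell_n(estuary, station, season)):
                    fish_id = f"{estuary}-{station}-{season}-{k:03d}"
                    empty = bool(rng.random() < config.vacuity[estuary])
                    length = max(float(rng.normal(config.length_mean, config.length_sd)), 120.0)
                    fish_rows.append(
                        {
                            "fish_id": fish_id,
                            "estuary": estuary,
                            "station": station,
                            "season": season,
                            "total_length": round(length, 1),
                            "gut_empty": empty,
                        }
                    )
                    if not empty:
                        probs = rng.dirichlet(alpha)
                        n_items = 1 + (rng.poisson(config.mean_items - 1)
                                       if config.mean_items > 1 else 0)
                        counts = rng.multinomial(n_items, probs)
                        for local_idx, count in enumerate(counts):
                            if count == 0:
                                continue
                            taxon_idx = support[local_idx]
                            masses = config.prey_mass_median[taxon_idx] * np.exp(
                                rng.normal(0.0, config.prey_mass_sigma, size=count)
                            )
                            prey_rows.append(
                                {
                                    "fish_id": fish_id,
                                    "taxon_name": taxa[taxon_idx],
                                    "count": int(count),
                                    "weight": float(masses.sum()),
                                }
                            )
                    d13c, d15n = rng.multivariate_normal(mean, cov)
                    iso_rows.append(
                        {
                            "fish_id": fish_id,
                            "delta13C": float(d13c),
                            "delta15N": float(d15n),
                            "cn_ratio": float(np.clip(rng.normal(3.3, 0.25), 2.5, 4.5)),
                        }
                    )
    dataset = Dataset(
        fish=pd.DataFrame(fish_rows),
        prey=pd.DataFrame(prey_rows, columns=["fish_id", "taxon_name", "count", "weight"]),
        taxonomy=config.taxonomy.copy(),
        isotopes=pd.DataFrame(iso_rows),
        baselines=truth.baselines.copy(),
    )
    return dataset, truth


def default_config(n_fish: int = 5, seed: int = 0) -> SyntheticConfig:
    """A generic study-structured configuration with monotone gradients.

    Six estuaries share a 12-taxon pool with estuary-specific diet
    compositions; δ13C is enriched by 1.5‰ per step toward the seaward
    station and δ15N by 0.8‰, both strictly monotone along the gradient.
    """
    taxa = [
        "amphipod_a", "amphipod_b", "crab_a", "shrimp_a",
        "polychaete_a", "insect_a", "insect_b", "gastropod_a",
        "bivalve_a", "fish_a", "fish_b", "fish_c",
    ]
    taxonomy = pd.DataFrame(
        {
            "taxon_name": taxa,
            "category": [
                "Malacostraca", "Malacostraca", "Malacostraca", "Malacostraca",
                "Polychaeta", "Insecta", "Insecta", "Gastropoda",
                "Bivalvia", "Actinopterygii", "Actinopterygii", "Actinopterygii",
            ],
            "habitat_origin": ["MB", "MBF", "M", "M", "MBF", "F", "F", "F",
                               "M", "MBF", "MB", "MBF"],
        }
    )
    estuaries = ["Slack", "Wimereux", "Liane", "Canche", "Authie", "Somme"]
    rng = np.random.default_rng(seed)
    compositions = {}
    for i, estuary in enumerate(estuaries):
        base = rng.dirichlet(np.full(len(taxa), 2.0))
        # small estuaries fish-dominated, large ones crustacean-dominated
        tilt = np.ones(len(taxa))
        if i < 3:
            tilt[9:] = 4.0
        else:
            tilt[:4] = 4.0
        comp = base * tilt
        compositions[estuary] = comp / comp.sum()
    vacuity = {e: 0.2 for e in estuaries}
    isotope_means = {}
    isotope_cov = {}
    for i, estuary in enumerate(estuaries):
        d13c_upper = -28.0 + 0.5 * i
        d15n_upper = 13.0 + 0.4 * i
        for j, station in enumerate(("upper", "middle", "lower")):
            isotope_means[(estuary, station)] = (
                d13c_upper + 1.5 * j,  # enrichment toward the sea
                d15n_upper + 0.8 * j,
            )
            isotope_cov[(estuary, station)] = np.array([[1.2, 0.2], [0.2, 0.8]])
    mass = np.array([0.03, 0.03, 2.0, 0.4, 0.3, 0.01, 0.01, 0.2, 0.5, 5.0, 3.0, 4.0])
    return SyntheticConfig(
        taxa=taxa,
        taxonomy=taxonomy,
        estuaries=estuaries,
        diet_compositions=compositions,
        vacuity=vacuity,
        isotope_means=isotope_means,
        isotope_cov=isotope_cov,
        n_fish=n_fish,
        prey_mass_median=mass,
        seed=seed,
    )


def paperlike_config(n_scale: float = 1.0, seed: int = 0) -> SyntheticConfig:
    """Configuration anchored to the study's printed summary tables.

    Diet compositions are the per-estuary %IRI columns of the pooled
    prey table (blanks → 0, renormalized); vacuity the printed
    per-estuary rates; isotope means and diagonal covariances the
    per-station δ summaries; per-cell sample sizes the design table's
    station counts spread over the four seasons. Per-taxon mass medians
    are set from the pooled weight-to-number ratio (%W/%N), which is the
    mass scale the printed compositions imply, times a 0.1 g reference
    amphipod mass. ``n_scale`` multiplies every cell's sample size for
    recovery tests.
    """
    diet = load_fixture("table2_diet")
    vacuity_tbl = load_fixture("table2_vacuity")
    iso = load_fixture("table3_isotopes")
    design = load_fixture("table1_design")

    taxa = diet["taxon"].tolist()
    taxonomy = diet[["taxon", "category", "habitat_origin"]].rename(
        columns={"taxon": "taxon_name"}
    )
    estuaries = ["Slack", "Wimereux", "Liane", "Canche", "Authie", "Somme"]
    compositions = {}
    for estuary in estuaries:
        column = diet[f"pct_iri_{estuary.lower()}"].fillna(0.0).to_numpy(dtype=float)
        compositions[estuary] = column / column.sum()
    vacuity = {
        row["estuary"]: float(row["vacuity_pct"]) / 100.0
        for _, row in vacuity_tbl.iterrows()
        if row["estuary"] != "Total"
    }
    isotope_means = {}
    isotope_cov = {}
    for _, row in iso.iterrows():
        key = (row["estuary"], row["station"])
        isotope_means[key] = (float(row["d13c_mean"]), float(row["d15n_mean"]))
        sd13 = float(row["d13c_sd"]) if row["d13c_sd"] == row["d13c_sd"] else 1.0
        sd15 = float(row["d15n_sd"]) if row["d15n_sd"] == row["d15n_sd"] else 1.0
        isotope_cov[key] = np.diag([max(sd13, 0.2) ** 2, max(sd15, 0.2) ** 2])
    n_fish = {}
    for _, row in design.iterrows():
        total = int(float(row["n"]))
        per_season = np.full(len(SEASONS), total // len(SEASONS), dtype=int)
        per_season[: total % len(SEASONS)] += 1
        for season, count in zip(SEASONS, per_season):
            n_fish[(row["estuary"], row["station"], season)] = int(round(count * n_scale))
    ratio = (diet["pctW"] / diet["pctN"]).to_numpy(dtype=float)
    mass = 0.1 * ratio / ratio[taxa.index("Gammarus zaddachi")]
    return SyntheticConfig(
        taxa=taxa,
        taxonomy=taxonomy,
        estuaries=estuaries,
        diet_compositions=compositions,
        vacuity=vacuity,
        isotope_means=isotope_means,
        isotope_cov=isotope_cov,
        n_fish=n_fish,
        prey_mass_median=mass,
        seed=seed,
    )
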