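"""End-to-end orchestration: diet → overlap → isotopes → niches → stats.

Runs every analysis stage on one dataset with a single validated
configuration, writing each stage's artifact to the output directory
along with a machine-readable manifest (config hash, seed, package
version). A single user-facing seed fans out to per-stage seeds by
stable hashing of the stage name, so stages are independently
reproducible and uncorrelated.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data_model import Dataset, write_report
from . import diet_metrics as dm
from . import isotope_niche as iso
from . import community_stats as cs

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]


@dataclass
class PipelineConfig:
    """Validated parameters for a full pipeline run."""

    out_dir: str
    group_by: list[str] = field(default_factory=lambda: ["estuary"])
    tdf: float = 3.4
    tp_base: float = 1.0
    overlap_level: str = "taxon"
    alpha: float = 0.95
    n_iter: int = 10_000
    n_perm: int = 9999
    simprof_perm: int = 999
    seed: int = 0

    def __post_init__(self) -> None:
        if self.overlap_level not in ("taxon", "category"):
            raise ValueError("overlap_level must be 'taxon' or 'category'")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if min(self.n_iter, self.n_perm, self.simprof_perm) < 1:
            raise ValueError("iteration and permutation counts must be positive")
        if self.tdf <= 0:
            raise ValueError("tdf must be positive")


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed below 2^31 by hashing the stage name."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def run_pipeline(dataset: Dataset, config: PipelineConfig) -> dict[str, Path]:
    """Run all stages; returns a mapping of stage name → artifact path.

    Stages needing isotope data are skipped (and logged) when the
    dataset has none. Any stage error aborts with the stage name;
    artifacts already written are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    stage = "init"
    try:
        # --- diet stages -------------------------------------------------
        stage = "diet"
        t0 = time.perf_counter()
        pct = dm.prey_percentages(dataset, config.group_by)
        iri = dm.iri_table(pct)
        write_report(iri.data, out / "diet.csv")
        artifacts["diet"] = out / "diet.csv"

        stage = "vacuity"
        vac = dm.vacuity_rate(dataset, config.group_by)
        write_report(vac, out / "vacuity.csv")
        artifacts["vacuity"] = out / "vacuity.csv"

        stage = "habitat"
        habitat = dm.habitat_composition(iri, dataset.taxonomy)
        write_report(habitat, out / "habitat.csv")
        artifacts["habitat"] = out / "habitat.csv"

        stage = "sdoi"
        sdoi = dm.overlap_matrix(iri, dataset.taxonomy, level=config.overlap_level)
        write_report(sdoi.reset_index(names="group"), out / "sdoi.csv")
        artifacts["sdoi"] = out / "sdoi.csv"
        logger.info("diet stages done in %.2fs", time.perf_counter() - t0)

        # --- diet community statistics ----------------------------------
        stage = "diet_stats"
        t0 = time.perf_counter()
        wide = iri.data.pivot_table(
            index=config.group_by or None, columns="taxon",
            values="pct_iri", fill_value=0.0, aggfunc="sum",
        ) if config.group_by else None
        per_fish = _per_fish_diet(dataset)
        groups = dataset.fish.set_index("fish_id").loc[per_fish.index, config.group_by[0]]
        stats_out: dict[str, object] = {}
        if groups.nunique() >= 2 and groups.value_counts().min() >= 2:
            dist = cs.distance_matrix(per_fish, metric="bray_curtis")
            seed = stage_seed(config.seed, "permanova")
            res = cs.permanova(dist, groups.to_numpy(), n_perm=config.n_perm, seed=seed)
            stats_out["permanova"] = _result_dict(res)
            res_a = cs.anosim(dist, groups.to_numpy(), n_perm=config.n_perm,
                              seed=stage_seed(config.seed, "anosim"))
            stats_out["anosim"] = _result_dict(res_a)
            if groups.nunique() >= 3:
                pairwise = cs.pairwise_permanova(
                    dist, groups.to_numpy(), n_perm=config.n_perm,
                    seed=stage_seed(config.seed, "pairwise"))
                stats_out["pairwise_permanova"] = [_result_dict(r) for r in pairwise]
            simper_res = cs.simper(per_fish, groups.to_numpy())
            stats_out["simper"] = [
                {
                    "group_a": r.group_a,
                    "group_b": r.group_b,
                    "average_dissimilarity": r.average_dissimilarity,
                    "cutoff_set": r.cutoff_set,
                }
                for r in simper_res
            ]
        if wide is not None and len(wide) >= 3:
            part = cs.upgma_simprof(wide, n_perm=config.simprof_perm,
                                    seed=stage_seed(config.seed, "simprof"))
            stats_out["simprof"] = {
                "n_groups": part.n_groups,
                "assignments": {str(k): int(v) for k, v in part.group_assignments.items()},
            }
        write_report(stats_out, out / "diet_stats.json", format="json")
        artifacts["diet_stats"] = out / "diet_stats.json"
        logger.info("diet statistics done in %.2fs", time.perf_counter() - t0)

        # --- isotope stages ----------------------------------------------
        if not len(dataset.isotopes):
            logger.info("no isotope table: isotope stages skipped")
            _write_manifest(out, config, artifacts, skipped=["niche", "niche_overlap",
                                                             "isotope_stats"])
            return artifacts

        stage = "niche"
        t0 = time.perf_counter()
        kept, _ = iso.screen_cn(dataset.isotopes)
        merged = kept.merge(dataset.fish, on="fish_id")
        params = iso.TrophicPositionParams(tdf=config.tdf, tp_base=config.tp_base)
        if len(dataset.baselines):
            tp_values = []
            for _, row in merged.iterrows():
                base = iso.match_baseline(dataset.baselines, row["estuary"],
                                          row["station"], row["season"])
                tp_values.append(float(iso.trophic_position(row["delta15N"],
                                                            (base[0], base[1]), params)))
            merged["tp"] = tp_values
        summaries = []
        groups_points: dict[str, np.ndarray] = {}
        for key, sub in merged.groupby(config.group_by, sort=True):
            key = key if isinstance(key, tuple) else (key,)
            pts = sub[["delta13C", "delta15N"]].to_numpy()
            if len(pts) < 2:
                continue
            summary = iso.niche_summary(
                pts, group_key=key, n_iter=config.n_iter,
                seed=stage_seed(config.seed, f"sea:{key}"))
            record = {k: " / ".join(map(str, key)) for k in ["group"]}
            record.update({
                "n": summary.n, "mean13C": summary.mean13C, "mean15N": summary.mean15N,
                "NR": summary.NR, "CR": summary.CR, "TA": summary.TA, "CD": summary.CD,
                "MNND": summary.MNND, "SDNND": summary.SDNND,
                "SEA": summary.SEA, "SEAc": summary.SEAc,
            })
            if summary.sea_posterior is not None:
                record["SEA_post_mean"] = float(summary.sea_posterior.mean())
            if "tp" in merged.columns:
                record["TP"] = float(sub["tp"].mean())
            summaries.append(record)
            if len(pts) >= 4:
                groups_points[record["group"]] = pts
        write_report(pd.DataFrame(summaries), out / "niche_summary.csv")
        artifacts["niche"] = out / "niche_summary.csv"
        logger.info("niche summaries done in %.2fs", time.perf_counter() - t0)

        stage = "niche_overlap"
        t0 = time.perf_counter()
        overlap_rows = []
        labels = list(groups_points)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                res_ab, res_ba = iso.niche_region_overlap(
                    groups_points[a], groups_points[b], alpha=config.alpha,
                    n_iter=config.n_iter,
                    seed=stage_seed(config.seed, f"overlap:{a}|{b}"),
                    labels=(a, b))
                for r in (res_ab, res_ba):
                    overlap_rows.append({
                        "from_group": r.from_group, "to_group": r.to_group,
                        "alpha": r.alpha, "posterior_mean_pct": r.posterior_mean,
                        "ci_low_pct": r.credible_interval[0],
                        "ci_high_pct": r.credible_interval[1],
                        "n_iter": r.n_iter,
                    })
        write_report(pd.DataFrame(overlap_rows), out / "niche_overlap.csv")
        artifacts["niche_overlap"] = out / "niche_overlap.csv"
        logger.info("niche overlaps done in %.2fs", time.perf_counter() - t0)

        stage = "isotope_stats"
        iso_groups = merged[config.group_by[0]]
        iso_stats: dict[str, object] = {}
        if iso_groups.nunique() >= 2 and iso_groups.value_counts().min() >= 2:
            dist = cs.distance_matrix(merged[["delta13C", "delta15N"]], metric="euclidean")
            res = cs.permanova(dist, iso_groups.to_numpy(), n_perm=config.n_perm,
                               seed=stage_seed(config.seed, "iso_permanova"))
            iso_stats["permanova"] = _result_dict(res)
        write_report(iso_stats, out / "isotope_stats.json", format="json")
        artifacts["isotope_stats"] = out / "isotope_stats.json"

        _write_manifest(out, config, artifacts, skipped=[])
        return artifacts
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _per_fish_diet(dataset: Dataset) -> pd.DataFrame:
    """Per-fish prey-count matrix over taxa (non-empty guts only)."""
    prey = dataset.prey
    wide = prey.pivot_table(index="fish_id", columns="taxon_name",
                            values="count", fill_value=0.0, aggfunc="sum")
    return wide.astype(float)


def _result_dict(res: cs.PermutationTestResult) -> dict:
    out = {
        "statistic": res.statistic_name,
        "observed": res.observed,
        "df": list(res.df) if res.df else None,
        "n_perm": res.n_perm,
        "p_value": res.p_value,
    }
    if res.groups is not None:
        out["groups"] = list(map(str, res.groups))
    if res.p_adjusted is not None:
        out["p_adjusted"] = res.p_adjusted
    return out


def _write_manifest(out: Path, config: PipelineConfig, artifacts: dict, skipped: list) -> None:
    payload = asdict(config)
    config_hash = hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()[:16]
    manifest = {
        "version": __version__,
        "config": payload,
        "config_hash": config_hash,
        "seed": config.seed,
        "artifacts": {k: str(v.name) for k, v in artifacts.items()},
        "skipped_stages": skipped,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1) + "\n")
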