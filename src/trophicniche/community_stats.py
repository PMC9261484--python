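"""Permutation-based multivariate statistics on diet and isotope matrices.

Distance-based one-way tests (PERMANOVA pseudo-F, ANOSIM R), pairwise
PERMANOVA with Benjamini–Hochberg adjustment, SIMPER decomposition of
between-group Bray–Curtis dissimilarity, group-average (UPGMA)
clustering pruned by the SIMPROF heterogeneity test, and redundancy
analysis (RDA) with forward covariate selection and variance
partitioning of adjusted R².

All permutation p-values use the add-one convention
p = (#{permuted statistic ≥ observed} + 1) / (n_perm + 1) — the observed
labelling counts as one permutation, so p is never 0 — except when the
full permutation group is enumerated, where p is the exact fraction of
arrangements at least as extreme. Every stochastic routine takes a seed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DistanceMatrix",
    "PermutationTestResult",
    "SimperResult",
    "SimprofPartition",
    "RdaResult",
    "distance_matrix",
    "permanova",
    "pairwise_permanova",
    "anosim",
    "simper",
    "upgma_simprof",
    "rda_varpart",
    "normalize_covariates",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with sample labels."""

    labels: list
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix must have a zero diagonal")

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass
class PermutationTestResult:
    statistic_name: str
    observed: float
    n_perm: int
    p_value: float
    seed: object = None
    df: tuple[int, int] | None = None
    groups: tuple | None = None
    p_adjusted: float | None = None


@dataclass
class SimperResult:
    """Taxon-wise decomposition of between-group Bray–Curtis dissimilarity."""

    group_a: object
    group_b: object
    average_dissimilarity: float
    contributions: pd.DataFrame  # taxon, mean_contribution_pct, cumulative_pct
    cutoff_set: list


@dataclass
class SimprofPartition:
    """UPGMA tree plus the coarsest SIMPROF-homogeneous partition."""

    linkage: np.ndarray
    labels: list
    group_assignments: pd.Series
    n_groups: int
    node_p_values: dict = field(default_factory=dict)


@dataclass
class RdaResult:
    constrained_variance_fraction: float
    axis_eigenvalues: np.ndarray
    selected_covariates: list
    varpart_fractions: dict
    selection_p_values: dict = field(default_factory=dict)


def distance_matrix(samples: pd.DataFrame, metric: str = "bray_curtis") -> DistanceMatrix:
    """Pairwise distances between sample rows.

    Bray–Curtis BC(x, y) = Σ|x_i − y_i| / Σ(x_i + y_i) on non-negative
    abundance rows; Euclidean is the standard L2 metric on e.g. raw
    per-mil isotope values.
    """
    values = np.asarray(samples, dtype=float)
    labels = list(samples.index) if isinstance(samples, pd.DataFrame) else list(range(len(values)))
    if len(values) < 2:
        raise ValueError("at least two samples are required")
    if metric == "bray_curtis":
        if np.any(values < 0):
            raise ValueError("Bray–Curtis requires non-negative entries")
        if np.any(values.sum(axis=1) == 0):
            raise ValueError("Bray–Curtis is undefined for an all-zero sample")
        dist = squareform(pdist(values, metric="braycurtis"))
    elif metric == "euclidean":
        dist = squareform(pdist(values, metric="euclidean"))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(labels=labels, values=dist, metric=metric)


def _group_codes(groups) -> tuple[np.ndarray, list]:
    codes, uniques = pd.factorize(np.asarray(groups), sort=True)
    return codes, list(uniques)


def _check_groups(codes: np.ndarray, uniques: list) -> None:
    if len(uniques) < 2:
        raise ValueError("at least two groups are required")
    for g, label in enumerate(uniques):
        if (codes == g).sum() < 2:
            raise ValueError(f"group {label!r} has fewer than two samples")


def _pseudo_f(d2: np.ndarray, perm_codes: np.ndarray, n_groups: int) -> np.ndarray:
    """One-way PERMANOVA pseudo-F for each row of permuted group codes.

    Uses the sums-of-squared-distances identity of the Gower-centred
    formulation: SS_total = ΣΣ_{i<j} d²/N, SS_within = Σ_g ΣΣ_{i<j∈g} d²/n_g.
    """
    perm_codes = np.atleast_2d(perm_codes)
    n = d2.shape[0]
    ss_total = d2.sum() / (2 * n)
    ss_within = np.zeros(len(perm_codes))
    for g in range(n_groups):
        member = (perm_codes == g).astype(float)
        n_g = member[0].sum()
        ss_within += np.einsum("pi,ij,pj->p", member, d2, member) / (2 * n_g)
    ss_between = ss_total - ss_within
    df_between = n_groups - 1
    df_within = n - n_groups
    return (ss_between / df_between) / (ss_within / df_within)


def _permutation_pvalue(observed, permuted, exhaustive):
    greater = np.sum(permuted >= observed - 1e-12)
    if exhaustive:
        return float(greater) / len(permuted)
    return float(greater + 1) / (len(permuted) + 1)


def _enumerate_codes(codes: np.ndarray):
    """All distinct arrangements of the group-label multiset."""
    n = len(codes)
    perms = sorted(set(itertools.permutations(codes.tolist())))
    return np.array(perms, dtype=int).reshape(-1, n)


def _count_arrangements(codes: np.ndarray) -> float:
    from math import factorial

    total = factorial(len(codes))
    for g in np.unique(codes):
        total //= factorial(int((codes == g).sum()))
    return total


def permanova(
    dist: DistanceMatrix,
    groups,
    n_perm: int = 9999,
    seed=None,
    exhaustive: bool | None = None,
) -> PermutationTestResult:
    """One-way PERMANOVA on a distance matrix.

    ``exhaustive=True`` (or automatically when the number of distinct
    label arrangements does not exceed ``n_perm``) enumerates the full
    permutation group and returns an exact p-value; otherwise ``n_perm``
    uniform random permutations with the add-one convention.
    """
    codes, uniques = _group_codes(groups)
    _check_groups(codes, uniques)
    d2 = dist.values**2
    a = len(uniques)
    n = len(codes)
    observed = float(_pseudo_f(d2, codes, a)[0])
    if exhaustive is None:
        exhaustive = _count_arrangements(codes) <= min(n_perm, 10_000)
    if exhaustive:
        perms = _enumerate_codes(codes)
        f_perm = _pseudo_f(d2, perms, a)
        p = _permutation_pvalue(observed, f_perm, exhaustive=True)
        n_used = len(perms)
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(codes) for _ in range(n_perm)])
        f_perm = _pseudo_f(d2, perms, a)
        p = _permutation_pvalue(observed, f_perm, exhaustive=False)
        n_used = n_perm
    return PermutationTestResult(
        statistic_name="pseudo-F",
        observed=observed,
        n_perm=n_used,
        p_value=p,
        seed=seed,
        df=(a - 1, n - a),
        groups=tuple(uniques),
    )


def pairwise_permanova(
    dist: DistanceMatrix,
    groups,
    n_perm: int = 9999,
    seed=None,
) -> list[PermutationTestResult]:
    """All unordered pairwise PERMANOVAs with Benjamini–Hochberg FDR."""
    codes, uniques = _group_codes(groups)
    _check_groups(codes, uniques)
    rng = np.random.default_rng(seed)
    results = []
    for i, j in itertools.combinations(range(len(uniques)), 2):
        mask = (codes == i) | (codes == j)
        idx = np.where(mask)[0]
        sub = DistanceMatrix(
            labels=[dist.labels[k] for k in idx],
            values=dist.values[np.ix_(idx, idx)],
            metric=dist.metric,
        )
        sub_seed = int(rng.integers(0, 2**31 - 1))
        res = permanova(sub, codes[idx], n_perm=n_perm, seed=sub_seed, exhaustive=False)
        res.groups = (uniques[i], uniques[j])
        results.append(res)
    raw = [r.p_value for r in results]
    _, adjusted, _, _ = multipletests(raw, method="fdr_bh")
    for r, p_adj in zip(results, adjusted):
        r.p_adjusted = float(p_adj)
    return results


def _anosim_r(ranks_sq: np.ndarray, perm_codes: np.ndarray) -> np.ndarray:
    perm_codes = np.atleast_2d(perm_codes)
    n = ranks_sq.shape[0]
    m = n * (n - 1) / 2
    total = ranks_sq.sum() / 2
    within_sum = np.zeros(len(perm_codes))
    within_count = 0.0
    for g in np.unique(perm_codes[0]):
        member = (perm_codes == g).astype(float)
        n_g = member[0].sum()
        within_sum += np.einsum("pi,ij,pj->p", member, ranks_sq, member) / 2
        within_count += n_g * (n_g - 1) / 2
    between_count = m - within_count
    r_within = within_sum / within_count
    r_between = (total - within_sum) / between_count
    return (r_between - r_within) / (m / 2)


def anosim(
    dist: DistanceMatrix,
    groups,
    n_perm: int = 9999,
    seed=None,
    exhaustive: bool | None = None,
) -> PermutationTestResult:
    """One-way ANOSIM: R = (mean between rank − mean within rank)/(M/2)."""
    codes, uniques = _group_codes(groups)
    _check_groups(codes, uniques)
    n = len(codes)
    ranks = squareform(rankdata(dist.condensed()), checks=False)
    observed = float(_anosim_r(ranks, codes)[0])
    if exhaustive is None:
        exhaustive = _count_arrangements(codes) <= min(n_perm, 10_000)
    if exhaustive:
        perms = _enumerate_codes(codes)
        r_perm = _anosim_r(ranks, perms)
        p = _permutation_pvalue(observed, r_perm, exhaustive=True)
        n_used = len(perms)
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(codes) for _ in range(n_perm)])
        r_perm = _anosim_r(ranks, perms)
        p = _permutation_pvalue(observed, r_perm, exhaustive=False)
        n_used = n_perm
    return PermutationTestResult(
        statistic_name="R",
        observed=observed,
        n_perm=n_used,
        p_value=p,
        seed=seed,
        df=(len(uniques) - 1, n - len(uniques)),
        groups=tuple(uniques),
    )


def simper(
    samples: pd.DataFrame,
    groups,
    threshold: float = 0.8,
) -> list[SimperResult]:
    """SIMPER: taxon contributions to between-group Bray–Curtis dissimilarity.

    For each sample pair (i in group a, j in group b) the Bray–Curtis
    dissimilarity splits exactly into per-taxon terms
    |x_ik − x_jk| / Σ_m (x_im + x_jm); averaging over pairs gives each
    taxon's mean contribution. ``cutoff_set`` lists the taxa reaching the
    cumulative ``threshold`` (default 80%) of the total.
    """
    values = np.asarray(samples, dtype=float)
    taxa = list(samples.columns)
    codes, uniques = _group_codes(groups)
    results = []
    for gi, gj in itertools.combinations(range(len(uniques)), 2):
        rows_a = values[codes == gi]
        rows_b = values[codes == gj]
        contrib = np.zeros(len(taxa))
        n_pairs = 0
        for xa in rows_a:
            for xb in rows_b:
                denom = (xa + xb).sum()
                if denom == 0:
                    continue
                contrib += np.abs(xa - xb) / denom
                n_pairs += 1
        if n_pairs == 0:
            raise ValueError("no usable sample pairs between groups")
        delta = contrib / n_pairs  # per-taxon mean dissimilarity terms
        total = delta.sum()
        pct = 100.0 * delta / total
        order = np.argsort(-pct, kind="stable")
        cumulative = np.cumsum(pct[order])
        table = pd.DataFrame(
            {
                "taxon": [taxa[k] for k in order],
                "mean_contribution_pct": pct[order],
                "cumulative_pct": cumulative,
            }
        )
        reach = int(np.searchsorted(cumulative, 100.0 * threshold) + 1)
        results.append(
            SimperResult(
                group_a=uniques[gi],
                group_b=uniques[gj],
                average_dissimilarity=float(total),
                contributions=table,
                cutoff_set=table["taxon"].head(reach).tolist(),
            )
        )
    return results


def _simprof_pi(profile: np.ndarray, expected: np.ndarray) -> float:
    return float(np.abs(profile - expected).sum())


def _simprof_test(values: np.ndarray, n_perm: int, rng: np.random.Generator) -> float:
    """SIMPROF p-value for heterogeneity of one set of samples.

    The statistic π compares the ordered Bray–Curtis profile of the
    samples with the mean ordered profile under independent permutation
    of each variable across samples; the null distribution of π comes
    from a second, independent batch of permutations.
    """
    n, k = values.shape
    observed_profile = np.sort(pdist(values, metric="braycurtis"))

    def permuted_profile():
        permuted = values.copy()
        for col in range(k):
            permuted[:, col] = permuted[rng.permutation(n), col]
        return np.sort(pdist(permuted, metric="braycurtis"))

    expected = np.mean([permuted_profile() for _ in range(n_perm)], axis=0)
    pi_obs = _simprof_pi(observed_profile, expected)
    pi_null = np.array([_simprof_pi(permuted_profile(), expected) for _ in range(n_perm)])
    return _permutation_pvalue(pi_obs, pi_null, exhaustive=False)


def upgma_simprof(
    samples: pd.DataFrame,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed=None,
) -> SimprofPartition:
    """Group-average clustering on Bray–Curtis, pruned by SIMPROF.

    Agglomerates samples by UPGMA on Bray–Curtis dissimilarity, then
    tests each node top-down: a node whose samples show no significant
    multivariate structure (SIMPROF p > alpha) becomes one output group;
    a heterogeneous node is split and its children tested in turn.
    """
    values = np.asarray(samples, dtype=float)
    labels = list(samples.index)
    n = len(values)
    if n < 3:
        raise ValueError("at least three samples are required")
    condensed = pdist(values, metric="braycurtis")
    link = linkage(condensed, method="average")
    # members of each internal node
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for step, (left, right, _, _) in enumerate(link):
        members[n + step] = members[int(left)] + members[int(right)]

    rng = np.random.default_rng(seed)
    assignments = np.full(n, -1, dtype=int)
    node_p: dict[int, float] = {}
    next_group = [0]

    def visit(node: int) -> None:
        idx = members[node]
        if len(idx) < 3:
            heterogeneous = False
        else:
            p = _simprof_test(values[idx], n_perm, rng)
            node_p[node] = p
            heterogeneous = p <= alpha
        if heterogeneous:
            left, right = int(link[node - n][0]), int(link[node - n][1])
            visit(left)
            visit(right)
        else:
            assignments[idx] = next_group[0]
            next_group[0] += 1

    visit(2 * n - 2)
    series = pd.Series(assignments, index=labels, name="group")
    return SimprofPartition(
        linkage=link,
        labels=labels,
        group_assignments=series,
        n_groups=int(series.nunique()),
        node_p_values=node_p,
    )


def normalize_covariates(covariates: pd.DataFrame, log: bool = True) -> pd.DataFrame:
    """Log-transform (log1p for zero-containing columns), centre and scale."""
    out = covariates.astype(float).copy()
    if log:
        for column in out.columns:
            col = out[column]
            if (col > 0).all():
                out[column] = np.log(col)
            elif (col >= 0).all():
                out[column] = np.log1p(col)
    out = (out - out.mean()) / out.std(ddof=1)
    return out


def _rda_r2(Y: np.ndarray, X: np.ndarray) -> float:
    """Fraction of total variance of centred Y explained by regression on X."""
    if X.shape[1] == 0:
        return 0.0
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    fitted = X @ beta
    return float((fitted**2).sum() / (Y**2).sum())


def _adjusted_r2(r2: float, n: int, p: int) -> float:
    if n - p - 1 <= 0:
        return float("nan")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _forward_select(Y, X_df, n_perm, alpha, rng):
    """Forward covariate selection by permutation pseudo-F at ``alpha``."""
    selected: list[str] = []
    p_values: dict[str, float] = {}
    remaining = list(X_df.columns)
    n = len(Y)
    while remaining:
        best = None
        X_cur = X_df[selected].to_numpy() if selected else np.empty((n, 0))
        if selected:
            beta, *_ = np.linalg.lstsq(X_cur, Y, rcond=None)
            resid = Y - X_cur @ beta
        else:
            resid = Y
        for name in remaining:
            x_new = X_df[[name]].to_numpy()
            if selected:
                bx, *_ = np.linalg.lstsq(X_cur, x_new, rcond=None)
                x_res = x_new - X_cur @ bx
            else:
                x_res = x_new
            if np.linalg.norm(x_res) < 1e-10 * max(1.0, np.linalg.norm(x_new)):
                continue  # collinear with what is already in the model
            r2_add = _rda_r2(resid, x_res)
            if best is None or r2_add > best[1]:
                best = (name, r2_add, x_res)
        if best is None:
            break
        name, r2_add, x_res = best
        # permutation test of the added term on reduced-model residuals
        stats = np.empty(n_perm)
        for b in range(n_perm):
            perm = rng.permutation(n)
            stats[b] = _rda_r2(resid[perm], x_res)
        p = _permutation_pvalue(r2_add, stats, exhaustive=False)
        if p > alpha:
            break
        selected.append(name)
        p_values[name] = p
        remaining.remove(name)
    return selected, p_values


def rda_varpart(
    response: pd.DataFrame,
    covariates: pd.DataFrame,
    covariate_sets: dict[str, list[str]] | None = None,
    n_perm: int = 999,
    seed=None,
    select_alpha: float = 0.05,
) -> RdaResult:
    """Redundancy analysis with forward selection and variance partitioning.

    The multivariate response is centred and regressed on the covariate
    matrix; RDA axes are the eigen-decomposition of the fitted values.
    Covariates are forward-selected by Monte Carlo permutation tests
    (``n_perm`` permutations at ``select_alpha``); explained variance is
    reported as Ezekiel-adjusted R². ``covariate_sets`` names groups of
    covariates whose unique and shared adjusted-R² fractions are
    obtained by differencing full and reduced models.
    """
    Y = np.asarray(response, dtype=float)
    Y = Y - Y.mean(axis=0)
    # centre the covariates as well: the intercept is absorbed, so an
    # exactly linear response reaches R^2 = 1
    X_df = covariates.astype(float) - covariates.astype(float).mean()
    n = len(Y)
    if len(X_df) != n:
        raise ValueError("response and covariates must be row-aligned")
    # drop covariates that are collinear within machine tolerance
    X = X_df.to_numpy()
    if X.shape[1]:
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            keep: list[str] = []
            for name in X_df.columns:
                trial = X_df[keep + [name]].to_numpy()
                if np.linalg.matrix_rank(trial) == len(keep) + 1:
                    keep.append(name)
                else:
                    warnings.warn(f"dropping collinear covariate {name!r}")
            X_df = X_df[keep]
    rng = np.random.default_rng(seed)
    selected, p_values = _forward_select(Y, X_df, n_perm, select_alpha, rng)
    X_sel = X_df[selected].to_numpy() if selected else np.empty((n, 0))
    r2 = _rda_r2(Y, X_sel)
    adj = _adjusted_r2(r2, n, X_sel.shape[1]) if selected else 0.0
    if selected:
        beta, *_ = np.linalg.lstsq(X_sel, Y, rcond=None)
        fitted = X_sel @ beta
        sv = np.linalg.svd(fitted, compute_uv=False)
        eigenvalues = (sv**2) / (n - 1)
        eigenvalues = eigenvalues[eigenvalues > 1e-12]
    else:
        eigenvalues = np.array([])

    varpart: dict[str, float] = {}
    if covariate_sets:
        def adj_for(columns: list[str]) -> float:
            columns = [c for c in columns if c in X_df.columns]
            Xs = X_df[columns].to_numpy() if columns else np.empty((n, 0))
            return _adjusted_r2(_rda_r2(Y, Xs), n, Xs.shape[1]) if columns else 0.0

        names = list(covariate_sets)
        union_cols = sorted({c for cols in covariate_sets.values() for c in cols})
        total = adj_for(union_cols)
        varpart["total"] = total
        for name in names:
            others = sorted({c for other, cols in covariate_sets.items()
                             if other != name for c in cols})
            varpart[f"unique_{name}"] = total - adj_for(others)
        shared = total - sum(varpart[f"unique_{name}"] for name in names)
        varpart["shared"] = shared
    return RdaResult(
        constrained_variance_fraction=adj,
        axis_eigenvalues=eigenvalues,
        selected_covariates=selected,
        varpart_fractions=varpart,
        selection_p_values=p_values,
    )
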