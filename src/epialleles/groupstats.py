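"""Between-group statistics on epiallele compositions and summary statistics.

Composition tests treat the reads at a locus as a population of individuals
belonging to epiallele species. Samples are compared through PERMANOVA: a
Bray-Curtis distance matrix over per-sample species frequencies, a one-factor
pseudo-F decomposition, and a label-permutation null. The permutation
p-value uses the (1 + b) / (1 + n_perm) estimator and is never exactly zero;
for small designs the null can be enumerated exhaustively.

Summary statistics are compared per window with an exact rank-sum test
(Wilcoxon-Mann-Whitney, two groups) or Kruskal-Wallis (more than two), and
with a one-covariate ANCOVA (ordinary least squares with a group x covariate
interaction). All per-window p-values are adjusted with the
Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kruskal, norm, rankdata
from statsmodels.stats.multitest import multipletests

from .types import EpialleleTable

#: Largest number of label rearrangements enumerated for an exact test.
_MAX_EXACT = 500_000


# ---------------------------------------------------------------------------
# interchange helpers

def tables_to_frame(tables: Iterable[EpialleleTable]) -> pd.DataFrame:
    """Long-format epiallele counts: window_id, sample_id, strand, epiallele, count."""
    rows = [
        (t.window_id, t.sample_id, t.strand, epi, n)
        for t in tables
        for epi, n in sorted(t.counts.items())
    ]
    return pd.DataFrame(rows, columns=["window_id", "sample_id", "strand", "epiallele", "count"])


def composition_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    """Samples x species relative-frequency matrix for one window.

    `counts` holds long-format counts for a single window. Species missing
    in a sample get 0; each row is normalized to sum to 1, so the result is
    invariant to per-sample sequencing depth.
    """
    if counts.empty:
        raise ValueError("no epiallele counts supplied")
    if counts["window_id"].nunique() > 1:
        raise ValueError("composition_matrix expects counts from a single window")
    wide = (
        counts.pivot_table(index="sample_id", columns="epiallele", values="count",
                           aggfunc="sum", fill_value=0)
        .astype(float)
        .sort_index()
    )
    wide = wide[sorted(wide.columns)]
    totals = wide.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("sample with zero epiallele counts")
    return wide.div(totals, axis=0)


# ---------------------------------------------------------------------------
# PERMANOVA

def _pseudo_f_terms(d2: np.ndarray, labels: np.ndarray) -> Tuple[float, float, float]:
    """(SS_total, SS_within, SS_among) of the one-factor decomposition."""
    n = len(labels)
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return ss_total, ss_within, ss_total - ss_within


def pseudo_f(d2: np.ndarray, labels: np.ndarray) -> Tuple[float, float]:
    """PERMANOVA pseudo-F and R^2 for squared distances d2 and group labels."""
    labels = np.asarray(labels)
    n = len(labels)
    a = len(np.unique(labels))
    if a < 2:
        raise ValueError("need at least two groups")
    ss_total, ss_within, ss_among = _pseudo_f_terms(d2, labels)
    r2 = ss_among / ss_total if ss_total > 0 else 0.0
    if ss_within == 0:
        return math.inf if ss_among > 0 else 0.0, r2
    f = (ss_among / (a - 1)) / (ss_within / (n - a))
    return f, r2


def _pseudo_f_many(d2: np.ndarray, label_matrix: np.ndarray) -> np.ndarray:
    """Pseudo-F for every row of a (n_perm x n) matrix of label vectors."""
    n = d2.shape[0]
    groups = np.unique(label_matrix)
    a = len(groups)
    ss_total = d2.sum() / (2.0 * n)
    ss_within = np.zeros(label_matrix.shape[0])
    for g in groups:
        mask = (label_matrix == g).astype(float)
        n_g = mask[0].sum()  # group sizes are permutation-invariant
        ss_within += np.einsum("pi,ij,pj->p", mask, d2, mask) / (2.0 * n_g)
    ss_among = ss_total - ss_within
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_among / (a - 1)) / (ss_within / (n - a))
    f[ss_within == 0] = np.inf
    return f


def permanova(
    freq: pd.DataFrame,
    labels: Sequence[str],
    n_perm: int = 999,
    seed: Optional[int] = None,
    metric: str = "braycurtis",
    method: str = "montecarlo",
) -> Tuple[float, float, float]:
    """One-factor PERMANOVA on a samples x species frequency matrix.

    Returns (pseudo-F, R^2, p). `method="exact"` enumerates every distinct
    label rearrangement (small designs only) and reports the exact
    permutation p; the default draws `n_perm` random label shuffles and uses
    p = (1 + b) / (1 + n_perm) where b counts permuted F >= observed F.
    """
    labels = np.asarray(labels)
    x = np.asarray(freq, dtype=float)
    if len(labels) != x.shape[0]:
        raise ValueError("one label per sample row is required")
    d2 = squareform(pdist(x, metric=metric)) ** 2
    f_obs, r2 = pseudo_f(d2, labels)
    tol = 1e-12
    if method == "exact":
        perms = sorted(set(itertools.permutations(labels)))
        if len(perms) > _MAX_EXACT:
            raise ValueError("design too large for exhaustive enumeration")
        f_all = _pseudo_f_many(d2, np.array(perms, dtype=labels.dtype))
        p = float(np.mean(f_all >= f_obs - tol))
    elif method == "montecarlo":
        rng = np.random.default_rng(seed)
        perm_idx = np.array([rng.permutation(len(labels)) for _ in range(n_perm)])
        f_all = _pseudo_f_many(d2, labels[perm_idx])
        b = int(np.sum(f_all >= f_obs - tol))
        p = (1 + b) / (1 + n_perm)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(f_obs), float(r2), float(p)


def _group_sizes(meta: pd.DataFrame, group_col: str, samples: Sequence[str]) -> Dict[str, int]:
    sub = meta[meta["sample_id"].isin(samples)]
    return sub.groupby(group_col)["sample_id"].nunique().to_dict()


def epistat(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    group_col: str = "group",
    min_per_group: int = 3,
    n_perm: int = 999,
    seed: Optional[int] = None,
    metric: str = "braycurtis",
    method: str = "montecarlo",
) -> pd.DataFrame:
    """PERMANOVA of epiallele composition per window, across all windows.

    `counts` is the long-format epiallele count table for all samples;
    `metadata` maps sample_id to a group label. Windows with fewer than
    `min_per_group` samples in any group are reported untested (p = NaN).
    BH adjustment runs across the tested windows.
    """
    groups_all = metadata[group_col].unique()
    if len(groups_all) < 2:
        raise ValueError(f"metadata column {group_col!r} defines a single group; need >= 2")
    if min_per_group < 2:
        raise ValueError("min_per_group must be >= 2")
    group_of = metadata.set_index("sample_id")[group_col]
    rows = []
    rng = np.random.default_rng(seed)
    for window_id, sub in counts.groupby("window_id", sort=True):
        freq = composition_matrix(sub)
        samples = [s for s in freq.index if s in group_of.index]
        freq = freq.loc[samples]
        sizes = _group_sizes(metadata, group_col, samples)
        ok = len(sizes) == len(groups_all) and all(v >= min_per_group for v in sizes.values())
        if not ok:
            rows.append((window_id, np.nan, np.nan, np.nan, _sizes_str(sizes), False))
            continue
        labels = group_of.loc[samples].to_numpy()
        sub_seed = int(rng.integers(0, 2**31 - 1))
        f, r2, p = permanova(freq, labels, n_perm=n_perm, seed=sub_seed,
                             metric=metric, method=method)
        rows.append((window_id, f, r2, p, _sizes_str(sizes), True))
    out = pd.DataFrame(rows, columns=["window_id", "pseudo_f", "r2", "p", "n_per_group", "tested"])
    out["p_adj"] = np.nan
    tested = out["tested"]
    if tested.any():
        out.loc[tested, "p_adj"] = adjust_fdr(out.loc[tested, "p"].to_numpy())
    return out


def _sizes_str(sizes: Dict[str, int]) -> str:
    return ",".join(f"{g}:{n}" for g, n in sorted(sizes.items()))


def pairtest(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    window_id: str,
    group_col: str = "group",
    n_perm: int = 999,
    seed: Optional[int] = None,
    metric: str = "braycurtis",
) -> pd.DataFrame:
    """Post-hoc pairwise PERMANOVA between every group pair at one window.

    Defined for three or more groups (with two, the overall test in
    `epistat` already is the pairwise comparison). BH adjustment runs across
    the pairs within the window.
    """
    groups = sorted(metadata[group_col].unique())
    if len(groups) < 3:
        raise ValueError("pairtest requires >= 3 groups; with 2 use epistat directly")
    sub = counts[counts["window_id"] == window_id]
    if sub.empty:
        raise ValueError(f"window {window_id!r} absent from the count table")
    freq = composition_matrix(sub)
    group_of = metadata.set_index("sample_id")[group_col]
    rng = np.random.default_rng(seed)
    rows = []
    for g1, g2 in itertools.combinations(groups, 2):
        samples = [s for s in freq.index if group_of.get(s) in (g1, g2)]
        labels = group_of.loc[samples].to_numpy()
        f, r2, p = permanova(freq.loc[samples], labels, n_perm=n_perm,
                             seed=int(rng.integers(0, 2**31 - 1)), metric=metric)
        rows.append((window_id, g1, g2, f, r2, p))
    out = pd.DataFrame(rows, columns=["window_id", "group1", "group2", "pseudo_f", "r2", "p"])
    out["p_adj"] = adjust_fdr(out["p"].to_numpy())
    return out


def driver_species(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    window_id: str,
    group_col: str = "group",
    pair: Optional[Tuple[str, str]] = None,
) -> pd.DataFrame:
    """SIMPER-style ranking of the species driving between-group dissimilarity.

    The Bray-Curtis dissimilarity between two frequency vectors decomposes
    additively over species: d(x, y) = sum_s |x_s - y_s| / sum_s (x_s + y_s).
    Each species' contribution is averaged over all between-group sample
    pairs; contributions sum to the mean between-group dissimilarity.
    """
    sub = counts[counts["window_id"] == window_id]
    if sub.empty:
        raise ValueError(f"window {window_id!r} absent from the count table")
    freq = composition_matrix(sub)
    group_of = metadata.set_index("sample_id")[group_col]
    groups = sorted(group_of.loc[[s for s in freq.index if s in group_of.index]].unique())
    if pair is None:
        if len(groups) != 2:
            raise ValueError("driver_species needs exactly 2 groups or an explicit pair")
        pair = (groups[0], groups[1])
    a = [s for s in freq.index if group_of.get(s) == pair[0]]
    b = [s for s in freq.index if group_of.get(s) == pair[1]]
    if not a or not b:
        raise ValueError(f"empty group in pair {pair}")
    contrib = np.zeros(freq.shape[1])
    n_pairs = 0
    for sa in a:
        for sb in b:
            x, y = freq.loc[sa].to_numpy(), freq.loc[sb].to_numpy()
            denom = (x + y).sum()
            contrib += np.abs(x - y) / denom
            n_pairs += 1
    contrib /= n_pairs
    out = pd.DataFrame({
        "window_id": window_id,
        "epiallele": freq.columns,
        "contribution": contrib,
    })
    total = contrib.sum()
    out["fraction"] = out["contribution"] / total if total > 0 else 0.0
    return out.sort_values("contribution", ascending=False, kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# rank-based tests on summary statistics

def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Two-sided Wilcoxon-Mann-Whitney test; returns (U of x over y, p).

    The null is enumerated exhaustively over all label rearrangements when
    the design is small enough (two-sided p = proportion of rearrangements
    with a rank sum at least as far from its null mean as observed; exact in
    the presence of ties). Larger designs use the normal approximation with
    tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w_obs = ranks[:n1].sum()
    u_obs = w_obs - n1 * (n1 + 1) / 2.0
    mu = n1 * (n1 + n2 + 1) / 2.0
    if math.comb(n1 + n2, n1) <= _MAX_EXACT:
        dev = abs(w_obs - mu)
        hits = total = 0
        for idx in itertools.combinations(range(n1 + n2), n1):
            total += 1
            if abs(ranks[list(idx)].sum() - mu) >= dev - 1e-12:
                hits += 1
        return float(u_obs), hits / total
    # normal approximation with tie correction
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 == 0:
        return float(u_obs), 1.0
    z = (abs(w_obs - mu) - 0.5) / math.sqrt(sigma2)
    return float(u_obs), float(2 * norm.sf(max(z, 0.0)))


def diffstat(
    summaries: pd.DataFrame,
    metadata: pd.DataFrame,
    statistic: str,
    group_col: str = "group",
    min_per_group: int = 3,
) -> pd.DataFrame:
    """Compare one summary statistic between groups, per window.

    `summaries` is long-format: one row per (window_id, sample_id) with the
    statistic columns. Two groups -> rank-sum test; more -> Kruskal-Wallis.
    Per-group medians are reported; constant windows are flagged degenerate
    with p = 1. BH adjustment across tested windows.
    """
    if statistic not in summaries.columns:
        raise ValueError(f"statistic {statistic!r} not in the summary table")
    groups = sorted(metadata[group_col].unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    test_name = "wilcoxon" if len(groups) == 2 else "kruskal-wallis"
    group_of = metadata.set_index("sample_id")[group_col]
    rows = []
    for window_id, sub in summaries.groupby("window_id", sort=True):
        sub = sub.dropna(subset=[statistic])
        values = {g: sub.loc[[group_of.get(s) == g for s in sub["sample_id"]], statistic].to_numpy()
                  for g in groups}
        medians = {g: (float(np.median(v)) if len(v) else np.nan) for g, v in values.items()}
        if any(len(v) < min_per_group for v in values.values()):
            rows.append([window_id, test_name, np.nan, np.nan, medians, False, False])
            continue
        pooled = np.concatenate(list(values.values()))
        if np.all(pooled == pooled[0]):
            rows.append([window_id, test_name, np.nan, 1.0, medians, True, True])
            continue
        if len(groups) == 2:
            stat, p = rank_sum_test(values[groups[0]], values[groups[1]])
        else:
            stat, p = kruskal(*values.values())
        rows.append([window_id, test_name, float(stat), float(p), medians, True, False])
    out = pd.DataFrame(rows, columns=["window_id", "test", "statistic", "p",
                                      "_medians", "tested", "degenerate"])
    for g in groups:
        out[f"median_{g}"] = out["_medians"].map(lambda m: m[g])
    out = out.drop(columns="_medians")
    out["p_adj"] = np.nan
    tested = out["tested"]
    if tested.any():
        out.loc[tested, "p_adj"] = adjust_fdr(out.loc[tested, "p"].to_numpy())
    return out


def diffmodel(
    summaries: pd.DataFrame,
    metadata: pd.DataFrame,
    statistic: str,
    group_col: str = "group",
    covariate_col: str = "time",
) -> pd.DataFrame:
    """ANCOVA of one summary statistic: statistic ~ group * covariate, per window.

    Ordinary-least-squares fit with a group x covariate interaction; the
    reported p-values are the ANOVA F-tests of the group, covariate and
    interaction terms. Per-group slopes come from the covariate coefficient
    plus the interaction offsets. Rank-deficient windows are flagged and
    skipped.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if statistic not in summaries.columns:
        raise ValueError(f"statistic {statistic!r} not in the summary table")
    meta = metadata.set_index("sample_id")
    groups = sorted(meta[group_col].unique())
    rows = []
    for window_id, sub in summaries.groupby("window_id", sort=True):
        df = pd.DataFrame({
            "value": sub[statistic].to_numpy(),
            "group": [meta.loc[s, group_col] for s in sub["sample_id"]],
            "cov": [float(meta.loc[s, covariate_col]) for s in sub["sample_id"]],
        }).dropna()
        counts = df.groupby("group").size()
        n_params = 2 * len(groups)
        if len(counts) < len(groups) or (counts < 2).any() or len(df) <= n_params \
                or df.groupby("group")["cov"].nunique().min() < 2:
            rows.append({"window_id": window_id, "tested": False})
            continue
        model = smf.ols("value ~ C(group) + cov + C(group):cov", data=df).fit()
        if model.df_resid <= 0 or np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
            rows.append({"window_id": window_id, "tested": False})
            continue
        anova = sm.stats.anova_lm(model, typ=2)
        base_slope = model.params["cov"]
        cov_params = model.cov_params()
        slopes = {}
        for g in groups:
            key = f"C(group)[T.{g}]:cov"
            slopes[f"slope_{g}"] = float(base_slope + model.params.get(key, 0.0))
            if key in model.params.index:
                var = (cov_params.loc["cov", "cov"] + cov_params.loc[key, key]
                       + 2 * cov_params.loc["cov", key])
            else:
                var = cov_params.loc["cov", "cov"]
            slopes[f"slope_se_{g}"] = float(np.sqrt(max(var, 0.0)))
        row = {
            "window_id": window_id,
            "tested": True,
            "p_group": float(anova.loc["C(group)", "PR(>F)"]),
            "p_covariate": float(anova.loc["cov", "PR(>F)"]),
            "p_interaction": float(anova.loc["C(group):cov", "PR(>F)"]),
            **slopes,
            **{f"coef_{k}": float(v) for k, v in model.params.items()},
        }
        rows.append(row)
    out = pd.DataFrame(rows)
    if "tested" in out.columns and out["tested"].any():
        for col in ("p_group", "p_covariate", "p_interaction"):
            tested = out["tested"].fillna(False)
            out.loc[tested, f"{col}_adj"] = adjust_fdr(out.loc[tested, col].to_numpy())
    return out


# ---------------------------------------------------------------------------
# ordination

def ordinate(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    window_id: str,
    method: str = "PCA",
    group_col: str = "group",
    n_axes: int = 2,
) -> Tuple[pd.DataFrame, np.ndarray]:
    """Sample ordination for one window: PCA or CCA.

    PCA: singular-value decomposition of the column-centered frequency
    matrix; returns sample scores and the variance fraction per axis.
    CCA: correspondence analysis of the count matrix constrained on group
    indicators (weighted regression of the chi-square-standardized matrix on
    the constraints, then SVD); at most (number of groups - 1) constrained
    axes. Returns sample scores and the fraction of total inertia per axis.
    """
    sub = counts[counts["window_id"] == window_id]
    if sub.empty:
        raise ValueError(f"window {window_id!r} absent from the count table")
    if method == "PCA":
        freq = composition_matrix(sub)
        if freq.shape[0] < 3:
            raise ValueError("ordination needs >= 3 samples")
        x = freq.to_numpy() - freq.to_numpy().mean(axis=0)
        u, s, _ = np.linalg.svd(x, full_matrices=False)
        k = min(n_axes, len(s))
        scores = u[:, :k] * s[:k]
        var = s**2
        explained = var[:k] / var.sum() if var.sum() > 0 else np.zeros(k)
        cols = [f"PC{i + 1}" for i in range(k)]
        return pd.DataFrame(scores, index=freq.index, columns=cols), explained
    if method == "CCA":
        wide = (
            sub.pivot_table(index="sample_id", columns="epiallele", values="count",
                            aggfunc="sum", fill_value=0)
            .astype(float).sort_index()
        )
        if wide.shape[0] < 3:
            raise ValueError("ordination needs >= 3 samples")
        group_of = metadata.set_index("sample_id")[group_col]
        labels = np.array([group_of[s] for s in wide.index])
        y = wide.to_numpy()
        p = y / y.sum()
        r = p.sum(axis=1)
        c = p.sum(axis=0)
        q = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        # constraints: group dummies, row-weighted and centered
        dummies = pd.get_dummies(labels).to_numpy(dtype=float)
        xw = np.sqrt(r)[:, None] * (dummies - (r @ dummies))
        proj, *_ = np.linalg.lstsq(xw, q, rcond=None)
        fitted = xw @ proj
        u, s, _ = np.linalg.svd(fitted, full_matrices=False)
        keep = s > 1e-12
        u, s = u[:, keep], s[keep]
        k = min(n_axes, len(s))
        scores = (u[:, :k] * s[:k]) / np.sqrt(r)[:, None]
        total_inertia = (q**2).sum()
        explained = (s[:k] ** 2) / total_inertia if total_inertia > 0 else np.zeros(k)
        cols = [f"CCA{i + 1}" for i in range(k)]
        return pd.DataFrame(scores, index=wide.index, columns=cols), explained
    raise ValueError(f"method must be PCA or CCA, got {method!r}")


# ---------------------------------------------------------------------------
# multiple testing and the combined significance filter

def adjust_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def significant_regions(
    diffstat_results: pd.DataFrame,
    epistat_results: pd.DataFrame,
    groups: Sequence[str],
    p_threshold: float = 0.05,
    min_abs_median_diff: float = 0.10,
    composition_p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Convenience filter combining the statistic and composition tests.

    Keeps windows with diffstat p <= p_threshold, an absolute between-group
    median difference >= min_abs_median_diff (two groups), and PERMANOVA
    p <= composition_p_threshold. Thresholds are parameters, not policy.
    """
    if len(groups) != 2:
        raise ValueError("the combined filter is defined for two groups")
    g1, g2 = groups
    merged = diffstat_results.merge(
        epistat_results[["window_id", "p"]].rename(columns={"p": "p_composition"}),
        on="window_id", how="inner",
    )
    delta = (merged[f"median_{g1}"] - merged[f"median_{g2}"]).abs()
    keep = (
        (merged["p"] <= p_threshold)
        & (delta >= min_abs_median_diff)
        & (merged["p_composition"] <= composition_p_threshold)
    )
    out = merged[keep.fillna(False)].copy()
    out["median_diff"] = (out[f"median_{g1}"] - out[f"median_{g2}"])
    return out.reset_index(drop=True)
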