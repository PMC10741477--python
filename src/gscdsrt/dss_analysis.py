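"""Drug-level heterogeneity statistics on a cultures × drugs DSS matrix.

Covers the selective DSS (sDSS), responder filtering at DSS ≥ 10, pairwise
Spearman correlation, per-drug one-sided F-tests of inter- vs intra-tumor
variance with Benjamini–Hochberg adjustment, the ΔDSS/ΔSD quadrant analysis,
hierarchical clustering with Newick export, and PCA of culture profiles.

Missing-cell policy: pairwise deletion for correlations, complete-case drugs
for PCA, per-drug non-missing values for the variance tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# Selective DSS
# ---------------------------------------------------------------------------

def sdss(matrix: pd.DataFrame, reference_ids) -> pd.DataFrame:
    """Selective DSS: each culture's DSS minus the per-drug mean over the
    reference cohort (computed over non-missing reference values)."""
    reference_ids = list(reference_ids)
    if not reference_ids:
        raise ValueError("reference set is empty")
    missing = set(reference_ids) - set(matrix.index)
    if missing:
        raise KeyError(f"reference cultures not in matrix: {sorted(missing)}")
    ref_mean = matrix.loc[reference_ids].mean(axis=0, skipna=True)
    if ref_mean.isna().any():
        bad = ref_mean.index[ref_mean.isna()].tolist()
        raise ValueError(f"drugs with no reference values: {bad}")
    return matrix.sub(ref_mean, axis=1)


def filter_responders(
    matrix: pd.DataFrame,
    threshold: float = 10.0,
    scope: str = "any_culture",
) -> list[str] | pd.Series:
    """Drugs with a moderate-to-strong response (DSS ≥ threshold).

    ``any_culture``: drugs whose maximum DSS over the given cultures reaches
    the threshold (inclusive). ``per_culture``: per-culture count of such
    drugs.
    """
    if scope == "any_culture":
        hit = matrix.max(axis=0, skipna=True) >= threshold
        return [str(d) for d in matrix.columns[hit]]
    if scope == "per_culture":
        return (matrix >= threshold).sum(axis=1)
    raise ValueError(f"unknown scope {scope!r}")


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

def correlation_matrix(
    matrix: pd.DataFrame, method: str = "spearman", min_shared: int = 3
) -> tuple[pd.DataFrame, dict]:
    """Pairwise culture × culture correlation over shared non-missing drugs.

    Returns the correlation matrix (diagonal 1) and a summary dict with the
    mean ± SD of the off-diagonal entries. Pairs sharing fewer than
    ``min_shared`` drugs get a missing cell with a warning.
    """
    cultures = list(matrix.index)
    corr = pd.DataFrame(np.eye(len(cultures)), index=cultures, columns=cultures)
    vals = matrix.to_numpy(dtype=float)
    for i in range(len(cultures)):
        for j in range(i + 1, len(cultures)):
            shared = np.isfinite(vals[i]) & np.isfinite(vals[j])
            if shared.sum() < min_shared:
                warnings.warn(
                    f"pair ({cultures[i]}, {cultures[j]}): only {int(shared.sum())} "
                    "shared drugs; correlation left missing"
                )
                corr.iat[i, j] = corr.iat[j, i] = np.nan
                continue
            if method == "spearman":
                r = stats.spearmanr(vals[i, shared], vals[j, shared]).statistic
            elif method == "pearson":
                r = stats.pearsonr(vals[i, shared], vals[j, shared]).statistic
            else:
                raise ValueError(f"unknown method {method!r}")
            corr.iat[i, j] = corr.iat[j, i] = r
    off = corr.to_numpy()[~np.eye(len(cultures), dtype=bool)]
    off = off[np.isfinite(off)]
    summary = {"mean": float(np.mean(off)) if off.size else np.nan,
               "sd": float(np.std(off, ddof=1)) if off.size > 1 else np.nan,
               "n_pairs": int(off.size // 2)}
    return corr, summary


# ---------------------------------------------------------------------------
# Variance F-tests
# ---------------------------------------------------------------------------

@dataclass
class VarianceTestResult:
    drug_id: str
    var_inter: float
    var_intra: float
    f_stat: float
    df: tuple[int, int]
    p_one_sided: float
    p_fdr: float
    significant: bool


def f_test_upper(var_a: np.ndarray, var_b: np.ndarray,
                 df_a: np.ndarray, df_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised one-sided F-test of H1: σ²_a > σ²_b.

    F = var_a/var_b with (df_a, df_b) degrees of freedom; upper-tail p.
    var_b = 0 with var_a > 0 gives F = +inf, p = 0.
    """
    var_a = np.asarray(var_a, dtype=float)
    var_b = np.asarray(var_b, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = var_a / var_b
    f = np.where((var_b == 0) & (var_a > 0), np.inf, f)
    p = np.where(np.isinf(f), 0.0, stats.f.sf(np.where(np.isinf(f), 1.0, f), df_a, df_b))
    return f, p


def variance_f_tests(
    matrix: pd.DataFrame,
    group_a,
    group_b,
    alpha: float = 0.05,
    fdr_method: str = "fdr_bh",
) -> pd.DataFrame:
    """Per-drug one-sided F-tests of var(group_a) > var(group_b).

    In the study design group_a is the reference cohort (inter-tumor
    variance) and group_b the multiregional cultures (intra-tumor variance).
    Drugs with fewer than 2 non-missing values in either group, or with both
    variances zero, are skipped (listed in the ``skipped`` attribute of the
    returned frame's ``attrs``). BH-FDR is applied across tested drugs.
    """
    group_a, group_b = list(group_a), list(group_b)
    rows, skipped = [], []
    for drug in matrix.columns:
        a = matrix.loc[group_a, drug].dropna().to_numpy(dtype=float)
        b = matrix.loc[group_b, drug].dropna().to_numpy(dtype=float)
        if a.size < 2 or b.size < 2:
            skipped.append((str(drug), "insufficient_values"))
            continue
        va, vb = float(np.var(a, ddof=1)), float(np.var(b, ddof=1))
        if va == 0.0 and vb == 0.0:
            skipped.append((str(drug), "both_variances_zero"))
            continue
        f, p = f_test_upper(va, vb, a.size - 1, b.size - 1)
        rows.append((str(drug), va, vb, float(f), a.size - 1, b.size - 1, float(p)))

    out = pd.DataFrame(
        rows, columns=["drug", "var_inter", "var_intra", "f_stat",
                       "df_inter", "df_intra", "p_one_sided"],
    )
    if len(out):
        out["p_fdr"] = multipletests(out["p_one_sided"], method=fdr_method)[1]
        out["significant"] = out["p_fdr"] < alpha
    else:
        out["p_fdr"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    out.attrs["skipped"] = skipped
    out.attrs["alpha"] = alpha
    return out


# ---------------------------------------------------------------------------
# ΔDSS / ΔSD quadrants
# ---------------------------------------------------------------------------

QUADRANTS = ("specific-homogeneous", "specific-heterogeneous",
             "nonspecific-homogeneous", "nonspecific-heterogeneous")


def delta_analysis(
    matrix: pd.DataFrame, tumor_ids, reference_ids
) -> pd.DataFrame:
    """Per-drug ΔDSS = mean(tumor) − mean(reference) against
    ΔSD = SD(reference) − SD(tumor).

    Positive ΔDSS marks drugs more effective in the multiregional (single
    tumor) cultures; positive ΔSD marks intratumorally homogeneous
    responses. Ties (Δ = 0) are routed conservatively to "nonspecific" /
    "heterogeneous". Output is sorted by ΔDSS descending.
    """
    tumor_ids, reference_ids = list(tumor_ids), list(reference_ids)
    if not tumor_ids or not reference_ids:
        raise ValueError("both groups must be non-empty")
    if len(tumor_ids) < 2 or len(reference_ids) < 2:
        raise ValueError("need >= 2 cultures per group for SDs")
    t = matrix.loc[tumor_ids]
    r = matrix.loc[reference_ids]
    out = pd.DataFrame({
        "delta_dss": t.mean(axis=0) - r.mean(axis=0),
        "delta_sd": r.std(axis=0, ddof=1) - t.std(axis=0, ddof=1),
    })
    out["quadrant"] = [
        ("specific" if dd > 0 else "nonspecific") + "-" +
        ("homogeneous" if ds > 0 else "heterogeneous")
        for dd, ds in zip(out["delta_dss"], out["delta_sd"])
    ]
    out.index.name = "drug"
    out.attrs["tie_rule"] = "delta=0 -> nonspecific / heterogeneous"
    return out.sort_values("delta_dss", ascending=False, kind="mergesort")


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(Z, rd=False)

    def rec(node, parent_dist) -> str:
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.get_left(), node.dist)
        right = rec(node.get_right(), node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


@dataclass
class ClusterResult:
    ordered: pd.DataFrame
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_newick: str
    col_newick: str


def cluster_heatmap(
    matrix: pd.DataFrame,
    drug_filter=None,
    metric: str = "euclidean",
    method: str = "complete",
    max_missing_frac: float = 0.0,
) -> ClusterResult:
    """Agglomerative clustering of cultures and of drugs.

    ``drug_filter`` restricts the columns (e.g. the DSS ≥ 10 responder set).
    Rows/columns are pre-sorted lexicographically so equal-distance merges
    break ties deterministically. Emits Newick trees for both axes plus the
    leaf-ordered matrix.
    """
    m = matrix if drug_filter is None else matrix.loc[:, list(drug_filter)]
    miss = float(m.isna().to_numpy().mean())
    if miss > max_missing_frac:
        raise ValueError(f"missing fraction {miss:.3f} exceeds allowed {max_missing_frac}")
    if m.empty:
        raise ValueError("empty matrix after filtering")
    if float(np.nanstd(m.to_numpy(dtype=float))) == 0.0:
        raise ValueError("matrix is constant: nothing to cluster")
    m = m.sort_index(axis=0).sort_index(axis=1)

    def link(data: np.ndarray) -> np.ndarray | None:
        if data.shape[0] < 2:
            return None
        return hierarchy.linkage(pdist(data, metric=metric), method=method)

    vals = m.to_numpy(dtype=float)
    row_Z = link(vals)
    col_Z = link(vals.T)
    row_order = hierarchy.leaves_list(row_Z) if row_Z is not None else np.arange(len(m))
    col_order = (hierarchy.leaves_list(col_Z) if col_Z is not None
                 else np.arange(m.shape[1]))
    ordered = m.iloc[row_order, col_order]

    def newick(Z, labels):
        if Z is None:
            return f"{labels[0]}:0;" if labels else ";"
        return _linkage_to_newick(Z, labels)

    return ClusterResult(
        ordered=ordered,
        row_linkage=row_Z,
        col_linkage=col_Z,
        row_newick=newick(row_Z, [str(i) for i in m.index]),
        col_newick=newick(col_Z, [str(c) for c in m.columns]),
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_view(
    matrix: pd.DataFrame,
    log_transform: bool = True,
    pseudo: float = 0.01,
    n_components: int | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of culture profiles after complete-case drug selection.

    Drugs with any missing culture are dropped first (the analysis uses only
    drugs represented in all cultures). With ``log_transform`` the entries
    become log2(value + pseudo) before centering. Returns per-culture scores
    and the explained-variance fractions.
    """
    complete = matrix.dropna(axis=1, how="any").sort_index(axis=0).sort_index(axis=1)
    vals = complete.to_numpy(dtype=float)
    if log_transform:
        if (vals < 0).any():
            raise ValueError("negative values are incompatible with the log transform")
        vals = np.log2(vals + pseudo)
    k = n_components or min(len(complete) - 1, complete.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(vals)
    score_df = pd.DataFrame(scores, index=complete.index,
                            columns=[f"PC{i+1}" for i in range(scores.shape[1])])
    score_df.attrs["n_drugs_used"] = complete.shape[1]
    return score_df, pca.explained_variance_ratio_


# ---------------------------------------------------------------------------
# Drug-class summary of sDSS
# ---------------------------------------------------------------------------

def class_summary(
    sdss_matrix: pd.DataFrame, drug_class_map: dict | pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """Mean sDSS per culture × drug class plus per-class drug counts.

    Unmapped drugs fall into class "other" (with a warning when the map is
    entirely empty).
    """
    cmap = dict(drug_class_map) if not isinstance(drug_class_map, dict) else drug_class_map
    if not cmap:
        warnings.warn("empty drug-class map: all drugs assigned to 'other'")
    classes = pd.Series({d: cmap.get(d, "other") for d in sdss_matrix.columns},
                        name="drug_class")
    means = sdss_matrix.T.groupby(classes).mean().T
    counts = classes.value_counts().sort_index()
    return means, counts
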