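"""Comparative statistics on concentration tables.

The downstream analysis mirrors the standard metabolomics workflow: per-variable
auto-scaling (mean 0, SD 1), PCA and Ward/Euclidean hierarchical clustering on
the scaled matrix, per-metabolite two-group screening with a normality-driven
choice between Welch's t test and the Wilcoxon–Mann–Whitney test, Benjamini–
Hochberg FDR control, volcano (fold change × significance) selection, and the
cross-condition regression of TIF:plasma concentration ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, CrossReferenceError, ValidationError
from .io import SampleSheet
from .quantify import ConcentrationTable


@dataclass
class ScaledMatrix:
    """Auto-scaled samples × metabolites matrix with its scaling parameters."""

    values: pd.DataFrame
    means: pd.Series
    sds: pd.Series
    dropped: dict[str, str]  # metabolite -> reason

    def unscale(self) -> pd.DataFrame:
        return self.values * self.sds + self.means


def autoscale(
    table: ConcentrationTable | pd.DataFrame,
    sample_ids: list[str] | None = None,
) -> ScaledMatrix:
    """Mean-center and unit-variance scale each metabolite (sample SD, ddof=1).

    Metabolites with any censored cell in the selected samples are dropped
    (censoring is pairwise-complete in univariate tests, but multivariate
    analyses need a complete matrix), as are zero-variance metabolites.
    """
    wide = table.wide() if isinstance(table, ConcentrationTable) else table
    if sample_ids is not None:
        wide = wide.loc[sample_ids]
    if len(wide) < 2:
        raise ValidationError("auto-scaling needs at least 2 samples")
    dropped: dict[str, str] = {}
    complete = wide.dropna(axis=1)
    for m in wide.columns.difference(complete.columns):
        dropped[m] = "censored cell in subset"
    sds = complete.std(ddof=1)
    for m in complete.columns[sds == 0]:
        dropped[m] = "zero variance"
    kept = complete.loc[:, sds > 0]
    if kept.shape[1] == 0:
        raise ValidationError("no metabolite with nonzero variance to scale")
    means = kept.mean()
    sds = kept.std(ddof=1)
    return ScaledMatrix(values=(kept - means) / sds, means=means, sds=sds, dropped=dropped)


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples × components
    loadings: pd.DataFrame  # metabolites × components
    explained_variance_ratio: np.ndarray


def run_pca(scaled: ScaledMatrix) -> PCAResult:
    """PCA of the auto-scaled matrix; ratios are non-increasing and sum to 1."""
    X = scaled.values.to_numpy()
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValidationError("PCA needs at least 2 samples and 2 metabolites")
    k = min(n, p)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    comp_names = [f"PC{i+1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=scaled.values.index, columns=comp_names),
        loadings=pd.DataFrame(
            pca.components_.T, index=scaled.values.columns, columns=comp_names
        ),
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


@dataclass
class ClusteringResult:
    linkage: np.ndarray  # scipy linkage matrix
    leaf_order: list[int]
    labels: pd.Series | None  # k-group labels when a cut was requested


def hierarchical_cluster(scaled: ScaledMatrix, k: int | None = None) -> ClusteringResult:
    """Agglomerative Ward clustering on Euclidean distances of the scaled matrix.

    Uses the squared-Euclidean Ward update (Ward.D2-equivalent): merge heights
    are non-decreasing and, given a fixed input row order, the merge order is
    deterministic (ties resolved by lowest pair index).
    """
    X = scaled.values.to_numpy()
    if len(X) < 2:
        raise ValidationError("clustering needs at least 2 samples")
    if k is not None and (k < 1 or k > len(X)):
        raise ValidationError(f"k={k} outside [1, n_samples={len(X)}]")
    Z = hierarchy.linkage(X, method="ward", metric="euclidean")
    order = list(hierarchy.leaves_list(Z))
    labels = None
    if k is not None:
        flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        labels = pd.Series(flat, index=scaled.values.index, name="cluster")
    return ClusteringResult(linkage=Z, leaf_order=order, labels=labels)


def univariate_compare(
    table: ConcentrationTable,
    sample_sheet: SampleSheet,
    group_factor: str,
    group_a: str,
    group_b: str,
    alpha_normality: float = 0.05,
    min_n: int = 3,
) -> pd.DataFrame:
    """Two-group screening per metabolite with normality-driven test choice.

    Both groups are Shapiro–Wilk tested at ``alpha_normality``; if either
    rejects, the metabolite is compared by a two-sided Wilcoxon–Mann–Whitney
    test, otherwise by an unpaired two-tailed Welch's t test (unequal
    variances, Welch–Satterthwaite df).  p-values are Benjamini–Hochberg
    adjusted across all tested metabolites.  The fold change is the ratio of
    arithmetic group means (log2), on pairwise-complete quantified values.
    Metabolites with fewer than ``min_n`` quantified values in either group
    are skipped and recorded with method "skipped".
    """
    if group_factor not in sample_sheet.frame.columns:
        raise CrossReferenceError(f"unknown group factor {group_factor!r}")
    samples_a = sample_sheet.samples_where(**{group_factor: group_a})
    samples_b = sample_sheet.samples_where(**{group_factor: group_b})
    if not samples_a or not samples_b:
        raise CrossReferenceError(
            f"group(s) not found in sample sheet: "
            f"{[g for g, s in ((group_a, samples_a), (group_b, samples_b)) if not s]}"
        )
    wide = table.wide()
    rows = []
    for m in wide.columns:
        a = wide.loc[wide.index.intersection(samples_a), m].dropna().to_numpy()
        b = wide.loc[wide.index.intersection(samples_b), m].dropna().to_numpy()
        if len(a) < min_n or len(b) < min_n:
            rows.append(
                {
                    "metabolite_id": m,
                    "method": "skipped",
                    "p_value": np.nan,
                    "log2_fold_change": np.nan,
                    "mean_a": np.nan,
                    "mean_b": np.nan,
                    "n_a": len(a),
                    "n_b": len(b),
                }
            )
            continue
        normal = (
            sps.shapiro(a).pvalue >= alpha_normality
            and sps.shapiro(b).pvalue >= alpha_normality
        )
        if normal:
            res = sps.ttest_ind(a, b, equal_var=False)
            method, p = "welch_t", float(res.pvalue)
        else:
            res = sps.mannwhitneyu(a, b, alternative="two-sided")
            method, p = "mann_whitney", float(res.pvalue)
        rows.append(
            {
                "metabolite_id": m,
                "method": method,
                "p_value": p,
                "log2_fold_change": float(np.log2(a.mean() / b.mean())),
                "mean_a": float(a.mean()),
                "mean_b": float(b.mean()),
                "n_a": len(a),
                "n_b": len(b),
            }
        )
    results = pd.DataFrame(rows)
    results["q_value"] = np.nan
    tested = results["p_value"].notna()
    if tested.any():
        results.loc[tested, "q_value"] = benjamini_hochberg(
            results.loc[tested, "p_value"].to_numpy()
        )
    return results


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch's t statistic, Welch–Satterthwaite df and two-tailed p."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def volcano_select(
    results: pd.DataFrame,
    fc_threshold: float = 1.5,
    sig_mode: str = "raw_p",
    sig_threshold: float = 0.01,
) -> list[str]:
    """Metabolites passing both the fold-change and the significance gate.

    Fold change is a ratio threshold in either direction
    (|log2 FC| >= log2(fc_threshold)); significance is raw p (``raw_p``) or BH
    q (``fdr_q``) strictly below ``sig_threshold``.
    """
    if sig_mode not in ("raw_p", "fdr_q"):
        raise ConfigError(f"unknown sig_mode {sig_mode!r}")
    if len(results) == 0:
        raise ValidationError("empty results table")
    metric = results["p_value"] if sig_mode == "raw_p" else results["q_value"]
    mask = (
        (results["log2_fold_change"].abs() >= np.log2(fc_threshold))
        & (metric < sig_threshold)
        & metric.notna()
    )
    return list(results.loc[mask, "metabolite_id"])


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    pearson_r: float
    pearson_p: float
    n_metabolites: int


def regress_ratio_vectors(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """Simple OLS of y on x with Pearson correlation; r² = pearson_r²."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("ratio regression needs >= 3 paired points")
    fit = sps.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        pearson_r=float(fit.rvalue),
        pearson_p=float(fit.pvalue),
        n_metabolites=len(x),
    )


def ratio_regression(
    table: ConcentrationTable,
    sample_sheet: SampleSheet,
    group_factor: str,
    group_x: str,
    group_y: str,
    animal_factor: str = "animal_id",
    log_space: bool = False,
) -> RegressionResult:
    """Regression of per-metabolite TIF:plasma ratios between two conditions.

    For each animal with a matched TIF and plasma sample, the per-metabolite
    ratio TIF/plasma is computed; ratios are averaged over the animals of each
    condition, and the condition-y means are regressed on the condition-x
    means over metabolites quantified in both fluids in both conditions.
    ``log_space`` fits the same line on log-transformed ratios.
    """
    for col in (group_factor, animal_factor, "matrix_type"):
        if col not in sample_sheet.frame.columns:
            raise CrossReferenceError(f"sample sheet lacks column {col!r}")
    wide = table.wide()
    sheet = sample_sheet.frame
    ratios: dict[str, pd.DataFrame] = {}
    for group in (group_x, group_y):
        rows = {}
        for animal, sub in sheet[sheet[group_factor] == group].groupby(animal_factor):
            tif = sub.loc[sub["matrix_type"] == "tif", "sample_id"]
            plasma = sub.loc[sub["matrix_type"] == "plasma", "sample_id"]
            if len(tif) != 1 or len(plasma) != 1:
                continue
            t, p = wide.loc[tif.iloc[0]], wide.loc[plasma.iloc[0]]
            rows[animal] = t / p
        if not rows:
            raise ValidationError(f"no matched TIF/plasma pairs in group {group!r}")
        ratios[group] = pd.DataFrame(rows).T  # animals × metabolites
    mean_x = ratios[group_x].mean(axis=0, skipna=False)
    mean_y = ratios[group_y].mean(axis=0, skipna=False)
    keep = mean_x.notna() & mean_y.notna()
    x, y = mean_x[keep].to_numpy(), mean_y[keep].to_numpy()
    if log_space:
        x, y = np.log2(x), np.log2(y)
    return regress_ratio_vectors(x, y)
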