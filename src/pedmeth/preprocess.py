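"""Probe-level filtering and summarization to analysis-ready matrices.

Stages (in the order the pipeline applies them):

1. promoter-window filter: keep (probe, gene) pairs within 300 bp of a TSS;
2. gene-level summarization: per gene, the mean of its probes' values;
3. invariant-category filter: drop probes whose per-sample level category
   (low/medium/high at beta 0.2/0.6) is identical across every sample of
   every supplied cohort;
4. expression-correlation filter: keep probes whose M values are
   significantly (Spearman, BH) correlated with their gene's tumor
   expression;
5. cross-normal divergence filter: drop probes differentially methylated
   (FDR < 0.05, |log2 FC| >= 2, sex-adjusted) between any pair of normal
   cohorts;
6. batch correction (see :mod:`pedmeth.batch`) and a PCA QC export.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .diffmeth import bh_adjust, fit_linear_dm
from .types import FilterReport, MethylationMatrix

DEFAULT_TSS_WINDOW_BP = 300


def filter_promoter_probes(
    annotation: pd.DataFrame, window_bp: int = DEFAULT_TSS_WINDOW_BP
) -> tuple[pd.DataFrame, FilterReport]:
    """Keep (probe, gene) pairs with TSS distance <= window_bp (inclusive)."""
    keep = annotation["tss_distance_bp"] <= window_bp
    removed = annotation.loc[~keep]
    removed_ids = (removed["probe_id"] + "|" + removed["gene_symbol"]).tolist()
    report = FilterReport(
        stage_name=f"promoter_window_{window_bp}bp",
        n_features_in=len(annotation),
        n_features_out=int(keep.sum()),
        removed_ids=removed_ids,
    )
    return annotation.loc[keep].reset_index(drop=True), report


def summarize_gene_level(
    matrix: MethylationMatrix, annotation: pd.DataFrame
) -> MethylationMatrix:
    """Per gene per sample, the arithmetic mean of its probes' values.

    Probes mapping to several genes contribute to each gene independently;
    genes with no probes in the matrix are absent from the output.
    """
    ann = annotation[annotation["probe_id"].isin(matrix.values.index)]
    if ann.empty:
        raise ValueError("no annotated probes present in the matrix")
    probe_vals = matrix.values.loc[ann["probe_id"]]
    probe_vals = probe_vals.set_index(ann["gene_symbol"].to_numpy())
    gene_vals = probe_vals.groupby(level=0).mean()
    gene_vals.index.name = "gene"
    return MethylationMatrix(gene_vals, matrix.scale)


def _level_codes(values: np.ndarray, low: float, high: float) -> np.ndarray:
    """Per-cell level category code: 0 low (<low), 1 medium, 2 high (>high)."""
    return np.where(values < low, 0, np.where(values > high, 2, 1))


def filter_invariant_category_probes(
    matrices: list[MethylationMatrix],
    low: float = 0.2,
    high: float = 0.6,
) -> FilterReport:
    """Flag probes in the same level category for every sample everywhere.

    Operates on beta matrices; probes present in all supplied matrices are
    assessed across the union of samples.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    shared = matrices[0].values.index
    for m in matrices[1:]:
        shared = shared.intersection(m.values.index)
    codes = [
        _level_codes(m.values.loc[shared].to_numpy(), low, high) for m in matrices
    ]
    all_codes = np.hstack(codes)
    invariant = (all_codes == all_codes[:, [0]]).all(axis=1)
    removed = shared[invariant].tolist()
    return FilterReport(
        stage_name="invariant_category",
        n_features_in=len(shared),
        n_features_out=len(shared) - len(removed),
        removed_ids=removed,
    )


def _rank_rows(a: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, a)


def filter_expression_correlated_probes(
    meth: MethylationMatrix,
    expression: pd.DataFrame,
    annotation: pd.DataFrame,
    alpha: float = 0.05,
) -> FilterReport:
    """Retain probes whose M values correlate with their gene's expression.

    Spearman correlation across the tumor samples shared by the two
    matrices, BH-adjusted across probes; adjusted p < alpha (either sign)
    retains the probe.  Probes whose gene has no expression row, or with a
    degenerate (constant) vector, are removed and tallied separately.
    """
    shared_samples = [s for s in meth.sample_ids if s in expression.columns]
    if len(shared_samples) < 3:
        raise ValueError("need >= 3 shared tumor samples")
    first_gene = (
        annotation[annotation["probe_id"].isin(meth.values.index)]
        .drop_duplicates("probe_id")
        .set_index("probe_id")["gene_symbol"]
    )
    probes = [p for p in meth.feature_ids if p in first_gene.index]
    no_gene = [p for p in meth.feature_ids if p not in first_gene.index]
    with_expr = [p for p in probes if first_gene[p] in expression.index]
    no_expr = [p for p in probes if first_gene[p] not in expression.index]

    mvals = meth.values.loc[with_expr, shared_samples].to_numpy()
    evals = expression.loc[[first_gene[p] for p in with_expr], shared_samples].to_numpy()
    n = len(shared_samples)
    meth_const = np.ptp(mvals, axis=1) == 0
    expr_const = np.ptp(evals, axis=1) == 0
    degenerate = meth_const | expr_const

    rm = _rank_rows(mvals)
    re_ = _rank_rows(evals)
    rm = rm - rm.mean(axis=1, keepdims=True)
    re_ = re_ - re_.mean(axis=1, keepdims=True)
    denom = np.sqrt((rm**2).sum(axis=1) * (re_**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rm * re_).sum(axis=1) / denom
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(rho) == 1.0, 0.0, p)
    p = np.where(degenerate, np.nan, p)

    valid = ~np.isnan(p)
    fdr = np.full_like(p, np.nan)
    if valid.any():
        fdr[valid] = bh_adjust(p[valid])
    retained = valid & (fdr < alpha)
    removed_ids = [p_ for p_, keep in zip(with_expr, retained) if not keep]
    removed_ids += no_expr + no_gene
    return FilterReport(
        stage_name="expression_correlation",
        n_features_in=len(meth.feature_ids),
        n_features_out=len(meth.feature_ids) - len(removed_ids),
        removed_ids=removed_ids,
        extra={
            "n_no_expression": len(no_expr) + len(no_gene),
            "n_degenerate": int(degenerate.sum()),
            "n_tested": int(valid.sum()),
        },
    )


def filter_cross_normal_divergent_probes(
    normals: dict[str, MethylationMatrix],
    metadata: pd.DataFrame,
    alpha: float = 0.05,
    lfc_threshold: float = 2.0,
) -> FilterReport:
    """Drop probes differentially methylated between ANY pair of normal cohorts.

    Uses the sex-adjusted moderated linear model on M values; a probe
    meeting FDR < alpha and |log2 FC| >= lfc_threshold in any cohort pair is
    excluded.
    """
    names = sorted(normals)
    if len(names) < 2:
        raise ValueError("need >= 2 normal datasets")
    shared = normals[names[0]].values.index
    for n in names[1:]:
        shared = shared.intersection(normals[n].values.index)
    flagged: set[str] = set()
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            res = fit_linear_dm(
                _hcat(normals[a], normals[b], shared),
                metadata,
                group_a=normals[a].sample_ids,
                group_b=normals[b].sample_ids,
                alpha=alpha,
                lfc_threshold=lfc_threshold,
                contrast=f"{a}_vs_{b}",
            )
            flagged.update(res.significant_features())
    removed = sorted(flagged)
    return FilterReport(
        stage_name="cross_normal_divergence",
        n_features_in=len(shared),
        n_features_out=len(shared) - len(removed),
        removed_ids=removed,
    )


def _hcat(a: MethylationMatrix, b: MethylationMatrix, features) -> MethylationMatrix:
    vals = pd.concat([a.values.loc[features], b.values.loc[features]], axis=1)
    return MethylationMatrix(vals, a.scale)


def pca_qc(matrix: MethylationMatrix, metadata: pd.DataFrame) -> pd.DataFrame:
    """First two sample-space principal components, for batch-structure QC."""
    X = matrix.values.to_numpy().T  # samples x features
    n_comp = min(2, X.shape[0], X.shape[1])
    pca = PCA(n_components=n_comp)
    if np.allclose(X.var(axis=0), 0):
        scores = np.zeros((X.shape[0], 2))
    else:
        scores = pca.fit_transform(X)
        if scores.shape[1] < 2:
            scores = np.column_stack([scores, np.zeros(X.shape[0])])
    return pd.DataFrame(
        {
            "sample_id": matrix.sample_ids,
            "PC1": scores[:, 0],
            "PC2": scores[:, 1],
            "dataset_id": metadata.loc[matrix.sample_ids, "dataset_id"].to_numpy(),
        }
    )


def batch_separation_statistic(pca_table: pd.DataFrame) -> float:
    """Between-batch spread of PC1 centroids over mean within-batch spread.

    Used only in QC reports/tests to show that batch correction reduces the
    dataset clustering visible in PC1.
    """
    groups = pca_table.groupby("dataset_id")["PC1"]
    centroids = groups.mean()
    within = groups.std(ddof=1).mean()
    between = centroids.std(ddof=1)
    if within == 0:
        return np.inf if between > 0 else 0.0
    return float(between / within)


def chain_reports(reports: list[FilterReport]) -> None:
    """Assert the output of stage k equals the input of stage k+1."""
    for prev, nxt in zip(reports, reports[1:]):
        if prev.n_features_out != nxt.n_features_in:
            raise ValueError(
                f"filter chain mismatch: {prev.stage_name} out "
                f"{prev.n_features_out} != {nxt.stage_name} in {nxt.n_features_in}"
            )
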