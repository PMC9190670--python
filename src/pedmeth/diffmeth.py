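"""Per-feature linear-model differential methylation on the M scale.

For each feature an ordinary least squares model ``M ~ intercept + group +
sex`` is fit; the group coefficient is the log2 fold change (difference of
group means on the M scale, which is already a log2 ratio).  Residual
variances are moderated by empirical-Bayes shrinkage toward a scaled
inverse-chi-square prior whose hyperparameters (d0, s0^2) are estimated by
moment-matching the log residual variances (digamma/trigamma moments).  The
moderated t-statistic has d0 + d degrees of freedom.  P-values are adjusted
with the Benjamini-Hochberg step-up procedure, and a feature is called
significant when FDR < alpha AND |log2 FC| >= the fold-change threshold.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator

from .types import MethylationMatrix

logger = logging.getLogger(__name__)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved).

    adj_(i) = min_{j >= i} m * p_(j) / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    m = p.size
    if m == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    ranked = m * p[order] / np.arange(1, m + 1)
    adj = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = adj
    return out


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone, convex)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if -dif / x < 1e-8:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate (d0, s0^2) of the inverse-chi-square variance prior.

    Moment matching on log variances: if s^2 ~ s0^2 F(df, d0), then
    log(s^2) has closed-form mean/variance in terms of digamma/trigamma
    functions, which we invert.  Returns d0 = inf when the observed spread
    of variances is no larger than expected from sampling alone.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = np.maximum(s2, 1e-300)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    n = len(e)
    if n < 2:
        return np.inf, float(np.exp(emean))
    evar = float(np.sum((e - emean) ** 2) / (n - 1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return d0, s0_sq


def squeeze_variances(s2: np.ndarray, df: float, d0: float, s0_sq: float) -> np.ndarray:
    """Posterior (shrunken) variances s~^2 = (d0 s0^2 + d s^2) / (d0 + d)."""
    if np.isinf(d0):
        return np.full_like(np.asarray(s2, dtype=float), s0_sq)
    return (d0 * s0_sq + df * np.asarray(s2, dtype=float)) / (d0 + df)


@dataclass
class DMResultTable:
    """Wrapper holding the per-feature differential results for one contrast."""

    contrast: str
    table: pd.DataFrame  # feature_id, log2_fc, t_stat, p_value, fdr, significant

    def significant_features(self) -> list[str]:
        return self.table.loc[self.table["significant"], "feature_id"].tolist()


class ModeratedTTestDM(BaseEstimator):
    """Two-group differential test with optional sex covariate and EB moderation.

    Parameters
    ----------
    alpha : float
        FDR threshold for the significance call.
    lfc_threshold : float
        Minimum absolute log2 fold change (difference of group means on the
        M scale) for the significance call.
    moderated : bool
        If False, skip variance shrinkage (ordinary OLS t; the d0 = 0 limit).

    Attributes (after :meth:`fit`)
    ------------------------------
    results_ : pandas.DataFrame
        Columns feature_id, log2_fc, t_stat, p_value, fdr, significant.
    d0_, s0_sq_ : float
        Estimated prior degrees of freedom and prior variance.
    residual_df_ : float
        Residual degrees of freedom of the linear model.
    """

    def __init__(self, alpha: float = 0.05, lfc_threshold: float = 2.0, moderated: bool = True):
        self.alpha = alpha
        self.lfc_threshold = lfc_threshold
        self.moderated = moderated

    def fit(self, X, group, sex=None, feature_ids=None, contrast: str = "group"):
        """Fit per-feature linear models.

        Parameters
        ----------
        X : array-like (n_features, n_samples)
            M-values.
        group : array-like of {0, 1}
            Group membership per sample (1 = group A, 0 = group B);
            log2_fc is mean(A) - mean(B) adjusted for sex.
        sex : array-like of {0, 1}, optional
            Sex covariate per sample; omitted from the design if constant.
        """
        Y = np.asarray(X, dtype=float)
        if Y.ndim != 2:
            raise ValueError("X must be 2-D (features x samples)")
        n_features, n_samples = Y.shape
        group = np.asarray(group, dtype=float)
        if group.shape != (n_samples,):
            raise ValueError("group length must match sample count")
        for label, count in (("A", group.sum()), ("B", (1 - group).sum())):
            if count < 2:
                raise ValueError(f"group {label} has fewer than 2 samples")
        cols = [np.ones(n_samples), group]
        if sex is not None:
            sex = np.asarray(sex, dtype=float)
            if np.ptp(sex) > 0:
                cols.append(sex)
        design = np.column_stack(cols)
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            raise ValueError("design matrix is rank deficient (group confounded with sex?)")
        df_resid = n_samples - rank
        if df_resid < 1:
            raise ValueError("no residual degrees of freedom")

        pinv = np.linalg.pinv(design)
        coef = Y @ pinv.T  # (features, n_params)
        fitted = coef @ design.T
        resid = Y - fitted
        s2 = (resid**2).sum(axis=1) / df_resid
        xtx_inv = np.linalg.inv(design.T @ design)
        se_unscaled = np.sqrt(xtx_inv[1, 1])

        if self.moderated:
            d0, s0_sq = fit_variance_prior(s2, df_resid)
        else:
            d0, s0_sq = 0.0, 0.0
        if d0 > 0:
            s2_post = squeeze_variances(s2, df_resid, d0, s0_sq)
            df_total = d0 + df_resid
        else:
            s2_post = s2
            df_total = df_resid

        log2_fc = coef[:, 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            t_stat = log2_fc / (np.sqrt(s2_post) * se_unscaled)
        t_stat = np.where(np.isfinite(t_stat), t_stat, 0.0)
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t_stat))
        else:
            p = 2.0 * stats.t.sf(np.abs(t_stat), df_total)
        fdr = bh_adjust(p)
        significant = (fdr < self.alpha) & (np.abs(log2_fc) >= self.lfc_threshold)

        if feature_ids is None:
            feature_ids = [f"f{i}" for i in range(n_features)]
        self.results_ = pd.DataFrame(
            {
                "feature_id": list(feature_ids),
                "contrast": contrast,
                "log2_fc": log2_fc,
                "t_stat": t_stat,
                "p_value": p,
                "fdr": fdr,
                "significant": significant,
            }
        )
        self.d0_ = d0
        self.s0_sq_ = s0_sq
        self.residual_df_ = df_resid
        self.n_features_in_ = n_features
        return self


SEX_CODES = {"female": 0.0, "male": 1.0}


def _design_vectors(metadata: pd.DataFrame, sample_ids: list[str]):
    """Return (kept sample ids, sex codes) dropping unknown-sex samples."""
    meta = metadata.loc[sample_ids]
    known = meta["sex"].isin(SEX_CODES)
    n_dropped = int((~known).sum())
    if n_dropped:
        logger.info("dropping %d unknown-sex samples from linear model", n_dropped)
    kept = meta.index[known].tolist()
    sex = meta.loc[kept, "sex"].map(SEX_CODES).to_numpy()
    return kept, sex, n_dropped


def fit_linear_dm(
    m_matrix: MethylationMatrix,
    metadata: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    alpha: float = 0.05,
    lfc_threshold: float = 2.0,
    moderated: bool = True,
    contrast: str | None = None,
) -> DMResultTable:
    """Differential test of group A vs group B with sex covariate.

    Unknown-sex samples are dropped (with a logged count) before fitting.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"samples in both groups: {sorted(overlap)[:5]}")
    kept_a, sex_a, _ = _design_vectors(metadata, list(group_a))
    kept_b, sex_b, _ = _design_vectors(metadata, list(group_b))
    if len(kept_a) < 2 or len(kept_b) < 2:
        raise ValueError("each group needs >= 2 samples with known sex")
    samples = kept_a + kept_b
    sub = m_matrix.subset_samples(samples)
    group = np.concatenate([np.ones(len(kept_a)), np.zeros(len(kept_b))])
    sex = np.concatenate([sex_a, sex_b])
    est = ModeratedTTestDM(alpha=alpha, lfc_threshold=lfc_threshold, moderated=moderated)
    name = contrast or "A_vs_B"
    est.fit(sub.values.to_numpy(), group, sex=sex, feature_ids=sub.feature_ids, contrast=name)
    return DMResultTable(name, est.results_)


def tumor_vs_normal_dm(
    tumors: dict[str, MethylationMatrix],
    normal: MethylationMatrix,
    metadata: pd.DataFrame,
    alpha: float = 0.05,
    lfc_threshold: float = 2.0,
) -> tuple[dict[str, DMResultTable], pd.Series]:
    """Each tumor type vs the pooled (batch-adjusted) normal reference.

    Returns the per-type result tables and, per feature, the number of tumor
    types in which it is significant.
    """
    results: dict[str, DMResultTable] = {}
    flag_counts = None
    for tumor_type, matrix in tumors.items():
        res = fit_linear_dm(
            _concat(matrix, normal),
            metadata,
            group_a=matrix.sample_ids,
            group_b=normal.sample_ids,
            alpha=alpha,
            lfc_threshold=lfc_threshold,
            contrast=f"{tumor_type}_vs_normal",
        )
        results[tumor_type] = res
        sig = res.table.set_index("feature_id")["significant"].astype(int)
        flag_counts = sig if flag_counts is None else flag_counts.add(sig, fill_value=0)
    if flag_counts is None:
        flag_counts = pd.Series(dtype=int)
    return results, flag_counts.astype(int)


def pairwise_tumor_dm(
    tumors: dict[str, MethylationMatrix],
    metadata: pd.DataFrame,
    alpha: float = 0.05,
    lfc_threshold: float = 2.0,
) -> tuple[dict[tuple[str, str], DMResultTable], pd.DataFrame]:
    """All C(T, 2) pairwise tumor-type contrasts with sex covariate.

    Returns per-pair tables and a per-feature summary: whether the feature
    is significant in any pair, and the pair with maximal |log2 FC| among
    its significant pairs (the headline-difference pair).
    """
    pairs = list(itertools.combinations(sorted(tumors), 2))
    results: dict[tuple[str, str], DMResultTable] = {}
    best: dict[str, tuple[float, str]] = {}
    any_sig: dict[str, bool] = {}
    for a, b in pairs:
        res = fit_linear_dm(
            _concat(tumors[a], tumors[b]),
            metadata,
            group_a=tumors[a].sample_ids,
            group_b=tumors[b].sample_ids,
            alpha=alpha,
            lfc_threshold=lfc_threshold,
            contrast=f"{a}_vs_{b}",
        )
        results[(a, b)] = res
        for _, row in res.table.iterrows():
            fid = row["feature_id"]
            any_sig[fid] = any_sig.get(fid, False) or bool(row["significant"])
            if row["significant"]:
                cur = best.get(fid)
                if cur is None or abs(row["log2_fc"]) > cur[0]:
                    best[fid] = (abs(row["log2_fc"]), f"{a}_vs_{b}")
    summary = pd.DataFrame(
        {
            "feature_id": list(any_sig),
            "significant_any_pair": [any_sig[f] for f in any_sig],
            "max_abs_log2_fc": [best.get(f, (np.nan, None))[0] for f in any_sig],
            "max_pair": [best.get(f, (np.nan, None))[1] for f in any_sig],
        }
    )
    return results, summary


def volcano_table(result: DMResultTable) -> pd.DataFrame:
    """Plot-ready volcano export: (feature, log2_fc, -log10 fdr, significant)."""
    t = result.table
    with np.errstate(divide="ignore"):
        neg_log10 = -np.log10(t["fdr"].to_numpy())
    return pd.DataFrame(
        {
            "feature_id": t["feature_id"],
            "log2_fc": t["log2_fc"],
            "neg_log10_fdr": neg_log10,
            "significant": t["significant"],
        }
    )


def _concat(a: MethylationMatrix, b: MethylationMatrix) -> MethylationMatrix:
    if a.scale != b.scale:
        raise ValueError("cannot concatenate matrices on different scales")
    shared = a.values.index.intersection(b.values.index)
    vals = pd.concat([a.values.loc[shared], b.values.loc[shared]], axis=1)
    return MethylationMatrix(vals, a.scale)
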