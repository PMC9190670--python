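"""Empirical-Bayes location-scale batch adjustment (parametric ComBat).

Beta matrices are logit-transformed, adjusted on the M scale, and mapped
back through the inverse logit so outputs stay inside (0, 1).  The
adjustment standardizes each feature, estimates per-batch per-feature
location (gamma) and scale (delta) parameters, shrinks them toward batch
means via normal / inverse-gamma priors fit by the method of moments, and
removes the shrunken effects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .transforms import matrix_to_beta, matrix_to_m
from .types import BETA, M, MethylationMatrix


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _aprior(delta_hat):
    m = delta_hat.mean()
    s2 = delta_hat.var(ddof=1)
    return (2.0 * s2 + m**2) / s2


def _bprior(delta_hat):
    m = delta_hat.mean()
    s2 = delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _it_sol(s_data, g_hat, d_hat, g_bar, t2, a, b, conv=1e-4):
    """Iterative solution for the per-batch EB-adjusted location/scale."""
    n = s_data.shape[1]
    g_old = g_hat.copy()
    d_old = d_hat.copy()
    for _ in range(500):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = ((s_data - g_new[:, None]) ** 2).sum(axis=1)
        d_new = _postvar(sum2, n, a, b)
        change = max(
            np.max(np.abs(g_new - g_old) / np.abs(g_old)),
            np.max(np.abs(d_new - d_old) / d_old),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


class ComBatCorrector(BaseEstimator, TransformerMixin):
    """Parametric empirical-Bayes batch correction on a continuous scale.

    fit/transform operate on arrays of shape (n_features, n_samples) with a
    batch label per sample; fit_transform adjusts the very data the
    parameters were estimated from (the standard usage).

    Attributes (after fit_transform)
    --------------------------------
    gamma_star_, delta_star_ : arrays (n_batches, n_features)
        Shrunken per-batch location and scale effects.
    grand_mean_, pooled_var_ : arrays (n_features,)
    batches_ : list of batch labels in processing order.
    """

    def __init__(self, parametric: bool = True):
        self.parametric = parametric  # non-parametric mode intentionally unsupported

    def fit_transform(self, X, y=None, *, batch):
        if not self.parametric:
            raise NotImplementedError("only the parametric EB adjustment is implemented")
        X = np.asarray(X, dtype=float)
        batch = np.asarray(batch)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (features x samples)")
        if batch.shape[0] != X.shape[1]:
            raise ValueError("one batch label per sample required")
        batches = list(pd.unique(batch))
        if len(batches) < 2:
            raise ValueError("batch correction requires >= 2 batches")
        idx = {b: np.flatnonzero(batch == b) for b in batches}
        for b, ix in idx.items():
            if len(ix) < 2:
                raise ValueError(f"batch {b!r} has fewer than 2 samples")
        n_array = X.shape[1]

        # Feature standardization using fitted batch means
        batch_design = np.zeros((n_array, len(batches)))
        for j, b in enumerate(batches):
            batch_design[idx[b], j] = 1.0
        n_batches = np.array([len(idx[b]) for b in batches], dtype=float)
        b_hat = np.stack([X[:, idx[b]].mean(axis=1) for b in batches])  # (B, G)
        grand_mean = (n_batches[:, None] * b_hat).sum(axis=0) / n_array
        resid = X - (b_hat.T @ batch_design.T)
        var_pooled = (resid**2).sum(axis=1) / n_array
        var_pooled = np.maximum(var_pooled, 1e-12)
        stand_mean = grand_mean[:, None] * np.ones((1, n_array))
        s_data = (X - stand_mean) / np.sqrt(var_pooled)[:, None]

        gamma_star = np.empty_like(b_hat)
        delta_star = np.empty_like(b_hat)
        gamma_hat = np.stack([s_data[:, idx[b]].mean(axis=1) for b in batches])
        delta_hat = np.stack([s_data[:, idx[b]].var(axis=1, ddof=1) for b in batches])
        for j, b in enumerate(batches):
            g_bar = gamma_hat[j].mean()
            t2 = gamma_hat[j].var(ddof=1)
            a = _aprior(delta_hat[j])
            bb = _bprior(delta_hat[j])
            gamma_star[j], delta_star[j] = _it_sol(
                s_data[:, idx[b]], gamma_hat[j], delta_hat[j], g_bar, t2, a, bb
            )

        adjusted = s_data.copy()
        for j, b in enumerate(batches):
            adjusted[:, idx[b]] = (
                (s_data[:, idx[b]] - gamma_star[j][:, None]) / np.sqrt(delta_star[j])[:, None]
            )
        adjusted = adjusted * np.sqrt(var_pooled)[:, None] + stand_mean

        self.batches_ = batches
        self.gamma_star_ = gamma_star
        self.delta_star_ = delta_star
        self.grand_mean_ = grand_mean
        self.pooled_var_ = var_pooled
        return adjusted

    def fit(self, X, y=None, *, batch):
        self.fit_transform(X, batch=batch)
        return self


def batch_correct(
    combined: MethylationMatrix,
    metadata: pd.DataFrame,
    enabled: bool = True,
) -> MethylationMatrix:
    """Logit -> parametric ComBat -> inverse-logit batch adjustment.

    ``metadata`` supplies the ``dataset_id`` batch label per sample.  With
    ``enabled=False`` (e.g. a single batch) the input is returned unchanged.
    """
    if not enabled:
        return combined
    was_beta = combined.scale == BETA
    m_matrix = matrix_to_m(combined)
    batch = metadata.loc[m_matrix.sample_ids, "dataset_id"].to_numpy()
    corrector = ComBatCorrector()
    adjusted = corrector.fit_transform(m_matrix.values.to_numpy(), batch=batch)
    out = MethylationMatrix(
        pd.DataFrame(adjusted, index=m_matrix.values.index, columns=m_matrix.values.columns),
        M,
    )
    return matrix_to_beta(out) if was_beta else out
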