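"""Beta/M scale transforms.

M = log2(beta / (1 - beta)); the logit (base 2) of the beta value.  Betas
are epsilon-clamped to [1e-6, 1 - 1e-6] before the logit so boundary values
stay finite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import BETA, M, MethylationMatrix

EPS = 1e-6


def clamp_beta(beta, eps: float = EPS):
    """Clamp beta values into [eps, 1 - eps]."""
    return np.clip(beta, eps, 1.0 - eps)


def beta_to_m(beta, eps: float = EPS):
    """log2(beta / (1 - beta)) with epsilon clamping; elementwise."""
    b = clamp_beta(np.asarray(beta, dtype=float), eps)
    return np.log2(b / (1.0 - b))


def m_to_beta(m):
    """Inverse logit: 2^m / (2^m + 1); elementwise, numerically stable."""
    m = np.asarray(m, dtype=float)
    # expit(m * ln 2) without overflow for large |m|
    out = np.where(m >= 0, 1.0 / (1.0 + np.exp2(-m)), np.exp2(m) / (1.0 + np.exp2(m)))
    return out


def matrix_to_m(matrix: MethylationMatrix, eps: float = EPS) -> MethylationMatrix:
    if matrix.scale == M:
        return matrix
    vals = pd.DataFrame(
        beta_to_m(matrix.values.to_numpy(), eps),
        index=matrix.values.index,
        columns=matrix.values.columns,
    )
    return MethylationMatrix(vals, M)


def matrix_to_beta(matrix: MethylationMatrix) -> MethylationMatrix:
    if matrix.scale == BETA:
        return matrix
    vals = pd.DataFrame(
        m_to_beta(matrix.values.to_numpy()),
        index=matrix.values.index,
        columns=matrix.values.columns,
    )
    return MethylationMatrix(vals, BETA)
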