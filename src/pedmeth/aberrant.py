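"""Hyper/hypomethylation calling against a normal reference.

Per gene, the normal cohort (batch-corrected, gene-level beta values)
yields a reference mean and SD; a tumor is hypermethylated for a gene when
its value lies strictly more than k (default 3) SDs above the reference
mean, hypomethylated when strictly more than k SDs below.  Genes with zero
reference SD are excluded from the callable set.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .types import CancerGeneEntry, EventMatrix, MethylationMatrix

logger = logging.getLogger(__name__)

STATES = ("hyper", "hypo", "none")


def build_normal_reference(normal: MethylationMatrix) -> pd.DataFrame:
    """Per-gene reference mean/SD (n-1 denominator) over all normal samples.

    Returns a DataFrame indexed by gene with columns mean, sd, n_samples
    and callable (sd > 0); zero-SD genes are flagged and logged.
    """
    arr = normal.values.to_numpy()
    if arr.shape[1] < 2:
        raise ValueError("need >= 2 normal samples for a reference")
    mean = arr.mean(axis=1)
    sd = arr.std(axis=1, ddof=1)
    callable_ = sd > 0
    n_flagged = int((~callable_).sum())
    if n_flagged:
        logger.info("%d genes with zero reference SD excluded from calling", n_flagged)
    return pd.DataFrame(
        {
            "mean": mean,
            "sd": sd,
            "n_samples": arr.shape[1],
            "callable": callable_,
        },
        index=normal.values.index,
    )


def call_aberrant(tumor_value: float, mean: float, sd: float, k: float = 3.0) -> dict:
    """Single-value aberration call: z = (value - mean) / sd, strict +/- k."""
    if sd <= 0:
        return {"z": np.nan, "state": "none"}
    z = (tumor_value - mean) / sd
    state = "hyper" if z > k else ("hypo" if z < -k else "none")
    return {"z": float(z), "state": state}


class AberrationCaller(BaseEstimator):
    """fit on the normal gene-level matrix; predict states for tumors.

    Parameters
    ----------
    k : float
        Number of reference SDs beyond which a tumor value is called
        aberrant (strict inequality).

    Attributes (after fit)
    ----------------------
    reference_ : pandas.DataFrame with per-gene mean, sd, n_samples, callable.
    """

    def __init__(self, k: float = 3.0):
        self.k = k

    def fit(self, X: MethylationMatrix, y=None):
        self.reference_ = build_normal_reference(X)
        return self

    def predict_z(self, tumors: MethylationMatrix) -> pd.DataFrame:
        ref = self.reference_.reindex(tumors.values.index)
        if ref["mean"].isna().any():
            missing = ref.index[ref["mean"].isna()].tolist()
            raise ValueError(f"genes missing from reference: {missing[:5]}")
        sd = ref["sd"].to_numpy()[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (tumors.values.to_numpy() - ref["mean"].to_numpy()[:, None]) / sd
        z = pd.DataFrame(z, index=tumors.values.index, columns=tumors.values.columns)
        z[~ref["callable"].to_numpy()] = np.nan
        return z

    def predict(self, tumors: MethylationMatrix) -> pd.DataFrame:
        """Genes x tumors matrix of states ('hyper' | 'hypo' | 'none')."""
        z = self.predict_z(tumors)
        arr = z.to_numpy()
        state = np.full(arr.shape, "none", dtype=object)
        with np.errstate(invalid="ignore"):
            state[arr > self.k] = "hyper"
            state[arr < -self.k] = "hypo"
        return pd.DataFrame(state, index=z.index, columns=z.columns)


def calls_to_long(states: pd.DataFrame, z: pd.DataFrame | None = None) -> pd.DataFrame:
    """Long-format (gene, tumor_sample, z, state) export of a state matrix."""
    long = states.stack().rename("state").reset_index()
    long.columns = ["gene", "tumor_sample", "state"]
    if z is not None:
        zl = z.stack(future_stack=True).rename("z").reset_index()
        zl.columns = ["gene", "tumor_sample", "z"]
        long = long.merge(zl, on=["gene", "tumor_sample"], how="left")
    return long


def states_to_event_matrices(states: pd.DataFrame) -> tuple[EventMatrix, EventMatrix]:
    """Split a state matrix into (hyper, hypo) boolean event matrices."""
    return (
        EventMatrix(states == "hyper", "hyper"),
        EventMatrix(states == "hypo", "hypo"),
    )


def tumor_aberration_proportions(
    states: pd.DataFrame, callable_genes: pd.Index | None = None
) -> pd.DataFrame:
    """Per tumor sample, fractions of callable genes hyper/hypomethylated."""
    if callable_genes is not None:
        states = states.loc[states.index.intersection(callable_genes)]
    n = states.shape[0]
    if n == 0:
        raise ValueError("no callable genes")
    frac_hyper = (states == "hyper").sum(axis=0) / n
    frac_hypo = (states == "hypo").sum(axis=0) / n
    return pd.DataFrame(
        {
            "tumor_sample": states.columns,
            "frac_hyper": frac_hyper.to_numpy(),
            "frac_hypo": frac_hypo.to_numpy(),
            "n_callable_genes": n,
        }
    )


def _gene_classes(classes: list[CancerGeneEntry], genes: pd.Index) -> pd.Series:
    role = pd.Series("other", index=genes)
    for entry in classes:
        if entry.role in ("oncogene", "tsg") and entry.gene_symbol in role.index:
            role[entry.gene_symbol] = entry.role
    return role


def class_stratified_rates(
    states_by_type: dict[str, pd.DataFrame],
    mutations: EventMatrix,
    classes: list[CancerGeneEntry],
) -> pd.DataFrame:
    """Aberration and mutation rates per tumor type and gene class.

    For each tumor type and event type (hyper, hypo, mutation), the rate is
    the fraction of (gene x tumor) pairs in the class carrying the event.
    Ambiguous census genes fall into 'other'.  Empty classes yield NaN.
    """
    rows = []
    for tumor_type, states in states_by_type.items():
        genes = states.index
        role = _gene_classes(classes, genes)
        samples = [s for s in states.columns if s in mutations.hits.columns]
        mut = mutations.hits.reindex(index=genes, columns=states.columns, fill_value=False)
        for event_type, hits in (
            ("hyper", states == "hyper"),
            ("hypo", states == "hypo"),
            ("mutation", mut),
        ):
            if event_type == "mutation" and not samples:
                continue
            for cls in ("oncogene", "tsg", "other"):
                cls_genes = role.index[role == cls]
                n_pairs = len(cls_genes) * hits.shape[1]
                if n_pairs == 0:
                    rate = np.nan
                else:
                    rate = float(hits.loc[cls_genes].to_numpy().sum() / n_pairs)
                rows.append(
                    {
                        "tumor_type": tumor_type,
                        "event_type": event_type,
                        "gene_class": cls,
                        "n_genes": len(cls_genes),
                        "n_tumors": hits.shape[1],
                        "rate": rate,
                    }
                )
    return pd.DataFrame(rows)


def compare_onc_tsg_mean_m(
    normal_m: MethylationMatrix, classes: list[CancerGeneEntry]
) -> dict:
    """One-sided Welch t-test: are oncogenes methylated above TSGs in normals?

    Per-gene mean M across normal samples; alternative hypothesis is
    oncogene mean > TSG mean.
    """
    role = _gene_classes(classes, normal_m.values.index)
    gene_means = normal_m.values.mean(axis=1)
    onc = gene_means[role == "oncogene"]
    tsg = gene_means[role == "tsg"]
    if len(onc) < 2 or len(tsg) < 2:
        raise ValueError("need >= 2 genes per class")
    t_stat, p = stats.ttest_ind(onc, tsg, equal_var=False, alternative="greater")
    return {
        "t_stat": float(t_stat),
        "one_sided_p": float(p),
        "mean_oncogene": float(onc.mean()),
        "mean_tsg": float(tsg.mean()),
        "n_oncogene": int(len(onc)),
        "n_tsg": int(len(tsg)),
    }
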