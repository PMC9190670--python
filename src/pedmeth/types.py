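"""Core domain types shared across the pipeline.

The central container is :class:`MethylationMatrix`, a features-by-samples
matrix of beta values (methylated / total signal, in [0, 1]) or M-values
(log2(beta / (1 - beta))).  Sample metadata, probe annotation and event
matrices are plain pandas objects with validated schemas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BETA = "beta"
M = "M"

SEXES = ("female", "male", "unknown")
CONDITIONS = ("normal", "tumor")
IMPACTS = ("HIGH", "MODERATE", "LOW", "MODIFIER")
SIFT_LEVELS = ("deleterious", "tolerated", "other")
POLYPHEN_LEVELS = ("damaging", "probably_damaging", "benign", "other")
GENE_ROLES = ("oncogene", "tsg", "ambiguous")

LEVELS = ("low", "medium", "high")
VARIANCES = ("low", "high")


class MethylationMatrix:
    """Features x samples methylation matrix on the beta or M scale.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are features (probes or genes), columns are sample ids.
    scale : {"beta", "M"}
        Scale of the stored values.  Beta values must lie in [0, 1];
        M-values are unbounded but must be finite.
    """

    def __init__(self, values: pd.DataFrame, scale: str):
        if scale not in (BETA, M):
            raise ValueError(f"scale must be 'beta' or 'M', got {scale!r}")
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        if values.columns.has_duplicates:
            dups = values.columns[values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        arr = values.to_numpy(dtype=float)
        if arr.size and not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                "non-finite value at feature "
                f"{values.index[bad[0]]!r}, sample {values.columns[bad[1]]!r}"
            )
        if scale == BETA and arr.size:
            bad_mask = (arr < 0) | (arr > 1)
            if bad_mask.any():
                i, j = np.argwhere(bad_mask)[0]
                raise ValueError(
                    f"beta value {arr[i, j]} out of [0, 1] at feature "
                    f"{values.index[i]!r}, sample {values.columns[j]!r}"
                )
        self.values = values.astype(float)
        self.scale = scale

    @property
    def feature_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids) -> "MethylationMatrix":
        return MethylationMatrix(self.values.loc[:, list(sample_ids)], self.scale)

    def subset_features(self, feature_ids) -> "MethylationMatrix":
        return MethylationMatrix(self.values.loc[list(feature_ids)], self.scale)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"MethylationMatrix({self.shape[0]} features x {self.shape[1]} "
            f"samples, scale={self.scale})"
        )


METADATA_COLUMNS = ["sample_id", "dataset_id", "sex", "condition", "tumor_type"]


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata table and return it indexed by sample_id.

    ``tumor_type`` must be present exactly for tumor samples (NaN/None for
    normals).
    """
    missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    meta = metadata.copy()
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    bad_sex = set(meta["sex"]) - set(SEXES)
    if bad_sex:
        raise ValueError(f"unknown sex values: {bad_sex}")
    bad_cond = set(meta["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise ValueError(f"unknown condition values: {bad_cond}")
    tt = meta["tumor_type"]
    is_tumor = meta["condition"] == "tumor"
    if (is_tumor & tt.isna()).any():
        raise ValueError("tumor samples must have tumor_type")
    if (~is_tumor & tt.notna()).any():
        raise ValueError("normal samples must not have tumor_type")
    return meta.set_index("sample_id", drop=False)


def check_metadata_covers(matrix: MethylationMatrix, metadata: pd.DataFrame) -> None:
    missing = set(matrix.sample_ids) - set(metadata["sample_id"])
    if missing:
        raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")


@dataclass(frozen=True)
class MutationRecord:
    sample_id: str
    gene_symbol: str
    impact: str
    sift: str | None = None
    polyphen: str | None = None

    def __post_init__(self):
        if self.impact not in IMPACTS:
            raise ValueError(f"unknown impact {self.impact!r}")


@dataclass(frozen=True)
class FusionRecord:
    sample_id: str
    gene_a: str
    gene_b: str

    def __post_init__(self):
        if self.gene_a == self.gene_b:
            raise ValueError("fusion partners must differ")


@dataclass(frozen=True)
class CancerGeneEntry:
    gene_symbol: str
    role: str  # oncogene | tsg | ambiguous
    tier: int

    def __post_init__(self):
        if self.role not in GENE_ROLES:
            raise ValueError(f"unknown role {self.role!r}")


@dataclass
class FilterReport:
    """Tally of one filtering stage: what went in, what was removed."""

    stage_name: str
    n_features_in: int
    n_features_out: int
    removed_ids: list[str] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_features_out != self.n_features_in - len(self.removed_ids):
            raise ValueError(
                f"{self.stage_name}: n_out ({self.n_features_out}) != "
                f"n_in ({self.n_features_in}) - removed ({len(self.removed_ids)})"
            )

    def to_dict(self) -> dict:
        return {
            "stage_name": self.stage_name,
            "n_features_in": self.n_features_in,
            "n_features_out": self.n_features_out,
            "n_removed": len(self.removed_ids),
            "removed_ids": list(self.removed_ids),
            **({"extra": self.extra} if self.extra else {}),
        }


class EventMatrix:
    """Genes x tumor-samples boolean event matrix (mutation, hyper or hypo)."""

    EVENT_TYPES = ("mutation", "hyper", "hypo", "aberrant")

    def __init__(self, hits: pd.DataFrame, event_type: str):
        if event_type not in self.EVENT_TYPES:
            raise ValueError(f"unknown event_type {event_type!r}")
        if hits.index.has_duplicates or hits.columns.has_duplicates:
            raise ValueError("duplicate gene or sample ids in EventMatrix")
        self.hits = hits.astype(bool)
        self.event_type = event_type

    @property
    def genes(self) -> list[str]:
        return self.hits.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.hits.columns.tolist()

    def row_sums(self) -> pd.Series:
        return self.hits.sum(axis=1)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"EventMatrix({self.event_type}, {len(self.genes)} genes x "
            f"{len(self.samples)} samples, {int(self.hits.to_numpy().sum())} events)"
        )


def combine_event_matrices(a: EventMatrix, b: EventMatrix, event_type: str = "aberrant") -> EventMatrix:
    """Elementwise OR of two event matrices on aligned gene/sample axes."""
    genes = a.hits.index.union(b.hits.index)
    samples = a.hits.columns.union(b.hits.columns)
    ah = a.hits.reindex(index=genes, columns=samples, fill_value=False)
    bh = b.hits.reindex(index=genes, columns=samples, fill_value=False)
    return EventMatrix(ah | bh, event_type)
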