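"""Gene methylation-level / variance categorization and consistency labels.

Per dataset, a gene is assigned a level category from the median beta
across samples (low < 0.2, high > 0.6, medium otherwise) and a variance
category from the coefficient of variation (low CV < 0.5, high otherwise;
boundaries fall to medium / high-variance).  Across datasets, genes are
labelled consistent (same category everywhere), semiconsistent (same in
all but one) or inconsistent, and normal-vs-tumor modal categories are
tabulated into a change table.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .types import MethylationMatrix

LEVEL_ORDER = ("low", "medium", "high")
VARIANCE_ORDER = ("low", "high")
CATEGORY_ORDER = [(lv, vr) for lv in LEVEL_ORDER for vr in VARIANCE_ORDER]


@dataclass(frozen=True)
class CategoryThresholds:
    low_max_median: float = 0.2
    high_min_median: float = 0.6
    high_min_cv: float = 0.5

    def __post_init__(self):
        if not (0 < self.low_max_median < self.high_min_median < 1):
            raise ValueError("need 0 < low_max_median < high_min_median < 1")
        if self.high_min_cv <= 0:
            raise ValueError("high_min_cv must be positive")


def percent(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage with decimal half-up rounding (as printed in summaries)."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    pct = Decimal(numerator) / Decimal(denominator) * 100
    quantum = Decimal(1).scaleb(-ndigits)
    return float(pct.quantize(quantum, rounding=ROUND_HALF_UP))


def categorize_gene(values, thresholds: CategoryThresholds = CategoryThresholds()) -> dict:
    """Category of one gene in one dataset from its per-sample betas.

    Returns a dict with median_beta, cv, level and variance.  CV uses the
    sample (n-1) standard deviation on the beta scale; a zero mean yields
    CV = 0 by convention.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need >= 2 samples to categorize")
    if (arr < 0).any() or (arr > 1).any():
        raise ValueError("betas must lie in [0, 1]")
    med = float(np.median(arr))
    mean = float(arr.mean())
    cv = 0.0 if mean == 0 else float(arr.std(ddof=1) / mean)
    if med < thresholds.low_max_median:
        level = "low"
    elif med > thresholds.high_min_median:
        level = "high"
    else:
        level = "medium"
    variance = "low" if cv < thresholds.high_min_cv else "high"
    return {"median_beta": med, "cv": cv, "level": level, "variance": variance}


def categorize_matrix(
    matrix: MethylationMatrix,
    dataset_id: str,
    thresholds: CategoryThresholds = CategoryThresholds(),
) -> pd.DataFrame:
    """Vectorized per-gene categorization of one dataset's beta matrix."""
    arr = matrix.values.to_numpy()
    if arr.shape[1] < 2:
        raise ValueError("need >= 2 samples to categorize")
    med = np.median(arr, axis=1)
    mean = arr.mean(axis=1)
    sd = arr.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean == 0, 0.0, sd / mean)
    level = np.where(
        med < thresholds.low_max_median,
        "low",
        np.where(med > thresholds.high_min_median, "high", "medium"),
    )
    variance = np.where(cv < thresholds.high_min_cv, "low", "high")
    return pd.DataFrame(
        {
            "gene": matrix.feature_ids,
            "dataset_id": dataset_id,
            "median_beta": med,
            "cv": cv,
            "level": level,
            "variance": variance,
        }
    )


def _category_key(level: str, variance: str) -> tuple[int, int]:
    return (LEVEL_ORDER.index(level), VARIANCE_ORDER.index(variance))


def modal_category(categories: list[tuple[str, str]]) -> tuple[str, str]:
    """Most frequent (level, variance) pair; ties broken by the fixed order
    low < medium < high crossed with low < high variance."""
    if not categories:
        raise ValueError("no categories supplied")
    counts: dict[tuple[str, str], int] = {}
    for cat in categories:
        counts[cat] = counts.get(cat, 0) + 1
    return min(counts, key=lambda c: (-counts[c], _category_key(*c)))


def classify_consistency(categories: list[tuple[str, str]]) -> dict:
    """Consistency label for one gene across datasets.

    consistent = same category in every dataset; semiconsistent = in all
    but one; inconsistent otherwise (generalizes the 4/3/<=2 rule to any
    dataset count).
    """
    n = len(categories)
    if n < 2:
        raise ValueError("need >= 2 datasets")
    modal = modal_category(categories)
    n_agreeing = sum(1 for c in categories if c == modal)
    if n_agreeing == n:
        label = "consistent"
    elif n_agreeing == n - 1:
        label = "semiconsistent"
    else:
        label = "inconsistent"
    return {"label": label, "modal_category": modal, "n_agreeing": n_agreeing}


def consistency_table(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-gene consistency labels from stacked per-dataset profiles.

    ``profiles`` must have columns gene, dataset_id, level, variance (as
    produced by :func:`categorize_matrix`).
    """
    rows = []
    for gene, sub in profiles.groupby("gene", sort=True):
        cats = list(zip(sub["level"], sub["variance"]))
        res = classify_consistency(cats)
        rows.append(
            {
                "gene": gene,
                "label": res["label"],
                "modal_level": res["modal_category"][0],
                "modal_variance": res["modal_category"][1],
                "n_agreeing": res["n_agreeing"],
                "n_datasets": len(cats),
            }
        )
    return pd.DataFrame(rows)


def _fmt(cat: tuple[str, str]) -> str:
    return f"{cat[0]}/{cat[1]}"


def category_change_table(
    normal_modal: pd.Series, tumor_modal: pd.Series
) -> tuple[pd.DataFrame, dict]:
    """Normal -> tumor modal-category change table plus aggregate counts.

    Both inputs map gene -> (level, variance).  Rows cover ordered category
    pairs with normal != tumor and at least one changed gene; the
    percentage is relative to the number of genes in the normal category.
    Aggregates count total changed genes, level increases (low -> medium or
    medium -> high, at any variance) and variance low -> high moves.
    """
    genes = normal_modal.index.intersection(tumor_modal.index)
    nm = normal_modal.loc[genes]
    tm = tumor_modal.loc[genes]
    rows = []
    totals = nm.value_counts()
    changed_mask = nm != tm
    pair_counts = (
        pd.DataFrame({"normal": nm[changed_mask], "tumor": tm[changed_mask]})
        .value_counts()
        .sort_index()
    )
    for (ncat, tcat), count in pair_counts.items():
        total = int(totals[ncat])
        rows.append(
            {
                "normal_category": _fmt(ncat),
                "tumor_category": _fmt(tcat),
                "total_genes_normal": total,
                "n_changed": int(count),
                # raw percentage; round with :func:`percent` for display
                "pct_changed": 100.0 * int(count) / total,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "normal_category",
            "tumor_category",
            "total_genes_normal",
            "n_changed",
            "pct_changed",
        ],
    )
    level_idx = {lv: i for i, lv in enumerate(LEVEL_ORDER)}
    n_changed = int(changed_mask.sum())
    level_up = sum(
        1
        for n, t in zip(nm[changed_mask], tm[changed_mask])
        if level_idx[t[0]] == level_idx[n[0]] + 1
    )
    var_up = sum(
        1
        for n, t in zip(nm[changed_mask], tm[changed_mask])
        if n[1] == "low" and t[1] == "high"
    )
    aggregates = {
        "n_genes": int(len(genes)),
        "n_changed": n_changed,
        "n_level_increase": int(level_up),
        "pct_level_increase": percent(level_up, n_changed) if n_changed else None,
        "n_variance_low_to_high": int(var_up),
        "pct_variance_low_to_high": percent(var_up, n_changed) if n_changed else None,
    }
    return table, aggregates


def high_variance_overlap(
    per_dataset_flags: pd.DataFrame, pooled_flags: pd.Series
) -> tuple[int, int, float]:
    """Overlap between per-dataset and pooled high-variance gene sets.

    ``per_dataset_flags`` is genes x datasets of booleans (high variance in
    that dataset); ``pooled_flags`` is the per-gene flag computed across all
    normal samples combined.  Returns (number of genes high-variance in at
    least one dataset, how many of those are also pooled-high-variance, and
    the fraction).
    """
    any_dataset = per_dataset_flags.any(axis=1)
    genes_any = per_dataset_flags.index[any_dataset]
    pooled = pooled_flags.reindex(genes_any, fill_value=False)
    n_any = int(any_dataset.sum())
    n_both = int(pooled.sum())
    fraction = n_both / n_any if n_any else float("nan")
    return n_any, n_both, fraction
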