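"""Synthetic multi-cohort methylation, mutation and fusion data.

The generator emulates the statistical structure the analysis assumes:

* per-gene methylation archetypes (level low/medium/high crossed with
  variance low/high) drawn as logistic-normal noise on the M scale, so
  betas respect [0, 1];
* several normal cohorts with per-(cohort, gene) batch shifts and optional
  sex effects on a random gene subset;
* tumor cohorts drawn from the same generative model, with per-tumor
  planted hyper/hypomethylation (regime replacement at +/- k reference SDs)
  and optional tumor-type-specific differential genes (fixed M shift);
* gene-level mutation/fusion events with a controllable co-occurrence
  relationship to the planted methylation events (independent, exclusive or
  co-occurring), emitted through the VCF/BEDPE writers so the parsers are
  exercised end-to-end.

Every stage records truth tables sufficient to score the downstream
callers.  All randomness flows from ``SimulationConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as pio
from .transforms import beta_to_m, m_to_beta
from .types import (
    BETA,
    EventMatrix,
    FusionRecord,
    MethylationMatrix,
    MutationRecord,
    validate_metadata,
)

# Archetype noise regimes calibrated so planted categories sit well clear of
# the 0.2 / 0.6 / CV 0.5 thresholds under the default sample sizes.
ARCHETYPE_PARAMS = {
    ("low", "low"): {"beta_range": (0.06, 0.13), "noise": ("beta_sd", 0.02)},
    ("medium", "low"): {"beta_range": (0.28, 0.45), "noise": ("beta_sd", 0.02)},
    ("high", "low"): {"beta_range": (0.72, 0.88), "noise": ("beta_sd", 0.02)},
    ("low", "high"): {"beta_range": (0.07, 0.12), "noise": ("m_sd", 1.5)},
    ("medium", "high"): {"beta_range": (0.28, 0.36), "noise": ("m_sd", 2.2)},
    # high/high is not reachable with logistic-normal noise (betas are
    # bounded above), matching its near-absence in real cohorts.
}

DEFAULT_ARCHETYPE_FRACTIONS = {
    ("low", "low"): 0.65,
    ("medium", "low"): 0.17,
    ("high", "low"): 0.15,
    ("low", "high"): 0.015,
    ("medium", "high"): 0.015,
}


@dataclass
class SimulationConfig:
    """Study design and effect sizes for the synthetic cohorts."""

    n_genes: int = 2000
    probes_per_gene: int = 2
    n_normal_datasets: int = 4
    samples_per_dataset: int = 30
    tumor_types: dict = field(
        default_factory=lambda: {"wilms": 40, "neuroblastoma": 40, "osteosarcoma": 40}
    )
    archetype_fractions: dict = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPE_FRACTIONS)
    )
    batch_shift_sd: float = 0.3  # M scale, per (dataset, gene)
    sex_effect_sd: float = 0.5  # M scale, on a random gene subset
    sex_gene_fraction: float = 0.05
    probe_offset_sd: float = 0.15  # M scale, per probe
    probe_jitter_sd: float = 0.05  # M scale, per probe per sample
    distant_probe_fraction: float = 0.25  # extra probe beyond the TSS window
    frac_hyper: float = 0.05  # planted per-tumor fractions of genes
    frac_hypo: float = 0.10
    aberration_shift_sd_units: float = 4.0
    aberration_residual_sd_frac: float = 0.25
    n_dm_genes_per_type: int = 5
    dm_shift_m: float = 4.0
    expr_correlated_fraction: float = 0.5
    expr_slope: float = -1.5
    expr_noise_sd: float = 1.0
    mutation_rate: float = 0.03  # raw planted event rate per gene x tumor
    damaging_fraction: float = 0.8
    fusion_fraction: float = 0.1
    cooccurrence_mode: str = "independent"  # independent | exclusive | cooccurring
    seed: int = 0

    def __post_init__(self):
        total = sum(self.archetype_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"archetype fractions sum to {total}, expected 1")
        if any(f < 0 for f in self.archetype_fractions.values()):
            raise ValueError("archetype fractions must be non-negative")
        if self.cooccurrence_mode not in ("independent", "exclusive", "cooccurring"):
            raise ValueError(f"unknown cooccurrence_mode {self.cooccurrence_mode!r}")


@dataclass
class NormalSimulation:
    matrices: dict  # dataset_id -> probe-level beta MethylationMatrix
    metadata: pd.DataFrame
    annotation: pd.DataFrame
    gene_truth: pd.DataFrame  # gene, level, variance, mu_beta, sigma_m, sex_effect_m
    probe_truth: pd.DataFrame  # probe_id, gene, offset_m, promoter


@dataclass
class TumorSimulation:
    matrices: dict  # tumor_type -> probe-level beta MethylationMatrix
    metadata: pd.DataFrame
    aberration_truth: pd.DataFrame  # tumor_sample, gene, direction
    dm_truth: pd.DataFrame  # tumor_type, gene, shift_m
    reference: pd.DataFrame  # per-gene mean/sd used for planting (gene-level beta)
    expression: pd.DataFrame  # genes x tumor samples


def _draw_archetypes(config: SimulationConfig, rng) -> pd.DataFrame:
    genes = [f"GENE{i:05d}" for i in range(config.n_genes)]
    cats = list(config.archetype_fractions)
    fractions = np.array([config.archetype_fractions[c] for c in cats])
    counts = np.floor(fractions * config.n_genes).astype(int)
    # distribute the remainder to the largest fractional parts
    remainder = config.n_genes - counts.sum()
    frac_part = fractions * config.n_genes - counts
    for i in np.argsort(-frac_part)[:remainder]:
        counts[i] += 1
    labels = np.repeat(np.arange(len(cats)), counts)
    rng.shuffle(labels)
    rows = []
    for gene, lab in zip(genes, labels):
        level, variance = cats[lab]
        params = ARCHETYPE_PARAMS[(level, variance)]
        lo, hi = params["beta_range"]
        mu_beta = rng.uniform(lo, hi)
        kind, value = params["noise"]
        if kind == "beta_sd":
            sigma_m = value / (np.log(2) * mu_beta * (1 - mu_beta))
        else:
            sigma_m = value
        rows.append(
            {
                "gene": gene,
                "level": level,
                "variance": variance,
                "mu_beta": mu_beta,
                "mu_m": float(beta_to_m(mu_beta)),
                "sigma_m": sigma_m,
            }
        )
    truth = pd.DataFrame(rows).set_index("gene", drop=False)
    sex_genes = rng.random(config.n_genes) < config.sex_gene_fraction
    truth["sex_effect_m"] = np.where(
        sex_genes, rng.normal(0.0, config.sex_effect_sd, config.n_genes), 0.0
    )
    return truth


def _probe_layout(config: SimulationConfig, truth: pd.DataFrame, rng) -> pd.DataFrame:
    rows = []
    for gene in truth.index:
        for p in range(config.probes_per_gene):
            rows.append(
                {
                    "probe_id": f"cg_{gene}_{p}",
                    "gene_symbol": gene,
                    "tss_distance_bp": int(rng.integers(0, 301)),
                    "offset_m": rng.normal(0.0, config.probe_offset_sd),
                }
            )
        if rng.random() < config.distant_probe_fraction:
            rows.append(
                {
                    "probe_id": f"cg_{gene}_far",
                    "gene_symbol": gene,
                    "tss_distance_bp": int(rng.integers(301, 601)),
                    "offset_m": rng.normal(0.0, 2 * config.probe_offset_sd),
                }
            )
    layout = pd.DataFrame(rows)
    layout["promoter"] = layout["tss_distance_bp"] <= 300
    return layout


def _sample_cohort(
    truth: pd.DataFrame,
    layout: pd.DataFrame,
    n_samples: int,
    batch_shift_m: np.ndarray,
    sex_is_male: np.ndarray,
    rng,
    config: SimulationConfig,
    gene_m_override=None,
) -> pd.DataFrame:
    """Probe-level beta values for one cohort (probes x samples)."""
    n_genes = len(truth)
    gene_m = (
        truth["mu_m"].to_numpy()[:, None]
        + batch_shift_m[:, None]
        + truth["sex_effect_m"].to_numpy()[:, None] * sex_is_male[None, :]
        + truth["sigma_m"].to_numpy()[:, None] * rng.standard_normal((n_genes, n_samples))
    )
    if gene_m_override is not None:
        mask, values = gene_m_override
        gene_m = np.where(mask, values, gene_m)
    gene_pos = {g: i for i, g in enumerate(truth.index)}
    probe_rows = layout["gene_symbol"].map(gene_pos).to_numpy()
    probe_m = (
        gene_m[probe_rows]
        + layout["offset_m"].to_numpy()[:, None]
        + config.probe_jitter_sd * rng.standard_normal((len(layout), n_samples))
    )
    return pd.DataFrame(m_to_beta(probe_m), index=layout["probe_id"].to_numpy())


def simulate_normals(config: SimulationConfig) -> NormalSimulation:
    """Multi-batch normal cohorts with planted gene archetypes."""
    rng = np.random.default_rng(config.seed)
    truth = _draw_archetypes(config, rng)
    layout = _probe_layout(config, truth, rng)
    matrices = {}
    meta_rows = []
    for d in range(config.n_normal_datasets):
        dataset_id = f"normal{d}"
        batch_shift = rng.normal(0.0, config.batch_shift_sd, config.n_genes)
        sex_is_male = rng.random(config.samples_per_dataset) < 0.5
        sample_ids = [f"{dataset_id}_s{j:03d}" for j in range(config.samples_per_dataset)]
        betas = _sample_cohort(
            truth, layout, config.samples_per_dataset, batch_shift, sex_is_male, rng, config
        )
        betas.columns = sample_ids
        matrices[dataset_id] = MethylationMatrix(betas, BETA)
        for sid, male in zip(sample_ids, sex_is_male):
            meta_rows.append(
                {
                    "sample_id": sid,
                    "dataset_id": dataset_id,
                    "sex": "male" if male else "female",
                    "condition": "normal",
                    "tumor_type": None,
                }
            )
    metadata = validate_metadata(pd.DataFrame(meta_rows))
    annotation = layout[["probe_id", "gene_symbol", "tss_distance_bp"]].copy()
    probe_truth = layout[["probe_id", "gene_symbol", "offset_m", "promoter"]].rename(
        columns={"gene_symbol": "gene"}
    )
    return NormalSimulation(matrices, metadata, annotation, truth, probe_truth)


def pooled_normal_gene_matrix(sim: NormalSimulation) -> MethylationMatrix:
    """Promoter-probe, gene-level beta matrix pooled over all normal cohorts."""
    from .preprocess import filter_promoter_probes, summarize_gene_level

    ann, _ = filter_promoter_probes(sim.annotation)
    pooled = pd.concat([m.values for m in sim.matrices.values()], axis=1)
    return summarize_gene_level(MethylationMatrix(pooled, BETA), ann)


def simulate_tumors(config: SimulationConfig, normal_sim: NormalSimulation) -> TumorSimulation:
    """Tumor cohorts with planted aberrations and differential genes.

    Aberrations replace the tumor's gene value with a draw at
    mean +/- shift_units * SD of the pooled normal gene-level reference
    (residual SD = aberration_residual_sd_frac * reference SD), so planted
    events sit a known number of reference SDs from the mean.  Genes whose
    reference band would cross 0 or 1 are ineligible for that direction.
    """
    rng = np.random.default_rng(config.seed + 1)
    truth = normal_sim.gene_truth
    layout = normal_sim.probe_truth.rename(columns={"gene": "gene_symbol"})
    genes = truth.index.to_numpy()
    n_genes = len(genes)

    gene_ref = pooled_normal_gene_matrix(normal_sim)
    ref_mean = gene_ref.values.mean(axis=1).reindex(genes)
    ref_sd = gene_ref.values.std(axis=1, ddof=1).reindex(genes)
    reference = pd.DataFrame({"mean": ref_mean, "sd": ref_sd})

    margin = (config.aberration_shift_sd_units + 1.5) * ref_sd
    hyper_ok = (ref_mean + margin <= 0.98).to_numpy()
    hypo_ok = (ref_mean - margin >= 0.02).to_numpy()

    # type-specific differential genes: low/low archetype, disjoint per type
    lowlow = truth.index[(truth["level"] == "low") & (truth["variance"] == "low")]
    dm_pool = rng.permutation(lowlow.to_numpy())
    dm_rows = []
    dm_assign: dict[str, set] = {}
    cursor = 0
    for tumor_type in config.tumor_types:
        chosen = dm_pool[cursor : cursor + config.n_dm_genes_per_type]
        cursor += config.n_dm_genes_per_type
        dm_assign[tumor_type] = set(chosen)
        dm_rows += [
            {"tumor_type": tumor_type, "gene": g, "shift_m": config.dm_shift_m}
            for g in chosen
        ]
    dm_truth = pd.DataFrame(dm_rows, columns=["tumor_type", "gene", "shift_m"])

    matrices = {}
    meta_rows = []
    ab_rows = []
    expr_blocks = []
    expr_correlated = rng.random(n_genes) < config.expr_correlated_fraction
    for tumor_type, n_tumors in config.tumor_types.items():
        sample_ids = [f"{tumor_type}_t{j:03d}" for j in range(n_tumors)]
        sex_is_male = rng.random(n_tumors) < 0.5
        n_hyper = int(round(config.frac_hyper * n_genes))
        n_hypo = int(round(config.frac_hypo * n_genes))
        override_mask = np.zeros((n_genes, n_tumors), dtype=bool)
        override_m = np.zeros((n_genes, n_tumors))
        hyper_idx = np.flatnonzero(hyper_ok)
        hypo_idx = np.flatnonzero(hypo_ok)
        if n_hyper > len(hyper_idx) or n_hypo > len(hypo_idx):
            raise ValueError("not enough eligible genes for the requested fractions")
        for j, sid in enumerate(sample_ids):
            chosen_hyper = rng.choice(hyper_idx, size=n_hyper, replace=False)
            remaining = np.setdiff1d(hypo_idx, chosen_hyper, assume_unique=False)
            chosen_hypo = rng.choice(remaining, size=n_hypo, replace=False)
            for idx_set, sign, label in (
                (chosen_hyper, 1.0, "hyper"),
                (chosen_hypo, -1.0, "hypo"),
            ):
                target_beta = (
                    ref_mean.to_numpy()[idx_set]
                    + sign * config.aberration_shift_sd_units * ref_sd.to_numpy()[idx_set]
                    + config.aberration_residual_sd_frac
                    * ref_sd.to_numpy()[idx_set]
                    * rng.standard_normal(len(idx_set))
                )
                target_beta = np.clip(target_beta, 1e-4, 1 - 1e-4)
                override_mask[idx_set, j] = True
                override_m[idx_set, j] = beta_to_m(target_beta)
                ab_rows += [
                    {"tumor_sample": sid, "gene": genes[i], "direction": label}
                    for i in idx_set
                ]
        betas = _sample_cohort(
            truth,
            layout,
            n_tumors,
            np.zeros(n_genes),
            sex_is_male,
            rng,
            config,
            gene_m_override=(override_mask, override_m),
        )
        betas.columns = sample_ids
        if dm_assign[tumor_type]:
            dm_probe_mask = layout["gene_symbol"].isin(dm_assign[tumor_type]).to_numpy()
            m_vals = beta_to_m(betas.to_numpy())
            m_vals[dm_probe_mask] += config.dm_shift_m
            betas = pd.DataFrame(m_to_beta(m_vals), index=betas.index, columns=betas.columns)
        matrices[tumor_type] = MethylationMatrix(betas, BETA)
        for sid, male in zip(sample_ids, sex_is_male):
            meta_rows.append(
                {
                    "sample_id": sid,
                    "dataset_id": f"tumor_{tumor_type}",
                    "sex": "male" if male else "female",
                    "condition": "tumor",
                    "tumor_type": tumor_type,
                }
            )
        # tumor gene expression: anticorrelated with methylation for a subset
        gene_m_mat = beta_to_m(
            MethylationMatrix(betas, BETA).values.to_numpy()
        )
        gene_level_m = (
            pd.DataFrame(gene_m_mat, index=betas.index)
            .groupby(layout.set_index("probe_id").loc[betas.index, "gene_symbol"].to_numpy())
            .mean()
            .reindex(genes)
        )
        expr = np.where(
            expr_correlated[:, None],
            10.0 + config.expr_slope * gene_level_m.to_numpy(),
            5.0 + 2.0 * rng.standard_normal((n_genes, n_tumors)),
        ) + config.expr_noise_sd * rng.standard_normal((n_genes, n_tumors))
        expr_blocks.append(pd.DataFrame(expr, index=genes, columns=sample_ids))

    metadata = validate_metadata(pd.DataFrame(meta_rows))
    aberration_truth = pd.DataFrame(ab_rows, columns=["tumor_sample", "gene", "direction"])
    expression = pd.concat(expr_blocks, axis=1)
    return TumorSimulation(matrices, metadata, aberration_truth, dm_truth, reference, expression)


def aberration_truth_matrices(
    tumor_sim: TumorSimulation, genes: list[str]
) -> tuple[EventMatrix, EventMatrix]:
    """Planted (hyper, hypo) truth as boolean gene x tumor matrices."""
    samples = [s for m in tumor_sim.matrices.values() for s in m.sample_ids]
    out = []
    for direction in ("hyper", "hypo"):
        hits = pd.DataFrame(False, index=pd.Index(genes, name="gene"), columns=samples)
        sub = tumor_sim.aberration_truth[tumor_sim.aberration_truth["direction"] == direction]
        for _, row in sub.iterrows():
            if row["gene"] in hits.index:
                hits.loc[row["gene"], row["tumor_sample"]] = True
        out.append(EventMatrix(hits, direction))
    return out[0], out[1]


def simulate_events(
    config: SimulationConfig,
    methylation_events: EventMatrix,
    out_dir=None,
) -> tuple[EventMatrix, list[MutationRecord], list[FusionRecord]]:
    """Plant gene x tumor mutation events relative to the methylation truth.

    Returns the truth EventMatrix of functional (filter-passing) events plus
    the raw records.  Under ``exclusive`` mode events avoid aberrant
    (gene, tumor) cells; ``cooccurring`` restricts them to aberrant cells;
    ``independent`` ignores the methylation truth.  A
    ``1 - damaging_fraction`` share of SNVs is annotated to fail the
    consequence filter; a ``fusion_fraction`` share is emitted as fusions
    (partner genes outside the analysis universe).  With ``out_dir`` set,
    per-sample VCF and BEDPE files are written through the core writers.
    """
    rng = np.random.default_rng(config.seed + 2)
    meth = methylation_events.hits
    genes = list(meth.index)
    samples = list(meth.columns)
    base = np.full(meth.shape, config.mutation_rate)
    aberrant = meth.to_numpy()
    if config.cooccurrence_mode == "exclusive":
        rate = np.where(aberrant, 0.0, base)
    elif config.cooccurrence_mode == "cooccurring":
        rate = np.where(aberrant, np.minimum(3 * base, 1.0), 0.0)
    else:
        rate = base
    planted = rng.random(meth.shape) < rate

    truth = pd.DataFrame(False, index=meth.index, columns=meth.columns)
    mutations: list[MutationRecord] = []
    fusions: list[FusionRecord] = []
    n_fus = 0
    for gi, si in zip(*np.nonzero(planted)):
        gene, sample = genes[gi], samples[si]
        if rng.random() < config.fusion_fraction:
            n_fus += 1
            fusions.append(FusionRecord(sample, gene, f"FUSPART{n_fus:05d}"))
            truth.iloc[gi, si] = True
        elif rng.random() < config.damaging_fraction:
            if rng.random() < 0.5:
                rec = MutationRecord(sample, gene, "HIGH")
            elif rng.random() < 0.5:
                rec = MutationRecord(sample, gene, "MODERATE", sift="deleterious")
            else:
                rec = MutationRecord(
                    sample, gene, "MODERATE", sift=None, polyphen="probably_damaging"
                )
            mutations.append(rec)
            truth.iloc[gi, si] = True
        else:
            mutations.append(
                MutationRecord(sample, gene, "MODERATE", sift="tolerated", polyphen="benign")
            )
    truth_matrix = EventMatrix(truth, "mutation")

    if out_dir is not None:
        from pathlib import Path

        out_dir = Path(out_dir)
        (out_dir / "vcf").mkdir(parents=True, exist_ok=True)
        (out_dir / "bedpe").mkdir(parents=True, exist_ok=True)
        by_sample_mut: dict[str, list[MutationRecord]] = {s: [] for s in samples}
        by_sample_fus: dict[str, list[FusionRecord]] = {s: [] for s in samples}
        for rec in mutations:
            by_sample_mut[rec.sample_id].append(rec)
        for fus in fusions:
            by_sample_fus[fus.sample_id].append(fus)
        for s in samples:
            pio.write_vcf_mutations(by_sample_mut[s], out_dir / "vcf" / f"{s}.vcf")
            pio.write_bedpe_fusions(by_sample_fus[s], out_dir / "bedpe" / f"{s}.bedpe")
    return truth_matrix, mutations, fusions


def simulate_event_study(
    n_genes: int,
    n_tumors: int,
    meth_events_per_gene: int,
    mutation_rate: float,
    mode: str,
    seed: int,
) -> tuple[EventMatrix, EventMatrix]:
    """Small-scale (mutation, methylation) event-matrix pair for mutex tests.

    Each gene receives exactly ``meth_events_per_gene`` methylation events at
    uniformly random tumors; mutations are then planted at ``mutation_rate``
    per cell under the requested co-occurrence mode.
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i:03d}" for i in range(n_genes)]
    samples = [f"T{i:03d}" for i in range(n_tumors)]
    meth = np.zeros((n_genes, n_tumors), dtype=bool)
    for g in range(n_genes):
        meth[g, rng.choice(n_tumors, size=meth_events_per_gene, replace=False)] = True
    if mode == "exclusive":
        rate = np.where(meth, 0.0, mutation_rate)
    elif mode == "cooccurring":
        rate = np.where(meth, min(3 * mutation_rate, 1.0), 0.0)
    elif mode == "independent":
        rate = np.full(meth.shape, mutation_rate)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    mut = rng.random(meth.shape) < rate
    idx = pd.Index(genes, name="gene")
    return (
        EventMatrix(pd.DataFrame(mut, index=idx, columns=samples), "mutation"),
        EventMatrix(pd.DataFrame(meth, index=idx, columns=samples), "aberrant"),
    )
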