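"""End-to-end orchestration of the analysis stages on one configuration.

Stage order: preprocess -> categorize -> diffmeth -> aberrant -> events ->
mutex.  Intermediate artifacts are serialized as TSV/JSON in the output
directory so each stage is independently re-runnable; the run report
aggregates filter tallies, the category-change table, differential tables,
aberration proportions, class-stratified rates and the mutual-exclusivity
results.  All randomness is seeded from the config.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import aberrant as ab
from . import categorize as cat
from . import diffmeth as dm
from . import events as ev
from . import io as pio
from . import mutex as mx
from . import preprocess as pp
from . import synthetic as syn
from .batch import batch_correct
from .transforms import matrix_to_m
from .types import MethylationMatrix

logger = logging.getLogger(__name__)


def cohort_summary(metadata: pd.DataFrame) -> dict:
    """Cohort totals and sex fractions, as reported in study summaries."""
    from .categorize import percent

    normal = metadata[metadata["condition"] == "normal"]
    tumor = metadata[metadata["condition"] == "tumor"]
    out = {
        "n_normal": int(len(normal)),
        "n_tumor": int(len(tumor)),
        "n_tumors_per_type": tumor["dataset_id"].value_counts().to_dict(),
    }
    for name, sub in (("normal", normal), ("tumor", tumor)):
        if len(sub):
            out[f"pct_female_{name}"] = percent(int((sub["sex"] == "female").sum()), len(sub))
    return out


class StageError(RuntimeError):
    def __init__(self, stage: str, code: str, cause: Exception):
        super().__init__(f"stage {stage} failed [{code}]: {cause}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    out_dir: str = "pedmeth_run"
    seed: int = 0
    alpha: float = 0.05
    lfc_threshold: float = 2.0
    z_k: float = 3.0
    min_events: int = 5
    n_permutations: int = 10_000
    window_bp: int = 300
    thresholds: cat.CategoryThresholds = field(default_factory=cat.CategoryThresholds)
    batch_correction: bool = True
    stages: dict = field(
        default_factory=lambda: {
            "categorize": True,
            "diffmeth": True,
            "aberrant": True,
            "events": True,
            "mutex": True,
        }
    )
    simulation: syn.SimulationConfig | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        thresholds = raw.pop("thresholds", None)
        cfg = cls(**raw)
        if sim is not None:
            sim.setdefault("seed", cfg.seed)
            sim = dict(sim)
            if "tumor_types" in sim:
                sim["tumor_types"] = dict(sim["tumor_types"])
            af = sim.pop("archetype_fractions", None)
            kwargs = dict(sim)
            if af is not None:
                kwargs["archetype_fractions"] = {
                    tuple(k.split("/")): v for k, v in af.items()
                }
            cfg.simulation = syn.SimulationConfig(**kwargs)
        if thresholds is not None:
            cfg.thresholds = cat.CategoryThresholds(**thresholds)
        return cfg


def _stage(report: dict, name: str, code: str, fn):
    t0 = time.time()
    try:
        result = fn()
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        raise StageError(name, code, exc) from exc
    logger.info("stage %s finished in %.1fs", name, time.time() - t0)
    report.setdefault("timings_s", {})[name] = round(time.time() - t0, 2)
    return result


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full synthetic-study pipeline; returns the aggregated report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}
    sim_cfg = config.simulation or syn.SimulationConfig(seed=config.seed)

    # ---- simulate ----------------------------------------------------
    normal_sim = _stage(report, "simulate_normals", "SIM", lambda: syn.simulate_normals(sim_cfg))
    tumor_sim = _stage(
        report, "simulate_tumors", "SIM", lambda: syn.simulate_tumors(sim_cfg, normal_sim)
    )
    metadata = pd.concat([normal_sim.metadata, tumor_sim.metadata])

    # ---- preprocess --------------------------------------------------
    def _preprocess():
        ann, promoter_report = pp.filter_promoter_probes(normal_sim.annotation, config.window_bp)
        normal_gene = {
            d: pp.summarize_gene_level(m, ann) for d, m in normal_sim.matrices.items()
        }
        tumor_gene = {
            t: pp.summarize_gene_level(m, ann) for t, m in tumor_sim.matrices.items()
        }
        pooled_normal = MethylationMatrix(
            pd.concat([m.values for m in normal_gene.values()], axis=1), "beta"
        )
        corrected_normal = batch_correct(pooled_normal, metadata, enabled=config.batch_correction)
        # probe-level DM-track filters
        all_probe = list(normal_sim.matrices.values()) + list(tumor_sim.matrices.values())
        invariant_report = pp.filter_invariant_category_probes(
            all_probe, config.thresholds.low_max_median, config.thresholds.high_min_median
        )
        keep_probes = [
            p
            for p in all_probe[0].values.index.intersection(
                pd.Index(ann["probe_id"].unique())
            )
            if p not in set(invariant_report.removed_ids)
        ]
        tumor_probe_pool = MethylationMatrix(
            pd.concat([m.values for m in tumor_sim.matrices.values()], axis=1), "beta"
        ).subset_features(keep_probes)
        expr_report = pp.filter_expression_correlated_probes(
            matrix_to_m(tumor_probe_pool), tumor_sim.expression, ann, config.alpha
        )
        dm_probes = [
            p for p in keep_probes if p not in set(expr_report.removed_ids)
        ]
        normals_m = {
            d: matrix_to_m(m.subset_features([p for p in dm_probes if p in m.values.index]))
            for d, m in normal_sim.matrices.items()
        }
        cross_report = pp.filter_cross_normal_divergent_probes(
            normals_m, metadata, config.alpha, config.lfc_threshold
        )
        final_probes = [p for p in dm_probes if p not in set(cross_report.removed_ids)]
        reports = [promoter_report, invariant_report, expr_report, cross_report]
        for r in reports:
            (out / f"filter_{r.stage_name}.json").write_text(json.dumps(r.to_dict()))
        pca = pp.pca_qc(pooled_normal, metadata)
        pca_corrected = pp.pca_qc(corrected_normal, metadata)
        report["preprocess"] = {
            "filters": [
                {k: v for k, v in r.to_dict().items() if k != "removed_ids"}
                for r in reports
            ],
            "batch_separation_before": pp.batch_separation_statistic(pca),
            "batch_separation_after": pp.batch_separation_statistic(pca_corrected),
        }
        return ann, normal_gene, tumor_gene, corrected_normal, final_probes

    ann, normal_gene, tumor_gene, corrected_normal, dm_probes = _stage(
        report, "preprocess", "PRE", _preprocess
    )

    # ---- categorize --------------------------------------------------
    if config.stages.get("categorize", True):
        def _categorize():
            profiles = pd.concat(
                [cat.categorize_matrix(m, d, config.thresholds) for d, m in normal_gene.items()]
            )
            consistency = cat.consistency_table(profiles)
            normal_modal = consistency.set_index("gene").apply(
                lambda r: (r["modal_level"], r["modal_variance"]), axis=1
            )
            tumor_profiles = pd.concat(
                [cat.categorize_matrix(m, t, config.thresholds) for t, m in tumor_gene.items()]
            )
            tumor_consistency = cat.consistency_table(tumor_profiles)
            tumor_modal = tumor_consistency.set_index("gene").apply(
                lambda r: (r["modal_level"], r["modal_variance"]), axis=1
            )
            change_table, aggregates = cat.category_change_table(normal_modal, tumor_modal)
            change_table.to_csv(out / "category_change_table.tsv", sep="\t", index=False)
            consistency.to_csv(out / "normal_consistency.tsv", sep="\t", index=False)
            label_counts = consistency["label"].value_counts().to_dict()
            n_genes = len(consistency)
            return {
                "n_genes": n_genes,
                "label_counts": label_counts,
                "pct_consistent": cat.percent(label_counts.get("consistent", 0), n_genes),
                "change_aggregates": aggregates,
            }

        report["categorize"] = _stage(report, "categorize", "CAT", _categorize)

    # ---- diffmeth ----------------------------------------------------
    if config.stages.get("diffmeth", True):
        def _diffmeth():
            normal_m = matrix_to_m(corrected_normal)
            tumors_m = {t: matrix_to_m(m) for t, m in tumor_gene.items()}
            results, flag_counts = dm.tumor_vs_normal_dm(
                tumors_m, normal_m, metadata, config.alpha, config.lfc_threshold
            )
            for t, res in results.items():
                dm.volcano_table(res).to_csv(out / f"dm_{t}_vs_normal.tsv", sep="\t", index=False)
            pair_results, pair_summary = dm.pairwise_tumor_dm(
                tumors_m, metadata, config.alpha, config.lfc_threshold
            )
            pair_summary.to_csv(out / "dm_pairwise_summary.tsv", sep="\t", index=False)
            return {
                "n_significant_per_type": {
                    t: int(res.table["significant"].sum()) for t, res in results.items()
                },
                "n_features_multi_type": int((flag_counts > 1).sum()),
                "n_pairwise_contrasts": len(pair_results),
                "n_significant_any_pair": int(pair_summary["significant_any_pair"].sum()),
            }

        report["diffmeth"] = _stage(report, "diffmeth", "DM", _diffmeth)

    # ---- aberrant ----------------------------------------------------
    states_by_type: dict[str, pd.DataFrame] = {}
    if config.stages.get("aberrant", True):
        def _aberrant():
            caller = ab.AberrationCaller(k=config.z_k).fit(corrected_normal)
            callable_genes = caller.reference_.index[caller.reference_["callable"]]
            summaries = {}
            for t, m in tumor_gene.items():
                states = caller.predict(m.subset_features(corrected_normal.feature_ids))
                states_by_type[t] = states
                props = ab.tumor_aberration_proportions(states, callable_genes)
                props.to_csv(out / f"aberration_proportions_{t}.tsv", sep="\t", index=False)
                summaries[t] = {
                    "mean_frac_hyper": float(props["frac_hyper"].mean()),
                    "mean_frac_hypo": float(props["frac_hypo"].mean()),
                }
            return summaries

        report["aberrant"] = _stage(report, "aberrant", "AB", _aberrant)

    # ---- events ------------------------------------------------------
    mutation_matrix = None
    if config.stages.get("events", True):
        def _events():
            genes = corrected_normal.feature_ids
            hyper, hypo = syn.aberration_truth_matrices(tumor_sim, genes)
            from .types import combine_event_matrices

            meth_events = combine_event_matrices(hyper, hypo)
            truth, mut_records, fus_records = syn.simulate_events(
                sim_cfg, meth_events, out_dir=out / "events"
            )
            # parse back through the readers to exercise the full path
            parsed_mut = []
            parsed_fus = []
            for sample in truth.samples:
                parsed_mut += pio.read_vcf_mutations(
                    out / "events" / "vcf" / f"{sample}.vcf", sample
                )
                parsed_fus += pio.read_bedpe_fusions(
                    out / "events" / "bedpe" / f"{sample}.bedpe", sample
                )
            damaging = ev.filter_damaging(parsed_mut)
            matrix = ev.build_mutation_matrix(damaging, parsed_fus, genes, truth.samples)
            pio.write_event_matrix_tsv(matrix, out / "mutation_matrix.tsv")
            summary = ev.event_frequency_summary(matrix, states_by_type)
            matches_truth = bool((matrix.hits == truth.hits).all().all())
            return matrix, {"round_trip_matches_truth": matches_truth, **summary}

        mutation_matrix, ev_summary = _stage(report, "events", "EV", _events)
        report["events"] = ev_summary

    # ---- mutex -------------------------------------------------------
    if config.stages.get("mutex", True) and mutation_matrix is not None and states_by_type:
        def _mutex():
            states = pd.concat(states_by_type.values(), axis=1)
            hyper, hypo = ab.states_to_event_matrices(states)
            from .types import combine_event_matrices

            meth = combine_event_matrices(hyper, hypo)
            genes = mx.filter_testable_genes(mutation_matrix, meth, config.min_events)
            if not genes:
                return {"n_testable_genes": 0}
            result = mx.permutation_test(
                mutation_matrix,
                meth,
                genes,
                n_permutations=config.n_permutations,
                seed=config.seed,
            )
            (out / "mutex_result.json").write_text(json.dumps(result.to_dict()))
            return {"n_testable_genes": len(genes), **result.to_dict()}

        report["mutex"] = _stage(report, "mutex", "MX", _mutex)

    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
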