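"""Gene-level somatic-mutation events from annotated variants and fusions.

A variant counts as damaging when it (1) has HIGH impact, or (2) has
MODERATE impact and is deleterious by SIFT, or damaging / probably_damaging
by PolyPhen-2.  A gene is 'mutated' in a tumor when it carries at least one
damaging SNV/indel or participates in an RNA fusion (fusions hit both
partner genes).
"""

from __future__ import annotations

import logging

import pandas as pd

from .types import EventMatrix, FusionRecord, MutationRecord

logger = logging.getLogger(__name__)

_DAMAGING_POLYPHEN = {"damaging", "probably_damaging"}


def is_damaging(record: MutationRecord) -> bool:
    if record.impact == "HIGH":
        return True
    if record.impact == "MODERATE":
        if record.sift == "deleterious":
            return True
        if record.polyphen in _DAMAGING_POLYPHEN:
            return True
    return False


def filter_damaging(records: list[MutationRecord]) -> list[MutationRecord]:
    """Keep HIGH-impact or damaging MODERATE-impact records (order preserved)."""
    return [r for r in records if is_damaging(r)]


def build_mutation_matrix(
    mutations: list[MutationRecord],
    fusions: list[FusionRecord],
    genes: list[str],
    samples: list[str],
) -> EventMatrix:
    """Boolean genes x samples matrix of mutation events.

    hits[g, s] is True iff sample s has at least one (already filtered)
    mutation in gene g or a fusion with g as either partner.  Records
    referring to genes or samples outside the supplied universes are
    ignored with a logged count.
    """
    hits = pd.DataFrame(False, index=pd.Index(genes, name="gene"), columns=list(samples))
    gene_set = set(genes)
    sample_set = set(samples)
    n_ignored = 0
    for rec in mutations:
        if rec.gene_symbol in gene_set and rec.sample_id in sample_set:
            hits.loc[rec.gene_symbol, rec.sample_id] = True
        else:
            n_ignored += 1
    for fus in fusions:
        if fus.sample_id not in sample_set:
            n_ignored += 1
            continue
        for gene in (fus.gene_a, fus.gene_b):
            if gene in gene_set:
                hits.loc[gene, fus.sample_id] = True
            else:
                n_ignored += 1
    if n_ignored:
        logger.info("%d event records outside the gene/sample universe ignored", n_ignored)
    return EventMatrix(hits, "mutation")


def event_frequency_summary(
    mutation_matrix: EventMatrix,
    aberrant_states_by_type: dict[str, pd.DataFrame],
) -> dict:
    """Cohort-level event frequencies.

    Per tumor type: fraction of tumors with at least one aberrantly
    methylated gene; overall: the gene x tumor mutation rate.
    """
    per_type = {}
    for tumor_type, states in aberrant_states_by_type.items():
        any_aberrant = ((states == "hyper") | (states == "hypo")).any(axis=0)
        per_type[tumor_type] = {
            "n_tumors": int(states.shape[1]),
            "frac_tumors_with_aberration": float(any_aberrant.mean()),
        }
    hits = mutation_matrix.hits.to_numpy()
    return {
        "per_tumor_type": per_type,
        "mutation_rate_gene_by_tumor": float(hits.mean()) if hits.size else 0.0,
    }
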