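"""Permutation test for mutation / aberrant-methylation mutual exclusivity.

The observed statistic is the number of (gene, tumor) pairs carrying both
a mutation and an aberrant-methylation event.  The null is built by
shuffling, independently for each gene, that gene's methylation-status
vector across tumors (preserving the gene's event count) while holding the
mutation matrix fixed; with 10,000 permutations the empirical p-value is

    p = (#{null <= observed} + 1) / (n_permutations + 1)

so small p indicates fewer co-occurrences than chance, i.e. mutual
exclusivity.  Only genes with at least ``min_events`` events of each type
are tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import CancerGeneEntry, EventMatrix

DEFAULT_MIN_EVENTS = 5
DEFAULT_N_PERMUTATIONS = 10_000


@dataclass
class MutexResult:
    observed_cooccurrences: int
    null_counts: np.ndarray = field(repr=False)
    null_mean: float = 0.0
    empirical_p: float = 1.0
    n_permutations: int = 0
    n_genes_tested: int = 0
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "observed_cooccurrences": int(self.observed_cooccurrences),
            "null_mean": float(self.null_mean),
            "empirical_p": float(self.empirical_p),
            "n_permutations": int(self.n_permutations),
            "n_genes_tested": int(self.n_genes_tested),
            "seed": int(self.seed),
        }


def filter_testable_genes(
    mutation: EventMatrix, methylation: EventMatrix, min_events: int = DEFAULT_MIN_EVENTS
) -> list[str]:
    """Genes with >= min_events events (inclusive) in BOTH matrices."""
    shared = mutation.hits.index.intersection(methylation.hits.index)
    mut_counts = mutation.hits.loc[shared].sum(axis=1)
    meth_counts = methylation.hits.loc[shared].sum(axis=1)
    keep = (mut_counts >= min_events) & (meth_counts >= min_events)
    return shared[keep].tolist()


def _aligned(mutation: EventMatrix, methylation: EventMatrix, genes: list[str]):
    samples = mutation.hits.columns.intersection(methylation.hits.columns)
    if len(samples) < 2:
        raise ValueError("need >= 2 shared tumors")
    mut = mutation.hits.loc[genes, samples].to_numpy(dtype=bool)
    meth = methylation.hits.loc[genes, samples].to_numpy(dtype=bool)
    return mut, meth, list(samples)


def count_cooccurrences(
    mutation: EventMatrix, methylation: EventMatrix, genes: list[str]
) -> int:
    """Number of (gene, tumor) pairs with both event types."""
    if not genes:
        return 0
    mut, meth, _ = _aligned(mutation, methylation, genes)
    return int((mut & meth).sum())


def permutation_test(
    mutation: EventMatrix,
    methylation: EventMatrix,
    genes: list[str],
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    chunk_size: int = 512,
) -> MutexResult:
    """Left-tail permutation test of mutation/methylation co-occurrence.

    Each permutation independently shuffles every gene's methylation-status
    vector across tumors; mutation status is held constant.  Small p =
    evidence of mutual exclusivity.
    """
    if not genes:
        raise ValueError("no testable genes")
    mut, meth, _ = _aligned(mutation, methylation, genes)
    n_genes, n_tumors = meth.shape
    observed = int((mut & meth).sum())
    row_counts = meth.sum(axis=1)

    rng = np.random.default_rng(seed)
    null_counts = np.empty(n_permutations, dtype=np.int64)
    done = 0
    checked = False
    while done < n_permutations:
        size = min(chunk_size, n_permutations - done)
        # A random permutation per (replicate, gene): argsort of iid uniforms
        keys = rng.random((size, n_genes, n_tumors))
        order = np.argsort(keys, axis=2)
        permuted = np.take_along_axis(
            np.broadcast_to(meth, (size, n_genes, n_tumors)), order, axis=2
        )
        if not checked:
            # shuffling must preserve each gene's event count
            assert (permuted[0].sum(axis=1) == row_counts).all()
            checked = True
        null_counts[done : done + size] = (permuted & mut).sum(axis=(1, 2))
        done += size

    p = (int((null_counts <= observed).sum()) + 1) / (n_permutations + 1)
    return MutexResult(
        observed_cooccurrences=observed,
        null_counts=null_counts,
        null_mean=float(null_counts.mean()),
        empirical_p=float(p),
        n_permutations=n_permutations,
        n_genes_tested=len(genes),
        seed=seed,
    )


def directional_permutation_test(
    mutation: EventMatrix,
    hypo: EventMatrix,
    hyper: EventMatrix,
    classes: list[CancerGeneEntry],
    min_events: int = DEFAULT_MIN_EVENTS,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
) -> dict[str, MutexResult]:
    """Class-directional exclusivity tests.

    Direction 1: oncogene mutation vs hypomethylation of the same gene.
    Direction 2: tumor-suppressor mutation vs hypermethylation.
    Each restricts the generic permutation machinery to the gene class.
    """
    roles = pd.Series({e.gene_symbol: e.role for e in classes})
    results: dict[str, MutexResult] = {}
    for name, meth_matrix, role in (
        ("oncogene_hypo", hypo, "oncogene"),
        ("tsg_hyper", hyper, "tsg"),
    ):
        class_genes = roles.index[roles == role]
        if len(class_genes) == 0:
            raise ValueError(f"no genes in class {role!r}")
        testable = filter_testable_genes(mutation, meth_matrix, min_events)
        genes = [g for g in testable if g in set(class_genes)]
        if not genes:
            raise ValueError(f"no testable genes in class {role!r}")
        results[name] = permutation_test(
            mutation, meth_matrix, genes, n_permutations=n_permutations, seed=seed
        )
    return results


def exact_single_gene_p(n_tumors: int, n_mut: int, n_meth: int, observed: int) -> float:
    """Exact left-tail p for one gene by hypergeometric enumeration.

    Shuffling one gene's methylation vector uniformly over the C(n, k)
    placements makes the overlap with the fixed mutation set
    hypergeometric; P(overlap <= observed) is the exact permutation null.
    Includes the same +1/(N+1)-style finite-sample convention in the limit
    N -> inf, i.e. plain CDF.
    """
    from scipy.stats import hypergeom

    return float(hypergeom.cdf(observed, n_tumors, n_mut, n_meth))
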