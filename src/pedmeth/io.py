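"""Readers and writers for every external format the pipeline touches.

Matrices, annotation and census tables are TSV (gzip accepted); somatic
variants are VCF 4.2 with a VEP-style CSQ consequence annotation; RNA
fusions are BEDPE with two gene-symbol columns.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .types import (
    BETA,
    CancerGeneEntry,
    FusionRecord,
    MethylationMatrix,
    MutationRecord,
    validate_metadata,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Methylation matrices and tabular inputs
# ---------------------------------------------------------------------------

def read_methylation_tsv(path, scale: str) -> MethylationMatrix:
    """Read a features x samples TSV (first column = feature ids).

    Rows containing any non-numeric cell are rejected with an error; beta
    values outside [0, 1] raise an error naming the offending cell.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no features")
    numeric = df.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    if numeric.isna().any().any():
        bad = numeric.isna().any(axis=1)
        raise ValueError(
            f"{path}: non-numeric or missing values in rows "
            f"{numeric.index[bad].tolist()[:5]}"
        )
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    return MethylationMatrix(numeric, scale)


def write_methylation_tsv(matrix: MethylationMatrix, path) -> None:
    """Write a matrix as TSV with full (repr) float precision.

    ``repr`` round-trips IEEE doubles exactly, so write-then-read is
    bit-exact.
    """
    df = matrix.values
    out = df.map(repr)
    out.to_csv(path, sep="\t", index_label="feature_id")


def read_sample_metadata_tsv(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    if "tumor_type" not in meta.columns:
        meta["tumor_type"] = None
    meta["tumor_type"] = meta["tumor_type"].where(meta["tumor_type"].notna(), None)
    return validate_metadata(meta)


def write_sample_metadata_tsv(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def read_probe_annotation(path) -> pd.DataFrame:
    """Read probe annotation: columns probe_id, gene_symbol, tss_distance_bp.

    A probe may map to several genes; (probe, gene) pairs must be unique.
    """
    ann = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "gene_symbol": str})
    required = {"probe_id", "gene_symbol", "tss_distance_bp"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"{path}: annotation missing columns {sorted(missing)}")
    if ann.duplicated(["probe_id", "gene_symbol"]).any():
        raise ValueError(f"{path}: duplicate (probe, gene) pairs")
    if (ann["tss_distance_bp"] < 0).any():
        raise ValueError(f"{path}: negative TSS distances")
    return ann


def write_probe_annotation(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t", index=False)


def read_cancer_gene_census(path) -> list[CancerGeneEntry]:
    """Read a cancer-gene-census TSV (gene, tier, role columns).

    Keeps tier-1 rows only.  A role string listing both oncogene and TSG is
    recorded as ``ambiguous`` (such genes are excluded from role-stratified
    analyses downstream).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower().strip(): c for c in df.columns}
    gene_col = cols.get("gene") or cols.get("gene_symbol")
    tier_col = cols.get("tier")
    role_col = cols.get("role") or cols.get("role in cancer")
    if tier_col is None:
        raise ValueError(f"{path}: missing tier column")
    if gene_col is None or role_col is None:
        raise ValueError(f"{path}: missing gene or role column")
    entries: list[CancerGeneEntry] = []
    for _, row in df.iterrows():
        try:
            tier = int(row[tier_col])
        except (TypeError, ValueError):
            continue
        if tier != 1:
            continue
        roles = {r.strip().lower() for r in str(row[role_col]).split(",") if r.strip()}
        has_onc = "oncogene" in roles
        has_tsg = "tsg" in roles or "tumour suppressor" in roles or "tumor suppressor" in roles
        if has_onc and has_tsg:
            role = "ambiguous"
        elif has_onc:
            role = "oncogene"
        elif has_tsg:
            role = "tsg"
        else:
            continue
        entries.append(CancerGeneEntry(str(row[gene_col]), role, tier))
    return entries


def census_to_frame(entries: list[CancerGeneEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.gene_symbol, e.role, e.tier) for e in entries],
        columns=["gene_symbol", "role", "tier"],
    )


# ---------------------------------------------------------------------------
# VCF (somatic mutations)
# ---------------------------------------------------------------------------

@dataclass
class CsqDialect:
    """Names of the consequence subfields inside the CSQ INFO annotation.

    The annotation layout varies by annotation tool; the defaults follow the
    common VEP layout.
    """

    csq_tag: str = "CSQ"
    gene_field: str = "SYMBOL"
    impact_field: str = "IMPACT"
    sift_field: str = "SIFT"
    polyphen_field: str = "PolyPhen"


def _map_sift(raw: str | None) -> str | None:
    if not raw:
        return None
    token = raw.split("(")[0].strip().lower()
    if token.startswith("deleterious"):
        return "deleterious"
    if token.startswith("tolerated"):
        return "tolerated"
    return "other"


def _map_polyphen(raw: str | None) -> str | None:
    if not raw:
        return None
    token = raw.split("(")[0].strip().lower()
    if token == "probably_damaging":
        return "probably_damaging"
    if token == "damaging":
        return "damaging"
    if token == "benign":
        return "benign"
    return "other"


def read_vcf_mutations(path, sample_id: str, dialect: CsqDialect | None = None) -> list[MutationRecord]:
    """Parse annotated somatic variants into per-(variant, gene) records.

    No consequence filtering happens here; see
    :func:`pedmeth.events.filter_damaging`.
    """
    dialect = dialect or CsqDialect()
    vcf = VCF(str(path))
    try:
        header = vcf.get_header_type(dialect.csq_tag)
    except KeyError as exc:
        raise ValueError(f"{path}: missing {dialect.csq_tag} INFO header") from exc
    desc = header.get("Description", "")
    if "Format:" not in desc:
        raise ValueError(f"{path}: {dialect.csq_tag} header lacks Format definition")
    fields = desc.split("Format:")[1].strip().strip('"').split("|")
    fields = [f.strip() for f in fields]
    idx = {name: i for i, name in enumerate(fields)}
    for required in (dialect.gene_field, dialect.impact_field):
        if required not in idx:
            raise ValueError(f"{path}: CSQ field {required!r} not in {fields}")
    records: list[MutationRecord] = []
    for variant in vcf:
        csq = variant.INFO.get(dialect.csq_tag)
        if not csq:
            continue
        for entry in csq.split(","):
            parts = entry.split("|")

            def get(field_name):
                i = idx.get(field_name)
                if i is None or i >= len(parts):
                    return None
                return parts[i] or None

            gene = get(dialect.gene_field)
            impact = get(dialect.impact_field)
            if not gene or not impact:
                continue
            impact = impact.upper()
            if impact not in ("HIGH", "MODERATE", "LOW", "MODIFIER"):
                logger.warning("unknown impact %r in %s; treating as MODIFIER", impact, path)
                impact = "MODIFIER"
            records.append(
                MutationRecord(
                    sample_id=sample_id,
                    gene_symbol=gene,
                    impact=impact,
                    sift=_map_sift(get(dialect.sift_field)),
                    polyphen=_map_polyphen(get(dialect.polyphen_field)),
                )
            )
    return records


VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=1,length=249250621>
##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations. Format: Allele|SYMBOL|IMPACT|SIFT|PolyPhen">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf_mutations(records: list[MutationRecord], path) -> None:
    """Write records as a minimal VCF 4.2 with a VEP-style CSQ field.

    One variant line per record (synthetic positions); exercises the same
    CSQ layout :func:`read_vcf_mutations` parses by default.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write(VCF_HEADER)
        for i, rec in enumerate(records, start=1):
            sift = rec.sift or ""
            poly = rec.polyphen or ""
            csq = f"A|{rec.gene_symbol}|{rec.impact}|{sift}|{poly}"
            fh.write(f"1\t{1000 + i}\t.\tC\tA\t50\tPASS\tCSQ={csq}\n")


# ---------------------------------------------------------------------------
# BEDPE (RNA fusions)
# ---------------------------------------------------------------------------

def read_bedpe_fusions(path, sample_id: str) -> list[FusionRecord]:
    """Read a BEDPE fusion table; the two gene symbols sit in columns 7-8.

    Self-fusions (gene_a == gene_b) are skipped with a warning.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    fusions: list[FusionRecord] = []
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                raise ValueError(f"{path}:{lineno}: expected >= 8 BEDPE columns")
            gene_a, gene_b = parts[6], parts[7]
            if gene_a == gene_b:
                logger.warning("%s:%d: self-fusion %s-%s skipped", path, lineno, gene_a, gene_b)
                continue
            fusions.append(FusionRecord(sample_id, gene_a, gene_b))
    return fusions


def write_bedpe_fusions(fusions: list[FusionRecord], path) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for i, fus in enumerate(fusions):
            start = 1000 + 10 * i
            fh.write(
                f"1\t{start}\t{start + 1}\t2\t{start + 5}\t{start + 6}\t"
                f"{fus.gene_a}\t{fus.gene_b}\n"
            )


# ---------------------------------------------------------------------------
# Event matrices / generic tables
# ---------------------------------------------------------------------------

def write_event_matrix_tsv(matrix, path) -> None:
    matrix.hits.astype(int).to_csv(path, sep="\t", index_label="gene")


def read_event_matrix_tsv(path, event_type: str):
    from .types import EventMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    return EventMatrix(df.astype(bool), event_type)
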