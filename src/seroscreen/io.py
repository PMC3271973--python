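"""Reading and writing the pipeline's table formats.

All tables are plain text: expression matrices and annotations as TSV,
cohort/surveillance/plate tables as CSV, exon models as BED.  Numeric
values round-trip at full precision (17 significant digits).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .expression import ExpressionMatrix, union_exon_length
from .surveillance import SurveillanceSet

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_annotation",
    "write_annotation",
    "read_serum_cohort",
    "write_serum_cohort",
    "read_surveillance",
    "write_surveillance",
    "read_plate",
    "read_counts",
    "read_exon_bed",
]

SERUM_REQUIRED = {"subject_id", "group", "igfbp4"}
SERUM_OPTIONAL = {"ca125", "age", "ethnicity"}


def _check_columns(df: pd.DataFrame, required: set[str], kind: str) -> None:
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{kind} table missing mandatory columns: {sorted(missing)}")


def read_expression_matrix(matrix_path, samples_path) -> ExpressionMatrix:
    """Matrix TSV (genes in rows, header = sample ids) + samples TSV
    (sample_id, group)."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0, float_precision="round_trip")
    samples = pd.read_csv(samples_path, sep="\t")
    _check_columns(samples, {"sample_id", "group"}, "samples")
    groups = samples.set_index("sample_id")["group"]
    groups.index = groups.index.astype(str).str.strip()
    values.columns = values.columns.astype(str).str.strip()
    return ExpressionMatrix(values=values, sample_groups=groups)


def write_expression_matrix(matrix: ExpressionMatrix, matrix_path, samples_path) -> None:
    matrix.values.to_csv(matrix_path, sep="\t", index_label="gene_id", float_format="%.17g")
    pd.DataFrame(
        {"sample_id": matrix.sample_ids, "group": [matrix.sample_groups[s] for s in matrix.sample_ids]}
    ).to_csv(samples_path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    """Annotation TSV: gene_id, length_bp, secreted (0/1)."""
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, {"gene_id", "length_bp", "secreted"}, "annotation")
    df = df.set_index("gene_id")
    df["secreted"] = df["secreted"].astype(bool)
    if (df["length_bp"] <= 0).any():
        raise ValueError("annotation: length_bp must be > 0")
    return df


def write_annotation(annotation: pd.DataFrame, path) -> None:
    out = annotation.copy()
    out["secreted"] = out["secreted"].astype(int)
    out.to_csv(path, sep="\t", index_label="gene_id")


def read_serum_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, SERUM_REQUIRED, "serum cohort")
    if df["subject_id"].duplicated().any():
        raise ValueError("serum cohort: duplicate subject ids")
    if (df["igfbp4"] < 0).any():
        raise ValueError("serum cohort: igfbp4 must be >= 0")
    return df


def write_serum_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False, float_format="%.17g")


def read_surveillance(path) -> SurveillanceSet:
    return SurveillanceSet(readings=pd.read_csv(path, float_precision="round_trip"))


def write_surveillance(sset: SurveillanceSet, path) -> None:
    sset.readings.to_csv(path, index=False, float_format="%.17g")


def read_plate(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, {"well_id", "role", "a450", "a620", "replicate_group"}, "plate")
    return df


def read_counts(path) -> dict[str, int]:
    """Counts TSV: gene_id, count."""
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, {"gene_id", "count"}, "counts")
    return dict(zip(df["gene_id"], df["count"].astype(int)))


def read_exon_bed(path) -> dict[str, int]:
    """BED exon models (chrom, start, end, gene_id) -> union-exon length per gene."""
    bed = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "gene_id"], comment="#"
    )
    lengths = {}
    for gene, exons in bed.groupby("gene_id", sort=False):
        lengths[gene] = union_exon_length(
            list(zip(exons["chrom"], exons["start"], exons["end"]))
        )
    return lengths


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
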