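"""Coverage (RPKM) quantification and per-gene expression summaries.

Expression is measured as mapped reads per kilobase of exon per million
mapped reads (RPKM), the length- and depth-normalized "coverage" unit that
the downstream biomarker screen filters and ranks.  Gene models are union
exon models: overlapping exons are merged before the kilobase
normalization so shared sequence is never counted twice.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "union_exon_length",
    "compute_rpkm",
    "summarize_gene",
    "expression_percentile",
    "qpcr_relative_expression",
]


@dataclass
class ExpressionMatrix:
    """Gene-by-sample coverage matrix with per-sample disease-group labels.

    Parameters
    ----------
    values
        DataFrame of non-negative coverage values, genes in rows
        (index = gene ids), samples in columns (columns = sample ids).
    sample_groups
        Series mapping every sample id to a group label (e.g. disease
        stage).  Must cover all columns of ``values``.
    """

    values: pd.DataFrame
    sample_groups: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids in expression matrix")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids in expression matrix")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("coverage values must be non-negative")
        self.sample_groups = pd.Series(self.sample_groups)
        missing = self.values.columns.difference(self.sample_groups.index)
        if len(missing):
            raise ValueError(f"samples without a group label: {list(missing)}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def groups(self) -> dict[str, list[str]]:
        """Map group label -> list of sample ids, in column order."""
        out: dict[str, list[str]] = {}
        for s in self.values.columns:
            out.setdefault(self.sample_groups[s], []).append(s)
        return out


def union_exon_length(intervals: Iterable[tuple[str, int, int]]) -> int:
    """Total length of the union of exon intervals, in bp.

    Intervals are ``(chrom, start, end)``, 0-based half-open.  Overlapping
    or nested intervals on the same chromosome are merged before summing.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        if end <= start:
            raise ValueError(f"degenerate interval {chrom}:{start}-{end}")
        by_chrom.setdefault(chrom, []).append((int(start), int(end)))
    total = 0
    for spans in by_chrom.values():
        spans.sort()
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
        total += cur_e - cur_s
    return total


def compute_rpkm(
    read_counts: Mapping[str, int],
    lengths_bp: Mapping[str, float],
    total_mapped_reads: int,
) -> pd.Series:
    """Reads per kilobase of union exon per million mapped reads.

    coverage(g) = count(g) / (length_kb(g) * total_mapped_reads / 1e6)

    Parameters
    ----------
    read_counts
        Mapped-read count per gene.
    lengths_bp
        Union-exon length per gene in bp; must cover every counted gene.
    total_mapped_reads
        Library size (all mapped reads), > 0.
    """
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be > 0")
    missing = [g for g in read_counts if g not in lengths_bp]
    if missing:
        raise KeyError(f"no exon-length annotation for gene(s): {missing[:5]}")
    genes = list(read_counts)
    counts = np.array([read_counts[g] for g in genes], dtype=float)
    if (counts < 0).any():
        raise ValueError("read counts must be non-negative")
    kb = np.array([lengths_bp[g] for g in genes], dtype=float) / 1e3
    if (kb <= 0).any():
        raise ValueError("exon lengths must be positive")
    per_million = total_mapped_reads / 1e6
    return pd.Series(counts / (kb * per_million), index=genes, name="rpkm")


def summarize_gene(matrix: ExpressionMatrix, gene: str) -> pd.DataFrame:
    """Per-group coverage summary (n, mean, sd, min, max) for one gene.

    The standard deviation uses the n-1 (sample) denominator and is
    reported as NaN for single-sample groups.
    """
    if gene not in matrix.values.index:
        raise KeyError(f"unknown gene: {gene}")
    rows = []
    for group, samples in matrix.groups().items():
        v = matrix.values.loc[gene, samples].to_numpy(dtype=float)
        rows.append(
            {
                "group": group,
                "n": len(v),
                "mean": v.mean(),
                "sd": v.std(ddof=1) if len(v) > 1 else np.nan,
                "min": v.min(),
                "max": v.max(),
            }
        )
    return pd.DataFrame(rows)


def expression_percentile(
    matrix: ExpressionMatrix, gene: str
) -> tuple[pd.Series, float]:
    """Per-sample top-fraction rank of a gene among expressed genes.

    A gene's top-fraction in a sample is the fraction of expressed genes
    (coverage > 0 in that sample) with strictly greater coverage, so the
    top-expressed gene scores 0.0 and ties are not pushed down.  Returns
    the per-sample fractions and their average; the gene must be expressed
    in at least one sample.
    """
    if gene not in matrix.values.index:
        raise KeyError(f"unknown gene: {gene}")
    vals = matrix.values
    g = vals.loc[gene]
    if not (g > 0).any():
        raise ValueError(f"gene {gene} is not expressed in any sample")
    fracs = {}
    for s in vals.columns:
        col = vals[s].to_numpy(dtype=float)
        expressed = col[col > 0]
        if len(expressed) == 0:
            continue
        fracs[s] = float((expressed > g[s]).sum()) / len(expressed)
    series = pd.Series(fracs, name="top_fraction")
    return series, float(series.mean())


def qpcr_relative_expression(
    ct_target: float, ct_housekeepers: Sequence[float]
) -> float:
    """Relative expression from qRT-PCR cycle numbers (2^-dCt).

    dCt = ct_target - mean(ct_housekeepers); normalization against the
    arithmetic mean of the housekeeping-gene Ct values (e.g. B2M, GAPDH).
    """
    if len(ct_housekeepers) == 0:
        raise ValueError("at least one housekeeping Ct is required")
    cts = np.asarray(ct_housekeepers, dtype=float)
    if not np.isfinite(cts).all() or not np.isfinite(ct_target):
        raise ValueError("Ct values must be finite")
    delta_ct = ct_target - cts.mean()
    return float(2.0 ** (-delta_ct))
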