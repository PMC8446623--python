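"""Copy-number validation from long-read depth.

In a haploid-represented assembly, a gene assembled once but present twice
in the genome (a collapsed paralog) attracts ~2× the median read depth,
while heterozygous alleles assembled separately (haplotype-specific copies)
attract ~0.5×.  Comparing each gene's mean depth to the genome-wide median
gene coverage therefore flags copies whose assembled copy number is
suspect.  Default thresholds (ratio ≥ 1.5× → collapsed, ≤ 0.6× →
haplotype-specific) sit between the 1× and 2×/0.5× expectations with a
noise margin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_MEDIAN_COVERAGE = 32.23  # genome equivalents
DEFAULT_HIGH_RATIO = 1.5
DEFAULT_LOW_RATIO = 0.6


@dataclass
class CoverageRecord:
    gene_id: str
    mean_depth: float
    ratio: float | None = None
    status: str | None = None  # normal | collapsed | haplotype_specific

    def __post_init__(self):
        if self.mean_depth < 0:
            raise ValueError(f"{self.gene_id}: negative depth")


def summarize_gene_coverage(
    depth: pd.DataFrame,
    intervals: pd.DataFrame | None = None,
) -> list[CoverageRecord]:
    """Mean depth per gene.

    ``depth`` is either a per-gene table (columns ``gene_id``,
    ``mean_depth``) or a per-base table (columns ``chromosome``, ``pos``
    0-based, ``depth``) in which case ``intervals`` (columns ``gene_id``,
    ``chromosome``, ``start``, ``end``) is required; bases absent from the
    table count as depth 0 with a warning.
    """
    if {"gene_id", "mean_depth"} <= set(depth.columns):
        return [
            CoverageRecord(str(r.gene_id), float(r.mean_depth))
            for r in depth.itertuples()
        ]
    if not {"chromosome", "pos", "depth"} <= set(depth.columns):
        raise ValueError(
            "depth table needs either (gene_id, mean_depth) or "
            "(chromosome, pos, depth) columns"
        )
    if intervals is None:
        raise ValueError("per-base depth requires gene intervals")
    records = []
    by_chrom = {c: g.set_index("pos")["depth"] for c, g in depth.groupby("chromosome")}
    for r in intervals.itertuples():
        if r.end <= r.start:
            raise ValueError(f"{r.gene_id}: empty interval")
        n = r.end - r.start
        series = by_chrom.get(r.chromosome)
        if series is None:
            logger.warning("%s: no depth data for %s; depth 0", r.gene_id,
                           r.chromosome)
            total, covered = 0.0, 0
        else:
            window = series.loc[(series.index >= r.start) & (series.index < r.end)]
            total, covered = float(window.sum()), len(window)
        if covered < n:
            logger.warning(
                "%s: %d of %d bases missing from depth table; counted as 0",
                r.gene_id, n - covered, n,
            )
        records.append(CoverageRecord(str(r.gene_id), total / n))
    return records


def classify_copy_status(
    records: Sequence[CoverageRecord],
    median_cov: float = DEFAULT_MEDIAN_COVERAGE,
    high_ratio: float = DEFAULT_HIGH_RATIO,
    low_ratio: float = DEFAULT_LOW_RATIO,
) -> tuple[list[CoverageRecord], dict]:
    """Set status per gene by depth ratio to the genome-wide median, and
    summarize how many copies deviate."""
    if median_cov <= 0:
        raise ValueError("median_cov must be > 0")
    if not 0 < low_ratio < 1 < high_ratio:
        raise ValueError("need 0 < low_ratio < 1 < high_ratio")
    out = []
    for rec in records:
        ratio = rec.mean_depth / median_cov
        if ratio >= high_ratio:
            status = "collapsed"
        elif ratio <= low_ratio:
            status = "haplotype_specific"
        else:
            status = "normal"
        out.append(CoverageRecord(rec.gene_id, rec.mean_depth, ratio, status))
    deviating = sum(r.status != "normal" for r in out)
    summary = {
        "n_genes": len(out),
        "n_deviating": deviating,
        "fraction_deviating": deviating / len(out) if out else 0.0,
        "n_collapsed": sum(r.status == "collapsed" for r in out),
        "n_haplotype_specific": sum(
            r.status == "haplotype_specific" for r in out
        ),
    }
    return out, summary


def records_to_table(records: Sequence[CoverageRecord], path) -> None:
    pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "mean_depth": [round(r.mean_depth, 3) for r in records],
            "ratio_to_median": [
                None if r.ratio is None else round(r.ratio, 3) for r in records
            ],
            "status": [r.status for r in records],
        }
    ).to_csv(path, sep="\t", index=False)
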