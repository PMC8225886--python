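"""Peak-to-gene assignment and per-class expression summaries.

Each classified peak is linked to the single gene whose TSS is closest to
the peak summit on the same chromosome, within a maximum distance window
(default 100 kb, a conventional regulatory-assignment span). Distances are
unsigned; gene strand is carried for reporting only. Linked genes are then
pooled per peak class and summarized (mean, median, quartiles of the log2
fold change), the numbers behind per-class line plots and box plots.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .classify import ClassifiedPeak
from .errors import ConfigurationError, SchemaError
from .interval_io import ExpressionRecord, GeneAnchor, Peak

__all__ = [
    "PeakGeneLink",
    "ClassExpressionSummary",
    "nearest_gene",
    "summarize_by_class",
    "export_plot_tables",
]

logger = logging.getLogger(__name__)

DEFAULT_MAX_DISTANCE = 100_000


@dataclass(frozen=True)
class PeakGeneLink:
    """A peak linked to its nearest gene within the distance window."""

    peak_name: str
    gene_id: str
    distance: int
    label: str


@dataclass(frozen=True)
class ClassExpressionSummary:
    """Distribution of linked-gene log2 fold changes for one peak class."""

    label: str
    condition: str
    n_genes: int
    mean: float
    median: float
    q25: float
    q75: float
    gene_ids: tuple[str, ...]
    values: tuple[float, ...]


def nearest_gene(peaks: Sequence[ClassifiedPeak | Peak],
                 peak_coords: Mapping[str, Peak] | None,
                 genes: Sequence[GeneAnchor],
                 max_distance: int = DEFAULT_MAX_DISTANCE,
                 ) -> list[PeakGeneLink]:
    """Link each peak to the gene minimizing |summit - TSS| on its chromosome.

    ``peaks`` may be classified records (with ``peak_coords`` supplying the
    genomic intervals by name) or bare :class:`Peak` objects. Ties in
    distance go to the lexicographically smaller gene_id. Peaks with no
    gene within ``max_distance`` (or none on their chromosome) are omitted
    and counted in the log.
    """
    if not genes:
        raise ConfigurationError("gene list is empty")
    if max_distance <= 0:
        raise ConfigurationError(
            f"max_distance must be > 0, got {max_distance}")

    by_chrom: dict[str, list[GeneAnchor]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda g: (g.tss, g.gene_id))
    tss_arrays = {c: [g.tss for g in gs] for c, gs in by_chrom.items()}

    links: list[PeakGeneLink] = []
    n_no_chrom = n_out_of_range = 0
    for item in peaks:
        if isinstance(item, Peak):
            peak, label = item, "unclassified"
        else:
            if peak_coords is None or item.peak_name not in peak_coords:
                raise ConfigurationError(
                    f"no coordinates supplied for peak {item.peak_name!r}")
            peak, label = peak_coords[item.peak_name], item.label
        gs = by_chrom.get(peak.chrom)
        if gs is None:
            n_no_chrom += 1
            continue
        tss = tss_arrays[peak.chrom]
        i = bisect_left(tss, peak.summit)
        candidates = [gs[j] for j in (i - 1, i) if 0 <= j < len(gs)]
        dmin = min(abs(peak.summit - g.tss) for g in candidates)
        if dmin > max_distance:
            n_out_of_range += 1
            continue
        # All genes at distance exactly dmin (several may share a TSS, or
        # sit symmetrically about the summit); tie-break on gene_id.
        tied: list[GeneAnchor] = []
        for t in {peak.summit - dmin, peak.summit + dmin}:
            lo = bisect_left(tss, t)
            while lo < len(gs) and gs[lo].tss == t:
                tied.append(gs[lo])
                lo += 1
        best = min(tied, key=lambda g: g.gene_id)
        links.append(PeakGeneLink(peak_name=peak.name, gene_id=best.gene_id,
                                  distance=dmin, label=label))
    logger.info(
        "nearest_gene: %d linked, %d beyond %d bp, %d on chromosomes "
        "without genes", len(links), n_out_of_range, max_distance, n_no_chrom)
    return links


def summarize_by_class(
    links: Sequence[PeakGeneLink],
    expression: Mapping[str, Sequence[ExpressionRecord]] | Sequence[ExpressionRecord],
    conditions: Sequence[str] | None = None,
) -> list[ClassExpressionSummary]:
    """Per-(class, condition) distribution of linked-gene log2 fold changes.

    ``expression`` is either a mapping of condition name to expression
    records or a bare record list (treated as a single condition named
    'default'). Genes linked by several peaks of the same class count
    once; genes without an expression record are skipped and logged.
    """
    if not isinstance(expression, Mapping):
        expression = {"default": expression}
    if conditions is None:
        conditions = sorted(expression)
    missing = [c for c in conditions if c not in expression]
    if missing:
        raise SchemaError(
            f"condition(s) absent from expression table: {', '.join(missing)}")

    genes_per_label: dict[str, set[str]] = {}
    for link in links:
        genes_per_label.setdefault(link.label, set()).add(link.gene_id)

    summaries: list[ClassExpressionSummary] = []
    for label in sorted(genes_per_label):
        for cond in conditions:
            table = {r.gene_id: r.log2fc for r in expression[cond]}
            gene_ids = sorted(genes_per_label[label])
            have = [g for g in gene_ids if g in table]
            skipped = len(gene_ids) - len(have)
            if skipped:
                logger.info("summarize_by_class: %d linked gene(s) lack "
                            "expression records (%s, %s)", skipped, label, cond)
            if not have:
                continue
            vals = np.array([table[g] for g in have], dtype=float)
            summaries.append(ClassExpressionSummary(
                label=label, condition=cond, n_genes=len(have),
                mean=float(np.mean(vals)), median=float(np.median(vals)),
                q25=float(np.percentile(vals, 25)),
                q75=float(np.percentile(vals, 75)),
                gene_ids=tuple(have), values=tuple(float(v) for v in vals)))
    return summaries


def export_plot_tables(summaries: Sequence[ClassExpressionSummary],
                       box_path: str | Path, line_path: str | Path) -> None:
    """Write the box-plot and line-plot tables behind per-class figures.

    The box table gives q25/median/q75 with whiskers at 1.5*IQR clamped
    to the most extreme data point inside the fence; the line table gives
    the per-class per-condition mean log2 fold change. Quartiles use
    linear interpolation between closest ranks.
    """
    if not summaries:
        raise ConfigurationError("no summaries to export")
    with Path(box_path).open("w") as fh:
        fh.write("label\tcondition\tn_genes\tq25\tmedian\tq75\t"
                 "whisker_low\twhisker_high\n")
        for s in summaries:
            vals = np.array(s.values)
            iqr = s.q75 - s.q25
            lo_fence, hi_fence = s.q25 - 1.5 * iqr, s.q75 + 1.5 * iqr
            w_lo = float(vals[vals >= lo_fence].min())
            w_hi = float(vals[vals <= hi_fence].max())
            fh.write(f"{s.label}\t{s.condition}\t{s.n_genes}\t{s.q25:.6f}\t"
                     f"{s.median:.6f}\t{s.q75:.6f}\t{w_lo:.6f}\t{w_hi:.6f}\n")
    with Path(line_path).open("w") as fh:
        fh.write("label\tcondition\tmean_log2fc\n")
        for s in summaries:
            fh.write(f"{s.label}\t{s.condition}\t{s.mean:.6f}\n")
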