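"""Synthetic two-condition ChIP-seq/RNA-seq datasets with planted truth.

Generates genomes-in-miniature: peaks with planted gained / depleted /
maintained subpopulations, negative-binomial read counts for two
conditions whose normalized means differ by the planted log ratio,
replicate peak sets with dropout and boundary jitter plus decoy peaks,
evenly spaced gene TSS annotations, and gene-expression fold changes
coupled to the class of the nearest peak. Every stage of the downstream
pipeline can therefore be scored against known truth.

All randomness flows from ``SyntheticConfig.seed`` through a single
``numpy`` generator, so identical configs give byte-identical outputs.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .errors import AlignmentError, ConfigurationError
from .interval_io import (ExpressionRecord, GeneAnchor, Peak, PeakCountRecord,
                          write_counts, write_expression, write_peaks,
                          write_tss)

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_peaks",
    "generate_counts",
    "generate_replicate_peaksets",
    "generate_tss",
    "generate_expression",
    "write_dataset",
]

MIN_PEAK_WIDTH = 50


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the generator; defaults are the standard study-scale
    simulation (2000 peaks, planted natural-log effect 2, mean count 500,
    NB dispersion 0.02)."""

    n_chromosomes: int = 3
    chrom_length: int = 5_000_000
    n_peaks: int = 2000
    peak_width_mean: float = 300.0
    peak_width_sd: float = 100.0
    fraction_gained: float = 0.15
    fraction_depleted: float = 0.15
    fraction_maintained: float = 0.60
    effect_size_logfc: float = 2.0
    nb_dispersion: float = 0.02
    mean_count: float = 500.0
    library_size_ratio: float = 1.0
    n_genes: int = 1000
    tss_spacing: int = 15_000
    expression_coupling: float = 1.0
    expression_noise_sd: float = 0.5
    replicate_jitter: float = 0.2
    boundary_noise_sd: float = 20.0
    decoy_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_gained", "fraction_depleted",
                     "fraction_maintained", "replicate_jitter",
                     "expression_coupling"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        total = (self.fraction_gained + self.fraction_depleted
                 + self.fraction_maintained)
        if total > 1.0 + 1e-12:
            raise ConfigurationError(
                f"class fractions sum to {total:.4f} > 1")
        for name in ("n_chromosomes", "chrom_length", "n_genes",
                     "tss_spacing"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(
                    f"{name} must be positive, got {getattr(self, name)}")
        if self.n_peaks < 0:
            raise ConfigurationError(f"n_peaks must be >= 0, got {self.n_peaks}")
        if self.peak_width_mean < MIN_PEAK_WIDTH:
            raise ConfigurationError(
                f"peak_width_mean must be >= {MIN_PEAK_WIDTH}, "
                f"got {self.peak_width_mean}")
        if self.chrom_length <= 4 * self.peak_width_mean:
            raise ConfigurationError(
                "chrom_length must exceed several peak widths")
        if self.mean_count <= 0 or self.nb_dispersion < 0:
            raise ConfigurationError(
                "mean_count must be > 0 and nb_dispersion >= 0")
        if self.library_size_ratio <= 0:
            raise ConfigurationError("library_size_ratio must be > 0")


@dataclass
class SyntheticTruth:
    """Ground truth for one generated dataset.

    true_class / true_logratio are aligned with the generated peak list;
    nearest_gene maps peak name to the gene minimizing summit-TSS distance
    (exhaustive-search definition); gene_response maps gene_id to its
    planted mean log2 fold change.
    """

    peak_names: list[str] = field(default_factory=list)
    true_class: dict[str, str] = field(default_factory=dict)
    true_logratio: dict[str, float] = field(default_factory=dict)
    nearest_gene: dict[str, str] = field(default_factory=dict)
    gene_response: dict[str, float] = field(default_factory=dict)


def _rng(config: SyntheticConfig, stream: str) -> np.random.Generator:
    # Independent substream per stage so adding a stage never perturbs
    # the draws of another; crc32 is stable across processes (unlike hash()).
    tag = zlib.crc32(stream.encode()) % (2**31)
    seed = np.random.SeedSequence([config.seed % (2**31), tag])
    return np.random.default_rng(seed)


def generate_peaks(config: SyntheticConfig) -> tuple[list[Peak], SyntheticTruth]:
    """Place peaks on the synthetic genome and plant their class labels.

    Widths are truncated normal (minimum 50 bp); the summit sits uniformly
    in the central half of the interval. Class labels are assigned by the
    configured fractions, the remainder 'unclassified' with intermediate
    true log ratios drawn uniformly in (-effect/2, +effect/2).
    """
    rng = _rng(config, "peaks")
    truth = SyntheticTruth()
    if config.n_peaks == 0:
        return [], truth

    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    records = []
    for i in range(config.n_peaks):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        width = max(MIN_PEAK_WIDTH,
                    int(round(rng.normal(config.peak_width_mean,
                                         config.peak_width_sd))))
        width = min(width, config.chrom_length - 1)
        start = int(rng.integers(0, config.chrom_length - width))
        end = start + width
        lo = start + width // 4
        hi = max(lo + 1, end - width // 4)
        summit = int(rng.integers(lo, hi))
        records.append((chrom, start, end, summit))
    records.sort(key=lambda r: (r[0], r[1], r[2]))

    n = config.n_peaks
    n_gain = int(round(config.fraction_gained * n))
    n_depl = int(round(config.fraction_depleted * n))
    n_main = int(round(config.fraction_maintained * n))
    n_main = min(n_main, n - n_gain - n_depl)
    labels = (["gained"] * n_gain + ["depleted"] * n_depl
              + ["maintained"] * n_main
              + ["unclassified"] * (n - n_gain - n_depl - n_main))
    rng.shuffle(labels)

    peaks: list[Peak] = []
    width_digits = len(str(max(n - 1, 1)))
    for i, ((chrom, start, end, summit), label) in enumerate(
            zip(records, labels)):
        name = f"peak_{i:0{width_digits}d}"
        peaks.append(Peak(chrom=chrom, start=start, end=end, name=name,
                          summit=summit))
        truth.peak_names.append(name)
        truth.true_class[name] = label
        if label == "gained":
            lr = config.effect_size_logfc
        elif label == "depleted":
            lr = -config.effect_size_logfc
        elif label == "maintained":
            lr = 0.0
        else:
            lr = float(rng.uniform(-config.effect_size_logfc / 2,
                                   config.effect_size_logfc / 2))
        truth.true_logratio[name] = lr
    return peaks, truth


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """Negative binomial by (mean, dispersion); Poisson in the limit."""
    if dispersion < 1e-8:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_counts(peaks: Sequence[Peak], truth: SyntheticTruth,
                    config: SyntheticConfig) -> list[PeakCountRecord]:
    """Draw two-condition NB counts whose normalized means encode the truth.

    For a peak with planted log ratio r the depth-normalized means are
    split symmetrically, mean_count * exp(-r/2) and mean_count * exp(+r/2),
    so E[t2/lib2] = exp(r) * E[t1/lib1]; raw means are rescaled by each
    library's size relative to the mean library size.
    """
    if len(peaks) != len(truth.peak_names):
        raise AlignmentError(
            f"peaks ({len(peaks)}) and truth ({len(truth.peak_names)}) "
            f"are not aligned")
    rng = _rng(config, "counts")
    lib1 = int(round(2e7))
    lib2 = int(round(lib1 * config.library_size_ratio))
    mean_lib = (lib1 + lib2) / 2.0
    lr = np.array([truth.true_logratio[p.name] for p in peaks])
    mu1 = config.mean_count * np.exp(-lr / 2) * (lib1 / mean_lib)
    mu2 = config.mean_count * np.exp(+lr / 2) * (lib2 / mean_lib)
    t1 = _nb_draw(rng, mu1, config.nb_dispersion)
    t2 = _nb_draw(rng, mu2, config.nb_dispersion)
    return [PeakCountRecord(peak_name=p.name, t1=int(a), t2=int(b),
                            lib1=lib1, lib2=lib2)
            for p, a, b in zip(peaks, t1, t2)]


def _jitter_peak(peak: Peak, rng: np.random.Generator,
                 config: SyntheticConfig) -> Peak:
    shift_s = int(round(rng.normal(0, config.boundary_noise_sd)))
    shift_e = int(round(rng.normal(0, config.boundary_noise_sd)))
    start = max(0, peak.start + shift_s)
    end = min(config.chrom_length, max(start + MIN_PEAK_WIDTH,
                                       peak.end + shift_e))
    start = min(start, end - MIN_PEAK_WIDTH) if end - MIN_PEAK_WIDTH > 0 else 0
    summit = min(max(peak.summit, start), end - 1)
    return Peak(chrom=peak.chrom, start=start, end=end, name=peak.name,
                summit=summit)


def generate_replicate_peaksets(peaks: Sequence[Peak],
                                config: SyntheticConfig,
                                ) -> tuple[list[Peak], list[Peak]]:
    """Two replicate peak sets: dropout, boundary jitter, and decoys.

    Each true peak enters each replicate independently with probability
    1 - replicate_jitter, with Gaussian boundary noise; each replicate
    additionally carries ceil(decoy_fraction * n_peaks) decoy peaks drawn
    at the same width distribution at random positions, present in that
    replicate only.
    """
    rng = _rng(config, "replicates")
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    reps: list[list[Peak]] = []
    n_decoys = math.ceil(config.decoy_fraction * len(peaks))
    for r in (1, 2):
        rep: list[Peak] = []
        for peak in peaks:
            if rng.random() < config.replicate_jitter:
                continue
            rep.append(_jitter_peak(peak, rng, config))
        for d in range(n_decoys):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            width = max(MIN_PEAK_WIDTH,
                        int(round(rng.normal(config.peak_width_mean,
                                             config.peak_width_sd))))
            width = min(width, config.chrom_length - 1)
            start = int(rng.integers(0, config.chrom_length - width))
            rep.append(Peak(chrom=chrom, start=start, end=start + width,
                            name=f"decoy_rep{r}_{d:04d}",
                            summit=start + width // 2))
        rep.sort(key=lambda p: (p.chrom, p.start, p.end))
        reps.append(rep)
    return reps[0], reps[1]


def generate_tss(peaks: Sequence[Peak], truth: SyntheticTruth,
                 config: SyntheticConfig) -> list[GeneAnchor]:
    """Evenly spaced gene TSS annotations; fills the truth nearest-gene map.

    Genes are laid out every ``tss_spacing`` bases across the chromosomes
    with alternating strand. The truth assignment is computed by exhaustive
    search over all peak-gene pairs (minimum |summit - tss| on the same
    chromosome, ties to the smaller gene_id).
    """
    genes: list[GeneAnchor] = []
    per_chrom = math.ceil(config.n_genes / config.n_chromosomes)
    gid = 0
    for c in range(config.n_chromosomes):
        for k in range(per_chrom):
            if gid >= config.n_genes:
                break
            tss = (k + 1) * config.tss_spacing
            if tss >= config.chrom_length:
                break
            genes.append(GeneAnchor(gene_id=f"gene_{gid:05d}",
                                    chrom=f"chr{c + 1}", tss=tss,
                                    strand="+" if gid % 2 == 0 else "-"))
            gid += 1
    # Exhaustive-search truth: the definitionally correct assignment.
    for peak in peaks:
        best: tuple[int, str] | None = None
        for g in genes:
            if g.chrom != peak.chrom:
                continue
            d = abs(peak.summit - g.tss)
            if best is None or (d, g.gene_id) < best:
                best = (d, g.gene_id)
        if best is not None:
            truth.nearest_gene[peak.name] = best[1]
    return genes


def generate_expression(truth: SyntheticTruth, config: SyntheticConfig,
                        ) -> list[ExpressionRecord]:
    """Gene log2 fold changes coupled to the class of the nearest peak.

    A gene nearest to a gained peak gets mean +coupling * effect/ln2 (the
    planted binding effect re-expressed in log2), a depleted-linked gene
    the negative, everything else 0; Gaussian noise with
    ``expression_noise_sd`` on top. When several peaks share a nearest
    gene, the strongest planted |log ratio| wins.
    """
    rng = _rng(config, "expression")
    gene_ids = sorted({g for g in truth.nearest_gene.values()})
    effect_l2 = config.effect_size_logfc / math.log(2)
    planted: dict[str, float] = {}
    for peak_name, gene_id in truth.nearest_gene.items():
        cls = truth.true_class.get(peak_name, "unclassified")
        if cls == "gained":
            resp = config.expression_coupling * effect_l2
        elif cls == "depleted":
            resp = -config.expression_coupling * effect_l2
        else:
            resp = 0.0
        if gene_id not in planted or abs(resp) > abs(planted[gene_id]):
            planted[gene_id] = resp
    records: list[ExpressionRecord] = []
    all_genes = [f"gene_{i:05d}" for i in range(config.n_genes)]
    for gene_id in all_genes:
        mean = planted.get(gene_id, 0.0)
        truth.gene_response[gene_id] = mean
        records.append(ExpressionRecord(
            gene_id=gene_id,
            log2fc=float(mean + rng.normal(0, config.expression_noise_sd))))
    return records


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("peak_name\ttrue_class\ttrue_logratio\tnearest_gene\n")
        for name in truth.peak_names:
            fh.write(f"{name}\t{truth.true_class[name]}\t"
                     f"{truth.true_logratio[name]:.6f}\t"
                     f"{truth.nearest_gene.get(name, 'NA')}\n")


def write_dataset(config: SyntheticConfig, outdir: str | Path) -> dict:
    """Generate and write a full synthetic dataset; returns file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    peaks, truth = generate_peaks(config)
    rep1, rep2 = generate_replicate_peaksets(peaks, config)
    counts = generate_counts(peaks, truth, config)
    genes = generate_tss(peaks, truth, config)
    expression = generate_expression(truth, config)

    paths = {
        "peaks_bed": outdir / "peaks.bed",
        "peaks_narrowpeak": outdir / "peaks.narrowPeak",
        "rep1": outdir / "rep1.narrowPeak",
        "rep2": outdir / "rep2.narrowPeak",
        "counts": outdir / "counts.tsv",
        "tss": outdir / "tss.tsv",
        "expression": outdir / "expression.tsv",
        "truth": outdir / "truth.tsv",
        "config": outdir / "config.yaml",
    }
    write_peaks(peaks, paths["peaks_bed"], format="bed")
    write_peaks(peaks, paths["peaks_narrowpeak"], format="narrowPeak")
    write_peaks(rep1, paths["rep1"], format="narrowPeak")
    write_peaks(rep2, paths["rep2"], format="narrowPeak")
    write_counts(counts, paths["counts"])
    write_tss(genes, paths["tss"])
    write_expression(expression, paths["expression"])
    write_truth(truth, paths["truth"])
    with paths["config"].open("w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
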