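"""Differential binding classification by MAD-scaled log count ratios.

Each peak gets a per-peak log ratio of depth-normalized read counts
between the comparison condition (t2) and the reference (t1),

    rc = log((n2 + pseudocount) / (n1 + pseudocount)),
    n_i = t_i * (mean library size / lib_i),

so that larger rc means stronger binding in the comparison condition.
The ratios are then expressed in robust units,

    zc = (rc - median(rc)) / MAD(rc),   MAD = median(|rc - median(rc)|),

with the MAD left unscaled (no 1.4826 Gaussian consistency factor), and
peaks are labeled by MAD-multiple thresholds: gained when zc >= k_change,
depleted when zc <= -k_change, maintained when |zc| <= k_maintained, and
unclassified in the gap between the two cutoffs (with the defaults
k_maintained = 0.5 < k_change = 1 the three named classes cannot tile the
line). Classification is invariant to rescaling all ratios by a positive
constant and class sizes are invariant to a common shift, so the log base
and any global depth imbalance cannot change labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import (ConfigurationError, DegenerateSpreadError,
                     UndefinedRatioError)
from .interval_io import PeakCountRecord

__all__ = [
    "ClassificationParams",
    "ClassifiedPeak",
    "compute_rc",
    "classify",
    "rank_peaks",
    "LABELS",
]

LABELS = ("gained", "depleted", "maintained", "unclassified")


@dataclass(frozen=True)
class ClassificationParams:
    """Thresholds and conventions for the ratio classifier.

    k_change: MAD multiples defining gained/depleted (1.0 for the standard
        three-class split; 4.0 for a stringent gained-only selection).
    k_maintained: MAD multiples bounding the maintained class (0.5).
    pseudocount: reads added to both normalized counts to keep the ratio
        finite at zero counts.
    normalize: 'library_size' scales counts to the mean library size
        before the ratio; 'none' uses raw counts.
    """

    k_change: float = 1.0
    k_maintained: float = 0.5
    pseudocount: float = 0.5
    normalize: str = "library_size"

    def __post_init__(self) -> None:
        if self.k_change <= 0:
            raise ConfigurationError(f"k_change must be > 0, got {self.k_change}")
        if self.k_maintained <= 0:
            raise ConfigurationError(
                f"k_maintained must be > 0, got {self.k_maintained}")
        if self.k_maintained >= self.k_change:
            raise ConfigurationError(
                f"k_maintained ({self.k_maintained}) must be < "
                f"k_change ({self.k_change})")
        if self.pseudocount < 0:
            raise ConfigurationError(
                f"pseudocount must be >= 0, got {self.pseudocount}")
        if self.normalize not in ("library_size", "none"):
            raise ConfigurationError(
                f"normalize must be 'library_size' or 'none', "
                f"got {self.normalize!r}")


@dataclass(frozen=True)
class ClassifiedPeak:
    """A peak name with its log ratio, robust score and class label."""

    peak_name: str
    rc: float
    zc: float = field(default=math.nan)
    label: str = "unclassified"


def compute_rc(counts: Sequence[PeakCountRecord],
               params: ClassificationParams = ClassificationParams(),
               ) -> list[ClassifiedPeak]:
    """Per-peak log ratio of normalized counts, comparison over reference.

    Returns one record per input count row with ``rc`` filled and ``zc`` /
    ``label`` left for :func:`classify`. With ``pseudocount=0``, any peak
    whose count is zero in either condition makes the ratio undefined and
    raises :class:`UndefinedRatioError` listing the offending peaks.
    """
    out: list[ClassifiedPeak] = []
    bad: list[str] = []
    for rec in counts:
        if params.normalize == "library_size":
            mean_lib = (rec.lib1 + rec.lib2) / 2.0
            n1 = rec.t1 * (mean_lib / rec.lib1)
            n2 = rec.t2 * (mean_lib / rec.lib2)
        else:
            n1, n2 = float(rec.t1), float(rec.t2)
        num, den = n2 + params.pseudocount, n1 + params.pseudocount
        if num <= 0 or den <= 0:
            bad.append(rec.peak_name)
            continue
        out.append(ClassifiedPeak(peak_name=rec.peak_name,
                                  rc=math.log(num / den)))
    if bad:
        raise UndefinedRatioError(
            "undefined log ratio (zero count, pseudocount=0) for peaks: "
            + ", ".join(bad))
    return out


def classify(rcs: Sequence[ClassifiedPeak],
             params: ClassificationParams = ClassificationParams(),
             ) -> list[ClassifiedPeak]:
    """Assign gained/depleted/maintained/unclassified labels by MAD multiples.

    Requires at least 3 peaks and a strictly positive MAD; a zero MAD
    (all ratios identical) raises :class:`DegenerateSpreadError` rather
    than emitting arbitrary labels.
    """
    if len(rcs) < 3:
        raise ConfigurationError(
            f"classification needs >= 3 peaks, got {len(rcs)}")
    values = np.array([r.rc for r in rcs], dtype=float)
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    if mad == 0.0:
        raise DegenerateSpreadError(
            "MAD of the log ratios is zero (all peaks have identical "
            "ratios); thresholds are undefined")
    out: list[ClassifiedPeak] = []
    for rec, rc in zip(rcs, values):
        zc = (rc - med) / mad
        if zc >= params.k_change:
            label = "gained"
        elif zc <= -params.k_change:
            label = "depleted"
        elif abs(zc) <= params.k_maintained:
            label = "maintained"
        else:
            label = "unclassified"
        out.append(replace(rec, zc=zc, label=label))
    return out


def rank_peaks(classified: Iterable[ClassifiedPeak], label: str,
               top_fraction: float = 1.0) -> list[ClassifiedPeak]:
    """Top fraction of one class, strongest |zc| first.

    Returns the first ceil(top_fraction * n) peaks of the requested label
    sorted by |zc| descending, ties broken by peak name so the selection
    is deterministic. An absent label yields an empty list.
    """
    if not (0.0 < top_fraction <= 1.0):
        raise ConfigurationError(
            f"top_fraction must be in (0, 1], got {top_fraction}")
    subset = [c for c in classified if c.label == label]
    subset.sort(key=lambda c: (-abs(c.zc), c.peak_name))
    if not subset:
        return []
    return subset[: math.ceil(top_fraction * len(subset))]
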