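"""Shared brute-force oracles and fixtures.

The oracles here are deliberately naive (quadratic scans, exhaustive
enumeration) and independent of the package's implementations; they define
correctness for the interval, digestion and modification operations.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from cistromad.interval_io import GeneAnchor, Peak


def brute_force_consensus(rep1, rep2, min_overlap=1):
    """O(n^2) all-pairs reference for the replicate-consensus rule."""
    kept = []
    for a in rep1:
        for b in rep2:
            if a.chrom == b.chrom and \
                    min(a.end, b.end) - max(a.start, b.start) >= min_overlap:
                kept.append(a)
                break
    return sorted(kept, key=lambda p: (p.chrom, p.start, p.end, p.name))


def brute_force_nearest(peak, genes, max_distance):
    """Exhaustive nearest-TSS search with the lexicographic tie rule."""
    best = None
    for g in genes:
        if g.chrom != peak.chrom:
            continue
        d = abs(peak.summit - g.tss)
        if d > max_distance:
            continue
        if best is None or (d, g.gene_id) < (best[0], best[1].gene_id):
            best = (d, g)
    return best


def brute_force_digest(sequence, max_missed, kp_rule=True):
    """All peptides as (start0, sequence, n_missed) via substring scan."""
    cuts = [0] + [i for i in range(1, len(sequence))
                  if sequence[i - 1] in "KR"
                  and not (kp_rule and sequence[i] == "P")] + [len(sequence)]
    out = set()
    for i, j in itertools.combinations(range(len(cuts)), 2):
        n_missed = j - i - 1
        if n_missed <= max_missed:
            out.add((cuts[i], sequence[cuts[i]:cuts[j]], n_missed))
    return out


# Published monoisotopic residue masses (5 decimals), kept independent of
# the package's mass source on purpose.
ORACLE_AA_MONO = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
ORACLE_WATER = 18.01056
ORACLE_DELTAS = {"carbamidomethyl": 57.02146, "oxidation": 15.99491,
                 "hydroxamic_acid": 15.01090}


def brute_force_modified_masses(sequence, max_variable):
    """All (frozen mod placement, mass) forms from the independent table.

    Fixed carbamidomethyl on every C; oxidation on M and hydroxamic acid on
    D/E variable, at most ``max_variable`` total, one mod per residue.
    """
    base = sum(ORACLE_AA_MONO[aa] for aa in sequence) + ORACLE_WATER
    base += sum(ORACLE_DELTAS["carbamidomethyl"]
                for aa in sequence if aa == "C")
    candidates = []
    for i, aa in enumerate(sequence):
        if aa == "M":
            candidates.append((i + 1, "oxidation"))
        if aa in "DE":
            candidates.append((i + 1, "hydroxamic_acid"))
    forms = {}
    for k in range(0, min(max_variable, len(candidates)) + 1):
        for combo in itertools.combinations(candidates, k):
            mass = base + sum(ORACLE_DELTAS[name] for _, name in combo)
            forms[frozenset(combo)] = mass
    return forms


def random_peaks(rng, n, chroms=("chr1", "chr2"), span=10_000, prefix="p"):
    peaks = []
    for i in range(n):
        start = int(rng.integers(0, span))
        width = int(rng.integers(1, 400))
        peaks.append(Peak(chrom=str(rng.choice(chroms)), start=start,
                          end=start + width, name=f"{prefix}{i}",
                          summit=start + width // 2))
    return peaks


def random_genes(rng, n, chroms=("chr1", "chr2"), span=10_000):
    return [GeneAnchor(gene_id=f"g{i:03d}", chrom=str(rng.choice(chroms)),
                       tss=int(rng.integers(0, span)),
                       strand="+" if i % 2 == 0 else "-")
            for i in range(n)]


def random_protein(rng, length):
    alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    return "".join(rng.choice(alphabet, size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
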