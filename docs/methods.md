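# Methods

## Scope

`cistromad` implements the computational core of a two-condition ChIP-seq
comparison as used to study transcription-factor cistrome remodeling (for
example, STAT1α binding under IFNγ with and without PARP inhibition), plus a
desk-scale implementation of hydroxylamine mass-shift mapping of
ADP-ribosylation sites. Read alignment, peak calling, differential
expression, motif discovery and MS/MS fragment scoring are upstream or
downstream of this package and out of scope; peaks, counts and fold changes
arrive as plain tables.

## Replicate-consensus peaks

The final peak set for a condition is the set of replicate-1 peaks that
overlap at least `min_overlap` bases (default 1 bp, the weakest faithful
reading of "overlapped in both replicates") with at least one replicate-2
peak. The output carries the replicate-1 intervals rather than merged
unions: this anchor-replicate convention preserves each peak's summit,
which the nearest-gene step needs. Overlap queries use per-chromosome
sorted lists with binary search (O(n log n)); the test suite defines
correctness by an all-pairs quadratic oracle.

## The log-ratio classifier

For each peak with reads t1 (reference) and t2 (comparison) and library
sizes lib1, lib2:

    n_i = t_i * (mean(lib1, lib2) / lib_i)          (depth normalization)
    rc  = ln((n2 + pseudocount) / (n1 + pseudocount))

Positive rc means enrichment in the comparison condition. The sign
convention is deliberate: the classifier is used to ask "where did binding
go up under co-treatment", so the comparison condition is the numerator.
Labels come from robust units:

    zc  = (rc - median(rc)) / MAD(rc),  MAD = median(|rc - median(rc)|)

with the MAD unscaled (no 1.4826 Gaussian consistency factor — the cutoffs
are defined in MAD multiples, not standard deviations) and centered at the
median rather than zero, so a global depth shift cannot corrupt labels.
Labels: gained if zc >= k_change, depleted if zc <= -k_change, maintained
if |zc| <= k_maintained, otherwise unclassified. Defaults k_change = 1,
k_maintained = 0.5; a stringent gained-only selection uses k_change = 4
together with `rank_peaks` (top fraction by |zc|, ceiling rule, name
tie-break). With k_maintained < k_change the three named classes cannot
tile the line, hence the explicit unclassified gap. The MAD is computed
jointly over all input peaks.

Parameter notes:

- pseudocount (default 0.5 reads) keeps rc finite at zero counts; with
  pseudocount 0 a zero count raises an error listing the offending peaks.
- Normalization to the mean library size is harmless to the labels (labels
  are invariant to any common shift of rc, which is what a depth imbalance
  induces) but keeps rc interpretable as a per-peak effect size.
- The natural log is fixed; classification is invariant to the base
  (scale equivariance of median and MAD).
- A zero MAD (all ratios identical) raises an error rather than emitting
  arbitrary labels.

At k_change = 1 the gained/depleted classes are deliberately liberal: in a
mixture where most peaks are unchanged, 1 MAD of the rc distribution is
close to the spread of the null peaks, so a tail of truly unchanged peaks
crosses the cutoff. Class purity therefore depends on the composition of
the peak set; the planted-truth simulations below quantify recovery of
truly changed peaks, not purity.

## Nearest-gene integration

Each classified peak is linked to the single gene whose TSS minimizes
|summit − TSS| on the same chromosome, within `max_distance` (default
100 kb, a conventional regulatory-assignment window; configurable).
Distance is unsigned and strand is ignored for assignment (kept for
reporting). Ties go to the lexicographically smaller gene identifier so
runs are reproducible. A single nearest gene is assigned per peak (not the
two flanking genes some regulatory-domain tools report). Genes linked by
several peaks of one class are counted once per class. Per-class summaries
report mean, median and quartiles of the linked genes' log2 fold changes;
quartiles use linear interpolation between closest ranks, and box-plot
whiskers sit at the most extreme data point within 1.5×IQR of the box.
For a '+'-strand gene the TSS is the annotated start; for '−' strand it is
the annotated end − 1.

## MS site mapping

Tryptic digestion cleaves C-terminal to K/R, suppressed before proline
(configurable off), with up to 3 missed cleavages by default. Modified
forms are enumerated with fixed carbamidomethyl-C (+57.02146 Da) and
variable oxidized-M (+15.99491 Da) and hydroxamic-acid D/E; the
hydroxamic-acid delta is computed from atomic monoisotopic masses as the
−COOH → −CONHOH replacement, i.e. +N +H = 15.0109 Da. At most 3 variable
modifications per peptide by default, with a hard cap of 10^4 forms per
peptide — exceeding it is an error, never silent truncation. Residue and
atomic masses come from pyteomics' reference tables; the test suite
cross-checks them against an independently embedded published table.

Matching declares a theoretical form observed when
|theoretical m/z − observed m/z| / theoretical m/z ≤ 10 ppm (denominator:
theoretical m/z; the convention is stated because the relative window is
asymmetric under denominator choice). Matched forms carrying the
hydroxamic-acid modification are aggregated into site calls with the best
ppm error. Precursor-only matching cannot localize a modification among
several candidate residues of the same peptide: positional isomers have
identical mass, so their positions are reported as one ambiguity group
(this mirrors the adjacent-acidic-residue ambiguity inherent to the
experimental method). Fragment-ion scoring, which could resolve such
groups, is out of scope.

## The synthetic-data generator

The generator emulates the data structures the pipeline consumes, with
known truth:

- **Peaks**: uniform placement over `n_chromosomes × chrom_length`
  (default 3 × 5 Mb), truncated-normal widths (mean 300 bp, sd 100 bp,
  minimum 50 bp), summit uniform in the central half of the interval.
- **Classes**: fractions 0.15 gained / 0.15 depleted / 0.60 maintained by
  default; the 10% remainder gets intermediate true log ratios uniform in
  (−effect/2, +effect/2), modeling peaks that belong to no clean class.
- **Counts**: negative binomial parameterized by mean and dispersion (the
  standard model for sequencing counts; dispersion below 1e-8 falls back
  to Poisson so the Poisson limit is exactly testable). A planted log
  ratio r splits the normalized means symmetrically,
  mean·exp(∓r/2), so E[t2/lib2] = e^r · E[t1/lib1]. Defaults: mean 500
  reads, dispersion 0.02, effect |r| = 2, equal library sizes of 2×10^7.
- **Replicates**: each true peak enters each replicate independently with
  probability 1 − replicate_jitter (default 0.2), with Gaussian boundary
  noise (sd 20 bp); each replicate adds ceil(0.25·n_peaks) decoy peaks
  present in that replicate only, giving the consensus step something to
  reject.
- **TSS annotations**: genes every `tss_spacing` bases (default 15 kb,
  which tiles the default genome) with alternating strand. The truth
  nearest-gene map is computed by exhaustive search over all peak–gene
  pairs — the definitional answer the fast implementation must reproduce.
- **Expression**: a gene nearest to a gained peak gets mean log2FC
  +coupling·effect/ln 2 (the binding effect re-expressed in log2),
  depleted-linked genes the negative, all others 0, plus Gaussian noise
  (sd 0.5, a typical RNA-seq fold-change spread). When peaks of different
  classes share a nearest gene the largest-|effect| class wins.

All randomness derives from a single integer seed, fanned out through
fixed per-stage substreams (crc32-tagged `SeedSequence`s), so adding a
stage never perturbs another stage's draws and identical configs give
byte-identical output files.

What the generator does *not* emulate: GC or mappability bias, correlated
replicate noise, peak-width/signal coupling, overdispersion heterogeneity,
multi-gene regulatory domains, and any calibration to a real dataset — the
NB parameters are plausible, not estimated from deposited data. Passing
recovery tests therefore demonstrates internal consistency of the method
under its own assumptions, not performance on real sequencing data.

## Simulation sizes and verification

The recovery simulations use 2000 peaks × 20 seeds for classifier
parameter recovery (planted effect 2, mean 500, dispersion 0.02: ≥90%
recovery of planted gained/depleted at k_change = 1, ≤5% of planted
changed peaks mislabeled maintained), 800 peaks × 3 seeds per coupling
level for the expression-integration monotonicity check, and 100
randomized fixtures for each brute-force oracle comparison (consensus,
nearest-gene, digestion, modification enumeration). These sizes give
stable Monte-Carlo estimates while keeping the full suite fast. The
planted-site MS fixture constrains each tryptic peptide to at most one
acidic residue so that precursor-only matching can localize sites exactly,
and regenerates until all theoretical forms are ≥25 ppm apart and decoys
≥50 ppm from every form — without mass isolation, exact recovery would be
ill-posed rather than hard.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open everywhere internally; narrowPeak
  summit offsets and BED midpoints are converted at the format boundary
  only. Duplicate peak names are an error, never silently merged.
- Ranking ties break on the peak name; nearest-gene ties on the gene id.
- Classification boundaries are inclusive (zc = k_change is gained).
- Manifest files record the version, seed, every resolved parameter,
  input digests and per-stage record counts; outputs are a pure function
  of (inputs, config, seed), and only the manifest timestamp differs
  between identical runs.
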