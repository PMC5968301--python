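# Methods

This note documents the models, parameter choices and numerical
conventions behind `spectyper`, and what the synthetic validation does
and does not demonstrate.

## Spectral preprocessing

Raw spectra are continuous m/z–intensity traces on the 2,000–20,000 m/z
biotyping range. Preprocessing touches only the intensity axis.

* **Smoothing** — Savitzky–Golay, window 11 points, polynomial order 3.
  A wider window (e.g. 21 points) produces measurable sidelobe artifacts
  around peaks a few Da wide, which peak picking then mistakes for minor
  peaks; 11 points suppresses noise while keeping peak shape and area.
* **Baseline** — SNIP-style iterative clipping: the baseline estimate
  starts as the spectrum and for window sizes m = 1..40 each point is
  clipped to `min(b[i], (b[i−m]+b[i+m])/2)`. Constant and linear trends
  are removed exactly; a Gaussian peak on a linear ramp keeps its area to
  within a few percent (tested at 5 %). Smoothing runs **before** the
  subtraction: clipping against unsmoothed noise tracks the lower noise
  envelope and leaves a positive residue several noise sigmas high.
* **Peak picking** — local maxima above `snr × σ` with σ the MAD-based
  noise estimate (scaled to Gaussian), default SNR 3, prominence half the
  height threshold, plus a relative-intensity floor of 1 % of the tallest
  candidate. The floor is needed because smoothed noise is correlated:
  its shallow maxima can clear a pure SNR bar in an otherwise sparse
  spectrum. All criteria are scale-invariant, so peak lists are invariant
  to global intensity rescaling. Peak lists are max-normalized to 1.0.
* **QC** — a spectrum is *flat-lined* if its relative dynamic range falls
  below 0.01 or fewer than 10 peaks are detectable; it is an *outlier*
  if its mean Pearson correlation to the rest of its replicate cohort, on
  1-Da binned profiles, falls below 0.5. The named eliminations are
  standard; the numeric cutoffs are this package's defaults and are
  configurable.

## MSP construction

Peaks pooled over all replicate peak lists are chained into clusters by
single linkage on the m/z axis with a 2.0 Da tolerance (a few hundred ppm
in the 3–12 kDa range). A cluster's frequency is the fraction of
replicates contributing at least one member; the filter is **strict**
(`> 0.75`), so a peak present in exactly 75 % of replicates is dropped.
Consensus m/z is the intensity-weighted mean of cluster members;
consensus intensity the plain mean, re-normalized. Entries require ≥ 10
contributing spectra and record full provenance (parameters, source
spectrum ids, the choice of "per contributing peak list" as the
frequency denominator). Construction is invariant to replicate order,
and raising the frequency floor can only remove peaks.

Libraries are versioned JSON (schema 1.0): diffable, portable, loadable
without binary dependencies. Duplicate entry names and truncated or
mismatched-schema files are rejected at load time.

## Log-score composite

The commercial score underlying the 0–3 scale is proprietary; this
package uses the widely described three-component composite

`score = max(0, log10(1000 · s_query · s_ref · s_int))`, capped at 3,

with greedy one-to-one nearest-m/z matching within 2.0 Da. `s_ref`
weights reference peaks by their MSP frequency by default, so missing an
always-present peak costs more than missing a borderline one. With fewer
than three matched pairs a Pearson correlation is meaningless: `s_int`
is 1.0 when the match covers both peak sets completely, otherwise a
neutral 0.5; with ≥ 3 pairs a constant intensity vector on both sides
counts as 1.0, on one side as 0.5. Every component is reported in the
`ScoredHit`, so scores are auditable. Self-identification of an entry's
own consensus peaks is exactly 3.0; disjoint peak sets score 0. Ranking
ties break lexicographically by entry name for determinism.

Only the scale, ceiling, thresholds and rubric semantics are contracted;
numerical agreement with vendor scores on real instrument data is not a
goal.

## Consensus rubric

A species-level identification requires the same top entry with log
score ≥ 2.2 in at least 3 replicates (of 4 by default); "consistently"
is read as *same top entry*, since identification reports carry a single
entry per isolate. Each replicate is represented by its best-scoring
acquisition. Everything short of species consensus is reported as
unidentified / potentially novel: a genus-level fallback (same genus at
a configurable threshold) is implemented but **disabled by default**,
because the operating rubric treats scores below 2.2 as unidentified
regardless of agreement — a uniform 2.03 consensus on one entry is an
unidentified isolate, not a genus-level call. Raising the threshold can
only move calls toward unidentified.

## Composite correlation index

Profiles are binned into 3 Da half-open bins on [3,000, 12,000) m/z and
total-normalized; replicates are averaged per strain (each strain needs
at least two spectra). The range is split into 10 contiguous interval
blocks; each interval contributes `max(0, r)` with `r` the Pearson
correlation of the two profiles inside it, and the CCI is the mean over
intervals. Intervals where both profiles are flat contribute 1.0
(identical shape), where exactly one is flat 0.0 — this fixes the 0/0
correlation case explicitly. The index is symmetric, bounded in [0, 1],
1 on the diagonal, and invariant to global intensity rescaling. Only
own-interval correlations enter the composition; cross-interval terms
are a known alternative and are not used.

The mass bounds are in Da (m/z); values above 0.9 are rendered red in
the heatmap export and annotated, matching the strong-correlation
convention.

## Dendrograms

Binned profiles are clustered agglomeratively with Euclidean distance
and average linkage (UPGMA, via scipy); entries are sorted by label
before clustering so the result is independent of input order. Output is
a newick string whose branch lengths are merge-height differences, plus
the merge table.

## 16S rRNA layer

* **Identity** — global alignment (match +1, mismatch −1, gap open −2,
  gap extend −0.5; Biopython's pairwise aligner); identity = matches /
  aligned columns, **excluding terminal-gap columns** (internal gaps
  count in the denominator as mismatch columns; both conventions are
  exposed). Near-identical ~1.4 kb sequences are insensitive to the
  scoring parameters. If the forward-orientation identity falls below
  60 %, the reverse complement is also aligned and the better value kept:
  a gapped global alignment of unrelated nucleotide sequences scores
  about 50 %, so a 50 % trigger can miss a reversed read, and taking the
  maximum over orientations means a correctly oriented pair is never
  down-scored.
* **Taxonomy** — best reference by identity (ties lexicographic);
  ≥ 98.7 % species, > 95 % genus, otherwise unclassified.
* **OTUs** — average-linkage clustering of `1 − identity/100` distances
  cut at 1 − similarity (default 99 %); the representative minimizes the
  summed distance to its cluster, ties lexicographic. (The upstream
  toolchain describes its clustering as "neighbor joining", which does
  not map onto a documented option of that tool; average linkage is the
  defensible reading and is what is implemented.)
* **Trees** — neighbor joining implemented here with deterministic
  tie-breaks by label order; negative branch lengths are clamped to zero
  with the deficit shifted to the sister branch so pairwise path lengths
  are preserved, and additive matrices are therefore reproduced exactly.
  An independent implementation (scikit-bio) serves as the test oracle.
  Maximum-likelihood inference and reference-alignment-based orientation
  are out of scope.

## Concordance analysis

Per isolate, the 16S call and the MALDI call are assigned to exactly one
category: `species_concordant` (names agree, score ≥ 2.2),
`maldi_confident_discordant` (names differ, score ≥ 2.2 against a
characterized type-strain entry), `potentially_novel` (MALDI consensus
unidentified — below 2.2 even with reference spectra of close relatives
present), `taxgroup_unresolved`, or `genus_only`. Taxonomic-group
membership is configuration, not hard-coded biology: a YAML registry
ships with the *B. pumilus* group (*pumilus*, *safensis*,
*australimaris*, *zhangzhouensis*) and the *B. cereus* group (*cereus*,
*thuringiensis*, *anthracis*). `taxgroup_unresolved` is modelled as a
*library-completeness condition* — the 16S call lands in a registered
group and type-strain spectra of competing members are missing — rather
than as an intrinsic property of the isolate. Species names are
normalized before comparison (abbreviated genus initials, strain
suffixes such as `_FO36b^T` stripped; a trailing `^T` marks a type
strain). A genus-level mismatch between the methods is a data
inconsistency and raises. Category counts always partition the record
set, and raising the score threshold is monotone toward
`potentially_novel`.

## Synthetic data

The generator reproduces the statistical structure the analysis relies
on, with no claim of instrument realism (no isotope envelopes, detector
saturation or physical TOF peak shapes):

* a species is a **latent fingerprint**: 30 peaks uniform over
  2,000–20,000 m/z with a minimum spacing of three peak FWHMs (so
  unequal neighbours stay resolvable), base intensities uniform on
  [0.1, 1], per-peak occurrence probabilities uniform on [0.85, 1];
* a replicate spectrum renders each present peak (Bernoulli occurrence)
  as a Gaussian of sigma 3 ± 0.3 Da at a jittered position (sd 1 Da)
  with log-normally perturbed height (CV 0.25), on a 1 Da grid, plus an
  exponential-decay baseline (amplitude 0.1) and additive Gaussian noise
  (sd 0.003). These defaults give single-replicate self-scores around
  2.5–2.9 against the species MSP — comfortably identifiable yet far
  from noise-free;
* strain variants perturb a few peaks (add / remove / intensity-shift)
  of the parent fingerprint;
* 16S sets derive from a random ancestor; a taxonomic group places its
  members on a single shared variable position, so four members of a
  1,400-base gene are pairwise ≥ 99.9 % identical while their spectral
  fingerprints are independent — the contrast the concordance layer must
  resolve. Other species diverge by 25–60 substitutions (library) or
  60–100 (out-of-library).

The default study scenario mirrors the acquisition design: 20 library
species (including one 4-member taxonomic group and one species with 7
strain variants), MSPs from 8 biological replicates × 3 acquisitions,
unknowns identified from 4 replicates, 5 additional species absent from
the library, and a CCI panel of the 7 strains plus 2 outgroup strains
(≥ 2 spectra each). Every generator is a pure function of (config,
seed); scenarios re-written with the same seed are byte-identical.

Because fingerprints of different species are drawn independently, the
synthetic scenario is an *easy* discrimination problem compared with
real congeneric bacteria, whose ribosomal-protein masses overlap
substantially. Passing the end-to-end recovery checks therefore
demonstrates the pipeline's correctness and calibration under its own
model assumptions, not field accuracy on real spectra.

## Problem sizes and determinism

The default end-to-end run (≈ 600 simulated spectra of 18,001 points,
20-entry library, 25 unknowns) completes in well under a minute on one
CPU; tests use the same scenario plus reduced variants. All randomness
flows through `numpy.random.default_rng` seeded from the configuration;
reports embed the resolved configuration and seed.

## Known limitations

* Vendor binary formats (fid/acqu, proprietary MSP exports) are not
  read; input is mzML or two-column CSV/TSV.
* The log-score composite matches the published scale semantics but is
  not numerically identical to any commercial implementation.
* The mzML writer/reader covers the profile-spectrum subset used here
  (32/64-bit float arrays, none/zlib compression), not the full schema.
* 16S identity uses pairwise global alignment rather than a curated
  reference multiple alignment; for heavily indel-divergent sequences
  the identity convention (terminal-gap exclusion) matters and is
  configurable.
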