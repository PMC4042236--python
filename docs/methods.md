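# Methods

## Problem and scope

`bindpat` compares exactly two ChIP-seq samples.  Peak calling is out of
scope: enriched regions arrive as BED from any external caller, and any
control-sample correction is assumed to have happened there.  The package's
job is (1) putting the two read libraries on a comparable scale, (2)
deciding which enriched regions are differentially enriched, and (3)
labelling those regions Only / Shift / Unchanged with respect to annotated
genes.

All internal coordinates are 0-based half-open (BED convention); wiggle
output converts to 1-based positions.  Duplicate reads are kept at the I/O
layer — deduplication is a normalization concern, and the NEB method models
per-position multiplicities explicitly.

## Normalization

**Linear.**  p = x/n with n the library size.  Correct when the only
difference between libraries is depth.

**NEB via Simple Good-Turing.**  A "read species" is a distinct
(chrom, start, end, strand) tuple; n_c counts species seen exactly c times
and S = Σ c·n_c is the depth.  The Turing estimate c\* = (c+1)·n_{c+1}/n_c
is used for low counts; for the sparse tail a least-squares line through
log Z_c vs log c (Z_c spreads n_c over the gap between neighboring observed
counts) supplies smoothed estimates, switching at the first count where the
raw and smoothed estimates differ by less than 1.65 standard deviations —
the Gale–Sampson rule.  Unseen mass is p₀ = n₁/S; each species observed c
times gets p_c\* = (1 − p₀)·c\*/S\*, S\* = Σ n_c·c\*, so total mass is 1.
Degenerate spectra are handled explicitly: a single observed count value
carries no frequency-of-frequency signal and is left unadjusted; n₁ = 0
gives p₀ = 0 with a logged warning.

Two application levels exist (`neb_level`):

* `read` (default): adjust per-position multiplicities, then sum adjusted
  proportions into bins;
* `bin`: count raw reads into bins first, then treat each bin as a species
  and SGT-adjust the pooled bin counts of each sample.

**Quantile.**  Applied at the bin level, pooled over all bins of all
enriched regions of both samples: sample B's values go through
F₁⁻¹(F₂(x)), with average ranks for ties in B and type-7 (linear
interpolation) quantiles of A — deterministic and rank-preserving.  Sample
A is always the reference; since the downstream test is rank-based the
choice of reference does not affect which regions are called.

**Reporting scale.**  Proportion-scale methods produce bin values of order
1/S (~1e-6), on which an absolute difference cutoff of 0.8 would be
meaningless.  The ratio r is scale-free; the difference d is therefore
reported (and thresholded) after multiplying by the geometric mean
√(S₁·S₂), restoring count-like magnitudes.  Count-scale methods (`none`,
`quantile`) use scale 1.

## Binning and counting

The primary parameter is the bin width in bp (default 30); each enriched
region gets ⌈length/width⌉ bins, the last bin covering the remainder, and
regions shorter than one bin become a single bin.  A fixed-bin-count mode
(`fixed_bin_count`) is available for users who prefer a constant number of
bins per region regardless of width.  Reads are assigned to the bin
containing their midpoint (boundary goes to the right bin, half-open
convention); midpoint assignment never double-counts a read across bins.
No fragment-size extension is applied — reads are used as placed.

## Differential testing

Bins of one region are positionally matched across samples, so the paired
signed-rank test is the default; the rank-sum test is available for users
who do not trust pairing.  Both one-sided p-values are always computed:
A-enrichment is judged by p(θ>0), B-enrichment by p(θ<0) — one-sided,
matching the two directional alternatives.

Exactness: the signed-rank null (conditional on the observed tie pattern,
zero differences dropped, average ranks) is enumerated by dynamic
programming over doubled ranks for up to 25 non-zero pairs; the rank-sum
null for pooled sizes up to 20 without ties.  Beyond those sizes a normal
approximation with tie correction and 0.5 continuity correction is used.
The thresholds keep per-region cost well under a millisecond while making
the default 30-bp configuration exact for regions up to ~750 bp.

DER calling combines three cutoffs (all must pass): p < α (default 0.05,
raw; Benjamini–Hochberg per source sample via `correction: bh`), ratio
r ≥ 1.2 (A) or ≤ 1/1.2 (B), and |d| ≥ 0.8 on the reporting scale.  Zero
denominators give r = +∞ (the ratio cutoff passes; all-zero regions have
p = 1 and are never DERs).

## Pattern classification

Gene association uses the edge gap (0 if overlapping) with a 100-kb limit;
isoform rows sharing a gene name count as one gene identity.  Partner
distance is center-to-center by default — robust to width differences
between broad and narrow regions — with an edge-gap mode (`partner_metric:
edge`).  When several partners share a gene, the nearest single partner
decides the label (ties: smaller start coordinate, then chromosome name),
so every gene-associated DER gets exactly one label and label counts
partition the DER set.  Intergenic DERs (no gene within 100 kb) are
excluded from the three-way classification and reported separately.

## Synthetic data generator

The generator emulates: two libraries of configurable depth, uniform
background reads, rectangular enriched spans emitting Poisson read counts
at a fold over background, 36-bp fixed-width tags, and a PCR-duplication
step that replaces a configurable fraction of reads with copies of other
reads (producing non-trivial count spectra, n₂, n₃ > 0).  Planted
configurations realize each pattern class with known truth: Only_A/Only_B
(one sample enriched), Unchanged (disjoint A- and B-spans ≤ 1 kb apart,
each enriched in its own sample), Shift (same, 1–100 kb apart), Null
(equal enrichment in both).  Each non-Null entry gets a designated gene a
few kb away; entries are spaced (default 250 kb) so genes never link
distinct entries.

What it does **not** emulate: peaked (non-rectangular) enrichment shapes,
GC/mappability bias, fragment-length effects, chromatin input background
structure, or biological replicates.  Passing the recovery tests therefore
shows the pipeline's logic is correct under its own model assumptions, not
that the default cutoffs are optimal for any particular real dataset.

Default study conditions used by the tests and `scripts/acceptance.py`:
pattern recovery uses 15 peaks per class (60 total), fold 8, width 300 bp,
2×10⁵ reads/sample over a ~15-Mb chromosome (background rate 0.002,
duplication 0.15); the null/imbalance scenario uses 2000 equally enriched
regions (fold 5, width 300 bp) with depths 3×10⁵ vs 1×10⁵.  The type-I
simulation draws 20 Poisson(5) bins per region for 2500 regions.  These
sizes make the full suite run in seconds while leaving Monte-Carlo error
comfortably inside the asserted bands.

## Known limitations and observed behavior

* **Read-level NEB under depth imbalance.**  With the generator's
  constant-rate PCR-duplication model, the count spectra of a deep and a
  shallow library differ in shape, and the resulting Good-Turing
  proportions are only partially depth-consistent: a 3× depth imbalance
  leaves a residual ~1.7× systematic ratio, so read-level NEB removes far
  fewer spurious calls than linear or quantile normalization in that
  scenario (it still never does worse than no normalization).  Under pure
  multinomial sampling without the duplication step, Good-Turing
  proportions are depth-consistent and NEB normalizes fully.  The
  bin-level variant (`neb_level: bin`) is insensitive to per-position
  duplication structure and compensates the imbalance almost completely.
* Exact p-values are discrete; at small bin counts the achievable
  significance levels are coarse (a 5-bin region cannot reach p < 1/32).
* No replicate-aware variance model: a consistent shift across bins of a
  single pair of libraries is treated as signal.
* The three patterns are gene-anchored by definition; regulatory regions
  far from any annotated gene are only ever reported as intergenic.
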