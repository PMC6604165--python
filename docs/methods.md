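# Methods

## Coordinate model

All coordinates are 0-based, half-open (BED convention); DANPOS-style
1-based tables are converted on read. The nucleosome map is the fixed
coordinate system: raw calls are sorted, overlapping neighbours are trimmed
at the midpoint of their overlap (a call fully contained in its predecessor
is dropped), and ids are assigned in (chromosome, start) order. After
trimming the map partitions the bases it covers, so midpoint containment
assigns every fragment to at most one nucleosome. Midpoint containment was
chosen over any-overlap because it is unambiguous for ~147-bp intervals
probed by ~150-bp fragments, and it makes per-nucleosome counts sum to at
most the library size.

## Candidate gate

A nucleosome enters testing when its ChIP count exceeds its depth-scaled
input count by at least `min_excess` reads (default 4, boundary
inclusive). The comparator is depth-scaled input rather than an absolute
count so the gate is meaningful at any sequencing depth; the scale factor
is N_chip / N_input on whole-library totals.

## Background rates

Two Poisson rates per nucleosome, both floored at the genome-wide rate
N_chip × width / effective_genome_size (default effective genome size
2.7 Gb, human):

* **λ_local** (ChIP): fragments in a `local_window_bp` window (default
  10 kb) centered on the dyad, truncated at chromosome ends with the
  denominator renormalized, excluding (a) the nucleosome's own interval
  and (b) every *likely-signal* nucleosome — one whose excess over scaled
  input already reaches `min_excess`. Exclusion (b) exists because marked
  nucleosomes cluster (promoter-proximal marks especially), and a local
  mean contaminated by neighbouring true peaks inflates λ_local by
  several fold, silently destroying the fold-change gate for genuine
  peaks. Masking candidate intervals from the background — the same
  signal-exclusion logic conventional peak callers apply when estimating
  backgrounds — restores an unbiased local rate. With no exclusion list
  the function reduces to the plain own-interval-excluded window mean,
  which is what the brute-force oracle tests check.
* **λ_input**: the same window estimate computed on the input library,
  multiplied by N_chip / N_input. The *raw* per-nucleosome input count is
  deliberately not used as a rate: it is a small integer (≈1–2 at
  realistic input depths) whose scaled value is far too noisy — a single
  extra input read triples the rate estimate and rejects a true peak on
  fold change. The window estimate has ~10× smaller relative error and
  the input library has no signal structure to blur.

## Shape filter

Crosslinked ChIP produces two recognizable within-nucleosome artifact
shapes: mass displaced toward one edge (*oblique*) and a dyad dip with
high edges (*U-shaped*). Both are scored on the ChIP fragment-midpoint
histogram across the nucleosome (default 21 equal bins; reduced to an odd
count for narrow intervals):

* asymmetry = (center of mass − central bin) / half-width ∈ [−1, 1];
  verdict *oblique* when |asymmetry| > `a_max` (default 0.5);
* dip ratio = mean(central third) / mean(flanking thirds); verdict
  *U-shaped* when < `d_min` (default 0.5); an empty flank yields an +∞
  sentinel (dyad-peaked, never filtered).

Profiles with fewer than `shape_min_reads` (default 10) fragments are not
evaluable and pass through — the statistical tests, not the shape filter,
judge sparse candidates. A profile tripping both gates is labelled
oblique (checked first); either label removes the peak. The metrics are
the simplest statistics that operationalize the two artifact classes; the
defaults place the planted artifacts of the synthetic study (offset
0.4 × width) several-fold past the thresholds while genuine dyad-centered
enrichment (jitter sd 20 bp) scores |asymmetry| ≈ 0.05 and dip ratio ≫ 1.
Input profiles are not used: per-nucleosome input coverage is too sparse
to carry shape information.

## Statistical tests

For each surviving candidate, two one-sided Poisson upper-tail p-values
P(X ≥ k) (survival function at k − 1, so P(X ≥ 0) = 1) against λ_local
and λ_input; p-values are floored at 1e−300 to stay in (0, 1]. Fold
changes use a pseudocount c = 0.5: fold = (k + c)/(λ + c). Benjamini–
Hochberg adjustment (hand-written step-up with cumulative-minimum
monotonization and a cap at 1; cross-checked against statsmodels in the
tests) is applied separately to the two p-value families across all
candidates of one mark; shape-removed candidates never enter the family.
A peak is accepted iff p ≤ 0.01, fold ≥ 4, FDR ≤ 0.01 in *both* tests;
the recorded reject reason is the first failed gate in the fixed order
(p_local, p_input, fold_local, fold_input, fdr_local, fdr_input).
Poisson (not negative-binomial) backgrounds are assumed throughout; real
replicates show overdispersion that this model does not capture.

## Multivalent categories and codes

Because all marks are called on one map, the multivalent join is exact on
nucleosome id. Categories are "+"-joined mark names in the conventional
order (H3K4me3, H3K9ac, H3K9me3, H3K27ac, H3K27me3), with the standard
aliases T (H3K4me3/H3K9ac/H3K27ac), D (H3K4me3/H3K9ac), A (H3K4me3).
Occupancy is summarized genome-wide (denominator: all map nucleosomes)
and near TSSs (denominator: nucleosomes whose dyads lie within ±2 kb of
any TSS — a within-window relative occupancy).

A gene's histone code is the category string of nucleosomes with dyads in
[tss − w, tss + w] (default w = 2 kb), read 5′→3′ on the gene strand;
unmarked map nucleosomes appear as an explicit `unmarked` symbol, and a
dyad exactly at the TSS counts as downstream (direction of transcription).
For clustering, the nearest 15 nucleosomes per side are one-hot encoded
over the category alphabet (outer slots padded `absent`), giving a
fixed-width matrix; k-means (default k = 13, fixed seed, 10 restarts)
labels are renumbered by descending cluster size. Per-gene counts of
chosen categories (default T, D, A) and of all marked slots ("codes") are
split upstream/downstream/total; expression association is the Spearman
correlation between cluster-median RPKM and cluster-median counts, with
undefined (constant-input) correlations reported as NaN. One-hot slots and
Spearman-on-medians are this package's featurization choices; nothing in
the category definitions depends on them.

## Synthetic data

The generator emulates the study conditions end to end: phased nucleosome
arrays (width 147 bp, spacing 200 bp, so 1 chromosome of 200 kb holds
exactly 1,000 nucleosomes), MNase coverage of 20 fragments/nucleosome with
truncated-normal midpoint jitter (sd 20 bp) around the dyad, a uniform
background Poisson process of 0.01 fragments/bp for ChIP and input, and at
each truly marked nucleosome Poisson(enrichment_fold × background_rate ×
width) extra dyad-centered fragments (default fold 20 → ≈29 signal
fragments over ≈1.5 background). Defaults: 100 randomly marked
nucleosomes with categories drawn from fixed weights, and 30 artifacts
(alternating oblique/U-shaped, displaced 0.4 × width, sd 8 bp) planted at
unmarked nucleosomes with the same fragment yield — so they pass the
candidate and enrichment gates and must be caught by shape alone.
Optionally two promoter archetypes are planted at gene TSSs ("active":
T at downstream slots +1..+3 and D at −1; "polycomb": H3K27me3 at
−2..+2), and expression follows RPKM = 10 × (planted downstream T count)
+ lognormal(−1, 0.25) noise. A fixed seed gives byte-identical files.

What the generator does *not* emulate — MNase sequence/GC bias, duplicate
reads, fragment-length variation, overdispersed backgrounds, chromatin
domains, overlapping/fuzzy nucleosomes — bounds what passing tests show:
they validate the algorithmic contracts and the statistical machinery
under the stated model, not performance on real libraries.

## Problem sizes and numerical choices

The default synthetic study (1,000 nucleosomes, ~6,000 ChIP fragments per
mark) keeps every check fast while leaving all rates at their realistic
per-nucleosome values; the statistical oracles run k ≤ 100 at four λ
values to double precision (agreement ≤ 1e−12). Degenerate inputs are
handled explicitly: empty maps and empty libraries are errors; an empty
candidate set yields empty (not failing) outputs; zero-background windows
fall back to the genome-wide floor; p-value underflow is floored; k-means
refuses k larger than the number of distinct code rows.

## Known limitations

* Poisson backgrounds understate biological variance; no replicate logic.
* The shape metrics are two scalar summaries; mixed or multi-modal
  artifact shapes outside the oblique/U taxonomy pass unfiltered.
* Broad domains spanning many nucleosomes are intentionally out of scope —
  every call is a single nucleosome.
* BED/BEDPE are the reference fragment dialects; coordinate-sorted
  alignment files should be reduced to fragments upstream.
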