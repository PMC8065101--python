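# Methods

This note records the models behind each pipeline stage, the parameter
choices that matter, what the synthetic cohort does and does not emulate,
and the numerical decisions a maintainer would want to know.

## Data model and coordinates

All genomic coordinates are 1-based inclusive (the VCF and Sequenza
convention); BED-style inputs must be converted at the boundary.
Chromosome names are normalised to a no-`chr`-prefix form. Expression
matrices hold log2(linear + 1) values, so a linear expression of 0 is
representable; the cytolytic index inverts this transform before taking
geometric means. VAFs read from VCF are computed as
alt_depth / (ref_depth + alt_depth) from the `AD` field; sites without `AD`
carry no VAF.

## Carrier classification and biallelic status

A PTV is any variant annotated stop_gained, frameshift, splice_donor or
splice_acceptor; pathogenicity curation is deliberately out of scope, so
PTV status is purely consequence-based. Carrier grouping gives germline
PTVs precedence over somatic ones, missense-only carriers of the three
study genes are set aside in an `excluded_missense` category, and PTVs in
two different study genes raise an error rather than being silently
resolved (the situation is biologically possible but rare enough that it
should be inspected by hand).

Locus LOH is called by two routes:

1. **ASCN route** — the allele-specific copy-number segment overlapping
   the variant's own position (never a gene lookup table) has minor copy
   number 0; a coverage gap yields `unknown`.
2. **VAF route** — tumour VAF exceeds germline VAF by strictly more than
   0.20. The threshold is an *absolute* allele-fraction difference
   (20 percentage points), not a ratio: a relative reading would call LOH
   on differences as small as 0.13 vs 0.10, which no reviewer would accept
   as evidence of allele loss.

Resolution order: a second somatic PTV in the gene is decisive; otherwise
agreement of the two routes decides; on disagreement an optional per-locus
shallow-WGS copy-number state (`loss` → biallelic) breaks the tie; any
remaining combination (unknowns, missing tie-break) defaults to
monoallelic with an `insufficient_evidence` flag, because downstream
summaries dichotomise and the conservative error is to under-call
biallelic loss. For somatic-only carriers there is no germline VAF, so the
ASCN call alone decides unless two distinct somatic PTVs already prove
biallelic inactivation. The full 3×3×2×(3+1) evidence table is enumerated
in the tests, along with the monotonicity property that adding LOH
evidence never demotes a biallelic call.

## Signature refitting

Catalogues follow the canonical 96-channel convention: six
pyrimidine-centred substitution classes × 16 flanking contexts, with
purine-reference SNVs reverse-complemented before binning. The refit is a
greedy forward algorithm: normalise the catalogue to a spectrum; per
iteration, golden-section-search the weight increment for every signature
(negative increments down to −w_k allowed, so weights can shrink), apply
the single best one, and stop when the SSE improvement falls below `tol`;
finally normalise weights to sum to 1 and zero those below 0.06 without
renormalising, so reported weights may sum to less than 1. Samples with
fewer than 15 SNVs are reported as `insufficient` with no exposures.

Numerical choices:

* `tol = 1e-4`. With the reconstruction normalised to a probability
  spectrum the total SSE is itself of order 1e-3; a coarser threshold
  stops after one or two signatures and systematically under-fits minor
  contributions, inflating whichever flat profile can absorb the leftover
  mass. At 1e-4 a five-signature mixture's mean weight is recovered to
  ±0.003 on near-noise-free catalogues, and the refit SSE matches a
  0.01-resolution brute-force grid search for K ≤ 3.
* No trinucleotide-content renormalisation of exome catalogues is applied
  by default; catalogues are refit as counted.
* The packaged 96×13 matrix is a **deterministic synthetic stand-in**, not
  the reference COSMIC matrix (which is not redistributable here). It
  carries the thirteen signature names commonly refit in breast cancer;
  "Signature 3" is built near-flat and "Signature 5" relatively
  featureless, mirroring the real profiles' character — including their
  mutual confusability: only the combined mass of the two flat profiles is
  well determined, exactly as with the real signatures. Any 96×K TSV can
  be substituted.

## Genomic scar scores

From ASCN segments per sample:

* **LOH score** — maximal runs of minor copy number 0 strictly longer than
  15 Mb that do not cover the whole chromosome (position 1 to the
  chromosome-map length).
* **TAI score** — allelic-imbalance runs (major ≠ minor) of at least 11 Mb
  that reach a chromosome end, do not cross the centromere interval, and
  do not span the whole chromosome.
* **LST score** — per arm, after dropping segments under 3 Mb and merging
  same-state neighbours, breakpoints whose flanking segments are each at
  least 10 Mb and separated by less than 3 Mb.
* **HRD-sum** = LOH + TAI + LST.

Open points in the published score definitions were resolved as follows:
LOH/TAI runs merge only strictly contiguous segments, while LST merging of
identical states tolerates sub-3 Mb gaps (the smoothing window); a segment
belongs to the arm containing its midpoint and segments straddling the
centromere are split at its boundaries; whole-*arm* LOH events are counted
(only whole-chromosome ones are excluded). Ploidy is not used — there is
no near-tetraploid LST adjustment — which is a documented limitation for
genome-doubled tumours.

## Immune and pathway indices

CYT is the geometric mean of the linear-scale GZMA and PRF1 levels, each
offset by 0.01 (the offset keeps zero-expression samples finite and
defines the floor value 0.01). The ssGSEA score ranks all genes within a
sample (average ranks on ties; gene name breaks walk-order ties for
determinism) and sums the difference between the weighted in-set
cumulative distribution (weights rank^0.25) and the uniform out-of-set
one; being rank-based it is invariant to monotone transforms of a sample's
values. The packaged immune gene set is a documented stand-in of ~30
canonical lymphocyte and cytotoxicity markers, replaceable via GMT — the
exact signature used by the cited infiltration tool is internal to it.
`geneset_mean_z` (mean across set genes of per-gene z-scores, sd with
ddof = 1, constant genes dropped with a warning) is an explicit stand-in
for pathway-level summaries whose published derivation is unstated.

## Group statistics

All tests are two-sided. Mann–Whitney U uses the exact null distribution
(dynamic-programming enumeration, cached per size pair) when
n_x·n_y ≤ 400 and the data are tie-free, else a tie-corrected,
continuity-corrected normal approximation; the implementation is
cross-checked against both full labelling enumeration (all partitions up
to n = 10) and scipy. Chi-square is Pearson's statistic without continuity
correction. The bootstrap size-correction draws 30 controls *without
replacement* (sampling with replacement would duplicate patients) per
iteration, 1000 iterations, and reports the median per-iteration p; the
even-count median uses standard interpolation. Both the raw and corrected
p are reported side by side, since published figures do not always state
which was used. No multiple-testing adjustment is applied across metrics.
Calibration is verified empirically: with carriers drawn from the pool's
own distribution the corrected-p rejection rate at 0.05 stays within
binomial error of 0.05, and complete separation yields the minimal exact
two-sided p for the (9, 30) size pair.

## Synthetic cohort

The generator emulates the study design the defaults encode: carrier
groups of 9 PALB2 / 16 BRCA1 / 14 BRCA2 tumours (6/10/11 germline), with
biallelic subsets 3/7/7 — the PALB2 subset split as two LOH tumours and
one somatic second hit — against 500 non-carriers. Per-stratum somatic SNV
counts are negative binomial (dispersion 1.0) with rate parameters solved
numerically so the distribution *median* matches the targets
(125/146/214 biallelic and 74/42/68 monoallelic vs 46 non-carrier);
signature-3 weights are Beta-distributed around stratum means
(0.489/0.444/0.395 vs 0.082, concentration 30), with the remaining mass
split over four peaked signatures; scar event counts are Poisson with
medians targeting LOH 14/19/13, TAI 27/26/19, LST 22/26/21 in biallelic
strata and 6/9/7 otherwise (monoallelic carriers share the non-carrier
background rates, which is what the emulated study observed). Germline-het
VAFs are Normal(0.5, 0.02) and shift to 0.5 + purity/2 under locus LOH
(default purity 0.7, giving a ΔVAF of 0.35, comfortably above the 0.20
rule). Expression is a log-normal baseline with immune genes shifted up by
1.2 log2 units in BRCA1 tumours and the carrier's own gene shifted down
1.0 in biallelic tumours.

Scar events are implanted with geometric isolation: interior minor-copy-0
segments (16–28 Mb) for LOH, telomeric imbalanced segments for TAI, and
adjacent balanced-state pairs for LST, every event separated from its
neighbours and from the (1,1) baseline by 3.5 Mb coverage gaps — wider
than the LST smoothing window — so each implanted event contributes to
exactly one score and the ground-truth counts (recorded from construction
arithmetic, not by calling the scorer) are exactly recoverable. Carrier
loci without implanted LOH are covered by a pinned copy-neutral segment so
random events cannot create spurious locus LOH. The genome is a reduced
synthetic one: 22 autosomes with realistic lengths and centromeres, no sex
chromosomes.

What the generator does **not** emulate — and hence what passing recovery
tests do not show about real data: subclonality and purity variation
within a sample, segmentation noise and miscalled copy numbers, germline
contamination of somatic calls, driver-gene mutations outside the three
study genes, correlated event lengths, and real expression covariance
structure. Recovery results on this cohort demonstrate correctness of the
algorithms under their stated assumptions, not robustness to real-world
noise.

## Problem sizes

The default test suite exercises small cohorts (20–30 non-carriers;
80 for the byte-determinism check) and the acceptance script runs the full
539-sample default cohort; both complete in well under a minute of compute
for everything except signature refitting, which dominates at roughly
25 ms per sample.

## Known limitations

* PTV status is consequence-annotation-based; no transcript-set or
  pathogenicity curation.
* No ploidy adjustment in LST; scar scores assume diploid background.
* The packaged signature matrix and immune set are synthetic stand-ins;
  analyses of real cohorts must substitute the reference COSMIC matrix and
  a validated immune signature.
* Bootstrap p values depend on the seed through control resampling;
  reported results should always carry the seed, as the CLI logs do.
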