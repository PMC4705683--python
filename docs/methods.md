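# Methods

## Model references

A model reference is the concatenation of two cytogenetic band sequences
from different chromosomes, representing the product of a recombination.
Band coordinates are stored 1-based inclusive; UCSC cytoBand input (0-based
half-open) is converted on load, and sub-bands are collapsed to their major
band by default since the method operates at major-band resolution. The
junction offset equals the first band's length — joining 16q13
(56,700,001–57,400,000) to 8q24 puts it at exactly 700 kb. The default
orientation joins both bands forward-strand (A end → B start); the three
other strand combinations are available as options. N-heavy references
(e.g. centromeric bands) are flagged in the manifest but scored like any
other region.

The packaged band table (`data/grch37_major_bands.synthetic.tsv`) is a
synthetic ideogram: real hg19 chromosome lengths and the standard 320
major-band names, with proportional band coordinates except 16q13 and 8q24,
which sit at their published positions. It is a stand-in for the UCSC
cytoBand table, adequate for band arithmetic and the worked example, but
its interior band boundaries are approximations and should not be used for
annotation of real data.

## Candidate reads and filters

Only pairs the primary aligner could not place consistently are realigned:
mates on different chromosomes ("discordant" in the strict
cross-chromosome sense; wrong-orientation same-chromosome pairs are not
extracted) and pairs with one or both mates unmapped. Library statistics
(insert mean/s.d., mean summed Phred) come from a seeded reservoir sample
of up to 10^6 properly-paired primary reads. Model alignments are kept
only if the read's summed Phred strictly exceeds the library mean and
strictly more than 50% of its bases are CIGAR-aligned (M/=/X); both
thresholds are strict, so a 50M50S read is discarded. Insert size is the
absolute SAM template length.

## Realignment

The built-in aligner is deliberately minimal because downstream scoring
consumes only positions, CIGAR match fractions, map quality and template
lengths: exact 15-mer seeding over an indexed reference, then ungapped
verification of each candidate diagonal. The aligned (M) segment of a
diagonal is the maximum-scoring contiguous run under +1/match, −2/mismatch
(ties: smallest start, then longest), with tails soft-clipped; a hit
requires an exact seed on the diagonal, an M run of at least the seed
length, and a mismatch rate ≤ 5% within the M run. All hits are reported;
map quality is 60 for a unique hit and 0 otherwise, sufficient for the
mapq < 30 noise characterization. External SAM/BAM against the same
references can replace this stage.

## Region scoring

Log insert sizes of both-mates-mapped filtered pairs are fitted with a
two-component Gaussian mixture (unequal variances, exactly two components
— the observed distributions are consistently bimodal, so no model
selection over component counts). EM is initialized by splitting at the
median log insert, making the fit deterministic for given data; tolerance
1e-6, at most 500 iterations, variances floored at 1e-6 (a degenerate
all-equal input is flagged and still scored). Components are ordered by
mean; EMr per component is the mean responsibility, so EMr₁ + EMr₂ = 1.
Natural logs are used; the base cannot affect responsibilities.

Signal pairs are those assigned to the second component whose insert
deviates more than 4 s.d. from the library mean; pairs within 2 s.d. with
mapq < 30 are confirmed noise (the mapq rule is descriptive, not a
pre-filter). If most second-component pairs violate the 4 s.d. rule the
fit is flagged inconsistent. Signal pairs qualify for clustering only if
one mate starts at or before the junction offset and the other after it;
they are binned by leftmost mate start into sliding windows (default
window = 2 × mean insert, step = window/2 — unstated upstream, chosen to
make a breakpoint's spanning pairs, which spread over roughly one insert
length, fall into one window). Tx = EMr₂ + W_max/N_b, with the ratio
defined as 0 when N_b = 0.

**Noise cutoff.** Regions are discarded when the noise component doubly
dominates the signal component: EMr₁ > 2·EMr₂, i.e. EMr₂ ≤ 1/3
(configurable). An even-split cutoff (EMr₂ ≤ 1/2) is too aggressive as a
default for a structural reason: pairs whose one read straddles the true
breakpoint realign to the model with ordinary insert sizes — the clipped
read and its mate both sit at the breakpoint locus — so genuine breakpoint
support is absorbed by the first component. Since the straddle window
(≈ 2 × read length) and the spanning window (≈ insert − 2 × read length)
have comparable widths at typical short-read geometries, a true region's
EMr₂ legitimately hovers near 0.5. The double-domination rule still
discards regions whose second distribution is poorly defined relative to
the noise mode, which is what the cutoff exists to do.

## Calling

Passing regions are clustered on Tx by one-dimensional Lloyd k-means with
k = 4 centroids seeded at Q1, Q2, Q3 and the maximum of the scores.
Everything is deterministic: assignment ties go to the lower-index
centroid, empty clusters keep their centroid, and centroids are kept
sorted. The cluster with the highest mean Tx is the call set. With fewer
than two passing regions, or all scores identical, nothing is called; with
fewer than k distinct scores, k falls back to the number of distinct
values. On labelled simulations the false positive rate is decoys in the
top cluster over all decoys (unscorable and cutoff-failed decoys count in
the denominator, never as calls). Germline subtraction removes tumor
top-cluster regions whose unordered band pair also appears in the germline
top cluster — matching at band-pair granularity, the resolution the method
actually has.

## Reference selection (differential evolution)

Individual fitness is the product of the two bands' smoothed breakpoint
probabilities (counts plus pseudocount 1, so unreported bands stay
reachable; bands are treated as independent marginals, and pooled counts
are assumed rather than per-cancer-type tables). Diversity is the Shannon
entropy of band usage across the population, rescaled over its attainable
range: every pair contributes two distinct bands, so the entropy of a
population lies in [ln 2, ln n_bands], and the score maps that interval to
[0, 1] — a population of identical pairs scores exactly 0, uniform usage 1.
The population objective is mean fitness + λ·diversity (λ = 1). Per
generation each individual is crossed with probability CR (exchange one
partner with a random other individual) and mutated with probability F per
slot (frequency-weighted replacement); a candidate replaces its parent only
if the objective does not decrease, and the loop stops at the diversity
target or the generation cap. Defaults (population 278, CR 0.5, F 0.1,
50 generations, target 0.8) are configurable; no upstream values exist for
them. Intra-chromosomal pairs are excluded, matching the scope of the
reference builder. Duplicates may arise during evolution and are
deduplicated on output.

## Synthetic data generator

The generator emulates the study conditions end-to-end:

* **Genome**: uniform-composition chromosomes (default two of 1 Mb) with an
  exact band partition (default 5 bands/chromosome, named by the arm/band
  grammar).
* **Variant**: one reciprocal inter-chromosomal translocation; junction
  positions are drawn strictly inside bands with a 10 kb margin (junctions
  on band boundaries are rejected), and both derivative chromosomes carry
  the junction. A variant fraction parameter mixes variant and reference
  fragments to emulate tumor heterogeneity (default 1.0, a clonal event).
* **Reads**: 100 bp mates, fragment length N(400, 50) truncated at the read
  length, 30× coverage, fragments uniform along chromosomes. Per-base
  qualities are drawn around the Phred value matching the configured error
  rate (default 0.5%, with s.d. 3 jitter; an optional position-decay model
  exists), and substitution errors are then drawn per base from those
  qualities, so quality strings and the error process agree. No indels —
  downstream scoring consumes positions, match fractions and insert sizes,
  not indel realism.
* **Background noise**: three candidate-read classes emulate what real
  discordant/unmapped sets contain — cross-chromosome chimeric pairs
  (0.5% of pairs; mapping-error background that populates decoy regions
  with large-insert alignments), same-locus small-insert junk (0.08%;
  the small-insert noise mode), and random unalignable garbage (0.05%).
* **Aligned-sample emulation**: the previously-aligned BAM the pipeline
  expects is written directly from the truth table (a "perfect" primary
  aligner): reads inside conserved segments are mapped at lifted reference
  coordinates, junction-spanning pairs become cross-chromosome discordant
  records, junction-straddling reads become unmapped records, noise classes
  are emitted as mismapped/unmapped. Concordant pairs — used only for
  library statistics — are emitted as a seeded 20,000-pair subsample. This
  replaces an external aligner run, which at these scales would add only
  runtime, not information; it also means primary-alignment artifacts
  (soft-clip conventions, ambiguous placements near the junction) are
  idealized.

What passing simulated tests does **not** show: performance on real tumors
(repeat-driven multi-mapping, GC and coverage bias, indels, subclonal
complexity, real karyotype priors), robustness of the library-statistics
thresholds to heterogeneous quality profiles, or behaviour at
whole-genome/centromere scale. The simulation validates the statistical
machinery — mixture separation, window clustering, quartile-seeded calling
and FPR accounting — under the geometry the method assumes.

## Problem sizes

The calibration runs 20 seeded datasets, each a 2 × 1 Mb genome at 30×
coverage (~300,000 pairs), scored over all 25 inter-chromosomal band pairs
(1 true region + 24 decoys, i.e. 480 decoy regions pooled). These sizes
were chosen so a complete calibration is a coffee-break computation on one
core while keeping per-region read counts (dozens of pairs) in the regime
where the mixture fit is meaningful. The unit-test pipeline uses 200 kb
chromosomes with proportionally raised noise rates so that decoy regions
remain scorable at the smaller candidate volume.

## Known limitations

* Only inter-chromosomal two-segment models; inversions, duplications and
  multi-segment derivatives are out of scope.
* Window clustering localizes support, not breakpoints; reported regions
  are band pairs, not base-pair coordinates.
* The DE objective uses independent band marginals; co-occurrence of band
  pairs in real karyotypes is not modelled.
* The all-hits aligner is ungapped and not intended for production-scale
  data; use an external aligner and import the SAM for real samples.
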