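# Methods

`graftmobile` implements the computational chain of a reciprocal grafting
study between cucumber (*Cucumis sativus*, "Csa") and pumpkin (*Cucurbita
moschata*, "Cmo"): detecting mRNAs that crossed the graft junction,
classifying their movement, calling differential genes and metabolites with
a heterograft-vs-homograft delta-of-delta contrast, and joining the three
molecular layers into a network. This note records the models, the
parameters that matter, and the design choices made where the procedure was
genuinely open.

## Experimental design model

A grafted plant is written scion/rootstock. The full design crosses the
four combinations (Csa/Csa, Cmo/Cmo, Csa/Cmo, Cmo/Csa) with two tissues
(leaf = scion side, root = rootstock side), two conditions (control and 6-h
chilling) and three biological replicates — three being the replicate
number of the emulated assay design. Every tissue has a *resident* species;
in a heterograft the other partner is *foreign*, and foreign transcripts in
a tissue are the evidence of cross-junction movement.

## Species-of-origin read assignment

The two transcriptomes are modelled as homolog pairs of equal length whose
divergence is substitution-only, so position *i* on one homolog aligns with
position *i* on the other and the differing positions are *diagnostic
sites*. Reads (150 bp, single-end, forward strand) are placed by exact
k-mer seeding (k = 25, up to 5 seeds per read) followed by mismatch
verification against both homologs at the seeded offset; a read must match
at least one homolog with at most `max_mismatch` (default 1) mismatches or
it is unmapped. The origin is the species whose alleles the read carries at
*all* covered diagnostic sites; reads supporting both species are
ambiguous, reads covering no site are uninformative, and both are excluded
from counts rather than split fractionally — a deliberate refusal to invent
a probabilistic assignment model. With one tolerated mismatch and several
seeds, a read carrying at most one substitution always retains an exact
seed (pigeonhole), so the seeded search is equivalent to the exhaustive
sliding-window scan that serves as its test oracle.

A transcript is called mobile into a heterograft tissue when (i) foreign
origin-assigned reads summed over replicates reach `min_reads` (default 5),
(ii) it is detected in `min_replicates` (default 2) replicates, and (iii)
the matched homograft of the resident species — same tissue and condition,
where no junction exists to cross — shows at most `max_background` (default
0) foreign-looking reads. The strict zero-background default is the
conservative reading of artifact screening; it is configurable because the
original count thresholds are not published. A known consequence of the
strict veto: a homograft read with a sequencing error exactly at its only
covered diagnostic site is indistinguishable from a genuine foreign read
and vetoes that transcript's call (~4 % of destinations at 0.5 % per-base
error in the validation conditions). Recovery rate under error is therefore
measured over pooled replicate simulations rather than a single eight-plant
run, whose recall is quantized in steps of 1/8.

## Movement direction and chilling response

Direction is defined per transcript and condition relative to the
transcript's species of origin, aggregated over destination tissues:
detected only where its species is the scion → scion-to-rootstock; only
where it is the rootstock → rootstock-to-scion; both → bidirectional.
Comparing control and chilling assignments yields four mutually exclusive
categories: chilling-induced, chilling-reduced, direction-changed and
direction-maintained. Percentages are reported to one decimal with
round-half-up (banker's rounding reproduces none of the published
direction percentages; round-half-up reproduces all but one, 148/247 =
59.92 % printed elsewhere as 60.0 %, whose rounding rule is unclear and
which is therefore not asserted anywhere).

## The delta-of-delta contrast

For a feature measured in a tissue, with pseudocount `pc` (default 1)
guarding zeros and replicate aggregation by arithmetic mean (median
available):

    delta1 = log2(mean het + pc) − log2(mean homo + pc)   at control
    delta2 = the same at chilling
    statistic = delta2 − delta1

Features with statistic > 2 are up-calls, < −2 down-calls (strictly, so a
statistic of exactly ±2 is not called). The published procedure mixes ratio
language ("fold") with subtraction notation; log-space subtraction makes
both readings consistent and makes the ±2 cutoffs interpretable as a
4-fold change of the het/homo ratio between conditions. A raw-space mode
(plain differences, magnitude thresholded at 2^t) is available behind
`log_space=False` for sensitivity checks. No multiple-testing layer is
added: the rule is a pure threshold and is reproduced as such. DEG calling
(on FPKM, `counts·10⁹/(total·length)`) and DIM calling (on ion intensity)
are the same code path with two thin callers.

## Metabolite clustering set, normalization, clustering, PCA

Per tissue × graft combination, R = (mean chilling intensity)/(mean control
intensity) and Z = log2 R. The default retention rule is the literal
published one — min(Z) > 2 or max(Z) < −2, i.e. *every* combination
strongly responding in the same direction — with the likely-intended
permissive variant (max(Z) > 2 or min(Z) < −2) behind a flag; the literal
rule is unusually strict, and fixing it silently would hide a real
ambiguity in the source procedure. The published ratio definition contains
a self-ratio typo ("chilling X / chilling X"); it is implemented as
chilling/control per tissue × combination.

Min–max normalization is x* = (x − min)/(max − min) over the sample set
(error on constant vectors). Clustering of retained Z (or log2 fold-change)
profiles is agglomerative with average linkage on Euclidean distance, cut
to k = 8 flat clusters; the published work names only a heat-map web tool,
so the linkage/metric convention is fixed here for reproducibility. PCA is
column-centered; the sign of each component is fixed by making its
largest-magnitude loading positive, and the top-10 positive and negative
loadings per component are reported.

## Integration

* **Orthology**: best-hit global alignment (match +1, mismatch −1, gap −2)
  of every species-A transcript against species-B, deduplicated to
  one-to-one by keeping the highest-scoring pair per B-id (ties to the
  lexicographically smallest id). A simple deterministic aligner replaces
  the original BLAST-based search, which is unnecessary at this scale.
* **Gene–metabolite correlation**: Pearson correlation over het-vs-homo
  log2 fold-change *contrast vectors* — one component per (heterograft ×
  tissue × condition) cell, giving 4 shared components per gene (8 per
  metabolite) — thresholded at |cor| ≥ 0.95 with at least `min_points` = 4
  shared components. The contrast-vector reading (rather than
  per-replicate vectors) follows the worked example of the source
  procedure; the table inputs also support a replicate-dimension
  correlation by passing differently shaped tables.
* **Pathway enrichment**: one-sided hypergeometric upper tail with
  Benjamini–Hochberg adjustment. The original work names no test; this
  choice is recorded here as a package decision, not a source fact.
* **Network**: mobile–DEG edges require the mobile transcript's ortholog to
  be a called DEG sharing at least one pathway id; DEG–DIM edges come from
  the correlation table, signed. Exports are a TSV edge list and SIF.

## Synthetic data generator

The generator emulates the study's raw inputs with planted ground truth:

* Homolog pairs: random sequences with Binomial(L, divergence) substitutions
  (at least one per pair so every pair is discriminable), no indels —
  matching the alignment-free position-correspondence assumption of the
  origin assigner.
* Reads: Poisson(depth) uniformly positioned forward-strand reads per
  resident transcript per replicate, exact planted counts for foreign
  transcripts, i.i.d. per-base substitution errors.
* Expression/intensity: multiplicative lognormal replicate noise (both are
  positive right-skewed measures); a planted effect is realized entirely in
  the chilling heterograft group so delta1 = 0 and delta2 equals the target,
  making the round trip exact in the noiseless case. Planted correlations
  copy ± the gene's expected contrast profile onto a metabolite.
* Annotation: Poisson(1) pathways per feature drawn without replacement,
  plus a deliberately over-represented pathway recorded in the truth table.

Defaults (30 pairs, 500-b transcripts, 1 % divergence, 150-bp reads, depth
20, 3 replicates) are the validation study conditions. The generator does
not model library-prep bias, indels, paralogy, isoforms, 3′ coverage bias,
strandedness, or pooling variance within a replicate; passing tests
demonstrate correctness of the calling logic under the stated error model,
not performance on real libraries, where alignment, multi-mapping and
paralogy would dominate the error budget.

Truth tables are emitted alongside the data and never read by any analysis
stage; tests and the reproduction script compare outputs against them.

## Numerical and degenerate-input choices

Coordinates are 0-based half-open internally. Tie-breaks are deterministic
(smallest offset, then smallest pair index; lexicographic ids in joins) and
all outputs are stably sorted, so identical inputs give identical files.
Validation problem sizes (30 pairs × 500 b for mobility, 500 genes and 300
metabolites for the round trip, ≤ 100 × 100 tables for oracle comparisons)
were chosen as the smallest instances that exercise every code path while
keeping the whole suite fast on a laptop. Degenerate inputs raise rather
than guess: divergence 0 without an explicit flag, constant vectors in
min–max, k larger than the row count, zero group means with pseudocount 0,
missing design groups (named in the error), and homograft destinations in a
mobility plan are all errors.
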