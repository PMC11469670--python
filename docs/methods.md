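# Methods

This note documents the models, the numerical choices and the design
decisions behind `crmscan`, and what the synthetic fixtures do and do
not demonstrate.

## Scoring models

All three methods are generative training/background model pairs; a
window's score is the summed per-position log likelihood ratio (nats).
Counting is double-stranded: every training or background sequence
contributes its forward and reverse-complement kmers, and words
containing N are skipped.

**Markov chains (hexMCD).** For order m, the transition estimate is

    P(b | c) = (n(cb) + γ·mm(cb) + α) / Σ_b' (n(cb') + γ·mm(cb') + α)

where n are (m+1)-word counts, mm(cb) sums the counts of all words at
Hamming distance 1 from cb, γ (default 0.1) is the mismatch-smoothing
weight and α = 1 is a Laplace pseudocount. hexMCD is the order-5 chain
with mismatch smoothing. γ and α are explicit stand-ins: the mismatch
idea is part of the method's definition but no published weight exists,
and a small γ de-sparsifies rare 6-mer contexts without drowning the
signal. α applied identically to both models makes entirely unseen
contexts contribute exactly 0 to the log ratio.

**IMM.** Glimmer-style interpolation over orders 0–5:

    P_m(b|c) = λ_m(c)·P̂_m(b|c) + (1 − λ_m(c))·P_{m−1}(b|suffix(c))

with λ = 1 when the context count is ≥ C (default 400), λ = 0 for
unseen contexts, and otherwise λ = conf · count/C where conf is the
chi-square CDF (3 df) of the observed next-base counts against the
lower-order prediction, zeroed below 0.5. Per-order estimates P̂ carry
the same Laplace α, so C = 0 makes the IMM collapse exactly onto the
pure order-5 chain — a tested degeneracy.

**PAC-rc.** 6-mers collapse with their reverse complements into 2080
classes; each class gets a per-position rate λ = (count + 1) /
(positions + 2080). A window of L word positions scores

    Σ_classes [ n_c · log(λ_t/λ_b) − L·(λ_t − λ_b) ]

which is exactly the summed log Poisson pmf ratio (the test suite
verifies this against `scipy.stats.poisson.logpmf`).

**Strand symmetry.** A forward-strand conditional product is *not*
exactly reverse-complement invariant even with double-stranded counts
(context edge effects leave ~10% relative asymmetry on short windows).
The per-word contribution tables are therefore symmetrized —
contrib(w) ← (contrib(w) + contrib(revcomp(w))) / 2 — which makes all
three scorers exactly strand invariant while still scanning only the
forward strand. This equals averaging the two strand log ratios.

**Scanning.** Windows are 500 bp every 10 bp, organized as 25
instances offset 0, 10, …, 240 with intra-instance stride 250 (the
stride is the inferred spacing that makes 25 offsets tile every 10-bp
start exactly once; it is configurable). Scan scores are computed by a
per-word table lookup and prefix sum, so a scaffold costs O(length)
per model; windows with > 50% N are skipped (an N-rich window carries
no usable kmer signal).

## Post-processing

Per instance, the top-N windows by score are kept (ties at the value
cutoff all retained), then the elbow of the descending sorted score
curve suppresses everything at or below it. The elbow is the point of
maximum perpendicular distance to the chord joining the first and last
curve points; retention is rank-exclusive (ranks strictly before the
elbow index survive; an exactly linear curve suppresses nothing). Ties
in score break deterministically by genomic position.

Surviving windows enter the tile profile as their score *in excess of
the elbow cut value*. The cut is the instance's adaptive noise
threshold, so the retained evidence is height above it; this also
keeps the zero-baseline profile meaningful when absolute
log-likelihood-ratio scores are negative (common for PAC-rc, whose
per-position divergence between training and background is large).

The 10-bp tile profile takes the maximum surviving-window value over
covering windows — max, not sum, so runs of adjacent mediocre windows
cannot concatenate into one broad element; this is what keeps final
predictions compact. Peak calling finds local maxima within
contiguous nonzero groups (plateaus count once, apex at the leftmost
tile); a peak's amplitude is its height above the higher of its
bounding valleys, with group edges as zero-valleys (topographic
prominence). Peaks above the elbow of the genome-wide amplitude curve
become predictions spanning valley to valley (the valley tile goes to
the right-hand peak, so two peaks in one group abut). The exact
amplitude and boundary rules are configurable stand-ins — the
published record names the quantities without formulas — and the
prominence/valley versions here are the standard parameter-free
choices.

Predictions from all methods and training sets merge when overlapping
or abutting (max score, union of labels), and lengths beyond the Tukey
upper fence Q3 + 1.5·IQR (linear-interpolation quantiles) are dropped.

Top-N is 5000 per instance at genome scale. On the 200-kb test
fixture (~800 windows per instance) that cut is a no-op, so
fixture-scale runs use N = 150, chosen as a similarly selective
fraction; this is a study-condition scaling, recorded wherever it is
used.

## Locus assignment and orthology

A prediction's putative targets are the nearest non-overlapping genes
5' and 3' of it, measured edge-to-edge in reference coordinates and
ignoring strand; genes overlapping the prediction are excluded from
candidacy, ties break toward the smaller gene start. The locus is the
whole region between the flanking genes; a prediction inside one gene
takes that gene's span (kind `intronic`), one overlapping two or more
genes takes their combined span (`gene_overlap`). A prediction poking
out of its gene extends the locus to the neighboring intergenic
boundary — never to the prediction's own coordinates, because locus
identity must be a pure function of gene geometry for real and
permuted predictions to share keys.

Ortholog joining maps each flanking (or enclosing) gene to its
possibly-many D. melanogaster ortholog ids from a 2-column TSV; the
cross-species key set of a locus is the union over either flank (the
least restrictive reading; the enclosing gene's orthologs for
intronic/gene-overlap loci). Joining never alters predictions.

## Permutation statistics

The shuffle engine places each feature independently and uniformly
over the non-excluded genome (exclusion = merged CDS intervals, or
exons when no CDS exists): a gap is chosen with probability
proportional to its number of valid start positions, then a uniform
start — exactly uniform over all valid placements genome-wide.
Placements may overlap each other; lengths are preserved; a feature
longer than every gap is an error. One master seed spawns independent
per-permutation substreams, so results are reproducible under any
evaluation order.

* **Per-locus excess** (default 1000 permutations): a locus with at
  least one real prediction is flagged when its real count exceeds the
  maximum count over all permutations (empirical p < 1/n).
* **Cross-species common loci** (default 360): each species'
  predictions are merged, shuffled, re-assigned and re-keyed; the
  number of keys present in ≥ k species is compared to the null by
  z-score; z ≥ 1.645 (one-sided p < 0.05, uncorrected) is the
  significance criterion. When the null standard deviation is 0 the z
  is reported as NaN — with few species or tiny prediction sets the
  counts are too unstable for a z-criterion, and the statistic should
  only be read in regimes where the null counts are large enough for
  the normal approximation (the calibration test uses 8 species at
  k = 3 for this reason; at smaller counts the discrete, right-skewed
  null makes the criterion fire above its nominal rate).
* **Open-chromatin overlap** (default 500): a prediction counts once
  when any single peak covers ≥ f of its length (f = 0.1, boundary
  inclusive). Fold enrichment is observed count / permutation-mean
  count.

Two caveats worth knowing. First, real predictions are merged before
testing (so they never overlap) while permuted placements may overlap;
at high prediction density this conditioning slightly inflates the
observed key counts relative to the null. It is negligible when
predictions are sparse relative to the genome, as at genome scale.
Second, the per-locus test presupposes loci much larger than
predictions; when a locus barely exceeds the prediction length the
coding-excluded shuffle may be unable to reach it at all and the
empirical p degenerates. Both effects are fixture-scale phenomena.

## Synthetic fixtures

The generator emulates the full input bundle: a genome with planted
enhancer-like elements, two-exon gene models (one 2-kb intron),
chromatin peaks coincident with planted elements at a configurable
rate plus noise peaks, training/background FASTA sets drawn from the
same generative models, and ortholog tables.

The planted element model concentrates its signal in the central 40%
of the 500-bp element: a shifted base composition (AT-depleted,
GC-enriched) plus exactly 20 enriched 6-mers from a 5-word vocabulary
at random non-overlapping core positions, with plain-background
flanks. The core-and-flanks architecture mirrors real enhancers,
whose scan signal peaks at the element rather than decaying linearly
with window offset, and the fixed motif dose makes one training set
one functional class. The genomic background is deliberately *not*
clean: composition drifts in 2-kb blocks (a Beta(1,8)-distributed
mixing fraction toward the planted composition, emulating
isochore-like heterogeneity) and the motif vocabulary occurs
genome-wide at a 0.012/bp baseline. This graded noise floor is
essential — every elbow threshold in post-processing presupposes a
signal-plus-noise curve with a knee, and on an implausibly clean
two-class genome the elbow machinery degenerates. Each element sits
in a 1-kb quiet (homogeneous, sprinkle-free) neighborhood so its peak
is bounded by clean valleys; `element_margin` additionally controls
the distance between elements and genes (100 bp by default; the
locus-statistic computations use 1200 bp so that predictions do not
poke into exons, see the caveat above).

Multi-species fixtures plant elements inside introns of genes mapped
to shared Dmel ortholog ids, so every element contributes exactly one
locus key and the shared-key truth is exact at sharing rate 1.

What passing tests on these fixtures show: the scorers implement
their definitions exactly (oracle equivalence to 1e-9), the pipeline
recovers concentrated kmer signal at realistic noise levels, and the
permutation machinery is calibrated and powered. What they do not
show: performance on real enhancer grammar (cooperative motif
arrangements, repeats, assembly artifacts), robustness to annotation
errors, or the absolute sensitivity/specificity trade-off on any real
genome. The elbow-based amplitude threshold in particular is known to
be unstable on short mixed curves (tens of peaks): with the default
fixture one method (IMM) retains a noise-peak fraction slightly above
one-in-five while recovering all planted elements — an intrinsic
property of the chord-distance elbow at this scale, not of the scoring
model.

## Defaults at a glance

| parameter | default | notes |
| --- | --- | --- |
| window / resolution | 500 bp / 10 bp | 25 instances, stride 250 bp |
| top-N per instance | 5000 | 150 at 200-kb fixture scale |
| hexMCD γ, α | 0.1, 1.0 | mismatch smoothing, Laplace |
| IMM C, α | 400, 1.0 | Glimmer threshold |
| PAC-rc pseudocount | 1.0 | per class |
| N-window skip | > 50% N | configurable |
| permutations | 1000 / 360 / 500 | locus / common / chromatin |
| overlap fraction f | 0.1 | boundary inclusive |
| significance | z ≥ 1.645 | one-sided, uncorrected |
| Tukey fence | Q3 + 1.5·IQR | on prediction lengths |

Tandem-repeat masking is an upstream concern: the pipeline consumes
soft-masked FASTA and records the masker parameter string
("2 7 7 80 10 50 500 -m -h") in the run manifest for provenance only.
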