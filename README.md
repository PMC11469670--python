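# crmscan

Supervised kmer-model enhancer prediction and permutation-based
validation for (insect) regulatory-genome annotation.

Newly sequenced genomes are usually annotated for genes but almost
never for the cis-regulatory modules (CRMs) — enhancers and silencers —
that control when and where those genes are expressed. `crmscan`
implements a complete annotation workflow for this problem: given a
soft-masked genome, a GFF3 gene annotation, and a *training set* of
known enhancers sharing a functional character (say, wing-disc
enhancers) with a ~10-fold larger background of similarly sized
non-enhancer sequence, it predicts new enhancer-like intervals
genome-wide, assigns them putative target genes and loci, and tests
the resulting annotation against permutation nulls.

## The statistical core

Three discriminative scoring methods, each a pair of generative models
fit to the training (t) and background (b) sets; a 500-bp window *w*
is scored by the log-likelihood ratio

    S(w) = log P_t(w) − log P_b(w)

* **IMM** — interpolated Markov model blending chains of orders 0–5
  with Glimmer-style data-dependent weights λ_m(c) (full weight for
  contexts seen ≥ C = 400 times, a chi-square confidence otherwise).
* **hexMCD** — a fifth-order Markov chain over 6-mers with one-away
  mismatch count smoothing (weight γ = 0.1).
* **PAC-rc** — Poisson word-count overrepresentation of the 2080
  reverse-complement-collapsed 6-mer classes:
  S(w) = Σ_c log [ Pois(n_c; λ_t,c L) / Pois(n_c; λ_b,c L) ].

All counting is double-stranded and the per-word score tables are
symmetrized over reverse complements, so S(w) = S(revcomp(w)) exactly.

The genome is scanned at high density — 500-bp windows every 10 bp,
organized as 25 staggered instances — and post-processed: per instance
the top-N windows are kept and everything below the elbow of the
sorted score curve is zeroed; surviving windows pool into a 10-bp tile
profile (tile = max covering-window score above the elbow cut); peaks
are called with topographic prominence ("amplitude"); peaks above the
elbow of the amplitude curve become predictions; overlapping
predictions merge and Tukey-fence length outliers (> Q3 + 1.5·IQR) are
dropped. Three permutation statistics (BEDTools-shuffle-style nulls
with coding regions excluded) validate the annotation: per-locus
prediction excess (1000 shuffles, empirical p), cross-species
common-locus enrichment via Dmel-ortholog locus keys (360 shuffles,
z ≥ 1.645), and open-chromatin overlap enrichment (500 shuffles,
single-peak coverage ≥ 10% of the prediction).

## Worked example

Everything is runnable on bundled synthetic fixtures — no downloads.
The scripts in `examples/` each demonstrate one capability; for
instance the scan-and-predict example:

```sh
python examples/02_scan_and_predict.py
```

prints (abridged):

```
23 predictions (1 length outliers removed)
            prediction   len   score  overlaps planted element?
scaf1:    450-1440      990    18.2  yes
scaf1:   4140-5170     1030    23.1  yes
scaf1:  19240-20090     850     6.0  no
...
20/20 planted elements overlapped by a prediction; median length
reflects the compact peak-called extents.
```

Each line is one final prediction (coordinates, length, peak score)
and whether it hits one of the 20 planted enhancer-like elements. The
permutation-statistics example prints, among others:

```
open-chromatin overlap:
  observed 100.0% of predictions, null 20.1% +/- 8.9
  z = 8.98, fold enrichment = 4.98 (significant)
```

meaning the predictions coincide with (synthetic) chromatin peaks five
times more often than shuffled placements do.

The same workflow is available from the shell:

```sh
crmscan simulate --outdir fixture --n-species 3
crmscan run-all --genome fixture/genome.fa \
    --annotation fixture/annotation.gff3 \
    --enhancers fixture/training.fa --background fixture/background.fa \
    --peaks fixture/peaks.bed --orthologs fixture/orthologs.tsv \
    --species-config fixture/multispecies/species.cfg --outdir run1
```

which writes predictions (modified BED + GFF3), the three statistics
TSVs, logs and a reproducibility manifest under `run1/`. `crmscan
show-config` prints every tunable default.

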