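"""Self-contained synthetic fixtures for every pipeline stage.

A fixture is a toy genome with planted enhancer-like elements whose
kmer composition differs measurably from the genomic background, plus
two-exon gene models, open-chromatin peaks optionally coincident with
the planted elements, training/background FASTA sets, and ortholog
tables. Everything is deterministic under the spec's seed and emitted
in exactly the formats the pipeline consumes.

The planted sequence model is an order-0 composition shift plus a small
set of enriched 6-mers spliced in at elevated frequency — strong enough
for desk-scale recovery tests without mimicking any real motif grammar.
Multi-species fixtures plant a controlled fraction of elements inside
introns of genes that map to common D. melanogaster ortholog ids, so
cross-species locus sharing is known by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import jensenshannon

from .formats_io import Gene, GeneAnnotation, Genome, Exon, write_fasta
from .models import kmer_ids, encode
from .postprocess import Prediction

BASES = np.array(list("ACGT"))

DEFAULT_BG_COMP = (0.3, 0.2, 0.2, 0.3)  # A C G T
DEFAULT_PLANTED_COMP = (0.22, 0.28, 0.28, 0.22)
DEFAULT_ENRICHED_6MERS = (
    "CAGGTA", "TAATCC", "GGATTA", "CACGTG", "TGACGT",
)
DEFAULT_MOTIFS_PER_ELEMENT = 20  # enriched 6-mers per planted element core
DEFAULT_BG_MOTIF_RATE = 0.012  # baseline motif occurrence in genomic background


@dataclass
class SynthSpec:
    n_scaffolds: int = 1
    scaffold_lengths: tuple[int, ...] = (200_000,)
    bg_composition: tuple[float, float, float, float] = DEFAULT_BG_COMP
    planted_composition: tuple[float, float, float, float] = DEFAULT_PLANTED_COMP
    enriched_6mers: tuple[str, ...] = DEFAULT_ENRICHED_6MERS
    motifs_per_element: int = DEFAULT_MOTIFS_PER_ELEMENT
    bg_motif_rate: float = DEFAULT_BG_MOTIF_RATE
    core_fraction: float = 0.4
    element_buffer: int = 1000  # quiet background around each element
    element_margin: int = 100  # minimum gap between an element and a gene
    n_planted: int = 20
    planted_length: int = 500
    n_genes: int = 60
    exon_length: int = 200
    intron_length: int = 2000
    n_train: int = 20
    bg_ratio: int = 10
    peak_coincidence: float = 1.0
    peak_length: int = 300
    n_noise_peaks: int = 30
    ortholog_mapping_rate: float = 0.9
    n_species: int = 12
    seed: int = 0

    @property
    def gene_span(self) -> int:
        return 2 * self.exon_length + self.intron_length


@dataclass
class Fixture:
    genome: Genome
    annot: GeneAnnotation
    truth: list[tuple[str, int, int]]
    peaks: list[tuple[str, int, int]]
    training_seqs: list[str]
    background_seqs: list[str]
    orthologs: dict[str, frozenset[str]]
    manifest: dict[str, object]
    spec: SynthSpec

    def truth_predictions(self) -> list[Prediction]:
        return [Prediction(scaffold=sid, start=s, end=e, peak_score=1.0,
                           amplitude=1.0, methods=("truth",),
                           training_sets=("planted",), id=f"truth_{i}")
                for i, (sid, s, e) in enumerate(self.truth)]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit all fixture files under outdir; returns the path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "annotation": outdir / "annotation.gff3",
            "truth": outdir / "truth.bed",
            "peaks": outdir / "peaks.bed",
            "training": outdir / "training.fa",
            "background": outdir / "background.fa",
            "orthologs": outdir / "orthologs.tsv",
            "manifest": outdir / "manifest.txt",
        }
        write_fasta(self.genome.scaffolds, paths["genome"])
        _write_gff3_annotation(self.annot, paths["annotation"])
        _write_bed3(self.truth, paths["truth"])
        _write_bed3(self.peaks, paths["peaks"])
        write_fasta([(f"train_{i}", s) for i, s in enumerate(self.training_seqs)],
                    paths["training"])
        write_fasta([(f"bg_{i}", s) for i, s in enumerate(self.background_seqs)],
                    paths["background"])
        with open(paths["orthologs"], "w") as fh:
            for gid in sorted(self.orthologs):
                for dmel in sorted(self.orthologs[gid]):
                    fh.write(f"{gid}\t{dmel}\n")
        with open(paths["manifest"], "w") as fh:
            for k, v in self.manifest.items():
                fh.write(f"{k}={v}\n")
        return paths


def _write_bed3(intervals, path) -> None:
    with open(path, "w") as fh:
        for sid, s, e in intervals:
            fh.write(f"{sid}\t{s}\t{e}\n")


def _write_gff3_annotation(annot: GeneAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        exons_by_gene: dict[str, list[Exon]] = {}
        for ex in annot.exons:
            exons_by_gene.setdefault(ex.gene_id, []).append(ex)
        cds_by_gene: dict[str, list[Exon]] = {}
        for c in annot.cds:
            cds_by_gene.setdefault(c.gene_id, []).append(c)
        for g in annot.genes:
            fh.write(f"{g.scaffold}\tsynth\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")
            for i, ex in enumerate(sorted(exons_by_gene.get(g.gene_id, []),
                                          key=lambda e: e.start)):
                fh.write(f"{ex.scaffold}\tsynth\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                         f"{ex.strand}\t.\tID={g.gene_id}.e{i};Parent={g.gene_id}\n")
            for i, c in enumerate(sorted(cds_by_gene.get(g.gene_id, []),
                                         key=lambda e: e.start)):
                fh.write(f"{c.scaffold}\tsynth\tCDS\t{c.start + 1}\t{c.end}\t.\t"
                         f"{c.strand}\t.\tID={g.gene_id}.c{i};Parent={g.gene_id}\n")


# ---------------------------------------------------------------------------
# Sequence models


def draw_background(rng: np.random.Generator, length: int,
                    comp: tuple[float, ...],
                    motifs: tuple[str, ...] = (),
                    motif_rate: float = 0.0,
                    planted_comp: tuple[float, ...] | None = None,
                    block_len: int = 2000,
                    block_mix_beta: tuple[float, float] = (1.0, 8.0)) -> str:
    """Heterogeneous order-0 background.

    Real genomes are not compositionally uniform (isochores, local GC
    drift) and carry motif-like words everywhere at low frequency; both
    features give a scan its graded noise floor of weak spurious peaks,
    which the elbow thresholds in post-processing rely on. Composition
    varies in blocks: each ``block_len`` block mixes the base
    composition toward ``planted_comp`` by a Beta-distributed fraction
    (mostly near zero, occasionally substantial), and enriched 6-mers
    are sprinkled at ``motif_rate`` per position.
    """
    base = np.asarray(comp, dtype=np.float64)
    chunks: list[np.ndarray] = []
    pos = 0
    target = np.asarray(planted_comp, dtype=np.float64) if planted_comp is not None else base
    while pos < length:
        n = min(block_len, length - pos)
        t = rng.beta(*block_mix_beta) if planted_comp is not None else 0.0
        p = (1 - t) * base + t * target
        chunks.append(rng.choice(4, size=n, p=p / p.sum()))
        pos += n
    arr = BASES[np.concatenate(chunks)]
    if motifs and motif_rate > 0 and length >= 6:
        n_mot = rng.binomial(length, motif_rate)
        pos_arr = rng.integers(0, length - 5, size=n_mot)
        for p in pos_arr:
            arr[p:p + 6] = list(motifs[rng.integers(len(motifs))])
    return "".join(arr)


def draw_planted(rng: np.random.Generator, length: int, spec: SynthSpec) -> str:
    """Draw from the planted model.

    The central ``core_fraction`` of the element carries the signal: a
    shifted base composition plus exactly ``motifs_per_element``
    enriched 6-mers at random non-overlapping core positions; the
    flanks are plain background. This core-and-flanks architecture
    emulates real enhancers, whose scan signal peaks sharply at the
    element center rather than decaying linearly with window offset,
    and the fixed motif dose keeps element strength homogeneous (one
    training set = one functional class)."""
    core_lo = int(length * (1 - spec.core_fraction) / 2)
    core_hi = int(length * (1 + spec.core_fraction) / 2)
    core_len = core_hi - core_lo
    arr = np.empty(length, dtype="<U1")
    arr[:core_lo] = BASES[rng.choice(4, size=core_lo, p=np.asarray(spec.bg_composition))]
    arr[core_hi:] = BASES[rng.choice(4, size=length - core_hi,
                                     p=np.asarray(spec.bg_composition))]
    arr[core_lo:core_hi] = BASES[rng.choice(4, size=core_len,
                                            p=np.asarray(spec.planted_composition))]
    # place motifs on a 6-spaced grid of core slots so they never overlap
    n_slots = core_len // 6
    n_mot = min(spec.motifs_per_element, n_slots)
    slots = rng.choice(n_slots, size=n_mot, replace=False)
    for sl in slots:
        p = core_lo + int(sl) * 6
        arr[p:p + 6] = list(spec.enriched_6mers[rng.integers(len(spec.enriched_6mers))])
    return "".join(arr)


def kmer_js_divergence(seqs_a: list[str], seqs_b: list[str], k: int = 6) -> float:
    """Jensen-Shannon divergence between the 6-mer frequency spectra of
    two sequence collections (recorded in the fixture manifest)."""
    def spectrum(seqs):
        counts = np.zeros(4 ** k)
        for s in seqs:
            ids, valid = kmer_ids(encode(s), k)
            if valid.any():
                counts += np.bincount(ids[valid], minlength=4 ** k)
        return counts / counts.sum()
    return float(jensenshannon(spectrum(seqs_a), spectrum(seqs_b), base=2))


# ---------------------------------------------------------------------------
# Single-species fixture


def _layout(rng: np.random.Generator, spec: SynthSpec, L: int,
            planted_in_introns: bool = False,
            planted_gene_indices: list[int] | None = None
            ) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Place n_genes gene spans and planted elements on one scaffold.

    Intergenic planting puts at most one element per intergenic slot so
    no two elements are adjacent without an intervening gene; intronic
    planting centers elements in the introns of the given gene indices.
    Returns (gene spans, element spans).
    """
    n_items = spec.n_genes
    used = n_items * spec.gene_span
    n_gaps = n_items + 1
    planted_slots: list[int] = []
    if not planted_in_introns:
        if spec.n_planted > n_gaps:
            raise ValueError("n_planted exceeds available intergenic slots")
        used += spec.n_planted * spec.planted_length
        planted_slots = sorted(rng.choice(n_gaps, size=spec.n_planted, replace=False))
    min_gap = 100
    margin = max(min_gap, spec.element_margin)
    needed = used + min_gap * n_gaps + 2 * margin * spec.n_planted
    if needed > L:
        raise ValueError(f"infeasible geometry: need >= {needed} bp, scaffold is {L} bp")
    # distribute the slack over the gaps
    slack = L - needed
    extra = rng.multinomial(slack, np.ones(n_gaps) / n_gaps)

    genes: list[tuple[int, int]] = []
    elements: list[tuple[int, int]] = []
    pos = 0
    for slot in range(n_gaps):
        pos += min_gap + int(extra[slot])
        if slot in planted_slots:
            pos += margin - min_gap
            elements.append((pos, pos + spec.planted_length))
            pos += spec.planted_length + margin
        if slot < n_items:
            genes.append((pos, pos + spec.gene_span))
            pos += spec.gene_span
    if planted_in_introns:
        for gi in (planted_gene_indices or []):
            gs, _ = genes[gi]
            intron_start = gs + spec.exon_length
            mid = intron_start + (spec.intron_length - spec.planted_length) // 2
            elements.append((mid, mid + spec.planted_length))
    return genes, elements


def make_fixture(spec: SynthSpec) -> Fixture:
    """Build the complete single-species fixture (deterministic in seed)."""
    rng = np.random.default_rng(spec.seed)
    if len(spec.scaffold_lengths) != spec.n_scaffolds:
        raise ValueError("scaffold_lengths must have n_scaffolds entries")

    genome_seqs: dict[str, str] = {}
    annot = GeneAnnotation(feature_types_present={"gene", "exon", "CDS"})
    truth: list[tuple[str, int, int]] = []
    peaks: list[tuple[str, int, int]] = []
    orthologs: dict[str, frozenset[str]] = {}
    # split genes/elements across scaffolds proportionally to length
    lens = np.asarray(spec.scaffold_lengths, dtype=np.float64)
    gene_alloc = _proportional(spec.n_genes, lens)
    elem_alloc = _proportional(spec.n_planted, lens)

    gene_counter = 0
    for si in range(spec.n_scaffolds):
        sid = f"scaf{si + 1}"
        L = spec.scaffold_lengths[si]
        sub = SynthSpec(**{**spec.__dict__,
                           "n_genes": int(gene_alloc[si]),
                           "n_planted": int(elem_alloc[si])})
        genes, elements = _layout(rng, sub, L)
        seq = list(draw_background(rng, L, spec.bg_composition,
                                   spec.enriched_6mers, spec.bg_motif_rate,
                                   planted_comp=spec.planted_composition))
        for (es, ee) in elements:
            # quiet (homogeneous, sprinkle-free) neighborhood so each
            # element's scan peak is bounded by clean valleys
            qs, qe = max(0, es - spec.element_buffer), min(L, ee + spec.element_buffer)
            seq[qs:qe] = draw_background(rng, qe - qs, spec.bg_composition)
            seq[es:ee] = draw_planted(rng, ee - es, spec)
            truth.append((sid, es, ee))
            if rng.random() < spec.peak_coincidence:
                off = int(rng.integers(-spec.peak_length // 2, spec.peak_length // 2 + 1))
                ps = max(0, es + off)
                peaks.append((sid, ps, min(L, ps + spec.peak_length)))
        genome_seqs[sid] = "".join(seq)
        for gs, ge in genes:
            gid = f"g{gene_counter}"
            gene_counter += 1
            annot.genes.append(Gene(gid, sid, gs, ge))
            e1 = Exon(gid, sid, gs, gs + spec.exon_length)
            e2 = Exon(gid, sid, ge - spec.exon_length, ge)
            annot.exons.extend([e1, e2])
            annot.cds.extend([e1, e2])
            if rng.random() < spec.ortholog_mapping_rate:
                orthologs[gid] = frozenset({f"FBgn{gene_counter - 1:07d}"})
    for pi in range(spec.n_noise_peaks):
        si = int(rng.integers(spec.n_scaffolds))
        sid = f"scaf{si + 1}"
        L = spec.scaffold_lengths[si]
        ps = int(rng.integers(0, L - spec.peak_length))
        peaks.append((sid, ps, ps + spec.peak_length))
    peaks.sort()

    training = [draw_planted(rng, spec.planted_length, spec)
                for _ in range(spec.n_train)]
    background = [draw_background(rng, spec.planted_length, spec.bg_composition,
                                  spec.enriched_6mers, spec.bg_motif_rate,
                                  planted_comp=spec.planted_composition)
                  for _ in range(spec.n_train * spec.bg_ratio)]

    manifest: dict[str, object] = {
        "seed": spec.seed,
        "n_scaffolds": spec.n_scaffolds,
        "scaffold_lengths": ",".join(map(str, spec.scaffold_lengths)),
        "n_planted": spec.n_planted,
        "planted_length": spec.planted_length,
        "n_genes": spec.n_genes,
        "n_train": spec.n_train,
        "bg_ratio": spec.bg_ratio,
        "peak_coincidence": spec.peak_coincidence,
        "motifs_per_element": spec.motifs_per_element,
        "bg_motif_rate": spec.bg_motif_rate,
        "kmer_jsd_train_vs_bg": round(kmer_js_divergence(training, background), 4),
    }
    return Fixture(genome=Genome(scaffolds=genome_seqs), annot=annot, truth=truth,
                   peaks=peaks, training_seqs=training, background_seqs=background,
                   orthologs=orthologs, manifest=manifest, spec=spec)


def _proportional(n: int, weights: np.ndarray) -> np.ndarray:
    """Deterministic largest-remainder split of n items by weight."""
    frac = weights / weights.sum() * n
    base = np.floor(frac).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(frac - base))
    base[order[:rem]] += 1
    return base


# ---------------------------------------------------------------------------
# Multi-species fixture


@dataclass
class SpeciesBundle:
    name: str
    annot: GeneAnnotation
    scaffold_lengths: dict[str, int]
    predictions: list[Prediction]
    orthologs: dict[str, frozenset[str]]
    planted_gene_indices: list[int] = field(default_factory=list)


@dataclass
class MultiFixture:
    species: list[SpeciesBundle]
    shared_keys: list[str]
    spec: SynthSpec
    sharing: float


def make_multispecies_fixture(spec: SynthSpec, sharing: float) -> MultiFixture:
    """Per-species bundles with a controlled locus-sharing rate.

    Each species gets an independent gene layout. A shared pool of
    ``n_planted`` Dmel ortholog ids defines candidate shared loci; with
    probability ``sharing`` a species' planted element goes into the
    intron of the gene mapping to the next shared id, otherwise into a
    uniformly chosen non-shared gene. Elements sit in introns so each
    contributes exactly one ortholog locus key, making the shared-key
    truth list exact at sharing=1.
    """
    if not (0.0 <= sharing <= 1.0):
        raise ValueError("sharing rate must lie in [0, 1]")
    if spec.n_species < 2:
        raise ValueError("need at least 2 species")
    if spec.n_planted > spec.n_genes:
        raise ValueError("n_planted exceeds n_genes")
    rng = np.random.default_rng(spec.seed)
    shared_ids = [f"Dmel_shared_{i}" for i in range(spec.n_planted)]
    shared_gene_idx = sorted(rng.choice(spec.n_genes, size=spec.n_planted,
                                        replace=False).tolist())

    species: list[SpeciesBundle] = []
    for si in range(spec.n_species):
        name = f"sp{si + 1}"
        annot = GeneAnnotation(feature_types_present={"gene", "exon", "CDS"})
        sid = "scaf1"
        L = spec.scaffold_lengths[0]
        planted_genes: list[int] = []
        fallback_pool = [g for g in range(spec.n_genes) if g not in shared_gene_idx]
        for j, gidx in enumerate(shared_gene_idx):
            if rng.random() < sharing:
                planted_genes.append(gidx)
            else:
                if not fallback_pool:
                    raise ValueError("not enough non-shared genes for unshared elements")
                pick = int(rng.integers(len(fallback_pool)))
                planted_genes.append(fallback_pool.pop(pick))
        genes, elements = _layout(rng, SynthSpec(**{**spec.__dict__, "n_planted": 0}),
                                  L, planted_in_introns=True,
                                  planted_gene_indices=planted_genes)
        orthologs: dict[str, frozenset[str]] = {}
        for gi, (gs, ge) in enumerate(genes):
            gid = f"{name}_g{gi}"
            annot.genes.append(Gene(gid, sid, gs, ge))
            e1 = Exon(gid, sid, gs, gs + spec.exon_length)
            e2 = Exon(gid, sid, ge - spec.exon_length, ge)
            annot.exons.extend([e1, e2])
            annot.cds.extend([e1, e2])
            if gi in shared_gene_idx:
                dmel = shared_ids[shared_gene_idx.index(gi)]
            else:
                dmel = f"Dmel_{name}_g{gi}"
            if rng.random() < spec.ortholog_mapping_rate or gi in planted_genes:
                orthologs[gid] = frozenset({dmel})
        preds = [Prediction(scaffold=sid, start=s, end=e, peak_score=1.0,
                            amplitude=1.0, methods=("truth",),
                            training_sets=("planted",), id=f"{name}_p{i}")
                 for i, (s, e) in enumerate(sorted(elements))]
        species.append(SpeciesBundle(name=name, annot=annot,
                                     scaffold_lengths={sid: L},
                                     predictions=preds, orthologs=orthologs,
                                     planted_gene_indices=planted_genes))
    return MultiFixture(species=species, shared_keys=shared_ids, spec=spec,
                        sharing=sharing)
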