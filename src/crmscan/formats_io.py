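"""Reading, writing and preflight validation of the standard formats.

The pipeline touches FASTA (soft- or hard-masked genomes), GFF3 gene
annotation, BED (open-chromatin peaks and the modified-BED prediction
dialect) and plain TSV. All internal coordinates are 0-based half-open;
GFF3's 1-based inclusive convention is converted exactly once, at the
file boundary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .errors import FormatError

logger = logging.getLogger(__name__)

_VALID_BASES = set("ACGTNacgtn")


@dataclass
class Genome:
    """A genome as an ordered mapping of scaffold id -> DNA sequence.

    Lowercase bases mark soft-masked (tandem-repeat) positions; they are
    uppercased for kmer counting but window-level N/masking filters see
    the original case.
    """

    scaffolds: dict[str, str]
    masked_convention: str = "soft"

    def __post_init__(self) -> None:
        for sid, seq in self.scaffolds.items():
            if not seq:
                raise FormatError(f"scaffold {sid!r} has an empty sequence")

    @property
    def lengths(self) -> dict[str, int]:
        return {sid: len(s) for sid, s in self.scaffolds.items()}

    def __len__(self) -> int:
        return len(self.scaffolds)


@dataclass(frozen=True)
class Gene:
    gene_id: str
    scaffold: str
    start: int  # 0-based half-open
    end: int
    strand: str = "+"


@dataclass(frozen=True)
class Exon:
    gene_id: str
    scaffold: str
    start: int
    end: int
    strand: str = "+"


@dataclass
class GeneAnnotation:
    """Gene and exon models plus CDS intervals (for coding-exclusion masks)."""

    genes: list[Gene] = field(default_factory=list)
    exons: list[Exon] = field(default_factory=list)
    cds: list[Exon] = field(default_factory=list)
    feature_types_present: set[str] = field(default_factory=set)

    def genes_by_scaffold(self) -> dict[str, list[Gene]]:
        out: dict[str, list[Gene]] = {}
        for g in self.genes:
            out.setdefault(g.scaffold, []).append(g)
        for lst in out.values():
            lst.sort(key=lambda g: (g.start, g.end))
        return out

    def exon_intervals(self) -> dict[str, np.ndarray]:
        """Merged exon intervals per scaffold as an (n, 2) int array."""
        return _merged_intervals(self.exons)

    def coding_intervals(self) -> dict[str, np.ndarray]:
        """Merged CDS intervals per scaffold; falls back to exons when the
        annotation carries no CDS features."""
        return _merged_intervals(self.cds if self.cds else self.exons)


def _merged_intervals(feats: Sequence[Exon]) -> dict[str, np.ndarray]:
    per: dict[str, list[tuple[int, int]]] = {}
    for f in feats:
        per.setdefault(f.scaffold, []).append((f.start, f.end))
    out: dict[str, np.ndarray] = {}
    for sid, ivals in per.items():
        ivals.sort()
        merged: list[list[int]] = []
        for s, e in ivals:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[sid] = np.array(merged, dtype=np.int64)
    return out


@dataclass
class PreflightReport:
    n_scaffolds: int
    scaffold_sizes: dict[str, int]
    feature_types_present: set[str]
    mean_intergenic_distance: float  # NaN when undefined
    dropped_scaffolds: list[str]
    issues: list[str] = field(default_factory=list)

    def lines(self) -> list[str]:
        out = [
            f"scaffolds retained: {self.n_scaffolds}",
            f"scaffolds dropped (no genes): {len(self.dropped_scaffolds)}"
            + (f" [{', '.join(self.dropped_scaffolds)}]" if self.dropped_scaffolds else ""),
            f"feature types present: {', '.join(sorted(self.feature_types_present)) or '(none)'}",
            f"mean intergenic distance: "
            + ("undefined" if np.isnan(self.mean_intergenic_distance)
               else f"{self.mean_intergenic_distance:.1f} bp"),
        ]
        for sid, size in self.scaffold_sizes.items():
            out.append(f"scaffold {sid}: {size} bp")
        out.extend(self.issues)
        return out


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> Genome:
    """Read a (soft-masked) multi-FASTA genome.

    Case is preserved so downstream code can see soft masking. Duplicate
    record ids and non-ACGTN characters are format errors naming the
    offending record/position.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"FASTA file not found: {path}")
    scaffolds: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in scaffolds:
            raise FormatError(f"duplicate FASTA record id: {rec.id!r}")
        seq = str(rec.seq)
        bad = set(seq) - _VALID_BASES
        if bad:
            ch = sorted(bad)[0]
            pos = seq.index(ch)
            raise FormatError(
                f"record {rec.id!r}: invalid character {ch!r} at position {pos}"
            )
        if not seq:
            raise FormatError(f"record {rec.id!r} has an empty sequence")
        scaffolds[rec.id] = seq
    if not scaffolds:
        raise FormatError(f"no FASTA records in {path}")
    return Genome(scaffolds=scaffolds)


def write_fasta(seqs: dict[str, str] | Iterable[tuple[str, str]], path: str | Path,
                width: int = 70) -> None:
    if isinstance(seqs, dict):
        seqs = seqs.items()
    with open(path, "w") as fh:
        for sid, seq in seqs:
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

_ATTR_RE = re.compile(r"([^;=]+)=([^;]*)")

_GENE_TYPES = {"gene", "protein_coding_gene", "pseudogene"}
_TRANSCRIPT_TYPES = {
    "mRNA", "transcript", "tRNA", "rRNA", "snRNA", "snoRNA", "ncRNA",
    "lnc_RNA", "miRNA", "pre_miRNA", "pseudogenic_transcript",
}


def _parse_attrs(s: str) -> dict[str, str]:
    return {m.group(1).strip(): m.group(2).strip() for m in _ATTR_RE.finditer(s)}


def read_gff3(path: str | Path) -> GeneAnnotation:
    """Read a GFF3 annotation, keeping gene, exon and CDS features.

    Coordinates are converted from GFF's 1-based inclusive to internal
    0-based half-open. Every feature type observed in column 3 is
    recorded (the preflight report surfaces this census). Exons/CDS are
    attached to their gene by walking Parent attributes through any
    intermediate transcript features; orphans are dropped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"GFF3 file not found: {path}")

    annot = GeneAnnotation()
    # (type, scaffold, start0, end, strand, attrs) keyed by feature ID
    id_info: dict[str, tuple[str, str | None]] = {}  # id -> (ftype, parent)
    genes_by_id: dict[str, Gene] = {}
    pending: list[tuple[str, str, str, int, int, str]] = []  # subfeatures
    n_lines = 0

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(parts)}")
            seqid, _src, ftype, s1, e1, _score, strand, _phase, attrs_s = parts
            try:
                start1, end1 = int(s1), int(e1)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric coordinate") from None
            if end1 < start1:
                raise FormatError(f"{path}:{lineno}: end {end1} < start {start1}")
            n_lines += 1
            annot.feature_types_present.add(ftype)
            start, end = start1 - 1, end1  # -> 0-based half-open
            attrs = _parse_attrs(attrs_s)
            fid = attrs.get("ID")
            parent = attrs.get("Parent")
            if parent and "," in parent:
                parent = parent.split(",")[0]
            if fid:
                id_info[fid] = (ftype, parent)
            if ftype in _GENE_TYPES:
                gid = fid or attrs.get("Name") or f"gene_{lineno}"
                g = Gene(gid, seqid, start, end, strand if strand in "+-" else "+")
                genes_by_id[gid] = g
                annot.genes.append(g)
            elif ftype in ("exon", "CDS"):
                pending.append((ftype, seqid, parent or "", start, end, strand))

    for ftype, seqid, parent, start, end, strand in pending:
        gid = _resolve_gene(parent, genes_by_id, id_info)
        if gid is None:
            logger.warning("dropping %s at %s:%d-%d: no parent gene found", ftype, seqid, start, end)
            continue
        feat = Exon(gid, seqid, start, end, strand if strand in "+-" else "+")
        (annot.exons if ftype == "exon" else annot.cds).append(feat)

    # exon spans must lie within their gene's span
    for ex in annot.exons + annot.cds:
        g = genes_by_id.get(ex.gene_id)
        if g is not None and not (g.start <= ex.start and ex.end <= g.end):
            raise FormatError(
                f"feature of gene {ex.gene_id!r} at {ex.scaffold}:{ex.start}-{ex.end} "
                f"lies outside the gene span {g.start}-{g.end}"
            )
    if n_lines == 0:
        logger.warning("GFF3 file %s contains no feature lines", path)
    return annot


def _resolve_gene(parent: str, genes: dict[str, Gene],
                  id_info: dict[str, tuple[str, str | None]], max_depth: int = 5) -> str | None:
    pid = parent
    for _ in range(max_depth):
        if not pid:
            return None
        if pid in genes:
            return pid
        info = id_info.get(pid)
        if info is None:
            # ID heuristic: exon IDs of the form <gene>-E1 / <gene>.exon1
            stem = re.split(r"[.\-:]", pid)[0]
            return stem if stem in genes else None
        pid = info[1] or ""
    return None


def write_gff3(predictions, path: str | Path, source: str = "crmscan") -> None:
    """Write final predictions as GFF3 enhancer features (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for p in predictions:
            attrs = (
                f"ID={p.id};methods={','.join(p.methods)};"
                f"training_sets={','.join(p.training_sets)};amplitude={p.amplitude!r}"
            )
            fh.write(
                f"{p.scaffold}\t{source}\tenhancer\t{p.start + 1}\t{p.end}\t"
                f"{p.peak_score!r}\t.\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Preflight


def mean_intergenic_distance(annot: GeneAnnotation) -> float:
    """Mean gap between adjacent same-scaffold genes.

    Adjacent pairs (by start coordinate) that overlap or nest are
    discarded. Returns NaN when no usable pair exists.
    """
    gaps: list[int] = []
    for genes in annot.genes_by_scaffold().values():
        for a, b in zip(genes, genes[1:]):
            if b.start < a.end:  # overlapping or nested pair
                continue
            gaps.append(b.start - a.end)
    return float(np.mean(gaps)) if gaps else float("nan")


def preflight(genome: Genome, annot: GeneAnnotation) -> tuple[Genome, GeneAnnotation, PreflightReport]:
    """Validate genome + annotation and drop gene-less scaffolds.

    Retained sequences and coordinates are never altered; only whole
    scaffolds without any annotated gene are removed. A gene that refers
    to a scaffold absent from the genome is a hard error.
    """
    issues: list[str] = []
    for g in annot.genes:
        if g.scaffold not in genome.scaffolds:
            raise FormatError(f"gene {g.gene_id!r} references unknown scaffold {g.scaffold!r}")

    with_genes = {g.scaffold for g in annot.genes}
    dropped = [sid for sid in genome.scaffolds if sid not in with_genes]
    kept = {sid: seq for sid, seq in genome.scaffolds.items() if sid in with_genes}
    if not kept:
        raise FormatError("no scaffold carries an annotated gene")
    out_genome = Genome(scaffolds=kept, masked_convention=genome.masked_convention)

    mid = mean_intergenic_distance(annot)
    if np.isnan(mid):
        issues.append("mean intergenic distance undefined (<2 usable gene pairs)")
    for g in annot.genes[:3]:
        issues.append(f"sample gene: {g.gene_id} {g.scaffold}:{g.start}-{g.end} ({g.strand})")
    for e in annot.exons[:3]:
        issues.append(f"sample exon: {e.gene_id} {e.scaffold}:{e.start}-{e.end}")

    report = PreflightReport(
        n_scaffolds=len(kept),
        scaffold_sizes={sid: len(s) for sid, s in kept.items()},
        feature_types_present=set(annot.feature_types_present),
        mean_intergenic_distance=mid,
        dropped_scaffolds=dropped,
        issues=issues,
    )
    return out_genome, annot, report


# ---------------------------------------------------------------------------
# BED


def read_bed_intervals(path: str | Path) -> list[tuple[str, int, int]]:
    """Read a BED3+ file of plain intervals (e.g. open-chromatin peaks)."""
    out: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric coordinate") from None
            if start > end:
                raise FormatError(f"{path}:{lineno}: start {start} > end {end}")
            out.append((parts[0], start, end))
    return out


_BED_NA = "."


def write_bed(predictions, path: str | Path) -> None:
    """Write predictions in the modified-BED dialect.

    Columns: scaffold, start, end, id, peak_score, strand ('.'),
    methods (comma-joined), training_sets (comma-joined), amplitude,
    upstream flanking gene, downstream flanking gene. The read/write
    pair round-trips losslessly (floats via repr).
    """
    with open(path, "w") as fh:
        for p in predictions:
            fh.write(
                "\t".join([
                    p.scaffold, str(p.start), str(p.end), p.id, repr(p.peak_score), ".",
                    ",".join(p.methods), ",".join(p.training_sets), repr(p.amplitude),
                    p.upstream_gene or _BED_NA, p.downstream_gene or _BED_NA,
                ]) + "\n"
            )


def read_bed(path: str | Path):
    """Read predictions written by :func:`write_bed`."""
    from .postprocess import Prediction

    preds = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise FormatError(f"{path}:{lineno}: expected >=9 columns in modified BED")
            try:
                start, end = int(parts[1]), int(parts[2])
                score, amp = float(parts[4]), float(parts[8])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric coordinate or score") from None
            if start > end:
                raise FormatError(f"{path}:{lineno}: start {start} > end {end}")
            up = parts[9] if len(parts) > 9 and parts[9] != _BED_NA else None
            down = parts[10] if len(parts) > 10 and parts[10] != _BED_NA else None
            preds.append(Prediction(
                scaffold=parts[0], start=start, end=end, id=parts[3],
                peak_score=score, amplitude=amp,
                methods=tuple(parts[6].split(",")) if parts[6] else (),
                training_sets=tuple(parts[7].split(",")) if parts[7] else (),
                upstream_gene=up, downstream_gene=down,
            ))
    return preds
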