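"""Target-gene and locus assignment plus ortholog joining.

A prediction's putative targets are its closest 5' and 3' flanking
genes, measured edge-to-edge in reference coordinates and ignoring
strand; genes overlapping the prediction are excluded from flanking
candidacy. The prediction's *locus* — the unit of the per-locus and
cross-species statistics — is the whole region between the flanking
genes; a prediction inside a gene takes the enclosing gene's full span,
and one overlapping two genes takes the combined span of both.

Ortholog joining annotates each flanking gene with its (possibly empty,
possibly many) D. melanogaster ortholog ids; it never changes the
predictions themselves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import FormatError
from .formats_io import Gene, GeneAnnotation, Genome
from .postprocess import Prediction

logger = logging.getLogger(__name__)


@dataclass
class LocusAssignment:
    prediction_id: str
    scaffold: str
    upstream_gene: str | None
    downstream_gene: str | None
    locus_start: int
    locus_end: int
    locus_kind: str  # intergenic | intronic | gene_overlap
    enclosing_genes: tuple[str, ...] = ()
    upstream_orthologs: frozenset[str] = frozenset()
    downstream_orthologs: frozenset[str] = frozenset()
    enclosing_orthologs: frozenset[str] = frozenset()

    @property
    def locus_key(self) -> tuple[str, int, int]:
        return (self.scaffold, self.locus_start, self.locus_end)

    @property
    def ortholog_keys(self) -> frozenset[str]:
        """Dmel ortholog ids keying this locus for cross-species
        comparison: the enclosing gene's orthologs for intronic or
        gene-overlap loci, otherwise those of either flanking gene."""
        if self.locus_kind != "intergenic" and self.enclosing_orthologs:
            return self.enclosing_orthologs
        return self.upstream_orthologs | self.downstream_orthologs


@dataclass
class OrthologTable:
    """Many-to-many mapping species gene id -> D. melanogaster gene id."""

    mapping: dict[str, frozenset[str]] = field(default_factory=dict)

    def orthologs(self, gene_id: str | None) -> frozenset[str]:
        if gene_id is None:
            return frozenset()
        return self.mapping.get(gene_id, frozenset())

    @property
    def n_genes(self) -> int:
        return len(self.mapping)


def read_ortholog_table(path: str | Path) -> OrthologTable:
    """Read a 2-column TSV (species gene id, Dmel gene id); an optional
    third confidence column is ignored; duplicate rows collapse."""
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected >=2 TSV columns")
            mapping.setdefault(parts[0], set()).add(parts[1])
    return OrthologTable(mapping={k: frozenset(v) for k, v in mapping.items()})


# ---------------------------------------------------------------------------


def closest_flanking_genes(pred: Prediction, annot: GeneAnnotation
                           ) -> tuple[Gene | None, Gene | None]:
    """Nearest non-overlapping genes 5' and 3' of the prediction.

    5' means gene end <= prediction start, 3' means gene start >=
    prediction end, in reference orientation. Genes overlapping the
    prediction are not flanking candidates. Equal-distance ties break
    toward the smaller gene start.
    """
    up: Gene | None = None
    down: Gene | None = None
    for g in annot.genes:
        if g.scaffold != pred.scaffold:
            continue
        if g.end > pred.start and g.start < pred.end:
            continue  # overlaps the prediction
        if g.end <= pred.start:
            if up is None or g.end > up.end or (g.end == up.end and g.start < up.start):
                up = g
        elif g.start >= pred.end:
            if down is None or g.start < down.start or (
                    g.start == down.start and g.end < down.end):
                down = g
    return up, down


def assign_locus(pred: Prediction, annot: GeneAnnotation,
                 genome: Genome | None = None,
                 scaffold_lengths: dict[str, int] | None = None) -> LocusAssignment:
    """Assign the prediction's locus per the flanking-gene rules.

    * overlaps no gene -> locus spans from the upstream gene's end to
      the downstream gene's start (clipped to scaffold bounds when a
      side is absent); kind ``intergenic``.
    * overlaps exactly one gene (e.g. sits in an intron) -> locus is the
      enclosing gene's full span; kind ``intronic``.
    * overlaps two or more genes -> locus is the combined span of all of
      them; kind ``gene_overlap``.
    """
    if scaffold_lengths is None:
        scaffold_lengths = genome.lengths if genome is not None else {}
    overlapping = [g for g in annot.genes
                   if g.scaffold == pred.scaffold
                   and g.end > pred.start and g.start < pred.end]
    up, down = closest_flanking_genes(pred, annot)
    scaffold_end = scaffold_lengths.get(pred.scaffold)

    if len(overlapping) >= 2:
        start = min(g.start for g in overlapping)
        end = max(g.end for g in overlapping)
        kind = "gene_overlap"
    elif len(overlapping) == 1:
        g = overlapping[0]
        start, end = g.start, g.end
        kind = "intronic"
    else:
        start = up.end if up is not None else 0
        if down is not None:
            end = down.start
        elif scaffold_end is not None:
            end = scaffold_end
        else:
            end = pred.end
        kind = "intergenic"
    if kind != "intergenic":
        # a prediction poking out of its gene(s) extends the locus to
        # the neighboring intergenic boundary, never to the prediction's
        # own coordinates: locus identity must be a pure function of the
        # gene geometry so that real and permuted predictions falling in
        # the same region share a locus key
        if pred.start < start:
            start = up.end if up is not None else 0
        if pred.end > end:
            if down is not None:
                end = down.start
            elif scaffold_end is not None:
                end = scaffold_end
            else:
                end = pred.end
    return LocusAssignment(
        prediction_id=pred.id,
        scaffold=pred.scaffold,
        upstream_gene=up.gene_id if up else None,
        downstream_gene=down.gene_id if down else None,
        locus_start=start,
        locus_end=end,
        locus_kind=kind,
        enclosing_genes=tuple(g.gene_id for g in overlapping),
    )


def assign_loci(preds: list[Prediction], annot: GeneAnnotation,
                scaffold_lengths: dict[str, int]) -> list[LocusAssignment]:
    return [assign_locus(p, annot, scaffold_lengths=scaffold_lengths) for p in preds]


def join_orthologs(assignments: list[LocusAssignment], table: OrthologTable
                   ) -> list[LocusAssignment]:
    """Annotate flanking genes with their Dmel ortholog sets.

    A pure annotation: coordinates and counts are untouched. A species
    gene absent from the table gets an empty set (counted in the
    unmapped fraction by :func:`mapped_fraction`).
    """
    out = []
    for a in assignments:
        enc: frozenset[str] = frozenset()
        for gid in a.enclosing_genes:
            enc = enc | table.orthologs(gid)
        out.append(replace(a,
                           upstream_orthologs=table.orthologs(a.upstream_gene),
                           downstream_orthologs=table.orthologs(a.downstream_gene),
                           enclosing_orthologs=enc))
    return out


def mapped_fraction(annot: GeneAnnotation, table: OrthologTable) -> float:
    """Fraction of annotated genes with at least one Dmel ortholog."""
    if not annot.genes:
        return float("nan")
    mapped = sum(1 for g in annot.genes if table.orthologs(g.gene_id))
    return mapped / len(annot.genes)


class LocusIndex:
    """Vectorized batch locus assignment over a fixed annotation.

    Precomputes per-scaffold gene arrays so that the permutation tests
    can re-assign thousands of shuffled intervals cheaply. Produces
    assignments identical to :func:`assign_locus` (including tie
    breaks), which serves as the reference implementation.
    """

    def __init__(self, annot: GeneAnnotation, scaffold_lengths: dict[str, int]):
        self.scaffold_lengths = dict(scaffold_lengths)
        self._genes: dict[str, tuple] = {}
        for sid, genes in annot.genes_by_scaffold().items():
            gs = np.array([g.start for g in genes], dtype=np.int64)
            ge = np.array([g.end for g in genes], dtype=np.int64)
            ids = [g.gene_id for g in genes]
            self._genes[sid] = (gs, ge, ids)

    def assign(self, scaffold: str, starts, ends, ids=None) -> list[LocusAssignment]:
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        P = len(starts)
        if ids is None:
            ids = [f"iv_{i}" for i in range(P)]
        slen = self.scaffold_lengths.get(scaffold)
        if scaffold not in self._genes:
            return [LocusAssignment(ids[i], scaffold, None, None, 0,
                                    slen if slen is not None else int(ends[i]),
                                    "intergenic") for i in range(P)]
        gs, ge, gids = self._genes[scaffold]
        G = len(gs)
        ov = (gs[None, :] < ends[:, None]) & (ge[None, :] > starts[:, None])
        n_ov = ov.sum(axis=1)
        # flanking candidates exclude overlapping genes
        K = np.int64(max(int(ge.max()), int(gs.max())) + 2) if G else np.int64(2)
        up_mask = (ge[None, :] <= starts[:, None])
        down_mask = (gs[None, :] >= ends[:, None])
        # upstream: max end, ties -> smaller start
        up_key = np.where(up_mask, ge[None, :] * K - gs[None, :], np.int64(-1))
        up_idx = up_key.argmax(axis=1)
        has_up = up_key.max(axis=1) >= 0
        # downstream: min start, ties -> smaller end
        down_key = np.where(down_mask, gs[None, :] * K + ge[None, :],
                            np.iinfo(np.int64).max)
        down_idx = down_key.argmin(axis=1)
        has_down = down_key.min(axis=1) < np.iinfo(np.int64).max

        ov_start = np.where(ov, gs[None, :], np.iinfo(np.int64).max).min(axis=1)
        ov_end = np.where(ov, ge[None, :], np.int64(-1)).max(axis=1)

        out: list[LocusAssignment] = []
        for i in range(P):
            if n_ov[i] >= 1:
                ls, le = int(ov_start[i]), int(ov_end[i])
                kind = "gene_overlap" if n_ov[i] >= 2 else "intronic"
                enc = tuple(gids[j] for j in np.nonzero(ov[i])[0])
                # extend to intergenic boundaries, not to the prediction
                if starts[i] < ls:
                    ls = int(ge[up_idx[i]]) if has_up[i] else 0
                if ends[i] > le:
                    if has_down[i]:
                        le = int(gs[down_idx[i]])
                    elif slen is not None:
                        le = slen
                    else:
                        le = int(ends[i])
            else:
                ls = int(ge[up_idx[i]]) if has_up[i] else 0
                if has_down[i]:
                    le = int(gs[down_idx[i]])
                elif slen is not None:
                    le = slen
                else:
                    le = int(ends[i])
                kind = "intergenic"
                enc = ()
            out.append(LocusAssignment(
                prediction_id=ids[i],
                scaffold=scaffold,
                upstream_gene=gids[int(up_idx[i])] if has_up[i] else None,
                downstream_gene=gids[int(down_idx[i])] if has_down[i] else None,
                locus_start=ls, locus_end=le, locus_kind=kind,
                enclosing_genes=enc,
            ))
        return out

    def assign_intervals(self, intervals) -> list[LocusAssignment]:
        """Assign loci to (scaffold, start, end[, id]) tuples, preserving order."""
        by_scaf: dict[str, list[int]] = {}
        for i, iv in enumerate(intervals):
            by_scaf.setdefault(iv[0], []).append(i)
        result: list[LocusAssignment | None] = [None] * len(intervals)
        for sid, idxs in by_scaf.items():
            starts = [intervals[i][1] for i in idxs]
            ends = [intervals[i][2] for i in idxs]
            ids = [intervals[i][3] if len(intervals[i]) > 3 else f"iv_{i}"
                   for i in idxs]
            for j, a in zip(idxs, self.assign(sid, starts, ends, ids)):
                result[j] = a
        return list(result)  # type: ignore[arg-type]


def attach_flanks(preds: list[Prediction], assignments: list[LocusAssignment]
                  ) -> list[Prediction]:
    """Copy flanking-gene ids onto predictions for modified-BED output."""
    by_id = {a.prediction_id: a for a in assignments}
    out = []
    for p in preds:
        a = by_id.get(p.id)
        if a is None:
            out.append(p)
        else:
            out.append(replace(p, upstream_gene=a.upstream_gene,
                               downstream_gene=a.downstream_gene))
    return out
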