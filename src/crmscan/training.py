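"""Training-set assembly: known-enhancer FASTA plus a ~10x background.

A training set pairs a curated collection of functionally related
enhancers (e.g. all known wing-disc enhancers) with a roughly ten-fold
larger set of similarly sized non-enhancer sequences that defines the
null kmer distribution. Curated backgrounds shipped with a training set
take precedence; :func:`sample_background` exists to build backgrounds
for synthetic fixtures by drawing from a genome's non-coding space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import FormatError
from .formats_io import Genome, GeneAnnotation, read_fasta

logger = logging.getLogger(__name__)

TARGET_BG_RATIO = 10.0


@dataclass
class TrainingSet:
    name: str
    enhancers: list[str]
    background: list[str]

    @property
    def bg_ratio(self) -> float:
        return len(self.background) / len(self.enhancers)


def load_training_set(enh_fasta: str | Path, bg_fasta: str | Path, name: str) -> TrainingSet:
    """Load the enhancer and background FASTA pair for one training set.

    The background:enhancer count ratio is logged; a warning is emitted
    when it deviates from the 10-fold design by more than a factor of 2.
    An empty enhancer file is a hard error.
    """
    enh = [s for _, s in _records(enh_fasta)]
    bg = [s for _, s in _records(bg_fasta)]
    if not enh:
        raise FormatError(f"training set {name!r}: enhancer file {enh_fasta} is empty")
    ts = TrainingSet(name=name, enhancers=enh, background=bg)
    ratio = ts.bg_ratio
    logger.info("training set %s: %d enhancers, %d background (ratio %.1f)",
                name, len(enh), len(bg), ratio)
    if not (TARGET_BG_RATIO / 2 <= ratio <= TARGET_BG_RATIO * 2):
        logger.warning("training set %s: background ratio %.1f deviates from the "
                       "10-fold design by >2x", name, ratio)
    return ts


def _records(path: str | Path):
    genome = read_fasta(path)
    return list(genome.scaffolds.items())


def sample_background(genome: Genome, annot: GeneAnnotation, lengths: Sequence[int],
                      n: int, seed: int) -> list[str]:
    """Draw n non-coding sequences with lengths sampled from ``lengths``.

    Each sequence is placed uniformly over the genome's non-exonic space
    (sampling of positions is with replacement, so backgrounds may
    overlap each other). Deterministic under a fixed seed.
    """
    if n == 0:
        return []
    if not lengths:
        raise ValueError("no lengths supplied")
    rng = np.random.default_rng(seed)
    exons = annot.exon_intervals()

    # eligible gaps (scaffold, start, end) in non-exonic space
    gaps: list[tuple[str, int, int]] = []
    for sid, seq in genome.scaffolds.items():
        prev = 0
        for s, e in exons.get(sid, np.empty((0, 2), dtype=np.int64)):
            if s > prev:
                gaps.append((sid, prev, int(s)))
            prev = max(prev, int(e))
        if len(seq) > prev:
            gaps.append((sid, prev, len(seq)))

    chosen_lengths = rng.choice(np.asarray(lengths), size=n, replace=True)
    total_gap = sum(e - s for _, s, e in gaps)
    if total_gap < int(chosen_lengths.sum()):
        raise ValueError(
            f"insufficient non-coding space: have {total_gap} bp, "
            f"need {int(chosen_lengths.sum())} bp")

    out: list[str] = []
    for L in chosen_lengths:
        L = int(L)
        starts = np.array([max(0, (e - s) - L + 1) for _, s, e in gaps], dtype=np.float64)
        if starts.sum() == 0:
            raise ValueError(f"no non-coding gap can hold a {L} bp sequence")
        gi = rng.choice(len(gaps), p=starts / starts.sum())
        sid, gs, ge = gaps[gi]
        pos = gs + int(rng.integers(0, (ge - gs) - L + 1))
        out.append(genome.scaffolds[sid][pos:pos + L].upper())
    return out
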