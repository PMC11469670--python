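"""High-density genome scan: 500-bp windows at effective 10-bp spacing.

The scan is organized as 25 staggered instances. Instance ``lb`` scores
windows starting at lb, lb+250, lb+500, ... so the union over the
offsets 0, 10, ..., 240 tiles every 10-bp start position exactly once.
Each instance is an independent unit of work whose top-N windows feed
post-processing.

Scoring is vectorized: a trained pair reduces to a per-word additive
contribution table (see :mod:`crmscan.models`), so a scaffold is scored
with one table lookup pass and a prefix sum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .formats_io import Genome
from .models import ModelPair, encode, kmer_ids

logger = logging.getLogger(__name__)


@dataclass
class ScanConfig:
    window_w: int = 500
    resolution: int = 10
    stride: int = 250
    n_top: int = 5000  # the 'thiwt' retention count per instance
    max_n_fraction: float = 0.5  # windows with more N than this are skipped

    def __post_init__(self) -> None:
        if self.stride % self.resolution != 0:
            raise ValueError("resolution must divide the intra-instance stride")

    @property
    def instance_offsets(self) -> list[int]:
        return list(range(0, self.stride, self.resolution))


@dataclass
class WindowScoreSet:
    method: str
    training_set: str
    lb: int
    records: list[tuple[str, int, float]] = field(default_factory=list)

    def scores(self) -> np.ndarray:
        return np.array([r[2] for r in self.records], dtype=np.float64)


def enumerate_windows(genome: Genome, cfg: ScanConfig, lb: int) -> list[tuple[str, int]]:
    """Window start positions for one instance offset.

    Starts are lb, lb+stride, ... while the full window fits on the
    scaffold; a scaffold shorter than the window yields no windows.
    """
    if lb not in cfg.instance_offsets:
        raise ValueError(f"lb={lb} is not one of the configured instance offsets")
    out: list[tuple[str, int]] = []
    for sid, seq in genome.scaffolds.items():
        L = len(seq)
        if L < cfg.window_w:
            logger.info("scaffold %s (%d bp) shorter than window; skipped", sid, L)
            continue
        for start in range(lb, L - cfg.window_w + 1, cfg.stride):
            out.append((sid, start))
    return out


def scan_genome(genome: Genome, pair: ModelPair, cfg: ScanConfig, lb: int,
                training_set: str = "") -> WindowScoreSet:
    """Score every enumerated window of one instance.

    Windows with more than ``max_n_fraction`` ambiguous (N) bases are
    omitted. The result is deterministic and identical to calling
    :func:`crmscan.models.score_window` on each window.
    """
    k = pair.word_len
    table = pair.contrib_table()
    ws = WindowScoreSet(method=pair.method, training_set=training_set, lb=lb)
    w = cfg.window_w
    for sid, seq in genome.scaffolds.items():
        L = len(seq)
        if L < w:
            continue
        codes = encode(seq)
        ids, valid = kmer_ids(codes, k)
        contrib = np.where(valid, table[ids], 0.0)
        cum = np.concatenate([[0.0], np.cumsum(contrib)])
        n_cum = np.concatenate([[0], np.cumsum(codes < 0)])
        starts = np.arange(lb, L - w + 1, cfg.stride)
        if len(starts) == 0:
            continue
        n_frac = (n_cum[starts + w] - n_cum[starts]) / w
        scores = cum[starts + w - k + 1] - cum[starts]
        for s, sc, nf in zip(starts, scores, n_frac):
            if nf > cfg.max_n_fraction:
                continue
            ws.records.append((sid, int(s), float(sc)))
    return ws


def top_n(ws: WindowScoreSet, n_top: int) -> WindowScoreSet:
    """Retain windows scoring at least the n_top-th ranked score.

    The threshold is a score value, not a count: ties at the cutoff are
    all retained. With fewer than n_top windows everything is kept.
    """
    if len(ws.records) <= n_top:
        if len(ws.records) < n_top:
            logger.info("instance lb=%d has %d < %d windows; all retained",
                        ws.lb, len(ws.records), n_top)
        return WindowScoreSet(ws.method, ws.training_set, ws.lb, list(ws.records))
    scores = ws.scores()
    cutoff = np.sort(scores)[::-1][n_top - 1]
    kept = [r for r in ws.records if r[2] >= cutoff]
    return WindowScoreSet(ws.method, ws.training_set, ws.lb, kept)
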