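"""From per-instance window scores to final compact enhancer predictions.

The pipeline is: (1) per instance, keep the top-N windows and zero
everything below the elbow of the surviving sorted score curve; (2) pool
all instances into a per-scaffold 10-bp tile profile (tile value = max
surviving-window score covering the tile); (3) call peaks on the
profile, measuring each peak's amplitude as its height above the higher
of its two bounding valleys (group edges count as zero-valleys); (4)
keep peaks whose amplitude exceeds the elbow of the sorted amplitude
curve; (5) merge overlapping/abutting predictions across methods and
training sets; (6) drop length outliers above the Tukey upper fence
(Q3 + 1.5*IQR).

The elbow-zeroing step is what keeps predictions compact: it prevents
runs of adjacent low-scoring windows from concatenating into one broad
element.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .scan import ScanConfig, WindowScoreSet, top_n

logger = logging.getLogger(__name__)


@dataclass
class Prediction:
    """A final called enhancer interval (0-based half-open)."""

    scaffold: str
    start: int
    end: int
    peak_score: float
    amplitude: float
    methods: tuple[str, ...]
    training_sets: tuple[str, ...]
    id: str = ""
    upstream_gene: str | None = None
    downstream_gene: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TileProfile:
    scaffold: str
    origin: int
    resolution: int
    values: np.ndarray


@dataclass
class Peak:
    scaffold: str
    peak_tile: int  # absolute tile index (leftmost tile of a plateau)
    peak_score: float
    amplitude: float
    left_bound: int  # prediction extent in tiles, half-open
    right_bound: int
    group_bounds: tuple[int, int]


# ---------------------------------------------------------------------------
# Elbow thresholding


def elbow_index(sorted_desc: np.ndarray) -> int:
    """Index of maximum perpendicular distance from the first-last chord.

    Expects a descending-sorted curve of length >= 3. Ties break toward
    the smaller index; an exactly linear curve returns the last index
    (so that thresholding at the elbow has no effect).
    """
    y = np.asarray(sorted_desc, dtype=np.float64)
    n = len(y)
    if n < 3:
        raise ValueError("elbow needs at least 3 points")
    x = np.arange(n, dtype=np.float64)
    # |cross product| of (P1-P0) with (Pi-P0); normalization is constant
    d = np.abs((n - 1) * (y - y[0]) - x * (y[-1] - y[0]))
    scale = max(np.abs(y[0] - y[-1]), 1.0)
    if d.max() <= 1e-9 * scale * (n - 1):
        return n - 1
    return int(np.argmax(d))


def elbow_keep_count(values: np.ndarray) -> int | None:
    """Number of top-ranked values retained by elbow thresholding.

    The retained set is the ranks strictly before the elbow index of
    the descending sorted curve (the elbow point itself and everything
    below it are suppressed). Returns None when no thresholding applies:
    fewer than 3 values, or an exactly linear curve, whose elbow is
    degenerate and where filtering would have no principled effect.
    """
    v = np.sort(np.asarray(values, dtype=np.float64))[::-1]
    if len(v) < 3:
        logger.info("only %d values; elbow thresholding skipped", len(v))
        return None
    idx = elbow_index(v)
    # the chord distance vanishes at both endpoints, so the argmax can
    # only land on the last index when the curve is exactly linear
    if idx == len(v) - 1:
        return None
    return idx


def instance_filter(ws: WindowScoreSet, n_top: int) -> WindowScoreSet:
    """Top-N rank threshold, then elbow zeroing, for one scan instance.

    Windows below the n_top-th ranked score are eliminated; the elbow of
    the surviving sorted score curve is then found and every score at or
    below it is reset to zero (suppressed windows are simply dropped — a
    zero tile value and an absent window are equivalent downstream).
    Ties at the elbow break deterministically by genomic position.

    Surviving scores are re-expressed as height above the elbow cut
    value: the elbow is the instance's adaptive noise threshold, so the
    retained evidence for a window is its score in excess of that
    threshold. This keeps the downstream zero-baseline profile
    meaningful regardless of the absolute scale of the log-likelihood
    ratios (which is training-set dependent).
    """
    kept = top_n(ws, n_top)
    if len(kept.records) < 3:
        return kept
    n_keep = elbow_keep_count(kept.scores())
    if n_keep is None:
        return kept
    ranked = sorted(kept.records, key=lambda r: (-r[2], r[0], r[1]))
    cut = ranked[n_keep][2]  # score of the first suppressed window
    survivors = sorted((sid, start, score - cut)
                       for sid, start, score in ranked[:n_keep] if score > cut)
    return WindowScoreSet(ws.method, ws.training_set, ws.lb, survivors)


# ---------------------------------------------------------------------------
# Tile profile and peak calling


def build_tile_profile(instances: list[WindowScoreSet], cfg: ScanConfig,
                       scaffold_lengths: dict[str, int]) -> list[TileProfile]:
    """Pool surviving windows of all instances into per-scaffold profiles.

    Tile t covers [t*res, (t+1)*res); its value is the maximum surviving
    window score among windows overlapping it (max, not sum, so adjacent
    mediocre windows cannot pile up into a broad high region).
    """
    methods = {ws.method for ws in instances}
    tsets = {ws.training_set for ws in instances}
    if len(methods) > 1 or len(tsets) > 1:
        raise ValueError("all instances must share one method and training set")
    res, w = cfg.resolution, cfg.window_w
    profiles: dict[str, np.ndarray] = {}
    for ws in instances:
        for sid, start, score in ws.records:
            if sid not in profiles:
                n_tiles = -(-scaffold_lengths[sid] // res)
                profiles[sid] = np.zeros(n_tiles, dtype=np.float64)
            a = start // res
            b = -(-(start + w) // res)
            arr = profiles[sid]
            np.maximum(arr[a:b], score, out=arr[a:b])
    return [TileProfile(scaffold=sid, origin=0, resolution=res, values=vals)
            for sid, vals in sorted(profiles.items())]


def call_peaks(profile: TileProfile) -> list[Peak]:
    """Peak calling with topographic prominence within nonzero groups.

    Contiguous nonzero runs form groups. Peaks are local maxima (a
    plateau counts once, apex at its leftmost tile). A peak's amplitude
    is its value minus the higher of its two bounding valleys, where
    group edges count as valleys of value 0. Prediction extents split
    each group at the valley tiles (valley tile assigned to the
    right-hand peak), so two peaks in one group abut at their valley.
    """
    v = profile.values
    peaks: list[Peak] = []
    n = len(v)
    i = 0
    while i < n:
        if v[i] <= 0:
            i += 1
            continue
        j = i
        while j < n and v[j] > 0:
            j += 1
        peaks.extend(_group_peaks(profile, i, j))
        i = j
    return peaks


def _group_peaks(profile: TileProfile, g0: int, g1: int) -> list[Peak]:
    v = profile.values[g0:g1]
    n = len(v)
    apexes: list[int] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        left_ok = i == 0 or v[i - 1] < v[i]
        right_ok = j == n - 1 or v[j + 1] < v[i]
        if left_ok and right_ok:
            apexes.append(i)  # leftmost tile of the plateau
        i = j + 1
    # valleys between consecutive apexes: leftmost minimum tile
    valleys: list[int] = []
    for a, b in zip(apexes, apexes[1:]):
        seg = v[a + 1:b]
        valleys.append(a + 1 + int(np.argmin(seg)))
    out: list[Peak] = []
    for idx, a in enumerate(apexes):
        lv = v[valleys[idx - 1]] if idx > 0 else 0.0
        rv = v[valleys[idx]] if idx < len(valleys) else 0.0
        left = valleys[idx - 1] if idx > 0 else 0
        right = valleys[idx] if idx < len(valleys) else n
        out.append(Peak(
            scaffold=profile.scaffold,
            peak_tile=g0 + a,
            peak_score=float(v[a]),
            amplitude=float(v[a] - max(lv, rv)),
            left_bound=g0 + left,
            right_bound=g0 + right,
            group_bounds=(g0, g1),
        ))
    return out


def amplitude_filter(peaks: list[Peak], cfg: ScanConfig, method: str = "",
                     training_set: str = "") -> list[Prediction]:
    """Keep peaks above the elbow of the genome-wide amplitude curve.

    With fewer than 3 peaks no thresholding applies. Retained peaks
    become predictions spanning valley to valley, snapped to the tile
    grid.
    """
    if not peaks:
        return []
    if len(peaks) < 3:
        logger.info("only %d peaks; amplitude thresholding skipped", len(peaks))
        retained = peaks
    else:
        n_keep = elbow_keep_count(np.array([p.amplitude for p in peaks]))
        if n_keep is None:
            retained = peaks
        else:
            ranked = sorted(peaks, key=lambda p: (-p.amplitude, p.scaffold, p.peak_tile))
            retained = ranked[:n_keep]
    res = cfg.resolution
    preds = []
    for i, p in enumerate(sorted(retained, key=lambda p: (p.scaffold, p.peak_tile))):
        preds.append(Prediction(
            scaffold=p.scaffold,
            start=p.left_bound * res,
            end=p.right_bound * res,
            peak_score=p.peak_score,
            amplitude=p.amplitude,
            methods=(method,) if method else (),
            training_sets=(training_set,) if training_set else (),
            id=f"{method or 'pred'}_{training_set or 'na'}_{i}",
        ))
    return preds


# ---------------------------------------------------------------------------
# Merging and outlier removal


def merge_predictions(pred_sets: list[list[Prediction]]) -> list[Prediction]:
    """Union overlapping or abutting predictions across methods/sets.

    The merged record carries the maximum peak score and amplitude and
    the union of method and training-set labels.
    """
    flat = [p for ps in pred_sets for p in ps]
    flat.sort(key=lambda p: (p.scaffold, p.start, p.end))
    out: list[Prediction] = []
    for p in flat:
        if out and out[-1].scaffold == p.scaffold and p.start <= out[-1].end:
            prev = out[-1]
            out[-1] = replace(
                prev,
                end=max(prev.end, p.end),
                peak_score=max(prev.peak_score, p.peak_score),
                amplitude=max(prev.amplitude, p.amplitude),
                methods=tuple(sorted(set(prev.methods) | set(p.methods))),
                training_sets=tuple(sorted(set(prev.training_sets) | set(p.training_sets))),
            )
        else:
            out.append(replace(p))
    for i, p in enumerate(out):
        out[i] = replace(p, id=f"merged_{i}")
    return out


def length_outlier_filter(preds: list[Prediction]) -> tuple[list[Prediction], int]:
    """Drop predictions longer than the Tukey upper fence Q3 + 1.5*IQR.

    Quantiles use linear interpolation. With fewer than 4 predictions
    the filter is a no-op. Returns (kept predictions, number dropped).
    """
    if len(preds) < 4:
        return list(preds), 0
    lengths = np.array([p.length for p in preds], dtype=np.float64)
    q1, q3 = np.percentile(lengths, [25, 75])
    fence = q3 + 1.5 * (q3 - q1)
    kept = [p for p in preds if p.length <= fence]
    n_dropped = len(preds) - len(kept)
    if n_dropped:
        logger.info("length outlier filter dropped %d of %d predictions "
                    "(fence %.0f bp)", n_dropped, len(preds), fence)
    return kept, n_dropped


# ---------------------------------------------------------------------------
# Orchestration


def run_postprocess(instances: list[WindowScoreSet], cfg: ScanConfig,
                    scaffold_lengths: dict[str, int]) -> list[Prediction]:
    """Full post-processing for one method + training set."""
    if not instances:
        return []
    method = instances[0].method
    tset = instances[0].training_set
    filtered = [instance_filter(ws, cfg.n_top) for ws in instances]
    profiles = build_tile_profile(filtered, cfg, scaffold_lengths)
    peaks = [pk for prof in profiles for pk in call_peaks(prof)]
    return amplitude_filter(peaks, cfg, method=method, training_set=tset)
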