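"""The three discriminative kmer scoring methods: IMM, hexMCD and PAC-rc.

Each method fits a generative model to the training (known enhancer)
sequences and an identically parameterized model to the ~10x larger
background set; a candidate window is scored by the log-likelihood ratio
of the two. All counting is double-stranded (each sequence contributes
its forward and reverse-complement kmers) so that scores are strand
symmetric even though windows are scored on the forward strand only.

* hexMCD — a fifth-order Markov chain over 6-mers with one-away-mismatch
  count smoothing (weight ``gamma``) to de-sparsify rare contexts.
* IMM — an interpolated Markov model blending chains of orders 0..5 with
  Glimmer-style data-dependent weights (count threshold ``C`` plus a
  chi-square confidence for sparse contexts).
* PAC-rc — Poisson word-count overrepresentation of reverse-complement
  collapsed 6-mer classes (2080 classes).

Internally each trained pair reduces to a flat per-word additive
contribution table, which makes genome scanning a table lookup plus a
sliding sum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import chi2 as _chi2

from .errors import FormatError

METHODS = ("imm", "hexmcd", "pacrc")

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMP = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def encode(seq: str) -> np.ndarray:
    """Encode DNA to int8 codes A=0 C=1 G=2 T=3, anything else -1."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def kmer_ids(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-start kmer ids (base-4, first base most significant) and a
    validity mask (False where the word contains a non-ACGT code)."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (win >= 0).all(axis=1)
    pows = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    ids = (win.astype(np.int64) * pows).sum(axis=1)
    ids[~valid] = 0
    return ids, valid


def _count_words(seqs: Sequence[str], k: int, both_strands: bool = True) -> np.ndarray:
    """Count k-words over sequences (and their reverse complements)."""
    counts = np.zeros(4 ** k, dtype=np.int64)
    for seq in seqs:
        for s in ((seq, revcomp(seq)) if both_strands else (seq,)):
            ids, valid = kmer_ids(encode(s), k)
            if valid.any():
                counts += np.bincount(ids[valid], minlength=4 ** k)
    return counts


# ---------------------------------------------------------------------------
# Kmer count container (public counting op)


@dataclass
class KmerCounts:
    k: int
    counts: dict[str, int]
    total: int
    strand_mode: str = "both_strands"


def _id_to_word(i: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[i % 4])
        i //= 4
    return "".join(reversed(out))


def count_kmers(seqs: Sequence[str], k: int) -> KmerCounts:
    """Count kmers over sequences and their reverse complements.

    Words containing N (or any non-ACGT character) are skipped; a
    sequence shorter than k contributes nothing.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    arr = _count_words(seqs, k, both_strands=True)
    nz = np.nonzero(arr)[0]
    counts = {_id_to_word(int(i), k): int(arr[i]) for i in nz}
    return KmerCounts(k=k, counts=counts, total=int(arr.sum()))


# ---------------------------------------------------------------------------
# Markov chain (plain and mismatch-smoothed, the hexMCD building block)


@dataclass
class MarkovChainModel:
    """Order-m Markov chain with Laplace and optional mismatch smoothing.

    ``transition[c, b]`` is P(base b | context c) where context ids are
    base-4 with the earliest base most significant. The smoothed
    numerator is ``n(cb) + gamma * mm(cb) + alpha`` where ``mm`` sums the
    counts of all (m+1)-words at Hamming distance 1 from ``cb``.
    """

    order: int
    transition: np.ndarray  # (4^m, 4)
    context_counts: np.ndarray  # (4^m,)
    alpha: float = 1.0
    gamma: float = 0.0

    def log_prob_table(self) -> np.ndarray:
        """log P flattened over all (m+1)-words."""
        return np.log(self.transition).ravel()


def _mismatch_sums(counts: np.ndarray, k: int) -> np.ndarray:
    """For each k-word, the summed count of its 3k Hamming-1 neighbors."""
    grid = counts.reshape((4,) * k).astype(np.float64)
    total = np.zeros_like(grid)
    for axis in range(k):
        total += grid.sum(axis=axis, keepdims=True) - grid
    return total.reshape(-1)


def fit_markov(seqs: Sequence[str], order: int, alpha: float = 1.0,
               gamma: float = 0.0) -> MarkovChainModel:
    """Fit an order-m chain from double-stranded (m+1)-word counts."""
    if order < 0:
        raise ValueError("order must be >= 0")
    k = order + 1
    n = _count_words(seqs, k).astype(np.float64)
    num = n + alpha
    if gamma > 0:
        num = num + gamma * _mismatch_sums(n, k)
    num = num.reshape(4 ** order, 4)
    trans = num / num.sum(axis=1, keepdims=True)
    ctx = n.reshape(4 ** order, 4).sum(axis=1)
    return MarkovChainModel(order=order, transition=trans, context_counts=ctx,
                            alpha=alpha, gamma=gamma)


def fit_hexmcd(seqs: Sequence[str], alpha: float = 1.0, gamma: float = 0.1) -> MarkovChainModel:
    """The hexMCD component model: order-5 chain smoothed over one-away
    6-mer mismatches."""
    return fit_markov(seqs, order=5, alpha=alpha, gamma=gamma)


# ---------------------------------------------------------------------------
# Interpolated Markov model (Glimmer-style)


@dataclass
class IMMModel:
    """IMM combining chains of orders 0..max_order.

    Interpolation weight for a context c at order m is 1 when the
    context was seen at least ``C`` times; for sparser contexts a
    chi-square comparison of the order-m base distribution against the
    order-(m-1) interpolated prediction yields a confidence that scales
    the weight by count/C, and contexts never seen fall back entirely.
    """

    max_order: int
    C: float
    alpha: float
    interpolated: np.ndarray  # (4^max_order, 4): P_imm(b | full context)
    order_counts: list[np.ndarray] = field(default_factory=list, repr=False)

    def log_prob_table(self) -> np.ndarray:
        return np.log(self.interpolated).ravel()


def fit_imm(seqs: Sequence[str], max_order: int = 5, C: float = 400.0,
            alpha: float = 1.0) -> IMMModel:
    order_counts = [_count_words(seqs, m + 1).astype(np.float64)
                    for m in range(max_order + 1)]
    # Laplace-smoothed per-order conditionals
    p_imm = None
    for m, n in enumerate(order_counts):
        nm = n.reshape(4 ** m, 4)
        ctx = nm.sum(axis=1)
        p_hat = (nm + alpha) / (nm + alpha).sum(axis=1, keepdims=True)
        if m == 0:
            p_imm = p_hat
            continue
        suffix = np.arange(4 ** m) % (4 ** (m - 1))
        p_lower = p_imm[suffix]
        lam = np.zeros(4 ** m)
        seen = ctx > 0
        full = ctx >= max(C, 1.0)
        lam[full & seen] = 1.0
        sparse = seen & ~full
        if sparse.any() and C > 0:
            exp = ctx[sparse, None] * p_lower[sparse]
            stat = ((nm[sparse] - exp) ** 2 / exp).sum(axis=1)
            conf = _chi2.cdf(stat, df=3)
            w = np.where(conf < 0.5, 0.0, conf * ctx[sparse] / C)
            lam[sparse] = np.minimum(w, 1.0)
        p_imm = lam[:, None] * p_hat + (1.0 - lam)[:, None] * p_lower
    return IMMModel(max_order=max_order, C=C, alpha=alpha,
                    interpolated=p_imm, order_counts=order_counts)


# ---------------------------------------------------------------------------
# PAC-rc: Poisson word overrepresentation on revcomp-collapsed 6-mers


def _rc_ids(k: int) -> np.ndarray:
    """Reverse-complement word id for every k-word id."""
    ids = np.arange(4 ** k, dtype=np.int64)
    rc = np.zeros_like(ids)
    tmp = ids.copy()
    for _ in range(k):
        rc = rc * 4 + (3 - tmp % 4)
        tmp //= 4
    return rc


def _class_map(k: int = 6) -> np.ndarray:
    """Map each k-word id to its reverse-complement-collapsed class id
    (the smaller of the word id and its revcomp id)."""
    ids = np.arange(4 ** k, dtype=np.int64)
    return np.minimum(ids, _rc_ids(k))


_CLASS_MAP6 = _class_map(6)
N_CLASSES6 = len(np.unique(_CLASS_MAP6))  # 2080


@dataclass
class PoissonWordModel:
    """Per-position occurrence rates of the 2080 revcomp 6-mer classes.

    ``word_rates[w]`` is the rate of the class containing 6-mer w, so a
    window's class-count statistics reduce to per-position lookups.
    """

    k: int
    word_rates: np.ndarray  # (4^k,) rate of class(word)
    pseudocount: float
    total_positions: float

    @property
    def class_rates(self) -> np.ndarray:
        return self.word_rates[np.unique(_CLASS_MAP6)]


def fit_pacrc(seqs: Sequence[str], pseudocount: float = 1.0) -> PoissonWordModel:
    """Fit class rates lambda = (class count + pc) / (positions + pc * n_classes).

    Counting is forward strand only; the revcomp collapse itself
    provides strand symmetry (a palindromic 6-mer forms a class of one,
    so its class count equals its plain count).
    """
    word_counts = _count_words(seqs, 6, both_strands=False).astype(np.float64)
    class_counts = np.bincount(_CLASS_MAP6, weights=word_counts, minlength=4 ** 6)
    total = word_counts.sum()
    denom = total + pseudocount * N_CLASSES6
    rates_per_word_class = (class_counts + pseudocount) / denom
    # class_counts is indexed by word id but only class-representative
    # entries are meaningful; broadcast back through the class map
    word_rates = rates_per_word_class[_CLASS_MAP6]
    return PoissonWordModel(k=6, word_rates=word_rates, pseudocount=pseudocount,
                            total_positions=total)


# ---------------------------------------------------------------------------
# Model pair + scoring


@dataclass
class ModelPair:
    """A trained (training, background) model pair for one method."""

    method: str
    train_model: object
    bg_model: object
    _contrib: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")

    @property
    def word_len(self) -> int:
        if self.method == "pacrc":
            return 6
        if self.method == "imm":
            return self.train_model.max_order + 1
        return self.train_model.order + 1

    def contrib_table(self) -> np.ndarray:
        """Additive per-word score contribution.

        For the Markov scorers this is the per-position conditional
        log-likelihood ratio; for PAC-rc it is the class log-rate ratio
        minus the per-position Poisson mean difference, so that a window
        score is exactly the summed log Poisson pmf ratio over classes.

        The table is symmetrized over reverse complements (each word's
        contribution is averaged with its revcomp's), which makes every
        scorer exactly strand invariant while still scanning the
        forward strand only. PAC-rc's class collapse already has this
        property; for the Markov scorers it averages the two strand
        likelihood ratios.
        """
        if self._contrib is None:
            if self.method == "pacrc":
                lt = self.train_model.word_rates
                lb = self.bg_model.word_rates
                cls = np.unique(_CLASS_MAP6)
                d = float(self.train_model.word_rates[cls].sum()
                          - self.bg_model.word_rates[cls].sum())
                table = np.log(lt / lb) - d
            else:
                table = (self.train_model.log_prob_table()
                         - self.bg_model.log_prob_table())
            rc = _rc_ids(self.word_len)
            self._contrib = 0.5 * (table + table[rc])
        return self._contrib


def train_model_pair(method: str, train_seqs: Sequence[str], bg_seqs: Sequence[str],
                     **params) -> ModelPair:
    """Fit the training/background pair for one method with shared parameters."""
    if method == "imm":
        fit = lambda s: fit_imm(s, **params)
    elif method == "hexmcd":
        fit = lambda s: fit_hexmcd(s, **params)
    elif method == "pacrc":
        fit = lambda s: fit_pacrc(s, **params)
    else:
        raise ValueError(f"unknown method {method!r}")
    return ModelPair(method=method, train_model=fit(train_seqs), bg_model=fit(bg_seqs))


def score_window(pair: ModelPair, window: str) -> float:
    """Log-likelihood-ratio score of one window under a trained pair.

    Positions whose word contains N are skipped. Returns NaN for a
    window shorter than the model word length (the undefined-score
    sentinel, excluded downstream).
    """
    k = pair.word_len
    if len(window) < k:
        return float("nan")
    ids, valid = kmer_ids(encode(window), k)
    table = pair.contrib_table()
    return float(table[ids[valid]].sum())


def score_markov(pair: ModelPair, window: str) -> float:
    if pair.method not in ("hexmcd",):
        raise ValueError("score_markov expects a hexmcd pair")
    return score_window(pair, window)


def score_imm(pair: ModelPair, window: str) -> float:
    if pair.method != "imm":
        raise ValueError("score_imm expects an imm pair")
    return score_window(pair, window)


def score_pacrc(pair: ModelPair, window: str) -> float:
    if pair.method != "pacrc":
        raise ValueError("score_pacrc expects a pacrc pair")
    return score_window(pair, window)


# ---------------------------------------------------------------------------
# Serialization

_FORMAT_VERSION = 1


def save_model_pair(pair: ModelPair, path: str | Path) -> None:
    def pack(model):
        if pair.method == "pacrc":
            return {"k": model.k, "word_rates": model.word_rates.tolist(),
                    "pseudocount": model.pseudocount,
                    "total_positions": model.total_positions}
        if pair.method == "imm":
            return {"max_order": model.max_order, "C": model.C, "alpha": model.alpha,
                    "interpolated": model.interpolated.ravel().tolist()}
        return {"order": model.order, "alpha": model.alpha, "gamma": model.gamma,
                "transition": model.transition.ravel().tolist(),
                "context_counts": model.context_counts.tolist()}

    doc = {"format_version": _FORMAT_VERSION, "method": pair.method,
           "train": pack(pair.train_model), "bg": pack(pair.bg_model)}
    Path(path).write_text(json.dumps(doc))


def load_model_pair(path: str | Path) -> ModelPair:
    doc = json.loads(Path(path).read_text())
    if doc.get("format_version") != _FORMAT_VERSION:
        raise FormatError(f"unsupported model file version in {path}")
    method = doc["method"]

    def unpack(d):
        if method == "pacrc":
            return PoissonWordModel(k=d["k"], word_rates=np.array(d["word_rates"]),
                                    pseudocount=d["pseudocount"],
                                    total_positions=d["total_positions"])
        if method == "imm":
            arr = np.array(d["interpolated"]).reshape(4 ** d["max_order"], 4)
            return IMMModel(max_order=d["max_order"], C=d["C"], alpha=d["alpha"],
                            interpolated=arr)
        n_ctx = len(d["context_counts"])
        return MarkovChainModel(order=d["order"],
                                transition=np.array(d["transition"]).reshape(n_ctx, 4),
                                context_counts=np.array(d["context_counts"]),
                                alpha=d["alpha"], gamma=d["gamma"])

    return ModelPair(method=method, train_model=unpack(doc["train"]),
                     bg_model=unpack(doc["bg"]))
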