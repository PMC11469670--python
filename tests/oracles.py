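"""Independent brute-force reference implementations.

Everything here is written with plain dict/loop string processing (and
scipy's Poisson pmf for PAC-rc), deliberately sharing no code with the
vectorized implementations in crmscan.models — these are the oracles
the scorers are checked against.
"""

import math
from itertools import product

from scipy.stats import chi2 as _chi2
from scipy.stats import poisson as _poisson

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq):
    return "".join(_COMP[b] for b in reversed(seq))


def word_counts(seqs, k, both_strands=True):
    counts = {}
    for s in seqs:
        variants = (s, rc(s)) if both_strands else (s,)
        for v in variants:
            for i in range(len(v) - k + 1):
                w = v[i:i + k]
                if set(w) <= set("ACGT"):
                    counts[w] = counts.get(w, 0) + 1
    return counts


def _hamming1_sum(word, counts):
    total = 0
    for i, b in enumerate(word):
        for alt in "ACGT":
            if alt != b:
                total += counts.get(word[:i] + alt + word[i + 1:], 0)
    return total


def markov_prob(counts, context, base, alpha, gamma):
    num = {}
    for b in "ACGT":
        w = context + b
        n = counts.get(w, 0)
        num[b] = n + alpha + (gamma * _hamming1_sum(w, counts) if gamma else 0.0)
    return num[base] / sum(num.values())


def naive_markov_score(train_seqs, bg_seqs, window, order, alpha=1.0, gamma=0.0):
    k = order + 1
    if len(window) < k:
        return float("nan")
    ct = word_counts(train_seqs, k)
    cb = word_counts(bg_seqs, k)
    score = 0.0
    for i in range(order, len(window)):
        w = window[i - order:i + 1]
        if not set(w) <= set("ACGT"):
            continue
        pt = markov_prob(ct, w[:-1], w[-1], alpha, gamma)
        pb = markov_prob(cb, w[:-1], w[-1], alpha, gamma)
        score += math.log(pt / pb)
    return score


def naive_imm_prob(order_counts, context, base, C, alpha):
    """Glimmer-style interpolated probability, recursive formulation."""
    m = len(context)
    counts = order_counts[m]
    ctx_count = sum(counts.get(context + b, 0) for b in "ACGT")
    p_hat = {b: (counts.get(context + b, 0) + alpha) /
             (ctx_count + 4 * alpha) for b in "ACGT"}
    if m == 0:
        return p_hat[base]
    p_lower = {b: naive_imm_prob(order_counts, context[1:], b, C, alpha)
               for b in "ACGT"}
    if ctx_count >= max(C, 1.0):
        lam = 1.0
    elif ctx_count == 0:
        lam = 0.0
    else:
        stat = sum((counts.get(context + b, 0) - ctx_count * p_lower[b]) ** 2
                   / (ctx_count * p_lower[b]) for b in "ACGT")
        conf = _chi2.cdf(stat, df=3)
        lam = 0.0 if conf < 0.5 else min(1.0, conf * ctx_count / C)
    return lam * p_hat[base] + (1 - lam) * p_lower[base]


def naive_imm_score(train_seqs, bg_seqs, window, max_order, C, alpha=1.0):
    if len(window) < max_order + 1:
        return float("nan")
    oct_ = [word_counts(train_seqs, m + 1) for m in range(max_order + 1)]
    ocb = [word_counts(bg_seqs, m + 1) for m in range(max_order + 1)]
    score = 0.0
    for i in range(max_order, len(window)):
        w = window[i - max_order:i + 1]
        if not set(w) <= set("ACGT"):
            continue
        pt = naive_imm_prob(oct_, w[:-1], w[-1], C, alpha)
        pb = naive_imm_prob(ocb, w[:-1], w[-1], C, alpha)
        score += math.log(pt / pb)
    return score


def naive_pacrc_score(train_seqs, bg_seqs, window, pseudocount=1.0):
    """PAC-rc via the explicit Poisson pmf ratio over all 2080 classes."""
    k = 6
    if len(window) < k:
        return float("nan")
    classes = sorted({min(w, rc(w)) for w in ("".join(p) for p in product("ACGT", repeat=k))})

    def class_rates(seqs):
        wc = word_counts(seqs, k, both_strands=False)
        total = sum(wc.values())
        cc = {c: 0 for c in classes}
        for w, n in wc.items():
            cc[min(w, rc(w))] += n
        denom = total + pseudocount * len(classes)
        return {c: (cc[c] + pseudocount) / denom for c in classes}

    lt, lb = class_rates(train_seqs), class_rates(bg_seqs)
    wc = word_counts([window], k, both_strands=False)
    cw = {c: 0 for c in classes}
    L = 0
    for i in range(len(window) - k + 1):
        w = window[i:i + k]
        if set(w) <= set("ACGT"):
            cw[min(w, rc(w))] += 1
            L += 1
    score = 0.0
    for c in classes:
        score += (_poisson.logpmf(cw[c], lt[c] * L)
                  - _poisson.logpmf(cw[c], lb[c] * L))
    return score


def brute_force_overlap_count(preds, peaks, f=0.1):
    """O(n*m) overlap counting: a prediction counts once if any single
    peak covers at least f of its length (boundary inclusive)."""
    n = 0
    for (ps, a, b) in preds:
        for (qs, c, d) in peaks:
            if ps == qs and min(b, d) - max(a, c) >= f * (b - a):
                n += 1
                break
    return n


def brute_force_locus(pred, genes, scaffold_len):
    """Exhaustive locus assignment over all genes on one scaffold.

    genes: list of (gene_id, start, end) on the prediction's scaffold.
    Returns (upstream_id, downstream_id, locus_start, locus_end, kind).
    """
    s, e = pred
    overlapping = [(gid, gs, ge) for gid, gs, ge in genes if ge > s and gs < e]
    up = down = None
    for gid, gs, ge in genes:
        if ge > s and gs < e:
            continue
        if ge <= s and (up is None or ge > up[2] or (ge == up[2] and gs < up[1])):
            up = (gid, gs, ge)
        if gs >= e and (down is None or gs < down[1] or (gs == down[1] and ge < down[2])):
            down = (gid, gs, ge)
    if overlapping:
        ls = min(g[1] for g in overlapping)
        le = max(g[2] for g in overlapping)
        kind = "gene_overlap" if len(overlapping) >= 2 else "intronic"
        if s < ls:
            ls = up[2] if up else 0
        if e > le:
            le = down[1] if down else scaffold_len
    else:
        ls = up[2] if up else 0
        le = down[1] if down else scaffold_len
        kind = "intergenic"
    return (up[0] if up else None, down[0] if down else None, ls, le, kind)
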