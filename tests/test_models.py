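import math

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from crmscan.models import (
    ModelPair, count_kmers, fit_hexmcd, fit_imm, fit_markov, fit_pacrc,
    load_model_pair, revcomp, save_model_pair, score_window, train_model_pair,
)


def random_seqs(rng, n, length):
    return ["".join(rng.choice(list("ACGT"), size=length)) for _ in range(n)]


class TestKmerCounting:
    def test_double_stranded_counts(self):
        kc = count_kmers(["ACGA"], 2)
        assert kc.counts == {"AC": 1, "CG": 2, "GA": 1, "TC": 1, "GT": 1}
        assert kc.total == 6

    def test_single_base_strand_symmetry(self):
        kc = count_kmers(["AAAA"], 1)
        assert kc.counts == {"A": 4, "T": 4}

    def test_words_with_n_skipped(self):
        assert count_kmers(["ANA"], 2).total == 0

    def test_short_sequence_contributes_nothing(self):
        assert count_kmers(["AC"], 3).total == 0


class TestMarkovChain:
    def test_strand_symmetric_transitions(self):
        # both-strand counting forces P(A) == P(T) for an order-0 chain
        m = fit_markov(["AAAAAAAA"], order=0)
        assert m.transition[0, 0] == pytest.approx(m.transition[0, 3])

    def test_transitions_near_uniform_on_random_input(self):
        rng = np.random.default_rng(0)
        m = fit_markov(random_seqs(rng, 1, 500_000), order=1)
        assert np.allclose(m.transition, 0.25, atol=0.01)

    def test_unseen_context_is_uniform_with_laplace(self):
        m = fit_markov(["AAAA"], order=2, alpha=1.0)
        # context CG never seen -> Laplace gives exactly 1/4
        assert np.allclose(m.transition[1 * 4 + 2], 0.25)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        for gamma in (0.0, 0.1):
            m = fit_markov(random_seqs(rng, 5, 200), order=3, gamma=gamma)
            assert np.allclose(m.transition.sum(axis=1), 1.0, atol=1e-12)


class TestScoring:
    def test_identical_models_score_zero(self):
        rng = np.random.default_rng(2)
        seqs = random_seqs(rng, 10, 300)
        for method in ("imm", "hexmcd", "pacrc"):
            pair = train_model_pair(method, seqs, seqs)
            w = "".join(rng.choice(list("ACGT"), size=120))
            assert score_window(pair, w) == pytest.approx(0.0, abs=1e-9)

    def test_order0_closed_form(self):
        # train strongly prefers A, bg is uniform: score of "A"*n is
        # n * log(P_train(A) / 0.25) exactly
        train = ["A" * 10000]
        bg = random_seqs(np.random.default_rng(3), 4, 10000)
        tm = fit_markov(train, order=0, alpha=1.0)
        bm = fit_markov(bg, order=0, alpha=1.0)
        pair = ModelPair("hexmcd", tm, bm)
        n = 100
        expected = n * (math.log(tm.transition[0, 0]) - math.log(bm.transition[0, 0]))
        assert score_window(pair, "A" * n) == pytest.approx(expected, rel=1e-12)

    def test_window_shorter_than_word_is_nan(self):
        rng = np.random.default_rng(4)
        pair = train_model_pair("pacrc", random_seqs(rng, 5, 100),
                                random_seqs(rng, 5, 100))
        assert math.isnan(score_window(pair, "ACGT"))

    def test_positions_with_n_skipped(self):
        rng = np.random.default_rng(5)
        seqs = random_seqs(rng, 5, 200)
        pair = train_model_pair("hexmcd", seqs, random_seqs(rng, 5, 200))
        w = "ACGTAC" * 5
        # embedding an N-containing stretch only removes affected words
        s_clean = score_window(pair, w)
        s_n = score_window(pair, w + "N" * 6 + w)
        assert s_n == pytest.approx(2 * s_clean, abs=1e-9)


@pytest.fixture(scope="module")
def pairs():
    rng = np.random.default_rng(6)
    train = random_seqs(rng, 10, 400)
    bg = random_seqs(rng, 40, 400)
    return {m: train_model_pair(m, train, bg) for m in ("imm", "hexmcd", "pacrc")}


class TestReverseComplementInvariance:
    def test_pacrc_exactly_invariant(self, pairs):
        rng = np.random.default_rng(7)
        for _ in range(5):
            w = "".join(rng.choice(list("ACGT"), size=200))
            assert score_window(pairs["pacrc"], w) == pytest.approx(
                score_window(pairs["pacrc"], revcomp(w)), abs=1e-9)

    @pytest.mark.parametrize("method", ["imm", "hexmcd"])
    def test_markov_invariant_with_both_strand_training(self, pairs, method):
        rng = np.random.default_rng(8)
        for _ in range(5):
            w = "".join(rng.choice(list("ACGT"), size=200))
            a, b = score_window(pairs[method], w), score_window(pairs[method], revcomp(w))
            assert a == pytest.approx(b, abs=1e-6 * max(1.0, abs(a)))


class TestIMM:
    def test_forced_top_order_equals_pure_chain(self):
        # C=0 makes every seen context fully weighted: IMM == order-5 chain
        rng = np.random.default_rng(9)
        train = random_seqs(rng, 5, 20000)
        bg = random_seqs(rng, 5, 20000)
        imm_pair = ModelPair("imm", fit_imm(train, C=0.0), fit_imm(bg, C=0.0))
        chain_pair = ModelPair("hexmcd", fit_markov(train, 5, gamma=0.0),
                               fit_markov(bg, 5, gamma=0.0))
        for _ in range(5):
            w = "".join(rng.choice(list("ACGT"), size=100))
            assert score_window(imm_pair, w) == pytest.approx(
                score_window(chain_pair, w), abs=1e-9)

    def test_order0_structure_recovered(self):
        # data with pure order-0 structure: the full IMM score approaches
        # the order-0 chain score on long windows
        rng = np.random.default_rng(10)
        p_train, p_bg = [0.4, 0.1, 0.1, 0.4], [0.25, 0.25, 0.25, 0.25]
        draw = lambda p, n: "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])
        train, bg = [draw(p_train, 100000)], [draw(p_bg, 100000)]
        imm_pair = ModelPair("imm", fit_imm(train), fit_imm(bg))
        chain_pair = ModelPair("hexmcd", fit_markov(train, 0), fit_markov(bg, 0))
        w = draw(p_train, 2000)
        s_imm = score_window(imm_pair, w)
        s0 = score_window(chain_pair, w[5:])  # same scored positions
        assert s_imm == pytest.approx(s0, rel=0.15)

    def test_interpolated_rows_sum_to_one(self):
        rng = np.random.default_rng(11)
        model = fit_imm(random_seqs(rng, 5, 500))
        assert np.allclose(model.interpolated.sum(axis=1), 1.0, atol=1e-12)


class TestPacRC:
    def test_equal_rates_score_zero(self):
        rng = np.random.default_rng(12)
        seqs = random_seqs(rng, 10, 300)
        pair = train_model_pair("pacrc", seqs, seqs)
        assert score_window(pair, "ACGTACGTACGT") == pytest.approx(0.0, abs=1e-12)

    def test_poisson_ratio_single_class(self):
        # one class with lambda_t*L=2, lambda_b*L=1, observed 3, others
        # equal: score = 3*ln2 - 1
        from crmscan.models import PoissonWordModel, _CLASS_MAP6, N_CLASSES6
        L = 495  # 6-mer positions in a 500bp window
        base = np.full(4 ** 6, 1e-4)
        lt, lb = base.copy(), base.copy()
        w0 = 0  # AAAAAA (palindinstance-free class rep)
        cls_members = np.nonzero(_CLASS_MAP6 == _CLASS_MAP6[w0])[0]
        lt[cls_members] = 2.0 / L
        lb[cls_members] = 1.0 / L
        tm = PoissonWordModel(k=6, word_rates=lt, pseudocount=0, total_positions=1)
        bm = PoissonWordModel(k=6, word_rates=lb, pseudocount=0, total_positions=1)
        pair = ModelPair("pacrc", tm, bm)
        window = "AAAAAA" + "AAAAAA"[0] * 2  # "A"*8 -> 3 occurrences of AAAAAA
        window = "A" * 8 + "CGT" * 164  # pad to 500 bp
        window = window[:500]
        s = score_window(pair, window)
        # c_w=3 for the AAAAAA class; the padding classes have equal rates
        # (contribute 0); per-position constant terms use the true L
        Lw = len(window) - 5
        expected = 3 * math.log(2.0) - Lw * (2.0 / L - 1.0 / L)
        assert s == pytest.approx(expected, abs=1e-9)

    def test_palindromic_class_count(self):
        # a palindromic 6-mer is its own reverse complement: class of one
        from crmscan.models import _CLASS_MAP6
        from tests.oracles import rc as rc_str
        pal = "ACGCGT"
        assert rc_str(pal) == pal
        ids = np.nonzero(_CLASS_MAP6 == _CLASS_MAP6[_word_id(pal)])[0]
        assert len(ids) == 1

    def test_all_class_rates_positive(self):
        rng = np.random.default_rng(13)
        m = fit_pacrc(random_seqs(rng, 3, 100))
        assert (m.class_rates > 0).all()
        from crmscan.models import N_CLASSES6
        assert len(m.class_rates) == N_CLASSES6 == 2080


def _word_id(w):
    i = 0
    for b in w:
        i = i * 4 + "ACGT".index(b)
    return i


class TestDiscrimination:
    @pytest.mark.parametrize("method", ["imm", "hexmcd", "pacrc"])
    def test_training_model_windows_score_higher(self, method, fixture1):
        from crmscan.synthgen import draw_planted, draw_background
        rng = np.random.default_rng(14)
        spec = fixture1.spec
        pair = train_model_pair(method, fixture1.training_seqs,
                                fixture1.background_seqs)
        pos = [score_window(pair, draw_planted(rng, 500, spec)) for _ in range(200)]
        neg = [score_window(pair, draw_background(rng, 500, spec.bg_composition))
               for _ in range(200)]
        assert np.mean(pos) > np.mean(neg)
        assert mannwhitneyu(pos, neg, alternative="greater").pvalue < 1e-6


class TestSerialization:
    @pytest.mark.parametrize("method", ["imm", "hexmcd", "pacrc"])
    def test_round_trip_preserves_scores(self, method, tmp_path):
        rng = np.random.default_rng(15)
        pair = train_model_pair(method, random_seqs(rng, 5, 300),
                                random_seqs(rng, 20, 300))
        path = tmp_path / "model.json"
        save_model_pair(pair, path)
        loaded = load_model_pair(path)
        w = "".join(rng.choice(list("ACGT"), size=150))
        assert score_window(loaded, w) == pytest.approx(score_window(pair, w), abs=1e-12)
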