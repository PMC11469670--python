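import numpy as np
import pytest

from crmscan.permstats import (
    IntervalShuffler, PermutationResult, ShuffleSpec, SpeciesData, _summarize,
    chromatin_overlap, chromatin_overlap_test, common_loci, common_loci_test,
    per_locus_excess, shuffle_intervals,
)
from crmscan.postprocess import Prediction
from crmscan.synthgen import SynthSpec, make_multispecies_fixture
from tests.conftest import make_annotation
from tests.oracles import brute_force_overlap_count


def pred(start, end, scaffold="s1", pid=None):
    return Prediction(scaffold=scaffold, start=start, end=end, peak_score=1,
                      amplitude=1, methods=(), training_sets=(),
                      id=pid or f"p{start}")


class TestShuffle:
    @pytest.fixture
    def spec(self):
        excl = {"s1": np.array([[2000, 3000], [7000, 8000]]),
                "s2": np.array([[0, 500]])}
        return ShuffleSpec(scaffold_lengths={"s1": 10_000, "s2": 5_000},
                           exclusion=excl, n_permutations=20, seed=0)

    def test_lengths_preserved_exactly(self, spec):
        feats = [("s1", 100, 600), ("s1", 4000, 4300), ("s2", 1000, 2500)]
        for placed in shuffle_intervals(feats, spec):
            assert sorted(e - s for _, s, e in placed) == [300, 500, 1500]

    def test_never_intersects_exclusion(self, spec):
        feats = [("s1", 0, 400)] * 5
        for placed in shuffle_intervals(feats, spec):
            for sid, s, e in placed:
                for xs, xe in spec.exclusion.get(sid, []):
                    assert not (s < xe and e > xs)

    def test_in_bounds(self, spec):
        feats = [("s1", 0, 900)] * 5
        for placed in shuffle_intervals(feats, spec):
            for sid, s, e in placed:
                assert 0 <= s < e <= spec.scaffold_lengths[sid]

    def test_deterministic_under_seed(self, spec):
        feats = [("s1", 0, 400)] * 3
        assert shuffle_intervals(feats, spec) == shuffle_intervals(feats, spec)

    def test_oversized_feature_is_error(self, spec):
        shuffler = IntervalShuffler(spec.scaffold_lengths, spec.exclusion)
        with pytest.raises(ValueError, match="length"):
            shuffler.shuffle(np.array([50_000]), np.random.default_rng(0))


class TestChromatinOverlap:
    def test_boundary_fraction_inclusive(self):
        n, _ = chromatin_overlap([("s1", 0, 500)], [("s1", 450, 500)], f=0.1)
        assert n == 1

    def test_below_fraction_not_counted(self):
        n, _ = chromatin_overlap([("s1", 0, 500)], [("s1", 460, 500)], f=0.1)
        assert n == 0

    def test_multiple_peaks_count_once(self):
        peaks = [("s1", 0, 100), ("s1", 200, 300), ("s1", 400, 500)]
        n, frac = chromatin_overlap([("s1", 0, 500)], peaks, f=0.1)
        assert n == 1 and frac == 1.0

    def test_matches_brute_force_on_random_fixture(self):
        rng = np.random.default_rng(0)
        preds = [("s1", int(s), int(s) + int(rng.integers(50, 800)))
                 for s in rng.integers(0, 100_000, size=300)]
        peaks = [("s1", int(s), int(s) + int(rng.integers(50, 500)))
                 for s in rng.integers(0, 100_000, size=300)]
        n, _ = chromatin_overlap(preds, peaks, f=0.1)
        assert n == brute_force_overlap_count(preds, peaks, f=0.1)

    def test_saturated_peaks_give_fold_one(self):
        preds = [pred(1000 * i, 1000 * i + 500) for i in range(10)]
        peaks = [("s1", 0, 50_000)]
        res = chromatin_overlap_test(preds, peaks, {"s1": 50_000}, n=30, seed=0)
        assert res.observed == 100.0
        assert res.fold_enrichment == pytest.approx(1.0)

    def test_planted_coincidence_is_enriched(self, fixture1):
        preds = fixture1.truth_predictions()
        res = chromatin_overlap_test(preds, fixture1.peaks,
                                     fixture1.genome.lengths,
                                     exclusion=fixture1.annot.coding_intervals(),
                                     n=100, seed=0)
        assert res.z > 1.645 and res.fold_enrichment > 1


class TestSummaryArithmetic:
    def test_z_and_fold(self):
        null = np.array([4.0, 2.0, 6.0])  # mean 4, sd 2
        res = _summarize(10.0, null)
        assert res.z == pytest.approx(3.0)
        assert res.fold_enrichment == pytest.approx(2.5)
        assert res.significant

    def test_zero_sd_gives_nan_z(self):
        res = _summarize(5.0, np.array([2.0, 2.0, 2.0]))
        assert np.isnan(res.z) and not res.significant


class TestCommonLoci:
    def test_set_arithmetic(self):
        sets = {"a": {"g1", "g2"}, "b": {"g1", "g3"}, "c": {"g1"}}
        counts = common_loci(sets, [2, 3])
        assert counts == {2: 1, 3: 1}

    def test_identical_sets(self):
        sets = {s: {"x", "y", "z"} for s in "abcd"}
        assert common_loci(sets, [2, 4]) == {2: 3, 4: 3}

    def test_disjoint_sets(self):
        sets = {"a": {"g1"}, "b": {"g2"}}
        assert common_loci(sets, [2]) == {2: 0}


class TestPerLocusExcess:
    def test_concentrated_predictions_flagged(self):
        # 6 predictions crowded into one locus of a large genome
        genes = [(f"g{i}", "s1", 20_000 * i, 20_000 * i + 2000) for i in range(10)]
        annot = make_annotation(genes, [(g[0], "s1", g[2], g[2] + 500) for g in genes])
        preds = [pred(22_500 + 900 * i, 23_000 + 900 * i) for i in range(6)]
        results = per_locus_excess(preds, annot, {"s1": 200_000}, n=200, seed=0)
        assert len(results) == 1
        assert results[0].real_count == 6 and results[0].significant

    def test_locus_without_predictions_not_tested(self):
        genes = [("g0", "s1", 0, 1000), ("g1", "s1", 5000, 6000)]
        annot = make_annotation(genes)
        results = per_locus_excess([pred(2000, 2500)], annot, {"s1": 50_000},
                                  n=50, seed=0)
        assert len(results) == 1  # only the locus holding the prediction


class TestCommonLociTest:
    def test_planted_sharing_detected(self):
        fix = make_multispecies_fixture(
            SynthSpec(seed=0, n_species=6, n_planted=10), sharing=1.0)
        species = [SpeciesData(name=sp.name, annot=sp.annot,
                               scaffold_lengths=sp.scaffold_lengths,
                               predictions=sp.predictions,
                               orthologs=_table(sp.orthologs))
                   for sp in fix.species]
        results = common_loci_test(species, k_range=[5], n=60, seed=0)
        assert results[5].observed >= 10
        assert results[5].z > 1.645

    def test_empty_ortholog_species_excluded(self, caplog):
        fix = make_multispecies_fixture(
            SynthSpec(seed=1, n_species=3, n_planted=5), sharing=1.0)
        species = [SpeciesData(name=sp.name, annot=sp.annot,
                               scaffold_lengths=sp.scaffold_lengths,
                               predictions=sp.predictions,
                               orthologs=_table(sp.orthologs))
                   for sp in fix.species]
        from crmscan.annotate import OrthologTable
        species.append(SpeciesData(name="bare", annot=fix.species[0].annot,
                                   scaffold_lengths=fix.species[0].scaffold_lengths,
                                   predictions=fix.species[0].predictions,
                                   orthologs=OrthologTable({})))
        results = common_loci_test(species, k_range=[2], n=20, seed=0)
        assert 2 in results  # ran with the three usable species


def _table(mapping):
    from crmscan.annotate import OrthologTable
    return OrthologTable(dict(mapping))
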