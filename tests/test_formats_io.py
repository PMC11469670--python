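import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crmscan.errors import FormatError
from crmscan.formats_io import (
    mean_intergenic_distance, preflight, read_bed, read_bed_intervals,
    read_fasta, read_gff3, write_bed,
)
from crmscan.formats_io import Genome
from crmscan.postprocess import Prediction
from tests.conftest import make_annotation


class TestFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">s1\nACGT\n")
        g = read_fasta(p)
        assert list(g.scaffolds) == ["s1"] and len(g.scaffolds["s1"]) == 4

    def test_case_preserved_for_soft_masking(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">s1\nACgtN\n")
        assert read_fasta(p).scaffolds["s1"] == "ACgtN"

    def test_duplicate_id_is_error(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">s1\nACGT\n>s1\nGGGG\n")
        with pytest.raises(FormatError, match="s1"):
            read_fasta(p)

    def test_invalid_character_names_position(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">s1\nACXT\n")
        with pytest.raises(FormatError, match=r"'X'.*position 2"):
            read_fasta(p)


class TestGff3:
    def test_coordinates_become_zero_based_half_open(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text("s1\t.\tgene\t101\t200\t.\t+\t.\tID=g1\n")
        a = read_gff3(p)
        assert (a.genes[0].start, a.genes[0].end) == (100, 200)

    def test_non_gene_types_recorded_but_not_genes(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text("s1\t.\tgene\t1\t100\t.\t+\t.\tID=g1\n"
                     "s1\t.\tncRNA\t10\t40\t.\t+\t.\tID=n1;Parent=g1\n")
        a = read_gff3(p)
        assert "ncRNA" in a.feature_types_present
        assert len(a.genes) == 1

    def test_exon_attached_through_transcript_parent(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text("s1\t.\tgene\t1\t300\t.\t+\t.\tID=g1\n"
                     "s1\t.\tmRNA\t1\t300\t.\t+\t.\tID=t1;Parent=g1\n"
                     "s1\t.\texon\t1\t100\t.\t+\t.\tID=e1;Parent=t1\n")
        a = read_gff3(p)
        assert a.exons[0].gene_id == "g1"

    def test_orphan_exon_dropped_with_warning(self, tmp_path, caplog):
        p = tmp_path / "a.gff3"
        p.write_text("s1\t.\texon\t1\t100\t.\t+\t.\tID=zzz;Parent=nothing\n")
        a = read_gff3(p)
        assert a.exons == []

    def test_end_before_start_is_error(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text("s1\t.\tgene\t200\t100\t.\t+\t.\tID=g1\n")
        with pytest.raises(FormatError):
            read_gff3(p)

    def test_empty_file_gives_empty_annotation(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text("##gff-version 3\n")
        a = read_gff3(p)
        assert a.genes == [] and a.exons == []

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 10_000), st.integers(1, 500)),
                    min_size=1, max_size=20))
    def test_coordinate_conversion_is_a_bijection(self, spans):
        # writing 1-based inclusive and reading back restores the exact
        # internal 0-based half-open intervals
        import tempfile
        from pathlib import Path

        intervals = [(s, s + ln) for s, ln in spans]
        lines = ["##gff-version 3"]
        for i, (s, e) in enumerate(intervals):
            lines.append(f"s1\t.\tgene\t{s + 1}\t{e}\t.\t+\t.\tID=g{i}")
        with tempfile.TemporaryDirectory() as tmp:
            p = Path(tmp) / "a.gff3"
            p.write_text("\n".join(lines) + "\n")
            a = read_gff3(p)
        assert [(g.start, g.end) for g in a.genes] == intervals


class TestPreflight:
    def test_geneless_scaffold_dropped(self):
        g = Genome({"s1": "A" * 100, "s2": "C" * 100})
        a = make_annotation([("g1", "s2", 10, 50)])
        g2, _, rep = preflight(g, a)
        assert rep.dropped_scaffolds == ["s1"]
        assert list(g2.scaffolds) == ["s2"]
        assert g2.scaffolds["s2"] == "C" * 100  # sequences untouched

    def test_all_scaffolds_with_genes_kept(self):
        g = Genome({"s1": "A" * 100})
        a = make_annotation([("g1", "s1", 10, 50)])
        _, _, rep = preflight(g, a)
        assert rep.dropped_scaffolds == []

    def test_unknown_scaffold_is_hard_error(self):
        g = Genome({"s1": "A" * 100})
        a = make_annotation([("g1", "nope", 10, 50)])
        with pytest.raises(FormatError):
            preflight(g, a)

    def test_report_mean_intergenic_distance(self):
        g = Genome({"s1": "A" * 400})
        a = make_annotation([("g1", "s1", 0, 100), ("g2", "s1", 200, 300)])
        _, _, rep = preflight(g, a)
        assert rep.mean_intergenic_distance == 100


class TestMeanIntergenicDistance:
    def test_overlapping_pair_skipped(self):
        a = make_annotation([("g1", "s1", 0, 100), ("g2", "s1", 200, 300),
                             ("g3", "s1", 250, 400)])
        assert mean_intergenic_distance(a) == 100

    def test_abutting_genes_count_as_zero(self):
        a = make_annotation([("g1", "s1", 0, 100), ("g2", "s1", 100, 200)])
        assert mean_intergenic_distance(a) == 0

    def test_single_gene_undefined(self):
        a = make_annotation([("g1", "s1", 0, 100)])
        assert np.isnan(mean_intergenic_distance(a))

    def test_nested_pair_skipped(self):
        a = make_annotation([("g1", "s1", 0, 1000), ("g2", "s1", 10, 20)])
        assert np.isnan(mean_intergenic_distance(a))


class TestBed:
    def _random_predictions(self, rng, n=100):
        preds = []
        for i in range(n):
            s = int(rng.integers(0, 10_000))
            preds.append(Prediction(
                scaffold=f"s{rng.integers(1, 4)}", start=s,
                end=s + int(rng.integers(100, 2000)),
                peak_score=float(rng.normal()), amplitude=float(abs(rng.normal())),
                methods=("imm",), training_sets=("setA",), id=f"p{i}",
                upstream_gene=f"g{i}" if rng.random() < 0.5 else None,
                downstream_gene=None))
        return preds

    def test_round_trip_is_lossless(self, tmp_path):
        rng = np.random.default_rng(0)
        preds = self._random_predictions(rng)
        path = tmp_path / "p.bed"
        write_bed(preds, path)
        assert read_bed(path) == preds

    def test_written_line_layout(self, tmp_path):
        p = Prediction(scaffold="s1", start=100, end=850, peak_score=12.5,
                       amplitude=3.0, methods=("imm",), training_sets=("t",),
                       id="x")
        path = tmp_path / "p.bed"
        write_bed([p], path)
        fields = path.read_text().strip().split("\t")
        assert fields[:3] == ["s1", "100", "850"]
        assert fields[4] == "12.5"

    def test_start_after_end_is_error(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("s1\t500\t100\n")
        with pytest.raises(FormatError, match="1"):
            read_bed_intervals(path)

    def test_non_numeric_coordinate_names_line(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("s1\t100\t200\ns1\tabc\t300\n")
        with pytest.raises(FormatError, match="2"):
            read_bed_intervals(path)
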