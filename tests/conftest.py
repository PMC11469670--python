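import numpy as np
import pytest

from crmscan.formats_io import Gene, GeneAnnotation, Exon, Genome
from crmscan.models import train_model_pair
from crmscan.postprocess import length_outlier_filter, run_postprocess
from crmscan.scan import ScanConfig, scan_genome
from crmscan.synthgen import SynthSpec, make_fixture

# study conditions for fixture-scale scans: the per-instance top-N cut is
# scaled to the 200-kb fixture (~800 windows/instance) the way the
# full-size default relates to a real genome's millions of windows
FIXTURE_N_TOP = 150
FIXTURE_SEED = 0  # the generator's default seed


def make_annotation(genes, exons=()):
    """Annotation from (gene_id, scaffold, start, end) tuples."""
    a = GeneAnnotation()
    for g in genes:
        a.genes.append(Gene(*g))
    for e in exons:
        a.exons.append(Exon(*e))
    return a


@pytest.fixture(scope="session")
def fixture1():
    return make_fixture(SynthSpec(seed=FIXTURE_SEED))


@pytest.fixture(scope="session")
def scan_cfg():
    return ScanConfig(n_top=FIXTURE_N_TOP)


@pytest.fixture(scope="session")
def pipeline_predictions(fixture1, scan_cfg):
    """Final post-processed predictions per method on the default fixture."""
    out = {}
    for method in ("imm", "hexmcd", "pacrc"):
        pair = train_model_pair(method, fixture1.training_seqs,
                                fixture1.background_seqs)
        instances = [scan_genome(fixture1.genome, pair, scan_cfg, lb)
                     for lb in scan_cfg.instance_offsets]
        preds = run_postprocess(instances, scan_cfg, fixture1.genome.lengths)
        kept, _ = length_outlier_filter(preds)
        out[method] = kept
    return out


def random_genome(rng, length=5000, n_scaffolds=1):
    return Genome(scaffolds={
        f"s{i}": "".join(rng.choice(list("ACGT"), size=length))
        for i in range(n_scaffolds)})


def reciprocal_overlap_ok(a, b, frac=0.5):
    ov = max(0, min(a[2], b[2]) - max(a[1], b[1]))
    return a[0] == b[0] and ov >= frac * (a[2] - a[1]) and ov >= frac * (b[2] - b[1])
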