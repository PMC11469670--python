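"""Assign target genes and loci to predictions and join orthologs.

Each prediction gets its closest 5' and 3' flanking genes (putative
targets) and a locus: the whole region between the flanking genes, or
the enclosing gene's span for intronic predictions. Flanking genes are
then joined to their D. melanogaster orthologs, which is how loci are
compared across species.
"""

from crmscan.annotate import OrthologTable, assign_loci, join_orthologs
from crmscan.synthgen import SynthSpec, make_fixture

fix = make_fixture(SynthSpec(seed=0))
preds = fix.truth_predictions()[:8]
assignments = assign_loci(preds, fix.annot, fix.genome.lengths)
assignments = join_orthologs(assignments, OrthologTable(dict(fix.orthologs)))

print(f"{'prediction':>10} {'up':>5} {'down':>5} {'locus':>18} {'kind':>11}  Dmel keys")
for a in assignments:
    print(f"{a.prediction_id:>10} {a.upstream_gene or '-':>5} "
          f"{a.downstream_gene or '-':>5} "
          f"{a.locus_start:>8}-{a.locus_end:<9} {a.locus_kind:>11}  "
          f"{','.join(sorted(a.ortholog_keys)) or '-'}")
print("\nThe locus is the unit of the per-locus and cross-species")
print("statistics; the Dmel ortholog ids of the flanking genes key a")
print("locus so it can be matched between species.")
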