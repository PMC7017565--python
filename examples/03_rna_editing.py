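"""Call candidate A-to-I RNA-editing sites from transcript evidence.

Simulates one gene, plants A→G edits in its transcript evidence, and
compares the evidence against the genomic exon sequence. A-to-I editing
is observed operationally as genomic A with transcript G on the sense
strand; other mismatches are logged but never called as editing.
"""

from sitescreen import call_editing
from sitescreen.editing import edit_candidates
from sitescreen.synthetic import SimConfig, simulate

bundle = simulate(SimConfig(seed=9, n_genes=1, edit_sites_per_gene=2.0))
model = bundle.models[0]
contig = bundle.contigs[0]
evidence = bundle.evidence[0]

sites = call_editing(model, contig, evidence)
for s in sites:
    print(f"{s.gene_id} {model.contig_id}:{s.genomic_pos + 1} "
          f"({model.strand}) {s.sense_strand_change} -> {s.status}"
          + (f" [{s.note}]" if s.note else ""))
truth = bundle.truth["genes"][model.gene_id]["edits"]
print(f"candidates: {len(edit_candidates(sites))}, planted: {len(truth)}")

# Every planted A>G site is recovered as candidate_edit with its 1-based
# genomic coordinate; the candidate count equals the generator's truth.
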