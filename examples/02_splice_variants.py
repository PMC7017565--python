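"""Map transcripts to a locus and classify an alternative acceptor.

Uses the canned two-exon fixture in which the variant transcript
splices its intron acceptor 12 nt upstream, exonizing intron bases that
add the in-frame tetrapeptide MSSS read across the exon junction.
"""

from sitescreen import diff_isoforms, enumerate_isoforms, map_transcript
from sitescreen.synthetic import make_alt_acceptor_fixture

contig, primary_tx, variant_tx = make_alt_acceptor_fixture("MSSS")
primary = map_transcript(primary_tx, contig)
variant = map_transcript(variant_tx, contig)

print(f"primary exons: {primary.exons}")
print(f"variant exons: {variant.exons}")
for ev in diff_isoforms([primary, variant], contig, primary=primary):
    frame = "in-frame" if ev.in_frame else "frameshifting"
    print(f"{ev.transcript_id}: {ev.kind}, +{ev.shift_nt} nt, {frame}, "
          f"adds '{ev.added_peptide}'")

configs = enumerate_isoforms(
    ["exon9a", "exon9b", "intron10_donor_ext", "intron10_acceptor_ext"]
)
print(f"{len(configs)} possible transcripts from 4 independent splice "
      f"features")

# The acceptor extension keeps the reading frame (12 % 3 == 0) and adds
# exactly 4 residues; four independent binary splice features span a
# 2^4 = 16-transcript isoform space.
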