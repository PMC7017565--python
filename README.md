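# sitescreen

In-silico screening of insecticide target-site genes: ortholog
assignment, splice-variant and RNA-editing analysis, resistance-allele
genotyping, motif/PTM scanning, and neighbor-joining phylogenetics —
exercisable end to end on synthetic genomes with known truth.

## The problem

When a pest genome is newly sequenced, the first question an
insecticide-resistance program asks is: *what do this species' target
sites look like in the susceptible state?* Target-site genes — the
voltage-gated and sodium-channel-like channels, the ryanodine receptor,
the cys-loop ligand-gated ion channel superfamily (nAChR α/β subunits,
GABA-, glutamate-, pH- and histamine-gated chloride channels), and the
phenolamine (octopamine/tyramine) GPCRs — carry well-characterized
resistance substitutions in other species (e.g. RDL A302S for
cyclodienes/fipronil, ryanodine-receptor G4946E for diamides). A
susceptible reference catalog of these genes, their splice isoforms,
editing sites and diagnostic motifs is the benchmark against which
later allele-frequency monitoring is read.

`sitescreen` packages that workflow as a tested library:

- **homology** — Smith–Waterman local search (BLOSUM62, gap 11/1) with
  Karlin–Altschul E-values, `E = K·m·n·e^{−λS}`; orthologs by
  reciprocal best hit with >95% query coverage and `E < 1e−100`;
  Needleman–Wunsch percent-identity tables; exact-overlap merging of
  split gene predictions; alignment-based deletion spans.
- **splicing** — transcripts mapped to their locus by exact seed-and-
  extend with a per-exon mismatch budget; every intron must satisfy the
  GT..AG donor/acceptor consensus; events classified as cassette exon,
  alternative donor/acceptor (signed shift, frame, added peptide) or
  intron retention; isoform spaces enumerated as 2^n feature
  combinations.
- **editing** — A-to-I editing called operationally as genomic A vs
  transcript G on the sense strand; known sites classified as
  candidate / genomically encoded / not detected.
- **resistance** — a versioned TSV catalog of nine published
  resistance substitutions projected onto query proteins by semi-global
  Gonnet alignment; per-site state: susceptible / resistant /
  divergent / unalignable.
- **motifs** — a PROSITE-pattern engine (sets, negations, wildcards,
  repeat counts, anchors) with the six canonical PTM patterns shipped,
  plus channel features: DEKA/DEEA selectivity filters, MFL fast
  inactivation, the cys-loop `C-x(13)-C`, pore filters (GEK and its
  KDR/PAR/ADR/SAR variants) in the window preceding TM2, and the GPCR
  DRY motif at the end of TM3.
- **phylo** — progressive MSA (Gonnet-250, gap open 10 / extend 0.2),
  p-distance or Poisson distances with pairwise deletion, Saitou–Nei
  neighbor joining, column-resampling bootstrap supports, Newick I/O.
- **synthetic** — a deterministic generator of genomes, GFF3, transcript
  evidence, proteomes and truth tables with planted splice variants,
  edits, resistance alleles, motifs and tree-structured families.
- **pipeline** — orchestration of all stages into per-gene TSV reports
  with a checksummed MANIFEST; byte-identical reruns under a fixed
  config.

## Worked example

```python
from sitescreen import diff_isoforms, map_transcript
from sitescreen.synthetic import make_alt_acceptor_fixture

contig, primary_tx, variant_tx = make_alt_acceptor_fixture("MSSS")
primary = map_transcript(primary_tx, contig)
variant = map_transcript(variant_tx, contig)
for ev in diff_isoforms([primary, variant], contig, primary=primary):
    print(ev.kind, ev.shift_nt, ev.in_frame, ev.added_peptide)
```

prints

```
alt_acceptor 12 True MSSS
```

i.e. the variant transcript splices its intron acceptor 12 nt upstream
of the primary acceptor; the shift is a multiple of 3, so the reading
frame is preserved, and the exonized intron bases add the tetrapeptide
`MSSS`, read across the new exon junction. The `examples/` directory
holds one such narrative script per capability (orthology, splicing,
editing, resistance, motifs, trees, the full pipeline); each prints
the numbers it computes and what they mean.

A shell entry point wraps the pipeline for batch use:

```sh
sitescreen simulate --out bundle --seed 7 --n-genes 20
sitescreen screen --genome bundle/genome.fasta --gff bundle/genes.gff3 \
    --transcripts bundle/evidence.fasta --proteome bundle/proteome.fasta \
    --refs bundle/references.fasta --out reports --seed 7
```

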