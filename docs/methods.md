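# Methods

This note records the models, algorithms, parameter choices and known
limitations behind each module, in the order the pipeline runs them.

## Coordinates and data model

All internal coordinates are 0-based half-open; GFF3's 1-based closed
intervals are converted at the parsing boundary and converted back by
every report writer. A `GeneModel` stores exons in genomic order with
strand; transcription order is derived on demand. IUPAC ambiguity
letters are accepted in DNA input but treated as mismatches by every
downstream comparator — conservative for editing and mutation calls.
Translation uses the standard nuclear genetic code only (insect nuclear
genes); codons containing ambiguity letters translate to X, and
translation stops at the first stop codon with a flag when the CDS
length is not a multiple of 3.

## Ortholog assignment (homology)

Local search is optimal Smith–Waterman via `Bio.Align.PairwiseAligner`
with BLOSUM62 and BLAST-style affine gaps (open 11, extend 1; a gap of
length k costs 11 + k). Statistical significance uses the ungapped
Karlin–Altschul model, E = K·m·n·exp(−λS), with the published BLOSUM62
constants λ = 0.3176, K = 0.134; for other matrices λ is solved
numerically from Σ pᵢpⱼ e^{λsᵢⱼ} = 1 under Robinson–Robinson background
frequencies and K falls back to 0.1. This is deliberately simpler than
gapped BLAST statistics: the ortholog threshold (E < 1e−100 at >95%
query coverage) sits many orders of magnitude from the decision
boundary for true one-to-one target-site orthologs, so the calls are
insensitive to K. Orthology is reciprocal-best by default; a `one_way`
flag relaxes it, since published workflows do not always state which
rule they used. Ties everywhere break lexicographically by sequence id.

"Divergence" in identity tables is reported as
100·(substitutions + indel events)/ungapped columns — an explicitly
labeled approximation kept for table compatibility; percent identity,
not divergence, is the decision surface.

`merge_fragments` requires the suffix/prefix overlap to be exactly
identical (the observed split-prediction case was a 100%-identity,
152-residue overlap); the maximal qualifying overlap is chosen. A
mismatch-tolerant mode is intentionally absent from the default path.

## Transcript mapping and splice classification (splicing)

Transcripts match their own genome exactly except at editing sites, so
mapping is exact-match seed-and-extend rather than full dynamic-
programming spliced alignment: candidate exon chains are grown
left-to-right, opening an intron only at a donor consensus and closing
it only at an acceptor consensus (GT..AG by default; minus-strand genes
are mapped on the reverse-complemented contig so introns read
donor→acceptor). A per-exon mismatch budget (default 2) absorbs
editing mismatches. Chains are ranked by (total mismatches, intron
count) via iterative deepening, with leftmost donors as the final
tie-break — so a rare editing mismatch can never be traded for a
spurious extra intron, which matters for short terminal exons.
Minimum intron length is 30 nt (shorter gaps are deletions, not
introns); maximum 20 kb by default.

Events are classified pairwise against a designated primary transcript
(longest spliced CDS, ties lexicographic — callers can override, and
the worked examples do, because annotation pipelines number their
primary variant by other criteria). Alternative-acceptor upstream
shifts are positive extensions; `in_frame ⇔ shift mod 3 = 0`. The
added peptide of an in-frame extension is computed by splicing the
extension into the primary transcript and diffing the two translations
— necessary because an exonized acceptor extension always ends with
the old acceptor AG and is therefore never codon-aligned; its residues
read across the junction. Isoform spaces are enumerated as all 2^n
binary feature combinations in binary-counting order; configuration
tables emit X/– marks per transcript.

`find_missing_exon` local-searches an exon (nucleotide, or tBLASTn-like
against all six translation frames) against a locus and calls "absent"
when the best score falls below 50% of the exon's self-alignment score
— a scale-free floor that a diverged-but-present exon (~80% identity)
clears comfortably while random matches do not.

## RNA editing (editing)

Evidence is one assembled transcript per gene, not reads; there is no
coverage or quality model, mirroring an assembly-versus-genome
comparison. Every exonic mismatch is reported; A→G on the sense strand
(T→C on the genomic minus strand) is a candidate A-to-I site, all other
mismatches are logged as `non-AG-mismatch` and excluded from the edit
list. Sites within 3 nt of a splice junction carry a low-confidence
flag. Known-site catalogs are classified candidate / genomically
encoded (the genome already carries the edited base) / not detected.

## Resistance projection (resistance)

The shipped catalog carries nine published target-site substitutions,
each in its reference species' protein numbering exactly as cited
(numbering conventions differ between sources and are never
renumbered; the `numbering_note` column records the convention).
Projection aligns reference and query globally with free terminal gaps
(semi-global; Gonnet-250, gap open 10 / extend 0.2) so that fragments
and divergent termini yield `unalignable` rather than a misprojected
column — the fate of N-terminal sites against receptors whose
N-terminus does not align. State calls partition exhaustively:
susceptible (wild-type residue), resistant (published resistant
residue), divergent (neither), unalignable, plus `no_ortholog` at the
screen level. A low-confidence flag fires when identity in the
±20-residue window around the site falls below 50%, guarding against
paralog misprojection.

## Motifs and channel features (motifs)

The PROSITE engine supports residue letters, `x`, `[sets]`,
`{negated sets}`, `(n)`/`(n,m)` repeats, hyphen separators and the
`<`/`>` anchors, compiled to an element list and matched directly with
backtracking (greedy, maximal-repeat-first — equivalent to regex
semantics; the test suite proves equality against independently
compiled regexes). All overlapping matches are reported, one per start
position, 1-based. The unknown residue X in a sequence matches
wildcards and negated sets but never a positive set or letter; this is
the convention that makes published motif strings containing X (e.g. a
myristoylation site printed as `GXGATK`) evaluate correctly.

The shipped PTM catalog holds the six canonical patterns
(N-glycosylation `N-{P}-[ST]-{P}`, PKC `[ST]-x-[RK]`, CK2
`[ST]-x(2)-[DE]`, N-myristoylation `G-{EDRKHPFYW}-x(2)-[STAGCN]-{P}`,
amidation `x-G-[RK]-[RK]`, cAMP/cGMP `[RK](2)-x-[ST]`); the file
records its source and is user-replaceable. Channel features are
checked either over the whole protein (selectivity filter DEKA with
variant DEEA; fast-inactivation MFL; cys-loop `C-x(13)-C`) or in a
window anchored to user-supplied TM annotations: pore filters (GEK,
variants KDR/PAR/ADR/SAR) in the 10 residues immediately N-terminal of
TM2 ("immediately preceding" is not a published width; 10 is the
default and configurable), and the DRY motif within ±6 residues of the
TM3 end. TM annotations are inputs (GFF3 attributes or a sidecar); a
Kyte–Doolittle helper (window 19, threshold 1.6) can propose them but
is advisory only and never auto-trusted.

## Phylogenetics (phylo)

Alignment parameters follow the common protein setup of desktop
phylogenetics tools: Gonnet matrix with gap opening 10 and extension
0.2. The matrix is the Gonnet-250 log-odds table shipped with
biopython ("Gonnet" names a family; 250 PAM is the usual default).
Progressive alignment builds a UPGMA guide tree from pairwise
p-distances and merges profiles with an affine-gap profile-profile DP
using mean-of-pairs column scores; inputs are canonically sorted by id
first, so the result is input-order invariant. Distances use
p-distance with pairwise deletion of gap sites by default (the common
protein default), with Poisson correction −ln(1−p) switchable.

Neighbor joining is the Saitou–Nei Q-criterion agglomeration with ties
broken by the lexicographically lowest label pair; branch lengths by
the standard formulas, negative estimates clamped to zero and flagged
(the behaviour of mainstream implementations). On additive matrices
the reconstruction is exact (path lengths reproduce all pairwise
distances to < 1e−9, tested). Bootstrap resamples alignment columns
with replacement; support of an internal edge is the percentage of
replicate NJ trees containing the same bipartition; a fixed seed gives
identical supports across runs. The library default is 1000
replicates; the pipeline and acceptance runs use 100 and 10–25
respectively for desk-scale runtimes.

## Synthetic data (synthetic)

The generator emits what every stage assumes: multi-exon genes
(default 2–6 exons of 30–150 nt) with GT..AG introns of 40–120 nt,
≈40% of genes on the minus strand, cassette-exon variants (probability
0.3, length a multiple of 3), alternative-acceptor variants
(probability 0.3, shifts 12/15/7 nt — the first two frame-preserving,
matching the observed event sizes; 7 exercises the frameshift path),
Poisson-planted A→G edits (mean 1 per gene, at most 2 per exon so the
default mapper budget always suffices), reference/query protein pairs
for the resistance catalog (5% background substitutions, never inside
the ±20-residue site windows; the ryanodine-receptor reference is
generated at the realistic 5112-residue scale), one motif-carrier
protein per PTM pattern (embedding rejection-sampled so the pattern
has no accidental second match), and protein families diverged along a
known tree (each edge substitutes each residue independently with the
stated probability, ignoring branch lengths — a deliberate
simplification; back-substitution is possible but negligible at the
default 5%).

Default rates are the *susceptible-benchmark* condition: the
resistance plant rate is 0, matching a genome in which no resistance
alleles are expected; recovery tests pass explicit nonzero rates.
Gene loci are rejection-sampled so that exactly one consensus-
consistent exon chain reproduces the transcript (ambiguous splice
boundaries — possible by chance in random sequence — are regenerated,
capped at 25 attempts). Each output type draws from its own RNG
stream spawned from the master seed, so adding genes does not perturb
edit placement. All outputs are byte-deterministic under a fixed seed.

What the generator does **not** emulate: realistic base/codon
composition (uniform by default), read-level evidence or sequencing
error, selection, paralogy within the proteome, UTRs and promoters,
editing-level quantification. Passing tests therefore demonstrate the
*logic* of each stage under its stated data model, not robustness to
assembly artifacts or population variation in real data.

## Pipeline and determinism

`run_screen` executes homology → splicing → editing → resistance →
motifs → phylo; a stage failure writes a MANIFEST noting the failed
stage and retains completed outputs, then raises. Reports are TSV with
1-based positions; the MANIFEST lists sha256 checksums of every file;
the run log records version, config hash and seed, never timestamps,
so reruns with the same configuration are byte-identical. The tree
stage restricts itself to proteins ≤ 800 residues and at most 20 taxa
(sorted by id) — profile alignment is quadratic in length, and the
ryanodine-scale sequences would dominate runtime without adding
information to a subunit-level tree.

## Problem sizes used by the acceptance script

Isoform enumeration n = 4 features; splice arithmetic on the two
constructed acceptor-extension loci; fragment merge at 700 residues
with a 152-residue overlap; deletion span 156 of 600 residues;
Smith–Waterman oracle on 30 random pairs of length ≤ 8 over a 4-letter
alphabet (the brute-force enumeration is exponential, which is the
point); PROSITE oracle on 2000 random 30-mers × 6 patterns (the test
suite runs 10 000); transcript mapping and editing recovery on 300
random genes (the test suite runs 1000); resistance recovery at plant
rate 0.5 over the 9-entry catalog; NJ topology recovery over 100
seeded 4-leaf simulations at 5% per-edge divergence; determinism on a
6-gene seed-7 bundle run twice. These sizes are the package's own
desk-scale defaults; every recovery rate they measure is expected at
100% by construction of the noise-free data model.
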