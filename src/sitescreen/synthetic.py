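"""Synthetic genome/transcriptome/proteome generator with truth tables.

Emits multi-exon genes with GT..AG introns (minus-strand genes
included), cassette exons and alternative acceptor/donor variants,
planted A→G editing sites in the transcript evidence, reference/query
protein pairs carrying planted resistance alleles, proteins with
embedded PTM and channel motifs, and protein families diverged along a
known tree — everything each analysis stage assumes, with the planted
truth recorded alongside.

Gene loci are rejection-sampled so the consensus-consistent exon chain
is unique (ambiguous splice boundaries are regenerated); each output
type draws from its own RNG stream derived from the master seed, so
e.g. adding genes does not perturb edit placement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import motifs as motifs_mod
from .editing import call_editing
from .phylo import PhyloTree, TreeNode
from .resistance import MutationCatalogEntry, read_catalog
from .seqio import (
    GeneModel,
    STANDARD_CODE,
    SeqRecord,
    reverse_complement,
    spliced_transcript,
    write_fasta,
    write_gff3,
)
from .splicing import MIN_INTRON_LENGTH, SpliceConsensus, _spliced_match

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_NONSTOP_CODONS = sorted(
    c for c, aa in STANDARD_CODE.table.items() if aa != "*"
)


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (2, 6)
    intron_len: tuple[int, int] = (40, 120)
    cassette_prob: float = 0.3
    alt_site_prob: float = 0.3
    alt_site_shifts: tuple[int, ...] = (12, 15, 7)
    edit_sites_per_gene: float = 1.0
    resistance_plant_rate: float = 0.0
    subst_rate_per_edge: float = 0.05
    minus_strand_prob: float = 0.4
    flank: int = 100

    def __post_init__(self) -> None:
        if self.intron_len[0] < MIN_INTRON_LENGTH:
            raise ValueError(
                f"intron length range must start >= {MIN_INTRON_LENGTH}"
            )
        for p in (self.cassette_prob, self.alt_site_prob,
                  self.resistance_plant_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if any(s == 0 for s in self.alt_site_shifts):
            raise ValueError("alt-site shifts must be nonzero")


@dataclass
class GeneTruth:
    gene_id: str
    contig_id: str
    strand: str
    exons: list[tuple[int, int]]
    isoforms: dict[str, dict]  # isoform id -> {kind, exons, shift, ...}
    edits: list[dict]  # {transcript_pos, genomic_pos}


@dataclass
class SimBundle:
    config: SimConfig
    contigs: list[SeqRecord]
    models: list[GeneModel]
    variant_models: list[GeneModel]
    transcripts: list[SeqRecord]  # primary transcripts (clean)
    evidence: list[SeqRecord]  # primary transcripts with planted edits
    proteome: list[SeqRecord]
    references: list[SeqRecord]  # resistance reference proteins
    queries: list[SeqRecord]  # resistance query proteins
    truth: dict


def simulate(config: SimConfig) -> SimBundle:
    """Generate the full fixture bundle deterministically from the seed."""
    streams = np.random.SeedSequence(config.seed).spawn(5)
    rng_genome = np.random.default_rng(streams[0])
    rng_iso = np.random.default_rng(streams[1])
    rng_edit = np.random.default_rng(streams[2])
    rng_res = np.random.default_rng(streams[3])
    rng_motif = np.random.default_rng(streams[4])

    contigs: list[SeqRecord] = []
    models: list[GeneModel] = []
    variant_models: list[GeneModel] = []
    transcripts: list[SeqRecord] = []
    evidence: list[SeqRecord] = []
    proteome: list[SeqRecord] = []
    gene_truth: dict[str, dict] = {}

    for gi in range(config.n_genes):
        gene = _make_gene(config, rng_genome, rng_iso, gi)
        contigs.append(gene["contig"])
        models.append(gene["model"])
        variant_models.extend(gene["variant_models"])
        transcripts.append(gene["transcript"])
        transcripts.extend(gene["variant_transcripts"])

        ev, edits = _plant_edits(
            gene["model"], gene["contig"], rng_edit,
            config.edit_sites_per_gene,
        )
        evidence.append(ev)

        prot = _translate_cds(gene["transcript"])
        proteome.append(prot)
        gene_truth[gene["model"].gene_id] = {
            "contig_id": gene["contig"].id,
            "strand": gene["model"].strand,
            "exons": gene["model"].exons,
            "isoforms": gene["isoform_truth"],
            "edits": edits,
        }

    references, queries, res_truth = plant_resistance(
        read_catalog(), config.resistance_plant_rate, rng_res
    )
    motif_carriers, motif_truth = embed_ptm_motifs(rng_motif)
    proteome.extend(queries)
    proteome.extend(motif_carriers)

    truth = {
        "seed": config.seed,
        "genes": gene_truth,
        "resistance": res_truth,
        "motifs": motif_truth,
    }
    return SimBundle(
        config=config,
        contigs=contigs,
        models=models,
        variant_models=variant_models,
        transcripts=transcripts,
        evidence=evidence,
        proteome=proteome,
        references=references,
        queries=queries,
        truth=truth,
    )


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.choice(len(_NONSTOP_CODONS), size=n_codons - 2)
    return (
        "ATG"
        + "".join(_NONSTOP_CODONS[i] for i in body)
        + "TAA"
    )


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _make_intron(
    rng: np.random.Generator, length: int, acceptor_ext: int | None = None
) -> str:
    """GT..AG intron; optionally plants an upstream AG so the last
    acceptor_ext bases can be exonized by an alternative acceptor."""
    interior = _random_dna(rng, length - 4)
    intron = "GT" + interior + "AG"
    if acceptor_ext:
        k = acceptor_ext
        if length - k - 2 <= 2:
            raise ValueError("intron too short for planted acceptor")
        intron = intron[: length - k - 2] + "AG" + intron[length - k:]
    return intron


def _make_gene(config, rng, rng_iso, index: int) -> dict:
    """Build one locus; rejection-sample until the exon chain that
    reproduces the transcript under the splice consensus is unique."""
    consensus = SpliceConsensus()
    for _attempt in range(25):
        n_exons = int(rng.integers(*config.exons_per_gene, endpoint=True))
        exon_lens = [int(rng.integers(30, 150)) for _ in range(n_exons)]
        total = sum(exon_lens)
        exon_lens[-1] += (3 - total % 3) % 3
        total = sum(exon_lens)

        cds = _random_cds(rng, total // 3)
        strand = "-" if rng.random() < config.minus_strand_prob else "+"

        # choose isoform events up front so introns can host them
        want_alt = (
            n_exons >= 2 and rng_iso.random() < config.alt_site_prob
        )
        alt_shift = (
            int(rng_iso.choice(config.alt_site_shifts)) if want_alt else None
        )
        want_cassette = (
            n_exons >= 2 and rng_iso.random() < config.cassette_prob
        )

        intron_lens = [
            int(rng.integers(*config.intron_len, endpoint=True))
            for _ in range(n_exons - 1)
        ]
        alt_intron = int(rng_iso.integers(0, n_exons - 1)) if want_alt else None
        if alt_intron is not None and alt_shift is not None:
            intron_lens[alt_intron] = max(
                intron_lens[alt_intron], abs(alt_shift) + MIN_INTRON_LENGTH + 6
            )
        cassette_intron = (
            int(rng_iso.integers(0, n_exons - 1)) if want_cassette else None
        )

        # assemble the sense-strand locus
        parts = []
        exons_sense: list[tuple[int, int]] = []
        pos = config.flank
        parts.append(_random_dna(rng, config.flank))
        cds_pos = 0
        cassette_info = None
        for i, ln in enumerate(exon_lens):
            parts.append(cds[cds_pos : cds_pos + ln])
            exons_sense.append((pos, pos + ln))
            cds_pos += ln
            pos += ln
            if i < n_exons - 1:
                if cassette_intron == i:
                    cas_len = int(rng_iso.integers(10, 21)) * 3
                    cas_seq = "".join(
                        _NONSTOP_CODONS[k]
                        for k in rng_iso.choice(
                            len(_NONSTOP_CODONS), size=cas_len // 3
                        )
                    )
                    half_a = max(
                        MIN_INTRON_LENGTH, intron_lens[i] // 2
                    )
                    half_b = max(MIN_INTRON_LENGTH, intron_lens[i] - half_a)
                    ia = _make_intron(rng, half_a)
                    ib = _make_intron(rng, half_b)
                    parts.append(ia)
                    cassette_info = {
                        "interval": (pos + half_a, pos + half_a + cas_len),
                        "intron_index": i,
                    }
                    parts.append(cas_seq)
                    parts.append(ib)
                    pos += half_a + cas_len + half_b
                else:
                    ext = alt_shift if alt_intron == i else None
                    intron = _make_intron(rng, intron_lens[i], ext)
                    parts.append(intron)
                    pos += len(intron)
        parts.append(_random_dna(rng, config.flank))
        sense = "".join(parts)

        contig_seq = sense if strand == "+" else reverse_complement(sense)
        contig = SeqRecord(f"ctg{index:04d}", contig_seq, alphabet="dna")
        exons = (
            exons_sense
            if strand == "+"
            else sorted(
                (len(sense) - e, len(sense) - s) for s, e in exons_sense
            )
        )
        model = GeneModel(
            gene_id=f"gene{index:04d}",
            contig_id=contig.id,
            strand=strand,
            exons=exons,
        )
        transcript = SeqRecord(
            model.gene_id, cds, f"primary transcript of {model.gene_id}", "dna"
        )

        # uniqueness check: the mapped chain must equal the planted one
        # (scan the transcribed strand, i.e. the sense assembly)
        chain = _spliced_match(
            cds, sense, consensus, MIN_INTRON_LENGTH, 20000, 0
        )
        if chain != exons_sense:
            continue

        variant_models, variant_transcripts, isoform_truth = _make_isoforms(
            model, contig, alt_intron, alt_shift, cassette_info, strand,
            len(sense), consensus,
        )
        if variant_models is None:
            continue
        return {
            "contig": contig,
            "model": model,
            "transcript": transcript,
            "variant_models": variant_models,
            "variant_transcripts": variant_transcripts,
            "isoform_truth": isoform_truth,
        }
    raise RuntimeError(f"could not generate an unambiguous locus {index}")


def _make_isoforms(
    model, contig, alt_intron, alt_shift, cassette_info, strand,
    sense_len, consensus,
):
    """Build variant GeneModels for the planted events (sense coords in,
    genomic coords out); verifies each variant is itself mappable."""
    variant_models: list[GeneModel] = []
    variant_transcripts: list[SeqRecord] = []
    truth: dict[str, dict] = {}

    def to_genomic(ex_sense):
        if strand == "+":
            return sorted(ex_sense)
        return sorted((sense_len - e, sense_len - s) for s, e in ex_sense)

    def sense_exons(mdl):
        if strand == "+":
            return mdl.exons
        return sorted(
            (sense_len - e, sense_len - s) for s, e in mdl.exons
        )

    base_sense = sense_exons(model)

    if alt_intron is not None and alt_shift:
        ex = [list(e) for e in base_sense]
        ex[alt_intron + 1][0] -= alt_shift  # acceptor extension upstream
        if ex[alt_intron][1] < ex[alt_intron + 1][0] - MIN_INTRON_LENGTH + 1:
            vid = f"{model.gene_id}.alt_acceptor"
            mdl = GeneModel(vid, model.contig_id, strand,
                            to_genomic([tuple(e) for e in ex]))
            tx = spliced_transcript(mdl, [contig])
            tx.id = vid
            ok = _verify_variant(tx, contig, mdl, consensus)
            if not ok:
                return None, None, None
            variant_models.append(mdl)
            variant_transcripts.append(tx)
            truth[vid] = {
                "kind": "alt_acceptor",
                "intron_index": alt_intron,
                "shift_nt": alt_shift,
                "in_frame": alt_shift % 3 == 0,
            }

    if cassette_info is not None:
        s, e = cassette_info["interval"]
        i = cassette_info["intron_index"]
        ex = [tuple(x) for x in base_sense]
        ex = ex[: i + 1] + [(s, e)] + ex[i + 1 :]
        vid = f"{model.gene_id}.cassette"
        mdl = GeneModel(vid, model.contig_id, strand, to_genomic(ex))
        tx = spliced_transcript(mdl, [contig])
        tx.id = vid
        if not _verify_variant(tx, contig, mdl, consensus):
            return None, None, None
        variant_models.append(mdl)
        variant_transcripts.append(tx)
        truth[vid] = {
            "kind": "cassette_exon",
            "intron_index": i,
            "shift_nt": e - s,
            "in_frame": (e - s) % 3 == 0,
        }
    return variant_models, variant_transcripts, truth


def _verify_variant(tx, contig, mdl, consensus) -> bool:
    L = len(contig.residues)
    g = (
        contig.residues
        if mdl.strand == "+"
        else reverse_complement(contig.residues)
    )
    chain = _spliced_match(
        tx.residues, g, consensus, MIN_INTRON_LENGTH, 20000, 0
    )
    if chain is None:
        return False
    exons = (
        chain if mdl.strand == "+" else sorted((L - e, L - s) for s, e in chain)
    )
    return exons == mdl.exons


def _plant_edits(model, contig, rng, mean_sites):
    """Plant A→G edits (sense strand) in the primary transcript.

    At most 2 per exon so the evidence stays within the default
    mismatch budget of the mapper.
    """
    tx = spliced_transcript(model, [contig]).residues
    n_sites = int(rng.poisson(mean_sites))
    exon_of = []
    for i, (s, e) in enumerate(model.exons_in_transcription_order()):
        exon_of.extend([i] * (e - s))
    a_positions = [p for p, b in enumerate(tx) if b == "A"]
    rng.shuffle(a_positions)
    per_exon: dict[int, int] = {}
    chosen: list[int] = []
    for p in a_positions:
        if len(chosen) == n_sites:
            break
        if per_exon.get(exon_of[p], 0) >= 2:
            continue
        per_exon[exon_of[p]] = per_exon.get(exon_of[p], 0) + 1
        chosen.append(p)
    chosen.sort()
    edited = list(tx)
    coords = []
    pos_map = []
    for s, e in model.exons:
        pos_map.extend(range(s, e))
    if model.strand == "-":
        pos_map.reverse()
    for p in chosen:
        edited[p] = "G"
        coords.append({"transcript_pos": p, "genomic_pos": pos_map[p]})
    ev = SeqRecord(
        model.gene_id, "".join(edited),
        f"transcript evidence for {model.gene_id}", "dna",
    )
    return ev, coords


def _translate_cds(transcript: SeqRecord) -> SeqRecord:
    aa = []
    s = transcript.residues
    for i in range(0, len(s) - 2, 3):
        r = STANDARD_CODE.table.get(s[i : i + 3], "X")
        if r == "*":
            break
        aa.append(r)
    return SeqRecord(
        f"{transcript.id}_prot", "".join(aa),
        f"translation of {transcript.id}", "protein",
    )


_REFERENCE_LENGTHS = {
    "Dmel_DSC1": 2100,
    "Pxyl_Ryr": 5112,
    "Dmel_RDL": 560,
    "Rmic_TAR1": 450,
    "Rmic_OctB2R": 420,
}


def plant_resistance(
    catalog: list[MutationCatalogEntry],
    plant_rate: float,
    rng: np.random.Generator,
    background_subst: float = 0.05,
) -> tuple[list[SeqRecord], list[SeqRecord], dict]:
    """Synthesize reference proteins and ortholog queries per catalog.

    Each reference carries its wild-type residues at the cataloged
    positions; each query is the reference with background substitutions
    (never inside the ±20-residue site windows) plus, with probability
    plant_rate per entry, the resistant allele at the site itself.
    """
    by_ref: dict[str, list[MutationCatalogEntry]] = {}
    for e in catalog:
        by_ref.setdefault(e.reference_seq_id, []).append(e)

    references, queries = [], []
    truth: dict[str, list[dict]] = {"planted": [], "susceptible": []}
    for ref_id in sorted(by_ref):
        entries = by_ref[ref_id]
        length = _REFERENCE_LENGTHS.get(
            ref_id, max(e.position for e in entries) + 50
        )
        seq = list(
            "".join(AA20[i] for i in rng.integers(0, 20, size=length))
        )
        protected = set()
        for e in entries:
            seq[e.position - 1] = e.wild_type_aa
            protected.update(
                range(max(0, e.position - 21), e.position + 20)
            )
        ref = SeqRecord(
            ref_id, "".join(seq),
            f"synthetic reference for {entries[0].target_gene}", "protein",
        )
        references.append(ref)

        q = list(ref.residues)
        n_subst = int(background_subst * length)
        positions = rng.choice(length, size=min(n_subst, length), replace=False)
        for p in positions:
            if p in protected:
                continue
            q[p] = AA20[(AA20.index(q[p]) + 1 + int(rng.integers(0, 18))) % 20]
        for e in entries:
            if rng.random() < plant_rate:
                q[e.position - 1] = e.resistant_aa
                truth["planted"].append(
                    {"reference_seq_id": ref_id, "position": e.position}
                )
            else:
                truth["susceptible"].append(
                    {"reference_seq_id": ref_id, "position": e.position}
                )
        queries.append(
            SeqRecord(
                f"Atum_{entries[0].target_gene}", "".join(q),
                f"synthetic query ortholog of {ref_id}", "protein",
            )
        )
    return references, queries, truth


def _sample_from_pattern(
    pattern: motifs_mod.PrositePattern, rng: np.random.Generator
) -> str:
    out = []
    for el in pattern.elements:
        count = int(rng.integers(el.min_count, el.max_count + 1))
        for _ in range(count):
            if el.kind == "x":
                out.append(AA20[int(rng.integers(0, 20))])
            elif el.kind in ("letter", "set"):
                choices = sorted(el.residues)
                out.append(choices[int(rng.integers(0, len(choices)))])
            else:
                choices = sorted(set(AA20) - el.residues)
                out.append(choices[int(rng.integers(0, len(choices)))])
    return "".join(out)


def embed_ptm_motifs(
    rng: np.random.Generator,
    carrier_length: int = 120,
) -> tuple[list[SeqRecord], list[dict]]:
    """One carrier protein per shipped PTM pattern, motif planted at a
    recorded offset; carriers are rejection-sampled so the pattern has
    no accidental second match."""
    carriers, truth = [], []
    for pattern in motifs_mod.read_pattern_catalog():
        instance = _sample_from_pattern(pattern, rng)
        for _ in range(200):
            backbone = "".join(
                AA20[i] for i in rng.integers(0, 20, size=carrier_length)
            )
            offset = int(
                rng.integers(0, carrier_length - len(instance) + 1)
            )
            seq = (
                backbone[:offset] + instance
                + backbone[offset + len(instance):]
            )
            rec = SeqRecord(
                f"carrier_{pattern.pattern_id}", seq, alphabet="protein"
            )
            hits = motifs_mod.scan(pattern, rec)
            if [h.start for h in hits] == [offset + 1]:
                carriers.append(rec)
                truth.append(
                    {
                        "pattern_id": pattern.pattern_id,
                        "seq_id": rec.id,
                        "start": offset + 1,
                        "matched": instance,
                    }
                )
                break
        else:
            raise RuntimeError(
                f"could not embed {pattern.pattern_id} without extra matches"
            )
    return carriers, truth


def make_alt_acceptor_fixture(
    added_peptide: str = "MSSS", seed: int = 0
) -> tuple[SeqRecord, SeqRecord, SeqRecord]:
    """Two-exon locus whose variant transcript uses an acceptor spliced
    upstream, exonizing intron bases that add a short in-frame peptide.

    Supports the two cases an alternative acceptor can realize when the
    exonized stretch ends with the old acceptor AG: a 12-nt extension
    adding 4 residues (default peptide MSSS, reading across the exon
    junction) and a 15-nt extension adding 5 (SCLLQ). Returns
    (contig, primary transcript, variant transcript).
    """
    rng = np.random.default_rng(seed)
    if added_peptide == "MSSS":
        # exon1 ends with dangling "CT"; exonized 12-mer G ATG AGT TCT AG;
        # junction codon CT+G (L) matches primary CT+C (L), so the diff
        # is exactly MSSS
        dangle = "CT"
        ext = "G" + "ATG" + "AGT" + "TCT" + "AG"
        exon2_first = "C"
    elif added_peptide == "SCLLQ":
        # exon1 ends "AG"; exonized 15-mer C TGT CTT CTG CAG AG; the
        # trailing AG+A codon (R) matches the primary junction codon
        dangle = "AG"
        ext = "C" + "TGT" + "CTT" + "CTG" + "CAG" + "AG"
        exon2_first = "A"
    else:
        raise ValueError("supported peptides: MSSS, SCLLQ")

    body1 = "".join(
        _NONSTOP_CODONS[i] for i in rng.integers(0, len(_NONSTOP_CODONS), 20)
    )
    exon1 = "ATG" + body1 + dangle
    body2 = "".join(
        _NONSTOP_CODONS[i] for i in rng.integers(0, len(_NONSTOP_CODONS), 20)
    )
    exon2 = exon2_first + body2 + "TAA"
    filler = _random_dna(rng, 40)
    intron = "GT" + filler + "AG" + ext  # ext ends AG = primary acceptor
    flank5 = _random_dna(rng, 60)
    flank3 = _random_dna(rng, 60)
    contig = SeqRecord(
        "alt_acceptor_locus", flank5 + exon1 + intron + exon2 + flank3,
        alphabet="dna",
    )
    primary = SeqRecord(
        "tx_primary", exon1 + exon2, "primary transcript", "dna"
    )
    variant = SeqRecord(
        "tx_variant", exon1 + ext + exon2, "alt-acceptor variant", "dna"
    )
    return contig, primary, variant


def diverge_family(
    root: SeqRecord,
    tree: PhyloTree,
    rate: float,
    seed: int = 0,
) -> list[SeqRecord]:
    """Evolve a protein along a tree: each edge substitutes every residue
    independently with probability `rate` (to a uniformly random
    different residue). Leaves are labeled by the tree's leaf names."""
    rng = np.random.default_rng(seed)
    out: list[SeqRecord] = []

    def walk(node: TreeNode, seq: str) -> None:
        mutated = seq
        if node is not tree.root:
            chars = list(mutated)
            hits = np.nonzero(rng.random(len(chars)) < rate)[0]
            for p in hits:
                alternatives = AA20.replace(chars[p], "")
                chars[p] = alternatives[int(rng.integers(0, len(alternatives)))]
            mutated = "".join(chars)
        if node.is_leaf:
            out.append(SeqRecord(node.name, mutated, alphabet="protein"))
            return
        for child in node.children:
            walk(child, mutated)

    walk(tree.root, root.residues)
    out.sort(key=lambda r: r.id)
    return out


def write_bundle(bundle: SimBundle, outdir: str | Path) -> None:
    """Write the bundle in the same dialects the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.contigs, outdir / "genome.fasta")
    write_gff3(bundle.models + bundle.variant_models, outdir / "genes.gff3")
    write_fasta(bundle.transcripts, outdir / "transcripts.fasta")
    write_fasta(bundle.evidence, outdir / "evidence.fasta")
    write_fasta(bundle.proteome, outdir / "proteome.fasta")
    write_fasta(bundle.references, outdir / "references.fasta")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(bundle.truth, fh, indent=1, sort_keys=True, default=list)
    with open(outdir / "truth_genes.tsv", "w") as fh:
        fh.write("gene\tcontig\tstrand\texons\tn_isoforms\tn_edits\n")
        for gid, g in sorted(bundle.truth["genes"].items()):
            exons = ";".join(f"{s}-{e}" for s, e in g["exons"])
            fh.write(
                f"{gid}\t{g['contig_id']}\t{g['strand']}\t{exons}\t"
                f"{len(g['isoforms'])}\t{len(g['edits'])}\n"
            )
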