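"""Candidate A-to-I RNA-editing calls from genome/transcript comparison.

Editing is called operationally as an A→G mismatch on the sense strand
between the genomic exon sequence and assembled transcript evidence
(T→C on the genomic minus strand). Evidence is one assembled transcript
per gene, not reads, so no coverage or quality model applies. Mismatches
that are not A→G are logged but excluded from the edit list; mismatches
within 3 nt of a splice junction are flagged low-confidence.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqio import GeneModel, SeqRecord, spliced_transcript

JUNCTION_PROXIMITY_NT = 3


@dataclass
class EditingSite:
    gene_id: str
    transcript_pos: int  # 0-based position in the spliced transcript
    genomic_pos: int  # 0-based position on the contig
    genomic_base: str
    transcript_base: str
    sense_strand_change: str  # e.g. "A>G"
    status: str  # candidate_edit | genomically_encoded | not_detected
    note: str = ""


class EvidenceMismatchError(ValueError):
    """Transcript evidence does not map onto the gene model."""


def _transcript_to_genomic(model: GeneModel) -> list[int]:
    """Genomic coordinate of every spliced-transcript position."""
    coords: list[int] = []
    for s, e in model.exons:
        coords.extend(range(s, e))
    if model.strand == "-":
        coords.reverse()
    return coords


def _junction_offsets(model: GeneModel) -> set[int]:
    """Transcript positions within JUNCTION_PROXIMITY_NT of a junction."""
    lengths = [e - s for s, e in model.exons_in_transcription_order()]
    out: set[int] = set()
    pos = 0
    for ln in lengths[:-1]:
        pos += ln
        for d in range(JUNCTION_PROXIMITY_NT):
            out.add(pos - 1 - d)
            out.add(pos + d)
    return out


def call_editing(
    model: GeneModel,
    contig: SeqRecord,
    transcript_evidence: SeqRecord,
    mismatch_budget_per_exon: int = 2,
) -> list[EditingSite]:
    """Report every exonic genome/transcript mismatch, A→G as candidates.

    The evidence must have the same spliced length as the model and
    stay within the per-exon mismatch budget; otherwise the comparison
    is rejected as unmappable.
    """
    genomic_tx = spliced_transcript(model, [contig]).residues
    ev = transcript_evidence.residues
    if len(ev) != len(genomic_tx):
        raise EvidenceMismatchError(
            f"{model.gene_id}: evidence length {len(ev)} != spliced "
            f"length {len(genomic_tx)}"
        )
    coords = _transcript_to_genomic(model)
    junctions = _junction_offsets(model)

    # enforce the per-exon budget
    exon_mm: dict[int, int] = {}
    exon_index_of = []
    for i, (s, e) in enumerate(model.exons_in_transcription_order()):
        exon_index_of.extend([i] * (e - s))
    for pos, (gb, tb) in enumerate(zip(genomic_tx, ev)):
        if gb != tb:
            idx = exon_index_of[pos]
            exon_mm[idx] = exon_mm.get(idx, 0) + 1
    over = [i for i, c in exon_mm.items() if c > mismatch_budget_per_exon]
    if over:
        raise EvidenceMismatchError(
            f"{model.gene_id}: exon(s) {over} exceed the mismatch budget"
        )

    sites: list[EditingSite] = []
    for pos, (gb, tb) in enumerate(zip(genomic_tx, ev)):
        if gb == tb:
            continue
        change = f"{gb}>{tb}"
        status = "candidate_edit" if change == "A>G" else "non-AG-mismatch"
        note = ""
        if pos in junctions:
            note = "junction-proximal, low confidence"
        sites.append(
            EditingSite(
                gene_id=model.gene_id,
                transcript_pos=pos,
                genomic_pos=coords[pos],
                genomic_base=_genomic_base(gb, model.strand),
                transcript_base=tb,
                sense_strand_change=change,
                status=status,
                note=note,
            )
        )
    return sites


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _genomic_base(sense_base: str, strand: str) -> str:
    """Base as written on the contig's plus strand."""
    return sense_base if strand == "+" else _COMP.get(sense_base, "N")


def edit_candidates(sites: list[EditingSite]) -> list[EditingSite]:
    return [s for s in sites if s.status == "candidate_edit"]


def classify_known_sites(
    sites_catalog: list[tuple[str, int, str]],
    model: GeneModel,
    contig: SeqRecord,
    evidence: SeqRecord,
) -> list[EditingSite]:
    """Label cataloged sites as edited, genomically encoded, or absent.

    Catalog entries are (gene_id, transcript_pos 0-based, edited_base).
    A site whose genomic base already equals the edited base is
    "genomically_encoded" (constitutive); genomic A with transcript G is
    "candidate_edit"; anything else is "not_detected".
    """
    genomic_tx = spliced_transcript(model, [contig]).residues
    ev = evidence.residues
    coords = _transcript_to_genomic(model)
    out = []
    for gene_id, pos, edited_base in sites_catalog:
        if gene_id != model.gene_id:
            continue
        if not 0 <= pos < len(genomic_tx):
            raise ValueError(f"{gene_id}: catalog position {pos} out of range")
        gb = genomic_tx[pos]
        tb = ev[pos] if pos < len(ev) else "N"
        if gb == edited_base:
            status = "genomically_encoded"
        elif gb == "A" and tb == edited_base == "G":
            status = "candidate_edit"
        else:
            status = "not_detected"
        out.append(
            EditingSite(
                gene_id=gene_id,
                transcript_pos=pos,
                genomic_pos=coords[pos],
                genomic_base=_genomic_base(gb, model.strand),
                transcript_base=tb,
                sense_strand_change=f"{gb}>{tb}" if gb != tb else "",
                status=status,
            )
        )
    return out


def write_editing_report(
    sites: list[EditingSite], model: GeneModel, path: str
) -> None:
    """TSV report; genomic positions are 1-based contig coordinates."""
    with open(path, "w") as fh:
        fh.write("gene\tcontig_pos\tstrand\tchange\tstatus\tnote\n")
        for s in sites:
            fh.write(
                f"{s.gene_id}\t{model.contig_id}:{s.genomic_pos + 1}\t"
                f"{model.strand}\t{s.sense_strand_change}\t{s.status}\t"
                f"{s.note}\n"
            )
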