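"""Sequence and gene-model data structures plus FASTA/GFF3 I/O.

All internal coordinates are 0-based half-open. GFF3 uses 1-based closed
intervals and is converted at the boundary; report writers convert back.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable

DNA_ALPHABET = set("ACGTN" + "RYSWKMBDHV")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY" + "X*")

_COMPLEMENT = str.maketrans(
    "ACGTNRYSWKMBDHVacgtnryswkmbdhv",
    "TGCANYRSWMKVHDBtgcanyrswmkvhdb",
)


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; message names the offending line."""


class Gff3ParseError(ValueError):
    """Raised for structurally invalid GFF3 (bounds, linkage)."""


@dataclass
class SeqRecord:
    """A named sequence over a declared alphabet.

    alphabet is "dna" or "protein"; residues are stored uppercase.
    """

    id: str
    residues: str
    description: str = ""
    alphabet: str = "dna"

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        allowed = DNA_ALPHABET if self.alphabet == "dna" else PROTEIN_ALPHABET
        bad = set(self.residues) - allowed
        if bad:
            raise ValueError(
                f"record {self.id!r}: characters {sorted(bad)} not in "
                f"{self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "SeqRecord":
        if self.alphabet != "dna":
            raise ValueError("reverse_complement requires a DNA record")
        return SeqRecord(
            self.id, self.residues.translate(_COMPLEMENT)[::-1],
            self.description, "dna",
        )


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneModel:
    """Strand-aware exon chain on a contig.

    exons: sorted, non-overlapping (start, end) genomic intervals,
    0-based half-open. annotations maps feature names (e.g. "TM2") to
    (start, end) intervals in protein coordinates.
    """

    gene_id: str
    contig_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds_phase_offset: int = 0
    annotations: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        prev_end = -1
        for start, end in self.exons:
            if start >= end:
                raise ValueError(f"{self.gene_id}: empty exon ({start},{end})")
            if start < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or unsorted")
            prev_end = end
        if not 0 <= self.cds_phase_offset <= 2:
            raise ValueError(f"{self.gene_id}: phase must be 0..2")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def introns(self) -> list[tuple[int, int]]:
        """Genomic intervals between consecutive exons."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    def exons_in_transcription_order(self) -> list[tuple[int, int]]:
        return self.exons if self.strand == "+" else list(reversed(self.exons))


@dataclass
class GeneticCode:
    """Codon table with explicit start/stop sets; stops map to '*'."""

    table: dict[str, str]
    starts: frozenset[str]
    stops: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.table) != 64:
            raise ValueError("genetic code must map all 64 codons")

    @classmethod
    def standard(cls) -> "GeneticCode":
        t = CodonTable.unambiguous_dna_by_id[1]
        table = dict(t.forward_table)
        for stop in t.stop_codons:
            table[stop] = "*"
        return cls(table, frozenset(t.start_codons), frozenset(t.stop_codons))


STANDARD_CODE = GeneticCode.standard()


def _infer_alphabet(residues: str) -> str:
    return "dna" if set(residues.upper()) <= DNA_ALPHABET else "protein"


def read_fasta(path: str | os.PathLike, alphabet: str | None = None) -> list[SeqRecord]:
    """Read a (possibly wrapped) multi-record FASTA file.

    The alphabet is inferred per record unless declared by the caller.
    Raises FastaParseError naming the line for empty-sequence records.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            lineno = _find_header_line(path, rec.id)
            raise FastaParseError(
                f"{path}: record {rec.id!r} at line {lineno} has no sequence"
            )
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(
            SeqRecord(
                rec.id, seq, rec.description, alphabet or _infer_alphabet(seq)
            )
        )
    if not records and os.path.getsize(path):
        raise FastaParseError(f"{path}: no FASTA records found (line 1)")
    return records


def _find_header_line(path: str | os.PathLike, rec_id: str) -> int:
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if line.startswith(">") and line[1:].split()[:1] == [rec_id]:
                return i
    return 0


def write_fasta(records: Iterable[SeqRecord], path: str | os.PathLike, width: int = 60) -> None:
    """Write records as wrapped FASTA (60-column default)."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if rec.description and rec.description != rec.id:
                desc = rec.description
                if desc.startswith(rec.id + " "):
                    desc = desc[len(rec.id) + 1:]
                header = f"{rec.id} {desc}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


def read_gff3(path: str | os.PathLike, contigs: Sequence[SeqRecord]) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS features into one GeneModel per mRNA.

    GFF3 1-based closed intervals become 0-based half-open. TM-segment
    annotations may ride along as ``tm_annotations`` attributes of the
    form "TM1:10-32,TM2:45-67" (protein coordinates, 1-based closed).
    """
    bounds = {c.id: len(c) for c in contigs}
    mrnas: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int, int]]] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise Gff3ParseError(f"{path}:{lineno}: expected 9 columns")
            seqid, _, ftype, start, end, _, strand, phase, attrs = cols
            attrd = _parse_attrs(attrs)
            s, e = int(start) - 1, int(end)
            if ftype == "mRNA":
                mid = attrd.get("ID")
                if not mid:
                    raise Gff3ParseError(f"{path}:{lineno}: mRNA without ID")
                mrnas[mid] = {
                    "contig": seqid,
                    "strand": strand,
                    "attrs": attrd,
                }
            elif ftype in ("exon", "CDS"):
                parent = attrd.get("Parent")
                if not parent:
                    raise Gff3ParseError(
                        f"{path}:{lineno}: {ftype} without Parent linkage"
                    )
                if seqid in bounds and not (0 <= s < e <= bounds[seqid]):
                    raise Gff3ParseError(
                        f"{path}:{lineno}: {ftype} [{start},{end}] outside "
                        f"contig {seqid} (length {bounds[seqid]})"
                    )
                if ftype == "exon":
                    exons.setdefault(parent, []).append((s, e))
                else:
                    ph = int(phase) if phase in "012" else 0
                    cds.setdefault(parent, []).append((s, e, ph))

    models = []
    for mid, info in sorted(mrnas.items()):
        if mid not in exons:
            raise Gff3ParseError(f"{path}: mRNA {mid!r} has no exon children")
        if info["contig"] not in bounds:
            raise Gff3ParseError(
                f"{path}: mRNA {mid!r} on unknown contig {info['contig']!r}"
            )
        ex = sorted(exons[mid])
        phase = 0
        if mid in cds:
            ordered = sorted(cds[mid])
            first = ordered[0] if info["strand"] == "+" else ordered[-1]
            phase = first[2]
        annotations = {}
        tm = info["attrs"].get("tm_annotations")
        if tm:
            for part in tm.split(","):
                name, span = part.split(":")
                a, b = span.split("-")
                annotations[name] = (int(a) - 1, int(b))
        models.append(
            GeneModel(
                gene_id=mid,
                contig_id=info["contig"],
                strand=info["strand"],
                exons=ex,
                cds_phase_offset=phase,
                annotations=annotations,
            )
        )
    return models


def _parse_attrs(attrs: str) -> dict[str, str]:
    out = {}
    for piece in attrs.split(";"):
        piece = piece.strip()
        if piece and "=" in piece:
            k, v = piece.split("=", 1)
            out[k] = v
    return out


def write_gff3(models: Iterable[GeneModel], path: str | os.PathLike) -> None:
    """Write gene/mRNA/exon/CDS rows (1-based closed, version-3 pragma)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for mdl in models:
            s, e = mdl.span
            gene_id = f"gene_{mdl.gene_id}"
            attrs = f"ID={gene_id}"
            fh.write(
                f"{mdl.contig_id}\tsitescreen\tgene\t{s + 1}\t{e}\t.\t"
                f"{mdl.strand}\t.\t{attrs}\n"
            )
            extra = ""
            if mdl.annotations:
                tm = ",".join(
                    f"{k}:{a + 1}-{b}" for k, (a, b) in mdl.annotations.items()
                )
                extra = f";tm_annotations={tm}"
            fh.write(
                f"{mdl.contig_id}\tsitescreen\tmRNA\t{s + 1}\t{e}\t.\t"
                f"{mdl.strand}\t.\tID={mdl.gene_id};Parent={gene_id}{extra}\n"
            )
            for i, (xs, xe) in enumerate(mdl.exons, 1):
                fh.write(
                    f"{mdl.contig_id}\tsitescreen\texon\t{xs + 1}\t{xe}\t.\t"
                    f"{mdl.strand}\t.\tID={mdl.gene_id}.exon{i};"
                    f"Parent={mdl.gene_id}\n"
                )
            phase_first = mdl.cds_phase_offset
            for i, (xs, xe) in enumerate(mdl.exons, 1):
                is_first = (i == 1) if mdl.strand == "+" else (i == len(mdl.exons))
                ph = phase_first if is_first else "."
                fh.write(
                    f"{mdl.contig_id}\tsitescreen\tCDS\t{xs + 1}\t{xe}\t.\t"
                    f"{mdl.strand}\t{ph}\tID={mdl.gene_id}.cds{i};"
                    f"Parent={mdl.gene_id}\n"
                )


def spliced_transcript(model: GeneModel, contigs: Sequence[SeqRecord]) -> SeqRecord:
    """Concatenate exon sequences in transcription order.

    Minus-strand models are reverse-complemented.
    """
    contig = _contig_by_id(contigs, model.contig_id)
    seq = "".join(contig.residues[s:e] for s, e in model.exons)
    if model.strand == "-":
        seq = reverse_complement(seq)
    return SeqRecord(model.gene_id, seq, f"spliced {model.gene_id}", "dna")


def _contig_by_id(contigs: Sequence[SeqRecord], contig_id: str) -> SeqRecord:
    for c in contigs:
        if c.id == contig_id:
            return c
    raise KeyError(f"contig {contig_id!r} not found")


def translate(cds: SeqRecord, code: GeneticCode = STANDARD_CODE) -> SeqRecord:
    """Translate a CDS up to (not including) the first stop codon.

    Codons containing ambiguity letters translate to X. A length not
    divisible by 3 is flagged in the record description, matching the
    behaviour needed for frame-shift detection downstream.
    """
    if len(cds.residues) < 3:
        raise ValueError(f"{cds.id}: CDS shorter than one codon")
    flags = []
    if len(cds.residues) % 3:
        flags.append("length-not-multiple-of-3")
    aa = []
    for i in range(0, len(cds.residues) - len(cds.residues) % 3, 3):
        codon = cds.residues[i:i + 3]
        residue = code.table.get(codon, "X")
        if residue == "*":
            break
        aa.append(residue)
    if not aa:
        raise ValueError(f"{cds.id}: translation empty (immediate stop?)")
    desc = ";".join(flags) if flags else f"translation of {cds.id}"
    return SeqRecord(cds.id, "".join(aa), desc, "protein")
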