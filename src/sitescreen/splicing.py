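"""Transcript-to-genome mapping and alternative-splicing analysis.

Transcripts are mapped back to their locus by exact-match seed-and-extend
with a small per-exon mismatch budget (to tolerate RNA-editing sites);
every inferred intron must begin with the donor consensus and end with
the acceptor consensus (GT..AG by default). Pairwise comparison of the
mapped exon chains against a designated primary transcript classifies
cassette exons, alternative donor/acceptor usage and intron retention,
and reports the reading-frame consequence of each event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .seqio import (
    GeneModel,
    GeneticCode,
    STANDARD_CODE,
    SeqRecord,
    reverse_complement,
    spliced_transcript,
)

MIN_INTRON_LENGTH = 30  # shorter gaps are deletions, not introns
DEFAULT_MISMATCH_BUDGET = 2  # per exon; accommodates A-to-I editing


class UnmappableTranscript(ValueError):
    """No consensus-consistent exon chain reproduces the transcript."""


@dataclass(frozen=True)
class SpliceConsensus:
    donor: str = "GT"
    acceptor: str = "AG"

    def __post_init__(self) -> None:
        for s in (self.donor, self.acceptor):
            if len(s) != 2 or set(s) - set("ACGT"):
                raise ValueError("consensus dinucleotides must be 2-nt DNA")


@dataclass
class SpliceEvent:
    """One alternative-splicing difference relative to the primary model.

    shift_nt is signed: positive when the variant's exon is extended
    (sequence added relative to primary). For alt-site events in_frame
    is equivalent to shift_nt % 3 == 0.
    """

    kind: str  # cassette_exon | alt_acceptor | alt_donor | intron_retention
    transcript_id: str
    intron_index: int
    shift_nt: int
    added_peptide: str
    in_frame: bool


@dataclass
class IsoformConfig:
    transcript_id: str
    features: dict[str, bool]


@dataclass
class SpliceFeature:
    """A binary splice feature detectable from a mapped exon chain.

    kind "cassette": key is the exon's genomic (start, end); present
    when that exact exon appears in the chain. kind "boundary": key is
    ("start"|"end", coordinate); present when some exon carries that
    boundary (used for alternative donor/acceptor extensions).
    """

    name: str
    kind: str
    key: tuple

    def present(self, model: GeneModel) -> bool:
        if self.kind == "cassette":
            return tuple(self.key) in {tuple(e) for e in model.exons}
        side, coord = self.key
        idx = 0 if side == "start" else 1
        return any(e[idx] == coord for e in model.exons)


def map_transcript(
    transcript: SeqRecord,
    contig: SeqRecord,
    consensus: SpliceConsensus = SpliceConsensus(),
    min_intron: int = MIN_INTRON_LENGTH,
    max_intron: int = 20000,
    mismatch_budget: int = DEFAULT_MISMATCH_BUDGET,
) -> GeneModel:
    """Recover the exon chain that spells the transcript on the contig.

    Both strands are tried (plus first). Among consensus-consistent
    chains the leftmost-donor chain is returned. Raises
    UnmappableTranscript when no chain exists.
    """
    L = len(contig.residues)
    for strand in "+-":
        # scan the strand the gene is transcribed from, so introns read
        # donor..acceptor left to right; flip coordinates afterwards
        g = (
            contig.residues
            if strand == "+"
            else reverse_complement(contig.residues)
        )
        chain = _spliced_match(
            transcript.residues, g, consensus, min_intron, max_intron,
            mismatch_budget,
        )
        if chain is not None:
            exons = (
                chain
                if strand == "+"
                else sorted((L - e, L - s) for s, e in chain)
            )
            return GeneModel(
                gene_id=transcript.id,
                contig_id=contig.id,
                strand=strand,
                exons=exons,
            )
    raise UnmappableTranscript(
        f"unmappable transcript {transcript.id!r} on contig {contig.id!r}"
    )


def _spliced_match(
    t: str,
    g: str,
    consensus: SpliceConsensus,
    min_intron: int,
    max_intron: int,
    budget: int,
    total_budget: int | None = None,
    max_introns: int = 16,
) -> list[tuple[int, int]] | None:
    """Find the exon chain spelling t on g with consensus introns.

    Chains are ranked by (total mismatches, intron count) — iterative
    deepening — with leftmost donors as the final tie-break, so a rare
    editing mismatch never trades for a spurious extra intron. `budget`
    caps mismatches per exon; `total_budget` caps them overall.
    """
    if total_budget is None:
        total_budget = 0 if budget == 0 else max(budget, 6)
    for mm_quota in range(total_budget + 1):
        for intron_quota in range(max_introns + 1):
            chain = _match_with_quotas(
                t, g, consensus, min_intron, max_intron, budget,
                mm_quota, intron_quota,
            )
            if chain is not None:
                return chain
    return None


def _match_with_quotas(
    t: str,
    g: str,
    consensus: SpliceConsensus,
    min_intron: int,
    max_intron: int,
    per_exon: int,
    mm_quota: int,
    intron_quota: int,
) -> list[tuple[int, int]] | None:
    n, m = len(t), len(g)
    donor, acceptor = consensus.donor, consensus.acceptor
    failed: set[tuple[int, int, int, int]] = set()

    def seed_ok(ti: int, gi: int, mm_left: int) -> bool:
        k = min(8, n - ti)
        if gi + k > m:
            return False
        mm = 0
        cap = min(per_exon, mm_left)
        for j in range(k):
            if t[ti + j] != g[gi + j]:
                mm += 1
                if mm > cap:
                    return False
        return True

    def extend(
        ti: int, gi: int, mm_left: int, introns_left: int
    ) -> list[tuple[int, int]] | None:
        key = (ti, gi, mm_left, introns_left)
        if key in failed:
            return None
        mm = 0
        j = 0
        limit = min(n - ti, m - gi)
        while True:
            if ti + j == n:
                if j > 0 and introns_left == 0 and mm <= mm_left:
                    return [(gi, gi + j)]
                break
            if (
                j > 0
                and introns_left > 0
                and g[gi + j : gi + j + 2] == donor
            ):
                rest = find_acceptor(
                    ti + j, gi + j, mm_left - mm, introns_left - 1
                )
                if rest is not None:
                    return [(gi, gi + j)] + rest
            if j >= limit:
                break
            if t[ti + j] != g[gi + j]:
                mm += 1
                if mm > min(per_exon, mm_left):
                    break
            j += 1
        failed.add(key)
        return None

    def find_acceptor(
        ti: int, g_donor: int, mm_left: int, introns_left: int
    ) -> list[tuple[int, int]] | None:
        hi = min(m, g_donor + max_intron)
        ge = g_donor + min_intron
        while ge <= hi:
            pos = g.find(acceptor, ge - 2, hi)
            if pos == -1:
                return None
            ge = pos + 2
            if ge + (n - ti) <= m and seed_ok(ti, ge, mm_left):
                rest = extend(ti, ge, mm_left, introns_left)
                if rest is not None:
                    return rest
            ge += 1
        return None

    for g0 in range(0, m - n + 1 if n <= m else 0):
        if not seed_ok(0, g0, mm_quota):
            continue
        chain = extend(0, g0, mm_quota, intron_quota)
        if chain is not None:
            return chain
    return None


def primary_transcript(
    models: list[GeneModel], contig: SeqRecord
) -> GeneModel:
    """Designate the primary transcript: longest spliced CDS, ties by id."""
    def key(mdl: GeneModel) -> tuple[int, str]:
        length = sum(e - s for s, e in mdl.exons)
        return (-length, mdl.gene_id)

    return sorted(models, key=key)[0]


def diff_isoforms(
    models: list[GeneModel],
    contig: SeqRecord,
    primary: GeneModel | None = None,
    code: GeneticCode = STANDARD_CODE,
) -> list[SpliceEvent]:
    """Classify splice differences of each model against the primary.

    Alternative-acceptor upstream shifts are positive extensions; the
    added peptide is translated in the variant's CDS frame (codons that
    are new relative to the primary).
    """
    if len({mdl.contig_id for mdl in models}) > 1:
        raise ValueError("isoform models must share a contig")
    if primary is None:
        primary = primary_transcript(models, contig)
    events: list[SpliceEvent] = []
    for mdl in models:
        if mdl.gene_id == primary.gene_id:
            continue
        events.extend(_compare_pair(primary, mdl, contig, code))
    return events


def _compare_pair(
    primary: GeneModel,
    variant: GeneModel,
    contig: SeqRecord,
    code: GeneticCode,
) -> list[SpliceEvent]:
    p_ex = primary.exons_in_transcription_order()
    v_ex = variant.exons_in_transcription_order()
    strand = primary.strand
    events: list[SpliceEvent] = []

    def five_prime(e: tuple[int, int]) -> int:
        return e[0] if strand == "+" else e[1]

    def three_prime(e: tuple[int, int]) -> int:
        return e[1] if strand == "+" else e[0]

    p_set = {tuple(e) for e in p_ex}
    v_set = {tuple(e) for e in v_ex}

    # cassette exons: exact exon present in exactly one chain, whose
    # boundaries do not pairwise match an alt-site partner
    p_bounds = {b for e in p_ex for b in e}
    v_bounds = {b for e in v_ex for b in e}
    for i, e in enumerate(p_ex):
        if tuple(e) not in v_set and e[0] not in v_bounds and e[1] not in v_bounds:
            if not _retained_in(e, v_ex):
                events.append(
                    _event("cassette_exon", variant, i, -(e[1] - e[0]), "",
                           (e[1] - e[0]) % 3 == 0)
                )
    for i, e in enumerate(v_ex):
        if tuple(e) not in p_set and e[0] not in p_bounds and e[1] not in p_bounds:
            if _retained_in_chain(e, p_ex):
                shift = _retention_shift(e, p_ex)
                events.append(
                    _event("intron_retention", variant, i, shift, "",
                           shift % 3 == 0)
                )
            else:
                pep = ""
                if (e[1] - e[0]) % 3 == 0:
                    pep = _insertion_added_peptide(primary, contig, e, code)
                events.append(
                    _event("cassette_exon", variant, i, e[1] - e[0], pep,
                           (e[1] - e[0]) % 3 == 0)
                )

    # alt donor / acceptor: exons sharing one boundary, differing at other
    for i, ve in enumerate(v_ex):
        if tuple(ve) in p_set:
            continue
        for pe in p_ex:
            if tuple(pe) in v_set:
                continue
            if three_prime(ve) == three_prime(pe) and five_prime(ve) != five_prime(pe):
                # shared donor-side downstream boundary => acceptor differs
                shift = _signed_extension(pe, ve, strand, side="five")
                pep = ""
                if shift > 0 and shift % 3 == 0:
                    seg = _extension_interval(pe, ve, strand, side="five")
                    pep = _insertion_added_peptide(primary, contig, seg, code)
                events.append(
                    _event("alt_acceptor", variant, max(i - 1, 0), shift, pep,
                           shift % 3 == 0)
                )
            elif five_prime(ve) == five_prime(pe) and three_prime(ve) != three_prime(pe):
                shift = _signed_extension(pe, ve, strand, side="three")
                pep = ""
                if shift > 0 and shift % 3 == 0:
                    seg = _extension_interval(pe, ve, strand, side="three")
                    pep = _insertion_added_peptide(primary, contig, seg, code)
                events.append(
                    _event("alt_donor", variant, i, shift, pep,
                           shift % 3 == 0)
                )
    return events


def _event(kind, variant, intron_index, shift, pep, in_frame) -> SpliceEvent:
    return SpliceEvent(
        kind=kind,
        transcript_id=variant.gene_id,
        intron_index=intron_index,
        shift_nt=shift,
        added_peptide=pep,
        in_frame=in_frame,
    )


def _retained_in(exon: tuple[int, int], chain: list[tuple[int, int]]) -> bool:
    return any(s <= exon[0] and exon[1] <= e for s, e in chain)


def _retained_in_chain(exon: tuple[int, int], chain: list[tuple[int, int]]) -> bool:
    """exon spans >= 2 chain exons plus the intervening intron(s)."""
    covered = [e for e in chain if exon[0] <= e[0] and e[1] <= exon[1]]
    return len(covered) >= 2


def _retention_shift(exon: tuple[int, int], chain: list[tuple[int, int]]) -> int:
    covered = [e for e in chain if exon[0] <= e[0] and e[1] <= exon[1]]
    return (exon[1] - exon[0]) - sum(e - s for s, e in covered)


def _signed_extension(pe, ve, strand, side) -> int:
    """Positive when the variant exon is longer on the given side."""
    if side == "five":
        if strand == "+":
            return pe[0] - ve[0]
        return ve[1] - pe[1]
    if strand == "+":
        return ve[1] - pe[1]
    return pe[0] - ve[0]


def _extension_interval(pe, ve, strand, side) -> tuple[int, int]:
    """Genomic interval of sequence the variant adds on the given side."""
    if side == "five":
        return (ve[0], pe[0]) if strand == "+" else (pe[1], ve[1])
    return (pe[1], ve[1]) if strand == "+" else (ve[0], pe[0])


def _translate_string(s: str, code: GeneticCode) -> str:
    return "".join(
        code.table.get(s[i : i + 3], "X")
        for i in range(0, len(s) - len(s) % 3, 3)
    )


def _insertion_added_peptide(
    primary: GeneModel,
    contig: SeqRecord,
    genomic_interval: tuple[int, int],
    code: GeneticCode,
) -> str:
    """Residues an in-frame inserted segment adds to the primary protein.

    The segment (an exonized intron stretch or cassette exon) is spliced
    into the primary transcript at its genomic position and the two
    translations are diffed; this handles insertions that are not
    codon-aligned, where the added residues read across the junction.
    """
    strand = primary.strand
    ptx = spliced_transcript(primary, [contig]).residues
    if strand == "+":
        tpos = sum(e - s for s, e in primary.exons if e <= genomic_interval[0])
    else:
        tpos = sum(e - s for s, e in primary.exons if s >= genomic_interval[1])
    seg = contig.residues[genomic_interval[0] : genomic_interval[1]]
    if strand == "-":
        seg = reverse_complement(seg)
    hybrid = ptx[:tpos] + seg + ptx[tpos:]
    off = primary.cds_phase_offset
    p_prot = _translate_string(ptx[off:], code)
    h_prot = _translate_string(hybrid[off:], code)
    i = 0
    while i < len(p_prot) and i < len(h_prot) and p_prot[i] == h_prot[i]:
        i += 1
    j = 0
    while (
        j < len(p_prot) - i
        and j < len(h_prot) - i
        and p_prot[len(p_prot) - 1 - j] == h_prot[len(h_prot) - 1 - j]
    ):
        j += 1
    return h_prot[i : len(h_prot) - j].replace("*", "")


def enumerate_isoforms(features: list[str]) -> list[IsoformConfig]:
    """All 2^n on/off combinations, in binary-counting order.

    The first feature is the most significant bit; configuration 0 is
    the all-absent reference.
    """
    n = len(features)
    out = []
    for idx in range(2 ** n):
        flags = {
            f: bool(idx >> (n - 1 - j) & 1) for j, f in enumerate(features)
        }
        out.append(IsoformConfig(transcript_id=f"config{idx}", features=flags))
    return out


def config_table(
    transcripts: list[GeneModel], features: list[SpliceFeature]
) -> list[IsoformConfig]:
    """One feature-presence row per transcript."""
    rows = []
    for mdl in transcripts:
        rows.append(
            IsoformConfig(
                transcript_id=mdl.gene_id,
                features={f.name: f.present(mdl) for f in features},
            )
        )
    return rows


def collapse_duplicate_configs(
    rows: list[IsoformConfig],
) -> tuple[list[IsoformConfig], dict[str, int]]:
    """Collapse identical feature vectors; returns (unique rows, counts)."""
    seen: dict[tuple, IsoformConfig] = {}
    counts: dict[str, int] = {}
    for row in rows:
        key = tuple(sorted(row.features.items()))
        if key not in seen:
            seen[key] = row
            counts[row.transcript_id] = 1
        else:
            counts[seen[key].transcript_id] += 1
    return list(seen.values()), counts


def write_config_table(rows: list[IsoformConfig], path: str) -> None:
    """TSV with X (present) / – (absent) marks."""
    if not rows:
        return
    names = list(rows[0].features)
    with open(path, "w") as fh:
        fh.write("transcript\t" + "\t".join(names) + "\n")
        for row in rows:
            marks = ["X" if row.features[n] else "–" for n in names]
            fh.write(row.transcript_id + "\t" + "\t".join(marks) + "\n")


def find_missing_exon(
    ref_exon: SeqRecord,
    genomic: SeqRecord,
    as_protein: bool = False,
    score_floor_fraction: float = 0.5,
) -> tuple[tuple[int, int], float] | None:
    """Local-search an exon sequence against a genomic locus.

    Returns (genomic interval, percent identity) of the best local hit,
    or None when the best raw score falls below score_floor_fraction of
    the exon's self-alignment score — the "absent from genome" call.
    In protein mode the exon peptide is searched against all six
    translation frames (tBLASTn-like).
    """
    if as_protein:
        return _protein_exon_search(ref_exon, genomic, score_floor_fraction)
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -7
    aligner.extend_gap_score = -2
    self_score = aligner.align(ref_exon.residues, ref_exon.residues).score
    alns = aligner.align(genomic.residues, ref_exon.residues)
    if alns.score < score_floor_fraction * self_score:
        return None
    aln = alns[0]
    blocks = aln.aligned[0]
    interval = (int(blocks[0][0]), int(blocks[-1][1]))
    ident = _local_identity(str(aln[0]), str(aln[1]))
    return interval, ident


def _protein_exon_search(
    ref_exon: SeqRecord, genomic: SeqRecord, floor: float
) -> tuple[tuple[int, int], float] | None:
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -1
    self_score = aligner.align(ref_exon.residues, ref_exon.residues).score

    g = genomic.residues
    best = None
    for strand in "+-":
        seq = g if strand == "+" else reverse_complement(g)
        for frame in range(3):
            prot = "".join(
                STANDARD_CODE.table.get(seq[i : i + 3], "X")
                for i in range(frame, len(seq) - 2, 3)
            )
            if not prot:
                continue
            alns = aligner.align(prot, ref_exon.residues)
            if alns.score <= 0:
                continue
            if best is None or alns.score > best[0]:
                aln = alns[0]
                blocks = aln.aligned[0]
                ps, pe = int(blocks[0][0]), int(blocks[-1][1])
                if strand == "+":
                    interval = (frame + 3 * ps, frame + 3 * pe)
                else:
                    interval = (
                        len(g) - (frame + 3 * pe),
                        len(g) - (frame + 3 * ps),
                    )
                ident = _local_identity(str(aln[0]), str(aln[1]))
                best = (alns.score, interval, ident)
    if best is None or best[0] < floor * self_score:
        return None
    return best[1], best[2]


def _local_identity(row_a: str, row_b: str) -> float:
    cols = sum(1 for x, y in zip(row_a, row_b) if x != "-" or y != "-")
    ident = sum(1 for x, y in zip(row_a, row_b) if x == y and x != "-")
    return 100.0 * ident / cols if cols else 0.0
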