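"""Projection of known target-site resistance mutations onto orthologs.

A catalog of published resistance substitutions (each in its reference
species' protein numbering) is projected onto query proteins by
semi-global alignment (global with free terminal gaps, Gonnet-class
matrix). Each site is then called susceptible (wild-type residue),
resistant (published resistant residue), divergent (neither), or
unalignable (reference position opposite a gap or outside the aligned
region — the fate of N-terminal sites against proteins whose N-terminus
does not align).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

from .homology import global_alignment, identity_from_alignment
from .seqio import SeqRecord

CONFIDENCE_WINDOW = 20  # residues each side of the projected site
CONFIDENCE_MIN_IDENTITY = 50.0


@dataclass(frozen=True)
class MutationCatalogEntry:
    target_gene: str
    reference_species: str
    reference_seq_id: str
    position: int  # 1-based in the reference protein
    wild_type_aa: str
    resistant_aa: str
    insecticide_class: str
    numbering_note: str = ""

    def __post_init__(self) -> None:
        if self.wild_type_aa == self.resistant_aa:
            raise ValueError("wild-type and resistant residues must differ")
        if self.position < 1:
            raise ValueError("position is 1-based and must be >= 1")


@dataclass
class ResistanceCall:
    entry: MutationCatalogEntry
    query_id: str | None
    query_position: int | None  # 1-based in the query protein
    query_aa: str | None
    state: str  # susceptible | resistant | divergent | unalignable | no_ortholog
    low_confidence: bool = False


class CatalogWarning(UserWarning):
    """Reference/catalog drift (residue at cataloged position differs)."""


def read_catalog(path: str | None = None) -> list[MutationCatalogEntry]:
    """Read the mutation catalog TSV; defaults to the shipped catalog."""
    if path is None:
        ref = resources.files("sitescreen.data") / "resistance_catalog.tsv"
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    entries = []
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    for ln in lines[1:]:
        row = dict(zip(header, ln.split("\t")))
        entries.append(
            MutationCatalogEntry(
                target_gene=row["target_gene"],
                reference_species=row["reference_species"],
                reference_seq_id=row["reference_seq_id"],
                position=int(row["position"]),
                wild_type_aa=row["wild_type_aa"],
                resistant_aa=row["resistant_aa"],
                insecticide_class=row["insecticide_class"],
                numbering_note=row.get("numbering_note", ""),
            )
        )
    return entries


def write_catalog(entries: list[MutationCatalogEntry], path: str) -> None:
    cols = [
        "target_gene", "reference_species", "reference_seq_id", "position",
        "wild_type_aa", "resistant_aa", "insecticide_class", "numbering_note",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for e in entries:
            fh.write("\t".join(str(getattr(e, c)) for c in cols) + "\n")


def project_site(
    entry: MutationCatalogEntry,
    reference: SeqRecord,
    query: SeqRecord,
    matrix: str = "GONNET1992",
    gap_open: float = 10.0,
    gap_extend: float = 0.2,
) -> ResistanceCall:
    """Call the state of one cataloged site on a query protein."""
    if not query.residues:
        raise ValueError("empty query")
    pos0 = entry.position - 1
    if pos0 >= len(reference.residues):
        raise ValueError(
            f"{entry.reference_seq_id}: cataloged position {entry.position} "
            f"beyond reference length {len(reference.residues)}"
        )
    if reference.residues[pos0] != entry.wild_type_aa:
        warnings.warn(
            f"{entry.reference_seq_id} position {entry.position}: reference "
            f"has {reference.residues[pos0]}, catalog expects "
            f"{entry.wild_type_aa} (accession/version drift?)",
            CatalogWarning,
        )
    row_ref, row_q = global_alignment(
        reference, query, matrix, gap_open, gap_extend, free_end_gaps=True
    )
    ref_i = -1
    col_of_site = None
    for col, ch in enumerate(row_ref):
        if ch != "-":
            ref_i += 1
            if ref_i == pos0:
                col_of_site = col
                break
    assert col_of_site is not None

    q_aa = row_q[col_of_site]
    aligned_cols = [
        c for c, (x, y) in enumerate(zip(row_ref, row_q))
        if x != "-" and y != "-"
    ]
    outside = (
        not aligned_cols
        or col_of_site < aligned_cols[0]
        or col_of_site > aligned_cols[-1]
    )
    if q_aa == "-" or outside:
        return ResistanceCall(entry, query.id, None, None, "unalignable")

    q_pos = sum(1 for ch in row_q[: col_of_site + 1] if ch != "-")
    if q_aa == entry.wild_type_aa:
        state = "susceptible"
    elif q_aa == entry.resistant_aa:
        state = "resistant"
    else:
        state = "divergent"
    lo = max(0, col_of_site - CONFIDENCE_WINDOW)
    hi = col_of_site + CONFIDENCE_WINDOW + 1
    window_ident = identity_from_alignment(row_ref[lo:hi], row_q[lo:hi])
    return ResistanceCall(
        entry,
        query.id,
        q_pos,
        q_aa,
        state,
        low_confidence=window_ident < CONFIDENCE_MIN_IDENTITY,
    )


def screen(
    catalog: list[MutationCatalogEntry],
    references: list[SeqRecord],
    queries: list[SeqRecord],
    ortholog_map: dict[str, str | None],
    matrix: str = "GONNET1992",
) -> list[ResistanceCall]:
    """Project every catalog entry onto its mapped ortholog.

    ortholog_map maps query id -> reference seq id (as produced by
    homology.assign_orthologs). Entries whose reference has no assigned
    ortholog among the queries are reported with state "no_ortholog".
    """
    ref_by_id = {r.id: r for r in references}
    q_by_id = {q.id: q for q in queries}
    inverse: dict[str, list[str]] = {}
    for qid, rid in sorted(ortholog_map.items()):
        if rid is not None:
            inverse.setdefault(rid, []).append(qid)

    calls: list[ResistanceCall] = []
    for entry in catalog:
        if entry.reference_seq_id not in ref_by_id:
            raise KeyError(
                f"catalog references unknown sequence {entry.reference_seq_id!r}"
            )
        mapped = inverse.get(entry.reference_seq_id, [])
        if not mapped:
            calls.append(ResistanceCall(entry, None, None, None, "no_ortholog"))
            continue
        for qid in mapped:
            calls.append(
                project_site(entry, ref_by_id[entry.reference_seq_id],
                             q_by_id[qid], matrix=matrix)
            )
    return calls


def write_screen_report(calls: list[ResistanceCall], path: str) -> None:
    cols = [
        "target_gene", "reference_seq_id", "site", "insecticide_class",
        "query", "query_position", "query_aa", "state", "low_confidence",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in calls:
            e = c.entry
            site = f"{e.wild_type_aa}{e.position}{e.resistant_aa}"
            fh.write(
                "\t".join(
                    [
                        e.target_gene, e.reference_seq_id, site,
                        e.insecticide_class, c.query_id or "-",
                        str(c.query_position or "-"), c.query_aa or "-",
                        c.state, "yes" if c.low_confidence else "no",
                    ]
                )
                + "\n"
            )
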