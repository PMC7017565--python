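"""End-to-end screening pipeline: orchestration, config, reports.

Runs homology → splicing → editing → resistance → motifs → phylo over a
genome/annotation/transcript/protein bundle and writes per-stage TSV
reports, Newick trees, a per-gene text summary, and a MANIFEST with
checksums. Reports use 1-based coordinates; all internal computation is
0-based. Outputs are byte-identical for identical configs (no
timestamps are written).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .editing import call_editing, edit_candidates, write_editing_report
from .homology import (
    SearchThresholds,
    assign_orthologs,
    global_identity,
    write_identity_table,
)
from .motifs import (
    check_features,
    read_feature_catalog,
    read_pattern_catalog,
    scan,
    write_hit_report,
)
from .phylo import AlignParams, bootstrap, progressive_msa, write_newick
from .resistance import read_catalog, screen, write_screen_report
from .seqio import read_fasta, read_gff3, spliced_transcript
from .splicing import (
    SpliceConsensus,
    diff_isoforms,
    map_transcript,
    primary_transcript,
)


@dataclass
class RunConfig:
    genome: str
    gff: str
    transcripts: str  # transcript evidence FASTA (ids match mRNA ids)
    proteome: str
    refs: str
    out_dir: str
    catalog: str | None = None  # default: shipped resistance catalog
    seed: int = 0
    bootstrap_reps: int = 100
    thresholds: SearchThresholds = field(default_factory=SearchThresholds)
    align_params: AlignParams = field(default_factory=AlignParams)
    consensus: SpliceConsensus = field(default_factory=SpliceConsensus)
    max_tree_taxa: int = 20
    max_tree_seq_len: int = 800
    run_phylo: bool = True

    def digest(self) -> str:
        """Hash of the scientific configuration (output path excluded)."""
        payload = json.dumps(
            {
                k: str(v)
                for k, v in sorted(self.__dict__.items())
                if k != "out_dir"
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_screen(config: RunConfig) -> Path:
    """Execute all stages; returns the output directory.

    On stage failure a StageError propagates after the MANIFEST is
    written noting the failed stage; completed outputs are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    failed_stage: str | None = None

    contigs = read_fasta(config.genome, alphabet="dna")
    contig_by_id = {c.id: c for c in contigs}
    models = read_gff3(config.gff, contigs)
    evidence = {r.id: r for r in read_fasta(config.transcripts, alphabet="dna")}
    proteome = read_fasta(config.proteome, alphabet="protein")
    refs = read_fasta(config.refs, alphabet="protein")
    catalog = read_catalog(config.catalog)

    summary: dict[str, dict] = {}

    def record(path: Path) -> None:
        written.append(path)

    try:
        # ---- homology ------------------------------------------------
        stage = "homology"
        ortho = assign_orthologs(proteome, refs, config.thresholds)
        ref_by_id = {r.id: r for r in refs}
        reports = []
        for q in proteome:
            rid = ortho.get(q.id)
            if rid is not None:
                reports.append(global_identity(q, ref_by_id[rid]))
            summary.setdefault(q.id, {})["ortholog"] = rid or "none"
        write_identity_table(reports, out / "identity.tsv")
        record(out / "identity.tsv")
        with open(out / "orthologs.tsv", "w") as fh:
            fh.write("query\tref\n")
            for qid in sorted(ortho):
                fh.write(f"{qid}\t{ortho[qid] or '-'}\n")
        record(out / "orthologs.tsv")

        # ---- splicing ------------------------------------------------
        stage = "splicing"
        by_gene: dict[str, list] = {}
        for mdl in models:
            base = mdl.gene_id.split(".")[0]
            by_gene.setdefault(base, []).append(mdl)
        with open(out / "splice_events.tsv", "w") as fh:
            fh.write(
                "gene\ttranscript\tkind\tintron\tshift_nt\tin_frame\t"
                "added_peptide\n"
            )
            for base in sorted(by_gene):
                group = by_gene[base]
                contig = contig_by_id[group[0].contig_id]
                events = diff_isoforms(group, contig) if len(group) > 1 else []
                summary.setdefault(base, {})["splice_events"] = len(events)
                for ev in events:
                    fh.write(
                        f"{base}\t{ev.transcript_id}\t{ev.kind}\t"
                        f"{ev.intron_index}\t{ev.shift_nt}\t"
                        f"{'yes' if ev.in_frame else 'no'}\t"
                        f"{ev.added_peptide or '-'}\n"
                    )
        record(out / "splice_events.tsv")

        # ---- editing -------------------------------------------------
        stage = "editing"
        with open(out / "editing.tsv", "w") as fh:
            fh.write("gene\tcontig_pos\tstrand\tchange\tstatus\tnote\n")
            for mdl in models:
                if mdl.gene_id not in evidence:
                    summary.setdefault(mdl.gene_id, {})["editing"] = (
                        "no evidence"
                    )
                    continue
                contig = contig_by_id[mdl.contig_id]
                sites = call_editing(mdl, contig, evidence[mdl.gene_id])
                cands = edit_candidates(sites)
                summary.setdefault(
                    mdl.gene_id.split(".")[0], {}
                )["editing_candidates"] = len(cands)
                for s in sites:
                    fh.write(
                        f"{s.gene_id}\t{mdl.contig_id}:{s.genomic_pos + 1}\t"
                        f"{mdl.strand}\t{s.sense_strand_change}\t{s.status}\t"
                        f"{s.note}\n"
                    )
        record(out / "editing.tsv")

        # ---- resistance ----------------------------------------------
        stage = "resistance"
        calls = screen(catalog, refs, proteome, ortho)
        write_screen_report(calls, out / "resistance.tsv")
        record(out / "resistance.tsv")
        n_resistant = sum(1 for c in calls if c.state == "resistant")
        summary.setdefault("_global", {})["resistant_calls"] = n_resistant

        # ---- motifs --------------------------------------------------
        stage = "motifs"
        patterns = read_pattern_catalog()
        hits = []
        for pat in patterns:
            for rec in proteome:
                hits.extend(scan(pat, rec))
        write_hit_report(hits, out / "motif_hits.tsv")
        record(out / "motif_hits.tsv")

        features = read_feature_catalog()
        prot_by_id = {p.id: p for p in proteome}
        with open(out / "channel_features.tsv", "w") as fh:
            fh.write("protein\tfeature\tstatus\tobserved\tposition\n")
            for mdl in models:
                pid = f"{mdl.gene_id}_prot"
                if pid not in prot_by_id:
                    continue
                for rep in check_features(
                    prot_by_id[pid], mdl.annotations, features
                ):
                    fh.write(
                        f"{pid}\t{rep.feature_id}\t{rep.status}\t"
                        f"{rep.observed or '-'}\t{rep.position or '-'}\n"
                    )
        record(out / "channel_features.tsv")

        # ---- phylo ---------------------------------------------------
        stage = "phylo"
        if config.run_phylo:
            taxa = sorted(
                (
                    p
                    for p in proteome
                    if len(p.residues) <= config.max_tree_seq_len
                ),
                key=lambda p: p.id,
            )[: config.max_tree_taxa]
            if len(taxa) >= 3:
                msa = progressive_msa(taxa, config.align_params)
                tree = bootstrap(
                    msa, reps=config.bootstrap_reps, seed=config.seed
                )
                (out / "tree.nwk").write_text(write_newick(tree) + "\n")
                record(out / "tree.nwk")
    except Exception as exc:  # noqa: BLE001 - stage fault barrier
        failed_stage = stage
        _write_manifest(out, written, failed_stage)
        raise StageError(stage, exc) from exc

    # ---- per-gene text summary --------------------------------------
    with open(out / "summary.txt", "w") as fh:
        fh.write(f"sitescreen {__version__} run summary\n")
        fh.write(f"config {config.digest()} seed {config.seed}\n\n")
        for key in sorted(summary):
            if key == "_global":
                continue
            parts = ", ".join(
                f"{k}={v}" for k, v in sorted(summary[key].items())
            )
            fh.write(f"{key}: {parts}\n")
        g = summary.get("_global", {})
        fh.write(f"\nresistant calls: {g.get('resistant_calls', 0)}\n")
    record(out / "summary.txt")

    with open(out / "run.log", "w") as fh:
        fh.write(f"version\t{__version__}\n")
        fh.write(f"config_hash\t{config.digest()}\n")
        fh.write(f"seed\t{config.seed}\n")
    record(out / "run.log")

    _write_manifest(out, written, None)
    return out


def _write_manifest(out: Path, files: list[Path], failed_stage: str | None) -> None:
    with open(out / "MANIFEST", "w") as fh:
        if failed_stage:
            fh.write(f"# FAILED at stage: {failed_stage}\n")
        for f in sorted(set(files)):
            digest = hashlib.sha256(f.read_bytes()).hexdigest()
            fh.write(f"{digest}  {f.name}\n")
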