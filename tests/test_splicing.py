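"""Transcript mapping, splice-event classification, isoform enumeration."""

import numpy as np
import pytest

from sitescreen.seqio import SeqRecord, spliced_transcript
from sitescreen.splicing import (
    SpliceConsensus,
    SpliceFeature,
    UnmappableTranscript,
    collapse_duplicate_configs,
    config_table,
    diff_isoforms,
    enumerate_isoforms,
    find_missing_exon,
    map_transcript,
    primary_transcript,
)
from sitescreen.synthetic import (
    SimConfig,
    make_alt_acceptor_fixture,
    simulate,
)


def _dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _two_exon_locus(intron_ends=("GT", "AG"), seed=0):
    rng = np.random.default_rng(seed)
    exon1, exon2 = "ATGGCTGAAACT", "GGTCACCATTAA"
    intron = intron_ends[0] + _dna(rng, 36) + intron_ends[1]
    contig = SeqRecord(
        "locus", _dna(rng, 50) + exon1 + intron + exon2 + _dna(rng, 50)
    )
    return contig, SeqRecord("t", exon1 + exon2)


class TestMapTranscript:
    def test_gt_ag_boundaries_recovered(self):
        contig, tx = _two_exon_locus()
        model = map_transcript(tx, contig)
        assert len(model.exons) == 2
        s, e = model.introns()[0]
        assert contig.residues[s:s + 2] == "GT"
        assert contig.residues[e - 2:e] == "AG"
        assert spliced_transcript(model, [contig]).residues == tx.residues

    def test_gc_ag_intron_unmappable_under_default_consensus(self):
        contig, tx = _two_exon_locus(intron_ends=("GC", "AG"))
        with pytest.raises(UnmappableTranscript):
            map_transcript(tx, contig)
        # but mappable when the caller declares the consensus
        model = map_transcript(tx, contig, SpliceConsensus("GC", "AG"))
        assert len(model.exons) == 2

    def test_generator_truth_recovered_both_strands(self, bundle, contig_by_id):
        for mdl in bundle.models:
            tx = spliced_transcript(mdl, [contig_by_id[mdl.contig_id]])
            mapped = map_transcript(tx, contig_by_id[mdl.contig_id])
            assert mapped.exons == mdl.exons
            assert mapped.strand == mdl.strand

    def test_all_reported_introns_satisfy_consensus(self, bundle, contig_by_id):
        for mdl in bundle.models:
            contig = contig_by_id[mdl.contig_id]
            g = contig.residues
            for s, e in mdl.introns():
                if mdl.strand == "+":
                    assert g[s:s + 2] == "GT" and g[e - 2:e] == "AG"
                else:
                    assert g[s:s + 2] == "CT" and g[e - 2:e] == "AC"


class TestDiffIsoforms:
    def test_alt_acceptor_12nt_adds_msss(self):
        contig, prim, var = make_alt_acceptor_fixture("MSSS")
        mp, mv = map_transcript(prim, contig), map_transcript(var, contig)
        (ev,) = diff_isoforms([mp, mv], contig, primary=mp)
        assert ev.kind == "alt_acceptor"
        assert ev.shift_nt == 12
        assert ev.in_frame
        assert ev.added_peptide == "MSSS"

    def test_alt_acceptor_15nt_adds_scllq(self):
        contig, prim, var = make_alt_acceptor_fixture("SCLLQ")
        mp, mv = map_transcript(prim, contig), map_transcript(var, contig)
        (ev,) = diff_isoforms([mp, mv], contig, primary=mp)
        assert ev.shift_nt == 15
        assert ev.added_peptide == "SCLLQ"

    def test_identical_models_give_no_events(self):
        contig, tx = _two_exon_locus()
        m1 = map_transcript(tx, contig)
        m2 = map_transcript(SeqRecord("t2", tx.residues), contig)
        assert diff_isoforms([m1, m2], contig, primary=m1) == []

    def test_cassette_exon_detected_from_generator(self, bundle, contig_by_id):
        cassette_pairs = 0
        for vm in bundle.variant_models:
            base = vm.gene_id.split(".")[0]
            truth = bundle.truth["genes"][base]["isoforms"][vm.gene_id]
            prim = next(m for m in bundle.models if m.gene_id == base)
            contig = contig_by_id[vm.contig_id]
            events = diff_isoforms([prim, vm], contig, primary=prim)
            kinds = {e.kind for e in events}
            assert truth["kind"] in kinds
            ev = next(e for e in events if e.kind == truth["kind"])
            assert abs(ev.shift_nt) == abs(truth["shift_nt"])
            assert ev.in_frame == truth["in_frame"]
            if truth["kind"] == "cassette_exon":
                cassette_pairs += 1
        assert cassette_pairs > 0  # the bundle exercises cassette exons

    def test_in_frame_event_preserves_downstream_protein(self):
        from sitescreen.seqio import translate

        contig, prim, var = make_alt_acceptor_fixture("MSSS")
        p = translate(prim).residues
        v = translate(var).residues
        assert len(v) == len(p) + 4
        assert v.endswith(p[-10:])  # downstream of the event unchanged


class TestEnumerateIsoforms:
    def test_four_features_sixteen_configs(self):
        configs = enumerate_isoforms(
            ["exon9a", "exon9b", "intron10_donor_ext", "intron10_acceptor_ext"]
        )
        assert len(configs) == 16
        vectors = {tuple(c.features.values()) for c in configs}
        assert len(vectors) == 16  # all distinct

    def test_zero_features_single_reference(self):
        assert len(enumerate_isoforms([])) == 1

    @pytest.mark.parametrize("n", [1, 3, 5])
    def test_power_of_two(self, n):
        assert len(enumerate_isoforms([f"f{i}" for i in range(n)])) == 2 ** n


class TestConfigTable:
    def test_feature_marks_match_generator_truth(self, bundle, contig_by_id):
        for vm in bundle.variant_models:
            base = vm.gene_id.split(".")[0]
            truth = bundle.truth["genes"][base]["isoforms"][vm.gene_id]
            if truth["kind"] != "cassette_exon":
                continue
            prim = next(m for m in bundle.models if m.gene_id == base)
            extra = [e for e in vm.exons if e not in prim.exons]
            feat = SpliceFeature("cassette", "cassette", tuple(extra[0]))
            rows = config_table([prim, vm], [feat])
            marks = {r.transcript_id: r.features["cassette"] for r in rows}
            assert marks[vm.gene_id] is True
            assert marks[prim.gene_id] is False

    def test_duplicate_configs_collapse(self):
        contig, tx = _two_exon_locus()
        m1 = map_transcript(tx, contig)
        m2 = map_transcript(SeqRecord("t2", tx.residues), contig)
        feat = SpliceFeature("f", "cassette", tuple(m1.exons[0]))
        rows = config_table([m1, m2], [feat])
        unique, counts = collapse_duplicate_configs(rows)
        assert len(unique) == 1
        assert counts[unique[0].transcript_id] == 2


class TestFindMissingExon:
    def test_planted_exon_found_at_interval(self):
        rng = np.random.default_rng(9)
        exon = _dna(rng, 60)
        genomic = _dna(rng, 300) + exon + _dna(rng, 300)
        res = find_missing_exon(SeqRecord("e", exon), SeqRecord("g", genomic))
        assert res is not None
        (s, e), ident = res
        assert (s, e) == (300, 360)
        assert ident == pytest.approx(100.0)

    def test_absent_exon_returns_none(self):
        rng = np.random.default_rng(10)
        exon = _dna(rng, 60)
        genomic = _dna(rng, 600)
        assert find_missing_exon(
            SeqRecord("e", exon), SeqRecord("g", genomic)
        ) is None

    def test_diverged_exon_found_with_identity_reported(self):
        rng = np.random.default_rng(11)
        exon = list(_dna(rng, 110))
        genomic_exon = exon.copy()
        for p in rng.choice(110, size=20, replace=False):
            genomic_exon[p] = "ACGT"[(("ACGT".index(genomic_exon[p])) + 1) % 4]
        genomic = _dna(rng, 200) + "".join(genomic_exon) + _dna(rng, 200)
        res = find_missing_exon(
            SeqRecord("e", "".join(exon)), SeqRecord("g", genomic)
        )
        assert res is not None
        _, ident = res
        assert 70 <= ident < 100

    def test_protein_mode_finds_exon_in_frame(self):
        rng = np.random.default_rng(12)
        from sitescreen.synthetic import _NONSTOP_CODONS

        codons = [_NONSTOP_CODONS[i] for i in rng.integers(0, 61, 40)]
        exon_nt = "".join(codons)
        from sitescreen.seqio import translate

        pep = translate(SeqRecord("nt", exon_nt + "TAA")).residues
        genomic = _dna(rng, 151) + exon_nt + _dna(rng, 150)
        res = find_missing_exon(
            SeqRecord("p", pep, alphabet="protein"),
            SeqRecord("g", genomic),
            as_protein=True,
        )
        assert res is not None
        (s, e), ident = res
        assert s == 151 and e == 151 + len(exon_nt)
        assert ident == pytest.approx(100.0)


class TestPrimaryTranscript:
    def test_longest_then_lexicographic(self, bundle, contig_by_id):
        contig, prim, var = make_alt_acceptor_fixture("MSSS")
        mp, mv = map_transcript(prim, contig), map_transcript(var, contig)
        assert primary_transcript([mp, mv], contig).gene_id == mv.gene_id
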