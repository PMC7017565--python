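"""PROSITE pattern engine and channel-feature checks."""

import numpy as np
import pytest

from sitescreen.motifs import (
    ChannelFeature,
    PatternParseError,
    check_features,
    parse_pattern,
    read_feature_catalog,
    read_pattern_catalog,
    scan,
)
from sitescreen.seqio import SeqRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _prot(seq, pid="p"):
    return SeqRecord(pid, seq, alphabet="protein")


from oracles import regex_scan


class TestParsePattern:
    @pytest.mark.parametrize(
        "raw,width",
        [
            ("N-{P}-[ST]-{P}", 4),
            ("C-x(13)-C", 15),
            ("[ST]-x(2)-[DE]", 4),
            ("[RK](2)-x-[ST]", 4),
            ("G-{EDRKHPFYW}-x(2)-[STAGCN]-{P}", 6),
            ("x-G-[RK]-[RK]", 4),
        ],
    )
    def test_fixed_widths(self, raw, width):
        assert parse_pattern(raw).fixed_width == width

    def test_variable_repeat(self):
        p = parse_pattern("A-x(2,4)-C")
        assert p.min_width == 4 and p.max_width == 6

    @pytest.mark.parametrize(
        "raw", ["A-(3)", "A-[", "A-x(a)", "A--C", "a-b", "A-x(3,1)"]
    )
    def test_unsupported_constructs_rejected(self, raw):
        with pytest.raises(PatternParseError):
            parse_pattern(raw)

    def test_anchors(self):
        p = parse_pattern("<M-x(3)>")
        assert p.anchored_start and p.anchored_end


class TestScan:
    def test_shipped_patterns_match_regex_oracle_on_random_sequences(self):
        """Direct matcher agrees with a regex oracle everywhere."""
        rng = np.random.default_rng(33)
        patterns = read_pattern_catalog()
        extra = [parse_pattern("C-x(13)-C"), parse_pattern("A-x(2,4)-C")]
        for _ in range(2000):
            seq = "".join(AA20[i] for i in rng.integers(0, 20, 40))
            rec = _prot(seq)
            for pat in patterns + extra:
                mine = [(h.start, h.matched) for h in scan(pat, rec)]
                assert mine == regex_scan(pat, seq), pat.raw

    def test_overlapping_matches_reported(self):
        p = parse_pattern("[ST]-x-[RK]")
        hits = scan(p, _prot("STSRK"))
        assert [h.start for h in hits] == [2, 3]  # TSR and SRK overlap

    def test_sequence_shorter_than_width_no_hits(self):
        assert scan(parse_pattern("C-x(13)-C"), _prot("CCC")) == []

    def test_hit_invariants(self):
        rng = np.random.default_rng(34)
        seq = "".join(AA20[i] for i in rng.integers(0, 20, 200))
        for pat in read_pattern_catalog():
            rec = _prot(seq)
            for h in scan(pat, rec):
                assert seq[h.start - 1 : h.start - 1 + len(h.matched)] == h.matched
                assert len(h.matched) == pat.fixed_width


# Motif strings with their printed 1-based peptide offsets, by PTM class
# (octopamine/tyramine receptor survey); X is an unknown residue.
TABLE_MOTIFS = [
    ("PS00001", "NATA", 6), ("PS00001", "NSTL", 171), ("PS00001", "NGSN", 272),
    ("PS00001", "NNSL", 528), ("PS00001", "NETD", 17), ("PS00001", "NITV", 3),
    ("PS00006", "TDPE", 20), ("PS00006", "TLQE", 173), ("PS00006", "SSCD", 371),
    ("PS00006", "TGRE", 376), ("PS00006", "SLGD", 530), ("PS00006", "TFSE", 6),
    ("PS00005", "SSK", 52), ("PS00005", "SHK", 137), ("PS00005", "TTR", 224),
    ("PS00005", "SGK", 261), ("PS00005", "SRR", 502), ("PS00005", "SLR", 276),
    ("PS00008", "GSPHSN", 267), ("PS00008", "GSNSTT", 273),
    ("PS00008", "GIIVGG", 424), ("PS00008", "GISAGL", 269),
    ("PS00008", "GXGATK", 348), ("PS00008", "GLTVAT", 20),
    ("PS00009", "SGKR", 261), ("PS00009", "MGKR", 401), ("PS00009", "NGRR", 286),
    ("PS00004", "RRSS", 363), ("PS00004", "RRGS", 503), ("PS00004", "KRRS", 156),
    ("PS00004", "RRST", 288), ("PS00004", "RKST", 247), ("PS00004", "RRET", 365),
]


class TestSurveyMotifs:
    @pytest.mark.parametrize("pattern_id,motif,pos", TABLE_MOTIFS)
    def test_each_survey_motif_hits_its_class_pattern_at_offset(
        self, pattern_id, motif, pos
    ):
        """Every published motif string, embedded at its printed offset
        in a neutral carrier, is found by its class pattern there."""
        patterns = {p.pattern_id: p for p in read_pattern_catalog()}
        carrier = "P" * 600  # proline never satisfies these patterns
        seq = carrier[: pos - 1] + motif + carrier[pos - 1 + len(motif):]
        hits = scan(patterns[pattern_id], _prot(seq))
        starts = [h.start for h in hits]
        assert pos in starts


class TestCheckFeatures:
    def _subunit(self, pore="PAR"):
        rng = np.random.default_rng(35)
        seq = "".join(AA20[i] for i in rng.integers(0, 20, 200))
        # plant the pore motif 2 residues before the TM2 annotation
        tm2 = (120, 143)
        seq = seq[: tm2[0] - 5] + pore + seq[tm2[0] - 2 :]
        return _prot(seq, "subunit"), {"TM2": tm2}

    def test_pore_filter_variant_classes(self):
        features = [
            f for f in read_feature_catalog() if f.feature_id == "pore_filter"
        ]
        prot, ann = self._subunit("GEK")
        assert check_features(prot, ann, features)[0].status == "present"
        for variant in ("PAR", "KDR", "ADR", "SAR"):
            prot, ann = self._subunit(variant)
            rep = check_features(prot, ann, features)[0]
            assert rep.status == "variant"
            assert rep.observed == variant

    def test_missing_annotation_not_evaluable(self):
        features = [
            f for f in read_feature_catalog() if f.feature_id == "pore_filter"
        ]
        prot, _ = self._subunit()
        assert check_features(prot, {}, features)[0].status == "not_evaluable"

    def test_cys_loop_present_and_absent(self):
        feat = [f for f in read_feature_catalog() if f.feature_id == "cys_loop"]
        rng = np.random.default_rng(36)
        backbone = "".join(
            "ADEFGHIKLMNPQRSTVW"[i] for i in rng.integers(0, 18, 100)
        )  # cysteine-free
        absent = check_features(_prot(backbone), {}, feat)[0]
        assert absent.status == "absent"
        planted = backbone[:40] + "C" + backbone[41:54] + "C" + backbone[55:]
        present = check_features(_prot(planted), {}, feat)[0]
        assert present.status == "present"
        assert present.position == 41

    def test_selectivity_filter_variant(self):
        feat = [
            f for f in read_feature_catalog()
            if f.feature_id == "selectivity_filter"
        ]
        rng = np.random.default_rng(37)
        backbone = "".join(
            "CFGHILMNPQRSTVWY"[i] for i in rng.integers(0, 16, 120)
        )
        seq = backbone[:60] + "DEEA" + backbone[64:]
        rep = check_features(_prot(seq), {}, feat)[0]
        assert rep.status == "variant"
        assert rep.observed == "DEEA"

    def test_dry_motif_at_tm3_end(self):
        feat = [f for f in read_feature_catalog() if f.feature_id == "dry_motif"]
        rng = np.random.default_rng(38)
        backbone = "".join(
            "ACEFGHIKLMNPQSTVW"[i] for i in rng.integers(0, 17, 150)
        )
        tm3 = (70, 95)
        seq = backbone[:95] + "DRY" + backbone[98:]
        rep = check_features(_prot(seq), {"TM3": tm3}, feat)[0]
        assert rep.status == "present"
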