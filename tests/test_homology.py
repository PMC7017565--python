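"""Local/global alignment operations and ortholog assignment."""

import numpy as np
import pytest
from sitescreen.homology import (
    SearchThresholds,
    assign_orthologs,
    deletion_span,
    global_identity,
    local_search,
    merge_fragments,
)
from sitescreen.seqio import SeqRecord

from oracles import brute_force_local

AA = "ACDE"  # 4-letter alphabet for the brute-force oracle


def _prot(pid, seq):
    return SeqRecord(pid, seq, alphabet="protein")


class TestLocalSearch:
    def test_identical_subject_ranks_first_full_coverage(self):
        q = _prot("q", "MKVLATTGACDEFGHIKLMNPQRSTVWY")
        db = [
            _prot("other", "WWWWHHHHPPPPGGGG"),
            _prot("same", q.residues),
        ]
        hits = local_search(q, db)
        assert hits[0].subject_id == "same"
        assert hits[0].query_coverage == pytest.approx(1.0)
        assert hits[0].evalue < hits[1].evalue

    def test_unrelated_sequence_scores_poorly(self):
        q = _prot("q", "MKVLATTGACDEFGHIKL")
        hits = local_search(q, [_prot("rev", q.residues[::-1])])
        self_score = local_search(q, [q])[0].raw_score
        assert hits[0].raw_score < self_score / 2
        assert hits[0].evalue > local_search(q, [q])[0].evalue

    @pytest.mark.parametrize("seed", range(6))
    def test_smith_waterman_matches_brute_force_enumeration(self, seed):
        """SW raw scores equal exhaustive alignment enumeration (<=8 aa)."""
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list(AA), size=rng.integers(3, 9)))
        b = "".join(rng.choice(list(AA), size=rng.integers(3, 9)))
        hit = local_search(_prot("a", a), [_prot("b", b)])[0]
        assert hit.raw_score == pytest.approx(brute_force_local(a, b))


class TestGlobalIdentity:
    def test_identical_sequences_100(self):
        a = _prot("a", "MKVLATTGACDEFGHIKL")
        assert global_identity(a, a).percent_identity == 100.0

    def test_symmetric(self):
        a = _prot("a", "MKVLATTGACDEFGHIKL")
        b = _prot("b", "MKVLATSGACDEFAHIKL")
        assert global_identity(a, b).percent_identity == pytest.approx(
            global_identity(b, a).percent_identity
        )

    def test_monotone_under_point_mutations(self):
        rng = np.random.default_rng(1)
        base = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60))
        a = _prot("a", base)
        prev = 100.0
        mutated = list(base)
        positions = rng.choice(60, size=10, replace=False)
        for p in positions:
            mutated[p] = "W" if mutated[p] != "W" else "Y"
            ident = global_identity(
                a, _prot("m", "".join(mutated))
            ).percent_identity
            assert ident <= prev + 1e-9
            prev = ident

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            SeqRecord("e", "", alphabet="protein")


class TestMergeFragments:
    def test_simple_overlap(self):
        a = _prot("a", "MACDEFG")
        b = _prot("b", "EFGHIKL")
        assert merge_fragments(a, b, min_overlap=3).residues == "MACDEFGHIKL"

    def test_mismatch_in_overlap_returns_none(self):
        a = _prot("a", "MACDEFG")
        b = _prot("b", "EWGHIKL")
        assert merge_fragments(a, b, min_overlap=3) is None

    def test_overlap_below_minimum_returns_none(self):
        a = _prot("a", "MACDEFG")
        b = _prot("b", "FGHIKLM")
        assert merge_fragments(a, b, min_overlap=3) is None

    def test_associative_on_fragment_chain(self):
        rng = np.random.default_rng(2)
        full = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=120))
        f1, f2, f3 = full[:60], full[35:95], full[70:]
        a, b, c = _prot("1", f1), _prot("2", f2), _prot("3", f3)
        left = merge_fragments(merge_fragments(a, b, 20), c, 20)
        right = merge_fragments(a, merge_fragments(b, c, 20), 20)
        assert left.residues == right.residues == full

    def test_long_exact_overlap_counted_once(self):
        """A 152-residue C/N-terminal overlap merges two predictions."""
        rng = np.random.default_rng(3)
        full = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=500))
        frag_a, frag_b = full[:352], full[200:]  # overlap 152
        merged = merge_fragments(_prot("a", frag_a), _prot("b", frag_b), 100)
        assert merged.residues == full
        assert "152" in merged.description


class TestDeletionSpan:
    def test_identical_zero(self):
        a = _prot("a", "MKVLATTGACDEFGHIKL")
        assert deletion_span(a, a) == 0

    def test_recovers_internal_block_deletion(self):
        rng = np.random.default_rng(4)
        full = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=80))
        short = full[:30] + full[40:]
        assert deletion_span(_prot("s", short), _prot("f", full)) == 10


class TestAssignOrthologs:
    def _family(self, seed, n=40):
        rng = np.random.default_rng(seed)
        return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))

    def test_full_length_diverged_ortholog_assigned(self):
        base = self._family(5, 400)
        mutated = list(base)
        rng = np.random.default_rng(6)
        for p in rng.choice(400, size=28, replace=False):  # ~93% identity
            mutated[p] = "ACDEFGHIKLMNPQRSTVWY"[int(rng.integers(0, 20))]
        ortho = assign_orthologs(
            [_prot("q", "".join(mutated))], [_prot("ref", base)]
        )
        assert ortho["q"] == "ref"

    def test_partial_coverage_fails_threshold(self):
        base = self._family(7, 400)
        half = base[:200]
        ortho = assign_orthologs([_prot("q", base)], [_prot("ref", half)])
        assert ortho["q"] is None

    def test_reciprocal_best_only(self):
        base = self._family(8, 300)
        near = list(base)
        near[10] = "W" if near[10] != "W" else "Y"
        queries = [_prot("q_exact", base), _prot("q_near", "".join(near))]
        refs = [_prot("ref", base)]
        ortho = assign_orthologs(queries, refs)
        # only the reciprocal best query keeps the assignment
        assigned = [q for q, r in ortho.items() if r == "ref"]
        assert assigned == ["q_exact"]
        one_way = assign_orthologs(queries, refs, one_way=True)
        assert one_way["q_near"] == "ref"

    def test_thresholds_validate(self):
        with pytest.raises(ValueError):
            SearchThresholds(min_query_coverage=0)
        with pytest.raises(ValueError):
            SearchThresholds(max_evalue=0)
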