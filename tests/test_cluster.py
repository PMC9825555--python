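"""Cluster detection against the brute-force maximal-window oracle."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cgckit.cluster import CGCParams, find_cgcs
from cgckit.model import GeneClass

from conftest import brute_force_cgc_spans, make_contig


def spans(cgcs):
    return [c.ordinal_range for c in cgcs]


class TestRules:
    def test_lone_cazyme_is_no_cluster(self):
        assert find_cgcs(make_contig("C")) == []

    def test_cazyme_two_inserts_tc_forms_one_cluster(self):
        cgcs = find_cgcs(make_contig("C..T"), CGCParams(max_insert=2))
        assert spans(cgcs) == [(0, 3)]
        assert brute_force_cgc_spans("C..T", 2) == [(0, 3)]

    def test_three_inserts_split_at_default_join_at_three(self):
        codes = "C...T"
        assert find_cgcs(make_contig(codes), CGCParams(max_insert=2)) == []
        cgcs = find_cgcs(make_contig(codes), CGCParams(max_insert=3))
        assert spans(cgcs) == [(0, 4)]
        assert brute_force_cgc_spans(codes, 2) == []
        assert brute_force_cgc_spans(codes, 3) == [(0, 4)]

    def test_large_gap_splits_into_two_clusters(self):
        codes = "T.C...FC"
        cgcs = find_cgcs(make_contig(codes), CGCParams(max_insert=2))
        assert spans(cgcs) == [(0, 2), (6, 7)]
        assert brute_force_cgc_spans(codes, 2) == [(0, 2), (6, 7)]

    def test_boundaries_are_signature_genes(self):
        for codes in ("..C.T..", ".CT.", "C.T"):
            for c in find_cgcs(make_contig(codes)):
                assert c.genes[0].is_signature and c.genes[-1].is_signature

    def test_numbering_is_left_to_right_from_one(self):
        cgcs = find_cgcs(make_contig("CT...CF"))
        assert [c.cgc_id for c in cgcs] == ["G1_c1|CGC1", "G1_c1|CGC2"]

    def test_require_all_mode(self):
        codes = "CT.F"
        both = frozenset({GeneClass.TC, GeneClass.TF})
        assert spans(find_cgcs(make_contig(codes), CGCParams(required_other=both, require_all=True))) == [(0, 3)]
        assert find_cgcs(make_contig("CT.."), CGCParams(required_other=both, require_all=True)) == []

    def test_unsorted_input_rejected(self):
        genes = make_contig("CT")
        with pytest.raises(ValueError):
            find_cgcs(list(reversed(genes)))

    def test_keep_flanks_extends_without_overlap(self):
        codes = "..CT...CF.."
        cgcs = find_cgcs(make_contig(codes), CGCParams(max_insert=2, keep_flanks=True))
        assert len(cgcs) == 2
        (a_lo, a_hi), (b_lo, b_hi) = spans(cgcs)
        assert a_hi < b_lo  # never overlap
        assert a_lo <= 2 - 2 + 2 and b_hi >= 8  # flanks actually extend


def random_codes(rng, n):
    return "".join(rng.choice("CTFS....") for _ in range(n))


class TestOracleEquivalence:
    def test_random_contigs_match_brute_force(self):
        rng = random.Random(424242)
        for _ in range(300):
            n = rng.randint(1, 12)
            codes = random_codes(rng, n)
            max_insert = rng.randint(0, 3)
            got = spans(find_cgcs(make_contig(codes), CGCParams(max_insert=max_insert)))
            assert got == brute_force_cgc_spans(codes, max_insert), (codes, max_insert)

    @given(
        codes=st.text(alphabet="CTFS.", min_size=1, max_size=12),
        max_insert=st.integers(min_value=0, max_value=4),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_property_matches_oracle(self, codes, max_insert):
        got = spans(find_cgcs(make_contig(codes), CGCParams(max_insert=max_insert)))
        assert got == brute_force_cgc_spans(codes, max_insert)


class TestMonotonicity:
    @given(codes=st.text(alphabet="CTFS.", min_size=1, max_size=12))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_coverage_grows_with_max_insert(self, codes):
        genes = make_contig(codes)
        prev_cover: set[int] = set()
        prev_spans: list[tuple[int, int]] = []
        for d in range(0, 5):
            cgcs = find_cgcs(genes, CGCParams(max_insert=d))
            cover = {
                o for c in cgcs for o in range(c.ordinal_range[0], c.ordinal_range[1] + 1)
            }
            assert prev_cover <= cover
            # every cluster at d is contained in some cluster at d+1
            for lo, hi in prev_spans:
                assert any(a <= lo and hi <= b for a, b in spans(cgcs))
            prev_cover, prev_spans = cover, spans(cgcs)

    def test_determinism(self):
        genes = make_contig("CT..C.F..CS")
        a = find_cgcs(genes)
        b = find_cgcs(genes)
        assert [(c.cgc_id, c.ordinal_range) for c in a] == [
            (c.cgc_id, c.ordinal_range) for c in b
        ]
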