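"""Combination of the two approaches, percentages, dataset summaries."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cgckit.stats import combine, normalize_substrate, percentage, summarize, top_substrates


class TestCombine:
    def test_set_arithmetic(self):
        a1 = {"c1": "starch", "c2": "xylan"}
        a2 = {"c2": "xylan", "c3": "pectin"}
        rows, counts = combine(a1, a2, ["c1", "c2", "c3", "c4"])
        assert (counts.n_union, counts.n_both, counts.n_agree) == (3, 1, 1)

    def test_disjoint_sets(self):
        _, counts = combine({"a": "x"}, {"b": "y"}, ["a", "b"])
        assert counts.n_both == 0 and counts.n_agree == 0

    def test_identical_maps(self):
        m = {"a": "x", "b": "y"}
        _, counts = combine(m, dict(m), ["a", "b"])
        assert counts.n_agree == counts.n_both == counts.n_union == 2

    def test_agreement_is_case_insensitive(self):
        _, counts = combine({"a": "Starch "}, {"a": "starch"}, ["a"])
        assert counts.n_agree == 1

    def test_stray_cgc_id_rejected(self):
        with pytest.raises(ValueError):
            combine({"ghost": "x"}, {}, ["a"])

    substrate_maps = st.dictionaries(
        st.sampled_from([f"c{i}" for i in range(12)]),
        st.sampled_from(["starch", "xylan", "pectin"]),
        max_size=12,
    )

    @given(a1=substrate_maps, a2=substrate_maps)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_inclusion_exclusion(self, a1, a2):
        universe = [f"c{i}" for i in range(12)]
        _, counts = combine(a1, a2, universe)
        assert counts.n_union == len(a1) + len(a2) - counts.n_both
        assert 0 <= counts.n_agree <= counts.n_both <= min(len(a1), len(a2))


class TestPercentage:
    @pytest.mark.parametrize(
        "num,den,dec,expected",
        [
            (4183, 5111, 1, 81.8),
            (41447, 168906, 2, 24.54),
            (0, 10, 2, 0.0),
            (1, 3, 2, 33.33),
            (1, 8, 1, 12.5),
            (1, 800, 2, 0.13),  # exact half at the 3rd decimal: up, not to even
            (5, 800, 2, 0.63),
        ],
    )
    def test_half_up_rounding(self, num, den, dec, expected):
        assert percentage(num, den, dec) == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            percentage(1, 0)

    @given(
        num=st.integers(0, 1000),
        den=st.integers(1, 1000),
        k=st.integers(1, 7),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_scale_invariance(self, num, den, k):
        assert percentage(num, den, 4) == percentage(k * num, k * den, 4)


class TestSummarize:
    def test_counts_on_fixture(self, noise_free_bundle):
        from cgckit.cluster import find_cgcs_by_contig
        from cgckit.homology import assign_all
        from cgckit.voting import vote_substrate

        b = noise_free_bundle
        cgcs = find_cgcs_by_contig(b.genes)
        hom = assign_all(cgcs, b.puls, b.hits)
        smap = {e.ecami_subfamily: e for e in b.subfamily_map}
        tallies = [vote_substrate(c, smap) for c in cgcs]
        s = summarize(b.genes, cgcs, hom, tallies)

        assert s.n_proteins == len(b.genes)
        assert s.n_mags == b.spec.n_genomes
        assert s.n_cgcs == len(cgcs)
        # direct count oracle over the gene list
        assert s.n_cazymes == sum(
            g.gene_class.value == "CAZyme" for g in b.genes
        )
        assert s.n_cazymes_in_cgcs <= s.n_cazymes
        assert s.n_mags_with_cgcs == len({c.genome_id for c in cgcs})
        assert s.homology.n_cgcs_assigned == len(hom)
        assert sum(s.homology.substrate_counts.values()) == len(hom)
        assert s.homology.n_cgcs_assigned <= s.n_cgcs

    def test_empty_dataset_all_zero(self):
        s = summarize([], [], [], [])
        assert s.n_cgcs == 0 and s.n_cazymes == 0 and s.substrate_counts_union == {}

    def test_union_substrate_count_single_cgc(self):
        from cgckit.cluster import find_cgcs
        from cgckit.model import CGC, HomologyAssignment, PULMatch, VoteTally

        from conftest import make_contig

        genes = make_contig("CT")
        cgc = CGC("G1_c1|CGC1", genes)
        hom = [
            HomologyAssignment(
                "G1_c1|CGC1", "starch", PULMatch("G1_c1|CGC1", "P1", 100.0)
            )
        ]
        vote = [VoteTally("G1_c1|CGC1", {"starch": 1}, 1, 1, winner="starch")]
        s = summarize(genes, [cgc], hom, vote)
        assert s.substrate_counts_union == {"starch": 1}

    def test_top_substrates_ranking(self):
        counts = {"starch": 5, "xylan": 5, "pectin": 9, "mucin": 1}
        assert top_substrates(counts, 3) == [("pectin", 9), ("starch", 5), ("xylan", 5)]
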