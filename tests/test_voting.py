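"""Subfamily lookup and plurality voting."""

import random

import pytest

from cgckit.model import CGC, SubfamilyMapEntry
from cgckit.voting import annotate_cazyme_substrate, vote_substrate

from conftest import make_contig

SUBFAM_MAP = {
    "GH130_e13": SubfamilyMapEntry("GH130", "GH130_e13", ("2.4.1.-",), "mannan"),
    "GH13_e1": SubfamilyMapEntry("GH13", "GH13_e1", ("3.2.1.1",), "starch"),
    "GH10_e2": SubfamilyMapEntry("GH10", "GH10_e2", ("3.2.1.8",), "xylan"),
    "GH5_e9": SubfamilyMapEntry("GH5", "GH5_e9", (), None),  # uncharacterized
}


class TestLookup:
    def test_mapped_subfamily_returns_substrate(self):
        assert annotate_cazyme_substrate("GH130_e13", SUBFAM_MAP) == "mannan"

    def test_absent_subfamily_returns_none(self):
        assert annotate_cazyme_substrate("GH99_e1", SUBFAM_MAP) is None

    def test_subfamily_without_substrate_returns_none(self):
        assert annotate_cazyme_substrate("GH5_e9", SUBFAM_MAP) is None

    def test_unlabelled_gene_returns_none(self):
        assert annotate_cazyme_substrate(None, SUBFAM_MAP) is None


def _cgc(codes, subfams):
    return CGC(cgc_id="G1_c1|CGC1", genes=make_contig(codes, subfamilies=subfams))


class TestVote:
    def test_plurality_with_abstentions(self):
        # 6 CAZymes: 3 -> starch, 1 -> xylan, 2 unmapped
        cgc = _cgc(
            "CCCCCCT",
            {0: "GH13_e1", 1: "GH13_e1", 2: "GH13_e1", 3: "GH10_e2", 4: "GH5_e9"},
        )
        tally = vote_substrate(cgc, SUBFAM_MAP)
        assert tally.winner == "starch"
        assert tally.votes == {"starch": 3, "xylan": 1}
        assert tally.n_cazymes == 6 and tally.n_annotated == 4

    def test_tie_gives_no_winner(self):
        cgc = _cgc("CCCCT", {0: "GH13_e1", 1: "GH13_e1", 2: "GH10_e2", 3: "GH10_e2"})
        tally = vote_substrate(cgc, SUBFAM_MAP)
        assert tally.winner is None
        assert tally.tied == ["starch", "xylan"]

    def test_no_mapped_cazymes(self):
        tally = vote_substrate(_cgc("CT", {}), SUBFAM_MAP)
        assert tally.winner is None and tally.n_annotated == 0 and tally.tied == []

    def test_order_invariance(self):
        subfams = {0: "GH13_e1", 1: "GH10_e2", 2: "GH13_e1"}
        base = vote_substrate(_cgc("CCCT", subfams), SUBFAM_MAP)
        rng = random.Random(5)
        keys = [subfams.get(i) for i in range(3)]
        for _ in range(5):
            rng.shuffle(keys)
            permuted = {i: k for i, k in enumerate(keys) if k}
            again = vote_substrate(_cgc("CCCT", permuted), SUBFAM_MAP)
            assert again.votes == base.votes and again.winner == base.winner

    def test_min_votes_monotone(self):
        cgc = _cgc("CCT", {0: "GH13_e1", 1: "GH13_e1"})
        winners = [
            vote_substrate(cgc, SUBFAM_MAP, min_votes=mv).winner for mv in (1, 2, 3, 4)
        ]
        # once the winner disappears it never reappears at stricter settings
        seen_none = False
        for w in winners:
            if w is None:
                seen_none = True
            else:
                assert not seen_none
        assert winners[0] == "starch" and winners[-1] is None

    def test_strict_majority_mode(self):
        # 2 starch vs 1 xylan + 1 mannan: plurality yes, >50% of votes yes (2/4=50%? no)
        cgc = _cgc(
            "CCCCT",
            {0: "GH13_e1", 1: "GH13_e1", 2: "GH10_e2", 3: "GH130_e13"},
        )
        assert vote_substrate(cgc, SUBFAM_MAP).winner == "starch"
        assert vote_substrate(cgc, SUBFAM_MAP, strict_majority=True).winner is None

    def test_cgc_without_cazyme_rejected(self):
        with pytest.raises(ValueError):
            vote_substrate(CGC("x", make_contig("T")), SUBFAM_MAP)

    def test_conservation_of_votes(self, noise_free_bundle):
        # n_annotated equals the per-CAZyme lookup count on real-ish clusters
        from cgckit.cluster import find_cgcs_by_contig

        smap = {e.ecami_subfamily: e for e in noise_free_bundle.subfamily_map}
        for cgc in find_cgcs_by_contig(noise_free_bundle.genes):
            tally = vote_substrate(cgc, smap)
            expected = sum(
                annotate_cazyme_substrate(g.label.ecami_subfamily, smap) is not None
                for g in cgc.members()
                if g.gene_class.value == "CAZyme"
            )
            assert tally.n_annotated == expected
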