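"""PUL homology mapping: one-to-one pairing, eligibility, best-hit choice.

The greedy pairing is cross-checked against an exact maximum-weight
bipartite matching (scipy's linear_sum_assignment). Greedy is not optimal
in general; on instances where each query has a dominant partner (the
regime real CGC-vs-PUL alignments live in) it is, and that is asserted. On
arbitrary instances only the bound greedy <= optimal holds.
"""

import random

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from cgckit.homology import best_pul, pair_hits, score_pul
from cgckit.model import CGC, GeneClass, PairwiseHit, PULRecord

from conftest import make_contig


def _cgc(codes="CT"):
    return CGC(cgc_id="G1_c1|CGC1", genes=make_contig(codes))


def _pul(pul_id="PUL0001", substrate="mucin", classes=(GeneClass.CAZYME, GeneClass.TC)):
    return PULRecord(
        pul_id=pul_id,
        substrate=substrate,
        proteins=tuple((f"{pul_id}_p{i}", c) for i, c in enumerate(classes)),
    )


def _hit(q, s, bits, evalue=1e-30):
    return PairwiseHit(q, s, 50.0, evalue, bits)


class TestPairHits:
    def test_no_hits_empty(self):
        assert pair_hits(_cgc(), _pul(), []) == []

    def test_one_query_two_subjects_keeps_best(self):
        cgc, pul = _cgc(), _pul()
        q = cgc.protein_ids[0]
        hits = [_hit(q, f"{pul.pul_id}_p0", 120.0), _hit(q, f"{pul.pul_id}_p1", 80.0)]
        accepted = pair_hits(cgc, pul, hits)
        assert [(h.query_protein, h.subject_protein, h.bit_score) for h in accepted] == [
            (q, f"{pul.pul_id}_p0", 120.0)
        ]

    def test_disjoint_hits_both_accepted_order_independent(self):
        cgc, pul = _cgc(), _pul()
        q0, q1 = cgc.protein_ids
        hits = [_hit(q0, f"{pul.pul_id}_p0", 120.0), _hit(q1, f"{pul.pul_id}_p1", 80.0)]
        fwd = pair_hits(cgc, pul, hits)
        rev = pair_hits(cgc, pul, list(reversed(hits)))
        assert sorted(h.bit_score for h in fwd) == [80.0, 120.0]
        assert fwd == rev

    def test_evalue_filter(self):
        cgc, pul = _cgc(), _pul()
        weak = _hit(cgc.protein_ids[0], f"{pul.pul_id}_p0", 120.0, evalue=1e-2)
        assert pair_hits(cgc, pul, [weak], min_evalue=1e-4) == []
        assert len(pair_hits(cgc, pul, [weak], min_evalue=1e-1)) == 1

    def test_greedy_optimal_on_dominant_instances(self):
        # each query's true partner outscores every cross hit: greedy total
        # must equal the exact maximum-weight matching
        rng = random.Random(7)
        for _ in range(50):
            n = rng.randint(2, 6)
            cgc = _cgc("C" * n)
            pul = _pul(classes=(GeneClass.CAZYME,) * n)
            w = np.zeros((n, n))
            hits = []
            for i, q in enumerate(cgc.protein_ids):
                for j in range(n):
                    bits = rng.uniform(150, 250) if i == j else rng.uniform(10, 90)
                    w[i, j] = bits
                    hits.append(_hit(q, f"{pul.pul_id}_p{j}", round(bits, 1)))
            accepted = pair_hits(cgc, pul, hits)
            greedy_total = sum(h.bit_score for h in accepted)
            ri, ci = linear_sum_assignment(-np.round(w, 1))
            optimal = np.round(w, 1)[ri, ci].sum()
            assert greedy_total == pytest.approx(optimal)

    def test_greedy_never_beats_optimal(self):
        rng = random.Random(99)
        for _ in range(50):
            n = rng.randint(1, 6)
            m = rng.randint(1, 6)
            cgc = _cgc("C" * n)
            pul = _pul(classes=(GeneClass.CAZYME,) * m)
            w = np.array([[round(rng.uniform(0, 200), 1) for _ in range(m)] for _ in range(n)])
            hits = [
                _hit(q, f"{pul.pul_id}_p{j}", w[i, j])
                for i, q in enumerate(cgc.protein_ids)
                for j in range(m)
            ]
            greedy_total = sum(h.bit_score for h in pair_hits(cgc, pul, hits))
            ri, ci = linear_sum_assignment(-w)
            assert greedy_total <= w[ri, ci].sum() + 1e-9


class TestScorePul:
    def test_summed_bits_is_plain_sum(self):
        cgc, pul = _cgc("CCT"), _pul(classes=(GeneClass.CAZYME, GeneClass.CAZYME, GeneClass.TC))
        hits = [
            _hit(cgc.protein_ids[0], f"{pul.pul_id}_p0", 120.0),
            _hit(cgc.protein_ids[1], f"{pul.pul_id}_p1", 80.0),
            _hit(cgc.protein_ids[2], f"{pul.pul_id}_p2", 45.5),
        ]
        match = score_pul(cgc, pul, pair_hits(cgc, pul, hits))
        assert match.summed_bits == pytest.approx(245.5)
        assert match.n_cazyme_pairs == 2
        assert match.n_other_signature_pairs == 1
        assert match.eligible

    def test_cazyme_only_match_is_ineligible(self):
        cgc, pul = _cgc("CC"), _pul(classes=(GeneClass.CAZYME, GeneClass.CAZYME))
        hits = [
            _hit(cgc.protein_ids[0], f"{pul.pul_id}_p0", 120.0),
            _hit(cgc.protein_ids[1], f"{pul.pul_id}_p1", 90.0),
        ]
        match = score_pul(cgc, pul, pair_hits(cgc, pul, hits))
        assert match.n_cazyme_pairs == 2 and match.n_other_signature_pairs == 0
        assert not match.eligible

    def test_empty_pairs_score_zero_ineligible(self):
        match = score_pul(_cgc(), _pul(), [])
        assert match.summed_bits == 0.0 and not match.eligible

    def test_score_additivity(self):
        cgc, pul = _cgc("CT"), _pul()
        hits = [
            _hit(cgc.protein_ids[0], f"{pul.pul_id}_p0", 120.0),
            _hit(cgc.protein_ids[1], f"{pul.pul_id}_p1", 80.0),
        ]
        accepted = pair_hits(cgc, pul, hits)
        full = score_pul(cgc, pul, accepted).summed_bits
        partial = score_pul(cgc, pul, accepted[1:]).summed_bits
        assert full - partial == pytest.approx(accepted[0].bit_score)


class TestBestPul:
    def test_highest_summed_bits_wins(self):
        cgc = _cgc("CT")
        p1 = _pul("PUL0001", "mucin")
        p2 = _pul("PUL0002", "xylan")
        hits = [
            _hit(cgc.protein_ids[0], "PUL0001_p0", 200.0),
            _hit(cgc.protein_ids[1], "PUL0001_p1", 100.0),
            _hit(cgc.protein_ids[0], "PUL0002_p0", 150.0),
            _hit(cgc.protein_ids[1], "PUL0002_p1", 100.0),
        ]
        # exhaustive comparison over the candidate PULs
        a = best_pul(cgc, [p1, p2], hits)
        assert a is not None and a.substrate == "mucin"
        assert a.best_match.summed_bits == pytest.approx(300.0)

    def test_no_eligible_pul_gives_no_assignment(self):
        cgc = _cgc("CC")
        pul = _pul(classes=(GeneClass.CAZYME, GeneClass.CAZYME))
        hits = [_hit(cgc.protein_ids[0], f"{pul.pul_id}_p0", 200.0)]
        assert best_pul(cgc, [pul], hits) is None

    def test_tie_breaks_by_pairs_then_pul_id(self):
        cgc = _cgc("CT")
        pa = _pul("PUL000A", "starch")
        pb = _pul("PUL000B", "pectin")
        hits = [
            _hit(cgc.protein_ids[0], "PUL000A_p0", 150.0),
            _hit(cgc.protein_ids[1], "PUL000A_p1", 150.0),
            _hit(cgc.protein_ids[0], "PUL000B_p0", 150.0),
            _hit(cgc.protein_ids[1], "PUL000B_p1", 150.0),
        ]
        a = best_pul(cgc, [pb, pa], hits)
        assert a.best_match.pul_id == "PUL000A"  # equal bits+pairs -> smaller id

    def test_permutation_invariance(self):
        cgc = _cgc("CT")
        puls = [_pul("PUL0001", "mucin"), _pul("PUL0002", "xylan")]
        hits = [
            _hit(cgc.protein_ids[0], "PUL0001_p0", 180.0),
            _hit(cgc.protein_ids[1], "PUL0001_p1", 90.0),
            _hit(cgc.protein_ids[0], "PUL0002_p0", 120.0),
            _hit(cgc.protein_ids[1], "PUL0002_p1", 60.0),
        ]
        rng = random.Random(3)
        baseline = best_pul(cgc, puls, hits)
        for _ in range(10):
            shuffled = hits[:]
            rng.shuffle(shuffled)
            again = best_pul(cgc, list(reversed(puls)), shuffled)
            assert again.substrate == baseline.substrate
            assert again.best_match.pul_id == baseline.best_match.pul_id
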