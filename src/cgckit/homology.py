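"""Substrate transfer from characterized PULs by summed-bit-score homology.

A query CGC is compared against every reference PUL using precomputed
pairwise protein hits. Hits between a CGC and a PUL are reduced to a
one-to-one pairing (greedy by descending bit score, so one promiscuous
protein cannot inflate the score), the pair bit scores are summed, and the
best-scoring PUL transfers its curated substrate — provided the match
contains at least one CAZyme-CAZyme pair and at least one pair matched
within one of the other signature classes (TC/TF/STP on both sides).
"""

from __future__ import annotations

from typing import Callable, Iterable, Mapping, Optional, Sequence

from .model import (
    CGC,
    OTHER_SIGNATURE_CLASSES,
    GeneClass,
    HomologyAssignment,
    PairwiseHit,
    PULMatch,
    PULRecord,
)

DEFAULT_MIN_EVALUE = 1e-4


def pair_hits(
    cgc: CGC,
    pul: PULRecord,
    hits: Iterable[PairwiseHit],
    min_evalue: float = DEFAULT_MIN_EVALUE,
) -> list[PairwiseHit]:
    """One-to-one accepted hit pairs between a CGC and a PUL.

    Hits outside the (CGC member, PUL member) protein sets or with
    e-value > *min_evalue* are discarded; the rest are sorted by descending
    bit score (ties by protein ids, for order-independence) and accepted
    greedily so that each query and each subject protein occurs in at most
    one accepted pair.
    """
    cgc_proteins = set(cgc.protein_ids)
    pul_proteins = set(pul.protein_ids)
    candidates = [
        h
        for h in hits
        if h.query_protein in cgc_proteins
        and h.subject_protein in pul_proteins
        and h.e_value <= min_evalue
    ]
    candidates.sort(key=lambda h: (-h.bit_score, h.query_protein, h.subject_protein))
    used_q: set[str] = set()
    used_s: set[str] = set()
    accepted: list[PairwiseHit] = []
    for h in candidates:
        if h.query_protein in used_q or h.subject_protein in used_s:
            continue
        used_q.add(h.query_protein)
        used_s.add(h.subject_protein)
        accepted.append(h)
    return accepted


def score_pul(
    cgc: CGC,
    pul: PULRecord,
    accepted_pairs: Sequence[PairwiseHit],
    class_of: Optional[Callable[[str], GeneClass]] = None,
) -> PULMatch:
    """Summed-bit-score match of one CGC against one PUL.

    *class_of* maps a query protein id to its signature class (defaults to
    the CGC's own annotations; unknown proteins count as Other — they add to
    the score but not to eligibility). A pair counts as a CAZyme pair when
    both sides are CAZymes, and as an other-signature pair when both sides
    share one class among TC/TF/STP.
    """
    if class_of is None:
        own = {g.gene.protein_id: g.gene_class for g in cgc.genes}
        class_of = lambda pid: own.get(pid, GeneClass.OTHER)  # noqa: E731

    summed = 0.0
    n_caz = 0
    n_other = 0
    pairs: list[tuple[str, str, float]] = []
    for h in accepted_pairs:
        summed += h.bit_score
        q_cls = class_of(h.query_protein)
        s_cls = pul.class_of(h.subject_protein)
        if q_cls is GeneClass.CAZYME and s_cls is GeneClass.CAZYME:
            n_caz += 1
        elif q_cls is s_cls and q_cls in OTHER_SIGNATURE_CLASSES:
            n_other += 1
        pairs.append((h.query_protein, h.subject_protein, h.bit_score))
    return PULMatch(
        cgc_id=cgc.cgc_id,
        pul_id=pul.pul_id,
        summed_bits=summed,
        pairs=pairs,
        n_cazyme_pairs=n_caz,
        n_other_signature_pairs=n_other,
    )


def best_pul(
    cgc: CGC,
    pul_db: Sequence[PULRecord],
    all_hits: Iterable[PairwiseHit],
    substrate_map: Optional[Mapping[str, str]] = None,
    min_evalue: float = DEFAULT_MIN_EVALUE,
) -> Optional[HomologyAssignment]:
    """Assign the substrate of the best-matching eligible PUL, if any.

    Among eligible matches the one with the highest summed bit score wins;
    ties break by more accepted pairs, then by lexicographically smaller
    pul_id. Returns None when no PUL yields an eligible match.
    """
    if not pul_db:
        raise ValueError("pul_db is empty")
    hits = list(all_hits)
    # pre-bucket hits by subject PUL membership for speed on large hit tables
    subject_to_puls: dict[str, list[int]] = {}
    for idx, pul in enumerate(pul_db):
        for pid in pul.protein_ids:
            subject_to_puls.setdefault(pid, []).append(idx)
    cgc_proteins = set(cgc.protein_ids)
    hits_by_pul: dict[int, list[PairwiseHit]] = {}
    for h in hits:
        if h.query_protein not in cgc_proteins:
            continue
        for idx in subject_to_puls.get(h.subject_protein, ()):
            hits_by_pul.setdefault(idx, []).append(h)

    best: Optional[PULMatch] = None
    for idx in sorted(hits_by_pul):
        pul = pul_db[idx]
        accepted = pair_hits(cgc, pul, hits_by_pul[idx], min_evalue=min_evalue)
        match = score_pul(cgc, pul, accepted)
        if not match.eligible:
            continue
        if best is None or _match_rank(match) < _match_rank(best):
            best = match
    if best is None:
        return None
    smap = substrate_map if substrate_map is not None else {
        p.pul_id: p.substrate for p in pul_db
    }
    if best.pul_id not in smap:
        raise KeyError(f"PUL {best.pul_id!r} missing from substrate map")
    return HomologyAssignment(
        cgc_id=cgc.cgc_id, substrate=smap[best.pul_id], best_match=best
    )


def _match_rank(m: PULMatch) -> tuple[float, int, str]:
    # sort key: higher bits first, then more pairs, then smaller pul_id
    return (-m.summed_bits, -m.n_pairs, m.pul_id)


def assign_all(
    cgcs: Sequence[CGC],
    pul_db: Sequence[PULRecord],
    all_hits: Sequence[PairwiseHit],
    min_evalue: float = DEFAULT_MIN_EVALUE,
) -> list[HomologyAssignment]:
    """Run :func:`best_pul` over a collection of CGCs, skipping no-calls."""
    out = []
    for cgc in cgcs:
        a = best_pul(cgc, pul_db, all_hits, min_evalue=min_evalue)
        if a is not None:
            out.append(a)
    return out
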