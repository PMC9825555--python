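"""Substrate prediction by CAZyme-subfamily majority voting.

Each CAZyme in a CGC is looked up in the curated subfamily -> EC -> substrate
mapping table via its k-mer-classifier subfamily label; every CAZyme with a
mapped substrate casts one vote, and the cluster's substrate is the vote
winner. Many subfamilies contain no experimentally characterized member and
therefore carry no substrate; those CAZymes abstain.
"""

from __future__ import annotations

from collections import Counter
from typing import Mapping, Optional

from .model import CGC, GeneClass, SubfamilyMapEntry, VoteTally


def annotate_cazyme_substrate(
    ecami_subfamily: Optional[str],
    subfam_map: Mapping[str, SubfamilyMapEntry],
) -> Optional[str]:
    """Substrate of one CAZyme via its subfamily, or None.

    None when the gene has no subfamily label, the subfamily is absent from
    the table, or the table row carries no substrate.
    """
    if ecami_subfamily is None:
        return None
    entry = subfam_map.get(ecami_subfamily)
    if entry is None:
        return None
    return entry.substrate


def vote_substrate(
    cgc: CGC,
    subfam_map: Mapping[str, SubfamilyMapEntry],
    min_votes: int = 1,
    strict_majority: bool = False,
) -> VoteTally:
    """Plurality vote over the mapped substrates of a CGC's CAZymes.

    The winner is the unique substrate with the strictly highest vote count,
    provided that count is >= *min_votes* (and, under *strict_majority*,
    exceeds half of the cast votes). A tie at the top yields no winner and
    populates ``tied`` (alphabetical). A CAZyme with several subfamily
    labels casts at most one vote, through its recorded subfamily.
    """
    cazymes = cgc.members(GeneClass.CAZYME)
    if not cazymes:
        raise ValueError(f"CGC {cgc.cgc_id} contains no CAZyme")
    votes: Counter[str] = Counter()
    for g in cazymes:
        substrate = annotate_cazyme_substrate(g.label.ecami_subfamily, subfam_map)
        if substrate is not None:
            votes[substrate] += 1
    n_annotated = sum(votes.values())

    winner: Optional[str] = None
    tied: list[str] = []
    if votes:
        top = max(votes.values())
        leaders = sorted(s for s, c in votes.items() if c == top)
        if len(leaders) > 1:
            tied = leaders
        elif top >= min_votes and (
            not strict_majority or top * 2 > n_annotated
        ):
            winner = leaders[0]
    return VoteTally(
        cgc_id=cgc.cgc_id,
        votes=dict(sorted(votes.items())),
        n_cazymes=len(cazymes),
        n_annotated=n_annotated,
        winner=winner,
        tied=tied,
    )
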