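"""Combining the two substrate approaches and computing summary statistics.

Produces per-CGC combined assignments with agreement flags, the
union/intersection/agreement counts, and dataset-level summaries of the
kind published for CAZyme/CGC catalogs (counts and percentages of MAGs,
proteins, CAZymes and CGCs, per-substrate CGC distributions).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

from .model import CGC, AnnotatedGene, GeneClass, HomologyAssignment, VoteTally


@dataclass(frozen=True)
class CombinedAssignment:
    """Substrate calls for one CGC from both approaches."""

    cgc_id: str
    substrate_homology: Optional[str]
    substrate_voting: Optional[str]

    @property
    def both(self) -> bool:
        return self.substrate_homology is not None and self.substrate_voting is not None

    @property
    def agree(self) -> bool:
        return self.both and normalize_substrate(
            self.substrate_homology
        ) == normalize_substrate(self.substrate_voting)


@dataclass
class CombineCounts:
    n_union: int
    n_both: int
    n_agree: int


def normalize_substrate(name: Optional[str]) -> Optional[str]:
    """Case-folded, whitespace-trimmed substrate name for agreement checks.

    No ontology-based synonym merging is attempted: glycan nomenclature in
    the literature overlaps (pectin side chains recur in arabinogalactans),
    so agreement rates under exact matching are conservative.
    """
    if name is None:
        return None
    return name.strip().casefold()


def combine(
    homology: Mapping[str, str],
    voting: Mapping[str, str],
    universe: Iterable[str],
) -> tuple[list[CombinedAssignment], CombineCounts]:
    """Merge per-CGC substrate maps from the two approaches.

    *universe* is the full set of CGC ids under consideration; an assignment
    for an id outside it is a validation error. Returns one
    CombinedAssignment per assigned CGC (sorted by id) plus the
    union/both/agreement counts.
    """
    universe_set = set(universe)
    stray = (set(homology) | set(voting)) - universe_set
    if stray:
        raise ValueError(f"assignments outside the CGC universe: {sorted(stray)[:5]}")
    assigned = sorted(set(homology) | set(voting))
    rows = [
        CombinedAssignment(
            cgc_id=cid,
            substrate_homology=homology.get(cid),
            substrate_voting=voting.get(cid),
        )
        for cid in assigned
    ]
    counts = CombineCounts(
        n_union=len(rows),
        n_both=sum(r.both for r in rows),
        n_agree=sum(r.agree for r in rows),
    )
    return rows, counts


def percentage(numerator: int, denominator: int, decimals: int = 2) -> float:
    """100*numerator/denominator, rounded half-up to *decimals* places.

    Half-up rounding (not banker's) reproduces hand-computed table
    percentages exactly at their printed precision.
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage denominator is zero")
    value = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass
class ApproachSummary:
    """Per-approach substrate assignment statistics."""

    n_cgcs_assigned: int = 0
    n_mags_assigned: int = 0
    n_cazymes_assigned: int = 0
    substrate_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class DatasetSummary:
    """Dataset-level CAZyme/CGC/substrate statistics."""

    n_mags: int = 0
    n_proteins: int = 0
    n_cazymes: int = 0
    n_cgcs: int = 0
    n_mags_with_cazymes: int = 0
    n_mags_with_cgcs: int = 0
    n_cazymes_in_cgcs: int = 0
    homology: ApproachSummary = field(default_factory=ApproachSummary)
    voting: ApproachSummary = field(default_factory=ApproachSummary)
    substrate_counts_union: dict[str, int] = field(default_factory=dict)


def summarize(
    genes: Sequence[AnnotatedGene],
    cgcs: Sequence[CGC],
    homology_assignments: Sequence[HomologyAssignment],
    vote_tallies: Sequence[VoteTally],
) -> DatasetSummary:
    """Aggregate one dataset's annotation results.

    MAG counts come from the genome ids on the genes; assignment statistics
    count CGCs, their host MAGs and their member CAZymes per approach and
    for the union of both.
    """
    cgc_by_id = {c.cgc_id: c for c in cgcs}
    hom_map = {a.cgc_id: a.substrate for a in homology_assignments}
    vote_map = {t.cgc_id: t.winner for t in vote_tallies if t.winner is not None}

    summary = DatasetSummary(
        n_mags=len({g.gene.genome_id for g in genes}),
        n_proteins=len(genes),
        n_cazymes=sum(g.gene_class is GeneClass.CAZYME for g in genes),
        n_cgcs=len(cgcs),
        n_mags_with_cazymes=len(
            {g.gene.genome_id for g in genes if g.gene_class is GeneClass.CAZYME}
        ),
        n_mags_with_cgcs=len({c.genome_id for c in cgcs}),
        n_cazymes_in_cgcs=sum(
            len(c.members(GeneClass.CAZYME)) for c in cgcs
        ),
    )

    for approach, amap in (("homology", hom_map), ("voting", vote_map)):
        asum = ApproachSummary(
            n_cgcs_assigned=len(amap),
            n_mags_assigned=len(
                {cgc_by_id[cid].genome_id for cid in amap if cid in cgc_by_id}
            ),
            n_cazymes_assigned=sum(
                len(cgc_by_id[cid].members(GeneClass.CAZYME))
                for cid in amap
                if cid in cgc_by_id
            ),
            substrate_counts=dict(sorted(Counter(amap.values()).items())),
        )
        setattr(summary, approach, asum)

    union_substrates: Counter[str] = Counter()
    for cid in set(hom_map) | set(vote_map):
        # a CGC assigned by both approaches counts once, under the
        # homology substrate (the approach with wider coverage)
        union_substrates[hom_map.get(cid, vote_map.get(cid))] += 1
    summary.substrate_counts_union = dict(sorted(union_substrates.items()))
    return summary


def top_substrates(
    substrate_counts: Mapping[str, int], n: int = 20
) -> list[tuple[str, int]]:
    """Top-n substrate groups by CGC count (ties alphabetical)."""
    return sorted(substrate_counts.items(), key=lambda kv: (-kv[1], kv[0]))[:n]
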