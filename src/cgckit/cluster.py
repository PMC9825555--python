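"""CGC detection: chain signature genes along a contig into clusters.

A CAZyme gene cluster (CGC) is an ordered run of genes on one contig in
which consecutive signature genes (CAZyme/TC/TF/STP) are separated by at
most ``max_insert`` non-signature genes, bounded by signature genes at both
ends, and containing at least one CAZyme plus at least one gene from the
other signature classes. Gap counting is in genes, not base pairs; contig
ends terminate chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .model import (
    CGC,
    OTHER_SIGNATURE_CLASSES,
    SIGNATURE_CLASSES,
    AnnotatedGene,
    GeneClass,
)


@dataclass(frozen=True)
class CGCParams:
    """Cluster-rule parameters.

    max_insert
        Non-signature genes tolerated between two consecutive signature
        genes (default 2, the standard CGC-Finder setting).
    required_other
        Non-CAZyme signature classes accepted as the co-occurring partner;
        by default at least one of TC/TF/STP suffices. With *require_all*
        every listed class must be present.
    active_signature_set
        Classes treated as chain-extending signature genes during the scan
        (default: all four).
    keep_flanks
        Retain up to max_insert non-signature genes on each side of a
        cluster instead of trimming to the outermost signature genes.
    """

    max_insert: int = 2
    required_other: frozenset[GeneClass] = field(
        default_factory=lambda: frozenset(OTHER_SIGNATURE_CLASSES)
    )
    require_all: bool = False
    active_signature_set: frozenset[GeneClass] = field(
        default_factory=lambda: frozenset(SIGNATURE_CLASSES)
    )
    keep_flanks: bool = False

    def __post_init__(self) -> None:
        if self.max_insert < 0:
            raise ValueError("max_insert must be >= 0")
        bad = set(self.required_other) - set(OTHER_SIGNATURE_CLASSES)
        if bad:
            raise ValueError(f"required_other must be within TC/TF/STP, got {bad}")
        if GeneClass.OTHER in self.active_signature_set:
            raise ValueError("Other can never be a signature class")
        if not self.required_other:
            raise ValueError("required_other must name at least one class")


def find_cgcs(
    genes: Sequence[AnnotatedGene],
    params: CGCParams = CGCParams(),
) -> list[CGC]:
    """Detect CGCs on one contig of ordinal-sorted annotated genes.

    Scans left to right chaining signature genes whenever the run of
    non-signature genes between two of them is <= ``params.max_insert``;
    candidate spans are trimmed to their outermost signature genes (unless
    ``keep_flanks``), then kept iff they contain >=1 CAZyme and satisfy the
    ``required_other`` composition rule. Kept clusters are numbered CGC1,
    CGC2, ... left to right; clusters never overlap.
    """
    genes = list(genes)
    if not genes:
        return []
    contigs = {(g.gene.genome_id, g.gene.contig_id) for g in genes}
    if len(contigs) != 1:
        raise ValueError(f"find_cgcs expects one contig, got {sorted(contigs)}")
    ordinals = [g.gene.ordinal for g in genes]
    if ordinals != sorted(ordinals) or len(set(ordinals)) != len(ordinals):
        raise ValueError("genes must be sorted by ordinal with no duplicates")

    active = params.active_signature_set
    sig_positions = [
        i for i, g in enumerate(genes) if g.gene_class in active
    ]
    if not sig_positions:
        return []

    # Split the signature-gene sequence wherever the inter-signature gap
    # exceeds max_insert; each run is one candidate chain.
    chains: list[tuple[int, int]] = []  # (first sig index, last sig index)
    chain_start = sig_positions[0]
    prev = sig_positions[0]
    for pos in sig_positions[1:]:
        if pos - prev - 1 > params.max_insert:
            chains.append((chain_start, prev))
            chain_start = pos
        prev = pos
    chains.append((chain_start, prev))

    genome_id = genes[0].gene.genome_id
    contig_id = genes[0].gene.contig_id
    kept: list[CGC] = []
    for idx, (lo, hi) in enumerate(chains):
        members = genes[lo : hi + 1]
        if not _composition_ok(members, params):
            continue
        if params.keep_flanks:
            # Flanks never cross into a neighbouring chain's half of the gap,
            # so clusters stay non-overlapping in every mode.
            if idx > 0:
                gap = lo - chains[idx - 1][1] - 1
                left_room = min(params.max_insert, gap - gap // 2)
            else:
                left_room = min(params.max_insert, lo)
            if idx < len(chains) - 1:
                gap = chains[idx + 1][0] - hi - 1
                right_room = min(params.max_insert, gap // 2)
            else:
                right_room = min(params.max_insert, len(genes) - 1 - hi)
            flank_lo = max(0, lo - left_room)
            flank_hi = min(len(genes) - 1, hi + right_room)
            members = genes[flank_lo : flank_hi + 1]
        kept.append(
            CGC(
                cgc_id=f"{genome_id}_{contig_id}|CGC{len(kept) + 1}",
                genes=list(members),
            )
        )
    return kept


def _composition_ok(members: Sequence[AnnotatedGene], params: CGCParams) -> bool:
    classes = {g.gene_class for g in members}
    if GeneClass.CAZYME not in classes:
        return False
    if params.require_all:
        return params.required_other <= classes
    return bool(params.required_other & classes)


def find_cgcs_by_contig(
    genes: Iterable[AnnotatedGene],
    params: CGCParams = CGCParams(),
) -> list[CGC]:
    """Run :func:`find_cgcs` independently on every (genome, contig) group."""
    groups: dict[tuple[str, str], list[AnnotatedGene]] = {}
    for g in genes:
        groups.setdefault((g.gene.genome_id, g.gene.contig_id), []).append(g)
    cgcs: list[CGC] = []
    for key in sorted(groups):
        contig_genes = sorted(groups[key], key=lambda g: g.gene.ordinal)
        cgcs.extend(find_cgcs(contig_genes, params))
    return cgcs
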