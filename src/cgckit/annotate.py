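"""CAZyme consensus calling and signature classification.

CAZyme family calls come from three independent engines (an HMM scan, a
pairwise-alignment search and a k-mer classifier); a protein is accepted as a
CAZyme only when at least ``min_tools`` DISTINCT tools report it. Each gene
then receives exactly one signature class, with CAZyme taking precedence over
TC, TF and STP so that cluster anchors are never masked by a co-annotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .model import (
    AnnotatedGene,
    GeneClass,
    GeneRecord,
    SignatureLabel,
    Tool,
    ToolHit,
    is_ecami_subfamily,
)

#: Precedence when a protein carries calls in several classes.
CLASS_PRECEDENCE = (GeneClass.CAZYME, GeneClass.TC, GeneClass.TF, GeneClass.STP)


@dataclass(frozen=True)
class CazymeCall:
    """Consensus CAZyme annotation for one protein."""

    protein_id: str
    families: tuple[str, ...]
    ecami_subfamily: Optional[str] = None
    n_tools: int = 0


def consensus_cazyme(
    hits: Iterable[ToolHit],
    min_tools: int = 2,
    intersect_families: bool = False,
) -> dict[str, CazymeCall]:
    """Apply the >=``min_tools``-of-3 consensus rule to per-tool family calls.

    A protein is retained iff the number of distinct tools reporting any
    CAZyme family for it is at least *min_tools* (default 2, matching the
    standard run_dbcan-style filter). The retained family set is the union of
    families over reporting tools (set *intersect_families* for the stricter
    intersection across tools). When the k-mer tool reports an eCAMI-style
    subfamily (``GH130_e13``), it is recorded for downstream substrate voting.
    """
    if min_tools not in (1, 2, 3):
        raise ValueError(f"min_tools must be 1, 2 or 3, got {min_tools}")
    by_protein: dict[str, list[ToolHit]] = {}
    for hit in hits:
        if not isinstance(hit.tool, Tool):
            raise ValueError(f"unknown tool {hit.tool!r}")
        by_protein.setdefault(hit.protein_id, []).append(hit)

    calls: dict[str, CazymeCall] = {}
    for protein_id in sorted(by_protein):
        phits = by_protein[protein_id]
        tools = {h.tool for h in phits}
        if len(tools) < min_tools:
            continue
        if intersect_families:
            fam_sets = [
                {_family_key(h.family) for h in phits if h.tool is tool}
                for tool in tools
            ]
            keys = set.intersection(*fam_sets)
            families = sorted(
                {h.family for h in phits if _family_key(h.family) in keys}
            )
        else:
            families = sorted({h.family for h in phits})
        if not families:
            continue
        subfam = next(
            (
                h.family
                for h in sorted(phits, key=lambda h: h.family)
                if h.tool is Tool.KMER and is_ecami_subfamily(h.family)
            ),
            None,
        )
        calls[protein_id] = CazymeCall(
            protein_id=protein_id,
            families=tuple(families),
            ecami_subfamily=subfam,
            n_tools=len(tools),
        )
    return calls


def _family_key(family: str) -> str:
    # Tools disagree on subfamily granularity (GH5 vs GH5_1 vs GH5_e7);
    # family identity across tools is compared on the prefix.
    return family.split("_", 1)[0]


def classify_genes(
    genes: Sequence[GeneRecord],
    cazyme_map: Mapping[str, CazymeCall],
    signature_table: Mapping[str, GeneClass],
    precedence: Sequence[GeneClass] = CLASS_PRECEDENCE,
) -> list[AnnotatedGene]:
    """Assign each gene exactly one signature class.

    *cazyme_map* carries consensus CAZyme calls; *signature_table* carries
    TC/TF/STP calls per protein. When a protein has calls in several classes
    the first class in *precedence* wins; proteins with no call are Other.
    Output order and length equal the input's.
    """
    out: list[AnnotatedGene] = []
    for gene in genes:
        pid = gene.protein_id
        candidates: set[GeneClass] = set()
        if pid in cazyme_map:
            candidates.add(GeneClass.CAZYME)
        table_class = signature_table.get(pid)
        if table_class is not None and table_class is not GeneClass.OTHER:
            candidates.add(table_class)
        cls = next((c for c in precedence if c in candidates), GeneClass.OTHER)
        if cls is GeneClass.CAZYME:
            call = cazyme_map[pid]
            label = SignatureLabel(
                gene_class=cls,
                cazyme_families=call.families,
                ecami_subfamily=call.ecami_subfamily,
                detail=f"consensus:{call.n_tools}_tools",
            )
        else:
            label = SignatureLabel(gene_class=cls)
        out.append(AnnotatedGene(gene=gene, label=label))
    return out
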