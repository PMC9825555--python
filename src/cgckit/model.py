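"""Domain types for CAZyme gene cluster (CGC) detection and substrate prediction.

The central objects mirror the entities of a PUL-style annotation pipeline:
genes on contigs (:class:`GeneRecord`), their signature classification
(:class:`SignatureLabel`), detected clusters (:class:`CGC`), characterized
reference clusters with known substrates (:class:`PULRecord`), and the two
kinds of substrate evidence (:class:`PULMatch` / :class:`VoteTally`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class GeneClass(str, Enum):
    """Signature class of a gene.

    CAZymes are the cluster anchors; transporters (TC), transcription
    factors (TF) and signal transduction proteins (STP) are the other
    signature classes; everything else is Other.
    """

    CAZYME = "CAZyme"
    TC = "TC"
    TF = "TF"
    STP = "STP"
    OTHER = "Other"

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.value


#: The non-CAZyme signature classes.
OTHER_SIGNATURE_CLASSES = frozenset({GeneClass.TC, GeneClass.TF, GeneClass.STP})

#: All four signature classes.
SIGNATURE_CLASSES = frozenset({GeneClass.CAZYME}) | OTHER_SIGNATURE_CLASSES


class Tool(str, Enum):
    """The three CAZyme annotation engines whose hit tables we consume."""

    HMM = "hmm"
    ALIGNMENT = "alignment"
    KMER = "kmer"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


_ECAMI_SUBFAMILY_RE = re.compile(r"^[A-Za-z0-9]+_e\d+$")


def is_ecami_subfamily(name: str) -> bool:
    """True if *name* looks like a k-mer-tool subfamily label (``GH130_e13``).

    Subfamily names carry an ``e`` infix, distinguishing them from classical
    CAZy subfamilies such as ``GH5_1``.
    """
    return bool(_ECAMI_SUBFAMILY_RE.match(name))


def family_prefix(family: str) -> str:
    """CAZyme family name without any subfamily suffix (``GH5_1`` -> ``GH5``)."""
    return family.split("_", 1)[0]


@dataclass(frozen=True, order=True)
class GeneRecord:
    """One gene on a contig; coordinates are 1-based inclusive (GFF3)."""

    genome_id: str
    contig_id: str
    start: int
    end: int
    gene_id: str
    strand: str = "."
    protein_id: str = ""
    ordinal: int = -1

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class SignatureLabel:
    """Classification of a gene into one signature class, with detail."""

    gene_class: GeneClass
    cazyme_families: tuple[str, ...] = ()
    ecami_subfamily: Optional[str] = None
    detail: str = ""

    def __post_init__(self) -> None:
        if (self.gene_class is GeneClass.CAZYME) != bool(self.cazyme_families):
            raise ValueError(
                "cazyme_families must be non-empty iff gene_class is CAZyme "
                f"(got {self.gene_class} with families {self.cazyme_families})"
            )
        if self.ecami_subfamily is not None and not is_ecami_subfamily(
            self.ecami_subfamily
        ):
            raise ValueError(
                f"not an eCAMI-style subfamily name: {self.ecami_subfamily!r}"
            )


@dataclass(frozen=True)
class AnnotatedGene:
    """A gene together with its one signature label."""

    gene: GeneRecord
    label: SignatureLabel

    @property
    def gene_class(self) -> GeneClass:
        return self.label.gene_class

    @property
    def is_signature(self) -> bool:
        return self.label.gene_class is not GeneClass.OTHER


@dataclass(frozen=True)
class ToolHit:
    """One CAZyme family call from one tool for one protein."""

    protein_id: str
    tool: Tool
    family: str
    score: float = 0.0

    def __post_init__(self) -> None:
        if not isinstance(self.tool, Tool):
            raise ValueError(f"unknown tool {self.tool!r}")


@dataclass(frozen=True)
class PairwiseHit:
    """One pairwise protein alignment hit (BLAST tabular semantics)."""

    query_protein: str
    subject_protein: str
    identity: float
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.bit_score < 0:
            raise ValueError("bit_score must be >= 0")
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError("identity must be a percentage in [0, 100]")


@dataclass
class CGC:
    """An ordered run of genes on one contig satisfying the cluster rules.

    ``cgc_id`` has the form ``<genome>_<contig>|CGC<n>`` with n starting at 1
    in left-to-right contig order.
    """

    cgc_id: str
    genes: list[AnnotatedGene]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("a CGC must contain at least one gene")
        contigs = {g.gene.contig_id for g in self.genes}
        if len(contigs) != 1:
            raise ValueError(f"CGC {self.cgc_id} spans contigs {sorted(contigs)}")
        ordinals = [g.gene.ordinal for g in self.genes]
        if ordinals != list(range(ordinals[0], ordinals[0] + len(ordinals))):
            raise ValueError(f"CGC {self.cgc_id}: genes are not consecutive")

    @property
    def genome_id(self) -> str:
        return self.genes[0].gene.genome_id

    @property
    def contig_id(self) -> str:
        return self.genes[0].gene.contig_id

    @property
    def ordinal_range(self) -> tuple[int, int]:
        return (self.genes[0].gene.ordinal, self.genes[-1].gene.ordinal)

    @property
    def class_counts(self) -> dict[GeneClass, int]:
        counts: dict[GeneClass, int] = {}
        for g in self.genes:
            counts[g.gene_class] = counts.get(g.gene_class, 0) + 1
        return counts

    def members(self, gene_class: Optional[GeneClass] = None) -> list[AnnotatedGene]:
        if gene_class is None:
            return list(self.genes)
        return [g for g in self.genes if g.gene_class is gene_class]

    @property
    def protein_ids(self) -> list[str]:
        return [g.gene.protein_id for g in self.genes]


@dataclass(frozen=True)
class PULRecord:
    """A characterized gene cluster with member proteins and a curated substrate."""

    pul_id: str
    substrate: str
    proteins: tuple[tuple[str, GeneClass], ...]

    def __post_init__(self) -> None:
        if not self.substrate:
            raise ValueError(f"PUL {self.pul_id} has no substrate")

    @property
    def protein_ids(self) -> list[str]:
        return [p for p, _ in self.proteins]

    def class_of(self, protein_id: str) -> GeneClass:
        for pid, cls in self.proteins:
            if pid == protein_id:
                return cls
        return GeneClass.OTHER


@dataclass(frozen=True)
class SubfamilyMapEntry:
    """Subfamily -> EC numbers -> substrate row of the curated mapping table.

    Not every subfamily has characterized members, so ``substrate`` may be
    absent.
    """

    family: str
    ecami_subfamily: str
    ec_numbers: tuple[str, ...] = ()
    substrate: Optional[str] = None


@dataclass
class PULMatch:
    """Score of one CGC against one reference PUL.

    Eligible matches need at least one CAZyme-CAZyme pair and at least one
    pair matched within one of the other signature classes.
    """

    cgc_id: str
    pul_id: str
    summed_bits: float
    pairs: list[tuple[str, str, float]] = field(default_factory=list)
    n_cazyme_pairs: int = 0
    n_other_signature_pairs: int = 0

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def eligible(self) -> bool:
        return self.n_cazyme_pairs >= 1 and self.n_other_signature_pairs >= 1


@dataclass(frozen=True)
class HomologyAssignment:
    """Per-CGC substrate call transferred from the best-matching PUL."""

    cgc_id: str
    substrate: str
    best_match: PULMatch


@dataclass
class VoteTally:
    """Per-CGC result of subfamily substrate voting."""

    cgc_id: str
    votes: dict[str, int]
    n_cazymes: int
    n_annotated: int
    winner: Optional[str] = None
    tied: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if sum(self.votes.values()) != self.n_annotated:
            raise ValueError("vote counts must sum to n_annotated")
        if self.n_annotated > self.n_cazymes:
            raise ValueError("n_annotated cannot exceed n_cazymes")
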