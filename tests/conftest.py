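"""Shared builders: tiny contigs from class strings, and a reference
brute-force cluster enumerator kept independent of the scan implementation."""

from __future__ import annotations

import pytest

from cgckit.model import (
    OTHER_SIGNATURE_CLASSES,
    AnnotatedGene,
    GeneClass,
    GeneRecord,
    SignatureLabel,
)

#: single-letter shorthand used throughout the tests
CLASS_CODES = {
    "C": GeneClass.CAZYME,
    "T": GeneClass.TC,
    "F": GeneClass.TF,
    "S": GeneClass.STP,
    ".": GeneClass.OTHER,
}


def make_contig(
    codes: str,
    genome: str = "G1",
    contig: str = "c1",
    subfamilies: dict[int, str] | None = None,
) -> list[AnnotatedGene]:
    """Build an annotated contig from a class-code string like ``C..T``.

    *subfamilies* optionally assigns an eCAMI subfamily to the CAZyme at a
    given position.
    """
    genes = []
    for i, code in enumerate(codes):
        cls = CLASS_CODES[code]
        rec = GeneRecord(
            genome_id=genome,
            contig_id=contig,
            start=100 + 1000 * i,
            end=100 + 1000 * i + 899,
            gene_id=f"{genome}_{contig}_g{i}",
            protein_id=f"{genome}_{contig}_g{i}",
            ordinal=i,
        )
        if cls is GeneClass.CAZYME:
            label = SignatureLabel(
                gene_class=cls,
                cazyme_families=("GH13",),
                ecami_subfamily=(subfamilies or {}).get(i),
            )
        else:
            label = SignatureLabel(gene_class=cls)
        genes.append(AnnotatedGene(gene=rec, label=label))
    return genes


def brute_force_cgc_spans(
    codes: str,
    max_insert: int,
    required_other: frozenset = frozenset(OTHER_SIGNATURE_CLASSES),
    require_all: bool = False,
) -> list[tuple[int, int]]:
    """Independent oracle: enumerate every contiguous window, keep the valid
    maximal ones, then apply the composition rules.

    A window [i, j] is valid when it starts and ends on a signature gene and
    every internal run of consecutive non-signature genes has length
    <= max_insert; it is maximal when no valid window strictly contains it.
    """
    classes = [CLASS_CODES[c] for c in codes]
    n = len(classes)
    sig = [cls is not GeneClass.OTHER for cls in classes]

    def valid(i: int, j: int) -> bool:
        if not (sig[i] and sig[j]):
            return False
        run = 0
        for k in range(i, j + 1):
            if sig[k]:
                run = 0
            else:
                run += 1
                if run > max_insert:
                    return False
        return True

    windows = [(i, j) for i in range(n) for j in range(i, n) if valid(i, j)]
    maximal = [
        (i, j)
        for (i, j) in windows
        if not any(
            (a <= i and j <= b and (a, b) != (i, j)) for (a, b) in windows
        )
    ]
    kept = []
    for i, j in sorted(maximal):
        present = set(classes[i : j + 1])
        if GeneClass.CAZYME not in present:
            continue
        if require_all:
            if not required_other <= present:
                continue
        elif not (required_other & present):
            continue
        kept.append((i, j))
    return kept


@pytest.fixture(scope="session")
def noise_free_bundle():
    """A seeded noise-free fixture bundle shared across tests."""
    from cgckit.fixtures import FixtureSpec, make_fixture

    return make_fixture(FixtureSpec(seed=11, n_genomes=6, n_implanted_cgcs=12))
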