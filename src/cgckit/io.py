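"""Readers and writers for the external file formats.

GFF3 goes through :mod:`gffutils`; FASTA through :mod:`Bio.SeqIO`; all the
tabular formats (BLAST outfmt-6 hits, the curated mapping tables, the
annotation/result TSVs) through :mod:`pandas`. Coordinates stay 1-based
inclusive end to end, as in GFF3.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    CGC,
    AnnotatedGene,
    GeneClass,
    GeneRecord,
    PairwiseHit,
    PULRecord,
    SignatureLabel,
    SubfamilyMapEntry,
    Tool,
    ToolHit,
    is_ecami_subfamily,
)

PathLike = Union[str, os.PathLike]


class ParseError(ValueError):
    """A file does not conform to its expected format."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant (duplicate keys, bad spans)."""


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GFF_FEATURE_TYPES = ("gene", "CDS")


def read_gff(path: PathLike, genome_id: Optional[str] = None) -> list[GeneRecord]:
    """Read gene records from a GFF3 file.

    Features of type ``gene`` (or ``CDS`` where no genes are present) are
    used; each must carry an ``ID`` attribute. A ``genome`` attribute, when
    present, overrides *genome_id* (default: the file stem). A ``protein_id``
    attribute names the encoded protein (default: the gene ID). Records are
    returned sorted by (contig, start, end, gene_id) with 0-based ordinals
    assigned per contig.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        return []
    default_genome = genome_id or path.stem
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="error",
        )
    except Exception as exc:  # gffutils raises assorted error types
        raise ParseError(f"{path}: not valid GFF3: {exc}") from exc

    features = list(db.features_of_type("gene"))
    if not features:
        features = list(db.features_of_type("CDS"))

    records = []
    seen_ids: dict[str, set[str]] = {}
    for feat in features:
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        genome = feat.attributes.get("genome", [default_genome])[0]
        protein = feat.attributes.get("protein_id", [gene_id])[0]
        if feat.start > feat.end:
            raise ValidationError(
                f"{path}: gene {gene_id}: start {feat.start} > end {feat.end}"
            )
        if gene_id in seen_ids.setdefault(genome, set()):
            raise ValidationError(f"{path}: duplicate gene id {gene_id!r}")
        seen_ids[genome].add(gene_id)
        records.append(
            GeneRecord(
                genome_id=genome,
                contig_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                gene_id=gene_id,
                strand=feat.strand if feat.strand in "+-" else ".",
                protein_id=protein,
            )
        )
    return assign_ordinals(records)


def assign_ordinals(records: Iterable[GeneRecord]) -> list[GeneRecord]:
    """Sort records by (genome, contig, start, end, gene_id) and number each
    gene 0..n-1 along its contig. Ties on start break by end then gene_id."""
    ordered = sorted(
        records, key=lambda r: (r.genome_id, r.contig_id, r.start, r.end, r.gene_id)
    )
    out: list[GeneRecord] = []
    counters: dict[tuple[str, str], int] = {}
    for rec in ordered:
        key = (rec.genome_id, rec.contig_id)
        ordinal = counters.get(key, 0)
        counters[key] = ordinal + 1
        out.append(
            GeneRecord(
                genome_id=rec.genome_id,
                contig_id=rec.contig_id,
                start=rec.start,
                end=rec.end,
                gene_id=rec.gene_id,
                strand=rec.strand,
                protein_id=rec.protein_id,
                ordinal=ordinal,
            )
        )
    return out


def write_gff(records: Sequence[GeneRecord], path: PathLike) -> None:
    """Write gene records as GFF3 ``gene`` features (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in sorted(
            records, key=lambda r: (r.genome_id, r.contig_id, r.start, r.end, r.gene_id)
        ):
            attrs = f"ID={r.gene_id};genome={r.genome_id};protein_id={r.protein_id}"
            fh.write(
                "\t".join(
                    [
                        r.contig_id,
                        "cgckit",
                        "gene",
                        str(r.start),
                        str(r.end),
                        ".",
                        r.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: PathLike) -> dict[str, str]:
    """Protein id -> sequence."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=pid, description="") for pid, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)
# ---------------------------------------------------------------------------

_OUTFMT6_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


def read_hits(path: PathLike) -> list[PairwiseHit]:
    """Read pairwise protein hits from 12-column BLAST tabular (outfmt 6)."""
    path = Path(path)
    if path.stat().st_size == 0:
        return []
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=_OUTFMT6_COLUMNS,
            comment="#",
            dtype={"qseqid": str, "sseqid": str},
        )
    except Exception as exc:
        raise ParseError(f"{path}: not BLAST outfmt-6: {exc}") from exc
    if df.shape[1] != 12:
        raise ParseError(f"{path}: expected 12 columns, got {df.shape[1]}")
    for col in ("pident", "evalue", "bitscore"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ParseError(f"{path}: non-numeric values in column {col}")
        if df[col].isna().any():
            raise ParseError(f"{path}: missing values in column {col}")
    return [
        PairwiseHit(
            query_protein=row.qseqid,
            subject_protein=row.sseqid,
            identity=float(row.pident),
            e_value=float(row.evalue),
            bit_score=float(row.bitscore),
        )
        for row in df.itertuples(index=False)
    ]


def write_hits(hits: Sequence[PairwiseHit], path: PathLike) -> None:
    """Write hits as minimal outfmt-6 rows (placeholder alignment columns)."""
    rows = []
    for h in hits:
        rows.append(
            [
                h.query_protein,
                h.subject_protein,
                f"{h.identity:.1f}",
                100,
                0,
                0,
                1,
                100,
                1,
                100,
                f"{h.e_value:.2e}",
                f"{h.bit_score:.1f}",
            ]
        )
    pd.DataFrame(rows, columns=_OUTFMT6_COLUMNS).to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# Curated mapping tables
# ---------------------------------------------------------------------------


def read_mapping_tables(
    pul_map_path: PathLike, subfam_map_path: PathLike
) -> tuple[dict[str, str], dict[str, SubfamilyMapEntry]]:
    """Load the PUL->substrate and subfamily->EC->substrate mapping tables.

    Duplicate keys are rejected; an empty substrate cell means the subfamily
    has no assigned substrate (no characterized members).
    """
    return read_pul_substrate_map(pul_map_path), read_subfamily_map(subfam_map_path)


def read_pul_substrate_map(path: PathLike) -> dict[str, str]:
    df = _read_tsv(path, ["pul_id", "substrate"])
    mapping: dict[str, str] = {}
    for row in df.itertuples(index=False):
        pul_id = str(row.pul_id)
        if pul_id in mapping:
            raise ValidationError(f"{path}: duplicate pul_id {pul_id!r}")
        substrate = "" if pd.isna(row.substrate) else str(row.substrate).strip()
        if not substrate:
            raise ValidationError(f"{path}: PUL {pul_id!r} has empty substrate")
        mapping[pul_id] = substrate
    return mapping


def read_subfamily_map(path: PathLike) -> dict[str, SubfamilyMapEntry]:
    df = _read_tsv(path, ["family", "ecami_subfamily", "ec_numbers", "substrate"])
    mapping: dict[str, SubfamilyMapEntry] = {}
    for row in df.itertuples(index=False):
        subfam = str(row.ecami_subfamily)
        if subfam in mapping:
            raise ValidationError(f"{path}: duplicate subfamily {subfam!r}")
        ecs = (
            tuple(e for e in str(row.ec_numbers).split(";") if e and e != "nan")
            if not pd.isna(row.ec_numbers)
            else ()
        )
        substrate = None if pd.isna(row.substrate) else str(row.substrate).strip()
        mapping[subfam] = SubfamilyMapEntry(
            family=str(row.family),
            ecami_subfamily=subfam,
            ec_numbers=ecs,
            substrate=substrate or None,
        )
    return mapping


def write_pul_substrate_map(mapping: Mapping[str, str], path: PathLike) -> None:
    pd.DataFrame(
        sorted(mapping.items()), columns=["pul_id", "substrate"]
    ).to_csv(path, sep="\t", index=False)


def write_subfamily_map(
    entries: Iterable[SubfamilyMapEntry], path: PathLike
) -> None:
    rows = [
        {
            "family": e.family,
            "ecami_subfamily": e.ecami_subfamily,
            "ec_numbers": ";".join(e.ec_numbers),
            "substrate": e.substrate or "",
        }
        for e in sorted(entries, key=lambda e: e.ecami_subfamily)
    ]
    pd.DataFrame(rows, columns=["family", "ecami_subfamily", "ec_numbers", "substrate"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# PUL protein class table
# ---------------------------------------------------------------------------


def read_pul_proteins(path: PathLike, substrate_map: Mapping[str, str]) -> list[PULRecord]:
    """Assemble PULRecords from a (pul_id, protein_id, gene_class) table plus
    the PUL->substrate map. Every pul_id must have a mapped substrate."""
    df = _read_tsv(path, ["pul_id", "protein_id", "gene_class"])
    puls: dict[str, list[tuple[str, GeneClass]]] = {}
    for row in df.itertuples(index=False):
        try:
            cls = GeneClass(str(row.gene_class))
        except ValueError as exc:
            raise ValidationError(
                f"{path}: unknown gene_class {row.gene_class!r}"
            ) from exc
        puls.setdefault(str(row.pul_id), []).append((str(row.protein_id), cls))
    records = []
    for pul_id in sorted(puls):
        if pul_id not in substrate_map:
            raise ValidationError(f"PUL {pul_id!r} has no mapped substrate")
        records.append(
            PULRecord(
                pul_id=pul_id,
                substrate=substrate_map[pul_id],
                proteins=tuple(puls[pul_id]),
            )
        )
    return records


def write_pul_proteins(puls: Iterable[PULRecord], path: PathLike) -> None:
    rows = [
        {"pul_id": p.pul_id, "protein_id": pid, "gene_class": cls.value}
        for p in puls
        for pid, cls in p.proteins
    ]
    pd.DataFrame(rows, columns=["pul_id", "protein_id", "gene_class"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Annotation tables
# ---------------------------------------------------------------------------


def read_cazyme_hits(path: PathLike) -> list[ToolHit]:
    """Read per-tool CAZyme family calls (protein_id, tool, family, score)."""
    df = _read_tsv(path, ["protein_id", "tool", "family", "score"])
    hits = []
    for row in df.itertuples(index=False):
        try:
            tool = Tool(str(row.tool))
        except ValueError as exc:
            raise ValidationError(f"{path}: unknown tool {row.tool!r}") from exc
        hits.append(
            ToolHit(
                protein_id=str(row.protein_id),
                tool=tool,
                family=str(row.family),
                score=float(row.score),
            )
        )
    return hits


def write_cazyme_hits(hits: Iterable[ToolHit], path: PathLike) -> None:
    rows = [
        {
            "protein_id": h.protein_id,
            "tool": h.tool.value,
            "family": h.family,
            "score": h.score,
        }
        for h in hits
    ]
    pd.DataFrame(rows, columns=["protein_id", "tool", "family", "score"]).to_csv(
        path, sep="\t", index=False
    )


def read_signature_labels(path: PathLike) -> dict[str, GeneClass]:
    """Read TC/TF/STP calls: protein_id -> class."""
    df = _read_tsv(path, ["protein_id", "gene_class"], optional=["detail"])
    table: dict[str, GeneClass] = {}
    for row in df.itertuples(index=False):
        try:
            cls = GeneClass(str(row.gene_class))
        except ValueError as exc:
            raise ValidationError(
                f"{path}: unknown gene_class {row.gene_class!r}"
            ) from exc
        table[str(row.protein_id)] = cls
    return table


def write_signature_labels(
    labels: Mapping[str, GeneClass], path: PathLike, detail: str = ""
) -> None:
    rows = [
        {"protein_id": pid, "gene_class": cls.value, "detail": detail}
        for pid, cls in sorted(labels.items())
    ]
    pd.DataFrame(rows, columns=["protein_id", "gene_class", "detail"]).to_csv(
        path, sep="\t", index=False
    )


def write_annotated_genes(genes: Sequence[AnnotatedGene], path: PathLike) -> None:
    rows = [
        {
            "gene_id": g.gene.gene_id,
            "genome_id": g.gene.genome_id,
            "contig": g.gene.contig_id,
            "start": g.gene.start,
            "end": g.gene.end,
            "strand": g.gene.strand,
            "protein_id": g.gene.protein_id,
            "gene_class": g.gene_class.value,
            "families": ";".join(g.label.cazyme_families),
            "ecami_subfamily": g.label.ecami_subfamily or "",
        }
        for g in genes
    ]
    pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "genome_id",
            "contig",
            "start",
            "end",
            "strand",
            "protein_id",
            "gene_class",
            "families",
            "ecami_subfamily",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_annotated_genes(path: PathLike) -> list[AnnotatedGene]:
    df = _read_tsv(
        path,
        [
            "gene_id",
            "genome_id",
            "contig",
            "start",
            "end",
            "strand",
            "protein_id",
            "gene_class",
            "families",
            "ecami_subfamily",
        ],
    )
    records = []
    for row in df.itertuples(index=False):
        records.append(
            GeneRecord(
                genome_id=str(row.genome_id),
                contig_id=str(row.contig),
                start=int(row.start),
                end=int(row.end),
                gene_id=str(row.gene_id),
                strand=str(row.strand),
                protein_id=str(row.protein_id),
            )
        )
    records = assign_ordinals(records)
    by_id = {(r.genome_id, r.gene_id): r for r in records}
    genes = []
    for row in df.itertuples(index=False):
        cls = GeneClass(str(row.gene_class))
        fams = (
            tuple(str(row.families).split(";"))
            if not pd.isna(row.families) and str(row.families)
            else ()
        )
        subfam = (
            str(row.ecami_subfamily)
            if not pd.isna(row.ecami_subfamily) and str(row.ecami_subfamily)
            else None
        )
        genes.append(
            AnnotatedGene(
                gene=by_id[(str(row.genome_id), str(row.gene_id))],
                label=SignatureLabel(
                    gene_class=cls, cazyme_families=fams, ecami_subfamily=subfam
                ),
            )
        )
    genes.sort(key=lambda g: (g.gene.genome_id, g.gene.contig_id, g.gene.ordinal))
    return genes


# ---------------------------------------------------------------------------
# CGC table
# ---------------------------------------------------------------------------


def write_cgcs(cgcs: Sequence[CGC], path: PathLike) -> None:
    rows = []
    for c in cgcs:
        counts = c.class_counts
        rows.append(
            {
                "cgc_id": c.cgc_id,
                "genome_id": c.genome_id,
                "contig": c.contig_id,
                "ordinal_start": c.ordinal_range[0],
                "ordinal_end": c.ordinal_range[1],
                "n_genes": len(c.genes),
                "n_cazyme": counts.get(GeneClass.CAZYME, 0),
                "n_tc": counts.get(GeneClass.TC, 0),
                "n_tf": counts.get(GeneClass.TF, 0),
                "n_stp": counts.get(GeneClass.STP, 0),
                "n_other": counts.get(GeneClass.OTHER, 0),
                "gene_ids": ";".join(g.gene.gene_id for g in c.genes),
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "cgc_id",
            "genome_id",
            "contig",
            "ordinal_start",
            "ordinal_end",
            "n_genes",
            "n_cazyme",
            "n_tc",
            "n_tf",
            "n_stp",
            "n_other",
            "gene_ids",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_cgcs(path: PathLike, genes: Sequence[AnnotatedGene]) -> list[CGC]:
    """Rehydrate CGCs from cgc.tsv plus the annotated gene list."""
    df = _read_tsv(path, ["cgc_id", "genome_id", "contig", "ordinal_start", "ordinal_end"])
    index: dict[tuple[str, str, int], AnnotatedGene] = {
        (g.gene.genome_id, g.gene.contig_id, g.gene.ordinal): g for g in genes
    }
    cgcs = []
    for row in df.itertuples(index=False):
        members = [
            index[(str(row.genome_id), str(row.contig), o)]
            for o in range(int(row.ordinal_start), int(row.ordinal_end) + 1)
        ]
        cgcs.append(CGC(cgc_id=str(row.cgc_id), genes=members))
    return cgcs


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _read_tsv(
    path: PathLike, required: list[str], optional: Optional[list[str]] = None
) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=required + (optional or []))
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse TSV: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return df
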