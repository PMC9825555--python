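"""Synthetic test-data generator: genomes with implanted CGCs.

Generates a self-contained file bundle in the formats the toolkit consumes:
a mock PUL database with curated substrates, genomes whose contigs carry
implanted copies of those PULs plus background genes, consistent pairwise
hit tables linking implant proteins to their source PULs, per-tool CAZyme
hit tables, TC/TF/STP label tables, both curated mapping TSVs, protein
FASTA, and a truth table recording every implant. With a fixed seed the
bundle is byte-identical across runs.

Background signature genes are deliberately isolated (spaced further apart
than the insert tolerance, and never a CAZyme next to a TC/TF/STP) so that
every true cluster in the bundle is an implant; the truth table is then a
complete reference for recovery measurements. Bit scores are fabricated,
not computed by alignment: implant-to-source hits get high scores, decoy
CAZyme-to-CAZyme hits against other PULs get low ones, which exercises both
best-hit selection and the eligibility rule.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import io as cgio
from .model import (
    AnnotatedGene,
    GeneClass,
    GeneRecord,
    PairwiseHit,
    PULRecord,
    SignatureLabel,
    SubfamilyMapEntry,
    Tool,
    ToolHit,
)

_SUBSTRATES = (
    "starch",
    "xylan",
    "pectin",
    "mucin",
    "cellulose",
    "beta-glucan",
    "arabinogalactan",
    "chitin",
    "mannan",
    "host glycan",
    "alginate",
    "fructan",
    "galactomannan",
    "xyloglucan",
    "carrageenan",
    "agarose",
    "laminarin",
    "human milk polysaccharide",
    "capsular polysaccharide",
    "rhamnogalacturonan",
)

_CAZYME_FAMILY_POOL = (
    "GH2", "GH3", "GH5", "GH10", "GH13", "GH16", "GH26", "GH28",
    "GH43", "GH92", "GH130", "PL1", "PL8", "CE1", "GT2", "GT4",
)

_OTHER_SIG_CLASSES = (GeneClass.TC, GeneClass.TF, GeneClass.STP)

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic bundle.

    Defaults give a small but non-trivial community: 6 genomes of 2 contigs
    with 40 genes each, a 20-PUL reference spanning 20 substrates, and 12
    implanted clusters. Noise knobs: *drop_hit_prob* removes implant-to-
    source hits, *bitscore_jitter_sd* perturbs bit scores,
    *mislabel_prob* flips an implant gene's class label to Other.
    """

    seed: int = 0
    n_genomes: int = 6
    contigs_per_genome: int = 2
    genes_per_contig: int = 40
    n_implanted_cgcs: int = 12
    n_puls: int = 20
    implant_composition: Optional[Sequence[Sequence[GeneClass]]] = None
    pul_substrates: Sequence[str] = _SUBSTRATES
    drop_hit_prob: float = 0.0
    bitscore_jitter_sd: float = 0.0
    mislabel_prob: float = 0.0

    def __post_init__(self) -> None:
        for p in (self.drop_hit_prob, self.mislabel_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.implant_composition is not None:
            for comp in self.implant_composition:
                if GeneClass.CAZYME not in comp:
                    raise ValueError("every implant composition needs a CAZyme")


@dataclass
class FixtureBundle:
    """In-memory fixture; `write` materializes the file bundle."""

    spec: FixtureSpec
    genes: list[AnnotatedGene]
    puls: list[PULRecord]
    pul_substrate_map: dict[str, str]
    subfamily_map: list[SubfamilyMapEntry]
    cazyme_hits: list[ToolHit]
    signature_labels: dict[str, GeneClass]
    hits: list[PairwiseHit]
    sequences: dict[str, str]
    truth: list[dict] = field(default_factory=list)

    def write(self, out_dir: Path | str) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cgio.write_gff([g.gene for g in self.genes], out / "genes.gff3")
        cgio.write_fasta(self.sequences, out / "proteins.faa")
        cgio.write_cazyme_hits(self.cazyme_hits, out / "cazyme_hits.tsv")
        cgio.write_signature_labels(self.signature_labels, out / "signature_labels.tsv")
        cgio.write_hits(self.hits, out / "hits.tsv")
        cgio.write_pul_substrate_map(self.pul_substrate_map, out / "pul_substrate.tsv")
        cgio.write_subfamily_map(self.subfamily_map, out / "subfamily_substrate.tsv")
        cgio.write_pul_proteins(self.puls, out / "pul_proteins.tsv")
        pd.DataFrame(
            self.truth,
            columns=[
                "genome_id",
                "contig_id",
                "ordinal_start",
                "ordinal_end",
                "source_pul",
                "substrate",
            ],
        ).to_csv(out / "truth.tsv", sep="\t", index=False)
        return out


def make_fixture(spec: FixtureSpec) -> FixtureBundle:
    """Generate the full bundle deterministically from ``spec.seed``."""
    rng = random.Random(spec.seed)

    # --- reference PULs, one substrate each, with a consistent subfamily map
    substrates = list(spec.pul_substrates)
    puls: list[PULRecord] = []
    pul_substrate_map: dict[str, str] = {}
    subfam_entries: dict[str, SubfamilyMapEntry] = {}
    pul_protein_class: dict[str, GeneClass] = {}
    pul_subfamily_of: dict[str, list[str]] = {}  # pul_id -> subfamily per CAZyme

    for i in range(spec.n_puls):
        pul_id = f"PUL{i + 1:04d}"
        substrate = substrates[i % len(substrates)]
        n_caz = rng.randint(1, 3)
        n_other = rng.randint(1, 2)
        classes = [GeneClass.CAZYME] * n_caz + [
            rng.choice(_OTHER_SIG_CLASSES) for _ in range(n_other)
        ]
        rng.shuffle(classes)
        proteins = []
        subfams = []
        for j, cls in enumerate(classes):
            pid = f"{pul_id}_p{j + 1}"
            proteins.append((pid, cls))
            pul_protein_class[pid] = cls
            if cls is GeneClass.CAZYME:
                fam = rng.choice(_CAZYME_FAMILY_POOL)
                subfam = f"{fam}_e{i + 1}{j}"
                subfams.append(subfam)
                # every subfamily used by this PUL maps to its substrate,
                # so unanimous voting recovers the implant's truth
                subfam_entries[subfam] = SubfamilyMapEntry(
                    family=fam,
                    ecami_subfamily=subfam,
                    ec_numbers=(f"3.2.1.{rng.randint(1, 150)}",),
                    substrate=substrate,
                )
        puls.append(
            PULRecord(pul_id=pul_id, substrate=substrate, proteins=tuple(proteins))
        )
        pul_substrate_map[pul_id] = substrate
        pul_subfamily_of[pul_id] = subfams

    # a few uncharacterized subfamilies with no substrate (abstaining voters)
    for k in range(5):
        fam = rng.choice(_CAZYME_FAMILY_POOL)
        subfam = f"{fam}_e9{k}"
        subfam_entries.setdefault(
            subfam,
            SubfamilyMapEntry(family=fam, ecami_subfamily=subfam),
        )

    # --- genomes: background genes plus implanted PUL copies
    genes: list[AnnotatedGene] = []
    cazyme_hits: list[ToolHit] = []
    signature_labels: dict[str, GeneClass] = {}
    hits: list[PairwiseHit] = []
    sequences: dict[str, str] = {}
    truth: list[dict] = []

    contig_slots = [
        (g, c)
        for g in range(spec.n_genomes)
        for c in range(spec.contigs_per_genome)
    ]
    implant_slots = [
        contig_slots[i % len(contig_slots)] for i in range(spec.n_implanted_cgcs)
    ]

    for genome_idx, contig_idx in contig_slots:
        genome_id = f"G{genome_idx + 1:03d}"
        contig_id = f"c{contig_idx + 1}"
        n_implants_here = sum(
            1 for s in implant_slots if s == (genome_idx, contig_idx)
        )
        contig_genes, contig_truth = _build_contig(
            rng,
            spec,
            genome_id,
            contig_id,
            n_implants_here,
            puls,
            pul_subfamily_of,
        )
        genes.extend(contig_genes)
        truth.extend(contig_truth)

    # --- per-gene annotation evidence and sequences
    for ag in genes:
        pid = ag.gene.protein_id
        sequences[pid] = "".join(rng.choice(_AA) for _ in range(60))
        if ag.gene_class is GeneClass.CAZYME:
            fam = ag.label.cazyme_families[0]
            cazyme_hits.append(ToolHit(pid, Tool.HMM, fam.split("_", 1)[0], 1e-20))
            kmer_fam = ag.label.ecami_subfamily or fam
            cazyme_hits.append(ToolHit(pid, Tool.KMER, kmer_fam, 50.0))
            if rng.random() < 0.5:
                cazyme_hits.append(
                    ToolHit(pid, Tool.ALIGNMENT, fam.split("_", 1)[0], 1e-30)
                )
        elif ag.gene_class in _OTHER_SIG_CLASSES:
            signature_labels[pid] = ag.gene_class
    for pid, cls in pul_protein_class.items():
        sequences[pid] = "".join(rng.choice(_AA) for _ in range(60))

    # --- pairwise hits: implant protein -> its source PUL protein (strong),
    #     plus weak CAZyme-only decoy hits against a different PUL
    gene_index = {
        (g.gene.genome_id, g.gene.contig_id, g.gene.ordinal): g for g in genes
    }
    for t in truth:
        pul = next(p for p in puls if p.pul_id == t["source_pul"])
        span = range(t["ordinal_start"], t["ordinal_end"] + 1)
        members = [gene_index[(t["genome_id"], t["contig_id"], o)] for o in span]
        sig_members = [m for m in members if m.gene_class is not GeneClass.OTHER]
        for member, (subject_pid, subject_cls) in zip(sig_members, pul.proteins):
            if rng.random() < spec.drop_hit_prob:
                continue
            bits = 180.0 + rng.uniform(0, 40)
            if spec.bitscore_jitter_sd > 0:
                bits += rng.gauss(0.0, spec.bitscore_jitter_sd)
            hits.append(
                PairwiseHit(
                    query_protein=member.gene.protein_id,
                    subject_protein=subject_pid,
                    identity=round(rng.uniform(40, 95), 1),
                    e_value=1e-50,
                    bit_score=round(max(bits, 30.0), 1),
                )
            )
            # decoy: weak CAZyme hit against a different PUL (ineligible on
            # its own since no other-signature pair accompanies it)
            if subject_cls is GeneClass.CAZYME and rng.random() < 0.5:
                other = rng.choice([p for p in puls if p.pul_id != pul.pul_id])
                caz_subjects = [
                    pid
                    for pid, cls in other.proteins
                    if cls is GeneClass.CAZYME
                ]
                if caz_subjects:
                    hits.append(
                        PairwiseHit(
                            query_protein=member.gene.protein_id,
                            subject_protein=rng.choice(caz_subjects),
                            identity=round(rng.uniform(25, 40), 1),
                            e_value=1e-6,
                            bit_score=round(rng.uniform(35, 60), 1),
                        )
                    )

    hits.sort(key=lambda h: (h.query_protein, h.subject_protein, -h.bit_score))
    return FixtureBundle(
        spec=spec,
        genes=genes,
        puls=puls,
        pul_substrate_map=pul_substrate_map,
        subfamily_map=sorted(
            subfam_entries.values(), key=lambda e: e.ecami_subfamily
        ),
        cazyme_hits=cazyme_hits,
        signature_labels=signature_labels,
        hits=hits,
        sequences=sequences,
        truth=truth,
    )


def _build_contig(
    rng: random.Random,
    spec: FixtureSpec,
    genome_id: str,
    contig_id: str,
    n_implants: int,
    puls: Sequence[PULRecord],
    pul_subfamily_of: dict[str, list[str]],
) -> tuple[list[AnnotatedGene], list[dict]]:
    """One contig: Other-gene background, isolated signature decoys, implants."""
    max_insert_guard = 3  # spacing guard > default max_insert of 2

    # class sequence for the background
    classes: list[tuple[GeneClass, Optional[str]]] = []
    since_last_sig = max_insert_guard  # allow a decoy early on
    for _ in range(spec.genes_per_contig):
        if since_last_sig >= max_insert_guard and rng.random() < 0.15:
            # isolated decoy: lone CAZyme (no partner class) or lone TC
            if rng.random() < 0.5:
                fam = rng.choice(_CAZYME_FAMILY_POOL)
                classes.append((GeneClass.CAZYME, fam))
            else:
                classes.append((rng.choice(_OTHER_SIG_CLASSES), None))
            since_last_sig = 0
        else:
            classes.append((GeneClass.OTHER, None))
            since_last_sig += 1

    # implant insertion points, padded so implants never touch a decoy
    segments: list[list[tuple[str, GeneClass, Optional[str], Optional[str]]]] = []
    # each entry: (kind, class, family, subfamily); kind "bg" or pul_id
    bg_seq = [("bg", cls, fam, None) for cls, fam in classes]
    chosen_puls = [rng.choice(puls) for _ in range(n_implants)]
    # split background into n_implants+1 chunks with >= guard Other genes kept
    chunk = len(bg_seq) // (n_implants + 1) if n_implants else len(bg_seq)
    pos = 0
    merged: list[tuple[str, GeneClass, Optional[str], Optional[str]]] = []
    for i, pul in enumerate(chosen_puls):
        merged.extend(bg_seq[pos : pos + chunk])
        merged.extend([("pad", GeneClass.OTHER, None, None)] * max_insert_guard)
        subfams = iter(pul_subfamily_of[pul.pul_id])
        for j, (pid, cls) in enumerate(pul.proteins):
            mislabeled = rng.random() < spec.mislabel_prob
            use_cls = GeneClass.OTHER if mislabeled else cls
            if cls is GeneClass.CAZYME:
                subfam = next(subfams, None)
                fam = subfam.split("_", 1)[0] if subfam else "GH13"
                merged.append((pul.pul_id, use_cls, fam, subfam))
            else:
                merged.append((pul.pul_id, use_cls, None, None))
            # occasional inserted Other gene inside the implant (<= 2)
            if j < len(pul.proteins) - 1 and rng.random() < 0.3:
                merged.append(("ins", GeneClass.OTHER, None, None))
        merged.extend([("pad", GeneClass.OTHER, None, None)] * max_insert_guard)
        pos += chunk
    merged.extend(bg_seq[pos:])

    genes: list[AnnotatedGene] = []
    truth: list[dict] = []
    start = 101
    implant_open: Optional[dict] = None
    for ordinal, (kind, cls, fam, subfam) in enumerate(merged):
        gene_id = f"{genome_id}_{contig_id}_g{ordinal + 1:04d}"
        rec = GeneRecord(
            genome_id=genome_id,
            contig_id=contig_id,
            start=start,
            end=start + 900 - 1,
            gene_id=gene_id,
            strand=rng.choice("+-"),
            protein_id=gene_id,
            ordinal=ordinal,
        )
        start += 1000  # fixed grid spacing; coordinates are not load-bearing
        if cls is GeneClass.CAZYME:
            label = SignatureLabel(
                gene_class=cls,
                cazyme_families=(fam or "GH13",),
                ecami_subfamily=subfam,
            )
        else:
            label = SignatureLabel(gene_class=cls)
        genes.append(AnnotatedGene(gene=rec, label=label))

        is_implant_member = kind not in ("bg", "pad", "ins")
        if is_implant_member:
            if implant_open is None or implant_open["source_pul"] != kind:
                if implant_open is not None:
                    truth.append(implant_open)
                implant_open = {
                    "genome_id": genome_id,
                    "contig_id": contig_id,
                    "ordinal_start": ordinal,
                    "ordinal_end": ordinal,
                    "source_pul": kind,
                    "substrate": next(
                        p.substrate for p in puls if p.pul_id == kind
                    ),
                }
            else:
                implant_open["ordinal_end"] = ordinal
        elif kind in ("bg", "pad") and implant_open is not None:
            truth.append(implant_open)
            implant_open = None
    if implant_open is not None:
        truth.append(implant_open)
    return genes, truth
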