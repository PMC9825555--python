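"""File-to-file pipeline steps shared by the CLI and the examples.

Each step reads the standard TSV/GFF3 inputs, runs the corresponding
library operation and writes the standard outputs, so a whole analysis is a
chain of four calls: annotate -> detect clusters -> predict substrates ->
summarize.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd

from . import io as cgio
from .annotate import classify_genes, consensus_cazyme
from .cluster import CGCParams, find_cgcs_by_contig
from .homology import DEFAULT_MIN_EVALUE, assign_all
from .stats import CombineCounts, combine, percentage
from .voting import vote_substrate


def run_annotate(
    gff: Path,
    cazyme_hits: Path,
    signature_table: Path,
    out: Path,
    min_tools: int = 2,
) -> int:
    """GFF3 + hit tables -> annotated_genes.tsv; returns the gene count."""
    genes = cgio.read_gff(gff)
    hits = cgio.read_cazyme_hits(cazyme_hits)
    table = cgio.read_signature_labels(signature_table)
    cazyme_map = consensus_cazyme(hits, min_tools=min_tools)
    annotated = classify_genes(genes, cazyme_map, table)
    cgio.write_annotated_genes(annotated, out)
    return len(annotated)


def run_cgc(annotated_genes: Path, out: Path, params: CGCParams = CGCParams()) -> int:
    """annotated_genes.tsv -> cgc.tsv; returns the cluster count."""
    genes = cgio.read_annotated_genes(annotated_genes)
    cgcs = find_cgcs_by_contig(genes, params)
    cgio.write_cgcs(cgcs, out)
    return len(cgcs)


def run_substrate_homology(
    annotated_genes: Path,
    cgc_table: Path,
    hits: Path,
    pul_map: Path,
    pul_proteins: Path,
    out: Path,
    min_evalue: float = DEFAULT_MIN_EVALUE,
) -> int:
    genes = cgio.read_annotated_genes(annotated_genes)
    cgcs = cgio.read_cgcs(cgc_table, genes)
    pairwise = cgio.read_hits(hits)
    substrate_map = cgio.read_pul_substrate_map(pul_map)
    pul_db = cgio.read_pul_proteins(pul_proteins, substrate_map)
    assignments = assign_all(cgcs, pul_db, pairwise, min_evalue=min_evalue)
    rows = [
        {
            "cgc_id": a.cgc_id,
            "substrate": a.substrate,
            "pul_id": a.best_match.pul_id,
            "summed_bits": round(a.best_match.summed_bits, 1),
            "n_pairs": a.best_match.n_pairs,
            "n_cazyme_pairs": a.best_match.n_cazyme_pairs,
            "n_other_signature_pairs": a.best_match.n_other_signature_pairs,
        }
        for a in assignments
    ]
    pd.DataFrame(
        rows,
        columns=[
            "cgc_id",
            "substrate",
            "pul_id",
            "summed_bits",
            "n_pairs",
            "n_cazyme_pairs",
            "n_other_signature_pairs",
        ],
    ).to_csv(out, sep="\t", index=False)
    return len(rows)


def run_substrate_voting(
    annotated_genes: Path,
    cgc_table: Path,
    subfam_map: Path,
    out: Path,
    min_votes: int = 1,
    strict_majority: bool = False,
) -> int:
    genes = cgio.read_annotated_genes(annotated_genes)
    cgcs = cgio.read_cgcs(cgc_table, genes)
    smap = cgio.read_subfamily_map(subfam_map)
    rows = []
    for cgc in cgcs:
        tally = vote_substrate(
            cgc, smap, min_votes=min_votes, strict_majority=strict_majority
        )
        rows.append(
            {
                "cgc_id": tally.cgc_id,
                "substrate": tally.winner or "NA",
                "votes": ";".join(f"{s}:{c}" for s, c in tally.votes.items()),
                "n_cazymes": tally.n_cazymes,
                "n_annotated": tally.n_annotated,
                "tied": ";".join(tally.tied),
            }
        )
    pd.DataFrame(
        rows,
        columns=["cgc_id", "substrate", "votes", "n_cazymes", "n_annotated", "tied"],
    ).to_csv(out, sep="\t", index=False)
    return sum(1 for r in rows if r["substrate"] != "NA")


def run_stats(
    annotated_genes: Path,
    cgc_table: Path,
    homology_table: Path,
    voting_table: Path,
    out_dir: Path,
    decimals: int = 2,
) -> CombineCounts:
    """Combined assignments + summary tables; returns the combine counts."""
    genes = cgio.read_annotated_genes(annotated_genes)
    cgcs = cgio.read_cgcs(cgc_table, genes)
    universe = [c.cgc_id for c in cgcs]

    hom_df = pd.read_csv(homology_table, sep="\t", dtype=str)
    hom_map = dict(zip(hom_df["cgc_id"], hom_df["substrate"]))
    vote_df = pd.read_csv(voting_table, sep="\t", dtype=str)
    vote_map = {
        r.cgc_id: r.substrate
        for r in vote_df.itertuples(index=False)
        if r.substrate != "NA"
    }

    rows, counts = combine(hom_map, vote_map, universe)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "cgc_id": r.cgc_id,
                "substrate_homology": r.substrate_homology or "NA",
                "substrate_voting": r.substrate_voting or "NA",
                "both": int(r.both),
                "agree": int(r.agree),
            }
            for r in rows
        ],
        columns=["cgc_id", "substrate_homology", "substrate_voting", "both", "agree"],
    ).to_csv(out_dir / "combined_assignments.tsv", sep="\t", index=False)

    n_cgcs = len(universe)
    summary_rows = [
        ("n_cgcs", n_cgcs, ""),
        ("n_cgcs_assigned_homology", len(hom_map), ""),
        ("n_cgcs_assigned_voting", len(vote_map), ""),
        ("n_cgcs_assigned_any", counts.n_union, ""),
        ("n_cgcs_assigned_both", counts.n_both, ""),
        ("n_cgcs_agree", counts.n_agree, ""),
    ]
    pct_rows = []
    if n_cgcs:
        pct_rows.append(
            ("pct_cgcs_assigned_any", percentage(counts.n_union, n_cgcs, decimals), "%")
        )
    if counts.n_union:
        pct_rows.append(
            ("pct_both_of_any", percentage(counts.n_both, counts.n_union, decimals), "%")
        )
    if counts.n_both:
        pct_rows.append(
            ("pct_agree_of_both", percentage(counts.n_agree, counts.n_both, 1), "%")
        )
    pd.DataFrame(
        summary_rows + pct_rows, columns=["metric", "value", "unit"], dtype=object
    ).to_csv(out_dir / "summary_stats.tsv", sep="\t", index=False)

    dist_rows = []
    for approach, amap in (("homology", hom_map), ("voting", vote_map)):
        counts_by_substrate: dict[str, int] = {}
        for s in amap.values():
            counts_by_substrate[s] = counts_by_substrate.get(s, 0) + 1
        for substrate, n in sorted(counts_by_substrate.items()):
            dist_rows.append(
                {"substrate": substrate, "approach": approach, "cgc_count": n}
            )
    pd.DataFrame(
        dist_rows, columns=["substrate", "approach", "cgc_count"]
    ).to_csv(out_dir / "substrate_distribution.tsv", sep="\t", index=False)
    return counts
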