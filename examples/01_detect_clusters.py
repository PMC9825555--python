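"""Detect CAZyme gene clusters on a hand-built contig.

A CGC is a run of genes in which consecutive signature genes (CAZyme, TC,
TF, STP) are separated by at most `max_insert` non-signature genes, and
which contains at least one CAZyme plus one other signature gene.
"""

from cgckit import CGCParams, GeneClass, GeneRecord, SignatureLabel, find_cgcs
from cgckit.model import AnnotatedGene

# a 9-gene contig: CAZyme, 2 unknowns, transporter | big gap | lone CAZyme
layout = [
    ("amyA", GeneClass.CAZYME, ("GH13",)),
    ("hyp1", GeneClass.OTHER, ()),
    ("hyp2", GeneClass.OTHER, ()),
    ("susC", GeneClass.TC, ()),
    ("hyp3", GeneClass.OTHER, ()),
    ("hyp4", GeneClass.OTHER, ()),
    ("hyp5", GeneClass.OTHER, ()),
    ("hyp6", GeneClass.OTHER, ()),
    ("celB", GeneClass.CAZYME, ("GH5",)),
]

genes = []
for i, (name, cls, fams) in enumerate(layout):
    rec = GeneRecord("demoMAG", "contig1", 100 + 1500 * i, 1300 + 1500 * i,
                     name, "+", name, ordinal=i)
    genes.append(AnnotatedGene(rec, SignatureLabel(cls, cazyme_families=fams)))

for max_insert in (2, 4):
    cgcs = find_cgcs(genes, CGCParams(max_insert=max_insert))
    print(f"max_insert={max_insert}: {len(cgcs)} cluster(s)")
    for c in cgcs:
        members = ", ".join(f"{g.gene.gene_id}({g.gene_class})" for g in c.genes)
        print(f"  {c.cgc_id}: {members}")

# With max_insert=2 only amyA..susC clusters (celB sits past a 4-gene gap and
# alone lacks a transporter partner); at max_insert=4 the chain reaches celB
# and the whole span becomes one cluster.
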