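"""Tiny shared builder for the example scripts."""

from cgckit import GeneClass, GeneRecord, SignatureLabel
from cgckit.model import CGC, AnnotatedGene


def demo_cgc(extra_subfamilies: list[str] | None = None) -> CGC:
    """A small cluster: GH13 CAZyme, optional extra CAZymes carrying the
    given eCAMI subfamilies, and a SusC-like transporter."""
    extra = extra_subfamilies or []
    spec: list[tuple[str, GeneClass, str | None]] = [
        ("q_gh13", GeneClass.CAZYME, None)
    ]
    spec += [(f"q_caz{i + 1}", GeneClass.CAZYME, sf) for i, sf in enumerate(extra)]
    spec.append(("q_susc", GeneClass.TC, None))

    genes = []
    for i, (name, cls, subfam) in enumerate(spec):
        if cls is GeneClass.CAZYME:
            family = subfam.split("_", 1)[0] if subfam else "GH13"
            label = SignatureLabel(cls, cazyme_families=(family,),
                                   ecami_subfamily=subfam)
        else:
            label = SignatureLabel(cls)
        rec = GeneRecord("demoMAG", "contig1", 100 + 1200 * i, 1100 + 1200 * i,
                         name, "+", name, ordinal=i)
        genes.append(AnnotatedGene(rec, label))
    return CGC("demoMAG_contig1|CGC1", genes)
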