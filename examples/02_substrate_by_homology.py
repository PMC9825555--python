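"""Assign a cluster the substrate of its best-matching characterized PUL.

Candidate PULs are ranked by the sum of bit scores over a one-to-one
pairing of the cluster's proteins with the PUL's proteins; a match only
counts if it pairs at least one CAZyme with a CAZyme and one TC/TF/STP
gene with a gene of the same class.
"""

from cgckit import GeneClass, PairwiseHit, PULRecord, best_pul
from cgckit.model import CGC
from examples_util import demo_cgc

cgc = demo_cgc()  # CAZyme + transporter, protein ids q_gh13 / q_susc

mucin_pul = PULRecord(
    "PUL0007", "mucin",
    (("PUL0007_gh", GeneClass.CAZYME), ("PUL0007_tc", GeneClass.TC)),
)
starch_pul = PULRecord(
    "PUL0015", "starch",
    (("PUL0015_gh", GeneClass.CAZYME), ("PUL0015_tc", GeneClass.TC)),
)

hits = [
    # strong, class-consistent matches to the mucin PUL
    PairwiseHit("q_gh13", "PUL0007_gh", 62.0, 1e-80, 245.0),
    PairwiseHit("q_susc", "PUL0007_tc", 48.5, 1e-40, 133.0),
    # weaker matches to the starch PUL
    PairwiseHit("q_gh13", "PUL0015_gh", 35.0, 1e-20, 96.0),
    PairwiseHit("q_susc", "PUL0015_tc", 31.0, 1e-15, 80.0),
]

assignment = best_pul(cgc, [mucin_pul, starch_pul], hits)
m = assignment.best_match
print(f"query cluster : {cgc.cgc_id}")
print(f"best PUL      : {m.pul_id} (summed bits {m.summed_bits:.1f}, "
      f"{m.n_cazyme_pairs} CAZyme pair, {m.n_other_signature_pairs} other-signature pair)")
print(f"substrate     : {assignment.substrate}")
# The mucin PUL wins 378.0 to 176.0 summed bits, so the cluster inherits
# its curated substrate, mucin.
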