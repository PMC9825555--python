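"""Assign a cluster substrate by majority voting over CAZyme subfamilies.

Each CAZyme with an eCAMI-style subfamily is looked up in the curated
subfamily -> EC -> substrate table; mapped CAZymes vote, unmapped ones
abstain, and the plurality winner becomes the cluster's substrate.
"""

from cgckit import SubfamilyMapEntry, vote_substrate
from examples_util import demo_cgc

subfam_map = {
    "GH130_e13": SubfamilyMapEntry("GH130", "GH130_e13", ("2.4.1.-",), "mannan"),
    "GH130_e5": SubfamilyMapEntry("GH130", "GH130_e5", ("2.4.1.319",), "mannan"),
    "GH2_e3": SubfamilyMapEntry("GH2", "GH2_e3", ("3.2.1.23",), "host glycan"),
    "GH5_e90": SubfamilyMapEntry("GH5", "GH5_e90", (), None),  # uncharacterized
}

# cluster with 4 extra CAZymes: two mannan subfamilies, one host-glycan,
# one uncharacterized; the leading GH13 gene carries no subfamily label
cgc = demo_cgc(["GH130_e13", "GH130_e5", "GH2_e3", "GH5_e90"])

tally = vote_substrate(cgc, subfam_map)
print(f"cluster      : {tally.cgc_id}")
print(f"CAZymes      : {tally.n_cazymes} total, {tally.n_annotated} with a mapped substrate")
print(f"votes        : {tally.votes}")
print(f"substrate    : {tally.winner}")
# mannan wins 2 votes to 1; the two CAZymes without a usable subfamily
# (no label / no characterized member) abstain rather than dilute the call.
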