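"""Published dbCAN-seq microbiome release counts, as input data.

These are the released catalog sizes for the four MAG environments (human
gut, human oral, cow rumen, marine): MAGs, proteins, CAZymes, CGCs, and
substrate-assignment counts from the two prediction approaches. They serve
as numerators/denominators for the percentage summaries — the full catalogs
themselves (thousands of MAGs) are not shipped or reprocessed here.
"""

from __future__ import annotations

from types import MappingProxyType

#: Catalog counts per environment. Keys: dataset -> metric -> count.
DBCAN_SEQ_COUNTS = MappingProxyType(
    {
        "human_gut": {
            "n_mags": 4744,
            "n_proteins": 10_231_988,
            "n_cazymes": 261_386,
            "n_mags_with_cazymes": 4741,
            "n_cgcs": 94_276,
            "n_mags_with_cgcs": 4688,
            "n_cazymes_in_cgcs": 146_039,
            "n_cgcs_homology": 26_846,
            "n_mags_homology": 3841,
            "n_cazymes_homology": 65_589,
            "n_cgcs_voting": 3720,
            "n_mags_voting": 1611,
            "n_cazymes_voting": 15_089,
        },
        "human_oral": {
            "n_mags": 452,
            "n_proteins": 787_607,
            "n_cazymes": 17_899,
            "n_mags_with_cazymes": 449,
            "n_cgcs": 6_131,
            "n_mags_with_cgcs": 440,
            "n_cazymes_in_cgcs": 9_010,
            "n_cgcs_homology": 1407,
            "n_mags_homology": 339,
            "n_cazymes_homology": 3_218,
            "n_cgcs_voting": 210,
            "n_mags_voting": 115,
            "n_cazymes_voting": 698,
        },
        "cow_rumen": {
            "n_mags": 2729,
            "n_proteins": 5_343_176,
            "n_cazymes": 164_889,
            "n_mags_with_cazymes": 2720,
            "n_cgcs": 50_132,
            "n_mags_with_cgcs": 2704,
            "n_cazymes_in_cgcs": 74_934,
            "n_cgcs_homology": 10_222,
            "n_mags_homology": 2089,
            "n_cazymes_homology": 25_999,
            "n_cgcs_voting": 2361,
            "n_mags_voting": 945,
            "n_cazymes_voting": 9436,
        },
        "marine": {
            "n_mags": 1496,
            "n_proteins": 3_489_050,
            "n_cazymes": 53_872,
            "n_mags_with_cazymes": 1491,
            "n_cgcs": 18_367,
            "n_mags_with_cgcs": 1475,
            "n_cazymes_in_cgcs": 24_510,
            "n_cgcs_homology": 2099,
            "n_mags_homology": 742,
            "n_cazymes_homology": 5_605,
            "n_cgcs_voting": 373,
            "n_mags_voting": 192,
            "n_cazymes_voting": 1557,
        },
        "total": {
            "n_mags": 9421,
            "n_proteins": 19_851_821,
            "n_cazymes": 498_046,
            "n_mags_with_cazymes": 9401,
            "n_cgcs": 168_906,
            "n_mags_with_cgcs": 9307,
            "n_cazymes_in_cgcs": 254_493,
            "n_cgcs_homology": 40_574,
            "n_mags_homology": 7011,
            "n_cazymes_homology": 100_411,
            "n_cgcs_voting": 6664,
            "n_mags_voting": 2863,
            "n_cazymes_voting": 26_780,
        },
    }
)

#: Release-wide substrate-overlap counts between the two approaches.
DBCAN_SEQ_OVERLAP = MappingProxyType(
    {
        "n_cgcs_any_substrate": 41_447,
        "n_cgcs_both_approaches": 5_111,
        "n_cgcs_agree": 4_183,
        "n_puls_in_reference": 612,
    }
)
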