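# Methods

## Scope and model

cgckit operates downstream of sequence search: it consumes per-tool CAZyme
hit tables, TC/TF/STP label tables, gene coordinates (GFF3) and pairwise
protein hits (BLAST tabular), and is responsible for the combinatorial and
statistical layer — consensus calling, cluster detection, substrate
assignment and agreement statistics. The search engines themselves (HMM
scans, alignment search, k-mer classification) are external, which keeps
the toolkit testable end to end with fabricated hit tables.

## Signature annotation

A protein is accepted as a CAZyme when **distinct tools**, not hits, reach
the threshold: ≥2 of the 3 tools by default (`min_tools`, 1–3). The
retained family set is the union of families over the reporting tools;
tools disagree on subfamily granularity (`GH5` vs `GH5_1` vs `GH5_e7`), so
cross-tool family identity is compared on the prefix before the first
underscore, and an intersection mode is available (`intersect_families`).
When the k-mer tool reports an `e`-style subfamily it is kept for voting.

Each gene gets exactly one class. When calls conflict the precedence is
CAZyme > TC > TF > STP — CAZymes anchor clusters, so they are never masked
by a co-annotation; the order is configurable. Unannotated genes are Other.

## Cluster detection

The scan is linear over each contig's ordinal-sorted genes: signature
genes chain while the run of intervening non-signature genes is
≤ `max_insert` (default 2); a longer run closes the chain. Chains are
trimmed to their outermost signature genes, then kept iff they contain ≥1
CAZyme and ≥1 gene in `required_other` (default: any of TC/TF/STP;
`require_all` demands every listed class). Gaps are counted in genes, not
base pairs, and contigs are treated as independent linear sequences —
fragmented assemblies simply yield truncated or missed clusters rather
than joined ones.

Two deliberately open choices, both flag-controlled:

* **STP extends chains by default** (`active_signature_set`): the
  composition requirement is the precise rule; restricting which classes
  extend a chain is left to the user.
* **Trailing non-signature genes are trimmed**; `keep_flanks` retains up
  to `max_insert` flanking genes per side, with flank extension capped at
  the midpoint of the gap to the neighbouring chain so clusters can never
  overlap.

Correctness is established against a brute-force oracle that enumerates
all maximal valid windows on random contigs of ≤12 genes; the scan and the
oracle agree on 1000+ seeded random contigs, and cluster coverage is
monotone in `max_insert`.

## Substrate by PUL homology

Hits between a cluster and a reference PUL are filtered at
`min_evalue` ≤ 1e-4 (a conventional protein-homology cutoff; the ranking
is driven by bit scores, not by this threshold), then paired one-to-one
greedily by descending bit score with deterministic tie-breaks. One-to-one
pairing stops a single promiscuous protein from inflating the score.
Greedy matching is not globally optimal for arbitrary weight matrices; in
the dominant-partner regime of real homology (each protein's true ortholog
far outscores cross hits) it coincides with the exact maximum-weight
matching, which the tests verify against `linear_sum_assignment`, along
with the general bound greedy ≤ optimal.

Eligibility requires class agreement on both sides of a pair — a "CAZyme
match" is a CAZyme paired with a CAZyme, an "other-signature match" pairs
two genes of the same TC/TF/STP class. The best eligible PUL (highest
summed bits; ties by more pairs, then smaller PUL id) transfers its
substrate. No minimum summed-bits floor is applied: an eligible match of
any score is accepted, and clusters with no eligible PUL get no call.

## Substrate by subfamily voting

"Majority" is implemented as **plurality with a strict maximum**: a
substrate wins when it uniquely tops the tally and reaches `min_votes`
(default 1 — partially annotated clusters still get calls, which is the
intended behaviour of the voting walk-through this mirrors). A
`strict_majority` flag demands >50% of cast votes instead. CAZymes without
a subfamily, with an unmapped subfamily, or whose subfamily has no
characterized member abstain. Ties yield no call rather than a
multi-substrate label, so downstream agreement statistics always compare
single labels.

## Agreement and percentages

Substrate equality is exact string match after case-folding and trimming;
no synonym merging across the overlapping glycan nomenclature (pectin /
arabinogalactan / galactan …) is attempted, so measured agreement is a
conservative floor. Percentages use half-up rounding at the requested
precision (2 decimals for table statistics, 1 for agreement), which
reproduces hand-computed published values exactly; Python's default
round-half-even would not.

## Synthetic communities

The fixture generator emulates the *structure* of annotated MAGs, not
their sequences: genomes of linear contigs on a fixed 1 kb coordinate grid
(coordinates are irrelevant to the ordinal-based logic), a 20-substrate
PUL reference with 2–5 proteins per PUL, implanted copies of reference
PULs (with ≤2 inserted Other genes), and a background of Other genes with
isolated decoy signature genes spaced so they can never satisfy the
cluster rules. Hit tables are fabricated, not aligned: implant proteins
hit their source PUL at 180–220 bits, plus low-bit CAZyme-only decoy hits
against wrong PULs that exercise the eligibility rule. Subfamily labels of
implanted CAZymes map to the source PUL's substrate, so on noise-free
input both approaches must recover 100% of implants — a structural
identity, not a statistical claim. Noise knobs: `drop_hit_prob` (hit
loss), `bitscore_jitter_sd` (score noise), `mislabel_prob` (class-label
corruption). Everything derives from one `random.Random(seed)`, making
bundles byte-identical per seed.

What passing these tests does **not** show: robustness to real divergence
levels, to fragmented or contaminated assemblies, to mispredicted gene
models, or to the actual error profiles of the three annotation tools —
real hit tables are messier than fabricated ones in ways the noise knobs
only sketch.

## Published-catalog statistics

The four-environment MAG catalogs behind the released database (~9 400
genomes, ~20 M proteins) are not reprocessable at package-test scale. The
released counts are therefore shipped as input data
(`cgckit.datasets`) and the percentage layer recomputes every published
table percentage from its numerator/denominator — verifying the
statistical arithmetic, not the upstream annotation. The synthetic
pipeline runs in `scripts/acceptance.py` use 10 genomes × 3 contigs × ~30
genes with 60 implants against a 20-PUL reference, sized so the whole
script completes in seconds.

## Numerical and degenerate-input choices

* Gene-order ties (equal start) break by end, then gene id.
* Coordinates stay 1-based inclusive (GFF3) end to end.
* Strand is read and preserved but never conditions clustering or scoring.
* Empty inputs (no genes, no hits, no mapped CAZymes) yield empty outputs
  or explicit no-calls, never errors; invalid inputs (start > end,
  duplicate mapping keys, unknown tools/classes) fail fast with
  validation errors.
* All iteration over dicts/sets that reaches output passes through
  explicit sorts, so outputs are permutation-invariant and byte-stable.

## Known limitations

* Cross-contig clusters split by assembly fragmentation are not rejoined.
* The homology approach inherits reference bias: clusters targeting
  substrates absent from the PUL reference can only go uncalled or be
  mis-assigned to the nearest characterized relative.
* Voting ignores vote margins and EC-number multiplicity; a 2:1 tally and
  a 10:1 tally are equally confident calls.
* Substrate vocabulary is treated as flat strings; hierarchical glycan
  relationships are out of scope.
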