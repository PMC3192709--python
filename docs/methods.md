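# Methods

This note records the model behind `cctrace`, the conventions and defaults
it commits to, what the simulator does and does not emulate, and the design
choices that were genuinely open. It states no empirical result that the
test suite and `scripts/acceptance.py` do not themselves compute.

## The inference model

A homing group I intron propagates by endonuclease-mediated
double-strand-break repair. Repair copies the intron into an intron-lacking
allele together with a contiguous stretch of donor exon on one or both
flanks — the co-conversion tract (CCT). In a gene as conserved as plant
mitochondrial *cox1* (synonymous rates among the lowest known), the only
practical evidence of a tract is the cluster of substitutions it imports.
`cctrace` formalizes the published reasoning:

1. **Ancestral reconstruction.** Per alignment column, small-parsimony root
   states via the Hartigan generalization of Fitch (each internal node keeps
   the states occurring in a maximum number of children's state sets),
   which is exact for unit costs on trees of any arity — polychotomies are
   first-class throughout. Ties are broken by the majority state among
   intron-lacking taxa, then alphabetically; without a tree, the
   reconstruction falls back to a majority consensus of intron-lacking
   taxa. Columns gapped in a majority of intron-lacking taxa are ancestrally
   gaps; columns with no base information are N. The reconstructed ancestor
   is also the designated ungapped reference row on which signed exon
   positions are counted (+k is the k-th exon base 3′ of the insertion
   point, −k the k-th base 5′; there is no 0). Positions count raw
   nucleotides, not codons.

2. **Diagnostic sites.** Position p is diagnostic for a focal
   intron-bearing clade iff every member carries the same unambiguous base,
   that base differs from the ancestral state, and both are concrete
   (A/C/G/T). Ambiguity codes other than N are treated as mismatches here —
   conservative footprint calling — though primer matching (below) treats
   them permissively. Taxa with unknown intron status are excluded from
   evaluation rather than imputed.

3. **Homoplasy filter.** A site is flagged when its derived state occurs in
   at least one intron-lacking taxon (threshold configurable; default 1, a
   binary filter, which is exactly how the highly homoplasious −11 and +60
   positions are discarded in the literature). Flagged sites never
   contribute to bounds.

4. **Bounds.** The 3′ minimum tract length is the farthest positive
   non-homoplastic diagnostic position (0 if none). This is the only
   definition consistent with all published minimum lengths (35, 54, 63,
   78, 81 — each equals its farthest supporting site). Symmetrically for
   5′. With a candidate donor group, the conversion endpoint is bounded
   above by the first position past the lower bound at which the focal
   clade uniformly retains the ancestral state while the donor group
   uniformly differs; the open interval (lower, upper) brackets the
   endpoint, and upper is unbounded without donor evidence. The literature
   alternately calls the canonical tract 20 bp, 21 bp, and "minimally
   3–21 bp"; bounds here are computed from sites, so that ambiguity is
   reported, not resolved. The 5′ scan is implemented identically but its
   published support is weak and typically homoplastic; interpret 5′
   bounds with caution.

5. **Retroprocessing test.** RNA-mediated intron loss reverse-transcribes
   the spliced, edited mRNA, so it converts genomic C to T at C-to-U
   editing sites downstream of the lost intron. For an intron-lacking
   taxon: verdict `retro_signature` iff ≥1 downstream edit site (ancestral
   C, within a window, default 600 bp) shows T; `no_signature` iff all such
   sites remain C; `indeterminate` otherwise. Comparison is strictly at the
   DNA level.

6. **Loss with CCT retention.** A taxon that lacks the intron but matches
   the focal clade's derived state at *every* non-homoplastic diagnostic
   site is a secondary-loss candidate. Such a taxon would, by
   construction, flag every diagnostic site as homoplastic if it were
   included in the scan; the screen therefore evaluates each intron-lacking
   taxon against a report computed with that taxon excluded (leave-one-out).
   This is robust precisely because genuinely homoplasious sites have
   multiple intron-lacking carriers and stay flagged, while the full
   footprint carried only by the loss candidate becomes visible.

7. **Gain/loss parsimony.** Two extreme scenarios are compared by event
   count only (no likelihood — mirroring the published argument): a single
   Dollo gain at a named node followed by losses, versus one gain per
   maximal intron-bearing clade with no losses. On multifurcating trees the
   single-gain loss count is a range over binary resolutions. Exhaustive
   enumeration is used when the number of resolutions (product of
   (2k−3)!! over k-child polychotomies) is within a cap (default 10,000);
   beyond it, per-polychotomy optimization: at a polychotomy with a ≥ 1
   all-absent children and at least one other child, the contribution is
   min 1 (a resolution groups all absent children under one stem edge) and
   max a (a caterpillar isolates each). This is exact because a maximal
   lost subtree is a clade in the resolved tree and therefore can never
   span child groups of two different polychotomies, making contributions
   additive; the test suite checks the closed form against enumeration and
   against an independent minimum-cover oracle. Unknown tip states are
   assigned whichever state minimizes the count. Intron × CCT
   co-occurrence is summarized in a 2×2 table with a two-sided Fisher
   exact p-value; degenerate tables (a constant margin) are flagged with
   p = 1, and discordant taxa (CCT without intron, or vice versa) are
   listed.

## In-silico survey conventions

- Primer pairs are written 5′→3′ as synthesized; the reverse primer is
  matched as its reverse complement downstream of the forward footprint
  (standard PCR convention — orientation is not stated in the survey
  literature). Degenerate IUPAC codes intersect permissively.
- **Amplicon length includes both primer footprints.** Published product
  sizes never state this convention; it is the one under which inserting an
  intron adds exactly the intron's length to the product, and it makes the
  0.8-kb intron-less product self-consistent with primer positions.
- The built-in registry ships the six survey primers exactly as printed
  (cox1-1, -3, -4, -6 amplification; cox1-8, -10 intron-internal
  sequencing). The cox1-1/cox1-4 pair is quoted with products "750 bp or
  1735 bp", which is not self-consistent with a 967-bp intron
  (750 + 967 = 1717 ≠ 1735); this paper-internal rounding/geometry
  ambiguity is shipped as-is and no numeric consistency is asserted for
  that pair.
- Default mismatch budget is 0 (template quality is not modeled);
  configurable. Gel classification: absent within ±50 bp of the intron-less
  expectation, present at ≥ +500 bp (an angiosperm *cox1* intron is ~1 kb,
  so the bands are unambiguous), ambiguous between, `no_amplicon` when
  nothing amplifies.
- ORF lengths (both `longest_orf` and the simulator's `embed_orf`) include
  the terminating stop codon: an 840-bp ORF is ATG + 278 sense codons +
  stop. Forward strand only, ATG-initiated, ties broken by smallest start.

## The simulator

`simulate()` emulates the structure of an intron survey dataset: a
conserved exon alignment (default 200 bp around the insertion point,
insertion after exon base 100) evolving under Jukes–Cantor on a rooted
tree (user newick or Yule), with an explicit event schedule rather than
rates — the survey literature quantifies neither homing efficiency nor
loss rates, so events are placed deliberately and a rate mode is left as
future work. Defaults mirror the modeled system: intron length 967 bp
carrying an 840-bp ORF; a C-to-U editing site at +20 (edit sites are forced
to ancestral C); per-unit-length substitution rate 0.002, reflecting
near-invariant plant mitochondrial exons; retro conversion window 600 bp.

Events are applied at branch midpoints in schedule order. Homing copies the
donor's current exon states over the recipient at every position in
[−L5, +L3] (contiguous, extending outward from the insertion site — no
mosaic tracts) and makes the recipient subtree intron-bearing; the donor is
either an external sequence or another lineage, taken at its own branch
midpoint (the donor branch must precede the recipient in preorder, else a
config error). Retroprocessing loss removes the intron and applies C→T at
every currently-C edit site in (0, window]. A single RNG stream keyed by
the mandatory seed makes runs byte-reproducible.

What the simulator does **not** emulate: indels and alignment uncertainty,
codon-level selection, rate heterogeneity across sites or lineages,
recombination other than the tract copy, intra-individual heteroplasmy,
and PCR/sequencing error. Passing tests therefore demonstrate correctness
of the inference machinery under clean, JC-evolving data — not robustness
to misalignment or systematic error in real surveys.

## Toy datasets

The packaged fixtures encode the published footprint patterns with
synthetic taxa and a seeded random background (200-bp exon, insertion
after base 100). The canonical-tract positions inside (0, +20] are never
printed individually in the literature (only the count, 7, including the
+20 edit-site difference), so the fixtures place them at +3, +6, +9, +12,
+15, +18, +20 — third-position-like spacing that reproduces every printed
total: 7 canonical differences, 9 with +27 (G→A) and +35 (C→T), minimum
tract 35 bp; 54 bp from +30/+35/+54; endpoint interval (63, 70) from
+42/+45/+57/+60/+63 plus donor-retained native evidence at +70; 81 bp from
the single +81 T→C reversion. Homoplasious sites (−11, +60) are carried by
two intron-lacking taxa so they stay flagged even under leave-one-out
screening.

## Numerical and scale choices

- Diagnostic scan window defaults to ±200 bp; every published footprint
  lies within ±81.
- Codon-position site classes require a user-supplied reading-frame offset
  (codon position of exon base +1); without it, non-edit sites are classed
  `other` — the "third-position synonymous" label is descriptive and not
  load-bearing for bounds.
- Polychotomy enumeration cap 10,000 resolutions (see proof sketch above
  for exactness of the closed form beyond it).
- Test and acceptance problem sizes: toy alignments of 7–15 taxa × 200 bp;
  oracle equivalence on 200 random trees of ≤ 12 tips; parameter recovery
  on 500 rate-0 replicates with true tract lengths {10, 20, 35, 54, 81};
  retro discrimination on 60 replicates per noise level (rates 0, 0.01,
  0.05); PCR consistency on 12 simulated 8-taxon datasets. These sizes give
  exact or near-exhaustive coverage of the combinatorial space at desk
  scale.

## Known limitations

- The minimum-tract semantics is inherently one-sided: conversion beyond
  the farthest diagnostic site is invisible unless a donor group supplies
  retained-native evidence, so reported lengths are floors, not estimates.
- Ancestral reconstruction assumes the intron-lacking majority represents
  the native lineage; a dataset dominated by intron-bearing taxa would bias
  the ancestor toward the donor state and mask the tract.
- The gain/loss engine reproduces the computation for any user topology; it
  ships no claim about any particular published tree, whose polychotomies
  are presented only graphically in the literature.
- Maximum-likelihood tree inference, topology tests (e.g. the AU test),
  and editing-site prediction are out of scope; trees and edit positions
  are inputs.
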