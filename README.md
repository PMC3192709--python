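# cctrace

Detection of horizontal acquisition of mobile group I introns from the
footprints they leave in flanking exons.

## The problem

Homing group I introns — such as the ~1-kb intron found at one canonical
site in the angiosperm mitochondrial *cox1* gene — encode a site-specific
endonuclease that cleaves intron-lacking alleles and copies the intron in
via double-strand-break repair. The repair also replaces a stretch of the
host's flanking exon with donor-derived sequence: the **co-conversion tract
(CCT)**. Against the near-invariant background of plant mitochondrial
exons, a CCT shows up as a cluster of *diagnostic sites* — positions where
every member of an intron-containing clade shares a derived state that
intron-lacking relatives never carry. These clusters are the key evidence
for horizontal intron transfer, and their extent bounds the length of
co-conversion.

`cctrace` implements that inference as a tested pipeline:

- **Coordinate frame** — exon positions signed relative to the intron
  insertion point (+k downstream, −k upstream, no 0), counted on an
  ungapped reference row (the reconstructed ancestor).
- **In-silico intron survey** — degenerate-primer PCR prediction and
  gel-sizing classification (e.g. the 0.8-kb intron-less vs 1.8-kb
  intron-containing *cox1* products), intron extraction and ORF measurement.
- **CCT inference** — ancestral reconstruction (Fitch/Hartigan parsimony,
  exact on polychotomies), diagnostic-site calling, homoplasy filtering,
  and tract bounds: the 3′ minimum tract length is the farthest clean
  diagnostic position `max{ p > 0 : site p diagnostic, non-homoplastic }`,
  and with a candidate donor group the conversion endpoint is bracketed in
  an open interval `(lower, upper)` by the first downstream position where
  the focal clade demonstrably retains the native state while the donor
  differs.
- **Retroprocessing test** — RNA-mediated intron loss converts genomic C to
  T at downstream C-to-U editing sites; an intron-lacking gene with C at
  those sites never carried the intron, one with T is a loss candidate.
- **Gain/loss parsimony** — Dollo single-gain-with-losses versus
  independent-gains-no-loss scenario counts, with exact `[min, max]` loss
  ranges over all binary resolutions of polychotomies.
- **Forward simulator** — Jukes–Cantor exon evolution on a phylogeny with
  scheduled homing (tract copying from a donor lineage), vertical origins,
  and retroprocessing losses, emitting a truth table for validation.

## Worked example

```python
from cctrace import CoConversionModel, make_fixtures

bundle = make_fixtures("solanoideae9")   # toy alignment + tree + edit sites
model = CoConversionModel(
    bundle.locus, bundle.focal_clade,
    tree=bundle.phylogeny, edit_sites=bundle.edit_sites,
)
print(model.fit().summary())
```

```
Co-conversion tract report
==========================
focal clade (6 taxa): Hyoscyamus_A, Hyoscyamus_B, Physochlaina_A, Przewalskia_A, Scopolia_A, Mandragora_A
diagnostic sites: 11 (9 non-homoplastic)
3' minimum tract length: 35 bp
3' endpoint interval: (35, unbounded)
5' minimum tract length: 0 bp

position  ancestral  derived  class       homoplastic
     -11      G         A     other       yes
      +3      A         G     other       no
      +6      G         A     other       no
      +9      C         T     other       no
     +12      A         G     other       no
     +15      G         A     other       no
     +18      A         G     other       no
     +20      C         T     edit_site   no
     +27      G         A     other       no
     +35      C         T     other       no
     +60      G         A     other       yes
```

Reading: the six intron-bearing taxa share eleven derived states; two of
them (−11 and +60) also occur in intron-lacking taxa and are discarded as
homoplasy by the binary filter. The nine clean
sites include seven inside the canonical ~20-bp tract (among them the
C→T difference at the +20 editing site) plus two more at +27 and +35, so
co-conversion extended at least 35 bp into the 3′ exon. No donor group was
supplied, so the endpoint is unbounded above.

The same objects drive the rest of the pipeline: `res.retro_screen()`
tabulates the retroprocessing verdict for every intron-lacking taxon,
`res.loss_screen()` tests each one for intron loss with CCT retention
(leave-one-out), and `GainLossModel(tree, states, ["A,B,..."])` compares
gain/loss scenarios. The `cctrace` command exposes the stages as
subcommands (`ingest`, `simulate`, `survey`, `cct`, `gainloss`, `run`,
`fixtures`).

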