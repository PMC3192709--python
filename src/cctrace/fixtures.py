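"""Deterministic toy datasets reproducing published CCT footprint patterns.

Each fixture is a small synthetic exon alignment (plus tree, presence calls
and edit sites) around one intron insertion point, built so that the focal
intron-containing clade carries a documented cluster of derived states:

* ``solanoideae9`` — the canonical ~20-bp tract (7 differences including the
  +20 edit site) plus the two extra differences at +27 (G->A) and +35
  (C->T): 9 non-homoplastic diagnostic sites, 3' minimum tract 35 bp; the
  highly homoplasious -11 and +60 are included and flagged.
* ``acanthaceae`` — canonical tract plus derived states at +30/+35/+54 in a
  4-taxon clade: minimum tract 54 bp.
* ``musaceae`` — canonical tract plus eudicot-signature states at
  +42/+45/+57/+60/+63 in a monocot background, with an intron-bearing
  eudicot donor group that still differs from the natives at +70:
  endpoint interval (63, 70).
* ``brunfelsia`` — a single intron-bearing taxon with the canonical tract
  and a lone T->C reversion at +81: minimum tract 81 bp.
* ``cynomorium_loss`` — the solanoideae9 pattern plus one intron-*lacking*
  taxon that retains the full 9-site footprint (secondary loss with CCT
  retention).
* ``retro_loss`` — an intron-lacking taxon carrying T at the downstream
  C-to-U editing sites: the retroprocessing footprint.

All taxa and sequences are synthetic stand-ins; positions and counts are
the thing being modeled, not any real accession.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .frames import AlignedLocus, CoordinateFrame, EditSiteList
from .io import Phylogeny, read_tree_string, write_alignment, write_edit_sites, write_states

EXON_LEN = 200
INSERTION_POINT = 100  # exon bases 5' of the insertion point
CANONICAL_POSITIONS = (3, 6, 9, 12, 15, 18, 20)  # the 7 canonical-tract sites
CANONICAL_WINDOW = 20

# transition partner: the derived state used when none is dictated
_DERIVED = {"A": "G", "G": "A", "C": "T", "T": "C"}

FIXTURE_NAMES = (
    "solanoideae9",
    "acanthaceae",
    "musaceae",
    "brunfelsia",
    "cynomorium_loss",
    "retro_loss",
)


class UnknownFixture(ValueError):
    pass


@dataclass
class FixtureBundle:
    name: str
    locus: AlignedLocus
    phylogeny: Phylogeny
    edit_sites: EditSiteList
    focal_clade: tuple[str, ...]
    donor_clade: tuple[str, ...] = ()
    notes: str = ""
    expected: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_alignment(self.locus, outdir / "alignment.fasta")
        with open(outdir / "tree.nwk", "w") as fh:
            fh.write(self.phylogeny.as_newick() + "\n")
        write_states(self.locus.intron_present, outdir / "states.tsv")
        write_edit_sites(self.edit_sites, outdir / "edits.tsv")
        with open(outdir / "focal_clade.txt", "w") as fh:
            fh.write("\n".join(self.focal_clade) + "\n")
        if self.donor_clade:
            with open(outdir / "donor_clade.txt", "w") as fh:
                fh.write("\n".join(self.donor_clade) + "\n")


def _signed_index(pos: int) -> int:
    if pos == 0:
        raise ValueError("no position 0")
    return INSERTION_POINT + pos - 1 if pos > 0 else INSERTION_POINT + pos


def _ancestral_sequence(seed: int, constraints: dict[int, str]) -> list[str]:
    rng = np.random.default_rng(seed)
    seq = list("".join(rng.choice(["A", "C", "G", "T"], size=EXON_LEN)))
    for pos, base in constraints.items():
        seq[_signed_index(pos)] = base
    return seq


def _apply(seq: list[str], changes: dict[int, str]) -> str:
    out = list(seq)
    for pos, base in changes.items():
        out[_signed_index(pos)] = base
    return "".join(out)


def _derived_changes(ancestor: list[str], positions, dictated: dict[int, str] | None = None):
    dictated = dictated or {}
    changes = {}
    for pos in positions:
        changes[pos] = dictated.get(pos, _DERIVED[ancestor[_signed_index(pos)]])
    return changes


def _bundle(name, ancestor, focal, lacking, newick, edit_positions,
            derived, extra_rows=None, extra_states=None, donor_clade=(),
            homoplasy_rows=None, expected=None, notes=""):
    """Assemble a FixtureBundle from per-group sequence edits."""
    taxa, rows, states = [], [], {}
    for t in lacking:
        taxa.append(t)
        rows.append(_apply(ancestor, (homoplasy_rows or {}).get(t, {})))
        states[t] = False
    for t in focal:
        taxa.append(t)
        rows.append(_apply(ancestor, derived))
        states[t] = True
    for t, (row, present) in (extra_rows or {}).items():
        taxa.append(t)
        rows.append(row)
        states[t] = present
    frame = CoordinateFrame(insertion_column=INSERTION_POINT - 1)
    locus = AlignedLocus(taxa=taxa, rows=rows, frame=frame, intron_present=states)
    return FixtureBundle(
        name=name,
        locus=locus,
        phylogeny=read_tree_string(newick),
        edit_sites=EditSiteList.from_iterable(edit_positions),
        focal_clade=tuple(focal),
        donor_clade=tuple(donor_clade),
        expected=expected or {},
        notes=notes,
    )


def _solanoideae_parts():
    constraints = {20: "C", 27: "G", 35: "C", 44: "C", 92: "C", -11: "G", 60: "G"}
    ancestor = _ancestral_sequence(seed=20110927, constraints=constraints)
    focal = [
        "Hyoscyamus_A", "Hyoscyamus_B", "Physochlaina_A",
        "Przewalskia_A", "Scopolia_A", "Mandragora_A",
    ]
    lacking = [
        "Nicotiana_A", "Solanum_A", "Capsicum_A", "Petunia_A",
        "Datura_A", "Lycium_A", "Jaborosa_A", "Atropa_A",
    ]
    derived = _derived_changes(
        ancestor,
        CANONICAL_POSITIONS + (27, 35, -11, 60),
        dictated={20: "T", 27: "A", 35: "T"},
    )
    # -11 and +60 are highly homoplasious: two intron-lacking taxa carry the
    # same derived state, so the binary filter must exclude them (and must
    # keep excluding them in leave-one-out loss screening)
    homoplasy_rows = {
        "Datura_A": {-11: derived[-11], 60: derived[60]},
        "Lycium_A": {-11: derived[-11], 60: derived[60]},
        # a private substitution far from the tract, for realism
        "Solanum_A": {-50: _DERIVED[ancestor[_signed_index(-50)]]},
    }
    newick = (
        "((Hyoscyamus_A,Hyoscyamus_B,Physochlaina_A,Przewalskia_A,Scopolia_A,"
        "Mandragora_A),(Datura_A,Jaborosa_A,Atropa_A,Lycium_A),"
        "(Capsicum_A,Solanum_A),(Nicotiana_A,Petunia_A));"
    )
    return constraints, ancestor, focal, lacking, derived, homoplasy_rows, newick


def make_fixtures(name: str) -> FixtureBundle:
    """Build one of the packaged toy datasets by name."""
    if name == "solanoideae9":
        (_, ancestor, focal, lacking, derived,
         homoplasy_rows, newick) = _solanoideae_parts()
        return _bundle(
            "solanoideae9", ancestor, focal, lacking, newick,
            edit_positions=(20, 44, 92), derived=derived,
            homoplasy_rows=homoplasy_rows,
            expected={
                "diagnostic_sites": 9,
                "lower_bound_3prime": 35,
                "canonical_window_sites": 7,
            },
            notes="9 non-homoplastic diagnostic sites; -11/+60 flagged homoplastic",
        )

    if name == "cynomorium_loss":
        (_, ancestor, focal, lacking, derived,
         homoplasy_rows, newick) = _solanoideae_parts()
        loss_changes = {
            p: b for p, b in derived.items() if p not in (-11, 60)
        }
        newick = newick[:-2] + ",Cynomorium_A);"
        return _bundle(
            "cynomorium_loss", ancestor, focal, lacking, newick,
            edit_positions=(20, 44, 92), derived=derived,
            homoplasy_rows=homoplasy_rows,
            extra_rows={"Cynomorium_A": (_apply(ancestor, loss_changes), False)},
            expected={"loss_taxon": "Cynomorium_A"},
            notes="intron-lacking taxon retaining the full 9-site footprint",
        )

    if name == "retro_loss":
        (_, ancestor, focal, lacking, derived,
         homoplasy_rows, newick) = _solanoideae_parts()
        retro_changes = {20: "T", 44: "T"}  # C->T at downstream edit sites
        newick = newick[:-2] + ",Lost_lineage_A);"
        return _bundle(
            "retro_loss", ancestor, focal, lacking, newick,
            edit_positions=(20, 44, 92), derived=derived,
            homoplasy_rows=homoplasy_rows,
            extra_rows={"Lost_lineage_A": (_apply(ancestor, retro_changes), False)},
            expected={"retro_taxon": "Lost_lineage_A"},
            notes="retroprocessing footprint: T at ancestrally-C edit sites, no intron",
        )

    if name == "acanthaceae":
        constraints = {20: "C", 30: "G", 35: "C", 54: "G"}
        ancestor = _ancestral_sequence(seed=54035, constraints=constraints)
        focal = ["Sanchezia_A", "Justicia_A", "Barleria_A", "Thunbergia_A"]
        lacking = ["Sesamum_A", "Olea_A", "Lamium_A", "Antirrhinum_A", "Plantago_A"]
        derived = _derived_changes(
            ancestor, CANONICAL_POSITIONS + (30, 35, 54), dictated={20: "T"}
        )
        newick = (
            "((Sanchezia_A,Justicia_A,Barleria_A,Thunbergia_A),"
            "((Sesamum_A,Lamium_A),(Olea_A,Antirrhinum_A,Plantago_A)));"
        )
        return _bundle(
            "acanthaceae", ancestor, focal, lacking, newick,
            edit_positions=(20,), derived=derived,
            expected={"lower_bound_3prime": 54},
        )

    if name == "musaceae":
        constraints = {20: "C", 42: "G", 45: "C", 57: "C", 60: "G", 63: "G", 70: "G"}
        ancestor = _ancestral_sequence(seed=6370, constraints=constraints)
        focal = ["Musa_A", "Musella_A"]
        lacking = ["Zingiber_A", "Costus_A", "Elettaria_A", "Oryza_A"]
        derived = _derived_changes(
            ancestor,
            CANONICAL_POSITIONS + (42, 45, 57, 60, 63),
            dictated={20: "T", 57: "T", 60: "T"},
        )
        donors = ["Eudicot_donor_A", "Eudicot_donor_B"]
        # donors share the focal clade's tract but, past the conversion
        # endpoint, differ from the native lineage at +70
        donor_changes = dict(derived)
        donor_changes[70] = "A"
        extra_rows = {d: (_apply(ancestor, donor_changes), True) for d in donors}
        newick = (
            "(((Musa_A,Musella_A),(Zingiber_A,Costus_A,Elettaria_A),Oryza_A),"
            "(Eudicot_donor_A,Eudicot_donor_B));"
        )
        return _bundle(
            "musaceae", ancestor, focal, lacking, newick,
            edit_positions=(20,), derived=derived,
            extra_rows=extra_rows, donor_clade=donors,
            expected={"endpoint_interval": (63, 70)},
            notes="donor group retains derived states past the native +70 marker",
        )

    if name == "brunfelsia":
        constraints = {20: "C", 81: "T", 60: "G"}
        ancestor = _ancestral_sequence(seed=8160, constraints=constraints)
        focal = ["Brunfelsia_jam_A"]
        lacking = [
            "Brunfelsia_B", "Brunfelsia_C", "Brunfelsia_D",
            "Petunia_A", "Nicotiana_A", "Solanum_A",
        ]
        derived = _derived_changes(
            ancestor, CANONICAL_POSITIONS + (81, 60), dictated={20: "T", 81: "C"}
        )
        homoplasy_rows = {"Solanum_A": {60: derived[60]}}
        newick = (
            "(((Brunfelsia_jam_A,Brunfelsia_B),(Brunfelsia_C,Brunfelsia_D)),"
            "(Petunia_A,(Nicotiana_A,Solanum_A)));"
        )
        return _bundle(
            "brunfelsia", ancestor, focal, lacking, newick,
            edit_positions=(20,), derived=derived,
            homoplasy_rows=homoplasy_rows,
            expected={"lower_bound_3prime": 81},
            notes="single-taxon focal clade; +60 homoplastic, +81 reversion decisive",
        )

    raise UnknownFixture(f"unknown fixture {name!r}; options: {FIXTURE_NAMES}")
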