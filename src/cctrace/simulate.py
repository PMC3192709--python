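"""Forward simulator of exon evolution with intron homing and loss.

Emulates the data structure of a plant-mitochondrial intron survey: a highly
conserved exon alignment evolving under Jukes-Cantor on a rooted phylogeny,
into which a group I intron (default 967 bp, carrying an 840-bp
endonuclease-like ORF) is introduced by *homing* events.  Homing copies the
donor lineage's flanking exon sequence over the recipient's in a contiguous
tract [-L5, +L3] around the insertion point (co-conversion) and makes the
recipient subtree intron-bearing.  *Retroprocessing* losses remove the intron
on a branch and leave the characteristic footprint of RNA-mediated loss:
C-to-T substitution at downstream C-to-U editing sites.

Events are applied at branch midpoints, in schedule order; a homing donor is
either an external sequence supplied in the event or another lineage of the
tree, whose sequence is taken at its own branch midpoint (the donor branch
must therefore be visited before the recipient in preorder).
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field
from math import exp
from pathlib import Path

import dendropy
import numpy as np

from .frames import AlignedLocus, CoordinateFrame, EditSiteList
from .io import Phylogeny, write_alignment, write_states
from .survey import longest_orf

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOPS = ("TAA", "TAG", "TGA")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class Event:
    """One scheduled event on a branch (identified by the node below it).

    ``branch`` is a tip label, an internal-node label, or a comma-separated
    tip set (resolved to the MRCA).  For homing, ``donor`` names another
    branch the same way, or ``donor_sequence`` supplies an external
    (out-of-tree) donor exon sequence.
    """

    kind: str  # 'homing' | 'vertical_origin' | 'retro_loss'
    branch: str
    donor: str | None = None
    donor_sequence: str | None = None
    tract_5prime: int = 0
    tract_3prime: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("homing", "vertical_origin", "retro_loss"):
            raise SimulationError(f"unknown event kind {self.kind!r}")
        if self.tract_5prime < 0 or self.tract_3prime < 0:
            raise SimulationError("tract lengths must be >= 0")
        if self.kind == "homing" and self.donor is None and self.donor_sequence is None:
            raise SimulationError("homing event needs a donor or donor_sequence")


@dataclass
class SimulationConfig:
    """Study conditions for one simulated survey.

    Defaults mirror the system the package models: a 967-bp intron with an
    840-bp ORF at one canonical insertion site, near-invariant exons
    (synonymous rates in plant mitochondria are among the lowest known, so
    the default per-unit-length substitution rate is small), and a C-to-U
    editing site 20 bp downstream of the insertion point.
    """

    seed: int
    tree_newick: str | None = None
    n_tips: int | None = None
    exon_length: int = 200
    insertion_point: int = 100  # exon bases 5' of the insertion point
    root_sequence: str | None = None
    subst_rate: float = 0.002  # expected substitutions/site/unit branch length
    intron_length: int = 967
    orf_length: int = 840
    events: list[Event] = field(default_factory=list)
    edit_sites: tuple[int, ...] = (20,)
    retro_window: int = 600

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SimulationError("seed is mandatory")
        if (self.tree_newick is None) == (self.n_tips is None):
            raise SimulationError("supply exactly one of tree_newick or n_tips")


@dataclass
class EventRecord:
    kind: str
    branch: str
    tract_5prime: int
    tract_3prime: int
    converted_positions: tuple[int, ...]
    loss_positions: tuple[int, ...]


@dataclass
class SyntheticDataset:
    locus: AlignedLocus
    introns: dict[str, str]
    phylogeny: Phylogeny
    truth: list[EventRecord]
    edit_sites: EditSiteList

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_alignment(self.locus, outdir / "exons.fasta")
        with open(outdir / "introns.fasta", "w") as fh:
            for taxon, seq in sorted(self.introns.items()):
                fh.write(f">{taxon}\n{seq}\n")
        with open(outdir / "tree.nwk", "w") as fh:
            fh.write(self.phylogeny.as_newick() + "\n")
        write_states(self.locus.intron_present, outdir / "states.tsv")
        with open(outdir / "truth.tsv", "w") as fh:
            fh.write(
                "kind\tbranch\ttract_5prime\ttract_3prime\t"
                "converted_positions\tloss_positions\n"
            )
            for rec in self.truth:
                conv = ",".join(map(str, rec.converted_positions))
                loss = ",".join(map(str, rec.loss_positions))
                fh.write(
                    f"{rec.kind}\t{rec.branch}\t{rec.tract_5prime}\t"
                    f"{rec.tract_3prime}\t{conv}\t{loss}\n"
                )


def embed_orf(intron_length: int, orf_length: int, seed: int) -> str:
    """Random intron-like sequence whose longest forward ORF is exactly
    ``orf_length`` bp (ATG..stop, stop included); ``orf_length`` 0 means no
    enforced ORF (plain random sequence).

    Validated against an exhaustive forward-frame scan; the in-frame stop
    placed immediately 5' of the ORF prevents upstream extension.
    """
    rng = np.random.default_rng(seed)
    if orf_length == 0:
        return "".join(rng.choice(["A", "C", "G", "T"], size=intron_length))
    if orf_length % 3 != 0:
        raise SimulationError("orf_length must be divisible by 3")
    if orf_length > intron_length - 6:
        raise SimulationError("orf_length must be <= intron_length - 6")
    sense = [
        a + b + c
        for a in "ACGT" for b in "ACGT" for c in "ACGT"
        if a + b + c not in _STOPS and a + b + c != "ATG"
    ]
    flank_total = intron_length - orf_length
    left = flank_total // 2
    if left < 3:
        left = 3 if flank_total >= 3 else flank_total
    right = flank_total - left
    for _ in range(50):
        orf = "ATG" + "".join(rng.choice(sense, size=orf_length // 3 - 2)) + str(
            rng.choice(_STOPS)
        )
        l5 = "".join(rng.choice(["A", "C", "G", "T"], size=left))
        if left >= 3:
            l5 = l5[:-3] + "TAA"  # in-frame stop blocks upstream extension
        l3 = "".join(rng.choice(["A", "C", "G", "T"], size=right))
        seq = l5 + orf + l3
        start, length = longest_orf(seq)
        if length == orf_length and start == left:
            return seq
    raise SimulationError("failed to embed ORF after 50 attempts")  # pragma: no cover


def _signed_to_index(signed_pos: int, insertion_point: int) -> int:
    """Signed exon position -> 0-based index in an ungapped exon sequence."""
    if signed_pos == 0:
        raise SimulationError("signed position 0 does not exist")
    return insertion_point + signed_pos - 1 if signed_pos > 0 else insertion_point + signed_pos


def _jc_evolve(seq: np.ndarray, distance: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve a base array under Jukes-Cantor for the given expected
    substitutions/site."""
    if distance <= 0:
        return seq.copy()
    p_change = 0.75 * (1.0 - exp(-4.0 * distance / 3.0))
    out = seq.copy()
    hit = np.nonzero(rng.random(seq.size) < p_change)[0]
    for i in hit:
        choices = [b for b in b"ACGT" if b != out[i]]
        out[i] = rng.choice(choices)
    return out


def _yule_tree(n_tips: int, seed: int) -> dendropy.Tree:
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=_random.Random(seed),
    )
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"t{i}"
    return tree


def _resolve_branch(phylo: Phylogeny, label: str) -> dendropy.Node:
    return phylo.find_node(label)


def simulate(config: SimulationConfig) -> SyntheticDataset:
    """Run the forward simulation; byte-identical outputs for equal configs."""
    rng = np.random.default_rng(config.seed)
    if config.tree_newick is not None:
        tree = dendropy.Tree.get(
            data=config.tree_newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
        tree.is_rooted = True
    else:
        tree = _yule_tree(config.n_tips, config.seed)
    phylo = Phylogeny(tree)

    if config.root_sequence is not None:
        root_seq = np.frombuffer(
            config.root_sequence.upper().encode(), dtype="S1"
        ).copy()
        if root_seq.size != config.exon_length:
            raise SimulationError("root_sequence length != exon_length")
    else:
        root_seq = rng.choice(_BASES, size=config.exon_length)
    if not 0 < config.insertion_point < config.exon_length:
        raise SimulationError("insertion_point must lie inside the exon")
    # editing sites are genomically C in unedited (ancestral) lineages
    for pos in config.edit_sites:
        idx = _signed_to_index(pos, config.insertion_point)
        if not 0 <= idx < config.exon_length:
            raise SimulationError(f"edit site {pos} outside exon")
        root_seq[idx] = b"C"

    events_by_node: dict[int, list[Event]] = {}
    for ev in config.events:
        node = _resolve_branch(phylo, ev.branch)
        events_by_node.setdefault(id(node), []).append(ev)
    # schedule order within a branch follows the config order (already grouped)

    base_intron = embed_orf(
        config.intron_length, config.orf_length, int(rng.integers(2**31))
    )

    midpoint_seq: dict[int, np.ndarray] = {}
    node_state: dict[int, tuple[np.ndarray, bool, str | None]] = {}
    truth: list[EventRecord] = []

    def donor_midpoint(ev: Event) -> tuple[np.ndarray, str | None]:
        if ev.donor_sequence is not None:
            arr = np.frombuffer(ev.donor_sequence.upper().encode(), dtype="S1").copy()
            if arr.size != config.exon_length:
                raise SimulationError("donor_sequence length != exon_length")
            return arr, None
        donor_node = _resolve_branch(phylo, ev.donor)
        if id(donor_node) not in midpoint_seq:
            raise SimulationError(
                f"donor branch {ev.donor!r} not yet reached; order the schedule "
                "so donors precede recipients (preorder), or supply donor_sequence"
            )
        seq = midpoint_seq[id(donor_node)]
        _, donor_has_intron, donor_intron = node_state.get(
            id(donor_node), (None, False, None)
        )
        return seq, donor_intron if donor_has_intron else None

    def apply_events(node: dendropy.Node, seq: np.ndarray, has_intron: bool,
                     intron: str | None) -> tuple[np.ndarray, bool, str | None]:
        for ev in events_by_node.get(id(node), []):
            if ev.kind in ("homing", "vertical_origin"):
                if has_intron:
                    raise SimulationError(
                        f"{ev.kind} onto already intron-bearing branch {ev.branch!r}"
                    )
                converted: list[int] = []
                donor_intron: str | None = None
                if ev.donor is not None or ev.donor_sequence is not None:
                    donor_seq, donor_intron = donor_midpoint(ev)
                    for sp in range(-ev.tract_5prime, ev.tract_3prime + 1):
                        if sp == 0:
                            continue
                        idx = _signed_to_index(sp, config.insertion_point)
                        if 0 <= idx < seq.size and seq[idx] != donor_seq[idx]:
                            seq[idx] = donor_seq[idx]
                            converted.append(sp)
                intron = donor_intron if donor_intron is not None else base_intron
                has_intron = True
                truth.append(EventRecord(
                    kind=ev.kind, branch=ev.branch,
                    tract_5prime=ev.tract_5prime, tract_3prime=ev.tract_3prime,
                    converted_positions=tuple(sorted(converted)),
                    loss_positions=(),
                ))
            else:  # retro_loss
                if not has_intron:
                    raise SimulationError(
                        f"retro_loss on intron-lacking branch {ev.branch!r}"
                    )
                losses: list[int] = []
                for pos in sorted(config.edit_sites):
                    if 0 < pos <= config.retro_window:
                        idx = _signed_to_index(pos, config.insertion_point)
                        if 0 <= idx < seq.size and seq[idx] == b"C":
                            seq[idx] = b"T"
                            losses.append(pos)
                has_intron, intron = False, None
                truth.append(EventRecord(
                    kind="retro_loss", branch=ev.branch,
                    tract_5prime=0, tract_3prime=0,
                    converted_positions=(), loss_positions=tuple(losses),
                ))
        return seq, has_intron, intron

    root = tree.seed_node
    for node in tree.preorder_node_iter():
        if node is root:
            seq, has_intron, intron = root_seq.copy(), False, None
            seq, has_intron, intron = apply_events(node, seq, has_intron, intron)
        else:
            pseq, phas, pintron = node_state[id(node.parent_node)]
            blen = node.edge.length if node.edge.length is not None else 1.0
            half = config.subst_rate * blen / 2.0
            seq = _jc_evolve(pseq, half, rng)
            midpoint_seq[id(node)] = seq.copy()
            seq, has_intron, intron = apply_events(node, seq, phas, pintron)
            seq = _jc_evolve(seq, half, rng)
        node_state[id(node)] = (seq, has_intron, intron)

    unapplied = set(events_by_node) - {id(n) for n in tree.preorder_node_iter()}
    if unapplied:  # pragma: no cover - resolution already validates
        raise SimulationError("some events could not be placed")

    taxa, rows, states, introns = [], [], {}, {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        seq, has_intron, intron = node_state[id(leaf)]
        taxa.append(label)
        rows.append(seq.tobytes().decode())
        states[label] = has_intron
        if has_intron:
            if intron is None:  # pragma: no cover - defensive
                raise SimulationError(f"intron-bearing taxon {label} has no sequence")
            introns[label] = intron

    frame = CoordinateFrame(insertion_column=config.insertion_point - 1)
    locus = AlignedLocus(taxa=taxa, rows=rows, frame=frame, intron_present=states)
    return SyntheticDataset(
        locus=locus,
        introns=introns,
        phylogeny=phylo,
        truth=truth,
        edit_sites=EditSiteList.from_iterable(config.edit_sites),
    )
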