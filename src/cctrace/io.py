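"""Readers and writers for the formats the pipeline consumes.

FASTA alignments (Biopython), rooted newick trees with polychotomies
preserved (dendropy), and two small TSV tables: per-taxon intron
presence/absence and predicted C-to-U edit sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import pandas as pd
from Bio import SeqIO

from .frames import AlignedLocus, CoordinateFrame, EditSiteList, LocusError

_PRESENT_SYMBOLS = {"1", "+", "true", "present", "yes"}
_ABSENT_SYMBOLS = {"0", "-", "−", "false", "absent", "no"}
_UNKNOWN_SYMBOLS = {"?", "na", "nan", "unknown", ""}


class ReconciliationError(ValueError):
    """States/tree/alignment refer to inconsistent taxon sets."""


@dataclass
class Phylogeny:
    """A rooted tree; internal nodes may be polychotomies.

    Thin wrapper over a :class:`dendropy.Tree` so the rest of the package
    does not depend on dendropy details.
    """

    tree: dendropy.Tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def __post_init__(self) -> None:
        labels = self.tip_labels
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ReconciliationError(f"duplicate tip labels: {dupes}")

    def find_node(self, label: str) -> dendropy.Node:
        """Find a node by tip label, internal node label, or the MRCA of a
        comma-separated tip set."""
        for node in self.tree.preorder_node_iter():
            if node.taxon is not None and node.taxon.label == label:
                return node
            if node.label == label:
                return node
        if "," in label:
            tips = [t.strip() for t in label.split(",")]
            return self.mrca(tips)
        raise ReconciliationError(f"no node labelled {label!r}")

    def mrca(self, tip_labels: list[str]) -> dendropy.Node:
        taxa = [self.tree.taxon_namespace.get_taxon(t) for t in tip_labels]
        missing = [l for l, t in zip(tip_labels, taxa) if t is None]
        if missing:
            raise ReconciliationError(f"taxa absent from tree: {missing}")
        node = self.tree.mrca(taxa=taxa)
        if node is None:
            raise ReconciliationError(f"no MRCA for {tip_labels}")
        return node

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def read_alignment(path: str | Path, insertion_column: int) -> AlignedLocus:
    """Read a FASTA alignment and attach the insertion-point frame.

    All records must have equal aligned length; labels must be unique;
    lowercase is normalized to uppercase and U to T.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise LocusError(f"no FASTA records in {path}")
    taxa = [r.id for r in records]
    rows = [str(r.seq) for r in records]
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise LocusError(
            f"ragged alignment in {path}: record lengths {sorted(lengths)}"
        )
    aln_len = lengths.pop()
    if not 0 <= insertion_column < aln_len:
        raise LocusError(
            f"insertion_column {insertion_column} outside alignment of length {aln_len}"
        )
    frame = CoordinateFrame(insertion_column=insertion_column)
    return AlignedLocus(taxa=taxa, rows=rows, frame=frame)


def write_alignment(locus: AlignedLocus, path: str | Path) -> None:
    with open(path, "w") as fh:
        for taxon, row in zip(locus.taxa, locus.rows):
            fh.write(f">{taxon}\n{row}\n")


def read_tree(path: str | Path) -> Phylogeny:
    """Read a rooted newick tree, preserving polychotomies."""
    tree = dendropy.Tree.get(
        path=str(path),
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    tree.is_rooted = True
    return Phylogeny(tree)


def read_tree_string(newick: str) -> Phylogeny:
    tree = dendropy.Tree.get(
        data=newick,
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    tree.is_rooted = True
    return Phylogeny(tree)


def _parse_state(value: object) -> bool | None:
    s = str(value).strip().lower()
    if s in _PRESENT_SYMBOLS:
        return True
    if s in _ABSENT_SYMBOLS:
        return False
    if s in _UNKNOWN_SYMBOLS:
        return None
    raise LocusError(f"unrecognized presence symbol {value!r}")


def read_states(path: str | Path, phylogeny: Phylogeny | None = None) -> dict[str, bool | None]:
    """Read a two-column TSV of per-taxon intron presence calls.

    Columns ``taxon`` and ``present``; symbols 1/0, +/-, or unknown (?).
    If a tree is given, every taxon must be a tip of it.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = {c.lower(): c for c in df.columns}
    if "taxon" not in cols or "present" not in cols:
        raise LocusError(f"states file {path} must have columns 'taxon' and 'present'")
    states = {
        str(row[cols["taxon"]]).strip(): _parse_state(row[cols["present"]])
        for _, row in df.iterrows()
    }
    if phylogeny is not None:
        missing = sorted(set(states) - set(phylogeny.tip_labels))
        if missing:
            raise ReconciliationError(f"taxa in states but not in tree: {missing}")
    return states


def write_states(states: dict[str, bool | None], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon\tpresent\n")
        for taxon, state in states.items():
            symbol = "?" if state is None else ("1" if state else "0")
            fh.write(f"{taxon}\t{symbol}\n")


def read_edit_sites(path: str | Path) -> EditSiteList:
    """Read predicted C-to-U edit sites (columns: position, edited_base)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = {c.lower(): c for c in df.columns}
    if "position" not in cols:
        raise LocusError(f"edit-site file {path} must have a 'position' column")
    positions = [int(v) for v in df[cols["position"]]]
    return EditSiteList.from_iterable(positions)


def write_edit_sites(sites: EditSiteList, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tedited_base\n")
        for p in sites.positions:
            fh.write(f"{p}\tC\n")
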