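"""Co-conversion-tract (CCT) inference.

A homing intron's arrival leaves a footprint in the flanking exon: a
contiguous tract of donor-derived sequence.  Against the near-invariant
background of plant mitochondrial exons this footprint shows up as a cluster
of *diagnostic sites* — positions at which every member of a focal
intron-containing clade shares a derived state that intron-lacking taxa do
not carry.  This module reconstructs the ancestral exon sequence, calls
diagnostic sites, filters homoplastic ones, converts the survivors into
minimum-length / endpoint-interval bounds on the tract, and tests the
alternative explanation for intron absence: RNA-mediated loss
(retroprocessing), which would instead leave C-to-T changes at downstream
C-to-U editing sites.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import pandas as pd

from .frames import AlignedLocus, CoordinateFrame, EditSiteList, FrameError
from .io import Phylogeny

_BASES = "ACGT"


class CladeError(ValueError):
    """Focal clade inconsistent with intron presence calls."""


@dataclass(frozen=True)
class DiagnosticSite:
    """A position where the focal clade uniformly carries a derived state."""

    position: int
    ancestral_state: str
    derived_state: str
    site_class: str  # 'edit_site' | 'synonymous' | 'other'
    homoplasy_flag: bool

    def __post_init__(self) -> None:
        if self.ancestral_state == self.derived_state:
            raise ValueError("ancestral and derived states must differ")


@dataclass
class CCTReport:
    """Per-clade co-conversion bounds and the sites supporting them.

    ``lower_bound_3prime`` is the farthest non-homoplastic diagnostic
    position downstream of the insertion site — the *minimum* tract length.
    ``upper_bound_3prime`` is the first downstream position at which the
    clade demonstrably retains the native state while a candidate donor
    group differs (``None`` = unbounded).  The open interval between them
    brackets the conversion endpoint.
    """

    focal_clade: tuple[str, ...]
    sites: list[DiagnosticSite]
    lower_bound_3prime: int
    upper_bound_3prime: int | None
    lower_bound_5prime: int
    upper_bound_5prime: int | None

    @property
    def endpoint_interval(self) -> tuple[int, int | None]:
        return (self.lower_bound_3prime, self.upper_bound_3prime)

    def nonhomoplastic_sites(self) -> list[DiagnosticSite]:
        return [s for s in self.sites if not s.homoplasy_flag]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "position": s.position,
                    "ancestral_state": s.ancestral_state,
                    "derived_state": s.derived_state,
                    "site_class": s.site_class,
                    "homoplasy": s.homoplasy_flag,
                }
                for s in self.sites
            ]
        )


@dataclass
class RetroSignatureReport:
    """Per-taxon retroprocessing-footprint evaluation."""

    taxon: str
    site_states: dict[int, str]
    verdict: str  # 'retro_signature' | 'no_signature' | 'indeterminate'
    note: str = ""


@dataclass
class LossCheck:
    """Result of testing a taxon for intron loss with CCT retention."""

    taxon: str
    is_loss_with_cct: bool
    mismatches: list[tuple[int, str, str]] = field(default_factory=list)  # (pos, expected, observed)

    def __bool__(self) -> bool:
        return self.is_loss_with_cct


def _column_states(locus: AlignedLocus, column: int, taxa: Sequence[str]) -> list[str]:
    return [locus.row(t)[column] for t in taxa]


def reconstruct_ancestor(locus: AlignedLocus, tree: Phylogeny | None = None) -> str:
    """Reconstruct the ancestral exon sequence, column by column.

    With a tree: Fitch parsimony root state sets (generalized to
    polychotomies by majority over child sets), ties resolved by the
    majority state among intron-lacking taxa and then alphabetically.
    Without a tree: strict-majority consensus of the intron-lacking taxa
    (ties alphabetical).  Columns gapped in a majority of intron-lacking
    taxa are reconstructed as gaps; columns with no base information at all
    become N.
    """
    lacking = locus.intron_lacking_taxa() or list(locus.taxa)
    out = []
    for col in range(locus.length):
        states_all = _column_states(locus, col, locus.taxa)
        lack_states = _column_states(locus, col, lacking)
        if all(s in "-N" for s in states_all):
            out.append("N")
            continue
        gaps = sum(1 for s in lack_states if s == "-")
        if gaps * 2 > len(lack_states):
            out.append("-")
            continue
        if tree is not None:
            out.append(_fitch_root_state(locus, tree, col, lacking))
        else:
            counts = Counter(s for s in lack_states if s in _BASES)
            if not counts:
                counts = Counter(s for s in states_all if s in _BASES)
            best = max(counts.values())
            out.append(sorted(b for b, c in counts.items() if c == best)[0])
    return "".join(out)


def parsimony_root_states(
    locus: AlignedLocus, tree: Phylogeny, column: int
) -> frozenset[str]:
    """Set of most-parsimonious root states for one column (Fitch, in the
    Hartigan generalization that is exact on polychotomies: each node keeps
    the states occurring in a maximum number of children's sets)."""
    full = frozenset(_BASES)

    def state_set(node: dendropy.Node) -> frozenset[str]:
        if node.is_leaf():
            base = locus.row(node.taxon.label)[column]
            return frozenset(base) if base in _BASES else full
        child_sets = [state_set(c) for c in node.child_nodes()]
        counts = Counter()
        for s in child_sets:
            for b in s:
                counts[b] += 1
        best = max(counts.values())
        return frozenset(b for b, c in counts.items() if c == best)

    return state_set(tree.tree.seed_node)


def _fitch_root_state(
    locus: AlignedLocus, tree: Phylogeny, column: int, lacking: Sequence[str]
) -> str:
    root_set = parsimony_root_states(locus, tree, column)
    if len(root_set) == 1:
        return next(iter(root_set))
    # tie: majority among intron-lacking taxa restricted to the root set
    counts = Counter(
        s for s in _column_states(locus, column, lacking) if s in root_set
    )
    if counts:
        best = max(counts.values())
        return sorted(b for b, c in counts.items() if c == best)[0]
    return sorted(root_set)[0]


def ancestor_frame(locus: AlignedLocus, ancestor: str) -> CoordinateFrame:
    """Coordinate frame counting exon positions on the reconstructed
    ancestor (the designated ungapped reference row)."""
    return CoordinateFrame(
        insertion_column=locus.frame.insertion_column, reference_row=ancestor
    )


def _codon_position(signed_pos: int, frame_offset: int) -> int:
    # frame_offset = codon position (0-based) of exon position +1
    if signed_pos > 0:
        return (frame_offset + signed_pos - 1) % 3
    return (frame_offset + signed_pos) % 3


def call_diagnostic_sites(
    locus: AlignedLocus,
    ancestor: str,
    focal_clade: Sequence[str],
    edit_sites: EditSiteList | None = None,
    window: int = 200,
    exclude: Sequence[str] = (),
    homoplasy_threshold: int = 1,
    frame_offset: int | None = None,
) -> list[DiagnosticSite]:
    """Call sites at which the whole focal clade carries one derived state.

    A site is diagnostic iff every focal-clade member carries the same
    concrete base, that base differs from the ancestral state, and both
    states are unambiguous.  The homoplasy flag marks sites whose derived
    state also occurs in at least ``homoplasy_threshold`` intron-lacking
    taxa (``exclude`` removes taxa — e.g. a suspected secondary-loss taxon —
    from that scan).  Site classes: ``edit_site`` for positions in the edit
    list; ``synonymous`` for third codon positions when ``frame_offset``
    (codon position of exon base +1) is supplied; ``other`` otherwise.
    """
    focal_clade = list(focal_clade)
    if not focal_clade:
        raise CladeError("empty focal clade")
    for t in focal_clade:
        if locus.intron_present.get(t) is not True:
            raise CladeError(f"focal-clade taxon {t!r} is not intron-present")
    frame = ancestor_frame(locus, ancestor)
    edit_positions = set(edit_sites.positions) if edit_sites is not None else set()
    scan_lacking = [t for t in locus.intron_lacking_taxa() if t not in set(exclude)]

    sites: list[DiagnosticSite] = []
    for pos in [p for p in range(-window, window + 1) if p != 0]:
        try:
            col = frame.signed_to_column(pos)
        except FrameError:
            continue
        anc = ancestor[col]
        if anc not in _BASES:
            continue
        focal_states = set(_column_states(locus, col, focal_clade))
        if len(focal_states) != 1:
            continue
        derived = focal_states.pop()
        if derived not in _BASES or derived == anc:
            continue
        occurrences = sum(
            1 for s in _column_states(locus, col, scan_lacking) if s == derived
        )
        homoplastic = occurrences >= homoplasy_threshold
        if pos in edit_positions:
            site_class = "edit_site"
        elif frame_offset is not None:
            site_class = (
                "synonymous" if _codon_position(pos, frame_offset) == 2 else "other"
            )
        else:
            site_class = "other"
        sites.append(
            DiagnosticSite(
                position=pos,
                ancestral_state=anc,
                derived_state=derived,
                site_class=site_class,
                homoplasy_flag=homoplastic,
            )
        )
    return sorted(sites, key=lambda s: s.position)


def _first_retained_position(
    locus: AlignedLocus,
    ancestor: str,
    focal_clade: Sequence[str],
    donor_clade: Sequence[str],
    start: int,
    window: int,
    direction: int,
) -> int | None:
    """First position past ``start`` (in ``direction``) where the focal
    clade retains the ancestral state while the whole donor group differs."""
    frame = ancestor_frame(locus, ancestor)
    pos = start + direction if start != 0 else direction
    while abs(pos) <= window:
        if pos == 0:
            pos += direction
            continue
        try:
            col = frame.signed_to_column(pos)
        except FrameError:
            return None
        anc = ancestor[col]
        if anc in _BASES:
            focal_states = set(_column_states(locus, col, focal_clade))
            donor_states = set(_column_states(locus, col, donor_clade))
            if (
                focal_states == {anc}
                and len(donor_states) == 1
                and donor_states != {anc}
                and next(iter(donor_states)) in _BASES
            ):
                return pos
        pos += direction
    return None


def cct_bounds(
    sites: Sequence[DiagnosticSite],
    locus: AlignedLocus,
    focal_clade: Sequence[str],
    ancestor: str,
    donor_clade: Sequence[str] | None = None,
    window: int = 200,
) -> CCTReport:
    """Convert diagnostic sites into co-conversion tract bounds.

    The minimum tract length on each side is the farthest non-homoplastic
    diagnostic position (0 if none) — the definition under which the
    published minimum lengths all equal their farthest supporting site.
    With a candidate donor group, the endpoint is additionally bounded above
    by the first position where the focal clade demonstrably retains the
    native state while the donor differs.
    """
    nonh = [s for s in sites if not s.homoplasy_flag]
    lower3 = max((s.position for s in nonh if s.position > 0), default=0)
    lower5 = max((-s.position for s in nonh if s.position < 0), default=0)
    upper3 = upper5 = None
    if donor_clade:
        upper3 = _first_retained_position(
            locus, ancestor, focal_clade, donor_clade, lower3, window, +1
        )
        neg = _first_retained_position(
            locus, ancestor, focal_clade, donor_clade, -lower5, window, -1
        )
        upper5 = -neg if neg is not None else None
    kept = [
        s
        for s in sites
        if (upper3 is None or s.position <= upper3)
        and (upper5 is None or s.position >= -upper5)
    ]
    return CCTReport(
        focal_clade=tuple(focal_clade),
        sites=kept,
        lower_bound_3prime=lower3,
        upper_bound_3prime=upper3,
        lower_bound_5prime=lower5,
        upper_bound_5prime=upper5,
    )


def retro_signature(
    locus: AlignedLocus,
    taxon: str,
    ancestor: str,
    edit_sites: EditSiteList,
    window: int = 600,
) -> RetroSignatureReport:
    """Test an intron-lacking taxon for the retroprocessing footprint.

    Verdict ``retro_signature`` iff at least one downstream edit site within
    the window has ancestral C and observed T; ``no_signature`` iff every
    such site is still C; ``indeterminate`` when the taxon's states (or its
    presence call) cannot support either verdict.
    """
    if locus.intron_present.get(taxon) is not False:
        return RetroSignatureReport(
            taxon=taxon,
            site_states={},
            verdict="indeterminate",
            note="taxon is not called intron-lacking",
        )
    frame = ancestor_frame(locus, ancestor)
    states: dict[int, str] = {}
    saw_t = saw_c = False
    for pos in edit_sites.downstream(window):
        try:
            col = frame.signed_to_column(pos)
        except FrameError:
            continue
        if ancestor[col] != "C":
            continue  # site not ancestrally editable; uninformative
        obs = locus.row(taxon)[col]
        states[pos] = obs
        if obs == "T":
            saw_t = True
        elif obs == "C":
            saw_c = True
    if saw_t:
        verdict = "retro_signature"
    elif saw_c:
        verdict = "no_signature"
    else:
        verdict = "indeterminate"
    return RetroSignatureReport(taxon=taxon, site_states=states, verdict=verdict)


def intron_loss_with_cct(
    locus: AlignedLocus, taxon: str, cct_report: CCTReport
) -> LossCheck:
    """Does an intron-lacking taxon carry the focal clade's full footprint?

    True iff the taxon lacks the intron yet matches the derived state at
    every non-homoplastic diagnostic site of the report — the signature of
    secondary intron loss with CCT retention.  The report should have been
    computed with this taxon excluded from the homoplasy scan.
    """
    if locus.intron_present.get(taxon) is not False:
        return LossCheck(taxon=taxon, is_loss_with_cct=False)
    frame = ancestor_frame_from_report(locus, cct_report)
    mismatches: list[tuple[int, str, str]] = []
    for site in cct_report.nonhomoplastic_sites():
        col = frame.signed_to_column(site.position)
        obs = locus.row(taxon)[col]
        if obs != site.derived_state:
            mismatches.append((site.position, site.derived_state, obs))
    has_sites = bool(cct_report.nonhomoplastic_sites())
    return LossCheck(
        taxon=taxon,
        is_loss_with_cct=has_sites and not mismatches,
        mismatches=mismatches,
    )


def ancestor_frame_from_report(locus: AlignedLocus, report: CCTReport) -> CoordinateFrame:
    # Reports are produced in the locus's own frame; reuse it directly.
    return locus.frame
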