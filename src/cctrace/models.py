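"""Model/Results interface over the inference machinery.

`CoConversionModel` bundles an aligned locus, a phylogeny, a focal clade
and edit sites; `fit()` reconstructs the ancestor, calls diagnostic sites
and returns a `CCTResults` carrying the tract bounds, the retroprocessing
screen, the secondary-loss screen and a text `summary()`.  `GainLossModel`
does the same for the gain/loss parsimony comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import cct as _cct
from . import gainloss as _gl
from .frames import AlignedLocus, EditSiteList
from .io import Phylogeny, read_alignment, read_edit_sites, read_states, read_tree


class CoConversionModel:
    """Co-conversion footprint inference for one focal intron-bearing clade."""

    def __init__(
        self,
        locus: AlignedLocus,
        focal_clade: Sequence[str],
        tree: Phylogeny | None = None,
        edit_sites: EditSiteList | None = None,
        donor_clade: Sequence[str] | None = None,
        window: int = 200,
        exclude: Sequence[str] = (),
        homoplasy_threshold: int = 1,
        frame_offset: int | None = None,
    ) -> None:
        self.locus = locus
        self.focal_clade = tuple(focal_clade)
        self.tree = tree
        self.edit_sites = edit_sites or EditSiteList(())
        self.donor_clade = tuple(donor_clade) if donor_clade else ()
        self.window = window
        self.exclude = tuple(exclude)
        self.homoplasy_threshold = homoplasy_threshold
        self.frame_offset = frame_offset

    @classmethod
    def from_files(
        cls,
        alignment: str | Path,
        insertion_column: int,
        focal_clade: Sequence[str],
        tree: str | Path | None = None,
        states: str | Path | None = None,
        edits: str | Path | None = None,
        **kwargs,
    ) -> "CoConversionModel":
        locus = read_alignment(alignment, insertion_column)
        phylo = read_tree(tree) if tree else None
        if states:
            locus.intron_present.update(read_states(states, phylo))
        edit_list = read_edit_sites(edits) if edits else None
        return cls(locus, focal_clade, tree=phylo, edit_sites=edit_list, **kwargs)

    def fit(self) -> "CCTResults":
        ancestor = _cct.reconstruct_ancestor(self.locus, self.tree)
        frame = _cct.ancestor_frame(self.locus, ancestor)
        locus = self.locus.with_frame(frame)
        sites = _cct.call_diagnostic_sites(
            locus,
            ancestor,
            self.focal_clade,
            edit_sites=self.edit_sites,
            window=self.window,
            exclude=self.exclude,
            homoplasy_threshold=self.homoplasy_threshold,
            frame_offset=self.frame_offset,
        )
        report = _cct.cct_bounds(
            sites,
            locus,
            self.focal_clade,
            ancestor,
            donor_clade=self.donor_clade or None,
            window=self.window,
        )
        return CCTResults(model=self, ancestor=ancestor, locus=locus, report=report)


@dataclass
class CCTResults:
    """Fitted co-conversion footprint for one focal clade."""

    model: CoConversionModel
    ancestor: str
    locus: AlignedLocus
    report: _cct.CCTReport

    @property
    def sites(self) -> list[_cct.DiagnosticSite]:
        return self.report.sites

    @property
    def lower_bound_3prime(self) -> int:
        return self.report.lower_bound_3prime

    @property
    def upper_bound_3prime(self) -> int | None:
        return self.report.upper_bound_3prime

    @property
    def endpoint_interval(self) -> tuple[int, int | None]:
        return self.report.endpoint_interval

    def sites_frame(self) -> pd.DataFrame:
        return self.report.to_dataframe()

    def canonical_window_sites(self, window: int = 20) -> list[_cct.DiagnosticSite]:
        """Non-homoplastic diagnostic sites within the canonical (0, window] tract."""
        return [
            s for s in self.report.nonhomoplastic_sites() if 0 < s.position <= window
        ]

    def retro_screen(self, window: int = 600) -> pd.DataFrame:
        """Retroprocessing-footprint verdict for every intron-lacking taxon."""
        rows = []
        for taxon in self.locus.intron_lacking_taxa():
            rep = _cct.retro_signature(
                self.locus, taxon, self.ancestor, self.model.edit_sites, window=window
            )
            rows.append(
                {
                    "taxon": taxon,
                    "verdict": rep.verdict,
                    "site_states": ";".join(
                        f"{p}:{b}" for p, b in sorted(rep.site_states.items())
                    ),
                }
            )
        return pd.DataFrame(rows)

    def loss_screen(self) -> pd.DataFrame:
        """Leave-one-out test of every intron-lacking taxon for secondary
        intron loss with CCT retention."""
        rows = []
        for taxon in self.locus.intron_lacking_taxa():
            sites = _cct.call_diagnostic_sites(
                self.locus,
                self.ancestor,
                self.model.focal_clade,
                edit_sites=self.model.edit_sites,
                window=self.model.window,
                exclude=(*self.model.exclude, taxon),
                homoplasy_threshold=self.model.homoplasy_threshold,
                frame_offset=self.model.frame_offset,
            )
            report = _cct.cct_bounds(
                sites, self.locus, self.model.focal_clade, self.ancestor,
                donor_clade=self.model.donor_clade or None, window=self.model.window,
            )
            check = _cct.intron_loss_with_cct(self.locus, taxon, report)
            rows.append(
                {
                    "taxon": taxon,
                    "loss_with_cct": check.is_loss_with_cct,
                    "mismatches": ";".join(
                        f"{p}:{exp}>{obs}" for p, exp, obs in check.mismatches
                    ),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        r = self.report
        upper3 = "unbounded" if r.upper_bound_3prime is None else r.upper_bound_3prime
        lines = [
            "Co-conversion tract report",
            "==========================",
            f"focal clade ({len(r.focal_clade)} taxa): {', '.join(r.focal_clade)}",
            f"diagnostic sites: {len(r.sites)} "
            f"({len(r.nonhomoplastic_sites())} non-homoplastic)",
            f"3' minimum tract length: {r.lower_bound_3prime} bp",
            f"3' endpoint interval: ({r.lower_bound_3prime}, {upper3})",
            f"5' minimum tract length: {r.lower_bound_5prime} bp",
            "",
            "position  ancestral  derived  class       homoplastic",
        ]
        for s in r.sites:
            lines.append(
                f"{s.position:>+8d}  {s.ancestral_state:^9s}  {s.derived_state:^7s}"
                f"  {s.site_class:<10s}  {'yes' if s.homoplasy_flag else 'no'}"
            )
        return "\n".join(lines)


class GainLossModel:
    """Parsimony comparison of intron gain/loss scenarios on a tree."""

    def __init__(
        self,
        tree: Phylogeny,
        tip_states: dict[str, bool | None],
        candidate_gain_nodes: Sequence[str],
        resolution_cap: int = 10_000,
    ) -> None:
        self.tree = tree
        self.tip_states = dict(tip_states)
        self.candidate_gain_nodes = list(candidate_gain_nodes)
        self.resolution_cap = resolution_cap

    @classmethod
    def from_files(
        cls,
        tree: str | Path,
        states: str | Path,
        candidate_gain_nodes: Sequence[str],
        **kwargs,
    ) -> "GainLossModel":
        phylo = read_tree(tree)
        tip_states = read_states(states, phylo)
        return cls(phylo, tip_states, candidate_gain_nodes, **kwargs)

    def fit(self) -> "GainLossResults":
        scenarios = _gl.compare_scenarios(
            self.tree,
            self.tip_states,
            self.candidate_gain_nodes,
            resolution_cap=self.resolution_cap,
        )
        return GainLossResults(model=self, scenarios=scenarios)


@dataclass
class GainLossResults:
    model: GainLossModel
    scenarios: list[_gl.GainLossScenario] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return _gl.scenarios_to_dataframe(self.scenarios)

    def summary(self) -> str:
        lines = [
            "Gain/loss scenario comparison",
            "=============================",
            self.to_dataframe().to_string(index=False),
        ]
        return "\n".join(lines)
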