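"""End-to-end orchestration: simulate/ingest -> survey -> CCT -> gain/loss.

All reports are flat text (TSV + a plain summary) so runs are diffable;
a manifest records inputs, parameters and the seed.  The pipeline is pure
given (inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .frames import EditSiteList
from .gainloss import min_gains_no_loss
from .io import read_alignment, read_edit_sites, read_states, read_tree
from .models import CoConversionModel, GainLossModel
from .simulate import Event, SimulationConfig, simulate

log = logging.getLogger("cctrace")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Inputs and knobs for one pipeline run.

    Exactly one of (alignment/tree/states paths) or (simulation) must be
    supplied.  ``focal_clades`` maps a clade name to its taxon list.
    """

    outdir: Path
    seed: int = 0
    alignment: Path | None = None
    insertion_column: int | None = None
    tree: Path | None = None
    states: Path | None = None
    edits: Path | None = None
    simulation: SimulationConfig | None = None
    focal_clades: dict[str, list[str]] = field(default_factory=dict)
    donor_clade: list[str] = field(default_factory=list)
    window: int = 200
    homoplasy_threshold: int = 1
    gain_nodes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        has_paths = self.alignment is not None
        has_sim = self.simulation is not None
        if has_paths == has_sim:
            raise ConfigError(
                "supply exactly one of: input paths (alignment=...) or a "
                "simulation config (simulation=...)"
            )
        if has_paths and self.insertion_column is None:
            raise ConfigError("missing field: insertion_column")


def _infer_focal_clades(locus, phylo) -> dict[str, list[str]]:
    """One footprint clade per maximal intron-bearing subtree."""
    if not locus.intron_bearing_taxa():
        return {}
    _, placements = min_gains_no_loss(phylo, locus.intron_present)
    return {
        f"clade_{i}": sorted(tips)
        for i, tips in enumerate(sorted(placements, key=sorted), start=1)
    }


def parse_flat_config(path: str | Path) -> dict[str, str]:
    """Parse the documented flat ``key = value`` config dialect.

    Lines are ``key = value``; ``#`` starts a comment; repeated ``event``
    keys accumulate.  Event values are comma-separated
    ``kind,branch,donor,L5,L3`` fields (donor may be empty).
    """
    out: dict[str, object] = {}
    events: list[str] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"malformed config line: {raw!r}")
        key, value = (p.strip() for p in line.split("=", 1))
        if key == "event":
            events.append(value)
        else:
            out[key] = value
    out["events"] = events
    return out


def simulation_from_flat(cfg: dict, seed: int) -> SimulationConfig:
    events = []
    for spec in cfg.get("events", []):
        parts = [p.strip() for p in spec.split(",")]
        if len(parts) != 5:
            raise ConfigError(f"event needs kind,branch,donor,L5,L3: {spec!r}")
        kind, branch, donor, l5, l3 = parts
        events.append(
            Event(
                kind=kind,
                branch=branch,
                donor=donor or None,
                tract_5prime=int(l5),
                tract_3prime=int(l3),
            )
        )
    kwargs = dict(seed=seed, events=events)
    if "tree" in cfg:
        kwargs["tree_newick"] = cfg["tree"]
    if "n_tips" in cfg:
        kwargs["n_tips"] = int(cfg["n_tips"])
    for key, cast in [
        ("exon_length", int), ("insertion_point", int), ("subst_rate", float),
        ("intron_length", int), ("orf_length", int), ("retro_window", int),
    ]:
        if key in cfg:
            kwargs[key] = cast(cfg[key])
    if "edit_sites" in cfg:
        kwargs["edit_sites"] = tuple(
            int(p) for p in str(cfg["edit_sites"]).split(",")
        )
    return SimulationConfig(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write the report bundle; returns the outdir."""
    logging.basicConfig(
        stream=sys.stderr, level=logging.INFO, format="[cctrace:%(name)s] %(message)s"
    )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "inputs": {}}

    if config.simulation is not None:
        log.info("stage simulate: seed=%d", config.simulation.seed)
        dataset = simulate(config.simulation)
        dataset.write(outdir / "simulated")
        locus = dataset.locus
        phylo = dataset.phylogeny
        edit_sites = dataset.edit_sites
        manifest["inputs"]["simulation"] = {
            "seed": config.simulation.seed,
            "n_taxa": len(locus.taxa),
            "events": len(config.simulation.events),
        }
    else:
        for name in ("alignment", "tree", "states"):
            p = getattr(config, name)
            if p is None:
                raise ConfigError(f"missing field: {name}")
            manifest["inputs"][name] = {"path": str(p), "sha256": _sha256(Path(p))}
        log.info("stage ingest: %s", config.alignment)
        locus = read_alignment(config.alignment, config.insertion_column)
        phylo = read_tree(config.tree)
        states = read_states(config.states, phylo)
        if not states:
            raise ConfigError("states file is empty")
        locus.intron_present.update(states)
        edit_sites = (
            read_edit_sites(config.edits) if config.edits else EditSiteList(())
        )

    # survey stage: tabulate presence calls
    with open(outdir / "intron_calls.tsv", "w") as fh:
        fh.write("taxon\tintron_present\n")
        for taxon in locus.taxa:
            s = locus.intron_present.get(taxon)
            fh.write(f"{taxon}\t{'?' if s is None else int(s)}\n")

    focal_clades = config.focal_clades or _infer_focal_clades(locus, phylo)
    summaries = []
    cct_calls: dict[str, bool] = {t: False for t in locus.taxa}
    for clade_name, members in focal_clades.items():
        log.info("stage cct: clade %s (%d taxa)", clade_name, len(members))
        model = CoConversionModel(
            locus,
            members,
            tree=phylo,
            edit_sites=edit_sites,
            donor_clade=config.donor_clade or None,
            window=config.window,
            homoplasy_threshold=config.homoplasy_threshold,
        )
        res = model.fit()
        res.sites_frame().to_csv(outdir / f"cct_{clade_name}.tsv", sep="\t", index=False)
        res.retro_screen().to_csv(
            outdir / f"retro_{clade_name}.tsv", sep="\t", index=False
        )
        loss = res.loss_screen()
        loss.to_csv(outdir / f"loss_screen_{clade_name}.tsv", sep="\t", index=False)
        for t in members:
            cct_calls[t] = bool(res.report.nonhomoplastic_sites())
        if not loss.empty:
            for t in loss[loss["loss_with_cct"]]["taxon"]:
                cct_calls[t] = True
        summaries.append(f"[{clade_name}]\n{res.summary()}")

    # default single-gain candidate: MRCA of every intron-bearing taxon
    bearing = locus.intron_bearing_taxa()
    gain_nodes = config.gain_nodes or ([",".join(bearing)] if bearing else [])
    if gain_nodes:
        log.info("stage gainloss: %d candidate gain nodes", len(gain_nodes))
        gl = GainLossModel(phylo, locus.intron_present, gain_nodes).fit()
        gl.to_dataframe().to_csv(outdir / "gainloss.tsv", sep="\t", index=False)
        summaries.append(gl.summary())

    with open(outdir / "summary.txt", "w") as fh:
        fh.write("\n\n".join(summaries) + "\n")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("report bundle written to %s", outdir)
    return outdir
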