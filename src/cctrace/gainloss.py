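"""Constrained parsimony comparison of intron gain/loss scenarios.

Two extreme models account for a patchy intron distribution: a single gain
at an ancestral node followed by losses (Dollo parsimony — the intron,
once lost, is not regained within the model), or one independent gain per
intron-containing clade with no losses.  On trees with polychotomies the
loss count depends on how each polychotomy is resolved, so the engine
reports the [min, max] range over all binary resolutions — by exhaustive
enumeration up to a cap, beyond which per-polychotomy independent
optimization is used (exact, because a maximal lost subtree can never span
two different polychotomies' child groups, making contributions additive).

Unknown tip states are assigned whichever state minimizes the event count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterator, Sequence

import dendropy
import pandas as pd
from scipy.stats import fisher_exact

from .io import Phylogeny

# internal lightweight tree: ("leaf", label) | ("node", [children])
_Struct = tuple


class ModelViolation(ValueError):
    """Tip states incompatible with the requested gain model."""


@dataclass
class GainLossScenario:
    model: str  # 'single_gain_at_node' | 'free_gains_no_loss'
    gain_count: int
    loss_count_min: int
    loss_count_max: int
    event_placements: list[frozenset[str]] = field(default_factory=list)
    resolutions_enumerated: int = 0
    gain_node: str | None = None
    feasible: bool = True
    note: str = ""


def _to_struct(node: dendropy.Node) -> _Struct:
    if node.is_leaf():
        return ("leaf", node.taxon.label)
    return ("node", [_to_struct(c) for c in node.child_nodes()])


def _struct_tips(struct: _Struct) -> frozenset[str]:
    if struct[0] == "leaf":
        return frozenset([struct[1]])
    return frozenset().union(*(_struct_tips(c) for c in struct[1]))


def _double_factorial(n: int) -> int:
    out = 1
    while n > 1:
        out *= n
        n -= 2
    return out


def count_resolutions(struct: _Struct) -> int:
    """Number of fully binary resolutions of all polychotomies in a tree."""
    if struct[0] == "leaf":
        return 1
    k = len(struct[1])
    own = _double_factorial(2 * k - 3) if k > 2 else 1
    total = own
    for c in struct[1]:
        total *= count_resolutions(c)
    return total


def _int_topologies(n: int) -> Iterator:
    """All rooted binary shapes over n atomic items (as nested index pairs).

    Built by inserting each new item on every edge of every smaller shape,
    so exactly (2n-3)!! shapes are produced; items are opaque — their own
    subtree structure is never entered.
    """

    def insert_all(x, t):
        yield (x, t)
        if isinstance(t, tuple):
            a, b = t
            for s in insert_all(x, a):
                yield (s, b)
            for s in insert_all(x, b):
                yield (a, s)

    def rec(k):
        if k == 1:
            yield 0
            return
        for t in rec(k - 1):
            yield from insert_all(k - 1, t)

    yield from rec(n)


def enumerate_resolutions(struct: _Struct) -> Iterator[_Struct]:
    """All fully binary resolutions of a (possibly multifurcating) tree."""
    if struct[0] == "leaf":
        yield struct
        return
    child_lists = [list(enumerate_resolutions(c)) for c in struct[1]]
    k = len(child_lists)
    for combo in product(*child_lists):
        if k <= 2:
            yield ("node", list(combo))
            continue
        for shape in _int_topologies(k):

            def build(t):
                if isinstance(t, int):
                    return combo[t]
                return ("node", [build(t[0]), build(t[1])])

            yield build(shape)


@dataclass
class _LossStats:
    coverable: bool  # every tip below is absent or unknown
    has_absent: bool
    min_count: int
    max_count: int
    placements: list[frozenset[str]]  # lost-subtree tip sets for the min solution
    tips: frozenset[str]


def _loss_stats(struct: _Struct, states: dict[str, bool | None]) -> _LossStats:
    if struct[0] == "leaf":
        s = states.get(struct[1])
        tips = frozenset([struct[1]])
        if s is True:
            return _LossStats(False, False, 0, 0, [], tips)
        if s is False:
            return _LossStats(True, True, 0, 0, [], tips)
        return _LossStats(True, False, 0, 0, [], tips)
    rs = [_loss_stats(c, states) for c in struct[1]]
    tips = frozenset().union(*(r.tips for r in rs))
    has_absent = any(r.has_absent for r in rs)
    if all(r.coverable for r in rs):
        return _LossStats(True, has_absent, 0, 0, [], tips)
    lossy = [r for r in rs if r.coverable and r.has_absent]
    minc = sum(r.min_count for r in rs if not r.coverable) + (1 if lossy else 0)
    maxc = sum(r.max_count for r in rs if not r.coverable) + len(lossy)
    placements: list[frozenset[str]] = []
    for r in rs:
        if not r.coverable:
            placements.extend(r.placements)
    if lossy:
        placements.append(frozenset().union(*(r.tips for r in lossy)))
    return _LossStats(False, has_absent, minc, maxc, placements, tips)


def min_losses_single_gain(
    tree: Phylogeny,
    tip_states: dict[str, bool | None],
    gain_node: str,
    resolution_cap: int = 10_000,
) -> tuple[int, int, list[frozenset[str]], int]:
    """Loss-count range under a single gain at ``gain_node`` (Dollo).

    Returns (min, max, placements-for-min, resolutions_enumerated); the
    range is over all binary resolutions of polychotomies inside the gain
    subtree, exhaustively when their number is within ``resolution_cap``
    and by exact per-polychotomy optimization otherwise.
    """
    node = tree.find_node(gain_node)
    gain_struct = _to_struct(node)
    inside = _struct_tips(gain_struct)
    present = {t for t, s in tip_states.items() if s is True}
    outside_present = sorted(present - inside)
    if outside_present:
        raise ModelViolation(
            f"present tips outside gain node's subtree: {outside_present}"
        )

    def evaluate(struct: _Struct) -> _LossStats:
        st = _loss_stats(struct, tip_states)
        if st.coverable and st.has_absent:
            # the whole gain subtree could be lost in one event
            return _LossStats(False, True, 1, 1, [st.tips], st.tips)
        return st

    n_res = count_resolutions(gain_struct)
    if n_res <= resolution_cap:
        best_min, best_max, best_pl = None, None, []
        enumerated = 0
        for resolved in enumerate_resolutions(gain_struct):
            enumerated += 1
            st = evaluate(resolved)
            if best_min is None or st.min_count < best_min:
                best_min, best_pl = st.min_count, st.placements
            if best_max is None or st.max_count > best_max:
                best_max = st.max_count
        return best_min or 0, best_max or 0, best_pl, enumerated
    st = evaluate(gain_struct)
    return st.min_count, st.max_count, st.placements, 0


@dataclass
class _GainStats:
    all_present_possible: bool
    has_present: bool
    count: int
    placements: list[frozenset[str]]
    present_tips: frozenset[str]


def _gain_stats(struct: _Struct, states: dict[str, bool | None]) -> _GainStats:
    if struct[0] == "leaf":
        s = states.get(struct[1])
        tips = frozenset([struct[1]])
        if s is True:
            return _GainStats(True, True, 0, [], tips)
        if s is False:
            return _GainStats(False, False, 0, [], frozenset())
        return _GainStats(True, False, 0, [], frozenset())
    rs = [_gain_stats(c, states) for c in struct[1]]
    present_tips = frozenset().union(*(r.present_tips for r in rs))
    has_present = any(r.has_present for r in rs)
    if all(r.all_present_possible for r in rs):
        return _GainStats(True, has_present, 0, [], present_tips)
    count = sum(r.count for r in rs if not r.all_present_possible)
    placements: list[frozenset[str]] = []
    for r in rs:
        if not r.all_present_possible:
            placements.extend(r.placements)
    merged = [r for r in rs if r.all_present_possible and r.has_present]
    if merged:
        count += 1
        placements.append(frozenset().union(*(r.present_tips for r in merged)))
    return _GainStats(False, has_present, count, placements, present_tips)


def min_gains_no_loss(
    tree: Phylogeny, tip_states: dict[str, bool | None]
) -> tuple[int, list[frozenset[str]]]:
    """Minimum number of independent gains with zero losses.

    Each maximal intron-present subtree requires one gain; at a polychotomy,
    present children are grouped whenever a binary resolution could unite
    them, so the count is the minimum over all resolutions.
    """
    struct = _to_struct(tree.tree.seed_node)
    st = _gain_stats(struct, tip_states)
    if st.all_present_possible and st.has_present:
        return 1, [st.present_tips]
    return st.count, st.placements


def compare_scenarios(
    tree: Phylogeny,
    tip_states: dict[str, bool | None],
    candidate_gain_nodes: Sequence[str],
    resolution_cap: int = 10_000,
) -> list[GainLossScenario]:
    """One scenario row per model/candidate; parsimony counts only."""
    if not candidate_gain_nodes:
        raise ValueError("need at least one candidate gain node")
    any_present = any(s is True for s in tip_states.values())
    scenarios: list[GainLossScenario] = []
    for gain_node in candidate_gain_nodes:
        if not any_present:
            scenarios.append(
                GainLossScenario(
                    model="single_gain_at_node",
                    gain_node=gain_node,
                    gain_count=1,
                    loss_count_min=0,
                    loss_count_max=0,
                    feasible=False,
                    note="no intron-present tips: single-gain model infeasible",
                )
            )
            continue
        lo, hi, placements, n_res = min_losses_single_gain(
            tree, tip_states, gain_node, resolution_cap=resolution_cap
        )
        scenarios.append(
            GainLossScenario(
                model="single_gain_at_node",
                gain_node=gain_node,
                gain_count=1,
                loss_count_min=lo,
                loss_count_max=hi,
                event_placements=placements,
                resolutions_enumerated=n_res,
            )
        )
    gains, g_placements = min_gains_no_loss(tree, tip_states)
    scenarios.append(
        GainLossScenario(
            model="free_gains_no_loss",
            gain_count=gains,
            loss_count_min=0,
            loss_count_max=0,
            event_placements=g_placements,
        )
    )
    return scenarios


def scenarios_to_dataframe(scenarios: Sequence[GainLossScenario]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "model": s.model,
                "gain_node": s.gain_node or "",
                "gains": s.gain_count,
                "losses_min": s.loss_count_min,
                "losses_max": s.loss_count_max,
                "resolutions_enumerated": s.resolutions_enumerated,
                "feasible": s.feasible,
                "note": s.note,
            }
            for s in scenarios
        ]
    )


@dataclass
class CooccurrenceResult:
    table: pd.DataFrame  # 2x2: intron x CCT
    p_value: float
    discordant: list[str]
    degenerate: bool


def cooccurrence(
    intron_calls: dict[str, bool], cct_calls: dict[str, bool]
) -> CooccurrenceResult:
    """2x2 intron-presence x CCT-presence table with an exact test.

    The two-sided p-value is Fisher's exact (hypergeometric).  Taxa with a
    CCT but no intron (putative secondary losses) or vice versa are listed
    as discordant.  A table in which either margin is constant is flagged
    degenerate (p = 1 by construction).
    """
    taxa = sorted(set(intron_calls) & set(cct_calls))
    if len(taxa) < 2:
        raise ValueError("need both calls for at least 2 taxa")
    a = sum(1 for t in taxa if intron_calls[t] and cct_calls[t])
    b = sum(1 for t in taxa if intron_calls[t] and not cct_calls[t])
    c = sum(1 for t in taxa if not intron_calls[t] and cct_calls[t])
    d = sum(1 for t in taxa if not intron_calls[t] and not cct_calls[t])
    table = pd.DataFrame(
        [[a, b], [c, d]],
        index=["intron_present", "intron_absent"],
        columns=["cct_present", "cct_absent"],
    )
    degenerate = (a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0)
    p = 1.0 if degenerate else float(fisher_exact([[a, b], [c, d]])[1])
    discordant = [
        t for t in taxa if intron_calls[t] != cct_calls[t]
    ]
    return CooccurrenceResult(
        table=table, p_value=p, discordant=discordant, degenerate=degenerate
    )
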