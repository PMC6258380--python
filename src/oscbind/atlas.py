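"""Accessible first-order operations among diads and triads.

A first-order operation is a single selective square pulse applied to one
population of a settled two- or three-item pattern whose robust outcome
(stable over an onset window of at least 6 ms) is again a diad or triad.
Because the connectivity is uniform all-to-all, the operation set is closed
under population relabeling: scans are run for one representative of each
(start pattern, stimulated-role) pair and the resulting edges are expanded
over all permutations of the populations.  Shortest paths in the resulting
directed graph give the minimal number of sequential stimuli (the operation
order) needed to transform one pattern into another.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .classify import PhasePattern
from .params import ModelParameters, StimulusProtocol, StimulusPulse, preset
from .protocols import (
    PULSE_CLASSES,
    ROBUST_WINDOW,
    T_SINGLE,
    OnsetScanResult,
    onset_scan,
)

__all__ = [
    "OperationEdge",
    "OperationGraph",
    "representative_scans",
    "enumerate_first_order",
    "build_graph",
    "operation_order",
    "diameter",
]

#: pulse classes used when building the operation atlas
ATLAS_CLASSES = ("ignite", "stagger", "bind", "wts", "wta")

N_ATLAS = 5


def _bg(pulses) -> StimulusProtocol:
    return StimulusProtocol(tuple(StimulusPulse(*x) for x in pulses))


def _backgrounds() -> dict[str, StimulusProtocol]:
    """Pinned loading protocols for the representative start patterns."""
    third = T_SINGLE / 3.0
    ig = (2.0, 20.0)
    ld = (3.0, 8.0)
    return {
        "(1)(2)": _bg([(0, *ig, 100.0), (1, *ig, 625.0)]),
        "(12)": _bg([(0, *ig, 100.0), (1, *ig, 100.0)]),
        "(1)(2)(3)": _bg([(0, *ld, 300.0), (1, *ld, 300.0 + third),
                          (2, *ld, 300.0 + 2 * third)]),
        "(123)": _bg([(0, *ig, 100.0), (1, *ig, 100.0), (2, *ig, 100.0)]),
        "(12)(3)": _bg([(0, *ig, 100.0), (1, *ig, 100.0),
                        (2, *ig, 1326.0)]),
    }


def representative_scans() -> list[tuple[str, int]]:
    """(start partition, stimulated population) pairs covering every orbit
    of the permutation action: one active member per synchrony role plus
    one inactive population."""
    return [
        ("(1)(2)", 0), ("(1)(2)", 2),
        ("(12)", 0), ("(12)", 2),
        ("(1)(2)(3)", 0), ("(1)(2)(3)", 3),
        ("(123)", 0), ("(123)", 3),
        ("(12)(3)", 0), ("(12)(3)", 2), ("(12)(3)", 3),
    ]


def _partition_key(groups: tuple[tuple[int, ...], ...]) -> str:
    return "".join("(" + "".join(str(j + 1) for j in g) + ")" for g in groups)


def _permute_groups(groups, perm):
    return tuple(sorted(tuple(sorted(perm[j] for j in g)) for g in groups))


def _parse_partition(key: str) -> tuple[tuple[int, ...], ...]:
    groups = []
    for part in key.strip(")").split(")"):
        part = part.strip("(")
        groups.append(tuple(sorted(int(c) - 1 for c in part)))
    return tuple(sorted(groups))


@dataclass(frozen=True)
class OperationEdge:
    start: str                     # canonical partition of the start pattern
    stimulated: int                # population receiving the pulse (0-based)
    pulse_class: str
    window: tuple[float, float]    # robust onset window (ms, scan-relative)
    result: str                    # canonical partition of the outcome


@dataclass
class OperationGraph:
    edges: list[OperationEdge]
    N: int = N_ATLAS

    def nodes(self) -> set[str]:
        """All diad/triad partitions over the N populations."""
        out = set()
        for k in (2, 3):
            for combo in itertools.combinations(range(self.N), k):
                for part in _set_partitions(combo):
                    out.add(_partition_key(tuple(sorted(part))))
        return out

    def digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes())
        for e in self.edges:
            if g.has_edge(e.start, e.result):
                g[e.start][e.result]["ops"].append(e)
            else:
                g.add_edge(e.start, e.result, ops=[e])
        return g


def _set_partitions(items):
    items = list(items)
    if len(items) == 2:
        a, b = items
        yield ((a,), (b,))
        yield ((a, b),)
    elif len(items) == 3:
        a, b, c = items
        yield ((a,), (b,), (c,))
        yield ((a, b, c),)
        yield ((a, b), (c,))
        yield ((a, c), (b,))
        yield ((b, c), (a,))
    else:
        raise ValueError("only diads and triads enumerated")


def enumerate_first_order(
    params: ModelParameters,
    start: str,
    stimulated: int,
    pulse_classes=ATLAS_CLASSES,
    grid_step: float = 1.0,
    robust: float = ROBUST_WINDOW,
) -> list[OperationEdge]:
    """Robust first-order operations from one representative start pattern.

    Runs an onset scan per pulse class and keeps windows of at least
    ``robust`` ms whose settled outcome is again a diad or triad.  Outcomes
    where the stimulated population ended inactive are discarded (the
    stimulus is excitatory, so the stimulated population remains active;
    violations would indicate a classification failure).
    """
    bg = _backgrounds()[start]
    edges = []
    for cname in pulse_classes:
        scan = onset_scan(params, bg, PULSE_CLASSES[cname], stimulated,
                          grid_step=grid_step)
        for a, b, pat in scan.robust_windows:
            k = len(pat.active_populations)
            if k not in (2, 3):
                continue
            if stimulated not in pat.active_populations:
                continue
            edges.append(OperationEdge(
                start=start, stimulated=stimulated, pulse_class=cname,
                window=(a, b), result=_partition_key(pat.groups)))
    return edges


def build_graph(
    params: ModelParameters | None = None,
    pulse_classes=ATLAS_CLASSES,
    grid_step: float = 1.0,
    robust: float = ROBUST_WINDOW,
    progress=None,
) -> OperationGraph:
    """Operation graph over all diads and triads of the default network.

    Scans the representative (start, stimulated) pairs and closes the edge
    set under joint relabeling of populations.
    """
    if params is None:
        params = preset("paper-default")
    if params.N != N_ATLAS:
        raise ValueError(f"the operation atlas is built for N = {N_ATLAS}")
    raw: list[OperationEdge] = []
    for start, stim in representative_scans():
        raw.extend(enumerate_first_order(params, start, stim, pulse_classes,
                                         grid_step, robust))
        if progress is not None:
            progress(start, stim)
    # close under permutations
    seen = set()
    edges = []
    for e in raw:
        sg = _parse_partition(e.start)
        rg = _parse_partition(e.result)
        for perm in itertools.permutations(range(N_ATLAS)):
            s2 = _partition_key(_permute_groups(sg, perm))
            r2 = _partition_key(_permute_groups(rg, perm))
            stim2 = perm[e.stimulated]
            key = (s2, stim2, e.pulse_class, r2, e.window)
            if key in seen:
                continue
            seen.add(key)
            edges.append(OperationEdge(start=s2, stimulated=stim2,
                                       pulse_class=e.pulse_class,
                                       window=e.window, result=r2))
    return OperationGraph(edges=edges)


#: the canonical diad/triad patterns over populations 1..3; every other
#: diad/triad is a relabeling of one of these
CORE_NODES = (
    "(1)(2)", "(1)(3)", "(2)(3)", "(12)", "(13)", "(23)",
    "(1)(2)(3)", "(123)", "(12)(3)", "(13)(2)", "(1)(23)",
)


def operation_order(graph: OperationGraph | nx.DiGraph, a: str, b: str) -> float:
    """Minimal number of sequential selective stimuli transforming pattern
    ``a`` into pattern ``b`` through diads and triads (inf if unreachable)."""
    g = graph.digraph() if isinstance(graph, OperationGraph) else graph
    if a == b:
        return 0
    try:
        return nx.shortest_path_length(g, a, b)
    except nx.NetworkXNoPath:
        return float("inf")


def diameter(graph: OperationGraph | nx.DiGraph, nodes=CORE_NODES) -> float:
    """Maximum operation order over ordered pairs of the given patterns.

    Paths may pass through any diad or triad of the network; ``nodes``
    defaults to the canonical patterns over populations 1..3, which cover
    every pattern class up to relabeling.  Pass ``None`` to take the
    maximum over all 70 diad/triad patterns of the 5-population network
    (which can exceed the canonical diameter because widely separated
    population subsets need extra loading steps).
    """
    g = graph.digraph() if isinstance(graph, OperationGraph) else graph
    if nodes is None:
        nodes = list(g.nodes)
    best = 0
    for a in nodes:
        lengths = nx.single_source_shortest_path_length(g, a)
        for b in nodes:
            if b == a:
                continue
            if b not in lengths:
                return float("inf")
            best = max(best, lengths[b])
    return best
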