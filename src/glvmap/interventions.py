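"""Host-control mechanisms: consortium arrivals and host feeding.

Consortium arrivals add multi-species edges to an assembly map, letting
communities jump gaps.  Host feeding is modelled as a multilayer network:
one assembly map with a growth supplement ``f`` added to every intrinsic
rate and one without, joined by zero-cost switches at subcommunities viable
in both layers.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import networkx as nx
import numpy as np

from .assembly import (
    AssemblyEdge,
    AssemblyMap,
    build_assembly_map,
    invasion_outcome,
    members_of,
)
from .dynamics import DEFAULT_SETTINGS, IntegrationSettings, assess_viability
from .params import CommunityParameters

__all__ = [
    "MultilayerMap",
    "FeasibilityProfile",
    "augment_with_consortia",
    "build_multilayer_feeding_map",
    "multilayer_can_assemble",
    "feeding_feasibility_profile",
]

CONSORTIUM_BUDGET = 200_000  # max (node, consortium) invasions per augmentation


@dataclass
class MultilayerMap:
    """Fed (r + f) and unfed (f = 0) assembly maps with interlayer nodes."""

    unfed: AssemblyMap
    fed: AssemblyMap
    interlayer: frozenset[int]
    f: float


@dataclass
class FeasibilityProfile:
    """Per community size: fraction of size-k subsets viable, per layer."""

    sizes: np.ndarray
    unfed_fraction: np.ndarray
    fed_fraction: np.ndarray


def augment_with_consortia(
    amap: AssemblyMap,
    params: CommunityParameters,
    m: int,
    settings: IntegrationSettings = DEFAULT_SETTINGS,
) -> AssemblyMap:
    """Add edges for simultaneous arrivals of 2..m species.

    Base nodes and edges are preserved; only new multi-species edges are
    appended, so assembly can never be lost by raising ``m``.
    """
    if m < 2:
        raise ValueError("consortium size m must be at least 2")
    S = amap.S
    n_invasions = 0
    for mask in amap.nodes:
        n_absent = S - bin(mask).count("1")
        n_invasions += sum(comb(n_absent, k) for k in range(2, min(m, n_absent) + 1))
    if n_invasions > CONSORTIUM_BUDGET:
        raise ValueError(
            f"consortium augmentation needs {n_invasions} invasions, over the "
            f"budget of {CONSORTIUM_BUDGET}"
        )
    from .assembly import _resolve_edge

    new_edges = list(amap.edges)
    nodes = dict(amap.nodes)
    seen = {(e.source, e.target, e.arrivals) for e in new_edges}
    for mask in sorted(amap.nodes):
        absent = [i for i in range(S) if not mask & (1 << i)]
        eq = amap.nodes[mask].abundances
        for size in range(2, min(m, len(absent)) + 1):
            for consortium in combinations(absent, size):
                resolved = _resolve_edge(
                    params, mask, consortium, eq, nodes, settings, strict=False
                )
                if resolved is None:
                    continue
                target, category = resolved
                key = (mask, target, frozenset(consortium))
                if key in seen:
                    continue
                seen.add(key)
                new_edges.append(
                    AssemblyEdge(source=mask, target=target, arrivals=frozenset(consortium), category=category)
                )
    return AssemblyMap(S=S, climax=amap.climax, nodes=nodes, edges=new_edges, consortium_size=m)


def build_multilayer_feeding_map(
    params: CommunityParameters,
    f: float,
    settings: IntegrationSettings = DEFAULT_SETTINGS,
    consortium_size: int = 1,
) -> MultilayerMap:
    """Build fed and unfed assembly maps and their interlayer overlap.

    The unfed climax must be viable (the community has to stand on its own
    once feeding stops); the fed layer is built over the same species pool
    without requiring its climax to be viable.
    """
    if not f > 0:
        raise ValueError("feeding constant f must be positive (f=0 is the unfed layer)")
    unfed_params = params.with_feeding(0.0)
    fed_params = params.with_feeding(f)
    unfed = build_assembly_map(unfed_params, consortium_size=consortium_size, settings=settings)
    fed = build_assembly_map(
        fed_params, consortium_size=consortium_size, settings=settings, require_viable_climax=False
    )
    interlayer = frozenset(unfed.nodes) & frozenset(fed.nodes)
    return MultilayerMap(unfed=unfed, fed=fed, interlayer=interlayer, f=f)


def multilayer_can_assemble(mm: MultilayerMap) -> tuple[bool, list[tuple[str, int]] | None]:
    """Path search from the uncolonised state to the unfed climax.

    Nodes are (layer, subcommunity) pairs; edges are the two layers' assembly
    edges plus zero-cost layer switches at interlayer subcommunities.  The
    witness path is a list of (layer, mask) steps; consecutive steps with the
    same mask mark a feed-on/feed-off switch.
    """
    g = nx.DiGraph()
    for layer_name, layer in (("unfed", mm.unfed), ("fed", mm.fed)):
        for mask in layer.nodes:
            g.add_node((layer_name, mask))
        for e in layer.edges:
            g.add_edge((layer_name, e.source), (layer_name, e.target))
    for mask in mm.interlayer:
        g.add_edge(("unfed", mask), ("fed", mask))
        g.add_edge(("fed", mask), ("unfed", mask))
    source = ("unfed", 0)
    target = ("unfed", mm.unfed.climax)
    if source not in g or target not in g:
        return False, None
    try:
        path = nx.shortest_path(g, source, target)
    except nx.NetworkXNoPath:
        return False, None
    return True, [(layer, mask) for layer, mask in path]


def feeding_feasibility_profile(
    params: CommunityParameters,
    f: float,
    settings: IntegrationSettings = DEFAULT_SETTINGS,
) -> FeasibilityProfile:
    """Fraction of size-k subsets viable with and without feeding, all k."""
    if not f > 0:
        raise ValueError("feeding constant f must be positive")
    S = params.S
    unfed_params = params.with_feeding(0.0)
    fed_params = params.with_feeding(f)
    counts = {name: np.zeros(S + 1) for name in ("unfed", "fed")}
    for mask in range(1 << S):
        k = bin(mask).count("1")
        subset = members_of(mask)
        if assess_viability(unfed_params, subset, settings=settings).viable:
            counts["unfed"][k] += 1
        if assess_viability(fed_params, subset, settings=settings).viable:
            counts["fed"][k] += 1
    denom = np.array([comb(S, k) for k in range(S + 1)], dtype=float)
    return FeasibilityProfile(
        sizes=np.arange(S + 1),
        unfed_fraction=counts["unfed"] / denom,
        fed_fraction=counts["fed"] / denom,
    )
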