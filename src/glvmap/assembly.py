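"""Assembly maps: viable subcommunities and resolved invasions.

Subcommunities are encoded as bitmasks over the climax species pool.  The
assembly map is the directed graph whose nodes are all viable subsets
(including the uncolonised empty set) and whose edges are the outcomes of
introducing each absent species (or small consortium) at low density into a
resident community at equilibrium.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Iterator, Sequence

import networkx as nx
import numpy as np

from .dynamics import (
    DEFAULT_SETTINGS,
    IntegrationSettings,
    assess_viability,
    capped_derivative,
    integrate_to_equilibrium,
)
from .params import CommunityParameters, EquilibriumResult

__all__ = [
    "mask_of",
    "members_of",
    "AssemblyEdge",
    "AssemblyMap",
    "MapMetrics",
    "invasion_outcome",
    "build_assembly_map",
    "map_metrics",
]

ENUMERATION_LIMIT = 16
# Invader arrival density as a fraction of K_T.  Large enough for arriving
# consortia of obligate mutualists to clear their Allee threshold (the point
# of joint arrivals), small relative to the cap; single-invader outcomes are
# guarded by the rarity-limit growth test below.
DEFAULT_INVADER_FRACTION = 1e-3


class MapConstructionError(RuntimeError):
    """A settled invasion outcome does not correspond to any viable node."""


def mask_of(members: Iterable[int]) -> int:
    m = 0
    for i in members:
        m |= 1 << int(i)
    return m


def members_of(mask: int) -> tuple[int, ...]:
    out = []
    i = 0
    while mask:
        if mask & 1:
            out.append(i)
        mask >>= 1
        i += 1
    return tuple(out)


@dataclass(frozen=True)
class AssemblyEdge:
    """One resolved arrival: source and target nodes plus transition category.

    ``category`` is "augment" (diversity increases), "replace" (same
    diversity, different membership) or "crash" (diversity decreases).
    """

    source: int
    target: int
    arrivals: frozenset[int]
    category: str


@dataclass
class AssemblyMap:
    """Directed graph over viable subcommunities of one climax community."""

    S: int
    climax: int
    nodes: dict[int, EquilibriumResult]
    edges: list[AssemblyEdge]
    consortium_size: int = 1

    @property
    def empty(self) -> int:
        return 0

    def node_masks(self) -> list[int]:
        return sorted(self.nodes)

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for mask in self.nodes:
            g.add_node(mask, members=members_of(mask))
        for e in self.edges:
            g.add_edge(e.source, e.target, arrivals=sorted(e.arrivals), category=e.category)
        return g

    def simple_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((e.source, e.target) for e in self.edges)
        return g


@dataclass
class MapMetrics:
    """Summary statistics of an assembly map.

    ``predictability`` is 1/n_paths (0 when the climax is unreachable);
    ``path_entropy`` (log n_paths) and ``secondary_colonizer_fraction`` are
    reported as alternative predictability readouts.
    """

    n_viable: int
    n_edges: int
    can_assemble: bool
    n_paths: int
    predictability: float
    secondary_colonizers: int
    secondary_colonizer_fraction: float
    path_entropy: float
    paths_truncated: bool = False


def _categorise(source: int, arrivals_mask: int, target: int) -> str:
    if target == source:
        return "fail"
    ns, nt = bin(source).count("1"), bin(target).count("1")
    if nt > ns:
        return "augment"
    if nt == ns:
        return "replace"
    return "crash"


def invasion_outcome(
    params: CommunityParameters,
    resident: int | Iterable[int],
    invaders: Iterable[int],
    settings: IntegrationSettings = DEFAULT_SETTINGS,
    invader_density: float | None = None,
    resident_equilibrium: np.ndarray | None = None,
    full_output: bool = False,
):
    """Resolve the arrival of ``invaders`` into a viable resident community.

    Residents start at their equilibrium abundances and each invader at a
    low density (default 1e-3 x K_T).  Capped dynamics are integrated to
    convergence; the returned mask is the set of species surviving above the
    extinction threshold, with the transition category, or ``"fail"`` when
    the residents simply repel the arrival.
    """
    res_mask = resident if isinstance(resident, int) else mask_of(resident)
    inv = frozenset(int(i) for i in invaders)
    if not inv:
        raise ValueError("invaders must be nonempty")
    inv_mask = mask_of(inv)
    if res_mask & inv_mask:
        raise ValueError("invaders must be disjoint from residents")
    if invader_density is None:
        invader_density = DEFAULT_INVADER_FRACTION * params.K_T

    ext = settings.resolve_extinction(params)
    x0 = np.zeros(params.S)
    if res_mask:
        if resident_equilibrium is None:
            res = assess_viability(params, members_of(res_mask), settings=settings)
            if not res.viable:
                raise ValueError(f"resident {members_of(res_mask)} is not viable")
            resident_equilibrium = res.abundances
        x0[list(members_of(res_mask))] = resident_equilibrium
    for i in inv:
        x0[i] = invader_density
    total = x0.sum()
    if total > params.K_T:
        # arrivals into a capped community displace residents rather than
        # raise the (conserved) total above the cap
        x0 *= params.K_T / total

    if len(inv) == 1:
        # A single invader whose effective per-capita rate is negative in the
        # rarity limit at the resident attractor decays straight back out:
        # skip the simulation.
        (i,) = inv
        probe = x0.copy()
        probe[i] = 1.01 * ext
        rate = capped_derivative(probe, params, weighted_mean=settings.weighted_cap_mean)
        if rate[i] / probe[i] < -1e-9:
            if full_output:
                return res_mask, "fail", x0
            return res_mask, "fail"

    traj = integrate_to_equilibrium(params, x0, settings=settings)
    target = mask_of(np.nonzero(traj.final.x > ext)[0])
    if full_output:
        return target, _categorise(res_mask, inv_mask, target), traj.final.x
    return target, _categorise(res_mask, inv_mask, target)


def _consortia(absent: Sequence[int], max_size: int) -> Iterator[tuple[int, ...]]:
    for size in range(1, max_size + 1):
        yield from combinations(absent, size)


def _verify_discovered(
    params: CommunityParameters,
    mask: int,
    settled_x: np.ndarray,
    settings: IntegrationSettings,
) -> EquilibriumResult | None:
    """Re-assess a settled species set that enumeration had not marked viable.

    Multistable subsets can hold an attractor that the default viability
    starts miss but that invasion trajectories reach.  The candidate
    attractor (the invasion's own settled abundances) is accepted as a
    viable node only if the perturbation-return test passes there.
    """
    from .dynamics import _perturbation_returns

    members = members_of(mask)
    abundances = settled_x[list(members)]
    ext = settings.resolve_extinction(params)
    if np.any(abundances <= ext):
        return None
    if not _perturbation_returns(params, members, abundances, settings):
        return None
    return EquilibriumResult(
        subset=frozenset(members),
        abundances=abundances,
        feasible=True,
        stable=True,
        at_cap=bool(abundances.sum() >= params.K_T * (1 - 1e-6)),
    )


def _resolve_edge(
    params: CommunityParameters,
    mask: int,
    consortium: tuple[int, ...],
    eq: np.ndarray,
    nodes: dict[int, EquilibriumResult],
    settings: IntegrationSettings,
    strict: bool,
) -> tuple[int, str] | None:
    """One invasion, with node-discovery and longer-horizon retries.

    Returns (target, category) or None for fail/dropped edges.  Settled
    species sets absent from the node table are first re-assessed (they may
    be genuinely viable attractors enumeration missed, and are then added);
    otherwise the invasion is re-run at a longer horizon, and a persistent
    mismatch raises :class:`MapConstructionError` when ``strict`` — outcomes
    are never silently coerced onto the nearest node.
    """
    from dataclasses import replace as _replace

    def match_or_discover(target: int, final_x: np.ndarray, stg) -> bool:
        if target in nodes:
            return True
        discovered = _verify_discovered(params, target, final_x, stg)
        if discovered is not None:
            nodes[target] = discovered
            return True
        return False

    target, category, final_x = invasion_outcome(
        params, mask, consortium, settings=settings, resident_equilibrium=eq, full_output=True
    )
    if category == "fail":
        return None
    if match_or_discover(target, final_x, settings):
        return target, category

    # The trajectory may have converged onto a saddle (invasion starts are
    # fine-tuned: residents exactly at equilibrium).  Nudge off it and let
    # the dynamics find the genuine attractor.
    ext = settings.resolve_extinction(params)
    n = params.S
    for pattern in (0, 1):
        factors = np.where((np.arange(n) + pattern) % 2 == 0, 0.97, 1.03)
        x_p = np.maximum(final_x, 0.0) * factors
        total = x_p.sum()
        if total > params.K_T:
            x_p *= params.K_T / total
        traj = integrate_to_equilibrium(params, x_p, settings=settings)
        t2 = mask_of(np.nonzero(traj.final.x > ext)[0])
        c2 = _categorise(mask, mask_of(consortium), t2)
        if c2 == "fail":
            return None
        if match_or_discover(t2, traj.final.x, settings):
            return t2, c2

    longer = _replace(settings, horizon=settings.horizon * 4)
    target, category, final_x = invasion_outcome(
        params, mask, consortium, settings=longer, resident_equilibrium=eq, full_output=True
    )
    if category == "fail":
        return None
    if match_or_discover(target, final_x, longer):
        return target, category
    if strict:
        raise MapConstructionError(
            f"invasion of {consortium} into {members_of(mask)} settled at "
            f"{members_of(target)}, which could not be verified as a viable node"
        )
    warnings.warn(
        f"dropping unresolvable invasion of {consortium} into {members_of(mask)}",
        stacklevel=2,
    )
    return None


def build_assembly_map(
    params: CommunityParameters,
    consortium_size: int = 1,
    settings: IntegrationSettings = DEFAULT_SETTINGS,
    require_viable_climax: bool = True,
    strict: bool = True,
) -> AssemblyMap:
    """Enumerate viable subcommunities and resolve every arrival between them.

    All 2^S subsets are tested for viability; every (viable node, absent
    consortium of size <= ``consortium_size``) pair is resolved with
    :func:`invasion_outcome`.  Nodes discovered dynamically (multistable
    attractors reached by invasions but missed by the enumeration starts)
    are verified and added, and their own invasions resolved in turn.
    """
    S = params.S
    if S > ENUMERATION_LIMIT:
        raise ValueError(
            f"S={S} exceeds the exhaustive enumeration limit ({ENUMERATION_LIMIT}); "
            "reduce the pool or analyse subcommunities directly"
        )
    climax = (1 << S) - 1
    nodes: dict[int, EquilibriumResult] = {}
    for mask in range(1 << S):
        result = assess_viability(params, members_of(mask), settings=settings)
        if result.viable:
            nodes[mask] = result
    if require_viable_climax and climax not in nodes:
        raise ValueError("full community is not viable; no climax to map")

    edges: list[AssemblyEdge] = []
    done: set[int] = set()
    while True:
        pending = sorted(set(nodes) - done)
        if not pending:
            break
        for mask in pending:
            done.add(mask)
            absent = [i for i in range(S) if not mask & (1 << i)]
            eq = nodes[mask].abundances
            for consortium in _consortia(absent, consortium_size):
                resolved = _resolve_edge(params, mask, consortium, eq, nodes, settings, strict)
                if resolved is None:
                    continue
                target, category = resolved
                edges.append(
                    AssemblyEdge(
                        source=mask,
                        target=target,
                        arrivals=frozenset(consortium),
                        category=category,
                    )
                )
    return AssemblyMap(S=S, climax=climax, nodes=nodes, edges=edges, consortium_size=consortium_size)


def _count_simple_paths(g: nx.DiGraph, source: int, target: int, limit: int) -> tuple[int, bool]:
    if source not in g or target not in g:
        return 0, False
    n = 0
    if source == target:
        return 1, False
    for _ in nx.all_simple_paths(g, source, target):
        n += 1
        if n >= limit:
            return n, True
    return n, False


def map_metrics(
    amap: AssemblyMap,
    params: CommunityParameters | None = None,
    path_limit: int = 1_000_000,
) -> MapMetrics:
    """Compute summary metrics: viability counts, path counts, predictability."""
    g = amap.simple_digraph()
    n_paths, truncated = _count_simple_paths(g, amap.empty, amap.climax, path_limit)
    can_assemble = n_paths >= 1
    climax_members = members_of(amap.climax)
    secondary = sum(1 for i in climax_members if (1 << i) not in amap.nodes)
    n_climax = len(climax_members)
    return MapMetrics(
        n_viable=len(amap.nodes),
        n_edges=len(amap.edges),
        can_assemble=can_assemble,
        n_paths=n_paths,
        predictability=(1.0 / n_paths) if n_paths else 0.0,
        secondary_colonizers=secondary,
        secondary_colonizer_fraction=secondary / n_climax if n_climax else 0.0,
        path_entropy=math.log(n_paths) if n_paths else float("inf"),
        paths_truncated=truncated,
    )
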