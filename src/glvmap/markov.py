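"""Continuous-time Markov chain over assembly-map states.

Species arrive at rate gamma each and are lost at rate delta each; the
assembly map supplies arrival outcomes, and loss outcomes are obtained by
deleting a species and relaxing the remainder under capped dynamics
(cascading extinctions allowed).  The stationary distribution gives the
long-run probability of observing each viable subcommunity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .assembly import AssemblyMap, mask_of, members_of
from .dynamics import DEFAULT_SETTINGS, IntegrationSettings, integrate_to_equilibrium
from .params import CommunityParameters

__all__ = ["TransitionModel", "StationaryDistribution", "build_generator", "stationary_distribution", "occupancy_summary"]


class GeneratorError(RuntimeError):
    """A relaxed post-loss state was not a node of the assembly map."""


@dataclass
class TransitionModel:
    """CTMC generator over the viable subcommunity states."""

    states: list[int]  # bitmasks, ordered
    Q: np.ndarray
    gamma: float
    delta: float

    def index(self, mask: int) -> int:
        return self.states.index(mask)


@dataclass
class StationaryDistribution:
    """Long-run state probabilities and their aggregation by community size."""

    states: list[int]
    pi: np.ndarray
    by_size: np.ndarray
    most_likely_size: int
    size_tie: bool = False

    def prob(self, mask: int) -> float:
        return float(self.pi[self.states.index(mask)])


def _relax_after_loss(
    params: CommunityParameters,
    amap: AssemblyMap,
    state: int,
    lost: int,
    settings: IntegrationSettings,
) -> int:
    """Delete one species from a node and let the remainder settle."""
    remaining = state & ~(1 << lost)
    if remaining == 0:
        return 0
    if remaining in amap.nodes:
        # removal of one species from a viable node; if the remainder is a
        # viable node we still verify dynamically that no cascade occurs
        pass
    eq = amap.nodes[state].abundances
    x0 = np.zeros(params.S)
    x0[list(members_of(state))] = eq
    x0[lost] = 0.0
    traj = integrate_to_equilibrium(params, x0, settings=settings)
    ext = settings.resolve_extinction(params)
    settled = mask_of(np.nonzero(traj.final.x > ext)[0])
    if settled not in amap.nodes:
        raise GeneratorError(
            f"loss of species {lost} from {members_of(state)} relaxed to "
            f"{members_of(settled)}, which is not a viable node"
        )
    return settled


def build_generator(
    amap: AssemblyMap,
    params: CommunityParameters,
    gamma: float,
    delta: float,
    settings: IntegrationSettings = DEFAULT_SETTINGS,
    arrival_mode: str = "per_species",
) -> TransitionModel:
    """Assemble the CTMC generator matrix from an assembly map.

    Each absent species arrives at rate ``gamma`` (``arrival_mode
    "per_species"``; mode ``"uniform_total"`` spreads a total rate ``gamma``
    over the absent pool) and flows into its invasion outcome; failed
    invasions contribute nothing.  Each present species is lost at rate
    ``delta``, landing on the relaxed post-loss node.
    """
    if gamma <= 0 or delta <= 0:
        raise ValueError("gamma and delta must be positive")
    if arrival_mode not in ("per_species", "uniform_total"):
        raise ValueError(f"unknown arrival_mode {arrival_mode!r}")
    states = sorted(amap.nodes)
    idx = {m: k for k, m in enumerate(states)}
    n = len(states)
    Q = np.zeros((n, n))

    for e in amap.edges:
        if len(e.arrivals) != 1:
            continue  # the CTMC uses single-species events only
        rate = gamma
        if arrival_mode == "uniform_total":
            n_absent = amap.S - bin(e.source).count("1")
            rate = gamma / n_absent
        Q[idx[e.source], idx[e.target]] += rate

    for state in states:
        for lost in members_of(state):
            target = _relax_after_loss(params, amap, state, lost, settings)
            Q[idx[state], idx[target]] += delta

    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return TransitionModel(states=states, Q=Q, gamma=gamma, delta=delta)


def stationary_distribution(model: TransitionModel, S: int | None = None) -> StationaryDistribution:
    """Solve pi Q = 0, sum(pi) = 1 on the class reachable from the empty set."""
    states = model.states
    n = len(states)
    if 0 not in states:
        raise ValueError("model does not contain the empty state")
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    rows, cols = np.nonzero(model.Q > 0)
    g.add_edges_from(zip(rows.tolist(), cols.tolist()))
    start = states.index(0)
    reachable = sorted(nx.descendants(g, start) | {start})
    if len(reachable) < n:
        warnings.warn(
            f"{n - len(reachable)} states unreachable from the empty set; "
            "distribution is conditional on the reachable class",
            stacklevel=2,
        )
    sub = model.Q[np.ix_(reachable, reachable)]
    # renormalise the diagonal so rows sum to zero within the restricted class
    sub = sub.copy()
    np.fill_diagonal(sub, 0.0)
    np.fill_diagonal(sub, -sub.sum(axis=1))
    m = len(reachable)
    M = np.vstack([sub.T, np.ones((1, m))])
    b = np.zeros(m + 1)
    b[-1] = 1.0
    pi_sub, *_ = np.linalg.lstsq(M, b, rcond=None)
    pi_sub = np.clip(pi_sub, 0.0, None)
    pi_sub /= pi_sub.sum()
    pi = np.zeros(n)
    pi[reachable] = pi_sub

    if S is None:
        S = max(bin(m_).count("1") for m_ in states)
    by_size = np.zeros(S + 1)
    for k, mask in enumerate(states):
        by_size[bin(mask).count("1")] += pi[k]
    best = float(by_size.max())
    winners = np.nonzero(np.isclose(by_size, best, rtol=0, atol=1e-12))[0]
    return StationaryDistribution(
        states=states,
        pi=pi,
        by_size=by_size,
        most_likely_size=int(winners.max()),
        size_tie=len(winners) > 1,
    )


def occupancy_summary(dist: StationaryDistribution) -> dict:
    """Deterministic report of the size distribution and its mode."""
    return {
        "most_likely_size": dist.most_likely_size,
        "size_tie": dist.size_tie,
        "size_distribution": {int(k): float(p) for k, p in enumerate(dist.by_size)},
        "mean_size": float(np.dot(np.arange(len(dist.by_size)), dist.by_size)),
    }
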