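"""Independent brute-force oracle used by the test suite.

Implements the same model definition (capped gLV with extinction clamping)
through its own integration loop, and derives viability and invasion
outcomes purely from multi-start randomized simulation, with no reliance on
the package's linear-algebra shortcuts, node discovery or caching.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import odeint

EXT_FRACTION = 1e-6
BAND = 1e-3


def _rhs_factory(r, s, A, K):
    band = BAND * K
    lower = K - band

    def rhs(x, _t):
        x = np.maximum(x, 0.0)
        g = r - s * x + A @ x
        total = x.sum()
        if total <= lower:
            return x * g
        gbar = float(x @ g) / total
        w = min((total - lower) / band, 1.0)
        return x * (g - w * gbar)

    return rhs


def settle(r, s, A, K, x0, horizon=4000.0, tol=1e-6):
    """Integrate to (approximate) equilibrium; returns final abundances."""
    rhs = _rhs_factory(r, s, A, K)
    ext = EXT_FRACTION * K
    x = np.maximum(np.asarray(x0, float), 0.0)
    t = 0.0
    quiet = 0
    while t < horizon:
        seg = np.linspace(t, t + 50.0, 4)
        x = np.maximum(odeint(rhs, x, seg, rtol=1e-7, atol=1e-9, mxstep=50_000)[-1], 0.0)
        x[x < ext] = 0.0
        t += 50.0
        alive = x > 0
        if not alive.any():
            break
        rate = rhs(x, 0.0)
        if np.max(np.abs(rate[alive] / x[alive])) < tol:
            quiet += 1
            if quiet >= 2:
                break
        else:
            quiet = 0
    return x


def _members(x, K):
    return frozenset(np.nonzero(x > EXT_FRACTION * K)[0].tolist())


def subset_viable_oracle(params, subset, rng, n_starts=24):
    """Viability by randomized multi-start settling plus perturbation-return."""
    subset = sorted(subset)
    if not subset:
        return True
    idx = np.asarray(subset)
    r, s = params.r[idx] + params.f, params.s[idx]
    A = params.A[np.ix_(idx, idx)]
    K = params.K_T
    n = len(idx)
    for _ in range(n_starts):
        x0 = np.exp(rng.uniform(np.log(0.05), np.log(0.9 * K / n), size=n))
        xf = settle(r, s, A, K, x0)
        if _members(xf, K) != frozenset(range(n)):
            continue
        ok = True
        for _ in range(2):
            pert = xf * rng.uniform(0.92, 1.08, size=n)
            if pert.sum() > K:
                pert *= K / pert.sum()
            xr = settle(r, s, A, K, pert)
            if _members(xr, K) != frozenset(range(n)) or not np.allclose(xr, xf, rtol=2e-2, atol=EXT_FRACTION * K):
                ok = False
                break
        if ok:
            return True
    return False


def viable_subsets_oracle(params, rng, n_starts=24):
    S = params.S
    out = set()
    for mask in range(1 << S):
        subset = [i for i in range(S) if mask & (1 << i)]
        if subset_viable_oracle(params, subset, rng, n_starts=n_starts):
            out.add(mask)
    return out


def invasion_oracle(params, resident_members, invader, rng, n_draws=20):
    """Unique post-invasion species set across randomized low arrival
    densities; returns (mask, unique flag)."""
    S = params.S
    K = params.K_T
    r, s, A = params.r + params.f, params.s, params.A
    res = sorted(resident_members)
    if res:
        idx = np.asarray(res)
        base = settle(r[idx], s[idx], A[np.ix_(idx, idx)], K,
                      np.full(len(idx), min(1.0, 0.9 * K / len(idx))))
        if _members(base, K) != frozenset(range(len(idx))):
            base = settle(r[idx], s[idx], A[np.ix_(idx, idx)], K, np.full(len(idx), 0.9 * K / len(idx)))
    outcomes = set()
    for _ in range(n_draws):
        x0 = np.zeros(S)
        if res:
            x0[res] = base * rng.uniform(0.99, 1.01, size=len(res))
        x0[invader] = 1e-3 * K * rng.uniform(0.5, 2.0)
        if x0.sum() > K:
            x0 *= K / x0.sum()
        xf = settle(r, s, A, K, x0)
        outcomes.add(_members(xf, K))
    if len(outcomes) != 1:
        return None, False
    members = outcomes.pop()
    mask = 0
    for i in members:
        mask |= 1 << i
    return mask, True


def oracle_map(params, rng, n_starts=24, n_draws=12):
    """(viable masks, {(source, invader): target}) with ambiguous pairs
    collected separately."""
    nodes = viable_subsets_oracle(params, rng, n_starts=n_starts)
    edges = {}
    ambiguous = []
    for mask in sorted(nodes):
        residents = [i for i in range(params.S) if mask & (1 << i)]
        for inv in range(params.S):
            if mask & (1 << inv):
                continue
            target, unique = invasion_oracle(params, residents, inv, rng, n_draws=n_draws)
            if not unique:
                ambiguous.append((mask, inv))
                continue
            edges[(mask, inv)] = target
    return nodes, edges, ambiguous
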