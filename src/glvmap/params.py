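"""Core parameter and state containers for capped gLV communities.

A community is defined by intrinsic growth rates ``r``, self-regulation
coefficients ``s``, an interspecies interaction matrix ``A`` (entry
``A[i, j]`` is the per-abundance effect of species ``j`` on species ``i``,
zero diagonal), a total-population cap ``K_T``, and an optional uniform
host-feeding supplement ``f`` added to every intrinsic growth rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "CommunityParameters",
    "AbundanceState",
    "EquilibriumResult",
    "DEFAULT_CAP",
]

#: Total population cap used throughout unless overridden.
DEFAULT_CAP = 10_000.0


class ParameterError(ValueError):
    """Raised when community parameters are malformed."""


@dataclass(frozen=True)
class CommunityParameters:
    """Parameters of one gLV community.

    Parameters
    ----------
    r : array of shape (S,)
        Intrinsic growth rates (1/time).
    s : array of shape (S,)
        Self-regulation coefficients (per abundance per time); strictly
        positive.
    A : array of shape (S, S)
        Interspecies interaction matrix with zero diagonal; ``A[i, j]`` is
        the effect of species ``j`` on species ``i``.
    K_T : float
        Total population cap (abundance), > 0.
    f : float
        Host-feeding supplement added to every ``r_i`` (1/time).
    names : tuple of str
        Species names; defaults to ``sp0 .. sp{S-1}``.
    """

    r: np.ndarray
    s: np.ndarray
    A: np.ndarray
    K_T: float = DEFAULT_CAP
    f: float = 0.0
    names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        s = np.asarray(self.s, dtype=float)
        A = np.asarray(self.A, dtype=float)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "A", A)
        S = r.shape[0]
        if r.ndim != 1 or S < 1:
            raise ParameterError("r must be a 1-D vector with at least one species")
        if s.shape != (S,):
            raise ParameterError(f"s has shape {s.shape}, expected ({S},)")
        if A.shape != (S, S):
            raise ParameterError(f"A has shape {A.shape}, expected ({S}, {S})")
        if not np.all(s > 0):
            bad = int(np.argmin(s))
            raise ParameterError(f"self-regulation must be strictly positive (s[{bad}] = {s[bad]})")
        diag = np.abs(np.diag(A))
        if np.any(diag != 0):
            bad = int(np.argmax(diag))
            raise ParameterError(f"diagonal of A must be exactly zero (A[{bad},{bad}] = {A[bad, bad]})")
        if not self.K_T > 0:
            raise ParameterError(f"K_T must be positive, got {self.K_T}")
        if not self.names:
            object.__setattr__(self, "names", tuple(f"sp{i}" for i in range(S)))
        elif len(self.names) != S:
            raise ParameterError(f"{len(self.names)} names for {S} species")
        else:
            object.__setattr__(self, "names", tuple(self.names))
        if not (np.all(np.isfinite(r)) and np.all(np.isfinite(s)) and np.all(np.isfinite(A))):
            raise ParameterError("parameters must be finite")

    @property
    def S(self) -> int:
        """Number of species."""
        return self.r.shape[0]

    @property
    def effective_r(self) -> np.ndarray:
        """Intrinsic growth rates including host feeding, ``r + f``."""
        return self.r + self.f

    def with_feeding(self, f: float) -> "CommunityParameters":
        """Return a copy with the host-feeding supplement set to ``f``."""
        return replace(self, f=float(f))

    def restrict(self, subset: Sequence[int]) -> "CommunityParameters":
        """Return parameters restricted to the given species indices."""
        idx = np.asarray(sorted(subset), dtype=int)
        return CommunityParameters(
            r=self.r[idx],
            s=self.s[idx],
            A=self.A[np.ix_(idx, idx)],
            K_T=self.K_T,
            f=self.f,
            names=tuple(self.names[i] for i in idx),
        )


@dataclass
class AbundanceState:
    """Species abundances at a moment in time."""

    x: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if np.any(self.x < 0):
            raise ValueError("abundances must be nonnegative")


@dataclass
class EquilibriumResult:
    """Outcome of equilibrium analysis for a species subset.

    ``feasible`` means all subset species settle at strictly positive
    abundance; ``stable`` is linear asymptotic stability (interior case) or
    perturbation-return (cap case).  ``at_cap`` marks equilibria that sit on
    the total-abundance cap.  ``viable`` combines the two notions.
    """

    subset: frozenset[int]
    abundances: np.ndarray
    feasible: bool
    stable: bool
    max_re_eigenvalue: float = np.nan
    at_cap: bool = False
    marginal: bool = False

    @property
    def viable(self) -> bool:
        return bool(self.feasible and self.stable)
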