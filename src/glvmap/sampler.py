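"""Random climax-community generation.

Communities are initiated purely inhibitory (competitive or amensal pairs),
interaction magnitudes are drawn half-normal, a chosen proportion of entries
is then switched positive (facilitation), and the whole construction is
rejection-sampled on full-community viability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import IntegrationSettings, DEFAULT_SETTINGS, assess_viability
from .params import CommunityParameters

__all__ = ["SamplerSettings", "apply_facilitation", "sample_climax_community", "NoViableCommunityError"]


class NoViableCommunityError(RuntimeError):
    """Rejection-sampling budget exhausted without finding a viable community."""

    def __init__(self, attempts: int):
        self.attempts = attempts
        super().__init__(f"no viable community found in {attempts} attempts")


@dataclass(frozen=True)
class SamplerSettings:
    """Generator controls.

    ``C`` is the probability an (unordered) species pair interacts at all;
    ``sigma`` scales the half-normal interaction magnitudes; ``P_m`` is the
    proportion of nonzero entries switched from inhibitory to positive;
    ``amensal_fraction`` is the probability an interacting pair is one-sided
    (-/0) rather than bidirectional.  ``r_range`` gives the uniform support
    of the intrinsic growth rates (some species must lack independent growth
    for secondary colonizers to arise).
    """

    S: int = 10
    C: float = 0.5
    sigma: float = 0.05
    P_m: float = 0.0
    r_range: tuple[float, float] = (-0.5, 1.0)
    s_value: float = 1.0
    K_T: float = 10_000.0
    amensal_fraction: float = 0.5
    seed: int | None = None
    max_attempts: int = 10_000
    integration: IntegrationSettings = field(default=DEFAULT_SETTINGS)

    def __post_init__(self) -> None:
        if not 0 <= self.C <= 1:
            raise ValueError(f"C must lie in [0, 1], got {self.C}")
        if not 0 <= self.P_m <= 1:
            raise ValueError(f"P_m must lie in [0, 1], got {self.P_m}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be nonnegative, got {self.sigma}")
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be at least 1")


def apply_facilitation(A: np.ndarray, P_m: float, rng: np.random.Generator) -> np.ndarray:
    """Switch a proportion ``P_m`` of nonzero entries to positive sign.

    Exactly ``round(P_m * n_nonzero)`` off-diagonal nonzero entries, chosen
    uniformly at random, have their sign flipped to positive; magnitudes are
    untouched, so facilitation sweeps are magnitude-controlled.
    """
    if not 0 <= P_m <= 1:
        raise ValueError(f"P_m must lie in [0, 1], got {P_m}")
    A = np.asarray(A, dtype=float)
    if np.any(A[A != 0] > 0):
        raise ValueError("input matrix must be purely nonpositive off-diagonal")
    out = A.copy()
    rows, cols = np.nonzero(out)
    n = len(rows)
    k = int(round(P_m * n))
    if k:
        pick = rng.choice(n, size=k, replace=False)
        out[rows[pick], cols[pick]] = np.abs(out[rows[pick], cols[pick]])
    return out


def _draw_candidate(settings: SamplerSettings, rng: np.random.Generator) -> CommunityParameters:
    S = settings.S
    A = np.zeros((S, S))
    for i in range(S):
        for j in range(i + 1, S):
            if rng.random() >= settings.C:
                continue
            # half-normal magnitudes; pairs start competitive or amensal
            m_ij = abs(rng.normal(0.0, settings.sigma)) if settings.sigma > 0 else 0.0
            m_ji = abs(rng.normal(0.0, settings.sigma)) if settings.sigma > 0 else 0.0
            A[i, j] = -m_ij
            A[j, i] = -m_ji
            if rng.random() < settings.amensal_fraction:
                if rng.random() < 0.5:
                    A[i, j] = 0.0
                else:
                    A[j, i] = 0.0
    A = apply_facilitation(A, settings.P_m, rng)
    r = rng.uniform(*settings.r_range, size=S)
    s = np.full(S, settings.s_value)
    return CommunityParameters(r=r, s=s, A=A, K_T=settings.K_T)


def sample_climax_community(settings: SamplerSettings) -> tuple[CommunityParameters, int]:
    """Rejection-sample a community whose full species set is viable.

    Returns the parameters and the number of attempts used.  Raises
    :class:`NoViableCommunityError` when the budget is exhausted.
    """
    rng = np.random.default_rng(settings.seed)
    full = frozenset(range(settings.S))
    for attempt in range(1, settings.max_attempts + 1):
        params = _draw_candidate(settings, rng)
        result = assess_viability(params, full, settings=settings.integration)
        if result.viable:
            return params, attempt
    raise NoViableCommunityError(settings.max_attempts)
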