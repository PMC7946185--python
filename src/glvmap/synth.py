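"""Synthetic fixtures and cohorts.

Hand-built archetype communities with analytically known assembly-map
structure, and a longitudinal infant-cohort simulator with known interaction
ground truth, so the whole pipeline is testable without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import (
    DEFAULT_SETTINGS,
    IntegrationSettings,
    integrate_to_equilibrium,
)
from .params import CommunityParameters

__all__ = ["ARCHETYPES", "CohortSpec", "fixture_community", "recovery_community", "simulate_cohort"]

ARCHETYPES = (
    "independent",
    "obligate_pair",
    "commensal_chain",
    "competitive_exclusion",
    "mutualist_triangle",
    "humpty_dumpty",
)


def fixture_community(archetype: str) -> CommunityParameters:
    """Archetype communities with documented expected assembly structure.

    - ``independent``: 3 non-interacting species, all capable of independent
      growth; every subset viable, diamond-family map.
    - ``obligate_pair``: two strong mutualists, neither able to grow alone;
      only the empty set and the (cap-held) pair are viable, no edges.
    - ``commensal_chain``: sp0 grows alone, sp1 requires sp0, sp2 requires
      sp1; single forced assembly path.
    - ``competitive_exclusion``: sp1 strongly suppresses sp0 (one-sided);
      the pair is infeasible, invasion of sp1 into {sp0} is a replacement.
    - ``mutualist_triangle``: three obligate mutualists where every pair is
      non-viable; only a simultaneous triple arrival assembles it.
    - ``humpty_dumpty``: five obligate mutualists, all pairs interacting;
      every subset of size >= 3 is viable (held at the cap) but no singleton
      or pair is, so the viable climax has no single-arrival assembly path.
    """
    if archetype == "independent":
        return CommunityParameters(
            r=np.array([1.0, 0.8, 0.6]),
            s=np.ones(3),
            A=np.zeros((3, 3)),
            names=("t0", "t1", "t2"),
        )
    if archetype == "obligate_pair":
        A = np.array([[0.0, 1.5], [1.5, 0.0]])
        return CommunityParameters(r=np.array([-0.1, -0.1]), s=np.ones(2), A=A)
    if archetype == "commensal_chain":
        # s = 0.1 gives equilibria of order 10-100, well above cohort
        # detection limits, so failed low-density arrivals stay invisible
        A = np.zeros((3, 3))
        A[1, 0] = 0.5  # sp0 feeds sp1
        A[2, 1] = 0.3  # sp1 feeds sp2
        return CommunityParameters(
            r=np.array([1.0, -0.1, -0.05]), s=np.full(3, 0.1), A=A, names=("up", "mid", "down")
        )
    if archetype == "competitive_exclusion":
        A = np.zeros((2, 2))
        A[0, 1] = -1.5  # sp1 hits sp0 hard
        A[1, 0] = -0.1
        return CommunityParameters(r=np.array([1.0, 1.0]), s=np.ones(2), A=A)
    if archetype == "mutualist_triangle":
        A = np.full((3, 3), 0.7)
        np.fill_diagonal(A, 0.0)
        return CommunityParameters(r=np.full(3, -0.1), s=np.ones(3), A=A)
    if archetype == "humpty_dumpty":
        A = np.full((5, 5), 0.7)
        np.fill_diagonal(A, 0.0)
        return CommunityParameters(r=np.full(5, -0.1), s=np.ones(5), A=A)
    raise ValueError(f"unknown archetype {archetype!r}; choose from {ARCHETYPES}")


def recovery_community() -> CommunityParameters:
    """Six-taxon community with a known sparse interaction matrix, tuned for
    parameter-recovery experiments (slow dynamics relative to daily
    sampling, mixed-sign interactions of graded magnitude)."""
    S = 6
    A = np.zeros((S, S))
    for i, j, v in [
        (0, 1, 0.10), (1, 0, -0.08), (2, 0, 0.12), (3, 2, -0.06),
        (4, 3, 0.09), (5, 4, -0.10), (1, 3, 0.07), (2, 5, -0.05),
    ]:
        A[i, j] = v
    return CommunityParameters(
        r=np.array([0.40, 0.30, 0.20, 0.35, 0.25, 0.30]),
        s=np.full(S, 0.1),
        A=A,
        names=tuple(f"g{i}" for i in range(S)),
    )


@dataclass(frozen=True)
class CohortSpec:
    """Settings for one synthetic longitudinal cohort.

    Arrival windows give per-taxon uniform ranges (inclusive, in days) from
    which integer arrival days are drawn.  Observation noise is
    multiplicative lognormal; the detection limit censors observations after
    noise.  Antibiotic pulses (optional) suppress per-capita growth of all
    taxa by ``antibiotic_effect`` while active.
    """

    params: CommunityParameters
    n_subjects: int = 13
    sampling_days: tuple[float, ...] = tuple(float(d) for d in range(0, 42))
    arrival_windows: tuple[tuple[int, int], ...] | None = None
    arrival_density: float = 10.0
    noise_sd: float = 0.0
    detection_limit: float = 0.5
    n_antibiotics: int = 0
    antibiotic_effect: float = -1.0
    antibiotic_course_days: int = 3
    antibiotic_prob: float = 0.3  # probability a subject receives each course
    seed: int = 0
    integration: IntegrationSettings = field(default=DEFAULT_SETTINGS)

    def __post_init__(self) -> None:
        days = self.sampling_days
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("sampling schedule must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    def resolved_windows(self) -> list[tuple[int, int]]:
        if self.arrival_windows is not None:
            if len(self.arrival_windows) != self.params.S:
                raise ValueError("need one arrival window per taxon")
            return list(self.arrival_windows)
        # stagger arrivals across the first two thirds of the study window
        last = int(self.sampling_days[-1] * 2 / 3)
        S = self.params.S
        out = []
        for i in range(S):
            lo = int(round(i * last / max(S, 1)))
            out.append((lo, min(lo + max(last // S, 1) + 2, last)))
        return out


def _simulate_subject(
    spec: CohortSpec,
    arrivals: np.ndarray,
    abx_windows: list[tuple[float, float]],
    rng: np.random.Generator,
) -> np.ndarray:
    """True abundances at each sampling day for one subject."""
    params = spec.params
    S = params.S
    days = np.asarray(spec.sampling_days)
    # event times: arrivals and antibiotic on/off edges split the integration
    breakpoints = sorted(
        set(days)
        | set(float(a) for a in arrivals)
        | set(t for w in abx_windows for t in w)
    )
    x = np.zeros(S)
    t = breakpoints[0]
    out = np.zeros((len(days), S))
    day_index = {float(d): k for k, d in enumerate(days)}

    def active_effect(time: float) -> float:
        return spec.antibiotic_effect * sum(1 for a, b in abx_windows if a <= time < b)

    for i in np.nonzero(arrivals <= t)[0]:
        x[i] += spec.arrival_density
    if t in day_index:
        out[day_index[t]] = x
    for t_next in breakpoints[1:]:
        eff = active_effect((t + t_next) / 2)
        p = params if eff == 0 else params.with_feeding(params.f + eff)
        from dataclasses import replace

        settings = replace(spec.integration, horizon=t_next - t, chunk=t_next - t, convergence_tol=0.0)
        traj = integrate_to_equilibrium(p, x, settings=settings)
        x = traj.final.x.copy()
        for i in np.nonzero((arrivals > t) & (arrivals <= t_next))[0]:
            x[i] += spec.arrival_density
        if float(t_next) in day_index:
            out[day_index[float(t_next)]] = x
        t = t_next
    return out


def simulate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame, CommunityParameters]:
    """Simulate a longitudinal cohort under capped gLV dynamics.

    Per subject, each taxon arrives once at a drawn day (at low density),
    the community is integrated between events, and noisy observations are
    censored at the detection limit.  Returns the long-format observation
    table, the ground-truth arrival table, and the generating parameters.
    """
    rng = np.random.default_rng(spec.seed)
    params = spec.params
    taxa = list(params.names)
    windows = spec.resolved_windows()
    days = np.asarray(spec.sampling_days)
    abx_names = [f"abx{k}" for k in range(spec.n_antibiotics)]

    obs_rows = []
    truth_rows = []
    for subj in range(spec.n_subjects):
        sid = f"subject{subj:02d}"
        arrivals = np.array([float(rng.integers(lo, hi + 1)) for lo, hi in windows])
        abx_windows: list[tuple[float, float] | None] = []
        for _k in range(spec.n_antibiotics):
            if rng.random() < spec.antibiotic_prob:
                start = float(rng.integers(0, max(int(days[-1]) - spec.antibiotic_course_days, 1)))
                abx_windows.append((start, start + spec.antibiotic_course_days))
            else:
                abx_windows.append(None)
        active = [w for w in abx_windows if w is not None]
        true_x = _simulate_subject(spec, arrivals, active, rng)
        if spec.noise_sd > 0:
            noise = rng.lognormal(mean=0.0, sigma=spec.noise_sd, size=true_x.shape)
            observed = true_x * noise
        else:
            observed = true_x.copy()
        observed[observed < spec.detection_limit] = 0.0
        for k, d in enumerate(days):
            exposures = {}
            for i, name in enumerate(abx_names):
                w = abx_windows[i]
                exposures[name] = float(w is not None and w[0] <= d < w[1])
            for j, taxon in enumerate(taxa):
                row = {
                    "subject": sid,
                    "taxon": taxon,
                    "time_days": float(d),
                    "abundance": float(observed[k, j]),
                }
                row.update(exposures)
                obs_rows.append(row)
        for j, taxon in enumerate(taxa):
            truth_rows.append({"subject": sid, "taxon": taxon, "arrival_day": arrivals[j]})
    observations = pd.DataFrame(obs_rows)
    truth = pd.DataFrame(truth_rows)
    return observations, truth, params
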