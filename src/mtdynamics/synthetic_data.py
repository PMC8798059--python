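"""Stochastic generators of filament trajectories and nucleation outcomes.

These generators produce data with the statistical structure that the
downstream analysis assumes, standing in for microscope observations:

* plus-end trajectories alternating growth phases (exponentially
  distributed waiting times to catastrophe, constant hazard ``f_cat``)
  with rapid shrinkage back to the seed;
* seed-templated nucleation lags, exponential with the rate chosen so the
  probability of nucleating within 60 s equals the Hill law
  ``p(c) = c^s/(C^s + c^s)``;
* per-field spontaneous nucleation counts, Poisson with mean linear in
  tubulin concentration above the spontaneous critical concentration;
* slow constant-speed depolymerization of stabilized (GMPCPP) seeds.

Measurement noise enters here as a multiplicative jitter on per-interval
slopes (default 10% CV); imaging noise is added separately at render time.
All outputs are reproducible for a fixed integer seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dynamics_model import (
    ExperimentCondition,
    KineticParams,
    growth_velocity,
    hill_probability,
)

__all__ = [
    "FilamentTrajectory",
    "NucleationRecord",
    "sample_trajectory",
    "sample_nucleation_lags",
    "sample_spontaneous_count",
    "sample_gmpcpp_depolymerization",
]

GROWTH, SHRINK, PAUSE = "growth", "shrink", "pause"


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class FilamentTrajectory:
    """Piecewise-linear plus-end position of one filament.

    ``times`` are strictly increasing breakpoints in seconds starting at 0;
    ``lengths`` are µm beyond the seed plus end at those breakpoints;
    ``phases`` labels each of the ``len(times) - 1`` intervals.
    """

    times: np.ndarray
    lengths: np.ndarray
    phases: list[str]
    condition: ExperimentCondition | None = None
    origin: str = "seed_plus_end"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.times.shape != self.lengths.shape:
            raise ValueError("times and lengths must have equal length")
        if len(self.phases) != len(self.times) - 1:
            raise ValueError("need one phase label per interval")
        if self.times[0] != 0:
            raise ValueError("times must start at 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.lengths < -1e-12):
            raise ValueError("lengths must be non-negative")

    @property
    def duration_s(self) -> float:
        return float(self.times[-1])

    def length_at(self, t: float | np.ndarray) -> np.ndarray:
        """Linear interpolation of length at arbitrary times (seconds)."""
        return np.interp(np.asarray(t, dtype=float), self.times, self.lengths)

    def sampled(self, frame_interval_s: float) -> tuple[np.ndarray, np.ndarray]:
        """Lengths sampled on a regular frame grid (as a camera would see)."""
        t = np.arange(0.0, self.duration_s + 1e-9, frame_interval_s)
        return t, self.length_at(t)


@dataclass(frozen=True)
class NucleationRecord:
    """Outcome of one seed in a templated-nucleation assay."""

    seed_id: int
    lag_s: float
    censored: bool = False

    def __post_init__(self) -> None:
        if not self.censored and self.lag_s <= 0:
            raise ValueError("observed lag must be positive")


def sample_trajectory(
    condition: ExperimentCondition,
    params: KineticParams,
    duration_s: float,
    rng_seed: int | np.random.Generator | None = None,
    noise_cv: float = 0.10,
) -> FilamentTrajectory:
    """Simulate one seeded filament over ``duration_s`` seconds.

    Growth at ``growth_velocity(c)`` with catastrophes at constant hazard
    ``f_cat`` (min⁻¹); after catastrophe the filament shrinks at
    ``v_shrink`` back to the seed (length 0), then regrows.  Each
    interval's realized slope is jittered by a multiplicative Gaussian
    factor with coefficient of variation ``noise_cv``.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = _as_rng(rng_seed)
    c = condition.tubulin_conc_uM
    v_grow = growth_velocity(c, params)  # µm/min
    if v_grow <= 0:
        raise ValueError(
            f"growth velocity {v_grow:.4g} µm/min ≤ 0 at {c} µM tubulin: "
            "filament cannot elongate"
        )

    def jitter(v: float) -> float:
        if noise_cv <= 0:
            return v
        return max(v * (1.0 + noise_cv * rng.standard_normal()), 0.05 * v)

    times = [0.0]
    lengths = [0.0]
    phases: list[str] = []
    t, length = 0.0, 0.0
    growing = True
    while t < duration_s:
        if growing:
            v = jitter(v_grow) / 60.0  # µm/s
            if params.f_cat > 0:
                dt = rng.exponential(60.0 / params.f_cat)
            else:
                dt = duration_s - t
            dt = min(dt, duration_s - t)
            t += dt
            length += v * dt
            times.append(t)
            lengths.append(length)
            phases.append(GROWTH)
            growing = False
        else:
            if params.v_shrink <= 0:
                break
            v = jitter(params.v_shrink) / 60.0  # µm/s
            dt_empty = length / v  # time to shrink to the seed
            if params.f_rescue > 0:
                dt_rescue = rng.exponential(60.0 / params.f_rescue)
            else:
                dt_rescue = np.inf
            dt = min(dt_empty, dt_rescue, duration_s - t)
            if dt <= 0:
                growing = True
                continue
            t += dt
            length = max(length - v * dt, 0.0)
            times.append(t)
            lengths.append(length)
            phases.append(SHRINK)
            growing = True
    return FilamentTrajectory(
        np.array(times), np.array(lengths), phases, condition, origin="seed_plus_end"
    )


def sample_nucleation_lags(
    condition: ExperimentCondition,
    params: KineticParams,
    n_seeds: int,
    t_max_s: float,
    rng_seed: int | np.random.Generator | None = None,
    eps: float = 1e-6,
) -> list[NucleationRecord]:
    """Draw templated-nucleation lags for ``n_seeds`` seeds.

    Lags are exponential with rate λ(c) = −ln(1 − p(c))/60 s⁻¹, where
    p(c) is the Hill 1-minute nucleation probability, so that
    P(lag ≤ 60 s) = p(c) by construction.  Lags exceeding ``t_max_s``
    are right-censored.  When p(c) > 1 − ``eps`` the rate is capped
    (and a warning recorded) to keep λ finite.
    """
    if n_seeds <= 0:
        raise ValueError("n_seeds must be positive")
    rng = _as_rng(rng_seed)
    p = float(hill_probability(condition.tubulin_conc_uM, params.hill_C, params.hill_s))
    if p >= 1.0 - eps:
        warnings.warn(
            f"1-min nucleation probability {p:.8f} capped at {1 - eps}", stacklevel=2
        )
        p = 1.0 - eps
    records = []
    if p <= 0.0:
        for i in range(n_seeds):
            records.append(NucleationRecord(i, t_max_s, censored=True))
        return records
    lam = -np.log1p(-p) / 60.0  # s⁻¹
    lags = rng.exponential(1.0 / lam, size=n_seeds)
    for i, lag in enumerate(lags):
        if lag > t_max_s:
            records.append(NucleationRecord(i, t_max_s, censored=True))
        else:
            records.append(NucleationRecord(i, float(lag), censored=False))
    return records


def sample_spontaneous_count(
    condition: ExperimentCondition,
    params: KineticParams,
    rng_seed: int | np.random.Generator | None = None,
) -> int:
    """Number of spontaneously nucleated microtubules in one field of view.

    Poisson with mean ``spont_slope * max(0, c − spont_Cc)``: zero below
    the spontaneous critical concentration, linear above it.
    """
    rng = _as_rng(rng_seed)
    mean = params.spont_slope * max(0.0, condition.tubulin_conc_uM - params.spont_Cc)
    if mean == 0.0:
        return 0
    return int(rng.poisson(mean))


def sample_gmpcpp_depolymerization(
    params: KineticParams,
    duration_min: float,
    frame_interval_min: float = 1.0,
    rng_seed: int | np.random.Generator | None = None,
    initial_length_um: float = 8.0,
    noise_sd_um: float = 0.0,
) -> FilamentTrajectory:
    """Slow constant-speed shrinkage of a stabilized seed.

    The underlying length decreases at ``v_depoly_gmpcpp`` µm/min (clamped
    at 0); optional per-frame Gaussian localization noise of SD
    ``noise_sd_um`` is added on top, emulating tip-position measurement
    scatter at long frame intervals.
    """
    if duration_min <= 0 or frame_interval_min <= 0:
        raise ValueError("duration and frame interval must be positive")
    rng = _as_rng(rng_seed)
    t_min = np.arange(0.0, duration_min + 1e-9, frame_interval_min)
    lengths = np.maximum(initial_length_um - params.v_depoly_gmpcpp * t_min, 0.0)
    if noise_sd_um > 0:
        lengths = np.maximum(lengths + rng.normal(0.0, noise_sd_um, lengths.shape), 0.0)
    phase = SHRINK if params.v_depoly_gmpcpp > 0 else PAUSE
    return FilamentTrajectory(
        times=t_min * 60.0,
        lengths=lengths,
        phases=[phase] * (len(t_min) - 1),
        condition=None,
        origin="gmpcpp_seed",
    )
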