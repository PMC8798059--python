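"""Statistical layer: kinetic regression, Hill fits, event-rate estimation.

* :func:`fit_growth_kinetics` — OLS of mean growth velocity (converted to
  dimers/s) against tubulin concentration: slope = apparent on-rate k_a,
  −intercept = apparent off-rate k_d, critical concentration C_c = k_d/k_a
  with a delta-method standard error from the full fit covariance.
* :func:`fit_nucleation_hill` — nonlinear least squares of the 1-minute
  nucleation fraction against concentration with the Hill endpoints fixed
  at 0 and 1; free parameters are the half-max concentration C and
  steepness s.
* :func:`nucleation_ecdf` — Kaplan–Meier cumulative incidence of
  nucleation honoring right-censored seeds.
* :func:`fit_spontaneous_nucleation` — linear fit of mean per-field counts
  above the zero floor; the x-intercept is the spontaneous critical
  concentration.
* :func:`catastrophe_frequency` — events per total growth time with a
  bootstrap-over-filaments percentile confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .dynamics_model import (
    DEFAULT_GEOMETRY,
    GeometryConstants,
    umpermin_to_dimers_per_s,
)
from .synthetic_data import NucleationRecord
from .trace_analysis import DynamicsSummary

__all__ = [
    "LinearRateFit",
    "HillFit",
    "SpontaneousFit",
    "CatastropheFrequency",
    "fit_growth_kinetics",
    "fit_nucleation_hill",
    "nucleation_ecdf",
    "fit_spontaneous_nucleation",
    "catastrophe_frequency",
    "fold_change",
]


@dataclass(frozen=True)
class LinearRateFit:
    """Result of the growth-kinetics regression v = k_a·c − k_d (dimers/s)."""

    k_a: float
    k_a_se: float
    k_d: float
    k_d_se: float
    C_c: float
    C_c_se: float
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class HillFit:
    """Endpoint-constrained Hill fit p = c^s / (C^s + c^s)."""

    C: float
    C_se: float
    s: float
    s_se: float
    residual_ss: float
    n_points: int

    def __post_init__(self) -> None:
        if self.C <= 0 or self.s <= 0:
            raise ValueError("C and s must be positive")


@dataclass(frozen=True)
class SpontaneousFit:
    """Linear fit of mean per-field counts vs tubulin concentration."""

    slope: float
    slope_se: float
    critical_conc: float
    critical_conc_se: float
    n_points: int


@dataclass(frozen=True)
class CatastropheFrequency:
    """Catastrophe events per minute of growth, with bootstrap 95% CI."""

    frequency: float
    n_events: int
    total_time_min: float
    ci_low: float
    ci_high: float


def _ols_with_cov(x: np.ndarray, y: np.ndarray) -> tuple[float, float, np.ndarray, float]:
    """OLS y = a·x + b; returns (a, b, covariance of (a, b), R²)."""
    n = len(x)
    X = np.column_stack([x, np.ones(n)])
    coef, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 2:
        raise ValueError("singular design: need at least two distinct x values")
    fitted = X @ coef
    sse = float(np.sum((y - fitted) ** 2))
    dof = n - 2
    sigma2 = sse / dof if dof > 0 else 0.0
    cov = sigma2 * np.linalg.inv(X.T @ X)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    return float(coef[0]), float(coef[1]), cov, r2


def _ratio_delta_se(num: float, den: float, var_num: float, var_den: float, cov: float) -> float:
    """Delta-method SE of num/den for correlated (num, den) estimates."""
    r = num / den
    grad_n, grad_d = 1.0 / den, -num / den**2
    var = grad_n**2 * var_num + grad_d**2 * var_den + 2 * grad_n * grad_d * cov
    return float(np.sqrt(max(var, 0.0)))


def fit_growth_kinetics(
    samples_by_conc: dict[float, "np.ndarray | list[float]"],
    geometry: GeometryConstants = DEFAULT_GEOMETRY,
) -> LinearRateFit:
    """Fit k_a, k_d, C_c from growth velocities measured per concentration.

    ``samples_by_conc`` maps tubulin concentration (µM) to growth-velocity
    samples in µm/min.  Per-concentration mean velocities are converted to
    dimers/s and regressed on concentration; C_c = k_d / k_a with a
    delta-method SE using the full (k_a, k_d) covariance.
    """
    concs = np.array(sorted(samples_by_conc))
    if len(np.unique(concs)) < 2:
        raise ValueError("need at least 2 distinct concentrations")
    mean_v = np.array(
        [np.mean(np.asarray(samples_by_conc[c], dtype=float)) for c in concs]
    )
    v_dimers = np.asarray(umpermin_to_dimers_per_s(mean_v, geometry))
    ka, intercept, cov, r2 = _ols_with_cov(concs, v_dimers)
    if ka <= 0:
        raise ValueError("fitted k_a is not positive; data show no growth trend")
    kd = -intercept
    cc = kd / ka
    # C_c = -b/a: gradient (b/a², -1/a) wrt (a, b)
    grad = np.array([intercept / ka**2, -1.0 / ka])
    cc_var = float(grad @ cov @ grad)
    return LinearRateFit(
        k_a=ka,
        k_a_se=float(np.sqrt(max(cov[0, 0], 0.0))),
        k_d=kd,
        k_d_se=float(np.sqrt(max(cov[1, 1], 0.0))),
        C_c=cc,
        C_c_se=float(np.sqrt(max(cc_var, 0.0))),
        r_squared=r2,
        n_points=len(concs),
    )


def _hill(c: np.ndarray, C: float, s: float) -> np.ndarray:
    return c**s / (C**s + c**s)


def fit_nucleation_hill(
    concs: "np.ndarray | list[float]",
    fractions: "np.ndarray | list[float]",
    s_init: float = 3.0,
    s_bounds: tuple[float, float] = (0.5, 20.0),
) -> HillFit:
    """Fit the 1-minute nucleation probability to the constrained Hill law.

    ``fractions`` are per-concentration success fractions (seeds nucleated
    within 60 s / seeds observed).  The fit requires transition coverage:
    at least one fraction below 0.5 and one above, otherwise C is
    unidentifiable and the fit fails with a diagnostic.
    """
    c = np.asarray(concs, dtype=float)
    f = np.asarray(fractions, dtype=float)
    if len(c) < 3:
        raise ValueError("need at least 3 concentrations")
    if not (np.any(f < 0.5) and np.any(f > 0.5)):
        raise ValueError(
            "fractions do not span the transition (need one < 0.5 and one > 0.5); "
            "refusing to extrapolate the half-max concentration"
        )
    C0 = float(c[np.argmin(np.abs(f - 0.5))])
    popt, pcov = curve_fit(
        _hill,
        c,
        f,
        p0=[max(C0, 1e-6), s_init],
        bounds=([1e-12, s_bounds[0]], [np.inf, s_bounds[1]]),
        maxfev=20000,
    )
    resid = f - _hill(c, *popt)
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    return HillFit(
        C=float(popt[0]),
        C_se=float(se[0]),
        s=float(popt[1]),
        s_se=float(se[1]),
        residual_ss=float(np.sum(resid**2)),
        n_points=len(c),
    )


def nucleation_ecdf(
    records: list[NucleationRecord],
) -> tuple[np.ndarray, np.ndarray]:
    """Kaplan–Meier cumulative nucleation probability.

    Returns step-function knots ``(times_s, cum_prob)`` starting at
    (0, 0); right-censored records leave the risk set without an event.
    With no censoring this equals the empirical CDF.
    """
    if not records:
        raise ValueError("need at least one record")
    times = np.array([r.lag_s for r in records])
    events = np.array([not r.censored for r in records])
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    out_t, out_p = [0.0], [0.0]
    surv = 1.0
    n_at_risk = len(times)
    for t in np.unique(times):
        at_t = times == t
        d = int(np.sum(events & at_t))
        if d > 0:
            surv *= 1.0 - d / n_at_risk
            out_t.append(float(t))
            out_p.append(1.0 - surv)
        n_at_risk -= int(np.sum(at_t))
    return np.array(out_t), np.array(out_p)


def fit_spontaneous_nucleation(
    counts_by_conc: dict[float, "np.ndarray | list[int]"],
    zero_floor: float = 0.5,
) -> SpontaneousFit:
    """Linear fit of mean per-field counts vs concentration above the floor.

    Concentrations whose mean count is ≤ ``zero_floor`` (the below-critical
    plateau) are excluded.  The spontaneous critical concentration is the
    x-intercept −intercept/slope, with a delta-method SE.
    """
    concs = np.array(sorted(counts_by_conc))
    if len(concs) < 3:
        raise ValueError("need at least 3 concentrations")
    means = np.array([np.mean(np.asarray(counts_by_conc[c], float)) for c in concs])
    keep = means > zero_floor
    if keep.sum() < 2:
        raise ValueError("fewer than 2 concentrations with counts above the zero floor")
    slope, intercept, cov, _ = _ols_with_cov(concs[keep], means[keep])
    if slope <= 0:
        raise ValueError("non-positive slope: counts do not increase with concentration")
    cc = -intercept / slope
    grad = np.array([intercept / slope**2, -1.0 / slope])
    cc_se = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
    return SpontaneousFit(
        slope=slope,
        slope_se=float(np.sqrt(max(cov[0, 0], 0.0))),
        critical_conc=cc,
        critical_conc_se=cc_se,
        n_points=int(keep.sum()),
    )


def catastrophe_frequency(
    summary: DynamicsSummary,
    n_boot: int = 10_000,
    rng_seed: int | np.random.Generator | None = None,
) -> CatastropheFrequency:
    """Catastrophe frequency = events / total growth time, with 95% CI.

    The CI is a percentile bootstrap resampling whole filaments (the
    exchangeable unit), recomputing the ratio for each resample.
    """
    if summary.total_growth_time_min <= 0:
        raise ValueError("total growth time must be positive")
    freq = summary.n_catastrophes / summary.total_growth_time_min
    per = summary.per_filament
    if not per or n_boot <= 0:
        return CatastropheFrequency(
            freq, summary.n_catastrophes, summary.total_growth_time_min, freq, freq
        )
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    cats = np.array([c for c, _ in per], dtype=float)
    times = np.array([g for _, g in per], dtype=float)
    nf = len(per)
    idx = rng.integers(0, nf, size=(n_boot, nf))
    boot_c = cats[idx].sum(axis=1)
    boot_t = times[idx].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = np.where(boot_t > 0, boot_c / boot_t, np.nan)
    lo, hi = np.nanpercentile(ratios, [2.5, 97.5])
    return CatastropheFrequency(
        frequency=float(freq),
        n_events=summary.n_catastrophes,
        total_time_min=float(summary.total_growth_time_min),
        ci_low=float(lo),
        ci_high=float(hi),
    )


def fold_change(fit_a: LinearRateFit, fit_b: LinearRateFit) -> tuple[float, float]:
    """Ratio k_a(b) / k_a(a) with first-order error propagation."""
    if fit_a.k_a == 0:
        raise ValueError("reference k_a is zero")
    ratio = fit_b.k_a / fit_a.k_a
    se = abs(ratio) * np.sqrt(
        (fit_b.k_a_se / fit_b.k_a) ** 2 + (fit_a.k_a_se / fit_a.k_a) ** 2
    )
    return float(ratio), float(se)
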