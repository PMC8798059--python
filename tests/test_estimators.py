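"""Regression fits, Hill fits, censored ECDFs and event-rate intervals."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtdynamics.dynamics_model import (
    DEFAULT_GEOMETRY,
    dimers_per_s_to_umpermin,
    hill_probability,
)
from mtdynamics.estimators import (
    catastrophe_frequency,
    fit_growth_kinetics,
    fit_nucleation_hill,
    fit_spontaneous_nucleation,
    fold_change,
    nucleation_ecdf,
)
from mtdynamics.synthetic_data import NucleationRecord
from mtdynamics.trace_analysis import DynamicsSummary


def velocities_from_law(k_a, C_c, concs):
    """Noiseless µm/min velocities from v = k_a(c − C_c) in dimers/s."""
    return {
        c: [float(dimers_per_s_to_umpermin(k_a * (c - C_c)))] for c in concs
    }


class TestGrowthKinetics:
    def test_control_law_recovered_exactly(self):
        fit = fit_growth_kinetics(velocities_from_law(2.6, 2.89, [5.0, 10.0, 14.0]))
        assert fit.k_a == pytest.approx(2.6, rel=1e-9)
        assert fit.C_c == pytest.approx(2.89, rel=1e-9)
        assert fit.k_d == pytest.approx(2.6 * 2.89, rel=1e-9)
        assert fit.C_c == pytest.approx(fit.k_d / fit.k_a, rel=1e-12)

    def test_ckap2_law_recovered_exactly(self):
        fit = fit_growth_kinetics(
            velocities_from_law(142.0, 0.02, [0.05, 0.1, 0.2, 0.3])
        )
        assert fit.k_a == pytest.approx(142.0, rel=1e-9)
        assert fit.C_c == pytest.approx(0.02, rel=1e-9)

    def test_two_points_on_identity_line(self):
        # y = x in dimers/s units
        samples = {
            1.0: [float(dimers_per_s_to_umpermin(1.0))],
            2.0: [float(dimers_per_s_to_umpermin(2.0))],
        }
        fit = fit_growth_kinetics(samples)
        assert fit.k_a == pytest.approx(1.0, rel=1e-9)
        assert fit.k_d == pytest.approx(0.0, abs=1e-9)

    @given(
        concs=st.lists(
            st.floats(0.1, 50), min_size=3, max_size=8, unique=True
        ),
        k_a=st.floats(0.5, 200),
        cc=st.floats(0.01, 5),
        noise=st.lists(st.floats(-0.05, 0.05), min_size=8, max_size=8),
    )
    @settings(max_examples=40, derandomize=True)
    def test_matches_normal_equations_oracle(self, concs, k_a, cc, noise):
        samples = {
            c: [
                float(dimers_per_s_to_umpermin(k_a * (c - cc))) * (1 + e)
            ]
            for c, e in zip(concs, noise)
        }
        fit = fit_growth_kinetics(samples)
        # independent closed-form solution of the normal equations
        x = np.array(sorted(samples))
        y = np.array(
            [samples[c][0] * DEFAULT_GEOMETRY.dimers_per_um / 60.0 for c in x]
        )
        n = len(x)
        det = n * np.sum(x**2) - np.sum(x) ** 2
        slope = (n * np.sum(x * y) - np.sum(x) * np.sum(y)) / det
        intercept = (np.sum(y) - slope * np.sum(x)) / n
        if slope <= 0:
            return
        assert fit.k_a == pytest.approx(slope, rel=1e-9)
        assert fit.k_d == pytest.approx(-intercept, rel=1e-9, abs=1e-9)

    def test_singular_design_rejected(self):
        with pytest.raises(ValueError):
            fit_growth_kinetics({3.0: [1.0]})


class TestNucleationHill:
    @pytest.mark.parametrize(
        "C,s,concs",
        [
            (6.85, 3.37, [2, 4, 6, 8, 10, 12, 16, 20]),
            (0.05, 3.10, [0.01, 0.02, 0.035, 0.05, 0.075, 0.1, 0.15, 0.2]),
        ],
    )
    def test_noiseless_recovery(self, C, s, concs):
        fracs = [float(hill_probability(c, C, s)) for c in concs]
        fit = fit_nucleation_hill(concs, fracs)
        assert fit.C == pytest.approx(C, rel=1e-6)
        assert fit.s == pytest.approx(s, rel=1e-6)

    def test_no_transition_coverage_fails_with_diagnostic(self):
        with pytest.raises(ValueError, match="transition"):
            fit_nucleation_hill([1, 2, 3], [0.9, 0.95, 0.99])

    def test_degenerate_constant_half_fails(self):
        with pytest.raises(ValueError):
            fit_nucleation_hill([5, 5, 5], [0.5, 0.5, 0.5])


class TestNucleationEcdf:
    def test_uncensored_is_empirical_cdf(self):
        recs = [NucleationRecord(i, t) for i, t in enumerate([10.0, 20.0, 30.0])]
        t, p = nucleation_ecdf(recs)
        # at t = 20 s two of three have nucleated
        assert p[np.searchsorted(t, 20.0, side="right") - 1] == pytest.approx(2 / 3)

    def test_all_censored_identically_zero(self):
        recs = [NucleationRecord(i, 60.0, censored=True) for i in range(5)]
        t, p = nucleation_ecdf(recs)
        assert np.all(p == 0.0)

    def test_order_invariance_and_monotonicity(self, rng):
        lags = rng.exponential(30.0, 50)
        recs = [
            NucleationRecord(i, float(l), censored=l > 60.0) for i, l in enumerate(lags)
        ]
        t1, p1 = nucleation_ecdf(recs)
        t2, p2 = nucleation_ecdf(list(reversed(recs)))
        np.testing.assert_allclose(t1, t2)
        np.testing.assert_allclose(p1, p2)
        assert np.all(np.diff(p1) >= 0)
        assert p1.min() >= 0 and p1.max() <= 1

    def test_matches_exponential_cdf_within_dkw(self, rng):
        lam = 1 / 40.0
        lags = rng.exponential(1 / lam, 10_000)
        recs = [NucleationRecord(i, float(l)) for i, l in enumerate(lags)]
        t, p = nucleation_ecdf(recs)
        dkw = np.sqrt(np.log(2 / 0.05) / (2 * len(lags)))
        truth = 1 - np.exp(-lam * t)
        assert np.max(np.abs(p - truth)) < dkw

    def test_censoring_matches_kaplan_meier_reference(self, rng):
        lifelines = pytest.importorskip("lifelines")
        lags = rng.exponential(50.0, 300)
        censored = lags > 80.0
        obs = np.where(censored, 80.0, lags)
        recs = [
            NucleationRecord(i, float(o), censored=bool(c))
            for i, (o, c) in enumerate(zip(obs, censored))
        ]
        t, p = nucleation_ecdf(recs)
        km = lifelines.KaplanMeierFitter().fit(obs, ~censored)
        for ti, pi in zip(t[1:], p[1:]):
            assert pi == pytest.approx(
                1 - float(km.survival_function_at_times(ti).iloc[0]), abs=1e-9
            )


class TestSpontaneousFit:
    def test_control_critical_concentration(self):
        counts = {c: [2.0 * (c - 25.4)] for c in [26, 30, 35, 40, 45, 50]}
        fit = fit_spontaneous_nucleation(counts)
        assert fit.critical_conc == pytest.approx(25.4, rel=1e-9)

    def test_ckap2_critical_concentration(self):
        counts = {c: [100.0 * (c - 0.25)] for c in [0.3, 0.35, 0.4, 0.45, 0.5]}
        fit = fit_spontaneous_nucleation(counts)
        assert fit.critical_conc == pytest.approx(0.25, rel=1e-9)

    def test_below_critical_plateau_excluded(self):
        counts = {c: [max(0.0, 2.0 * (c - 25.4))] for c in [20, 22, 24, 30, 40, 50]}
        fit = fit_spontaneous_nucleation(counts)
        assert fit.critical_conc == pytest.approx(25.4, rel=1e-9)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            fit_spontaneous_nucleation({10: [0], 20: [0], 30: [0]})


class TestCatastropheFrequency:
    def test_ratio_of_totals(self):
        s = DynamicsSummary([], 26, 100.0, per_filament=[(26, 100.0)])
        f = catastrophe_frequency(s, n_boot=100, rng_seed=0)
        assert f.frequency == pytest.approx(0.26)

    def test_zero_events(self):
        s = DynamicsSummary([], 0, 50.0, per_filament=[(0, 25.0), (0, 25.0)])
        f = catastrophe_frequency(s, n_boot=1000, rng_seed=0)
        assert f.frequency == 0.0
        assert f.ci_low == 0.0

    def test_ci_brackets_point_estimate(self, rng):
        per = [(int(rng.poisson(2)), float(rng.uniform(5, 15))) for _ in range(100)]
        s = DynamicsSummary(
            [], sum(c for c, _ in per), sum(t for _, t in per), per_filament=per
        )
        f = catastrophe_frequency(s, n_boot=2000, rng_seed=1)
        assert f.ci_low <= f.frequency <= f.ci_high


class TestFoldChange:
    def _fit(self, k_a, se):
        from mtdynamics.estimators import LinearRateFit

        return LinearRateFit(k_a, se, 1.0, 0.1, 1.0 / k_a, 0.01, 0.99, 3)

    def test_identical_fits_unity(self):
        f = self._fit(2.6, 0.06)
        assert fold_change(f, f)[0] == pytest.approx(1.0)

    def test_ckap2_fold_increase(self):
        ratio, _ = fold_change(self._fit(2.6, 0.06), self._fit(142.0, 3.3))
        assert ratio == pytest.approx(54.6, abs=0.1)

    def test_se_matches_monte_carlo(self, rng):
        a, sa = 2.6, 0.06
        b, sb = 142.0, 3.3
        _, se = fold_change(self._fit(a, sa), self._fit(b, sb))
        draws = rng.normal(b, sb, 100_000) / rng.normal(a, sa, 100_000)
        assert se == pytest.approx(draws.std(ddof=1), rel=0.05)
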