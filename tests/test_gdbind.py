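"""Equilibrium dialysis, Job stoichiometry, and XO displacement solvers."""

import numpy as np
import pytest

from gdtandem.gdbind import (
    DataInconsistencyError,
    DialysisSetup,
    JobExperiment,
    NoBindingError,
    complex_1to1,
    estimate_mkd,
    find_job_maximum,
    geometric_mean_kd,
    job_curve,
    solve_dialysis_equilibrium,
    xo_displacement_titration,
)

# the equimolar per-site dialysis scenario used throughout
SCENARIO = dict(site_total=492.6, gd_total=492.6, v_in=2.0, v_out=2.0)


def bisection_oracle(setup: DialysisSetup, iters: int = 200) -> float:
    """Independent bisection on the monotone mass-balance residual."""
    S, G, kd = setup.site_total, setup.gd_total, setup.kd
    v_in, v_tot = setup.v_in, setup.v_in + setup.v_out

    def residual(g):
        return S * g / (kd + g) * v_in + g * v_tot - G * v_in

    lo, hi = 0.0, G * v_in / v_tot
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if residual(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


class TestDialysisEquilibrium:
    def test_infinite_affinity_limit(self):
        state = solve_dialysis_equilibrium(DialysisSetup(100.0, 50.0, 0.0))
        assert state.gd_free == 0.0
        assert state.complex == pytest.approx(50.0)

    def test_no_binding_limit(self):
        setup = DialysisSetup(**SCENARIO, kd=1e12)
        state = solve_dialysis_equilibrium(setup)
        assert state.complex == pytest.approx(0.0, abs=1e-3)
        # free Gd dilutes into both chambers
        assert state.gd_free == pytest.approx(492.6 * 2 / 4, rel=1e-3)

    def test_matches_bisection_oracle(self):
        setup = DialysisSetup(**SCENARIO, kd=0.21)
        state = solve_dialysis_equilibrium(setup)
        assert state.gd_free == pytest.approx(bisection_oracle(setup), abs=1e-6)

    @pytest.mark.parametrize("kd", [0.05, 0.21, 1.0, 10.0])
    def test_mass_balance_and_isotherm(self, kd):
        setup = DialysisSetup(**SCENARIO, kd=kd)
        s = solve_dialysis_equilibrium(setup)
        assert min(s.mbs_free, s.gd_free, s.complex) >= 0
        assert s.complex + s.mbs_free == pytest.approx(setup.site_total, rel=1e-9)
        assert s.complex * setup.v_in + s.gd_free * (
            setup.v_in + setup.v_out
        ) == pytest.approx(setup.gd_total * setup.v_in, rel=1e-9)
        assert s.mbs_free * s.gd_free / s.complex == pytest.approx(kd, rel=1e-6)


class TestEstimateMkd:
    def test_round_trip_random_setups(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            setup = DialysisSetup(
                site_total=float(rng.uniform(10, 1000)),
                gd_total=float(rng.uniform(10, 1000)),
                kd=float(10 ** rng.uniform(-2, 1.5)),
                v_in=float(rng.uniform(0.5, 5)),
                v_out=float(rng.uniform(0.5, 5)),
            )
            state = solve_dialysis_equilibrium(setup)
            est = estimate_mkd(
                state.gd_free, setup.site_total, setup.gd_total,
                setup.v_in, setup.v_out,
            )
            assert est == pytest.approx(setup.kd, rel=1e-6)

    def test_noisy_replicates_recover_scenario_kd(self):
        """Three 2%-noise replicates at the measured affinity, 1000 reps."""
        setup = DialysisSetup(**SCENARIO, kd=0.21)
        truth = solve_dialysis_equilibrium(setup).gd_free
        rng = np.random.default_rng(7)
        estimates = []
        for _ in range(1000):
            noisy = truth * (1 + 0.02 * rng.standard_normal(3))
            reps = [
                estimate_mkd(g, setup.site_total, setup.gd_total, 2.0, 2.0)
                for g in noisy
            ]
            estimates.append(geometric_mean_kd(reps))
        assert np.median(estimates) == pytest.approx(0.21, rel=0.10)

    def test_free_equal_to_dilution_means_no_binding(self):
        with pytest.raises(NoBindingError):
            estimate_mkd(492.6 * 2 / 4, 492.6, 492.6, 2.0, 2.0)

    def test_impossible_measurement_rejected(self):
        with pytest.raises(DataInconsistencyError):
            estimate_mkd(400.0, 492.6, 492.6, 2.0, 2.0)

    def test_geometric_mean(self):
        assert geometric_mean_kd([1.0, 100.0]) == pytest.approx(10.0)
        with pytest.raises(ValueError):
            geometric_mean_kd([])


class TestJobPlot:
    GRID = tuple(np.round(np.linspace(0.0, 1.0, 101), 10))

    def test_maximum_at_half_for_1to1(self):
        exp = JobExperiment(c_total=50.0, kd=0.2, x_grid=self.GRID)
        assert find_job_maximum(exp) == pytest.approx(0.5, abs=0.01)

    def test_weak_binding_closed_form(self):
        """Kd >> c_total: complex ~ P*L/Kd, proportional to x(1-x)."""
        exp = JobExperiment(c_total=1.0, kd=1e5, x_grid=self.GRID)
        curve = job_curve(exp)
        xs = np.asarray(self.GRID)
        expected = xs * (1 - xs) * exp.c_total**2 / exp.kd
        assert np.allclose(curve, expected, rtol=1e-3)
        assert find_job_maximum(exp) == pytest.approx(0.5, abs=1e-6)

    def test_curve_symmetric_under_reflection(self):
        exp = JobExperiment(c_total=50.0, kd=0.2, x_grid=self.GRID)
        curve = job_curve(exp)
        assert np.allclose(curve, curve[::-1], rtol=1e-9)

    @pytest.mark.parametrize("n_sites", [1, 2, 3, 4])
    def test_per_molecule_maximum_at_n_over_n_plus_1(self, n_sites):
        """Against an n-site protein counted per molecule, the peak moves to
        n/(n+1); brute-force grid search over the per-site equilibrium."""
        c_total, kd = 50.0, 0.05
        xs = np.linspace(0.005, 0.995, 991)
        bound = [
            complex_1to1(n_sites * (1 - x) * c_total, x * c_total, kd) for x in xs
        ]
        x_star = xs[int(np.argmax(bound))]
        assert x_star == pytest.approx(n_sites / (n_sites + 1), abs=0.01)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError, match="3 grid points"):
            find_job_maximum(JobExperiment(50.0, 0.2, (0.0, 1.0)))


class TestXoDisplacement:
    def test_zero_protein_equals_binary_equilibrium(self):
        signal = xo_displacement_titration(25.0, 25.0, 1.0, 0.1, [0.0])
        assert signal[0] == pytest.approx(complex_1to1(25.0, 25.0, 1.0), rel=1e-9)

    def test_complete_displacement_limit(self):
        signal = xo_displacement_titration(25.0, 25.0, 1.0, 1e-6, [1e6])
        assert signal[0] == pytest.approx(0.0, abs=1e-3)

    def test_monotone_nonincreasing_in_protein(self):
        grid = np.linspace(0, 200, 41)
        signal = xo_displacement_titration(25.0, 25.0, 1.0, 0.1, grid)
        assert np.all(np.diff(signal) <= 1e-12)

    def test_half_displacement_tracks_affinity_ratio(self):
        """Stronger competitor (lower Kd) halves the XO signal at lower
        protein concentration; grid-solver oracle on the 3-species system."""
        grid = np.linspace(0.0, 400.0, 801)

        def half_point(kd_protein):
            signal = xo_displacement_titration(25.0, 25.0, 1.0, kd_protein, grid)
            target = signal[0] / 2
            return grid[int(np.argmin(np.abs(signal - target)))]

        assert half_point(0.01) < half_point(1.0) < half_point(100.0)

    def test_mass_conservation(self):
        gd_total, xo_total = 30.0, 20.0
        for p in (0.0, 10.0, 50.0):
            g = xo_displacement_titration(gd_total, xo_total, 2.0, 0.5, [p])[0]
            # reconstruct species from the returned Gd-XO complex
            gd_free_grid = np.linspace(0, gd_total, 2_000_001)
            # independent fine-grid solution
            resid = (
                gd_free_grid
                + xo_total * gd_free_grid / (2.0 + gd_free_grid)
                + p * gd_free_grid / (0.5 + gd_free_grid)
                - gd_total
            )
            g_free = gd_free_grid[int(np.argmin(np.abs(resid)))]
            assert g == pytest.approx(xo_total * g_free / (2.0 + g_free), abs=1e-3)
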