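import math

import numpy as np
import pytest

from clonesim import (
    CloneSizeTable,
    CSCParams,
    GrowthParams,
    beta,
    csc_init,
    csc_tau_leap_grow,
    deterministic_grow,
    doubling_time,
    doubling_time_scan,
    tau_leap_grow,
)
from clonesim.growth import poisson_field

from .conftest import exact_ssa_birth


class TestDeterministic:
    def test_zero_rate_is_identity(self, small_table):
        out = deterministic_grow(small_table, 0.0, 5.0)
        assert np.allclose(out.sizes, small_table.sizes)

    def test_doubling_in_19_hours(self):
        r = 24.0 / 19.0 * math.log(2.0)  # per day
        t = CloneSizeTable(["a"], [100])
        out = deterministic_grow(t, r, 19.0 / 24.0)
        assert out.sizes[0] == pytest.approx(200.0)

    def test_three_day_growth_closed_form(self):
        r = 24.0 / 19.0 * math.log(2.0)
        t = CloneSizeTable(["a"], [300_000])
        out = deterministic_grow(t, r, 3.0)
        assert out.sizes[0] == pytest.approx(300_000 * 2 ** (72.0 / 19.0), rel=1e-12)

    def test_frequencies_invariant(self, rng):
        sizes = rng.integers(1, 100, size=30)
        t = CloneSizeTable([f"b{i}" for i in range(30)], sizes)
        out = deterministic_grow(t, 0.7, 2.3)
        assert np.allclose(out.sizes / out.n, sizes / sizes.sum())

    def test_negative_duration_errors(self, small_table):
        with pytest.raises(ValueError):
            deterministic_grow(small_table, 1.0, -1.0)


class TestPoissonField:
    def test_sparse_and_dense_have_matching_moments(self):
        # the superposition path must be distributionally identical to the
        # elementwise path; check mean/variance on a fixed intensity vector
        lam = np.array([0.002, 0.01, 0.05, 0.0, 0.003] * 40)
        rng = np.random.default_rng(5)
        draws = np.array([poisson_field(rng, lam) for _ in range(20_000)])
        mean = draws.mean(axis=0)
        se = np.sqrt(lam / draws.shape[0])
        assert np.all(np.abs(mean - lam) <= 4 * se + 1e-9)
        assert np.all(draws[:, 3] == 0)

    def test_zero_lam(self, rng):
        assert np.all(poisson_field(rng, np.zeros(5)) == 0)


class TestTauLeap:
    def test_extinct_clone_is_absorbing(self, rng):
        t = CloneSizeTable(list("ab"), [0, 10])
        grown, _ = tau_leap_grow(t, GrowthParams(n_crit=200, tau=0.01), rng)
        assert grown.sizes[0] == 0

    def test_no_leaps_if_already_critical(self, rng):
        t = CloneSizeTable(["a"], [100])
        grown, elapsed = tau_leap_grow(t, GrowthParams(n_crit=50), rng)
        assert elapsed == 0.0
        assert grown.sizes[0] == 100

    def test_empty_population_errors(self, rng):
        t = CloneSizeTable(["a"], [0])
        with pytest.raises(ValueError):
            tau_leap_grow(t, GrowthParams(n_crit=10), rng)

    def test_growth_never_shrinks(self, rng):
        t = CloneSizeTable(list("abc"), [5, 7, 9])
        grown, _ = tau_leap_grow(t, GrowthParams(n_crit=100, tau=0.01), rng)
        assert np.all(grown.sizes >= t.sizes)

    def test_mean_matches_exponential_growth(self):
        # one clone of 1000 cells grown for 1 day at r=1: E[n] = 1000 * e
        n0, r, reps = 1000, 1.0, 200
        finals = []
        for s in range(reps):
            rng = np.random.default_rng(s)
            t = CloneSizeTable(["a"], [n0])
            grown, _ = tau_leap_grow(
                t, GrowthParams(r=r, tau=0.0005, n_crit=10**9), rng, t_max=1.0
            )
            finals.append(grown.sizes[0])
        finals = np.array(finals, dtype=float)
        expected = n0 * math.e
        se = finals.std(ddof=1) / math.sqrt(reps)
        assert abs(finals.mean() - expected) < 3 * se

    def test_mean_trajectory_matches_exact_ssa(self):
        # tau-leap vs direct-method oracle on a small population
        n0, r, t_end, reps = 200, 1.0, 0.5, 300
        leap_finals, ssa_finals = [], []
        for s in range(reps):
            rng = np.random.default_rng(1000 + s)
            t = CloneSizeTable(list("abcd"), [n0 // 4] * 4)
            grown, _ = tau_leap_grow(
                t, GrowthParams(r=r, tau=0.001, n_crit=10**9), rng, t_max=t_end
            )
            leap_finals.append(grown.n)
            rng2 = np.random.default_rng(5000 + s)
            ssa_finals.append(
                exact_ssa_birth([n0 // 4] * 4, r, t_end, rng2).sum()
            )
        leap_finals = np.array(leap_finals, dtype=float)
        ssa_finals = np.array(ssa_finals, dtype=float)
        se = math.sqrt(
            leap_finals.var(ddof=1) / reps + ssa_finals.var(ddof=1) / reps
        )
        assert abs(leap_finals.mean() - ssa_finals.mean()) < 3 * se

    def test_tau_sensitivity(self):
        # quartering the leap step must not change the mean growth (the
        # leap approximation is insensitive to tau in this regime)
        means = {}
        for tau in (0.002, 0.0005):
            finals = []
            for s in range(150):
                t = CloneSizeTable(["a"], [500])
                grown, _ = tau_leap_grow(
                    t, GrowthParams(r=1.0, tau=tau, n_crit=10**9),
                    np.random.default_rng(s), t_max=1.0,
                )
                finals.append(grown.n)
            means[tau] = (np.mean(finals), np.std(finals, ddof=1) / math.sqrt(150))
        diff = abs(means[0.002][0] - means[0.0005][0])
        se = math.hypot(means[0.002][1], means[0.0005][1])
        assert diff < 3 * se

    def test_reproducible_bit_for_bit(self):
        t = CloneSizeTable(list("ab"), [50, 50])
        a, ea = tau_leap_grow(t, GrowthParams(n_crit=500, tau=0.01), np.random.default_rng(9))
        b, eb = tau_leap_grow(t, GrowthParams(n_crit=500, tau=0.01), np.random.default_rng(9))
        assert np.array_equal(a.sizes, b.sizes)
        assert ea == eb


class TestBeta:
    def test_growth_regime(self):
        b, regime = beta(CSCParams(p1=0.5, p2=0.5, p3=0.0, r_csc=1.0))
        assert b == pytest.approx(0.5)
        assert regime == "growth"

    def test_equilibrium(self):
        b, regime = beta(CSCParams(p1=0.25, p2=0.5, p3=0.25))
        assert b == 0.0
        assert regime == "equilibrium"

    def test_extinction(self):
        b, regime = beta(CSCParams(p1=0.0, p2=0.5, p3=0.5, r_csc=1.0))
        assert b == pytest.approx(-0.5)
        assert regime == "extinction"


class TestCSCInit:
    def test_all_stem_cells(self, rng):
        t = CloneSizeTable(list("ab"), [10, 20])
        state = csc_init(t, CSCParams(csc0=1.0), rng)
        assert np.array_equal(state.counts[:, 0], [10, 20])
        assert state.counts[:, 1:].sum() == 0

    def test_rounding_arithmetic(self, rng):
        # N=100, csc0=0.05, M=10: 5 stem cells; 95 remaining spread over the
        # 11 age classes -> 8 each (88), 7 left over placed at random; the
        # clone total is preserved exactly
        t = CloneSizeTable(["a"], [100])
        state = csc_init(t, CSCParams(csc0=0.05, M=10), rng)
        assert state.counts[0, 0] == 5
        assert np.all(state.counts[0, 1:] >= 8)
        assert state.counts.sum() == 100

    def test_totals_preserved(self, rng):
        sizes = rng.integers(1, 50, size=100)
        t = CloneSizeTable([f"b{i}" for i in range(100)], sizes)
        state = csc_init(t, CSCParams(), rng)
        assert np.array_equal(state.clone_sizes, sizes)

    def test_sigma_r_zero_gives_unit_multipliers(self, rng):
        t = CloneSizeTable(list("ab"), [10, 10])
        state = csc_init(t, CSCParams(sigma_r=0.0), rng)
        assert np.all(state.x == 1.0)

    def test_sigma_r_multipliers_clamped(self):
        rng = np.random.default_rng(3)
        t = CloneSizeTable([f"b{i}" for i in range(2000)], [5] * 2000)
        state = csc_init(t, CSCParams(sigma_r=2.0), rng)
        assert np.all(state.x >= 0.0)
        assert state.x.std() > 0


class TestCSCGrowth:
    def test_pure_stem_matches_birth_process(self):
        # p1=1, p3=0, no initial DCs: only self-renewal fires, which is the
        # plain birth process at rate r_csc; compare mean growth
        params = CSCParams(p1=1.0, p2=0.0, p3=0.0, csc0=1.0, r_csc=1.0)
        reps = 150
        csc_finals, leap_finals = [], []
        for s in range(reps):
            rng = np.random.default_rng(s)
            t = CloneSizeTable(["a"], [500])
            state = csc_init(t, params, rng)
            grown, _, extinct = csc_tau_leap_grow(
                state, params, 0.001, 10**9, rng, t_max=1.0
            )
            assert not extinct
            csc_finals.append(grown.total)
            rng2 = np.random.default_rng(10_000 + s)
            g2, _ = tau_leap_grow(
                t, GrowthParams(r=1.0, tau=0.001, n_crit=10**9), rng2, t_max=1.0
            )
            leap_finals.append(g2.n)
        csc_finals = np.array(csc_finals, dtype=float)
        leap_finals = np.array(leap_finals, dtype=float)
        se = math.sqrt(
            csc_finals.var(ddof=1) / reps + leap_finals.var(ddof=1) / reps
        )
        assert abs(csc_finals.mean() - leap_finals.mean()) < 3 * se

    def test_no_stem_cells_means_extinction(self, rng):
        params = CSCParams(csc0=0.0, M=3)
        t = CloneSizeTable(list("ab"), [50, 50])
        state = csc_init(t, params, rng)
        grown, elapsed, extinct = csc_tau_leap_grow(
            state, params, 0.001, 10**9, rng
        )
        assert extinct
        assert grown.total == 0

    def test_long_run_csc_fraction_independent_of_csc0(self):
        fracs = []
        for csc0 in (0.05, 0.5):
            params = CSCParams(csc0=csc0)
            rng = np.random.default_rng(77)
            t = CloneSizeTable(["a"], [500])
            state = csc_init(t, params, rng)
            grown, _, _ = csc_tau_leap_grow(state, params, 0.001, 2_000_000, rng)
            fracs.append(grown.csc_fraction)
        assert abs(fracs[0] - fracs[1]) < 0.005

    def test_reproducible(self):
        params = CSCParams()
        t = CloneSizeTable(list("ab"), [100, 100])
        outs = []
        for _ in range(2):
            rng = np.random.default_rng(4)
            state = csc_init(t, params, rng)
            grown, elapsed, _ = csc_tau_leap_grow(state, params, 0.001, 2000, rng)
            outs.append((grown.counts.copy(), elapsed))
        assert np.array_equal(outs[0][0], outs[1][0])
        assert outs[0][1] == outs[1][1]


class TestDoublingTime:
    def test_exact_doubling(self):
        assert doubling_time(100, 200, 7.0) == pytest.approx(7.0)

    def test_growth_phase_value(self):
        assert doubling_time(3e5, 4e6, 71.0) == pytest.approx(
            71.0 * math.log(2) / math.log(40.0 / 3.0)
        )
        assert doubling_time(3e5, 4e6, 71.0) == pytest.approx(19.0, abs=0.05)

    def test_no_growth_errors(self):
        with pytest.raises(ValueError):
            doubling_time(100, 100, 1.0)
        with pytest.raises(ValueError):
            doubling_time(100, 50, 1.0)


class TestDoublingTimeScan:
    def test_single_point_matches_direct_call(self, rng):
        params = CSCParams()
        t = CloneSizeTable([f"b{i}" for i in range(50)], [20] * 50)
        rng_a = np.random.default_rng(8)
        grid = doubling_time_scan(
            [10], [24.0 / 19.0], params, t, 10_000, 0.001, 1, rng_a, 19.0
        )
        rng_b = np.random.default_rng(8)
        state = csc_init(t, params, rng_b)
        grown, elapsed, _ = csc_tau_leap_grow(state, params, 0.001, 10_000, rng_b)
        direct = doubling_time(1000, grown.total, elapsed * 24.0)
        assert grid[0, 0] == pytest.approx(direct - 19.0)

    def test_extinct_points_are_missing(self, rng):
        # no stem cells and beta<0 guarantees extinction before n_crit
        params = CSCParams(p1=0.0, p2=0.5, p3=0.5, csc0=0.0, M=2)
        t = CloneSizeTable(["a"], [100])
        grid = doubling_time_scan([2], [1.0], params, t, 10**6, 0.001, 1, rng)
        assert np.isnan(grid[0, 0])

    def test_deviation_varies_along_r_dc(self, rng):
        # faster differentiated division shortens the doubling time
        params = CSCParams()
        t = CloneSizeTable([f"b{i}" for i in range(100)], [20] * 100)
        grid = doubling_time_scan(
            [10], [0.8, 1.26, 2.0], params, t, 30_000, 0.001, 2, rng
        )
        assert grid[0, 0] > grid[0, 1] > grid[0, 2]
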