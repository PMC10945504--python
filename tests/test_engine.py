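"""KMC engine: stochastic law oracles, determinism, state invariants."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from mtgrowth import (
    CALIBRATED_PARAMS,
    GDP,
    ILLUSTRATIVE_PARAMS,
    INTERFACE_ACTING,
    SELF_ACTING,
    KineticParams,
    LatticeConfig,
    SimProtocol,
    Simulation,
    SolutionState,
    Trace,
    estimate_growth_rate,
    run_protocol,
    scan,
    simulate_trace,
)


def one_pf_params(kd_long: float) -> KineticParams:
    weaken = 3500.0
    return KineticParams(
        kon_plus=1.0,
        kon_minus=1.0,
        kd_long=kd_long,
        kd_corner=kd_long / 10,
        kd_long_gdp=kd_long * weaken,
        kd_corner_gdp=kd_long / 10 * weaken,
    )


class TestStochasticLaws:
    def test_association_only_counts_are_poisson(self):
        """1 PF with dissociation disabled: events ~ Poisson(kon * C * T)."""
        cfg = LatticeConfig(n_protofilaments=1, polarity="plus")
        sol = SolutionState(tubulin_total=2.0)
        p = one_pf_params(kd_long=1e-12)  # koff ~ 0
        T = 50.0
        counts = []
        for seed in range(40):
            sim = Simulation(cfg, p, sol, rng=seed)
            sim.run(T)
            counts.append(sim.n_events["association"])
        lam = 2.0 * T
        mean_ci = 3 * math.sqrt(lam / len(counts))
        assert abs(np.mean(counts) - lam) < mean_ci

    def test_one_pf_growth_matches_birth_death_closed_form(self):
        """v = kon (C - K_D) dimers/s for a single protofilament."""
        cfg = LatticeConfig(n_protofilaments=1, polarity="plus")
        sol = SolutionState(tubulin_total=1.0)
        p = one_pf_params(kd_long=0.5)
        rates = [
            estimate_growth_rate(simulate_trace(cfg, p, sol, 300.0, seed=s))
            for s in range(25)
        ]
        # expected 0.5 dimers/s * 8 nm; allow 3 sigma of the replicate mean
        se = np.std(rates, ddof=1) / math.sqrt(len(rates))
        assert abs(np.mean(rates) - 4.0) < max(3 * se, 0.3)

    def test_blunt_end_initial_total_rate_is_hand_sum(self, cpp_solution):
        """Blunt 13-PF all-strong lattice: R = 13 kon C + sum of tip off-rates."""
        cfg = LatticeConfig(polarity="plus")
        p = CALIBRATED_PARAMS
        sim = Simulation(cfg, p, cpp_solution, rng=0)
        # every blunt tip has two full lateral bonds except the seam pair;
        # recompute independently from the koff table
        expected = 0.0
        for pf in range(13):
            expected += p.kon_plus * cpp_solution.tubulin_total
            if pf == 12:
                # plus-end seam tip: both half-partners sit 1-2 rows above
                # the blunt surface (unoccupied); only the full neighbor bonds
                b = 1.0
            else:
                # pf 0's half-partners sit 1-2 rows below (occupied): 2 bonds
                b = 2.0
            expected += p.kon_plus * p.kd_corner * (p.kd_corner / p.kd_long) ** (b - 1)
        assert sim.total_rate() == pytest.approx(expected, rel=1e-12)


class TestDeterminism:
    def test_same_seed_same_trace(self, plus_config, calibrated_params, cpp_solution):
        t1 = simulate_trace(plus_config, calibrated_params, cpp_solution, 60.0, seed=42)
        t2 = simulate_trace(plus_config, calibrated_params, cpp_solution, 60.0, seed=42)
        assert np.array_equal(t1.mean_length_nm, t2.mean_length_nm)

    def test_same_base_seed_same_result(self, plus_config, calibrated_params, cpp_solution):
        proto = SimProtocol(duration=30.0, n_replicates=3, base_seed=9)
        r1 = run_protocol(plus_config, calibrated_params, cpp_solution, proto)
        r2 = run_protocol(plus_config, calibrated_params, cpp_solution, proto)
        assert np.array_equal(r1.rates, r2.rates)

    def test_step_and_run_consume_identical_streams(
        self, plus_config, calibrated_params, cpp_solution
    ):
        """step() and the optimized run() loop realize the same trajectory."""
        sim_a = Simulation(plus_config, calibrated_params, cpp_solution, rng=5)
        sim_a.run(20.0)
        sim_b = Simulation(plus_config, calibrated_params, cpp_solution, rng=5)
        while sim_b.time < 20.0:
            ev, dt = sim_b.step()
            if ev is None:
                break
        # sim_b overshoots by one event at most; compare event counts loosely
        n_a = sum(sim_a.n_events.values())
        n_b = sum(sim_b.n_events.values())
        assert abs(n_a - n_b) <= 1
        assert sim_a.heights() == sim_b.heights() or abs(n_a - n_b) == 1


class TestStateInvariants:
    def test_zero_tubulin_is_monotone_non_increasing(self, plus_config, calibrated_params):
        sol = SolutionState(tubulin_total=0.0)
        tr = simulate_trace(plus_config, calibrated_params, sol, 120.0, seed=1)
        assert np.all(np.diff(tr.mean_length_nm) <= 1e-12)

    def test_stall_signal_when_no_events_possible(self):
        cfg = LatticeConfig(n_protofilaments=1, seed_rows=1, polarity="plus")
        sol = SolutionState(tubulin_total=0.0)
        sim = Simulation(cfg, CALIBRATED_PARAMS, sol, rng=0)
        event, dt = sim.step()
        assert event is None and math.isinf(dt)

    def test_stalled_trace_still_reaches_duration(self):
        cfg = LatticeConfig(n_protofilaments=1, seed_rows=1, polarity="plus")
        sol = SolutionState(tubulin_total=0.0)
        tr = simulate_trace(cfg, CALIBRATED_PARAMS, sol, 10.0, seed=0)
        assert tr.times[-1] == 10.0
        assert np.all(tr.mean_length_nm == 0.0)

    def test_columns_never_empty_and_contiguous(self, plus_config):
        sol = SolutionState(tubulin_total=0.05, frac_gdp_tubulin=0.5, free_frac_gdp=0.5)
        p = replace(CALIBRATED_PARAMS, k_exchange_gdp=0.4)
        sim = Simulation(plus_config, p, sol, rng=3)
        for _ in range(3000):
            ev, _ = sim.step()
            if ev is None:
                break
        state = sim.snapshot()
        assert all(len(col) >= 1 for col in state.columns)
        assert all(col[0].locked for col in state.columns)
        assert sim.heights() == [len(col) for col in state.columns]


class TestMechanismEquivalences:
    def test_minus_rate_table_identical_under_both_modes(self, minus_config):
        """Exhaustive check on randomized states: minus rates ignore the mode."""
        rng = np.random.default_rng(0)
        sol = SolutionState(tubulin_total=1.0, frac_gdp_tubulin=0.3)
        for _ in range(20):
            seed = int(rng.integers(1_000_000))
            sims = []
            for mech in (SELF_ACTING, INTERFACE_ACTING):
                p = replace(CALIBRATED_PARAMS, mechanism=mech)
                sim = Simulation(minus_config, p, sol, rng=seed)
                for _ in range(200):
                    if sim.step()[0] is None:
                        break
                sims.append(sim)
            assert sims[0].rates_table() == sims[1].rates_table()
            assert sims[0].heights() == sims[1].heights()

    def test_all_strong_lattice_modes_share_trajectories(
        self, plus_config, cpp_solution
    ):
        """With no GDP anywhere the two mechanisms define identical rates."""
        traces = [
            simulate_trace(
                plus_config,
                replace(CALIBRATED_PARAMS, mechanism=m),
                cpp_solution,
                60.0,
                seed=7,
            )
            for m in (SELF_ACTING, INTERFACE_ACTING)
        ]
        assert np.array_equal(traces[0].mean_length_nm, traces[1].mean_length_nm)


class TestGrowthRateEstimator:
    def test_exact_line(self):
        t = np.arange(11.0)
        assert estimate_growth_rate(Trace(t, 3.0 * t)) == pytest.approx(3.0)

    def test_constant_length(self):
        t = np.arange(11.0)
        assert estimate_growth_rate(Trace(t, np.full(11, 2.0))) == pytest.approx(0.0)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            estimate_growth_rate(Trace(np.array([0.0]), np.array([0.0])))

    def test_noisy_line_within_ols_ci(self, rng):
        t = np.arange(0.0, 200.0)
        sigma = 5.0
        y = 1.7 * t + sigma * rng.standard_normal(t.size)
        slope = estimate_growth_rate(Trace(t, y))
        se = sigma / math.sqrt(np.sum((t - t.mean()) ** 2))
        assert abs(slope - 1.7) < 4 * se


class TestProtocolAndScan:
    def test_single_replicate_sd_zero(self, plus_config, calibrated_params, cpp_solution):
        res = run_protocol(
            plus_config,
            calibrated_params,
            cpp_solution,
            SimProtocol(duration=20.0, n_replicates=1),
        )
        assert res.n == 1 and res.sd_rate == 0.0

    def test_empty_condition_list(self, plus_config, calibrated_params):
        ds = scan(plus_config, calibrated_params, SimProtocol(duration=10.0, n_replicates=1), [])
        assert len(ds) == 0 and ds.summary().empty

    def test_scan_shape_and_growth_monotone_in_tubulin(self, minus_config):
        proto = SimProtocol(duration=120.0, n_replicates=8, base_seed=2)
        concs = [0.5, 1.0, 1.5]
        ds = scan(
            minus_config,
            CALIBRATED_PARAMS,
            proto,
            [SolutionState(tubulin_total=c) for c in concs],
        )
        assert len(ds) == len(concs) * proto.n_replicates
        means = ds.summary().sort_values("tubulin_uM")["rate_nm_s_mean"].to_numpy()
        assert np.all(np.diff(means) > 0)
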