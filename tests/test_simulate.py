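"""Simulator: parameter sampling, logistic demography, burn-in equilibrium,
sweep conditioning, and VCF round-trips."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from sweeptime.simulate import (
    SCENARIOS,
    Population,
    SimulationParams,
    UnknownScenarioError,
    coalescent_burn_in,
    introduce_sweep,
    logistic_step,
    run_burn_in,
    run_sweep_phase,
    run_sweep_phase_direct,
    sample_parameters,
    simulate_sweep,
    _simulate_trajectory,
)
from sweeptime.vcfio import read_vcf, write_vcf

from conftest import small_params

SQRT6 = math.sqrt(6.0)


class TestSampleParameters:
    @pytest.mark.parametrize("scenario", SCENARIOS)
    def test_table_distributions(self, scenario, rng):
        for _ in range(200):
            p = sample_parameters(scenario, rng)
            assert 1000 <= p.NA <= 10000
            assert 1.0 / p.NA <= p.s <= 1.0
            assert 0.0 <= p.h <= 1.0
            assert 10**-8.5 <= p.mu <= 10**-7.5
            assert 1e-9 <= p.R <= 1e-7
            assert 1 <= p.ta <= 10**4
            if scenario == "constant":
                assert p.r == 0.0
            elif scenario in ("growth", "decay"):
                assert 0.0 < p.r < 0.5
            elif scenario == "cycling":
                assert 2.0 < p.r < SQRT6
            else:
                assert SQRT6 < p.r < 3.0
            if scenario == "growth":
                assert 1.005 <= p.K / p.NA <= 2.005
            elif scenario == "decay":
                assert 0.495 <= p.K / p.NA <= 0.995
            elif scenario in ("cycling", "chaotic"):
                assert 0.795 <= p.K / p.NA <= 1.205

    def test_unknown_scenario_rejected(self, rng):
        with pytest.raises(UnknownScenarioError):
            sample_parameters("bottleneck", rng)
        with pytest.raises(UnknownScenarioError):
            SimulationParams(scenario="bottleneck", NA=1000, s=0.1, h=0.5,
                             mu=1e-8, R=1e-8, ta=10, r=0.0, K=1000)


class TestLogisticMap:
    def test_pointwise(self):
        assert logistic_step(1000, 0.0, 5000) == 1000  # r=0: constant
        assert logistic_step(2000, 0.7, 2000) == 2000  # fixed point at K
        assert logistic_step(1000, 0.5, 2000) == 1250  # hand evaluation

    def test_constant_regime(self):
        N = 737
        for _ in range(500):
            N = logistic_step(N, 0.0, 1000)
        assert N == 737

    def test_convergence_regime(self):
        # monotone approach to K; integer rounding parks the size where the
        # per-generation increment drops below half an individual
        N = 500
        traj = []
        for _ in range(500):
            N = logistic_step(N, 0.25, 1000)
            traj.append(N)
        assert all(b >= a for a, b in zip(traj, traj[1:]))
        assert traj[-1] == traj[-2]  # stationary
        assert abs(traj[-1] - 1000) <= 5

    def test_decay_regime(self):
        N = 1500
        traj = []
        for _ in range(500):
            N = logistic_step(N, 0.25, 1000)
            traj.append(N)
        assert all(b <= a for a, b in zip(traj, traj[1:]))
        assert abs(traj[-1] - 1000) <= 5

    def test_two_cycle_regime(self):
        N = 900
        traj = []
        for _ in range(700):
            N = logistic_step(N, 2.2, 1000)
            traj.append(N)
        tail = traj[-100:]
        values = sorted(set(tail))
        assert len(values) == 2
        # strict alternation between the two sizes
        assert all(a != b for a, b in zip(tail, tail[1:]))

    def test_chaotic_regime_no_short_cycle(self):
        N = 900
        traj = []
        for _ in range(1500):
            N = logistic_step(N, 2.7, 1000)
            traj.append(N)
        tail = traj[-200:]
        for period in range(1, 9):
            assert any(
                tail[i] != tail[i + period] for i in range(len(tail) - period)
            ), f"unexpected cycle of period {period}"

    def test_floor_at_two(self):
        assert logistic_step(2, 2.9, 3) >= 2
        assert logistic_step(100, 2.99, 10) >= 2


class TestBurnIn:
    def test_forward_burn_in_length_and_determinism(self):
        p = small_params(NA=40, mu=2e-6)
        pop1 = run_burn_in(p, np.random.default_rng(5), burn_in_factor=2)
        pop2 = run_burn_in(p, np.random.default_rng(5), burn_in_factor=2)
        assert pop1.N == p.NA
        np.testing.assert_array_equal(pop1.haps, pop2.haps)
        np.testing.assert_array_equal(pop1.positions, pop2.positions)

    def test_forward_burn_in_diversity_matches_neutral_expectation(self):
        # per-site pairwise diversity at equilibrium is 4*NA*mu
        NA, mu, L = 60, 4e-6, 20_000
        p = small_params(NA=NA, mu=mu, R=1e-6, L=L)
        expected = 4 * NA * mu
        rng = np.random.default_rng(77)
        pis = []
        for _ in range(25):
            pop = run_burn_in(p, rng, burn_in_factor=10)
            counts = pop.haps.sum(axis=0)
            n_chr = 2 * pop.N
            pi = np.sum(2.0 * counts * (n_chr - counts) / (n_chr * (n_chr - 1)))
            pis.append(pi / L)
        mean_pi = np.mean(pis)
        se = np.std(pis, ddof=1) / np.sqrt(len(pis))
        assert abs(mean_pi - expected) < max(4 * se, 0.3 * expected)

    def test_coalescent_burn_in_diversity(self):
        NA, mu, L = 200, 2e-6, 20_000
        p = small_params(NA=NA, mu=mu, L=L)
        rng = np.random.default_rng(3)
        pis = []
        for _ in range(20):
            pop = coalescent_burn_in(p, rng)
            counts = pop.haps.sum(axis=0)
            n_chr = 2 * pop.N
            pi = np.sum(2.0 * counts * (n_chr - counts) / (n_chr * (n_chr - 1)))
            pis.append(pi / L)
        expected = 4 * NA * mu
        se = np.std(pis, ddof=1) / np.sqrt(len(pis))
        assert abs(np.mean(pis) - expected) < max(4 * se, 0.25 * expected)


class TestSweepPhase:
    def test_introduction_is_single_copy(self, rng):
        p = small_params()
        pop = coalescent_burn_in(p, rng)
        swept = introduce_sweep(pop, rng, p.L / 2)
        assert swept.sweep_count == 1
        assert swept.positions[swept.sweep_col] == p.L / 2

    def test_complete_sweep_fixes_and_excludes_sweep_site(self, small_result):
        res = small_result
        assert res.tf >= 1
        assert res.attempts <= 1000
        # the fixed sweep site is monomorphic and absent from sampled variants
        assert not np.any(res.positions == res.params.L / 2)
        counts = res.dosages.sum(axis=0)
        assert np.all(counts > 0)
        assert np.all(counts < 2 * res.params.n)

    def test_determinism_under_fixed_seed(self):
        p = small_params(seed=99)
        a = simulate_sweep(p)
        b = simulate_sweep(p)
        assert a.tf == b.tf and a.attempts == b.attempts
        np.testing.assert_array_equal(a.dosages, b.dosages)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_neutral_fixation_probability(self):
        # with s=0 and no conditioning, a new mutation fixes w.p. ~ 1/(2N)
        N = 25
        p = small_params(NA=N, s=0.0, h=0.5)
        rng = np.random.default_rng(8)
        fixes = 0
        reps = 4000
        for _ in range(reps):
            if _simulate_trajectory(p, rng) is not None:
                fixes += 1
        expected = 1.0 / (2 * N)
        lo, hi = sps.binom.interval(0.999, reps, expected)
        assert lo <= fixes <= hi

    def test_mean_fixation_time_matches_additive_theory(self):
        # classical additive-mutation expectation 2*ln(2*c*Ne - 1)/s, where s
        # is the per-allele-copy advantage: genotype fitnesses 1, 1+s, 1+2s
        NA, s_copy = 1000, 0.1
        p = small_params(NA=NA, s=2 * s_copy, h=0.5, ta=1)
        rng = np.random.default_rng(5)
        tfs = []
        while len(tfs) < 120:
            traj = _simulate_trajectory(p, rng)
            if traj is not None:
                tfs.append(len(traj[0]) - 1)
        expected = 2 * math.log(2 * p.c * NA - 1) / s_copy
        assert 0.75 * expected <= np.mean(tfs) <= 1.25 * expected

    def test_factored_and_direct_phases_agree_in_distribution(self):
        # tf distributions from the conditioned and the restart-everything
        # implementations must match (KS test at small scale)
        p = small_params(NA=60, s=0.25, h=0.5, mu=1e-6, ta=5, n=16)
        rng = np.random.default_rng(0)
        tf_f, tf_d = [], []
        for i in range(60):
            pi = small_params(NA=60, s=0.25, h=0.5, mu=1e-6, ta=5, n=16,
                              seed=1000 + i)
            pop = coalescent_burn_in(pi, np.random.default_rng(pi.seed))
            tf_f.append(run_sweep_phase(pop, pi, np.random.default_rng(2 * i)).tf)
            tf_d.append(
                run_sweep_phase_direct(pop, pi, np.random.default_rng(3 * i)).tf
            )
        assert sps.ks_2samp(tf_f, tf_d).pvalue > 0.01

    def test_abandoned_after_max_attempts(self):
        p = small_params(s=0.0, h=0.5, ta=1)  # neutral: loss almost certain
        pop = Population(N=p.NA, haps=np.zeros((2 * p.NA, 0), dtype=np.uint8),
                         positions=np.zeros(0))
        res = run_sweep_phase(pop, p, np.random.default_rng(0), max_attempts=5)
        assert res.status == "abandoned"
        assert res.attempts == 5
        assert res.dosages is None

    def test_demography_active_during_sweep(self):
        # growth scenario: population at sampling is above NA
        p = small_params(scenario="growth", NA=80, r=0.4, K=160, s=0.5, ta=50)
        res = simulate_sweep(p)
        assert res.status == "complete"


class TestVCF:
    def test_round_trip_dosages(self, small_result, tmp_path):
        path = tmp_path / "sim.vcf"
        write_vcf(small_result, str(path))
        dosages, positions, meta = read_vcf(str(path))
        np.testing.assert_array_equal(dosages, small_result.dosages)
        assert meta["tf"] == str(small_result.tf)
        assert meta["param_scenario"] == "constant"
        assert np.all(np.diff(positions) > 0)

    def test_unphased_separator(self, small_result, tmp_path):
        path = tmp_path / "sim.vcf"
        write_vcf(small_result, str(path))
        body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert body, "expected variant records"
        gt_fields = "\t".join(body)
        assert "|" not in gt_fields

    def test_toy_shape(self, tmp_path):
        from sweeptime.simulate import SweepResult

        p = small_params(n=2)
        res = SweepResult(
            params=p, tf=10, ta=3, attempts=1,
            dosages=np.array([[0, 1], [2, 1]], dtype=np.uint8),
            positions=np.array([100.2, 200.7]),
        )
        path = tmp_path / "toy.vcf"
        write_vcf(res, str(path))
        body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert len(body) == 2
        assert body[0].split("\t")[9:] == ["0/0", "1/1"]
        assert body[1].split("\t")[9:] == ["0/1", "0/1"]

    def test_abandoned_rejected(self):
        p = small_params()
        from sweeptime.simulate import SweepResult

        res = SweepResult(params=p, tf=None, ta=1, attempts=1000,
                          dosages=None, positions=None, status="abandoned")
        with pytest.raises(ValueError):
            write_vcf(res, "/tmp/nope.vcf")
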