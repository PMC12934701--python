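"""Summary statistics: hand-computed oracles, brute-force cross-checks, and
invariance properties."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from sweeptime.sumstats import (
    STAT_NAMES,
    GenotypeWindow,
    compute_all,
    diplotype_stats,
    extract_window,
    gkl_stats,
    hscan_stat,
    ld_stats,
    sfs_stats,
)

from conftest import random_window


def make_window(dosages, positions=None, center=None):
    dosages = np.asarray(dosages, dtype=np.uint8)
    if positions is None:
        positions = np.arange(dosages.shape[1], dtype=float) * 10 + 5
    positions = np.asarray(positions, dtype=float)
    if center is None:
        center = float(positions.mean())
    return GenotypeWindow(dosages=dosages, positions=positions, center=center)


class TestExtractWindow:
    def test_caps_at_max(self, rng):
        dosages = rng.integers(0, 3, size=(4, 200)).astype(np.uint8)
        positions = np.sort(rng.uniform(0, 1e5, 200))
        win = extract_window(dosages, positions, 5e4, max_snps=128)
        assert win.S == 128

    def test_keeps_all_when_fewer(self, rng):
        dosages = rng.integers(0, 3, size=(4, 50)).astype(np.uint8)
        positions = np.sort(rng.uniform(0, 1e5, 50))
        win = extract_window(dosages, positions, 5e4, max_snps=128)
        assert win.S == 50

    def test_nearest_to_center_with_lower_tie_break(self):
        positions = np.array([10.0, 40.0, 60.0, 90.0])
        dosages = np.tile(np.array([[0, 1, 2, 1]], dtype=np.uint8), (3, 1))
        win = extract_window(dosages, positions, 50.0, max_snps=2)
        # 40 and 60 are equidistant; with max_snps=2 both fit, so shrink to 1
        win1 = extract_window(dosages, positions, 50.0, max_snps=1)
        np.testing.assert_array_equal(win.positions, [40.0, 60.0])
        np.testing.assert_array_equal(win1.positions, [40.0])


class TestSFS:
    def test_single_site_oracle(self):
        # 4 diploids (2n=8), one site with alternate count 4
        dosages = np.array([[2], [2], [0], [0]])
        win = make_window(dosages)
        out = sfs_stats(win)
        assert out["pi"] == pytest.approx(32 / 56)
        a1 = sum(1.0 / i for i in range(1, 8))
        assert out["thetaW"] == pytest.approx(1 / a1)
        assert out["S"] == 1

    def test_pi_and_theta_against_tskit_oracle(self):
        # independent implementation: tskit's site diversity and Tajima's D
        import msprime

        ts = msprime.sim_ancestry(
            samples=12, population_size=500, sequence_length=5e4,
            recombination_rate=1e-8, random_seed=9, discrete_genome=False,
        )
        ts = msprime.sim_mutations(
            ts, rate=2e-7, model=msprime.BinaryMutationModel(),
            discrete_genome=False, random_seed=10,
        )
        G = ts.genotype_matrix()
        keep = (G.sum(axis=1) > 0) & (G.sum(axis=1) < 24) & (G.max(axis=1) == 1)
        G = G[keep]
        dosages = (G[:, 0::2] + G[:, 1::2]).T
        win = make_window(dosages, positions=np.arange(G.shape[0], dtype=float))
        out = sfs_stats(win)
        assert out["pi"] == pytest.approx(
            ts.diversity(span_normalise=False), rel=1e-9
        )
        assert out["D"] == pytest.approx(ts.Tajimas_D(), rel=1e-6)

    def test_monomorphic_window_degenerate(self):
        win = make_window(np.zeros((4, 0)))
        out = sfs_stats(win)
        assert out["S"] == 0 and out["pi"] == 0 and out["thetaW"] == 0
        assert np.isnan(out["D"]) and np.isnan(out["varD"])

    def test_varD_needs_two_blocks(self, rng):
        win = random_window(rng, n=8, S=20)
        assert np.isnan(sfs_stats(win)["varD"])  # only one complete block
        win2 = random_window(rng, n=8, S=34)
        # two complete 16-variant blocks
        assert np.isfinite(sfs_stats(win2)["varD"])


class TestDiplotypes:
    def test_degenerate_all_identical(self):
        win = make_window(np.ones((6, 4)))
        out = diplotype_stats(win)
        assert out == {
            "n_diplo": 1.0, "h1": 1.0, "h2": 0.0, "h12": 1.0,
            "h123": 1.0, "h2h1": 0.0,
        }

    def test_multiset_AABC_oracle(self):
        rows = np.array([
            [0, 0, 0], [0, 0, 0], [1, 1, 1], [2, 2, 2],
        ])
        out = diplotype_stats(make_window(rows))
        assert out["h1"] == pytest.approx(0.375)
        assert out["h2"] == pytest.approx(0.125)
        assert out["h12"] == pytest.approx(0.625)
        assert out["h123"] == pytest.approx(1.0)
        assert out["h2h1"] == pytest.approx(1 / 3)
        assert out["n_diplo"] == 3

    def test_h_identities_fuzz(self, rng):
        for _ in range(50):
            win = random_window(rng, n=int(rng.integers(4, 16)),
                                S=int(rng.integers(2, 10)))
            out = diplotype_stats(win)
            assert out["h123"] >= out["h12"] >= out["h1"] - 1e-12
            assert 1.0 / win.n - 1e-12 <= out["h1"] <= 1.0
            assert 0.0 <= out["h2h1"] < 1.0


class TestGkl:
    def test_mismatch_multiset_oracle(self):
        rows = np.array([[0, 0], [0, 1], [2, 2]])
        win = make_window(rows)
        out = gkl_stats(win)
        m = np.array([1.0, 2.0, 2.0])  # pairs (0,1), (0,2), (1,2)
        assert out["gkl_var"] == pytest.approx(np.var(m, ddof=1))
        assert out["gkl_skew"] == pytest.approx(sps.skew(m, bias=False))
        assert out["gkl_kurt"] == pytest.approx(
            sps.kurtosis(m, fisher=True, bias=False)
        )

    def test_degenerate_identical_rows(self):
        win = make_window(np.ones((5, 3)))
        out = gkl_stats(win)
        assert out["gkl_var"] == 0.0
        assert np.isnan(out["gkl_skew"]) and np.isnan(out["gkl_kurt"])

    def test_matches_naive_recomputation(self, rng):
        for _ in range(10):
            win = random_window(rng, n=10, S=8)
            out = gkl_stats(win)
            naive = [
                int(np.sum(win.dosages[i] != win.dosages[j]))
                for i, j in itertools.combinations(range(10), 2)
            ]
            assert out["gkl_var"] == pytest.approx(np.var(naive, ddof=1))
            if np.var(naive) > 0:
                assert out["gkl_skew"] == pytest.approx(
                    sps.skew(naive, bias=False)
                )


class TestLD:
    def test_identical_sites_give_r2_one(self):
        col = np.array([0, 1, 2, 1, 0, 2])
        win = make_window(np.column_stack([col, col, col]))
        out = ld_stats(win)
        assert out["r2_mean"] == pytest.approx(1.0)

    def test_omega_maximized_at_block_boundary(self, rng):
        # two independent blocks of three identical columns each
        a = rng.integers(0, 3, size=12)
        b = rng.permutation(a)
        dosages = np.column_stack([a, a, a, b, b, b])
        win = make_window(dosages)
        r2 = np.zeros((6, 6))
        d = dosages.astype(float)
        for i in range(6):
            for j in range(6):
                if i != j:
                    r2[i, j] = np.corrcoef(d[:, i], d[:, j])[0, 1] ** 2
        # brute-force omega over all splits
        best, best_l = -np.inf, None
        for l in range(2, 5):
            within = (
                sum(r2[i, j] for i in range(l) for j in range(i + 1, l))
                + sum(r2[i, j] for i in range(l, 6) for j in range(i + 1, 6))
            )
            n_within = l * (l - 1) // 2 + (6 - l) * (5 - l) // 2
            between = sum(r2[i, j] for i in range(l) for j in range(l, 6))
            ratio = (within / n_within) / (between / (l * (6 - l)))
            if ratio > best:
                best, best_l = ratio, l
        out = ld_stats(win)
        assert best_l == 3
        assert out["omega"] == pytest.approx(best)

    def test_omega_equals_bruteforce_on_random_windows(self, rng):
        for _ in range(8):
            S = int(rng.integers(6, 13))
            win = random_window(rng, n=12, S=S)
            out = ld_stats(win)
            d = win.dosages.astype(float)
            sd = d.std(axis=0)
            best = -np.inf
            for l in range(2, S - 1):
                w_sum = w_n = b_sum = b_n = 0.0
                for i in range(S):
                    for j in range(i + 1, S):
                        if sd[i] == 0 or sd[j] == 0:
                            continue
                        r2 = np.corrcoef(d[:, i], d[:, j])[0, 1] ** 2
                        if (i < l) == (j < l):
                            w_sum += r2
                            w_n += 1
                        else:
                            b_sum += r2
                            b_n += 1
                if w_n and b_n and b_sum > 0:
                    best = max(best, (w_sum / w_n) / (b_sum / b_n))
            if np.isfinite(best):
                assert out["omega"] == pytest.approx(best)
            else:
                assert np.isnan(out["omega"])

    def test_omega_requires_six_sites(self, rng):
        win = random_window(rng, n=10, S=5)
        assert np.isnan(ld_stats(win)["omega"])


class TestHscan:
    def test_identical_rows_reach_one(self):
        row = np.array([0, 1, 2, 1, 0])
        win = make_window(np.tile(row, (4, 1)))
        assert hscan_stat(win) == pytest.approx(1.0)

    def test_total_disagreement_gives_zero_tract(self):
        win = make_window(np.array([[0, 0, 0, 0], [2, 2, 2, 2]]))
        assert hscan_stat(win) == 0.0

    def test_partial_tract_oracle(self):
        # positions 0,10,20,30,40; center 25 => flanks are indices 2 and 3.
        # pair (0,1): agree exactly on indices 1..3 -> tract 30 - 10 = 20
        # pairs (0,2) and (1,2): disagree at flank index 2, agree at flank
        #   index 3 only; the run containing index 3 alone has zero span -> 0
        d = np.array([
            [0, 1, 1, 1, 0],
            [2, 1, 1, 1, 2],
            [1, 0, 2, 1, 1],
        ])
        pos = np.array([0.0, 10.0, 20.0, 30.0, 40.0])
        win = GenotypeWindow(dosages=d, positions=pos, center=25.0)
        expected = ((30 - 10) + 0 + 0) / 3 / 40.0
        assert hscan_stat(win) == pytest.approx(expected)

    def test_value_in_unit_interval(self, rng):
        for _ in range(30):
            win = random_window(rng, n=8, S=10)
            v = hscan_stat(win)
            assert 0.0 <= v <= 1.0


class TestComputeAll:
    def test_emits_exactly_17_statistics(self, rng):
        win = random_window(rng, n=12, S=40)
        vec = compute_all(win)
        assert len(STAT_NAMES) == 17
        assert vec.values().shape == (17,)

    def test_monomorphic_window_invalid(self):
        win = make_window(np.zeros((4, 0)), positions=np.zeros(0), center=0.0)
        assert not compute_all(win).valid

    def test_invariant_to_individual_order(self, rng):
        win = random_window(rng, n=10, S=34)
        perm = rng.permutation(10)
        win2 = GenotypeWindow(
            dosages=win.dosages[perm], positions=win.positions, center=win.center
        )
        np.testing.assert_allclose(
            compute_all(win).values(), compute_all(win2).values(),
            rtol=0, atol=1e-12,
        )

    def test_valid_on_rich_window(self, rng):
        win = random_window(rng, n=16, S=40)
        vec = compute_all(win)
        assert vec.valid
        assert vec.h1 >= 1.0 / 16 - 1e-12
        assert 0 <= vec.r2_mean <= 1

    def test_pi_thetaw_agree_at_neutral_equilibrium(self):
        # over replicate neutral coalescent draws, E[pi] = E[thetaW]
        import msprime

        pis, thetas = [], []
        for seed in range(1, 51):
            ts = msprime.sim_ancestry(
                samples=10, population_size=400, sequence_length=2e4,
                random_seed=seed, discrete_genome=False,
            )
            ts = msprime.sim_mutations(
                ts, rate=5e-7, model=msprime.BinaryMutationModel(),
                discrete_genome=False, random_seed=seed + 1000,
            )
            G = ts.genotype_matrix()
            if G.shape[0] < 2:
                continue
            keep = (G.sum(axis=1) > 0) & (G.sum(axis=1) < 20) & (G.max(axis=1) == 1)
            G = G[keep]
            dosages = (G[:, 0::2] + G[:, 1::2]).T
            out = sfs_stats(
                make_window(dosages, positions=np.arange(G.shape[0], dtype=float))
            )
            pis.append(out["pi"])
            thetas.append(out["thetaW"])
        ratio = np.mean(pis) / np.mean(thetas)
        assert 0.85 < ratio < 1.15
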