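"""Forward-time diploid Wright-Fisher simulator with logistic-map demography.

This module is the study's data generator.  A diploid population of ancestral
size ``NA`` is burned in neutrally, a single beneficial mutation is introduced
at the middle base of the chromosome, and the population then evolves under
selection and a logistic-map demography

    N_{t+1} = round(r * N_t * (1 - N_t / K) + N_t)

until the sweep allele fixes.  The time from introduction to fixation is the
time to fixation ``tf``; the population then evolves a further ``ta``
generations (the sweep age) before ``n`` individuals are sampled without
replacement and their unphased genotypes recorded.  Sweeps lost to drift are
restarted from the post-burn-in state with a fresh seed, up to
``max_attempts`` times, after which the replicate is abandoned.

Haplotypes are stored as a dense 0/1 matrix over currently segregating sites
(infinite-sites mutation at per-base rate ``mu``, positions continuous on
``[0, L)``), with one crossover process per meiosis at per-base rate ``R``.

Because the sweep allele's frequency trajectory is independent of the neutral
background, ``run_sweep_phase`` factorizes the simulation: it first draws the
diploid genotype-count trajectory of the beneficial allele alone (selection,
demography, and drift only), restarting cheaply on loss, and then simulates
the full population conditioned on the fixing trajectory.  This is
distributionally identical to restarting the whole simulation on every loss
(``run_sweep_phase_direct`` implements the unfactorized version and serves as
a cross-check) but avoids evolving the genome through discarded attempts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "SCENARIOS",
    "SimulationParams",
    "Population",
    "SweepResult",
    "sample_parameters",
    "logistic_step",
    "run_burn_in",
    "coalescent_burn_in",
    "introduce_sweep",
    "run_sweep_phase",
    "run_sweep_phase_direct",
    "simulate_sweep",
    "FULL_PROFILE",
    "DESK_PROFILE",
    "ScaleProfile",
    "UnknownScenarioError",
]

SCENARIOS = ("constant", "growth", "decay", "cycling", "chaotic")

_SQRT6 = math.sqrt(6.0)

# monomorphic columns are purged every this many generations (amortization;
# any value >= 1 is correct because fixed/lost columns are inert)
_CLEAN_EVERY = 8


class UnknownScenarioError(ValueError):
    """Raised when a demography label is not one of the five scenarios."""


@dataclass(frozen=True)
class ScaleProfile:
    """Parameter ranges defining the scale of a simulation study.

    ``full`` reproduces the published study conditions.  ``desk`` is a
    coalescent-rescaled profile for single-CPU runs: population sizes and
    chromosome length are reduced while ``4*N*mu*L``, ``4*N*R*L`` and the
    ``ta/N`` ratio are preserved, so windows carry a comparable number of
    segregating sites and sweep signals decay over comparable (rescaled)
    timescales.
    """

    name: str
    NA_range: tuple[int, int] = (1000, 10000)
    mu_log10_range: tuple[float, float] = (-8.5, -7.5)
    R_log10_range: tuple[float, float] = (-9.0, -7.0)
    ta_log10_range: tuple[float, float] = (0.0, 4.0)
    L: int = 100_000
    n: int = 128
    burn_in_factor: float = 10.0


FULL_PROFILE = ScaleProfile(name="full")
DESK_PROFILE = ScaleProfile(
    name="desk",
    NA_range=(200, 1000),
    mu_log10_range=(-7.0, -6.0),
    R_log10_range=(-7.5, -5.5),
    ta_log10_range=(0.0, 3.0),
    L=20_000,
    n=128,
    burn_in_factor=4.0,
)


@dataclass(frozen=True)
class SimulationParams:
    """One draw of the simulation parameters for a single sweep replicate."""

    scenario: str
    NA: int
    s: float
    h: float
    mu: float
    R: float
    ta: int
    r: float
    K: int
    L: int = 100_000
    n: int = 128
    c: int = 2  # ploidy
    seed: Optional[int] = None

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise UnknownScenarioError(
                f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}"
            )

    def as_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "NA": self.NA,
            "s": self.s,
            "h": self.h,
            "mu": self.mu,
            "R": self.R,
            "ta": self.ta,
            "r": self.r,
            "K": self.K,
            "L": self.L,
            "n": self.n,
            "c": self.c,
            "seed": self.seed,
        }


def sample_parameters(
    scenario: str,
    rng: np.random.Generator,
    profile: ScaleProfile = FULL_PROFILE,
) -> SimulationParams:
    """Draw one parameter set for *scenario* from the study's sampling
    distributions.

    ``NA ~ U(NA_range)``; ``s ~ LU(log10(1/NA), 0)``; ``h ~ U(0, 1)``;
    ``mu, R, ta`` log-uniform over the profile's log10 ranges; the logistic
    parameter ``r`` and carrying capacity ``K`` depend on the scenario
    (``r = 0`` for constant; ``U(0, 0.5)`` for growth/decay;
    ``U(2, sqrt(6))`` for cycling; ``U(sqrt(6), 3)`` for chaotic).
    """
    if scenario not in SCENARIOS:
        raise UnknownScenarioError(
            f"unknown scenario {scenario!r}; expected one of {SCENARIOS}"
        )
    NA = int(rng.integers(profile.NA_range[0], profile.NA_range[1] + 1))
    s = 10.0 ** rng.uniform(math.log10(1.0 / NA), 0.0)
    h = rng.uniform(0.0, 1.0)
    mu = 10.0 ** rng.uniform(*profile.mu_log10_range)
    R = 10.0 ** rng.uniform(*profile.R_log10_range)
    ta = max(1, int(round(10.0 ** rng.uniform(*profile.ta_log10_range))))
    if scenario == "constant":
        r, K = 0.0, NA
    elif scenario == "growth":
        r = rng.uniform(0.0, 0.5)
        K = int(round(NA * rng.uniform(1.01, 2.0)))
    elif scenario == "decay":
        r = rng.uniform(0.0, 0.5)
        K = int(round(NA * rng.uniform(0.5, 0.99)))
    elif scenario == "cycling":
        r = rng.uniform(2.0, _SQRT6)
        K = int(round(NA * rng.uniform(0.8, 1.2)))
    else:  # chaotic
        r = rng.uniform(_SQRT6, 3.0)
        K = int(round(NA * rng.uniform(0.8, 1.2)))
    seed = int(rng.integers(0, 2**31 - 1))
    return SimulationParams(
        scenario=scenario, NA=NA, s=s, h=h, mu=mu, R=R, ta=ta, r=r, K=K,
        L=profile.L, n=profile.n, seed=seed,
    )


def logistic_step(Nt: int, r: float, K: float) -> int:
    """One generation of the logistic-map demography, rounded to the nearest
    individual and floored at 2."""
    N_next = int(round(r * Nt * (1.0 - Nt / K) + Nt))
    return max(2, N_next)


@dataclass
class Population:
    """Forward-simulation state: 2N haplotypes over segregating sites.

    ``haps`` is a ``(2N, S)`` 0/1 matrix; chromosomes ``2i`` and ``2i+1``
    belong to diploid individual ``i``.  ``sweep_col`` indexes the beneficial
    allele's column while it segregates (None otherwise).
    """

    N: int
    haps: np.ndarray
    positions: np.ndarray
    sweep_col: Optional[int] = None
    generation: int = 0

    @property
    def sweep_count(self) -> int:
        if self.sweep_col is None:
            return 0
        return int(self.haps[:, self.sweep_col].sum())

    def copy(self) -> "Population":
        return Population(
            N=self.N,
            haps=self.haps.copy(),
            positions=self.positions.copy(),
            sweep_col=self.sweep_col,
            generation=self.generation,
        )


@dataclass
class SweepResult:
    """A completed (or abandoned) sweep replicate."""

    params: SimulationParams
    tf: Optional[int]
    ta: int
    attempts: int
    dosages: Optional[np.ndarray]  # (n, S) entries in {0, 1, 2}
    positions: Optional[np.ndarray]  # (S,) base coordinates, increasing
    status: str = "complete"  # or "abandoned"


# ---------------------------------------------------------------------------
# generation mechanics
# ---------------------------------------------------------------------------


def _apply_crossovers(
    new: np.ndarray,
    haps: np.ndarray,
    kidx: np.ndarray,
    base: np.ndarray,
    n_x: np.ndarray,
    positions: np.ndarray,
    L: int,
    anchor: float,
    rng: np.random.Generator,
) -> None:
    """Overwrite recombinant gametes in place.

    Gamete ``kidx[j]`` is a mosaic of chromosomes ``base[j]`` (which owns the
    segment containing *anchor*) and its sibling ``base[j] ^ 1``, with
    ``n_x[j]`` crossover points uniform on [0, L).  Single-crossover gametes
    (the vast majority at realistic R*L) are handled in one vectorized pass.
    """
    one = n_x == 1
    k1 = kidx[one]
    if k1.size:
        brk = rng.uniform(0.0, L, size=k1.size)
        b1 = base[one]
        use_other = (positions[None, :] >= brk[:, None]) != (
            anchor >= brk
        )[:, None]
        new[k1] = np.where(use_other, haps[b1 ^ 1], haps[b1])
    for j in np.flatnonzero(n_x >= 2):
        k = kidx[j]
        breaks = np.sort(rng.uniform(0.0, L, size=n_x[j]))
        seg = np.searchsorted(breaks, positions)
        seg_anchor = np.searchsorted(breaks, anchor)
        other = (seg - seg_anchor) % 2 == 1
        new[k] = np.where(other, haps[base[j] ^ 1], haps[base[j]])


def _mutate(
    new: np.ndarray,
    positions: np.ndarray,
    mu: float,
    L: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Append Poisson(2N' * mu * L) new singleton columns (infinite sites)."""
    n_gam = new.shape[0]
    n_mut = rng.poisson(n_gam * mu * L)
    if n_mut == 0:
        return new, positions
    mut_pos = rng.uniform(0.0, L, size=n_mut)
    carriers = rng.integers(0, n_gam, size=n_mut)
    cols = np.zeros((n_gam, n_mut), dtype=np.uint8)
    cols[carriers, np.arange(n_mut)] = 1
    return np.concatenate([new, cols], axis=1), np.concatenate([positions, mut_pos])


def _reproduce(
    pop: Population,
    N_next: int,
    s: float,
    h: float,
    mu: float,
    R: float,
    L: int,
    rng: np.random.Generator,
) -> Population:
    """One unconditioned generation: fitness-weighted parent choice, one
    gamete per parent with Poisson(R*L) crossovers, then mutation."""
    haps = pop.haps
    N = pop.N
    n_gam = 2 * N_next

    if pop.sweep_col is not None and s != 0.0:
        col = haps[:, pop.sweep_col]
        g = col[0::2].astype(np.int64) + col[1::2]
        w = np.ones(N)
        w[g == 1] = 1.0 + h * s
        w[g == 2] = 1.0 + s
        cdf = np.cumsum(w)
        parents = np.searchsorted(cdf, rng.random(n_gam) * cdf[-1])
    else:
        parents = rng.integers(0, N, size=n_gam)

    chrom = rng.integers(0, 2, size=n_gam)
    base = 2 * parents + chrom
    new = haps[base]  # copy via fancy indexing

    n_x = rng.poisson(R * L, size=n_gam)
    kidx = np.flatnonzero(n_x)
    if kidx.size:
        _apply_crossovers(new, haps, kidx, base[kidx], n_x[kidx],
                          pop.positions, L, 0.0, rng)

    new, positions = _mutate(new, pop.positions, mu, L, rng)
    return Population(
        N=N_next, haps=new, positions=positions,
        sweep_col=pop.sweep_col, generation=pop.generation + 1,
    )


def _clean_fixed_lost(pop: Population) -> None:
    """Drop monomorphic columns in place, preserving the sweep column index."""
    if pop.haps.shape[1] == 0:
        return
    counts = np.einsum("ij->j", pop.haps, dtype=np.int64)
    two_n = 2 * pop.N
    keep = (counts > 0) & (counts < two_n)
    if pop.sweep_col is not None:
        keep[pop.sweep_col] = True
    if keep.all():
        return
    if pop.sweep_col is not None:
        pop.sweep_col = int(keep[: pop.sweep_col].sum())
    pop.haps = np.ascontiguousarray(pop.haps[:, keep])
    pop.positions = pop.positions[keep]


# ---------------------------------------------------------------------------
# burn-in
# ---------------------------------------------------------------------------


def run_burn_in(
    params: SimulationParams,
    rng: Optional[np.random.Generator] = None,
    burn_in_factor: float = 10.0,
) -> Population:
    """Neutral forward burn-in: constant size NA for ``burn_in_factor * NA``
    generations under mutation ``mu`` and recombination ``R``, from an
    initially monomorphic population."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    pop = Population(
        N=params.NA,
        haps=np.zeros((2 * params.NA, 0), dtype=np.uint8),
        positions=np.zeros(0),
    )
    n_gen = int(round(burn_in_factor * params.NA))
    for g in range(n_gen):
        pop = _reproduce(pop, params.NA, 0.0, 0.0, params.mu, params.R, params.L, rng)
        if g % _CLEAN_EVERY == 0:
            _clean_fixed_lost(pop)
    _clean_fixed_lost(pop)
    return pop


def coalescent_burn_in(
    params: SimulationParams,
    rng: Optional[np.random.Generator] = None,
) -> Population:
    """Equilibrium standing variation drawn from the neutral coalescent
    (msprime) instead of forward burn-in.  Statistically equivalent to a long
    forward burn-in at constant size NA and much faster."""
    import msprime

    if rng is None:
        rng = np.random.default_rng(params.seed)
    seed_a = int(rng.integers(1, 2**31 - 1))
    seed_b = int(rng.integers(1, 2**31 - 1))
    ts = msprime.sim_ancestry(
        samples=params.NA,
        population_size=params.NA,
        sequence_length=params.L,
        recombination_rate=params.R,
        discrete_genome=False,
        random_seed=seed_a,
    )
    ts = msprime.sim_mutations(
        ts,
        rate=params.mu,
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,
        random_seed=seed_b,
    )
    if ts.num_sites > 0:
        haps = ts.genotype_matrix().T.astype(np.uint8)
        positions = np.array([site.position for site in ts.sites()])
        # keep strictly segregating, biallelic 0/1 columns
        counts = haps.sum(axis=0)
        keep = (counts > 0) & (counts < 2 * params.NA) & (haps.max(axis=0) <= 1)
        haps = np.ascontiguousarray(haps[:, keep])
        positions = positions[keep]
    else:
        haps = np.zeros((2 * params.NA, 0), dtype=np.uint8)
        positions = np.zeros(0)
    return Population(N=params.NA, haps=haps, positions=positions)


# ---------------------------------------------------------------------------
# sweep phase
# ---------------------------------------------------------------------------


def introduce_sweep(
    pop: Population,
    rng: np.random.Generator,
    position: float,
) -> Population:
    """Place the beneficial allele on one random chromosome at *position*
    (the middle base, L/2).  Initial frequency is one copy among 2N."""
    new = pop.copy()
    carrier = int(rng.integers(0, 2 * new.N))
    col = np.zeros((2 * new.N, 1), dtype=np.uint8)
    col[carrier, 0] = 1
    new.haps = np.concatenate([new.haps, col], axis=1)
    new.positions = np.append(new.positions, position)
    new.sweep_col = new.haps.shape[1] - 1
    return new


def _simulate_trajectory(
    params: SimulationParams,
    rng: np.random.Generator,
    max_gen: int = 2_000_000,
) -> Optional[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Simulate the sweep allele's genotype-count trajectory alone.

    Returns ``(N, n1, n2)`` arrays over generations 0..tf if the allele
    fixes, else None (lost).  Generation 0 is the introduction (one
    heterozygote); fixation means every one of the 2N chromosomes carries
    the allele.  Offspring genotypes are Multinomial over Hardy-Weinberg
    proportions at the fitness-weighted gamete frequency, which is exactly
    the marginal law of the full simulation's reproduction scheme.
    """
    s, h, r, K = params.s, params.h, params.r, params.K
    w1, w2 = 1.0 + h * s, 1.0 + s
    N = params.NA
    n1, n2 = 1, 0
    Ns, n1s, n2s = [N], [1], [0]
    for _ in range(max_gen):
        n0 = N - n1 - n2
        tot = n0 + n1 * w1 + n2 * w2
        pg = (0.5 * n1 * w1 + n2 * w2) / tot
        N_next = logistic_step(N, r, K)
        counts = rng.multinomial(
            N_next, [(1 - pg) ** 2, 2 * pg * (1 - pg), pg * pg]
        )
        n1, n2 = int(counts[1]), int(counts[2])
        N = N_next
        Ns.append(N)
        n1s.append(n1)
        n2s.append(n2)
        if n1 == 0 and n2 == 0:
            return None
        if n1 == 0 and n2 == N:
            return np.array(Ns), np.array(n1s), np.array(n2s)
    return None


def _reproduce_conditioned(
    pop: Population,
    counts_next: tuple[int, int, int],
    s: float,
    h: float,
    mu: float,
    R: float,
    L: int,
    sweep_pos: float,
    rng: np.random.Generator,
) -> Population:
    """One generation conditioned on next-generation sweep genotype counts.

    Gametes that must (or must not) carry the allele draw their parent from
    the genotype classes with probability proportional to fitness times the
    class's transmission probability of that allele state; for heterozygous
    parents the transmitted chromosome at the sweep site is the required one
    and crossover mosaics are anchored at the sweep position.
    """
    haps = pop.haps
    col = haps[:, pop.sweep_col]
    g = col[0::2].astype(np.int64) + col[1::2]
    idx0 = np.flatnonzero(g == 0)
    idx1 = np.flatnonzero(g == 1)
    idx2 = np.flatnonzero(g == 2)
    w1, w2 = 1.0 + h * s, 1.0 + s

    n0n, n1n, n2n = counts_next
    N_next = n0n + n1n + n2n
    n_gam = 2 * N_next

    # gamete slots: offspring blocks [class2 | class1 | class0]; within a
    # class-1 offspring the first gamete is the carrier one (exchangeable)
    a = np.zeros(n_gam, dtype=np.uint8)
    a[: 2 * n2n] = 1
    a[2 * n2n : 2 * n2n + 2 * n1n : 2] = 1

    parent = np.empty(n_gam, dtype=np.int64)
    base = np.empty(n_gam, dtype=np.int64)

    car = np.flatnonzero(a == 1)
    non = np.flatnonzero(a == 0)

    # carrier gametes: class 1 with weight 0.5*n1*w1, class 2 with n2*w2
    if car.size:
        wc1 = 0.5 * idx1.size * w1
        wc2 = idx2.size * w2
        from1 = rng.random(car.size) < (wc1 / (wc1 + wc2))
        k1 = car[from1]
        k2 = car[~from1]
        if k1.size:
            p = idx1[rng.integers(0, idx1.size, size=k1.size)]
            parent[k1] = p
            base[k1] = 2 * p + (1 - col[2 * p])  # the carrier chromosome
        if k2.size:
            p = idx2[rng.integers(0, idx2.size, size=k2.size)]
            parent[k2] = p
            base[k2] = 2 * p + rng.integers(0, 2, size=k2.size)
    # non-carrier gametes: class 0 with n0*w0, class 1 with 0.5*n1*w1
    if non.size:
        wn0 = idx0.size * 1.0
        wn1 = 0.5 * idx1.size * w1
        from1 = rng.random(non.size) < (wn1 / (wn0 + wn1))
        k1 = non[from1]
        k0 = non[~from1]
        if k1.size:
            p = idx1[rng.integers(0, idx1.size, size=k1.size)]
            parent[k1] = p
            base[k1] = 2 * p + col[2 * p]  # the non-carrier chromosome
        if k0.size:
            p = idx0[rng.integers(0, idx0.size, size=k0.size)]
            parent[k0] = p
            base[k0] = 2 * p + rng.integers(0, 2, size=k0.size)

    new = haps[base]
    n_x = rng.poisson(R * L, size=n_gam)
    kidx = np.flatnonzero(n_x)
    if kidx.size:
        _apply_crossovers(new, haps, kidx, base[kidx], n_x[kidx],
                          pop.positions, L, sweep_pos, rng)
    # mosaics are anchored at the sweep site, so the allele column already
    # equals the required states `a`
    new, positions = _mutate(new, pop.positions, mu, L, rng)
    return Population(
        N=N_next, haps=new, positions=positions,
        sweep_col=pop.sweep_col, generation=pop.generation + 1,
    )


def _sample_genotypes(
    pop: Population, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample n individuals without replacement; return their unphased dosage
    matrix over sites segregating within the sample, sorted by position."""
    idx = rng.choice(pop.N, size=n, replace=False)
    rows = np.empty(2 * n, dtype=np.intp)
    rows[0::2] = 2 * idx
    rows[1::2] = 2 * idx + 1
    sub = pop.haps[rows]
    dos = (sub[0::2].astype(np.int16) + sub[1::2]).astype(np.uint8)
    counts = sub.sum(axis=0)
    keep = (counts > 0) & (counts < 2 * n)
    dos = dos[:, keep]
    positions = pop.positions[keep]
    order = np.argsort(positions, kind="stable")
    return np.ascontiguousarray(dos[:, order]), positions[order]


def _finish_ta_and_sample(
    cur: Population,
    params: SimulationParams,
    tf: int,
    attempt: int,
    rng: np.random.Generator,
) -> SweepResult:
    """Post-fixation neutral phase (demography still active) then sampling."""
    for g in range(params.ta):
        N_next = logistic_step(cur.N, params.r, params.K)
        cur = _reproduce(cur, N_next, 0.0, 0.0, params.mu, params.R, params.L, rng)
        if g % _CLEAN_EVERY == 0:
            _clean_fixed_lost(cur)
    _clean_fixed_lost(cur)
    if cur.N < params.n:
        return SweepResult(
            params=params, tf=tf, ta=params.ta, attempts=attempt,
            dosages=None, positions=None, status="abandoned",
        )
    dosages, positions = _sample_genotypes(cur, params.n, rng)
    return SweepResult(
        params=params, tf=tf, ta=params.ta, attempts=attempt,
        dosages=dosages, positions=positions, status="complete",
    )


def run_sweep_phase(
    pop: Population,
    params: SimulationParams,
    rng: Optional[np.random.Generator] = None,
    max_attempts: int = 1000,
) -> SweepResult:
    """Run the conditioned sweep from a post-burn-in population.

    Attempts are drawn as allele-frequency trajectories alone (each with a
    fresh child seed, restart-on-loss); the first fixing trajectory is then
    realized as a full population simulation conditioned on it, followed by
    the ``ta`` neutral generations and sampling.  Equivalent in distribution
    to :func:`run_sweep_phase_direct`.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    sweep_pos = params.L / 2.0
    seeds = rng.spawn(max_attempts)

    for attempt in range(1, max_attempts + 1):
        arng = seeds[attempt - 1]
        traj = _simulate_trajectory(params, arng)
        if traj is None:
            continue
        Ns, n1s, n2s = traj
        tf = len(Ns) - 1
        cur = introduce_sweep(pop, arng, sweep_pos)
        cur.generation = 0
        for t in range(1, tf + 1):
            N_next = int(Ns[t])
            counts = (N_next - int(n1s[t]) - int(n2s[t]), int(n1s[t]), int(n2s[t]))
            cur = _reproduce_conditioned(
                cur, counts, params.s, params.h, params.mu, params.R,
                params.L, sweep_pos, arng,
            )
            if t % _CLEAN_EVERY == 0:
                _clean_fixed_lost(cur)
        cur.sweep_col = None  # fixed: now non-segregating
        _clean_fixed_lost(cur)
        return _finish_ta_and_sample(cur, params, tf, attempt, arng)

    return SweepResult(
        params=params, tf=None, ta=params.ta, attempts=max_attempts,
        dosages=None, positions=None, status="abandoned",
    )


def run_sweep_phase_direct(
    pop: Population,
    params: SimulationParams,
    rng: Optional[np.random.Generator] = None,
    max_attempts: int = 1000,
) -> SweepResult:
    """Unfactorized sweep phase: evolve the whole population every attempt,
    restoring the post-burn-in snapshot on loss.  Slower than
    :func:`run_sweep_phase` but identical in distribution; kept as an
    independent cross-check of the conditioned implementation."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    sweep_pos = params.L / 2.0
    seeds = rng.spawn(max_attempts)

    for attempt in range(1, max_attempts + 1):
        arng = seeds[attempt - 1]
        cur = introduce_sweep(pop, arng, sweep_pos)
        cur.generation = 0
        tf = None
        while True:
            N_next = logistic_step(cur.N, params.r, params.K)
            cur = _reproduce(
                cur, N_next, params.s, params.h, params.mu, params.R, params.L, arng
            )
            cnt = cur.sweep_count
            if cnt == 0:
                break  # lost: restart from snapshot
            if cnt == 2 * cur.N:
                tf = cur.generation
                cur.sweep_col = None
                _clean_fixed_lost(cur)
                break
            if cur.generation % _CLEAN_EVERY == 0:
                _clean_fixed_lost(cur)
        if tf is None:
            continue
        return _finish_ta_and_sample(cur, params, tf, attempt, arng)

    return SweepResult(
        params=params, tf=None, ta=params.ta, attempts=max_attempts,
        dosages=None, positions=None, status="abandoned",
    )


def simulate_sweep(
    params: SimulationParams,
    burn_in: str = "coalescent",
    burn_in_factor: Optional[float] = None,
    max_attempts: int = 1000,
    direct: bool = False,
) -> SweepResult:
    """Full replicate: burn-in, conditioned sweep, ta wait, sampling.

    ``burn_in`` is "coalescent" (msprime equilibrium draw) or "forward"
    (explicit neutral Wright-Fisher burn-in of ``burn_in_factor * NA``
    generations, default factor 10).
    """
    rng = np.random.default_rng(params.seed)
    if burn_in == "coalescent":
        pop = coalescent_burn_in(params, rng)
    elif burn_in == "forward":
        factor = 10.0 if burn_in_factor is None else burn_in_factor
        pop = run_burn_in(params, rng, burn_in_factor=factor)
    else:
        raise ValueError(f"unknown burn_in mode {burn_in!r}")
    phase = run_sweep_phase_direct if direct else run_sweep_phase
    return phase(pop, params, rng, max_attempts=max_attempts)
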