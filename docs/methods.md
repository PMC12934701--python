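# Methods

## Simulation model

Each replicate simulates a panmictic diploid Wright–Fisher population.
Generations are discrete and non-overlapping; each offspring draws two
parents independently with probability proportional to fitness, receives
one gamete from each (a crossover mosaic with Poisson(R·L) breakpoints per
meiosis), and acquires Poisson(μ·L) new mutations at continuous
infinite-sites positions uniform on [0, L).  Genotype fitnesses at the
sweep locus are 1, 1+hs, 1+s for 0/1/2 copies.

Demography follows the logistic map
N<sub>t+1</sub> = round(r·N<sub>t</sub>(1 − N<sub>t</sub>/K) + N<sub>t</sub>),
active from sweep introduction onward, with sizes rounded to the nearest
individual and floored at 2.  r = 0 is a constant population; 0 < r < 0.5
gives gradual growth or decay toward K; 2 < r < √6 a period-2 cycle;
√6 < r < 3 chaotic fluctuation.  Because sizes are integers, the cycling
regime settles onto exactly two alternating sizes, and the converging
regimes park one step below K once the per-generation increment rounds to
zero — the tests assert convergence into that integer neighborhood rather
than equality with K.

Parameters are drawn per replicate: N<sub>A</sub> uniform; s log-uniform on
[1/N<sub>A</sub>, 1]; h uniform on [0, 1]; μ, R, t<sub>a</sub> log-uniform;
r and K by scenario (growth K/N<sub>A</sub> ∈ [1.01, 2], decay
[0.5, 0.99], cycling/chaotic [0.8, 1.2]).

**Conditioning on fixation.**  The sweep allele's genotype-count trajectory
is independent of the neutral background, so the simulator factorizes the
conditioned sweep: it draws diploid genotype-count trajectories
(multinomial over Hardy–Weinberg proportions at the fitness-weighted gamete
frequency, demography applied deterministically) until one fixes — each
lost trajectory counts as one restart attempt, up to 1000, after which the
replicate is abandoned — and then simulates the full population conditioned
on that trajectory: gametes that must (or must not) carry the allele choose
parents with probability proportional to fitness × transmission
probability, and heterozygous parents transmit the required chromosome with
crossover mosaics anchored at the sweep position.  This is exactly
equivalent in distribution to restarting the whole simulation on every loss
(`run_sweep_phase_direct`, kept as a cross-check; a Kolmogorov–Smirnov test
on t<sub>f</sub> confirms agreement) but avoids evolving the genome through
discarded attempts.

**Burn-in.**  Equilibrium standing variation comes either from an explicit
neutral forward burn-in (default 10·N<sub>A</sub> generations; the tests
verify per-site diversity ≈ 4N<sub>A</sub>μ) or from a neutral coalescent
draw via msprime, which is statistically equivalent and much faster; the
study pipeline defaults to the coalescent burn-in.

## Scale profiles

The `full` profile is the study's condition set: N<sub>A</sub> ∈
[1000, 10000], L = 100 kb, n = 128, μ ∈ LU(−8.5, −7.5), R ∈ LU(−9, −7),
t<sub>a</sub> ∈ LU(0, 4), burn-in 10·N<sub>A</sub>.

The `desk` profile makes single-CPU replication possible via the standard
coalescent rescaling: N<sub>A</sub> ∈ [200, 1000], L = 20 kb, burn-in
factor 4, with μ ∈ LU(−7, −6), R ∈ LU(−7.5, −5.5) and t<sub>a</sub> ∈
LU(0, 3) chosen to preserve 4NμL, 4NRL, and the t<sub>a</sub>/N ratio.
Windows then carry a comparable number of segregating sites (≈90 on
average against the 128-variant cap) and sweep signals decay over
comparable rescaled timescales.  Without the rate rescaling a 20 kb window
at N<sub>A</sub> ≈ 600 would hold ≈0.4 segregating sites and every
statistic would be undefined.

Problem sizes used by the shipped analyses: the test suite's recovery
checks run 1800 desk simulations; `scripts/acceptance.py` runs 2000 (its
`--n-sims` flag overrides).  Correlations at these sizes carry test-set
standard errors of roughly ±0.05–0.08 on r.

## Statistics

All 17 statistics ignore phase.  π is the window total of the unbiased
per-site heterozygosity 2j(2n−j)/(2n(2n−1)); θ<sub>W</sub> = S/a₁; Tajima's
D uses the standard variance constants; Var[D] is the sample variance of D
over non-overlapping 16-variant blocks (complete blocks only, so S < 32
leaves it undefined).  Diplotype statistics treat each individual's window
row as one multilocus genotype: with sorted frequencies p₁ ≥ p₂ ≥ …,
h1 = Σp², h2 = h1 − p₁², h12 = (p₁+p₂)² + Σ<sub>i>2</sub>p², h123
analogously.  The gkl statistics are the bias-corrected sample variance,
skewness and excess kurtosis of pairwise genotype-mismatch counts.  Mean
r² averages squared Pearson correlations of dosage vectors over SNP pairs,
skipping zero-variance pairs.  Kim's ω maximizes, over split indices
ℓ ∈ [2, S−2], the ratio of mean within-block to mean between-block r²
(requiring S ≥ 6).  The unphased H-scan averages, over individual pairs,
the base-pair span of the maximal contiguous run of agreeing dosages
anchored at the variants flanking the window center, normalized by the
window span so it lies in [0, 1].  A record is valid only if all 17 values
are finite; invalid records are excluded downstream, which mirrors the
study-level filter and mostly removes windows too sparse for Var[D] or ω.

## Stratification

Completed simulations are downsampled to a uniform log10 t<sub>f</sub>
histogram (0.1-wide bins equalized to the minimum occupied bin).  Because
t<sub>f</sub> is continuous, the extreme bins of any finite sample hold a
handful of records and the bare rule would discard nearly everything; the
pipeline therefore equalizes over a dense t<sub>f</sub> span: bins holding
fewer than half the median occupied-bin count are dropped before
equalizing.  The fraction was chosen for retention stability (it keeps
roughly 60% of valid desk records versus under 20% for the bare rule or
fixed quantile trims, whose yield is erratic because one straggler bin
drags every bin down).  The bare rule remains available and is what the
unit tests exercise on toy histograms.  Splits are 80/10/10 with validation
and test floored.

A consequence of the desk profile worth keeping in mind when reading
correlations: attainable t<sub>f</sub> is bounded by roughly 4N
generations, so the desk N<sub>A</sub> range caps the retained uniform
log10 t<sub>f</sub> span near 1.8 decades, against roughly 2.6 at full
scale.  Pearson r depends on the truth variance as well as the prediction
error, so desk-scale correlations run a few hundredths below full-scale
ones even at equal per-record accuracy.

## ABC

The target is log10 t<sub>f</sub>.  Statistics enter the distance after the
model-scale transforms (log10 of π, θ<sub>W</sub>, ω) and division by the
training-set median absolute deviation (standard deviation when the MAD is
zero; constant statistics are dropped with a warning).  Rejection accepts
the ⌈tolerance·N⌉ nearest records by Euclidean distance with uniform
weights.  Local-linear and ridge adjustment fit an Epanechnikov-weighted
regression of the target on centered statistics over the accepted set and
shift the draws by θ* = θ − (S − s<sub>query</sub>)ᵀβ̂; a singular
local-linear design falls back to ridge (λ default 10⁻³, intercept
unpenalized).  Point estimates: weighted mean, weighted median, or the mode
of a Silverman-bandwidth Gaussian KDE.  The grid crosses 3 methods × 7
tolerances {0.025 … 0.3} × 3 estimates = 63 configurations, scored by
Pearson r between validation predictions and truth; ties break toward the
smaller tolerance, then rejection before the regression methods.

## Neural regressors

Both networks minimize MSE on log10 t<sub>f</sub> with Adam at its standard
10⁻³ rate, batches of 32, early stopping with patience 20, restore-best
weights, and a 200-epoch cap.  Raw statistic scales differ by orders of
magnitude, so the dense network standardizes inputs with training-set
z-scores.  The convolutional network takes the clustered n×128 image and
the 128-long position vector in two branches (conv 7/stride 2, then two
conv 3/stride 1, each followed by 2×2 max-pooling and dropout; the pooling
type and size are unspecified in the underlying design and fixed here as
max/2).  Training images are flipped horizontally or vertically (coin flip
per image) as augmentation.  Hyperparameters are drawn by uniform random
search (60 draws by default — enough to land in the top 5% of the
performance range with probability 1 − 0.95⁶⁰ ≈ 0.954); a model-based
optimizer can be slotted in, but random search keeps the tuner dependency-
free and statistically comparable at this draw count.  Predictive
uncertainty is Monte-Carlo dropout: 100 stochastic passes, mean as point
estimate, standard deviation as spread (exactly zero when all dropout rates
are zero).

The engine itself is a compact numpy implementation (dense, conv2d via
im2col, max-pool, inverted dropout, manual backprop) whose gradients are
verified against finite differences in the test suite.

## Evaluation

Partial R² of each statistic for log10(t<sub>f</sub>+t<sub>a</sub>) uses
two OLS fits per statistic — the full 17-term model and the model without
that statistic — with R²<sub>m</sub> = (SSE(m) − SSE(M))/SSE(m); records
whose log-transformed terms are undefined are dropped, and rank-deficient
reduced fits are flagged.  The fit uses the training set.  Model reports
give Pearson r with Fisher-z 95% CIs and a descriptive CI-overlap flag, and
stratify absolute error by sweep age (old: t<sub>a</sub> > 1000) to expose
the old-fast vs young-slow confusion.

## Numerical and design notes

- Acceptance counts use ⌈tolerance·N⌉; accepted sets equal an exhaustive
  distance sort (property-tested at N ≤ 200).
- Monomorphic columns are purged from the forward simulation every 8
  generations (inert between purges, so any cadence is exact).
- VCF output maps continuous positions to unique increasing 1-based
  integers; REF/ALT are synthetic A/T since the simulator is
  allele-label-free.
- Images pad missing columns on the right with black and carry position
  value 1.0 there to preserve monotonicity; dendrogram ties break by
  original row index, making encodings reproducible.
- The theory check on mean t<sub>f</sub> uses the classical additive-model
  expectation 2·ln(2cN<sub>e</sub>−1)/s, whose s is the per-allele-copy
  advantage — genotype fitnesses 1 : 1+s : 1+2s, i.e. (h = 0.5,
  s<sub>hom</sub> = 2s) in this parameterization.
- If the population shrinks below the sample size at sampling time
  (possible under decay), the replicate is marked abandoned.

## What the generator does and does not emulate

The synthetic data are single panmictic populations, complete hard sweeps
only, sampled at one time point, with neutral flanking variation and free
recombination-mutation scaling.  Real data add population structure,
soft/partial sweeps, background selection, variable recombination and
mutation landscapes, genotyping error and missingness — none of which are
modeled.  Passing recovery tests therefore show that the inference engines
extract the t<sub>f</sub> signal the model family encodes, not that the
fitted models transfer to natural populations without retraining on
realistic simulations.

## Known limitations

- The conditioned simulator assumes the sweep-site allele is the only
  selected variant; no interference among sweeps.
- The CNN is exercised at reduced image/filter sizes in the shipped
  analyses; full-scale (128×128, 60-draw tuning) training is supported but
  slow on one CPU in a numpy engine.
- ABC conventions (MAD scaling, ⌈tol·N⌉ acceptance, Silverman-KDE mode)
  are declared defaults; other ABC software draws these details
  differently.
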