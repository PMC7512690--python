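# Methods

## Model and measures

The package works with stationary zero-mean Gaussian descriptions of an
N-element dynamical system, summarized by the 2N × 2N covariance of the
past state X and the present state X′ (block order: past first). The
canonical generative model is the first-order vector autoregression
X′ = AX + E with innovation covariance Σ(E); its stationary covariance
solves the discrete Lyapunov equation Σ(X) = AΣ(X)Aᵀ + Σ(E) (solved
directly via `scipy.linalg.solve_discrete_lyapunov`) and the lag-one
cross-covariance is Σ(X)Aᵀ. Models with spectral radius ≥ 1 − 1e−9 are
rejected rather than regularized: the analysis is meaningful only for a
stationary law. Joint covariances can equally be estimated from a
(T × N) time series by lagged sample covariances (biased 1/T
normalization, symmetrized, optional diagonal jitter
ε = 1e−10·trace/dim when the estimate is numerically singular).

For a bipartition {S, S̄} with subsystem blocks M₁ = S, M₂ = S̄ (and
their present copies M₁′, M₂′), the three measures are KL divergences
from p to the nearest q in three nested model families:

* **Φ_MI** (mutual information): q = product of the two parts'
  (past, present) marginals; closed form
  Φ_MI = ½(log det Σ(M₁,M₁′) + log det Σ(M₂,M₂′) − log det Σ(X,X′)).
* **Φ_SI** (stochastic interaction): q factorizes the transition law,
  q(X′|X) = Π q(Mᵢ′|Mᵢ); closed form
  Φ_SI = Σᵢ H(Mᵢ′|Mᵢ) − H(X′|X), conditional entropies via
  log-determinant differences.
* **Φ_G** (geometric): q removes only *causal* cross-partition
  influence — the Markov constraint q(Mᵢ′|X) = q(Mᵢ′|Mᵢ) — while the
  equal-time dependence of the present may remain. No closed form
  exists; see the solver below.

All values are in nats (natural logarithm throughout; every benchmark
quantity here — zeros, counts, rates — is base-invariant). All
log-determinants go through Cholesky factorizations; full covariances
are never explicitly inverted inside the entropy terms, which keeps the
measures usable at 2N = 128 dimensions. Values in (−1e−9, 0) are
clamped to zero as float noise; anything more negative raises, since a
genuinely negative divergence indicates a bug or inconsistent input,
not roundoff.

## The geometric-measure solver

For Gaussians the constrained family of Φ_G is exactly: q(X) = p(X) and
X′ = BX + E′ with B block-diagonal with respect to the partition (each
part's present regresses only on its own past) and the innovation
covariance D left free — a free D is what keeps equal-time interactions
intact, since the conditional q(Mᵢ′|X) = N(Bᵢᵢ Mᵢ, Dᵢᵢ) depends on Mᵢ
only regardless of D's off-diagonal blocks. Writing R(B) for the
covariance of X′ − BX under p,

    2·KL(p‖q) = tr(D⁻¹ R(B)) − N + log det D − log det Σ(X′|X),

and the solver is exact block-coordinate descent:

1. given D, each within-part block of B solves the linear normal
   equations [D⁻¹(BΣ(X) − Σ(X′,X))]₍ᵢᵢ₎ = 0 (the two blocks are coupled
   through D⁻¹ and are updated Gauss–Seidel style);
2. given B, the optimal D is R(B) itself.

Each step minimizes the KL exactly in one parameter block, so the
objective is monotone non-increasing and the fixed point satisfies the
stationarity conditions of the constrained minimization; at
convergence Φ_G = ½(log det D − log det Σ(X′|X)). Iteration stops when
the max-abs change of (B, D) falls below `tol` (default 1e−8, cap
10,000 iterations; exceeding the cap raises — a partial value is never
returned silently). B is initialized from the full regression
Σ(X′,X)Σ(X)⁻¹ restricted to its within-part blocks. The solver is
cross-checked in the tests against a generic derivative-free
minimization of the same KL over all free parameters of q (agreement
to 1e−5), and against the analytic zero for block-decoupled models.
Because the parameter tolerance, not the value tolerance, controls
termination, Φ_G uses a slightly wider negative-clamp band (10·tol).

## Partition search

Bipartitions are canonicalized to the side containing element 1
(1-based in all I/O, 0-based internally), which identifies S with its
complement; there are 2^(N−1) − 1 of them, enumerable up to N = 24.
Φ(S) is a symmetric set function with Φ(∅) = Φ(Ω) = 0.

**Queyranne's algorithm** runs N − 1 pendant-pair phases. A phase
builds a maximum-adjacency ordering: starting from the first group, it
repeatedly appends the candidate u minimizing f(W ∪ {u}) − f({u}); the
last group of the ordering is the phase's candidate cut, and the last
two groups are merged for the next phase. For symmetric submodular f
(Φ_MI) the best candidate cut over all phases is the exact minimum; for
Φ_SI and Φ_G it is a heuristic whose empirical accuracy the benchmarks
quantify. Ties in the key and in candidate cuts are broken by lowest
original element index / earliest phase, making the search fully
deterministic.

*Evaluation counting.* Reported counts follow a strict convention:
every key evaluation counts f(W ∪ {u}) and f({u}) as two separate
oracle calls with no memoization (a forced last candidate is still
evaluated), plus one counted call per phase to record the candidate
cut. The total is then a function of N alone,
(N³ − N)/3 + N − 1 — e.g. 2679 at N = 20, 41,699 at N = 50, 87,423 at
N = 64. A memoizing oracle mode exists for performance but is never
used when reporting counts.

**Replica-exchange MCMC** runs R Metropolis chains at inverse
temperatures β₁ < … < β_R on p(S; β) ∝ exp(−βΦ(S)). Each sweep
attempts N uniformly chosen single-element flips per replica (proposals
that would empty or fill a side are rejected without an oracle call;
every evaluated proposal increments the oracle counter), then proposes
swaps between alternating neighbor pairs with probability
min(1, exp((βᵢ − βⱼ)(Φᵢ − Φⱼ))). Defaults: R = 8, geometric ladder. If
no ladder is given, a short seeded pilot walk estimates the median
single-flip |ΔΦ| = δ and sets β_max = log(20)/δ (≈5% acceptance of an
adverse flip at the coldest replica) and β_min = 0.1/δ. Convergence is
declared when the best-so-far partition is unchanged for W sweeps
(default W = 50·N) *and* every neighbor exchange rate over that window
is at least 0.1; a near-unity exchange rate only signals overlapping
replicas (wasted parallelism, not broken mixing), so no upper bound is
enforced. This criterion is a pragmatic design choice; alternatives
(e.g. equilibration tests on the energy trace) would serve equally.
All randomness derives from one master seed through independent
spawned streams, so runs are bit-reproducible. Sampling correctness is
tested against exact Boltzmann enumeration (χ² at N = 8) and a
two-replica product-law check.

## Synthetic network ensembles

The benchmark generator emulates weakly coupled linear networks:

* **normal**: A entries iid N(0, 0.01/N);
* **block**: two decoupled N/2 sub-networks with entries iid
  N(0, 0.02/N), off-diagonal blocks exactly zero — so the
  half-and-half cut is causally silent and Φ_G across it is exactly 0;
* Σ(E) ~ Wishart(scale σI, dof 2N), σ ∈ {0.01, 0.1} (mean 2NσI), which
  produces well-conditioned but non-diagonal noise, i.e. equal-time
  correlations across the whole system.

Draws are rejected and resampled (fresh substream) in the rare event of
spectral radius ≥ 1. These ensembles capture the regime the method
targets — many weakly interacting Gaussian channels — but not features
of real neural recordings such as nonstationarity, non-Gaussian
amplitude distributions, strong global rhythms, or measurement
artifacts; passing benchmarks demonstrates searcher accuracy on the
model class, not estimator robustness on raw data.

Accuracy of a heuristic against exhaustive ground truth is summarized
per trial by: CR (found partition equals *any* exhaustive minimizer
within Φ-tolerance 1e−9), RA (rank of the found partition's Φ among all
cuts), ER ((Φ_found − Φ_MIP)/(Φ̄ − Φ_MIP) with Φ̄ the mean over all
cuts including the MIP; defined as 0 when the denominator vanishes),
and CORR (absolute Pearson correlation of ±1 membership vectors,
complement-invariant). A hit forces RA = 1, ER = 0, CORR = 1 exactly.
When two searchers are compared without ground truth, a trial is
"even" when their Φ values agree within 1e−9.

## Experiment scales

The shipped experiment presets are sized so the full test suite and the
acceptance script each run in minutes on a single core; the scales are
part of the package's own benchmark design:

* Queyranne evaluation counts: N = 20, 50, 64 (count is data- and
  measure-independent).
* Φ_SI accuracy: N = 14, exhaustive over 8191 cuts; 100 trials in the
  acceptance script, 15 per setting in the test suite.
* Φ_G accuracy: N = 10 (511 cuts), 40 trials (script) / 10 per setting
  (tests); the full N = 14, 100-trial version of this experiment is
  available through `AccuracyConfig(n=14, trials=100, measures=("g",))`
  but is computationally heavy because each exhaustive scan performs
  thousands of iterative Φ_G solves.
* Queyranne-vs-REMCMC agreement: N = 20, Φ_SI, 5 trials, convergence
  window 300 sweeps.

## Known limitations

* Only bipartitions are searched; K-way partitions and the search for
  the Φ-maximizing "complex" subnetwork are out of scope.
* Only Gaussian (or Gaussian-approximated) laws are supported; for
  strongly non-Gaussian data the measures are those of the best
  Gaussian fit.
* No normalization of Φ by partition size is applied; normalized
  variants break the submodularity that motivates Queyranne's
  algorithm.
* Queyranne's algorithm has no optimality guarantee for Φ_SI/Φ_G; the
  benchmarks bound its empirical error on the shipped ensembles only.
* AR estimation utilities assume a single lag; higher-order or
  frequency-domain structure must be folded into the state vector by
  the caller.
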