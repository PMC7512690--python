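# phimip

Integrated-information measures for Gaussian dynamical systems, and fast
search for the **Minimum Information Partition** (MIP).

## The problem

Integrated information Φ quantifies how much a multivariate stochastic
system — a cortical electrode array, a biological network, a coupled
oscillator bank — behaves as one irreducible whole rather than as
independent parts. Φ is defined as the information lost when the joint
past/present law p(X, X′) is replaced by a "disconnected" law q in which
cross-partition interactions are removed:

    Φ(S) = min_q  D_KL[ p(X, X′) ‖ q(X, X′) ]

for a bipartition of the N elements into S and its complement. The MIP
is the bipartition where Φ is smallest — the split between the system's
least interdependent parts:

    S_MIP = argmin_{∅ ⊂ S ⊂ Ω} Φ(S)

Exhaustive search over all 2^(N−1) − 1 bipartitions is hopeless beyond
N ≈ 20. This package implements two practical searchers:

* **Queyranne's algorithm** — exact for symmetric *submodular* set
  functions with O(N³) oracle calls. Of the three Φ measures here,
  mutual information Φ_MI is submodular; stochastic interaction Φ_SI
  and geometric integrated information Φ_G are not, yet empirically the
  algorithm recovers their MIP almost perfectly.
* **Replica-exchange MCMC** (parallel tempering) over the Boltzmann
  family p(S; β) ∝ exp(−β Φ(S)) — a measure-agnostic stochastic
  baseline used to validate Queyranne's results where enumeration is
  impossible.

All three measures are computed in closed form (Φ_MI, Φ_SI) or by a
monotone block-coordinate solver (Φ_G) for stationary Gaussian systems,
in particular first-order vector autoregressions X′ = AX + E. They obey
Φ_G ≤ Φ_SI ≤ Φ_MI.

Intended users: computational neuroscientists and complex-systems
researchers applying integrated-information analysis to multichannel
time series (EEG/ECoG-scale, up to ~100 channels) or to simulated
network models.

## Worked example

```python
from phimip import MIPSearch, NetworkSpec, generate_network

# a 14-element AR(1) network: two causally decoupled 7-element blocks
model = generate_network(NetworkSpec(kind="block", n=14, sigma=0.1, seed=0))
problem = MIPSearch.from_ar_model(model.A, model.sigma_e, measure="g")

res = problem.fit(method="queyranne")
print(res.summary())
```

Output:

```
Minimum Information Partition search
====================================================
System size (N):        14
Measure:                geometric integrated information (phi_G)
Search method:          queyranne
Partition:              {1,2,3,4,5,6,7}|{8,9,10,11,12,13,14}
Phi at partition:       0 nats
Phi evaluations:        923
```

The searcher recovers the built-in block structure: the MIP separates
elements 1–7 from 8–14, the two halves generated without any
cross-connectivity, and Φ_G across that cut is exactly 0 because no
causal influence crosses it. (With `measure="si"` the same network
gives a different MIP, {5} vs the rest at Φ_SI ≈ 0.225 nats —
stochastic interaction also counts the equal-time noise correlations
that the Wishart-sampled Σ(E) spreads across the halves.) The 923
evaluations follow the fixed count (N³−N)/3 + N − 1 instead of the 8191
an exhaustive scan needs; the gap widens to 41,699 vs ≈ 5.6·10¹⁴ at
N = 50.

Raw time series work the same way via
`MIPSearch.from_time_series(series, lag=1, measure="si")`, which
estimates the lagged joint Gaussian from a (T × N) array, and the same
functionality is exposed on the command line:

```bash
phimip search --measure si --method queyranne --series ecog.csv --out mip.json
phimip bench accuracy --preset quick
```

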