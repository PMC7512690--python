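"""Replica-exchange MCMC minimization of Phi over bipartitions.

The Boltzmann family p(S; beta) ∝ exp(-beta * Phi(S)) concentrates on
low-Phi partitions as the inverse temperature beta grows.  Several
Metropolis chains ("replicas") run in parallel at different beta and
periodically exchange states, which lets cold replicas escape local
minima via the hot ones.  The minimizer is read off as the best
partition ever visited.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError
from .partitions import Bipartition
from .search import MIPSearchResult


@dataclass
class REMCMCConfig:
    """Tuning knobs for the replica-exchange search.

    If ``beta_min``/``beta_max`` are left unset they are chosen from a
    short seeded pilot walk: with delta the median single-flip |ΔPhi|,
    ``beta_max = log(20)/delta`` (coldest-replica acceptance of an
    adverse flip ≈ 5%) and ``beta_min = 0.1/delta`` (near-free hot
    replica).  The ladder is geometric.

    Convergence is declared when the best-so-far partition has not
    changed for ``window`` sweeps (default 50*N) and every
    neighboring-pair exchange rate over that window lies inside
    ``exchange_band``.  The band's default upper edge is 1.0: a
    near-unity exchange rate means neighboring replicas overlap, which
    wastes replicas but does not impair mixing, so only the lower edge
    (a stuck ladder) blocks convergence.
    """

    n_replicas: int = 8
    beta_min: float | None = None
    beta_max: float | None = None
    max_sweeps: int = 200_000
    window: int | None = None
    exchange_band: tuple[float, float] = (0.1, 1.0)
    pilot_flips: int = 64
    seed: int | None = None


class ReplicaEnsemble:
    """State of R replicas: memberships, energies, ladder, counters."""

    def __init__(self, n: int, betas, seed=None, init_states=None):
        self.n = int(n)
        self.betas = np.asarray(betas, dtype=float)
        if self.betas.ndim != 1 or len(self.betas) < 1:
            raise ValidationError("beta ladder must be a nonempty 1-D sequence")
        if np.any(self.betas < 0) or np.any(np.diff(self.betas) <= 0):
            raise ValidationError("beta ladder must be nonnegative and strictly increasing")
        self.r = len(self.betas)
        master = np.random.default_rng(seed)
        # one independent stream per replica plus one for exchanges/init
        streams = master.spawn(self.r + 1)
        self.rngs = streams[: self.r]
        self.exchange_rng = streams[self.r]
        self.states = np.zeros((self.r, self.n), dtype=bool)
        if init_states is not None:
            init_states = np.asarray(init_states, dtype=bool)
            if init_states.shape != self.states.shape:
                raise ValidationError("init_states must be (R, N) boolean")
            self.states[:] = init_states
        else:
            for k in range(self.r):
                while True:
                    s = self.exchange_rng.random(self.n) < 0.5
                    if 0 < s.sum() < self.n:
                        break
                self.states[k] = s
        self.energies = np.full(self.r, np.nan)
        self.best_value = np.inf
        self.best_state: np.ndarray | None = None
        self.best_sweep = 0
        self.sweep = 0
        self.exchange_parity = 0
        self.exchange_attempts = np.zeros(max(self.r - 1, 0), dtype=int)
        self.exchange_accepts = np.zeros(max(self.r - 1, 0), dtype=int)

    def initialize_energies(self, oracle) -> None:
        for k in range(self.r):
            self.energies[k] = oracle(np.flatnonzero(self.states[k]))
            self._update_best(k)

    def _update_best(self, k: int) -> None:
        if self.energies[k] < self.best_value:
            self.best_value = float(self.energies[k])
            self.best_state = self.states[k].copy()
            self.best_sweep = self.sweep

    @property
    def exchange_rates(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(
                self.exchange_attempts > 0,
                self.exchange_accepts / np.maximum(self.exchange_attempts, 1),
                np.nan,
            )

    def reset_exchange_counters(self) -> None:
        self.exchange_attempts[:] = 0
        self.exchange_accepts[:] = 0

    def best_partition(self) -> Bipartition:
        if self.best_state is None:
            raise ValidationError("ensemble has no evaluated state yet")
        return Bipartition.from_members(np.flatnonzero(self.best_state), self.n)


def mh_sweep(ensemble: ReplicaEnsemble, oracle) -> ReplicaEnsemble:
    """One Metropolis sweep: each replica attempts N single-element flips.

    Proposals that would empty or fill the subset are rejected without an
    oracle call; every other proposal costs exactly one evaluation.
    """
    n = ensemble.n
    for k in range(ensemble.r):
        rng = ensemble.rngs[k]
        beta = ensemble.betas[k]
        state = ensemble.states[k]
        size = int(state.sum())
        energy = ensemble.energies[k]
        flips = rng.integers(0, n, size=n)
        for j in flips:
            new_size = size + (-1 if state[j] else 1)
            if new_size == 0 or new_size == n:
                continue
            state[j] = not state[j]
            new_energy = oracle(np.flatnonzero(state))
            delta = new_energy - energy
            if delta <= 0 or rng.random() < math.exp(-beta * delta):
                energy = new_energy
                size = new_size
                if energy < ensemble.best_value:
                    ensemble.energies[k] = energy
                    ensemble._update_best(k)
            else:
                state[j] = not state[j]  # revert
        ensemble.energies[k] = energy
    return ensemble


def exchange_step(ensemble: ReplicaEnsemble) -> ReplicaEnsemble:
    """Propose swaps between neighboring replicas (alternating pairing).

    A swap between replicas at beta_i < beta_j with energies E_i, E_j is
    accepted with probability min(1, exp((beta_i - beta_j)(E_i - E_j))).
    No oracle calls are made.
    """
    if ensemble.r < 2:
        return ensemble
    start = ensemble.exchange_parity
    ensemble.exchange_parity = 1 - ensemble.exchange_parity
    for i in range(start, ensemble.r - 1, 2):
        j = i + 1
        ensemble.exchange_attempts[i] += 1
        log_ratio = (ensemble.betas[i] - ensemble.betas[j]) * (
            ensemble.energies[i] - ensemble.energies[j]
        )
        if log_ratio >= 0 or ensemble.exchange_rng.random() < math.exp(log_ratio):
            ensemble.exchange_accepts[i] += 1
            ensemble.states[[i, j]] = ensemble.states[[j, i]]
            ensemble.energies[[i, j]] = ensemble.energies[[j, i]]
    return ensemble


def _pilot_ladder(oracle, n: int, config: REMCMCConfig, rng) -> tuple[float, float]:
    """Estimate the single-flip energy scale and derive a beta range."""
    deltas = []
    state = np.zeros(n, dtype=bool)
    state[: max(1, n // 2)] = True
    energy = oracle(np.flatnonzero(state))
    for _ in range(config.pilot_flips):
        j = int(rng.integers(0, n))
        new_size = int(state.sum()) + (-1 if state[j] else 1)
        if new_size == 0 or new_size == n:
            continue
        state[j] = not state[j]
        new_energy = oracle(np.flatnonzero(state))
        if abs(new_energy - energy) > 0:
            deltas.append(abs(new_energy - energy))
        energy = new_energy
    delta = float(np.median(deltas)) if deltas else 1.0
    return 0.1 / delta, math.log(20.0) / delta


def geometric_ladder(beta_min: float, beta_max: float, r: int) -> np.ndarray:
    if not (0 < beta_min < beta_max):
        raise ValidationError("need 0 < beta_min < beta_max")
    return np.geomspace(beta_min, beta_max, r)


def remcmc_mip(oracle, n: int, config: REMCMCConfig | None = None) -> MIPSearchResult:
    """Replica-exchange search for the MIP.

    Alternates Metropolis sweeps and neighbor exchanges until the
    convergence criterion holds or ``max_sweeps`` is exhausted (the
    result is then flagged unconverged but still returns the best
    partition seen).  Fully deterministic given ``config.seed``.
    """
    config = config or REMCMCConfig()
    master = np.random.default_rng(config.seed)
    pilot_seed, ensemble_seed = master.integers(2**31, size=2)

    beta_min, beta_max = config.beta_min, config.beta_max
    if beta_min is None or beta_max is None:
        auto_min, auto_max = _pilot_ladder(
            oracle, n, config, np.random.default_rng(pilot_seed)
        )
        beta_min = beta_min if beta_min is not None else auto_min
        beta_max = beta_max if beta_max is not None else auto_max
    betas = geometric_ladder(beta_min, beta_max, config.n_replicas)

    ensemble = ReplicaEnsemble(n, betas, seed=ensemble_seed)
    ensemble.initialize_energies(oracle)
    window = config.window if config.window is not None else 50 * n
    lo, hi = config.exchange_band

    converged = False
    last_best_sweep = ensemble.best_sweep
    ensemble.reset_exchange_counters()
    while ensemble.sweep < config.max_sweeps:
        ensemble.sweep += 1
        mh_sweep(ensemble, oracle)
        exchange_step(ensemble)
        if ensemble.best_sweep != last_best_sweep:
            last_best_sweep = ensemble.best_sweep
            ensemble.reset_exchange_counters()
        elif ensemble.sweep - last_best_sweep >= window:
            rates = ensemble.exchange_rates
            if ensemble.r < 2 or bool(np.all((rates >= lo) & (rates <= hi))):
                converged = True
                break

    return MIPSearchResult(
        partition=ensemble.best_partition(),
        phi=float(ensemble.best_value),
        n_evals=getattr(oracle, "count", 0),
        method="remcmc",
        measure=getattr(getattr(oracle, "fn", oracle), "measure", None),
        diagnostics={
            "converged": converged,
            "sweeps": ensemble.sweep,
            "solution_found_sweep": ensemble.best_sweep,
            "betas": betas.tolist(),
            "exchange_rates": ensemble.exchange_rates.tolist(),
        },
    )
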