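"""Random AR network ensembles and searcher-accuracy benchmarks.

Two network architectures are used to stress the partition searchers:

* ``normal`` — every connectivity entry iid N(0, 0.01/N);
* ``block`` — two decoupled N/2-blocks whose entries are iid
  N(0, 0.02/N), off-diagonal blocks exactly zero (so the half-and-half
  cut carries no causal interaction).

Innovation covariances are drawn from a Wishart distribution with scale
matrix sigma*I and 2N degrees of freedom.  Accuracy of a heuristic
searcher against exhaustive ground truth is summarized by four metrics:
correct rate (CR), rank of the found partition (RA), error ratio (ER),
and the absolute sign-vector correlation (CORR).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ar_gaussian import ARModel, joint_gaussian, spectral_radius
from .exceptions import ValidationError
from .measures import make_phi_function
from .partitions import Bipartition
from .remcmc import REMCMCConfig, remcmc_mip
from .search import CountedOracle, exhaustive_mip, queyranne_mip

_RESAMPLE_CAP = 1000
_PHI_TOL = 1e-9


@dataclass(frozen=True)
class NetworkSpec:
    """Specification of one random AR network draw."""

    kind: str  # "normal" | "block"
    n: int
    sigma: float  # Wishart scale of the innovation covariance
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("normal", "block"):
            raise ValidationError(f"unknown network kind {self.kind!r}")
        if self.kind == "block" and self.n % 2:
            raise ValidationError("block networks need an even N")
        if self.sigma <= 0:
            raise ValidationError("sigma must be positive")
        if self.n < 2:
            raise ValidationError("need N >= 2")


def generate_network(spec: NetworkSpec) -> ARModel:
    """Sample a stationary AR model from the given ensemble.

    The connectivity and the Wishart innovation covariance are redrawn
    together (fresh substream) until the spectral radius is below one;
    at the ensemble's variances this virtually never recurs.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    for _ in range(_RESAMPLE_CAP):
        sub = rng.spawn(1)[0]
        if spec.kind == "normal":
            A = sub.normal(0.0, np.sqrt(0.01 / n), size=(n, n))
        else:
            h = n // 2
            A = np.zeros((n, n))
            A[:h, :h] = sub.normal(0.0, np.sqrt(0.02 / n), size=(h, h))
            A[h:, h:] = sub.normal(0.0, np.sqrt(0.02 / n), size=(h, h))
        sigma_e = stats.wishart.rvs(df=2 * n, scale=spec.sigma * np.eye(n), random_state=sub)
        if spectral_radius(A) < 1.0 - 1e-9:
            return ARModel(A, sigma_e)
    raise ValidationError(
        f"no stationary draw in {_RESAMPLE_CAP} attempts for {spec}"
    )


def error_ratio(phi_q: float, phi_mip: float, phi_bar: float, tol: float = _PHI_TOL) -> float:
    """(Phi_Q - Phi_MIP) / (Phi_bar - Phi_MIP); 0 when both differences vanish."""
    if phi_bar < phi_mip - tol:
        raise ValidationError(
            "mean Phi below the minimum: inconsistent inputs "
            f"(phi_bar={phi_bar}, phi_mip={phi_mip})"
        )
    num = phi_q - phi_mip
    den = phi_bar - phi_mip
    if abs(den) <= tol:
        return 0.0
    return num / den


def partition_correlation(p1: Bipartition, p2: Bipartition) -> float:
    """Absolute Pearson correlation of the two ±1 sign vectors.

    Invariant to replacing either partition by its complement.
    """
    if p1.n != p2.n:
        raise ValidationError("partitions are over different system sizes")
    s1 = p1.sign_vector.astype(float)
    s2 = p2.sign_vector.astype(float)
    s1 -= s1.mean()
    s2 -= s2.mean()
    denom = np.sqrt((s1 @ s1) * (s2 @ s2))
    if denom == 0:  # cannot happen for proper bipartitions with N >= 2
        return 1.0
    return float(abs(s1 @ s2) / denom)


@dataclass
class BenchmarkRecord:
    """Per-trial outcome of a searcher-vs-ground-truth comparison."""

    trial: int
    seed: int
    kind: str
    sigma: float
    measure: str
    mip_partition: Bipartition
    found_partition: Bipartition
    phi_mip: float
    phi_found: float
    phi_bar: float
    correct: bool
    rank: int
    error_ratio: float
    correlation: float
    n_evals_exhaustive: int
    n_evals_search: int


@dataclass
class AccuracyConfig:
    """Configuration of the exhaustive-vs-Queyranne accuracy experiment."""

    n: int = 14
    trials: int = 100
    kinds: tuple[str, ...] = ("normal", "block")
    sigmas: tuple[float, ...] = (0.01, 0.1)
    measures: tuple[str, ...] = ("si", "g")
    seed: int = 0
    phi_kwargs: dict = field(default_factory=dict)


def _trial_seeds(master_seed: int, count: int) -> np.ndarray:
    return np.random.default_rng(master_seed).integers(2**31, size=count)


def evaluate_trial(
    model: ARModel,
    measure: str,
    trial: int = 0,
    seed: int = 0,
    kind: str = "normal",
    sigma: float = 0.0,
    phi_kwargs: dict | None = None,
) -> BenchmarkRecord:
    """Exhaustive ground truth vs Queyranne for one model: the four metrics."""
    joint = joint_gaussian(model)
    n = model.n
    kwargs = phi_kwargs or {}
    ex_oracle = CountedOracle.for_measure(joint, measure, **kwargs)
    truth = exhaustive_mip(ex_oracle, n, ranking=True)
    q_oracle = CountedOracle.for_measure(joint, measure, **kwargs)
    found = queyranne_mip(q_oracle, n)

    phi_bar = truth.phi_mean
    # a hit is a match to ANY minimizer within tolerance
    minimizers = {p for p, v in truth.ranking if v <= truth.phi + _PHI_TOL}
    correct = found.partition in minimizers
    rank = truth.rank_of(found.partition)
    if correct:  # exact implications of a hit
        er, corr, rank = 0.0, 1.0, 1
    else:
        er = error_ratio(found.phi, truth.phi, phi_bar)
        corr = partition_correlation(truth.partition, found.partition)
    return BenchmarkRecord(
        trial=trial,
        seed=seed,
        kind=kind,
        sigma=sigma,
        measure=measure,
        mip_partition=truth.partition,
        found_partition=found.partition,
        phi_mip=truth.phi,
        phi_found=found.phi,
        phi_bar=phi_bar,
        correct=correct,
        rank=rank,
        error_ratio=er,
        correlation=corr,
        n_evals_exhaustive=truth.n_evals,
        n_evals_search=found.n_evals,
    )


def run_accuracy_benchmark(config: AccuracyConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exhaustive-vs-Queyranne accuracy over random network ensembles.

    Returns ``(records, summary)``: the per-trial records and the
    per-(kind, sigma, measure) means of CR/RA/ER/CORR.  The whole table
    is a pure function of ``config.seed``.
    """
    rows = []
    seeds = _trial_seeds(config.seed, config.trials)
    for kind in config.kinds:
        for sigma in config.sigmas:
            for trial, seed in enumerate(seeds):
                spec = NetworkSpec(kind=kind, n=config.n, sigma=sigma, seed=int(seed))
                model = generate_network(spec)
                for measure in config.measures:
                    rec = evaluate_trial(
                        model,
                        measure,
                        trial=trial,
                        seed=int(seed),
                        kind=kind,
                        sigma=sigma,
                        phi_kwargs=config.phi_kwargs,
                    )
                    rows.append(rec)
    records = pd.DataFrame(
        {
            "trial": [r.trial for r in rows],
            "seed": [r.seed for r in rows],
            "kind": [r.kind for r in rows],
            "sigma": [r.sigma for r in rows],
            "measure": [r.measure for r in rows],
            "mip_partition": [r.mip_partition.to_string() for r in rows],
            "found_partition": [r.found_partition.to_string() for r in rows],
            "phi_mip": [r.phi_mip for r in rows],
            "phi_found": [r.phi_found for r in rows],
            "phi_bar": [r.phi_bar for r in rows],
            "correct": [r.correct for r in rows],
            "rank": [r.rank for r in rows],
            "error_ratio": [r.error_ratio for r in rows],
            "correlation": [r.correlation for r in rows],
            "n_evals_exhaustive": [r.n_evals_exhaustive for r in rows],
            "n_evals_search": [r.n_evals_search for r in rows],
        }
    )
    summary = (
        records.groupby(["kind", "sigma", "measure"], sort=False)
        .agg(
            CR=("correct", "mean"),
            RA=("rank", "mean"),
            ER=("error_ratio", "mean"),
            CORR=("correlation", "mean"),
            trials=("trial", "count"),
        )
        .reset_index()
    )
    return records, summary


@dataclass
class ComparisonConfig:
    """Configuration of the Queyranne-vs-REMCMC comparison experiment."""

    n: int = 50
    trials: int = 20
    kinds: tuple[str, ...] = ("normal", "block")
    sigmas: tuple[float, ...] = (0.01, 0.1)
    measure: str = "si"
    seed: int = 0
    remcmc: REMCMCConfig = field(default_factory=REMCMCConfig)
    phi_kwargs: dict = field(default_factory=dict)
    phi_tol: float = _PHI_TOL


def run_comparison_benchmark(config: ComparisonConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Queyranne vs replica-exchange on ensembles too large for enumeration.

    Per trial, each searcher's partition and Phi are recorded; the winner
    is the lower Phi, a tie within ``phi_tol`` counting as "even".
    Returns per-trial records and a per-setting summary with winning
    percentages and evaluation-count statistics.
    """
    rows = []
    seeds = _trial_seeds(config.seed, config.trials)
    for kind in config.kinds:
        for sigma in config.sigmas:
            for trial, seed in enumerate(seeds):
                spec = NetworkSpec(kind=kind, n=config.n, sigma=sigma, seed=int(seed))
                model = generate_network(spec)
                joint = joint_gaussian(model)
                q_oracle = CountedOracle.for_measure(joint, config.measure, **config.phi_kwargs)
                q_res = queyranne_mip(q_oracle, config.n)
                r_oracle = CountedOracle.for_measure(joint, config.measure, **config.phi_kwargs)
                r_conf = REMCMCConfig(**{**config.remcmc.__dict__, "seed": int(seed)})
                r_res = remcmc_mip(r_oracle, config.n, r_conf)
                if abs(q_res.phi - r_res.phi) <= config.phi_tol:
                    winner = "even"
                elif q_res.phi < r_res.phi:
                    winner = "queyranne"
                else:
                    winner = "remcmc"
                rows.append(
                    {
                        "trial": trial,
                        "seed": int(seed),
                        "kind": kind,
                        "sigma": sigma,
                        "measure": config.measure,
                        "queyranne_partition": q_res.partition.to_string(),
                        "remcmc_partition": r_res.partition.to_string(),
                        "partitions_match": q_res.partition == r_res.partition,
                        "phi_queyranne": q_res.phi,
                        "phi_remcmc": r_res.phi,
                        "winner": winner,
                        "n_evals_queyranne": q_res.n_evals,
                        "n_evals_remcmc": r_res.n_evals,
                        "solution_found_sweep": r_res.diagnostics["solution_found_sweep"],
                        "remcmc_converged": r_res.diagnostics["converged"],
                    }
                )
    records = pd.DataFrame(rows)
    summary = (
        records.groupby(["kind", "sigma"], sort=False)
        .agg(
            queyranne_wins=("winner", lambda w: float(np.mean(w == "queyranne"))),
            even=("winner", lambda w: float(np.mean(w == "even"))),
            remcmc_wins=("winner", lambda w: float(np.mean(w == "remcmc"))),
            match_rate=("partitions_match", "mean"),
            n_evals_queyranne=("n_evals_queyranne", "first"),
            n_evals_remcmc_mean=("n_evals_remcmc", "mean"),
            n_evals_remcmc_std=("n_evals_remcmc", "std"),
            converged_rate=("remcmc_converged", "mean"),
        )
        .reset_index()
    )
    return records, summary
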