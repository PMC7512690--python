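"""Model/Results facade over the partition searchers.

``MIPSearch`` plays the role of a statsmodels-style model object: it is
built from data (an AR model, a joint covariance, or a raw multichannel
time series) plus a choice of integrated-information measure, and its
:meth:`fit` runs a search method and returns :class:`MIPResults` with
the found partition, its Phi, evaluation counts and a ``summary()``.
"""

from __future__ import annotations

import numpy as np

from .ar_gaussian import ARModel, JointGaussian, estimate_joint_gaussian, joint_gaussian
from .exceptions import ValidationError
from .remcmc import REMCMCConfig, remcmc_mip
from .search import CountedOracle, MIPSearchResult, exhaustive_mip, queyranne_mip


class MIPSearch:
    """Minimum-information-partition search problem for one Gaussian system.

    Parameters
    ----------
    joint : JointGaussian or (2N, 2N) array
        Stationary joint covariance over (past, present).
    measure : {"mi", "si", "g"}
        Integrated-information measure to minimize over bipartitions.

    Examples
    --------
    >>> model = MIPSearch.from_ar_model(A, sigma_e, measure="si")
    >>> res = model.fit(method="queyranne")
    >>> print(res.summary())
    """

    def __init__(self, joint, measure: str = "si", phi_kwargs: dict | None = None):
        if not isinstance(joint, JointGaussian):
            joint = JointGaussian(np.asarray(joint, dtype=float))
        self.joint = joint
        self.measure = measure.lower()
        self.phi_kwargs = dict(phi_kwargs or {})

    @classmethod
    def from_ar_model(cls, A, sigma_e, measure: str = "si", **kwargs) -> "MIPSearch":
        """Build from AR(1) parameters via the analytic stationary law."""
        return cls(joint_gaussian(ARModel(A, sigma_e)), measure=measure, **kwargs)

    @classmethod
    def from_time_series(
        cls, series, lag: int = 1, measure: str = "si", **kwargs
    ) -> "MIPSearch":
        """Build from a (T, N) multichannel series via lagged sample covariances."""
        return cls(estimate_joint_gaussian(series, lag=lag), measure=measure, **kwargs)

    @property
    def n(self) -> int:
        return self.joint.n

    def oracle(self, memoize: bool = False) -> CountedOracle:
        return CountedOracle.for_measure(
            self.joint, self.measure, memoize=memoize, **self.phi_kwargs
        )

    def fit(self, method: str = "queyranne", **options) -> "MIPResults":
        """Run a search method and return the results object.

        method : {"queyranne", "exhaustive", "remcmc"}; extra keyword
        options are passed through (``ranking=True`` for exhaustive,
        an :class:`REMCMCConfig` or its fields for remcmc).
        """
        method = method.lower()
        oracle = self.oracle()
        if method == "exhaustive":
            raw = exhaustive_mip(oracle, self.n, **options)
        elif method == "queyranne":
            raw = queyranne_mip(oracle, self.n)
        elif method == "remcmc":
            config = options.pop("config", None)
            if config is None:
                config = REMCMCConfig(**options)
            elif options:
                raise ValidationError("pass either config or individual options, not both")
            raw = remcmc_mip(oracle, self.n, config)
        else:
            raise ValidationError(f"unknown search method {method!r}")
        return MIPResults(self, raw)


class MIPResults:
    """Fitted MIP search: found partition, Phi, and diagnostics."""

    def __init__(self, model: MIPSearch, raw: MIPSearchResult):
        self.model = model
        self.raw = raw

    @property
    def partition(self):
        return self.raw.partition

    @property
    def phi(self) -> float:
        return self.raw.phi

    @property
    def n_evals(self) -> int:
        return self.raw.n_evals

    @property
    def method(self) -> str:
        return self.raw.method

    @property
    def diagnostics(self) -> dict:
        return self.raw.diagnostics

    def to_dict(self) -> dict:
        out = {
            "n": self.model.n,
            "measure": self.model.measure,
            "method": self.method,
            "partition": self.partition.to_string(),
            "partition_complement": ",".join(
                str(i + 1) for i in self.partition.complement
            ),
            "phi_nats": self.phi,
            "n_evals": self.n_evals,
        }
        out.update(self.raw.diagnostics)
        return out

    def summary(self) -> str:
        measure_names = {
            "mi": "mutual information (phi_MI)",
            "si": "stochastic interaction (phi_SI)",
            "g": "geometric integrated information (phi_G)",
        }
        lines = [
            "Minimum Information Partition search",
            "=" * 52,
            f"System size (N):        {self.model.n}",
            f"Measure:                {measure_names[self.model.measure]}",
            f"Search method:          {self.method}",
            f"Partition:              {self.partition}",
            f"Phi at partition:       {self.phi:.6g} nats",
            f"Phi evaluations:        {self.n_evals}",
        ]
        for key, val in self.raw.diagnostics.items():
            if key in ("betas", "exchange_rates"):
                continue
            lines.append(f"{key + ':':<24}{val}")
        return "\n".join(lines)

    def plot_objective(self, ax=None):
        """Bar the ranked Phi values (exhaustive fits with a ranking only)."""
        if self.raw.ranking is None:
            raise ValidationError("ranking available only for exhaustive fits with ranking=True")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        values = [v for _, v in self.raw.ranking]
        ax.plot(range(1, len(values) + 1), values, ".", ms=3)
        ax.set_xlabel("partition rank")
        ax.set_ylabel(f"phi_{self.model.measure} (nats)")
        ax.axhline(self.phi, color="r", lw=0.8)
        return ax
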