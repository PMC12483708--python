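"""Model and results objects.

:class:`GrowthMixtureModel` is built from a :class:`LongitudinalDataset`
(or a long-format DataFrame / CSV) and a class count.  ``fit()`` runs
multi-start maximum marginal likelihood and returns
:class:`MLFitResults`; ``sample()`` runs HMC on the marginalized
posterior and returns :class:`PosteriorResults`, which carries the
draws, convergence statistics, relabeling, pathology diagnostics,
heterogeneity summaries and predictive criteria.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .convergence import ConvergenceStats, convergence_stats
from .data import LongitudinalDataset, read_long_csv
from .diagnostics import DiagnosticsConfig, DiagnosticsReport, diagnostics_report
from .draws import DrawsStore
from .hmc import SamplerOptions
from .inference import fit_ml, sample_posterior
from .likelihood import classification_probs, mixture_loglik
from .params import MixtureParams, ModelSpec, PriorConfig
from .priors import log_posterior, log_prior
from .relabel import RelabelingResult, apply_relabeling, stephens_relabel
from .summaries import (heterogeneity_summary, loo, pointwise_loglik,
                        posterior_heterogeneity, waic)


class GrowthMixtureModel:
    """A K-class growth mixture model for long-format panel data.

    Parameters
    ----------
    data : LongitudinalDataset
    n_classes : int
        Number of latent classes K >= 1.
    prior : PriorConfig, optional
        Defaults to weakly informative D10N50 priors.
    time_variable : str
        Label for the time coding ("occasion" for 0..3 or "age" for
        age - 6); informational, the data carry the actual values.
    """

    def __init__(self, data: LongitudinalDataset, n_classes: int,
                 prior: PriorConfig | None = None,
                 time_variable: str = "occasion"):
        if not isinstance(data, LongitudinalDataset):
            raise TypeError("data must be a LongitudinalDataset")
        self.data = data
        self.spec = ModelSpec(n_classes=n_classes, time_variable=time_variable)
        self.prior = prior or PriorConfig()

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, n_classes: int,
                       id_col="id", time_col="time", y_col="y",
                       **kwargs) -> "GrowthMixtureModel":
        data = LongitudinalDataset.from_dataframe(df, id_col, time_col, y_col)
        return cls(data, n_classes, **kwargs)

    @classmethod
    def from_csv(cls, path, n_classes: int, **kwargs) -> "GrowthMixtureModel":
        return cls(read_long_csv(path), n_classes, **kwargs)

    # ------------------------------------------------------------------
    @property
    def n_classes(self) -> int:
        return self.spec.n_classes

    def loglike(self, params: MixtureParams) -> float:
        """Mixture marginal log-likelihood at ``params``."""
        return mixture_loglik(params, self.data)

    def logprior(self, params: MixtureParams) -> float:
        return log_prior(params, self.prior)

    def logposterior(self, params: MixtureParams) -> float:
        return log_posterior(params, self.prior, self.data)

    def classification_probs(self, params: MixtureParams) -> np.ndarray:
        return classification_probs(params, self.data)

    # ------------------------------------------------------------------
    def fit(self, n_starts: int = 20, seed: int = 1) -> "MLFitResults":
        """Multi-start maximum marginal likelihood."""
        best, llf, optima = fit_ml(self.data, self.spec, n_starts=n_starts,
                                   seed=seed)
        return MLFitResults(self, best, llf, optima)

    def sample(self, n_chains: int = 4, warmup: int = 1000,
               iters: int = 1000, seed: int = 1,
               options: SamplerOptions | None = None,
               init: str = "ml") -> "PosteriorResults":
        """HMC sampling of the marginalized posterior.

        ``init="ml"`` (jittered maximum-likelihood starts) is the
        applied-fitting default; ``init="moments"`` uses cruder
        data-informed starts; ``init="random"`` uses diffuse
        Uniform(-2, 2) starts, appropriate when studying
        initialization- and prior-dependent sampling pathology.
        """
        draws = sample_posterior(self.data, self.spec, self.prior,
                                 n_chains=n_chains, warmup=warmup,
                                 iters=iters, seed=seed, options=options,
                                 init=init)
        return PosteriorResults(self, draws)


class MLFitResults:
    """Maximum marginal likelihood fit with multi-start bookkeeping."""

    def __init__(self, model: GrowthMixtureModel, params: MixtureParams,
                 llf: float, local_optima):
        self.model = model
        self.params = params
        self.llf = float(llf)
        #: (loglik, params) of distinct local optima, best first
        self.local_optima = local_optima

    @property
    def n_local_optima(self) -> int:
        return len(self.local_optima)

    def classification_probs(self) -> np.ndarray:
        return self.model.classification_probs(self.params)

    def summary(self) -> pd.DataFrame:
        rows = []
        for k, cp in enumerate(self.params.classes, start=1):
            rows.append({"class": k, "pi": self.params.pi[k - 1],
                         "beta0": cp.beta0, "beta1": cp.beta1,
                         "beta2": cp.beta2, "sd_int": cp.sd_int,
                         "sd_slope": cp.sd_slope, "corr": cp.corr})
        df = pd.DataFrame(rows)
        df.attrs["loglik"] = self.llf
        df.attrs["sigma_resid"] = self.params.sigma_resid
        df.attrs["n_local_optima"] = self.n_local_optima
        return df


class PosteriorResults:
    """Posterior draws plus everything computed from them."""

    def __init__(self, model: GrowthMixtureModel, draws: DrawsStore,
                 relabeling: RelabelingResult | None = None):
        self.model = model
        self.draws = draws
        self.relabeling = relabeling
        self._pointwise = None

    # ------------------------------------------------------------------
    def classification_prob_array(self) -> np.ndarray:
        """(S, n, K) classification probabilities for every kept draw."""
        S = self.draws.n_chains * self.draws.n_iter
        out = np.empty((S, self.model.data.n_subjects, self.model.n_classes))
        s = 0
        for c in range(self.draws.n_chains):
            for params in self.draws.iter_draws(c):
                out[s] = self.model.classification_probs(params)
                s += 1
        return out

    def relabel(self) -> "PosteriorResults":
        """Stephens KL relabeling; returns new results on permuted draws."""
        probs = self.classification_prob_array()
        result = stephens_relabel(probs)
        new_draws = apply_relabeling(self.draws, result)
        return PosteriorResults(self.model, new_draws, relabeling=result)

    # ------------------------------------------------------------------
    def convergence(self) -> ConvergenceStats:
        return convergence_stats(self.draws)

    def diagnostics(self, config: DiagnosticsConfig | None = None
                    ) -> DiagnosticsReport:
        return diagnostics_report(self.draws, self.model.data, config)

    # ------------------------------------------------------------------
    def pointwise_loglik(self) -> np.ndarray:
        if self._pointwise is None:
            self._pointwise = pointwise_loglik(self.draws, self.model.data)
        return self._pointwise

    def waic(self):
        """(elpd_waic, p_waic, waic) on the mixed predictive density."""
        return waic(self.pointwise_loglik())

    def loo(self):
        """(elpd_loo, p_loo) via PSIS-LOO on the mixed predictive density."""
        return loo(self.pointwise_loglik())

    # ------------------------------------------------------------------
    def posterior_mean_params(self) -> MixtureParams:
        return self.draws.posterior_mean_params()

    def credible_interval(self, column: str, level: float = 0.95):
        """Equal-tailed posterior interval of one named parameter column."""
        j = self.draws.columns.index(column)
        x = self.draws.params[:, :, j].ravel()
        a = (1.0 - level) / 2.0
        return float(np.quantile(x, a)), float(np.quantile(x, 1.0 - a))

    def heterogeneity(self, class_index: int, t0: float, T: float,
                      a0: float = 2.0, mode: str = "draws") -> dict:
        """Posterior heterogeneity descriptors for one class."""
        return posterior_heterogeneity(self.draws, class_index, t0, T,
                                       a0=a0, mode=mode)

    def heterogeneity_at_posterior_mean(self, class_index: int, t0: float,
                                        T: float, a0: float = 2.0,
                                        grid=None) -> dict:
        pm = self.posterior_mean_params()
        return heterogeneity_summary(pm.classes[class_index], t0, T,
                                     a0=a0, grid=grid)

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        """Posterior means, SDs, equal-tailed intervals, R-hat and ESS."""
        flat = self.draws.params.reshape(-1, self.draws.params.shape[2])
        a = (1.0 - level) / 2.0
        df = pd.DataFrame({
            "parameter": self.draws.columns,
            "mean": flat.mean(axis=0),
            "sd": flat.std(axis=0, ddof=1),
            f"{100 * a:g}%": np.quantile(flat, a, axis=0),
            f"{100 * (1 - a):g}%": np.quantile(flat, 1 - a, axis=0),
        })
        if self.draws.n_chains >= 2 and self.draws.n_iter >= 4:
            cs = self.convergence()
            df["rhat"] = cs.rhat
            df["ess_bulk"] = cs.ess_bulk
            df["ess_tail"] = cs.ess_tail
        return df

    # ------------------------------------------------------------------
    def plot_trace_pi(self, **kwargs):
        from .plots import traceplot_pi
        return traceplot_pi(self.draws, **kwargs)

    def plot_diagnostics(self, config: DiagnosticsConfig | None = None,
                         **kwargs):
        from .plots import aligned_diagnostic_figure
        return aligned_diagnostic_figure(self.draws, self.model.data,
                                         config=config, **kwargs)

    def plot_trajectories(self, coverage: float = 0.5, **kwargs):
        from .plots import trajectory_plot
        return trajectory_plot(self.posterior_mean_params(),
                               self.model.data, coverage=coverage, **kwargs)
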