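"""Scikit-learn style estimator interfaces to the Bayesian samplers.

:class:`RDEXModel` fits one participant's trial table; fitted attributes
are the retained posterior draws (``samples_``), a summary table
(``summary_``) and per-parameter R-hat values (``rhat_``).
:class:`HierarchicalRDEXModel` fits several participants jointly with
population-level location/scale distributions. Both compose with sklearn
utilities (``get_params``/``set_params``/``clone``); ``score`` returns the
per-trial log-likelihood at the posterior mean.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import RunConfig
from .likelihood import CompiledTrials
from .simulate import trials_from_table

__all__ = ["RDEXModel", "HierarchicalRDEXModel"]


class RDEXModel(BaseEstimator):
    """Bayesian hybrid race model for one participant.

    Parameters
    ----------
    config:
        A :class:`~rdex.io.RunConfig`; ``None`` uses the default settings
        (selective-influence parameter map, default priors, chains = 3x the
        free parameter count).
    seed:
        Seed for the DE-MCMC sampler; overrides the config seed.
    """

    def __init__(self, config: RunConfig | None = None, seed: int | None = None):
        self.config = config
        self.seed = seed

    def _setup(self):
        cfg = self.config if self.config is not None else RunConfig()
        pmap = cfg.build_map()
        prior = cfg.build_prior(pmap)
        seed = cfg.seed if self.seed is None else self.seed
        return cfg, pmap, prior, seed

    def fit(self, X: pd.DataFrame, y=None) -> "RDEXModel":
        """Sample the posterior for a trial table ``X``."""
        from .inference import sample_individual

        cfg, pmap, prior, seed = self._setup()
        self.map_ = pmap
        self.prior_ = prior
        self.samples_ = sample_individual(
            X, pmap, prior, seed=seed, **cfg.sampler_kwargs()
        )
        self.summary_ = self.samples_.summary()
        self.rhat_ = self.samples_.rhat()
        self.posterior_mean_ = self.samples_.posterior_mean()
        self.n_features_in_ = pmap.n_params
        return self

    def score(self, X: pd.DataFrame, y=None) -> float:
        """Mean per-trial log-likelihood of ``X`` at the posterior mean."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "samples_")
        trials = trials_from_table(X)
        compiled = CompiledTrials(trials, self.map_)
        return compiled.loglik(self.posterior_mean_) / max(len(trials), 1)

    def sample_predictive(
        self, X: pd.DataFrame, n_draws: int = 100, seed: int | None = None
    ) -> list[pd.DataFrame]:
        """Posterior predictive replicates of the observed table ``X``."""
        from sklearn.utils.validation import check_is_fitted

        from .assess import posterior_predict

        check_is_fitted(self, "samples_")
        cfg = self.config if self.config is not None else RunConfig()
        return posterior_predict(
            X, self.samples_, self.map_, n_draws=n_draws, seed=seed,
            deadline=cfg.deadline,
        )


class HierarchicalRDEXModel(BaseEstimator):
    """Hierarchical Bayesian hybrid race model across participants.

    ``fit`` takes a trial table with a ``subject`` column (or a list of
    per-subject tables); fitted attributes are ``samples_``
    (:class:`~rdex.inference.HierarchicalSamples`), ``group_summary_`` and
    ``subject_means_``.
    """

    def __init__(self, config: RunConfig | None = None, seed: int | None = None):
        self.config = config
        self.seed = seed

    def fit(self, X, y=None) -> "HierarchicalRDEXModel":
        from .inference import HyperPriorSpec, sample_hierarchical

        cfg = self.config if self.config is not None else RunConfig()
        pmap = cfg.build_map()
        seed = cfg.seed if self.seed is None else self.seed
        if isinstance(X, pd.DataFrame):
            subjects = {s: sub for s, sub in X.groupby("subject", sort=True)}
        else:
            subjects = {i: tab for i, tab in enumerate(X)}
        self.map_ = pmap
        self.samples_ = sample_hierarchical(
            subjects, pmap, HyperPriorSpec(cfg.build_prior(pmap)),
            seed=seed, **cfg.sampler_kwargs(),
        )
        self.group_summary_ = self.samples_.group_summary()
        self.subject_means_ = np.stack(
            [
                self.samples_.subject(s).posterior_mean()
                for s in range(len(self.samples_.subjects))
            ]
        )
        self.n_features_in_ = pmap.n_params
        return self
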