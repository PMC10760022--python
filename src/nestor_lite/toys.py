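"""Analytically tractable toy problems for validating the nested-sampling loop.

These scorers satisfy the same contract as :class:`~nestor_lite.sampler.StructuralScorer`
but use exact, independent prior draws, so any discrepancy between a nested-
sampling estimate and the closed-form (or quadrature) evidence isolates the
NS loop itself rather than MCMC equilibration.
"""

from __future__ import annotations

import time
from typing import Callable

import numpy as np

from .sampler import SampleFailure


class RejectionToy:
    """Scorer with exact prior draws; constrained draws by plain rejection.

    Parameters
    ----------
    sample_prior:
        Maps a numpy Generator to one exact draw from the prior.
    log_likelihood_fn:
        Log-likelihood of a state.
    max_attempts:
        Rejection budget per constrained draw before reporting failure.
    """

    def __init__(
        self,
        sample_prior: Callable[[np.random.Generator], object],
        log_likelihood_fn: Callable[[object], float],
        max_attempts: int = 50,
    ):
        self._sample_prior = sample_prior
        self._log_lik = log_likelihood_fn
        self.max_attempts = max_attempts
        self.total_steps = 0
        self.total_time = 0.0

    def sample_from_modified_prior(self, rng: np.random.Generator):
        t0 = time.perf_counter()
        state = self._sample_prior(rng)
        self.total_time += time.perf_counter() - t0
        self.total_steps += 1
        return state

    def log_likelihood(self, state) -> float:
        return float(self._log_lik(state))

    def constrained_sample(self, log_l_threshold: float, rng: np.random.Generator):
        best = -np.inf
        for _ in range(self.max_attempts):
            state = self.sample_from_modified_prior(rng)
            ll = self.log_likelihood(state)
            if ll > log_l_threshold:
                return state
            best = max(best, ll)
        return SampleFailure(attempts=self.max_attempts, best_log_likelihood=best)

    @property
    def per_step_time(self) -> float:
        return self.total_time / self.total_steps if self.total_steps else 0.0


def uniform_gaussian_toy(max_attempts: int = 50) -> RejectionToy:
    """Uniform prior on [0, 10], log L(x) = −(x−5)²/2.

    True log-evidence is log(√(2π)/10) ≈ −1.3836 (the Gaussian mass fits well
    inside the prior support).
    """
    return RejectionToy(
        sample_prior=lambda rng: float(rng.uniform(0.0, 10.0)),
        log_likelihood_fn=lambda x: -0.5 * (x - 5.0) ** 2,
        max_attempts=max_attempts,
    )


def constant_likelihood_toy(log_l0: float, max_attempts: int = 50) -> RejectionToy:
    """Likelihood identically exp(log_l0): every point of the prior is a plateau."""
    return RejectionToy(
        sample_prior=lambda rng: float(rng.uniform()),
        log_likelihood_fn=lambda _x: log_l0,
        max_attempts=max_attempts,
    )
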