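"""The nested-sampling loop: live points, shrinkage, evidence quadrature.

Nested sampling turns the evidence integral Z = ∫ L(θ) π(θ) dθ into a
one-dimensional integral of likelihood L against prior mass X — the fraction
of the prior with likelihood above a threshold.  A population of ``n_live``
prior draws is maintained; at each iteration the worst live point is recorded
as a "dead point" at the deterministic shrinkage estimate X_i = exp(−i/n_live)
and replaced by a fresh draw from the prior constrained to exceed its
likelihood.  The evidence is accumulated by a rectangle rule on the L-vs-X
curve plus a remainder term from the surviving live points.

Termination follows three counters: consecutive constrained-sampling
failures, consecutive draws from a likelihood plateau, and a hard iteration
cap.  Plateaus (regions where the likelihood is exactly or nearly flat, e.g.
all crosslinks at their false-positive floor) are a classic failure mode of
the worst-point update: the strict inequality can never be satisfied, so the
plateau test watches for new draws whose likelihood gain over the threshold
is smaller than the shrinkage step.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np
from scipy.special import logsumexp

from .errors import InvalidParameterError, RunFailureError
from .sampler import SampleFailure


@dataclass(frozen=True)
class NSConfig:
    """Nested-sampling run parameters.

    ``n_live`` should be at least the number of free parameters of the
    representation (3 per flexible bead + 6 per rigid body) for the shrinkage
    estimate to be reliable.
    """

    n_live: int = 50
    max_iterations: int = 10_000
    max_consecutive_failures: int = 20
    max_plateau_hits: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_live < 2:
            raise InvalidParameterError(f"n_live must be >= 2, got {self.n_live}")
        for name in ("max_iterations", "max_consecutive_failures", "max_plateau_hits"):
            if getattr(self, name) < 1:
                raise InvalidParameterError(f"{name} must be >= 1")


@dataclass
class NSRunResult:
    """Outcome of one nested-sampling run."""

    log_evidence: float
    dead_log_likelihoods: list[float]
    termination: str  # 'failure-limit' | 'plateau-limit' | 'max-iterations'
    iterations: int
    per_step_time: float
    seed: int
    n_live: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "NSRunResult":
        return cls(**json.loads(Path(path).read_text()))


@runtime_checkable
class Scorer(Protocol):
    """What ns_run needs from a problem: prior draws, constrained draws, likelihoods."""

    def sample_from_modified_prior(self, rng: np.random.Generator): ...

    def constrained_sample(self, log_l_threshold: float, rng: np.random.Generator): ...

    def log_likelihood(self, state) -> float: ...


def prior_mass(i: int, n_live: int) -> float:
    """Deterministic shrinkage estimate X_i = exp(−i / n_live); X_0 = 1."""
    if i < 0 or n_live < 1:
        raise InvalidParameterError("require i >= 0 and n_live >= 1")
    return math.exp(-i / n_live)


def check_plateau(log_l_i: float, log_l_next: float, x_i: float, x_next: float) -> bool:
    """Likelihood-plateau test: L_{i+1}/L_i < X_i/X_{i+1} (strict), in log space."""
    if not (math.isfinite(log_l_i) and math.isfinite(log_l_next)):
        raise InvalidParameterError("plateau test requires finite log-likelihoods")
    if not (x_i > x_next > 0):
        raise InvalidParameterError("require X_i > X_next > 0")
    return (log_l_next - log_l_i) < (math.log(x_i) - math.log(x_next))


def integrate_evidence(
    dead_log_likelihoods: list[float] | np.ndarray,
    live_log_likelihoods: list[float] | np.ndarray,
    n_live: int,
    prior_masses: np.ndarray | None = None,
) -> float:
    """Log evidence by rectangle quadrature over prior mass plus a live-point remainder.

    Dead point i carries weight X_{i−1} − X_i with X_i = exp(−i/n_live); the
    prior mass X_N remaining after the last dead point is assigned the mean
    live-point likelihood.  The weights including the remainder sum to exactly
    1, so a constant likelihood yields log Z = log L exactly.  ``prior_masses``
    may supply an explicit mass grid X_0..X_N overriding the default schedule.
    """
    dead = np.asarray(dead_log_likelihoods, dtype=float)
    live = np.asarray(live_log_likelihoods, dtype=float)
    if dead.size == 0 and live.size == 0:
        raise InvalidParameterError("need at least one dead or live point")
    n = dead.size
    if prior_masses is not None:
        x = np.asarray(prior_masses, dtype=float)
        if x.size != n + 1:
            raise InvalidParameterError(f"prior_masses must have length {n + 1}")
        log_x = np.log(x)
    else:
        log_x = -np.arange(n + 1) / n_live
    terms = []
    if n:
        # log(X_{i-1} - X_i) = log X_{i-1} + log1p(-X_i/X_{i-1}), stable for small steps
        log_dx = log_x[:-1] + np.log1p(-np.exp(log_x[1:] - log_x[:-1]))
        terms.append(dead + log_dx)
    if live.size:
        log_remainder = logsumexp(live) - math.log(live.size) + log_x[-1]
        terms.append(np.array([log_remainder]))
    return float(logsumexp(np.concatenate(terms)))


def ns_run(scorer: Scorer, ns: NSConfig) -> NSRunResult:
    """One nested-sampling run over ``scorer``'s modified prior and likelihood.

    Each pass selects the worst live point (ties broken by lowest index),
    requests a constrained draw above its likelihood, and on success records
    the worst point as dead and inserts the replacement.  A constrained-
    sampling failure whose best rejected draw sits exactly on the threshold is
    counted as a plateau hit — the sampler *is* drawing from the constrained
    prior, which is flat there — while strictly sub-threshold failures feed
    the failure counter.  Failures do not advance the shrinkage index, since
    no prior mass was discarded.
    """
    rng = np.random.default_rng(ns.seed)
    try:
        live = [scorer.sample_from_modified_prior(rng) for _ in range(ns.n_live)]
        log_l = [float(scorer.log_likelihood(s)) for s in live]
    except Exception as exc:  # orchestrator may relaunch with a fresh seed
        raise RunFailureError(f"live-point initialization failed: {exc}") from exc

    dead: list[float] = []
    fail_count = 0
    plateau_count = 0
    termination = "max-iterations"
    for _pass in range(ns.max_iterations):
        worst = int(np.argmin(log_l))
        threshold = log_l[worst]
        result = scorer.constrained_sample(threshold, rng)
        if isinstance(result, SampleFailure):
            if result.best_log_likelihood == threshold:
                plateau_count += 1
                fail_count = 0
            else:
                fail_count += 1
                plateau_count = 0
        else:
            new_log_l = float(scorer.log_likelihood(result))
            dead.append(threshold)
            t = len(dead)
            live[worst] = result
            log_l[worst] = new_log_l
            x_prev, x_new = prior_mass(t - 1, ns.n_live), prior_mass(t, ns.n_live)
            finite = math.isfinite(threshold) and math.isfinite(new_log_l)
            if finite and check_plateau(threshold, new_log_l, x_prev, x_new):
                plateau_count += 1
            else:
                plateau_count = 0
            fail_count = 0
        if plateau_count >= ns.max_plateau_hits:
            termination = "plateau-limit"
            break
        if fail_count >= ns.max_consecutive_failures:
            termination = "failure-limit"
            break

    log_z = integrate_evidence(dead, log_l, ns.n_live)
    per_step = float(getattr(scorer, "per_step_time", 0.0))
    return NSRunResult(
        log_evidence=log_z,
        dead_log_likelihoods=dead,
        termination=termination,
        iterations=len(dead),
        per_step_time=per_step,
        seed=ns.seed,
        n_live=ns.n_live,
    )
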