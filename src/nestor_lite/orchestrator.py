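"""Run nested sampling over candidate representations and select the optimal ones.

For each candidate residues-per-bead level the experiment executes several
independent nested-sampling runs (relaunching failed ones with fresh seeds),
collates the mean log-evidence, its standard error across runs, and the mean
sampling time per MCMC step, and then applies the two-criterion selection
rule: among the candidates whose per-step sampling time is within a
``time_fold`` (default three-fold) range of the fastest, pick those whose
evidence interval (mean ± SEM) overlaps the best efficient candidate's.
"""

from __future__ import annotations

import logging
import warnings
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import spearmanr

from .assembly_model import ChainSpec, build_representation, read_topology_tsv
from .errors import InvalidParameterError, RunFailureError
from .nested_sampling import NSConfig, NSRunResult, ns_run
from .restraints import (
    Crosslink,
    RestraintConfig,
    read_crosslink_csv,
    repartition_restraints,
)
from .sampler import MoveSet, StructuralScorer

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    """Everything needed to evaluate a set of candidate representations."""

    chains: list[ChainSpec]
    crosslinks: list[Crosslink]
    candidates: list[int]
    n_runs: int = 5
    prior_fraction: float = 0.3
    repartition_seed: int = 0
    seed: int = 0
    xl_cutoff: float = 21.0
    xl_slope: float = 2.0
    xl_floor: float = 0.01
    ev_strength: float = 1.0
    conn_strength: float = 1.0
    moves: MoveSet = field(default_factory=MoveSet)
    n_live: int = 50
    max_iterations: int = 10_000
    max_consecutive_failures: int = 20
    max_plateau_hits: int = 20
    max_attempts: int = 50
    retry_cap: int = 2

    def __post_init__(self) -> None:
        if not self.candidates:
            raise InvalidParameterError("need at least one candidate representation")
        if self.n_runs < 1:
            raise InvalidParameterError("n_runs must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        """Load an experiment from YAML (topology TSV + crosslink CSV paths resolved
        relative to the YAML file)."""
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        base = path.parent
        chains = read_topology_tsv(base / raw["topology"])
        crosslinks = read_crosslink_csv(base / raw["crosslinks"])
        kwargs = {k: v for k, v in raw.items() if k not in ("topology", "crosslinks", "moves")}
        moves = MoveSet(**raw.get("moves", {}))
        return cls(chains=chains, crosslinks=crosslinks, moves=moves, **kwargs)

    def restraint_config(self) -> RestraintConfig:
        prior_set, lik_set = repartition_restraints(
            self.crosslinks, self.prior_fraction, self.repartition_seed
        )
        return RestraintConfig(
            prior_crosslinks=prior_set,
            likelihood_crosslinks=lik_set,
            xl_cutoff=self.xl_cutoff,
            xl_slope=self.xl_slope,
            xl_floor=self.xl_floor,
            ev_strength=self.ev_strength,
            conn_strength=self.conn_strength,
        )


@dataclass
class CollatedResult:
    """Per-representation summary across nested-sampling runs."""

    representation_label: str
    mean_logZ: float
    sem_logZ: float
    mean_per_step_time: float
    n_successful_runs: int
    runs: list[NSRunResult] = field(default_factory=list, repr=False)

    @property
    def failed(self) -> bool:
        return self.n_successful_runs == 0


@dataclass
class SelectionReport:
    """Outcome of the two-criterion selection rule."""

    optimal: list[str]
    evidence_ranking: list[str]
    efficient_set: list[str]
    rationale: dict[str, str]

    def to_dict(self) -> dict:
        return asdict(self)


def _derived_seed(*keys: int) -> int:
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2**31))


def _run_one(
    config: ExperimentConfig, residues_per_bead: int, run_index: int
) -> NSRunResult | None:
    """Execute one run (with relaunches) for one candidate; None if all retries fail."""
    topology = build_representation(config.chains, residues_per_bead)
    restraints = config.restraint_config()
    for attempt in range(config.retry_cap + 1):
        seed = _derived_seed(config.seed, residues_per_bead, run_index, attempt)
        scorer = StructuralScorer(
            topology, restraints, moves=config.moves, max_attempts=config.max_attempts
        )
        ns = NSConfig(
            n_live=config.n_live,
            max_iterations=config.max_iterations,
            max_consecutive_failures=config.max_consecutive_failures,
            max_plateau_hits=config.max_plateau_hits,
            seed=seed,
        )
        try:
            return ns_run(scorer, ns)
        except RunFailureError as exc:
            logger.warning(
                "run %d for representation %d failed (attempt %d): %s",
                run_index, residues_per_bead, attempt, exc,
            )
    return None


def collate_runs(
    label: str, runs: list[NSRunResult], per_step_time: float | None = None
) -> CollatedResult:
    """Mean log-evidence, across-run SEM and mean per-step time for one candidate.

    ``per_step_time`` may supply an externally measured sampling time (see
    :func:`measure_per_step_times`); otherwise the mean of the per-run
    estimates is used.
    """
    if not runs:
        return CollatedResult(
            label,
            float("nan"),
            float("nan"),
            float("nan") if per_step_time is None else per_step_time,
            0,
        )
    log_z = np.array([r.log_evidence for r in runs])
    if len(runs) == 1:
        warnings.warn(
            f"representation {label}: single run, SEM reported as 0", stacklevel=2
        )
        sem = 0.0
    else:
        sem = float(np.std(log_z, ddof=1) / np.sqrt(len(runs)))
    if per_step_time is None:
        per_step_time = float(np.mean([r.per_step_time for r in runs]))
    return CollatedResult(
        representation_label=label,
        mean_logZ=float(np.mean(log_z)),
        sem_logZ=sem,
        mean_per_step_time=per_step_time,
        n_successful_runs=len(runs),
        runs=runs,
    )


def measure_per_step_times(config: ExperimentConfig, n_rounds: int = 150) -> dict[str, float]:
    """Mean MCMC wall time per step for every candidate, by interleaved draws.

    Per-step costs of neighbouring representations can differ by only a few
    microseconds while CPU frequency and cache state drift by as much over the
    minutes a candidate sweep takes, so timing each candidate from its own
    nested-sampling runs confounds cost with when the runs happened to
    execute.  Here one prior draw per candidate is timed per round, with the
    candidate order rotated every round, so slow drift and cache-eviction
    effects average out across candidates; each scorer's first
    (initialization + warm-up) draw is untimed.  The RNG is derived from the
    experiment seed but separate from the run seeds, so evidence results are
    unaffected.
    """
    restraints = config.restraint_config()
    rng = np.random.default_rng(_derived_seed(config.seed, 999_983))
    labels = [str(rpb) for rpb in config.candidates]
    scorers = {}
    for rpb in config.candidates:
        topology = build_representation(config.chains, rpb)
        scorer = StructuralScorer(
            topology, restraints, moves=config.moves, max_attempts=config.max_attempts
        )
        scorer.sample_from_modified_prior(rng)
        scorers[str(rpb)] = scorer
    for k in range(n_rounds):
        order = labels[k % len(labels):] + labels[:k % len(labels)]
        for label in order:
            scorers[label].sample_from_modified_prior(rng)
    return {label: scorer.per_step_time for label, scorer in scorers.items()}


def run_candidates(config: ExperimentConfig, max_workers: int = 1) -> list[CollatedResult]:
    """Run ``config.n_runs`` nested-sampling runs per candidate and collate.

    Results are deterministic for a given config regardless of worker count:
    every run's seed is derived from (experiment seed, candidate, run index,
    attempt).  Candidates whose runs all fail are returned with
    ``n_successful_runs == 0`` and excluded from ranking downstream.
    Per-candidate sampling efficiency comes from a drift-cancelling
    round-robin measurement (:func:`measure_per_step_times`); each run's own
    wall-time estimate remains available in its :class:`NSRunResult`.
    """
    # interleave candidates by run index so slow timing drift (CPU frequency,
    # cache state) is spread evenly across candidates instead of biasing
    # whichever candidate happens to run first
    tasks = [(rpb, i) for i in range(config.n_runs) for rpb in config.candidates]
    if max_workers > 1:
        with ProcessPoolExecutor(max_workers=max_workers) as pool:
            outcomes = list(pool.map(_run_one, [config] * len(tasks),
                                     [t[0] for t in tasks], [t[1] for t in tasks]))
    else:
        outcomes = [_run_one(config, rpb, i) for rpb, i in tasks]
    step_times = measure_per_step_times(config)
    results = []
    for rpb in config.candidates:
        runs = [
            out for (c, _), out in zip(tasks, outcomes) if c == rpb and out is not None
        ]
        results.append(collate_runs(str(rpb), runs, per_step_time=step_times[str(rpb)]))
        logger.info(
            "representation %s: %d/%d runs succeeded", rpb, len(runs), config.n_runs
        )
    return results


def log_bayes_factor(a: CollatedResult, b: CollatedResult) -> float:
    """Log Bayes factor log K = mean log Z(a) − mean log Z(b) (equal representation priors)."""
    return a.mean_logZ - b.mean_logZ


def rank_representations(
    results: list[CollatedResult], time_fold: float = 3.0, sem_multiplier: float = 1.0
) -> SelectionReport:
    """Apply the two-criterion selection rule.

    Efficient candidates have mean per-step time within ``time_fold`` of the
    fastest; the optimal set is every efficient candidate whose evidence
    interval (mean ± ``sem_multiplier``·SEM) overlaps that of the best-evidence
    efficient candidate.
    """
    ok = [r for r in results if not r.failed]
    if not ok:
        raise InvalidParameterError("no successful candidate to rank")
    rationale: dict[str, str] = {
        r.representation_label: "all runs failed" for r in results if r.failed
    }
    t_min = min(r.mean_per_step_time for r in ok)
    efficient = [r for r in ok if r.mean_per_step_time <= time_fold * t_min]
    efficient_labels = {r.representation_label for r in efficient}
    best = max(efficient, key=lambda r: r.mean_logZ)
    optimal = []
    for r in ok:
        if r.representation_label not in efficient_labels:
            rationale[r.representation_label] = (
                f"excluded: per-step time {r.mean_per_step_time:.3g}s exceeds "
                f"{time_fold}x the fastest ({t_min:.3g}s)"
            )
            continue
        lo, hi = r.mean_logZ - sem_multiplier * r.sem_logZ, r.mean_logZ + sem_multiplier * r.sem_logZ
        b_lo = best.mean_logZ - sem_multiplier * best.sem_logZ
        b_hi = best.mean_logZ + sem_multiplier * best.sem_logZ
        if hi >= b_lo and lo <= b_hi:
            optimal.append(r.representation_label)
            rationale[r.representation_label] = (
                "optimal: efficient and evidence overlaps the best efficient candidate"
            )
        else:
            rationale[r.representation_label] = (
                f"excluded: evidence {best.mean_logZ - r.mean_logZ:.3f} log units below the "
                f"best efficient candidate and the ±{sem_multiplier:g} SEM intervals do not overlap"
            )
    ranking = [r.representation_label for r in sorted(ok, key=lambda r: -r.mean_logZ)]
    return SelectionReport(
        optimal=optimal,
        evidence_ranking=ranking,
        efficient_set=[r.representation_label for r in efficient],
        rationale=rationale,
    )


@dataclass
class RobustnessResult:
    """Evidence per candidate under independent prior/likelihood splits."""

    mean_logZ: pd.DataFrame  # rows: candidates, columns: repartition seeds
    sem_logZ: pd.DataFrame
    pairwise_spearman: list[float]
    mean_pairwise_spearman: float


def prior_robustness(
    config: ExperimentConfig,
    n_repartitions: int,
    seeds: list[int] | None = None,
    max_workers: int = 1,
) -> RobustnessResult:
    """Rerun the pipeline under independent random crosslink splits.

    Reports per-candidate evidence for each split and the Spearman rank
    correlation of the candidate orderings between splits (descriptive: the
    evidence *trend* is expected to be conserved across priors, but no
    quantitative threshold is enforced here).
    """
    if n_repartitions < 2:
        raise InvalidParameterError("need at least 2 repartitions to compare")
    if seeds is None:
        seeds = [_derived_seed(config.repartition_seed, 7919, k) for k in range(n_repartitions)]
    if len(seeds) != n_repartitions:
        raise InvalidParameterError("len(seeds) must equal n_repartitions")
    columns = {}
    sems = {}
    for s in seeds:
        cfg = ExperimentConfig(**{**asdict_shallow(config), "repartition_seed": s})
        results = run_candidates(cfg, max_workers=max_workers)
        columns[s] = {r.representation_label: r.mean_logZ for r in results if not r.failed}
        sems[s] = {r.representation_label: r.sem_logZ for r in results if not r.failed}
    mean_df = pd.DataFrame(columns)
    sem_df = pd.DataFrame(sems)
    pairwise = []
    cols = list(mean_df.columns)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            rho = spearmanr(mean_df[cols[i]], mean_df[cols[j]]).statistic
            pairwise.append(float(rho))
    return RobustnessResult(
        mean_logZ=mean_df,
        sem_logZ=sem_df,
        pairwise_spearman=pairwise,
        mean_pairwise_spearman=float(np.mean(pairwise)),
    )


def asdict_shallow(config: ExperimentConfig) -> dict:
    """Field dict of an ExperimentConfig without recursing into chains/crosslinks."""
    return {f: getattr(config, f) for f in config.__dataclass_fields__}


def desk_benchmark_config(seed: int = 0, n_runs: int = 3) -> ExperimentConfig:
    """The package's standard desk-scale experiment.

    A compact two-chain synthetic assembly (100 + 60 residues) with 40
    simulated crosslinks (25 Å cutoff, 10% false positives), candidates
    {1, 5, 20, 50} residues per bead, 25 live points, and a 200-pass iteration
    cap — sized so the full candidate sweep completes in a few minutes on one
    core while still separating the candidates' evidence and per-step cost.
    """
    from .synthetic_data import benchmark_dataset

    ref, links = benchmark_dataset(seed=seed)
    return ExperimentConfig(
        chains=list(ref.spec.chains),
        crosslinks=links,
        candidates=[1, 5, 20, 50],
        n_runs=n_runs,
        prior_fraction=0.3,
        repartition_seed=seed + 1,
        seed=seed,
        n_live=25,
        max_iterations=200,
    )
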