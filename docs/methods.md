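# Methods

## The problem

Integrative structural modeling represents a macromolecular assembly as
spherical beads, each covering a fixed number of contiguous residues, and
samples bead configurations against experimental restraints. The choice of
*representation* — how many residues per bead, which chains move rigidly —
trades sampling cost against fidelity to the data, and is usually made ad
hoc. This package treats the choice as Bayesian model selection: for each
candidate representation R it estimates the model evidence

    Z_R = ∫ L(θ) π(θ) dθ,

the likelihood of the crosslink data averaged over the prior on bead
coordinates θ. Evidence penalizes representations whose extra parameters do
not buy a proportionally larger high-likelihood region, so it balances fit
against complexity without a hand-tuned penalty. Representations are compared
by log Bayes factors, log K = log Z_a − log Z_b, assuming equal prior
probability for the representations themselves.

Because the evidence alone would always tolerate the most expensive
representation, the selection rule is two-criterion: a candidate must also
sample efficiently. Candidates whose mean wall time per MCMC step is within a
configurable fold (default 3×) of the fastest form the *efficient set*; among
those, every candidate whose evidence interval (mean ± 1 SEM across runs)
overlaps the best efficient candidate's interval is reported as optimal. The
efficiency filter is applied first, then the evidence-overlap test against
the best *efficient* candidate — this ordering is what makes a very accurate
but very slow candidate lose to an efficient runner-up with comparable
evidence. The SEM multiplier for "overlapping errors" is 1 by default and
configurable; nothing in the selection logic depends on absolute evidence
values, only differences.

## Repartitioned scoring

Nested sampling degrades when the prior is very unlike the posterior. The
scoring system is therefore repartitioned: a random subset of the crosslinks
(default fraction 0.3) is moved *into* the prior, leaving the rest as the
likelihood. The modified prior is

    log π̃(θ) = EV(θ) + Conn(θ) + Σ_{prior XLs} log p(d),

and the likelihood is the same sum over the remaining crosslinks. The product
π̃·L is identical for every split, which the test suite checks to floating
tolerance over randomized models and fractions.

Restraint forms, with defaults:

- **Crosslink satisfaction** p(d) = ω + (1−ω)/(1 + exp((d − d0)/λ)), with
  center-to-center bead distance d, midpoint d0 = 21 Å, width λ = 2 Å, and
  false-positive floor ω = 0.01. The floor bounds each term in (log ω, 0],
  which keeps log-likelihoods finite and creates genuine likelihood plateaus
  when all crosslinks of a configuration sit in the far tail — exactly the
  situation the plateau termination test must recognize.
- **Excluded volume** −(k_ev/2) Σ max(0, rᵢ + rⱼ − dᵢⱼ)² over all bead pairs
  not in the same rigid body; k_ev = 1 Å⁻².
- **Connectivity** −(k_conn/2) Σ max(0, dᵢⱼ − (rᵢ + rⱼ))² over beads adjacent
  along a chain; k_conn = 1 Å⁻².

Bead radii are volume-equivalent spheres at 130 Å³ per residue,
r(n) = (3n·130/4π)^(1/3); radii enter only the stereochemistry terms,
distances are always center-to-center. The stereochemistry prior is
*unnormalized*: nested sampling needs only prior MCMC and likelihood values,
so the normalization constant cancels within one representation. Evidence
comparisons *across* representations therefore assume the prior normalization
is comparable between candidates; this is an assumption of the method as
implemented, not a derived fact, and is the main caveat on absolute Bayes
factors (rankings in practice are driven by the likelihood term).

## Sampling

Prior draws come from single-temperature Metropolis MCMC. One move translates
a random flexible bead by an isotropic Gaussian (σ = 3 Å) or moves a random
rigid body (Gaussian translation σ = 3 Å plus rotation about its centroid by
an isotropic Gaussian rotation vector, σ = 0.3 rad). All proposals are
symmetric, so acceptance is min(1, exp(Δ log π̃)). Successive samples are
taken 50 Metropolis steps apart by default. The sampler sits behind a
three-method contract (prior draw, constrained draw, likelihood), so a
replica-exchange ladder could replace the single chain without touching the
nested-sampling loop; at the desk scales exercised here the modified prior is
mild enough that a single chain mixes (verified by Kolmogorov–Smirnov tests
against quadrature on a two-bead system).

Constrained draws — prior samples with log L strictly above a threshold — use
plain rejection: advance the chain, check the draw, give up after
`max_attempts` (default 50) consecutive rejections and report the best
rejected log-likelihood. New live points are thus fresh prior draws, not
evolved copies of surviving live points.

Initialization places each chain by a bond-respecting random walk (each bead
at contact distance from its predecessor) with chain starts uniform in a
bounding sphere of 3× the assembly's volume-equivalent radius (Σrᵢ³)^(1/3).
A sphere proportional to the *sum* of radii was rejected because it grows
linearly with bead count and would make the effective prior absurdly diffuse
at fine representations.

## Nested sampling

`ns_run` keeps `n_live` live points (default 50; it should be at least the
free-parameter count 3n + 6m — n flexible beads, m rigid bodies). Each
successful iteration records the worst live point as a dead point at the
deterministic shrinkage estimate X_t = exp(−t/n_live) and replaces it with a
constrained draw. Deterministic shrinkage was chosen over sampled widths
because it is the standard default and makes the quadrature exactly testable.

Evidence uses the rectangle rule in log space: log Z = logsumexp over dead
points of [log L_t + log(X_{t−1} − X_t)] combined with a remainder term
logsumexp(live) − log(n_live) + log X_final. The remainder makes the weights
sum to exactly 1, so a constant likelihood yields log Z = log L to machine
precision — the canonical sanity identity. The remainder also absorbs
truncation when a run terminates early, since the mean live likelihood is an
estimate of the integrand over the remaining mass. All arithmetic is in log
space; the mass differences use log1p(−exp(−1/n_live)) to stay stable for
large n_live. Worst-point ties break to the lowest bead index (argmin), so
runs are bit-reproducible for a given seed.

### Termination

Three counters, checked after every loop pass:

- **Plateau counter.** A new draw comes "from a likelihood plateau" when its
  log-likelihood exceeds the threshold by less than the shrinkage step:
  log L_new − log L_worst < 1/n_live (strict), the discrete form of
  L_{t+1}/L_t < X_t/X_{t+1}. A constrained-sampling failure whose best
  rejected draw equals the threshold *exactly* is also a plateau hit: the
  sampler is drawing from a region where the likelihood is literally flat
  (e.g. every crosslink at its floor ω), and a strict constraint can never be
  met there. Default limit: 20 consecutive hits.
- **Failure counter.** Strictly sub-threshold constrained-sampling failures
  (the sampler cannot reach the constrained region at all). Default limit:
  20 consecutive failures. Failures do not record a dead point and do not
  advance the shrinkage index — no prior mass was discarded.
- **Iteration cap.** A hard cap (default 10 000) on total loop passes
  guarantees termination; the reported iteration count equals the number of
  dead points.

Both convergence limits are configurable and deliberately conservative; they
are stopping heuristics, not estimates of anything.

Runs whose live points cannot even be initialized raise a run-failure error;
the orchestrator relaunches such runs with a fresh derived seed up to 2
retries, then marks the run (and, if all runs fail, the candidate) as failed
without affecting other candidates.

## Collation and reproducibility

Each candidate gets `n_runs` independent runs (default 5; the desk benchmark
uses 3). Reported per candidate: mean log Z, SEM = sd/√n across runs (0 with
an explicit warning when n = 1), and the mean wall time per MCMC step — the
efficiency criterion. Per-step time is measured in a dedicated phase that
interleaves one timed prior draw per candidate per round with the candidate
order rotated every round: neighbouring representations can differ by only a
few microseconds per step while CPU frequency and cache state drift by as
much over the minutes a sweep takes, so timing each candidate from its own
runs would confound cost with scheduling; interleaving cancels the drift.
Each run's own wall-time estimate is still recorded in its run JSON, and the
timing phase uses an RNG stream separate from the run seeds. Every run's seed
derives from
(experiment seed, candidate, run index, attempt) through a SeedSequence, so
results are identical for any worker count and parallelism is a pure
speed-up.

`prior_robustness` reruns the whole pipeline under independent crosslink
splits and reports per-candidate evidence per split plus the mean pairwise
Spearman rank correlation of the candidate orderings. The output is
descriptive — the evidence *trend* is expected to be conserved across priors,
but no threshold is enforced, because "conserved" has no canonical cutoff.

## Synthetic data

The generator emulates the statistical setting the method targets: compact
multi-chain assemblies and cutoff-type crosslink data with false positives.
Chains are fixed-bond (3.8 Å) random walks with soft self-avoidance
(2.5 Å clearance, best-effort over 30 direction tries) confined to a sphere
chosen so the radius of gyration approaches compactness × N^(1/3) × 3 Å.
Crosslinks are uniform draws from residue pairs within a cutoff (default
25 Å, a residue-level analogue of common crosslinker spans) with probability
1 − fp_rate, else uniform over all pairs (default fp_rate 0.1); duplicates
are allowed, as in real tables. Not emulated: secondary structure, realistic
contact order, sequence content, crosslinker chemistry, ambiguity between
chain copies. Passing tests therefore demonstrate correct evidence estimation
and ranking for compact assemblies with distance-cutoff data, not robustness
to every pathology of real XL-MS.

The standard desk benchmark (`desk_benchmark_config`) is two flexible chains
of 100 and 60 residues, 40 crosslinks (25 Å cutoff, 10% false positives, 30%
into the prior), candidates {1, 5, 20, 50} residues per bead, 25 live points,
3 runs per candidate and a 200-pass iteration cap — sizes chosen so the full
sweep runs in a few minutes on one core while the candidates still separate
in both evidence and per-step cost. The two analytic toys (uniform/Gaussian
in 1-D; a two-bead chain with one crosslink) use exact prior draws and
quadrature oracles so that discrepancies isolate the NS loop itself.

## Degenerate inputs and edge behavior

- Empty crosslink list: repartitioning returns two empty sets with a warning;
  the likelihood is identically 0 in log space, and a run terminates via the
  plateau counter with log Z = 0 exactly.
- Chains whose length does not divide residues_per_bead get a final smaller
  remainder bead (common coarse-graining practice; the alternative of a
  spilled-over larger bead changes nothing tested here).
- Self-crosslinks (same chain and residue on both sides) are rejected at
  construction; ambiguous crosslinks between chain copies are unsupported.
- A single-run candidate reports SEM 0 and warns rather than guessing an
  error bar.

## Known limitations

- Cross-representation evidence comparisons inherit the unnormalized-prior
  assumption above.
- Single-temperature Metropolis underestimates prior diversity on strongly
  multimodal modified priors (many prior crosslinks with conflicting
  geometry); the contract hook for replica exchange exists but is not
  implemented.
- Deterministic shrinkage ignores the stochasticity of the prior-mass
  contraction; the across-run SEM captures this empirically, which is why
  uncertainty is reported across runs rather than per run.
- Per-step wall time is a hardware-dependent quantity; only its *ratios*
  between candidates on the same machine are meaningful.
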