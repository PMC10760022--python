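# nestor-lite

Bayesian selection of coarse-grained representations for integrative
structural modeling, by nested-sampling estimation of the model evidence.

## The problem

Integrative models of macromolecular assemblies represent each chain as a
string of spherical beads, every bead covering a fixed number of contiguous
residues. Coarser beads are cheaper to sample; finer beads can fit the data
better. Practitioners usually pick the resolution by habit. This package
makes the choice objective: for each candidate representation R it estimates
the model evidence

    Z_R = P(D | R) = ∫ L(M_R) π(M_R) dM_R,

the crosslink likelihood averaged over the prior on bead coordinates, and
compares candidates by log Bayes factors log K = log Z_a − log Z_b. Evidence
automatically balances goodness-of-fit against the size of the parameter
space, so over-complex representations are penalized without ad-hoc terms.

The evidence integral is computed by **nested sampling**: a population of
live points drawn from the prior is iteratively contracted by replacing the
worst-likelihood point with a prior draw constrained to exceed it, converting
the high-dimensional integral into a 1-D integral of likelihood over prior
mass X_i = exp(−i/n_live). Because an uninformative stereochemistry prior is
far from the posterior, the posterior is *repartitioned*: a random 30% of the
crosslinks score inside the prior (together with excluded volume and chain
connectivity) and the remaining 70% form the likelihood — the product, and
hence the posterior, is unchanged.

A representation is reported **optimal** when it is efficient (mean wall time
per MCMC step within 3× of the fastest candidate) and its evidence interval
(mean ± SEM across independent runs) overlaps that of the best efficient
candidate.

See `docs/methods.md` for restraint functional forms, termination criteria,
defaults, and limitations.

## Worked example

Inputs are a topology TSV (one chain per row), a crosslink CSV
(`protein1,residue1,protein2,residue2`), and an experiment YAML. The
`nestor_lite.synthetic_data` module can fabricate a test system:

```python
import nestor_lite as nl
from nestor_lite.assembly_model import write_topology_tsv
from nestor_lite.restraints import write_crosslink_csv

spec = nl.AssemblySpec(chains=(nl.ChainSpec("A", 60), nl.ChainSpec("B", 40)), seed=11)
ref = nl.generate_reference_assembly(spec)
links = nl.simulate_crosslinks(ref, n=20, cutoff=25.0, fp_rate=0.1, seed=12)
write_topology_tsv(list(spec.chains), "topology.tsv")
write_crosslink_csv(links, "crosslinks.csv")
```

```yaml
# experiment.yaml
topology: topology.tsv
crosslinks: crosslinks.csv
candidates: [5, 10, 20]   # residues per bead
n_runs: 3
n_live: 25
max_iterations: 150
seed: 17
```

```sh
nestor-lite run --config experiment.yaml --out results/
```

prints the selection report (about half a minute on one core):

```json
{
 "optimal": ["10", "20"],
 "evidence_ranking": ["20", "10", "5"],
 "efficient_set": ["5", "10", "20"],
 "rationale": {
  "5": "excluded: evidence 12.149 log units below the best efficient candidate and the ±1 SEM intervals do not overlap",
  "10": "optimal: efficient and evidence overlaps the best efficient candidate",
  "20": "optimal: efficient and evidence overlaps the best efficient candidate"
 }
}
```

and writes `results/collated.csv` with the per-candidate numbers behind it:

```
label,mean_logZ,sem_logZ,mean_per_step_time,n_runs
5,-23.92,3.40,4.59e-05,3
10,-18.45,2.96,4.02e-05,3
20,-11.78,3.89,3.79e-05,3
```

Read: 20-residue beads achieve the highest evidence (log Z ≈ −11.7) for this
small, compact two-chain system — the 5-residue representation fits no better
yet averages its likelihood over a much larger parameter space (20 beads
instead of 5, i.e. 60 versus 15 degrees of freedom), which lowers its
evidence — and 10-residue beads are statistically indistinguishable
(intervals overlap), so both are reported optimal. All three candidates sample within 3× of each
other's per-step time, so none is excluded on efficiency. `results/` also
holds one JSON per nested-sampling run (evidence, dead-point likelihood
trace, termination reason, per-step time). `nestor-lite rank results/`
re-applies the selection rule with a different time fold;
`nestor-lite robustness --config experiment.yaml --repartitions 3` repeats
everything under independent 30% crosslink splits and reports the Spearman
rank correlation of the candidate orderings between splits.

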