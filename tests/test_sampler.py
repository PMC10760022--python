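import numpy as np
import pytest
from scipy.integrate import quad
from scipy.interpolate import interp1d
from scipy.stats import kstest

import nestor_lite as nl
from nestor_lite.restraints import CompiledScore
from nestor_lite.sampler import SampleFailure


def separation_density(contact, k_ev, k_conn):
    """Unnormalized prior density of the separation of two tethered beads.

    The isotropic Jacobian contributes d²; excluded volume penalizes overlap,
    connectivity penalizes stretch.
    """

    def p(d):
        gap = max(0.0, contact - d)
        stretch = max(0.0, d - contact)
        return d * d * np.exp(-0.5 * k_ev * gap**2 - 0.5 * k_conn * stretch**2)

    return p


class TestProposeMove:
    def test_zero_step_is_identity(self, small_model, rng):
        moves = nl.MoveSet(bead_step=0.0, rb_trans_step=0.0, rb_rot_step=0.0)
        out = nl.propose_move(small_model, moves, rng)
        np.testing.assert_allclose(out.coordinates, small_model.coordinates, atol=1e-12)

    def test_seeded_determinism(self, small_model):
        a = nl.propose_move(small_model, nl.MoveSet(), np.random.default_rng(9))
        b = nl.propose_move(small_model, nl.MoveSet(), np.random.default_rng(9))
        np.testing.assert_array_equal(a.coordinates, b.coordinates)

    def test_input_model_unmodified(self, small_model, rng):
        before = small_model.coordinates.copy()
        nl.propose_move(small_model, nl.MoveSet(), rng)
        np.testing.assert_array_equal(small_model.coordinates, before)

    def test_rigid_body_preserves_internal_distances(self, rng):
        chains = [nl.ChainSpec("R", 40, rigid_body="rb")]
        topo = nl.build_representation(chains, 10)
        model = nl.initialize_model(topo, rng)
        from scipy.spatial.distance import pdist

        before = pdist(model.coordinates)
        for _ in range(20):
            model = nl.propose_move(model, nl.MoveSet(), rng)
        np.testing.assert_allclose(pdist(model.coordinates), before, atol=1e-9)


class TestSampleFromModifiedPrior:
    def test_flat_prior_accepts_everything(self, rng):
        # a single free bead has no restraints: every proposal is accepted
        topo = nl.build_representation([nl.ChainSpec("A", 5)], 5)
        model = nl.StructureModel(np.zeros((1, 3)), topo)
        cfg = nl.RestraintConfig()
        moves = nl.MoveSet(n_steps_per_sample=1)
        for _ in range(100):
            new, steps, _ = nl.sample_from_modified_prior(model, cfg, moves, rng)
            assert steps == 1
            assert not np.array_equal(new.coordinates, model.coordinates)
            model = new

    def test_zero_steps_returns_input(self, small_model, rng):
        moves = nl.MoveSet(n_steps_per_sample=0)
        out, steps, per_step = nl.sample_from_modified_prior(
            small_model, nl.RestraintConfig(), moves, rng
        )
        assert steps == 0 and per_step == 0.0
        np.testing.assert_array_equal(out.coordinates, small_model.coordinates)

    def test_two_bead_separation_matches_boltzmann(self, two_bead_topology, rng):
        """Long-chain separation statistics match quadrature on the tether density."""
        cfg = nl.RestraintConfig(ev_strength=1.0, conn_strength=1.0)
        contact = two_bead_topology.radii.sum()
        moves = nl.MoveSet(n_steps_per_sample=50)
        model = nl.initialize_model(two_bead_topology, rng)
        seps = []
        for _ in range(3000):
            model, _, _ = nl.sample_from_modified_prior(model, cfg, moves, rng)
            seps.append(np.linalg.norm(model.coordinates[0] - model.coordinates[1]))
        seps = np.array(seps)
        p = separation_density(contact, 1.0, 1.0)
        hi = contact + 8.0
        norm = quad(p, 0, hi, limit=200)[0]
        mean = quad(lambda d: d * p(d), 0, hi, limit=200)[0] / norm
        second = quad(lambda d: d * d * p(d), 0, hi, limit=200)[0] / norm
        var = second - mean**2
        assert np.mean(seps) == pytest.approx(mean, rel=0.05)
        assert np.var(seps) == pytest.approx(var, rel=0.10)

    def test_metropolis_matches_target_distribution(self, two_bead_topology, rng):
        """Kolmogorov-Smirnov check of the sampled separation CDF."""
        cfg = nl.RestraintConfig(ev_strength=1.0, conn_strength=1.0)
        contact = two_bead_topology.radii.sum()
        moves = nl.MoveSet(n_steps_per_sample=50)
        model = nl.initialize_model(two_bead_topology, rng)
        # burn-in, then near-independent draws 50 steps apart
        for _ in range(20):
            model, _, _ = nl.sample_from_modified_prior(model, cfg, moves, rng)
        seps = []
        for _ in range(1500):
            model, _, _ = nl.sample_from_modified_prior(model, cfg, moves, rng)
            seps.append(np.linalg.norm(model.coordinates[0] - model.coordinates[1]))
        p = separation_density(contact, 1.0, 1.0)
        grid = np.linspace(0, contact + 8.0, 2000)
        pdf = np.array([p(d) for d in grid])
        cdf_vals = np.cumsum(pdf)
        cdf_vals /= cdf_vals[-1]
        cdf = interp1d(grid, cdf_vals, bounds_error=False, fill_value=(0.0, 1.0))
        result = kstest(np.array(seps), cdf)
        assert result.pvalue > 0.01


class TestConstrainedSample:
    def test_unconstrained_threshold_accepts_first_draw(self, two_bead_topology, rng):
        cfg = nl.RestraintConfig(likelihood_crosslinks=[nl.Crosslink("A", 3, "A", 8)])
        model = nl.initialize_model(two_bead_topology, rng)
        out = nl.constrained_sample(model, cfg, -np.inf, nl.MoveSet(), 10, rng)
        assert isinstance(out, nl.StructureModel)

    def test_constant_likelihood_fails_after_max_attempts(self, two_bead_topology, rng):
        # empty likelihood set: log-likelihood identically 0, strict > unattainable
        cfg = nl.RestraintConfig()
        model = nl.initialize_model(two_bead_topology, rng)
        out = nl.constrained_sample(model, cfg, 0.0, nl.MoveSet(n_steps_per_sample=2), 7, rng)
        assert isinstance(out, SampleFailure)
        assert out.attempts == 7
        assert out.best_log_likelihood == 0.0

    def test_seeded_determinism(self, two_bead_topology):
        cfg = nl.RestraintConfig(likelihood_crosslinks=[nl.Crosslink("A", 3, "A", 8)])
        outs = []
        for _ in range(2):
            rng = np.random.default_rng(33)
            model = nl.initialize_model(two_bead_topology, rng)
            outs.append(nl.constrained_sample(model, cfg, np.log(0.2), nl.MoveSet(), 50, rng))
        np.testing.assert_array_equal(outs[0].coordinates, outs[1].coordinates)

    def test_accepted_samples_exceed_threshold(self, two_bead_topology, rng):
        xl = nl.Crosslink("A", 3, "A", 8)
        cfg = nl.RestraintConfig(likelihood_crosslinks=[xl])
        score = CompiledScore(two_bead_topology, cfg)
        model = nl.initialize_model(two_bead_topology, rng)
        threshold = np.log(0.3)
        for _ in range(10):
            out = nl.constrained_sample(model, cfg, threshold, nl.MoveSet(), 50, rng)
            if isinstance(out, nl.StructureModel):
                assert score.log_likelihood(out.coordinates) > threshold


def test_scorer_per_step_time_scales_with_beads(rng):
    """Weak monotonicity: more beads cost at least as much per MCMC step."""
    chains = [nl.ChainSpec("A", 120)]
    times = {}
    for rpb in (60, 2):
        topo = nl.build_representation(chains, rpb)
        scorer = nl.StructuralScorer(topo, nl.RestraintConfig(), moves=nl.MoveSet(n_steps_per_sample=200))
        for _ in range(15):
            scorer.sample_from_modified_prior(rng)
        times[rpb] = scorer.per_step_time
    assert times[2] > times[60] > 0.0
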