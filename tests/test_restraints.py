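import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

import nestor_lite as nl
from nestor_lite.errors import CrosslinkMappingError, InvalidParameterError
from nestor_lite.restraints import read_crosslink_csv, write_crosslink_csv


def two_bead_model(topology, separation):
    return nl.StructureModel(
        np.array([[0.0, 0.0, 0.0], [separation, 0.0, 0.0]]), topology
    )


class TestRepartition:
    def test_thirty_percent_split(self, crosslinks_ten):
        prior, lik = nl.repartition_restraints(crosslinks_ten, 0.3, seed=7)
        assert len(prior) == 3 and len(lik) == 7
        assert set(prior) | set(lik) == set(crosslinks_ten)
        assert set(prior) & set(lik) == set()

    def test_zero_fraction(self, crosslinks_ten):
        prior, lik = nl.repartition_restraints(crosslinks_ten, 0.0, seed=7)
        assert prior == [] and lik == crosslinks_ten

    def test_seeded_determinism(self, crosslinks_ten):
        a = nl.repartition_restraints(crosslinks_ten, 0.3, seed=5)
        b = nl.repartition_restraints(crosslinks_ten, 0.3, seed=5)
        assert a == b

    def test_empty_list_warns(self, caplog):
        with caplog.at_level("WARNING"):
            prior, lik = nl.repartition_restraints([], 0.3, seed=0)
        assert prior == [] and lik == []
        assert any("empty" in m for m in caplog.messages)


class TestCrosslinkLoglik:
    def test_sigmoid_midpoint(self, two_bead_topology):
        xl = nl.Crosslink("A", 3, "A", 8)
        model = two_bead_model(two_bead_topology, 21.0)
        val = nl.crosslink_loglik(model, [xl], d0=21.0, slope=2.0, floor=0.01)
        assert val == pytest.approx(math.log(0.505), abs=1e-12)

    def test_floor_limit(self, two_bead_topology):
        xl = nl.Crosslink("A", 3, "A", 8)
        model = two_bead_model(two_bead_topology, 1e6)
        val = nl.crosslink_loglik(model, [xl], d0=21.0, slope=2.0, floor=0.01)
        assert val == pytest.approx(math.log(0.01), abs=1e-9)

    def test_log_additivity(self, two_bead_topology):
        xl = nl.Crosslink("A", 3, "A", 8)
        model = two_bead_model(two_bead_topology, 17.0)
        one = nl.crosslink_loglik(model, [xl])
        two = nl.crosslink_loglik(model, [xl, xl])
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_monotone_in_distance(self, two_bead_topology):
        xl = nl.Crosslink("A", 3, "A", 8)
        vals = [
            nl.crosslink_loglik(two_bead_model(two_bead_topology, d), [xl])
            for d in np.linspace(1, 60, 40)
        ]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_unmapped_crosslink_raises(self, two_bead_topology):
        model = two_bead_model(two_bead_topology, 10.0)
        with pytest.raises(CrosslinkMappingError, match="residue 99"):
            nl.crosslink_loglik(model, [nl.Crosslink("A", 1, "A", 99)])


class TestStereochemistry:
    def test_no_overlap_zero(self, two_bead_topology):
        r = two_bead_topology.radii.sum()
        model = two_bead_model(two_bead_topology, r + 5.0)
        assert nl.excluded_volume_logprior(model, 1.0) == 0.0

    def test_overlap_penalty(self):
        # two single-residue chains with radius forced via explicit geometry:
        # overlap of 1 Å at k_ev = 1 gives exactly -0.5
        topo = nl.build_representation([nl.ChainSpec("A", 5), nl.ChainSpec("B", 5)], 5)
        s = topo.radii[0] + topo.radii[1]
        model = two_bead_model(topo, s - 1.0)
        assert nl.excluded_volume_logprior(model, 1.0) == pytest.approx(-0.5, rel=1e-12)

    def test_connectivity_rest_length_and_stretch(self, two_bead_topology):
        s = two_bead_topology.radii.sum()
        assert nl.connectivity_logprior(two_bead_model(two_bead_topology, s), 1.0) == 0.0
        stretched = two_bead_model(two_bead_topology, s + 1.0)
        assert nl.connectivity_logprior(stretched, 1.0) == pytest.approx(-0.5, rel=1e-12)

    def test_single_bead_chain_no_connectivity(self):
        topo = nl.build_representation([nl.ChainSpec("A", 5)], 5)
        model = nl.StructureModel(np.zeros((1, 3)), topo)
        assert nl.connectivity_logprior(model, 1.0) == 0.0

    def test_rigid_body_pairs_excluded_from_ev(self, two_chain_specs):
        topo = nl.build_representation(two_chain_specs, 10)
        body = set(topo.rigid_bodies["body1"])
        for i, j in topo.ev_pairs:
            assert not (i in body and j in body)

    def test_rigid_transform_invariance(self, small_model, rng):
        rot = Rotation.from_rotvec(rng.normal(size=3))
        shift = rng.normal(size=3, scale=50)
        moved = nl.StructureModel(rot.apply(small_model.coordinates) + shift, small_model.topology)
        for fn in (nl.excluded_volume_logprior, nl.connectivity_logprior):
            assert fn(moved) == pytest.approx(fn(small_model), abs=1e-9)


class TestScoreModel:
    def test_all_crosslinks_in_prior_gives_zero_likelihood(self, small_model):
        xls = [nl.Crosslink("A", 1, "B", 1), nl.Crosslink("A", 15, "B", 15)]
        config = nl.RestraintConfig(prior_crosslinks=xls, likelihood_crosslinks=[])
        _, log_lik = nl.score_model(small_model, config)
        assert log_lik == 0.0

    def test_clean_configuration_scores_zero(self, two_bead_topology):
        s = two_bead_topology.radii.sum()
        model = two_bead_model(two_bead_topology, s)
        assert nl.score_model(model, nl.RestraintConfig()) == (pytest.approx(0.0, abs=1e-12), 0.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        split_seed=st.integers(min_value=0, max_value=2**31 - 1),
        coord_seed=st.integers(min_value=0, max_value=2**31 - 1),
        fraction=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_repartitioning_identity(self, split_seed, coord_seed, fraction):
        """The total posterior score is invariant to how crosslinks are split."""
        chains = [nl.ChainSpec("A", 30), nl.ChainSpec("B", 20)]
        topo = nl.build_representation(chains, 10)
        rng = np.random.default_rng(coord_seed)
        model = nl.StructureModel(rng.normal(scale=20, size=(topo.n_beads, 3)), topo)
        xls = [nl.Crosslink("A", 3 * i + 1, "B", 2 * i + 1) for i in range(10)]
        prior, lik = nl.repartition_restraints(xls, fraction, seed=split_seed)
        cfg = nl.RestraintConfig(prior_crosslinks=prior, likelihood_crosslinks=lik)
        ref = nl.RestraintConfig(prior_crosslinks=[], likelihood_crosslinks=xls)
        total = sum(nl.score_model(model, cfg))
        total_ref = sum(nl.score_model(model, ref))
        assert total == pytest.approx(total_ref, rel=1e-9, abs=1e-9)


def test_restraint_config_validation(crosslinks_ten):
    with pytest.raises(InvalidParameterError):
        nl.RestraintConfig(xl_floor=1.0)
    with pytest.raises(InvalidParameterError):
        nl.RestraintConfig(xl_cutoff=-1.0)
    with pytest.raises(InvalidParameterError):
        nl.RestraintConfig(
            prior_crosslinks=crosslinks_ten[:2], likelihood_crosslinks=crosslinks_ten[1:]
        )
    with pytest.raises(InvalidParameterError):
        nl.Crosslink("A", 1, "A", 1)


def test_crosslink_csv_round_trip(tmp_path, crosslinks_ten):
    path = tmp_path / "xl.csv"
    write_crosslink_csv(crosslinks_ten, path)
    assert read_crosslink_csv(path) == crosslinks_ten
    # duplicates survive unless deduplication requested
    write_crosslink_csv(crosslinks_ten + crosslinks_ten[:2], path)
    assert len(read_crosslink_csv(path)) == 12
    assert len(read_crosslink_csv(path, deduplicate=True)) == 10
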