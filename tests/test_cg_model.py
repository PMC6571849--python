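"""Unit tests for the coarse-grained model: specs, energies, polymers."""

import math

import numpy as np
import pytest

from lassocap.cg_model import (ConfigurationError, EnergyParams, Interactions,
                               MismatchError, NucleotideSequence, ProbeSpec,
                               SpecError, SystemState, TargetSpec,
                               bend_k_for_persistence, build_probe,
                               debye_length_nm, find_arm_complements,
                               init_configuration, interactions_from_specs,
                               persistence_length, total_energy,
                               total_energy_system)
from lassocap.synthetic import gen_wlc_chain, wlc_mean_square_r
from lassocap import _kernels as K

from conftest import make_state


def seq(s, name="s"):
    return NucleotideSequence(name, s)


class TestSequences:
    def test_rejects_empty_and_ambiguity_codes(self):
        with pytest.raises(SpecError):
            NucleotideSequence("x", "")
        for bad in ("ACGN", "ACGU", "acgt "):
            with pytest.raises(SpecError):
                NucleotideSequence("x", bad)

    def test_probe_concatenation(self):
        probe = ProbeSpec(seq("ACGT"), seq("TTTT"), seq("AAA"))
        built = build_probe(probe)
        assert built.seq == "ACGTAAATTTT"
        assert len(built) == 11

    def test_zero_adapter_is_mip_like(self):
        probe = ProbeSpec(seq("ACGT"), seq("TTTT"), None)
        assert build_probe(probe).seq == "ACGTTTTT"
        assert probe.adapter_length == 0

    def test_probe_length_arithmetic(self):
        probe = ProbeSpec(seq("A" * 20), seq("A" * 20), seq("C" * 242))
        assert probe.length == 282

    def test_empty_arm_rejected(self):
        with pytest.raises(SpecError):
            ProbeSpec(seq("ACGT"), seq(""), None)


class TestArmComplements:
    def test_two_base_antiparallel_pairing(self):
        # ext arm "AC" pairs the site containing "GT" (its reverse
        # complement) antiparallel: arm 5' end maps to site 3' end
        probe = ProbeSpec(seq("AC"), seq("AA"), None)
        target = TargetSpec(seq("GTCCTT"), ext_site=(0, 2), lig_site=(4, 6))
        ext, lig = find_arm_complements(probe, target)
        assert ext == [(0, 1), (1, 0)]
        assert lig == [(2, 5), (3, 4)]

    def test_pair_cardinality_matches_arm_length(self):
        arm = "ACGTACGTAC"  # 10 nt
        rc = "GTACGTACGT"
        probe = ProbeSpec(seq(arm), seq(arm), seq("AAAA"))
        target = TargetSpec(seq(rc + "TTTT" + rc), ext_site=(0, 10),
                            lig_site=(14, 24))
        ext, lig = find_arm_complements(probe, target)
        assert len(ext) == 10 and len(lig) == 10

    def test_mismatch_error_names_positions(self):
        probe = ProbeSpec(seq("ACGT"), seq("AAAA"), None)
        # site reverse complement of ACGT is ACGT; corrupting target
        # position 1 shows up at arm position 2 (antiparallel mapping)
        target = TargetSpec(seq("AGGTTTTT"), ext_site=(0, 4),
                            lig_site=(4, 8))
        with pytest.raises(MismatchError) as err:
            find_arm_complements(probe, target)
        assert err.value.positions == [2]

    def test_site_bounds_and_overlap_validation(self):
        with pytest.raises(SpecError):
            TargetSpec(seq("ACGTACGT"), ext_site=(0, 4), lig_site=(3, 7))
        with pytest.raises(SpecError):
            TargetSpec(seq("ACGT"), ext_site=(0, 5), lig_site=(0, 2))


class TestEnergy:
    def test_straight_separated_chains_have_zero_energy(self):
        params = EnergyParams()
        n = 10
        pos1 = np.zeros((n, 3))
        pos1[:, 0] = params.bond_r0 * np.arange(n) + 5
        pos1[:, 1] = 5.0
        pos2 = pos1.copy()
        pos2[:, 1] = 30.0
        st = make_state(np.vstack([pos1, pos2]), [0] * n + [1] * n, 60.0)
        inter = Interactions.from_pairs(2 * n, [(0, n)], [(n - 1, 2 * n - 1)])
        assert total_energy_system(st, inter, params) == pytest.approx(0.0, abs=1e-12)

    def test_stretched_bond_half_k_dr_squared(self):
        params = EnergyParams(bond_k=100.0)
        st = make_state([[5, 5, 5], [5 + params.bond_r0 + 0.1, 5, 5]],
                        [0, 0], 60.0)
        inter = Interactions.from_pairs(2, np.empty((0, 2)), np.empty((0, 2)))
        assert total_energy_system(st, inter, params) == pytest.approx(0.5, rel=1e-9)

    def test_three_bead_chain_matches_hand_sum(self):
        # bent trimer with printed coordinates; terms summed by hand from
        # the energy definitions (bond + Kratky-Porod bend; the 1-3 pair
        # sits beyond all non-bonded cutoffs)
        params = EnergyParams(bond_k=100.0, bond_r0=0.65, bend_k=2.8,
                              el_amplitude=0.0)
        pos = np.array([[5.0, 5.0, 5.0],
                        [5.65, 5.0, 5.0],
                        [5.65, 5.75, 5.0]])
        st = make_state(pos, [0, 0, 0], 60.0)
        inter = Interactions.from_pairs(3, np.empty((0, 2)), np.empty((0, 2)))
        e_bond = 0.5 * 100.0 * (0.65 - 0.65) ** 2 \
            + 0.5 * 100.0 * (0.75 - 0.65) ** 2
        e_bend = 2.8 * (1.0 - 0.0)  # right angle: cos(theta) = 0
        expected = e_bond + e_bend
        assert total_energy_system(st, inter, params) == pytest.approx(expected, rel=1e-12)

    def test_hybridization_well_and_cap(self):
        params = EnergyParams(hyb_epsilon=3.0, hyb_range=0.85,
                              cap_energy=100.0, el_amplitude=0.0)
        inter = Interactions.from_pairs(2, [(0, 1)], [(0, 1)])
        st = make_state([[5, 5, 5], [5.7, 5, 5]], [0, 1], 60.0)
        # r=0.7: inside well, just outside WCA cutoff (0.617 nm)
        assert total_energy_system(st, inter, params) == pytest.approx(-3.0)
        st2 = make_state([[5, 5, 5], [5, 5, 5]], [0, 1], 60.0)
        # coincident beads: capped repulsion minus the well depth, finite
        assert total_energy_system(st2, inter, params) == pytest.approx(100.0 - 3.0)

    def test_rigid_motion_and_rewrap_invariance(self):
        rng = np.random.default_rng(3)
        params = EnergyParams(hyb_epsilon=2.0)
        n = 8
        pos = rng.uniform(10, 14, size=(2 * n, 3))
        cid = [0] * n + [1] * n
        inter = Interactions.from_pairs(2 * n, [(0, n)], [(n - 1, 2 * n - 1)])
        st = make_state(pos.copy(), cid, 30.0)
        e0 = total_energy_system(st, inter, params)
        # random rotation + translation applied to all beads jointly
        from scipy.spatial.transform import Rotation
        R = Rotation.random(random_state=11).as_matrix()
        moved = pos @ R.T + np.array([17.3, -6.1, 44.0])
        st2 = make_state(moved, cid, 30.0)  # constructor wraps
        assert total_energy_system(st2, inter, params) == pytest.approx(e0, abs=1e-9)

    def test_energy_extensivity_on_duplicated_system(self):
        rng = np.random.default_rng(5)
        params = EnergyParams(hyb_epsilon=2.0)
        n = 6
        pos = rng.uniform(2, 8, size=(2 * n, 3))
        cid = np.array([0] * n + [1] * n)
        inter1 = Interactions.from_pairs(2 * n, [(0, n)], [(n - 1, 2 * n - 1)])
        st1 = make_state(pos.copy(), cid, 20.0)
        e1 = total_energy_system(st1, inter1, params)
        # duplicate far away in a doubled box: no cross interactions
        pos2 = np.vstack([pos, pos + np.array([25.0, 25.0, 0.0])])
        cid2 = np.concatenate([cid, cid + 2])
        inter2 = Interactions.from_pairs(
            4 * n, [(0, n), (2 * n, 3 * n)],
            [(n - 1, 2 * n - 1), (3 * n - 1, 4 * n - 1)])
        st2 = make_state(pos2, cid2, 40.0)
        e2 = total_energy_system(st2, inter2, params)
        assert e2 == pytest.approx(2 * e1, rel=1e-9, abs=1e-9)


class TestInitConfiguration:
    def _specs(self):
        probe = ProbeSpec(seq("ACGT"), seq("ACGT"), seq("A" * 42))
        rc = "ACGT"
        target = TargetSpec(seq(rc + "TTTTTTTT" + rc), ext_site=(0, 4),
                            lig_site=(12, 16))
        return probe, target

    def test_same_seed_is_bitwise_identical(self):
        probe, target = self._specs()
        s1 = init_configuration(probe, target, 60.0, 42)
        s2 = init_configuration(probe, target, 60.0, 42)
        assert np.array_equal(s1.pos, s2.pos)

    def test_bead_counts_match_sequences(self):
        probe, target = self._specs()
        st = init_configuration(probe, target, 60.0, 1)
        assert st.probe_positions.shape == (50, 3)
        assert st.target_positions.shape == (16, 3)
        assert np.all(st.pos >= 0) and np.all(st.pos < 60.0)

    def test_box_below_contour_rejected(self):
        probe, target = self._specs()
        # probe contour: 49 bonds x 0.65 nm = 31.85 nm
        with pytest.raises(ConfigurationError):
            init_configuration(probe, target, 20.0, 1)


class TestCalibration:
    def test_debye_length_formula(self):
        assert debye_length_nm(300.0) == pytest.approx(0.304 / math.sqrt(0.3))
        with pytest.raises(ValueError):
            debye_length_nm(0.0)

    def test_inconsistent_debye_rejected(self):
        with pytest.raises(ValueError):
            EnergyParams(salt_Na_mM=300.0, debye_length=1.0)

    def test_default_persistence_length_near_target(self):
        # bend_k default is tuned for ~1.5 nm at 300 mM Na+
        assert persistence_length(EnergyParams()) == pytest.approx(1.5, abs=0.05)

    def test_bend_k_solver_round_trips(self):
        k = bend_k_for_persistence(2.0, 0.65)
        assert persistence_length(EnergyParams(bend_k=k, ev_epsilon=0.0)) \
            == pytest.approx(2.0, rel=1e-6)


class TestWormLikeChainStatistics:
    """Free-chain <R^2> against the discrete WLC closed form."""

    @pytest.mark.parametrize("n_beads", [20, 50, 100])
    def test_direct_equilibrium_samples_match_closed_form(self, n_beads):
        params = EnergyParams(ev_epsilon=0.0, el_amplitude=0.0)
        exact = wlc_mean_square_r(n_beads, params.bond_k, params.bond_r0,
                                  params.bend_k)
        chains = gen_wlc_chain(n_beads, params.bond_k, params.bond_r0,
                               params.bend_k, seed=13, n_samples=20_000)
        r2 = np.sum((chains[:, -1] - chains[:, 0]) ** 2, axis=1)
        sem = r2.std(ddof=1) / np.sqrt(len(r2))
        assert abs(r2.mean() - exact) < max(3 * sem, 0.05 * exact)

    def test_mcmc_sampler_matches_closed_form_small_chain(self):
        # single free 20-bead chain sampled by the Metropolis engine
        n = 20
        params = EnergyParams(ev_epsilon=0.0, el_amplitude=0.0)
        exact = wlc_mean_square_r(n, params.bond_k, params.bond_r0,
                                  params.bend_k)
        from lassocap.sampler import MoveParams, run_sampler
        pos = np.zeros((n, 3))
        pos[:, 0] = params.bond_r0 * np.arange(n)
        st = make_state(pos + 100.0, [0] * n, 300.0)
        inter = Interactions.from_pairs(n, np.empty((0, 2)), np.empty((0, 2)))
        move = MoveParams(max_translation=0.35, seed=2)
        r2_series = []
        # chunks of 40k steps; record R^2 between chunks
        for c in range(500):
            run_sampler(st, inter, params, move, 40_000, stride=0,
                        seed=1000 + c, use_vmmc=False)
            d = st.pos[-1] - st.pos[0]
            d -= 300.0 * np.round(d / 300.0)
            r2_series.append(d @ d)
        r2_series = np.asarray(r2_series)[50:]
        sem = r2_series.std(ddof=1) / np.sqrt(len(r2_series))
        assert abs(r2_series.mean() - exact) < max(3 * sem, 0.05 * exact)
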