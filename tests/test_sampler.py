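"""Monte Carlo engines: Metropolis reference and VMMC cluster moves."""

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from lassocap.cg_model import EnergyParams, Interactions
from lassocap.sampler import MoveParams, metropolis_step, run_sampler, vmmc_step

from conftest import make_state


def free_bead_system(box=20.0):
    inter = Interactions.from_pairs(1, np.empty((0, 2)), np.empty((0, 2)))
    st = make_state([[5.0, 5.0, 5.0]], [0], box, seed=4)
    return st, inter


class TestSingleSteps:
    def test_zero_energy_change_always_accepted(self):
        # a single non-interacting bead: every move has dE = 0
        params = EnergyParams()
        st, inter = free_bead_system()
        move = MoveParams(seed=1)
        for _ in range(50):
            _, acc = metropolis_step(st, inter, params, move)
            assert acc

    def test_vmmc_isolated_bead_reduces_to_metropolis(self):
        # no neighbors within range: cluster is the seed bead alone and
        # the move is a plain rigid displacement, always accepted
        params = EnergyParams()
        st, inter = free_bead_system()
        move = MoveParams(seed=2)
        start = st.pos.copy()
        n_moved = 0
        for _ in range(50):
            _, acc = vmmc_step(st, inter, params, move)
            assert acc
            if not np.allclose(st.pos, start):
                n_moved += 1
            start = st.pos.copy()
        assert n_moved > 0

    def test_capped_overlap_acceptance_is_tiny(self):
        # two coincident beads: dE from the capped overlap ~ cap_energy,
        # so a move onto the partner is essentially never accepted
        params = EnergyParams(cap_energy=100.0, hyb_epsilon=0.0)
        inter = Interactions.from_pairs(2, np.empty((0, 2)), np.empty((0, 2)))
        accepted_onto_overlap = 0
        for s in range(200):
            st = make_state([[5.0, 5.0, 5.0], [5.0, 5.0, 5.2]], [0, 1],
                            20.0, seed=s)
            res = run_sampler(st, inter, params,
                              MoveParams(max_translation=0.3, seed=s), 20,
                              stride=0, use_vmmc=False)
            d = st.pos[0] - st.pos[1]
            d -= 20.0 * np.round(d / 20.0)
            if np.sqrt(d @ d) < 0.3:
                accepted_onto_overlap += 1
        assert accepted_onto_overlap <= 2


class TestHarmonicDimerBoltzmann:
    def test_bond_length_distribution_matches_closed_form(self):
        """Long Metropolis run on a harmonic dimer: the bond-length mean
        must match the exact Boltzmann average of p(b) ~ b^2 e^{-k(b-r0)^2/2}."""
        params = EnergyParams(ev_epsilon=0.0, el_amplitude=0.0, bend_k=0.0)
        inter = Interactions.from_pairs(2, np.empty((0, 2)), np.empty((0, 2)))
        st = make_state([[5, 5, 5], [5.65, 5, 5]], [0, 0], 20.0, seed=0)
        move = MoveParams(max_translation=0.25, seed=3)
        samples = []
        for c in range(400):
            run_sampler(st, inter, params, move, 2_000, stride=0,
                        seed=7000 + c, use_vmmc=False)
            d = st.pos[0] - st.pos[1]
            d -= 20.0 * np.round(d / 20.0)
            samples.append(np.sqrt(d @ d))
        samples = np.asarray(samples)[20:]
        k, r0 = params.bond_k, params.bond_r0
        z = quad(lambda b: b**2 * np.exp(-0.5 * k * (b - r0)**2), 0.01, 2)[0]
        exact_mean = quad(lambda b: b**3 * np.exp(-0.5 * k * (b - r0)**2),
                          0.01, 2)[0] / z
        sem = samples.std(ddof=1) / np.sqrt(len(samples))
        assert abs(samples.mean() - exact_mean) < 3 * sem + 1e-3

    def test_bound_dimer_cluster_moves_preserve_internal_distance(self):
        """A deeply bound Go dimer translates as one VMMC cluster; the
        internal distance distribution in an early window must match a late
        window (two-sample KS)."""
        params = EnergyParams(ev_epsilon=0.0, el_amplitude=0.0, bend_k=0.0,
                              hyb_epsilon=30.0, hyb_range=0.85)
        inter = Interactions.from_pairs(2, [(0, 1)], [(0, 1)])
        st = make_state([[5, 5, 5], [5.4, 5, 5]], [0, 1], 20.0, seed=0)
        move = MoveParams(max_translation=0.4, max_rotation=0.3, seed=5)
        dists = []
        for c in range(400):
            run_sampler(st, inter, params, move, 250, stride=0,
                        seed=3000 + c, use_vmmc=True)
            d = st.pos[0] - st.pos[1]
            d -= 20.0 * np.round(d / 20.0)
            dists.append(np.sqrt(d @ d))
        dists = np.asarray(dists)
        assert dists.max() < 0.85  # never unbound at 30 kT
        early, late = dists[50:200], dists[250:]
        p = stats.ks_2samp(early, late).pvalue
        assert p > 1e-3


class TestRunSampler:
    def test_acceptance_bookkeeping_is_exact(self, four_bead_toy):
        t = four_bead_toy
        res = run_sampler(t["new_state"](), t["inter"], t["params"],
                          t["move"], 5_000, bins=t["bins"], n_equil=500,
                          stride=5, seed=9)
        assert res.n_accepted + res.n_rejected == 5_500
        assert res.hist.sum() == 5_000
        assert len(res.traj_q_ex) == 1_000

    def test_seed_determinism_is_bitwise(self, four_bead_toy):
        t = four_bead_toy
        outs = []
        for _ in range(2):
            st = t["new_state"]()
            res = run_sampler(st, t["inter"], t["params"], t["move"],
                              20_000, bins=t["bins"], stride=10, seed=123)
            outs.append((st.pos.copy(), res.hist.copy(),
                         res.traj_q_ex.copy()))
        assert np.array_equal(outs[0][0], outs[1][0])
        assert np.array_equal(outs[0][1], outs[1][1])
        assert np.array_equal(outs[0][2], outs[1][2])

    def test_weight_scale_invariance(self, four_bead_toy):
        # doubling every weight shifts log-weights by a constant: the
        # trajectory must be bitwise identical (only ratios enter)
        t = four_bead_toy
        nq = t["bins"].n_intervals
        w = np.exp(np.random.default_rng(1).uniform(0, 2, (nq, nq)))
        runs = []
        for scale in (1.0, 2.0):
            st = t["new_state"]()
            res = run_sampler(st, t["inter"], t["params"], t["move"],
                              20_000, weights=scale * w, bins=t["bins"],
                              stride=10, seed=55)
            runs.append(res.hist.copy())
        assert np.array_equal(runs[0], runs[1])

    def test_uniform_weights_match_unweighted(self, four_bead_toy):
        t = four_bead_toy
        nq = t["bins"].n_intervals
        h = []
        for w in (None, np.ones((nq, nq))):
            st = t["new_state"]()
            res = run_sampler(st, t["inter"], t["params"], t["move"],
                              20_000, weights=w, bins=t["bins"], stride=0,
                              seed=77)
            h.append(res.hist.copy())
        assert np.array_equal(h[0], h[1])

    def test_zero_weight_rejected(self, four_bead_toy):
        t = four_bead_toy
        nq = t["bins"].n_intervals
        w = np.ones((nq, nq))
        w[0, 0] = 0.0
        with pytest.raises(ValueError):
            run_sampler(t["new_state"](), t["inter"], t["params"], t["move"],
                        100, weights=w, bins=t["bins"])

    def test_biased_two_state_occupancy_ratio(self, pair_toy):
        """Umbrella factor w1/w0 = 10 on one far cell multiplies its
        occupancy relative to a neighbour by ~10x compared to unbiased."""
        t = pair_toy
        nq = t["bins"].n_intervals
        w = np.ones((nq, nq))
        w[8, 8] = 10.0
        occ = {}
        for tag, weights in (("flat", None), ("biased", w)):
            st = t["new_state"](3)
            res = run_sampler(st, t["inter"], t["params"], t["move"],
                              2_000_000, weights=weights, bins=t["bins"],
                              stride=0, seed=31)
            occ[tag] = res.hist[8, 8] / max(res.hist[7, 7], 1)
        boost = occ["biased"] / occ["flat"]
        assert 7.0 < boost < 13.0

    def test_cluster_cap_rejections_are_counted(self):
        # bound 3-bead chain with cap 1: cluster moves recruiting a bonded
        # neighbour abort and are logged
        params = EnergyParams(ev_epsilon=0.0, el_amplitude=0.0, bend_k=0.0)
        inter = Interactions.from_pairs(3, np.empty((0, 2)), np.empty((0, 2)))
        st = make_state([[5, 5, 5], [5.65, 5, 5], [6.3, 5, 5]], [0, 0, 0],
                        20.0, seed=0)
        move = MoveParams(max_translation=2.0, cluster_size_cap=1, seed=6)
        res = run_sampler(st, inter, params, move, 5_000, stride=0, seed=6)
        assert res.n_cap_rejected > 0
        assert res.n_accepted + res.n_rejected == 5_000
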