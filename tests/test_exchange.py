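"""Candidate detection, conflict resolution, feedback rule, update execution."""

import numpy as np
import pytest

import pexkit as pk
from pexkit.errors import ConsistencyError, GeometryError
from pexkit.exchange import _donor_acceptor_species
from pexkit.geometry import minimum_image


def _bead_state(states, positions, bead_templates, box_length=40.0):
    by_state = {s: t for t in bead_templates for s in t.state_names}
    residues, charges, eps, rmin = [], [], [], []
    for rid, s in enumerate(states):
        t = by_state[s]
        residues.append(pk.Residue(id=rid, template=t, current_state_name=s,
                                   atom_start=rid))
        a = t.atoms_for(s)[0]
        charges.append(a.charge)
        eps.append(a.lj_epsilon)
        rmin.append(a.lj_rmin_half)
    return pk.SystemState(
        positions=np.asarray(positions, float),
        box=pk.BoxSpec.cubic(box_length),
        residues=residues,
        charges=np.array(charges),
        lj_epsilon=np.array(eps),
        lj_rmin_half=np.array(rmin),
        atom_names=["BD"] * len(states),
    )


def _reactions(r_max=1.55):
    return pk.single_bead_reactions(r_max=r_max)


class TestFindCandidates:
    @pytest.mark.parametrize("distance,expected", [(1.50, 1), (1.60, 0)])
    def test_distance_cutoff_is_strict(self, bead_templates, distance, expected):
        state = _bead_state(["IM1H", "OAC"],
                            [[5.0, 5.0, 5.0], [5.0 + distance, 5.0, 5.0]],
                            bead_templates)
        cands = pk.find_candidates(state, _reactions(1.55), bead_templates)
        assert len(cands) == expected
        if expected:
            assert cands[0].distance == pytest.approx(distance)
            assert cands[0].donor_residue == 0  # IM1H donates

    def test_periodic_wrap_detected(self, bead_templates):
        L = 40.0
        state = _bead_state(["IM1H", "OAC"],
                            [[0.5, 5.0, 5.0], [L - 1.0, 5.0, 5.0]],
                            bead_templates, box_length=L)
        cands = pk.find_candidates(state, _reactions(1.55), bead_templates)
        assert len(cands) == 1
        assert cands[0].distance == pytest.approx(1.5)

    def test_r_max_at_half_box_rejected(self, bead_templates):
        state = _bead_state(["IM1H", "OAC"], [[1, 1, 1], [3, 1, 1]],
                            bead_templates, box_length=10.0)
        with pytest.raises(GeometryError):
            pk.find_candidates(state, _reactions(5.0), bead_templates)

    def test_matches_brute_force_oracle_on_random_configs(self, bead_templates):
        """KD-tree candidate search equals the O(N^2) reference on 100 seeds."""
        r_max = 2.5
        reactions = _reactions(r_max)
        by_state = {s: t for t in bead_templates for s in t.state_names}
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = 60
            states = rng.choice(["IM1H", "OAC", "IM1", "HOAC"], size=n)
            L = 15.0
            pos = rng.random((n, 3)) * L
            state = _bead_state(list(states), pos, bead_templates, box_length=L)
            got = {
                (c.donor_residue, c.acceptor_residue, c.reaction.name)
                for c in pk.find_candidates(state, reactions, bead_templates)
            }
            expected = set()
            for rx in reactions:
                donor_sp, acc_sp = _donor_acceptor_species(rx, by_state)
                for i in range(n):
                    if states[i] != donor_sp:
                        continue
                    for j in range(n):
                        if i == j or states[j] != acc_sp:
                            continue
                        d = minimum_image(pos[j] - pos[i], state.box.array)
                        if np.sqrt(d @ d) < r_max:
                            expected.add((i, j, rx.name))
            assert got == expected, f"seed {seed}"

    def test_donor_is_protonated_reactant(self, bead_templates):
        # neutral->charged channel: the acid (HOAC) donates to the base (IM1)
        state = _bead_state(["IM1", "HOAC"], [[5, 5, 5], [6.2, 5, 5]],
                            bead_templates)
        cands = pk.find_candidates(state, _reactions(1.55), bead_templates)
        assert len(cands) == 1
        assert cands[0].donor_residue == 1
        assert cands[0].acceptor_residue == 0


class TestResolveConflicts:
    def _cand(self, donor, acceptor, dist, reaction):
        return pk.CandidatePair(donor_residue=donor, acceptor_residue=acceptor,
                                donor_atom="BD", acceptor_atom="BD",
                                distance=dist, reaction=reaction)

    def test_shared_donor_keeps_shortest(self):
        rx = _reactions(2.0)[0]
        kept = pk.resolve_conflicts(
            [self._cand(0, 1, 1.4, rx), self._cand(0, 2, 1.2, rx)]
        )
        assert [(c.donor_residue, c.acceptor_residue) for c in kept] == [(0, 2)]

    def test_disjoint_candidates_all_kept(self):
        rx = _reactions(2.0)[0]
        kept = pk.resolve_conflicts(
            [self._cand(0, 1, 1.4, rx), self._cand(2, 3, 1.5, rx)]
        )
        assert len(kept) == 2

    def test_chain_resolution_matches_greedy_oracle(self):
        # A-B at 1.3, B-C at 1.2: greedy takes B-C, then A-B conflicts on B
        rx = _reactions(2.0)[0]
        kept = pk.resolve_conflicts(
            [self._cand(0, 1, 1.3, rx), self._cand(1, 2, 1.2, rx)]
        )
        assert [(c.donor_residue, c.acceptor_residue) for c in kept] == [(1, 2)]

    def test_tie_break_deterministic(self):
        rx = _reactions(2.0)[0]
        kept = pk.resolve_conflicts(
            [self._cand(2, 3, 1.0, rx), self._cand(0, 1, 1.0, rx)]
        )
        assert (kept[0].donor_residue, kept[0].acceptor_residue) == (0, 1)


class TestFeedbackRule:
    def test_fixed_point_at_reference_count(self, atomistic):
        _, reactions = atomistic
        cation_anion = reactions[0]
        p = pk.update_probability(cation_anion.p_ref, cation_anion.c, 150, 150)
        assert p == pytest.approx(0.994)

    def test_cubic_increase(self):
        # 0.098 + 300 * (1.1 - 1)^3 = 0.098 + 0.3
        assert pk.update_probability(0.098, 300.0, 110, 100) == pytest.approx(0.398)

    def test_clamped_at_zero(self):
        # 0.098 - 0.3 < 0 -> clamp
        assert pk.update_probability(0.098, 300.0, 90, 100) == 0.0

    def test_clamped_at_one(self):
        assert pk.update_probability(0.9, 300.0, 150, 100) == 1.0

    def test_zero_reference_count_rejected(self):
        with pytest.raises(ValueError):
            pk.update_probability(0.5, 300.0, 10, 0)

    def test_swap_reactions_stay_at_reference(self, bead_templates):
        reactions = _reactions()
        ps = pk.ProbabilityState.from_reactions(
            reactions, {"IM1H": 150, "OAC": 150, "IM1": 350, "HOAC": 350}
        )
        ps.refresh({"IM1H": 100, "OAC": 100, "IM1": 400, "HOAC": 400})
        # composition-changing channels respond...
        assert ps.current[reactions[0].name] < reactions[0].p_ref
        assert ps.current[reactions[1].name] > reactions[1].p_ref
        # ...swap channels do not
        assert ps.current[reactions[2].name] == reactions[2].p_ref
        assert ps.current[reactions[3].name] == reactions[3].p_ref


class TestAcceptance:
    def _pairs(self, n, rx):
        return [
            pk.CandidatePair(donor_residue=2 * k, acceptor_residue=2 * k + 1,
                             donor_atom="BD", acceptor_atom="BD",
                             distance=1.0, reaction=rx)
            for k in range(n)
        ]

    def test_extreme_probabilities(self):
        rx_all = pk.TransferReaction(("IM1H", "OAC"), ("IM1", "HOAC"), 2.0, 1.0, 0.0)
        rx_none = pk.TransferReaction(("IM1H", "OAC"), ("IM1", "HOAC"), 2.0, 0.0, 0.0)
        for rx, expected in ((rx_all, 10), (rx_none, 0)):
            ps = pk.ProbabilityState.from_reactions([rx], {"IM1H": 1})
            got = pk.accept_transfers(self._pairs(10, rx), ps,
                                      np.random.default_rng(0))
            assert len(got) == expected

    def test_bernoulli_fraction(self):
        rx = pk.TransferReaction(("IM1H", "OAC"), ("IM1", "HOAC"), 2.0, 0.5, 0.0)
        ps = pk.ProbabilityState.from_reactions([rx], {"IM1H": 1})
        got = pk.accept_transfers(self._pairs(10_000, rx), ps,
                                  np.random.default_rng(123))
        assert len(got) / 10_000 == pytest.approx(0.5, abs=0.02)

    def test_seed_reproducibility(self):
        rx = pk.TransferReaction(("IM1H", "OAC"), ("IM1", "HOAC"), 2.0, 0.5, 0.0)
        ps = pk.ProbabilityState.from_reactions([rx], {"IM1H": 1})
        a = pk.accept_transfers(self._pairs(100, rx), ps, np.random.default_rng(7))
        b = pk.accept_transfers(self._pairs(100, rx), ps, np.random.default_rng(7))
        assert [c.donor_residue for c in a] == [c.donor_residue for c in b]
        assert 0 < len(a) < 100


class TestExecuteUpdate:
    def test_neutralisation_conserves_charge(self, bead_templates):
        state = _bead_state(["IM1H", "OAC"], [[5, 5, 5], [6.4, 5, 5]],
                            bead_templates)
        cands = pk.find_candidates(state, _reactions(1.55), bead_templates)
        state, events = pk.execute_update(state, cands)
        assert [r.current_state_name for r in state.residues] == ["IM1", "HOAC"]
        assert state.total_charge == 0
        e = events[0]
        assert (e.q_i_before, e.q_j_before, e.q_i_after, e.q_j_after) == (1, -1, 0, 0)
        assert e.r_ij == pytest.approx((1.4, 0.0, 0.0))

    def test_swap_exchanges_charge_classes(self, bead_templates):
        state = _bead_state(["IM1H", "IM1"], [[5, 5, 5], [6.4, 5, 5]],
                            bead_templates)
        before = state.species_counts()
        cands = pk.find_candidates(state, [_reactions(1.55)[2]], bead_templates)
        state, events = pk.execute_update(state, cands)
        assert state.species_counts() == before  # composition unchanged
        assert [r.current_state_name for r in state.residues] == ["IM1", "IM1H"]
        assert events[0].q_i_before == 1 and events[0].q_j_after == 1

    def test_empty_accepted_list_is_noop(self, bead_templates):
        state = _bead_state(["IM1H", "OAC"], [[5, 5, 5], [20, 5, 5]],
                            bead_templates)
        q = state.charges.copy()
        state, events = pk.execute_update(state, [])
        assert events == []
        assert np.array_equal(state.charges, q)

    def test_wrong_state_raises_consistency_error(self, bead_templates):
        state = _bead_state(["IM1H", "OAC"], [[5, 5, 5], [6.4, 5, 5]],
                            bead_templates)
        cands = pk.find_candidates(state, _reactions(1.55), bead_templates)
        pk.apply_state_to_residue(state, state.residues[0], "IM1")
        with pytest.raises(ConsistencyError):
            pk.execute_update(state, cands)


class TestInterpolation:
    def test_single_step_equals_instantaneous(self, bead_templates):
        mk = lambda: _bead_state(["IM1H", "OAC"], [[5, 5, 5], [6.4, 5, 5]],
                                 bead_templates)
        s1, s2 = mk(), mk()
        cands = pk.find_candidates(s1, _reactions(1.55), bead_templates)
        pk.execute_update(s1, cands)
        cands2 = pk.find_candidates(s2, _reactions(1.55), bead_templates)
        pk.execute_update(s2, cands2, swap_mode="interpolated", n_lambda_steps=1)
        assert np.array_equal(s1.charges, s2.charges)
        assert np.array_equal(s1.lj_epsilon, s2.lj_epsilon)

    def test_linear_path_and_charge_conservation(self, bead_templates):
        state = _bead_state(["IM1H", "OAC"], [[5, 5, 5], [6.4, 5, 5]],
                            bead_templates)
        cands = pk.find_candidates(state, _reactions(1.55), bead_templates)
        seen = []

        def hook(s, lam):
            seen.append((lam, s.charges.copy()))

        pk.execute_update(state, cands, swap_mode="interpolated",
                          n_lambda_steps=4, dynamics_hook=hook)
        assert [lam for lam, _ in seen] == pytest.approx([0.25, 0.5, 0.75])
        lam_half = dict((round(l, 2), q) for l, q in seen)[0.5]
        # every atomic charge is the mean of its two states
        assert lam_half == pytest.approx([0.5, -0.5])
        # total pair charge at every lambda equals the endpoint total
        for _, q in seen:
            assert q.sum() == pytest.approx(0.0, abs=1e-12)


class TestEngineInvariants:
    def test_charge_conserved_and_balanced_across_updates(self, bead_templates):
        """Mini exchange simulation: exact neutrality, per-event balance."""
        state = pk.build_system(15, 35, pk.BoxSpec.cubic(18.0), 3.0, seed=21,
                                templates=bead_templates)
        reactions = pk.single_bead_reactions(r_max=3.8)
        ps = pk.ProbabilityState.from_reactions(reactions, state.species_counts())
        rng = np.random.default_rng(5)
        drift = np.random.default_rng(6)
        all_events = []
        for _ in range(30):
            # random displacement instead of full dynamics: cheap mixing
            state.positions = (state.positions
                               + drift.normal(0, 0.4, state.positions.shape))
            state.positions %= state.box.array
            state, events = pk.run_update(state, reactions, bead_templates, ps, rng)
            all_events.extend(events)
            assert state.total_charge == 0
        assert len(all_events) > 0
        for e in all_events:
            assert e.q_i_after + e.q_j_after == e.q_i_before + e.q_j_before

    def test_identical_seed_identical_event_log(self, bead_templates):
        def one(seed):
            state = pk.build_system(10, 20, pk.BoxSpec.cubic(16.0), 3.0, seed=2,
                                    templates=bead_templates)
            ff = pk.ToyForceField(sigma=4.0, epsilon=0.5, screening_length=0.5,
                                  cutoff=7.0)
            integ = pk.IntegratorConfig(n_steps=200, seed=seed)
            upd = pk.UpdateConfig(update_interval=0.2, seed=seed + 1)
            res = pk.run(state, ff, integ, upd,
                         templates=bead_templates,
                         reactions=pk.single_bead_reactions(r_max=3.8),
                         frame_stride=10, record_energies=False)
            return [(e.time, e.residue_i, e.residue_j, e.reaction)
                    for e in res.events]

        assert one(42) == one(42)

    def test_update_opportunity_arithmetic(self):
        assert pk.n_update_opportunities(50_000.0, 10.0) == 5000
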