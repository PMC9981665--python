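"""Unfolding, segment cutting, diffusion, dipole corrections, conductivity."""

import numpy as np
import pandas as pd
import pytest

import pexkit as pk
from pexkit.errors import ConsistencyError
from pexkit.geometry import fold
from pexkit.transport import CORRECTION_CASES, event_dipole_jump


def _event(t, i, j, qib, qjb, qia, qja, r_ij, com_i=(0, 0, 0), com_j=(0, 0, 0)):
    return pk.TransferEvent(
        time=t, residue_i=i, residue_j=j, reaction="x",
        q_i_before=qib, q_j_before=qjb, q_i_after=qia, q_j_after=qja,
        com_i=com_i, com_j=com_j, r_ij=tuple(r_ij),
    )


class TestUnfold:
    def test_boundary_crossing_is_monotone(self):
        box = pk.BoxSpec.cubic(10.0)
        folded = np.array([[[9.5, 5, 5]], [[9.9, 5, 5]], [[0.3, 5, 5]],
                           [[0.7, 5, 5]]])
        out = pk.unfold(folded, box)
        x = out[:, 0, 0]
        assert np.all(np.diff(x) > 0)
        assert np.max(np.abs(np.diff(x))) < 1.0  # no box-sized jump

    def test_static_particles_unchanged(self):
        box = pk.BoxSpec.cubic(10.0)
        folded = np.tile(np.array([[1.0, 2.0, 3.0]]), (5, 1, 1))
        assert np.array_equal(pk.unfold(folded, box), folded)

    def test_fold_unfold_round_trip_exact(self):
        """Random continuous walks survive fold -> unfold bit-for-bit."""
        rng = np.random.default_rng(12)
        box = pk.BoxSpec.cubic(8.0)
        for _ in range(20):
            steps = rng.uniform(-3.5, 3.5, size=(40, 6, 3))  # < L/2 per frame
            walk = np.cumsum(steps, axis=0)
            walk -= walk[0] - rng.uniform(0, 8.0, size=(6, 3))  # start inside box
            recovered = pk.unfold(fold(walk, box.array), box)
            assert np.allclose(recovered, walk, atol=1e-9)

    def test_half_box_step_flags_aliasing(self):
        box = pk.BoxSpec.cubic(10.0)
        folded = np.array([[[0.0, 0, 0]], [[5.0, 0, 0]]])
        with pytest.raises(ConsistencyError, match="residue 0"):
            pk.unfold(folded, box)


class TestSegmentCutting:
    @pytest.fixture()
    def toy_series(self, bead_templates):
        times = np.linspace(0.0, 10.0, 21)
        unfolded = np.zeros((21, 2, 3))
        unfolded[:, 0, 0] = np.linspace(0, 5, 21)
        return times, unfolded

    def test_no_events_gives_full_segment(self, toy_series, bead_templates):
        times, unfolded = toy_series
        segs = pk.cut_segments_at_transfers(
            times, unfolded, [], ["IM1H", "OAC"], bead_templates, min_length=5.0
        )
        assert len(segs) == 2
        assert all(s.length == pytest.approx(10.0) for s in segs)
        assert {s.state for s in segs} == {"IM1H", "OAC"}

    def test_mid_run_event_splits_with_new_labels(self, toy_series, bead_templates):
        times, unfolded = toy_series
        ev = _event(5.0, 0, 1, 1, -1, 0, 0, (1, 0, 0))
        segs = pk.cut_segments_at_transfers(
            times, unfolded, [ev], ["IM1H", "OAC"], bead_templates, min_length=2.0
        )
        by_res = {}
        for s in segs:
            by_res.setdefault(s.residue_id, []).append(s)
        assert [s.state for s in sorted(by_res[0], key=lambda s: s.start_time)] == \
            ["IM1H", "IM1"]
        assert [s.state for s in sorted(by_res[1], key=lambda s: s.start_time)] == \
            ["OAC", "HOAC"]

    def test_min_length_filter_keeps_only_long_tail(self, toy_series, bead_templates):
        times, unfolded = toy_series
        ev = _event(3.0, 0, 1, 1, -1, 0, 0, (1, 0, 0))  # at 30% of the run
        segs = pk.cut_segments_at_transfers(
            times, unfolded, [ev], ["IM1H", "OAC"], bead_templates, min_length=5.0
        )
        res0 = [s for s in segs if s.residue_id == 0]
        assert len(res0) == 1
        assert res0[0].state == "IM1"
        assert res0[0].length == pytest.approx(7.0)

    def test_unknown_residue_in_event_rejected(self, toy_series, bead_templates):
        times, unfolded = toy_series
        ev = _event(5.0, 0, 9, 1, -1, 0, 0, (1, 0, 0))
        with pytest.raises(ConsistencyError, match="9"):
            pk.cut_segments_at_transfers(times, unfolded, [ev], ["IM1H", "OAC"],
                                         bead_templates, min_length=1.0)


class TestDiffusion:
    def _walk_segments(self, D, n, frames, dt, seed, state="IM1H"):
        rng = np.random.default_rng(seed)
        steps = rng.normal(0.0, np.sqrt(2 * D * dt), size=(frames - 1, n, 3))
        walk = np.concatenate([np.zeros((1, n, 3)), np.cumsum(steps, axis=0)])
        times = np.arange(frames) * dt
        return [
            pk.SegmentSeries(residue_id=k, state=state, start_time=0.0,
                             end_time=times[-1], times=times,
                             positions=walk[:, k, :])
            for k in range(n)
        ]

    def test_recovers_known_diffusion_coefficient(self):
        """Free Brownian walkers: estimator within 5% of the input D."""
        D_true, dt = 0.125, 0.5
        segs = self._walk_segments(D_true, 500, 200, dt, seed=77)
        table = pk.diffusion(segs, fit_window=(5.0, 25.0))
        D_est = table.loc[0, "D_A2_ps"]
        assert D_est == pytest.approx(D_true, rel=0.05)
        assert table.loc[0, "D_m2_s"] == pytest.approx(D_est * 1e-8)

    def test_static_trajectory_has_zero_diffusion(self):
        times = np.arange(50) * 1.0
        segs = [pk.SegmentSeries(0, "IM1H", 0.0, 49.0, times, np.ones((50, 3)))]
        table = pk.diffusion(segs, fit_window=(5.0, 20.0))
        assert table.loc[0, "D_A2_ps"] == pytest.approx(0.0, abs=1e-15)

    def test_identical_trajectories_identical_D(self):
        a = self._walk_segments(0.1, 20, 100, 1.0, seed=5, state="IM1H")
        b = self._walk_segments(0.1, 20, 100, 1.0, seed=5, state="OAC")
        table = pk.diffusion(a + b, fit_window=(5.0, 30.0)).set_index("species")
        assert table.loc["IM1H", "D_A2_ps"] == pytest.approx(
            table.loc["OAC", "D_A2_ps"]
        )

    def test_combined_groups_pool_segments(self):
        a = self._walk_segments(0.1, 10, 100, 1.0, seed=1, state="IM1H")
        b = self._walk_segments(0.1, 10, 100, 1.0, seed=2, state="IM1")
        table = pk.diffusion(a + b, fit_window=(5.0, 30.0),
                             combine={"IM1H/IM1": ("IM1H", "IM1")})
        tbl = table.set_index("species")
        assert tbl.loc["IM1H/IM1", "n_segments"] == 20

    def test_empty_segment_list_rejected(self):
        with pytest.raises(ValueError):
            pk.diffusion([], fit_window=(1.0, 2.0))


class TestCollectiveDipole:
    def test_all_neutral_is_zero(self):
        times = np.arange(4.0)
        unfolded = np.random.default_rng(0).random((4, 5, 3))
        dip = pk.collective_dipole(unfolded, np.zeros((4, 5)), times)
        assert np.all(dip.raw == 0.0)

    def test_single_charge_displacement(self):
        times = np.arange(2.0)
        unfolded = np.zeros((2, 1, 3))
        unfolded[1, 0, 0] = 1.0
        dip = pk.collective_dipole(unfolded, np.ones((2, 1)), times)
        assert dip.raw[1] - dip.raw[0] == pytest.approx([1.0, 0.0, 0.0])

    def test_neutral_pair_rigid_translation_constant(self):
        times = np.arange(3.0)
        unfolded = np.zeros((3, 2, 3))
        unfolded[:, 0, 0] = [0, 1, 2]
        unfolded[:, 1, 0] = [4, 5, 6]
        q = np.tile([1.0, -1.0], (3, 1))
        dip = pk.collective_dipole(unfolded, q, times)
        assert np.allclose(dip.raw, dip.raw[0])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ConsistencyError):
            pk.collective_dipole(np.zeros((3, 2, 3)), np.zeros((3, 4)),
                                 np.arange(3.0))


class TestTransferCorrection:
    def test_all_eight_cases_match_direct_evaluation(self):
        """Every admissible charge transition: coefficient = direct jump."""
        assert len(CORRECTION_CASES) == 8
        r_ij = np.array([0.7, -0.2, 0.1])
        r_i = np.array([3.0, 1.0, -2.0])  # arbitrary; physics uses r_ij only
        for (qib, qjb, qia, qja), coeff in CORRECTION_CASES.items():
            got = event_dipole_jump(qib, qjb, qia, qja, r_ij)
            # independent evaluation: dq_i r_i + dq_j (r_i + r_ij)
            direct = (qia - qib) * r_i + (qja - qjb) * (r_i + r_ij)
            assert got == pytest.approx(direct)
            assert got == pytest.approx(coeff * r_ij)

    def test_case_completeness_from_reaction_set(self, bead_templates):
        reactions = pk.single_bead_reactions(r_max=3.8)
        cases = pk.enumerate_correction_cases(reactions, bead_templates)
        assert cases == CORRECTION_CASES

    def test_unsupported_transition_rejected(self):
        with pytest.raises(ConsistencyError):
            event_dipole_jump(2, -2, 0, 0, np.zeros(3))

    def test_boundary_straddling_event_correction(self, bead_templates):
        """Raw dipole jumps of order L collapse to <= |r_ij| after correction."""
        L = 20.0
        box = pk.BoxSpec.cubic(L)
        times = np.arange(3.0)
        # i at 0.5, j at L - 0.5: minimum-image r_ij = (-1, 0, 0)
        unfolded = np.zeros((3, 2, 3))
        unfolded[:, 0, 0] = 0.5
        unfolded[:, 1, 0] = L - 0.5
        ev = _event(1.0, 0, 1, 0, 0, 1, -1, (-1.0, 0.0, 0.0))
        q = pk.charges_over_time([0, 0], [ev], times)
        dip = pk.collective_dipole(unfolded, q, times)
        raw_jump = dip.raw[1] - dip.raw[0]
        assert np.abs(raw_jump[0]) == pytest.approx(L - 1.0)  # box-scale artifact
        corrected = pk.transfer_correction(dip, [ev], unfolded)
        corr_jump = corrected.corrected[1] - corrected.corrected[0]
        assert corr_jump == pytest.approx([1.0, 0.0, 0.0])  # = -e * r_ij
        # piecewise-constant corrections, changing only at the event
        assert np.array_equal(corrected.corrections[1], corrected.corrections[2])
        assert np.all(corrected.corrections[0] == 0.0)

    def test_no_events_correction_is_identity(self):
        times = np.arange(4.0)
        unfolded = np.random.default_rng(3).random((4, 3, 3))
        q = np.tile([1.0, -1.0, 0.0], (4, 1))
        dip = pk.collective_dipole(unfolded, q, times)
        out = pk.transfer_correction(dip, pd.DataFrame(), unfolded)
        assert np.array_equal(out.corrected, dip.raw)


class TestConductivity:
    def _ion_walk(self, n_ions, frames, dt, D, seed):
        rng = np.random.default_rng(seed)
        steps = rng.normal(0.0, np.sqrt(2 * D * dt), size=(frames - 1, n_ions, 3))
        walk = np.concatenate([np.zeros((1, n_ions, 3)), np.cumsum(steps, axis=0)])
        return walk, np.arange(frames) * dt

    def test_neutral_system_returns_zero_with_warning(self):
        times = np.arange(100.0)
        dip = pk.DipoleSeries(times=times, raw=np.zeros((100, 3)),
                              corrections=np.zeros((100, 3)))
        with pytest.warns(UserWarning, match="neutral"):
            out = pk.conductivity(dip, 1000.0, 300.0, (5.0, 30.0))
        assert out["sigma_mS_cm"] == 0.0

    def test_nernst_einstein_closed_form(self):
        """200 non-interacting +/-1 ions: Einstein-Helfand sigma within 10%
        of sum q^2 D / (V kT)."""
        n, frames, dt, D = 200, 6000, 0.5, 0.1
        walk, times = self._ion_walk(n, frames, dt, D, seed=2024)
        q = np.tile(np.array([1.0, -1.0] * (n // 2)), (frames, 1))
        V, T = 50.0**3, 300.0
        dip = pk.collective_dipole(walk, q, times)
        out = pk.conductivity(dip, V, T, fit_window=(5.0, 30.0), origin_stride=2)
        ne = pk.nernst_einstein_conductivity(q[0], np.full(n, D), V, T)
        assert out["sigma_mS_cm"] == pytest.approx(ne["sigma_mS_cm"], rel=0.10)

    def test_transfer_free_trajectory_corrected_equals_raw(self):
        walk, times = self._ion_walk(10, 200, 1.0, 0.1, seed=9)
        q = np.tile([1.0, -1.0] * 5, (200, 1))
        dip = pk.collective_dipole(walk, q, times)
        corrected = pk.transfer_correction(dip, pd.DataFrame(), walk)
        a = pk.conductivity(dip, 1e4, 300.0, (10.0, 50.0))
        b = pk.conductivity(corrected, 1e4, 300.0, (10.0, 50.0))
        assert a["sigma_mS_cm"] == pytest.approx(b["sigma_mS_cm"])

    def test_invariance_translation_and_relabeling(self):
        walk, times = self._ion_walk(20, 300, 1.0, 0.1, seed=5)
        q = np.tile([1.0, -1.0] * 10, (300, 1))
        base = pk.conductivity(pk.collective_dipole(walk, q, times),
                               1e4, 300.0, (10.0, 60.0))
        shifted = pk.conductivity(
            pk.collective_dipole(walk + np.array([5.0, -3.0, 2.0]), q, times),
            1e4, 300.0, (10.0, 60.0))
        perm = np.random.default_rng(0).permutation(20)
        relabeled = pk.conductivity(
            pk.collective_dipole(walk[:, perm, :], q[:, perm], times),
            1e4, 300.0, (10.0, 60.0))
        assert base["sigma_mS_cm"] == pytest.approx(shifted["sigma_mS_cm"])
        assert base["sigma_mS_cm"] == pytest.approx(relabeled["sigma_mS_cm"])
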