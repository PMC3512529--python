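"""Interaction index, phase maps and the critical competition window."""

from dataclasses import replace

import numpy as np
import pytest

from il2x.interaction import (
    COEXISTENCE_BAND,
    critical_window,
    interaction_index,
    phase_map,
    treg_cell,
)
from il2x.simulate import ActivationSchedule, steady_state_endpoint


def _variant(cell, form):
    return replace(cell, feedback=replace(cell.feedback, form=form))


class TestInteractionIndex:
    def test_inert_partner_changes_nothing(self, default_cell, default_medium):
        out = interaction_index(1.0, 0.0, default_cell, default_medium)
        assert out.C[0] == pytest.approx(0.0, abs=0.02)

    def test_strong_cell_gains_from_subthreshold_partner(
        self, default_cell, default_medium
    ):
        """The committed cell harvests the IL-2 a sub-threshold neighbour
        secretes: cooperation for cell 1."""
        out = interaction_index(1.0, 0.35, default_cell, default_medium)
        assert out.C[0] > COEXISTENCE_BAND
        assert out.labels[0] == "cooperation"
        assert out.committed_alone[0] and not out.committed_alone[1]

    def test_stronger_cell_excludes_weaker_above_threshold(
        self, default_cell, default_medium
    ):
        """Both above their solo threshold, the later-saturating weaker cell
        is pushed below commitment: competitive exclusion."""
        out = interaction_index(0.65, 1.0, default_cell, default_medium)
        assert out.C[0] < -COEXISTENCE_BAND
        assert out.labels[0] == "excluded"
        assert out.C[1] > 0
        assert out.committed_alone[0]
        assert not out.committed_together[0]

    def test_quorum_commitment_just_below_threshold(
        self, default_cell, default_medium
    ):
        """Two equally, slightly sub-threshold cells pool their IL-2 and
        commit together although neither would alone."""
        from il2x.steady_state import find_commitment_threshold

        m_c = find_commitment_threshold(default_cell, default_medium).m_c
        m = m_c - 0.02
        out = interaction_index(m, m, default_cell, default_medium)
        assert not out.committed_alone.any()
        assert out.committed_together.all()

    def test_index_independent_of_sampling_grid(self, default_cell, default_medium):
        from il2x.simulate import SolverSettings

        a = interaction_index(0.8, 0.5, default_cell, default_medium)
        b = interaction_index(
            0.8, 0.5, default_cell, default_medium,
            solver=SolverSettings(sample_dt=10.0),
        )
        assert a.C == pytest.approx(b.C, rel=1e-5, abs=1e-6)


class TestPhaseMap:
    def test_exchange_symmetry_at_zero_delay(self, default_cell, default_medium):
        pm = phase_map(default_cell, default_medium, resolution=5)
        assert np.allclose(pm.C1, pm.C2.T, atol=1e-9)

    def test_linear_feedback_is_winner_takes_all(self, default_cell, default_medium):
        """With a linear feedback, wherever the weaker cell would commit on
        its own it is excluded by the stronger one, at every off-diagonal
        grid point; cooperation never rescues it."""
        lin = _variant(default_cell, "linear")
        pm = phase_map(lin, default_medium, resolution=5)
        K_f = lin.feedback.K_f
        cache = {}

        def alone_B(m):
            if m not in cache:
                end = steady_state_endpoint(
                    [lin.with_m(m)], default_medium,
                    ActivationSchedule.simultaneous(1, 5000.0),
                )
                cache[m] = end.B[0]
            return cache[m]

        checked = 0
        for j, m2 in enumerate(pm.m2_grid):
            for i, m1 in enumerate(pm.m1_grid):
                if m1 == m2:
                    continue
                weak_is_1 = m1 < m2
                m_weak = m1 if weak_is_1 else m2
                if alone_B(m_weak) < K_f:
                    continue  # exclusion undefined below the solo threshold
                label = pm.labels1[j, i] if weak_is_1 else pm.labels2[j, i]
                assert label == "excluded", (m1, m2, label)
                checked += 1
        assert checked > 0

    def test_no_feedback_interaction_is_never_competitive(
        self, default_cell, default_medium
    ):
        """Without receptor feedback cells only share IL-2: no cell loses
        more than the coexistence resolution, and none is excluded."""
        nofb = _variant(default_cell, "none")
        pm = phase_map(nofb, default_medium, resolution=5)
        assert np.nanmin([pm.C1, pm.C2]) > -COEXISTENCE_BAND
        assert not np.any(pm.labels1 == "excluded")
        assert not np.any(pm.labels2 == "excluded")


class TestCriticalWindow:
    def test_bisection_agrees_with_coarse_scan(self, default_cell, default_medium):
        """Brute-force oracle: a 25-min delay scan must bracket the
        bisection estimate within one step."""
        cw = critical_window(0.65, 1.0, default_cell, default_medium)
        assert cw.delta_t_c is not None
        K_f = default_cell.feedback.K_f
        step = 25.0
        lo = cw.delta_t_c - 2 * step
        outcomes = []
        for dt in np.arange(lo, lo + 5 * step, step):
            end = steady_state_endpoint(
                [default_cell.with_m(0.65), default_cell.with_m(1.0)],
                default_medium,
                ActivationSchedule.delayed_pair(dt, dt + 5000.0),
            )
            outcomes.append(end.B[0] < K_f)
        flips = [i for i in range(len(outcomes) - 1) if outcomes[i] != outcomes[i + 1]]
        assert len(flips) == 1
        flip_at = lo + step * flips[0]
        assert flip_at <= cw.delta_t_c <= flip_at + 2 * step

    def test_window_grows_with_strength_difference(
        self, default_cell, default_medium
    ):
        """The stronger the later cell relative to the earlier one, the
        longer it can wait and still exclude it."""
        m1 = 0.65
        dtcs = []
        for dm in (0.23, 0.26, 0.29, 0.32, 0.35):
            cw = critical_window(m1, m1 + dm, default_cell, default_medium, tol=20.0)
            # below a minimal gap the later cell cannot exclude at all: a
            # window of length zero
            dtcs.append(0.0 if cw.no_window else cw.delta_t_c)
        assert all(dtc is not None for dtc in dtcs)
        assert all(b >= a - 20.0 for a, b in zip(dtcs, dtcs[1:]))
        assert dtcs[-1] > dtcs[0]

    def test_linear_feedback_excludes_regardless_of_delay(
        self, default_cell, default_medium
    ):
        lin = _variant(default_cell, "linear")
        cw = critical_window(0.65, 1.0, lin, default_medium, horizon=3000.0)
        assert cw.always_excludes
        assert cw.delta_t_c is None

    def test_requires_stronger_second_cell(self, default_cell, default_medium):
        with pytest.raises(ValueError, match="m2 > m1"):
            critical_window(0.8, 0.5, default_cell, default_medium)

    def test_threshold_shift_orders_with_partner_pre_activation(
        self, default_cell, default_medium
    ):
        """The commitment threshold of a cell co-activated with a strong
        partner exceeds its solo threshold, and grows further when the
        partner pre-activates long before."""
        from il2x.steady_state import find_commitment_threshold

        K_f = default_cell.feedback.K_f
        solo = find_commitment_threshold(default_cell, default_medium).m_c

        def together_threshold(pre_delay):
            def committed(m2):
                sched = ActivationSchedule([0.0, pre_delay], pre_delay + 5000.0)
                end = steady_state_endpoint(
                    [default_cell.with_m(1.0), default_cell.with_m(m2)],
                    default_medium,
                    sched,
                )
                return end.B[1] >= K_f
            if not committed(1.0):
                return np.inf  # threshold beyond the physiological range
            lo, hi = 0.0, 1.0
            while hi - lo > 0.01:
                mid = 0.5 * (lo + hi)
                if committed(mid):
                    hi = mid
                else:
                    lo = mid
            return 0.5 * (lo + hi)

        thr_together = together_threshold(0.0)
        thr_late = together_threshold(2500.0)
        assert solo < thr_together
        assert thr_together < thr_late


class TestTregPreset:
    def test_treg_suppresses_effector(self, default_cell, default_medium):
        """A non-secreting, receptor-rich cell consumes IL-2 and raises the
        effector's commitment threshold."""
        treg = treg_cell(default_cell)
        assert treg.secretion.s == 0.0
        assert treg.g_c == pytest.approx(20 * default_cell.g_c)
        eff = default_cell.with_m(0.65)
        alone = steady_state_endpoint(
            [eff], default_medium, ActivationSchedule.simultaneous(1, 5000.0)
        )
        pair = steady_state_endpoint(
            [eff, treg.with_m(0.0)],
            default_medium,
            ActivationSchedule.simultaneous(2, 5000.0),
        )
        assert pair.B[0] < alone.B[0]
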