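import numpy as np
import pytest

from sizeconstancy.size_network import (
    Integrator,
    ScalingFunction,
    ShuntingConfig,
    ShuntingInstabilityError,
    StimulusEvent,
    StimulusProtocol,
    TopographicMap,
    default_size_map,
    distance_scale,
    interaction_kernels,
    roi_timecourses,
    scaled_size_tuning,
    shunting_equilibrium,
    simulate_dynamics,
)
from sizeconstancy.tuning import SizeCell, SizeScalingKind


# -- distance scaling --------------------------------------------------------


def test_scaling_kinds_constant_increasing_decreasing():
    c = 2.0
    kinds = {
        SizeScalingKind.INDEPENDENT: [c, c, c],
        SizeScalingKind.FARNESS: [c * 0.3, c * 0.6, c * 1.2],
        SizeScalingKind.NEARNESS: [c / 0.3, c / 0.6, c / 1.2],
    }
    for kind, expected in kinds.items():
        f = ScalingFunction(kind, constant=c)
        got = [distance_scale(f, d) for d in (0.3, 0.6, 1.2)]
        assert got == pytest.approx(expected)


def test_literal_nearness_mode_flips_the_monotonicity():
    f = ScalingFunction(SizeScalingKind.NEARNESS, constant=2.0, literal_nearness=True)
    assert distance_scale(f, 1.2) > distance_scale(f, 0.3)


def test_nonpositive_distance_rejected():
    f = ScalingFunction(SizeScalingKind.FARNESS)
    with pytest.raises(ValueError, match="distance"):
        distance_scale(f, 0.0)


def test_scaled_tuning_common_argmax_and_ordered_amplitudes():
    betas = np.linspace(0.0, 3.2, 321)
    distances = (0.3, 0.6, 1.2)
    for kind, order in [
        (SizeScalingKind.NEARNESS, -1),
        (SizeScalingKind.FARNESS, 1),
        (SizeScalingKind.INDEPENDENT, 0),
    ]:
        topo = default_size_map(n_cells=11, scaling_kind=kind)
        curves = [scaled_size_tuning(topo, betas, d)[:, 5] for d in distances]
        argmaxes = {int(np.argmax(c)) for c in curves}
        assert len(argmaxes) == 1  # peak position distance-invariant
        amps = [c.max() for c in curves]
        if order == 1:
            assert amps[0] < amps[1] < amps[2]
        elif order == -1:
            assert amps[0] > amps[1] > amps[2]
        else:
            assert amps[1] == pytest.approx(amps[0])
            assert amps[2] == pytest.approx(amps[0])


def test_amplitude_ratio_equals_gain_ratio():
    topo = default_size_map(n_cells=5, scaling_kind=SizeScalingKind.FARNESS)
    betas = np.linspace(0.0, 3.2, 65)
    r1 = scaled_size_tuning(topo, betas, 0.4)
    r2 = scaled_size_tuning(topo, betas, 1.6)
    np.testing.assert_allclose(r2, 4.0 * r1, rtol=1e-12)


# -- topographic map and kernels ---------------------------------------------


def test_map_ordering_and_kernel_width_validation():
    cells = [SizeCell(1.0, 0.4), SizeCell(0.5, 0.4)]
    with pytest.raises(ValueError, match="non-decreasing"):
        TopographicMap(cells=cells)
    with pytest.raises(ValueError, match="broader"):
        default_size_map(excitatory_kernel_width=0.6, inhibitory_kernel_width=0.2)


def test_kernels_symmetric_zero_diagonal_surround_dominant():
    topo = default_size_map(n_cells=21)
    exc, inh = interaction_kernels(topo)
    np.testing.assert_allclose(exc, exc.T)
    np.testing.assert_allclose(inh, inh.T)
    assert np.all(np.diag(exc) == 0) and np.all(np.diag(inh) == 0)
    assert np.all(exc >= 0) and np.all(inh >= 0)
    # at 3x the excitatory width the broader surround dominates the centre
    prefs = topo.preferred_sizes
    d3 = 3.0 * topo.excitatory_kernel_width
    j = int(np.argmin(np.abs(prefs - (prefs[0] + d3))))
    assert inh[0, j] > exc[0, j]


def test_adjacent_cells_have_near_maximal_excitation():
    topo = default_size_map(n_cells=33)
    exc, _ = interaction_kernels(topo)
    spacing = topo.preferred_sizes[1] - topo.preferred_sizes[0]
    expected = np.exp(-(spacing**2) / topo.excitatory_kernel_width**2)
    assert exc[0, 1] == pytest.approx(expected)


# -- protocol validation -----------------------------------------------------


def test_protocol_rejects_overlap_and_bad_events():
    e1 = StimulusEvent(0.0, 1.0, 0.6, 0.3)
    e2 = StimulusEvent(0.5, 1.5, 0.6, 0.6)
    with pytest.raises(ValueError, match="overlap"):
        StimulusProtocol(events=(e1, e2))
    with pytest.raises(ValueError, match="offset"):
        StimulusEvent(1.0, 1.0, 0.6, 0.3)
    with pytest.raises(ValueError, match="distance"):
        StimulusEvent(0.0, 1.0, 0.6, 0.0)


# -- shunting dynamics -------------------------------------------------------


def quiet_protocol(duration=1.0):
    # an event with zero angular drive far from any cell's preferred size
    return StimulusProtocol(
        events=(StimulusEvent(0.0, duration, 0.0, 0.3),),
        amplitude=1e-12,
        size_distance_scaling=False,
    )


def test_zero_input_decays_exponentially_at_rate_b1():
    topo = default_size_map(n_cells=6)
    cfg = ShuntingConfig(decay=2.0, dt=0.001, decay_distance_scaling=False,
                         relaxation_tail=0.0)
    s0 = np.full(6, 0.8)
    times, act = simulate_dynamics(topo, cfg, quiet_protocol(), initial_state=s0)
    expected = 0.8 * np.exp(-2.0 * times)
    np.testing.assert_allclose(act[:, 0], expected, atol=1e-6)


def test_constant_input_reaches_closed_form_equilibrium():
    """Simulated steady state matches (B2 E - B3 H)/(B1 + E + H) per cell."""
    topo = default_size_map(n_cells=8)
    cfg = ShuntingConfig(
        decay=1.0,
        excitatory_ceiling=1.0,
        inhibitory_floor=0.2,
        dt=0.002,
        decay_distance_scaling=False,
        relaxation_tail=0.0,
    )
    proto = StimulusProtocol(
        events=(StimulusEvent(0.0, 30.0, 1.6, 0.5),), size_distance_scaling=False
    )
    times, act = simulate_dynamics(topo, cfg, proto)
    exc_k, inh_k = interaction_kernels(topo)
    drive = scaled_size_tuning(topo, 1.6, 0.5)
    s_star = shunting_equilibrium(cfg, exc_k @ drive, inh_k @ drive)
    np.testing.assert_allclose(act[-1], s_star, atol=1e-6)


def test_activity_bounded_between_floor_and_ceiling():
    topo = default_size_map(n_cells=15)
    cfg = ShuntingConfig(inhibitory_floor=0.3, dt=0.005)
    proto = StimulusProtocol(
        events=(
            StimulusEvent(0.0, 1.0, 0.6, 0.3),
            StimulusEvent(1.5, 2.5, 0.6, 1.2, amplitude_factor=0.5),
        ),
        amplitude=5.0,
    )
    _, act = simulate_dynamics(topo, cfg, proto)
    assert np.all(act <= cfg.excitatory_ceiling + 1e-6)
    assert np.all(act >= -cfg.inhibitory_floor - 1e-6)


def test_euler_stability_bound_enforced():
    topo = default_size_map(n_cells=15)
    cfg = ShuntingConfig(dt=0.5, integrator=Integrator.EULER)
    proto = StimulusProtocol(events=(StimulusEvent(0.0, 1.0, 0.6, 1.2),), amplitude=10.0)
    with pytest.raises(ValueError, match="stability"):
        simulate_dynamics(topo, cfg, proto)


def test_halving_dt_changes_final_state_negligibly():
    topo = default_size_map(n_cells=10)
    proto = StimulusProtocol(
        events=(StimulusEvent(0.0, 1.0, 0.8, 0.6),), size_distance_scaling=False
    )
    finals = []
    for dt in (0.01, 0.005):
        cfg = ShuntingConfig(dt=dt, relaxation_tail=0.5)
        _, act = simulate_dynamics(topo, cfg, proto)
        finals.append(act[-1])
    assert np.max(np.abs(finals[0] - finals[1])) < 1e-4


def test_euler_and_rk4_agree_at_small_dt():
    topo = default_size_map(n_cells=8)
    proto = StimulusProtocol(events=(StimulusEvent(0.0, 0.5, 0.8, 0.6),))
    acts = {}
    for integ in (Integrator.EULER, Integrator.RK4):
        cfg = ShuntingConfig(dt=0.0005, integrator=integ, relaxation_tail=0.2)
        _, act = simulate_dynamics(topo, cfg, proto)
        acts[integ] = act[-1]
    np.testing.assert_allclose(acts[Integrator.EULER], acts[Integrator.RK4], atol=1e-5)


def test_literal_sign_mode_makes_excitation_suppressive():
    """The printed equation's minus on the excitatory term drives activity
    negative — the documented reason the standard form is the default."""
    topo = default_size_map(n_cells=8)
    proto = StimulusProtocol(events=(StimulusEvent(0.0, 1.0, 1.6, 0.5),),
                             size_distance_scaling=False)
    cfg = ShuntingConfig(literal_sign=True, decay_distance_scaling=False,
                         relaxation_tail=0.0)
    _, act = simulate_dynamics(topo, cfg, proto)
    assert act[-1].min() < 0


# -- ROI extraction ----------------------------------------------------------


def test_roi_partition_and_uniform_input():
    act = np.zeros((4, 10))
    act[:, 5] = 1.0  # single active cell in band 3 of 5
    roi = roi_timecourses(act, n_rois=5)
    assert roi.shape == (4, 5)
    assert np.all(roi[:, 2] > 0)
    assert np.all(np.delete(roi, 2, axis=1) == 0)
    uniform = roi_timecourses(np.ones((3, 10)), n_rois=5)
    np.testing.assert_allclose(uniform, 1.0)


def test_roi_count_must_not_exceed_cells():
    with pytest.raises(ValueError, match="n_rois"):
        roi_timecourses(np.zeros((2, 4)), n_rois=5)
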