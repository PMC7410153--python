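"""Lumped 0D circuit: steady-state nodal solve and RC transients vs closed forms."""

import math

import numpy as np
import pytest

from coroflow import (
    ActivityPresets,
    BranchModel,
    PhantomNetwork,
    apply_activity,
    simulate_transient,
    solve_steady_state,
)
from coroflow.network import stability_dt_bound
from coroflow.presets import Activity, Vessel
from coroflow.units import mmhg_to_dynes_cm2


def _branch(name, series_r, compliance=None, artery_r=0.0, outlet=0.0):
    return BranchModel(
        vessel=name,
        chamber_resistance=0.3 * series_r,
        catheter_resistance=0.7 * series_r,
        artery_resistance=artery_r,
        chamber_compliance=compliance,
        outlet_pressure=outlet,
    )


# ---------------------------------------------------------------------------
# steady state


def test_single_branch_ohm_analog():
    net = PhantomNetwork(
        branches=(_branch("LAD", 100_000.0),),
        inlet_pressure=mmhg_to_dynes_cm2(100.0),
    )
    sol = solve_steady_state(net)
    assert sol.branch_flows["LAD"] == pytest.approx(1.33322, rel=1e-9)
    assert sol.conservation_residual() < 1e-12


def test_three_identical_branches_split_inflow_evenly():
    net = PhantomNetwork(
        branches=tuple(_branch(v.value, 2e5) for v in Vessel),
        inlet_flow=3.0,
    )
    sol = solve_steady_state(net)
    for q in sol.branch_flows.values():
        assert q == pytest.approx(1.0, rel=1e-12)


def test_rest_network_matches_hand_computation():
    """Branch flows equal P/(R_coronary,v + R_chamber,v), computed by hand."""
    presets = {Vessel.LAD: 254_250.0, Vessel.LCX: 137_000.0, Vessel.RCA: 479_000.0}
    chambers = {Vessel.LAD: 1671.0, Vessel.LCX: 1820.0, Vessel.RCA: 591.0}
    p_in = mmhg_to_dynes_cm2(100.0)
    net = PhantomNetwork(
        branches=tuple(
            BranchModel(
                vessel=v.value,
                chamber_resistance=chambers[v],
                catheter_resistance=presets[v],
            )
            for v in Vessel
        ),
        inlet_pressure=p_in,
    )
    sol = solve_steady_state(net)
    for v in Vessel:
        expected = p_in / (presets[v] + chambers[v])
        assert sol.branch_flows[v.value] == pytest.approx(expected, rel=1e-9)
    assert sol.conservation_residual() < 1e-9


def _brute_force_flow_driven(branches, q_in, r_ao=None):
    """Independent nodal solve: one unknown aortic pressure from KCL via lstsq."""
    g = np.array([1.0 / (b.artery_resistance + b.chamber_resistance + b.catheter_resistance)
                  for b in branches])
    p_out = np.array([b.outlet_pressure for b in branches])
    g_ao = 0.0 if r_ao is None else 1.0 / r_ao
    # KCL: (sum g + g_ao) * P = q_in + g @ p_out  — solved as a 1x1 lstsq system
    a = np.array([[g.sum() + g_ao]])
    rhs = np.array([q_in + g @ p_out])
    p = np.linalg.lstsq(a, rhs, rcond=None)[0][0]
    return p, g * (p - p_out)


def test_flow_driven_matches_brute_force_nodal_solve():
    rng = np.random.default_rng(42)
    for _ in range(25):
        n = rng.integers(1, 5)
        branches = tuple(
            BranchModel(
                vessel=f"B{i}",
                chamber_resistance=float(rng.uniform(100, 5000)),
                catheter_resistance=float(rng.uniform(1e4, 5e5)),
                artery_resistance=float(rng.uniform(0, 1e3)),
                outlet_pressure=float(rng.uniform(0, 1e4)),
            )
            for i in range(n)
        )
        r_ao = float(rng.uniform(1e5, 1e6)) if rng.random() < 0.5 else None
        q_in = float(rng.uniform(0.5, 10.0))
        net = PhantomNetwork(branches=branches, inlet_flow=q_in,
                             aortic_outlet_resistance=r_ao)
        sol = solve_steady_state(net)
        p_ref, q_ref = _brute_force_flow_driven(branches, q_in, r_ao)
        assert sol.inlet_pressure == pytest.approx(p_ref, rel=1e-9)
        for b, q in zip(branches, q_ref):
            assert sol.branch_flows[b.vessel] == pytest.approx(q, rel=1e-9, abs=1e-12)
        assert sol.conservation_residual() < 1e-9


def test_conservation_holds_in_both_drive_modes():
    rng = np.random.default_rng(7)
    for _ in range(25):
        branches = tuple(
            _branch(f"B{i}", float(rng.uniform(1e4, 1e6)),
                    outlet=float(rng.uniform(0, 1e4)))
            for i in range(rng.integers(1, 4))
        )
        for kwargs in ({"inlet_pressure": float(rng.uniform(1e4, 2e5))},
                       {"inlet_flow": float(rng.uniform(0.1, 5.0))}):
            sol = solve_steady_state(PhantomNetwork(branches=branches, **kwargs))
            assert sol.conservation_residual() < 1e-9


def test_network_validation_errors():
    with pytest.raises(ValueError, match="at least one branch"):
        PhantomNetwork(branches=(), inlet_flow=1.0)
    with pytest.raises(ValueError, match="exactly one"):
        PhantomNetwork(branches=(_branch("LAD", 1e5),), inlet_flow=1.0,
                       inlet_pressure=1e5)
    with pytest.raises(ValueError, match="exactly one"):
        PhantomNetwork(branches=(_branch("LAD", 1e5),))
    with pytest.raises(ValueError, match="series resistance"):
        BranchModel(vessel="LAD", chamber_resistance=0.0, catheter_resistance=0.0)


# ---------------------------------------------------------------------------
# transients vs closed forms


def _single_rc(compliance=1e-4, series_r=1e5):
    return PhantomNetwork(
        branches=(_branch("LAD", series_r, compliance=compliance),),
        inlet_flow=1.0,  # drive mode unused by simulate_transient's waveform
    )


def test_constant_inflow_converges_to_steady_state():
    net = _single_rc()
    tau = 1e5 * 1e-4  # R_down · C = 10 s
    sol = simulate_transient(net, lambda t: 2.0, duration=12 * tau, dt=tau / 50)
    ss = solve_steady_state(PhantomNetwork(branches=net.branches, inlet_flow=2.0))
    final = sol.chamber_pressures["LAD"][-1]
    assert final == pytest.approx(ss.chamber_pressures["LAD"], rel=1e-3)


def test_discharge_decays_exponentially():
    net = _single_rc()
    tau = 10.0
    p0 = 50_000.0
    sol = simulate_transient(
        net, lambda t: 0.0, duration=tau, dt=tau / 1000,
        initial_pressures={"LAD": p0},
    )
    assert sol.chamber_pressures["LAD"][-1] / p0 == pytest.approx(math.exp(-1), rel=1e-6)


@pytest.mark.parametrize("omega_rc", [0.5, 2.0])
def test_sinusoid_attenuation_matches_first_order_low_pass(omega_rc):
    """Pressure amplitude follows |H| = R/√(1+(ωRC)²) within 2%."""
    r, c = 1e5, 1e-4
    tau = r * c
    omega = omega_rc / tau
    period = 2 * math.pi / omega
    mean, amp = 2.0, 0.5
    net = _single_rc(compliance=c, series_r=r)
    duration = 10 * tau + 3 * period
    dt = min(tau, period) / 200
    sol = simulate_transient(
        net, lambda t: mean + amp * math.sin(omega * t), duration=duration, dt=dt
    )
    settled = sol.times > duration - 2 * period
    t = sol.times[settled]
    p = sol.chamber_pressures["LAD"][settled]
    # least-squares fit of A·sin + B·cos + offset: amplitude = |A + iB|
    basis = np.column_stack([np.sin(omega * t), np.cos(omega * t), np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(basis, p, rcond=None)
    measured_amp = math.hypot(coef[0], coef[1])
    expected = amp * r / math.sqrt(1 + omega_rc**2)
    assert measured_amp == pytest.approx(expected, rel=0.02)


def test_small_compliance_limit_approaches_steady_flows():
    """Scaling C down 10× shrinks the outflow deviation from quasi-static ~10×."""
    r = 1e5
    omega = 1.0
    mean, amp = 2.0, 0.5
    deviations = []
    for c in (1e-5, 1e-6):
        tau = r * c
        period = 2 * math.pi / omega
        duration = 12 * tau + 2 * period
        net = _single_rc(compliance=c, series_r=r)
        sol = simulate_transient(
            net, lambda t: mean + amp * math.sin(omega * t),
            duration=duration, dt=tau / 100,
        )
        settled = sol.times > duration - period
        q_out = sol.branch_outflows["LAD"][settled]
        q_qs = mean + amp * np.sin(omega * sol.times[settled])  # quasi-static limit
        deviations.append(np.abs(q_out - q_qs).max())
    ratio = deviations[0] / deviations[1]
    assert 5.0 < ratio < 15.0


def test_halving_dt_converges_at_high_order():
    """RK4: halving dt shrinks the closed-form error by far more than 2×."""
    net = _single_rc()
    tau, p0 = 10.0, 40_000.0
    errors = []
    for dt in (tau / 10, tau / 20):
        sol = simulate_transient(
            net, lambda t: 0.0, duration=tau, dt=dt,
            initial_pressures={"LAD": p0},
        )
        errors.append(abs(sol.chamber_pressures["LAD"][-1] - p0 * math.exp(-1)))
    assert errors[0] / errors[1] > 8.0


def test_multi_branch_transient_conserves_inlet_flow():
    """With artery resistances set, the branch inflows sum to the pump flow."""
    net = PhantomNetwork(
        branches=tuple(
            _branch(v.value, 1e5 * (i + 1), compliance=1e-4, artery_r=500.0)
            for i, v in enumerate(Vessel)
        ),
        inlet_flow=1.0,
    )
    sol = simulate_transient(net, lambda t: 2.5, duration=5.0, dt=0.001)
    total_in = sum(sol.branch_inflows[v.value] for v in Vessel)
    assert np.allclose(total_in, sol.inlet_flow, rtol=1e-9)


def test_transient_validation_errors():
    net = _single_rc()
    bound = stability_dt_bound(net)
    with pytest.raises(ValueError, match="stability bound"):
        simulate_transient(net, lambda t: 1.0, duration=100.0, dt=2 * bound)
    with pytest.raises(ValueError, match="compliance"):
        simulate_transient(
            PhantomNetwork(branches=(_branch("LAD", 1e5),), inlet_flow=1.0),
            lambda t: 1.0, duration=1.0, dt=0.001,
        )
    with pytest.raises(ValueError, match="non-finite"):
        simulate_transient(net, lambda t: float("nan"), duration=1.0, dt=0.001)
    with pytest.raises(ValueError, match="split is undefined"):
        simulate_transient(
            PhantomNetwork(
                branches=tuple(_branch(v.value, 1e5, compliance=1e-4) for v in Vessel),
                inlet_flow=1.0,
            ),
            lambda t: 1.0, duration=1.0, dt=0.0001,
        )


def test_inlet_check_valve_clips_reverse_flow():
    net = _single_rc()
    sol = simulate_transient(net, lambda t: -1.0, duration=1.0, dt=0.01)
    assert np.all(sol.inlet_flow == 0.0)


# ---------------------------------------------------------------------------
# activity presets


def _rest_network():
    chambers = {Vessel.LAD: 1671.0, Vessel.LCX: 1820.0, Vessel.RCA: 591.0}
    presets = ActivityPresets.default()
    return PhantomNetwork(
        branches=tuple(
            BranchModel(
                vessel=v.value,
                chamber_resistance=chambers[v],
                catheter_resistance=presets[(v, Activity.REST)] - chambers[v],
            )
            for v in Vessel
        ),
        inlet_pressure=mmhg_to_dynes_cm2(100.0),
    )


def test_apply_activity_raises_flows_toward_exercise():
    net = _rest_network()
    rest = solve_steady_state(net)
    moderate = solve_steady_state(apply_activity(net, Activity.MODERATE_EXERCISE))
    for v in Vessel:
        assert moderate.branch_flows[v.value] > rest.branch_flows[v.value]


def test_apply_activity_uses_chamber_corrected_targets(presets):
    net = _rest_network()
    out = apply_activity(net, Activity.REST, presets)
    for b in out.branches:
        target = presets[(Vessel(b.vessel), Activity.REST)]
        assert b.catheter_resistance + b.chamber_resistance == pytest.approx(target, rel=1e-9)


def test_apply_activity_with_zero_chamber_matches_preset_exactly(presets):
    net = PhantomNetwork(
        branches=(BranchModel(vessel="LAD", chamber_resistance=0.0,
                              catheter_resistance=1e5),),
        inlet_pressure=1e5,
    )
    out = apply_activity(net, Activity.REST, presets)
    assert out.branches[0].catheter_resistance == pytest.approx(
        presets[(Vessel.LAD, Activity.REST)], rel=1e-12
    )


def test_apply_activity_does_not_mutate_input():
    net = _rest_network()
    before = tuple(b.catheter_resistance for b in net.branches)
    apply_activity(net, Activity.MODERATE_EXERCISE)
    assert tuple(b.catheter_resistance for b in net.branches) == before


def test_apply_activity_rejects_chamber_above_preset(presets):
    net = PhantomNetwork(
        branches=(BranchModel(vessel="LAD", chamber_resistance=5e5,
                              catheter_resistance=1e5),),
        inlet_pressure=1e5,
    )
    with pytest.raises(ValueError, match="non-physical"):
        apply_activity(net, Activity.MODERATE_EXERCISE, presets)
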