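"""Compartment-model solver against analytic oracles and linear-system laws."""

import numpy as np
import pytest

from emergepd.exceptions import InvalidInputError, InvalidParameterError
from emergepd.pk import (
    ConcentrationTrajectory,
    DoseSchedule,
    PkParams,
    emergence_decay,
    fentanyl_to_remifentanil,
    schnider_propofol,
    scott_fentanyl,
    simulate_compartments,
)

ONE_CPT = PkParams(v1=10.0, k10=0.1, k12=0.0, k21=0.0, k13=0.0, k31=0.0, ke0=0.5)
THREE_CPT = PkParams(v1=4.3, k10=0.35, k12=0.3, k21=0.07, k13=0.2, k31=0.004, ke0=0.45)


def test_zero_schedule_gives_zero_concentrations():
    res = simulate_compartments(THREE_CPT, DoseSchedule(), dt=0.5, duration=30)
    assert np.all(res.cp == 0) and np.all(res.ce == 0)


def test_one_compartment_bolus_matches_biexponential_closed_form():
    # Ce(t) = (D/v1) * ke0/(ke0-k10) * (exp(-k10 t) - exp(-ke0 t))
    dose = 100.0
    res = simulate_compartments(ONE_CPT, DoseSchedule(boluses=((0.0, dose),)), dt=0.25, duration=40)
    t = res.times[1:]
    exact = (dose / ONE_CPT.v1) * ONE_CPT.ke0 / (ONE_CPT.ke0 - ONE_CPT.k10) * (
        np.exp(-ONE_CPT.k10 * t) - np.exp(-ONE_CPT.ke0 * t)
    )
    assert np.max(np.abs(res.ce[1:] - exact) / exact) < 1e-6
    # plasma itself is mono-exponential
    assert np.allclose(res.cp[1:], dose / ONE_CPT.v1 * np.exp(-ONE_CPT.k10 * t), rtol=1e-9)


def test_constant_infusion_approaches_steady_state():
    rate = 5.0
    t_check = 20.0 / ONE_CPT.k10
    res = simulate_compartments(
        ONE_CPT, DoseSchedule(infusions=((0.0, t_check, rate),)), dt=1.0, duration=t_check
    )
    target = rate / (ONE_CPT.v1 * ONE_CPT.k10)
    assert abs(res.cp[-1] - target) / target < 0.01


def test_effect_site_lags_plasma_after_bolus():
    res = simulate_compartments(THREE_CPT, DoseSchedule(boluses=((0.0, 50.0),)), dt=0.1, duration=30)
    assert res.cp.argmax() == 0  # plasma peaks at the bolus
    assert res.times[res.ce.argmax()] > 0  # effect site strictly later
    assert np.all(res.ce >= 0) and np.all(res.cp >= 0)


def test_mass_conserved_without_elimination():
    closed = PkParams(v1=5.0, k10=0.0, k12=0.2, k21=0.05, k13=0.1, k31=0.01, ke0=0.3)
    sched = DoseSchedule(boluses=((0.0, 30.0),), infusions=((5.0, 15.0, 2.0),))
    res = simulate_compartments(closed, sched, dt=0.5, duration=60)
    total = res.states[:, :3].sum(axis=1)
    assert abs(total[-1] - (30.0 + 20.0)) < 1e-9


def test_dose_linearity_and_superposition():
    s1 = DoseSchedule(boluses=((0.0, 20.0),))
    s2 = DoseSchedule(boluses=((7.0, 35.0),))
    both = DoseSchedule(boluses=((0.0, 20.0), (7.0, 35.0)))
    r1 = simulate_compartments(THREE_CPT, s1, dt=0.5, duration=60)
    r2 = simulate_compartments(THREE_CPT, s2, dt=0.5, duration=60)
    rb = simulate_compartments(THREE_CPT, both, dt=0.5, duration=60)
    assert np.allclose(rb.ce, r1.ce + r2.ce, rtol=1e-9, atol=1e-12)
    double = simulate_compartments(
        THREE_CPT, DoseSchedule(boluses=((0.0, 40.0),)), dt=0.5, duration=60
    )
    assert np.allclose(double.ce, 2 * r1.ce, rtol=1e-9)


def test_effect_site_equilibrates_monotonically_to_constant_plasma():
    frozen = PkParams(v1=8.0, k10=0.0, k12=0.0, k21=0.0, k13=0.0, k31=0.0, ke0=0.25)
    res = simulate_compartments(frozen, DoseSchedule(boluses=((0.0, 40.0),)), dt=0.5, duration=40)
    cp = 40.0 / 8.0
    assert np.allclose(res.cp, cp)
    assert np.all(np.diff(res.ce) > 0)
    assert np.all(res.ce <= cp + 1e-12)
    # time constant 1/ke0: at t = 1/ke0 the gap has shrunk by 1/e
    idx = int(round((1 / frozen.ke0) / 0.5))
    assert abs((cp - res.ce[idx]) / cp - np.exp(-1)) < 1e-9


def test_grid_refinement_is_exact_at_common_nodes():
    # The exponential integrator is exact for grid-aligned piecewise-constant
    # dosing, so halving dt must reproduce the coarse nodes to round-off.
    sched = DoseSchedule(boluses=((0.0, 25.0),), infusions=((2.0, 10.0, 3.0),))
    coarse = simulate_compartments(THREE_CPT, sched, dt=1.0, duration=30)
    fine = simulate_compartments(THREE_CPT, sched, dt=0.5, duration=30)
    assert np.allclose(coarse.ce, fine.ce[::2], rtol=1e-12, atol=1e-14)


def test_emergence_decay_equals_continued_simulation():
    sched = DoseSchedule(boluses=((0.0, 50.0),), infusions=((0.0, 30.0, 4.0),))
    full = simulate_compartments(THREE_CPT, sched, dt=0.5, duration=60)
    k_stop = int(round(30.0 / 0.5))
    tail = emergence_decay(full.states[k_stop], THREE_CPT, horizon=30.0, dt=0.5)
    assert np.allclose(tail.ce, full.ce[k_stop:], rtol=1e-10)
    # eventually monotone decreasing past the post-stop peak, never negative
    peak = tail.ce.argmax()
    assert np.all(np.diff(tail.ce[peak:]) <= 1e-15)
    assert np.all(tail.ce >= 0)


def test_emergence_decay_trivia():
    zero = emergence_decay(np.zeros(4), THREE_CPT, horizon=20.0, dt=1.0)
    assert np.all(zero.ce == 0)
    long = emergence_decay([10.0, 5.0, 2.0, 3.0], THREE_CPT, horizon=8000.0, dt=20.0)
    assert long.ce[-1] < 1e-6


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(v1=0.0, k10=0.1, k12=0, k21=0, k13=0, k31=0, ke0=0.5),
        dict(v1=5.0, k10=-0.1, k12=0, k21=0, k13=0, k31=0, ke0=0.5),
        dict(v1=5.0, k10=0.1, k12=0, k21=0, k13=0, k31=0, ke0=0.0),
    ],
)
def test_invalid_pk_params_rejected(kwargs):
    with pytest.raises(InvalidParameterError):
        PkParams(**kwargs)


def test_invalid_solver_and_schedule_inputs_rejected():
    with pytest.raises(InvalidParameterError):
        simulate_compartments(ONE_CPT, DoseSchedule(), dt=0.0, duration=10)
    with pytest.raises(InvalidParameterError):
        simulate_compartments(ONE_CPT, DoseSchedule(), dt=2.0, duration=1.0)
    with pytest.raises(InvalidParameterError):
        DoseSchedule(boluses=((0.0, -5.0),))
    with pytest.raises(InvalidParameterError):
        DoseSchedule(infusions=((5.0, 5.0, 1.0),))


def test_fentanyl_to_remifentanil_conversion():
    assert fentanyl_to_remifentanil(0.0) == 0.0
    assert fentanyl_to_remifentanil(1.2) == pytest.approx(1.0)
    assert fentanyl_to_remifentanil(2.4, factor=1.2) == pytest.approx(2.0)
    x = np.array([0.6, 1.2, 3.0])
    assert np.allclose(fentanyl_to_remifentanil(2.0 * x), 2.0 * fentanyl_to_remifentanil(x))
    with pytest.raises(InvalidInputError):
        fentanyl_to_remifentanil(-1.0)
    with pytest.raises(InvalidParameterError):
        fentanyl_to_remifentanil(1.0, factor=0.0)


def test_trajectory_validation():
    with pytest.raises(InvalidInputError):
        ConcentrationTrajectory("p", [], [], [])
    with pytest.raises(InvalidInputError):
        ConcentrationTrajectory("p", [0, 0], [1, 1], [1, 1])
    with pytest.raises(InvalidInputError):
        ConcentrationTrajectory("p", [0, 1], [1, -1], [1, 1])


def test_literature_presets_are_valid_models():
    prop = schnider_propofol(54.6, 60.6, 159.5, "F")
    assert prop.v1 == pytest.approx(4.27)
    assert prop.ke0 == pytest.approx(0.456)
    assert all(getattr(prop, k) > 0 for k in ("k10", "k12", "k21", "k13", "k31"))
    fent = scott_fentanyl()
    assert fent.v1 == pytest.approx(12.7)
    with pytest.raises(InvalidParameterError):
        schnider_propofol(54.6, 60.6, 159.5, "x")
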