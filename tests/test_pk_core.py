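"""One-compartment infusion kinetics: closed-form values and structural laws."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cipropk.pk_core import (
    DoseEvent,
    PKParameters,
    Regimen,
    auc_steady_state,
    conc_profile,
    conc_single_infusion,
    elimination_params,
)


@pytest.mark.parametrize(
    "cl,vd,ke_exp,thalf_exp",
    [
        (21.5, 143.0, 0.15035, 4.610),  # 21.5/143, ln2*143/21.5
        (7.0, 7.0, 1.0, math.log(2)),  # identity case
        (18.59, 136.9, 18.59 / 136.9, 5.104),  # early-occasion medians
    ],
)
def test_elimination_params(cl, vd, ke_exp, thalf_exp):
    ke, thalf = elimination_params(PKParameters(cl, vd))
    assert ke == pytest.approx(ke_exp, rel=1e-3)
    assert thalf == pytest.approx(thalf_exp, rel=1e-3)


def test_concentration_at_end_of_infusion():
    # (800/21.5)(1 - exp(-0.15035*0.5)) with R0 = 400 mg / 0.5 h
    pk = PKParameters(21.5, 143.0)
    c = conc_single_infusion(pk, DoseEvent(0.0, 400.0, 0.5), 0.5)
    assert c == pytest.approx(2.695, rel=1e-3)


def test_concentration_zero_at_dose_start():
    pk = PKParameters(10.0, 100.0)
    assert conc_single_infusion(pk, DoseEvent(3.0, 400.0, 0.5), 3.0) == 0.0


def test_time_before_dose_rejected():
    pk = PKParameters(10.0, 100.0)
    with pytest.raises(ValueError):
        conc_single_infusion(pk, DoseEvent(3.0, 400.0, 0.5), 2.9)


def test_bolus_limit_matches_instantaneous_input():
    # T_inf -> 0: C -> (amount/Vd) * exp(-ke * tau)
    pk = PKParameters(20.0, 150.0)
    tau = 3.0
    c = conc_single_infusion(pk, DoseEvent(0.0, 400.0, 1e-7), tau)
    expected = 400.0 / 150.0 * math.exp(-pk.ke * tau)
    assert c == pytest.approx(expected, rel=1e-5)


@settings(derandomize=True, max_examples=50)
@given(
    cl=st.floats(1.0, 80.0),
    vd=st.floats(20.0, 400.0),
    amount=st.floats(100.0, 1000.0),
    dur=st.floats(0.1, 2.0),
)
def test_continuity_at_end_of_infusion(cl, vd, amount, dur):
    """The during- and post-infusion branches agree at tau = T_inf."""
    pk = PKParameters(cl, vd)
    ke = pk.ke
    r0 = amount / dur
    during = (r0 / cl) * (1.0 - math.exp(-ke * dur))
    after = (r0 / cl) * (1.0 - math.exp(-ke * dur)) * math.exp(-ke * 0.0)
    c = conc_single_infusion(pk, DoseEvent(0.0, amount, dur), dur)
    assert c == pytest.approx(during, rel=1e-9)
    assert c == pytest.approx(after, rel=1e-9)


def test_superposition_is_exact():
    pk = PKParameters(21.5, 143.0)
    e1 = DoseEvent(0.0, 400.0, 0.5)
    e2 = DoseEvent(12.0, 400.0, 0.5)
    reg = Regimen(events=(e1, e2), interval=12.0)
    t = np.linspace(12.5, 36.0, 40)
    total = conc_profile(pk, reg, t)
    parts = conc_single_infusion(pk, e1, t) + conc_single_infusion(pk, e2, t)
    np.testing.assert_array_equal(total, parts)


def test_linearity_in_dose():
    pk = PKParameters(15.0, 120.0)
    t = np.linspace(0.5, 48.0, 30)
    reg1 = Regimen.uniform(400.0, 12.0, 4)
    reg2 = Regimen.uniform(800.0, 12.0, 4)
    np.testing.assert_allclose(conc_profile(pk, reg2, t),
                               2.0 * conc_profile(pk, reg1, t), rtol=1e-12)


def test_single_event_profile_equals_single_infusion():
    pk = PKParameters(15.0, 120.0)
    reg = Regimen.uniform(400.0, 12.0, 1)
    t = np.linspace(0.0, 12.0, 25)
    np.testing.assert_allclose(conc_profile(pk, reg, t),
                               conc_single_infusion(pk, reg.events[0], t))


def test_steady_state_interval_auc_equals_dose_over_cl():
    """Trapezoid AUC over one interval at >=10 half-lives matches dose/CL."""
    pk = PKParameters(21.5, 143.0)  # t1/2 = 4.6 h -> 10 t1/2 = 46 h
    reg = Regimen.uniform(400.0, 12.0, 10)  # doses to 108 h
    t = np.arange(96.0, 108.0 + 1e-9, 0.005)
    auc = np.trapezoid(conc_profile(pk, reg, t), t)
    assert auc == pytest.approx(400.0 / 21.5, rel=0.01)
    # independent of Vd
    pk2 = PKParameters(21.5, 60.0)
    auc2 = np.trapezoid(conc_profile(pk2, reg, t), t)
    assert auc2 == pytest.approx(400.0 / 21.5, rel=0.01)


def test_auc24_examples():
    assert auc_steady_state(PKParameters(21.5, 143.0), 1200.0) == pytest.approx(
        55.81, rel=1e-3)
    assert auc_steady_state(PKParameters(10.0, 100.0), 10.0) == pytest.approx(1.0)
    # agreement with numerical steady-state AUC over 24 h
    pk = PKParameters(21.5, 143.0)
    reg = Regimen.uniform(400.0, 12.0, 12)
    t = np.arange(96.0, 120.0 + 1e-9, 0.005)
    auc_num = np.trapezoid(conc_profile(pk, reg, t), t)
    assert auc_steady_state(pk, 800.0) == pytest.approx(auc_num, rel=0.01)


def test_peak_at_end_of_infusion():
    pk = PKParameters(21.5, 143.0)
    reg = Regimen.uniform(400.0, 12.0, 10)
    t = np.arange(96.0, 108.0, 0.01)
    c = conc_profile(pk, reg, t)
    t_peak = t[np.argmax(c)]
    assert t_peak == pytest.approx(96.5, abs=0.02)


@pytest.mark.parametrize("cl,vd", [(0.0, 100.0), (-1.0, 100.0), (10.0, 0.0)])
def test_invalid_parameters_rejected(cl, vd):
    with pytest.raises(ValueError):
        PKParameters(cl, vd)


def test_invalid_events_rejected():
    with pytest.raises(ValueError):
        DoseEvent(0.0, 0.0, 0.5)
    with pytest.raises(ValueError):
        DoseEvent(0.0, 400.0, 0.0)
    with pytest.raises(ValueError):
        Regimen(events=(), interval=12.0)
    with pytest.raises(ValueError):
        Regimen(events=(DoseEvent(12.0, 400.0), DoseEvent(0.0, 400.0)), interval=12.0)
    with pytest.raises(ValueError):
        auc_steady_state(PKParameters(10.0, 100.0), 0.0)


def test_regimen_daily_dose():
    assert Regimen.uniform(400.0, 12.0, 4).daily_dose == 800.0
    assert Regimen.uniform(400.0, 8.0, 4).daily_dose == pytest.approx(1200.0)
    assert Regimen.uniform(600.0, 12.0, 4).daily_dose == 1200.0
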