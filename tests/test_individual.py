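"""MAP-Bayesian individual fitting and the two-stage covariate statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize as sopt

from cipropk.cohort import CohortConfig, _LogNormalSpec, sample_cohort, simulate_dataset
from cipropk.individual import (
    ErrorConfig,
    InsufficientDataError,
    PriorSpec,
    map_fit,
    map_fit_dataset,
    mann_whitney,
    ols_regression,
    two_stage_summary,
)
from cipropk.model import PopModel
from cipropk.pk_core import PKParameters, Regimen, conc_profile


REG = Regimen.uniform(400.0, 12.0, 9)
TIMES = np.array([13.5, 16.5, 24.0, 85.5, 88.5, 96.0])


def test_noise_free_recovery_with_flat_prior():
    y = conc_profile(PKParameters(20.0, 150.0), REG, TIMES)
    fit = map_fit(TIMES, y, REG, PriorSpec.flat())
    assert fit.pk.CL == pytest.approx(20.0, rel=1e-4)
    assert fit.pk.Vd == pytest.approx(150.0, rel=1e-4)
    assert fit.wss < 1e-8
    assert fit.rms < 1e-4
    assert fit.t_half == pytest.approx(math.log(2) * 150 / 20, rel=1e-4)


def test_prior_only_mode_with_no_data():
    prior = PriorSpec(cl=18.59, vd=136.9, cv_cl=0.5, cv_vd=0.5)
    fit = map_fit([], [], REG, prior)
    assert fit.pk.CL == prior.cl and fit.pk.Vd == prior.vd
    assert fit.n_obs == 0 and fit.wss == 0.0


def test_single_observation_rejected():
    with pytest.raises(InsufficientDataError):
        map_fit([13.5], [3.0], REG, PriorSpec.flat())
    with pytest.raises(InsufficientDataError):
        map_fit([], [], REG, PriorSpec.flat())  # flat prior has no no-data mode


def test_objective_trace_monotone_nonincreasing():
    rng = np.random.default_rng(3)
    y = conc_profile(PKParameters(25.0, 120.0), REG, TIMES)
    y = y * (1 + rng.normal(0, 0.1, y.shape))
    fit = map_fit(TIMES, y, REG, PriorSpec.default())
    tr = np.array(fit.trace)
    assert len(tr) >= 1
    assert np.all(np.diff(tr) <= 1e-9)


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_flat_prior_map_equals_weighted_least_squares(seed):
    """With no prior penalty the MAP mode is the WLS solution (independent oracle)."""
    rng = np.random.default_rng(seed)
    cl, vd = rng.uniform(8, 40), rng.uniform(60, 250)
    y = conc_profile(PKParameters(cl, vd), REG, TIMES)
    y = y * (1 + rng.normal(0, 0.08, y.shape)) + rng.normal(0, 0.05, y.shape)
    y = np.abs(y)
    ec = ErrorConfig()
    sigma = ec.sigma(y)

    def resid(p):
        f = conc_profile(PKParameters(p[0], p[1]), REG, TIMES)
        return (y - f) / sigma

    oracle = None
    for s_cl in (10.0, 20.0, 40.0):
        for s_vd in (80.0, 150.0, 250.0):
            r = sopt.least_squares(resid, [s_cl, s_vd], bounds=([0.1, 1], [200, 2000]))
            if oracle is None or r.cost < oracle.cost:
                oracle = r
    fit = map_fit(TIMES, y, REG, PriorSpec.flat(), ec)
    assert fit.pk.CL == pytest.approx(oracle.x[0], rel=1e-3)
    assert fit.pk.Vd == pytest.approx(oracle.x[1], rel=1e-3)
    assert fit.wss == pytest.approx(2 * oracle.cost, rel=1e-6)


def test_wss_at_optimum_not_worse_than_at_prior():
    rng = np.random.default_rng(8)
    prior = PriorSpec.default()
    y = conc_profile(PKParameters(30.0, 180.0), REG, TIMES)
    y = y * (1 + rng.normal(0, 0.1, y.shape))
    ec = ErrorConfig()
    fit = map_fit(TIMES, y, REG, prior, ec)
    sigma = ec.sigma(y)
    f_prior = conc_profile(PKParameters(prior.cl, prior.vd), REG, TIMES)
    wss_prior = float(np.sum(((y - f_prior) / sigma) ** 2))
    assert fit.wss <= wss_prior + 1e-9


def test_map_recovers_individual_clearance_in_cohort():
    """~100 profiles at the final-model truth, 10% proportional error:
    median recovered CL within 5% of the simulated individual CL."""
    truth = PopModel.final_estimates().with_(sigma_add=0.0, sigma_prop=0.10)
    cohort = sample_cohort(50, seed=31)
    df, sim_truth = simulate_dataset(cohort, truth, seed=32, return_truth=True)
    fits = map_fit_dataset(df, PriorSpec.default())
    merged = fits.merge(sim_truth, on=["SUBJ", "OCC"], suffixes=("_est", "_true"))
    ratio = merged.CL_est / merged.CL_true
    assert np.median(ratio) == pytest.approx(1.0, abs=0.05)


def test_mann_whitney_exact_small_sample():
    u, p = mann_whitney([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
    assert u == 0.0
    assert p == pytest.approx(0.1, abs=1e-12)  # 2/C(6,3)


def test_mann_whitney_identical_samples():
    a = [1.0, 2.0, 3.0, 4.0, 5.0]
    u, p = mann_whitney(a, a)
    assert u == pytest.approx(len(a) ** 2 / 2)
    assert p > 0.95


def test_mann_whitney_shift_invariant_and_empty_rejected():
    a, b = [1.0, 5.0, 2.5, 7.0], [3.0, 8.0, 9.0]
    u1, p1 = mann_whitney(a, b)
    u2, p2 = mann_whitney([x + 100 for x in a], [x + 100 for x in b])
    assert u1 == u2 and p1 == pytest.approx(p2)
    with pytest.raises(ValueError):
        mann_whitney([], [1.0])


def test_ols_perfect_fit_and_permutation_invariance():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    r = ols_regression(x, 2 * x)
    assert r.slope == pytest.approx(2.0) and r.r_squared == pytest.approx(1.0)
    rng = np.random.default_rng(5)
    x = rng.uniform(0, 3, 20)
    y = 18.54 * x + 3.261 + rng.normal(0, 5, 20)
    r1 = ols_regression(x, y)
    perm = rng.permutation(20)
    r2 = ols_regression(x[perm], y[perm])
    assert r1.slope == pytest.approx(r2.slope)
    assert r1.p_value == pytest.approx(r2.p_value)


def test_ols_degenerate_rejected():
    with pytest.raises(ValueError):
        ols_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        ols_regression([1.0, 2.0], [1.0, 2.0])


def test_ols_recovers_clearance_regression():
    """CL = 18.54*CLcr + 3.261 with noise tuned to r2 ~ 0.63 at n = 29."""
    rng = np.random.default_rng(12)
    clcr = np.exp(rng.normal(math.log(1.16), 0.847, 29))
    signal = 18.54 * clcr + 3.261
    noise_sd = np.std(18.54 * clcr) * math.sqrt(1 / 0.6275 - 1)
    y = signal + rng.normal(0, noise_sd, 29)
    r = ols_regression(clcr, y, covariate="CL~CLCR")
    assert r.slope == pytest.approx(18.54, rel=0.15)
    assert r.significant


def test_two_stage_identical_fits_give_zero_cv_and_null_comparisons():
    rows = []
    for s in range(1, 7):
        for occ in ("early", "delayed"):
            rows.append(dict(SUBJ=s, OCC=occ, CL=20.0, VD=140.0, THALF=4.85,
                             WSS=1.0, RMS=0.4, WT=90.0, CLCR=1.2, AGE=60.0,
                             HT=175.0, SEX="M", SMOKE="N"))
    out = two_stage_summary(pd.DataFrame(rows))
    assert all(v == pytest.approx(0.0) for v in out["cv_percent"].values())
    assert not out["paired"]["empty"]
    assert all(t["p"] > 0.9 for t in out["paired"]["tests"].values())


def test_two_stage_no_paired_subjects_flagged():
    rows = [dict(SUBJ=s, OCC="early", CL=20.0 + s, VD=140.0, THALF=4.8,
                 WSS=1.0, RMS=0.4, WT=90.0, CLCR=1.2) for s in range(1, 5)]
    out = two_stage_summary(pd.DataFrame(rows))
    assert out["paired"]["empty"] and out["paired"]["n_subjects"] == 0


def test_two_stage_cv_approaches_generating_omega():
    """As residual noise -> 0 and weight is fixed, CL/kg CV% -> the generating
    between-subject CV."""
    truth = PopModel(cl_pop=21.5, vd_pop=143.0, omega_cl=0.30, omega_vd=0.10,
                     sigma_add=1e-3, sigma_prop=1e-3, cl_law="none")
    cfg = CohortConfig(weight=_LogNormalSpec(90.0, 89.9, 90.1))
    cohort = sample_cohort(30, seed=41, config=cfg)
    df = simulate_dataset(cohort, truth, seed=42)
    fits = map_fit_dataset(df, PriorSpec.flat())
    out = two_stage_summary(fits)
    target = 100.0 * math.sqrt(math.exp(0.30**2) - 1.0)  # exact log-normal CV
    assert out["cv_percent"]["CL_KG"] == pytest.approx(target, abs=8.0)
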