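"""Mixed-effects estimation, covariate selection and simulation diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize as sopt

import cipropk.population as pop
from cipropk.cohort import sample_cohort, simulate_dataset
from cipropk.experiments import final_model
from cipropk.model import PopModel, typical_cl
from cipropk.pk_core import PKParameters, Regimen, conc_profile
from cipropk.population import (
    CovariateEffect,
    ModelSpec,
    bootstrap_ci,
    covariate_step,
    evaluate_ofv,
    nlme_fit,
    npde,
    resample_subjects,
    vpc,
    _CompiledData,
    _default_start,
    _ofv_at,
    _pack,
)


# ---------------------------------------------------------------------------
# typical values
# ---------------------------------------------------------------------------

def test_typical_cl_linear_law_values():
    m = final_model()
    assert typical_cl(m, 1.25) == pytest.approx(21.5)
    assert typical_cl(m, 0.5) == pytest.approx(11.84)  # 5.4 + 16.1*0.4


def test_typical_cl_reference_point_structure():
    lin = PopModel(cl_pop=10.0, vd_pop=100.0, theta_clcr=5.0, cl_law="linear")
    powm = PopModel(cl_pop=15.0, vd_pop=100.0, theta_clcr=0.75, cl_law="power")
    # at the reference the scaled covariate is 1: linear gives CLp + theta,
    # power gives CLp
    assert typical_cl(lin, 1.25) == pytest.approx(15.0)
    assert typical_cl(powm, 1.25) == pytest.approx(15.0)


def test_typical_cl_domain_errors():
    m = final_model()
    with pytest.raises(ValueError):
        typical_cl(m, 0.0)
    neg = PopModel(cl_pop=1.0, vd_pop=100.0, theta_clcr=-5.0, cl_law="linear")
    with pytest.raises(ValueError):
        typical_cl(neg, 2.0)  # extrapolates to nonpositive clearance


def test_pop_model_validation():
    with pytest.raises(ValueError):
        PopModel(cl_pop=-1.0, vd_pop=100.0)
    with pytest.raises(ValueError):
        PopModel(cl_pop=1.0, vd_pop=100.0, omega_cl=-0.1)
    with pytest.raises(ValueError):
        PopModel(cl_pop=1.0, vd_pop=100.0, cl_law="spline")


# ---------------------------------------------------------------------------
# OFV properties
# ---------------------------------------------------------------------------

def test_ofv_invariant_to_relabeling_and_reordering(truth_model, sim_dataset):
    ref = evaluate_ofv(sim_dataset, truth_model)
    # relabel subjects and present them in reverse order
    ids = list(sim_dataset.SUBJ.unique())
    parts = []
    for new, s in enumerate(reversed(ids), start=101):
        g = sim_dataset[sim_dataset.SUBJ == s].copy()
        g["SUBJ"] = new
        parts.append(g.iloc[::-1])  # reorder rows within subject too
    shuffled = pd.concat(parts, ignore_index=True)
    assert evaluate_ofv(shuffled, truth_model) == pytest.approx(ref, abs=1e-6)


def test_ofv_likelihood_dominance_at_truth(truth_model, sim_dataset):
    ref = evaluate_ofv(sim_dataset, truth_model)
    doubled = truth_model.with_(cl_pop=2 * 5.4, theta_clcr=2 * 16.1,
                                vd_pop=2 * 143.0)
    assert ref < evaluate_ofv(sim_dataset, doubled)


def test_fast_and_reference_inner_solvers_agree(truth_model, sim_dataset):
    if not pop._fast.HAVE_NUMBA:
        pytest.skip("numba unavailable; only the reference path exists")
    spec = ModelSpec.final()
    cd = _CompiledData(sim_dataset)
    x0 = _pack(_default_start(spec), spec)
    rng = np.random.default_rng(0)
    for _ in range(5):
        x = x0 + rng.normal(0, 0.1, x0.shape)
        pop._USE_FAST = True
        a = _ofv_at(cd, spec, x, {"eta": np.zeros((cd.n_subj, 2))})
        pop._USE_FAST = False
        b = _ofv_at(cd, spec, x, {"eta": np.zeros((cd.n_subj, 2))})
        pop._USE_FAST = pop._fast.HAVE_NUMBA
        assert a == pytest.approx(b, abs=1e-4)


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

def test_no_random_effects_limit_matches_pooled_nls():
    """omega = 0, additive-only error: fixed effects equal the NLS solution."""
    truth = PopModel(cl_pop=20.0, vd_pop=140.0, omega_cl=0.0, omega_vd=0.0,
                     sigma_add=0.3, sigma_prop=0.0, cl_law="none")
    cohort = sample_cohort(8, seed=51)
    df = simulate_dataset(cohort, truth, seed=52, regimen_policy="fixed-400q12")
    est = nlme_fit(df, ModelSpec.base(), n_starts=1)

    obs = df[df.EVID == 0]
    reg = Regimen.uniform(400.0, 12.0, 9)

    def resid(p):
        out = []
        for subj, g in obs.groupby("SUBJ"):
            f = conc_profile(PKParameters(p[0], p[1]), reg, g.TIME.to_numpy())
            out.append(g.DV.to_numpy() - f)
        return np.concatenate(out)

    nls = sopt.least_squares(resid, [15.0, 120.0], bounds=([1, 10], [100, 1000]))
    assert est.params["cl_pop"] == pytest.approx(nls.x[0], rel=0.02)
    assert est.params["vd_pop"] == pytest.approx(nls.x[1], rel=0.02)
    assert est.params["omega_cl"] < 0.05


def test_nlme_fit_preconditions(truth_model):
    cohort = sample_cohort(4, seed=53)
    df = simulate_dataset(cohort, truth_model, seed=54)
    with pytest.raises(ValueError, match=">= 6 subjects"):
        nlme_fit(df)
    cohort = sample_cohort(7, seed=55)
    df = simulate_dataset(cohort, truth_model, seed=56)
    # strip one subject down to a single observation
    obs_idx = df[(df.SUBJ == 1) & (df.EVID == 0)].index[1:]
    df2 = df.drop(obs_idx)
    with pytest.raises(ValueError, match="fewer than 2"):
        nlme_fit(df2)


def test_nlme_fit_deterministic(truth_model, sim_dataset):
    a = nlme_fit(sim_dataset, ModelSpec.final(), n_starts=1)
    b = nlme_fit(sim_dataset, ModelSpec.final(), n_starts=1)
    assert a.ofv == b.ofv
    assert a.params == b.params


def test_rse_reported_for_fixed_effects(truth_model, sim_dataset):
    est = nlme_fit(sim_dataset, ModelSpec.final(), n_starts=1, compute_rse=True)
    assert est.rse is not None
    for k in ("cl_pop", "vd_pop", "theta_CLCR_CL_linear"):
        assert np.isfinite(est.rse[k]) and est.rse[k] > 0


# ---------------------------------------------------------------------------
# covariate step
# ---------------------------------------------------------------------------

def test_covariate_step_selects_true_effect(truth_model, sim_dataset):
    candidates = [
        CovariateEffect("CLCR", "CL", "linear", 1.25),
        CovariateEffect("AGE", "CL", "linear", 58.0),
    ]
    best, ledger = covariate_step(sim_dataset, candidates, n_starts=1)
    included = ledger[ledger.included]
    assert "theta_CLCR_CL_linear" in best.params
    assert (included.candidate == "theta_CLCR_CL_linear").any()
    assert included.dofv.iloc[0] > 3.84
    # the ledger records every tested candidate with its OFV drop
    assert set(ledger.candidate) >= {"theta_CLCR_CL_linear", "theta_AGE_CL_linear"}
    # the ledger reports the unexplained CL variability before and after
    assert ledger.attrs["iiv_cl_cv_before"] > 0
    assert ledger.attrs["iiv_cl_cv_after"] > 0


def test_covariate_step_empty_candidates_returns_base(truth_model, sim_dataset):
    best, ledger = covariate_step(sim_dataset, [], n_starts=1)
    assert best.model is not None and best.model.cl_law == "none"
    assert len(ledger) == 0


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def test_bootstrap_requires_enough_replicates(sim_dataset):
    with pytest.raises(ValueError):
        bootstrap_ci(sim_dataset, ModelSpec.final(), n_boot=50)


def test_bootstrap_resampling_deterministic():
    ids = list(range(1, 31))
    a = resample_subjects(np.random.default_rng(9), ids)
    b = resample_subjects(np.random.default_rng(9), ids)
    assert a == b


def test_bootstrap_degenerate_for_cloned_subjects(truth_model):
    """With identical cloned subjects every resample carries the same
    information, so the CI collapses onto the point estimate."""
    cohort = sample_cohort(1, seed=61)
    one = simulate_dataset(cohort, truth_model, seed=62)
    parts = []
    for k in range(6):
        g = one.copy()
        g["SUBJ"] = k + 1
        parts.append(g)
    cloned = pd.concat(parts, ignore_index=True)
    out = bootstrap_ci(cloned, ModelSpec.base(), n_boot=100, seed=63,
                       n_starts=1, maxiter=600)
    assert out["failure_rate"] <= 0.2
    for name in ("cl_pop", "vd_pop"):
        s = out["parameters"][name]
        assert s["ci_hi"] - s["ci_lo"] <= 1e-6 * max(abs(s["median"]), 1.0)


def test_bootstrap_medians_near_point_estimates(truth_model, sim_dataset):
    """Median bootstrap estimates within 10% of the original fit's values."""
    est = nlme_fit(sim_dataset, ModelSpec.final(), n_starts=1)
    out = bootstrap_ci(sim_dataset, ModelSpec.final(), n_boot=100, seed=64,
                       n_starts=1)
    assert out["status"] == "ok"
    for name in ("vd_pop", "omega_cl"):
        med = out["parameters"][name]["median"]
        assert med == pytest.approx(est.params[name], rel=0.10)
    # typical clearance at the reference covariate is the stable functional
    cl_ref = out["parameters"]["cl_pop"]["median"] + \
        out["parameters"]["theta_CLCR_CL_linear"]["median"]
    assert cl_ref == pytest.approx(
        est.params["cl_pop"] + est.params["theta_CLCR_CL_linear"], rel=0.10)


# ---------------------------------------------------------------------------
# VPC / NPDE
# ---------------------------------------------------------------------------

def test_vpc_bands_collapse_without_variability():
    truth = PopModel(cl_pop=21.5, vd_pop=143.0, theta_clcr=16.1, cl_law="linear")
    cohort = sample_cohort(10, seed=71)
    df = simulate_dataset(cohort, truth, seed=72)
    v = vpc(df, truth, n_sim=100, seed=73)
    for _, row in v.iterrows():
        assert row.sim_p50_hi - row.sim_p50_lo == pytest.approx(0.0, abs=1e-9)
        assert row.obs_p50 == pytest.approx(row.sim_p50_med, rel=1e-9)


def test_npde_requires_enough_simulations(sim_dataset, truth_model):
    with pytest.raises(ValueError):
        npde(sim_dataset, truth_model, K=100)


def test_npde_invariant_to_subject_ordering(truth_model):
    cohort = sample_cohort(10, seed=74)
    df = simulate_dataset(cohort, truth_model, seed=75)
    r1 = npde(df, truth_model, K=300, seed=76)
    ids = list(df.SUBJ.unique())
    shuffled = pd.concat([df[df.SUBJ == s] for s in reversed(ids)],
                         ignore_index=True)
    r2 = npde(shuffled, truth_model, K=300, seed=76)
    assert np.allclose(np.sort(r1["npde"]), np.sort(r2["npde"]))
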