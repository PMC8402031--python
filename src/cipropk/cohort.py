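"""Synthetic ICU cohorts and simulated sparse concentration datasets.

The generator emulates a two-occasion therapeutic-drug-monitoring design in
critically ill adults: 30-min IV infusions of 400 or 600 mg every 8 or 12 h,
with three samples per occasion drawn 1 h, 4 h, and at trough (7.5 h after a
q8h infusion, 11.5 h after a q12h infusion) following the end of an infusion.
One profile is taken early in therapy (within 36 h of the first dose, here
after the second dose) and one delayed (72-96 h, here after the dose nearest
84 h).  Covariates are drawn from log-normal (positive, right-skewed) or
categorical distributions calibrated to the cohort's published medians and
ranges, with the stated ranges treated as approximate 95% intervals.

Datasets are long-format tables, one row per dose or observation event, with
occasion-specific covariates: renal function is re-measured on each sampling
day, and the delayed-phase creatinine clearance has a narrower spread than
the early phase (renal status stabilises over the first days of ICU care).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from cipropk.covariates import PatientCovariates
from cipropk.model import PopModel, typical_cl
from cipropk.pk_core import Regimen, _conc_infusion_raw

__all__ = [
    "StudyDesign",
    "CohortConfig",
    "Subject",
    "sample_cohort",
    "assign_regimen",
    "simulate_dataset",
    "write_dataset_csv",
    "read_dataset_csv",
    "DATASET_COLUMNS",
]

#: allowed (amount mg, interval h) regimens
ALLOWED_REGIMENS = ((400.0, 12.0), (400.0, 8.0), (600.0, 12.0))

DATASET_COLUMNS = [
    "SUBJ", "OCC", "TIME", "EVID", "AMT", "DUR", "DV", "CLCR",
    "AGE", "SEX", "WT", "HT", "BILI", "FLUID", "NOREPI", "FUROS",
    "SMOKE", "CVVHD",
]


@dataclass(frozen=True)
class StudyDesign:
    """Sampling design: infusion duration, per-occasion sample offsets, windows."""

    infusion_duration: float = 0.5  # h
    sample_offsets: tuple[float, ...] = (1.0, 4.0)  # h after end of infusion
    early_max: float = 36.0  # h after first dose
    delayed_window: tuple[float, float] = (72.0, 96.0)
    delayed_anchor: float = 84.0  # profile taken after the dose nearest this

    def __post_init__(self) -> None:
        if any(o <= 0 for o in self.sample_offsets):
            raise ValueError("sample offsets must be positive")

    def trough_offset(self, interval: float) -> float:
        """Trough sampling offset after end of infusion: 7.5 h (q8), 11.5 h (q12)."""
        off = interval - self.infusion_duration
        if off <= 0:
            raise ValueError("interval shorter than infusion duration")
        return off

    def occasion_offsets(self, interval: float) -> tuple[float, ...]:
        return tuple(self.sample_offsets) + (self.trough_offset(interval),)


@dataclass(frozen=True)
class _LogNormalSpec:
    """Log-normal target: median with (lo, hi) treated as a ~95% interval."""

    median: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError(f"invalid range ({self.lo}, {self.hi}): need 0 < lo < hi")
        if not (self.lo <= self.median <= self.hi):
            raise ValueError("median must lie within the range")

    @property
    def mu(self) -> float:
        return math.log(self.median)

    @property
    def sigma(self) -> float:
        return (math.log(self.hi) - math.log(self.lo)) / (2 * 1.959964)

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.clip(rng.lognormal(self.mu, self.sigma, size=n), self.lo, self.hi)


@dataclass(frozen=True)
class CohortConfig:
    """Marginal covariate targets (cohort medians and ranges).

    Defaults reproduce the published ICU cohort: CLcr median 1.16 mL/s
    (0.12-3.32) early and 1.36 (0.66-2.49) delayed, age 58 y (35-85),
    weight 90 kg (56-140), height 175 cm (150-196), ~72% male.
    """

    clcr_early: _LogNormalSpec = _LogNormalSpec(1.16, 0.12, 3.32)
    clcr_delayed: _LogNormalSpec = _LogNormalSpec(1.36, 0.66, 2.49)
    age: _LogNormalSpec = _LogNormalSpec(58.0, 35.0, 85.0)
    weight: _LogNormalSpec = _LogNormalSpec(90.0, 56.0, 140.0)
    height: _LogNormalSpec = _LogNormalSpec(175.0, 150.0, 196.0)
    bilirubin: _LogNormalSpec = _LogNormalSpec(11.3, 3.5, 90.3)
    serum_creatinine: _LogNormalSpec = _LogNormalSpec(85.0, 35.0, 400.0)
    male_fraction: float = 21.0 / 29.0
    smoking_probs: tuple[float, float, float] = (15 / 29, 6 / 29, 8 / 29)  # yes/no/NA
    #: correlation between early and delayed log-CLcr (0 = independent redraw)
    clcr_correlation: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.male_fraction <= 1):
            raise ValueError("male_fraction must be in [0, 1]")
        if not (-1 <= self.clcr_correlation <= 1):
            raise ValueError("clcr_correlation must be in [-1, 1]")


@dataclass
class Subject:
    """One virtual patient with per-occasion covariates."""

    subject_id: int
    early: PatientCovariates
    delayed: PatientCovariates


def _draw_covariates(
    rng: np.random.Generator, cfg: CohortConfig, n: int
) -> list[dict]:
    sex = np.where(rng.random(n) < cfg.male_fraction, "male", "female")
    age = cfg.age.draw(rng, n)
    weight = cfg.weight.draw(rng, n)
    height = cfg.height.draw(rng, n)
    bili = cfg.bilirubin.draw(rng, n)
    scr = cfg.serum_creatinine.draw(rng, n)
    fluid = np.clip(rng.normal(-490.0, 2100.0, size=n), -4000.0, 4300.0)
    norepi = np.where(
        rng.random(n) < 0.25,
        0.0,
        np.clip(rng.lognormal(math.log(20.0), 0.6, size=n), 0.0, 61.0),
    )
    furos = np.where(
        rng.random(n) < 0.4,
        0.0,
        np.clip(rng.lognormal(math.log(20.0), 0.9, size=n), 0.0, 320.0),
    )
    smoke_draw = rng.random(n)
    p_yes, p_no, _ = cfg.smoking_probs
    smoker = np.where(smoke_draw < p_yes, "yes", np.where(smoke_draw < p_yes + p_no, "no", "NA"))
    return [
        dict(
            sex=str(sex[i]), age=float(age[i]), weight=float(weight[i]),
            height=float(height[i]), serum_creatinine=float(scr[i]),
            bilirubin=float(bili[i]), fluid_balance=float(fluid[i]),
            norepinephrine_dose=float(norepi[i]), furosemide_dose=float(furos[i]),
            smoker=None if smoker[i] == "NA" else str(smoker[i]),
        )
        for i in range(n)
    ]


def sample_cohort(
    n: int, seed: int, config: Optional[CohortConfig] = None
) -> list[Subject]:
    """Draw ``n`` virtual patients, each with early- and delayed-occasion covariates.

    Demographics are shared across occasions; renal function (CLcr, serum
    creatinine) and the labile clinical covariates are re-drawn for the
    delayed occasion, with the delayed CLcr distribution narrower than the
    early one.  Measured CLcr is made internally consistent with the sampled
    serum creatinine by back-solving the urine side of Ucr*V/Scr.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    cfg = config or CohortConfig()
    rng = np.random.default_rng(seed)

    base = _draw_covariates(rng, cfg, n)
    # early CLcr
    z_early = rng.standard_normal(n)
    clcr_e = np.clip(
        np.exp(cfg.clcr_early.mu + cfg.clcr_early.sigma * z_early),
        cfg.clcr_early.lo, cfg.clcr_early.hi,
    )
    # delayed CLcr: optionally correlated in log space, narrower spread
    rho = cfg.clcr_correlation
    z_del = rho * z_early + math.sqrt(1 - rho**2) * rng.standard_normal(n)
    clcr_d = np.clip(
        np.exp(cfg.clcr_delayed.mu + cfg.clcr_delayed.sigma * z_del),
        cfg.clcr_delayed.lo, cfg.clcr_delayed.hi,
    )
    scr_d = cfg.serum_creatinine.draw(rng, n)
    fluid_d = np.clip(rng.normal(-500.0, 1400.0, size=n), -3502.0, 1900.0)
    urine_flow = np.clip(rng.lognormal(math.log(0.0174), 0.4, size=n), 0.002, 0.08)

    subjects = []
    for i in range(n):
        b = dict(base[i])
        flow = float(urine_flow[i])
        early = PatientCovariates(
            **b,
            urine_flow=flow,
            urine_creatinine=float(clcr_e[i]) * b["serum_creatinine"] / flow,
            clcr=float(clcr_e[i]),
        )
        bd = dict(base[i])
        bd["serum_creatinine"] = float(scr_d[i])
        bd["fluid_balance"] = float(fluid_d[i])
        delayed = PatientCovariates(
            **bd,
            urine_flow=flow,
            urine_creatinine=float(clcr_d[i]) * bd["serum_creatinine"] / flow,
            clcr=float(clcr_d[i]),
        )
        subjects.append(Subject(subject_id=i + 1, early=early, delayed=delayed))
    return subjects


def assign_regimen(
    policy: str,
    rng: Optional[np.random.Generator] = None,
    horizon: float = 96.0,
    infusion_duration: float = 0.5,
) -> Regimen:
    """Assign a dosing regimen under a policy.

    ``policy`` is ``"random-mix"`` (uniform over 400 mg q12h, 400 mg q8h,
    600 mg q12h — the regimens used clinically, 800-1200 mg/day) or
    ``"fixed-<amount>q<interval>"`` such as ``"fixed-400q12"``.
    """
    if policy == "random-mix":
        if rng is None:
            raise ValueError("random-mix policy requires an rng")
        amount, interval = ALLOWED_REGIMENS[rng.integers(len(ALLOWED_REGIMENS))]
    elif policy.startswith("fixed-"):
        try:
            amt_s, int_s = policy[len("fixed-"):].split("q")
            amount, interval = float(amt_s), float(int_s)
        except ValueError:
            raise ValueError(f"unparseable fixed policy {policy!r}") from None
        if (amount, interval) not in ALLOWED_REGIMENS:
            raise ValueError(
                f"regimen {amount} mg q{interval}h not among allowed {ALLOWED_REGIMENS}"
            )
    else:
        raise ValueError(f"unknown regimen policy {policy!r}")
    n_doses = int(horizon / interval) + 1
    return Regimen.uniform(amount, interval, n_doses, infusion_duration)


def _occasion_obs_times(regimen: Regimen, design: StudyDesign) -> dict[str, np.ndarray]:
    """Observation times (dosing-clock h) for the early and delayed occasions."""
    interval = regimen.interval
    dur = design.infusion_duration
    offsets = np.asarray(design.occasion_offsets(interval))
    starts = np.asarray([e.start_time for e in regimen.events])
    early_start = starts[1] if len(starts) > 1 else starts[0]
    # dose nearest the delayed anchor; earlier dose on ties
    delayed_start = starts[np.argmin(np.abs(starts - design.delayed_anchor))]
    out = {
        "early": early_start + dur + offsets,
        "delayed": delayed_start + dur + offsets,
    }
    if out["early"].max() > design.early_max:
        raise ValueError("early-occasion samples fall outside the 36-h window")
    return out


def _profile(regimen: Regimen, CL: float, Vd: float, times: np.ndarray) -> np.ndarray:
    total = np.zeros_like(times, dtype=float)
    for ev in regimen.events:
        total += _conc_infusion_raw(CL, Vd, ev.start_time, ev.amount, ev.infusion_duration, times)
    return total


def simulate_dataset(
    cohort: list[Subject],
    pop_model: PopModel,
    design: Optional[StudyDesign] = None,
    seed: int = 0,
    regimen_policy: str = "random-mix",
    return_truth: bool = False,
    truncate_negative: bool = False,
):
    """Simulate a long-format concentration dataset from a population model.

    Per subject i, CL_i = typical_cl(model, CLcr_i) * exp(eta_CL,i) with the
    occasion-specific CLcr, Vd_i = Vd_pop * exp(eta_Vd,i); when the model's
    inter-occasion SDs are nonzero an extra per-occasion effect is added on
    the log scale.  Observations are y = f*(1 + eps_prop) + eps_add.

    By default negative draws from the additive error tail are kept, so the
    simulated data follow exactly the probability model the estimation step
    assumes (the convention used when simulating for predictive checks).
    ``truncate_negative`` clips them at zero instead; note that at an
    additive SD near 1 mg/L this affects roughly a tenth of trough samples,
    heaps them at a value the bioanalytical assay could never report, and
    visibly distorts residual-variance estimates and likelihood-ratio
    calibration — useful only for sensitivity analyses.

    With a fixed seed the output is reproducible row for row.

    Returns the dataset DataFrame, plus a per-subject-occasion truth table
    (true CL, Vd) when ``return_truth`` is set.
    """
    if pop_model.cl_law == "none" and pop_model.theta_clcr != 0.0:
        raise ValueError("theta_clcr set but cl_law is 'none'")
    design = design or StudyDesign()
    rng = np.random.default_rng(seed)
    rows = []
    truth = []
    for subj in cohort:
        regimen = assign_regimen(
            regimen_policy, rng, infusion_duration=design.infusion_duration
        )
        eta_cl = rng.normal(0.0, pop_model.omega_cl) if pop_model.omega_cl > 0 else 0.0
        eta_vd = rng.normal(0.0, pop_model.omega_vd) if pop_model.omega_vd > 0 else 0.0
        obs_times = _occasion_obs_times(regimen, design)
        occ_cov = {"early": subj.early, "delayed": subj.delayed}

        for ev in regimen.events:
            occ = "early" if ev.start_time <= design.early_max else "delayed"
            rows.append(_row(subj, occ, occ_cov[occ], ev.start_time, evid=1,
                             amt=ev.amount, dur=ev.infusion_duration, dv=np.nan))

        for occ in ("early", "delayed"):
            cov = occ_cov[occ]
            iov_cl = rng.normal(0.0, pop_model.iov_cl) if pop_model.iov_cl > 0 else 0.0
            iov_vd = rng.normal(0.0, pop_model.iov_vd) if pop_model.iov_vd > 0 else 0.0
            cl_i = typical_cl(pop_model, cov.clcr) * math.exp(eta_cl + iov_cl)
            vd_i = pop_model.vd_pop * math.exp(eta_vd + iov_vd)
            f = _profile(regimen, cl_i, vd_i, obs_times[occ])
            eps_p = rng.normal(0.0, pop_model.sigma_prop, size=f.shape) if pop_model.sigma_prop > 0 else 0.0
            eps_a = rng.normal(0.0, pop_model.sigma_add, size=f.shape) if pop_model.sigma_add > 0 else 0.0
            y = f * (1.0 + eps_p) + eps_a
            if truncate_negative:
                y = np.maximum(y, 0.0)
            for t, dv in zip(obs_times[occ], y):
                rows.append(_row(subj, occ, cov, t, evid=0, amt=np.nan, dur=np.nan, dv=dv))
            truth.append(dict(SUBJ=subj.subject_id, OCC=occ, CL=cl_i, VD=vd_i,
                              CLCR=cov.clcr, TVCL=typical_cl(pop_model, cov.clcr)))

    df = pd.DataFrame(rows, columns=DATASET_COLUMNS)
    df = df.sort_values(["SUBJ", "TIME", "EVID"], ascending=[True, True, False],
                        kind="stable").reset_index(drop=True)
    if return_truth:
        return df, pd.DataFrame(truth)
    return df


def _row(subj: Subject, occ: str, cov: PatientCovariates, time: float,
         evid: int, amt: float, dur: float, dv: float) -> dict:
    return dict(
        SUBJ=subj.subject_id, OCC=occ, TIME=round(time, 2), EVID=evid,
        AMT=amt, DUR=dur, DV=dv, CLCR=cov.clcr, AGE=cov.age,
        SEX="M" if cov.sex == "male" else "F", WT=cov.weight, HT=cov.height,
        BILI=cov.bilirubin, FLUID=cov.fluid_balance,
        NOREPI=cov.norepinephrine_dose, FUROS=cov.furosemide_dose,
        SMOKE={None: ".", "yes": "Y", "no": "N"}[cov.smoker],
        CVVHD=int(cov.cvvhd),
    )


def write_dataset_csv(df: pd.DataFrame, path) -> None:
    """Write the long-format dataset; missing token '.', times with 2 decimals."""
    out = df.copy()
    out["TIME"] = out["TIME"].map(lambda t: f"{t:.2f}")
    out.to_csv(path, index=False, na_rep=".")


def read_dataset_csv(path) -> pd.DataFrame:
    """Read a dataset CSV written by :func:`write_dataset_csv`."""
    df = pd.read_csv(path, na_values=["."], keep_default_na=True,
                     dtype={"SMOKE": "string"})
    df["SMOKE"] = df["SMOKE"].fillna(".").astype(str)
    df["TIME"] = df["TIME"].astype(float)
    return df[DATASET_COLUMNS]
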