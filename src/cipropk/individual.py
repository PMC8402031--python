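"""MAP-Bayesian per-patient estimation and two-stage covariate statistics.

Each patient-occasion is fitted separately: the one-compartment infusion
model is individualised by minimising a penalised weighted least-squares
objective

    J(CL, Vd) = sum_j ((y_j - f_j) / sigma_j)^2
              + sum_p ((ln p - ln p_prior) / omega_prior_p)^2

i.e. the posterior mode under a log-normal population prior and a combined
residual weight sigma_j = sqrt((prop * y_j)^2 + add^2).  Weights are computed
from the observed concentrations so that the flat-prior limit is exactly
weighted least squares.  Goodness of fit is reported as the weighted sum of
squares (WSS, the data term at the optimum) and the root mean square
RMS = sqrt(WSS / n_obs).

The second stage relates the per-patient estimates to covariates with
univariate tools: ordinary least-squares regression for continuous
covariates, the Mann-Whitney U test for categorical ones and for the
early-versus-delayed occasion comparison.  The occasion comparison uses an
unpaired test even for subjects observed on both occasions, mirroring the
original analysis rather than substituting a paired test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from cipropk.pk_core import PKParameters, Regimen, DoseEvent, conc_profile

__all__ = [
    "PriorSpec",
    "ErrorConfig",
    "IndividualFit",
    "AssociationResult",
    "InsufficientDataError",
    "map_fit",
    "map_fit_dataset",
    "mann_whitney",
    "ols_regression",
    "two_stage_summary",
]


class InsufficientDataError(ValueError):
    """Too few observations to individualise the model."""


@dataclass(frozen=True)
class PriorSpec:
    """Log-normal population prior for the MAP objective.

    ``cv_cl``/``cv_vd`` are the log-scale SDs (approximately coefficients of
    variation); ``None`` means a flat (uninformative) prior on that parameter.
    """

    cl: float
    vd: float
    cv_cl: Optional[float] = 0.5
    cv_vd: Optional[float] = 0.5
    source: str = "unspecified"

    def __post_init__(self) -> None:
        if not (self.cl > 0 and self.vd > 0):
            raise ValueError("prior central values must be positive")
        for cv in (self.cv_cl, self.cv_vd):
            if cv is not None and not (cv > 0):
                raise ValueError("prior CVs must be positive (or None for flat)")

    @property
    def informative(self) -> bool:
        return self.cv_cl is not None and self.cv_vd is not None

    @classmethod
    def flat(cls, cl: float = 18.59, vd: float = 136.9) -> "PriorSpec":
        return cls(cl=cl, vd=vd, cv_cl=None, cv_vd=None, source="flat")

    @classmethod
    def default(cls) -> "PriorSpec":
        """Prior shipped with the package (see ``data/prior_default.yaml``)."""
        text = resources.files("cipropk").joinpath("data/prior_default.yaml").read_text()
        return cls.from_dict(yaml.safe_load(text))

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        return cls(cl=float(d["cl"]), vd=float(d["vd"]),
                   cv_cl=None if d.get("cv_cl") is None else float(d["cv_cl"]),
                   cv_vd=None if d.get("cv_vd") is None else float(d["cv_vd"]),
                   source=str(d.get("source", "unspecified")))

    @classmethod
    def from_yaml(cls, path) -> "PriorSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class ErrorConfig:
    """Residual weighting for the MAP objective: sigma = sqrt((prop*y)^2 + add^2)."""

    proportional: float = 0.10
    additive: float = 0.05

    def sigma(self, y: np.ndarray) -> np.ndarray:
        s = np.sqrt((self.proportional * y) ** 2 + self.additive**2)
        return np.maximum(s, 1e-9)


@dataclass
class IndividualFit:
    """Per-patient, per-occasion posterior-mode estimate with fit diagnostics."""

    pk: PKParameters
    t_half: float
    wss: float
    rms: float
    occasion: str = ""
    n_obs: int = 0
    converged: bool = True
    objective: float = float("nan")
    trace: tuple = ()


@dataclass
class AssociationResult:
    """One covariate-parameter association from the second-stage screen."""

    covariate: str
    kind: str  # "continuous" | "categorical"
    p_value: float
    slope: Optional[float] = None
    intercept: Optional[float] = None
    r_squared: Optional[float] = None
    u_statistic: Optional[float] = None
    n: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0,1]: {self.p_value}")
        if self.r_squared is not None and not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"r^2 out of [0,1]: {self.r_squared}")

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


#: box for the log-parameter search: CL in [0.05, 1000] L/h, Vd in [1, 10000] L
_LOG_BOUNDS = ((math.log(0.05), math.log(1000.0)), (math.log(1.0), math.log(10000.0)))


def _map_objective(log_params, times, y, sigma, regimen, prior):
    cl, vd = math.exp(log_params[0]), math.exp(log_params[1])
    f = conc_profile(PKParameters(cl, vd), regimen, times)
    j = float(np.sum(((y - f) / sigma) ** 2))
    if prior.cv_cl is not None:
        j += ((log_params[0] - math.log(prior.cl)) / prior.cv_cl) ** 2
    if prior.cv_vd is not None:
        j += ((log_params[1] - math.log(prior.vd)) / prior.cv_vd) ** 2
    return j


def map_fit(
    times: Sequence[float],
    concentrations: Sequence[float],
    regimen: Regimen,
    prior: PriorSpec,
    error_config: ErrorConfig = ErrorConfig(),
    occasion: str = "",
    grid: int = 5,
) -> IndividualFit:
    """Posterior-mode (MAP) fit of one patient-occasion.

    ``times`` are hours on the dosing clock (time since first dose).  A
    ``grid`` x ``grid`` multi-start in log-parameter space around the prior
    central values guards against local minima; ties are broken by lowest
    objective, then lowest CL, making the fit deterministic.

    With zero observations and an informative prior, the prior mode is
    returned (the no-data limit used when initialising therapy); otherwise at
    least two observations are required.
    """
    times = np.asarray(times, dtype=float)
    y = np.asarray(concentrations, dtype=float)
    n = len(y)
    if n == 0 and prior.informative:
        pk = PKParameters(prior.cl, prior.vd)
        return IndividualFit(pk=pk, t_half=pk.t_half, wss=0.0, rms=0.0,
                             occasion=occasion, n_obs=0, converged=True,
                             objective=0.0)
    if n < 2:
        raise InsufficientDataError(
            f"need >= 2 observations per occasion (got {n}) unless an "
            "informative prior is used with no data at all"
        )
    sigma = error_config.sigma(y)

    # multi-start grid in log space, spanning +-2 prior SDs (or +-1.5 if flat)
    half_cl = 2.0 * prior.cv_cl if prior.cv_cl is not None else 1.5
    half_vd = 2.0 * prior.cv_vd if prior.cv_vd is not None else 1.5
    lc0, lv0 = math.log(prior.cl), math.log(prior.vd)
    grid_cl = np.linspace(lc0 - half_cl, lc0 + half_cl, grid)
    grid_vd = np.linspace(lv0 - half_vd, lv0 + half_vd, grid)

    best = None
    for gc in grid_cl:
        for gv in grid_vd:
            iterates: list[np.ndarray] = []
            res = optimize.minimize(
                _map_objective, np.array([gc, gv]),
                args=(times, y, sigma, regimen, prior),
                method="L-BFGS-B", callback=lambda xk: iterates.append(np.copy(xk)),
                bounds=_LOG_BOUNDS,
                options=dict(maxiter=200, ftol=1e-14, gtol=1e-12),
            )
            cl = math.exp(res.x[0])
            cand = (res.fun, cl, res, iterates)
            if best is None or cand[:2] < best[:2]:
                best = cand
    if best is None or not np.isfinite(best[0]):
        raise RuntimeError(
            f"MAP fit failed to converge after {grid * grid} starts "
            f"(n_obs={n}, occasion={occasion!r})"
        )
    fun, _, res, iterates = best
    # objective trace along the accepted iterates (line-search monotone)
    local_trace = [
        _map_objective(xk, times, y, sigma, regimen, prior) for xk in iterates
    ]
    cl, vd = math.exp(res.x[0]), math.exp(res.x[1])
    pk = PKParameters(cl, vd)
    f = conc_profile(pk, regimen, times)
    wss = float(np.sum(((y - f) / sigma) ** 2))
    return IndividualFit(
        pk=pk, t_half=pk.t_half, wss=wss, rms=math.sqrt(wss / n),
        occasion=occasion, n_obs=n, converged=bool(res.success),
        objective=float(fun), trace=tuple(local_trace),
    )


def map_fit_dataset(
    df: pd.DataFrame,
    prior: Optional[PriorSpec] = None,
    error_config: ErrorConfig = ErrorConfig(),
) -> pd.DataFrame:
    """MAP-fit every subject-occasion of a long-format dataset.

    Returns a table with columns SUBJ, OCC, CL, VD, THALF, WSS, RMS plus the
    occasion covariates carried over from the observation rows.
    """
    prior = prior or PriorSpec.default()
    rows = []
    for subj, g in df.groupby("SUBJ", sort=False):
        doses = g[g["EVID"] == 1].sort_values("TIME")
        if len(doses) == 0:
            raise ValueError(f"subject {subj} has no dose events")
        events = tuple(
            DoseEvent(r.TIME, r.AMT, r.DUR) for r in doses.itertuples()
        )
        interval = float(np.median(np.diff([e.start_time for e in events]))) \
            if len(events) > 1 else 12.0
        regimen = Regimen(events=events, interval=interval)
        for occ, go in g[(g["EVID"] == 0) & g["DV"].notna()].groupby("OCC", sort=False):
            fit = map_fit(go["TIME"].to_numpy(), go["DV"].to_numpy(),
                          regimen, prior, error_config, occasion=str(occ))
            row = dict(SUBJ=subj, OCC=occ, CL=fit.pk.CL, VD=fit.pk.Vd,
                       THALF=fit.t_half, WSS=fit.wss, RMS=fit.rms)
            for c in ("CLCR", "AGE", "SEX", "WT", "HT", "BILI", "FLUID",
                      "NOREPI", "FUROS", "SMOKE"):
                if c in go.columns:
                    row[c] = go[c].iloc[0]
            rows.append(row)
    return pd.DataFrame(rows)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when min(n_a, n_b) <= 8 and there are no ties; the
    tie-corrected, continuity-corrected normal approximation otherwise.
    Returns (U of the first sample, two-sided p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def ols_regression(
    x: Sequence[float], y: Sequence[float], covariate: str = "x"
) -> AssociationResult:
    """Univariate least-squares regression of a PK parameter on a covariate.

    p-value is the two-sided t-test on the slope.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points for regression")
    if np.ptp(x) == 0:
        raise ValueError(f"degenerate design: covariate {covariate!r} is constant")
    res = stats.linregress(x, y)
    return AssociationResult(
        covariate=covariate, kind="continuous", p_value=float(res.pvalue),
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(res.rvalue**2), n=len(x),
    )


_CONTINUOUS = ("CLCR", "AGE", "WT", "HT", "BILI", "FLUID", "NOREPI", "FUROS")
_CATEGORICAL = ("SEX", "SMOKE")


def two_stage_summary(fits: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Second-stage statistics over a table of per-occasion individual fits.

    Input is the output of :func:`map_fit_dataset` (estimates plus occasion
    covariates).  Returns a dict with

    ``cv_percent``
        coefficients of variation (100*SD/mean) of the body-weight-normalised
        parameters Vd/kg, CL/kg and of t1/2, early phase;
    ``paired``
        early-vs-delayed Mann-Whitney comparisons (Vd/kg, CL/kg, t1/2, CLcr)
        restricted to subjects with both occasions — flagged empty when no
        subject completed both;
    ``associations``
        the univariate covariate screen for CL and Vd (regression for
        continuous covariates, U test for categorical), each subject-occasion
        contributing one point.
    """
    if fits["SUBJ"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    work = fits.copy()
    work["VD_KG"] = work["VD"] / work["WT"]
    work["CL_KG"] = work["CL"] / work["WT"]

    early = work[work["OCC"] == "early"]
    cv = {
        p: float(100.0 * early[p].std(ddof=1) / early[p].mean())
        for p in ("VD_KG", "CL_KG", "THALF")
    }

    both = set(work[work["OCC"] == "early"]["SUBJ"]) & \
        set(work[work["OCC"] == "delayed"]["SUBJ"])
    paired: dict = {"n_subjects": len(both), "empty": len(both) == 0, "tests": {}}
    if both:
        sub = work[work["SUBJ"].isin(both)]
        e = sub[sub["OCC"] == "early"]
        d = sub[sub["OCC"] == "delayed"]
        for p in ("VD_KG", "CL_KG", "THALF", "CLCR"):
            if p not in sub.columns:
                continue
            u, pv = mann_whitney(e[p].to_numpy(), d[p].to_numpy())
            paired["tests"][p] = dict(U=u, p=pv, significant=pv < alpha)

    assoc: list[AssociationResult] = []
    for param in ("CL", "VD"):
        for covn in _CONTINUOUS:
            if covn not in work.columns:
                continue
            m = work[covn].notna()
            if m.sum() < 3 or np.ptp(work.loc[m, covn].to_numpy(float)) == 0:
                continue
            r = ols_regression(work.loc[m, covn].to_numpy(float),
                               work.loc[m, param].to_numpy(float),
                               covariate=f"{param}~{covn}")
            assoc.append(r)
        for covn in _CATEGORICAL:
            if covn not in work.columns:
                continue
            col = work[covn].astype(str)
            cats = [c for c in col.unique() if c not in (".", "nan", "None")]
            if len(cats) != 2:
                continue
            a = work.loc[col == cats[0], param].to_numpy(float)
            b = work.loc[col == cats[1], param].to_numpy(float)
            if len(a) == 0 or len(b) == 0:
                continue
            u, pv = mann_whitney(a, b)
            assoc.append(AssociationResult(
                covariate=f"{param}~{covn}", kind="categorical",
                p_value=pv, u_statistic=u, n=len(a) + len(b)))
    return dict(cv_percent=cv, paired=paired, associations=assoc)
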