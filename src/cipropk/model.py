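"""Population PK model container and typical-value laws.

The population model is a one-compartment IV-infusion model with log-normal
between-subject variability on clearance and volume, a combined (additive +
proportional) residual error, and an optional renal-function covariate on
clearance.  The covariate enters scaled by a reference creatinine clearance
(1.25 mL/s, a typical ICU value), so that at the reference the linear and
power laws coincide with the typical-individual parameters:

    linear:  CL(CLcr) = CL_pop + theta * (CLcr / CLcr_ref)
    power:   CL(CLcr) = CL_pop * (CLcr / CLcr_ref) ** theta
    none:    CL(CLcr) = CL_pop

Between-subject variability is parameterised by the standard deviation omega
of the log-normal random effect; it is conventionally reported as a
coefficient of variation CV% = 100 * omega.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["PopModel", "typical_cl"]

CL_LAWS = ("none", "linear", "power")


@dataclass(frozen=True)
class PopModel:
    """Fixed effects, random-effect SDs and residual-error parameters.

    Attributes
    ----------
    cl_pop : float
        Population clearance intercept CL_pop (L/h).
    vd_pop : float
        Population volume of distribution Vd_pop (L).
    theta_clcr : float
        Covariate coefficient on clearance (L/h per scaled CLcr unit for the
        linear law; dimensionless exponent for the power law).
    omega_cl, omega_vd : float
        SDs of the log-normal between-subject random effects (CV% / 100).
    sigma_add : float
        Additive residual SD (mg/L).
    sigma_prop : float
        Proportional residual SD (fraction of the prediction).
    cl_law : str
        Covariate law on clearance: "none", "linear" or "power".
    clcr_ref : float
        Reference creatinine clearance for the covariate scaling (mL/s).
    iov_cl, iov_vd : float
        SDs of optional between-occasion (inter-occasion) random effects;
        zero by default — occasion effects were not supported by the data.
    """

    cl_pop: float
    vd_pop: float
    theta_clcr: float = 0.0
    omega_cl: float = 0.0
    omega_vd: float = 0.0
    sigma_add: float = 0.0
    sigma_prop: float = 0.0
    cl_law: str = "none"
    clcr_ref: float = 1.25
    iov_cl: float = 0.0
    iov_vd: float = 0.0

    def __post_init__(self) -> None:
        if not (self.cl_pop > 0):
            raise ValueError(f"cl_pop must be positive, got {self.cl_pop}")
        if not (self.vd_pop > 0):
            raise ValueError(f"vd_pop must be positive, got {self.vd_pop}")
        for name in ("omega_cl", "omega_vd", "sigma_add", "sigma_prop", "iov_cl", "iov_vd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.cl_law not in CL_LAWS:
            raise ValueError(f"cl_law must be one of {CL_LAWS}, got {self.cl_law!r}")

    @property
    def omega_cl_cv_percent(self) -> float:
        """Between-subject variability of CL reported as CV% (= 100 * omega)."""
        return 100.0 * self.omega_cl

    @property
    def omega_vd_cv_percent(self) -> float:
        return 100.0 * self.omega_vd

    def with_(self, **kwargs) -> "PopModel":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    @classmethod
    def final_estimates(cls) -> "PopModel":
        """The final covariate model: linear CLcr on CL.

        CL (L/h) = 5.4 + 16.1 * (CLcr / 1.25 mL/s), Vd = 143 L,
        omega_CL 44.9% CV, omega_Vd 34.8% CV, additive residual SD 0.981 mg/L,
        proportional residual SD 4.78%.
        """
        return cls(
            cl_pop=5.4,
            vd_pop=143.0,
            theta_clcr=16.1,
            omega_cl=0.449,
            omega_vd=0.348,
            sigma_add=0.981,
            sigma_prop=0.0478,
            cl_law="linear",
            clcr_ref=1.25,
        )


def typical_cl(model: PopModel, clcr: float) -> float:
    """Typical (population-predicted) clearance at a given CLcr (mL/s), in L/h.

    Raises a domain error if the covariate law extrapolates to a nonpositive
    clearance (inadmissible renal function for this model).
    """
    if not np.all(np.asarray(clcr) > 0):
        raise ValueError("clcr must be positive")
    x = np.asarray(clcr, dtype=float) / model.clcr_ref
    if model.cl_law == "linear":
        cl = model.cl_pop + model.theta_clcr * x
    elif model.cl_law == "power":
        cl = model.cl_pop * x**model.theta_clcr
    else:
        cl = model.cl_pop * np.ones_like(x)
    if np.any(cl <= 0):
        raise ValueError(
            f"typical clearance is nonpositive at CLcr={clcr}; "
            "covariate law does not extrapolate this far"
        )
    return float(cl) if np.isscalar(clcr) else cl
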