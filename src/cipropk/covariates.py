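"""Renal-function and body-size covariates.

Measured creatinine clearance from a timed urine collection, the four common
creatinine-based GFR estimation equations (CKD-EPI 2009, 4-variable IDMS MDRD,
Cockcroft-Gault, revised Lund-Malmö), DuBois body surface area and Boer lean
body mass.  All clearances are expressed in mL/s (mL/min divided by 60), serum
creatinine in µmol/L.

The indexed equations (CKD-EPI, MDRD, Lund-Malmö) return mL/s per 1.73 m² as
published, without BSA de-indexing; Cockcroft-Gault returns an absolute mL/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "PatientCovariates",
    "measured_clcr",
    "egfr",
    "bsa_dubois",
    "lbm_boer",
    "EGFR_FORMULAS",
]

#: µmol/L per mg/dL of creatinine
_UMOL_PER_MGDL = 88.4

EGFR_FORMULAS = ("CKD-EPI", "MDRD", "C-G", "L-M")


class MissingCovariateError(ValueError):
    """A formula requires a covariate that was not recorded."""

    def __init__(self, field: str, formula: str):
        super().__init__(f"{formula} requires covariate {field!r}, which is missing")
        self.field = field
        self.formula = formula


@dataclass
class PatientCovariates:
    """Per-occasion demographic, laboratory and clinical covariates.

    Missing values are represented as ``None`` and are never silently imputed;
    formulas that need them raise :class:`MissingCovariateError`.
    """

    sex: str  # "male" | "female"
    age: float  # years
    weight: Optional[float] = None  # kg
    height: Optional[float] = None  # cm
    serum_creatinine: Optional[float] = None  # µmol/L
    urine_creatinine: Optional[float] = None  # µmol/L
    urine_flow: Optional[float] = None  # mL/s
    clcr: Optional[float] = None  # measured creatinine clearance, mL/s
    bilirubin: Optional[float] = None  # µmol/L
    fluid_balance: Optional[float] = None  # mL/day
    norepinephrine_dose: Optional[float] = None  # mg/day
    furosemide_dose: Optional[float] = None  # mg/day
    smoker: Optional[str] = None  # "yes" | "no" | None (unknown)
    cvvhd: bool = False

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not (self.age > 0):
            raise ValueError(f"age must be positive, got {self.age}")
        for name in ("weight", "height", "serum_creatinine"):
            v = getattr(self, name)
            if v is not None and not (v > 0):
                raise ValueError(f"{name} must be positive if recorded, got {v}")


def measured_clcr(
    urine_creatinine: float, urine_flow: float, serum_creatinine: float
) -> float:
    """Measured creatinine clearance CLcr = Ucr * V / Scr (mL/s).

    ``urine_creatinine`` and ``serum_creatinine`` in µmol/L, ``urine_flow``
    (24-h urine output expressed as a rate) in mL/s.
    """
    if not (serum_creatinine > 0):
        raise ValueError("serum creatinine must be positive")
    if not (urine_creatinine > 0) or not (urine_flow > 0):
        raise ValueError("urine creatinine and urine flow must be positive")
    return urine_creatinine * urine_flow / serum_creatinine


def _require(cov: PatientCovariates, field: str, formula: str) -> float:
    v = getattr(cov, field)
    if v is None:
        raise MissingCovariateError(field, formula)
    return v


def _ckd_epi_2009(cov: PatientCovariates) -> float:
    """CKD-EPI 2009 creatinine equation, mL/min/1.73 m² (race term omitted)."""
    scr_mgdl = _require(cov, "serum_creatinine", "CKD-EPI") / _UMOL_PER_MGDL
    if cov.sex == "female":
        kappa, alpha, sex_f = 0.7, -0.329, 1.018
    else:
        kappa, alpha, sex_f = 0.9, -0.411, 1.0
    ratio = scr_mgdl / kappa
    return (
        141.0
        * min(ratio, 1.0) ** alpha
        * max(ratio, 1.0) ** -1.209
        * 0.993 ** cov.age
        * sex_f
    )


def _mdrd_4v(cov: PatientCovariates) -> float:
    """4-variable IDMS-traceable MDRD, mL/min/1.73 m²."""
    scr_mgdl = _require(cov, "serum_creatinine", "MDRD") / _UMOL_PER_MGDL
    sex_f = 0.742 if cov.sex == "female" else 1.0
    return 175.0 * scr_mgdl**-1.154 * cov.age**-0.203 * sex_f


def _cockcroft_gault(cov: PatientCovariates) -> float:
    """Cockcroft-Gault creatinine clearance, absolute mL/min (Scr in µmol/L)."""
    scr = _require(cov, "serum_creatinine", "C-G")
    weight = _require(cov, "weight", "C-G")
    sex_f = 0.85 if cov.sex == "female" else 1.0
    return (140.0 - cov.age) * weight * sex_f / (0.814 * scr)


def _lund_malmo_revised(cov: PatientCovariates) -> float:
    """Revised Lund-Malmö (2011), mL/min/1.73 m² (Scr in µmol/L)."""
    scr = _require(cov, "serum_creatinine", "L-M")
    if cov.sex == "female":
        if scr < 150:
            x = 2.50 + 0.0121 * (150.0 - scr)
        else:
            x = 2.50 - 0.926 * math.log(scr / 150.0)
    else:
        if scr < 180:
            x = 2.56 + 0.00968 * (180.0 - scr)
        else:
            x = 2.56 - 0.926 * math.log(scr / 180.0)
    return math.exp(x - 0.0158 * cov.age + 0.438 * math.log(cov.age))


_FORMULA_FUNCS = {
    "CKD-EPI": _ckd_epi_2009,
    "MDRD": _mdrd_4v,
    "C-G": _cockcroft_gault,
    "L-M": _lund_malmo_revised,
}


def egfr(formula: str, cov: PatientCovariates) -> float:
    """Estimated glomerular filtration rate / creatinine clearance in mL/s.

    ``formula`` is one of ``"CKD-EPI"`` (2009 creatinine equation),
    ``"MDRD"`` (4-variable IDMS), ``"C-G"`` (Cockcroft-Gault, needs weight) or
    ``"L-M"`` (revised Lund-Malmö).  Indexed formulas return mL/s per 1.73 m²;
    C-G returns absolute mL/s.  All are strictly decreasing in serum creatinine.
    """
    try:
        fn = _FORMULA_FUNCS[formula]
    except KeyError:
        raise ValueError(
            f"unknown formula {formula!r}; expected one of {EGFR_FORMULAS}"
        ) from None
    return fn(cov) / 60.0


def bsa_dubois(weight: float, height: float) -> float:
    """DuBois body surface area (m²): 0.007184 * W^0.425 * H^0.725 (kg, cm)."""
    if not (weight > 0 and height > 0):
        raise ValueError("weight and height must be positive")
    return 0.007184 * weight**0.425 * height**0.725


def lbm_boer(weight: float, height: float, sex: str) -> float:
    """Boer lean body mass (kg).

    male:   0.407*W + 0.267*H - 19.2
    female: 0.252*W + 0.473*H - 48.3
    """
    if not (weight > 0 and height > 0):
        raise ValueError("weight and height must be positive")
    if sex == "male":
        return 0.407 * weight + 0.267 * height - 19.2
    if sex == "female":
        return 0.252 * weight + 0.473 * height - 48.3
    raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
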