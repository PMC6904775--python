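"""Hill dose–survival model, EC50 estimation, and NMR relaxation helpers.

The survival of yeast cultures exposed to 5-FU follows a shallow sigmoid in
log dose,

    survival(d) = 100% / (1 + (d / EC50)**h),

with EC50 the half-effect dose (µM) and h > 0 the Hill exponent: survival is
100% at zero dose, 50% at d = EC50, and strictly decreasing in dose.  The
fit is a nonlinear least squares in log-dose parameter space (θ = log10 EC50,
h), with standard errors from the Jacobian and a pointwise 95% confidence
band for the fitted curve.

The NMR helper converts a Lorentzian line halfwidth Δν½ (Hz) to the
transverse relaxation time T2 = 1/(π·Δν½) — e.g. a ~17 Hz line corresponds
to T2 ≈ 20 ms, the signature of small unstructured RNA fragments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

__all__ = ["DoseResponseFit", "hill_survival", "fit_dose_response",
           "t2_from_linewidth", "linewidth_from_t2"]


def hill_survival(dose, ec50: float, hill: float):
    """Percent survival at ``dose`` (µM) under the Hill dose–survival model."""
    if ec50 <= 0:
        raise ValueError(f"EC50 must be > 0, got {ec50}")
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise ValueError("dose must be >= 0")
    out = 100.0 / (1.0 + (dose / ec50) ** hill)
    return float(out) if out.ndim == 0 else out


@dataclass
class DoseResponseFit:
    ec50: float               # µM
    hill: float
    ec50_se: float
    hill_se: float
    covariance: np.ndarray    # in (log10 EC50, hill) space
    doses: np.ndarray
    survival: np.ndarray
    residual_ss: float

    def predict(self, dose):
        return hill_survival(dose, self.ec50, self.hill)

    def confidence_band(self, dose, level: float = 0.95):
        """Pointwise confidence band (lower, upper) for the fitted curve."""
        dose = np.asarray(dose, dtype=float)
        theta = np.array([math.log10(self.ec50), self.hill])
        mid = self.predict(dose)
        # gradient of the model w.r.t. (log10 EC50, hill)
        with np.errstate(divide="ignore"):
            u = np.log(dose / self.ec50)
        frac = (dose / self.ec50) ** self.hill
        dnum = -100.0 * frac / (1.0 + frac) ** 2
        g = np.stack([dnum * (-self.hill * math.log(10.0)),
                      np.where(dose > 0, dnum * u, 0.0)], axis=-1)
        var = np.einsum("...i,ij,...j->...", g, self.covariance, g)
        dof = max(len(self.doses) - 2, 1)
        q = stats.t.ppf(0.5 + level / 2.0, dof)
        half = q * np.sqrt(np.maximum(var, 0.0))
        return np.clip(mid - half, 0.0, 100.0), np.clip(mid + half, 0.0, 100.0)


def fit_dose_response(doses, survival, *, p0=None) -> DoseResponseFit:
    """Fit the Hill dose–survival curve by nonlinear least squares.

    ``doses`` (µM, > 0) and ``survival`` (percent) are flat replicate arrays.
    Requires ≥4 distinct dose levels; data whose survival *increases* with
    dose (wrong sign, Hill ≤ 0) or is flat fail an identifiability check.
    """
    doses = np.asarray(doses, dtype=float).ravel()
    survival = np.asarray(survival, dtype=float).ravel()
    if doses.shape != survival.shape:
        raise ValueError("doses and survival must have equal length")
    if np.any(doses <= 0):
        raise ValueError("doses must be > 0 for the log-dose fit")
    if len(np.unique(doses)) < 4:
        raise ValueError("need at least 4 distinct dose levels")

    def model(logd, log_ec50, hill):
        return 100.0 / (1.0 + 10.0 ** (hill * (logd - log_ec50)))

    logd = np.log10(doses)
    if p0 is None:
        p0 = (float(np.median(logd)), 1.0)
    theta, cov = curve_fit(model, logd, survival, p0=p0, maxfev=20000)
    log_ec50, hill = theta
    if not np.all(np.isfinite(cov)):
        raise RuntimeError("fit is non-identifiable (singular covariance)")
    if hill <= 0:
        raise RuntimeError(
            f"non-identifiable or wrong-sign data: fitted Hill = {hill:.3g} <= 0 "
            "(survival does not decrease with dose)")
    ec50 = 10.0 ** log_ec50
    ec50_se = ec50 * math.log(10.0) * math.sqrt(cov[0, 0])  # delta method
    hill_se = math.sqrt(cov[1, 1])
    resid = survival - model(logd, *theta)
    return DoseResponseFit(ec50=float(ec50), hill=float(hill),
                           ec50_se=float(ec50_se), hill_se=float(hill_se),
                           covariance=cov, doses=doses, survival=survival,
                           residual_ss=float(resid @ resid))


def t2_from_linewidth(halfwidth_hz: float) -> float:
    """Transverse relaxation time T2 = 1/(π·Δν½) for a Lorentzian line (s)."""
    if halfwidth_hz <= 0:
        raise ValueError(f"halfwidth must be > 0 Hz, got {halfwidth_hz}")
    return 1.0 / (math.pi * halfwidth_hz)


def linewidth_from_t2(t2_s: float) -> float:
    """Inverse of :func:`t2_from_linewidth`: Δν½ = 1/(π·T2) (Hz)."""
    if t2_s <= 0:
        raise ValueError(f"T2 must be > 0 s, got {t2_s}")
    return 1.0 / (math.pi * t2_s)
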