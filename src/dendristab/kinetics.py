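"""Second-order aggregation kinetics, shelf-life factors and Tm-shift slopes.

Monomer loss follows the second-order rate law

    M(t) = M0 / (1 + k · M0 · t)      ⇔      1/M = 1/M0 + k·t

with k in mL·mg⁻¹·time⁻¹.  The default fit is nonlinear least squares on
M(t) (the linearized 1/M regression distorts the noise weighting at low M,
but is exposed as an option).  Derived times:

    t50 = 1/(k·M0)                      time to 50 % monomer loss
    t95 = (1/0.95 − 1)/(k·M0)           time to 5 % loss (shelf-life)

Against a no-additive reference sharing M0, the relative rate is k/k0 and
the shelf-life extension factor (SLEF) is t95/t95,0 = k0/k — an exact
algebraic identity under second-order kinetics.

Thermal-shift slopes dTm/d[c] (°C·M⁻¹) come from ordinary least squares on
(concentration, Tm) pairs within a declared linear range (default ≤ 0.2 M);
a positive slope conveys stabilization, negative destabilization.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .errors import DendristabError, KineticsDataError
from .model_io import KineticsTable


@dataclass
class KineticsFit:
    k: float  # mL·mg⁻¹·time⁻¹
    k_stderr: float
    m0: float
    method: str  # "nonlinear" | "linearized"
    residual_sd: float
    t50: float
    t95: float
    loss_fraction: float = 0.05
    time_unit: str = "min"
    label: str = ""
    converged: bool = True

    @property
    def finite(self) -> bool:
        return np.isfinite(self.t95)


@dataclass
class RateComparison:
    relative_rate: float  # k / k0
    slef: float  # t95 / t95,0
    shared_m0: bool

    def __iter__(self):
        return iter((self.relative_rate, self.slef))


@dataclass
class ThermalShiftFit:
    slope: float  # °C·M⁻¹
    intercept: float  # °C
    concentration_range: tuple  # (min, max) mol/L


def _second_order(t, k, m0):
    return m0 / (1.0 + k * m0 * t)


def loss_time(k: float, m0: float, loss_fraction: float) -> float:
    """Time for the monomer to drop to (1−f)·M0 under second-order loss."""
    if k <= 0:
        return np.inf
    return (1.0 / (1.0 - loss_fraction) - 1.0) / (k * m0)


def fit_second_order(
    table: KineticsTable,
    method: str = "nonlinear",
    loss_fraction: float = 0.05,
) -> KineticsFit:
    """Fit the second-order rate constant of a monomer-loss table.

    ``method="nonlinear"`` (default): least squares on M(t) with k ≥ 0.
    ``method="linearized"``: ordinary regression of 1/M on t.
    """
    if len(table.times) < 3:
        raise KineticsDataError("fits need at least 3 points")
    t = table.times
    m = table.monomer
    m0 = table.m0
    if np.all(np.diff(m) >= 0) and m[-1] > m[0]:
        warnings.warn(
            "monomer series is increasing; second-order loss does not apply "
            "(k will be ~0)",
            stacklevel=2,
        )
    if method == "nonlinear":
        # linearized slope as the starting point; a non-positive slope means
        # the series carries no second-order loss signal at all -> k = 0
        slope0 = np.polyfit(t, 1.0 / m, 1)[0]
        if slope0 <= 0:
            resid = m - m0
            dof = max(len(t) - 1, 1)
            return KineticsFit(
                k=0.0,
                k_stderr=np.nan,
                m0=m0,
                method=method,
                residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
                t50=np.inf,
                t95=np.inf,
                loss_fraction=loss_fraction,
                time_unit=table.time_unit,
                label=table.label,
            )
        try:
            popt, pcov = curve_fit(
                lambda tt, k: _second_order(tt, k, m0),
                t,
                m,
                p0=[slope0],
                bounds=(0.0, np.inf),
                maxfev=10000,
            )
        except RuntimeError as exc:
            raise DendristabError(
                f"nonlinear second-order fit did not converge: {exc}"
            ) from exc
        k = float(popt[0])
        k_stderr = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.nan
        resid = m - _second_order(t, k, m0)
    elif method == "linearized":
        slope, intercept = np.polyfit(t, 1.0 / m, 1)
        k = float(max(slope, 0.0))
        pred = 1.0 / (intercept + slope * t)
        resid = m - pred
        n = len(t)
        if n > 2:
            sxx = np.sum((t - t.mean()) ** 2)
            s2 = np.sum((1.0 / m - (intercept + slope * t)) ** 2) / (n - 2)
            k_stderr = float(np.sqrt(s2 / sxx))
        else:
            k_stderr = np.nan
    else:
        raise ValueError("method must be 'nonlinear' or 'linearized'")
    dof = max(len(t) - 1, 1)
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof))
    return KineticsFit(
        k=k,
        k_stderr=k_stderr,
        m0=m0,
        method=method,
        residual_sd=residual_sd,
        t50=loss_time(k, m0, 0.5),
        t95=loss_time(k, m0, loss_fraction),
        loss_fraction=loss_fraction,
        time_unit=table.time_unit,
        label=table.label,
    )


def compare_to_reference(fit: KineticsFit, reference_fit: KineticsFit) -> RateComparison:
    """Relative rate k/k0 and shelf-life extension factor t95/t95,0.

    With a shared M0 the SLEF equals k0/k exactly; otherwise it is computed
    from the two t95 values directly and flagged via ``shared_m0=False``.
    """
    if reference_fit.k <= 0:
        raise DendristabError("reference rate constant k0 is zero; ratios undefined")
    relative_rate = fit.k / reference_fit.k
    shared = np.isclose(fit.m0, reference_fit.m0)
    if shared:
        slef = reference_fit.k / fit.k if fit.k > 0 else np.inf
    else:
        slef = fit.t95 / reference_fit.t95
    return RateComparison(
        relative_rate=float(relative_rate), slef=float(slef), shared_m0=bool(shared)
    )


def fit_tm_slope(
    concs, tms, linear_max: float = 0.2
) -> ThermalShiftFit:
    """dTm/d[additive] slope (°C·M⁻¹) by ordinary least squares.

    Concentrations are mol/L and must lie within the declared linear range
    (default ≤ 0.2 M, where the Tm response is linear).
    """
    concs = np.asarray(concs, float)
    tms = np.asarray(tms, float)
    if concs.shape != tms.shape:
        raise KineticsDataError("concentration and Tm arrays differ in length")
    if len(np.unique(concs)) < 2:
        raise KineticsDataError("need at least 2 distinct concentrations")
    if np.any(concs > linear_max + 1e-12):
        raise KineticsDataError(
            f"concentrations above the declared linear range ({linear_max} M)"
        )
    slope, intercept = np.polyfit(concs, tms, 1)
    return ThermalShiftFit(
        slope=float(slope),
        intercept=float(intercept),
        concentration_range=(float(concs.min()), float(concs.max())),
    )
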