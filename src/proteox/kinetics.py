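"""Colorimetric pNPP phosphatase assay analysis.

Absorbance at 405 nm is converted to p-nitrophenolate concentration with
Beer-Lambert, using the extinction coefficient 17.8 mM^-1 cm^-1 and a path
length computed from the well geometry (liquid column height = volume over
well cross-section).  Initial velocities are the slope of the most linear
contiguous window of each progress curve; velocities across a substrate
series are fit to the Michaelis-Menten equation v = Vmax*S/(Km+S) by
nonlinear least squares, with 95% confidence intervals from the linearized
covariance and kcat = Vmax/[E].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "BeerLambertConfig",
    "KineticFit",
    "path_length",
    "absorbance_to_concentration",
    "initial_velocity",
    "fit_michaelis_menten",
    "compare_kinetics",
]


@dataclass(frozen=True)
class BeerLambertConfig:
    """Extinction coefficient and well geometry for A405 conversion."""

    epsilon_mM_cm: float = 17.8
    well_radius_mm: float = 4.0
    well_volume_ul: float = 100.0

    def __post_init__(self):
        if min(self.epsilon_mM_cm, self.well_radius_mm, self.well_volume_ul) <= 0:
            raise ValueError("all Beer-Lambert parameters must be positive")

    @property
    def path_cm(self) -> float:
        return path_length(self.well_volume_ul, self.well_radius_mm)


def path_length(volume_ul: float, radius_mm: float) -> float:
    """Liquid column height in cm: volume / (pi * r^2), unit-consistent.

    100 ul in a 4 mm-radius well gives 0.1 cm^3 / (pi * 0.16 cm^2) = 0.199 cm.
    """
    if volume_ul <= 0 or radius_mm <= 0:
        raise ValueError("volume and radius must be positive")
    volume_cm3 = volume_ul / 1000.0
    radius_cm = radius_mm / 10.0
    return volume_cm3 / (np.pi * radius_cm**2)


def absorbance_to_concentration(a405, config: BeerLambertConfig = BeerLambertConfig()):
    """Convert an A405 series to product concentration in mM (c = A/(eps*l)).

    Negative absorbances are clipped to zero with a warning.
    """
    a = np.asarray(a405, float)
    if np.any(a < 0):
        warnings.warn("negative absorbance values clipped to 0")
        a = np.clip(a, 0.0, None)
    return a / (config.epsilon_mM_cm * config.path_cm)


@dataclass(frozen=True)
class VelocityEstimate:
    slope_mM_min: float
    window: tuple[int, int]  # start index, stop index (exclusive)
    r_squared: float
    full_curve_fallback: bool = False


def _safe_linregress(t, c):
    res = stats.linregress(t, c)
    r2 = res.rvalue**2
    if not np.isfinite(r2):  # zero-variance segment
        return (0.0, 1.0) if np.allclose(c, c[0]) else (res.slope, 0.0)
    return res.slope, r2


def initial_velocity(
    times_min,
    conc_mM,
    min_window: int = 5,
    method: str = "tangent",
    return_details: bool = False,
):
    """Initial velocity (mM/min) from the most linear portion of the curve.

    ``method="tangent"`` (default): the window grows from the first time
    point and the length with the highest linear-fit R^2 wins; the reported
    velocity is the tangent at the window start from a quadratic fit over
    that window, which cancels the first-order slope decay that substrate
    depletion introduces even inside a visually linear segment.

    ``method="window"``: the plain slope of the max-R^2 contiguous window of
    at least ``min_window`` points anywhere in the curve (earliest on ties).

    With fewer points than ``min_window`` the full-curve slope is returned
    with a warning.  Both methods are invariant to a constant absorbance
    offset.  The chosen window and its R^2 are available via
    ``return_details``.
    """
    if method not in ("tangent", "window"):
        raise ValueError("method must be 'tangent' or 'window'")
    t = np.asarray(times_min, float)
    c = np.asarray(conc_mM, float)
    n = len(t)
    if n < 2:
        raise ValueError("need at least 2 time points")
    if n < min_window:
        warnings.warn("fewer points than the window; using the full-curve slope")
        slope, r2 = _safe_linregress(t, c)
        est = VelocityEstimate(slope, (0, n), r2, True)
        return est if return_details else est.slope_mM_min
    best = None
    if method == "tangent":
        for size in range(min_window, n + 1):
            slope, r2 = _safe_linregress(t[:size], c[:size])
            if best is None or r2 > best.r_squared + 1e-12:
                best = VelocityEstimate(slope, (0, size), r2)
        start, stop = best.window
        if stop - start >= 4:
            coeffs = np.polyfit(t[start:stop] - t[start], c[start:stop], 2)
            best = VelocityEstimate(float(coeffs[1]), best.window, best.r_squared)
    else:
        for size in range(min_window, n + 1):
            for start in range(0, n - size + 1):
                slope, r2 = _safe_linregress(t[start : start + size], c[start : start + size])
                if best is None or r2 > best.r_squared + 1e-12:
                    best = VelocityEstimate(slope, (start, start + size), r2)
    return best if return_details else best.slope_mM_min


@dataclass(frozen=True)
class KineticFit:
    """Michaelis-Menten parameters with 95% confidence intervals."""

    Km_mM: float
    Vmax_mM_min: float
    kcat_min: float
    enzyme_uM: float
    Km_ci: tuple[float, float]
    Vmax_ci: tuple[float, float]
    velocities: dict = field(default_factory=dict)  # S mM -> v0 mM/min
    residuals: np.ndarray | None = None


def _mm(s, vmax, km):
    return vmax * s / (km + s)


def fit_michaelis_menten(
    v0_mM_min, substrate_mM, enzyme_uM: float = 2.1
) -> KineticFit:
    """Nonlinear least-squares fit of v = Vmax*S/(Km+S).

    95% CIs use the linearized (delta-method) covariance with a t critical
    value; kcat = Vmax/[E] in min^-1 (default [E] 2.1 uM).
    """
    v = np.asarray(v0_mM_min, float)
    s = np.asarray(substrate_mM, float)
    if len(np.unique(s)) < 3:
        raise ValueError("need at least 3 distinct substrate concentrations")
    if np.allclose(v, 0.0):
        raise RuntimeError("all velocities are zero; Michaelis-Menten fit is degenerate")
    p0 = (max(v.max(), 1e-12), np.median(s))
    try:
        popt, pcov = optimize.curve_fit(_mm, s, v, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(
            f"Michaelis-Menten fit did not converge (start values {p0}): {exc}"
        ) from exc
    vmax, km = popt
    resid = v - _mm(s, *popt)
    dof = max(len(v) - 2, 1)
    tcrit = stats.t.ppf(0.975, dof)
    se = np.sqrt(np.diag(pcov))
    if km <= 0 or vmax <= 0:
        warnings.warn("fit returned a non-positive parameter; data may be saturating")
    # kcat: Vmax [mM/min] over [E] [uM] = [E]*1e-3 mM
    kcat = vmax / (enzyme_uM * 1e-3)
    return KineticFit(
        Km_mM=float(km),
        Vmax_mM_min=float(vmax),
        kcat_min=float(kcat),
        enzyme_uM=enzyme_uM,
        Km_ci=(float(km - tcrit * se[1]), float(km + tcrit * se[1])),
        Vmax_ci=(float(vmax - tcrit * se[0]), float(vmax + tcrit * se[0])),
        velocities={float(si): float(vi) for si, vi in zip(s, v)},
        residuals=resid,
    )


@dataclass(frozen=True)
class KineticComparison:
    """Fold changes between two fits, both orientations, with CI overlap flags."""

    Km_fold_a_over_b: float
    Vmax_fold_a_over_b: float
    kcat_fold_a_over_b: float
    Km_fold_b_over_a: float
    Vmax_fold_b_over_a: float
    kcat_fold_b_over_a: float
    Km_fold_ci: tuple[float, float]  # a/b, relative errors combined in quadrature
    Vmax_fold_ci: tuple[float, float]
    Km_ci_overlap: bool
    Vmax_ci_overlap: bool


def _fold_ci(a, a_ci, b, b_ci) -> tuple[float, float]:
    fold = a / b
    rel = np.sqrt(((a_ci[1] - a_ci[0]) / (2 * a)) ** 2 + ((b_ci[1] - b_ci[0]) / (2 * b)) ** 2)
    return (fold * (1 - rel), fold * (1 + rel))


def compare_kinetics(fit_a: KineticFit, fit_b: KineticFit) -> KineticComparison:
    """Fold changes (a/b and b/a) for Km, Vmax and kcat with propagated CIs."""
    overlap = lambda x, y: not (x[1] < y[0] or y[1] < x[0])
    return KineticComparison(
        Km_fold_a_over_b=fit_a.Km_mM / fit_b.Km_mM,
        Vmax_fold_a_over_b=fit_a.Vmax_mM_min / fit_b.Vmax_mM_min,
        kcat_fold_a_over_b=fit_a.kcat_min / fit_b.kcat_min,
        Km_fold_b_over_a=fit_b.Km_mM / fit_a.Km_mM,
        Vmax_fold_b_over_a=fit_b.Vmax_mM_min / fit_a.Vmax_mM_min,
        kcat_fold_b_over_a=fit_b.kcat_min / fit_a.kcat_min,
        Km_fold_ci=_fold_ci(fit_a.Km_mM, fit_a.Km_ci, fit_b.Km_mM, fit_b.Km_ci),
        Vmax_fold_ci=_fold_ci(fit_a.Vmax_mM_min, fit_a.Vmax_ci, fit_b.Vmax_mM_min, fit_b.Vmax_ci),
        Km_ci_overlap=overlap(fit_a.Km_ci, fit_b.Km_ci),
        Vmax_ci_overlap=overlap(fit_a.Vmax_ci, fit_b.Vmax_ci),
    )
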