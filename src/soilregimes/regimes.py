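"""Functional-regime classification, regime boundaries, and titration curves.

Fitted conditions are classified on the (x~0, gamma*C~0) plane into three
regimes of nitrate utilization:

* Regime I, acidic death — little functional biomass and little nutrient;
* Regime II, nutrient-limiting — large pre-existing biomass (x~0 >= 0.05
  mM/day), dynamics linear after early growth;
* Regime III, resurgent growth — small biomass but abundant nutrient
  (gamma*C~0 >= 1.5 mM/day), exponential takeoff of initially rare taxa.

Per-soil regime boundaries are located as midpoints between the adjacent
perturbed-pH conditions on either side of a label change, with the grid gap
as the uncertainty, and their trend against native pH is a weighted
least-squares line (weights 1/error).  Titration curves (endpoint pH vs
acid/base dose) are interpolated with a shape-preserving monotone spline so
that the dose required for a target pH is well defined.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq
from scipy.stats import linregress

__all__ = [
    "RegimeLabel",
    "BoundaryEstimate",
    "TitrationCurve",
    "TitrationInterpolator",
    "UnreachablePHError",
    "classify_regime",
    "regime_boundaries_per_soil",
    "boundary_trend_fit",
    "titration_interpolate",
    "rate_fold",
    "rate_fold_collapse",
    "DEFAULT_THRESHOLDS",
]

#: Regime thresholds: x~0 (mM/day) separating Regime II from I/III, and
#: gamma*C~0 (mM/day) separating Regime III from I at small x~0.
DEFAULT_THRESHOLDS: Dict[str, float] = {"x": 0.05, "c": 1.5}


class UnreachablePHError(ValueError):
    """Target pH lies outside what the titration curve can reach."""


@dataclass(frozen=True)
class RegimeLabel:
    regime: str  # "I", "II" or "III"
    x0_tilde: float
    gammaC0_tilde: float
    thresholds: Tuple[float, float]  # (x threshold, c threshold)


def classify_regime(
    x0_tilde: float,
    gammaC0_tilde: float,
    thresholds: Optional[Dict[str, float]] = None,
) -> RegimeLabel:
    """Assign a functional regime from the two fitted rate parameters.

    Regime II whenever x~0 >= threshold (the biomass test takes precedence,
    so high-biomass high-nutrient conditions are II); otherwise Regime III
    if gamma*C~0 >= threshold, else Regime I.  Exact ties go to the
    higher-activity regime.
    """
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    if not (np.isfinite(x0_tilde) and np.isfinite(gammaC0_tilde)):
        raise ValueError("regime classification requires finite inputs")
    if x0_tilde < 0 or gammaC0_tilde < 0:
        raise ValueError("regime classification requires non-negative inputs")
    if x0_tilde >= th["x"]:
        regime = "II"
    elif gammaC0_tilde >= th["c"]:
        regime = "III"
    else:
        regime = "I"
    return RegimeLabel(regime, x0_tilde, gammaC0_tilde, (th["x"], th["c"]))


@dataclass
class BoundaryEstimate:
    """Per-soil regime-transition pH estimates (NaN when absent)."""

    soil_id: str
    native_ph: float
    boundary_I_II_ph: float = float("nan")
    boundary_I_II_err: float = float("nan")
    boundary_II_III_ph: float = float("nan")
    boundary_II_III_err: float = float("nan")


def _first_transition(
    ph: np.ndarray, labels: Sequence[str], lo: str, hi: str
) -> Tuple[float, float]:
    """Midpoint between the first adjacent (lo, hi) label pair.

    Returns (midpoint pH, pH gap between the two conditions) or NaNs.
    """
    for i in range(len(labels) - 1):
        if labels[i] == lo and labels[i + 1] == hi:
            return (0.5 * (ph[i] + ph[i + 1]), ph[i + 1] - ph[i])
    return (float("nan"), float("nan"))


def regime_boundaries_per_soil(
    perturbed_ph: Sequence[float],
    labels: Sequence[str],
    soil_id: str = "",
    native_ph: float = float("nan"),
) -> BoundaryEstimate:
    """Locate the I->II and II->III transitions along the perturbed-pH axis.

    Expects labels ordered by ascending perturbed pH (the canonical pattern
    is I* II* III*).  A non-monotone label sequence triggers a warning and
    the first transition of each kind is used.  A transition that does not
    occur yields NaN.
    """
    ph = np.asarray(perturbed_ph, dtype=float)
    if np.any(np.diff(ph) <= 0):
        order = np.argsort(ph)
        ph = ph[order]
        labels = [labels[i] for i in order]
    labels = list(labels)

    # canonical sequence check: each regime should occupy one contiguous block
    order_key = {"I": 0, "II": 1, "III": 2}
    codes = [order_key[l] for l in labels]
    if any(codes[i + 1] < codes[i] for i in range(len(codes) - 1)):
        warnings.warn(
            f"non-monotone regime sequence for soil {soil_id!r}; "
            "using the first transition of each kind",
            stacklevel=2,
        )
    b12, e12 = _first_transition(ph, labels, "I", "II")
    b23, e23 = _first_transition(ph, labels, "II", "III")
    return BoundaryEstimate(
        soil_id=soil_id,
        native_ph=native_ph,
        boundary_I_II_ph=b12,
        boundary_I_II_err=e12,
        boundary_II_III_ph=b23,
        boundary_II_III_err=e23,
    )


@dataclass
class TrendFit:
    slope: float
    intercept: float
    slope_ci: Tuple[float, float]  # 95% confidence interval on the slope
    slope_se: float
    n: int
    equal_weights: bool = False


def boundary_trend_fit(
    native_ph: Sequence[float],
    boundary_ph: Sequence[float],
    errors: Optional[Sequence[float]] = None,
) -> TrendFit:
    """Weighted least squares of boundary pH on native pH (weights 1/error).

    NaN boundaries are dropped.  With fewer than 3 defined points the fit is
    rejected, except exactly 2 points which interpolate exactly but are
    flagged with an infinite-width confidence interval.
    """
    x = np.asarray(native_ph, dtype=float)
    y = np.asarray(boundary_ph, dtype=float)
    if errors is None:
        e = np.ones_like(y)
    else:
        e = np.asarray(errors, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y, e = x[keep], y[keep], e[keep]
    if x.size < 2:
        raise ValueError("need at least 2 soils with a defined boundary")
    if x.size == 2:
        slope = (y[1] - y[0]) / (x[1] - x[0])
        return TrendFit(
            slope=float(slope),
            intercept=float(y[0] - slope * x[0]),
            slope_ci=(-math.inf, math.inf),
            slope_se=math.inf,
            n=2,
        )
    equal = False
    if np.any(e <= 0) or np.all(~np.isfinite(e)):
        warnings.warn("non-positive boundary errors; falling back to equal weights",
                      stacklevel=2)
        w = np.ones_like(e)
        equal = True
    else:
        w = 1.0 / e
    res = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    ci = res.conf_int(alpha=0.05)
    return TrendFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        slope_se=float(res.bse[1]),
        n=int(x.size),
        equal_weights=equal,
    )


@dataclass
class TitrationCurve:
    """Endpoint slurry pH vs signed acid/base dose for one soil.

    ``dose_mM`` is negative for HCl and positive for NaOH; ``endpoint_ph``
    must be non-decreasing in dose.
    """

    dose_mM: np.ndarray
    endpoint_ph: np.ndarray
    soil_id: str = ""
    native_ph: float = float("nan")

    def __post_init__(self) -> None:
        self.dose_mM = np.asarray(self.dose_mM, dtype=float)
        self.endpoint_ph = np.asarray(self.endpoint_ph, dtype=float)
        order = np.argsort(self.dose_mM)
        self.dose_mM = self.dose_mM[order]
        self.endpoint_ph = self.endpoint_ph[order]
        if self.dose_mM.size < 5:
            raise ValueError("titration curve needs at least 5 dose points")
        if np.any(np.diff(self.endpoint_ph) < 0):
            raise ValueError("endpoint pH must be non-decreasing in dose")


class TitrationInterpolator:
    """Monotone (shape-preserving) interpolant of a titration curve.

    A PCHIP spline preserves the monotonicity of the data, which guarantees
    the inverse map dose(pH) is well defined — an unconstrained cubic spline
    can overshoot and lose invertibility near the buffering plateaus.
    """

    def __init__(self, curve: TitrationCurve):
        self.curve = curve
        # collapse exactly-flat runs minimally for strictness of the inverse
        self._interp = PchipInterpolator(curve.dose_mM, curve.endpoint_ph, extrapolate=False)
        self.ph_range = (float(curve.endpoint_ph[0]), float(curve.endpoint_ph[-1]))
        self.dose_range = (float(curve.dose_mM[0]), float(curve.dose_mM[-1]))

    def ph(self, dose: float) -> float:
        """Endpoint pH after adding ``dose`` mM of base (negative = acid)."""
        lo, hi = self.dose_range
        if dose < lo or dose > hi:
            raise ValueError(f"dose {dose} outside titrated range [{lo}, {hi}]")
        return float(self._interp(dose))

    def dose(self, target_ph: float, tol: float = 0.01) -> float:
        """Dose (mM) achieving ``target_ph`` within ``tol`` pH units."""
        lo, hi = self.ph_range
        if not (lo - tol <= target_ph <= hi + tol):
            raise UnreachablePHError(
                f"target pH {target_ph} unreachable for soil "
                f"{self.curve.soil_id!r} (range {lo:.2f}-{hi:.2f})"
            )
        target = float(np.clip(target_ph, lo, hi))
        f = lambda d: float(self._interp(d)) - target
        d_lo, d_hi = self.dose_range
        if f(d_lo) >= 0:
            return d_lo
        if f(d_hi) <= 0:
            return d_hi
        return float(brentq(f, d_lo, d_hi, xtol=1e-9))

    def dose_table(
        self, native_ph: Optional[float] = None, n_levels: int = 13,
        ph_min: float = 3.0, ph_max: float = 9.0,
    ) -> pd.DataFrame:
        """Doses for the standard perturbation design.

        ``n_levels`` target pH values evenly spaced over [ph_min, ph_max],
        with the level closest to the native pH replaced by the native pH
        itself (dose exactly 0).  Unreachable targets get NaN doses and are
        flagged, mirroring strongly buffered soils whose full range cannot
        be titrated.
        """
        if native_ph is None:
            native_ph = self.curve.native_ph
        targets = np.linspace(ph_min, ph_max, n_levels)
        if np.isfinite(native_ph):
            targets[int(np.argmin(np.abs(targets - native_ph)))] = native_ph
        rows = []
        for t in targets:
            try:
                d = 0.0 if (np.isfinite(native_ph) and t == native_ph) else self.dose(t)
                rows.append({"target_ph": t, "dose_mM": d, "reachable": True})
            except UnreachablePHError:
                rows.append({"target_ph": t, "dose_mM": float("nan"), "reachable": False})
        out = pd.DataFrame(rows)
        if not out["reachable"].all():
            warnings.warn(
                f"{(~out['reachable']).sum()} target pH levels unreachable for "
                f"soil {self.curve.soil_id!r}", stacklevel=2,
            )
        return out


def titration_interpolate(curve: TitrationCurve) -> TitrationInterpolator:
    """Build the monotone pH(dose) interpolant and its inverse for one soil."""
    return TitrationInterpolator(curve)


def rate_fold(x0_tilde: np.ndarray, gammaC0_tilde: np.ndarray) -> np.ndarray:
    """Model-derived nitrate-rate fold change: late CHL- rate over CHL+ rate.

    The CHL+ (no-growth) rate is x~0 and the late CHL- rate is
    x~0 + gamma*C~0, so the fold is 1 + gamma*C~0 / x~0.
    """
    x0 = np.asarray(x0_tilde, dtype=float)
    gc = np.asarray(gammaC0_tilde, dtype=float)
    return (x0 + gc) / x0


@dataclass
class CollapseFit:
    slope: float
    intercept: float
    r_squared: float
    n: int


def rate_fold_collapse(
    fits: pd.DataFrame,
    dose_col: str = "naoh_mM",
    regime_col: str = "regime",
    max_dose: float = 25.0,
    folds: Optional[np.ndarray] = None,
) -> CollapseFit:
    """Linear fit of rate fold-change vs NaOH dose across Regime II conditions.

    ``fits`` needs columns x0_tilde, gammaC0_tilde, the NaOH dose (mM, base
    additions positive) and the regime label; only Regime II points with
    dose in [0, ``max_dose``] enter the fit.  ``folds`` may supply
    measurement-derived fold changes instead of the model-derived default.
    """
    df = fits.copy()
    if folds is None:
        df["fold"] = rate_fold(df["x0_tilde"].to_numpy(), df["gammaC0_tilde"].to_numpy())
    else:
        df["fold"] = np.asarray(folds, dtype=float)
    sel = (df[regime_col] == "II") & (df[dose_col] >= 0) & (df[dose_col] <= max_dose)
    df = df[sel]
    if len(df) < 3:
        raise ValueError(f"need at least 3 Regime II points with dose in [0, {max_dose}]")
    res = linregress(df[dose_col].to_numpy(), df["fold"].to_numpy())
    return CollapseFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=len(df),
    )
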