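"""Water-status physiology and the fitted models linking sensors to midday stem
water potential.

The quantities modelled
-----------------------

Midday stem water potential (psi_stem, MPa, negative) is the reference index
of tree water status in anisohydric stone fruit.  Four model forms connect it
to spot physiology and to the continuous-sensor features:

* multilinear:  psi_stem = b0 + b1*psi_leaf + b2*gs + b3*VPD  (OLS);
* Lorentzian peak:  MAX_RGR = a / {1 + [(psi - c)/w]^2}  — nocturnal maximum
  fruit growth rate peaks at a mild deficit (the curve's centre c) and decays
  toward zero under severe deficit;
* linear:  MIN_RPCR = b0 + b1*psi — the strongest instantaneous leaf
  rehydration rate scales with deficit;
* expo-linear:  RSD_RGR/RSD_RPCR = k0 + k1*exp(k2*psi) + k3*psi — the
  nocturnal fruit-to-leaf variability ratio is linear at mild deficit and
  turns exponential under severe deficit.  The psi at which the exponential
  term first contributes a set fraction (default 1%) of the
  constant-plus-linear magnitude defines an operational water-deficit
  threshold for irrigation scheduling.

Each Model class is constructed from data and ``fit()`` returns a Results
object carrying named parameters, standard errors, confidence intervals,
R-squared, residual SE and a ``summary()`` table.  Reference parameter sets
from a published field calibration on deficit-irrigated nectarine are provided
for closed-form evaluation without refitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
import statsmodels.api as sm

from .exceptions import FitError, ValidationError

# ---------------------------------------------------------------------------
# Reference parameter sets (published field calibration, printed coefficients)
# ---------------------------------------------------------------------------

#: psi_stem = b0 + b1*psi_leaf + b2*gs + b3*VPD (MPa; gs in mmol m-2 s-1, VPD kPa)
REFERENCE_STEM_WP_COEFS = {"intercept": -0.311, "psi_leaf": 0.882, "gs": 0.004, "vpd": 0.077}

#: MAX_RGR = amplitude / {1 + [(psi - center)/width]^2} (per 15-min interval)
REFERENCE_PEAK_PARAMS = {"amplitude": 0.04, "center": -1.56, "width": 0.57}

#: MIN_RPCR = intercept + slope * psi_stem
REFERENCE_MIN_RPCR_COEFS = {"intercept": -0.70, "slope": 0.55}

#: nocturnal RSD_RGR/RSD_RPCR = k0 + k1*exp(k2*psi) + k3*psi
REFERENCE_EXPOLINEAR_PARAMS = {"k0": -0.07, "k1": 2.88e-7, "k2": -3.89, "k3": -0.12}


# ---------------------------------------------------------------------------
# Physiology primitives
# ---------------------------------------------------------------------------


def compute_rwc(fresh_weight, turgid_weight, dry_weight):
    """Leaf relative water content, %: 100 * (FW - DW) / (TW - DW).

    100% at full turgor (FW = TW), 0% at oven dryness (FW = DW).
    """
    fw = np.asarray(fresh_weight, dtype=float)
    tw = np.asarray(turgid_weight, dtype=float)
    dw = np.asarray(dry_weight, dtype=float)
    if np.any(dw <= 0):
        raise ValidationError("dry weight must be positive")
    if np.any(tw <= dw):
        raise ValidationError("turgid weight must exceed dry weight")
    rwc = 100.0 * (fw - dw) / (tw - dw)
    return rwc if rwc.ndim else float(rwc)


def correlate(x, y):
    """Pearson correlation: returns (r, two-sided p, n) on paired finite values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < 3:
        raise ValidationError(f"need >= 3 paired observations, got {len(x)}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance in one of the series")
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p), int(len(x))


def pair_spot_to_sensor(
    spots: pd.DataFrame,
    sensor_values: pd.Series,
    column: str = "sensor_value",
    max_gap: str | pd.Timedelta = "30min",
) -> pd.DataFrame:
    """Pair spot measurements with the nearest 15-min sensor value.

    Spot rows whose nearest sensor timestamp is further than ``max_gap``
    (default 30 min, spot curves being at 3-h intervals) remain unmatched
    (NaN).
    """
    spots = spots.sort_values("timestamp")
    sensor = sensor_values.dropna().rename(column).to_frame()
    merged = pd.merge_asof(
        spots,
        sensor,
        left_on="timestamp",
        right_index=True,
        direction="nearest",
        tolerance=pd.Timedelta(max_gap),
    )
    return merged


# ---------------------------------------------------------------------------
# Curve forms (closed-form evaluation)
# ---------------------------------------------------------------------------


def multilinear_predict(coefs: dict, psi_leaf, gs, vpd):
    """Evaluate the multilinear stem-water-potential form at given predictors."""
    return (
        coefs["intercept"]
        + coefs["psi_leaf"] * np.asarray(psi_leaf, dtype=float)
        + coefs["gs"] * np.asarray(gs, dtype=float)
        + coefs["vpd"] * np.asarray(vpd, dtype=float)
    )


def peak_curve(x, amplitude, center, width):
    """Lorentzian peak y = amplitude / {1 + [(x - center)/width]^2}.

    Even about ``center``, where it attains its maximum ``amplitude``.
    """
    x = np.asarray(x, dtype=float)
    return amplitude / (1.0 + ((x - center) / width) ** 2)


def linear_curve(x, intercept, slope):
    return intercept + slope * np.asarray(x, dtype=float)


def expolinear_curve(x, k0, k1, k2, k3):
    """Expo-linear y = k0 + k1*exp(k2*x) + k3*x."""
    x = np.asarray(x, dtype=float)
    return k0 + k1 * np.exp(k2 * x) + k3 * x


# ---------------------------------------------------------------------------
# Threshold detection and inversion
# ---------------------------------------------------------------------------


@dataclass
class ThresholdResult:
    """Water-deficit threshold detected on a fitted expo-linear model."""

    psi_threshold: float | None
    criterion: str
    fraction: float
    params: dict
    flag: str = ""


def detect_threshold(
    params: dict,
    fraction: float = 0.01,
    search_range: tuple[float, float] = (-10.0, 1.0),
    xtol: float = 1e-6,
) -> ThresholdResult:
    """Stem water potential where the exponential term becomes non-negligible.

    Solves k1*exp(k2*psi) = fraction * |k0 + k3*psi| for the most negative
    root in ``search_range`` — the deficit level below which the exponential
    component permanently exceeds the stated fraction of the
    constant-plus-linear magnitude.  Root located by Brent's method to
    ``xtol`` MPa.  Requires k1 > 0 and k2 < 0 (a deficit-amplified
    exponential); k1 = 0 yields a null threshold (purely linear model).
    """
    k0, k1, k2, k3 = params["k0"], params["k1"], params["k2"], params["k3"]
    criterion = "exponential contribution = fraction * |constant + linear|"
    if k1 == 0:
        return ThresholdResult(None, criterion, fraction, dict(params), flag="purely_linear")
    if k1 < 0 or k2 >= 0:
        raise ValidationError("threshold criterion requires k1 > 0 and k2 < 0")

    def gap(psi):
        return k1 * np.exp(k2 * psi) - fraction * abs(k0 + k3 * psi)

    lo, hi = search_range
    grid = np.linspace(lo, hi, 4001)
    values = np.array([gap(p) for p in grid])
    # scan upward from the most negative psi (where the exponential dominates)
    # for the first sign change: its root is the onset of linear behaviour.
    sign_change = np.flatnonzero(np.sign(values[:-1]) != np.sign(values[1:]))
    if values[0] <= 0 or sign_change.size == 0:
        return ThresholdResult(None, criterion, fraction, dict(params), flag="no_root_in_range")
    i = sign_change[0]
    root = scipy.optimize.brentq(gap, grid[i], grid[i + 1], xtol=xtol)
    return ThresholdResult(float(root), criterion, fraction, dict(params))


def invert_expolinear(
    ratio: float,
    params: dict,
    psi_range: tuple[float, float] = (-3.6, -0.8),
    xtol: float = 1e-6,
) -> tuple[float, str]:
    """Estimate psi_stem from an observed nocturnal RSD ratio by inverting the
    expo-linear form over its calibration range.

    Returns ``(psi, flag)``; out-of-range ratios are clamped to the nearer
    range endpoint and flagged.  The form must be monotonic over the range.
    """
    lo, hi = psi_range
    grid = np.linspace(lo, hi, 513)
    values = expolinear_curve(grid, **params)
    diffs = np.diff(values)
    if not (np.all(diffs <= 0) or np.all(diffs >= 0)):
        raise ValidationError("expo-linear form is not monotonic over the inversion range")
    y_lo, y_hi = float(values[0]), float(values[-1])
    y_min, y_max = min(y_lo, y_hi), max(y_lo, y_hi)
    if ratio < y_min or ratio > y_max:
        clamped = lo if abs(ratio - y_lo) <= abs(ratio - y_hi) else hi
        return float(clamped), "out_of_range"
    root = scipy.optimize.brentq(lambda p: expolinear_curve(p, **params) - ratio, lo, hi, xtol=xtol)
    return float(root), ""


# ---------------------------------------------------------------------------
# Results containers
# ---------------------------------------------------------------------------


class NonlinearResults:
    """Nonlinear least-squares results: named params, linearised SEs, diagnostics."""

    def __init__(self, model, params: pd.Series, cov: pd.DataFrame, y, yhat, message: str = ""):
        self.model = model
        self.params = params
        self.cov_params = cov
        self.nobs = int(len(y))
        resid = np.asarray(y, dtype=float) - np.asarray(yhat, dtype=float)
        self.df_resid = self.nobs - len(params)
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((y - np.mean(y)) ** 2))
        self.rsquared = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        self.residual_se = float(np.sqrt(ss_res / self.df_resid)) if self.df_resid > 0 else np.nan
        self.message = message
        self.resid = resid

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params.to_numpy())), index=self.params.index)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        t = scipy.stats.t.ppf(1.0 - alpha / 2.0, self.df_resid)
        return pd.DataFrame(
            {"lower": self.params - t * self.bse, "upper": self.params + t * self.bse}
        )

    def predict(self, x):
        return self.model.curve(np.asarray(x, dtype=float), *self.params.to_numpy())

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            f"{type(self.model).__name__} fit  (n = {self.nobs})",
            f"R-squared = {self.rsquared:.4f}   residual SE = {self.residual_se:.4g}",
            f"{'param':>12} {'estimate':>12} {'std err':>10} {'[0.025':>10} {'0.975]':>10}",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:>12} {self.params[name]:>12.6g} {self.bse[name]:>10.3g} "
                f"{ci.loc[name, 'lower']:>10.4g} {ci.loc[name, 'upper']:>10.4g}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "form": self.model.form,
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "rsquared": self.rsquared,
            "residual_se": self.residual_se,
            "n": self.nobs,
            "message": self.message,
        }


class PeakResults(NonlinearResults):
    """Lorentzian-peak fit results."""

    @property
    def argmax(self) -> float:
        """psi_stem at which the fitted curve attains its maximum (the centre)."""
        return float(self.params["center"])

    @property
    def peak_value(self) -> float:
        """Maximum of the fitted curve (the amplitude)."""
        return float(self.params["amplitude"])


class ExpoLinearResults(NonlinearResults):
    """Expo-linear fit results; parameters reported in natural (k1) scale.

    Confidence intervals for k1 come from the log-scale fit parameterisation
    (k1 > 0 is enforced by fitting log k1) and are exponentiated, so they are
    exact transforms of the fit-space intervals.
    """

    def __init__(self, model, params, cov, y, yhat, fit_params, fit_cov, message=""):
        super().__init__(model, params, cov, y, yhat, message)
        self.fit_params = fit_params  # (k0, log_k1, k2, k3)
        self.fit_cov = fit_cov

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        t = scipy.stats.t.ppf(1.0 - alpha / 2.0, self.df_resid)
        se = np.sqrt(np.diag(self.fit_cov))
        lower = self.fit_params - t * se
        upper = self.fit_params + t * se
        ci = pd.DataFrame({"lower": lower, "upper": upper}, index=["k0", "log_k1", "k2", "k3"])
        out = ci.rename(index={"log_k1": "k1"})
        out.loc["k1"] = np.exp(ci.loc["log_k1"])
        return out.loc[["k0", "k1", "k2", "k3"]]

    def threshold(self, fraction: float = 0.01, **kwargs) -> ThresholdResult:
        """Water-deficit threshold on the fitted parameters (see detect_threshold)."""
        return detect_threshold(self.params.to_dict(), fraction=fraction, **kwargs)

    def invert(self, ratio: float, psi_range: tuple[float, float] = (-3.6, -0.8)):
        """psi_stem estimate from an observed ratio (see invert_expolinear)."""
        return invert_expolinear(ratio, self.params.to_dict(), psi_range)


# ---------------------------------------------------------------------------
# Model classes
# ---------------------------------------------------------------------------


class StemWaterPotentialModel:
    """OLS of midday stem water potential on psi_leaf, gs and VPD.

    Thin wrapper over statsmodels OLS with named coefficients matching the
    multilinear form b0 + b1*psi_leaf + b2*gs + b3*VPD.
    """

    PREDICTORS = ("psi_leaf", "gs", "vpd")

    def __init__(self, psi_stem, psi_leaf, gs, vpd):
        y = np.asarray(psi_stem, dtype=float)
        X = np.column_stack([np.asarray(v, dtype=float) for v in (psi_leaf, gs, vpd)])
        if len(y) < 5:
            raise ValidationError("need at least 5 observations")
        design = np.column_stack([np.ones(len(y)), X])
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            names = ("intercept",) + self.PREDICTORS
            collinear = [
                names[j]
                for j in range(design.shape[1])
                if np.linalg.matrix_rank(np.delete(design, j, axis=1)) == rank
            ]
            raise ValidationError(f"rank-deficient design; collinear columns: {collinear}")
        self._y = y
        self._X = sm.add_constant(pd.DataFrame(X, columns=list(self.PREDICTORS)))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, response: str = "psi_stem", predictors=PREDICTORS):
        data = df.dropna(subset=[response, *predictors])
        return cls(data[response], *(data[p] for p in predictors))

    def fit(self) -> "StemWaterPotentialResults":
        res = sm.OLS(self._y, self._X).fit()
        return StemWaterPotentialResults(res)


class StemWaterPotentialResults:
    """Results of the multilinear stem-water-potential fit."""

    _RENAME = {"const": "intercept"}

    def __init__(self, sm_results):
        self._sm = sm_results
        self.params = sm_results.params.rename(self._RENAME)
        self.bse = sm_results.bse.rename(self._RENAME)
        self.rsquared = float(sm_results.rsquared)
        self.residual_se = float(np.sqrt(sm_results.scale))
        self.pvalue = float(sm_results.f_pvalue)
        self.nobs = int(sm_results.nobs)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = self._sm.conf_int(alpha)
        ci.columns = ["lower", "upper"]
        return ci.rename(index=self._RENAME)

    def predict(self, psi_leaf, gs, vpd):
        return multilinear_predict(self.params.to_dict(), psi_leaf, gs, vpd)

    def summary(self):
        return self._sm.summary()

    def to_dict(self) -> dict:
        return {
            "form": "multilinear",
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "rsquared": self.rsquared,
            "residual_se": self.residual_se,
            "p_value": self.pvalue,
            "n": self.nobs,
        }


class LinearRateModel:
    """Simple linear regression y = intercept + slope * psi (MIN_RPCR form)."""

    form = "linear"

    @staticmethod
    def curve(x, intercept, slope):
        return linear_curve(x, intercept, slope)

    def __init__(self, x, y):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if len(self.x) < 3:
            raise ValidationError("need at least 3 observations")

    def fit(self) -> NonlinearResults:
        X = sm.add_constant(self.x)
        res = sm.OLS(self.y, X).fit()
        params = pd.Series(res.params, index=["intercept", "slope"])
        cov = pd.DataFrame(res.cov_params().to_numpy() if hasattr(res.cov_params(), "to_numpy") else res.cov_params(), index=params.index, columns=params.index)
        return NonlinearResults(self, params, cov, self.y, res.fittedvalues)


class PeakRateModel:
    """Lorentzian-peak model for nocturnal MAX_RGR versus midday psi_stem.

    Fitted by nonlinear least squares (Levenberg-Marquardt via curve_fit)
    with initial values amplitude = max(y), center = x at max(y),
    width = half the x data range.
    """

    form = "lorentzian_peak"
    PARAM_NAMES = ("amplitude", "center", "width")

    @staticmethod
    def curve(x, amplitude, center, width):
        return peak_curve(x, amplitude, center, width)

    def __init__(self, x, y):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if len(self.x) < 4:
            raise ValidationError("need at least 4 observations")

    def initial_params(self) -> np.ndarray:
        a0 = float(np.max(self.y))
        c0 = float(self.x[np.argmax(self.y)])
        w0 = float((np.max(self.x) - np.min(self.x)) / 2.0) or 1.0
        return np.array([a0, c0, w0])

    def fit(self, p0=None, maxfev: int = 20000) -> PeakResults:
        p0 = self.initial_params() if p0 is None else np.asarray(p0, dtype=float)
        try:
            popt, pcov = scipy.optimize.curve_fit(
                self.curve, self.x, self.y, p0=p0, maxfev=maxfev, xtol=1e-12, ftol=1e-12
            )
        except RuntimeError as exc:  # pragma: no cover - depends on data
            raise FitError(f"peak fit did not converge: {exc}") from exc
        popt[2] = abs(popt[2])  # width enters squared; report the positive root
        params = pd.Series(popt, index=list(self.PARAM_NAMES))
        cov = pd.DataFrame(pcov, index=params.index, columns=params.index)
        return PeakResults(self, params, cov, self.y, self.curve(self.x, *popt))


class ExpoLinearModel:
    """Expo-linear model for the nocturnal RSD_RGR/RSD_RPCR ratio versus psi_stem.

    y = k0 + k1*exp(k2*x) + k3*x with k1 > 0 enforced by fitting log k1.
    Initialisation: OLS of y on x over the milder (upper) half of the psi
    range gives k0, k3; a log-linear fit of the positive residuals over the
    severe half gives k2 and log k1.  Convergence tolerance 1e-10 on the sum
    of squares.
    """

    form = "expolinear"
    PARAM_NAMES = ("k0", "k1", "k2", "k3")

    @staticmethod
    def curve(x, k0, k1, k2, k3):
        return expolinear_curve(x, k0, k1, k2, k3)

    def __init__(self, x, y):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if len(self.x) < 5:
            raise ValidationError("need at least 5 observations")

    def initial_params(self) -> np.ndarray:
        x, y = self.x, self.y
        mid = np.median(x)
        upper = x >= mid  # milder deficit: the exponential term is negligible there
        if upper.sum() < 2 or (~upper).sum() < 2:
            upper = x >= np.partition(x, len(x) // 2)[len(x) // 2]
        A = np.column_stack([np.ones(upper.sum()), x[upper]])
        k0, k3 = np.linalg.lstsq(A, y[upper], rcond=None)[0]
        resid = y - (k0 + k3 * x)
        severe = (~upper) & (resid > 0)
        if severe.sum() >= 2:
            B = np.column_stack([np.ones(severe.sum()), x[severe]])
            log_k1, k2 = np.linalg.lstsq(B, np.log(resid[severe]), rcond=None)[0]
        else:
            log_k1, k2 = np.log(1e-6), -3.0
        k2 = min(k2, -1e-3)
        return np.array([k0, log_k1, k2, k3])


    def fit(self, p0=None) -> ExpoLinearResults:
        theta0 = self.initial_params() if p0 is None else np.asarray(p0, dtype=float)

        def residuals(theta):
            k0, log_k1, k2, k3 = theta
            return self.curve(self.x, k0, np.exp(log_k1), k2, k3) - self.y

        sol = scipy.optimize.least_squares(
            residuals, theta0, method="lm", xtol=1e-12, ftol=1e-10, gtol=1e-12, max_nfev=20000
        )
        if not sol.success:
            raise FitError(f"expo-linear fit did not converge: {sol.message}")
        k0, log_k1, k2, k3 = sol.x
        dof = len(self.x) - 4
        s2 = float(np.sum(sol.fun**2) / dof) if dof > 0 else np.nan
        jtj = sol.jac.T @ sol.jac
        try:
            fit_cov = np.linalg.inv(jtj) * s2
        except np.linalg.LinAlgError:
            fit_cov = np.full((4, 4), np.nan)
        # delta-method covariance in the natural (k1) scale
        jac_nat = np.diag([1.0, np.exp(log_k1), 1.0, 1.0])
        nat_cov = jac_nat @ fit_cov @ jac_nat
        params = pd.Series([k0, np.exp(log_k1), k2, k3], index=list(self.PARAM_NAMES))
        cov = pd.DataFrame(nat_cov, index=params.index, columns=params.index)
        yhat = self.curve(self.x, *params.to_numpy())
        return ExpoLinearResults(self, params, cov, self.y, yhat, sol.x.copy(), fit_cov, sol.message)


def fit_multilinear_psistem(spots: pd.DataFrame) -> StemWaterPotentialResults:
    """Fit the multilinear psi_stem model from a spot-measurement table."""
    return StemWaterPotentialModel.from_dataframe(spots).fit()


def fit_peak_model(x, y) -> PeakResults:
    """Fit the Lorentzian peak MAX_RGR(psi_stem) model."""
    return PeakRateModel(x, y).fit()


def fit_expolinear(x, y) -> ExpoLinearResults:
    """Fit the expo-linear nocturnal RSD-ratio model."""
    return ExpoLinearModel(x, y).fit()
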