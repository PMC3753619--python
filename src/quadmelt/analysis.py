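"""Inverse pipeline: melting trace → baselines → θ(T) → van't Hoff fit.

The analysis follows the classical optical-melting protocol. A raw ramp
(absorbance at 260/295 nm or ellipticity at 280 nm versus temperature) is
first corrected with linear folded/unfolded baselines, converting signal
into folded fraction θ(T). Under the two-state assumption each θ defines
an equilibrium constant, and ordinary least squares of ln K against 1/T
yields the van't Hoff enthalpy and entropy:

    ln K(T) = ΔS/R − ΔH/(R·T)

:class:`VantHoffAnalyzer` wraps the stages as a scikit-learn style
estimator (``fit`` on one curve, fitted attributes with trailing
underscores, ``get_params``/``set_params``/``clone`` support). By default
it adds one refinement pass: the linear-baseline + two-state signal model
is re-fit globally by least squares, initialised from the staged estimate,
and the van't Hoff regression is re-run on the refined θ. This matters for
broad transitions whose plateaus are not fully reached inside the scanned
temperature range, where fixed-window baselines are biased (see
docs/methods.md). The plain staged functions are all exported for callers
who want the textbook procedure step by step.

Temperatures at these interfaces are °C (instrument convention); all
thermodynamic arithmetic is delegated to :mod:`quadmelt.thermo` in kelvin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import savgol_filter
from scipy.stats import linregress
from sklearn.base import BaseEstimator

from . import thermo
from .exceptions import (
    AnalysisError,
    DegenerateBaselineError,
    NoTransitionError,
    ValidationError,
)
from .thermo import Molecularity, ThermoParams, free_energy

MIN_RAMP_POINTS = 20


@dataclass
class MeltCurve:
    """One temperature ramp of one optical channel.

    ``channel`` is one of ``A260``, ``A295``, ``CD280`` (any other label is
    accepted and treated generically); ``meta`` carries experiment metadata
    such as pH, total strand concentration, ramp rate, pair label and
    replicate id.
    """

    temperature_c: np.ndarray
    signal: np.ndarray
    channel: str = "A260"
    ramp_direction: str = "heating"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.temperature_c = np.asarray(self.temperature_c, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.temperature_c.shape != self.signal.shape:
            raise ValidationError("temperature and signal must have equal length")
        if self.temperature_c.size < MIN_RAMP_POINTS:
            raise ValidationError(
                f"a ramp needs at least {MIN_RAMP_POINTS} points "
                f"(got {self.temperature_c.size})"
            )
        d = np.diff(self.temperature_c)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValidationError("temperatures must be strictly monotone in a ramp")
        if not np.all(np.isfinite(self.signal)):
            raise ValidationError("signal contains non-finite values")
        if self.ramp_direction not in ("heating", "cooling"):
            raise ValidationError("ramp_direction must be 'heating' or 'cooling'")

    def ascending(self) -> "MeltCurve":
        """The same ramp with temperatures sorted ascending."""
        if self.temperature_c[0] <= self.temperature_c[-1]:
            return self
        return MeltCurve(
            self.temperature_c[::-1].copy(),
            self.signal[::-1].copy(),
            channel=self.channel,
            ramp_direction=self.ramp_direction,
            meta=dict(self.meta),
        )


@dataclass(frozen=True)
class BaselineFit:
    """Linear folded/unfolded plateaus, signal = slope·T(°C) + intercept.

    ``lower`` is the folded plateau (the low-absorbance line for a
    hyperchromic 260 nm duplex transition; numerically the *higher* line
    for channels where folding raises the signal, e.g. quadruplex 295 nm),
    ``upper`` the unfolded plateau. ``windows`` records the temperature
    intervals the lines were fitted on.
    """

    lower: tuple[float, float]
    upper: tuple[float, float]
    windows: tuple[tuple[float, float], tuple[float, float]]

    def lower_at(self, t_c):
        return self.lower[0] * np.asarray(t_c, dtype=float) + self.lower[1]

    def upper_at(self, t_c):
        return self.upper[0] * np.asarray(t_c, dtype=float) + self.upper[1]


@dataclass
class ThetaProfile:
    """Baseline-corrected folded fraction versus temperature (°C)."""

    temperature_c: np.ndarray
    theta: np.ndarray

    def __post_init__(self):
        self.temperature_c = np.asarray(self.temperature_c, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.temperature_c.shape != self.theta.shape:
            raise ValidationError("temperature and theta must have equal length")
        if not np.all(np.isfinite(self.theta)):
            raise ValidationError("theta contains non-finite values")

    def ascending(self) -> "ThetaProfile":
        order = np.argsort(self.temperature_c)
        return ThetaProfile(self.temperature_c[order], self.theta[order])


@dataclass(frozen=True)
class VantHoffFit:
    """Per-curve thermodynamic estimates from one van't Hoff regression."""

    params: ThermoParams
    tm_obs_c: float  # θ = 0.5 crossing
    tm_deriv_c: float  # extremum of dθ/dT
    delta_G_std: float  # kJ/mol at 298.15 K
    r_squared: float
    theta_window: tuple[float, float]
    n_points_used: int
    meta: dict = field(default=None)

    def __post_init__(self):
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValidationError("r_squared must lie in [0, 1]")
        if self.meta is None:
            object.__setattr__(self, "meta", {})


def split_ramps(
    temperature_c: Sequence[float],
    signal: Sequence[float],
    channel: str = "A260",
    meta: dict | None = None,
    min_points: int = MIN_RAMP_POINTS,
) -> list[MeltCurve]:
    """Split a time-ordered temperature trace at direction reversals.

    A 90→10→90→10 °C protocol yields three ramps labelled cooling,
    heating, cooling; the turning point is shared between adjacent ramps.
    Segments shorter than ``min_points`` are discarded with a warning.
    """
    t = np.asarray(temperature_c, dtype=float)
    s = np.asarray(signal, dtype=float)
    if t.size != s.size or t.size < 2:
        raise ValidationError("trace needs equal-length temperature/signal arrays")
    steps = np.sign(np.diff(t))
    if np.all(steps == 0):
        raise AnalysisError("constant-temperature series contains no ramp")

    curves: list[MeltCurve] = []
    start = 0
    current = steps[0]
    boundaries = list(np.nonzero(steps[1:] != steps[:-1])[0] + 1) + [t.size - 1]
    for b in boundaries:
        seg = slice(start, b + 1)  # share the turning point
        direction = "heating" if current > 0 else "cooling"
        n = b + 1 - start
        if current == 0 or n < min_points:
            warnings.warn(
                f"discarding {direction if current else 'flat'} segment with "
                f"{n} points (< {min_points})",
                stacklevel=2,
            )
        else:
            m = dict(meta or {})
            m["ramp_index"] = len(curves)
            curves.append(
                MeltCurve(t[seg].copy(), s[seg].copy(), channel=channel,
                          ramp_direction=direction, meta=m)
            )
        start = b
        if b < steps.size:
            current = steps[b]
    if not curves:
        raise AnalysisError("no usable monotone segment found in trace")
    return curves


def fit_baselines(
    curve: MeltCurve,
    window_frac: float = 0.15,
    windows: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> BaselineFit:
    """Least-squares folded/unfolded baselines.

    By default the lines are fitted over the lowest and highest
    ``window_frac`` of the temperature span; explicit ``windows``
    ((t_lo, t_hi) low-temperature, (t_lo, t_hi) high-temperature, °C)
    override the fractions, e.g. to dodge a second transition.
    """
    t = curve.temperature_c
    s = curve.signal
    if windows is None:
        if not 0.0 < window_frac < 0.4:
            raise ValidationError("window_frac must lie in (0, 0.4)")
        t_min, t_max = float(t.min()), float(t.max())
        span = t_max - t_min
        windows = (
            (t_min, t_min + window_frac * span),
            (t_max - window_frac * span, t_max),
        )
    (lo_a, lo_b), (hi_a, hi_b) = windows
    if lo_b > hi_a:
        raise ValidationError("baseline windows must be disjoint")
    fits = []
    for w_lo, w_hi in windows:
        mask = (t >= w_lo) & (t <= w_hi)
        if mask.sum() < 3:
            raise ValidationError(
                f"degenerate baseline window [{w_lo}, {w_hi}] with "
                f"{int(mask.sum())} points (< 3)"
            )
        slope, intercept = np.polyfit(t[mask], s[mask], 1)
        fits.append((float(slope), float(intercept)))
    return BaselineFit(lower=fits[0], upper=fits[1], windows=windows)


def fraction_folded(curve: MeltCurve, baselines: BaselineFit) -> ThetaProfile:
    """Folded fraction from baseline correction, clipped to [0, 1].

    θ(T) = (upper(T) − signal(T)) / (upper(T) − lower(T)). Because
    ``lower`` is defined as the *folded* plateau, the same expression is
    valid for channels where folding raises the signal (the two lines swap
    numerical order and both differences change sign). The result is
    invariant under affine rescaling of the signal applied consistently to
    curve and baselines.
    """
    t = curve.temperature_c
    upper = baselines.upper_at(t)
    lower = baselines.lower_at(t)
    denom = upper - lower
    scale = max(float(np.max(np.abs(denom))), 1.0)
    if np.any(np.abs(denom) < 1e-12 * scale):
        raise DegenerateBaselineError(
            "folded and unfolded baselines coincide inside the temperature range"
        )
    theta = np.clip((upper - curve.signal) / denom, 0.0, 1.0)
    return ThetaProfile(t.copy(), theta)


def _smooth(theta: np.ndarray, window: int) -> np.ndarray:
    """Centered moving-window quadratic (Savitzky-Golay) smoothing."""
    n = theta.size
    w = min(window, n if n % 2 else n - 1)
    if w < 5:
        return theta
    return savgol_filter(theta, window_length=w, polyorder=2)


def melting_temperature(
    profile: ThetaProfile,
    method: str = "crossing",
    smooth_window: int = 11,
) -> float:
    """Melting temperature (°C) of a θ profile.

    ``crossing``
        Linear interpolation of the first θ = 0.5 crossing in the heating
        direction, on the smoothed profile; a warning is emitted when the
        smoothed profile crosses more than once.
    ``derivative``
        Temperature of the extremum of dθ/dT on the smoothed profile,
        refined by parabolic interpolation around the grid extremum.
    """
    prof = profile.ascending()
    t, theta = prof.temperature_c, _smooth(prof.theta, smooth_window)

    if method == "crossing":
        d = theta - 0.5
        crossings = []
        for i in range(d.size - 1):
            if d[i] == 0.0:
                crossings.append(float(t[i]))
            elif d[i] * d[i + 1] < 0.0:
                frac = d[i] / (d[i] - d[i + 1])
                crossings.append(float(t[i] + frac * (t[i + 1] - t[i])))
        if d[-1] == 0.0:
            crossings.append(float(t[-1]))
        if not crossings:
            raise NoTransitionError(
                "folded fraction never crosses 0.5 inside the temperature range"
            )
        if len(crossings) > 1:
            warnings.warn(
                f"{len(crossings)} θ=0.5 crossings; using the first in the "
                "heating direction",
                stacklevel=2,
            )
        return crossings[0]

    if method == "derivative":
        dtheta = np.gradient(theta, t)
        i = int(np.argmax(np.abs(dtheta)))
        if i == 0 or i == dtheta.size - 1:
            return float(t[i])
        # parabolic refinement through the three points around the extremum
        y0, y1, y2 = np.abs(dtheta[i - 1 : i + 2])
        denom = y0 - 2 * y1 + y2
        shift = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
        return float(t[i] + shift * (t[i + 1] - t[i]))

    raise ValidationError(f"unknown Tm method {method!r}")


def vant_hoff_fit(
    profile: ThetaProfile,
    molecularity: str | Molecularity,
    c_total: float | None = None,
    theta_window: tuple[float, float] = (0.15, 0.85),
    smooth_window: int = 11,
    meta: dict | None = None,
) -> VantHoffFit:
    """van't Hoff regression of one θ profile.

    Points with θ strictly inside ``theta_window`` are converted to
    equilibrium constants and ln K is regressed on 1/T (kelvin) by
    ordinary least squares: ΔH = −slope·R, ΔS = intercept·R. ΔG° at
    298.15 K and the regression r² are attached, along with the crossing
    and derivative melting temperatures of the profile.
    """
    lo, hi = theta_window
    if not (0.0 < lo < hi < 1.0):
        raise ValidationError("theta_window must satisfy 0 < lo < hi < 1")
    prof = profile.ascending()
    mask = (prof.theta > lo) & (prof.theta < hi)
    n_used = int(mask.sum())
    if n_used < 5:
        raise AnalysisError(
            f"only {n_used} points with θ in ({lo}, {hi}); need at least 5"
        )
    t_k = thermo.to_kelvin(prof.temperature_c[mask])
    ln_k = np.log(
        thermo.equilibrium_constant(prof.theta[mask], molecularity, c_total)
    )
    if not np.all(np.isfinite(ln_k)):
        raise AnalysisError("non-finite ln K inside the regression window")
    res = linregress(1.0 / t_k, ln_k)
    delta_H = -res.slope * thermo.R / 1e3  # kJ/mol
    delta_S = res.intercept * thermo.R  # J/(K mol)
    params = ThermoParams(delta_H, delta_S, molecularity, c_total)
    return VantHoffFit(
        params=params,
        tm_obs_c=melting_temperature(prof, "crossing", smooth_window),
        tm_deriv_c=melting_temperature(prof, "derivative", smooth_window),
        delta_G_std=free_energy(params).delta_G,
        r_squared=min(float(res.rvalue**2), 1.0),
        theta_window=(lo, hi),
        n_points_used=n_used,
        meta=dict(meta or {}),
    )


@dataclass(frozen=True)
class HysteresisReport:
    """Heating/cooling Tm discrepancy; a flag marks non-equilibrium melting."""

    delta_tm_c: float
    tolerance_c: float
    flagged: bool


def hysteresis(
    heating: VantHoffFit, cooling: VantHoffFit, tol: float = 1.0
) -> HysteresisReport:
    """|Tm(heating) − Tm(cooling)|, flagged above ``tol`` °C."""
    d = abs(heating.tm_obs_c - cooling.tm_obs_c)
    return HysteresisReport(delta_tm_c=d, tolerance_c=tol, flagged=d > tol)


@dataclass(frozen=True)
class SeparationReport:
    """Duplex/quadruplex Tm separation versus a minimum requirement."""

    separation_c: float
    min_separation_c: float
    passed: bool


def _tm_of(fit_or_tm) -> float:
    return float(getattr(fit_or_tm, "tm_obs_c", fit_or_tm))


def transition_separation(
    duplex_fit, quad_fit, min_sep: float = 25.0
) -> SeparationReport:
    """Check that the four-stranded transition clears the duplex one.

    Accepts :class:`VantHoffFit` objects or bare Tm values (°C). Windowed
    duplex analysis is only trustworthy when the separation passes.
    """
    sep = abs(_tm_of(quad_fit) - _tm_of(duplex_fit))
    return SeparationReport(
        separation_c=sep, min_separation_c=min_sep, passed=sep >= min_sep
    )


@dataclass(frozen=True)
class MolecularityReport:
    """Concentration-dependence test of the melting transition."""

    slope: float  # d(1/Tm) / d(ln c_total), 1/K per ln-unit
    expected_slope: float  # bimolecular theory: R/ΔH
    classification: str  # "unimolecular" or "bimolecular"
    intercept: float


def molecularity_test(
    tm_series: Sequence[tuple[float, float]], delta_H: float
) -> MolecularityReport:
    """Classify a transition by the concentration dependence of Tm.

    For bimolecular association 1/Tm is linear in ln c_total with slope
    R/ΔH; a unimolecular transition is concentration-invariant. The
    observed least-squares slope of 1/Tm (kelvin) versus ln c_total is
    compared against the expectation from the fitted ``delta_H`` (kJ/mol):
    below half the expected magnitude the transition is called
    unimolecular, otherwise bimolecular.
    """
    series = [(float(c), float(tm)) for c, tm in tm_series]
    if len({c for c, _ in series}) < 3:
        raise ValidationError("molecularity test needs >= 3 distinct concentrations")
    x = np.log([c for c, _ in series])
    y = np.array([1.0 / tm for _, tm in series])
    res = linregress(x, y)
    expected = thermo.R / (delta_H * 1e3)
    cls = (
        "unimolecular"
        if abs(res.slope) < 0.5 * abs(expected)
        else "bimolecular"
    )
    return MolecularityReport(
        slope=float(res.slope),
        expected_slope=float(expected),
        classification=cls,
        intercept=float(res.intercept),
    )


class VantHoffAnalyzer(BaseEstimator):
    """Fit the two-state melting model to a single curve.

    scikit-learn style estimator: hyperparameters at construction,
    :meth:`fit` on one :class:`MeltCurve` (or a ``(temperature_c, signal)``
    pair), fitted attributes with trailing underscores, and
    ``get_params``/``set_params``/``clone`` support so the analyzer
    composes with sklearn model-selection utilities.

    Parameters
    ----------
    molecularity : str
        ``bimolecular_hetero`` (duplex, the default) or ``unimolecular``.
    c_total : float or None
        Total strand concentration (mol/L); required for bimolecular fits.
    theta_window : (float, float)
        Folded-fraction window for the van't Hoff regression. The ends of
        the transition are baseline-dominated; (0.15, 0.85) is standard.
    baseline_window_frac : float
        Fraction of the temperature span used for each baseline window.
    baseline_windows : pair of (lo, hi) or None
        Explicit baseline windows (°C), overriding the fraction.
    smooth_window : int
        Savitzky-Golay window (points) for Tm extraction.
    refine : bool
        Re-fit baselines by a global least-squares fit of the full
        two-state signal model, then re-run the van't Hoff regression on
        the refined θ. Default True; set False for the textbook
        fixed-window procedure.

    Attributes
    ----------
    result_ : VantHoffFit
    baseline_ : BaselineFit
    theta_ : ThetaProfile
    delta_H_, delta_S_, tm_, tm_deriv_, delta_G_std_, r_squared_, \
n_points_used_
        Convenience scalars mirroring ``result_``.
    """

    def __init__(
        self,
        molecularity: str = "bimolecular_hetero",
        c_total: float | None = None,
        theta_window: tuple[float, float] = (0.15, 0.85),
        baseline_window_frac: float = 0.15,
        baseline_windows=None,
        smooth_window: int = 11,
        refine: bool = True,
    ):
        self.molecularity = molecularity
        self.c_total = c_total
        self.theta_window = theta_window
        self.baseline_window_frac = baseline_window_frac
        self.baseline_windows = baseline_windows
        self.smooth_window = smooth_window
        self.refine = refine

    # -- internal -----------------------------------------------------

    def _as_curve(self, X, y=None) -> MeltCurve:
        if isinstance(X, MeltCurve):
            return X
        if y is not None:
            t, s = np.asarray(X, dtype=float).ravel(), np.asarray(y, dtype=float)
        else:
            t, s = (np.asarray(a, dtype=float) for a in X)
        direction = "heating" if t[-1] >= t[0] else "cooling"
        return MeltCurve(t, s, ramp_direction=direction)

    def _staged_fit(self, curve: MeltCurve, baselines: BaselineFit):
        theta = fraction_folded(curve, baselines)
        fit = vant_hoff_fit(
            theta,
            self.molecularity,
            self.c_total,
            theta_window=self.theta_window,
            smooth_window=self.smooth_window,
            meta=curve.meta,
        )
        return theta, fit

    def _refine_baselines(
        self, curve: MeltCurve, baselines: BaselineFit, fit: VantHoffFit
    ) -> BaselineFit:
        t_c, sig = curve.temperature_c, curve.signal
        t_k = thermo.to_kelvin(t_c)
        molecularity = Molecularity(self.molecularity)

        def model(p):
            dh, ds, lo_a, lo_b, up_a, up_b = p
            params = ThermoParams(dh, ds, molecularity, self.c_total)
            th = thermo.theta_from_params(params, t_k)
            return th * (lo_a * t_c + lo_b) + (1.0 - th) * (up_a * t_c + up_b)

        p0 = np.array(
            [
                fit.params.delta_H,
                fit.params.delta_S,
                *baselines.lower,
                *baselines.upper,
            ]
        )
        sol = least_squares(lambda p: model(p) - sig, p0, method="lm", max_nfev=400)
        _, _, lo_a, lo_b, up_a, up_b = sol.x
        return BaselineFit(
            lower=(float(lo_a), float(lo_b)),
            upper=(float(up_a), float(up_b)),
            windows=baselines.windows,
        )

    # -- sklearn surface ----------------------------------------------

    def fit(self, X, y=None):
        """Fit the model to one melting curve.

        ``X`` may be a :class:`MeltCurve`, a ``(temperature_c, signal)``
        pair, or a temperature array with the signal passed as ``y``.
        """
        curve = self._as_curve(X, y)
        baselines = fit_baselines(
            curve,
            window_frac=self.baseline_window_frac,
            windows=self.baseline_windows,
        )
        theta, fit = self._staged_fit(curve, baselines)
        if self.refine:
            try:
                refined = self._refine_baselines(curve, baselines, fit)
                theta_r, fit_r = self._staged_fit(curve, refined)
            except (AnalysisError, ValidationError):
                warnings.warn(
                    "global baseline refinement failed; keeping the staged fit",
                    stacklevel=2,
                )
            else:
                baselines, theta, fit = refined, theta_r, fit_r

        self.curve_ = curve
        self.baseline_ = baselines
        self.theta_ = theta
        self.result_ = fit
        self.delta_H_ = fit.params.delta_H
        self.delta_S_ = fit.params.delta_S
        self.tm_ = fit.tm_obs_c
        self.tm_deriv_ = fit.tm_deriv_c
        self.delta_G_std_ = fit.delta_G_std
        self.r_squared_ = fit.r_squared
        self.n_points_used_ = fit.n_points_used
        return self

    def predict(self, temperature_c):
        """Fitted signal model evaluated at the given temperatures (°C)."""
        if not hasattr(self, "result_"):
            raise AnalysisError("call fit() before predict()")
        t_c = np.asarray(temperature_c, dtype=float)
        th = thermo.theta_from_params(self.result_.params, thermo.to_kelvin(t_c))
        return th * self.baseline_.lower_at(t_c) + (1.0 - th) * self.baseline_.upper_at(
            t_c
        )


def analyze_curve(curve: MeltCurve, **kwargs) -> VantHoffFit:
    """One-call pipeline: ``VantHoffAnalyzer(**kwargs).fit(curve).result_``."""
    return VantHoffAnalyzer(**kwargs).fit(curve).result_
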