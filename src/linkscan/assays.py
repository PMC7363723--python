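"""Biophysical assay models: one-site binding, thermal melt, ATPase endpoints.

Three measurement types are modelled, each with a small container class, a
scikit-learn style estimator, and a thin functional wrapper:

* **Fluorescence-polarization binding** — polarization of a fluorescent
  nucleotide probe (e.g. MANT-ATP) titrated with protein.  The one-site model
  is the hyperbola ``P(c) = P0 + (Pmax - P0) * c / (Kd + c)``; an optional
  ligand-depletion variant uses the exact quadratic bound fraction when the
  probe concentration is not negligible relative to Kd.
* **Thermal-shift melt curves** — dye fluorescence versus temperature.  Tm is
  the midpoint of a four-parameter Boltzmann sigmoid
  ``F(T) = Fpre + (Fpost - Fpre) / (1 + exp((Tm - T)/s))`` fitted on the
  ascending segment up to the fluorescence maximum (post-peak aggregation
  decline is truncated); the maximum of the smoothed first derivative serves
  as a fallback when the sigmoid fit fails.
* **Malachite-green ATPase endpoints** — free-phosphate concentrations after a
  fixed incubation; activity of a variant is reported relative to wild type
  as a ratio of blank-subtracted means with quotient error propagation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import FitError, NoTransitionError

__all__ = [
    "BindingCurve",
    "BindingFit",
    "MeltCurve",
    "MeltFit",
    "ATPaseMeasurement",
    "ActivityRatio",
    "OneSiteBindingModel",
    "BoltzmannMeltModel",
    "fit_one_site_binding",
    "extract_tm",
    "delta_tm",
    "relative_activity",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class BindingCurve:
    """Protein-titration polarization data (concentrations in uM)."""

    concentrations: np.ndarray
    polarization: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.polarization = np.asarray(self.polarization, dtype=float)
        if self.concentrations.shape != self.polarization.shape:
            raise ValueError("concentration and polarization arrays differ in shape")
        if np.any(self.concentrations <= 0):
            raise ValueError("protein concentrations must be positive")

    @property
    def n_distinct(self) -> int:
        return np.unique(self.concentrations).size


@dataclass
class BindingFit:
    """Result of a one-site binding fit (Kd in uM)."""

    kd: float | None
    p0: float
    pmax: float
    kd_se: float | None
    p0_se: float | None
    pmax_se: float | None
    residual_norm: float
    converged: bool
    censored: bool = False
    message: str = ""


@dataclass
class MeltCurve:
    """Thermal-shift fluorescence trace (temperatures in degC)."""

    temperatures: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperatures.shape != self.fluorescence.shape:
            raise ValueError("temperature and fluorescence arrays differ in shape")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperature grid must be strictly increasing")


@dataclass
class MeltFit:
    """Extracted melting transition (Tm in degC)."""

    tm: float
    slope: float
    f_pre: float
    f_post: float
    tm_se: float | None
    method: str  # "sigmoid" or "derivative"
    converged: bool


@dataclass
class ATPaseMeasurement:
    """Endpoint free-phosphate readings (uM) for one protein variant."""

    variant: str
    endpoints: np.ndarray

    def __post_init__(self) -> None:
        self.endpoints = np.asarray(self.endpoints, dtype=float)
        if self.endpoints.size < 2:
            raise ValueError("need at least two endpoint replicates")


@dataclass
class ActivityRatio:
    """Mutant/WT activity ratio with propagated standard deviation."""

    ratio: float
    sd: float
    mutant: str = ""
    wt: str = ""


# ---------------------------------------------------------------------------
# one-site binding
# ---------------------------------------------------------------------------


def _hyperbola(c: np.ndarray, p0: float, pmax: float, kd: float) -> np.ndarray:
    return p0 + (pmax - p0) * c / (kd + c)


def _depletion(c: np.ndarray, p0: float, pmax: float, kd: float, probe: float) -> np.ndarray:
    # exact bound fraction of the probe when ligand depletion matters
    b = c + probe + kd
    bound = (b - np.sqrt(b * b - 4.0 * c * probe)) / (2.0 * probe)
    return p0 + (pmax - p0) * bound


class OneSiteBindingModel(BaseEstimator, RegressorMixin):
    """One-site (single binding mode) fit of a polarization titration.

    Parameters
    ----------
    depletion : bool, default False
        Use the quadratic ligand-depletion form instead of the simple
        hyperbola.
    probe_conc : float, default 1.0
        Probe concentration in uM; only used when ``depletion`` is on.
    censor_factor : float, default 1.0
        The fit is flagged censored when the fitted Kd exceeds
        ``censor_factor`` times the highest tested concentration, mirroring
        the practice of reporting "Kd > max tested" for flat titrations.

    Attributes
    ----------
    kd_ : float or None
        Fitted dissociation constant in uM (None when censored).
    p0_, pmax_ : float
        Baseline and saturation polarization.
    kd_se_, p0_se_, pmax_se_ : float or None
        Standard errors from the fit covariance.
    censored_ : bool
        True when the curve carries no resolvable Kd in the tested range.
    fit_ : BindingFit
        Full result record.
    """

    def __init__(self, depletion: bool = False, probe_conc: float = 1.0,
                 censor_factor: float = 1.0):
        self.depletion = depletion
        self.probe_conc = probe_conc
        self.censor_factor = censor_factor

    def _model(self):
        if self.depletion:
            probe = self.probe_conc
            return lambda c, p0, pmax, kd: _depletion(c, p0, pmax, kd, probe)
        return _hyperbola

    def fit(self, X, y=None) -> "OneSiteBindingModel":
        if isinstance(X, BindingCurve):
            c, p = X.concentrations, X.polarization
        else:
            c = np.asarray(X, dtype=float).ravel()
            p = np.asarray(y, dtype=float).ravel()
        if c.shape != p.shape:
            raise ValueError("x and y must have the same length")
        if np.any(c <= 0):
            raise ValueError("concentrations must be positive")
        if np.unique(c).size < 5:
            raise FitError("need at least 5 distinct concentrations for a binding fit")

        model = self._model()
        cmin, cmax = float(c.min()), float(c.max())
        geo = float(np.exp(np.mean(np.log(c))))
        p_lo, p_hi = float(p.min()), float(p.max())
        span = p_hi - p_lo if p_hi > p_lo else 1.0

        best = None
        for kd0 in (cmin, geo, cmax):  # multi-start in Kd
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, pcov = curve_fit(
                        model, c, p,
                        p0=[p_lo, p_hi, kd0],
                        bounds=([p_lo - 10 * span, p_lo - 10 * span, 1e-9],
                                [p_hi + 10 * span, p_hi + 10 * span, 1e6 * cmax]),
                        maxfev=20000,
                    )
            except (RuntimeError, ValueError):
                continue
            ssr = float(np.sum((model(c, *popt) - p) ** 2))
            if best is None or ssr < best[2]:
                best = (popt, pcov, ssr)

        if best is None:
            self.fit_ = BindingFit(None, float("nan"), float("nan"), None, None,
                                   None, float("inf"), False,
                                   message="fit did not converge")
            self._store()
            return self

        popt, pcov, ssr = best
        p0_hat, pmax_hat, kd_hat = (float(v) for v in popt)
        ses = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else [None] * 3
        # censor when the Kd estimate escapes the tested range, or when the
        # fitted amplitude is indistinguishable from residual noise (flat curve)
        resid_sd = np.sqrt(ssr / max(c.size - 3, 1))
        flat = abs(pmax_hat - p0_hat) < 5.0 * resid_sd
        censored = bool(kd_hat > self.censor_factor * cmax or flat)
        self.fit_ = BindingFit(
            kd=None if censored else kd_hat,
            p0=p0_hat, pmax=pmax_hat,
            kd_se=None if censored else float(ses[2]),
            p0_se=float(ses[0]) if ses[0] is not None else None,
            pmax_se=float(ses[1]) if ses[1] is not None else None,
            residual_norm=float(np.sqrt(ssr)),
            converged=True,
            censored=censored,
            message=f"Kd > {cmax:g} uM (highest tested concentration)" if censored else "",
        )
        self._store()
        return self

    def _store(self) -> None:
        f = self.fit_
        self.kd_, self.p0_, self.pmax_ = f.kd, f.p0, f.pmax
        self.kd_se_, self.p0_se_, self.pmax_se_ = f.kd_se, f.p0_se, f.pmax_se
        self.censored_, self.converged_ = f.censored, f.converged

    def predict(self, X) -> np.ndarray:
        c = np.asarray(X, dtype=float).ravel()
        kd = self.kd_ if self.kd_ is not None else 1e6 * c.max()
        return self._model()(c, self.p0_, self.pmax_, kd)


def fit_one_site_binding(curve: BindingCurve, depletion: bool = False,
                         probe_conc: float = 1.0) -> BindingFit:
    """Fit ``P(c) = P0 + (Pmax-P0) c/(Kd+c)`` to a titration and return the fit."""
    est = OneSiteBindingModel(depletion=depletion, probe_conc=probe_conc)
    est.fit(curve)
    return est.fit_


# ---------------------------------------------------------------------------
# thermal melt
# ---------------------------------------------------------------------------


def _boltzmann(t: np.ndarray, f_pre: float, f_post: float, tm: float, slope: float) -> np.ndarray:
    return f_pre + (f_post - f_pre) / (1.0 + np.exp((tm - t) / slope))


def _smoothed_derivative_peak(t: np.ndarray, f: np.ndarray) -> tuple[float, float]:
    """Temperature of the max smoothed dF/dT and the peak height."""
    df = np.gradient(f, t)
    if df.size >= 5:  # 5-point moving average knocks down point noise
        kernel = np.ones(5) / 5.0
        df = np.convolve(df, kernel, mode="same")
    k = int(np.argmax(df))
    return float(t[k]), float(df[k])


class BoltzmannMeltModel(BaseEstimator, RegressorMixin):
    """Extract a melting temperature from a thermal-shift trace.

    The ascending segment of the curve (up to the global fluorescence
    maximum) is fitted with a four-parameter Boltzmann sigmoid; if that fit
    fails, the maximum of the smoothed first derivative is used and the
    ``method_`` attribute records the fallback.

    Attributes
    ----------
    tm_ : float
        Transition midpoint in degC.
    slope_ : float
        Transition width parameter in degC (sigmoid method only).
    tm_se_ : float or None
        Standard error of Tm from the fit covariance.
    method_ : str
        ``"sigmoid"`` or ``"derivative"``.
    fit_ : MeltFit
        Full result record.
    """

    def __init__(self, min_points: int = 20):
        self.min_points = min_points

    def fit(self, X, y=None) -> "BoltzmannMeltModel":
        if isinstance(X, MeltCurve):
            t, f = X.temperatures, X.fluorescence
        else:
            t = np.asarray(X, dtype=float).ravel()
            f = np.asarray(y, dtype=float).ravel()
        if t.size < self.min_points:
            raise FitError(f"need at least {self.min_points} temperature points")

        # truncate the post-peak aggregation decline
        peak = int(np.argmax(f))
        if peak < 5:
            raise NoTransitionError("fluorescence maximum at the start of the ramp")
        t_asc, f_asc = t[: peak + 1], f[: peak + 1]

        span = float(f_asc.max() - f_asc.min())
        scale = max(abs(float(f.max())), abs(float(f.min())), 1e-30)
        if span <= 1e-9 * scale:
            raise NoTransitionError("flat curve: no unfolding transition")

        tm0, dmax = _smoothed_derivative_peak(t_asc, f_asc)
        if dmax <= 0:
            raise NoTransitionError("monotone non-increasing curve: no transition")

        result = None
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(
                    _boltzmann, t_asc, f_asc,
                    p0=[float(f_asc.min()), float(f_asc.max()), tm0, 2.0],
                    bounds=([-np.inf, -np.inf, float(t.min()), 1e-3],
                            [np.inf, np.inf, float(t.max()), float(t.max() - t.min())]),
                    maxfev=20000,
                )
            tm_se = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else None
            result = MeltFit(
                tm=float(popt[2]), slope=float(popt[3]),
                f_pre=float(popt[0]), f_post=float(popt[1]),
                tm_se=tm_se, method="sigmoid", converged=True,
            )
        except (RuntimeError, ValueError):
            pass

        if result is None:  # derivative fallback
            step = float(np.median(np.diff(t)))
            result = MeltFit(
                tm=tm0, slope=float("nan"),
                f_pre=float(f_asc.min()), f_post=float(f_asc.max()),
                tm_se=step / 2.0, method="derivative", converged=True,
            )

        self.fit_ = result
        self.tm_, self.slope_ = result.tm, result.slope
        self.tm_se_, self.method_ = result.tm_se, result.method
        return self

    def predict(self, X) -> np.ndarray:
        t = np.asarray(X, dtype=float).ravel()
        slope = self.slope_ if np.isfinite(self.slope_) else 1e-3
        return _boltzmann(t, self.fit_.f_pre, self.fit_.f_post, self.tm_, slope)


def extract_tm(curve: MeltCurve) -> MeltFit:
    """Melting temperature of a thermal-shift trace (Boltzmann midpoint)."""
    est = BoltzmannMeltModel()
    est.fit(curve)
    return est.fit_


def delta_tm(fit_a: MeltFit, fit_b: MeltFit) -> tuple[float, float | None]:
    """Tm difference ``a - b`` in degC with root-sum-square error propagation."""
    if not (fit_a.converged and fit_b.converged):
        raise FitError("delta_tm requires two converged melt fits")
    d = fit_a.tm - fit_b.tm
    if fit_a.tm_se is None or fit_b.tm_se is None:
        return d, None
    return d, float(np.hypot(fit_a.tm_se, fit_b.tm_se))


# ---------------------------------------------------------------------------
# ATPase endpoints
# ---------------------------------------------------------------------------


def relative_activity(mutant: ATPaseMeasurement, wt: ATPaseMeasurement,
                      blank: float = 0.0) -> ActivityRatio:
    """Blank-subtracted mutant/WT mean ratio with quotient error propagation.

    The standard deviation of the ratio treats the two variant means as
    independent: ``sd = ratio * sqrt((sd_m/mean_m)^2 + (sd_w/mean_w)^2)``.
    """
    m = mutant.endpoints - blank
    w = wt.endpoints - blank
    mw, ww = float(np.mean(m)), float(np.mean(w))
    if ww <= 0:
        raise ValueError("blank-subtracted WT mean must be positive")
    ratio = mw / ww
    sm = float(np.std(m, ddof=1)) / np.sqrt(m.size)
    sw = float(np.std(w, ddof=1)) / np.sqrt(w.size)
    if mw == 0.0:
        sd = sm / ww
    else:
        sd = abs(ratio) * float(np.hypot(sm / mw, sw / ww))
    return ActivityRatio(ratio=ratio, sd=sd, mutant=mutant.variant, wt=wt.variant)
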