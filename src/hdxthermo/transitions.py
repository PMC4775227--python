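"""Thermal-transition, exponential-kinetics and Arrhenius fitting.

The two-state temperature response of a subpopulation fraction F(T) is
modelled with the thermal unfolding (van 't Hoff-shaped) equation

    F(T) = f0 + (fmax - f0) * e^x / (1 + e^x),
    x = (T - Tm) * dH / (R * T * Tm),

with T in Kelvin, Tm the transition midpoint and dH an *apparent* steepness
parameter.  Because the underlying conformational transition is irreversible
under the assay conditions, dH is never interpreted as an equilibrium
unfolding enthalpy; the fit is used only to locate the midpoint.

Time courses of the subpopulation fraction are fitted with a single
exponential, and rate constants across temperatures with the Arrhenius
relation ln k = ln A - Ea / (R T).
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats
from scipy.special import expit
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "GAS_CONSTANT",
    "celsius_to_kelvin",
    "kelvin_to_celsius",
    "thermal_model",
    "ThermalTransitionModel",
    "ExponentialKineticsModel",
    "ArrheniusModel",
    "fit_thermal_transition",
    "fit_kinetics",
    "arrhenius_fit",
]

#: Molar gas constant in J mol^-1 K^-1 (CODATA 2018 exact value).
GAS_CONSTANT = 8.314462618

_ZERO_C_IN_K = 273.15


def celsius_to_kelvin(t_c):
    return np.asarray(t_c, dtype=float) + _ZERO_C_IN_K


def kelvin_to_celsius(t_k):
    return np.asarray(t_k, dtype=float) - _ZERO_C_IN_K


def thermal_model(t_k, f0, fmax, tm_k, dh_j_mol):
    """Two-state thermal transition fraction at absolute temperature ``t_k``.

    Parameters
    ----------
    t_k : array-like
        Absolute temperature in Kelvin, strictly positive.
    f0, fmax : float
        Low- and high-temperature plateaus (any consistent scale; a falling
        transition is expressed as ``fmax < f0``).
    tm_k : float
        Transition midpoint in Kelvin (``tm_k > 0``).
    dh_j_mol : float
        Apparent steepness parameter in J/mol.

    Returns
    -------
    ndarray or float
        ``f0 + (fmax - f0) * expit(x)`` with
        ``x = (T - Tm) * dH / (R * T * Tm)``.  ``expit`` keeps the
        expression stable for |x| far beyond 700.
    """
    t_k = np.asarray(t_k, dtype=float)
    if np.any(t_k <= 0.0):
        raise ValueError("temperature must be positive (Kelvin)")
    if tm_k <= 0.0:
        raise ValueError("tm_k must be positive (Kelvin)")
    if not np.isfinite(dh_j_mol):
        raise ValueError("dh_j_mol must be finite")
    x = (t_k - tm_k) * dh_j_mol / (GAS_CONSTANT * t_k * tm_k)
    out = f0 + (fmax - f0) * expit(x)
    return out if out.ndim else float(out)


def _standard_errors(result, n_obs):
    """Parameter standard errors from a scipy least_squares result."""
    _, s, vt = np.linalg.svd(result.jac, full_matrices=False)
    threshold = np.finfo(float).eps * max(result.jac.shape) * s[0] if s.size else 0.0
    s = s[s > threshold]
    vt = vt[: s.size]
    cov = (vt.T / s**2) @ vt
    dof = max(n_obs - result.x.size, 1)
    sigma2 = 2.0 * result.cost / dof
    cov = cov * sigma2
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    return se, cov


class ThermalTransitionModel(BaseEstimator, RegressorMixin):
    """Least-squares fit of the thermal transition equation to fraction data.

    Parameters
    ----------
    f0_fixed, fmax_fixed : float or None
        Optionally pin one or both plateaus (e.g. 0 and 100 for percent-scale
        blue-native quantifications).
    scale : {"fraction", "percent"}
        Declared scale of the response values.  Only used for validation and
        report labelling; the model is fitted on the data as given.
    max_iter : int
        Cap on optimizer iterations.

    Attributes
    ----------
    f0_, fmax_ : float
        Fitted (or pinned) plateaus.
    tm_c_, tm_k_ : float
        Transition midpoint in Celsius / Kelvin.
    dh_app_j_mol_ : float
        Apparent steepness parameter (J/mol); not an equilibrium enthalpy.
    se_tm_c_, se_dh_j_mol_, se_f0_, se_fmax_ : float
        Standard errors (NaN for pinned parameters).
    extrapolation_flag_ : bool
        True when the fitted midpoint lies more than 10 K outside the
        sampled temperature range.
    converged_ : bool
    """

    def __init__(self, f0_fixed=None, fmax_fixed=None, scale="fraction", max_iter=500):
        self.f0_fixed = f0_fixed
        self.fmax_fixed = fmax_fixed
        self.scale = scale
        self.max_iter = max_iter

    def fit(self, T, f, se=None):
        """Fit to temperatures ``T`` (deg C) and fractions ``f``.

        ``se`` optionally supplies per-point standard errors used as inverse
        weights.
        """
        if self.scale not in ("fraction", "percent"):
            raise ValueError(f"unknown scale {self.scale!r}")
        t_c = np.asarray(T, dtype=float).ravel()
        f = np.asarray(f, dtype=float).ravel()
        if t_c.shape != f.shape:
            raise ValueError("T and f must have the same length")
        if not (np.isfinite(t_c).all() and np.isfinite(f).all()):
            raise ValueError("non-finite input")
        n_needed = 2 if (self.f0_fixed is not None and self.fmax_fixed is not None) else 4
        if np.unique(t_c).size < n_needed:
            raise ValueError(f"need at least {n_needed} distinct temperatures")
        if np.ptp(f) == 0.0:
            raise ValueError("all fractions are equal: no transition to fit")
        w = np.ones_like(f)
        if se is not None:
            se = np.asarray(se, dtype=float).ravel()
            if np.any(se > 0):
                w = 1.0 / np.where(se > 0, se, np.nanmin(se[se > 0]))

        t_k = celsius_to_kelvin(t_c)
        order = np.argsort(t_c)
        f_lo = f[order[0]] if self.f0_fixed is None else self.f0_fixed
        f_hi = f[order[-1]] if self.fmax_fixed is None else self.fmax_fixed
        # midpoint guess: sampled temperature closest to the half-range crossing
        half = 0.5 * (f_lo + f_hi)
        tm0 = t_k[np.argmin(np.abs(f - half))]
        dh0 = 3e5

        free = []  # (name, init, lower, upper)
        if self.f0_fixed is None:
            free.append(("f0", f_lo, -np.inf, np.inf))
        if self.fmax_fixed is None:
            free.append(("fmax", f_hi, -np.inf, np.inf))
        free.append(("tm", tm0, 1.0, np.inf))
        free.append(("dh", dh0, -np.inf, np.inf))
        names = [nm for nm, *_ in free]

        def unpack(theta):
            p = dict(zip(names, theta))
            f0 = p.get("f0", self.f0_fixed)
            fmax = p.get("fmax", self.fmax_fixed)
            return f0, fmax, p["tm"], p["dh"]

        def residuals(theta):
            f0, fmax, tm, dh = unpack(theta)
            return w * (thermal_model(t_k, f0, fmax, tm, dh) - f)

        res = optimize.least_squares(
            residuals,
            x0=[v for _, v, *_ in free],
            bounds=([lo for *_, lo, _ in free], [hi for *_, _, hi in free]),
            ftol=1e-12, xtol=1e-12, gtol=1e-12,
            max_nfev=self.max_iter * len(free),
        )
        f0, fmax, tm, dh = unpack(res.x)
        se_vec, _ = _standard_errors(res, t_k.size)
        se_map = dict(zip(names, se_vec))

        self.f0_ = float(f0)
        self.fmax_ = float(fmax)
        self.tm_k_ = float(tm)
        self.tm_c_ = float(kelvin_to_celsius(tm))
        self.dh_app_j_mol_ = float(dh)
        self.se_f0_ = float(se_map.get("f0", np.nan))
        self.se_fmax_ = float(se_map.get("fmax", np.nan))
        self.se_tm_c_ = float(se_map["tm"])
        self.se_dh_j_mol_ = float(se_map["dh"])
        self.converged_ = bool(res.success)
        self.extrapolation_flag_ = bool(
            tm < t_k.min() - 10.0 or tm > t_k.max() + 10.0
        )
        self.n_obs_ = int(t_k.size)
        return self

    def predict(self, T):
        """Model fraction at temperatures ``T`` in deg C."""
        return thermal_model(
            celsius_to_kelvin(T), self.f0_, self.fmax_, self.tm_k_, self.dh_app_j_mol_
        )


class ExponentialKineticsModel(BaseEstimator, RegressorMixin):
    """Single-exponential fit f(t) = f_end + (f_start - f_end) e^(-k t).

    The orientation (rising or falling) is inferred from the data; plateaus
    are free parameters.

    Attributes
    ----------
    k_per_s_ : float
        Rate constant, constrained positive.
    f_start_, f_end_ : float
    se_k_per_s_, se_f_start_, se_f_end_ : float
    converged_ : bool
        False when the optimizer fails or the rate collapses to the
        lower bound (effectively non-positive).
    """

    _K_FLOOR = 1e-12

    def __init__(self, max_iter=500):
        self.max_iter = max_iter

    def fit(self, t, f):
        t = np.asarray(t, dtype=float).ravel()
        f = np.asarray(f, dtype=float).ravel()
        if t.shape != f.shape:
            raise ValueError("t and f must have the same length")
        if np.unique(t).size < 4:
            raise ValueError("need at least 4 distinct time points")
        if np.any(t < 0):
            raise ValueError("time must be non-negative")
        span = np.ptp(f)
        if span == 0.0:
            raise ValueError("f_start equals f_end: no decay to fit")

        order = np.argsort(t)
        f_start0 = f[order[0]]
        f_end0 = f[order[-1]]
        if f_start0 == f_end0:  # noisy plateaus, nudge apart
            f_end0 = f_start0 + (np.sign(f[order[-1]] - f[order[0]]) or 1.0) * span
        # crude rate guess from the time at which half of the change occurred
        half = 0.5 * (f_start0 + f_end0)
        t_half = t[np.argmin(np.abs(f - half))]
        k0 = np.log(2.0) / t_half if t_half > 0 else 1.0 / max(np.median(t), 1.0)

        def residuals(theta):
            f_start, f_end, k = theta
            return f_end + (f_start - f_end) * np.exp(-k * t) - f

        res = optimize.least_squares(
            residuals,
            x0=[f_start0, f_end0, k0],
            bounds=([-np.inf, -np.inf, self._K_FLOOR], [np.inf, np.inf, np.inf]),
            ftol=1e-15, xtol=1e-15, gtol=1e-15,
            max_nfev=self.max_iter * 3,
        )
        f_start, f_end, k = res.x
        se, _ = _standard_errors(res, t.size)
        self.f_start_ = float(f_start)
        self.f_end_ = float(f_end)
        self.k_per_s_ = float(k)
        self.se_f_start_ = float(se[0])
        self.se_f_end_ = float(se[1])
        self.se_k_per_s_ = float(se[2])
        self.converged_ = bool(res.success and k > 10 * self._K_FLOOR)
        return self

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        return self.f_end_ + (self.f_start_ - self.f_end_) * np.exp(-self.k_per_s_ * t)


class ArrheniusModel(BaseEstimator, RegressorMixin):
    """Arrhenius regression: OLS of ln k on 1/T; Ea = -slope * R.

    Attributes
    ----------
    ea_j_mol_ : float
        Activation energy in J/mol (exactly ``-slope_ * R``).
    ln_pref_ : float
        Intercept (natural log of the pre-exponential factor).
    slope_, se_slope_, se_ea_j_mol_ : float
    temperatures_k_, rates_per_s_ : ndarray
        The fitted data, retained for reporting.
    """

    def fit(self, T, k):
        t_k = np.asarray(T, dtype=float).ravel()
        k = np.asarray(k, dtype=float).ravel()
        if t_k.shape != k.shape:
            raise ValueError("T and k must have the same length")
        if np.any(k <= 0):
            raise ValueError("all rate constants must be positive")
        if np.any(t_k <= 0):
            raise ValueError("temperatures must be positive (Kelvin)")
        if np.unique(t_k).size < 2:
            raise ValueError("need at least 2 distinct temperatures")
        reg = stats.linregress(1.0 / t_k, np.log(k))
        self.slope_ = float(reg.slope)
        self.ln_pref_ = float(reg.intercept)
        self.se_slope_ = float(reg.stderr)
        self.ea_j_mol_ = -self.slope_ * GAS_CONSTANT
        self.se_ea_j_mol_ = self.se_slope_ * GAS_CONSTANT
        self.temperatures_k_ = t_k.copy()
        self.rates_per_s_ = k.copy()
        return self

    def predict(self, T):
        t_k = np.asarray(T, dtype=float)
        return np.exp(self.ln_pref_ + self.slope_ / t_k)


def fit_thermal_transition(T, f, se=None, f0_fixed=None, fmax_fixed=None,
                           scale="fraction"):
    """Functional wrapper over :class:`ThermalTransitionModel`."""
    return ThermalTransitionModel(
        f0_fixed=f0_fixed, fmax_fixed=fmax_fixed, scale=scale
    ).fit(T, f, se=se)


def fit_kinetics(t, f):
    """Functional wrapper over :class:`ExponentialKineticsModel`."""
    return ExponentialKineticsModel().fit(t, f)


def arrhenius_fit(T_k, k):
    """Functional wrapper over :class:`ArrheniusModel` (T in Kelvin)."""
    return ArrheniusModel().fit(T_k, k)
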