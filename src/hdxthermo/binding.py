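"""DNA-binding equilibrium with fractional activity.

A fluorescently labelled heat-shock-element probe at concentration D is
titrated with protein trimer.  Only a per-condition fraction ``a_c`` of the
theoretical trimer concentration (monomer concentration / 3) is binding
competent, so the active protein is ``P = a_c * trimer``.  The fraction of
DNA bound follows the exact two-species solution of the mass-action
equilibrium

    bound = ((P + D + K) - sqrt((P + D + K)^2 - 4 P D)) / (2 D),

evaluated in the numerically stable equivalent form
``2 P / (P + D + K + sqrt(...))``, and the anisotropy readout is

    r = r_min + (r_max - r_min) * bound.

A single global fit over all pre-incubation conditions shares K_D, r_min and
r_max and estimates one active fraction per condition; the constancy of
``a_c`` along a dilution series encodes the observation that formed trimers
do not dissociate upon dilution.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator

from .transitions import _standard_errors

__all__ = [
    "bound_fraction_quadratic",
    "AnisotropyBindingModel",
    "fit_anisotropy_global",
    "fraction_active_surface",
]


def bound_fraction_quadratic(p_active_nM, dna_nM, kd_nM):
    """Exact fraction of DNA bound at active protein P, DNA D and K_D.

    All concentrations in nM (any single consistent unit works).  Vectorized
    over ``p_active_nM``.  ``dna_nM = 0`` reduces continuously to the
    hyperbolic limit ``P / (P + K)``.
    """
    p = np.asarray(p_active_nM, dtype=float)
    if np.any(p < 0):
        raise ValueError("active protein concentration must be non-negative")
    if dna_nM < 0:
        raise ValueError("dna_nM must be non-negative")
    if not kd_nM > 0:
        raise ValueError("kd_nM must be positive")
    s = p + dna_nM + kd_nM
    disc = s * s - 4.0 * p * dna_nM
    # algebraically identical to (s - sqrt(disc)) / (2 D) but free of
    # catastrophic cancellation, and valid at D = 0
    out = 2.0 * p / (s + np.sqrt(disc))
    out = np.clip(out, 0.0, 1.0)
    return out if out.ndim else float(out)


class AnisotropyBindingModel(BaseEstimator):
    """Global anisotropy fit: shared K_D / r_min / r_max, per-condition activity.

    Parameters
    ----------
    dna_nM : float
        Labelled probe concentration (default 10 nM).
    max_iter : int

    Attributes
    ----------
    kd_nM_ : float
        Shared dissociation constant of the fully active trimer.
    r_min_, r_max_ : float
        Shared anisotropy bounds (no binding / complete binding).
    active_fractions_ : dict
        Condition label -> fitted active fraction in [0, 1].
    se_kd_nM_, se_r_min_, se_r_max_, se_active_fractions_ : errors
    active_fraction_at_bound_ : dict
        Condition label -> bool, True when the estimate sits on 0 or 1.
    conditions_ : list of labels in input order
    converged_ : bool
    """

    def __init__(self, dna_nM=10.0, max_iter=500):
        self.dna_nM = dna_nM
        self.max_iter = max_iter

    def fit(self, data: pd.DataFrame, y=None):
        """Fit to a tidy table with columns condition, trimer_nM, anisotropy."""
        required = {"condition", "trimer_nM", "anisotropy"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if np.any(data["trimer_nM"].to_numpy(dtype=float) <= 0):
            raise ValueError("trimer_nM must be positive")
        r = data["anisotropy"].to_numpy(dtype=float)
        if np.ptp(r) == 0.0:
            raise ValueError("anisotropy shows no variation: nothing to fit")

        conditions = list(dict.fromkeys(data["condition"]))
        n_c = len(conditions)
        by_label = {label: grp for label, grp in data.groupby("condition", sort=False)}
        trimer = [by_label[c]["trimer_nM"].to_numpy(dtype=float) for c in conditions]
        aniso = [by_label[c]["anisotropy"].to_numpy(dtype=float) for c in conditions]

        r_min0 = float(r.min())
        span0 = float(np.ptp(r))
        kd0 = self.dna_nM / 2.0
        x0 = np.concatenate([[kd0, r_min0, span0], np.full(n_c, 0.5)])
        lb = np.concatenate([[1e-6, -np.inf, 1e-12], np.zeros(n_c)])
        ub = np.concatenate([[np.inf, np.inf, np.inf], np.ones(n_c)])

        def residuals(theta):
            kd, r_min, span = theta[:3]
            a = theta[3:]
            out = []
            for i in range(n_c):
                bound = bound_fraction_quadratic(a[i] * trimer[i], self.dna_nM, kd)
                out.append(r_min + span * bound - aniso[i])
            return np.concatenate(out)

        res = optimize.least_squares(
            residuals, x0, bounds=(lb, ub),
            ftol=1e-14, xtol=1e-14, gtol=1e-14,
            max_nfev=self.max_iter * x0.size,
        )
        kd, r_min, span = res.x[:3]
        a = res.x[3:]
        se, cov = _standard_errors(res, r.size)

        self.conditions_ = conditions
        self.kd_nM_ = float(kd)
        self.r_min_ = float(r_min)
        self.r_max_ = float(r_min + span)
        self.active_fractions_ = dict(zip(conditions, a.tolist()))
        self.se_kd_nM_ = float(se[0])
        self.se_r_min_ = float(se[1])
        v = cov[1, 1] + cov[2, 2] + 2.0 * cov[1, 2]
        self.se_r_max_ = float(np.sqrt(max(v, 0.0)))
        self.se_active_fractions_ = dict(zip(conditions, se[3:].tolist()))
        self.active_fraction_at_bound_ = {
            c: bool(ai < 1e-6 or ai > 1 - 1e-6) for c, ai in zip(conditions, a)
        }
        self.converged_ = bool(res.success)
        return self

    def predict(self, condition, trimer_nM):
        """Model anisotropy for one condition at trimer concentration(s)."""
        a = self.active_fractions_[condition]
        bound = bound_fraction_quadratic(
            a * np.asarray(trimer_nM, dtype=float), self.dna_nM, self.kd_nM_
        )
        return self.r_min_ + (self.r_max_ - self.r_min_) * bound


def fit_anisotropy_global(data, dna_nM=10.0) -> AnisotropyBindingModel:
    """Functional wrapper over :class:`AnisotropyBindingModel`."""
    return AnisotropyBindingModel(dna_nM=dna_nM).fit(data)


def fraction_active_surface(fits) -> pd.DataFrame:
    """Active-fraction surface over (temperature, pre-incubation concentration).

    ``fits`` is an iterable of fitted :class:`AnisotropyBindingModel`
    instances (one per independent replicate experiment) whose condition
    labels are ``(temperature_C, preincubation_nM)`` tuples.  Returns a tidy
    table with mean and SEM of the active fraction across replicates; the
    per-concentration temperature profiles feed the thermal transition fit
    to give concentration-resolved midpoints.
    """
    rows = []
    for rep, fit in enumerate(fits):
        for (temp, conc), a in fit.active_fractions_.items():
            rows.append({
                "temperature_C": float(temp),
                "preincubation_nM": float(conc),
                "replicate": rep,
                "active_fraction": float(a),
            })
    if not rows:
        raise ValueError("no fitted conditions supplied")
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["temperature_C", "preincubation_nM"])["active_fraction"]
        .agg(active_fraction_mean="mean",
             active_fraction_sem=lambda s: s.sem(ddof=1) if len(s) > 1 else 0.0,
             n="count")
        .reset_index()
    )
    return out
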