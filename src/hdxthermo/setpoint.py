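"""Monomer-dimer mass-action model of the concentration-dependent midpoint.

The observed transition midpoint Tm of the thermosensor depends on total
protein concentration.  Assuming a monomer-dimer pre-equilibrium

    2 M <-> D,    K = [M]^2 / [D]   (dissociation constant, monomer units)

and that the measured Tm interpolates linearly between a monomer midpoint
Tm_M and a (lower) dimer midpoint Tm_D with the fraction of protein in the
dimer state:

    Tm(c) = Tm_M + f_D(c) * (Tm_D - Tm_M).

The quadratic mass-action solution gives, for total monomer-unit
concentration c,

    [M] = K (sqrt(1 + 8 c / K) - 1) / 4,   [D] = [M]^2 / K,

and by default f_D is the fraction of monomer *units* in dimers, 2[D]/c,
which is exactly 1/2 at c = K.  The alternative molecule-count convention
f_D = [D]/([M]+[D]) is available via ``fraction_convention="molecules"``.

Fitting (c, Tm) data yields rough estimates of (K, Tm_M, Tm_D); the fit is
sensitive to points at low concentration, and a caveat flag is raised when
none are sampled.  The same forward model simulates chaperone-induced
parameter changes and maps cellular concentration estimates to predicted
setpoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin

from .transitions import _standard_errors

__all__ = [
    "DimerParams",
    "monomer_dimer_fraction",
    "tm_of_concentration",
    "DimerSetpointModel",
    "fit_dimer_model",
    "simulate_variants",
    "cellular_setpoint",
]


@dataclass(frozen=True)
class DimerParams:
    """Parameters of the monomer-dimer setpoint model.

    ``kd_dim_nM`` is the dissociation constant [M]^2/[D] in monomer-unit nM;
    ``tm_dimer_c < tm_monomer_c`` (the dimer activates at lower temperature).
    """

    kd_dim_nM: float
    tm_monomer_c: float
    tm_dimer_c: float
    fraction_convention: str = "units"

    def __post_init__(self):
        if not self.kd_dim_nM > 0:
            raise ValueError("kd_dim_nM must be positive")
        if not self.tm_dimer_c < self.tm_monomer_c:
            raise ValueError("tm_dimer_c must be below tm_monomer_c")
        if self.fraction_convention not in ("units", "molecules"):
            raise ValueError("fraction_convention must be 'units' or 'molecules'")

    def replace(self, **overrides) -> "DimerParams":
        import dataclasses

        return dataclasses.replace(self, **overrides)


def monomer_dimer_fraction(c_total_nM, kd_dim_nM, convention="units"):
    """Equilibrium composition of the monomer-dimer system.

    Returns a dict with ``monomer_nM``, ``dimer_nM`` and
    ``fraction_in_dimer``.  Mass conservation [M] + 2[D] = c holds exactly;
    ``c_total_nM = 0`` gives fraction 0 by continuity.  Vectorized.
    """
    c = np.asarray(c_total_nM, dtype=float)
    if np.any(c < 0):
        raise ValueError("c_total_nM must be non-negative")
    if not kd_dim_nM > 0:
        raise ValueError("kd_dim_nM must be positive")
    m = kd_dim_nM * (np.sqrt(1.0 + 8.0 * c / kd_dim_nM) - 1.0) / 4.0
    d = m * m / kd_dim_nM
    with np.errstate(invalid="ignore", divide="ignore"):
        if convention == "units":
            frac = np.where(c > 0, 2.0 * d / np.where(c > 0, c, 1.0), 0.0)
        elif convention == "molecules":
            tot = m + d
            frac = np.where(tot > 0, d / np.where(tot > 0, tot, 1.0), 0.0)
        else:
            raise ValueError("convention must be 'units' or 'molecules'")
    scalar = c.ndim == 0
    return {
        "monomer_nM": float(m) if scalar else m,
        "dimer_nM": float(d) if scalar else d,
        "fraction_in_dimer": float(frac) if scalar else frac,
    }


def tm_of_concentration(c_total_nM, params: DimerParams):
    """Predicted transition midpoint (deg C) at total concentration c (nM).

    Monotone non-increasing in c and bounded in [Tm_D, Tm_M].
    """
    frac = monomer_dimer_fraction(
        c_total_nM, params.kd_dim_nM, params.fraction_convention
    )["fraction_in_dimer"]
    return params.tm_monomer_c + frac * (params.tm_dimer_c - params.tm_monomer_c)


class DimerSetpointModel(BaseEstimator, RegressorMixin):
    """Least-squares fit of the monomer-dimer setpoint model to (c, Tm) data.

    Parameters
    ----------
    fraction_convention : {"units", "molecules"}
        Dimer-fraction bookkeeping (see module docstring).
    max_iter : int

    Attributes
    ----------
    kd_dim_nM_, tm_monomer_c_, tm_dimer_c_ : float
    se_kd_dim_nM_, se_tm_monomer_c_, se_tm_dimer_c_ : float
    params_ : DimerParams
    low_conc_caveat_ : bool
        True when no data point lies below kd/3: the monomer plateau is then
        an extrapolation and the estimates are rough.
    kd_identifiable_ : bool
        True when at least one sampled concentration falls inside the
        transition region (dimer fraction between 0.1 and 0.9).
    converged_ : bool
    """

    def __init__(self, fraction_convention="units", max_iter=500):
        self.fraction_convention = fraction_convention
        self.max_iter = max_iter

    def fit(self, c, tm):
        c = np.asarray(c, dtype=float).ravel()
        tm = np.asarray(tm, dtype=float).ravel()
        if c.shape != tm.shape:
            raise ValueError("c and tm must have the same length")
        if np.any(c <= 0):
            raise ValueError("concentrations must be positive")
        if np.unique(c).size < 3:
            raise ValueError("need at least 3 distinct concentrations")
        if np.ptp(tm) == 0.0:
            raise ValueError("flat Tm data: model is degenerate")

        tm_m0 = float(tm.max())
        tm_d0 = float(tm.min())
        kd0 = float(np.exp(np.mean(np.log(c))))
        lb = [1e-9, -np.inf, -np.inf]
        ub = [np.inf, np.inf, np.inf]

        def residuals(theta):
            kd, tm_m, tm_d = theta
            frac = monomer_dimer_fraction(c, kd, self.fraction_convention)[
                "fraction_in_dimer"]
            return tm_m + frac * (tm_d - tm_m) - tm

        res = optimize.least_squares(
            residuals, [kd0, tm_m0, tm_d0], bounds=(lb, ub),
            ftol=1e-14, xtol=1e-14, gtol=1e-14,
            max_nfev=self.max_iter * 3,
        )
        kd, tm_m, tm_d = res.x
        se, _ = _standard_errors(res, c.size)

        self.kd_dim_nM_ = float(kd)
        self.tm_monomer_c_ = float(tm_m)
        self.tm_dimer_c_ = float(tm_d)
        self.se_kd_dim_nM_ = float(se[0])
        self.se_tm_monomer_c_ = float(se[1])
        self.se_tm_dimer_c_ = float(se[2])
        self.converged_ = bool(res.success)
        frac = monomer_dimer_fraction(c, kd, self.fraction_convention)[
            "fraction_in_dimer"]
        self.kd_identifiable_ = bool(np.any((frac > 0.1) & (frac < 0.9)))
        self.low_conc_caveat_ = bool(not np.any(c < kd / 3.0))
        self.params_ = (
            DimerParams(kd, tm_m, tm_d, self.fraction_convention)
            if tm_d < tm_m else None
        )
        return self

    def predict(self, c):
        params = self.params_
        if params is None:
            # inverted orientation: evaluate the raw interpolation directly
            frac = monomer_dimer_fraction(
                c, self.kd_dim_nM_, self.fraction_convention)["fraction_in_dimer"]
            return self.tm_monomer_c_ + frac * (self.tm_dimer_c_ - self.tm_monomer_c_)
        return tm_of_concentration(c, params)


def fit_dimer_model(c, tm, **kwargs) -> DimerSetpointModel:
    """Functional wrapper over :class:`DimerSetpointModel`."""
    return DimerSetpointModel(**kwargs).fit(c, tm)


def simulate_variants(base: DimerParams, variants, c_grid) -> pd.DataFrame:
    """Tm-vs-concentration curves for a base model and parameter overrides.

    ``variants`` maps a variant name to a dict of ``DimerParams`` field
    overrides (e.g. chaperone effects as a lowered dimerization K_D and/or
    dimer midpoint).  The base model is always included under ``"base"``.
    """
    c_grid = np.asarray(c_grid, dtype=float)
    curves = {"base": base}
    for name, overrides in dict(variants).items():
        curves[name] = base.replace(**overrides)
    rows = []
    for name, params in curves.items():
        tm = tm_of_concentration(c_grid, params)
        for ci, ti in zip(c_grid, np.atleast_1d(tm)):
            rows.append({"variant": name, "c_nM": float(ci), "tm_C": float(ti)})
    return pd.DataFrame(rows)


def cellular_setpoint(mass_fraction, total_protein_mg_per_ml, mw_kDa,
                      enrichment_fold, model: DimerParams | None = None):
    """Cytosolic and locally enriched concentration and the implied setpoint.

    ``mass_fraction`` is the protein's share of total cellular protein mass;
    with total protein in mg/ml and molecular weight in kDa the cytosolic
    concentration in nM is ``mass_fraction * total * 1e6 / mw``.  Nuclear
    accumulation multiplies this by ``enrichment_fold``; when a
    :class:`DimerParams` model is given, the predicted Tm at the local
    concentration is included.
    """
    for name, v in (("mass_fraction", mass_fraction),
                    ("total_protein_mg_per_ml", total_protein_mg_per_ml),
                    ("mw_kDa", mw_kDa), ("enrichment_fold", enrichment_fold)):
        if not v > 0:
            raise ValueError(f"{name} must be positive")
    cytosolic = mass_fraction * total_protein_mg_per_ml * 1e6 / mw_kDa
    local = cytosolic * enrichment_fold
    out = {"cytosolic_nM": float(cytosolic), "local_nM": float(local)}
    if model is not None:
        out["predicted_tm_C"] = float(tm_of_concentration(local, model))
    return out
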