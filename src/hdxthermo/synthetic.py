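"""Synthetic data generators mirroring the models the pipeline fits.

The generators produce bimodal isotope envelopes whose subpopulation weights
follow a thermal-transition or exponential law, anisotropy titrations with
partial activity, and noisy (concentration, Tm) datasets.  Every generator
is seeded explicitly and returns the true parameters alongside the data so
that recovery can be asserted in tests.  These emulate the *statistical*
structure of centroided HDX-MS peak lists and plate-reader titrations, not
raw instrument data: there is no chromatography, no charge-state envelope
beyond the declared charge, and the natural isotopic fine structure is
subsumed into the low-exchanging Gaussian, exactly as the fitted model
assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding import bound_fraction_quadratic
from .envelopes import IsotopeCluster
from .setpoint import DimerParams, tm_of_concentration
from .transitions import celsius_to_kelvin, thermal_model

__all__ = [
    "ThermalLaw",
    "ExponentialLaw",
    "ExplicitFractions",
    "ExchangeScenario",
    "BindingScenario",
    "TmScenario",
    "simulate_isotope_envelope",
    "simulate_series",
    "simulate_anisotropy",
    "simulate_tm_dataset",
    "standard_thermal_scenario",
    "standard_kinetic_scenario",
]

#: Compromise isotopologue spacing (Da per unit charge) between the 13C and
#: 2H mass differences; generator and fitter share whatever spacing the data
#: carry, so this only affects synthesis.
DEFAULT_ISOTOPE_SPACING = 1.00336


@dataclass(frozen=True)
class ThermalLaw:
    """Thermal-transition law for the high-exchanging fraction vs T (deg C).

    The default steepness (3.5e5 J/mol at Tm near 309 K) makes the 10-90 %
    transition span roughly 10 deg C.
    """

    f0: float = 0.0
    fmax: float = 1.0
    tm_c: float = 36.15
    dh_j_mol: float = 3.5e5

    def __call__(self, t_c):
        return thermal_model(
            celsius_to_kelvin(t_c), self.f0, self.fmax,
            float(celsius_to_kelvin(self.tm_c)), self.dh_j_mol,
        )


@dataclass(frozen=True)
class ExponentialLaw:
    """Single-exponential law for the fraction vs time (s)."""

    k_per_s: float
    f_start: float = 0.0
    f_end: float = 1.0

    def __call__(self, t_s):
        t_s = np.asarray(t_s, dtype=float)
        out = self.f_end + (self.f_start - self.f_end) * np.exp(-self.k_per_s * t_s)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class ExplicitFractions:
    """Explicit per-condition fractions, matched to condition_values by order."""

    values: tuple

    def __call__(self, _x):
        raise TypeError("ExplicitFractions are indexed, not evaluated")


def _check_finite(name, value):
    if not np.all(np.isfinite(value)):
        raise ValueError(f"scenario field {name!r} must be finite")


@dataclass(frozen=True)
class ExchangeScenario:
    """Recipe for a synthetic bimodal envelope series.

    Defaults emulate a singly charged peptic peptide near m/z 1155 with a
    2 % intensity noise floor and a thermal transition at 36.15 deg C.
    """

    peptide_id: str = "159-168"
    charge: int = 1
    n_peaks: int = 12
    mz_start: float = 1154.0
    isotope_spacing: float = DEFAULT_ISOTOPE_SPACING
    centroid_low: float = 1157.5
    centroid_high: float = 1161.5
    sigma_true: float = 1.0
    condition_axis: str = "temperature_C"
    condition_values: tuple = (20.0, 30.0, 34.0, 36.0, 38.0, 40.0, 42.0)
    fraction_law: object = field(default_factory=ThermalLaw)
    noise_rel: float = 0.02
    total_area: float = 1e6
    seed: int = 0

    def __post_init__(self):
        for name in ("mz_start", "isotope_spacing", "centroid_low",
                     "centroid_high", "sigma_true", "noise_rel", "total_area"):
            _check_finite(name, getattr(self, name))
        _check_finite("condition_values", np.asarray(self.condition_values, float))
        if self.charge < 1:
            raise ValueError("scenario field 'charge' must be a positive integer")
        if self.n_peaks < 6:
            raise ValueError("scenario field 'n_peaks' must be >= 6")
        if not self.centroid_low < self.centroid_high:
            raise ValueError("centroid_low must be below centroid_high")
        if not self.sigma_true > 0:
            raise ValueError("scenario field 'sigma_true' must be positive")
        if self.noise_rel < 0:
            raise ValueError("scenario field 'noise_rel' must be >= 0")
        if self.condition_axis not in ("temperature_C", "time_s"):
            raise ValueError("condition_axis must be 'temperature_C' or 'time_s'")
        if len(self.condition_values) == 0:
            raise ValueError("condition_values must be non-empty")

    @property
    def mz_grid(self) -> np.ndarray:
        step = self.isotope_spacing / self.charge
        return self.mz_start + step * np.arange(self.n_peaks)


def simulate_isotope_envelope(scenario: ExchangeScenario, fraction_high,
                              rng=None) -> IsotopeCluster:
    """One synthetic envelope at a given high-exchanging fraction.

    Peak intensities are the two-Gaussian mixture density evaluated on the
    isotope grid, scaled so the discrete sum approximates ``total_area``,
    with additive Gaussian noise (sd = noise_rel * max clean intensity)
    truncated at zero.
    """
    if not 0.0 <= fraction_high <= 1.0:
        raise ValueError("fraction_high must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    mz = scenario.mz_grid
    step = scenario.isotope_spacing / scenario.charge
    sig = scenario.sigma_true
    dens = (
        (1.0 - fraction_high) * _normal_pdf(mz, scenario.centroid_low, sig)
        + fraction_high * _normal_pdf(mz, scenario.centroid_high, sig)
    )
    clean = scenario.total_area * step * dens
    if scenario.noise_rel > 0:
        noise = rng.normal(0.0, scenario.noise_rel * clean.max(), size=mz.size)
        intensity = np.clip(clean + noise, 0.0, None)
    else:
        intensity = clean
    axis = scenario.condition_axis
    return IsotopeCluster(scenario.peptide_id, scenario.charge, axis,
                          float("nan"), mz, intensity)


def _normal_pdf(x, mu, sigma):
    z = (x - mu) / sigma
    return np.exp(-0.5 * z * z) / (sigma * np.sqrt(2.0 * np.pi))


def true_fractions(scenario: ExchangeScenario) -> np.ndarray:
    """The generator's true high-exchanging fraction at each condition."""
    law = scenario.fraction_law
    values = np.asarray(scenario.condition_values, dtype=float)
    if isinstance(law, ExplicitFractions):
        fr = np.asarray(law.values, dtype=float)
        if fr.size != values.size:
            raise ValueError("ExplicitFractions length must match condition_values")
    elif isinstance(law, ThermalLaw):
        if scenario.condition_axis != "temperature_C":
            raise ValueError("thermal law requires a temperature_C axis")
        fr = np.asarray(law(values), dtype=float)
    elif isinstance(law, ExponentialLaw):
        if scenario.condition_axis != "time_s":
            raise ValueError("exponential law requires a time_s axis")
        fr = np.asarray(law(values), dtype=float)
    else:
        raise TypeError(f"unknown fraction law {law!r}")
    if np.any((fr < 0) | (fr > 1)):
        raise ValueError("fraction law produced values outside [0, 1]")
    return fr


def simulate_series(scenario: ExchangeScenario):
    """Envelope series following the scenario's fraction law.

    Returns ``(clusters, fractions)`` where ``fractions`` are the true
    per-condition high-exchanging fractions.  A fixed seed gives
    bit-identical output.
    """
    fr = true_fractions(scenario)
    rng = np.random.default_rng(scenario.seed)
    clusters = []
    for value, f in zip(scenario.condition_values, fr):
        cl = simulate_isotope_envelope(scenario, float(f), rng=rng)
        cl.condition_value = float(value)
        clusters.append(cl)
    return clusters, fr


@dataclass(frozen=True)
class BindingScenario:
    """Recipe for synthetic anisotropy titrations with partial activity.

    ``conditions`` holds ``(label, active_fraction, top_trimer_nM)`` triples;
    each condition is serially diluted ``n_dilutions`` times by
    ``dilution_factor``.  Defaults mirror a four-concentration heat-shock
    panel titrated against 10 nM labelled probe with K_D = 1.1 nM.
    """

    kd_nM: float = 1.1
    r_min: float = 0.05
    r_max: float = 0.25
    dna_nM: float = 10.0
    conditions: tuple = (
        ("100nM", 0.0, 100.0 / 3.0),
        ("300nM", 0.2, 300.0 / 3.0),
        ("1000nM", 0.6, 1000.0 / 3.0),
        ("5000nM", 0.9, 5000.0 / 3.0),
    )
    dilution_factor: float = 2.0
    n_dilutions: int = 12
    noise_sd: float = 0.004
    seed: int = 0

    def __post_init__(self):
        if not self.kd_nM > 0:
            raise ValueError("kd_nM must be positive")
        if not self.r_min < self.r_max:
            raise ValueError("r_min must be below r_max")
        if not self.dna_nM > 0:
            raise ValueError("dna_nM must be positive")
        if not self.dilution_factor > 1:
            raise ValueError("dilution_factor must exceed 1")
        if self.n_dilutions < 1:
            raise ValueError("n_dilutions must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for label, a, top in self.conditions:
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"condition {label!r}: active_fraction outside [0,1]")
            if not top > 0:
                raise ValueError(f"condition {label!r}: top_trimer_nM must be positive")


def simulate_anisotropy(scenario: BindingScenario):
    """Synthetic anisotropy dataset plus the true generating parameters.

    Returns ``(data, truth)``: a tidy DataFrame with columns condition,
    trimer_nM, anisotropy, replicate_id, and a dict of the true parameters.
    """
    rng = np.random.default_rng(scenario.seed)
    rows = []
    for label, a, top in scenario.conditions:
        trimer = top / scenario.dilution_factor ** np.arange(scenario.n_dilutions)
        bound = bound_fraction_quadratic(a * trimer, scenario.dna_nM, scenario.kd_nM)
        r = scenario.r_min + (scenario.r_max - scenario.r_min) * bound
        if scenario.noise_sd > 0:
            r = r + rng.normal(0.0, scenario.noise_sd, size=trimer.size)
        for t, ri in zip(trimer, r):
            rows.append({"condition": label, "trimer_nM": float(t),
                         "anisotropy": float(ri), "replicate_id": 0})
    truth = {
        "kd_nM": scenario.kd_nM,
        "r_min": scenario.r_min,
        "r_max": scenario.r_max,
        "active_fractions": {label: a for label, a, _ in scenario.conditions},
    }
    return pd.DataFrame(rows), truth


@dataclass(frozen=True)
class TmScenario:
    """Recipe for noisy (concentration, Tm) datasets from a dimer model."""

    model: DimerParams = field(
        default_factory=lambda: DimerParams(330.0, 53.0, 33.0))
    concentrations_nM: tuple = (50.0, 150.0, 500.0, 1500.0, 5000.0)
    noise_sd_C: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if np.any(np.asarray(self.concentrations_nM, float) <= 0):
            raise ValueError("concentrations_nM must be positive")
        if self.noise_sd_C < 0:
            raise ValueError("noise_sd_C must be >= 0")


def simulate_tm_dataset(scenario: TmScenario) -> pd.DataFrame:
    """Noisy Tm-vs-concentration points drawn around the model curve."""
    rng = np.random.default_rng(scenario.seed)
    c = np.asarray(scenario.concentrations_nM, dtype=float)
    tm = np.atleast_1d(tm_of_concentration(c, scenario.model)).astype(float)
    if scenario.noise_sd_C > 0:
        tm = tm + rng.normal(0.0, scenario.noise_sd_C, size=c.size)
    return pd.DataFrame({"concentration_nM": c, "tm_C": tm})


def standard_thermal_scenario(seed=0, noise_rel=0.02) -> ExchangeScenario:
    """Seven-temperature series with the 36.15 deg C midpoint default law."""
    return ExchangeScenario(seed=seed, noise_rel=noise_rel)


def standard_kinetic_scenario(k_per_s, seed=0, noise_rel=0.02,
                                falling=True) -> ExchangeScenario:
    """Kinetic series at the standard 10-1000 s time points.

    ``falling=True`` tracks a low-exchanging population decaying away, i.e.
    the high-exchanging fraction rises from 0 to 1 with rate ``k_per_s``.
    """
    f_start, f_end = (0.0, 1.0) if falling else (1.0, 0.0)
    return ExchangeScenario(
        condition_axis="time_s",
        condition_values=(10.0, 30.0, 60.0, 100.0, 300.0, 600.0, 1000.0),
        fraction_law=ExponentialLaw(k_per_s, f_start=f_start, f_end=f_end),
        seed=seed, noise_rel=noise_rel,
    )
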