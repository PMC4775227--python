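"""Two-Gaussian deconvolution of bimodal HDX-MS isotope envelopes.

In the EX1 exchange regime a peptide's isotope cluster is a superposition of
two subpopulations — a low-exchanging (light) and a high-exchanging (heavy)
envelope.  Each envelope is approximated by a Gaussian evaluated at the
discrete isotope-peak positions:

    I(mu) = A1/(sigma sqrt(2 pi)) exp(-((mu - mu1)/sigma)^2 / 2)
          + A2/(sigma sqrt(2 pi)) exp(-((mu - mu2)/sigma)^2 / 2)

All spectra of one temperature or time series are fitted jointly with the
centroids mu1 < mu2 and the width sigma shared across the series and the two
areas A1, A2 free per spectrum.  The fitted parameters are then used to
attribute each observed peak intensity to the two subpopulations, which
yields the fraction of high-exchanging molecules per condition — the raw
datum for all downstream transition and kinetic fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator

from .transitions import _standard_errors

__all__ = [
    "IsotopeCluster",
    "SubpopulationSplit",
    "UptakeResult",
    "evaluate_bimodal",
    "BimodalSeriesModel",
    "fit_bimodal_series",
    "split_peak_intensities",
    "centroid",
    "centroid_uptake",
    "uptake_difference",
]

_SQRT_2PI = np.sqrt(2.0 * np.pi)

CONDITION_TYPES = ("temperature_C", "time_s", "control")
CONTROL_TAGS = ("unexchanged", "fully_deuterated")


@dataclass
class IsotopeCluster:
    """One peptide/charge isotope envelope at one condition.

    ``peaks`` are centroided (m/z, intensity) pairs with strictly increasing
    m/z, at least 4 peaks, and consecutive spacings within +/-20 % of the
    median spacing.  ``condition_value`` is a number for temperature/time
    series or one of the control tags ``unexchanged`` / ``fully_deuterated``.
    """

    peptide_id: str
    charge: int
    condition_type: str
    condition_value: object
    mz: np.ndarray = field(repr=False)
    intensity: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.charge < 1:
            raise ValueError(f"{self._tag()}: charge must be a positive integer")
        if self.condition_type not in CONDITION_TYPES:
            raise ValueError(
                f"{self._tag()}: unknown condition_type {self.condition_type!r}"
            )
        if self.condition_type == "control":
            if self.condition_value not in CONTROL_TAGS:
                raise ValueError(
                    f"{self._tag()}: control condition_value must be one of "
                    f"{CONTROL_TAGS}"
                )
        else:
            self.condition_value = float(self.condition_value)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError(f"{self._tag()}: mz/intensity must be equal-length 1-D")
        if self.mz.size < 4:
            raise ValueError(f"{self._tag()}: needs at least 4 peaks, got {self.mz.size}")
        d = np.diff(self.mz)
        if np.any(d <= 0):
            raise ValueError(f"{self._tag()}: m/z values must be strictly increasing")
        med = np.median(d)
        if np.any(np.abs(d - med) > 0.2 * med):
            raise ValueError(
                f"{self._tag()}: peak spacing deviates more than 20 % from the median"
            )
        if np.any(self.intensity < 0):
            raise ValueError(f"{self._tag()}: negative intensity")

    def _tag(self):
        return f"cluster {self.peptide_id}/{self.charge}+ @ {self.condition_value}"

    @property
    def spacing(self) -> float:
        """Median peak spacing in Da/e."""
        return float(np.median(np.diff(self.mz)))

    @property
    def span(self) -> float:
        return float(self.mz[-1] - self.mz[0])


@dataclass
class SubpopulationSplit:
    """Per-peak attribution of observed intensity to the two subpopulations."""

    intensity_low: np.ndarray
    intensity_high: np.ndarray
    f_high: float

    @property
    def f_low(self) -> float:
        return 1.0 - self.f_high


@dataclass
class UptakeResult:
    """Centroid-based deuteron uptake with two-point back-exchange correction."""

    centroid: float
    deuterons: float
    corrected_deuterons: float


def _gauss(mu, center, sigma):
    z = (np.asarray(mu, dtype=float) - center) / sigma
    return np.exp(-0.5 * z * z) / (sigma * _SQRT_2PI)


def evaluate_bimodal(mu, a1, a2, mu1_bar, mu2_bar, sigma):
    """Two-Gaussian mixture intensity at position(s) ``mu``.

    ``a1`` and ``a2`` are the areas of the low- and high-exchanging
    components, ``mu1_bar``/``mu2_bar`` their centroids and ``sigma`` the
    single shared width.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return a1 * _gauss(mu, mu1_bar, sigma) + a2 * _gauss(mu, mu2_bar, sigma)


def centroid(cluster: IsotopeCluster) -> float:
    """Intensity-weighted mean m/z of a cluster."""
    total = cluster.intensity.sum()
    if total <= 0:
        raise ValueError(f"{cluster._tag()}: zero total intensity")
    return float(np.dot(cluster.mz, cluster.intensity) / total)


class BimodalSeriesModel(BaseEstimator):
    """Global two-Gaussian fit to a temperature or time series of envelopes.

    The centroids and width are shared across all spectra of the series; the
    component areas are free per spectrum, constrained non-negative.  Control
    spectra (``condition_type == "control"``) inform the initialization only
    and are excluded from the fit.

    Parameters
    ----------
    max_iter : int
        Iteration cap for each optimizer start.
    restarts : int
        Number of jittered restarts tried before declaring non-convergence.
    sse_rtol : float
        Relative cost-change convergence tolerance.
    min_component_fraction : float
        A component whose largest per-spectrum area share stays below this
        value across the whole series is declared unidentifiable (its shared
        centroid is then arbitrary).

    Attributes
    ----------
    mu1_bar_, mu2_bar_, sigma_ : float
        Shared parameters, with ``mu1_bar_ < mu2_bar_`` enforced so that
        "high-exchanging" always refers to the heavier centroid.
    areas_ : ndarray of shape (n_spectra, 2)
        Per-spectrum component areas (A1, A2), non-negative.
    f_high_ : ndarray of shape (n_spectra,)
        A2 / (A1 + A2) per spectrum.
    se_f_high_, se_areas_ : ndarray
        Delta-method / covariance standard errors.
    residual_sse_ : ndarray of shape (n_spectra,)
    conditions_ : list
        ``(condition_type, condition_value)`` per fitted spectrum, in input
        order.
    converged_ : bool
    mu1_identifiable_, mu2_identifiable_ : bool
    """

    def __init__(self, max_iter=500, restarts=3, sse_rtol=1e-10,
                 min_component_fraction=0.02):
        self.max_iter = max_iter
        self.restarts = restarts
        self.sse_rtol = sse_rtol
        self.min_component_fraction = min_component_fraction

    # -- initialization helpers ------------------------------------------
    @staticmethod
    def _rms_width(cluster):
        c = centroid(cluster)
        w = cluster.intensity / cluster.intensity.sum()
        return float(np.sqrt(np.dot(w, (cluster.mz - c) ** 2)))

    def _initial_areas(self, cluster, mu1, mu2, sigma):
        """Coarse 11-point fraction-grid split of the total area."""
        total = cluster.intensity.sum() * cluster.spacing
        best, best_sse = (total, 0.0), np.inf
        for g in np.linspace(0.0, 1.0, 11):
            model = evaluate_bimodal(cluster.mz, (1 - g) * total, g * total,
                                     mu1, mu2, sigma)
            sse = float(np.sum((model - cluster.intensity) ** 2))
            if sse < best_sse:
                best, best_sse = ((1 - g) * total, g * total), sse
        return best

    def fit(self, clusters, y=None):
        clusters = list(clusters)
        if not clusters:
            raise ValueError("empty series")
        pep, chg = clusters[0].peptide_id, clusters[0].charge
        for c in clusters:
            if (c.peptide_id, c.charge) != (pep, chg):
                raise ValueError(
                    f"series mixes peptides/charges: {c._tag()} vs {pep}/{chg}+"
                )
        controls = {c.condition_value: c for c in clusters
                    if c.condition_type == "control"}
        series = [c for c in clusters if c.condition_type != "control"]
        if not series:
            raise ValueError("series contains only control spectra")

        order = np.argsort([c.condition_value for c in series])
        lowest, highest = series[order[0]], series[order[-1]]
        c_init_1 = centroid(controls.get("unexchanged", lowest))
        c_init_2 = centroid(controls.get("fully_deuterated", highest))
        mu1_0, mu2_0 = sorted((c_init_1, c_init_2))
        sigma0 = max(self._rms_width(lowest), 0.25 * lowest.spacing)
        spacing = float(np.median([c.spacing for c in series]))
        if mu2_0 - mu1_0 < spacing:
            mu2_0 = mu1_0 + max(spacing, 2.0 * sigma0)

        span = max(c.span for c in series)
        mz_lo = min(c.mz[0] for c in series)
        mz_hi = max(c.mz[-1] for c in series)
        n = len(series)

        area0 = np.empty((n, 2))
        for i, c in enumerate(series):
            area0[i] = self._initial_areas(c, mu1_0, mu2_0, sigma0)

        gap_floor = 1e-6
        lb = np.concatenate([[mz_lo - span, gap_floor, 1e-4],
                             np.zeros(2 * n)])
        ub = np.concatenate([[mz_hi + span, 2.0 * span, span],
                             np.full(2 * n, np.inf)])

        def residuals(theta):
            mu1, gap, sigma = theta[:3]
            areas = theta[3:].reshape(n, 2)
            out = []
            for i, c in enumerate(series):
                out.append(
                    evaluate_bimodal(c.mz, areas[i, 0], areas[i, 1],
                                     mu1, mu1 + gap, sigma) - c.intensity
                )
            return np.concatenate(out)

        x0 = np.concatenate([[mu1_0, mu2_0 - mu1_0, sigma0], area0.ravel()])
        x0 = np.clip(x0, lb, ub)
        rng = np.random.default_rng(0)  # jitter only; fit itself is deterministic
        best = None
        for attempt in range(1 + self.restarts):
            start = x0.copy()
            if attempt:
                start[0] += rng.normal(0.0, 0.5 * spacing)
                start[1] = abs(start[1] + rng.normal(0.0, spacing))
                start[2] = abs(start[2] * rng.uniform(0.5, 1.5))
                start = np.clip(start, lb, ub)
            res = optimize.least_squares(
                residuals, start, bounds=(lb, ub),
                ftol=self.sse_rtol, xtol=1e-14, gtol=1e-14,
                max_nfev=self.max_iter * x0.size,
            )
            if best is None or res.cost < best.cost:
                best = res
            if res.success:
                break
        res = best

        mu1, gap, sigma = res.x[:3]
        areas = res.x[3:].reshape(n, 2)
        n_obs = sum(c.mz.size for c in series)
        se, cov = _standard_errors(res, n_obs)

        self.peptide_id_ = pep
        self.charge_ = chg
        self.mu1_bar_ = float(mu1)
        self.mu2_bar_ = float(mu1 + gap)
        self.sigma_ = float(sigma)
        self.areas_ = areas
        self.conditions_ = [(c.condition_type, c.condition_value) for c in series]
        self.clusters_ = series
        self.converged_ = bool(res.success)

        self.se_mu1_bar_ = float(se[0])
        # var(mu2) = var(mu1) + var(gap) + 2 cov(mu1, gap)
        v = cov[0, 0] + cov[1, 1] + 2.0 * cov[0, 1]
        self.se_mu2_bar_ = float(np.sqrt(max(v, 0.0)))
        self.se_sigma_ = float(se[2])
        self.se_areas_ = se[3:].reshape(n, 2)

        totals = areas.sum(axis=1)
        with np.errstate(invalid="ignore"):
            self.f_high_ = np.where(totals > 0, areas[:, 1] / totals, np.nan)
        se_f = np.full(n, np.nan)
        for i in range(n):
            if totals[i] <= 0:
                continue
            j1, j2 = 3 + 2 * i, 4 + 2 * i
            g = np.array([-areas[i, 1], areas[i, 0]]) / totals[i] ** 2
            sub = cov[np.ix_([j1, j2], [j1, j2])]
            se_f[i] = np.sqrt(max(g @ sub @ g, 0.0))
        self.se_f_high_ = se_f

        self.residual_sse_ = np.array([
            float(np.sum((evaluate_bimodal(c.mz, areas[i, 0], areas[i, 1],
                                           self.mu1_bar_, self.mu2_bar_,
                                           self.sigma_) - c.intensity) ** 2))
            for i, c in enumerate(series)
        ])
        shares_high = np.where(totals > 0, areas[:, 1] / totals, 0.0)
        shares_low = np.where(totals > 0, areas[:, 0] / totals, 0.0)
        self.mu2_identifiable_ = bool(shares_high.max() >= self.min_component_fraction)
        self.mu1_identifiable_ = bool(shares_low.max() >= self.min_component_fraction)
        return self

    def predict(self, mz, index):
        """Fitted mixture intensity for spectrum ``index`` at positions ``mz``."""
        a1, a2 = self.areas_[index]
        return evaluate_bimodal(mz, a1, a2, self.mu1_bar_, self.mu2_bar_, self.sigma_)

    def split(self, cluster: IsotopeCluster) -> SubpopulationSplit:
        """Attribute each peak of ``cluster`` to the two subpopulations.

        ``cluster`` must be one of the fitted spectra (matched by condition).
        Each observed intensity is divided proportionally to the two fitted
        component densities at the peak position, so conservation is exact
        per peak.
        """
        if not self.converged_:
            raise ValueError("fit did not converge; refusing to split")
        key = (cluster.condition_type, cluster.condition_value)
        try:
            idx = self.conditions_.index(key)
        except ValueError:
            raise KeyError(f"no fitted spectrum with condition {key}") from None
        a1, a2 = self.areas_[idx]
        w1 = a1 * _gauss(cluster.mz, self.mu1_bar_, self.sigma_)
        w2 = a2 * _gauss(cluster.mz, self.mu2_bar_, self.sigma_)
        tot = w1 + w2
        degenerate = tot < 1e-300
        if degenerate.any():
            warnings.warn(
                f"{cluster._tag()}: {int(degenerate.sum())} peak(s) beyond both "
                "component tails; splitting 50/50", stacklevel=2,
            )
        frac_low = np.where(degenerate, 0.5, np.divide(
            w1, np.where(degenerate, 1.0, tot)))
        i_low = cluster.intensity * frac_low
        i_high = cluster.intensity - i_low  # exact conservation per peak
        total = cluster.intensity.sum()
        f_high = float(i_high.sum() / total) if total > 0 else np.nan
        return SubpopulationSplit(i_low, i_high, f_high)


def fit_bimodal_series(clusters, **kwargs) -> BimodalSeriesModel:
    """Functional wrapper over :class:`BimodalSeriesModel`."""
    return BimodalSeriesModel(**kwargs).fit(clusters)


def split_peak_intensities(cluster, fit: BimodalSeriesModel) -> SubpopulationSplit:
    """Functional wrapper over :meth:`BimodalSeriesModel.split`."""
    return fit.split(cluster)


def centroid_uptake(cluster, unexchanged, fully_deuterated,
                    n_exchangeable) -> UptakeResult:
    """Deuteron uptake of ``cluster`` with two-point back-exchange correction.

    ``deuterons`` is the raw charge-corrected centroid shift against the
    unexchanged control; ``corrected_deuterons`` rescales the shift by the
    fully deuterated control so that the controls map to 0 and
    ``n_exchangeable`` exactly.
    """
    for other in (unexchanged, fully_deuterated):
        if (other.peptide_id, other.charge) != (cluster.peptide_id, cluster.charge):
            raise ValueError("controls must share peptide and charge with the cluster")
    c = centroid(cluster)
    c0 = centroid(unexchanged)
    c100 = centroid(fully_deuterated)
    if c100 <= c0:
        raise ValueError(
            "fully deuterated centroid must exceed the unexchanged centroid"
        )
    return UptakeResult(
        centroid=c,
        deuterons=(c - c0) * cluster.charge,
        corrected_deuterons=n_exchangeable * (c - c0) / (c100 - c0),
    )


def uptake_difference(uptake_table, reference_condition):
    """Per-peptide uptake difference against a reference condition.

    Parameters
    ----------
    uptake_table : pandas.DataFrame
        Tidy table with columns ``peptide_id``, ``condition_value``,
        ``uptake`` and optionally ``sem`` (replicate-level SEM).
    reference_condition : scalar
        The condition subtracted from every other condition, per peptide.

    Returns
    -------
    pandas.DataFrame
        Columns ``peptide_id``, ``condition_value``, ``delta_uptake`` and
        ``delta_sem`` (quadrature-propagated; NaN without SEMs).
    """
    import pandas as pd

    df = uptake_table.copy()
    if "sem" not in df.columns:
        df["sem"] = np.nan
    rows = []
    for pep, grp in df.groupby("peptide_id", sort=False):
        ref = grp[grp["condition_value"] == reference_condition]
        if ref.empty:
            raise ValueError(
                f"peptide {pep!r}: reference condition {reference_condition!r} missing"
            )
        ref_u = float(ref["uptake"].iloc[0])
        ref_s = float(ref["sem"].iloc[0])
        for _, r in grp.iterrows():
            rows.append({
                "peptide_id": pep,
                "condition_value": r["condition_value"],
                "delta_uptake": float(r["uptake"]) - ref_u,
                "delta_sem": float(np.sqrt(r["sem"] ** 2 + ref_s ** 2)),
            })
    return pd.DataFrame(rows)
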