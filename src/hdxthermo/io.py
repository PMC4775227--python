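"""Tabular formats, run configuration, JSON reports and the pipeline driver.

The pipeline starts from centroided isotope-cluster peak lists as plain
CSV/TSV (columns: peptide_id, charge, condition_type, condition_value, mz,
intensity) — raw vendor files and peptide identification are upstream of
this package.  Fit results are written as JSON reports that echo the run
configuration and the convention decisions in force (fraction scale,
dimer-fraction convention, the "apparent" labelling of the transition
steepness), with non-finite numbers replaced by null plus a flag.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import envelopes, synthetic, transitions
from .envelopes import IsotopeCluster

__all__ = [
    "RunConfig",
    "PipelineError",
    "read_spectra",
    "write_spectra",
    "write_truth",
    "fractions_table",
    "write_fractions",
    "read_fractions",
    "write_report",
    "run_pipeline",
]

SPECTRA_COLUMNS = ["peptide_id", "charge", "condition_type", "condition_value",
                   "mz", "intensity"]


class PipelineError(RuntimeError):
    """A required pipeline stage failed or did not converge."""


@dataclass
class RunConfig:
    """Run-wide settings echoed verbatim into every report."""

    seed: int = 0
    sse_rtol: float = 1e-10
    max_iter: int = 500
    restarts: int = 3
    fraction_scale: str = "fraction"  # or "percent"
    dimer_fraction_convention: str = "units"
    out_dir: str | None = None

    def __post_init__(self):
        if self.fraction_scale not in ("fraction", "percent"):
            raise ValueError("fraction_scale must be 'fraction' or 'percent'")
        if self.dimer_fraction_convention not in ("units", "molecules"):
            raise ValueError("dimer_fraction_convention must be 'units' or 'molecules'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_spectra(path) -> list[IsotopeCluster]:
    """Read a spectra CSV/TSV into validated isotope clusters.

    Rows are grouped by (peptide_id, charge, condition_type, condition_value)
    in file order; each group must satisfy the cluster invariants (strictly
    increasing m/z, >= 4 peaks, near-uniform spacing, non-negative
    intensity).  Errors name the offending column or row.
    """
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in SPECTRA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    neg = df.index[df["intensity"].astype(float) < 0]
    if len(neg):
        # +2: header line plus 1-based numbering
        raise ValueError(f"{path}: negative intensity at line {neg[0] + 2}")
    clusters = []
    keys = ["peptide_id", "charge", "condition_type", "condition_value"]
    for (pep, chg, ctype, cval), grp in df.groupby(keys, sort=False):
        mz = grp["mz"].to_numpy(dtype=float)
        if np.any(np.diff(mz) <= 0):
            raise ValueError(
                f"{path}: non-monotone m/z within cluster {pep}/{chg}+ @ {cval}"
            )
        clusters.append(IsotopeCluster(
            str(pep), int(chg), str(ctype),
            cval if ctype == "control" else float(cval),
            mz, grp["intensity"].to_numpy(dtype=float),
        ))
    return clusters


def write_spectra(clusters, path) -> None:
    """Write clusters to the spectra CSV/TSV dialect (full float precision)."""
    rows = []
    for c in clusters:
        for mz, inten in zip(c.mz, c.intensity):
            rows.append((c.peptide_id, c.charge, c.condition_type,
                         c.condition_value, repr(float(mz)), repr(float(inten))))
    df = pd.DataFrame(rows, columns=SPECTRA_COLUMNS)
    df.to_csv(path, sep=_sep_for(path), index=False)


def write_truth(scenario, fractions, path) -> None:
    """Sidecar JSON with the generator's true parameters for test harnesses."""
    payload = {
        "scenario": _jsonify(dataclasses.asdict(scenario)),
        "true_fractions": [float(f) for f in np.asarray(fractions).ravel()],
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def fractions_table(fit: envelopes.BimodalSeriesModel) -> pd.DataFrame:
    """Tidy per-spectrum subpopulation fractions from a converged series fit."""
    rows = []
    for (ctype, cval), f, se in zip(fit.conditions_, fit.f_high_, fit.se_f_high_):
        rows.append({
            "peptide_id": fit.peptide_id_,
            "charge": fit.charge_,
            "condition_type": ctype,
            "condition_value": cval,
            "f_high": f,
            "se_f_high": se,
            "converged": fit.converged_,
        })
    return pd.DataFrame(rows)


def write_fractions(fit, path) -> None:
    fractions_table(fit).to_csv(path, sep="\t", index=False)


def read_fractions(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _jsonify(obj):
    """Recursively convert to JSON-safe values; non-finite numbers -> None."""
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    if isinstance(obj, (float, np.floating)):
        v = float(obj)
        return v if math.isfinite(v) else None
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    return obj


def write_report(payload: dict, path, config: RunConfig | None = None) -> None:
    """Write a JSON fit report with config echo and convention block."""
    body = {
        "conventions": {
            "fraction_scale": config.fraction_scale if config else "fraction",
            "dimer_fraction_convention":
                config.dimer_fraction_convention if config else "units",
            "dh_is_apparent": True,
            "temperature_io_unit": "C",
            "concentration_unit": "nM",
        },
        "config": config.as_dict() if config else None,
        "report": _jsonify(payload),
    }
    flags = _nonfinite_flags(payload)
    if flags:
        body["nonfinite_fields"] = flags
    Path(path).write_text(json.dumps(body, indent=2, sort_keys=True))


def _nonfinite_flags(payload, prefix=""):
    flags = []
    if isinstance(payload, dict):
        for k, v in payload.items():
            flags.extend(_nonfinite_flags(v, f"{prefix}{k}."))
    elif isinstance(payload, (list, tuple, np.ndarray)):
        for i, v in enumerate(payload):
            flags.extend(_nonfinite_flags(v, f"{prefix}{i}."))
    elif isinstance(payload, (float, np.floating)) and not math.isfinite(payload):
        flags.append(prefix[:-1])
    return flags


STAGES = ("simulate", "deconvolve", "fit-transition", "fit-kinetics",
          "arrhenius", "fit-setpoint")


def run_pipeline(config: RunConfig, stages, scenario=None, spectra=None,
                 rates=None, tm_points=None) -> dict:
    """Run an ordered list of stages and return the report bundle.

    Stages operate on a shared context: ``simulate`` generates an envelope
    series from ``scenario`` (default: the thermal standard scenario seeded
    from the config), ``deconvolve`` fits the bimodal series, and
    ``fit-transition`` / ``fit-kinetics`` fit the resulting fractions.
    ``arrhenius`` consumes ``rates`` (pairs of temperature in deg C and rate
    in 1/s) and ``fit-setpoint`` consumes ``tm_points`` (pairs of nM, deg C).
    Unknown stages and missing upstream artifacts raise
    :class:`PipelineError`; so does any required fit that fails to converge.
    The bundle is deterministic for a fixed config.
    """
    stages = list(stages)
    for s in stages:
        if s not in STAGES:
            raise PipelineError(f"unknown stage {s!r}")
    report: dict = {"stages": {}}
    clusters = spectra
    fractions = None
    fit = None

    for stage in stages:
        if stage == "simulate":
            scen = scenario or synthetic.standard_thermal_scenario(seed=config.seed)
            clusters, true_fr = synthetic.simulate_series(scen)
            report["stages"]["simulate"] = {
                "n_spectra": len(clusters),
                "condition_axis": scen.condition_axis,
                "true_fractions": list(map(float, true_fr)),
            }
        elif stage == "deconvolve":
            if clusters is None:
                raise PipelineError("deconvolve: no spectra available "
                                    "(run simulate or pass spectra)")
            fit = envelopes.BimodalSeriesModel(
                max_iter=config.max_iter, restarts=config.restarts,
                sse_rtol=config.sse_rtol,
            ).fit(clusters)
            if not fit.converged_:
                raise PipelineError("deconvolve: global bimodal fit did not converge")
            fractions = fractions_table(fit)
            report["stages"]["deconvolve"] = {
                "mu1_bar": fit.mu1_bar_, "mu2_bar": fit.mu2_bar_,
                "sigma": fit.sigma_,
                "mu1_identifiable": fit.mu1_identifiable_,
                "mu2_identifiable": fit.mu2_identifiable_,
                "f_high": list(map(float, fit.f_high_)),
                "residual_sse": list(map(float, fit.residual_sse_)),
            }
        elif stage == "fit-transition":
            if fractions is None:
                raise PipelineError("fit-transition: no fractions available")
            sub = fractions[fractions["condition_type"] == "temperature_C"]
            if sub.empty:
                raise PipelineError("fit-transition: no temperature-series fractions")
            tfit = transitions.ThermalTransitionModel(
                scale=config.fraction_scale
            ).fit(sub["condition_value"], sub["f_high"], se=sub["se_f_high"])
            if not tfit.converged_:
                raise PipelineError("fit-transition: fit did not converge")
            report["stages"]["fit-transition"] = {
                "tm_C": tfit.tm_c_, "se_tm_C": tfit.se_tm_c_,
                "dh_apparent_J_mol": tfit.dh_app_j_mol_,
                "f0": tfit.f0_, "fmax": tfit.fmax_,
                "extrapolation_flag": tfit.extrapolation_flag_,
            }
        elif stage == "fit-kinetics":
            if fractions is None:
                raise PipelineError("fit-kinetics: no fractions available")
            sub = fractions[fractions["condition_type"] == "time_s"]
            if sub.empty:
                raise PipelineError("fit-kinetics: no time-series fractions")
            kfit = transitions.ExponentialKineticsModel().fit(
                sub["condition_value"], sub["f_high"])
            if not kfit.converged_:
                raise PipelineError("fit-kinetics: fit did not converge")
            report["stages"]["fit-kinetics"] = {
                "k_per_s": kfit.k_per_s_, "se_k_per_s": kfit.se_k_per_s_,
                "f_start": kfit.f_start_, "f_end": kfit.f_end_,
            }
        elif stage == "arrhenius":
            if rates is None:
                raise PipelineError("arrhenius: no rates supplied")
            rates_arr = np.asarray(rates, dtype=float)
            afit = transitions.ArrheniusModel().fit(
                transitions.celsius_to_kelvin(rates_arr[:, 0]), rates_arr[:, 1])
            report["stages"]["arrhenius"] = {
                "ea_kJ_mol": afit.ea_j_mol_ / 1e3,
                "se_ea_kJ_mol": afit.se_ea_j_mol_ / 1e3,
                "ln_pref": afit.ln_pref_,
            }
        elif stage == "fit-setpoint":
            from . import setpoint as sp

            if tm_points is None:
                raise PipelineError("fit-setpoint: no (concentration, Tm) points")
            pts = np.asarray(tm_points, dtype=float)
            sfit = sp.DimerSetpointModel(
                fraction_convention=config.dimer_fraction_convention
            ).fit(pts[:, 0], pts[:, 1])
            if not sfit.converged_:
                raise PipelineError("fit-setpoint: fit did not converge")
            report["stages"]["fit-setpoint"] = {
                "kd_dim_nM": sfit.kd_dim_nM_,
                "tm_monomer_C": sfit.tm_monomer_c_,
                "tm_dimer_C": sfit.tm_dimer_c_,
                "low_conc_caveat": sfit.low_conc_caveat_,
                "kd_identifiable": sfit.kd_identifiable_,
            }

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_report(report, out / "report.json", config)
        if fractions is not None:
            fractions.to_csv(out / "fractions.tsv", sep="\t", index=False)
    return report
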