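"""Method-performance figures: calibration, ICH LOD/LOQ, precision, accuracy,
matrix effect, extraction recovery, cartridge-reuse QC and solvent budget.

Calibration regresses the peak-area ratio (PAR, analyte over internal
standard) on nominal concentration; detection limits follow the ICH
intercept-dispersion approach, LOD = 3.3 σ/S and LOQ = 10 σ/S with S the
slope and σ the standard error of the intercept.  Matrix effect (ME%) and
extraction recovery (RE%) compare the means of three spiking sets:

    ME% = 100 * Set2 / Set3        RE% = 100 * Set1 / Set2

where Set1 is spiked before extraction, Set2 spiked into blank extract, and
Set3 the neat solution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._errors import CalibrationError, ConfigurationError, DataError
from .design import Worklist, WorklistStep

__all__ = [
    "CalibrationCurve",
    "PerformanceReport",
    "ProtocolBudget",
    "ReuseQC",
    "fit_calibration",
    "lod_loq",
    "precision_rsd",
    "accuracy_pct",
    "matrix_effect",
    "extraction_recovery",
    "cartridge_reuse_qc",
    "solvent_budget",
    "performance_from_sets",
]

LOD_FACTOR = 3.3
LOQ_FACTOR = 10.0


@dataclass
class CalibrationCurve:
    """Linear PAR-vs-concentration calibration with ICH detection limits."""

    analyte: str
    slope: float
    intercept: float
    r_squared: float
    sd_intercept: float
    residual_sd: float
    n_points: int
    lod: float | None = None
    loq: float | None = None
    weighting: str | None = None
    sigma_source: str = "intercept_se"

    def predict(self, concentration: float) -> float:
        """Forward model: expected PAR at a given concentration (pg/mL)."""
        return self.intercept + self.slope * concentration

    def to_dict(self) -> dict:
        return {
            "analyte": self.analyte,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "sd_intercept": self.sd_intercept,
            "residual_sd": self.residual_sd,
            "n_points": self.n_points,
            "lod_pg_ml": self.lod,
            "loq_pg_ml": self.loq,
            "weighting": self.weighting,
            "sigma_source": self.sigma_source,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        return cls(
            analyte=d["analyte"],
            slope=d["slope"],
            intercept=d["intercept"],
            r_squared=d["r_squared"],
            sd_intercept=d["sd_intercept"],
            residual_sd=d["residual_sd"],
            n_points=d["n_points"],
            lod=d.get("lod_pg_ml"),
            loq=d.get("loq_pg_ml"),
            weighting=d.get("weighting"),
            sigma_source=d.get("sigma_source", "intercept_se"),
        )


def fit_calibration(
    levels: Sequence[tuple[float, float]] | pd.DataFrame,
    analyte: str = "",
    weighting: str | None = None,
    sigma: str = "intercept_se",
) -> CalibrationCurve:
    """Least-squares calibration line through (concentration, PAR) points.

    Unweighted OLS by default; ``weighting='1/x'`` switches to WLS with
    weights 1/concentration (the zero-concentration level inherits the
    weight of the smallest nonzero level).  ``sigma`` selects the dispersion
    fed to the detection limits: the intercept standard error (default) or
    the residual standard deviation.
    """
    if isinstance(levels, pd.DataFrame):
        pairs = list(zip(levels.iloc[:, 0].astype(float), levels.iloc[:, 1].astype(float)))
    else:
        pairs = [(float(c), float(p)) for c, p in levels]
    if sigma not in ("intercept_se", "residual_sd"):
        raise ValueError(f"unknown sigma source {sigma!r}")
    conc = np.array([c for c, _ in pairs])
    par = np.array([p for _, p in pairs])
    if np.any(conc < 0):
        raise CalibrationError("calibration concentrations must be non-negative")
    distinct = np.unique(conc)
    if distinct.size == 1:
        raise CalibrationError("degenerate calibration: zero concentration spread")
    if distinct.size < 3:
        raise CalibrationError(
            f"calibration needs >= 3 distinct levels, got {distinct.size}"
        )

    if weighting is None:
        res = stats.linregress(conc, par)
        slope, intercept = float(res.slope), float(res.intercept)
        r_squared = float(res.rvalue**2)
        sd_intercept = float(res.intercept_stderr)
    elif weighting == "1/x":
        w = np.where(conc > 0, conc, distinct[distinct > 0].min())
        model = sm.WLS(par, sm.add_constant(conc), weights=1.0 / w).fit()
        intercept, slope = float(model.params[0]), float(model.params[1])
        r_squared = float(model.rsquared)
        sd_intercept = float(model.bse[0])
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    resid = par - (intercept + slope * conc)
    residual_sd = float(np.sqrt(np.sum(resid**2) / (conc.size - 2)))
    curve = CalibrationCurve(
        analyte=analyte,
        slope=slope,
        intercept=intercept,
        r_squared=r_squared,
        sd_intercept=sd_intercept,
        residual_sd=residual_sd,
        n_points=int(conc.size),
        weighting=weighting,
        sigma_source=sigma,
    )
    if slope > 0:
        curve.lod, curve.loq = lod_loq(curve)
    return curve


def lod_loq(curve: CalibrationCurve, sigma_value: float | None = None) -> tuple[float, float]:
    """ICH detection limits: (3.3 σ/S, 10 σ/S).

    σ defaults to the dispersion named by ``curve.sigma_source``; the ratio
    LOQ/LOD is exactly 10/3.3 whenever both derive from the same σ and slope.
    """
    if curve.slope <= 0:
        raise CalibrationError(
            f"analyte {curve.analyte!r}: non-positive slope {curve.slope}"
        )
    if sigma_value is None:
        sigma_value = (
            curve.sd_intercept if curve.sigma_source == "intercept_se" else curve.residual_sd
        )
    if sigma_value < 0:
        raise CalibrationError("sigma must be non-negative")
    return LOD_FACTOR * sigma_value / curve.slope, LOQ_FACTOR * sigma_value / curve.slope


def precision_rsd(replicates: Sequence[float]) -> float:
    """Relative standard deviation (%): 100 * sample sd / mean."""
    vals = np.asarray(list(replicates), dtype=float)
    if vals.size < 2:
        raise ValueError("precision needs at least 2 replicates")
    mean = float(np.mean(vals))
    if mean == 0:
        raise DataError("RSD undefined: replicate mean is zero")
    return 100.0 * float(np.std(vals, ddof=1)) / abs(mean)


def accuracy_pct(determined: Sequence[float], nominal: float) -> float:
    """Accuracy (%): 100 * mean determined concentration / nominal."""
    vals = np.asarray(list(determined), dtype=float)
    if vals.size == 0:
        raise ValueError("accuracy needs at least one determined value")
    if nominal <= 0:
        raise ValueError(f"nominal concentration must be positive, got {nominal}")
    return 100.0 * float(np.mean(vals)) / nominal


def matrix_effect(set2_mean: float, set3_mean: float) -> float:
    """ME% = 100 * Set2 / Set3 (post-extraction spike over neat solution)."""
    if set3_mean <= 0:
        raise ValueError(f"Set3 mean must be positive, got {set3_mean}")
    return 100.0 * set2_mean / set3_mean


def extraction_recovery(set1_mean: float, set2_mean: float) -> float:
    """RE% = 100 * Set1 / Set2 (pre-extraction spike over post-extraction spike)."""
    if set2_mean <= 0:
        raise ValueError(f"Set2 mean must be positive, got {set2_mean}")
    return 100.0 * set1_mean / set2_mean


class ReuseQC(NamedTuple):
    n_reuses_within_threshold: int
    verdict: str  # "within_threshold" | "degraded"


def cartridge_reuse_qc(series: Sequence[float], rsd_threshold: float = 5.0) -> ReuseQC:
    """How many consecutive extractions a cartridge sustains within an RSD bound.

    Returns the largest prefix length k for which the RSD of the first k
    intensities stays below ``rsd_threshold`` (a single extraction has RSD 0
    and always qualifies), plus a verdict: ``within_threshold`` if the full
    series qualifies, ``degraded`` otherwise.
    """
    vals = np.asarray(list(series), dtype=float)
    if vals.size < 2:
        raise ValueError("cartridge QC needs at least 2 extractions")
    if np.any(vals < 0):
        raise DataError("negative intensity in cartridge series")
    k = 1
    for j in range(2, vals.size + 1):
        if precision_rsd(vals[:j]) < rsd_threshold:
            k = j
    verdict = "within_threshold" if k == vals.size else "degraded"
    return ReuseQC(k, verdict)


@dataclass(frozen=True)
class ProtocolBudget:
    """Per-extraction reagent and sample volumes."""

    steps: tuple[WorklistStep, ...]
    total_solvent_mL: float
    urine_volume_mL: float

    def to_dict(self) -> dict:
        return {
            "total_solvent_mL": self.total_solvent_mL,
            "urine_volume_mL": self.urine_volume_mL,
            "n_steps": len(self.steps),
        }


def solvent_budget(worklist: Worklist | Sequence[WorklistStep]) -> ProtocolBudget:
    """Total reagent (non-sample) volume of one extraction, in mL.

    Sample-loading steps are excluded from the solvent total and reported
    separately as the urine volume.
    """
    steps = list(worklist.steps) if isinstance(worklist, Worklist) else list(worklist)
    if not steps:
        raise ValueError("empty worklist: nothing to budget")
    run_ids = {s.run_id for s in steps}
    if len(run_ids) > 1:
        raise ValueError(
            f"solvent budget is per extraction; worklist spans runs {sorted(run_ids)}"
        )
    for s in steps:
        if s.is_sample is None:
            raise ConfigurationError(
                f"step {s.step!r}: not labeled as sample or reagent"
            )
    solvent = sum(s.volume_uL for s in steps if not s.is_sample) / 1000.0
    urine = sum(s.volume_uL for s in steps if s.is_sample) / 1000.0
    return ProtocolBudget(tuple(steps), solvent, urine)


@dataclass
class PerformanceReport:
    """Per-analyte method-performance summary mirroring a validation table."""

    analyte: str
    precision_rsd_pct: float | None = None
    accuracy_pct: float | None = None
    extraction_recovery_pct: float | None = None
    matrix_effect_pct: float | None = None
    set_means: dict[str, float] = field(default_factory=dict)
    set_replicates: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "analyte": self.analyte,
            "precision_rsd_pct": self.precision_rsd_pct,
            "accuracy_pct": self.accuracy_pct,
            "extraction_recovery_pct": self.extraction_recovery_pct,
            "matrix_effect_pct": self.matrix_effect_pct,
            "set_means": self.set_means,
            "set_replicates": self.set_replicates,
        }


def performance_from_sets(
    sets: pd.DataFrame,
    analyte: str,
    cqi_replicates: Sequence[float] | None = None,
    cqi_nominal: float | None = None,
) -> PerformanceReport:
    """Assemble a performance report from a long set table and optional CQI data.

    ``sets`` needs columns analyte/set/replicate/response with set labels
    Set1/Set2/Set3; ME% and RE% follow from the set means.  CQI replicate
    determinations supply precision (RSD%) and, with a nominal value,
    accuracy.
    """
    sub = sets[sets["analyte"] == analyte]
    if sub.empty:
        raise DataError(f"no set data for analyte {analyte!r}")
    means = sub.groupby("set")["response"].mean().to_dict()
    counts = sub.groupby("set")["response"].count().to_dict()
    missing = {"Set1", "Set2", "Set3"} - set(means)
    if missing:
        raise DataError(f"analyte {analyte!r}: missing sets {sorted(missing)}")
    report = PerformanceReport(
        analyte=analyte,
        matrix_effect_pct=matrix_effect(means["Set2"], means["Set3"]),
        extraction_recovery_pct=extraction_recovery(means["Set1"], means["Set2"]),
        set_means={k: float(v) for k, v in means.items()},
        set_replicates={k: int(v) for k, v in counts.items()},
    )
    if cqi_replicates is not None:
        report.precision_rsd_pct = precision_rsd(cqi_replicates)
        if cqi_nominal is not None:
            report.accuracy_pct = accuracy_pct(cqi_replicates, cqi_nominal)
    return report
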