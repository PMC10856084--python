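"""Synthetic instrument data with the statistical structure the analysis assumes.

Every pipeline input can be generated here: screening responses with a
planted linear factor-effect structure plus additive Gaussian noise,
calibration tables with proportional (CV-parameterized) noise around a true
line, Set1/Set2/Set3 spiking triplets with planted matrix-effect and
recovery ratios, CQI replicate determinations, cartridge-reuse series, and
LOQ-censored sample batches.  All generators are pure functions of
(config, seed).

Default parameters mirror the µSPE study conditions: two oxazaphosphorine
analytes with calibration slopes ~0.02 PAR per pg/mL over 0-50 pg/mL,
replicate CVs of 18.7% and 21.6%, matrix effects of 93% and 88%, recoveries
of 77% and 79%, and a 23-sample batch carrying two positives for one
analyte (27 and 182 pg/mL) and one for the other (95 pg/mL).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from ._errors import ConfigurationError
from .design import ScreeningDesign
from .quantify import SampleBatch, SampleRecord
from .screening import ResponseSet
from .validation import CalibrationCurve, fit_calibration

__all__ = [
    "ScreeningResponseModel",
    "CalibrationModel",
    "SetTripletModel",
    "BatchModel",
    "GeneratorConfig",
    "simulate_screening_responses",
    "simulate_calibration",
    "simulate_me_re_sets",
    "simulate_cqi_replicates",
    "simulate_batch",
]

DEFAULT_LEVELS: tuple[float, ...] = (0.0, 5.0, 10.0, 20.0, 35.0, 50.0)


class ScreeningResponseModel(BaseModel):
    """Planted main-effects model for one screening response (coded scale)."""

    intercept: float
    coefficients: dict[str, float] = Field(default_factory=dict)
    noise_sd: float = Field(0.0, ge=0)
    nonnegative: bool = True


class CalibrationModel(BaseModel):
    """True calibration line and proportional replicate noise for one analyte."""

    slope: float = Field(gt=0)
    intercept: float = Field(ge=0)
    cv_pct: float = Field(0.0, ge=0)
    levels: tuple[float, ...] = DEFAULT_LEVELS

    @field_validator("levels")
    @classmethod
    def _levels_ok(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        if any(c < 0 for c in v):
            raise ValueError("calibration levels must be non-negative")
        if len(set(v)) < 3:
            raise ValueError("need >= 3 distinct calibration levels")
        return v


class SetTripletModel(BaseModel):
    """Planted ME%/RE% ratios for the three spiking sets of one analyte."""

    me_pct: float = Field(gt=0, le=200)
    re_pct: float = Field(gt=0, le=200)
    base_response: float = Field(50.0, gt=0)
    cv_pct: float = Field(5.0, ge=0)
    n_replicates: int = Field(4, ge=2)


class BatchModel(BaseModel):
    """Composition of a monitoring batch: size and planted positives."""

    n_samples: int = Field(23, ge=0)
    positives: dict[str, list[float]] = Field(
        default_factory=lambda: {
            "iphosphamide": [27.0, 182.0],
            "cyclophosphamide": [95.0],
        }
    )
    cv_pct: float = Field(0.0, ge=0)

    @field_validator("positives")
    @classmethod
    def _non_negative(cls, v: dict[str, list[float]]) -> dict[str, list[float]]:
        for analyte, concs in v.items():
            if any(c < 0 for c in concs):
                raise ValueError(f"negative planted concentration for {analyte}")
        return v


def _default_screening() -> dict[str, ScreeningResponseModel]:
    return {
        "cyclophosphamide_area": ScreeningResponseModel(
            intercept=50_000.0,
            coefficients={"x4": 8_000.0, "x2": -6_000.0, "x5": 4_000.0},
            noise_sd=2_000.0,
        ),
        "iphosphamide_area": ScreeningResponseModel(
            intercept=48_000.0,
            coefficients={"x4": 7_500.0, "x2": -5_500.0, "x5": 3_800.0, "x6": 2_500.0},
            noise_sd=2_000.0,
        ),
        "duration_s": ScreeningResponseModel(
            intercept=760.0,
            coefficients={
                "x5": -60.0, "x3": 40.0, "x8": -25.0, "x1": 15.0,
                "x2": 10.0, "x6": -8.0, "x9": -8.0,
            },
            noise_sd=9.0,
        ),
        # internal standard: zero planted effects, the robustness expectation
        "is_area": ScreeningResponseModel(intercept=60_000.0, noise_sd=2_000.0),
    }


def _default_calibration() -> dict[str, CalibrationModel]:
    return {
        "iphosphamide": CalibrationModel(slope=0.019, intercept=0.055, cv_pct=18.7),
        "cyclophosphamide": CalibrationModel(slope=0.020, intercept=0.094, cv_pct=21.6),
    }


def _default_sets() -> dict[str, SetTripletModel]:
    return {
        "iphosphamide": SetTripletModel(me_pct=93.0, re_pct=77.0),
        "cyclophosphamide": SetTripletModel(me_pct=88.0, re_pct=79.0),
    }


class GeneratorConfig(BaseModel):
    """Bundle of generator parameters; ``seed`` is mandatory for any stochastic call."""

    seed: int
    screening: dict[str, ScreeningResponseModel] = Field(default_factory=_default_screening)
    calibration: dict[str, CalibrationModel] = Field(default_factory=_default_calibration)
    sets: dict[str, SetTripletModel] = Field(default_factory=_default_sets)
    batch: BatchModel = Field(default_factory=BatchModel)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict) or "seed" not in doc:
            raise ConfigurationError(f"{path}: generator config requires a 'seed' key")
        return cls(**doc)


def _rng(config: GeneratorConfig, seed: int | None) -> np.random.Generator:
    return np.random.default_rng(config.seed if seed is None else seed)


def simulate_screening_responses(
    design: ScreeningDesign,
    config: GeneratorConfig,
    seed: int | None = None,
) -> ResponseSet:
    """Draw every configured response for every run of a design.

    Each run's mean is the planted linear model evaluated on its coded row
    (center rows therefore scatter around the intercept); noise is additive
    Gaussian.  Responses flagged ``nonnegative`` have negative draws
    resampled.  Planting a coefficient on a dummy factor is a configuration
    error.
    """
    rng = _rng(config, seed)
    real_names = {
        f.name for f in design.factors if f.role == "real"
    }
    values: dict[int, dict[str, float]] = {rid: {} for rid in design.run_ids}
    for resp_name, model in config.screening.items():
        unknown = set(model.coefficients) - set(design.factor_names)
        if unknown:
            raise ConfigurationError(
                f"response {resp_name!r}: coefficients for unknown factors {sorted(unknown)}"
            )
        on_dummies = set(model.coefficients) - real_names
        if on_dummies:
            raise ConfigurationError(
                f"response {resp_name!r}: coefficients planted on dummy factors "
                f"{sorted(on_dummies)}"
            )
        b = np.array([model.coefficients.get(n, 0.0) for n in design.factor_names])
        means = model.intercept + design.coded_matrix @ b
        for rid, mu in zip(design.run_ids, means):
            y = mu + rng.normal(0.0, model.noise_sd) if model.noise_sd > 0 else mu
            if model.nonnegative:
                tries = 0
                while y < 0:
                    y = mu + rng.normal(0.0, model.noise_sd)
                    tries += 1
                    if tries > 1000:
                        raise ConfigurationError(
                            f"response {resp_name!r}: cannot draw non-negative value "
                            f"around mean {mu} with sd {model.noise_sd}"
                        )
            values[rid][resp_name] = float(y)
    return ResponseSet(values)


def simulate_calibration(
    config: GeneratorConfig,
    levels: Sequence[float] | None = None,
    seed: int | None = None,
    analytes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Simulate one calibration table per analyte: columns analyte/level_pg_ml/par.

    Nonzero levels get proportional noise, PAR = (a + b c)(1 + N(0, CV/100));
    the zero level gets additive noise with sd = CV/100 x true intercept.
    """
    rng = _rng(config, seed)
    names = list(analytes) if analytes is not None else list(config.calibration)
    rows = []
    for name in names:
        if name not in config.calibration:
            raise ConfigurationError(f"no calibration model for analyte {name!r}")
        model = config.calibration[name]
        lv = tuple(levels) if levels is not None else model.levels
        if any(c < 0 for c in lv):
            raise ValueError("calibration levels must be non-negative")
        if len(set(lv)) < 3:
            raise ValueError("need >= 3 distinct calibration levels")
        for c in lv:
            true = model.intercept + model.slope * c
            if c == 0:
                par = true + rng.normal(0.0, model.cv_pct / 100.0 * model.intercept)
            else:
                par = true * (1.0 + rng.normal(0.0, model.cv_pct / 100.0))
            rows.append({"analyte": name, "level_pg_ml": float(c), "par": float(par)})
    return pd.DataFrame(rows, columns=["analyte", "level_pg_ml", "par"])


def simulate_me_re_sets(
    config: GeneratorConfig,
    seed: int | None = None,
    analytes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Simulate the three spiking sets: columns analyte/set/replicate/response.

    Set3 replicates scatter around the base response (neat solution), Set2
    around base x ME/100 (post-extraction spike), Set1 around
    base x ME/100 x RE/100 (pre-extraction spike); noise is proportional.
    """
    rng = _rng(config, seed)
    names = list(analytes) if analytes is not None else list(config.sets)
    rows = []
    for name in names:
        if name not in config.sets:
            raise ConfigurationError(f"no set-triplet model for analyte {name!r}")
        m = config.sets[name]
        set3 = m.base_response
        set2 = set3 * m.me_pct / 100.0
        set1 = set2 * m.re_pct / 100.0
        for label, center in (("Set1", set1), ("Set2", set2), ("Set3", set3)):
            noise = rng.normal(0.0, m.cv_pct / 100.0, size=m.n_replicates)
            for i, e in enumerate(noise, start=1):
                rows.append(
                    {
                        "analyte": name,
                        "set": label,
                        "replicate": i,
                        "response": float(center * (1.0 + e)),
                    }
                )
    return pd.DataFrame(rows, columns=["analyte", "set", "replicate", "response"])


def simulate_cqi_replicates(
    nominal: float,
    cv_pct: float,
    n: int,
    seed: int,
) -> np.ndarray:
    """Replicate CQI determinations at a nominal concentration with proportional noise."""
    if nominal <= 0:
        raise ValueError("nominal concentration must be positive")
    if n < 2:
        raise ValueError("need at least 2 replicates")
    rng = np.random.default_rng(seed)
    return nominal * (1.0 + rng.normal(0.0, cv_pct / 100.0, size=n))


def _true_curves(config: GeneratorConfig, seed: int | None) -> dict[str, CalibrationCurve]:
    # Derive per-analyte curves (with LOD/LOQ) by simulating one calibration
    # table and fitting it; deterministic given (config, seed).
    table = simulate_calibration(config, seed=seed)
    curves = {}
    for name, sub in table.groupby("analyte"):
        curves[name] = fit_calibration(sub[["level_pg_ml", "par"]], analyte=str(name))
    return curves


def simulate_batch(
    config: GeneratorConfig,
    curves: Mapping[str, CalibrationCurve] | None = None,
    seed: int | None = None,
) -> SampleBatch:
    """Simulate a monitoring batch of PARs with planted positives.

    Positive samples get PAR = curve(c) x (1 + N(0, CV/100)); all other
    sample x analyte pairs draw a PAR uniformly below the PAR equivalent of
    the curve's LOD, so they censor below the limit of detection.  Curves
    may be passed explicitly (e.g. the batch's own calibration); otherwise
    they are derived by simulating and fitting one calibration per analyte.
    """
    rng = _rng(config, seed)
    if curves is None:
        curves = _true_curves(config, seed)
    for analyte in config.batch.positives:
        if analyte not in curves:
            raise ConfigurationError(f"no calibration curve for analyte {analyte!r}")
    n = config.batch.n_samples
    total_pos = sum(len(v) for v in config.batch.positives.values())
    if total_pos > n:
        raise ConfigurationError(
            f"{total_pos} planted positives exceed batch size {n}"
        )
    sample_ids = [f"s{i + 1:02d}" for i in range(n)]
    # planted positives occupy the leading sample ids, one sample per positive
    assignments: dict[tuple[str, str], float] = {}
    cursor = 0
    for analyte, concs in config.batch.positives.items():
        for c in concs:
            assignments[(sample_ids[cursor], analyte)] = c
            cursor += 1
    records = []
    cv = config.batch.cv_pct / 100.0
    for sid in sample_ids:
        for analyte, curve in curves.items():
            if (sid, analyte) in assignments:
                c = assignments[(sid, analyte)]
                par = curve.predict(c) * (1.0 + (rng.normal(0.0, cv) if cv > 0 else 0.0))
            else:
                if curve.lod is None:
                    raise ConfigurationError(
                        f"curve for {analyte!r} lacks an LOD; cannot draw negatives"
                    )
                par = rng.uniform(0.0, max(curve.predict(curve.lod), 0.0))
            records.append(SampleRecord(sid, analyte, max(float(par), 0.0)))
    return SampleBatch(records, metadata={"collection": "24h_urine", "seed": config.seed})
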