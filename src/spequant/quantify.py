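"""LOQ-censored quantification of sample batches.

Peak-area ratios are converted to concentrations by inverting the
calibration line and then censored against the curve's detection limits:
at or above the LOQ a sample is quantified (a "positive"); between LOD and
LOQ the value is retained but flagged below-LOQ; below the LOD the value is
suppressed entirely so the censoring stays auditable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from ._errors import CalibrationError, ConfigurationError, DataError
from .validation import CalibrationCurve

__all__ = [
    "SampleStatus",
    "SampleRecord",
    "SampleBatch",
    "SampleResult",
    "BatchReport",
    "inverse_predict",
    "censor",
    "batch_report",
]


class SampleStatus(str, enum.Enum):
    QUANTIFIED = "quantified"
    BELOW_LOQ = "below_loq"
    BELOW_LOD = "below_lod"


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    analyte: str
    par: float


@dataclass
class SampleBatch:
    """Measured peak-area ratios, one row per sample x analyte."""

    samples: list[SampleRecord]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for s in self.samples:
            if s.par < 0:
                raise DataError(f"sample {s.sample_id}/{s.analyte}: negative PAR {s.par}")
            key = (s.sample_id, s.analyte)
            if key in seen:
                raise DataError(f"duplicate sample/analyte pair {key}")
            seen.add(key)

    @property
    def sample_ids(self) -> list[str]:
        return sorted({s.sample_id for s in self.samples})

    @property
    def analytes(self) -> list[str]:
        return sorted({s.analyte for s in self.samples})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, metadata: dict | None = None) -> "SampleBatch":
        required = {"sample_id", "analyte", "par"}
        if not required <= set(frame.columns):
            raise DataError(f"batch table needs columns {sorted(required)}")
        samples = [
            SampleRecord(str(r.sample_id), str(r.analyte), float(r.par))
            for r in frame.itertuples(index=False)
        ]
        return cls(samples, metadata or {})

    @classmethod
    def from_csv(cls, path) -> "SampleBatch":
        return cls.from_frame(pd.read_csv(path))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"sample_id": s.sample_id, "analyte": s.analyte, "par": s.par} for s in self.samples],
            columns=["sample_id", "analyte", "par"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class SampleResult:
    sample_id: str
    analyte: str
    concentration: float | None  # pg/mL; None when suppressed below the LOD
    status: SampleStatus
    curve_analyte: str

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "analyte": self.analyte,
            "conc_pg_ml": self.concentration,
            "status": self.status.value,
        }


def inverse_predict(curve: CalibrationCurve, par: float) -> float:
    """Back-calculate concentration from a PAR; may be negative before censoring."""
    if curve.slope <= 0:
        raise CalibrationError(
            f"analyte {curve.analyte!r}: cannot invert non-positive slope {curve.slope}"
        )
    return (par - curve.intercept) / curve.slope


def censor(concentration: float, curve: CalibrationCurve) -> SampleStatus:
    """Censoring status against the curve's limits (LOQ inclusive)."""
    if curve.lod is None or curve.loq is None:
        raise CalibrationError(
            f"analyte {curve.analyte!r}: LOD/LOQ not populated on curve"
        )
    if concentration >= curve.loq:
        return SampleStatus.QUANTIFIED
    if concentration >= curve.lod:
        return SampleStatus.BELOW_LOQ
    return SampleStatus.BELOW_LOD


@dataclass
class BatchReport:
    results: list[SampleResult]
    n_tested: int
    n_positive: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [r.to_dict() for r in self.results],
            columns=["sample_id", "analyte", "conc_pg_ml", "status"],
        )

    def summary(self) -> dict:
        return {"n_tested": self.n_tested, "n_positive": self.n_positive}


def batch_report(
    batch: SampleBatch,
    curves: Mapping[str, CalibrationCurve],
) -> BatchReport:
    """Quantify and censor every sample x analyte; count positives per analyte.

    A positive is a quantifiable result (concentration >= LOQ); below-LOQ
    detections are listed but not counted.  Results are ordered by
    (sample_id, analyte).
    """
    for analyte in batch.analytes:
        if analyte not in curves:
            raise ConfigurationError(f"no calibration curve for analyte {analyte!r}")
    results: list[SampleResult] = []
    n_positive = {a: 0 for a in batch.analytes}
    for rec in sorted(batch.samples, key=lambda s: (s.sample_id, s.analyte)):
        curve = curves[rec.analyte]
        conc = inverse_predict(curve, rec.par)
        status = censor(conc, curve)
        if status is SampleStatus.QUANTIFIED:
            n_positive[rec.analyte] += 1
        results.append(
            SampleResult(
                sample_id=rec.sample_id,
                analyte=rec.analyte,
                concentration=None if status is SampleStatus.BELOW_LOD else conc,
                status=status,
                curve_analyte=curve.analyte,
            )
        )
    return BatchReport(results=results, n_tested=len(batch.sample_ids), n_positive=n_positive)
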