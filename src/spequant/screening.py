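"""Main-effects analysis of Plackett-Burman screening responses.

Responses (analyte peak areas, S/N ratios, extraction duration) are fitted
by ordinary least squares on the coded factorial block:

    y = b0 + sum_i b_i x_i + e,      x_i in {-1, +1}

Dummy columns carry no physical effect, so their coefficients estimate the
random error: the screening rule flags a factor significant when its
coefficient exceeds the largest dummy coefficient in magnitude (a t-test
against the RMS dummy coefficient is available as an alternative).
Replicated mid-level runs are held out of the fit and used to validate the
model: the experimental mean (with its t-based confidence half-width) must
overlap the predicted response b0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ConfigurationError, FitError, IncompleteDataError
from .design import ScreeningDesign

__all__ = [
    "ResponseSet",
    "ScreeningFit",
    "ValidationVerdict",
    "Recommendation",
    "fit_screening_model",
    "estimate_error_from_dummies",
    "flag_significant",
    "validate_at_center",
    "recommend_conditions",
]


@dataclass
class ResponseSet:
    """Per-run response values: ``values[run_id][response_name] -> value``."""

    values: dict[int, dict[str, float]]

    @property
    def response_names(self) -> list[str]:
        names: list[str] = []
        for d in self.values.values():
            for n in d:
                if n not in names:
                    names.append(n)
        return names

    def vector(self, run_ids: Sequence[int], response_name: str) -> np.ndarray:
        out = np.empty(len(run_ids))
        for i, rid in enumerate(run_ids):
            try:
                v = self.values[rid][response_name]
            except KeyError:
                raise IncompleteDataError(
                    f"run {rid} has no value for response {response_name!r}"
                ) from None
            if not np.isfinite(v):
                raise IncompleteDataError(
                    f"run {rid}: non-finite value for response {response_name!r}"
                )
            out[i] = v
        return out

    # long-format CSV: run_id,response,value
    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ResponseSet":
        required = {"run_id", "response", "value"}
        if not required <= set(frame.columns):
            raise IncompleteDataError(
                f"responses table needs columns {sorted(required)}"
            )
        values: dict[int, dict[str, float]] = {}
        for row in frame.itertuples(index=False):
            values.setdefault(int(row.run_id), {})[str(row.response)] = float(row.value)
        return cls(values)

    @classmethod
    def from_csv(cls, path) -> "ResponseSet":
        return cls.from_frame(pd.read_csv(path))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"run_id": rid, "response": name, "value": val}
            for rid, d in sorted(self.values.items())
            for name, val in d.items()
        ]
        return pd.DataFrame(rows, columns=["run_id", "response", "value"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class ScreeningFit:
    """Fitted main-effects model for one response, on the coded scale."""

    response_name: str
    intercept: float
    coefficients: np.ndarray
    factor_names: tuple[str, ...]
    dummy_index: tuple[int, ...]
    n_runs: int
    df_resid: int
    effect_se: float | None = None
    dummy_band: float | None = None
    significant: dict[str, bool] | None = None
    significance_rule: str | None = None
    alpha: float | None = None

    @property
    def predicted_center(self) -> float:
        """Model prediction at the all-zero (mid-level) point: the intercept."""
        return self.intercept

    @property
    def dummy_coefficients(self) -> np.ndarray:
        return self.coefficients[list(self.dummy_index)]

    def coefficient(self, name: str) -> float:
        return float(self.coefficients[self.factor_names.index(name)])

    def to_dict(self) -> dict:
        return {
            "response": self.response_name,
            "intercept": self.intercept,
            "coefficients": dict(zip(self.factor_names, map(float, self.coefficients))),
            "dummy_factors": [self.factor_names[i] for i in self.dummy_index],
            "effect_se": self.effect_se,
            "dummy_band": self.dummy_band,
            "significant": self.significant,
            "significance_rule": self.significance_rule,
            "alpha": self.alpha,
            "n_runs": self.n_runs,
            "df_resid": self.df_resid,
        }


def fit_screening_model(
    design: ScreeningDesign,
    responses: ResponseSet,
    response_name: str,
) -> ScreeningFit:
    """OLS fit of one response on the coded factorial block (center runs held out).

    For an orthogonal PB block this equals the classical contrasts
    ``b0 = mean(y)``, ``b_i = (1/N) sum_j x_ij y_j``; the implementation uses
    a generic least-squares solve so corrupted plans are caught by the rank
    check rather than silently mis-estimated.
    """
    run_ids = design.factorial_run_ids
    X = design.factorial_block.astype(float)
    y = responses.vector(run_ids, response_name)
    n, k = X.shape
    A = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(A) < k + 1:
        raise FitError(
            f"design matrix for response {response_name!r} is rank-deficient"
        )
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return ScreeningFit(
        response_name=response_name,
        intercept=float(beta[0]),
        coefficients=beta[1:],
        factor_names=tuple(design.factor_names),
        dummy_index=tuple(design.dummy_indices),
        n_runs=n,
        df_resid=n - k - 1,
    )


def estimate_error_from_dummies(fit: ScreeningFit) -> tuple[float, float]:
    """Random-error estimate from dummy coefficients.

    Returns ``(effect_se, dummy_band)`` where ``effect_se`` is the RMS of the
    dummy coefficients and ``dummy_band`` their largest magnitude; both are
    stored on the fit.
    """
    d = fit.dummy_coefficients
    if d.size == 0:
        raise ConfigurationError(
            f"response {fit.response_name!r}: no dummy factors in the design"
        )
    fit.effect_se = float(np.sqrt(np.mean(d**2)))
    fit.dummy_band = float(np.max(np.abs(d)))
    return fit.effect_se, fit.dummy_band


def flag_significant(
    fit: ScreeningFit,
    rule: str = "dummy_band",
    alpha: float = 0.05,
) -> dict[str, bool]:
    """Flag factors whose coefficients exceed the random-error estimate.

    ``dummy_band`` (screening default): significant iff |b_i| strictly
    exceeds the largest dummy coefficient magnitude.  ``t_test``: significant
    iff |b_i| / effect_se > t(1 - alpha/2, df = number of dummies).
    """
    if rule not in ("dummy_band", "t_test"):
        raise ValueError(f"unknown significance rule {rule!r}")
    if fit.effect_se is None or fit.dummy_band is None:
        estimate_error_from_dummies(fit)
    flags: dict[str, bool] = {}
    if rule == "dummy_band":
        for name, b in zip(fit.factor_names, fit.coefficients):
            flags[name] = bool(abs(b) > fit.dummy_band)
    else:
        crit = stats.t.ppf(1 - alpha / 2, df=len(fit.dummy_index))
        for name, b in zip(fit.factor_names, fit.coefficients):
            if fit.effect_se == 0:
                flags[name] = bool(abs(b) > 0)
            else:
                flags[name] = bool(abs(b) / fit.effect_se > crit)
    fit.significant = flags
    fit.significance_rule = rule
    fit.alpha = alpha
    return flags


@dataclass(frozen=True)
class ValidationVerdict:
    """Model-validation outcome at the replicated mid-level points.

    The verdict is determined solely by the stored intervals: the model is
    validated iff [experimental ± hw] and [predicted ± hw] overlap.
    """

    experimental_mean: float
    experimental_halfwidth: float
    predicted: float
    predicted_halfwidth: float
    alpha: float
    verdict: str
    precision_rsd: float = float("nan")
    predicted_halfwidth_dummy: float | None = None

    @property
    def validated(self) -> bool:
        return self.verdict == "validated"

    @classmethod
    def from_intervals(
        cls,
        experimental_mean: float,
        experimental_halfwidth: float,
        predicted: float,
        predicted_halfwidth: float,
        alpha: float = 0.05,
        precision_rsd: float = float("nan"),
        predicted_halfwidth_dummy: float | None = None,
    ) -> "ValidationVerdict":
        if experimental_halfwidth < 0 or predicted_halfwidth < 0:
            raise ValueError("half-widths must be non-negative")
        overlap = abs(experimental_mean - predicted) <= (
            experimental_halfwidth + predicted_halfwidth
        )
        return cls(
            experimental_mean=experimental_mean,
            experimental_halfwidth=experimental_halfwidth,
            predicted=predicted,
            predicted_halfwidth=predicted_halfwidth,
            alpha=alpha,
            verdict="validated" if overlap else "not_validated",
            precision_rsd=precision_rsd,
            predicted_halfwidth_dummy=predicted_halfwidth_dummy,
        )

    def to_dict(self) -> dict:
        return {
            "experimental_mean": self.experimental_mean,
            "experimental_halfwidth": self.experimental_halfwidth,
            "predicted": self.predicted,
            "predicted_halfwidth": self.predicted_halfwidth,
            "predicted_halfwidth_dummy": self.predicted_halfwidth_dummy,
            "alpha": self.alpha,
            "verdict": self.verdict,
            "precision_rsd": self.precision_rsd,
        }


def validate_at_center(
    fit: ScreeningFit,
    center_values: Sequence[float],
    alpha: float = 0.05,
) -> ValidationVerdict:
    """Compare replicate responses at the mid-level point against the prediction.

    The experimental mean carries the t-based half-width
    ``t(1 - alpha/2, n - 1) * sd / sqrt(n)``; the same half-width is applied
    to the predicted response b0 (the replicate interval is the only
    experimental dispersion estimate available).  A secondary dummy-based
    prediction half-width ``t(1 - alpha/2, n_dummies) * effect_se`` is
    reported when the error estimate is present.
    """
    vals = np.asarray(list(center_values), dtype=float)
    if vals.size < 2:
        raise IncompleteDataError(
            "model validation needs at least 2 mid-level replicates"
        )
    n = vals.size
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1))
    hw = float(stats.t.ppf(1 - alpha / 2, df=n - 1) * sd / np.sqrt(n))
    hw_dummy = None
    if fit.effect_se is not None and fit.dummy_index:
        hw_dummy = float(
            stats.t.ppf(1 - alpha / 2, df=len(fit.dummy_index)) * fit.effect_se
        )
    rsd = float("nan") if mean == 0 else 100.0 * sd / abs(mean)
    return ValidationVerdict.from_intervals(
        experimental_mean=mean,
        experimental_halfwidth=hw,
        predicted=fit.predicted_center,
        predicted_halfwidth=hw,
        alpha=alpha,
        precision_rsd=rsd,
        predicted_halfwidth_dummy=hw_dummy,
    )


@dataclass(frozen=True)
class Recommendation:
    """Chosen coded level per factor, with the decision trace that produced it."""

    levels: dict[str, int]
    trace: list[dict]

    def to_dict(self) -> dict:
        return {"levels": self.levels, "trace": self.trace}


def recommend_conditions(
    fits: Iterable[ScreeningFit] | Mapping[str, ScreeningFit],
    objectives: Mapping[str, str],
    priority: Sequence[str] | None = None,
) -> Recommendation:
    """Choose a coded level (−1/0/+1) per real factor from the fitted models.

    For each factor, the highest-priority response in which it is significant
    decides: a positive coefficient under ``maximize`` (or negative under
    ``minimize``) selects +1, otherwise −1.  Factors significant in no
    prioritized response stay at 0, annotated "free".
    """
    if not objectives:
        raise ValueError("objectives must name at least one response")
    for obj in objectives.values():
        if obj not in ("maximize", "minimize"):
            raise ValueError(f"unknown objective {obj!r}")
    if isinstance(fits, Mapping):
        by_name = dict(fits)
    else:
        by_name = {f.response_name: f for f in fits}
    priority = list(priority) if priority is not None else list(objectives)
    missing = [r for r in priority if r not in by_name]
    if missing:
        raise ValueError(f"no fit supplied for prioritized responses {missing}")

    for resp in priority:
        fit = by_name[resp]
        if fit.significant is None:
            flag_significant(fit)

    first = by_name[priority[0]]
    real_names = [
        n for i, n in enumerate(first.factor_names) if i not in first.dummy_index
    ]

    levels: dict[str, int] = {}
    trace: list[dict] = []
    for name in real_names:
        chosen = None
        for resp in priority:
            fit = by_name[resp]
            if name not in fit.factor_names or not fit.significant.get(name, False):
                continue
            b = fit.coefficient(name)
            obj = objectives[resp]
            level = 1 if (b > 0) == (obj == "maximize") else -1
            chosen = {
                "factor": name,
                "level": level,
                "decided_by": resp,
                "objective": obj,
                "coefficient": b,
            }
            break
        if chosen is None:
            chosen = {"factor": name, "level": 0, "decided_by": None,
                      "objective": None, "coefficient": None, "note": "free"}
        levels[name] = chosen["level"]
        trace.append(chosen)
    return Recommendation(levels=levels, trace=trace)
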