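"""Plackett-Burman screening designs for extraction-method development.

A Plackett-Burman (PB) design screens up to ``N - 1`` two-level factors in
``N`` runs (``N`` a multiple of 4), estimating main effects only.  Columns
not assigned to a physical variable ("dummy" factors) carry no real effect,
so their fitted coefficients estimate the random error of the experiment.
Replicated mid-level runs (center / validation points) are appended to
validate model predictions and measure replicate precision.

This module builds such designs, translates between coded (−1/0/+1) and
real factor levels, loads plan tables from CSV, and expands a design into a
liquid-handler worklist (step, reagent, volume, dispense/aspirate speed).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from ._errors import ConfigurationError, DesignSizeError, PlanError

__all__ = [
    "FactorDefinition",
    "ScreeningDesign",
    "StepTemplate",
    "WorklistStep",
    "Worklist",
    "PB_GENERATORS",
    "STUDY_PROTOCOL",
    "SELECTED_CONDITIONS",
    "build_pb_design",
    "code_level",
    "decode_level",
    "load_plan_table",
    "load_factor_definitions",
    "assemble_worklist",
    "worklist_from_settings",
    "example_factor_definitions",
    "example_screening_plan",
]

#: Cyclic generator rows for standard PB designs.  Row i of the factorial
#: block is the generator cyclically shifted by i; an all-minus row closes
#: the design.  N = 16 uses a non-cyclic Hadamard construction and is not
#: supported; requests for 12 < k <= 15 factors are served by N = 20.
PB_GENERATORS: dict[int, str] = {
    4: "++-",
    8: "+++-+--",
    12: "++-+++---+-",
    20: "++--++++-+-+----++-",
    24: "+++++-+-++--++--+-+----",
}

_CODE_TOL = 1e-9


@dataclass(frozen=True)
class FactorDefinition:
    """One screened factor: name, physical unit and low/center/high levels.

    Real factors have ``center == (low + high) / 2``; dummy factors are
    dimensionless placeholders whose only admissible levels are −1, 0, +1.
    """

    name: str
    unit: str = ""
    low: float = -1.0
    high: float = 1.0
    center: float | None = None
    role: str = "real"

    def __post_init__(self) -> None:
        if self.role not in ("real", "dummy"):
            raise ConfigurationError(f"factor {self.name!r}: unknown role {self.role!r}")
        if not self.low < self.high:
            raise ConfigurationError(
                f"factor {self.name!r}: low ({self.low}) must be < high ({self.high})"
            )
        mid = 0.5 * (self.low + self.high)
        if self.center is None:
            object.__setattr__(self, "center", mid)
        elif self.role == "real" and abs(self.center - mid) > _CODE_TOL * max(1.0, abs(mid)):
            raise ConfigurationError(
                f"factor {self.name!r}: center {self.center} is not the midpoint of "
                f"[{self.low}, {self.high}]"
            )
        if self.role == "dummy" and (self.low, self.high) != (-1.0, 1.0):
            raise ConfigurationError(
                f"dummy factor {self.name!r} must have levels -1/+1, got "
                f"[{self.low}, {self.high}]"
            )

    @property
    def half_range(self) -> float:
        return 0.5 * (self.high - self.low)


def code_level(factor: FactorDefinition, real_value: float) -> float:
    """Translate a real-unit level to the coded scale: −1 at low, 0 at center, +1 at high."""
    lo, hi = factor.low, factor.high
    span = hi - lo
    if not (lo - _CODE_TOL * span) <= real_value <= (hi + _CODE_TOL * span):
        raise ValueError(
            f"factor {factor.name!r}: value {real_value} outside [{lo}, {hi}]"
        )
    return (real_value - factor.center) / factor.half_range


def decode_level(factor: FactorDefinition, coded: float) -> float:
    """Inverse of :func:`code_level`: map a coded level back to real units."""
    return factor.center + coded * factor.half_range


@dataclass
class ScreeningDesign:
    """A coded PB screening plan: factorial block plus optional center runs.

    ``coded_matrix`` holds one row per run with entries in {−1, 0, +1};
    center/validation rows are all-zero.  ``randomized_order`` is the run
    execution order (a permutation of ``run_ids``); the matrix itself is
    stored in plan order.
    """

    factors: list[FactorDefinition]
    coded_matrix: np.ndarray
    run_ids: list[int]
    center_run_ids: list[int] = field(default_factory=list)
    randomized_order: list[int] | None = None

    def __post_init__(self) -> None:
        self.coded_matrix = np.asarray(self.coded_matrix, dtype=int)
        if self.coded_matrix.shape != (len(self.run_ids), len(self.factors)):
            raise PlanError(
                f"coded matrix shape {self.coded_matrix.shape} does not match "
                f"{len(self.run_ids)} runs x {len(self.factors)} factors"
            )
        if self.randomized_order is None:
            self.randomized_order = list(self.run_ids)

    # -- structure ---------------------------------------------------------

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def dummy_indices(self) -> list[int]:
        return [i for i, f in enumerate(self.factors) if f.role == "dummy"]

    @property
    def factorial_run_ids(self) -> list[int]:
        center = set(self.center_run_ids)
        return [r for r in self.run_ids if r not in center]

    @property
    def n_factorial(self) -> int:
        return len(self.factorial_run_ids)

    def row(self, run_id: int) -> np.ndarray:
        return self.coded_matrix[self.run_ids.index(run_id)]

    @property
    def factorial_block(self) -> np.ndarray:
        """Coded matrix restricted to factorial (non-center) runs, in plan order."""
        center = set(self.center_run_ids)
        keep = [i for i, r in enumerate(self.run_ids) if r not in center]
        return self.coded_matrix[keep]

    def validate(self) -> None:
        """Check PB structural invariants; raise :class:`PlanError` on violation."""
        X = self.factorial_block
        n, k = X.shape
        if n % 4 != 0 or n <= k:
            raise PlanError(f"factorial run count {n} invalid for {k} factors")
        if not set(np.unique(X)) <= {-1, 1}:
            raise PlanError("factorial rows must be coded -1/+1 in every column")
        if np.any(X.sum(axis=0) != 0):
            raise PlanError("factorial columns must balance -1 and +1 counts")
        if not np.array_equal(X.T @ X, n * np.eye(k, dtype=int)):
            raise PlanError("factorial columns are not mutually orthogonal")
        center = set(self.center_run_ids)
        for i, r in enumerate(self.run_ids):
            if r in center and np.any(self.coded_matrix[i] != 0):
                raise PlanError(f"center run {r} is not coded all-zero")

    # -- real-unit views ---------------------------------------------------

    def real_settings(self, run_id: int) -> dict[str, float]:
        """Real-unit factor settings for one run, decoded from the coded row."""
        return {
            f.name: decode_level(f, c)
            for f, c in zip(self.factors, self.row(run_id))
        }

    def to_plan_frame(self) -> pd.DataFrame:
        """Plan table with real-unit levels, one row per run in plan order."""
        rows = [
            {"run_id": r, **self.real_settings(r)}
            for r in self.run_ids
        ]
        return pd.DataFrame(rows)

    def to_plan_csv(self, path) -> None:
        self.to_plan_frame().to_csv(path, index=False)


def _choose_n_runs(k: int, n_runs: int | None) -> int:
    supported = sorted(PB_GENERATORS)
    if n_runs is not None:
        if n_runs not in supported:
            raise DesignSizeError(
                f"unsupported run count {n_runs}; supported: {supported}"
            )
        if k > n_runs - 1:
            minimum = next((n for n in supported if n - 1 >= k), None)
            raise DesignSizeError(
                f"{k} factors exceed the {n_runs - 1}-factor capacity of the "
                f"{n_runs}-run design; minimum run count is {minimum}"
            )
        return n_runs
    for n in supported:
        if n - 1 >= k:
            return n
    raise DesignSizeError(
        f"{k} factors exceed the capacity of the largest supported design "
        f"({supported[-1]} runs, {supported[-1] - 1} factors)"
    )


def build_pb_design(
    n_real: int,
    n_dummy: int = 0,
    n_center: int = 0,
    seed: int | None = None,
    factors: Sequence[FactorDefinition] | None = None,
    n_runs: int | None = None,
) -> ScreeningDesign:
    """Build a PB screening design with dummy columns and center points.

    Parameters
    ----------
    n_real, n_dummy
        Number of physical and dummy factors.  Together they must fit in
        ``N - 1`` columns of the chosen ``N``-run design (the smallest
        supported ``N`` is picked automatically unless ``n_runs`` is given).
    n_center
        All-zero (mid-level) validation rows appended after the factorial
        block.
    seed
        Seeds the Fisher-Yates shuffle producing ``randomized_order``.
        Identical seeds give identical orders.
    factors
        Definitions for the real factors, in column order.  Defaults to
        generic coded factors x1..xn with levels −1/+1.
    """
    if n_real < 1:
        raise ValueError("need at least one real factor")
    if n_dummy < 0 or n_center < 0:
        raise ValueError("n_dummy and n_center must be non-negative")
    k = n_real + n_dummy
    n = _choose_n_runs(k, n_runs)

    if factors is None:
        factors = [FactorDefinition(name=f"x{i + 1}") for i in range(n_real)]
    else:
        factors = list(factors)
        if len(factors) != n_real:
            raise ConfigurationError(
                f"{len(factors)} factor definitions supplied for n_real={n_real}"
            )
        if any(f.role != "real" for f in factors):
            raise ConfigurationError("supplied factor definitions must all have role 'real'")
    factors = factors + [
        FactorDefinition(name=f"x{n_real + j + 1}", role="dummy")
        for j in range(n_dummy)
    ]

    gen = np.array([1 if c == "+" else -1 for c in PB_GENERATORS[n]], dtype=int)
    block = np.vstack(
        [np.roll(gen, i) for i in range(n - 1)] + [-np.ones(n - 1, dtype=int)]
    )[:, :k]
    coded = np.vstack([block, np.zeros((n_center, k), dtype=int)])

    run_ids = list(range(1, n + n_center + 1))
    center_run_ids = run_ids[n:]
    rng = np.random.default_rng(seed)
    order = [run_ids[i] for i in rng.permutation(len(run_ids))]
    design = ScreeningDesign(
        factors=factors,
        coded_matrix=coded,
        run_ids=run_ids,
        center_run_ids=center_run_ids,
        randomized_order=order,
    )
    design.validate()
    return design


# -- plan table I/O --------------------------------------------------------


def load_factor_definitions(path) -> list[FactorDefinition]:
    """Read factor definitions from a YAML file with a top-level ``factors`` list."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "factors" not in doc:
        raise ConfigurationError(f"{path}: expected a mapping with a 'factors' list")
    out = []
    for entry in doc["factors"]:
        try:
            out.append(FactorDefinition(**entry))
        except TypeError as exc:
            raise ConfigurationError(f"{path}: bad factor entry {entry!r}: {exc}") from exc
    return out


def _infer_factors(frame: pd.DataFrame) -> list[FactorDefinition]:
    factors = []
    for col in frame.columns:
        vals = frame[col].to_numpy(dtype=float)
        lo, hi = float(vals.min()), float(vals.max())
        if lo == hi:
            raise PlanError(f"column {col!r}: all levels identical ({lo})")
        role = "dummy" if set(np.unique(vals)) <= {-1.0, 0.0, 1.0} else "real"
        factors.append(FactorDefinition(name=str(col), low=lo, high=hi, role=role))
    return factors


def load_plan_table(path, factors: Sequence[FactorDefinition] | None = None) -> ScreeningDesign:
    """Reconstruct a :class:`ScreeningDesign` from a real-unit plan CSV.

    The file must have a ``run_id`` (or ``#``) column followed by one column
    per factor.  Factor levels are coded from the supplied definitions, or
    inferred per column (low = min, high = max) when none are given.
    Factorial rows must code to ±1 in every column; rows at the coded
    mid-level, and replicated rows that match neither pattern (the plan's
    validation points), are recorded as center runs with all-zero coding.
    """
    try:
        frame = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise PlanError(f"{path}: could not parse plan table: {exc}") from exc
    if frame.empty:
        raise PlanError(f"{path}: plan table has no runs")

    id_col = frame.columns[0]
    if id_col not in ("run_id", "#"):
        raise PlanError(f"{path}: first column must be 'run_id', found {id_col!r}")
    run_ids = [int(v) for v in frame[id_col]]
    if len(set(run_ids)) != len(run_ids):
        raise PlanError(f"{path}: duplicate run ids")
    body = frame.drop(columns=[id_col])

    numeric = body.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = numeric.isna().stack()
        row_idx, col = bad[bad].index[0]
        raise PlanError(
            f"{path}: non-numeric value {body.at[row_idx, col]!r} at run "
            f"{run_ids[row_idx]}, column {col!r}"
        )

    if factors is None:
        factors = _infer_factors(numeric)
    else:
        factors = list(factors)
        missing = [f.name for f in factors if f.name not in numeric.columns]
        if missing:
            raise PlanError(f"{path}: plan lacks factor columns {missing}")
        numeric = numeric[[f.name for f in factors]]

    coded = np.empty(numeric.shape, dtype=float)
    for j, f in enumerate(factors):
        col = numeric.iloc[:, j].to_numpy(dtype=float)
        try:
            coded[:, j] = [code_level(f, v) for v in col]
        except ValueError as exc:
            raise PlanError(f"{path}: {exc}") from exc

    def _near(x, target):
        return np.all(np.abs(x - target) <= 1e-6)

    row_tuples = [tuple(r) for r in numeric.itertuples(index=False)]
    counts: dict[tuple, int] = {}
    for t in row_tuples:
        counts[t] = counts.get(t, 0) + 1

    out = np.zeros(coded.shape, dtype=int)
    center_run_ids: list[int] = []
    for i, rid in enumerate(run_ids):
        row = coded[i]
        if _near(np.abs(row), 1.0):
            out[i] = np.sign(row).astype(int)
        elif _near(row, 0.0) or counts[row_tuples[i]] >= 2:
            center_run_ids.append(rid)  # mid-level or replicated validation point
        else:
            raise PlanError(
                f"{path}: run {rid} is neither a +/-1 factorial row nor a "
                "replicated/mid-level validation row"
            )

    design = ScreeningDesign(
        factors=list(factors),
        coded_matrix=out,
        run_ids=run_ids,
        center_run_ids=center_run_ids,
        randomized_order=list(run_ids),
    )
    design.validate()
    return design


def example_factor_definitions() -> list[FactorDefinition]:
    """Factor definitions of the bundled µSPE screening study (9 real + 2 dummy)."""
    ref = resources.files("spequant.data") / "example_factors.yaml"
    with resources.as_file(ref) as path:
        return load_factor_definitions(path)


def example_screening_plan() -> ScreeningDesign:
    """The bundled 12-run PB plan with three replicated validation points.

    Nine real factors (conditioning/equilibration/wash volumes, wash
    composition, five dispense speeds) plus two dummy columns; validation
    replicates are runs 1, 6 and 7.
    """
    factors = example_factor_definitions()
    ref = resources.files("spequant.data") / "example_plan.csv"
    with resources.as_file(ref) as path:
        return load_plan_table(path, factors=factors)


# -- worklist assembly -----------------------------------------------------


@dataclass(frozen=True)
class StepTemplate:
    """One protocol step; volume/speeds are numbers (µL, µL/s) or factor names."""

    name: str
    reagent: str
    volume: float | str
    dispense_speed: float | str
    aspirate_speed: float | str = 15.0
    is_sample: bool = False
    repeat: int = 1


@dataclass(frozen=True)
class WorklistStep:
    run_id: int
    step: str
    reagent: str
    volume_uL: float
    dispense_uLs: float
    aspirate_uLs: float
    is_sample: bool = False


@dataclass
class Worklist:
    """Fully resolved per-run protocol steps in real units."""

    steps: list[WorklistStep]

    @property
    def run_ids(self) -> list[int]:
        seen: list[int] = []
        for s in self.steps:
            if s.run_id not in seen:
                seen.append(s.run_id)
        return seen

    def for_run(self, run_id: int) -> "Worklist":
        return Worklist([s for s in self.steps if s.run_id == run_id])

    def to_frame(self) -> pd.DataFrame:
        cols = ["run_id", "step", "reagent", "volume_uL", "dispense_uLs", "aspirate_uLs", "is_sample"]
        return pd.DataFrame([{c: getattr(s, c) for c in cols} for s in self.steps], columns=cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


#: Step templates of the automated µSPE extraction protocol: conditioning,
#: equilibration, duplicate sample loading, wash, elution and a fixed final
#: methanol syringe wash.  Volumes referencing mL-unit factors are scaled to µL.
STUDY_PROTOCOL: tuple[StepTemplate, ...] = (
    StepTemplate("condition", "methanol", "x1", "x6"),
    StepTemplate("equilibrate", "KOH 0.01 M", "x2", "x7"),
    StepTemplate("load_sample", "basified urine", 500.0, "x5", is_sample=True, repeat=2),
    StepTemplate("wash", "KOH 0.01 M H2O:MeOH", "x3", "x8"),
    StepTemplate("elute", "1% formic acid MeOH:H2O 90:10", 200.0, "x9"),
    StepTemplate("syringe_wash", "methanol", 300.0, 15.0),
)

#: Extraction conditions selected after screening (real units: mL, %MeOH, µL/s).
SELECTED_CONDITIONS: dict[str, float] = {
    "x1": 0.2, "x2": 0.2, "x3": 0.5, "x4": 10.0, "x5": 25.0,
    "x6": 55.0, "x7": 55.0, "x8": 25.0, "x9": 10.0,
}

_UL_PER_UNIT = {"mL": 1000.0, "µL": 1.0, "uL": 1.0, "": 1.0}


def _resolve(
    value: float | str,
    settings: dict[str, float],
    factor_by_name: dict[str, FactorDefinition],
    kind: str,
) -> float:
    if isinstance(value, str):
        if value not in settings:
            raise ConfigurationError(
                f"protocol references unmapped parameter {value!r}"
            )
        real = settings[value]
        unit = factor_by_name[value].unit if value in factor_by_name else ""
        if kind == "volume":
            scale = _UL_PER_UNIT.get(unit)
            if scale is None:
                raise ConfigurationError(
                    f"factor {value!r} with unit {unit!r} cannot supply a volume"
                )
            return real * scale
        return real
    return float(value)


def worklist_from_settings(
    settings: dict[str, float],
    factors: Sequence[FactorDefinition] = (),
    protocol: Sequence[StepTemplate] = STUDY_PROTOCOL,
    run_id: int = 1,
) -> Worklist:
    """Expand a protocol template for one run with explicit real-unit settings."""
    by_name = {f.name: f for f in factors}
    steps: list[WorklistStep] = []
    for tpl in protocol:
        vol = _resolve(tpl.volume, settings, by_name, "volume")
        disp = _resolve(tpl.dispense_speed, settings, by_name, "speed")
        asp = _resolve(tpl.aspirate_speed, settings, by_name, "speed")
        if vol <= 0 or disp <= 0 or asp <= 0:
            raise ConfigurationError(
                f"step {tpl.name!r}: volumes and speeds must be strictly positive"
            )
        for _ in range(tpl.repeat):
            steps.append(
                WorklistStep(run_id, tpl.name, tpl.reagent, vol, disp, asp, tpl.is_sample)
            )
    return Worklist(steps)


def assemble_worklist(
    design: ScreeningDesign,
    protocol: Sequence[StepTemplate] = STUDY_PROTOCOL,
) -> Worklist:
    """Expand a protocol template into per-run steps for every run of a design.

    Template parameters naming a factor take that run's decoded real-unit
    setting (mL volumes scaled to µL); numeric parameters pass through
    unchanged.
    """
    steps: list[WorklistStep] = []
    for rid in design.run_ids:
        settings = design.real_settings(rid)
        steps.extend(
            worklist_from_settings(settings, design.factors, protocol, run_id=rid).steps
        )
    return Worklist(steps)
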