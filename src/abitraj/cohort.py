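"""Longitudinal cohort tables for acquired brain injury (ABI) outcome analysis.

A cohort is stored in *long* format: one row per patient per clinical
evaluation (``T0`` admission to the rehabilitation unit, ``T1`` roughly four
months post-event, ``T2`` discharge), with the days since injury of each
evaluation, a set of mixed continuous/categorical clinical variables, and the
Glasgow Outcome Scale (GOS, 1-5) recorded at discharge.  The GOS is binarized
into a ``positive`` (GOS >= 4) versus ``negative`` (GOS < 4) discharge
outcome, which is the prediction target of the whole pipeline.

Every variable must be declared in a :class:`VariableDictionary` giving its
type (continuous or categorical) and, for categoricals, the admissible level
set.  Loading validates each row against the dictionary and reports offending
rows by index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

EVALUATIONS = ("T0", "T1", "T2")
POSITIVE = "positive"
NEGATIVE = "negative"

#: columns with a fixed meaning; everything else must be a declared variable
RESERVED_COLUMNS = ("patient_id", "evaluation", "eval_time", "gos", "outcome")


class CohortValidationError(ValueError):
    """Raised when a cohort file violates its variable dictionary.

    ``problems`` is a list of human-readable messages, each naming the
    offending row index of the input table.
    """

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__(
            "cohort validation failed:\n" + "\n".join(f"  - {p}" for p in self.problems)
        )


@dataclass(frozen=True)
class Variable:
    """Declaration of one clinical variable."""

    name: str
    kind: str  # "continuous" | "categorical"
    levels: tuple[str, ...] | None = None
    time_invariant: bool = False

    def __post_init__(self):
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown variable kind {self.kind!r} for {self.name!r}")
        if self.kind == "categorical" and not self.levels:
            raise ValueError(f"categorical variable {self.name!r} needs a level set")
        if self.kind == "continuous" and self.levels:
            raise ValueError(f"continuous variable {self.name!r} cannot have levels")


class VariableDictionary:
    """Ordered mapping ``name -> Variable`` with YAML (de)serialization."""

    def __init__(self, variables: list[Variable]):
        self._vars: dict[str, Variable] = {}
        for v in variables:
            if v.name in self._vars:
                raise ValueError(f"duplicate variable {v.name!r}")
            self._vars[v.name] = v

    def __iter__(self):
        return iter(self._vars.values())

    def __contains__(self, name: str) -> bool:
        return name in self._vars

    def __getitem__(self, name: str) -> Variable:
        return self._vars[name]

    def __len__(self) -> int:
        return len(self._vars)

    @property
    def names(self) -> list[str]:
        return list(self._vars)

    def continuous(self) -> list[str]:
        return [v.name for v in self if v.kind == "continuous"]

    def categorical(self) -> list[str]:
        return [v.name for v in self if v.kind == "categorical"]

    def subset(self, names: list[str]) -> "VariableDictionary":
        missing = [n for n in names if n not in self]
        if missing:
            raise KeyError(f"undeclared variables: {missing}")
        return VariableDictionary([self._vars[n] for n in names])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "VariableDictionary":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        out = []
        for name, decl in raw.items():
            out.append(
                Variable(
                    name=name,
                    kind=decl["type"],
                    levels=tuple(decl["levels"]) if decl.get("levels") else None,
                    time_invariant=bool(decl.get("time_invariant", False)),
                )
            )
        return cls(out)

    def to_yaml(self, path: str | Path) -> None:
        raw = {}
        for v in self:
            decl: dict = {"type": v.kind}
            if v.levels:
                decl["levels"] = list(v.levels)
            if v.time_invariant:
                decl["time_invariant"] = True
            raw[v.name] = decl
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def binarize_gos(gos: int) -> str:
    """Binarize a Glasgow Outcome Scale value: ``positive`` iff GOS >= 4.

    GOS levels are 1 death, 2 vegetative, 3 severe disability, 4 moderate
    disability, 5 good recovery; 4-5 count as a positive discharge outcome.
    """
    g = int(gos)
    if g != gos or not 1 <= g <= 5:
        raise ValueError(f"GOS must be an integer in 1..5, got {gos!r}")
    return POSITIVE if g >= 4 else NEGATIVE


@dataclass
class CohortTable:
    """Validated long-format cohort: one row per patient per evaluation."""

    data: pd.DataFrame
    dictionary: VariableDictionary

    @property
    def patient_ids(self) -> list:
        return list(dict.fromkeys(self.data["patient_id"]))

    def outcomes(self) -> pd.Series:
        """Per-patient binary outcome (constant across a patient's rows)."""
        return self.data.groupby("patient_id", sort=False)["outcome"].first()

    def n_patients(self) -> int:
        return self.data["patient_id"].nunique()

    def subset(self, patient_ids) -> "CohortTable":
        ids = set(patient_ids)
        return CohortTable(
            self.data[self.data["patient_id"].isin(ids)].reset_index(drop=True),
            self.dictionary,
        )

    def write_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    def write_xlsx(self, path: str | Path) -> None:
        self.data.to_excel(path, index=False)


def _validate(df: pd.DataFrame, dictionary: VariableDictionary) -> list[str]:
    problems: list[str] = []
    for col in RESERVED_COLUMNS[:4]:
        if col not in df.columns:
            problems.append(f"missing required column {col!r}")
    if problems:
        return problems

    declared = set(dictionary.names)
    for col in df.columns:
        if col not in declared and col not in RESERVED_COLUMNS:
            problems.append(f"undeclared variable column {col!r}")

    bad_eval = ~df["evaluation"].isin(EVALUATIONS)
    for idx in df.index[bad_eval]:
        problems.append(f"row {idx}: unknown evaluation {df.at[idx, 'evaluation']!r}")

    for idx, g in df["gos"].items():
        if pd.isna(g):
            problems.append(f"row {idx}: missing GOS")
            continue
        try:
            binarize_gos(g)
        except ValueError:
            problems.append(f"row {idx}: GOS {g!r} outside 1..5")

    t = pd.to_numeric(df["eval_time"], errors="coerce")
    for idx in df.index[t.isna() | (t <= 0)]:
        problems.append(f"row {idx}: eval_time {df.at[idx, 'eval_time']!r} not a positive number")

    # T0 < T1 < T2 within patient
    order = {e: i for i, e in enumerate(EVALUATIONS)}
    for pid, grp in df.groupby("patient_id", sort=False):
        grp = grp.assign(_t=t[grp.index]).dropna(subset=["_t"])
        grp = grp.sort_values("evaluation", key=lambda s: s.map(order))
        times = grp["_t"].to_numpy(dtype=float)
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            problems.append(f"patient {pid!r}: eval_time not strictly increasing across T0<T1<T2")

    for var in dictionary:
        if var.name not in df.columns:
            continue
        col = df[var.name]
        if var.kind == "continuous":
            coerced = pd.to_numeric(col, errors="coerce")
            bad = coerced.isna() & col.notna() & (col.astype(str).str.strip() != "")
            for idx in df.index[bad]:
                problems.append(
                    f"row {idx}: non-numeric value {col[idx]!r} for continuous variable {var.name!r}"
                )
        else:
            levels = set(var.levels)
            bad = col.notna() & ~col.isin(levels)
            for idx in df.index[bad]:
                problems.append(
                    f"row {idx}: value {col[idx]!r} of {var.name!r} outside level set {sorted(levels)}"
                )
    return problems


def load_cohort(path: str | Path, dictionary: VariableDictionary) -> CohortTable:
    """Read and validate a long-format cohort table (CSV or XLSX).

    CSV is comma-separated UTF-8 with "." decimals; XLSX uses the first sheet
    and requires a header row.  Empty strings and NaN are the missing markers.
    Raises :class:`CohortValidationError` listing every offending row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, sheet_name=0)
    else:
        df = pd.read_csv(path, encoding="utf-8")
    df = df.replace({"": np.nan})

    problems = _validate(df, dictionary)
    if problems:
        raise CohortValidationError(problems)

    df = df.copy()
    df["eval_time"] = pd.to_numeric(df["eval_time"])
    df["gos"] = df["gos"].astype(int)
    for name in dictionary.continuous():
        if name in df.columns:
            df[name] = pd.to_numeric(df[name], errors="coerce")
    df["outcome"] = df["gos"].map(binarize_gos)
    ordering = {e: i for i, e in enumerate(EVALUATIONS)}
    df = df.sort_values(
        ["patient_id", "evaluation"],
        key=lambda s: s.map(ordering) if s.name == "evaluation" else s,
        kind="stable",
    ).reset_index(drop=True)
    return CohortTable(df, dictionary)


@dataclass(frozen=True)
class SplitResult:
    """Outcome-stratified train/validation partition of the patient IDs."""

    train_ids: tuple
    valid_ids: tuple
    seed: int
    fraction: float

    def __post_init__(self):
        if set(self.train_ids) & set(self.valid_ids):
            raise ValueError("train and validation IDs overlap")


def stratified_split(
    cohort: CohortTable, validation_fraction: float = 0.30, seed: int = 0
) -> SplitResult:
    """Split patients into training/validation, balanced on the binary outcome.

    Per outcome stratum exactly ``floor(fraction * stratum size)`` patients go
    to validation, sampled uniformly without replacement; with strata of
    116 negatives and 27 positives at fraction 0.30 this yields 34 + 8 = 42
    validation patients.  Deterministic given ``seed``.
    """
    if not 0 < validation_fraction < 1:
        raise ValueError("validation_fraction must be in (0, 1)")
    outcomes = cohort.outcomes()
    rng = np.random.default_rng(seed)
    valid: list = []
    train: list = []
    for label in (NEGATIVE, POSITIVE):
        ids = sorted(outcomes.index[outcomes == label], key=str)
        if not ids:
            raise ValueError(f"outcome stratum {label!r} is empty")
        n_valid = int(np.floor(validation_fraction * len(ids)))
        if n_valid == 0:
            warnings.warn(
                f"stratum {label!r} (n={len(ids)}) receives no validation patients",
                stacklevel=2,
            )
        chosen = rng.choice(len(ids), size=n_valid, replace=False)
        chosen_set = set(chosen.tolist())
        valid.extend(ids[i] for i in sorted(chosen_set))
        train.extend(ids[i] for i in range(len(ids)) if i not in chosen_set)
    return SplitResult(tuple(train), tuple(valid), seed, validation_fraction)


def long_format(
    cohort: CohortTable, evaluations=EVALUATIONS, variables: list[str] | None = None
) -> pd.DataFrame:
    """Rows of (patient_id, evaluation, eval_time, variables..., outcome).

    One row per patient per available evaluation in ``evaluations``;
    evaluations whose clinical variables are all missing are omitted (a
    patient discharged before T1 simply contributes no T1 row).
    """
    evaluations = [e for e in EVALUATIONS if e in set(evaluations)]
    if variables is None:
        variables = [v.name for v in cohort.dictionary if v.name in cohort.data.columns]
    df = cohort.data[cohort.data["evaluation"].isin(evaluations)]
    if variables:
        keep = ~df[variables].isna().all(axis=1)
        df = df[keep]
    cols = ["patient_id", "evaluation", "eval_time", *variables, "outcome"]
    return df[cols].reset_index(drop=True)
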