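"""End-to-end analysis: split -> screen -> FAMD -> MM fits -> bands -> rule -> validate.

All model fitting (screening, FAMD, Michaelis-Menten curves, Monte-Carlo
bands, the crossover day) uses the training sample only; validation patients
are merely projected onto the training components and classified by the
threshold rule, exactly as a newly admitted patient would be.  Every stage's
artifact can be written to an output directory, and the whole run is
reproducible from the configuration plus one master seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import famd as famd_mod
from .classifier import ClassifierRule, classify_patient, find_crossover
from .cohort import (
    NEGATIVE,
    POSITIVE,
    CohortTable,
    VariableDictionary,
    load_cohort,
    long_format,
    stratified_split,
)
from .metrics import confusion, metrics
from .screening import screen_cohort, screening_report, select_variables
from .synthetic import SimulationConfig, simulate_mixed_cohort
from .trajectory import MMFit, compare_params, fit_mm, monte_carlo_band

log = logging.getLogger("abitraj")


@dataclass
class RunConfig:
    """Settings of one analysis run (defaults follow the reference study)."""

    input_path: str | None = None  # cohort CSV/XLSX; None -> simulate
    dictionary_path: str | None = None
    simulation: SimulationConfig | None = None
    validation_fraction: float = 0.30
    screening_alpha: float = 0.05
    model_component: int = 1  # 1-based FAMD dimension fed to the MM stage
    n_draws: int = 10_000
    band_level: float = 0.95
    grid_start: float = 0.0
    grid_stop: float = 600.0
    grid_step: float = 1.0
    combine: str = "earliest"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.grid_step <= 0 or self.grid_stop <= self.grid_start:
            raise ValueError("invalid time grid")
        if self.input_path is None and self.simulation is None:
            self.simulation = SimulationConfig(seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = SimulationConfig(**sim)
        return cfg

    def grid(self) -> np.ndarray:
        return np.arange(self.grid_start, self.grid_stop + self.grid_step, self.grid_step)


def _subseeds(master: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


@dataclass
class RunReport:
    """Consolidated artifacts of one pipeline run."""

    config: RunConfig
    split: object
    screening: pd.DataFrame
    kept_variables: list[str]
    famd_model: famd_mod.FAMDModel
    variance_explained: np.ndarray
    contributions_dim1: pd.Series
    fits: dict[str, MMFit]
    param_tests: dict[str, tuple[float, float]]
    rule: ClassifierRule
    train_scores: pd.DataFrame
    valid_scores: pd.DataFrame
    table3: dict[str, object]  # metrics per time-point row

    def summary(self) -> dict:
        return {
            "seed": self.config.seed,
            "n_train": len(self.split.train_ids),
            "n_valid": len(self.split.valid_ids),
            "kept_variables": self.kept_variables,
            "variance_explained_pct": [round(100 * v, 2) for v in self.variance_explained[:5]],
            "mm_fits": {
                g: {
                    "a": f.params.a,
                    "m": f.params.m,
                    "K": f.params.K,
                    "se": f.se,
                    "rss": f.rss,
                    "n": f.n,
                }
                for g, f in self.fits.items()
            },
            "param_tests": {k: {"z": z, "p": p} for k, (z, p) in self.param_tests.items()},
            "t_star": self.rule.t_star,
            "no_separation": self.rule.no_separation,
            "validation": {k: m.as_dict() for k, m in self.table3.items()},
        }


def _famd_scores_to_series(scores: pd.DataFrame, rows: pd.DataFrame, comp: int) -> pd.DataFrame:
    out = rows.loc[scores.index, ["patient_id", "evaluation", "eval_time", "outcome"]].copy()
    out["score"] = scores[f"dim{comp}"]
    return out.reset_index(drop=True)


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> RunReport:
    """Execute the full analysis and return a consolidated report."""
    seeds = _subseeds(config.seed, 4)

    # --- load or simulate the cohort -------------------------------------
    if config.input_path is not None:
        dictionary = VariableDictionary.from_yaml(config.dictionary_path)
        cohort = load_cohort(config.input_path, dictionary)
        log.info("loaded cohort: %d patients", cohort.n_patients())
    else:
        sim = config.simulation
        cohort = simulate_mixed_cohort(sim)
        log.info("simulated cohort: %d patients (seed %d)", sim.n_patients, sim.seed)
    dictionary = cohort.dictionary

    # --- stratified split -------------------------------------------------
    split = stratified_split(cohort, config.validation_fraction, seeds[0])
    train = cohort.subset(split.train_ids)
    valid = cohort.subset(split.valid_ids)
    log.info("split: %d training / %d validation", len(split.train_ids), len(split.valid_ids))

    # --- univariable screening on the training sample ---------------------
    train_long = long_format(train)
    results = screen_cohort(train_long, dictionary)
    kept = select_variables(results, config.screening_alpha)
    if not kept:
        raise RuntimeError("screening kept no variables")
    log.info("screening kept %d/%d variables", len(kept), len(dictionary))

    # --- FAMD on training rows (complete cases), validation projected -----
    encoded = famd_mod.encode(train_long, dictionary, variables=kept)
    model = famd_mod.fit_famd(encoded)
    if encoded.n_dropped:
        log.info("FAMD dropped %d incomplete training rows", encoded.n_dropped)
    comp = config.model_component  # 1-based
    # orient the modeled dimension: positive-outcome group scores high
    train_dim = model.scores_[f"dim{comp}"]
    outc = train_long.loc[model.scores_.index, "outcome"]
    if train_dim[outc == POSITIVE].mean() < train_dim[outc == NEGATIVE].mean():
        model.flip_component(comp - 1)
    train_scores = _famd_scores_to_series(model.scores_, train_long, comp)

    valid_long = long_format(valid)
    v_complete = valid_long[valid_long[kept].notna().all(axis=1)]
    n_dropped_valid = len(valid_long) - len(v_complete)
    if n_dropped_valid:
        log.info("validation: %d incomplete rows cannot be projected", n_dropped_valid)
    v_scores = famd_mod.project(model, v_complete, dictionary)
    valid_scores = _famd_scores_to_series(v_scores, v_complete, comp)

    # --- Michaelis-Menten fits per outcome group (training only) ----------
    fits: dict[str, MMFit] = {}
    for group in (NEGATIVE, POSITIVE):
        sub = train_scores[train_scores["outcome"] == group]
        if len(sub) < 4:
            raise RuntimeError(f"fewer than 4 training observations in group {group!r}")
        fits[group] = fit_mm(sub["eval_time"].to_numpy(), sub["score"].to_numpy())
        log.info(
            "MM fit %s: a=%.3f m=%.3f K=%.2f (RSS %.1f, n %d)",
            group, fits[group].params.a, fits[group].params.m, fits[group].params.K,
            fits[group].rss, fits[group].n,
        )
    param_tests = {w: compare_params(fits[POSITIVE], fits[NEGATIVE], w) for w in ("a", "m", "K")}

    # --- Monte-Carlo bands and the threshold rule --------------------------
    grid = config.grid()
    band_neg = monte_carlo_band(
        fits[NEGATIVE], grid, config.n_draws, config.band_level, seeds[1], group=NEGATIVE
    )
    band_pos = monte_carlo_band(
        fits[POSITIVE], grid, config.n_draws, config.band_level, seeds[2], group=POSITIVE
    )
    rule = find_crossover(band_neg, band_pos)
    log.info("crossover day t* = %.1f%s", rule.t_star, " (no separation)" if rule.no_separation else "")

    # --- classify the validation sample, Table-3 style ---------------------
    truths = valid.outcomes().to_dict()
    total_n = len(split.valid_ids)
    table3 = {}
    for row_name, evals, combine in (
        ("T0", ("T0",), "earliest"),
        ("T0+T1", ("T0", "T1"), config.combine),
        ("T1", ("T1",), "latest"),
    ):
        preds = {}
        for pid in split.valid_ids:
            sub = valid_scores[
                (valid_scores["patient_id"] == pid)
                & (valid_scores["evaluation"].isin(evals))
            ]
            obs = list(zip(sub["eval_time"], sub["score"], sub["evaluation"]))
            preds[pid] = classify_patient(rule, obs, combine=combine, patient_id=pid).label
        counts = confusion(preds, truths)
        table3[row_name] = metrics(counts, total_n)

    report = RunReport(
        config=config,
        split=split,
        screening=screening_report(results),
        kept_variables=kept,
        famd_model=model,
        variance_explained=famd_mod.variance_explained(model),
        contributions_dim1=famd_mod.contributions(model, comp - 1),
        fits=fits,
        param_tests=param_tests,
        rule=rule,
        train_scores=train_scores,
        valid_scores=valid_scores,
        table3=table3,
    )
    if outdir is not None:
        write_artifacts(report, Path(outdir), band_neg, band_pos)
    return report


def write_artifacts(
    report: RunReport, outdir: Path, band_neg=None, band_pos=None
) -> None:
    """Write every stage artifact (CSV tables, JSON models and summary)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.screening.to_csv(outdir / "screening.csv", index=False)
    report.famd_model.to_json(outdir / "famd_model.json")
    report.train_scores.to_csv(outdir / "train_scores.csv", index=False)
    report.valid_scores.to_csv(outdir / "valid_scores.csv", index=False)
    for g, f in report.fits.items():
        f.to_json(outdir / f"mm_fit_{g}.json")
    if band_neg is None:
        band_neg, band_pos = report.rule.band_neg, report.rule.band_pos
    pd.concat([band_neg.to_frame(), band_pos.to_frame()]).to_csv(
        outdir / "bands.csv", index=False
    )
    with open(outdir / "report.json", "w") as fh:
        json.dump(report.summary(), fh, indent=1, default=float)
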