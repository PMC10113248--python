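"""Synthetic ABI cohorts with the statistical structure the analysis assumes.

A cohort of ``n_patients`` is generated as follows.  Each patient belongs to
the negative-outcome group with probability ``prop_negative`` (default 0.81,
the observed prevalence of GOS < 4).  Evaluation times in days since injury
are drawn as: T0 uniform on [10, 93] (admission to the rehabilitation unit,
mean 45 days), T1 normal around 167 days, T2 = T1 plus a normal offset of
about 40 days; the draw is repeated until T0 < T1 < T2.  The patient's
latent clinical status at each visit is the group's Michaelis-Menten curve
plus Gaussian noise; default parameter triples are the fitted values of the
reference cohort, (a, m, K) = (-4.73, 11.56, 44.87) for the positive group
and (-3.01, 4.61, 91.99) for the negative one.  Each T1 visit is deleted
with probability ``missing_t1_rate`` (default 0.07, patients unobserved or
discharged at four months).

Observed mixed variables are then derived from the latent score through a
declared link per variable: continuous variables are affine in the latent
score with Gaussian noise (optionally clipped to the instrument range);
categorical variables cut the latent range at strictly increasing
thresholds, mapping successive intervals to successive levels.  GOS is drawn
as 4-5 in the positive group and 1-3 in the negative group, so the binarized
outcome equals the generating group by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import NEGATIVE, POSITIVE, CohortTable, Variable, VariableDictionary
from .trajectory import MMParams, mm_value


@dataclass(frozen=True)
class ContinuousLink:
    """value = intercept + slope * latent + N(0, noise_sd^2), clipped."""

    name: str
    slope: float
    intercept: float
    noise_sd: float = 0.0
    lo: float | None = None
    hi: float | None = None
    decimals: int | None = None
    time_invariant: bool = False


@dataclass(frozen=True)
class CategoricalLink:
    """Levels cut the latent axis at strictly increasing thresholds.

    ``levels[i]`` is emitted when the (noisy) latent value falls in the i-th
    interval; with ``noise_sd > 0`` the category boundaries are soft.  With
    ``probabilities`` set, the variable ignores the latent score and is drawn
    i.i.d. from those level probabilities (e.g. sex).
    """

    name: str
    levels: tuple[str, ...]
    thresholds: tuple[float, ...] = ()
    noise_sd: float = 0.0
    probabilities: tuple[float, ...] | None = None
    time_invariant: bool = False

    def __post_init__(self):
        if self.probabilities is None:
            if len(self.thresholds) != len(self.levels) - 1:
                raise ValueError(f"{self.name}: need len(levels)-1 thresholds")
            if any(
                b <= a for a, b in zip(self.thresholds, self.thresholds[1:])
            ):
                raise ValueError(f"{self.name}: thresholds must be strictly increasing")
        elif len(self.probabilities) != len(self.levels):
            raise ValueError(f"{self.name}: need one probability per level")


def default_variable_map() -> list:
    """Links emulating the clinical instruments of the reference cohort.

    Latent scores roughly span [-5, 7]; slopes and intercepts place each
    instrument near its published group means, with ranges clipped to the
    scale limits (CRS-r 0-23, RLAS 1-8, ERBI-A -325-0, ERBI-B 0-100).
    """
    return [
        ContinuousLink("age", slope=-2.5, intercept=52.0, noise_sd=15.0, lo=18, hi=89,
                       decimals=0, time_invariant=True),
        ContinuousLink("icu_days", slope=-1.5, intercept=44.0, noise_sd=18.0, lo=10,
                       hi=144, decimals=0, time_invariant=True),
        ContinuousLink("crs_r", slope=1.2, intercept=14.0, noise_sd=2.0, lo=0, hi=23,
                       decimals=0),
        ContinuousLink("rlas", slope=0.45, intercept=4.3, noise_sd=0.8, lo=1, hi=8,
                       decimals=0),
        ContinuousLink("erbi_a", slope=14.0, intercept=-120.0, noise_sd=25.0,
                       lo=-325, hi=0, decimals=0),
        ContinuousLink("erbi_b", slope=8.0, intercept=20.0, noise_sd=12.0, lo=0,
                       hi=100, decimals=0),
        CategoricalLink("sex", levels=("M", "F"), probabilities=(0.63, 0.37),
                        time_invariant=True),
        CategoricalLink("tracheostomy", levels=("Presence", "Absence"),
                        thresholds=(1.5,), noise_sd=1.0),
        CategoricalLink("feeding_modality", levels=("PEG", "NG tube", "Oral"),
                        thresholds=(-0.5, 2.0), noise_sd=1.0),
        CategoricalLink("diagnosis", levels=("VS/UWS", "MCS", "Emerged from MCS"),
                        thresholds=(-1.0, 1.0), noise_sd=1.0),
    ]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator (defaults: the reference cohort)."""

    n_patients: int = 143
    prop_negative: float = 0.81
    params_pos: MMParams = MMParams(-4.73, 11.56, 44.87)
    params_neg: MMParams = MMParams(-3.01, 4.61, 91.99)
    noise_sd: float = 2.0
    t0_range: tuple[float, float] = (10.0, 93.0)
    t1_mean: float = 167.0
    t1_sd: float = 30.0
    t2_offset_mean: float = 40.0
    t2_offset_sd: float = 10.0
    missing_t1_rate: float = 0.07
    seed: int = 0
    variable_map: tuple = field(default_factory=lambda: tuple(default_variable_map()))

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if not 0.0 < self.prop_negative < 1.0:
            raise ValueError("prop_negative must be in (0, 1)")
        if self.params_pos.K <= 0 or self.params_neg.K <= 0:
            raise ValueError("K must be positive in both parameter triples")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0.0 <= self.missing_t1_rate <= 1.0:
            raise ValueError("missing_t1_rate must be in [0, 1]")
        if not (0 < self.t0_range[0] < self.t0_range[1]):
            raise ValueError("t0_range must be positive and increasing")

    def dictionary(self) -> VariableDictionary:
        out = []
        for link in self.variable_map:
            if isinstance(link, ContinuousLink):
                out.append(Variable(link.name, "continuous",
                                    time_invariant=link.time_invariant))
            else:
                out.append(Variable(link.name, "categorical", tuple(link.levels),
                                    time_invariant=link.time_invariant))
        return VariableDictionary(out)


def _draw_times(cfg: SimulationConfig, rng: np.random.Generator) -> tuple[float, float, float]:
    lo, hi = cfg.t0_range
    for _ in range(1000):
        t0 = rng.uniform(lo, hi)
        t1 = rng.normal(cfg.t1_mean, cfg.t1_sd)
        t2 = t1 + rng.normal(cfg.t2_offset_mean, cfg.t2_offset_sd)
        if t0 < t1 < t2:
            return t0, t1, t2
    raise RuntimeError("could not draw ordered evaluation times")


def simulate_scores(config: SimulationConfig) -> pd.DataFrame:
    """Latent-score rows: (patient_id, evaluation, eval_time, score, outcome).

    Scores lie on the patient's group curve plus N(0, noise_sd^2); T1 rows
    are deleted with probability ``missing_t1_rate``.  Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for i in range(config.n_patients):
        pid = f"P{i + 1:04d}"
        group = NEGATIVE if rng.random() < config.prop_negative else POSITIVE
        params = config.params_neg if group == NEGATIVE else config.params_pos
        t0, t1, t2 = _draw_times(config, rng)
        drop_t1 = rng.random() < config.missing_t1_rate
        for ev, t in (("T0", t0), ("T1", t1), ("T2", t2)):
            if ev == "T1" and drop_t1:
                continue
            t = round(t, 1)  # recorded to 0.1 day; the score is observed at it
            score = mm_value(params, t) + rng.normal(0.0, config.noise_sd)
            rows.append(
                {
                    "patient_id": pid,
                    "evaluation": ev,
                    "eval_time": t,
                    "score": score,
                    "outcome": group,
                }
            )
    return pd.DataFrame(rows)


def simulate_mixed_cohort(config: SimulationConfig) -> CohortTable:
    """Full synthetic cohort: observed mixed variables driven by the latent score.

    Returns a :class:`CohortTable` ready for the whole pipeline; it passes
    ``load_cohort`` validation when written and re-read.  GOS is drawn 4-5
    for the positive group and 1-3 for the negative one, so the binarized
    outcome coincides with the generating group.
    """
    scores = simulate_scores(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    dictionary = config.dictionary()

    gos_map: dict[str, int] = {}
    invariant: dict[tuple[str, str], object] = {}
    records = []
    for pid, grp in scores.groupby("patient_id", sort=False):
        outcome = grp["outcome"].iloc[0]
        if outcome == POSITIVE:
            gos_map[pid] = int(rng.choice([4, 5], p=[0.6, 0.4]))
        else:
            gos_map[pid] = int(rng.choice([1, 2, 3], p=[0.05, 0.35, 0.60]))
        latent_t0 = float(grp["score"].iloc[0])
        for link in config.variable_map:
            if not link.time_invariant:
                continue
            invariant[(pid, link.name)] = _draw_value(link, latent_t0, rng)
        for _, row in grp.iterrows():
            rec = {
                "patient_id": pid,
                "evaluation": row["evaluation"],
                "eval_time": row["eval_time"],
                "gos": gos_map[pid],
            }
            for link in config.variable_map:
                if link.time_invariant:
                    rec[link.name] = invariant[(pid, link.name)]
                else:
                    rec[link.name] = _draw_value(link, float(row["score"]), rng)
            records.append(rec)

    df = pd.DataFrame(records)
    df["outcome"] = scores.groupby("patient_id", sort=False)["outcome"].first().reindex(
        df["patient_id"]
    ).to_numpy()
    return CohortTable(df, dictionary)


def _draw_value(link, latent: float, rng: np.random.Generator):
    if isinstance(link, ContinuousLink):
        v = link.intercept + link.slope * latent + rng.normal(0.0, link.noise_sd)
        if link.lo is not None:
            v = max(v, link.lo)
        if link.hi is not None:
            v = min(v, link.hi)
        return round(v, link.decimals) if link.decimals is not None else v
    if link.probabilities is not None:
        return str(rng.choice(link.levels, p=link.probabilities))
    z = latent + rng.normal(0.0, link.noise_sd)
    idx = int(np.searchsorted(link.thresholds, z))
    return link.levels[idx]
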