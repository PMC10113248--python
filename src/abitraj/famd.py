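"""Factorial Analysis of Mixed Data (FAMD): PCA for mixed-type tables.

Continuous columns are z-scored (population standard deviation); each
categorical level becomes a 0/1 indicator column divided by the square root
of its level proportion and then centered.  With that weighting, a PCA of the
encoded matrix (uniform row weights 1/n) balances the influence of
continuous and categorical variables — the Pagès formulation used by the
standard FAMD implementations.  On a continuous-only table the procedure
reduces exactly to classical PCA of the correlation matrix.

The fitted model retains all centers, scales and level proportions, so new
rows (e.g. a held-out validation sample) can be projected onto the training
components; projecting the training rows reproduces the stored scores
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import VariableDictionary


@dataclass
class EncodingMeta:
    """Everything needed to re-apply the training encoding to new rows."""

    variables: list[str]
    columns: list[str]  # encoded column names, "<var>" or "<var>=<level>"
    col_variable: list[str]  # parent variable per encoded column
    centers: dict[str, float]  # continuous: mean
    scales: dict[str, float]  # continuous: population sd
    level_props: dict[str, float]  # "<var>=<level>" -> training proportion


@dataclass
class Encoded:
    values: np.ndarray  # n x p, fully finite
    meta: EncodingMeta
    row_index: pd.Index  # rows of the input kept (complete cases)
    n_dropped: int


@dataclass
class FAMDModel:
    meta: EncodingMeta
    loadings: np.ndarray  # p x k, orthonormal columns (right singular vectors)
    eigenvalues: np.ndarray  # k, = squared singular values / n
    scores_: pd.DataFrame  # training row scores, columns dim1..dimk
    n_rows: int

    def n_components(self) -> int:
        return len(self.eigenvalues)

    def flip_component(self, comp: int) -> None:
        """Negate one component's loadings and training scores in place."""
        self.loadings[:, comp] *= -1.0
        self.scores_.iloc[:, comp] *= -1.0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "variables": self.meta.variables,
            "columns": self.meta.columns,
            "col_variable": self.meta.col_variable,
            "centers": self.meta.centers,
            "scales": self.meta.scales,
            "level_props": self.meta.level_props,
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "n_rows": self.n_rows,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FAMDModel":
        payload = json.loads(Path(path).read_text())
        meta = EncodingMeta(
            variables=payload["variables"],
            columns=payload["columns"],
            col_variable=payload["col_variable"],
            centers=payload["centers"],
            scales=payload["scales"],
            level_props=payload["level_props"],
        )
        return cls(
            meta=meta,
            loadings=np.asarray(payload["loadings"], dtype=float),
            eigenvalues=np.asarray(payload["eigenvalues"], dtype=float),
            scores_=pd.DataFrame(),
            n_rows=int(payload["n_rows"]),
        )


def encode(
    df: pd.DataFrame,
    dictionary: VariableDictionary,
    variables: list[str] | None = None,
    meta: EncodingMeta | None = None,
) -> Encoded:
    """Build the weighted encoded matrix for a mixed-type table.

    Rows with any missing value among ``variables`` are dropped (complete
    case) and counted in ``n_dropped``.  When ``meta`` is given (projection),
    the stored training centers/scales/proportions are applied instead of
    recomputing them, and an unseen categorical level raises.
    """
    if variables is None:
        variables = meta.variables if meta else [
            v.name for v in dictionary if v.name in df.columns
        ]
    sub = df[variables]
    keep = sub.notna().all(axis=1)
    sub = sub[keep]
    n = len(sub)
    if n == 0:
        raise ValueError("no complete rows to encode")

    fitting = meta is None
    if fitting:
        meta = EncodingMeta(
            variables=list(variables),
            columns=[],
            col_variable=[],
            centers={},
            scales={},
            level_props={},
        )

    blocks: list[np.ndarray] = []
    for name in variables:
        var = dictionary[name]
        if var.kind == "continuous":
            x = sub[name].to_numpy(dtype=float)
            if fitting:
                mu, sd = float(x.mean()), float(x.std(ddof=0))
                if sd == 0.0:
                    raise ValueError(f"zero-variance continuous column {name!r}")
                meta.centers[name] = mu
                meta.scales[name] = sd
                meta.columns.append(name)
                meta.col_variable.append(name)
            else:
                mu, sd = meta.centers[name], meta.scales[name]
            blocks.append(((x - mu) / sd)[:, None])
        else:
            col = sub[name].astype(str)
            if fitting:
                present = [lv for lv in var.levels if (col == lv).any()]
                if len(present) < 2:
                    raise ValueError(
                        f"categorical column {name!r} has a single observed level"
                    )
                for lv in present:
                    key = f"{name}={lv}"
                    meta.level_props[key] = float((col == lv).mean())
                    meta.columns.append(key)
                    meta.col_variable.append(name)
                levels = present
            else:
                levels = [
                    k.split("=", 1)[1]
                    for k, v in zip(meta.columns, meta.col_variable)
                    if v == name
                ]
                unseen = set(col.unique()) - set(levels)
                if unseen:
                    raise ValueError(
                        f"unseen level(s) {sorted(unseen)} of {name!r} in projection rows"
                    )
            for lv in levels:
                p = meta.level_props[f"{name}={lv}"]
                ind = (col == lv).to_numpy(dtype=float) / np.sqrt(p)
                # centered indicator: training mean of ind is p/sqrt(p) = sqrt(p)
                blocks.append((ind - np.sqrt(p))[:, None])

    X = np.hstack(blocks)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite entries in the encoded matrix")
    return Encoded(X, meta, sub.index, int((~keep).sum()))


def fit_famd(encoded: Encoded, row_labels: pd.DataFrame | None = None) -> FAMDModel:
    """PCA of the encoded matrix with uniform row weights 1/n.

    Eigenvalues are squared singular values of X/sqrt(n); scores are the rows
    projected on the loadings.  The sign of each component is fixed so that
    the encoded column with the largest absolute loading is positive, making
    scores deterministic across runs and platforms.
    """
    X = encoded.values
    n = X.shape[0]
    _, s, Vt = np.linalg.svd(X / np.sqrt(n), full_matrices=False)
    V = Vt.T
    eig = s**2
    for k in range(V.shape[1]):
        j = int(np.argmax(np.abs(V[:, k])))
        if V[j, k] < 0:
            V[:, k] *= -1.0
    scores = X @ V
    cols = [f"dim{i + 1}" for i in range(V.shape[1])]
    scores_df = pd.DataFrame(scores, index=encoded.row_index, columns=cols)
    if row_labels is not None:
        scores_df = row_labels.loc[encoded.row_index].join(scores_df)
    return FAMDModel(encoded.meta, V, eig, scores_df, n)


def project(
    model: FAMDModel,
    df: pd.DataFrame,
    dictionary: VariableDictionary,
) -> pd.DataFrame:
    """Project new rows onto the training components.

    Rows must be complete on the model's variables (incomplete rows raise);
    categorical levels unseen in training raise.  Projecting the training
    table reproduces the stored training scores exactly.
    """
    sub = df[model.meta.variables]
    if sub.isna().any(axis=None):
        bad = sub.index[sub.isna().any(axis=1)].tolist()
        raise ValueError(f"missing values in projection rows {bad}")
    enc = encode(df, dictionary, variables=model.meta.variables, meta=model.meta)
    scores = enc.values @ model.loadings
    cols = [f"dim{i + 1}" for i in range(model.loadings.shape[1])]
    return pd.DataFrame(scores, index=enc.row_index, columns=cols)


def variance_explained(model: FAMDModel) -> np.ndarray:
    """Fraction of total variance per component (sums to 1)."""
    return model.eigenvalues / model.eigenvalues.sum()


def contributions(model: FAMDModel, comp: int = 0) -> pd.Series:
    """Per-variable percentage contribution to one component (sums to 100).

    Level columns of a categorical variable are aggregated into a single
    entry for the parent variable.
    """
    if not 0 <= comp < model.n_components():
        raise IndexError(f"component {comp} out of range")
    ctr = 100.0 * model.loadings[:, comp] ** 2
    out: dict[str, float] = {}
    for var, c in zip(model.meta.col_variable, ctr):
        out[var] = out.get(var, 0.0) + float(c)
    return pd.Series(out).sort_values(ascending=False)
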