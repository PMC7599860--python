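"""Linear QSPR model construction, validation and refinement.

Workflow: prune descriptor pairs whose absolute pairwise correlation
exceeds a threshold (keeping the member better correlated with the
response), autoscale, fit ordinary least squares on the standardized
predictors, judge the fit by the training r^2 and the leave-one-out
cross-validated q^2 = 1 - PRESS/TSS, then iteratively drop the weakest
term until r^2 and q^2 sit close together and further removals would
cost real explanatory power.

The two published fixed-coefficient models for synthetic-membrane
permeability (``eq2``, three descriptors) and thickness-normalized flux
(``eq3``, six descriptors) are available as frozen predictors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LinearQSPRModel",
    "cross_correlation_filter",
    "drop_rank_deficient",
    "fit_linear",
    "loo_q2",
    "refine",
    "representative_split",
    "predict_published",
    "PUBLISHED_MODELS",
]


# ---------------------------------------------------------------------------
# correlation pruning
# ---------------------------------------------------------------------------

def cross_correlation_filter(
    X: pd.DataFrame,
    y: Sequence[float],
    threshold: float = 0.70,
) -> tuple[list[str], list[dict]]:
    """Remove one member of every descriptor pair with |r| > threshold.

    Pairs are processed in descending |pairwise r|; within a still-intact
    pair the member with the smaller |corr(x, y)| is dropped (ties drop
    the lexicographically later name).  Returns the retained column names
    and a removal log.
    """
    X = pd.DataFrame(X).astype(float)
    y = np.asarray(y, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 descriptors")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 observations")
    if (X.std(ddof=1) == 0).any():
        bad = X.columns[X.std(ddof=1) == 0].tolist()
        raise ValueError(f"constant column(s): {bad}")
    corr = X.corr().abs()
    ycorr = {c: abs(np.corrcoef(X[c], y)[0, 1]) for c in X.columns}
    pairs = []
    cols = list(X.columns)
    for ai in range(len(cols)):
        for bi in range(ai + 1, len(cols)):
            a, b = cols[ai], cols[bi]
            r = float(corr.loc[a, b])
            if r > threshold:
                pairs.append((r, a, b))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    removed: set[str] = set()
    log: list[dict] = []
    for r, a, b in pairs:
        if a in removed or b in removed:
            continue
        if ycorr[a] > ycorr[b]:
            drop = b
        elif ycorr[b] > ycorr[a]:
            drop = a
        else:
            drop = max(a, b)  # lexicographic tie-break: keep the earlier name
        removed.add(drop)
        log.append(
            {"removed": drop, "kept": a if drop == b else b,
             "pair_r": r, "y_corr_removed": ycorr[drop]}
        )
    retained = [c for c in cols if c not in removed]
    return retained, log


# ---------------------------------------------------------------------------
# standardized OLS
# ---------------------------------------------------------------------------

@dataclass
class LinearQSPRModel:
    """OLS model on z-scored predictors (standardized coefficients)."""

    terms: list[str]
    coefficients: np.ndarray        # standardized scale, aligned with terms
    intercept: float
    x_means: pd.Series
    x_sds: pd.Series
    r2_train: float
    q2_loo: Optional[float] = None
    r2_test: Optional[float] = None
    refinement_trace: list[dict] = field(default_factory=list)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        xz = (pd.DataFrame(X)[self.terms] - self.x_means) / self.x_sds
        return self.intercept + xz.to_numpy() @ self.coefficients

    def to_dict(self) -> dict:
        return {
            "terms": list(self.terms),
            "coefficients": [float(c) for c in self.coefficients],
            "intercept": float(self.intercept),
            "x_means": {k: float(v) for k, v in self.x_means.items()},
            "x_sds": {k: float(v) for k, v in self.x_sds.items()},
            "r2_train": float(self.r2_train),
            "q2_loo": None if self.q2_loo is None else float(self.q2_loo),
            "r2_test": None if self.r2_test is None else float(self.r2_test),
            "refinement_trace": self.refinement_trace,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: Mapping) -> "LinearQSPRModel":
        return cls(
            terms=list(d["terms"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            x_means=pd.Series(d["x_means"], dtype=float),
            x_sds=pd.Series(d["x_sds"], dtype=float),
            r2_train=float(d["r2_train"]),
            q2_loo=d.get("q2_loo"),
            r2_test=d.get("r2_test"),
            refinement_trace=list(d.get("refinement_trace", [])),
        )


def _ols_standardized(X: pd.DataFrame, y: np.ndarray):
    means = X.mean()
    sds = X.std(ddof=1)
    if (sds == 0).any():
        bad = X.columns[sds == 0].tolist()
        raise ValueError(f"constant column(s): {bad}")
    xz = ((X - means) / sds).to_numpy()
    design = np.column_stack([np.ones(len(xz)), xz])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name the offending terms via near-perfect pairwise correlation
        corr = pd.DataFrame(xz, columns=X.columns).corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        collinear = sorted(corr.columns[(corr > 1 - 1e-10).any()].tolist())
        raise ValueError(f"rank-deficient design; collinear terms: {collinear or list(X.columns)}")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ beta
    return beta[0], beta[1:], fitted, means, sds


def _r2(y: np.ndarray, fitted: np.ndarray) -> float:
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("response has zero variance")
    return 1.0 - ss_res / ss_tot


def drop_rank_deficient(X: pd.DataFrame, tol: float = 1e-8) -> list[str]:
    """Greedy full-rank column subset, scanning left to right.

    Level-based descriptor tables (many columns constant within a factor
    level) are often rank-deficient even after correlation pruning; OLS
    needs a full-rank design.  Returns the retained column names."""
    X = pd.DataFrame(X).astype(float)
    z = (X - X.mean()) / X.std(ddof=1).replace(0, 1.0)
    kept: list[str] = []
    basis = None
    for col in z.columns:
        v = z[col].to_numpy()
        if basis is None:
            if np.linalg.norm(v) > tol:
                basis = v[:, None] / np.linalg.norm(v)
                kept.append(col)
            continue
        resid = v - basis @ (basis.T @ v)
        if np.linalg.norm(resid) > tol * max(1.0, np.linalg.norm(v)):
            basis = np.column_stack([basis, resid / np.linalg.norm(resid)])
            kept.append(col)
    return kept


def fit_linear(X_train: pd.DataFrame, y_train: Sequence[float]) -> LinearQSPRModel:
    """OLS on zero-mean unit-variance predictors; reports training r^2."""
    X = pd.DataFrame(X_train).astype(float)
    y = np.asarray(y_train, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need more than terms+1={p+1} training rows, have {n}")
    intercept, coefs, fitted, means, sds = _ols_standardized(X, y)
    return LinearQSPRModel(
        terms=list(X.columns),
        coefficients=coefs,
        intercept=float(intercept),
        x_means=means,
        x_sds=sds,
        r2_train=_r2(y, fitted),
    )


def loo_q2(X_train: pd.DataFrame, y_train: Sequence[float]) -> float:
    """Leave-one-out q^2 = 1 - PRESS/TSS.

    Scaling is re-estimated inside each fold, so every held-out
    prediction comes from a model that never saw the left-out row.
    """
    X = pd.DataFrame(X_train).astype(float)
    y = np.asarray(y_train, dtype=float)
    n = len(y)
    if n < X.shape[1] + 3:
        raise ValueError("too few observations for leave-one-out validation")
    press = 0.0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        intercept, coefs, _, means, sds = _ols_standardized(X.iloc[mask], y[mask])
        xz = ((X.iloc[i] - means) / sds).to_numpy(dtype=float)
        pred = intercept + xz @ coefs
        press += (y[i] - pred) ** 2
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise ValueError("response has zero variance")
    return 1.0 - press / tss


def refine(
    model: LinearQSPRModel,
    X_train: pd.DataFrame,
    y_train: Sequence[float],
    prox_tol: float = 0.15,
    max_r2_drop: float = 0.02,
) -> LinearQSPRModel:
    """Backward refinement: repeatedly drop the weakest term.

    The weakest term is the one with the smallest absolute standardized
    coefficient.  Refinement stops once r^2 and q^2 are within
    ``prox_tol`` of each other and the next removal would cost more than
    ``max_r2_drop`` of r^2; the full trace is recorded on the returned
    model.
    """
    X = pd.DataFrame(X_train).astype(float)
    y = np.asarray(y_train, dtype=float)
    current = model
    terms = list(model.terms)
    q2 = loo_q2(X[terms], y)
    trace = [{"terms": list(terms), "removed": None,
              "r2": current.r2_train, "q2": q2}]
    while len(terms) > 1:
        weakest_i = int(np.argmin(np.abs(current.coefficients)))
        weakest = terms[weakest_i]
        reduced_terms = [t for t in terms if t != weakest]
        reduced = fit_linear(X[reduced_terms], y)
        q2_reduced = loo_q2(X[reduced_terms], y)
        close = abs(current.r2_train - q2) <= prox_tol
        costly = (current.r2_train - reduced.r2_train) > max_r2_drop
        if close and costly:
            break
        terms = reduced_terms
        current, q2 = reduced, q2_reduced
        trace.append({"terms": list(terms), "removed": weakest,
                      "r2": current.r2_train, "q2": q2})
    current.q2_loo = q2
    current.refinement_trace = trace
    return current


def r2_test(
    model: LinearQSPRModel,
    X_test: pd.DataFrame,
    y_test: Sequence[float],
    predictive: bool = False,
) -> float:
    """Test-set quality: squared Pearson correlation between predicted
    and observed (default), or predictive R^2 about the train mean with
    ``predictive=True``."""
    y = np.asarray(y_test, dtype=float)
    pred = model.predict(X_test)
    if predictive:
        return _r2(y, pred)
    if np.std(pred) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(pred, y)[0, 1] ** 2)


# ---------------------------------------------------------------------------
# representative train/test split
# ---------------------------------------------------------------------------

def representative_split(
    data: pd.DataFrame,
    test_size: int = 6,
    seed: int = 0,
    factors: Sequence[str] = ("permeant", "vehicle", "membrane"),
) -> pd.Series:
    """Seeded greedy split labelling rows ``train``/``test``.

    The test set is chosen to jointly cover as many factor levels as
    possible (all permeants and membranes, and at least 3 vehicles for
    the full factorial design); every level stays represented in train.
    Returns a Series of labels aligned with ``data``'s index.
    """
    factors = [f for f in factors if f in data.columns]
    if not factors:
        raise ValueError("no factorial metadata columns present")
    if not (0 < test_size < len(data)):
        raise ValueError(f"test_size must be in (0, {len(data)}), got {test_size}")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(data)))
    levels = {f: set(data[f]) for f in factors}
    test_idx: list[int] = []
    covered = {f: set() for f in factors}
    # greedy: repeatedly take the row adding the most uncovered levels
    remaining = order.copy()
    while len(test_idx) < test_size and remaining:
        best, best_gain = None, -1
        for pos in remaining:
            row = data.iloc[pos]
            gain = sum(1 for f in factors if row[f] not in covered[f])
            if gain > best_gain:
                best, best_gain = pos, gain
        test_idx.append(best)
        remaining.remove(best)
        for f in factors:
            covered[f].add(data.iloc[best][f])
    # factors small enough to fit in the test set must be fully covered
    for f in factors:
        if len(levels[f]) <= test_size and covered[f] != levels[f]:
            raise ValueError(
                f"test set of {test_size} cannot cover levels {sorted(levels[f] - covered[f])} "
                f"of factor {f!r}"
            )
    labels = pd.Series("train", index=data.index, name="split")
    labels.iloc[test_idx] = "test"
    # train must retain every level
    train = data[labels == "train"]
    for f in factors:
        missing = levels[f] - set(train[f])
        if missing:
            raise ValueError(f"split leaves factor {f!r} levels {sorted(missing)} out of train")
    return labels


# ---------------------------------------------------------------------------
# published fixed-coefficient models
# ---------------------------------------------------------------------------

#: Frozen coefficient sets of the two published synthetic-membrane models.
#: ``eq2`` predicts the permeability coefficient Kp; ``eq3`` predicts
#: thickness-normalized flux.  Inputs are on the models' own
#: (standardized) scale.
PUBLISHED_MODELS: dict[str, dict] = {
    "eq2": {
        "intercept": 0.6976,
        "coefficients": {
            "solubility": 0.41902,
            "lip_acc_vehicle": -0.85524,
            "dH_exp_drug": 0.64106,
        },
    },
    "eq3": {
        "intercept": 1.08083,
        "coefficients": {
            "weight_ratio": 0.23534,
            "logKow_vehicle": -0.36141,
            "MPt_permeant": -0.24036,
            "dH_exp_membrane": -1.01839,
            "dP_exp_membrane": 0.47908,
            "opr_brigid_vehicle": -0.34680,
        },
    },
}


def predict_published(model_id: str, inputs: Mapping[str, float]) -> float:
    """Evaluate a published fixed-coefficient model on named inputs."""
    try:
        spec = PUBLISHED_MODELS[model_id]
    except KeyError:
        raise KeyError(
            f"unknown published model {model_id!r}; choose from {sorted(PUBLISHED_MODELS)}"
        ) from None
    missing = [k for k in spec["coefficients"] if k not in inputs]
    if missing:
        raise KeyError(f"missing input(s) for {model_id}: {missing}")
    return spec["intercept"] + sum(
        coef * float(inputs[name]) for name, coef in spec["coefficients"].items()
    )
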