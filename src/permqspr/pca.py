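"""PCA with iterative loadings-based descriptor elimination.

The selection algorithm mirrors a chemometrics workflow: fit a PCA on
autoscaled descriptors, remove the descriptor with the lowest absolute
loading on PC1 (it contributes least to the variance the model explains),
refit, and repeat — stopping when a removal would decrease the explained
variance of PC1 or break the orthogonality of the components, or when a
configured minimum number of descriptors is reached.

Two PCA back ends are provided.  Exact SVD keeps scores orthogonal by
construction, so only the variance-drop stop can fire; NIPALS with a
capped iteration count can genuinely lose orthogonality, which is the
regime where the orthogonality stop is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScaledMatrix",
    "PCAModel",
    "SelectionTrace",
    "EliminationConfig",
    "zscale",
    "fit_pca",
    "hotelling_outliers",
    "iterative_elimination",
]


@dataclass
class ScaledMatrix:
    """Column-autoscaled matrix (zero mean, unit sample variance)."""

    values: pd.DataFrame
    means: pd.Series
    sds: pd.Series
    roles: Optional[dict[str, str]] = None

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)

    def drop(self, column: str) -> "ScaledMatrix":
        roles = None
        if self.roles is not None:
            roles = {k: v for k, v in self.roles.items() if k != column}
        return ScaledMatrix(
            values=self.values.drop(columns=[column]),
            means=self.means.drop(column),
            sds=self.sds.drop(column),
            roles=roles,
        )

    def inverse(self) -> pd.DataFrame:
        return self.values * self.sds + self.means


def zscale(matrix: pd.DataFrame, roles: Optional[dict[str, str]] = None) -> ScaledMatrix:
    """Zero-mean unit-variance scaling (sample sd, ddof=1) per column."""
    df = pd.DataFrame(matrix).astype(float)
    if len(df) < 2:
        raise ValueError("need at least 2 observations to autoscale")
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValueError(f"missing values in columns {bad}; rows with NaN are rejected")
    means = df.mean()
    sds = df.std(ddof=1)
    constant = sds[sds == 0].index.tolist()
    if constant:
        raise ValueError(f"constant column(s) cannot be autoscaled: {constant}")
    return ScaledMatrix(values=(df - means) / sds, means=means, sds=sds, roles=roles)


@dataclass
class PCAModel:
    loadings: pd.DataFrame          # descriptors x components
    scores: pd.DataFrame            # observations x components
    explained_variance: np.ndarray  # percent, per retained component
    algorithm: str                  # "svd" | "nipals"
    total_variance: float           # sum of column variances of the input

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def orthogonality(self) -> float:
        """Max |cosine| between pairs of score vectors (0 = orthogonal)."""
        t = self.scores.to_numpy()
        k = t.shape[1]
        if k < 2:
            return 0.0
        norms = np.linalg.norm(t, axis=0)
        c = (t.T @ t) / np.outer(norms, norms)
        off = np.abs(c - np.diag(np.diag(c)))
        return float(off.max())


def _fix_signs(loadings: np.ndarray, scores: np.ndarray) -> None:
    # deterministic orientation: the largest-|loading| entry is positive
    for k in range(loadings.shape[1]):
        col = loadings[:, k]
        idx = int(np.argmax(np.abs(col)))
        if col[idx] < 0:
            loadings[:, k] *= -1.0
            scores[:, k] *= -1.0


def _nipals(x: np.ndarray, n_components: int, max_iter: int, tol: float):
    """NIPALS power iteration with deflation; may be inexact when capped."""
    xr = x.copy()
    n, p = x.shape
    scores = np.zeros((n, n_components))
    loadings = np.zeros((p, n_components))
    var = np.zeros(n_components)
    for k in range(n_components):
        t = xr[:, int(np.argmax(np.var(xr, axis=0)))].copy()
        if np.allclose(t, 0):
            t = np.ones(n)
        for _ in range(max_iter):
            pvec = xr.T @ t / (t @ t)
            pvec /= np.linalg.norm(pvec)
            t_new = xr @ pvec
            if np.linalg.norm(t_new - t) <= tol * np.linalg.norm(t_new):
                t = t_new
                break
            t = t_new
        scores[:, k] = t
        loadings[:, k] = pvec
        var[k] = t @ t
        xr = xr - np.outer(t, pvec)
    return scores, loadings, var


def fit_pca(
    m: ScaledMatrix,
    n_components: int = 2,
    algorithm: str = "svd",
    max_iter: int = 500,
    tol: float = 1e-9,
) -> PCAModel:
    """Fit a PCA on an autoscaled matrix.

    Explained variances are percentages of the total variance of the
    input matrix; component signs follow a fixed convention (the
    largest-magnitude loading of each component is positive).
    """
    x = m.values.to_numpy()
    n, p = x.shape
    max_rank = min(n - 1, p)
    if not (1 <= n_components <= max_rank):
        raise ValueError(
            f"n_components must be in [1, {max_rank}] for a {n}x{p} matrix"
        )
    total = float(np.sum(np.var(x, axis=0, ddof=1)))
    if total == 0:
        raise ValueError("degenerate matrix: zero total variance")
    if algorithm == "svd":
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        scores = (u * s)[:, :n_components]
        loadings = vt.T[:, :n_components]
        comp_var = (s[:n_components] ** 2) / (n - 1)
    elif algorithm == "nipals":
        scores, loadings, ss = _nipals(x, n_components, max_iter, tol)
        comp_var = ss / (n - 1)
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    loadings = loadings.copy()
    scores = scores.copy()
    _fix_signs(loadings, scores)
    ev = 100.0 * comp_var / total
    comps = [f"PC{k+1}" for k in range(n_components)]
    return PCAModel(
        loadings=pd.DataFrame(loadings, index=m.columns, columns=comps),
        scores=pd.DataFrame(scores, index=m.values.index, columns=comps),
        explained_variance=ev,
        algorithm=algorithm,
        total_variance=total,
    )


def hotelling_outliers(model: PCAModel, alpha: float = 0.05) -> list:
    """Observations whose Hotelling T^2 over the retained components
    exceeds the F-distribution critical limit at level ``alpha``.

    T^2_i = sum_k t_ik^2 / var(t_k);  limit = k(n-1)/(n-k) * F_{1-alpha}(k, n-k).
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    t = model.scores.to_numpy()
    n, k = t.shape
    if k >= n:
        raise ValueError("need more observations than components for Hotelling T^2")
    var = t.var(axis=0, ddof=1)
    t2 = np.sum(t**2 / var, axis=1)
    limit = k * (n - 1) / (n - k) * stats.f.ppf(1 - alpha, k, n - k)
    flagged = np.nonzero(t2 > limit)[0]
    return [model.scores.index[i] for i in flagged]


@dataclass
class EliminationConfig:
    n_components: int = 2
    algorithm: str = "svd"
    tol_var: float = 0.1      # max tolerated EV1 drop, percentage points
    tol_orth: float = 0.01    # max pairwise |cos| between score vectors
    floor: int = 2            # never reduce below this many descriptors
    nipals_max_iter: int = 500
    nipals_tol: float = 1e-9


@dataclass
class RemovalRecord:
    descriptor: str
    abs_pc1_loading: float
    ev1_before: float
    ev1_after: float
    orthogonality_after: float


@dataclass
class SelectionTrace:
    removed: list[RemovalRecord] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)
    termination: str = ""  # variance-drop | orthogonality-loss | floor-reached

    def to_dict(self) -> dict:
        return {
            "removed": [asdict(r) for r in self.removed],
            "retained": list(self.retained),
            "termination": self.termination,
        }


def iterative_elimination(m: ScaledMatrix, config: EliminationConfig | None = None) -> SelectionTrace:
    """Iteratively drop the descriptor with the lowest |PC1 loading|.

    Each tentative removal is committed only if PC1's explained variance
    does not fall by more than ``tol_var`` percentage points and the
    refitted components stay orthogonal within ``tol_orth``; otherwise
    the descriptor is restored and the loop stops.  Ties on |loading|
    break lexicographically by descriptor name.
    """
    cfg = config or EliminationConfig()
    if len(m.columns) < 3:
        raise ValueError("need at least 3 descriptors to run elimination")
    if cfg.floor < cfg.n_components:
        raise ValueError("floor must be >= n_components")

    def fit(cur: ScaledMatrix) -> PCAModel:
        return fit_pca(
            cur, n_components=cfg.n_components, algorithm=cfg.algorithm,
            max_iter=cfg.nipals_max_iter, tol=cfg.nipals_tol,
        )

    trace = SelectionTrace()
    current = m
    model = fit(current)
    while True:
        if len(current.columns) <= cfg.floor:
            trace.termination = "floor-reached"
            break
        pc1 = model.loadings["PC1"].abs()
        # ties within numerical noise of the minimum break lexicographically
        candidate = sorted(pc1.index[pc1 <= pc1.min() + 1e-12])[0]
        reduced = current.drop(candidate)
        new_model = fit(reduced)
        ev1_before = float(model.explained_variance[0])
        ev1_after = float(new_model.explained_variance[0])
        orth = new_model.orthogonality()
        if ev1_after < ev1_before - cfg.tol_var:
            trace.termination = "variance-drop"
            break
        if orth > cfg.tol_orth:
            trace.termination = "orthogonality-loss"
            break
        trace.removed.append(
            RemovalRecord(
                descriptor=candidate,
                abs_pc1_loading=float(pc1[candidate]),
                ev1_before=ev1_before,
                ev1_after=ev1_after,
                orthogonality_after=orth,
            )
        )
        current, model = reduced, new_model
    trace.retained = list(current.columns)
    return trace
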