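"""Voxelwise general linear model with binary gas-condition regressors.

The design holds an intercept, one binary indicator per breathing condition
(1 during the block, 0 otherwise, so the fit captures the average plateau
rather than transients), and mean-centred nuisance columns (6 rigid-body
motion parameters, RVT, BPM).  Fitting is ordinary least squares per voxel;
condition responsiveness is tested with an omnibus F over the gas columns
(or per-condition t tests), and voxels are selected with step-down
Holm-Bonferroni control of the family-wise error across voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synth import GasProtocol

__all__ = [
    "DesignMatrix", "GLMResult", "build_design", "fit_glm", "holm_select",
    "orthogonalize_confounds",
]

NUISANCE_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z", "rvt", "bpm")


@dataclass
class DesignMatrix:
    matrix: np.ndarray  # (n_volumes, n_columns)
    names: list
    condition_names: list

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def with_confounds(self, extra: np.ndarray, names) -> "DesignMatrix":
        """Append extra (already conditioned) confound columns."""
        extra = np.atleast_2d(np.asarray(extra, float))
        if extra.shape[0] != self.n_volumes:
            extra = extra.T
        return DesignMatrix(
            matrix=np.hstack([self.matrix, extra]),
            names=self.names + list(names),
            condition_names=list(self.condition_names),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.names)


def build_design(protocol: GasProtocol, nuisance=None) -> DesignMatrix:
    """Design matrix: intercept, binary gas-condition columns, nuisance columns.

    ``nuisance`` is an (n_volumes, 8) table (DataFrame or array) of the six
    motion parameters plus RVT and BPM; its columns are mean-centred so the
    intercept keeps the baseline interpretation.
    """
    n = protocol.n_volumes
    cols = [np.ones(n)]
    names = ["intercept"]
    condition_names = []
    occupancy = np.zeros(n, dtype=int)
    for label in protocol.condition_labels:
        indicator = protocol.volumes_in(label).astype(float)
        occupancy += indicator.astype(int)
        cols.append(indicator)
        names.append(label)
        condition_names.append(label)
    if np.any(occupancy > 1):
        raise ValueError("overlapping condition blocks in protocol")
    if nuisance is not None:
        if isinstance(nuisance, pd.DataFrame):
            nuis_names = list(nuisance.columns)
            nuis = nuisance.to_numpy(float)
        else:
            nuis = np.asarray(nuisance, float)
            nuis_names = list(NUISANCE_COLUMNS[: nuis.shape[1]])
        if nuis.shape[0] != n:
            raise ValueError(
                f"nuisance length {nuis.shape[0]} != protocol sample count {n}"
            )
        nuis = nuis - nuis.mean(axis=0, keepdims=True)
        cols.extend(nuis.T)
        names.extend(nuis_names)
    return DesignMatrix(
        matrix=np.column_stack(cols), names=names, condition_names=condition_names
    )


def orthogonalize_confounds(confounds: np.ndarray, against: np.ndarray,
                            tol: float = 1e-10) -> np.ndarray:
    """Project confound columns onto the orthogonal complement of a design.

    Used for drift regressors: removing their task-parallel component
    attributes ambiguous low-frequency variance to the task columns, so
    adding them to the model cannot shrink condition estimates.  Columns
    that become (numerically) zero are dropped; the survivors are
    re-orthonormalised.
    """
    confounds = np.atleast_2d(np.asarray(confounds, float))
    if confounds.shape[0] != against.shape[0]:
        confounds = confounds.T
    q, _ = np.linalg.qr(against)
    resid = confounds - q @ (q.T @ confounds)
    qc, rc = np.linalg.qr(resid)
    keep = np.abs(np.diag(rc)) > tol * max(resid.shape)
    return qc[:, keep]


@dataclass
class GLMResult:
    """Per-voxel OLS estimates; condition betas are the %ΔBOLD plateaus."""

    beta: np.ndarray  # (n_voxels, p)
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray  # two-sided
    dof: int
    sigma2: np.ndarray  # (n_voxels,)
    names: list
    condition_names: list
    f_stat: np.ndarray = field(default=None)
    f_p: np.ndarray = field(default=None)

    def coef(self, name: str) -> np.ndarray:
        return self.beta[:, self.names.index(name)]

    def tstat(self, name: str) -> np.ndarray:
        return self.t[:, self.names.index(name)]

    def pvalue(self, name: str) -> np.ndarray:
        return self.p[:, self.names.index(name)]


def _collinear_columns(X: np.ndarray, names) -> list:
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    return [names[i] for i in np.flatnonzero(diag <= tol)]


def fit_glm(data: np.ndarray, design: DesignMatrix) -> GLMResult:
    """Ordinary least squares per voxel; ``data`` is (n_volumes, n_voxels).

    Returns coefficients, standard errors, two-sided t/p per column, and the
    omnibus F test over the gas-condition columns.  Voxels containing NaN
    propagate NaN estimates.
    """
    X = design.matrix
    n, p = X.shape
    data = np.asarray(data, float)
    if data.ndim == 1:
        data = data[:, None]
    if data.shape[0] != n:
        raise ValueError(f"data has {data.shape[0]} time points, design has {n}")
    if n <= p:
        raise ValueError("fewer time points than design columns")
    if np.linalg.matrix_rank(X) < p:
        bad = _collinear_columns(X, design.names)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")

    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ data  # (p, V)
    resid = data - X @ beta
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof  # (V,)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.outer(sigma2, np.diag(xtx_inv)))  # (V, p)
        t = beta.T / se
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)

    f_stat = f_p = None
    cond_idx = [design.names.index(c) for c in design.condition_names]
    if cond_idx:
        q = len(cond_idx)
        contrast_cov_inv = np.linalg.inv(xtx_inv[np.ix_(cond_idx, cond_idx)])
        b_c = beta[cond_idx, :]  # (q, V)
        with np.errstate(divide="ignore", invalid="ignore"):
            f_stat = np.einsum("qv,qr,rv->v", b_c, contrast_cov_inv, b_c) / (q * sigma2)
        f_p = stats.f.sf(f_stat, q, dof)
    return GLMResult(
        beta=beta.T, se=se, t=t, p=pvals, dof=dof, sigma2=sigma2,
        names=list(design.names), condition_names=list(design.condition_names),
        f_stat=f_stat, f_p=f_p,
    )


def holm_select(p_values, alpha: float = 0.05) -> np.ndarray:
    """Step-down Holm-Bonferroni rejections over a family of p-values.

    Sort ascending and reject while ``p_(i) <= alpha / (m - i)`` (0-based);
    the first failure stops the procedure.  NaN entries are excluded from
    the family and never rejected.  Returns a boolean mask.
    """
    p = np.asarray(p_values, float)
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    valid = np.isfinite(p)
    m = int(valid.sum())
    if m == 0:
        raise ValueError("empty family of p-values")
    pv = p[valid]
    order = np.argsort(pv, kind="stable")
    thresholds = alpha / (m - np.arange(m))
    passed = pv[order] <= thresholds
    cutoff = np.argmin(passed) if not passed.all() else m
    reject_sorted = np.zeros(m, dtype=bool)
    reject_sorted[:cutoff] = True
    reject_valid = np.zeros(m, dtype=bool)
    reject_valid[order] = reject_sorted
    out = np.zeros(p.shape, dtype=bool)
    out[valid] = reject_valid
    return out
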