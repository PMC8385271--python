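"""First-level general linear model for one subject's run.

The design holds the HRF-convolved task regressor, the six head-motion
regressors, discrete-cosine drift terms implementing the high-pass filter
(default cutoff 1/128 Hz), and an intercept. Fitting is OLS followed by an
AR(1) prewhitening step: the lag-1 autocorrelation of the OLS residuals is
estimated (pooled over the analysis mask by default), both sides of the
regression are whitened, and the model is refit. The task-regressor
coefficient per voxel is the output beta map.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .cohort import BoldRun
from .paradigm import ParadigmSpec, task_regressor

__all__ = ["DesignMatrix", "BetaMap", "build_design", "fit_glm_ar1"]

log = logging.getLogger(__name__)

DEFAULT_HP_CUTOFF_HZ = 1.0 / 128.0


@dataclass
class DesignMatrix:
    """Per-run design: ``matrix`` is n_volumes x k, names align to columns."""

    matrix: np.ndarray
    column_names: list[str]

    @property
    def task_index(self) -> int:
        return self.column_names.index("task")


@dataclass
class BetaMap:
    """Task-regressor coefficient per voxel for one subject."""

    values: np.ndarray  # 3D
    subject_id: str
    label: int
    ar1_coeff: float = 0.0


def _dct_drift_columns(n_volumes: int, tr: float, cutoff_hz: float) -> np.ndarray:
    """DCT-II basis columns with frequency k/(2*N*tr) below the cutoff."""
    n_k = int(np.floor(2.0 * n_volumes * tr * cutoff_hz))
    v = np.arange(n_volumes)
    cols = [np.cos(np.pi * k * (2 * v + 1) / (2 * n_volumes)) for k in range(1, n_k + 1)]
    return np.column_stack(cols) if cols else np.empty((n_volumes, 0))


def build_design(
    paradigm: ParadigmSpec,
    motion: np.ndarray,
    hp_cutoff_hz: float = DEFAULT_HP_CUTOFF_HZ,
) -> DesignMatrix:
    """Assemble task + motion + drift + intercept columns.

    All-zero motion columns are dropped with a warning (they would make the
    design rank-deficient without carrying information); any remaining
    collinearity raises, naming the offending columns.
    """
    if hp_cutoff_hz <= 0:
        raise ValueError("hp_cutoff_hz must be positive")
    n = paradigm.n_volumes
    motion = np.asarray(motion, dtype=float)
    if motion.shape != (n, 6):
        raise ValueError(f"motion table must be {n} x 6, got {motion.shape}")

    cols = [task_regressor(paradigm)]
    names = ["task"]
    for j in range(6):
        if np.allclose(motion[:, j], 0.0):
            warnings.warn(
                f"motion column {j} is all zeros and was dropped from the design",
                stacklevel=2,
            )
            continue
        cols.append(motion[:, j])
        names.append(f"motion_{j}")
    drift = _dct_drift_columns(n, paradigm.tr_seconds, hp_cutoff_hz)
    for k in range(drift.shape[1]):
        cols.append(drift[:, k])
        names.append(f"drift_dct_{k + 1}")
    cols.append(np.ones(n))
    names.append("intercept")

    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns that do not increase the rank of what precedes them
        bad = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
                bad.append(names[j])
        raise ValueError(f"design matrix is rank-deficient; collinear columns: {bad}")
    return DesignMatrix(matrix=X, column_names=names)


def _ols(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # X is validated full-rank at design construction; pinv solve is far
    # faster than lstsq's SVD driver when Y has thousands of columns
    beta = np.linalg.pinv(X) @ Y
    return beta, Y - X @ beta


def _ar1_bias_map(X: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Expected raw lag-1 residual autocorrelation for each true AR(1) value.

    OLS residuals e = M eps (M the residual-forming matrix of X) understate
    the autocorrelation of eps, badly so when the design contains slow
    regressors (drift, motion random walks). With A the symmetrised lag-1
    operator, E[e'Ae] / E[e'e] = tr(A M S M) / tr(M S M) for S the AR(1)
    correlation matrix; tabulating this over ``grid`` lets the raw estimate
    be inverted by interpolation (method-of-moments correction).
    """
    n = X.shape[0]
    Q, _ = np.linalg.qr(X)
    M = np.eye(n) - Q @ Q.T
    A = np.diag(np.full(n - 1, 0.5), 1) + np.diag(np.full(n - 1, 0.5), -1)
    lagdist = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    out = np.empty(grid.size)
    for i, rho in enumerate(grid):
        S = rho ** lagdist if rho != 0 else np.eye(n)  # integer exponents
        MSM = M @ S @ M
        out[i] = np.trace(A @ MSM) / np.trace(MSM)
    return out


def fit_glm_ar1(
    run: BoldRun,
    design: DesignMatrix,
    pooled_ar: bool = True,
) -> BetaMap:
    """Prewhitened GLM fit; returns the task beta per voxel.

    The AR(1) coefficient is the lag-1 autocorrelation of the OLS residuals,
    pooled over all in-mask voxels by default (one global value — stabler at
    short runs) or estimated voxelwise with ``pooled_ar=False``. Voxels with
    zero temporal variance get beta 0 and a logged warning.
    """
    X = design.matrix
    n, k = X.shape
    if run.data.shape[-1] != n:
        raise ValueError("design rows must equal run volumes")
    grid = run.grid_shape
    Y = run.data.reshape(-1, n).T  # n_volumes x n_voxels
    variances = Y.var(axis=0)
    mask = variances > 0
    n_dead = int((~mask).sum())
    if n_dead:
        log.warning(
            "subject %s: %d zero-variance voxel(s) set to beta 0",
            run.subject_id,
            n_dead,
        )
    betas = np.zeros(Y.shape[1])
    if mask.any():
        Ym = Y[:, mask]
        _, resid = _ols(X, Ym)
        rho_grid = np.linspace(-0.5, 0.95, 30)
        bias_curve = _ar1_bias_map(X, rho_grid)

        def lag1(r: np.ndarray, axis: int = 0) -> np.ndarray:
            num = (r[1:] * r[:-1]).sum(axis=axis)
            den = (r**2).sum(axis=axis)
            with np.errstate(invalid="ignore", divide="ignore"):
                raw = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
            # invert the OLS-projection bias (raw is monotone in true rho)
            rho = np.interp(raw, bias_curve, rho_grid)
            return np.clip(rho, -0.95, 0.95)

        if pooled_ar:
            rho_val = float(lag1(resid, axis=None))
            W_first = np.sqrt(1.0 - rho_val**2)
            Xw = X.copy()
            Xw[1:] = X[1:] - rho_val * X[:-1]
            Xw[0] *= W_first
            Yw = Ym.copy()
            Yw[1:] = Ym[1:] - rho_val * Ym[:-1]
            Yw[0] *= W_first
            beta_w, _ = _ols(Xw, Yw)
            betas[mask] = beta_w[design.task_index]
            rho_out = rho_val
        else:
            rho = lag1(resid)  # per voxel
            rho_out = float(np.median(rho))
            beta_cols = np.empty(Ym.shape[1])
            # whiten per voxel; loop over unique rounded rho values for speed
            rho_r = np.round(rho, 3)
            for val in np.unique(rho_r):
                sel = rho_r == val
                W_first = np.sqrt(1.0 - val**2)
                Xw = X.copy()
                Xw[1:] = X[1:] - val * X[:-1]
                Xw[0] *= W_first
                Yv = Ym[:, sel].copy()
                Yv[1:] = Ym[1:, sel] - val * Ym[:-1, sel]
                Yv[0] *= W_first
                bw, _ = _ols(Xw, Yv)
                beta_cols[sel] = bw[design.task_index]
            betas[mask] = beta_cols
    else:
        rho_out = 0.0
    return BetaMap(
        values=betas.reshape(grid),
        subject_id=run.subject_id,
        label=run.label,
        ar1_coeff=rho_out,
    )
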