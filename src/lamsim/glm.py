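"""Per-run GLM fitting and contrast estimation.

Each run is fit separately with ordinary least squares.  Detrending
(intercept, linear trend, single-cycle sine and cosine) is implemented as
nuisance regressors inside the design matrix, which is the same projection
as pre-filtering but keeps one contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bold_sim import boxcar, convolve_with_hrf
from .design import TASK_D_MINUS, TASK_D_PLUS, BlockSchedule
from .neural_model import LAYERS

PER_CONDITION = "per_condition"
PER_BLOCK = "per_block"

NUISANCE_LABELS = ("intercept", "linear", "sin", "cos")


@dataclass(frozen=True)
class DesignMatrix:
    """Volumes x regressors matrix with labelled task columns."""

    X: np.ndarray
    labels: tuple[str, ...]
    mode: str
    n_task: int  # leading columns are task regressors, the rest nuisance

    def __post_init__(self) -> None:
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("design matrix is rank deficient")

    def column(self, label: str) -> int:
        return self.labels.index(label)


@dataclass(frozen=True)
class BetaEstimates:
    betas: np.ndarray      # voxels x regressors
    residuals: np.ndarray  # voxels x volumes
    labels: tuple[str, ...]


def build_design_matrix(
    schedule: BlockSchedule, kernel: np.ndarray, mode: str = PER_CONDITION
) -> DesignMatrix:
    """HRF-convolved task regressors plus the four nuisance columns.

    ``per_condition`` pools blocks of a condition into one regressor (4
    columns); ``per_block`` models every block separately (20 columns at the
    default design, used for SVM training patterns).
    """
    n = schedule.n_volumes
    t = np.arange(n) * schedule.tr
    duration = n * schedule.tr

    if mode == PER_CONDITION:
        conditions = sorted({b.condition for b in schedule.blocks})
        task_cols, labels = [], []
        for cond in conditions:
            box = np.zeros(n)
            for b in schedule.blocks:
                if b.condition == cond:
                    box += boxcar(schedule, b.onset, b.duration)
            task_cols.append(convolve_with_hrf(box, kernel))
            labels.append(cond)
    elif mode == PER_BLOCK:
        task_cols, labels = [], []
        for i, b in enumerate(schedule.blocks):
            box = boxcar(schedule, b.onset, b.duration)
            task_cols.append(convolve_with_hrf(box, kernel))
            labels.append(f"block{i:02d}:{b.condition}")
    else:
        raise ValueError(f"unknown mode {mode!r}")

    nuisance = [
        np.ones(n),
        t - t.mean(),
        np.sin(2 * np.pi * t / duration),
        np.cos(2 * np.pi * t / duration),
    ]
    X = np.column_stack(task_cols + nuisance)
    return DesignMatrix(
        X=X, labels=tuple(labels) + NUISANCE_LABELS, mode=mode, n_task=len(task_cols)
    )


def fit_glm(y: np.ndarray, dm: DesignMatrix) -> BetaEstimates:
    """OLS fit of every voxel's timeseries against the design matrix."""
    y = np.atleast_2d(y)
    if y.shape[1] != dm.X.shape[0]:
        raise ValueError("number of volumes does not match the design matrix")
    betas, *_ = np.linalg.lstsq(dm.X, y.T, rcond=None)
    betas = betas.T
    residuals = y - betas @ dm.X.T
    return BetaEstimates(betas=betas, residuals=residuals, labels=dm.labels)


def face_minus_house_vector(labels: tuple[str, ...]) -> np.ndarray:
    """Contrast vector (F45 + F135) - (H45 + H135) over labelled columns."""
    c = np.zeros(len(labels))
    for label, w in (("F45", 1.0), ("F135", 1.0), ("H45", -1.0), ("H135", -1.0)):
        c[labels.index(label)] = w
    return c


@dataclass(frozen=True)
class ContrastEstimates:
    """Per-voxel contrasts averaged within each run context."""

    taskdplus: np.ndarray
    taskdminus: np.ndarray
    preference_sign: int = 1

    def to_frame(self, layer: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "voxel_id": np.arange(len(self.taskdplus)),
                "layer": np.asarray(LAYERS, dtype=object)[layer],
                "taskdplus": self.taskdplus,
                "taskdminus": self.taskdminus,
            }
        )


def run_contrast(fit: BetaEstimates, preference_sign: int = 1) -> np.ndarray:
    """Signed face-minus-house contrast of one run's per-condition betas."""
    return preference_sign * (fit.betas[:, : len(fit.labels)] @ face_minus_house_vector(fit.labels))


def contrast_estimates(
    fits: list[tuple[BlockSchedule, BetaEstimates]], preference_sign: int = 1
) -> ContrastEstimates:
    """Average the per-run contrasts within each context.

    ``preference_sign`` is flipped (-1) for house-preferring regions so the
    region-mean contrast stays positive.
    """
    by_context: dict[str, list[np.ndarray]] = {TASK_D_PLUS: [], TASK_D_MINUS: []}
    for schedule, fit in fits:
        by_context[schedule.context].append(run_contrast(fit, preference_sign))
    for context, values in by_context.items():
        if not values:
            raise ValueError(f"no runs for context {context}")
    return ContrastEstimates(
        taskdplus=np.mean(by_context[TASK_D_PLUS], axis=0),
        taskdminus=np.mean(by_context[TASK_D_MINUS], axis=0),
        preference_sign=preference_sign,
    )


def zscore_timeseries(y: np.ndarray) -> np.ndarray:
    """Per-voxel temporal z-scoring of one run.

    Zero-variance voxels cannot be normalized; their rows are returned as
    NaN so downstream metrics treat them as missing.
    """
    y = np.atleast_2d(y)
    mean = y.mean(axis=1, keepdims=True)
    sd = y.std(axis=1, keepdims=True)
    z = np.full_like(y, np.nan, dtype=float)
    ok = sd[:, 0] > 0
    z[ok] = (y[ok] - mean[ok]) / sd[ok]
    return z


def contrast_tstats(
    fits: list[BetaEstimates],
    dms: list[DesignMatrix],
    contrast: np.ndarray,
) -> np.ndarray:
    """t-statistic of the run-averaged contrast with pooled residual variance.

    Diagnostic only (used to compare the simulated contrast-to-noise against
    real data); inference across subjects is out of scope.
    """
    if len(fits) != len(dms) or not fits:
        raise ValueError("need matching, non-empty fits and design matrices")
    n_runs = len(fits)
    contrast = np.asarray(contrast, dtype=float)
    values = np.mean([fit.betas @ contrast for fit in fits], axis=0)
    if not contrast.any():
        return np.zeros_like(values)

    rss = np.zeros(values.shape)
    fitted_power = np.zeros(values.shape)
    df = 0
    var_factor = 0.0
    for fit, dm in zip(fits, dms):
        n, p = dm.X.shape
        if n <= p:
            raise ValueError("no residual degrees of freedom")
        rss += np.sum(fit.residuals**2, axis=1)
        fitted_power += np.sum((fit.betas @ dm.X.T) ** 2, axis=1)
        df += n - p
        xtx_inv = np.linalg.inv(dm.X.T @ dm.X)
        var_factor += float(contrast @ xtx_inv @ contrast)
    sigma2 = rss / df
    # a perfect (noiseless) fit leaves only round-off in the residuals
    if np.any(sigma2 <= 1e-20 * np.maximum(fitted_power, 1e-300)):
        raise ValueError("zero residual variance: t-statistic undefined")
    se = np.sqrt(sigma2 * var_factor / n_runs**2)
    return values / se
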