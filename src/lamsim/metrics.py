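"""Attentional-modulation metrics and superficial-bias diagnostics.

Seven metrics are benchmarked: three ratio-family metrics on contrast
estimates (per-voxel ratio, ROI ratio, Deming regression slope), two
normalization approaches (temporal z-scoring, L2 normalization of betas)
and two multivoxel methods (cross-validated SVM accuracy and the linear
discriminant contrast, LDC).  A raw-contrast profile serves as the
uncorrected baseline.

All univariate metrics consume :class:`~lamsim.glm.ContrastEstimates`; the
multivariate metrics consume per-run betas and residuals from TaskD+ runs.
Layer profiles are ordered (superficial, middle, deep).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .glm import BetaEstimates, ContrastEstimates, face_minus_house_vector, zscore_timeseries
from .neural_model import LAYERS

#: profile templates used to score a laminar profile's shape
BIAS_VECTOR = np.array([1.0, 0.0, -1.0])
ATTENTION_VECTOR = np.array([0.5, -1.0, 0.5])


@dataclass(frozen=True)
class LaminarProfile:
    """One metric value per cortical layer; NaN marks a missing layer."""

    name: str
    values: np.ndarray
    n_used: np.ndarray

    def __post_init__(self) -> None:
        if len(self.values) != len(LAYERS):
            raise ValueError("profile needs one value per layer")


@dataclass(frozen=True)
class DemingConfig:
    """Error-variance ratio of the errors-in-variables fit (1 = orthogonal)."""

    delta: float = 1.0

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be positive")


def layer_masks(layer: np.ndarray) -> list[np.ndarray]:
    return [np.asarray(layer) == i for i in range(len(LAYERS))]


def deming_slope(x: np.ndarray, y: np.ndarray, delta: float = 1.0) -> float:
    """Deming (errors-in-variables) regression slope of y on x.

    With delta = 1 this is orthogonal regression, minimizing perpendicular
    distances to the line.  Returns NaN when the sample covariance is zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        return np.nan
    s_xx = np.var(x, ddof=1)
    s_yy = np.var(y, ddof=1)
    s_xy = np.cov(x, y, ddof=1)[0, 1]
    if s_xy == 0:
        return np.nan
    term = s_yy - delta * s_xx
    return (term + np.sqrt(term**2 + 4.0 * delta * s_xy**2)) / (2.0 * s_xy)


# ---------------------------------------------------------------------------
# univariate metrics on contrast estimates
# ---------------------------------------------------------------------------

def metric_voxel_ratio(c: ContrastEstimates, layer: np.ndarray) -> LaminarProfile:
    """Mean over voxels of the per-voxel TaskD+/TaskD- contrast ratio.

    Voxels with exactly zero TaskD- contrast are excluded; no outlier
    handling beyond that — the metric's heavy-tail instability is a finding,
    not a bug.
    """
    values, n_used = [], []
    for mask in layer_masks(layer):
        dplus, dminus = c.taskdplus[mask], c.taskdminus[mask]
        ok = np.isfinite(dplus) & np.isfinite(dminus) & (dminus != 0)
        values.append(np.mean(dplus[ok] / dminus[ok]) if ok.any() else np.nan)
        n_used.append(int(ok.sum()))
    return LaminarProfile("voxel_ratio", np.array(values), np.array(n_used))


def metric_roi_ratio(c: ContrastEstimates, layer: np.ndarray) -> LaminarProfile:
    """Ratio of layer-summed TaskD+ to layer-summed TaskD- contrasts."""
    values, n_used = [], []
    for mask in layer_masks(layer):
        dplus, dminus = c.taskdplus[mask], c.taskdminus[mask]
        ok = np.isfinite(dplus) & np.isfinite(dminus)
        denom = np.sum(dminus[ok])
        values.append(np.sum(dplus[ok]) / denom if denom != 0 else np.nan)
        n_used.append(int(ok.sum()))
    return LaminarProfile("roi_ratio", np.array(values), np.array(n_used))


def metric_deming(
    c: ContrastEstimates, layer: np.ndarray, cfg: DemingConfig = DemingConfig()
) -> LaminarProfile:
    """Per-layer Deming slope of TaskD+ regressed on TaskD- contrasts."""
    values, n_used = [], []
    for mask in layer_masks(layer):
        dplus, dminus = c.taskdplus[mask], c.taskdminus[mask]
        ok = np.isfinite(dplus) & np.isfinite(dminus)
        values.append(deming_slope(dminus[ok], dplus[ok], cfg.delta))
        n_used.append(int(ok.sum()))
    return LaminarProfile("deming", np.array(values), np.array(n_used))


def raw_contrast_profile(c: ContrastEstimates, layer: np.ndarray) -> LaminarProfile:
    """Uncorrected baseline: layer mean of the TaskD+ contrast."""
    values, n_used = [], []
    for mask in layer_masks(layer):
        dplus = c.taskdplus[mask]
        ok = np.isfinite(dplus)
        values.append(np.mean(dplus[ok]) if ok.any() else np.nan)
        n_used.append(int(ok.sum()))
    return LaminarProfile("raw", np.array(values), np.array(n_used))


# ---------------------------------------------------------------------------
# normalization metrics
# ---------------------------------------------------------------------------

def metric_zscore(
    taskdplus_runs: list[tuple[np.ndarray, "object"]],
    layer: np.ndarray,
    fit_fn,
    preference_sign: int = 1,
) -> LaminarProfile:
    """TaskD+ contrast after temporally z-scoring each run's data.

    ``taskdplus_runs`` holds (data, design_matrix) pairs for the TaskD+
    runs; ``fit_fn(data, dm)`` refits the GLM (injected to avoid a circular
    dependency on the orchestration layer).  Zero-variance voxels propagate
    as NaN and are excluded per layer.
    """
    contrasts = []
    for y, dm in taskdplus_runs:
        fit = fit_fn(zscore_timeseries(y), dm)
        cvec = face_minus_house_vector(fit.labels)
        contrasts.append(preference_sign * (fit.betas @ cvec))
    mean_contrast = np.mean(contrasts, axis=0)

    values, n_used = [], []
    for mask in layer_masks(layer):
        vals = mean_contrast[mask]
        ok = np.isfinite(vals)
        values.append(np.mean(vals[ok]) if ok.any() else np.nan)
        n_used.append(int(ok.sum()))
    return LaminarProfile("zscore", np.array(values), np.array(n_used))


def metric_l2norm(
    taskdplus_fits: list[BetaEstimates],
    layer: np.ndarray,
    preference_sign: int = 1,
) -> LaminarProfile:
    """TaskD+ contrast after L2-normalizing each voxel's condition betas.

    The norm is taken over the four condition betas within each run;
    zero-norm voxels are excluded.
    """
    contrasts = []
    for fit in taskdplus_fits:
        n_cond = len(fit.labels) - 4  # trailing 4 columns are nuisance
        cond = fit.betas[:, :n_cond]
        norm = np.linalg.norm(cond, axis=1, keepdims=True)
        normalized = np.where(norm > 0, cond / np.where(norm > 0, norm, 1.0), np.nan)
        cvec = face_minus_house_vector(fit.labels)[:n_cond]
        contrasts.append(preference_sign * (normalized @ cvec))
    mean_contrast = np.mean(contrasts, axis=0)

    values, n_used = [], []
    for mask in layer_masks(layer):
        vals = mean_contrast[mask]
        ok = np.isfinite(vals)
        values.append(np.mean(vals[ok]) if ok.any() else np.nan)
        n_used.append(int(ok.sum()))
    return LaminarProfile("l2norm", np.array(values), np.array(n_used))


# ---------------------------------------------------------------------------
# multivoxel metrics (TaskD+ runs only, leave-one-run-out)
# ---------------------------------------------------------------------------

def metric_svm(
    block_betas: list[np.ndarray],
    block_labels: list[np.ndarray],
    layer: np.ndarray,
    C: float = 1.0,
) -> LaminarProfile:
    """Leave-one-run-out linear SVM decoding of the attended category.

    ``block_betas[r]`` is voxels x blocks for run r; ``block_labels[r]``
    the attended category per block.  Accuracy is averaged over the four
    folds, per layer.
    """
    n_runs = len(block_betas)
    if n_runs < 2:
        raise ValueError("need at least two runs for cross-validation")
    for labels in block_labels:
        if len(np.unique(labels)) < 2:
            raise ValueError("degenerate fold: a run contains a single class")

    values, n_used = [], []
    for mask in layer_masks(layer):
        accuracies = []
        for test in range(n_runs):
            train_idx = [r for r in range(n_runs) if r != test]
            X_train = np.vstack([block_betas[r][mask].T for r in train_idx])
            y_train = np.concatenate([block_labels[r] for r in train_idx])
            X_test = block_betas[test][mask].T
            y_test = block_labels[test]
            clf = SVC(kernel="linear", C=C)
            clf.fit(X_train, y_train)
            accuracies.append(float(np.mean(clf.predict(X_test) == y_test)))
        values.append(float(np.mean(accuracies)))
        n_used.append(int(mask.sum()))
    return LaminarProfile("svm", np.array(values), np.array(n_used))


def _ledoit_wolf_from_stats(
    scatter: np.ndarray, quartic: float, n: int
) -> tuple[np.ndarray, float]:
    """Ledoit-Wolf shrunk covariance from sufficient statistics.

    ``scatter`` = sum_i x_i x_i^T, ``quartic`` = sum_i ||x_i||^4 over n
    zero-mean samples.  Shrinks toward a scaled identity with analytically
    chosen intensity; equivalent to sklearn's ``LedoitWolf`` with
    ``assume_centered=True``.
    """
    p = scatter.shape[0]
    S = scatter / n
    mu = np.trace(S) / p
    frob2 = float(np.sum(S**2))
    d2 = (frob2 - p * mu**2) / p
    if d2 <= 0:
        return mu * np.eye(p), 1.0
    b2 = min((quartic - n * frob2) / (p * n**2), d2)
    shrinkage = max(b2, 0.0) / d2
    return (1.0 - shrinkage) * S + shrinkage * mu * np.eye(p), shrinkage


def ledoit_wolf_covariance(samples: np.ndarray) -> tuple[np.ndarray, float]:
    """Shrunk covariance of zero-mean samples (rows = observations)."""
    samples = np.asarray(samples, dtype=float)
    scatter = samples.T @ samples
    quartic = float(np.sum(np.sum(samples**2, axis=1) ** 2))
    return _ledoit_wolf_from_stats(scatter, quartic, samples.shape[0])


def metric_ldc(
    run_contrasts: list[np.ndarray],
    run_residuals: list[np.ndarray],
    layer: np.ndarray,
) -> LaminarProfile:
    """Cross-validated linear discriminant contrast.

    Per layer and fold: the discriminant is the mean training-run contrast
    whitened by the shrinkage-regularized covariance of the pooled training
    residuals; its dot product with the held-out run's contrast is averaged
    over folds and divided by sqrt(number of voxels in the layer).
    """
    n_runs = len(run_contrasts)
    if n_runs != len(run_residuals) or n_runs < 2:
        raise ValueError("need matching contrasts and residuals for >= 2 runs")

    values, n_used = [], []
    for mask in layer_masks(layer):
        p = int(mask.sum())
        # per-run sufficient statistics of the residual samples (time x voxels)
        scatters, quartics, counts = [], [], []
        for res in run_residuals:
            x = res[mask].T
            scatters.append(x.T @ x)
            quartics.append(float(np.sum(np.sum(x**2, axis=1) ** 2)))
            counts.append(x.shape[0])

        stats = []
        for test in range(n_runs):
            train = [r for r in range(n_runs) if r != test]
            scatter = sum(scatters[r] for r in train)
            quartic = sum(quartics[r] for r in train)
            n = sum(counts[r] for r in train)
            cov, _ = _ledoit_wolf_from_stats(scatter, quartic, n)
            c_train = np.mean([run_contrasts[r][mask] for r in train], axis=0)
            try:
                weights = np.linalg.solve(cov, c_train)
            except np.linalg.LinAlgError as err:
                raise np.linalg.LinAlgError(
                    "shrunk residual covariance is singular"
                ) from err
            stats.append(float(weights @ run_contrasts[test][mask]))
        values.append(float(np.mean(stats)) / np.sqrt(p))
        n_used.append(p)
    return LaminarProfile("ldc", np.array(values), np.array(n_used))


# ---------------------------------------------------------------------------
# profile scoring
# ---------------------------------------------------------------------------

def contribution_scores(profile: LaminarProfile | np.ndarray) -> tuple[float, float]:
    """Superficial-bias and attentional-modulation scores of a profile.

    The profile is normalized by its mean, then dotted with [1, 0, -1]
    (bias) and [0.5, -1, 0.5] (V-shaped attentional modulation).  A
    near-zero mean makes the normalization meaningless; both scores are
    returned as NaN in that case.
    """
    values = profile.values if isinstance(profile, LaminarProfile) else np.asarray(profile, dtype=float)
    if not np.all(np.isfinite(values)):
        return (np.nan, np.nan)
    mean = values.mean()
    if abs(mean) < 1e-12 * max(1.0, np.max(np.abs(values))):
        return (np.nan, np.nan)
    normalized = values / mean
    return (float(normalized @ BIAS_VECTOR), float(normalized @ ATTENTION_VECTOR))
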