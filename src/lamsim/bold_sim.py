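"""BOLD timeseries generation: HRF convolution, noise and superficial bias.

The measured signal per voxel and volume is

    y(v,t) = L_bias(l(v)) * (h(v,t) + E_p(v,t)) + E_t(v,t)

where ``h`` is the HRF-convolved neural boxcar, ``E_p`` a low-rank
physiological noise term that scales with the layer bias, and ``E_t``
additive thermal (Rician magnitude) noise that does not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.stats import gamma as gamma_dist

from .design import BlockSchedule
from .neural_model import (
    LAYERS,
    AttentionProfile,
    StimulusContext,
    VoxelPopulation,
    block_amplitude,
)


@dataclass(frozen=True)
class NoiseParams:
    """Physiological (structured) and thermal (Rician) noise levels."""

    sigma_p: float = 11.0
    sigma_t: float = 15.0
    n_physio_components: int = 20

    def __post_init__(self) -> None:
        if self.sigma_p < 0 or self.sigma_t < 0:
            raise ValueError("noise sds must be non-negative")
        if self.n_physio_components < 1:
            raise ValueError("need at least one physiological component")


@dataclass(frozen=True)
class LayerBias:
    """Multiplicative superficial-bias factor per layer.

    The default is strictly decreasing with depth and chosen so the raw
    layer-mean TaskD+ contrast, proportional to l_bias * (a - 1) at gains
    [3, 2, 3], also decreases strictly with depth; the ratio-family metrics
    are invariant to the exact values.
    """

    l_bias: tuple[float, float, float] = (4.0, 2.5, 1.0)

    def __post_init__(self) -> None:
        if len(self.l_bias) != len(LAYERS):
            raise ValueError("layer bias needs one value per layer")
        if any(b <= 0 for b in self.l_bias):
            raise ValueError("layer bias must be positive")

    def factor(self, layer: np.ndarray | int) -> np.ndarray:
        return np.asarray(self.l_bias)[layer]


@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma HRF parameters (seconds)."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    peak_undershoot_ratio: float = 6.0
    kernel_length: float = 32.0


@dataclass(frozen=True)
class RunData:
    schedule: BlockSchedule
    y: np.ndarray       # voxels x volumes, measured
    clean: np.ndarray   # voxels x volumes, noise-free biased signal retained for tests


@dataclass(frozen=True)
class SimulatedSession:
    runs: tuple[RunData, ...]

    @property
    def n_voxels(self) -> int:
        return self.runs[0].y.shape[0]


def hrf_kernel(hrf: HRFParams = HRFParams(), tr: float = 2.39) -> np.ndarray:
    """Double-gamma HRF sampled at the TR, peak-normalized to 1."""
    if tr <= 0:
        raise ValueError("tr must be positive")
    t = np.arange(0.0, hrf.kernel_length, tr)
    peak = gamma_dist.pdf(t, hrf.peak_delay / hrf.peak_dispersion, scale=hrf.peak_dispersion)
    undershoot = gamma_dist.pdf(
        t, hrf.undershoot_delay / hrf.undershoot_dispersion, scale=hrf.undershoot_dispersion
    )
    kernel = peak - undershoot / hrf.peak_undershoot_ratio
    return kernel / np.max(np.abs(kernel))


def boxcar(schedule: BlockSchedule, onset: float, duration: float) -> np.ndarray:
    """Unit boxcar over the volumes acquired within [onset, onset+duration)."""
    t = np.arange(schedule.n_volumes) * schedule.tr
    return ((t >= onset - 1e-9) & (t < onset + duration - 1e-9)).astype(float)


def neural_timecourse(
    schedule: BlockSchedule, vox: VoxelPopulation, attn: AttentionProfile
) -> np.ndarray:
    """Voxels x volumes boxcar matrix of block response amplitudes."""
    tc = np.zeros((vox.n_voxels, schedule.n_volumes))
    for block in schedule.blocks:
        ctx = StimulusContext(schedule.context, block.attended_category)
        amp = block_amplitude(vox.n_face, vox.n_house, vox.layer, ctx, attn)
        on = boxcar(schedule, block.onset, block.duration)
        tc += np.outer(amp, on)
    return tc


def convolve_with_hrf(timecourse: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Causal convolution along time, truncated to the input length."""
    kernel = np.asarray(kernel, dtype=float)
    if kernel.size == 0:
        raise ValueError("kernel must be non-empty")
    tc = np.atleast_2d(np.asarray(timecourse, dtype=float))
    n = tc.shape[1]
    out = signal.fftconvolve(tc, kernel[None, :], mode="full", axes=1)[:, :n]
    return out if np.asarray(timecourse).ndim == 2 else out[0]


def sample_physio_noise(
    n_voxels: int, n_volumes: int, noise: NoiseParams, rng: np.random.Generator
) -> np.ndarray:
    """Low-rank structured noise: random mixes of shared Gaussian components.

    Each voxel's series is a random-weight combination of
    ``n_physio_components`` shared time vectors, recentred and rescaled per
    voxel to sd ``sigma_p``.
    """
    if noise.sigma_p == 0:
        return np.zeros((n_voxels, n_volumes))
    components = rng.standard_normal((noise.n_physio_components, n_volumes))
    weights = rng.standard_normal((n_voxels, noise.n_physio_components))
    e = weights @ components
    e -= e.mean(axis=1, keepdims=True)
    sd = e.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0  # degenerate voxel stays all-zero
    return e * (noise.sigma_p / sd)


def sample_thermal_noise(
    n_voxels: int, n_volumes: int, noise: NoiseParams, rng: np.random.Generator
) -> np.ndarray:
    """Rician magnitude noise with zero offset: sqrt(g1^2 + g2^2), g ~ N(0, sigma_t)."""
    if noise.sigma_t == 0:
        return np.zeros((n_voxels, n_volumes))
    g = rng.normal(0.0, noise.sigma_t, size=(2, n_voxels, n_volumes))
    return np.hypot(g[0], g[1])


def simulate_session(
    vox: VoxelPopulation,
    attn: AttentionProfile,
    schedules: list[BlockSchedule],
    bias: LayerBias,
    noise: NoiseParams,
    kernel: np.ndarray,
    rng: np.random.Generator,
) -> SimulatedSession:
    """Generate the measured timeseries for every run.

    Noise is drawn independently per run (runs are detrended individually
    downstream, so no cross-run structure is modelled).
    """
    lb = bias.factor(vox.layer)[:, None]
    runs = []
    for schedule in schedules:
        h = convolve_with_hrf(neural_timecourse(schedule, vox, attn), kernel)
        e_p = sample_physio_noise(vox.n_voxels, schedule.n_volumes, noise, rng)
        e_t = sample_thermal_noise(vox.n_voxels, schedule.n_volumes, noise, rng)
        y = lb * (h + e_p) + e_t
        runs.append(RunData(schedule=schedule, y=y, clean=lb * h))
    return SimulatedSession(runs=tuple(runs))
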