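"""Voxel neural populations and layer-dependent attentional gain.

Each voxel holds two purely selective neuronal populations (face / house)
whose sizes are drawn from half-normal (or folded-normal) distributions.
Attention multiplies the response of the attended category's population by a
layer-dependent gain ``a(l) >= 1``; the unattended population is unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import TASK_D_MINUS, TASK_D_PLUS

#: canonical layer ordering used throughout (index 0 = superficial)
LAYERS = ("superficial", "middle", "deep")

HALF_NORMAL = "half_normal"
FOLDED_NORMAL = "folded_normal"


@dataclass(frozen=True)
class PopulationParams:
    """Population-level scales of the voxel count distributions.

    ``sd_face``/``sd_house`` are the half-normal scales of the per-voxel
    neural counts for a face-selective region.  ``subject_sd`` is the spread
    of the truncated Gaussian used to perturb the scales per simulated
    subject.  In the no-preference scenario both categories use a folded
    normal with mean ``folded_mean`` (0) and the same sd.
    """

    sd_face: float = 1.1
    sd_house: float = 0.5
    subject_sd: float = 0.25
    distribution_kind: str = HALF_NORMAL
    folded_mean: float = 0.0
    #: draw ONE subject scale for both categories (no-preference scenario:
    #: keeps the expected face-house difference exactly zero per subject, so
    #: any regional preference arises only from finite-sample chance)
    shared_subject_scale: bool = False

    def __post_init__(self) -> None:
        if self.sd_face < 0 or self.sd_house < 0 or self.subject_sd < 0:
            raise ValueError("scale parameters must be non-negative")
        if self.distribution_kind not in (HALF_NORMAL, FOLDED_NORMAL):
            raise ValueError(f"unknown distribution_kind {self.distribution_kind!r}")


@dataclass(frozen=True)
class AttentionProfile:
    """Multiplicative attentional gain per layer (superficial, middle, deep)."""

    a: tuple[float, float, float] = (3.0, 2.0, 3.0)

    def __post_init__(self) -> None:
        if len(self.a) != len(LAYERS):
            raise ValueError("attention profile needs one gain per layer")
        if any(g < 1 for g in self.a):
            raise ValueError("attentional gain must be >= 1")

    def gain(self, layer: np.ndarray | int) -> np.ndarray:
        return np.asarray(self.a)[layer]


@dataclass(frozen=True)
class StimulusContext:
    """Which categories are on screen and which one is attended.

    TaskD+ blocks present both categories (attended + distractor); TaskD-
    blocks present only the attended category.
    """

    context: str
    attended_category: str

    def __post_init__(self) -> None:
        if self.context not in (TASK_D_PLUS, TASK_D_MINUS):
            raise ValueError(f"unknown context {self.context!r}")
        if self.attended_category not in ("face", "house"):
            raise ValueError(f"unknown category {self.attended_category!r}")

    def present(self, category: str) -> float:
        """Stimulus indicator f(c): 1 if the category is on screen."""
        if self.context == TASK_D_PLUS:
            return 1.0
        return 1.0 if category == self.attended_category else 0.0


@dataclass(frozen=True)
class VoxelPopulation:
    """Per-voxel neural counts and layer assignment (the ground truth)."""

    n_face: np.ndarray
    n_house: np.ndarray
    layer: np.ndarray  # int codes indexing LAYERS

    def __post_init__(self) -> None:
        if not (len(self.n_face) == len(self.n_house) == len(self.layer)):
            raise ValueError("per-voxel arrays must have equal length")
        if np.any(self.n_face < 0) or np.any(self.n_house < 0):
            raise ValueError("neural counts must be non-negative")

    @property
    def n_voxels(self) -> int:
        return len(self.layer)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "voxel_id": np.arange(self.n_voxels),
                "layer": np.asarray(LAYERS, dtype=object)[self.layer],
                "n_face": self.n_face,
                "n_house": self.n_house,
            }
        )


@dataclass(frozen=True)
class TrueContrasts:
    """Noise-free per-voxel contrast responses for the two run contexts."""

    r_dplus: np.ndarray
    r_dminus: np.ndarray


def sample_subject_scales(
    pop: PopulationParams, rng: np.random.Generator
) -> tuple[float, float]:
    """Draw this subject's half-normal scales.

    Each scale comes from a Gaussian centred on the population value
    (sd ``subject_sd``) truncated to [0, 2 x population value] by rejection.
    """

    def draw(mean: float) -> float:
        if pop.subject_sd == 0:
            return mean
        while True:
            s = rng.normal(mean, pop.subject_sd)
            if 0.0 <= s <= 2.0 * mean:
                return s

    if pop.shared_subject_scale:
        if pop.sd_face != pop.sd_house:
            raise ValueError("shared subject scale requires equal population scales")
        shared = draw(pop.sd_face)
        return shared, shared
    return draw(pop.sd_face), draw(pop.sd_house)


def assign_layers(n_voxels: int) -> np.ndarray:
    """Deterministic contiguous near-equal thirds (superficial first)."""
    sizes = [len(chunk) for chunk in np.array_split(np.arange(n_voxels), len(LAYERS))]
    return np.repeat(np.arange(len(LAYERS)), sizes)


def sample_voxels(
    n_voxels: int,
    scale_face: float,
    scale_house: float,
    rng: np.random.Generator,
    distribution_kind: str = HALF_NORMAL,
    folded_mean: float = 0.0,
) -> VoxelPopulation:
    """Sample per-voxel neural counts.

    ``half_normal`` draws |N(0, scale)|; ``folded_normal`` draws
    |N(folded_mean, scale)| (identical when ``folded_mean`` is 0).  Counts
    are kept continuous.
    """
    if scale_face < 0 or scale_house < 0:
        raise ValueError("scales must be non-negative")
    mean = folded_mean if distribution_kind == FOLDED_NORMAL else 0.0
    n_face = np.abs(rng.normal(mean, scale_face, size=n_voxels)) if scale_face > 0 else np.zeros(n_voxels)
    n_house = np.abs(rng.normal(mean, scale_house, size=n_voxels)) if scale_house > 0 else np.zeros(n_voxels)
    return VoxelPopulation(n_face=n_face, n_house=n_house, layer=assign_layers(n_voxels))


def block_amplitude(
    n_face: float | np.ndarray,
    n_house: float | np.ndarray,
    layer: int | np.ndarray,
    ctx: StimulusContext,
    attn: AttentionProfile,
) -> float | np.ndarray:
    """Neural response amplitude sum_c f(c) * n(v,c) * g(c).

    The attended category's population is scaled by the layer gain a(l);
    the unattended population responds with gain 1 when present.
    """
    gain = attn.gain(layer)
    g_face = gain if ctx.attended_category == "face" else 1.0
    g_house = gain if ctx.attended_category == "house" else 1.0
    return (
        ctx.present("face") * np.asarray(n_face) * g_face
        + ctx.present("house") * np.asarray(n_house) * g_house
    )


def true_contrasts(vox: VoxelPopulation, attn: AttentionProfile) -> TrueContrasts:
    """Noise-free attend-face minus attend-house responses per context.

    TaskD+: (a*n_f + n_h) - (n_f + a*n_h) = (a-1)(n_f - n_h)
    TaskD-: a*n_f - a*n_h = a(n_f - n_h)
    """
    a = attn.gain(vox.layer)
    diff = vox.n_face - vox.n_house
    return TrueContrasts(r_dplus=(a - 1.0) * diff, r_dminus=a * diff)
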