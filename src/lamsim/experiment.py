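"""Scenario orchestration and Monte-Carlo benchmarking of the metrics.

An *iteration* corresponds to one simulated subject: subject-level scales
are drawn, a voxel population sampled, an eight-run session simulated,
GLMs fit and all requested metrics computed.  ``run_monte_carlo`` repeats
this over deterministically derived seeds and summarizes each metric's
per-layer distribution (median, 25th/75th percentiles) together with its
superficial-bias / attentional-modulation contribution scores.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import bold_sim, glm, metrics as met, neural_model as nm
from .design import TASK_D_PLUS, ATTENDED_CATEGORY, DesignSpec, generate_schedules
from .neural_model import LAYERS

ALL_METRICS = (
    "raw",
    "voxel_ratio",
    "roi_ratio",
    "deming",
    "zscore",
    "l2norm",
    "svm",
    "ldc",
)
UNIVARIATE_METRICS = ("raw", "voxel_ratio", "roi_ratio", "deming", "zscore", "l2norm")

SCENARIO_NAMES = ("selective", "no_preference", "high_noise", "noiseless")


@dataclass(frozen=True)
class Scenario:
    """Complete parameterization of one simulation condition."""

    name: str = "selective"
    attention: nm.AttentionProfile = field(default_factory=nm.AttentionProfile)
    population: nm.PopulationParams = field(default_factory=nm.PopulationParams)
    noise: bold_sim.NoiseParams = field(default_factory=bold_sim.NoiseParams)
    bias: bold_sim.LayerBias = field(default_factory=bold_sim.LayerBias)
    hrf: bold_sim.HRFParams = field(default_factory=bold_sim.HRFParams)
    design: DesignSpec = field(default_factory=DesignSpec)
    n_voxels: int = 2500
    preference_sign: int = 1

    def describe(self) -> dict:
        return {
            "name": self.name,
            "attention": list(self.attention.a),
            "sd_face": self.population.sd_face,
            "sd_house": self.population.sd_house,
            "subject_sd": self.population.subject_sd,
            "distribution_kind": self.population.distribution_kind,
            "sigma_p": self.noise.sigma_p,
            "sigma_t": self.noise.sigma_t,
            "layer_bias": list(self.bias.l_bias),
            "n_voxels": self.n_voxels,
            "tr": self.design.tr,
        }


def make_scenario(name: str = "selective", n_voxels: int = 2500, **overrides) -> Scenario:
    """Build one of the named scenarios, with optional field overrides."""
    kwargs: dict = {"name": name, "n_voxels": n_voxels}
    if name == "selective":
        pass
    elif name == "no_preference":
        kwargs["population"] = nm.PopulationParams(
            sd_face=0.7,
            sd_house=0.7,
            distribution_kind=nm.FOLDED_NORMAL,
            folded_mean=0.0,
            shared_subject_scale=True,
        )
    elif name == "high_noise":
        kwargs["noise"] = bold_sim.NoiseParams(sigma_p=20.0, sigma_t=30.0)
    elif name == "noiseless":
        kwargs["noise"] = bold_sim.NoiseParams(sigma_p=0.0, sigma_t=0.0)
    elif name != "custom":
        raise ValueError(f"unknown scenario {name!r}")
    kwargs.update(overrides)
    return Scenario(**kwargs)


@dataclass(frozen=True)
class IterationResult:
    """All metric profiles and scores for one simulated subject."""

    seed_entropy: int
    profiles: dict[str, met.LaminarProfile]
    scores: dict[str, tuple[float, float]]


def simulate_subject(
    scenario: Scenario, rng: np.random.Generator
) -> tuple[nm.VoxelPopulation, bold_sim.SimulatedSession, np.ndarray]:
    """Sample one subject and simulate the full eight-run session."""
    scale_face, scale_house = nm.sample_subject_scales(scenario.population, rng)
    vox = nm.sample_voxels(
        scenario.n_voxels,
        scale_face,
        scale_house,
        rng,
        distribution_kind=scenario.population.distribution_kind,
        folded_mean=scenario.population.folded_mean,
    )
    schedules = generate_schedules(scenario.design, rng)
    kernel = bold_sim.hrf_kernel(scenario.hrf, scenario.design.tr)
    session = bold_sim.simulate_session(
        vox, scenario.attention, schedules, scenario.bias, scenario.noise, kernel, rng
    )
    return vox, session, kernel


def _session_contrasts(
    session: bold_sim.SimulatedSession, kernel: np.ndarray, preference_sign: int
) -> tuple[glm.ContrastEstimates, list, list]:
    """Per-condition GLM fits for all runs and the averaged contrasts."""
    fits, dplus = [], []
    for run in session.runs:
        dm = glm.build_design_matrix(run.schedule, kernel, glm.PER_CONDITION)
        fit = glm.fit_glm(run.y, dm)
        fits.append((run.schedule, fit))
        if run.schedule.context == TASK_D_PLUS:
            dplus.append((run, dm, fit))
    contrasts = glm.contrast_estimates(fits, preference_sign)
    return contrasts, fits, dplus


def run_iteration(
    scenario: Scenario,
    seed: int | np.random.SeedSequence,
    metric_names: tuple[str, ...] | None = None,
) -> IterationResult:
    """One Monte-Carlo iteration (one simulated subject), fully seed-determined."""
    names = tuple(metric_names) if metric_names is not None else ALL_METRICS
    unknown = set(names) - set(ALL_METRICS)
    if unknown:
        raise ValueError(f"unknown metrics: {sorted(unknown)}")
    seed_seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(seed_seq)

    vox, session, kernel = simulate_subject(scenario, rng)
    sign = scenario.preference_sign
    contrasts, _, dplus = _session_contrasts(session, kernel, sign)
    layer = vox.layer

    profiles: dict[str, met.LaminarProfile] = {}
    if "raw" in names:
        profiles["raw"] = met.raw_contrast_profile(contrasts, layer)
    if "voxel_ratio" in names:
        profiles["voxel_ratio"] = met.metric_voxel_ratio(contrasts, layer)
    if "roi_ratio" in names:
        profiles["roi_ratio"] = met.metric_roi_ratio(contrasts, layer)
    if "deming" in names:
        profiles["deming"] = met.metric_deming(contrasts, layer)
    if "zscore" in names:
        profiles["zscore"] = met.metric_zscore(
            [(run.y, dm) for run, dm, _ in dplus], layer, glm.fit_glm, sign
        )
    if "l2norm" in names:
        profiles["l2norm"] = met.metric_l2norm([fit for _, _, fit in dplus], layer, sign)
    if "svm" in names:
        block_betas, block_labels = [], []
        for run, _, _ in dplus:
            dm_b = glm.build_design_matrix(run.schedule, kernel, glm.PER_BLOCK)
            fit_b = glm.fit_glm(run.y, dm_b)
            block_betas.append(fit_b.betas[:, : dm_b.n_task])
            block_labels.append(
                np.array(
                    [ATTENDED_CATEGORY[b.condition] for b in run.schedule.blocks],
                    dtype=object,
                )
            )
        profiles["svm"] = met.metric_svm(block_betas, block_labels, layer)
    if "ldc" in names:
        run_cons = [glm.run_contrast(fit, sign) for _, _, fit in dplus]
        run_res = [fit.residuals for _, _, fit in dplus]
        profiles["ldc"] = met.metric_ldc(run_cons, run_res, layer)

    scores = {name: met.contribution_scores(profile) for name, profile in profiles.items()}
    return IterationResult(
        seed_entropy=int(seed_seq.entropy), profiles=profiles, scores=scores
    )


@dataclass(frozen=True)
class MonteCarloSummary:
    """Distribution of each metric's profile and scores across iterations."""

    scenario: dict
    n_iterations: int
    profile_values: dict[str, np.ndarray]  # metric -> (n_iterations, 3)
    score_values: dict[str, np.ndarray]    # metric -> (n_iterations, 2) [bias, attention]

    def profile_quantiles(self, metric: str) -> np.ndarray:
        """(3 layers, 3 quantiles) array of [p25, median, p75]."""
        vals = self.profile_values[metric]
        return np.nanpercentile(vals, [25, 50, 75], axis=0).T

    def score_quantiles(self, metric: str) -> np.ndarray:
        """(2 scores, 3 quantiles) array for [bias, attention]."""
        vals = self.score_values[metric]
        return np.nanpercentile(vals, [25, 50, 75], axis=0).T

    def median_profile(self, metric: str) -> np.ndarray:
        return np.nanmedian(self.profile_values[metric], axis=0)

    def median_scores(self, metric: str) -> tuple[float, float]:
        bias, attention = np.nanmedian(self.score_values[metric], axis=0)
        return float(bias), float(attention)

    def layer_iqr(self, metric: str) -> np.ndarray:
        q = self.profile_quantiles(metric)
        return q[:, 2] - q[:, 0]

    def iterations_frame(self) -> pd.DataFrame:
        rows = []
        for metric, vals in self.profile_values.items():
            for i in range(vals.shape[0]):
                for j, layer in enumerate(LAYERS):
                    rows.append((i, metric, layer, vals[i, j]))
        return pd.DataFrame(rows, columns=["iteration", "metric", "layer", "value"])

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for metric in self.profile_values:
            q = self.profile_quantiles(metric)
            for j, layer in enumerate(LAYERS):
                rows.append((metric, layer, q[j, 1], q[j, 0], q[j, 2]))
            sq = self.score_quantiles(metric)
            for k, score in enumerate(("bias_score", "attention_score")):
                rows.append((metric, score, sq[k, 1], sq[k, 0], sq[k, 2]))
        return pd.DataFrame(rows, columns=["metric", "layer", "median", "p25", "p75"])

    def to_json(self) -> str:
        payload = {
            "scenario": self.scenario,
            "n_iterations": self.n_iterations,
            "metrics": {},
        }
        for metric in self.profile_values:
            q = self.profile_quantiles(metric)
            sq = self.score_quantiles(metric)
            payload["metrics"][metric] = {
                "layers": {
                    layer: {"p25": q[j, 0], "median": q[j, 1], "p75": q[j, 2]}
                    for j, layer in enumerate(LAYERS)
                },
                "bias_score": {"p25": sq[0, 0], "median": sq[0, 1], "p75": sq[0, 2]},
                "attention_score": {"p25": sq[1, 0], "median": sq[1, 1], "p75": sq[1, 2]},
            }
        return json.dumps(payload, indent=2, default=float)


def run_monte_carlo(
    scenario: Scenario,
    n_iterations: int = 200,
    base_seed: int | np.random.SeedSequence = 0,
    workers: int = 1,
    metric_names: tuple[str, ...] | None = None,
) -> MonteCarloSummary:
    """Repeat ``run_iteration`` over a deterministic seed ladder.

    Iteration seeds are spawned from ``base_seed`` up front, so the summary
    is identical regardless of ``workers`` or execution order.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    ss = base_seed if isinstance(base_seed, np.random.SeedSequence) else np.random.SeedSequence(base_seed)
    seeds = ss.spawn(n_iterations)

    if workers > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=workers)(
            delayed(run_iteration)(scenario, s, metric_names) for s in seeds
        )
    else:
        results = [run_iteration(scenario, s, metric_names) for s in seeds]

    names = list(results[0].profiles)
    profile_values = {
        m: np.array([r.profiles[m].values for r in results]) for m in names
    }
    score_values = {m: np.array([r.scores[m] for r in results]) for m in names}
    return MonteCarloSummary(
        scenario=scenario.describe(),
        n_iterations=n_iterations,
        profile_values=profile_values,
        score_values=score_values,
    )


def pooled_deming_slope(scenario: Scenario, seed: int | np.random.SeedSequence) -> float:
    """Deming slope of TaskD+ vs TaskD- contrasts pooled over all voxels.

    Single-subject figure-of-merit for how well the simulation matches the
    overall selectivity of real data (ignores the layer partition).
    """
    seed_seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(seed_seq)
    vox, session, kernel = simulate_subject(scenario, rng)
    contrasts, _, _ = _session_contrasts(session, kernel, scenario.preference_sign)
    return float(met.deming_slope(contrasts.taskdminus, contrasts.taskdplus))


#: scenario fields addressable in a parameter sweep grid
_SWEEP_FIELDS = {
    "sigma_p": lambda s, v: replace(s, noise=replace(s.noise, sigma_p=v)),
    "sigma_t": lambda s, v: replace(s, noise=replace(s.noise, sigma_t=v)),
    "sd_face": lambda s, v: replace(s, population=replace(s.population, sd_face=v)),
    "sd_house": lambda s, v: replace(s, population=replace(s.population, sd_house=v)),
    "attention": lambda s, v: replace(s, attention=nm.AttentionProfile(tuple(v))),
    "layer_bias": lambda s, v: replace(s, bias=bold_sim.LayerBias(tuple(v))),
    "n_voxels": lambda s, v: replace(s, n_voxels=int(v)),
}


def parameter_sweep(
    base: Scenario,
    grid: dict[str, list],
    n_iterations: int = 50,
    base_seed: int = 0,
    metric_names: tuple[str, ...] | None = None,
    workers: int = 1,
) -> pd.DataFrame:
    """Monte-Carlo summaries over a Cartesian parameter grid (long format)."""
    unknown = set(grid) - set(_SWEEP_FIELDS)
    if unknown:
        raise ValueError(f"unknown sweep fields: {sorted(unknown)}")
    keys = list(grid)
    cells = list(itertools.product(*(grid[k] for k in keys)))
    cell_seeds = np.random.SeedSequence(base_seed).spawn(len(cells))

    frames = []
    for cell, cell_seed in zip(cells, cell_seeds):
        scenario = base
        for key, value in zip(keys, cell):
            scenario = _SWEEP_FIELDS[key](scenario, value)
        summary = run_monte_carlo(
            scenario, n_iterations, cell_seed, workers=workers, metric_names=metric_names
        )
        frame = summary.summary_frame()
        for key, value in zip(keys, cell):
            frame[key] = [str(value)] * len(frame) if isinstance(value, (list, tuple)) else value
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def load_real_contrasts(path) -> tuple[glm.ContrastEstimates, np.ndarray]:
    """Read a tidy per-voxel contrast table (the real-data entry point).

    Expects columns voxel_id, layer, taskdplus, taskdminus with all three
    layer labels present.
    """
    table = pd.read_csv(path)
    required = {"voxel_id", "layer", "taskdplus", "taskdminus"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    labels = set(table["layer"])
    unknown = labels - set(LAYERS)
    if unknown:
        raise ValueError(f"unknown layer labels: {sorted(unknown)}")
    absent = set(LAYERS) - labels
    if absent:
        raise ValueError(f"layers missing from file: {sorted(absent)}")
    layer = np.array([LAYERS.index(l) for l in table["layer"]])
    contrasts = glm.ContrastEstimates(
        taskdplus=table["taskdplus"].to_numpy(dtype=float),
        taskdminus=table["taskdminus"].to_numpy(dtype=float),
    )
    return contrasts, layer


def univariate_profiles(
    contrasts: glm.ContrastEstimates, layer: np.ndarray
) -> dict[str, met.LaminarProfile]:
    """The contrast-table metrics (usable on real data): ratios, Deming, raw."""
    return {
        "raw": met.raw_contrast_profile(contrasts, layer),
        "voxel_ratio": met.metric_voxel_ratio(contrasts, layer),
        "roi_ratio": met.metric_roi_ratio(contrasts, layer),
        "deming": met.metric_deming(contrasts, layer),
    }
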