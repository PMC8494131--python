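"""Block-design experimental schedules on a TR-aligned time grid.

The paradigm alternates attention between face and house image streams at
two diagonal locations, giving four block conditions (H45, H135, F45, F135).
Runs come in two contexts: distractor-present (``TaskD+``, both categories on
screen) and distractor-absent (``TaskD-``, only the attended category shown).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("H45", "H135", "F45", "F135")
TASK_D_PLUS = "TaskD+"
TASK_D_MINUS = "TaskD-"

#: category attended in each condition
ATTENDED_CATEGORY = {"H45": "house", "H135": "house", "F45": "face", "F135": "face"}


@dataclass(frozen=True)
class DesignSpec:
    """Timing and run-structure parameters of the block design.

    Defaults reproduce the attention paradigm the simulator is matched to:
    20 blocks of 10 trials per run, four TaskD+ and four TaskD- runs,
    TR of 2.39 s.
    """

    tr: float = 2.39
    n_taskdplus_runs: int = 4
    n_taskdminus_runs: int = 4
    blocks_per_run: int = 20
    trials_per_block: int = 10
    cue_duration: float = 0.35
    post_cue_fixation: float = 0.55
    stim_duration: float = 0.95
    post_stim_fixation: float = 0.55
    rest_duration: float = 1.56
    conditions: tuple[str, ...] = CONDITIONS

    def __post_init__(self) -> None:
        durations = (
            self.tr,
            self.cue_duration,
            self.post_cue_fixation,
            self.stim_duration,
            self.post_stim_fixation,
            self.rest_duration,
        )
        if any(d <= 0 for d in durations):
            raise ValueError("all durations must be > 0")
        counts = (
            self.n_taskdplus_runs,
            self.n_taskdminus_runs,
            self.blocks_per_run,
            self.trials_per_block,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be > 0")
        if self.blocks_per_run % len(self.conditions) != 0:
            raise ValueError(
                f"blocks_per_run ({self.blocks_per_run}) must be divisible by "
                f"the number of conditions ({len(self.conditions)})"
            )

    @property
    def block_active_duration(self) -> float:
        """Cue + fixation + trials; the span covered by the design boxcar."""
        return (
            self.cue_duration
            + self.post_cue_fixation
            + self.trials_per_block * (self.stim_duration + self.post_stim_fixation)
        )

    @property
    def volumes_per_block(self) -> int:
        # Active + rest (17.46 s at defaults) is not a whole number of TRs;
        # the slot is rounded UP so every block onset stays on the TR grid.
        return math.ceil((self.block_active_duration + self.rest_duration) / self.tr)

    @property
    def volumes_per_run(self) -> int:
        return self.blocks_per_run * self.volumes_per_block

    @property
    def n_runs(self) -> int:
        return self.n_taskdplus_runs + self.n_taskdminus_runs


@dataclass(frozen=True)
class Block:
    condition: str
    attended_category: str
    onset: float
    duration: float


@dataclass(frozen=True)
class BlockSchedule:
    """One run's randomized block ordering placed on the TR grid."""

    run_id: str
    context: str
    blocks: tuple[Block, ...]
    n_volumes: int
    tr: float

    def onsets(self) -> np.ndarray:
        return np.array([b.onset for b in self.blocks])

    def to_events(self) -> pd.DataFrame:
        """BIDS-style events table (onset, duration, trial_type)."""
        return pd.DataFrame(
            {
                "onset": [b.onset for b in self.blocks],
                "duration": [b.duration for b in self.blocks],
                "trial_type": [b.condition for b in self.blocks],
            }
        )


def make_default_design() -> DesignSpec:
    """Return the paradigm's default :class:`DesignSpec`."""
    return DesignSpec()


def generate_schedules(
    design: DesignSpec, rng: np.random.Generator
) -> list[BlockSchedule]:
    """Generate one randomized :class:`BlockSchedule` per run.

    Conditions are balanced within each run (``blocks_per_run / 4`` blocks
    each) and independently shuffled per run.  TaskD+ runs precede TaskD-
    runs in the returned list; the contexts are analysed separately so the
    ordering carries no signal.
    """
    reps = design.blocks_per_run // len(design.conditions)
    base = np.repeat(np.array(design.conditions, dtype=object), reps)
    slot = design.volumes_per_block * design.tr

    contexts = [TASK_D_PLUS] * design.n_taskdplus_runs + [
        TASK_D_MINUS
    ] * design.n_taskdminus_runs
    schedules = []
    for i, context in enumerate(contexts):
        order = rng.permutation(base)
        blocks = tuple(
            Block(
                condition=cond,
                attended_category=ATTENDED_CATEGORY[cond],
                onset=j * slot,
                duration=design.block_active_duration,
            )
            for j, cond in enumerate(order)
        )
        schedules.append(
            BlockSchedule(
                run_id=f"run{i + 1:02d}",
                context=context,
                blocks=blocks,
                n_volumes=design.volumes_per_run,
                tr=design.tr,
            )
        )
    return schedules


def write_events_tsv(schedule: BlockSchedule, path) -> None:
    schedule.to_events().to_csv(path, sep="\t", index=False)
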