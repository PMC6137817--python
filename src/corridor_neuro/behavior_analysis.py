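"""Trial outcomes, success rate and the spatial modulation index (SMI).

The SMI measures how spatially targeted pre-reward licking is: the observed
success rate (early-rewarded trials / total trials) divided by the mean
success rate of a permutation null in which each trial's pre-reward licks
are re-placed uniformly at random along the pre-reward corridor.  Uniform
licking gives SMI near 1, few well-placed licks give SMI > 1, and frequent
off-target licking gives SMI < 1.

Convention (recorded in the report): the null re-places lick *positions*
uniformly on [0, default_reward_pos); post-reward (drinking) licks are
excluded from both the observed counts and the null, since they are caused
by the reward itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from corridor_neuro.synthetic_session import TaskGeometry, Trial

__all__ = [
    "BehaviorReport",
    "success_rate",
    "compute_smi",
    "learning_curve",
    "EXPERT_SUCCESS_THRESHOLD",
]

#: sessions are "expert" when success_rate strictly exceeds this fraction
EXPERT_SUCCESS_THRESHOLD = 0.75


@dataclass(frozen=True)
class BehaviorReport:
    """Behavior metrics for one session."""

    n_trials: int
    n_early: int
    success_rate: float
    smi: float  # NaN when undefined (no pre-reward licks anywhere)
    smi_defined: bool
    shuffled_mean_success: float
    n_permutations: int
    seed: int
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_trials": self.n_trials,
            "n_early": self.n_early,
            "success_rate": self.success_rate,
            "smi": None if not self.smi_defined else self.smi,
            "smi_defined": self.smi_defined,
            "shuffled_mean_success": self.shuffled_mean_success,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "metadata": self.metadata,
        }


def success_rate(trials: list[Trial]) -> float:
    """Fraction of early-rewarded trials."""
    if not trials:
        raise ValueError("no trials")
    n_early = sum(t.reward_type == "early" for t in trials)
    return n_early / len(trials)


def compute_smi(
    trials: list[Trial],
    geometry: TaskGeometry | None = None,
    n_permutations: int = 1000,
    seed: int = 0,
) -> BehaviorReport:
    """Spatial modulation index of licking with a uniform re-placement null.

    For each permutation, every trial keeps its pre-reward lick count but
    each lick is re-placed uniformly on [0, default_reward_pos); the trial
    "succeeds" if at least one re-placed lick falls in
    [reward_zone_onset, early_window_end).  SMI = observed success rate /
    mean permuted success rate.  Deterministic given ``seed``.  When no
    trial has any pre-reward lick the null success rate is 0 and the SMI is
    reported undefined (NaN, ``smi_defined=False``) rather than infinite.
    """
    if not trials:
        raise ValueError("no trials")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    geometry = geometry or TaskGeometry()
    rng = np.random.default_rng(seed)

    n_early = sum(t.reward_type == "early" for t in trials)
    observed = n_early / len(trials)
    lick_counts = np.array([len(t.pre_reward_licks()) for t in trials])

    lo = geometry.reward_zone_onset
    hi = geometry.early_window_end
    span = geometry.default_reward_pos

    # one uniform position draw per (permutation, lick); a permuted trial
    # succeeds when any of its re-placed licks lands in the reward window
    total_licks = int(lick_counts.sum())
    if total_licks == 0:
        shuffled_mean = 0.0
    else:
        draws = rng.uniform(0.0, span, size=(n_permutations, total_licks))
        hits = (draws >= lo) & (draws < hi)
        edges = np.concatenate([[0], np.cumsum(lick_counts)])
        trial_success = np.stack(
            [
                hits[:, edges[i] : edges[i + 1]].any(axis=1)
                if lick_counts[i]
                else np.zeros(n_permutations, dtype=bool)
                for i in range(len(trials))
            ],
            axis=1,
        )
        shuffled_mean = float(trial_success.mean(axis=1).mean())

    defined = shuffled_mean > 0
    smi = observed / shuffled_mean if defined else float("nan")

    return BehaviorReport(
        n_trials=len(trials),
        n_early=n_early,
        success_rate=observed,
        smi=smi,
        smi_defined=defined,
        shuffled_mean_success=shuffled_mean,
        n_permutations=n_permutations,
        seed=seed,
        metadata={
            "null": "uniform re-placement of pre-reward lick positions on "
            f"[0, {span}) cm; drinking licks excluded",
        },
    )


def learning_curve(sessions: list[BehaviorReport]) -> pd.DataFrame:
    """Ordered per-day table of success rate and SMI with the expert flag.

    The expert criterion is a success rate strictly greater than 75%.
    """
    rows = [
        {
            "day": i,
            "success_rate": rep.success_rate,
            "smi": rep.smi,
            "expert": rep.success_rate > EXPERT_SUCCESS_THRESHOLD,
        }
        for i, rep in enumerate(sessions)
    ]
    return pd.DataFrame(rows, columns=["day", "success_rate", "smi", "expert"])
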