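"""End-to-end experiment runner: simulate -> dF/F0 -> behavior -> classify -> decode.

A run config describes the task geometry, the planted neuron population,
the calcium model, a per-day schedule of lick policies (novice to expert),
and the analysis parameters.  ``run_experiment`` produces per-day reports
plus a cross-day summary (SMI trajectory, fraction of task-responsive
neurons, decoder accuracies, pre-reward lick histograms split by gain and
cue condition) and is fully reproducible from the config and seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from corridor_neuro.behavior_analysis import compute_smi, learning_curve
from corridor_neuro.neuron_classification import classify_neurons
from corridor_neuro.population_decoder import decode_cue_type, decode_outcome
from corridor_neuro.synthetic_session import (
    CalciumModel,
    LickPolicy,
    NeuronSpec,
    SessionBundle,
    TaskGeometry,
    Trial,
    simulate_session,
    write_session,
)
from corridor_neuro.trace_processing import compute_dff

__all__ = ["RunConfig", "run_experiment", "lick_histogram", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; message names the stage and the cause."""


@dataclass
class RunConfig:
    """Declarative description of a multi-day synthetic experiment."""

    geometry: TaskGeometry = field(default_factory=TaskGeometry)
    calcium: CalciumModel = field(default_factory=CalciumModel)
    neurons: list[NeuronSpec] = field(default_factory=list)
    days: list[dict] = field(default_factory=list)  # name, lick_policy, n_trials
    n_permutations: int = 1000
    alpha: float = 0.001
    window_cm: float = 20.0
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.days:
            raise ValueError("schedule must contain at least one day")

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        neurons: list[NeuronSpec] = []
        for item in cfg.get("neurons", []):
            item = dict(item)
            n = int(item.pop("n", 1))
            neurons.extend(NeuronSpec(**item) for _ in range(n))
        analysis = cfg.get("analysis", {})
        return cls(
            geometry=TaskGeometry(**cfg.get("geometry", {})),
            calcium=CalciumModel(**cfg.get("calcium", {})),
            neurons=neurons,
            days=list(cfg["days"]),
            n_permutations=int(analysis.get("permutations", 1000)),
            alpha=float(analysis.get("alpha", 0.001)),
            window_cm=float(analysis.get("window_cm", 20.0)),
            seed=int(cfg.get("seed", 0)),
            out_dir=cfg.get("out_dir"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def lick_histogram(
    trials: list[Trial],
    geometry: TaskGeometry,
    gain: float | None = None,
    cued: bool | None = None,
    bin_width_cm: float = 5.0,
    frame_of_reference: str = "virtual",
) -> tuple[np.ndarray, np.ndarray]:
    """Pre-reward lick histogram normalized to % of the maximal bin.

    Optionally restricted to trials with the given ``gain`` and/or ``cued``
    flag.  Returns (bin_centers, percent_of_max); both empty when the
    selected trials contain no pre-reward lick.
    """
    sel = [
        t
        for t in trials
        if (gain is None or t.gain == gain) and (cued is None or t.cued == cued)
    ]
    attr = {"virtual": "virtual_cm", "treadmill": "treadmill_cm"}[frame_of_reference]
    pos = np.array(
        [getattr(lk, attr) for t in sel for lk in t.pre_reward_licks()], dtype=float
    )
    if pos.size == 0:
        return np.empty(0), np.empty(0)
    length = geometry.corridor_length
    if frame_of_reference == "treadmill":
        length = geometry.corridor_length / geometry.low_gain
    edges = np.arange(0.0, length + bin_width_cm, bin_width_cm)
    counts, _ = np.histogram(pos, bins=edges)
    percent = 100.0 * counts / counts.max()
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, percent


def _day_seed(base: int, day_index: int) -> int:
    return int(base) * 1000 + day_index


def run_experiment(config: RunConfig, write_sessions: bool = False) -> dict:
    """Run the full pipeline for every scheduled day and summarize across days.

    Returns a dict with ``days`` (per-day behavior report, label counts and
    decoder results), ``learning_curve``, the Pearson correlation between
    the per-day fraction of task-responsive neurons and the SMI, and lick
    histograms split by gain and cue for the final day.  Deterministic
    given the config (all stage seeds derive from ``config.seed``).
    """
    day_results = []
    behavior_reports = []
    bundles: list[SessionBundle] = []
    for d, day in enumerate(config.days):
        seed = _day_seed(config.seed, d)
        name = day.get("name", f"day{d}")
        try:
            policy = LickPolicy(**day.get("lick_policy", {}))
            bundle = simulate_session(
                geometry=config.geometry,
                lick_policy=policy,
                neuron_specs=config.neurons,
                calcium=config.calcium,
                n_trials=int(day.get("n_trials", 40)),
                seed=seed,
            )
        except Exception as exc:
            raise StageError(f"simulate[{name}]: {exc}") from exc

        try:
            behavior = compute_smi(
                bundle.trials,
                config.geometry,
                n_permutations=config.n_permutations,
                seed=seed + 1,
            )
        except Exception as exc:
            raise StageError(f"behavior[{name}]: {exc}") from exc

        result: dict = {"name": name, "behavior": behavior.to_dict()}
        labels = None
        if config.neurons:
            try:
                dff = compute_dff(bundle.fluorescence, config.calcium.frame_rate)
                labels = classify_neurons(
                    bundle, dff, window_cm=config.window_cm,
                    alpha=config.alpha, seed=seed + 2,
                )
            except Exception as exc:
                raise StageError(f"classify[{name}]: {exc}") from exc
            result["fraction_task_responsive"] = float(labels["task_responsive"].mean())
            result["fraction_reward_location"] = float(
                (labels["reward_location"] == True).mean()  # noqa: E712 (None-safe)
            )
            result["fraction_gain_modulated"] = float(
                (labels["gain_modulated"] == True).mean()  # noqa: E712
            )
            result["category_counts"] = (
                labels.loc[labels.task_responsive, "category"].value_counts().to_dict()
            )
            for task_name, decoder in (
                ("outcome", decode_outcome),
                ("cue", decode_cue_type),
            ):
                try:
                    rep = decoder(bundle, dff, seed=seed + 3)
                    result[f"decoder_{task_name}"] = {
                        "accuracy": rep.accuracy,
                        "chance_level": rep.chance_level,
                    }
                except ValueError as exc:
                    result[f"decoder_{task_name}"] = {"skipped": str(exc)}

        behavior_reports.append(behavior)
        bundles.append(bundle)
        day_results.append(result)

        if write_sessions and config.out_dir:
            write_session(bundle, Path(config.out_dir) / f"session_{name}")
        if config.out_dir and labels is not None:
            out = Path(config.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            labels.to_csv(out / f"labels_{name}.csv", index=False)

    curve = learning_curve(behavior_reports)

    frac_vs_smi = float("nan")
    fracs = [r.get("fraction_task_responsive") for r in day_results]
    smis = [r["behavior"]["smi"] for r in day_results]
    ok = [
        i
        for i in range(len(fracs))
        if fracs[i] is not None and smis[i] is not None and np.isfinite(smis[i])
    ]
    if len(ok) >= 2 and np.std([fracs[i] for i in ok]) > 0 and np.std([smis[i] for i in ok]) > 0:
        frac_vs_smi = float(
            np.corrcoef([fracs[i] for i in ok], [smis[i] for i in ok])[0, 1]
        )

    final = bundles[-1]
    histograms = {}
    for cued_flag, cue_name in ((True, "cued"), (False, "uncued")):
        for g, g_name in ((1.0, "gain1"), (final.geometry.low_gain, "gain075")):
            centers, pct = lick_histogram(
                final.trials, final.geometry, gain=g, cued=cued_flag,
                frame_of_reference="virtual",
            )
            histograms[f"{cue_name}_{g_name}"] = {
                "bin_centers_cm": centers.tolist(),
                "percent_of_max": pct.tolist(),
            }

    return {
        "days": day_results,
        "learning_curve": curve.to_dict(orient="records"),
        "task_responsive_vs_smi_correlation": frac_vs_smi,
        "final_day_lick_histograms": histograms,
        "seed": config.seed,
    }
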