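"""Synthetic session-bundle generator for the virtual-corridor reward task.

A session bundle holds everything one recording day produces: per-frame
behavior (time, treadmill and virtual position, speed, licks), a trial table
with reward events, and a neurons x frames raw-fluorescence matrix produced
by passing planted event trains through a calcium-indicator forward model.
Every stochastic element is driven by a single seeded generator so bundles
are bit-reproducible.

Task geometry (defaults): the virtual corridor shows a grating that switches
to black walls at the reward-zone onset (80 cm).  A lick within the first
20 cm of the zone (80-100 cm) triggers an early reward at the lick position;
otherwise a default reward is delivered at 100 cm.  On uncued trials the
black walls are absent but the reward rule is unchanged.  On low-gain trials
the treadmill-to-corridor gain drops from 1 to 0.75, so 80 cm of running
advances the corridor by only 60 cm.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

__all__ = [
    "TaskGeometry",
    "LickPolicy",
    "NeuronSpec",
    "CalciumModel",
    "LickEvent",
    "Trial",
    "SessionBundle",
    "SessionIOError",
    "simulate_session",
    "trials_from_licks",
    "apply_reward_rule",
    "noise_free_rate",
    "write_session",
    "read_session",
]

NEURON_CATEGORIES = (
    "corridor",
    "locomotion",
    "lick",
    "reward_zone",
    "gain_anchored_treadmill",
    "gain_anchored_virtual",
    "grating_offset",
    "untuned",
)

LICK_MODES = ("novice", "expert", "uniform", "confined_off_target", "none")


@dataclass(frozen=True)
class TaskGeometry:
    """Corridor layout and trial-schedule periods.

    ``uncued_period`` / ``gain_period`` of 0 disable the respective
    manipulation; a period of 5 makes every fifth trial uncued / low gain.
    """

    corridor_length: float = 120.0
    reward_zone_onset: float = 80.0
    early_window_end: float = 100.0
    default_reward_pos: float = 100.0
    low_gain: float = 0.75
    uncued_period: int = 0
    gain_period: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.reward_zone_onset < self.early_window_end <= self.corridor_length):
            raise ValueError(
                "require 0 < reward_zone_onset < early_window_end <= corridor_length"
            )
        if self.default_reward_pos != self.early_window_end:
            raise ValueError("default_reward_pos must equal early_window_end")
        if not (0 < self.low_gain <= 1.0):
            raise ValueError("low_gain must be in (0, 1]")
        if self.uncued_period < 0 or self.gain_period < 0:
            raise ValueError("schedule periods must be >= 0")

    @property
    def early_window_width(self) -> float:
        return self.early_window_end - self.reward_zone_onset

    def trial_gain(self, index: int) -> float:
        if self.gain_period and (index % self.gain_period) == self.gain_period - 1:
            return self.low_gain
        return 1.0

    def trial_cued(self, index: int) -> bool:
        if self.uncued_period and (index % self.uncued_period) == self.uncued_period - 1:
            return False
        return True


@dataclass(frozen=True)
class LickPolicy:
    """Where and how often the simulated animal licks before the reward.

    ``rate`` is the expected number of pre-reward licks per cm of pre-reward
    corridor (lick counts are Poisson).  ``anchor`` selects the coordinate
    frame in which expert lick positions are drawn: ``virtual``,
    ``treadmill``, or ``cue_dependent`` (virtual on cued trials, treadmill on
    uncued trials -- the strategy expert animals exhibit under gain changes).
    """

    mode: str = "uniform"
    rate: float = 0.05
    target_center: float = 90.0
    target_sd: float = 4.0
    anchor: str = "virtual"

    def __post_init__(self) -> None:
        if self.mode not in LICK_MODES:
            raise ValueError(f"unknown lick-policy mode {self.mode!r}")
        if self.rate < 0:
            raise ValueError("lick rate must be >= 0")
        if self.mode == "expert" and self.target_sd <= 0:
            raise ValueError("expert mode requires target_sd > 0")
        if self.anchor not in ("virtual", "treadmill", "cue_dependent"):
            raise ValueError(f"unknown lick anchor {self.anchor!r}")


@dataclass(frozen=True)
class NeuronSpec:
    """Planted tuning of one synthetic neuron.

    ``anchor_pos`` (cm) and ``width_cm`` parameterize position-tuned
    categories; ``anchor_frame`` selects treadmill vs virtual coordinates for
    the two gain-anchored categories (other categories use their natural
    frame).  Rates are event rates in events/s.
    """

    category: str = "untuned"
    peak_rate: float = 5.0
    baseline_rate: float = 0.1
    anchor_pos: float = 85.0
    anchor_frame: str = "virtual"
    width_cm: float = 8.0

    def __post_init__(self) -> None:
        if self.category not in NEURON_CATEGORIES:
            raise ValueError(f"unknown neuron category {self.category!r}")
        if self.peak_rate < 0 or self.baseline_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.anchor_frame not in ("virtual", "treadmill"):
            raise ValueError(f"unknown anchor frame {self.anchor_frame!r}")


@dataclass(frozen=True)
class CalciumModel:
    """Forward model turning event trains into raw fluorescence.

    F(t) = baseline_F * (1 + amplitude_per_event * (events (*) exp kernel))
           + N(0, noise_sd).  Single-exponential decay, GCaMP6f-like default
    tau of 0.4 s; acquisition at 40 Hz.
    """

    frame_rate: float = 40.0
    decay_tau: float = 0.4
    amplitude_per_event: float = 0.2
    baseline_F: float = 100.0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.decay_tau <= 0:
            raise ValueError("decay_tau must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def kernel(self, n_frames: int | None = None) -> np.ndarray:
        """Exponential decay kernel sampled at the frame rate (peak 1)."""
        if n_frames is None:
            n_frames = max(1, int(np.ceil(8 * self.decay_tau * self.frame_rate)))
        t = np.arange(n_frames) / self.frame_rate
        return np.exp(-t / self.decay_tau)


@dataclass(frozen=True)
class LickEvent:
    time_s: float
    virtual_cm: float
    treadmill_cm: float
    post_reward: bool = False


@dataclass(frozen=True)
class Trial:
    """One corridor traversal: schedule flags, licks, and its reward event."""

    trial_id: int
    gain: float
    cued: bool
    reward_type: str  # "early" | "default"
    reward_virtual_pos: float
    reward_time: float
    licks: tuple[LickEvent, ...] = ()
    start_frame: int = 0
    end_frame: int = 0  # exclusive

    def pre_reward_licks(self) -> list[LickEvent]:
        return [lk for lk in self.licks if not lk.post_reward]


@dataclass
class SessionBundle:
    """All behavioral and neural time series for one simulated recording day.

    ``frames`` columns: time_s, trial_id, treadmill_cm, virtual_cm,
    speed_cm_s, lick.  Positions reset to 0 at each trial start and
    virtual_cm == gain * treadmill_cm within each trial.  ``fluorescence``
    is raw F, neurons x frames.
    """

    geometry: TaskGeometry
    calcium: CalciumModel
    frames: pd.DataFrame
    trials: list[Trial]
    fluorescence: np.ndarray
    ground_truth: list[NeuronSpec]
    rng_seed: int

    @property
    def n_neurons(self) -> int:
        return self.fluorescence.shape[0]

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def trial_frame_slice(self, trial: Trial) -> slice:
        return slice(trial.start_frame, trial.end_frame)

    def __eq__(self, other: object) -> bool:  # round-trip identity
        if not isinstance(other, SessionBundle):
            return NotImplemented
        return (
            self.geometry == other.geometry
            and self.calcium == other.calcium
            and self.trials == other.trials
            and self.ground_truth == other.ground_truth
            and self.rng_seed == other.rng_seed
            and self.frames.equals(other.frames)
            and self.fluorescence.shape == other.fluorescence.shape
            and bool(np.array_equal(self.fluorescence, other.fluorescence))
        )


class SessionIOError(ValueError):
    """Raised when a session bundle on disk violates a bundle invariant."""


# ---------------------------------------------------------------------------
# reward rule
# ---------------------------------------------------------------------------

def apply_reward_rule(
    lick_virtual_positions: np.ndarray, geometry: TaskGeometry
) -> tuple[str, float]:
    """Reward outcome for a trial given time-ordered pre-reward lick positions.

    The first lick whose virtual position falls in
    [reward_zone_onset, early_window_end) triggers an early reward at that
    position; with no such lick the default reward is delivered at
    ``default_reward_pos``.
    """
    pos = np.asarray(lick_virtual_positions, dtype=float)
    hit = (pos >= geometry.reward_zone_onset) & (pos < geometry.early_window_end)
    if hit.any():
        return "early", float(pos[np.argmax(hit)])
    return "default", float(geometry.default_reward_pos)


# ---------------------------------------------------------------------------
# lick generation
# ---------------------------------------------------------------------------

def _draw_lick_positions(
    policy: LickPolicy,
    geometry: TaskGeometry,
    gain: float,
    cued: bool,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw candidate pre-reward lick positions, returned as (virtual, treadmill).

    Positions are drawn in the policy's anchor frame and converted with the
    trial gain; draws outside [0, default_reward_pos) virtual are discarded.
    """
    if policy.mode == "none":
        return np.empty(0), np.empty(0)
    n = rng.poisson(policy.rate * geometry.default_reward_pos)
    if n == 0:
        return np.empty(0), np.empty(0)

    anchor = policy.anchor
    if anchor == "cue_dependent":
        anchor = "virtual" if cued else "treadmill"

    if policy.mode in ("uniform", "novice"):
        virtual = rng.uniform(0.0, geometry.default_reward_pos, size=n)
    elif policy.mode == "confined_off_target":
        hi = min(policy.target_center, geometry.reward_zone_onset)
        virtual = rng.uniform(0.0, hi, size=n)
    else:  # expert
        draws = rng.normal(policy.target_center, policy.target_sd, size=n)
        virtual = draws * gain if anchor == "treadmill" else draws

    keep = (virtual >= 0.0) & (virtual < geometry.default_reward_pos)
    virtual = np.sort(virtual[keep])
    return virtual, virtual / gain


def trials_from_licks(
    licks_per_trial: list[np.ndarray] | list[list[float]],
    geometry: TaskGeometry | None = None,
    gain: float = 1.0,
    cued: bool = True,
    assumed_speed: float = 15.0,
    truncate_at_reward: bool = True,
) -> list[Trial]:
    """Build a trial list from per-trial virtual lick positions (cm).

    Applies the reward rule exactly; lick times are synthesized from an
    assumed constant speed.  With ``truncate_at_reward`` (the default,
    mirroring simulated sessions) licks beyond the reward position are kept
    but flagged post-reward; with ``truncate_at_reward=False`` every listed
    lick counts as pre-reward, which is the construction behind the
    closed-form permutation-null oracle.  Convenient for behavior-level
    analyses that do not need frames or fluorescence.
    """
    geometry = geometry or TaskGeometry()
    trials: list[Trial] = []
    for i, raw in enumerate(licks_per_trial):
        pos = np.sort(np.asarray(raw, dtype=float))
        rtype, rpos = apply_reward_rule(pos, geometry)
        events = tuple(
            LickEvent(
                time_s=float(p / assumed_speed),
                virtual_cm=float(p),
                treadmill_cm=float(p / gain),
                post_reward=bool(truncate_at_reward and p > rpos),
            )
            for p in pos
        )
        trials.append(
            Trial(
                trial_id=i,
                gain=gain,
                cued=cued,
                reward_type=rtype,
                reward_virtual_pos=rpos,
                reward_time=float(rpos / assumed_speed),
                licks=events,
            )
        )
    return trials


# ---------------------------------------------------------------------------
# planted rate functions
# ---------------------------------------------------------------------------

def _gauss(x: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - center) / width) ** 2)


def noise_free_rate(
    spec: NeuronSpec,
    geometry: TaskGeometry,
    time_s: np.ndarray,
    treadmill_cm: np.ndarray,
    virtual_cm: np.ndarray,
    speed_cm_s: np.ndarray,
    cued: bool,
    lick_times: np.ndarray,
    typical_speed: float = 15.0,
) -> np.ndarray:
    """Planted event rate (events/s) over the frames of a single trial.

    Categories: ``corridor`` fires while the grating is visible (always on
    uncued trials, before the reward-zone onset on cued ones);
    ``grating_offset`` fires at the cued grating-to-black transition only;
    ``locomotion`` scales with running speed; ``lick`` bumps around each
    lick; ``reward_zone`` and the two gain-anchored categories are Gaussian
    bumps at ``anchor_pos`` in their respective coordinate frames.
    """
    base = np.full(time_s.shape, spec.baseline_rate, dtype=float)
    cat = spec.category
    if cat == "untuned":
        return base
    if cat == "corridor":
        grating = np.ones_like(virtual_cm, dtype=bool)
        if cued:
            grating &= virtual_cm < geometry.reward_zone_onset
        return base + spec.peak_rate * grating
    if cat == "grating_offset":
        if not cued:
            return base
        return base + spec.peak_rate * _gauss(
            virtual_cm, geometry.reward_zone_onset, 4.0
        )
    if cat == "locomotion":
        return base + spec.peak_rate * np.clip(speed_cm_s / typical_speed, 0, 2)
    if cat == "lick":
        rate = base.copy()
        for t in lick_times:
            rate += spec.peak_rate * _gauss(time_s, t, 0.1)
        return rate
    if cat == "reward_zone":
        return base + spec.peak_rate * _gauss(virtual_cm, spec.anchor_pos, spec.width_cm)
    if cat == "gain_anchored_treadmill":
        return base + spec.peak_rate * _gauss(
            treadmill_cm, spec.anchor_pos, spec.width_cm
        )
    if cat == "gain_anchored_virtual":
        return base + spec.peak_rate * _gauss(virtual_cm, spec.anchor_pos, spec.width_cm)
    raise ValueError(f"unknown neuron category {cat!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_session(
    geometry: TaskGeometry | None = None,
    lick_policy: LickPolicy | None = None,
    neuron_specs: list[NeuronSpec] | None = None,
    calcium: CalciumModel | None = None,
    n_trials: int = 40,
    seed: int = 0,
    speed_median: float = 15.0,
    speed_sigma: float = 0.4,
    reward_slowdown: float = 0.3,
    drinking_licks_mean: float = 6.0,
) -> SessionBundle:
    """Simulate one recording day and return the full session bundle.

    Per trial: mean speed is lognormal (median ``speed_median``, shape
    ``speed_sigma``) with smooth within-trial modulation and a slowdown dip
    of depth ``reward_slowdown`` approaching the reward zone; the trial ends
    when the virtual position reaches the corridor length.  Licks follow the
    policy, the reward rule is applied exactly, and a post-reward burst of
    drinking licks (Poisson mean ``drinking_licks_mean``) is appended and
    flagged.  Fluorescence is the calcium forward model applied to
    inhomogeneous-Poisson event trains from each neuron's planted rate.
    """
    if n_trials < 1:
        raise ValueError("invalid trial count")
    geometry = geometry or TaskGeometry()
    lick_policy = lick_policy or LickPolicy()
    calcium = calcium or CalciumModel()
    neuron_specs = list(neuron_specs or [])

    rng = np.random.default_rng(seed)
    dt = 1.0 / calcium.frame_rate

    frame_cols: dict[str, list[np.ndarray]] = {
        "time_s": [],
        "trial_id": [],
        "treadmill_cm": [],
        "virtual_cm": [],
        "speed_cm_s": [],
        "lick": [],
    }
    trials: list[Trial] = []
    rates_per_trial: list[np.ndarray] = []  # (n_neurons, n_trial_frames)

    t0 = 0.0
    frame_cursor = 0
    slow_center = geometry.reward_zone_onset + 0.5 * geometry.early_window_width
    for i in range(n_trials):
        gain = geometry.trial_gain(i)
        cued = geometry.trial_cued(i)

        mean_speed = speed_median * np.exp(speed_sigma * rng.standard_normal())
        mod_period = rng.uniform(3.0, 6.0)
        mod_phase = rng.uniform(0, 2 * np.pi)

        # integrate treadmill position frame by frame until the corridor ends
        tread = [0.0]
        speeds = []
        virtual = 0.0
        k = 0
        max_frames = int(600 * calcium.frame_rate)
        while virtual < geometry.corridor_length and k < max_frames:
            v = mean_speed * (1.0 + 0.25 * np.sin(2 * np.pi * k * dt / mod_period + mod_phase))
            v *= 1.0 - reward_slowdown * _gauss(np.array([virtual]), slow_center, 10.0)[0]
            v = max(v, 1.0)
            speeds.append(v)
            tread.append(tread[-1] + v * dt)
            virtual = gain * tread[-1]
            k += 1
        tread_arr = np.asarray(tread[:-1])
        speed_arr = np.asarray(speeds)
        virt_arr = gain * tread_arr
        nf = len(tread_arr)
        time_arr = t0 + dt * np.arange(nf)

        # licks: candidate pre-reward positions -> reward rule -> drinking burst
        lick_virt, lick_tread = _draw_lick_positions(lick_policy, geometry, gain, cued, rng)
        rtype, rpos = apply_reward_rule(lick_virt, geometry)
        keep = lick_virt <= rpos
        lick_virt, lick_tread = lick_virt[keep], lick_tread[keep]
        lick_times = np.interp(lick_virt, virt_arr, time_arr)
        reward_time = float(np.interp(rpos, virt_arr, time_arr))

        n_drink = rng.poisson(drinking_licks_mean)
        drink_times = reward_time + np.cumsum(rng.exponential(0.15, size=n_drink))
        drink_times = drink_times[drink_times < time_arr[-1]]
        drink_virt = np.interp(drink_times, time_arr, virt_arr)

        events = [
            LickEvent(float(t), float(p), float(p / gain), False)
            for t, p in zip(lick_times, lick_virt)
        ] + [
            LickEvent(float(t), float(p), float(p / gain), True)
            for t, p in zip(drink_times, drink_virt)
        ]
        events.sort(key=lambda e: e.time_s)

        all_lick_times = np.array([e.time_s for e in events])
        lick_flag = np.zeros(nf, dtype=bool)
        if all_lick_times.size:
            idx = np.clip(((all_lick_times - t0) / dt).astype(int), 0, nf - 1)
            lick_flag[idx] = True

        frame_cols["time_s"].append(time_arr)
        frame_cols["trial_id"].append(np.full(nf, i))
        frame_cols["treadmill_cm"].append(tread_arr)
        frame_cols["virtual_cm"].append(virt_arr)
        frame_cols["speed_cm_s"].append(speed_arr)
        frame_cols["lick"].append(lick_flag)

        trials.append(
            Trial(
                trial_id=i,
                gain=gain,
                cued=cued,
                reward_type=rtype,
                reward_virtual_pos=rpos,
                reward_time=reward_time,
                licks=tuple(events),
                start_frame=frame_cursor,
                end_frame=frame_cursor + nf,
            )
        )

        if neuron_specs:
            trial_rates = np.vstack(
                [
                    noise_free_rate(
                        spec,
                        geometry,
                        time_arr,
                        tread_arr,
                        virt_arr,
                        speed_arr,
                        cued,
                        all_lick_times,
                        typical_speed=speed_median,
                    )
                    for spec in neuron_specs
                ]
            )
            rates_per_trial.append(trial_rates)

        frame_cursor += nf
        t0 = time_arr[-1] + dt

    frames = pd.DataFrame({k: np.concatenate(v) for k, v in frame_cols.items()})
    frames["trial_id"] = frames["trial_id"].astype(int)

    n_frames_total = len(frames)
    if neuron_specs:
        rates = np.hstack(rates_per_trial)
        event_counts = rng.poisson(rates * dt)
        kernel = calcium.kernel()
        signal = fftconvolve(event_counts.astype(float), kernel[None, :], axes=1)[
            :, :n_frames_total
        ]
        fluor = calcium.baseline_F * (1.0 + calcium.amplitude_per_event * signal)
        if calcium.noise_sd > 0:
            fluor = fluor + rng.normal(0.0, calcium.noise_sd, size=fluor.shape)
    else:
        fluor = np.empty((0, n_frames_total))

    return SessionBundle(
        geometry=geometry,
        calcium=calcium,
        frames=frames,
        trials=trials,
        fluorescence=fluor,
        ground_truth=neuron_specs,
        rng_seed=seed,
    )


# ---------------------------------------------------------------------------
# disk format
# ---------------------------------------------------------------------------
# Layout under one directory: frames.csv, trials.csv, licks.csv,
# fluorescence.csv (neurons x frames), session.json (geometry, calcium,
# neuron specs, seed).  Floats are written with repr precision so that a
# round trip is bit-exact.

_FLOAT_FMT = "%.17g"


def write_session(bundle: SessionBundle, path: str | Path) -> Path:
    """Write a session bundle to ``path`` (a directory, created if needed)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    bundle.frames.to_csv(path / "frames.csv", index=False, float_format=_FLOAT_FMT)

    trial_rows = []
    lick_rows = []
    for tr in bundle.trials:
        trial_rows.append(
            {
                "trial_id": tr.trial_id,
                "gain": tr.gain,
                "cued": tr.cued,
                "reward_type": tr.reward_type,
                "reward_virtual_pos": tr.reward_virtual_pos,
                "reward_time": tr.reward_time,
                "start_frame": tr.start_frame,
                "end_frame": tr.end_frame,
            }
        )
        for lk in tr.licks:
            lick_rows.append(
                {
                    "trial_id": tr.trial_id,
                    "time_s": lk.time_s,
                    "virtual_cm": lk.virtual_cm,
                    "treadmill_cm": lk.treadmill_cm,
                    "post_reward": lk.post_reward,
                }
            )
    pd.DataFrame(trial_rows).to_csv(path / "trials.csv", index=False, float_format=_FLOAT_FMT)
    lick_cols = ["trial_id", "time_s", "virtual_cm", "treadmill_cm", "post_reward"]
    pd.DataFrame(lick_rows, columns=lick_cols).to_csv(
        path / "licks.csv", index=False, float_format=_FLOAT_FMT
    )

    np.savetxt(path / "fluorescence.csv", bundle.fluorescence, fmt=_FLOAT_FMT, delimiter=",")

    sidecar = {
        "geometry": dataclasses.asdict(bundle.geometry),
        "calcium": dataclasses.asdict(bundle.calcium),
        "neuron_specs": [dataclasses.asdict(s) for s in bundle.ground_truth],
        "rng_seed": bundle.rng_seed,
        "n_neurons": bundle.n_neurons,
        "n_frames": bundle.n_frames,
    }
    (path / "session.json").write_text(json.dumps(sidecar, indent=1))
    return path


def _validate_bundle(bundle: SessionBundle) -> None:
    """Check bundle invariants; raise SessionIOError naming the first failure."""
    t = bundle.frames["time_s"].to_numpy()
    if not np.all(np.diff(t) > 0):
        raise SessionIOError("frame times not strictly increasing")
    if bundle.fluorescence.ndim != 2 or (
        bundle.fluorescence.size and bundle.fluorescence.shape[1] != bundle.n_frames
    ):
        raise SessionIOError(
            "fluorescence matrix shape does not match the number of behavior frames"
        )
    geom = bundle.geometry
    for tr in bundle.trials:
        sl = bundle.trial_frame_slice(tr)
        tread = bundle.frames["treadmill_cm"].to_numpy()[sl]
        virt = bundle.frames["virtual_cm"].to_numpy()[sl]
        if not np.allclose(virt, tr.gain * tread, atol=1e-6):
            raise SessionIOError(
                f"trial {tr.trial_id}: virtual_cm != gain * treadmill_cm"
            )
        if tr.reward_type == "early":
            if not (geom.reward_zone_onset <= tr.reward_virtual_pos < geom.early_window_end):
                raise SessionIOError(
                    f"trial {tr.trial_id}: early reward outside "
                    f"[{geom.reward_zone_onset}, {geom.early_window_end}) cm"
                )
        elif tr.reward_type == "default":
            if tr.reward_virtual_pos != geom.default_reward_pos:
                raise SessionIOError(
                    f"trial {tr.trial_id}: default reward not at {geom.default_reward_pos} cm"
                )
        else:
            raise SessionIOError(f"trial {tr.trial_id}: unknown reward type {tr.reward_type!r}")


def read_session(path: str | Path) -> SessionBundle:
    """Read a session bundle written by :func:`write_session` and validate it."""
    path = Path(path)
    sidecar = json.loads((path / "session.json").read_text())
    geometry = TaskGeometry(**sidecar["geometry"])
    calcium = CalciumModel(**sidecar["calcium"])
    specs = [NeuronSpec(**s) for s in sidecar["neuron_specs"]]

    frames = pd.read_csv(path / "frames.csv", float_precision="round_trip")
    frames["lick"] = frames["lick"].astype(bool)

    licks = pd.read_csv(path / "licks.csv", float_precision="round_trip")
    licks_by_trial: dict[int, list[LickEvent]] = {}
    for row in licks.itertuples():
        licks_by_trial.setdefault(int(row.trial_id), []).append(
            LickEvent(
                time_s=float(row.time_s),
                virtual_cm=float(row.virtual_cm),
                treadmill_cm=float(row.treadmill_cm),
                post_reward=bool(row.post_reward),
            )
        )

    trials = []
    for row in pd.read_csv(path / "trials.csv", float_precision="round_trip").itertuples():
        trials.append(
            Trial(
                trial_id=int(row.trial_id),
                gain=float(row.gain),
                cued=bool(row.cued),
                reward_type=str(row.reward_type),
                reward_virtual_pos=float(row.reward_virtual_pos),
                reward_time=float(row.reward_time),
                licks=tuple(licks_by_trial.get(int(row.trial_id), [])),
                start_frame=int(row.start_frame),
                end_frame=int(row.end_frame),
            )
        )

    if sidecar["n_neurons"] == 0:
        fluor = np.empty((0, len(frames)))
    else:
        fluor = np.loadtxt(path / "fluorescence.csv", delimiter=",", ndmin=2)

    bundle = SessionBundle(
        geometry=geometry,
        calcium=calcium,
        frames=frames,
        trials=trials,
        fluorescence=fluor,
        ground_truth=specs,
        rng_seed=int(sidecar["rng_seed"]),
    )
    if sidecar["n_frames"] != len(frames):
        raise SessionIOError("frames.csv length does not match sidecar n_frames")
    _validate_bundle(bundle)
    return bundle
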