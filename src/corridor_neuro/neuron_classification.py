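"""Statistical classification of neurons from spatially binned dF/F0.

Task-responsive neurons show a significant change in mean activity before
(R_pre) versus after (R_post) the reward-zone onset across trials (paired
two-sided Wilcoxon signed rank, alpha 0.001, window 20 cm each side).
Responsive neurons are assigned a response category (corridor, locomotion,
lick, reward_zone) by a decision cascade; reward-location neurons must show
R_post > R_pre (one-sided) in both cued and uncued trials, which implicitly
excludes grating-offset responders; gain-modulated neurons must have their
trial-averaged peak within -5/+20 cm of the (expected) reward-zone onset in
physical treadmill coordinates under both gain conditions.

No multiple-testing correction is applied across neurons (per-neuron alpha).
Cascade thresholds are reconstructions, surfaced as keyword arguments and
recorded in the output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from corridor_neuro.synthetic_session import SessionBundle, TaskGeometry, Trial
from corridor_neuro.trace_processing import (
    DffTrace,
    SpatialResponse,
    bin_by_position,
    default_bin_edges,
    smoothed_speed,
    spatial_response,
)

__all__ = [
    "TaskResponse",
    "LickTestResult",
    "NeuronLabel",
    "classify_task_responsive",
    "assign_category",
    "lick_response_test",
    "classify_reward_location",
    "classify_gain_modulated",
    "distance_time_consistency",
    "classify_neurons",
]

DEFAULT_ALPHA = 0.001
DEFAULT_WINDOW_CM = 20.0
SPEED_CORR_THRESHOLD = 0.3
MIN_TRIALS = 6


@dataclass(frozen=True)
class TaskResponse:
    responsive: bool
    direction: str | None  # "increase" | "decrease"
    p_value: float
    r_pre_mean: float
    r_post_mean: float
    n_trials: int
    underpowered: bool = False


@dataclass(frozen=True)
class LickTestResult:
    mean_licking: float
    mean_non_licking: float
    p_value: float
    n_events: int
    skipped: bool = False
    notice: str = ""


@dataclass(frozen=True)
class NeuronLabel:
    """Classification record for one neuron (None = undetermined)."""

    neuron_id: int
    task_responsive: bool
    direction: str | None
    category: str
    reward_location: bool | None
    gain_modulated: bool | None
    p_pre_post: float
    p_cued: float
    p_uncued: float
    peak_gain1_cm: float
    peak_gain075_cm: float


def _window_trial_means(
    spatial: SpatialResponse, lo: float, hi: float
) -> np.ndarray:
    """Per-trial nanmean of the bins whose center falls in [lo, hi)."""
    centers = spatial.bin_centers
    mask = (centers >= lo) & (centers < hi)
    if not mask.any():
        return np.full(spatial.matrix.shape[0], np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(spatial.matrix[:, mask], axis=1)


def _signed_rank(
    post: np.ndarray, pre: np.ndarray, alternative: str = "two-sided"
) -> float:
    """Paired Wilcoxon signed-rank p-value; p = 1.0 when all pairs are tied."""
    ok = np.isfinite(post) & np.isfinite(pre)
    post, pre = post[ok], pre[ok]
    if post.size < 2 or np.all(post == pre):
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.wilcoxon(post, pre, alternative=alternative).pvalue)


def classify_task_responsive(
    spatial: SpatialResponse,
    geometry: TaskGeometry,
    window_cm: float = DEFAULT_WINDOW_CM,
    alpha: float = DEFAULT_ALPHA,
) -> TaskResponse:
    """Paired two-sided signed-rank test of R_pre vs R_post across trials.

    R_pre is the per-trial mean dF/F0 over [onset - window, onset), R_post
    over [onset, onset + window).  A neuron is task-responsive when
    p < alpha; the direction is the sign of the median paired difference.
    Sessions with fewer trials than the test can resolve at ``alpha`` are
    flagged ``underpowered``.
    """
    onset = geometry.reward_zone_onset
    r_pre = _window_trial_means(spatial, onset - window_cm, onset)
    r_post = _window_trial_means(spatial, onset, onset + window_cm)
    ok = np.isfinite(r_pre) & np.isfinite(r_post)
    n = int(ok.sum())
    # smallest n at which the exact signed-rank two-sided p can go below alpha
    underpowered = n < 2 or 2.0 * 0.5**n >= alpha
    p = _signed_rank(r_post[ok], r_pre[ok])
    diff_median = float(np.median(r_post[ok] - r_pre[ok])) if n else 0.0
    direction = None
    if diff_median > 0:
        direction = "increase"
    elif diff_median < 0:
        direction = "decrease"
    return TaskResponse(
        responsive=bool(p < alpha),
        direction=direction,
        p_value=p,
        r_pre_mean=float(np.nanmean(r_pre[ok])) if n else float("nan"),
        r_post_mean=float(np.nanmean(r_post[ok])) if n else float("nan"),
        n_trials=n,
        underpowered=underpowered,
    )


def _session_speed(bundle: SessionBundle) -> np.ndarray:
    """Per-frame running speed from treadmill position, computed per trial."""
    out = np.empty(bundle.n_frames)
    tread = bundle.frames["treadmill_cm"].to_numpy()
    for tr in bundle.trials:
        sl = bundle.trial_frame_slice(tr)
        out[sl] = smoothed_speed(tread[sl], bundle.calcium.frame_rate)
    return out


def assign_category(
    task: TaskResponse,
    dff: DffTrace,
    bundle: SessionBundle,
    neuron: int,
    spatial: SpatialResponse | None = None,
    speed_corr_threshold: float = SPEED_CORR_THRESHOLD,
    lick_alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
) -> tuple[str, bool]:
    """Response category of a task-responsive neuron; returns (category, ambiguous).

    Cascade: decrease-type neurons are ``locomotion`` when the session-wide
    Pearson correlation between dF/F0 and running speed reaches the
    threshold, otherwise ``corridor`` when mean activity on the grating
    section exceeds the reward-zone mean.  Increase-type neurons are
    ``lick`` when the corridor-lick test is significantly positive,
    otherwise ``reward_zone``.  The speed check runs first because a
    speed-coupled neuron also tends to satisfy the corridor contrast
    whenever the animal slows in the reward zone; satisfying both marks the
    call ambiguous.
    """
    if not task.responsive:
        return "other", False
    geom = bundle.geometry
    if spatial is None:
        spatial = spatial_response(dff, bundle, neuron)

    if task.direction == "decrease":
        speed = _session_speed(bundle)
        trace = dff.values[neuron]
        corr = float(np.corrcoef(trace, speed)[0, 1]) if trace.std() > 0 else 0.0
        grating = _window_trial_means(spatial, 0.0, geom.reward_zone_onset)
        zone = _window_trial_means(spatial, geom.reward_zone_onset, geom.early_window_end)
        corridor_like = bool(np.nanmean(grating) > np.nanmean(zone))
        if corr >= speed_corr_threshold:
            return "locomotion", corridor_like
        if corridor_like:
            return "corridor", False
        return "other", False

    res = lick_response_test(dff, bundle, neuron=neuron, seed=seed)
    if (
        not res.skipped
        and res.p_value < lick_alpha
        and res.mean_licking > res.mean_non_licking
    ):
        return "lick", False
    return "reward_zone", False


def lick_response_test(
    dff: DffTrace,
    bundle: SessionBundle,
    neuron: int | None = None,
    reward_zone_excluded: bool = True,
    window_s: float = 0.25,
    min_events: int = 10,
    seed: int = 0,
) -> LickTestResult:
    """Compare dF/F0 around corridor licks with duration-matched quiet periods.

    Qualifying licks are pre-reward licks outside the reward zone.  Each
    lick window (+-``window_s``) is paired with a random same-length window
    from the same trial that does not overlap any lick window; the pairs
    are compared with a Wilcoxon signed-rank test.  With ``neuron`` given
    the pairing is across events for that neuron; with ``neuron=None`` the
    per-event means are averaged per neuron and paired across neurons.
    """
    geom = bundle.geometry
    rng = np.random.default_rng(seed)
    time = bundle.frames["time_s"].to_numpy()
    frame_rate = bundle.calcium.frame_rate
    half = max(1, int(round(window_s * frame_rate)))

    lick_means: list[np.ndarray] = []
    quiet_means: list[np.ndarray] = []
    values = dff.values if neuron is None else dff.values[[neuron]]

    for tr in bundle.trials:
        all_lick_t = np.array([lk.time_s for lk in tr.licks])
        qual = [
            lk
            for lk in tr.pre_reward_licks()
            if not reward_zone_excluded or lk.virtual_cm < geom.reward_zone_onset
        ]
        lo, hi = tr.start_frame, tr.end_frame
        for lk in qual:
            c = int(np.searchsorted(time, lk.time_s))
            a, b = max(lo, c - half), min(hi, c + half + 1)
            if b <= a:
                continue
            # matched quiet window: same length, no overlap with any lick
            for _ in range(50):
                qa = int(rng.integers(lo, max(lo + 1, hi - (b - a))))
                qb = qa + (b - a)
                q_t = time[qa:qb]
                if all_lick_t.size and np.any(
                    np.min(np.abs(q_t[:, None] - all_lick_t[None, :]), axis=0) < window_s
                ):
                    continue
                lick_means.append(values[:, a:b].mean(axis=1))
                quiet_means.append(values[:, qa:qb].mean(axis=1))
                break

    if len(lick_means) < min_events:
        return LickTestResult(
            float("nan"), float("nan"), float("nan"), len(lick_means),
            skipped=True, notice="fewer than required corridor licks",
        )

    lick_arr = np.vstack(lick_means)  # events x neurons(sel)
    quiet_arr = np.vstack(quiet_means)
    if neuron is not None:
        a, b = lick_arr[:, 0], quiet_arr[:, 0]
    else:
        a, b = lick_arr.mean(axis=0), quiet_arr.mean(axis=0)
    p = _signed_rank(a, b)
    return LickTestResult(
        mean_licking=float(a.mean()),
        mean_non_licking=float(b.mean()),
        p_value=p,
        n_events=lick_arr.shape[0],
    )


def classify_reward_location(
    spatial_cued: SpatialResponse,
    spatial_uncued: SpatialResponse,
    geometry: TaskGeometry,
    window_cm: float = DEFAULT_WINDOW_CM,
    alpha: float = DEFAULT_ALPHA,
    min_trials: int = MIN_TRIALS,
) -> tuple[bool | None, float, float]:
    """Reward-location flag: R_post > R_pre (one-sided) in cued AND uncued trials.

    Returns (flag, p_cued, p_uncued); flag is None (undetermined) when the
    uncued set has fewer than ``min_trials`` trials.  Neurons responding
    only to the cued grating offset fail the uncued test, so they are
    excluded implicitly.
    """
    onset = geometry.reward_zone_onset
    ps = []
    for sp in (spatial_cued, spatial_uncued):
        pre = _window_trial_means(sp, onset - window_cm, onset)
        post = _window_trial_means(sp, onset, onset + window_cm)
        ps.append(_signed_rank(post, pre, alternative="greater"))
    p_cued, p_uncued = ps
    if spatial_uncued.matrix.shape[0] < min_trials:
        return None, p_cued, p_uncued
    return bool(p_cued < alpha and p_uncued < alpha), p_cued, p_uncued


def classify_gain_modulated(
    spatial_gain1: SpatialResponse,
    spatial_gain075: SpatialResponse,
    geometry: TaskGeometry,
    window: tuple[float, float] = (-5.0, 20.0),
) -> tuple[bool | None, float, float]:
    """Gain-modulation flag from trial-averaged peak positions.

    Both spatial responses must be in physical treadmill coordinates, where
    the trained reward-zone onset sits at the same running distance in both
    gain conditions.  The neuron is flagged when the trial-averaged profile
    peaks within [onset + window[0], onset + window[1]) cm of treadmill
    distance in the gain-1 trials AND within the same window around the
    *expected* onset in the gain-0.75 trials.  Returns
    (flag, peak_gain1_cm, peak_gain075_cm); flag is None when either
    profile is all-missing.  Depends only on argmax positions, so it is
    invariant to overall response scaling.
    """
    for sp in (spatial_gain1, spatial_gain075):
        if sp.frame_of_reference != "treadmill":
            raise ValueError("gain classification requires treadmill-frame responses")
    onset = geometry.reward_zone_onset
    lo, hi = onset + window[0], onset + window[1]

    peaks = []
    for sp in (spatial_gain1, spatial_gain075):
        avg = sp.trial_average()
        if not np.isfinite(avg).any():
            return None, float("nan"), float("nan")
        peaks.append(float(sp.bin_centers[np.nanargmax(avg)]))
    flag = all(lo <= pk < hi for pk in peaks)
    return bool(flag), peaks[0], peaks[1]


def distance_time_consistency(
    dff: DffTrace,
    bundle: SessionBundle,
    neuron: int,
    trials: list[Trial] | None = None,
    time_bin_s: float = 0.25,
    min_trials: int = 10,
) -> tuple[float, float]:
    """Coefficient of variation of the per-trial peak location, by alignment.

    Each trial's response profile is binned by corridor position and,
    separately, by time from trial onset; the across-trial CV (std/mean) of
    the peak location is returned for both alignments.  A position-locked
    neuron driven at variable running speeds has cv_distance < cv_time.
    """
    trials = trials if trials is not None else bundle.trials
    if len(trials) < min_trials:
        raise ValueError(f"need >= {min_trials} trials")
    geom = bundle.geometry
    pos_edges = default_bin_edges(geom)
    durations = []
    peak_pos, peak_time = [], []
    time = bundle.frames["time_s"].to_numpy()
    vpos = bundle.frames["virtual_cm"].to_numpy()
    for tr in trials:
        sl = bundle.trial_frame_slice(tr)
        vals = dff.values[neuron, sl]
        t = time[sl] - time[sl][0]
        durations.append(t[-1])
        prof_pos = bin_by_position(vals, vpos[sl], pos_edges)
        t_edges = np.arange(0.0, t[-1] + time_bin_s, time_bin_s)
        prof_time = bin_by_position(vals, t, t_edges)
        if np.isfinite(prof_pos).any():
            centers = 0.5 * (pos_edges[:-1] + pos_edges[1:])
            peak_pos.append(centers[np.nanargmax(prof_pos)])
        if np.isfinite(prof_time).any():
            centers = 0.5 * (t_edges[:-1] + t_edges[1:])
            peak_time.append(centers[np.nanargmax(prof_time)])
    durations = np.asarray(durations)
    if durations.std() / durations.mean() < 0.01:
        warnings.warn("near-constant trial durations; alignments degenerate", stacklevel=2)

    def _cv(x: list[float]) -> float:
        arr = np.asarray(x)
        return float(arr.std() / arr.mean()) if len(arr) and arr.mean() != 0 else float("nan")

    return _cv(peak_pos), _cv(peak_time)


def classify_neurons(
    bundle: SessionBundle,
    dff: DffTrace,
    window_cm: float = DEFAULT_WINDOW_CM,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
) -> pd.DataFrame:
    """Full per-neuron label table for a session.

    Columns: neuron_id, task_responsive, direction, category,
    reward_location, gain_modulated, p_pre_post, p_cued, p_uncued,
    peak_gain1_cm, peak_gain075_cm.  Reward-location and gain flags are NA
    when the session lacks the required trial types.  Gain classification
    uses uncued trials only, in treadmill coordinates.
    """
    geom = bundle.geometry
    cued = [t for t in bundle.trials if t.cued]
    uncued = [t for t in bundle.trials if not t.cued]
    unc_g1 = [t for t in uncued if t.gain == 1.0]
    unc_glow = [t for t in uncued if t.gain != 1.0]
    tread_edges = default_bin_edges(geom, frame_of_reference="treadmill")

    rows = []
    for n in range(bundle.n_neurons):
        sp_all = spatial_response(dff, bundle, n)
        task = classify_task_responsive(sp_all, geom, window_cm=window_cm, alpha=alpha)
        category, _ambig = assign_category(task, dff, bundle, n, spatial=sp_all, seed=seed)

        reward_loc: bool | None = None
        p_cued = p_uncued = float("nan")
        if cued and uncued:
            sp_c = spatial_response(dff, bundle, n, trials=cued)
            sp_u = spatial_response(dff, bundle, n, trials=uncued)
            reward_loc, p_cued, p_uncued = classify_reward_location(
                sp_c, sp_u, geom, window_cm=window_cm, alpha=alpha
            )

        gain_mod: bool | None = None
        pk1 = pk075 = float("nan")
        if unc_g1 and unc_glow:
            sp1 = spatial_response(
                dff, bundle, n, bin_edges=tread_edges,
                frame_of_reference="treadmill", trials=unc_g1,
            )
            sp075 = spatial_response(
                dff, bundle, n, bin_edges=tread_edges,
                frame_of_reference="treadmill", trials=unc_glow,
            )
            gain_mod, pk1, pk075 = classify_gain_modulated(sp1, sp075, geom)

        rows.append(
            {
                "neuron_id": n,
                "task_responsive": task.responsive,
                "direction": task.direction,
                "category": category,
                "reward_location": reward_loc,
                "gain_modulated": gain_mod,
                "p_pre_post": task.p_value,
                "p_cued": p_cued,
                "p_uncued": p_uncued,
                "peak_gain1_cm": pk1,
                "peak_gain075_cm": pk075,
            }
        )
    return pd.DataFrame(rows)
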