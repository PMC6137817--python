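"""dF/F0 extraction and spatial binning of activity along the corridor.

Baseline F0 is the 5th percentile of the low-pass-smoothed raw trace
(zero-phase FIR, default 1 Hz cutoff, 60th order); dF/F0 = (F - F0) / F0.
Input traces are assumed already neuropil-decontaminated -- no
decontamination is performed here.

Spatial binning averages dF/F0 over the frames whose (trial-relative)
position falls in each half-open bin [a, b); bins a trial never visits are
NaN, never zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import filtfilt, firwin

from corridor_neuro.synthetic_session import SessionBundle, TaskGeometry, Trial

__all__ = [
    "FilterSpec",
    "DffTrace",
    "SpatialResponse",
    "compute_dff",
    "bin_by_position",
    "window_mean",
    "spatial_response",
    "default_bin_edges",
    "smoothed_speed",
]


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase low-pass FIR used for baseline estimation."""

    cutoff_hz: float = 1.0
    order: int = 60
    zero_phase: bool = True

    def taps(self, frame_rate: float) -> np.ndarray:
        # Hamming-window design; numtaps = order + 1
        return firwin(self.order + 1, self.cutoff_hz, fs=frame_rate)


@dataclass(frozen=True)
class DffTrace:
    """Per-neuron dF/F0 trace with its baseline and filter provenance."""

    values: np.ndarray  # (n_neurons, n_frames)
    f0: np.ndarray  # (n_neurons,)
    filter_spec: FilterSpec

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]


@dataclass
class SpatialResponse:
    """Trials x position-bins matrix of mean dF/F0 for one neuron.

    ``matrix[t, b]`` is the mean dF/F0 over the frames of trial ``t`` whose
    position (in ``frame_of_reference`` coordinates, 0 at trial start) falls
    in ``[bin_edges[b], bin_edges[b+1])``; NaN where the trial has no frame
    in the bin.
    """

    matrix: np.ndarray
    bin_edges: np.ndarray
    frame_of_reference: str = "virtual"  # "virtual" | "treadmill"
    normalization: str = "raw"  # "raw" | "per_neuron_max"
    trial_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.bin_edges) > 0):
            raise ValueError("bin_edges must be strictly increasing")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def trial_average(self) -> np.ndarray:
        """Per-bin mean over trials, ignoring NaN bins."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.matrix, axis=0)

    def normalized(self) -> "SpatialResponse":
        peak = np.nanmax(np.abs(self.matrix))
        mat = self.matrix / peak if peak > 0 else self.matrix.copy()
        return SpatialResponse(
            mat, self.bin_edges, self.frame_of_reference, "per_neuron_max", self.trial_ids
        )

    def select(self, mask: np.ndarray) -> "SpatialResponse":
        """Restrict to a boolean subset of trials."""
        return SpatialResponse(
            self.matrix[mask],
            self.bin_edges,
            self.frame_of_reference,
            self.normalization,
            self.trial_ids[mask] if self.trial_ids.size else self.trial_ids,
        )


def compute_dff(
    raw: np.ndarray,
    frame_rate: float,
    filter_spec: FilterSpec | None = None,
) -> DffTrace:
    """dF/F0 from raw fluorescence (neurons x frames, or a single trace).

    The raw trace is low-pass filtered (forward-backward for zero phase),
    F0 is the per-neuron 5th percentile of the smoothed trace, and
    dF/F0 = (raw - F0) / F0.  Scale-invariant: multiplying raw F by any
    positive constant leaves the result unchanged.
    """
    filter_spec = filter_spec or FilterSpec()
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    if raw.shape[1] < filter_spec.order + 1:
        raise ValueError(
            f"trace shorter than filter: need > {filter_spec.order} frames"
        )
    if np.any(raw <= 0):
        raise ValueError("invalid fluorescence: raw F must be positive")

    taps = filter_spec.taps(frame_rate)
    padlen = min(3 * len(taps), raw.shape[1] - 1)
    if filter_spec.zero_phase:
        smoothed = filtfilt(taps, [1.0], raw, axis=1, padlen=padlen)
    else:
        smoothed = np.apply_along_axis(lambda x: np.convolve(x, taps, "same"), 1, raw)

    f0 = np.percentile(smoothed, 5, axis=1)
    if np.any(f0 <= 0):
        raise ValueError("invalid fluorescence: non-positive baseline F0")
    values = (raw - f0[:, None]) / f0[:, None]
    return DffTrace(values=values, f0=f0, filter_spec=filter_spec)


def _trial_positions(
    bundle: SessionBundle, trial: Trial, frame_of_reference: str
) -> np.ndarray:
    col = {"virtual": "virtual_cm", "treadmill": "treadmill_cm"}[frame_of_reference]
    return bundle.frames[col].to_numpy()[trial.start_frame : trial.end_frame]


def bin_by_position(
    dff_values: np.ndarray,
    positions: np.ndarray,
    bin_edges: np.ndarray,
) -> np.ndarray:
    """Per-bin mean of ``dff_values`` over frames, half-open bins [a, b).

    ``dff_values`` and ``positions`` are aligned per frame (one trial).
    Returns one value per bin; bins without any frame are NaN.
    """
    bin_edges = np.asarray(bin_edges, dtype=float)
    if not np.all(np.diff(bin_edges) > 0):
        raise ValueError("bin_edges must be strictly increasing")
    dff_values = np.asarray(dff_values, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if positions.size and (
        positions.min() >= bin_edges[-1] or positions.max() < bin_edges[0]
    ):
        warnings.warn("bins outside traversed range; all bins empty", stacklevel=2)
    idx = np.digitize(positions, bin_edges) - 1  # [a, b) bins
    n_bins = len(bin_edges) - 1
    out = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            out[b] = dff_values[sel].mean()
    return out


def window_mean(
    dff_values: np.ndarray,
    positions: np.ndarray,
    window: tuple[float, float],
) -> float:
    """Mean dF/F0 over the frames with position in [start, end); NaN if none."""
    start, end = window
    positions = np.asarray(positions, dtype=float)
    sel = (positions >= start) & (positions < end)
    if not sel.any():
        return float("nan")
    return float(np.asarray(dff_values, dtype=float)[sel].mean())


def default_bin_edges(
    geometry: TaskGeometry, width_cm: float = 2.0, frame_of_reference: str = "virtual"
) -> np.ndarray:
    """Half-open 2-cm bins spanning the corridor in the chosen frame.

    In treadmill coordinates the traversed range extends to
    corridor_length / low_gain on low-gain trials, so bins cover that range.
    """
    length = geometry.corridor_length
    if frame_of_reference == "treadmill":
        length = geometry.corridor_length / geometry.low_gain
    n = int(np.ceil(length / width_cm))
    return width_cm * np.arange(n + 1)


def spatial_response(
    dff: DffTrace,
    bundle: SessionBundle,
    neuron: int,
    bin_edges: np.ndarray | None = None,
    frame_of_reference: str = "virtual",
    trials: list[Trial] | None = None,
) -> SpatialResponse:
    """Trials x bins spatial response matrix for one neuron."""
    if bin_edges is None:
        bin_edges = default_bin_edges(bundle.geometry, frame_of_reference=frame_of_reference)
    trials = trials if trials is not None else bundle.trials
    rows = []
    for tr in trials:
        pos = _trial_positions(bundle, tr, frame_of_reference)
        vals = dff.values[neuron, tr.start_frame : tr.end_frame]
        rows.append(bin_by_position(vals, pos, bin_edges))
    return SpatialResponse(
        matrix=np.vstack(rows) if rows else np.empty((0, len(bin_edges) - 1)),
        bin_edges=np.asarray(bin_edges, dtype=float),
        frame_of_reference=frame_of_reference,
        trial_ids=np.array([t.trial_id for t in trials], dtype=int),
    )


def smoothed_speed(
    treadmill_cm: np.ndarray, frame_rate: float, smooth_s: float = 0.2
) -> np.ndarray:
    """Running speed from treadmill position: central difference, boxcar-smoothed."""
    speed = np.gradient(np.asarray(treadmill_cm, dtype=float)) * frame_rate
    n = max(1, int(round(smooth_s * frame_rate)))
    kernel = np.ones(n) / n
    return np.convolve(speed, kernel, mode="same")
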