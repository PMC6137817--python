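"""Template-matching population decoder for trial labels.

A held-out trial is assigned to the class whose template — the mean
population feature vector of that class, excluding the held-out trial —
has the highest Pearson correlation with the trial's own vector
(leave-one-out cross-validation).  Class imbalance is handled by repeated
random subsampling to the minority class size; the mean accuracy over
repeats is reported.  Correlation-based matching makes the decoder
invariant to per-neuron affine rescaling of the features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from corridor_neuro.synthetic_session import SessionBundle, Trial
from corridor_neuro.trace_processing import DffTrace, window_mean

__all__ = [
    "DecoderReport",
    "build_features",
    "template_decode",
    "decode_outcome",
    "decode_cue_type",
]

DEFAULT_WINDOW_CM = 20.0
DEFAULT_SUBSAMPLE_REPEATS = 100


@dataclass
class DecoderReport:
    """Cross-validated decoding result."""

    task: str  # "outcome" | "cue" | "custom"
    accuracy: float
    chance_level: float
    classes: list
    per_trial: pd.DataFrame  # trial_id, true_label, predicted_label, score per class
    cv_scheme: str = "leave-one-out"
    balance: str = ""
    seed: int = 0
    n_subsample_repeats: int = 0
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "accuracy": self.accuracy,
            "chance_level": self.chance_level,
            "classes": [str(c) for c in self.classes],
            "cv_scheme": self.cv_scheme,
            "balance": self.balance,
            "seed": self.seed,
            "n_subsample_repeats": self.n_subsample_repeats,
            "per_trial": self.per_trial.to_dict(orient="records"),
            "notes": self.notes,
        }


def build_features(
    dff: DffTrace,
    bundle: SessionBundle,
    trials: list[Trial] | None = None,
    window_cm: tuple[float, float] | None = None,
    frame_of_reference: str = "virtual",
    max_missing_frac: float = 0.5,
) -> tuple[np.ndarray, list[Trial], list[str]]:
    """Trials x neurons feature matrix of window-mean dF/F0.

    The default window is [onset - 20, onset + 20) cm around the
    reward-zone onset.  A neuron missing on a trial (no frames in the
    window) is imputed with that neuron's mean over the other trials;
    trials missing more than ``max_missing_frac`` of neurons are dropped.
    Returns (features, kept_trials, log_messages).
    """
    geom = bundle.geometry
    if window_cm is None:
        onset = geom.reward_zone_onset
        window_cm = (onset - DEFAULT_WINDOW_CM, onset + DEFAULT_WINDOW_CM)
    trials = trials if trials is not None else bundle.trials
    col = {"virtual": "virtual_cm", "treadmill": "treadmill_cm"}[frame_of_reference]
    pos_all = bundle.frames[col].to_numpy()

    feats = np.full((len(trials), dff.n_neurons), np.nan)
    for i, tr in enumerate(trials):
        sl = bundle.trial_frame_slice(tr)
        pos = pos_all[sl]
        for n in range(dff.n_neurons):
            feats[i, n] = window_mean(dff.values[n, sl], pos, window_cm)

    log: list[str] = []
    missing_frac = np.isnan(feats).mean(axis=1) if feats.size else np.zeros(len(trials))
    keep = missing_frac <= max_missing_frac
    dropped = [tr.trial_id for tr, k in zip(trials, keep) if not k]
    if dropped:
        warnings.warn(f"dropped trials with >50% missing neurons: {dropped}", stacklevel=2)
        log.append(f"dropped trials {dropped}")
    feats = feats[keep]
    kept_trials = [tr for tr, k in zip(trials, keep) if k]

    n_imputed = int(np.isnan(feats).sum())
    if n_imputed:
        col_means = np.nanmean(feats, axis=0)
        idx = np.where(np.isnan(feats))
        feats[idx] = col_means[idx[1]]
        log.append(f"imputed {n_imputed} missing entries with per-neuron session means")
    return feats, kept_trials, log


def _similarity(vec: np.ndarray, template: np.ndarray, notes: list) -> float:
    """Pearson correlation; negative Euclidean distance when degenerate."""
    if np.std(vec) == 0 or np.std(template) == 0 or vec.size < 2:
        if "euclidean-fallback" not in notes:
            notes.append("euclidean-fallback")
        return -float(np.linalg.norm(vec - template))
    return float(np.corrcoef(vec, template)[0, 1])


def _loo_predict(
    features: np.ndarray, labels: np.ndarray, classes: np.ndarray, notes: list
) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out template matching; returns (predictions, scores)."""
    n = len(labels)
    preds = np.empty(n, dtype=object)
    scores = np.full((n, len(classes)), np.nan)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        sims = []
        for j, cls in enumerate(classes):
            sel = mask & (labels == cls)
            template = features[sel].mean(axis=0)
            s = _similarity(features[i], template, notes)
            sims.append(s)
            scores[i, j] = s
        preds[i] = classes[int(np.argmax(sims))]
    return preds, scores


def template_decode(
    features: np.ndarray,
    labels: np.ndarray | list,
    trial_ids: np.ndarray | list | None = None,
    seed: int = 0,
    n_subsample_repeats: int = DEFAULT_SUBSAMPLE_REPEATS,
    task: str = "custom",
) -> DecoderReport:
    """Leave-one-out template-matching decoder.

    Templates are per-class mean feature vectors excluding the held-out
    trial; the predicted class maximizes Pearson correlation with the
    held-out vector.  With balanced classes the reported accuracy is the
    plain LOO accuracy; with imbalance it is the mean LOO accuracy over
    ``n_subsample_repeats`` random subsamples of the majority class down to
    the minority count (deterministic given ``seed``).  Per-trial
    predictions always come from the full LOO pass.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if features.ndim != 2 or len(labels) != features.shape[0]:
        raise ValueError("features must be trials x neurons aligned with labels")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 classes with >= 2 trials each")
    if trial_ids is None:
        trial_ids = np.arange(len(labels))
    trial_ids = np.asarray(trial_ids)
    rng = np.random.default_rng(seed)
    notes: list = []

    preds, scores = _loo_predict(features, labels, classes, notes)
    full_accuracy = float(np.mean(preds == labels))

    balanced = counts.min() == counts.max()
    if balanced:
        accuracy = full_accuracy
        balance = "classes balanced; no subsampling"
        n_rep = 0
    else:
        m = int(counts.min())
        accs = []
        for _ in range(n_subsample_repeats):
            idx = np.concatenate(
                [
                    rng.choice(np.where(labels == cls)[0], size=m, replace=False)
                    for cls in classes
                ]
            )
            sub_preds, _ = _loo_predict(features[idx], labels[idx], classes, notes)
            accs.append(np.mean(sub_preds == labels[idx]))
        accuracy = float(np.mean(accs))
        n_rep = n_subsample_repeats
        balance = f"subsampled majority class to {m} trials, {n_rep} repeats"

    per_trial = pd.DataFrame(
        {
            "trial_id": trial_ids,
            "true_label": labels,
            "predicted_label": preds,
            **{f"score_{cls}": scores[:, j] for j, cls in enumerate(classes)},
        }
    )
    return DecoderReport(
        task=task,
        accuracy=accuracy,
        chance_level=1.0 / len(classes),
        classes=list(classes),
        per_trial=per_trial,
        balance=balance,
        seed=seed,
        n_subsample_repeats=n_rep,
        notes=notes + ([] if balanced else [f"full-LOO accuracy {full_accuracy:.3f}"]),
    )


def decode_outcome(
    bundle: SessionBundle,
    dff: DffTrace,
    seed: int = 0,
    window_cm: tuple[float, float] | None = None,
) -> DecoderReport:
    """Decode trial outcome (early vs default reward) from population activity."""
    feats, kept, log = build_features(dff, bundle, window_cm=window_cm)
    labels = np.array([t.reward_type for t in kept])
    report = template_decode(
        feats, labels, trial_ids=[t.trial_id for t in kept], seed=seed, task="outcome"
    )
    report.notes.extend(log)
    return report


def decode_cue_type(
    bundle: SessionBundle,
    dff: DffTrace,
    seed: int = 0,
    window_cm: tuple[float, float] | None = None,
) -> DecoderReport:
    """Decode cued vs uncued from population activity on successful trials only."""
    successes = [t for t in bundle.trials if t.reward_type == "early"]
    n_unc = sum(not t.cued for t in successes)
    n_cue = sum(t.cued for t in successes)
    if n_unc < 2 or n_cue < 2:
        raise ValueError("insufficient trials: need >= 2 successful trials per cue type")
    feats, kept, log = build_features(dff, bundle, trials=successes, window_cm=window_cm)
    labels = np.array(["cued" if t.cued else "uncued" for t in kept])
    report = template_decode(
        feats, labels, trial_ids=[t.trial_id for t in kept], seed=seed, task="cue"
    )
    report.notes.extend(log)
    return report
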