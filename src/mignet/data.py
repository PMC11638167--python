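"""Trial containers, sliding-window segmentation, splits and EDF loading.

The decoding protocol operates on short windows cut from 4-s motor-imagery
trials: a window of 160 samples (1 s at 160 Hz) slid with a stride of 20
samples, giving 25 overlapping segments per trial. Train/test splits are
made at the *trial* level, stratified by class, **before** windowing, so
overlapping windows of one trial can never straddle the split.

The real-data path reads PhysioNet EEG Motor Movement/Imagery recordings
(EDF+, 64 channels at 160 Hz). Class coding follows the dataset convention:

    runs 4, 8, 12:  T1 -> 0 (left fist),  T2 -> 1 (right fist)
    runs 6, 10, 14: T1 -> 2 (both fists), T2 -> 3 (both feet)

Rest periods (T0), baseline runs and executed-movement runs are ignored.
Subjects 88, 89, 92, 100 and 104 carry known recording defects and are
excluded by default.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import signal

from .montage import MontageLayout

__all__ = [
    "Trial",
    "EEGSegment",
    "sliding_window",
    "split_trials",
    "bandpass_filter",
    "load_physionet_subject",
    "trials_from_raw",
    "segments_to_arrays",
    "save_segments",
    "load_segments",
    "EXCLUDED_SUBJECTS",
    "CLASS_NAMES",
]

logger = logging.getLogger(__name__)

#: subjects with incomplete recordings, excluded from analysis by default
EXCLUDED_SUBJECTS = frozenset({88, 89, 92, 100, 104})

CLASS_NAMES = ("left fist", "right fist", "both fists", "both feet")

# imagery runs -> (label for T1, label for T2)
_IMAGERY_RUNS = {4: (0, 1), 8: (0, 1), 12: (0, 1), 6: (2, 3), 10: (2, 3), 14: (2, 3)}


@dataclass(frozen=True)
class Trial:
    """One motor-imagery trial: C x L samples with a 4-class label."""

    data: np.ndarray  # (C, L)
    label: int
    subject_id: int
    trial_id: int

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError(f"trial data must be (C, L), got {data.shape}")
        if not np.all(np.isfinite(data)):
            raise ValueError("trial data contains non-finite values")
        if not 0 <= self.label < len(CLASS_NAMES):
            raise ValueError(f"label {self.label} out of range")
        object.__setattr__(self, "data", data)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class EEGSegment:
    """One windowed C x T fragment of a trial, inheriting its label."""

    data: np.ndarray  # (C, T)
    label: int
    subject_id: int
    trial_id: int
    window_index: int


def sliding_window(trial: Trial, window: int = 160, stride: int = 20) -> list[EEGSegment]:
    """Cut a trial into overlapping windows.

    Segment ``w`` covers samples ``[w*stride, w*stride + window)``; the
    number of segments is ``floor((L - window) / stride) + 1``.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    L = trial.n_samples
    if window > L:
        raise ValueError(f"window {window} exceeds trial length {L}")
    n = (L - window) // stride + 1
    return [
        EEGSegment(
            data=trial.data[:, w * stride : w * stride + window],
            label=trial.label,
            subject_id=trial.subject_id,
            trial_id=trial.trial_id,
            window_index=w,
        )
        for w in range(n)
    ]


def window_trials(trials: Iterable[Trial], window: int = 160, stride: int = 20) -> list[EEGSegment]:
    """Sliding-window every trial and concatenate the segments."""
    out: list[EEGSegment] = []
    for t in trials:
        out.extend(sliding_window(t, window, stride))
    return out


def split_trials(
    trials: Sequence[Trial], ratio: float = 0.8, seed: int = 0
) -> tuple[list[Trial], list[Trial]]:
    """Stratified trial-level train/test split (before any windowing).

    Per class, ``floor(ratio * n)`` trials go to the training set and the
    remainder to the test set; the assignment is a seeded permutation.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    rng = np.random.default_rng(seed)
    by_class: dict[int, list[int]] = {}
    for i, t in enumerate(trials):
        by_class.setdefault(t.label, []).append(i)
    for lbl, idx in by_class.items():
        if len(idx) < 2:
            raise ValueError(f"class {lbl} has fewer than 2 trials; cannot split")
    train_idx: list[int] = []
    test_idx: list[int] = []
    for lbl in sorted(by_class):
        idx = np.array(by_class[lbl])
        perm = rng.permutation(len(idx))
        n_train = int(np.floor(ratio * len(idx)))
        train_idx.extend(idx[perm[:n_train]])
        test_idx.extend(idx[perm[n_train:]])
    return [trials[i] for i in sorted(train_idx)], [trials[i] for i in sorted(test_idx)]


def bandpass_filter(
    data: np.ndarray, fs: float, low: float = 1.0, high: float = 35.0, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    PhysioNet recordings ship already filtered to 1-35 Hz, so this is *not*
    applied by the loader by default; it exists for raw custom inputs.
    """
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, data, axis=-1)


def _canonical_name(ch: str) -> str:
    return ch.replace(".", "").strip().upper()


def trials_from_raw(
    data: np.ndarray,
    sfreq: float,
    ch_names: Sequence[str],
    annotations: Sequence[tuple[float, str]],
    run_number: int,
    subject_id: int,
    montage: MontageLayout,
    trial_seconds: float = 4.0,
    expected_sfreq: float = 160.0,
    first_trial_id: int = 0,
) -> list[Trial]:
    """Cut labeled trials out of one continuous recording.

    ``annotations`` is a list of (onset seconds, code) with codes T0/T1/T2.
    Channels are reordered to the canonical montage order; trials extending
    past the end of the recording are dropped with a warning.
    """
    if sfreq != expected_sfreq:
        raise ValueError(f"expected sampling rate {expected_sfreq} Hz, got {sfreq}")
    if run_number not in _IMAGERY_RUNS:
        raise ValueError(f"run {run_number} is not an imagery run {sorted(_IMAGERY_RUNS)}")
    names = [_canonical_name(c) for c in ch_names]
    try:
        order = [names.index(n) for n in montage.names]
    except ValueError as exc:
        missing = [n for n in montage.names if n not in names]
        raise ValueError(f"recording is missing montage channels {missing}") from exc
    data = np.asarray(data, dtype=float)[order]
    L = int(round(trial_seconds * sfreq))
    t1_label, t2_label = _IMAGERY_RUNS[run_number]
    label_map = {"T1": t1_label, "T2": t2_label}
    trials: list[Trial] = []
    tid = first_trial_id
    for onset, code in annotations:
        code = code.strip()
        if code == "T0":
            continue
        if code not in label_map:
            raise ValueError(f"unknown annotation code {code!r}")
        start = int(round(onset * sfreq))
        if start + L > data.shape[1]:
            logger.warning("dropping truncated trial at %.2f s (run %d)", onset, run_number)
            continue
        trials.append(
            Trial(data=data[:, start : start + L], label=label_map[code],
                  subject_id=subject_id, trial_id=tid)
        )
        tid += 1
    return trials


_EDF_NAME_RE = re.compile(r"S(\d{3})R(\d{2})", re.IGNORECASE)


def load_physionet_subject(
    edf_paths: Sequence[str | Path],
    montage: MontageLayout,
    exclude_bad_subjects: bool = True,
    trial_seconds: float = 4.0,
) -> list[Trial]:
    """Load one subject's imagery trials from PhysioNet EDF files.

    File names must follow the PhysioNet convention ``S###R##.edf``; only
    the imagery runs (4, 8, 12 and 6, 10, 14) are used, others are skipped
    with a log message. Requires :mod:`mne` for EDF reading.
    """
    import mne

    trials: list[Trial] = []
    subject_seen: set[int] = set()
    for path in edf_paths:
        path = Path(path)
        m = _EDF_NAME_RE.search(path.stem)
        if not m:
            raise ValueError(f"{path.name}: cannot parse subject/run from file name")
        subject_id, run = int(m.group(1)), int(m.group(2))
        subject_seen.add(subject_id)
        if exclude_bad_subjects and subject_id in EXCLUDED_SUBJECTS:
            logger.info("skipping excluded subject %d (%s)", subject_id, path.name)
            continue
        if run not in _IMAGERY_RUNS:
            logger.info("skipping non-imagery run %d (%s)", run, path.name)
            continue
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        ann = [(float(on), str(desc)) for on, desc in zip(raw.annotations.onset,
                                                         raw.annotations.description)]
        trials.extend(
            trials_from_raw(
                raw.get_data(), float(raw.info["sfreq"]), raw.ch_names, ann,
                run_number=run, subject_id=subject_id, montage=montage,
                trial_seconds=trial_seconds, first_trial_id=len(trials),
            )
        )
    if len(subject_seen) > 1:
        logger.warning("files span multiple subjects: %s", sorted(subject_seen))
    return trials


# ---------------------------------------------------------------------------
# segment archive (NPZ interchange format)

def segments_to_arrays(segments: Sequence[EEGSegment]) -> dict[str, np.ndarray]:
    """Stack segments into arrays: data (N,C,T), labels/subject/trial/window (N,)."""
    return {
        "data": np.stack([s.data for s in segments]),
        "labels": np.array([s.label for s in segments], dtype=np.int64),
        "subject": np.array([s.subject_id for s in segments], dtype=np.int64),
        "trial": np.array([s.trial_id for s in segments], dtype=np.int64),
        "window": np.array([s.window_index for s in segments], dtype=np.int64),
    }


def save_segments(path: str | Path, segments: Sequence[EEGSegment]) -> None:
    np.savez(path, **segments_to_arrays(segments))


def save_trials(path: str | Path, trials: Sequence[Trial]) -> None:
    """Archive whole trials (data [N x C x L], labels, subject, trial)."""
    np.savez(
        path,
        data=np.stack([t.data for t in trials]),
        labels=np.array([t.label for t in trials], dtype=np.int64),
        subject=np.array([t.subject_id for t in trials], dtype=np.int64),
        trial=np.array([t.trial_id for t in trials], dtype=np.int64),
    )


def load_trials(path: str | Path) -> list[Trial]:
    with np.load(path) as z:
        return [
            Trial(data=z["data"][i], label=int(z["labels"][i]),
                  subject_id=int(z["subject"][i]), trial_id=int(z["trial"][i]))
            for i in range(z["data"].shape[0])
        ]


def load_segments(path: str | Path) -> list[EEGSegment]:
    with np.load(path) as z:
        return [
            EEGSegment(data=z["data"][i], label=int(z["labels"][i]),
                       subject_id=int(z["subject"][i]), trial_id=int(z["trial"][i]),
                       window_index=int(z["window"][i]))
            for i in range(z["data"].shape[0])
        ]
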