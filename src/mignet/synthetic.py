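"""Synthetic 4-class motor-imagery EEG with controllable separability.

Each trial is 1/f-shaped background noise plus a class-specific band-limited
oscillation whose amplitude falls off over the scalp as a Gaussian around a
class-specific focus electrode — a simplified event-related-synchronization
proxy for the sensorimotor rhythms that distinguish imagery of the left
fist, right fist, both fists and both feet. The default class foci follow
the motor homunculus (left fist -> right motor cortex C4, right fist -> C3,
both fists -> vertex CZ, both feet -> FCZ) and the default bands place the
single-fist classes in the mu rhythm and the bimanual classes in distinct
beta sub-bands.

Cross-subject variability is emulated by per-subject log-normal channel
gains and a per-subject shift of each class's center frequency; montage
geometry itself is fixed. The ``snr_db`` dial scales oscillation power
against total background power and is the single knob tests use to move
between chance-level and easily decodable data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .data import Trial
from .montage import MontageLayout

__all__ = ["SyntheticConfig", "generate_dataset", "class_separability", "bandpower_features"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults mirror the real-data recording protocol
    (64 channels, 160 Hz, 4-s trials, 4 classes)."""

    n_subjects: int = 1
    trials_per_class: int = 21  # 84 trials/subject -> 2100 windowed segments
    fs: float = 160.0
    trial_seconds: float = 4.0
    classes: int = 4
    class_centers: tuple[str, ...] = ("C4", "C3", "CZ", "FCZ")
    class_bands: tuple[tuple[float, float], ...] = ((8, 12), (8, 12), (15, 22), (25, 32))
    spatial_sigma: float = 0.5          # Gaussian falloff, montage length units
    snr_db: float = 0.0                 # oscillation power vs background power
    background_exponent: float = 0.7    # amplitude spectrum ~ 1/f^exponent
    subject_gain_sd: float = 0.2        # log-normal channel gain spread
    subject_freq_jitter_hz: float = 1.0 # per-subject class-band center shift
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trials_per_class < 1:
            raise ValueError("trials_per_class must be >= 1")
        if self.classes < 1 or self.classes > len(self.class_centers):
            raise ValueError("classes must be in [1, len(class_centers)]")
        for lo, hi in self.class_bands[: self.classes]:
            if not (0 < lo < hi < self.fs / 2):
                raise ValueError(f"band ({lo}, {hi}) outside (0, fs/2)")
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int], exponent: float) -> np.ndarray:
    """White noise shaped to a 1/f^exponent amplitude spectrum along axis -1."""
    C, L = shape
    white = rng.standard_normal((C, L))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(L)
    scale = np.ones_like(f)
    scale[1:] = f[1:] ** (-exponent)
    scale[0] = 0.0
    shaped = np.fft.irfft(spec * scale, n=L, axis=-1)
    return shaped / shaped.std()


def _band_oscillation(
    rng: np.random.Generator, L: int, fs: float, lo: float, hi: float, n_components: int = 3
) -> np.ndarray:
    """Unit-variance sum of random-phase sinusoids with frequencies in [lo, hi]."""
    t = np.arange(L) / fs
    freqs = rng.uniform(lo, hi, size=n_components)
    phases = rng.uniform(0, 2 * np.pi, size=n_components)
    x = np.sum([np.sin(2 * np.pi * f * t + p) for f, p in zip(freqs, phases)], axis=0)
    return x / x.std()


def generate_dataset(cfg: SyntheticConfig, layout: MontageLayout) -> list[Trial]:
    """Deterministic (given ``cfg.seed``) list of labeled synthetic trials."""
    for name in cfg.class_centers[: cfg.classes]:
        layout.index(name)  # raises for unknown electrodes
    rng = np.random.default_rng(cfg.seed)
    C = layout.n_channels
    L = int(round(cfg.fs * cfg.trial_seconds))
    # spatial weight of each class's oscillation over electrodes
    weights = np.empty((cfg.classes, C))
    for k in range(cfg.classes):
        center = layout.coords[layout.index(cfg.class_centers[k])]
        d2 = ((layout.coords - center) ** 2).sum(-1)
        weights[k] = np.exp(-d2 / (2 * cfg.spatial_sigma**2))
    snr_lin = 10.0 ** (cfg.snr_db / 10.0)

    trials: list[Trial] = []
    tid = 0
    for subj in range(cfg.n_subjects):
        gains = rng.lognormal(mean=0.0, sigma=cfg.subject_gain_sd, size=C)
        jitter = rng.normal(0.0, cfg.subject_freq_jitter_hz, size=cfg.classes)
        for k in range(cfg.classes):
            lo, hi = cfg.class_bands[k]
            lo = max(0.5, lo + jitter[k])
            hi = min(cfg.fs / 2 - 0.5, hi + jitter[k])
            for _ in range(cfg.trials_per_class):
                bg = _pink_noise(rng, (C, L), cfg.background_exponent)
                osc = _band_oscillation(rng, L, cfg.fs, lo, hi)
                sig = weights[k][:, None] * osc[None, :]
                # scale oscillation so total signal power / total noise power = snr
                p_sig = float((sig**2).mean())
                p_bg = float((bg**2).mean())
                amp = np.sqrt(snr_lin * p_bg / p_sig) if p_sig > 0 else 0.0
                x = gains[:, None] * (bg + amp * sig)
                trials.append(Trial(data=x, label=k, subject_id=subj, trial_id=tid))
                tid += 1
    return trials


def bandpower_features(
    trials: list[Trial],
    fs: float = 160.0,
    bands: tuple[tuple[float, float], ...] = ((4, 8), (8, 13), (13, 22), (22, 35)),
) -> np.ndarray:
    """Per-trial log band-power feature matrix (N, C * n_bands), Welch PSD."""
    feats = []
    for t in trials:
        f, pxx = signal.welch(t.data, fs=fs, nperseg=min(256, t.n_samples), axis=-1)
        cols = []
        for lo, hi in bands:
            sel = (f >= lo) & (f < hi)
            cols.append(np.log(pxx[:, sel].mean(axis=-1) + 1e-20))
        feats.append(np.concatenate(cols))
    return np.asarray(feats)


def class_separability(trials: list[Trial], fs: float = 160.0) -> float:
    """Fisher-style class-separability score of log band-power features.

    Pools the between- and within-class scatter of per-trial feature vectors
    into an ANOVA-style variance ratio and returns its excess over the
    chance expectation,

        score = max(F - 1, 0),  F = [tr(S_b)/(K-1)] / [tr(S_w)/(N-K)],

    so identically distributed classes score ~0 regardless of sample size,
    and the score grows with the oscillation SNR.
    """
    labels = np.array([t.label for t in trials])
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to measure separability")
    X = bandpower_features(trials, fs=fs)
    N, K = len(X), len(classes)
    grand = X.mean(axis=0)
    s_between = 0.0
    s_within = 0.0
    for k in classes:
        Xk = X[labels == k]
        mu = Xk.mean(axis=0)
        s_between += len(Xk) * float(((mu - grand) ** 2).sum())
        s_within += float(((Xk - mu) ** 2).sum())
    if s_within == 0:
        return np.inf
    f_stat = (s_between / (K - 1)) / (s_within / (N - K))
    return max(f_stat - 1.0, 0.0)
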