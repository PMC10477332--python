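"""Synthetic benchmarks: planted feature tables and two-class EEG epoch sets.

The table generator plants three kinds of columns -- label-relevant
(class-shifted Gaussians), redundant (noisy strictly monotone transforms of a
relevant parent, calibrated so their MIC with the parent exceeds the
redundancy threshold) and irrelevant (independent noise, verified to sit
below the irrelevance threshold) -- so the filter and wrapper stages can be
validated against known ground truth.

The EEG generator emulates a 19-channel, 256 Hz, two-class resting-state
acquisition: 58 subjects, 240 s each, cut into non-overlapping 10 s epochs
(1392 epochs in total). Each channel is a sum of five band-limited
oscillations (2/6/10/20/40 Hz) with a 1/f-like amplitude profile, random
phase per epoch, additive Gaussian noise, and class-dependent per-band
amplitude multipliers (by default the patient class has 1.5x alpha power).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import EpochSet, FeatureMatrix
from .mic import MicConfig, compute_mic

#: 10-20 montage labels of the emulated 19-channel cap.
CHANNELS_1020 = ["Fp1", "F3", "C3", "P3", "O1", "F7", "T3", "T5", "Fz",
                 "Fp2", "F4", "C4", "P4", "O2", "F8", "T4", "T6", "Cz", "Pz"]

BAND_CENTER_HZ = {"delta": 2.0, "theta": 6.0, "alpha": 10.0,
                  "beta": 20.0, "gamma": 40.0}

#: Roughly 1/f base amplitudes (arbitrary signal units).
BAND_AMPLITUDE = {"delta": 4.0, "theta": 3.0, "alpha": 2.5,
                  "beta": 1.5, "gamma": 0.8}


@dataclass(frozen=True)
class TableSpec:
    n_samples: int = 300
    n_relevant: int = 5
    n_redundant: int = 3
    n_irrelevant: int = 12
    class_gap: float = 2.0  # between-class mean shift, in SD units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_relevant < 1:
            raise ValueError("need at least one relevant feature")
        if min(self.n_redundant, self.n_irrelevant) < 0:
            raise ValueError("counts must be nonnegative")
        if self.class_gap <= 0:
            raise ValueError("class_gap must be positive")


@dataclass(frozen=True)
class TableTruth:
    """Ground-truth column roles of a generated table."""

    relevant: tuple[int, ...]
    redundant: tuple[tuple[int, int], ...]  # (clone index, parent index)
    irrelevant: tuple[int, ...]


# strictly increasing maps used to plant MIC-detectable (but nonlinearly
# related) redundant clones
_MONOTONE_TRANSFORMS = (
    lambda v: v ** 3,
    lambda v: np.exp(v / 2.0),
    lambda v: v + np.tanh(v),
)


def gen_feature_table(spec: TableSpec,
                      mic_config: MicConfig | None = None
                      ) -> tuple[FeatureMatrix, TableTruth]:
    """Generate a planted table; a pure function of the spec (and its seed).

    Redundant clones are verified at generation time to have MIC > 0.8 with
    their parent (noise is halved and the clone re-drawn until this holds;
    the noiseless monotone transform has MIC 1, so calibration terminates).
    Irrelevant columns are re-drawn until their MIC with the label is < 0.2.
    Labels are balanced.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    labels = np.zeros(n, dtype=int)
    labels[n // 2:] = 1

    cols: list[np.ndarray] = []
    names: list[str] = []

    relevant_idx = []
    for i in range(spec.n_relevant):
        col = rng.normal(loc=labels * spec.class_gap, scale=1.0, size=n)
        relevant_idx.append(len(cols))
        cols.append(col)
        names.append(f"rel{i}")

    redundant_pairs = []
    for i in range(spec.n_redundant):
        parent_pos = i % spec.n_relevant
        parent = cols[relevant_idx[parent_pos]]
        transform = _MONOTONE_TRANSFORMS[i % len(_MONOTONE_TRANSFORMS)]
        base = transform(parent)
        noise_scale = 0.05
        clone = None
        for _ in range(8):
            cand = base + noise_scale * np.std(base) * rng.standard_normal(n)
            if compute_mic(cand, parent, mic_config).value > 0.8:
                clone = cand
                break
            noise_scale /= 2.0
        if clone is None:
            clone = base  # noiseless monotone transform: MIC is exactly 1
            achieved = compute_mic(clone, parent, mic_config).value
            if achieved <= 0.8:
                raise RuntimeError(
                    f"redundancy calibration failed (achieved MIC {achieved:.3f})")
        redundant_pairs.append((len(cols), relevant_idx[parent_pos]))
        cols.append(clone)
        names.append(f"red{i}_of_rel{parent_pos}")

    irrelevant_idx = []
    y = labels.astype(float)
    for i in range(spec.n_irrelevant):
        col = None
        for _ in range(20):
            cand = rng.standard_normal(n)
            if compute_mic(cand, y, mic_config).value < 0.2:
                col = cand
                break
        if col is None:
            raise RuntimeError(
                "could not draw an independent column with label-MIC < 0.2")
        irrelevant_idx.append(len(cols))
        cols.append(col)
        names.append(f"irr{i}")

    F = FeatureMatrix(values=np.column_stack(cols), names=names, labels=labels)
    truth = TableTruth(relevant=tuple(relevant_idx),
                       redundant=tuple(redundant_pairs),
                       irrelevant=tuple(irrelevant_idx))
    return F, truth


@dataclass(frozen=True)
class EegSpec:
    n_subjects: int = 58
    duration_s: float = 240.0
    fs: float = 256.0
    n_channels: int = 19
    epoch_s: float = 10.0
    band_effects: dict = field(default_factory=lambda: {"alpha": 1.5})
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.n_channels <= 0 or self.n_subjects <= 0:
            raise ValueError("fs, n_channels and n_subjects must be positive")
        if self.epoch_s > self.duration_s:
            raise ValueError("epoch_s cannot exceed duration_s")


def gen_eeg_dataset(spec: EegSpec) -> EpochSet:
    """Two-class multichannel epoch set; a pure function of the spec.

    Subjects split evenly into class 0 (control) and class 1 (patient);
    ``band_effects`` multiplies the named bands' oscillation amplitudes for
    class 1. Recordings are truncated to whole epochs.
    """
    rng = np.random.default_rng(spec.seed)
    n_per_subject = int(spec.duration_s // spec.epoch_s)
    n_samples = int(round(spec.epoch_s * spec.fs))
    n_epochs = spec.n_subjects * n_per_subject
    t = np.arange(n_samples) / spec.fs

    if spec.n_channels == 19:
        channel_names = list(CHANNELS_1020)
    else:
        channel_names = [f"ch{i}" for i in range(spec.n_channels)]

    subject_class = (np.arange(spec.n_subjects) >=
                     spec.n_subjects // 2).astype(int)
    data = np.empty((n_epochs, spec.n_channels, n_samples))
    labels = np.empty(n_epochs, dtype=int)

    e = 0
    for s in range(spec.n_subjects):
        cls = int(subject_class[s])
        for _ in range(n_per_subject):
            epoch = rng.standard_normal(
                (spec.n_channels, n_samples)) * spec.noise_sd
            for band, f0 in BAND_CENTER_HZ.items():
                amp = BAND_AMPLITUDE[band]
                if cls == 1:
                    amp *= spec.band_effects.get(band, 1.0)
                phases = rng.uniform(0.0, 2.0 * np.pi, size=spec.n_channels)
                epoch += amp * np.sin(2.0 * np.pi * f0 * t[None, :]
                                      + phases[:, None])
            data[e] = epoch
            labels[e] = cls
            e += 1
    return EpochSet(data=data, fs=spec.fs, labels=labels,
                    channel_names=channel_names)
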