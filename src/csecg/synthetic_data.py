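"""Synthetic annotated ECG: records, segments and an imbalanced benchmark.

Each heartbeat is a sum of Gaussian waves (P, Q, R, S, T), with
class-conditional morphology:

========  ==========================================================
class     morphology
========  ==========================================================
N         canonical P-QRS-T
S         premature (shortened preceding RR), reduced/absent P wave
V         wide high-amplitude QRS, no P wave, discordant (negative) T
F         midpoint morphology between N and V
Q         randomised morphology (unclassifiable beats)
========  ==========================================================

Records add a sinusoidal baseline wander, a powerline sinusoid and white
noise, and carry MIT-BIH beat symbols (N/A/V/F/Q) so they round-trip
through :mod:`csecg.ecg_io`. Every generator is fully deterministic given
its seed, and ground-truth R and T fiducials are emitted analytically so
detection and segmentation close the loop without a reference database.

``imbalanced_benchmark`` produces a ~5,000-segment training set and a
~2,000-segment test set with the extreme class imbalance of the MIT-BIH
database (about 0.895 : 0.028 : 0.070 : 0.008 : 0.00015 over N:S:V:F:Q,
the Q class floor-clamped to two segments per split) and distinct
per-split "subject" morphology parameters to mimic inter-patient shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ecg_io import AAMI_CLASSES, BeatAnnotation, ECGRecord
from .segment import HALF_SEGMENT, SegmentDataset, rescale_interval

#: MIT-BIH symbol emitted for each synthetic AAMI class.
CLASS_SYMBOL = {"N": "N", "S": "A", "V": "V", "F": "F", "Q": "Q"}

#: MIT-BIH-like class proportions over N, S, V, F, Q.
IMBALANCED_PROPORTIONS = (0.8947, 0.0276, 0.0696, 0.0080, 0.00015)

# (amplitude mV, width s, offset s from the R peak) per wave
_WAVES_N = (
    (0.15, 0.025, -0.20),   # P
    (-0.10, 0.010, -0.040),  # Q
    (1.20, 0.012, 0.0),      # R
    (-0.25, 0.015, 0.035),   # S
    (0.35, 0.060, 0.30),     # T
)
_WAVES_V = (
    (0.0, 0.025, -0.20),     # no P
    (-0.15, 0.020, -0.060),
    (1.50, 0.040, 0.0),      # wide, tall QRS
    (-0.40, 0.030, 0.060),
    (-0.40, 0.070, 0.30),    # discordant T
)
_WAVES_S = (
    (0.05, 0.025, -0.16),    # reduced P
    (-0.10, 0.010, -0.040),
    (1.10, 0.012, 0.0),
    (-0.25, 0.015, 0.035),
    (0.30, 0.055, 0.28),
)
_WAVES_F = tuple(                      # midpoint of N and V
    ((a1 + a2) / 2, (w1 + w2) / 2, (o1 + o2) / 2)
    for (a1, w1, o1), (a2, w2, o2) in zip(_WAVES_N, _WAVES_V)
)
WAVE_TABLE: dict[str, tuple[tuple[float, float, float], ...]] = {
    "N": _WAVES_N, "S": _WAVES_S, "V": _WAVES_V, "F": _WAVES_F,
}

#: T-wave offset from R per class (the ground-truth T fiducial).
_T_OFFSET = {"N": 0.30, "S": 0.28, "V": 0.30, "F": 0.30, "Q": 0.30}


@dataclass(frozen=True)
class NoiseConfig:
    baseline_amp: float = 0.10      # mV
    baseline_hz: float = 0.25
    powerline_amp: float = 0.02     # mV
    powerline_hz: float = 60.0
    white_sigma: float = 0.01       # mV


@dataclass(frozen=True)
class SyntheticConfig:
    fs: float = 360.0
    duration_s: float = 60.0
    mean_hr_bpm: float = 75.0
    hr_jitter: float = 0.05         # RR coefficient of variation
    class_proportions: tuple[float, ...] = IMBALANCED_PROPORTIONS
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    seed: int = 0

    def validate(self) -> None:
        p = np.asarray(self.class_proportions, dtype=float)
        if p.size != len(AAMI_CLASSES) or np.any(p < 0):
            raise ValueError("class_proportions must be 5 nonnegative values")
        if not np.isclose(p.sum(), 1.0, atol=1e-3):
            raise ValueError("class_proportions must sum to 1")
        if self.fs <= 2 * self.noise.powerline_hz:
            raise ValueError("fs must exceed twice the powerline frequency")
        if 60.0 / self.mean_hr_bpm < 0.40:
            raise ValueError(
                "beats overlap: mean RR below 400 ms at this heart rate"
            )


@dataclass(frozen=True)
class GroundTruth:
    """Analytic per-beat fiducials emitted alongside a synthetic record."""

    r_indices: np.ndarray
    t_indices: np.ndarray
    labels: tuple[str, ...]        # AAMI classes, beat order


def _beat_waves(label: str, rng: np.random.Generator,
                subject: dict[str, float] | None = None):
    """Wave parameter tuples for one beat (Q beats are randomised)."""
    if label == "Q":
        n_waves = rng.integers(3, 7)
        return [
            (rng.uniform(-0.8, 1.2), rng.uniform(0.01, 0.08),
             rng.uniform(-0.30, 0.35))
            for _ in range(n_waves)
        ]
    amp_scale = subject.get("amp", 1.0) if subject else 1.0
    width_scale = subject.get("width", 1.0) if subject else 1.0
    return [(a * amp_scale, w * width_scale, o) for a, w, o in WAVE_TABLE[label]]


def _add_beat(signal: np.ndarray, fs: float, r_time: float,
              waves, jitter: np.ndarray | None = None) -> None:
    """Add one beat's Gaussian waves to the signal in place."""
    n = signal.size
    for k, (amp, width, offset) in enumerate(waves):
        if amp == 0.0:
            continue
        if jitter is not None:
            amp = amp * jitter[k]
        centre = r_time + offset
        lo = max(int((centre - 5 * width) * fs), 0)
        hi = min(int((centre + 5 * width) * fs) + 1, n)
        if lo >= hi:
            continue
        t = np.arange(lo, hi) / fs
        signal[lo:hi] += amp * np.exp(-0.5 * ((t - centre) / width) ** 2)


def synthesize_record(
    config: SyntheticConfig | None = None,
) -> tuple[ECGRecord, list[BeatAnnotation], GroundTruth]:
    """Generate one annotated record plus its analytic ground truth."""
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    n = int(round(config.duration_s * fs))
    signal = np.zeros(n)

    p = np.asarray(config.class_proportions, dtype=float)
    p = p / p.sum()
    mean_rr = 60.0 / config.mean_hr_bpm

    # beat schedule: premature (S) beats shorten the preceding RR interval
    r_times: list[float] = []
    labels: list[str] = []
    t = 0.5
    margin = mean_rr + 0.5
    while t < config.duration_s - margin:
        label = AAMI_CLASSES[rng.choice(len(AAMI_CLASSES), p=p)]
        rr = mean_rr * (1 + config.hr_jitter * rng.standard_normal())
        rr = max(rr, 0.4)
        if label == "S":
            rr *= 0.70          # premature atrial beat
        t += rr
        if t >= config.duration_s - 0.5:
            break
        r_times.append(t)
        labels.append(label)
    if len(r_times) < 2:
        raise ValueError("record too short to hold two beats")

    for r_time, label in zip(r_times, labels):
        waves = _beat_waves(label, rng)
        _add_beat(signal, fs, r_time, waves)

    noise = config.noise
    time_axis = np.arange(n) / fs
    if noise.baseline_amp:
        signal += noise.baseline_amp * np.sin(
            2 * np.pi * noise.baseline_hz * time_axis + rng.uniform(0, 2 * np.pi)
        )
    if noise.powerline_amp:
        signal += noise.powerline_amp * np.sin(
            2 * np.pi * noise.powerline_hz * time_axis + rng.uniform(0, 2 * np.pi)
        )
    if noise.white_sigma:
        signal += noise.white_sigma * rng.standard_normal(n)

    r_indices = np.array([int(round(rt * fs)) for rt in r_times])
    t_indices = np.array(
        [int(round((rt + _T_OFFSET[lb]) * fs)) for rt, lb in zip(r_times, labels)]
    )
    record = ECGRecord(
        record_id=f"synth{config.seed:03d}", fs=fs, samples=signal,
    )
    annotations = [
        BeatAnnotation(sample_index=int(i), symbol=CLASS_SYMBOL[lb])
        for i, lb in zip(r_indices, labels)
    ]
    truth = GroundTruth(
        r_indices=r_indices, t_indices=t_indices, labels=tuple(labels),
    )
    return record, annotations, truth


def _synthesize_one_segment(
    label: str, rng: np.random.Generator,
    subject: dict[str, float] | None = None,
    white_sigma: float = 0.01,
) -> np.ndarray:
    """One 400-sample two-interval segment for a beat of the given class.

    A three-beat context (N, N, target) is synthesised analytically and the
    two T-to-T intervals surrounding the target beat are rescaled to 200
    samples each — the same construction the segmentation stage performs,
    bypassing peak detection.
    """
    fs = 360.0
    rr1 = 0.80 * (1 + 0.05 * rng.standard_normal())
    rr2 = 0.80 * (1 + 0.05 * rng.standard_normal())
    if label == "S":
        rr2 *= 0.70
    r0, r1 = 0.5, 0.5 + rr1
    r2 = r1 + rr2
    duration = r2 + 0.8
    n = int(duration * fs)
    signal = np.zeros(n)
    for r_time, beat_label in ((r0, "N"), (r1, "N"), (r2, label)):
        waves = _beat_waves(beat_label, rng, subject)
        jitter = 1 + 0.05 * rng.standard_normal(len(waves))
        _add_beat(signal, fs, r_time, waves, jitter)
    if white_sigma:
        signal += white_sigma * rng.standard_normal(n)
    t0 = int((r0 + _T_OFFSET["N"]) * fs)
    t1 = int((r1 + _T_OFFSET["N"]) * fs)
    t2 = int((r2 + _T_OFFSET[label]) * fs)
    return np.concatenate([
        rescale_interval(signal[t0: t1 + 1], HALF_SEGMENT),
        rescale_interval(signal[t1: t2 + 1], HALF_SEGMENT),
    ])


def synthesize_segments(
    n_per_class: tuple[int, ...] | np.ndarray,
    seed: int = 0,
    subject: dict[str, float] | None = None,
    white_sigma: float = 0.01,
) -> SegmentDataset:
    """Labelled 400-sample segments with exactly the requested class counts."""
    n_per_class = np.asarray(n_per_class, dtype=int)
    if n_per_class.size != len(AAMI_CLASSES):
        raise ValueError("n_per_class must give one count per AAMI class")
    if np.any(n_per_class < 0) or n_per_class.sum() == 0:
        raise ValueError("class counts must be nonnegative and not all zero")
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for c, count in enumerate(n_per_class):
        label = AAMI_CLASSES[c]
        for _ in range(int(count)):
            rows.append(_synthesize_one_segment(label, rng, subject, white_sigma))
            labels.append(c)
    X = np.vstack(rows)
    y = np.array(labels, dtype=int)
    order = rng.permutation(len(y))          # shuffle class blocks together
    return SegmentDataset(
        X=X[order], y=y[order],
        record_ids=[f"synthseg{seed:03d}"] * len(y),
    )


def _split_counts(n_total: int, proportions: np.ndarray) -> np.ndarray:
    counts = np.maximum(np.round(n_total * proportions).astype(int), 0)
    counts[4] = max(counts[4], 2)            # Q floor-clamp
    counts[1:] = np.maximum(counts[1:], 1)
    counts[0] = max(n_total - counts[1:].sum(), 1)
    return counts


def imbalanced_benchmark(
    seed: int = 0, n_train: int = 5000, n_test: int = 2000
) -> tuple[SegmentDataset, SegmentDataset]:
    """Desk-scale train/test sets with MIT-BIH-like class imbalance.

    The two splits use disjoint "subject" morphology parameters (wave
    amplitudes and widths perturbed by about +/-15% in opposite directions)
    to mimic the inter-patient distribution shift.
    """
    rng = np.random.default_rng(seed)
    p = np.asarray(IMBALANCED_PROPORTIONS)
    p = p / p.sum()
    train_subject = {"amp": 1.0 + rng.uniform(0.05, 0.15),
                     "width": 1.0 - rng.uniform(0.05, 0.15)}
    test_subject = {"amp": 1.0 - rng.uniform(0.05, 0.15),
                    "width": 1.0 + rng.uniform(0.05, 0.15)}
    train = synthesize_segments(
        _split_counts(n_train, p), seed=seed * 2 + 1, subject=train_subject,
    )
    test = synthesize_segments(
        _split_counts(n_test, p), seed=seed * 2 + 2, subject=test_subject,
    )
    return train, test
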