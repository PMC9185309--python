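"""Beat segmentation: R-peak detection, T-point location, T-to-T segments.

The classifier's input unit is a pair of consecutive T-to-T intervals: for a
beat whose R peak falls in the interval (T[k-1], T[k]], the interval ending
at T[k-1] and the interval ending at T[k] are each rescaled to 200 samples
by linear interpolation and concatenated into one 400-sample vector. Beats
without a complete preceding interval (the first one or two beats of a
record) are dropped and counted.

R peaks are found with the Pan–Tompkins algorithm: 5–15 Hz band-pass,
five-point derivative, squaring, 150 ms moving-window integration, and dual
adaptive thresholds with a 200 ms refractory period and the 360 ms T-wave
discrimination rule. The T point of each beat is the sample of maximum
absolute amplitude in the window from 80 ms after the R peak to
min(400 ms, 70% of the current RR interval) — the absolute value handles
inverted T waves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as _signal

from .ecg_io import AAMI_CLASSES, AAMI_INDEX, BeatAnnotation, ECGRecord

logger = logging.getLogger(__name__)

SEGMENT_LENGTH = 400          # two concatenated 200-sample T-to-T intervals
HALF_SEGMENT = 200

# Pan-Tompkins constants (seconds)
_BANDPASS_HZ = (5.0, 15.0)
_INTEGRATION_S = 0.150
_REFRACTORY_S = 0.200
_TWAVE_WINDOW_S = 0.360

# T-search window relative to the R peak
_T_MIN_OFFSET_S = 0.080
_T_MAX_OFFSET_S = 0.400
_T_MAX_RR_FRACTION = 0.7


@dataclass(frozen=True)
class BeatSegment:
    """One 400-sample training vector with its AAMI label and provenance."""

    values: np.ndarray
    label: str
    record_id: str
    beat_index: int

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (SEGMENT_LENGTH,):
            raise ValueError(
                f"segment must have exactly {SEGMENT_LENGTH} samples, "
                f"got shape {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("segment contains non-finite values")
        if self.label not in AAMI_CLASSES:
            raise ValueError(f"unknown AAMI class {self.label!r}")
        object.__setattr__(self, "values", values)


@dataclass
class SegmentDataset:
    """A labelled collection of beat segments (columnar storage).

    ``X`` is an ``(n, 400)`` float matrix, ``y`` the integer AAMI labels in
    :data:`~csecg.ecg_io.AAMI_CLASSES` order.
    """

    X: np.ndarray
    y: np.ndarray
    record_ids: list[str] = field(default_factory=list)
    beat_indices: np.ndarray | None = None
    dropped: int = 0

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float).reshape(-1, SEGMENT_LENGTH)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y disagree on the number of segments")
        if not self.record_ids:
            self.record_ids = [""] * len(self.y)
        if self.beat_indices is None:
            self.beat_indices = np.arange(len(self.y))
        self.beat_indices = np.asarray(self.beat_indices, dtype=int)

    def __len__(self) -> int:
        return int(self.y.shape[0])

    def __getitem__(self, i: int) -> BeatSegment:
        return BeatSegment(
            values=self.X[i],
            label=AAMI_CLASSES[self.y[i]],
            record_id=self.record_ids[i],
            beat_index=int(self.beat_indices[i]),
        )

    @property
    def class_counts(self) -> np.ndarray:
        """Per-class segment counts in AAMI class order."""
        return np.bincount(self.y, minlength=len(AAMI_CLASSES))

    def subset(self, idx: np.ndarray) -> "SegmentDataset":
        idx = np.asarray(idx)
        return SegmentDataset(
            X=self.X[idx],
            y=self.y[idx],
            record_ids=[self.record_ids[i] for i in idx],
            beat_indices=self.beat_indices[idx],
        )

    @staticmethod
    def concatenate(parts: list["SegmentDataset"]) -> "SegmentDataset":
        return SegmentDataset(
            X=np.concatenate([p.X for p in parts]),
            y=np.concatenate([p.y for p in parts]),
            record_ids=[r for p in parts for r in p.record_ids],
            beat_indices=np.concatenate([p.beat_indices for p in parts]),
            dropped=sum(p.dropped for p in parts),
        )

    # -- persistence (CSV: label,record_id,beat_index,v0..v399) ------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        header = "label,record_id,beat_index," + ",".join(
            f"v{i}" for i in range(SEGMENT_LENGTH)
        )
        with open(path, "w") as fh:
            fh.write(header + "\n")
            for i in range(len(self)):
                values = ",".join(f"{v:.8g}" for v in self.X[i])
                fh.write(
                    f"{AAMI_CLASSES[self.y[i]]},{self.record_ids[i]},"
                    f"{int(self.beat_indices[i])},{values}\n"
                )

    @staticmethod
    def load(path: str | Path) -> "SegmentDataset":
        labels: list[int] = []
        record_ids: list[str] = []
        beat_indices: list[int] = []
        rows: list[np.ndarray] = []
        with open(path) as fh:
            next(fh)  # header
            for line in fh:
                label, record_id, beat_index, rest = line.split(",", 3)
                labels.append(AAMI_INDEX[label])
                record_ids.append(record_id)
                beat_indices.append(int(beat_index))
                rows.append(np.fromstring(rest, sep=","))
        X = np.vstack(rows) if rows else np.empty((0, SEGMENT_LENGTH))
        return SegmentDataset(
            X=X, y=np.array(labels, dtype=int),
            record_ids=record_ids, beat_indices=np.array(beat_indices, int),
        )


# ---------------------------------------------------------------------------
# Pan-Tompkins R-peak detection
# ---------------------------------------------------------------------------

def detect_r_peaks(samples: np.ndarray, fs: float) -> np.ndarray:
    """Detect R-peak sample indices with the Pan–Tompkins algorithm.

    Returns strictly increasing indices, no two closer than the 200 ms
    refractory period, each aligned to the local extremum of the band-passed
    signal. Records shorter than the 2 s initialisation window are an error.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2 * fs:
        raise ValueError("record shorter than the 2 s detector initialisation")

    band = _bandpass(samples, fs)
    # five-point derivative, squaring, moving-window integration
    deriv = np.convolve(band, np.array([1, 2, 0, -2, -1]) * fs / 8.0, "same")
    squared = deriv**2
    win = max(int(round(_INTEGRATION_S * fs)), 1)
    mwi = np.convolve(squared, np.ones(win) / win, "same")

    refractory = int(round(_REFRACTORY_S * fs))
    candidates, _ = _signal.find_peaks(mwi, distance=refractory)
    if candidates.size == 0:
        return np.array([], dtype=int)

    # dual adaptive thresholds initialised from the first 2 s
    init = mwi[: int(2 * fs)]
    spk = 0.25 * float(init.max())
    npk = 0.5 * float(init.mean())
    accepted: list[int] = []
    slope_at: dict[int, float] = {}
    for c in candidates:
        threshold = npk + 0.25 * (spk - npk)
        peak = float(mwi[c])
        is_signal = peak > threshold
        if is_signal and accepted:
            since_last = c - accepted[-1]
            if since_last < int(_TWAVE_WINDOW_S * fs):
                # T-wave discrimination: reject if the upslope is less than
                # half of the previous accepted peak's upslope
                slope = _max_slope(deriv, c, win)
                if slope < 0.5 * slope_at[accepted[-1]]:
                    is_signal = False
        if is_signal:
            accepted.append(int(c))
            slope_at[int(c)] = _max_slope(deriv, c, win)
            spk = 0.125 * peak + 0.875 * spk
        else:
            npk = 0.125 * peak + 0.875 * npk

    refined = _refine_to_signal(band, np.array(accepted, dtype=int), fs)
    # enforce the refractory period after refinement
    out: list[int] = []
    for idx in refined:
        if not out or idx - out[-1] >= refractory:
            out.append(int(idx))
    return np.array(out, dtype=int)


def _bandpass(samples: np.ndarray, fs: float) -> np.ndarray:
    low, high = _BANDPASS_HZ
    sos = _signal.butter(2, [low, high], btype="bandpass", fs=fs, output="sos")
    return _signal.sosfiltfilt(sos, samples)


def _max_slope(deriv: np.ndarray, idx: int, win: int) -> float:
    lo = max(idx - win, 0)
    return float(np.abs(deriv[lo: idx + 1]).max())


def _refine_to_signal(band: np.ndarray, peaks: np.ndarray, fs: float) -> np.ndarray:
    """Snap each integrator peak to the band-passed QRS extremum before it."""
    back = int(round(0.225 * fs))
    refined = []
    for p in peaks:
        lo = max(p - back, 0)
        refined.append(lo + int(np.argmax(np.abs(band[lo: p + 1]))))
    return np.array(sorted(set(refined)), dtype=int)


# ---------------------------------------------------------------------------
# T points and segment extraction
# ---------------------------------------------------------------------------

def locate_t_points(
    samples: np.ndarray, fs: float, r_peaks: np.ndarray
) -> np.ndarray:
    """One T index per R peak (max |amplitude| in the standard T window).

    The search window is [R + 80 ms, R + min(400 ms, 0.7*RR)]; the last beat
    reuses the previous RR interval. Requires at least two R peaks.
    """
    samples = np.asarray(samples, dtype=float)
    r_peaks = np.asarray(r_peaks, dtype=int)
    if r_peaks.size < 2:
        raise ValueError("need at least 2 R peaks to bound T-search windows")
    rr = np.diff(r_peaks)
    t_points = np.empty(r_peaks.size, dtype=int)
    for i, r in enumerate(r_peaks):
        rr_i = rr[i] if i < rr.size else rr[-1]
        lo = r + int(round(_T_MIN_OFFSET_S * fs))
        hi = r + int(
            round(min(_T_MAX_OFFSET_S * fs, _T_MAX_RR_FRACTION * rr_i))
        )
        hi = min(hi, samples.size - 1)
        lo = min(lo, hi)
        t_points[i] = lo + int(np.argmax(np.abs(samples[lo: hi + 1])))
    return t_points


def rescale_interval(values: np.ndarray, n: int = HALF_SEGMENT) -> np.ndarray:
    """Linearly resample a variable-length interval to exactly ``n`` samples.

    Endpoints are preserved and monotone inputs stay monotone.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("interval must contain at least 2 samples")
    if values.size == n:
        return values.copy()
    old_grid = np.linspace(0.0, 1.0, values.size)
    new_grid = np.linspace(0.0, 1.0, n)
    return np.interp(new_grid, old_grid, values)


def extract_segments(
    record: ECGRecord,
    annotations: list[BeatAnnotation],
    t_points: np.ndarray,
) -> SegmentDataset:
    """Build the two-interval T-to-T dataset for one record.

    For a beat whose R index lies in (T[k-1], T[k]] the segment is
    rescale(T[k-2]..T[k-1]) ++ rescale(T[k-1]..T[k]); an index exactly on a
    T point is assigned to the following interval. Beats without two
    preceding T points are dropped (counted in ``dropped``).
    """
    t_points = np.asarray(t_points, dtype=int)
    x = record.samples
    segments: list[np.ndarray] = []
    labels: list[int] = []
    beat_indices: list[int] = []
    dropped = 0
    for beat_index, ann in enumerate(annotations):
        k = int(np.searchsorted(t_points, ann.sample_index, side="right"))
        if k < 2 or k >= t_points.size:
            dropped += 1
            continue
        first = x[t_points[k - 2]: t_points[k - 1] + 1]
        second = x[t_points[k - 1]: t_points[k] + 1]
        if first.size < 2 or second.size < 2:
            dropped += 1
            continue
        segments.append(
            np.concatenate([rescale_interval(first), rescale_interval(second)])
        )
        labels.append(AAMI_INDEX[ann.aami_class])
        beat_indices.append(beat_index)
    if dropped:
        logger.info(
            "record %s: dropped %d beat(s) without a full preceding interval",
            record.record_id, dropped,
        )
    X = np.vstack(segments) if segments else np.empty((0, SEGMENT_LENGTH))
    return SegmentDataset(
        X=X,
        y=np.array(labels, dtype=int),
        record_ids=[record.record_id] * len(labels),
        beat_indices=np.array(beat_indices, dtype=int),
        dropped=dropped,
    )


def segment_record(
    record: ECGRecord,
    annotations: list[BeatAnnotation],
    preprocessed: np.ndarray | None = None,
) -> SegmentDataset:
    """Convenience chain: detect R peaks, locate T points, extract segments."""
    x = record.samples if preprocessed is None else np.asarray(preprocessed)
    working = ECGRecord(
        record_id=record.record_id, fs=record.fs,
        samples=x, lead_name=record.lead_name,
    )
    r_peaks = detect_r_peaks(x, record.fs)
    t_points = locate_t_points(x, record.fs, r_peaks)
    return extract_segments(working, annotations, t_points)
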