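"""ECG record / annotation I/O and the AAMI evaluation splits.

Reads single-lead ECG records with per-beat annotations, maps MIT-BIH beat
symbols onto the five AAMI classes (N, S, V, F, Q), and materialises the
standard inter-patient DS1/DS2 record split used for generalisation studies
on the MIT-BIH arrhythmia database (paced records 102, 104, 107 and 217 are
excluded throughout).

Two on-disk layouts are supported:

* the package's plain-text fixture layout — a ``<name>.ecg`` header+sample
  file plus a ``<name>.ann`` CSV sidecar (``sample_index,symbol``) — which is
  what every test and the synthetic generator use, and
* real WFDB records, if the optional ``wfdb`` package is installed.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

#: Sentinel AAMI class for annotation symbols that are not beats
#: (rhythm changes, signal-quality flags, comments ...).
UNMAPPED = "UNMAPPED"

AAMI_CLASSES: tuple[str, ...] = ("N", "S", "V", "F", "Q")

#: Index of each AAMI class in label vectors / confusion matrices.
AAMI_INDEX: dict[str, int] = {c: i for i, c in enumerate(AAMI_CLASSES)}

# MIT-BIH beat symbol -> AAMI class. Beat symbols only; anything absent is a
# non-beat annotation and maps to UNMAPPED.
SYMBOL_TO_AAMI: dict[str, str] = {
    # N: normal + bundle branch block + escape beats
    "N": "N", "L": "N", "R": "N", "e": "N", "j": "N",
    # S: supraventricular ectopic
    "A": "S", "a": "S", "J": "S", "S": "S",
    # V: ventricular ectopic
    "V": "V", "E": "V",
    # F: fusion of ventricular and normal
    "F": "F",
    # Q: paced / fusion of paced and normal / unclassifiable
    "/": "Q", "f": "Q", "Q": "Q",
}

#: Records rejected from the 48-record database (paced / low quality).
EXCLUDED_RECORDS: frozenset[str] = frozenset({"102", "104", "107", "217"})

_DS1 = (
    "101", "106", "108", "109", "112", "114", "115", "116", "118", "119",
    "122", "124", "201", "203", "205", "207", "208", "209", "215", "220",
    "223", "230",
)
_DS2 = (
    "100", "103", "105", "111", "113", "117", "121", "123", "200", "202",
    "210", "212", "213", "214", "219", "221", "222", "228", "231", "232",
    "233", "234",
)


@dataclass(frozen=True)
class ECGRecord:
    """A sampled single-lead voltage trace."""

    record_id: str
    fs: float                     # sampling rate, Hz
    samples: np.ndarray           # lead voltage, mV
    lead_name: str = "MLII"

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D vector")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples contain non-finite values")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class BeatAnnotation:
    """One annotated beat: R-peak fiducial sample index + symbol + class."""

    sample_index: int
    symbol: str
    aami_class: str = field(default="")

    def __post_init__(self) -> None:
        if not self.aami_class:
            object.__setattr__(
                self, "aami_class", map_symbol_to_aami(self.symbol)
            )


@dataclass(frozen=True)
class DatasetSplit:
    """A named set of record identifiers (DS1 / DS2 / ALL)."""

    name: str
    record_ids: tuple[str, ...]


def map_symbol_to_aami(symbol: str) -> str:
    """Map a single-character MIT-BIH beat symbol to its AAMI class.

    Non-beat annotation symbols (e.g. ``'+'`` rhythm change) return
    :data:`UNMAPPED`.
    """
    if len(symbol) != 1:
        raise ValueError(f"beat symbol must be a single character: {symbol!r}")
    return SYMBOL_TO_AAMI.get(symbol, UNMAPPED)


def make_split(name: str) -> DatasetSplit:
    """Return the inter-patient record split.

    ``DS1`` (22 training records), ``DS2`` (22 test records) or ``ALL``
    (their union, 44 records). The four paced records are in neither.
    """
    key = name.upper()
    if key == "DS1":
        return DatasetSplit("DS1", _DS1)
    if key == "DS2":
        return DatasetSplit("DS2", _DS2)
    if key == "ALL":
        return DatasetSplit("ALL", tuple(sorted(_DS1 + _DS2)))
    raise ValueError(f"unknown split {name!r}; expected DS1, DS2 or ALL")


# ---------------------------------------------------------------------------
# Fixture format
#
#   <name>.ecg   line 1: "fs=<float> lead=<name> record_id=<id>"
#                lines 2..: one voltage sample per line
#   <name>.ann   CSV with header "sample_index,symbol"
# ---------------------------------------------------------------------------

def save_record(
    path: str | Path,
    record: ECGRecord,
    annotations: list[BeatAnnotation] | None = None,
) -> None:
    """Write ``<path>.ecg`` (and ``<path>.ann`` if annotations given)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path.with_suffix(".ecg"), "w") as fh:
        fh.write(
            f"fs={record.fs:.10g} lead={record.lead_name} "
            f"record_id={record.record_id}\n"
        )
        np.savetxt(fh, record.samples, fmt="%.8g")
    if annotations is not None:
        with open(path.with_suffix(".ann"), "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["sample_index", "symbol"])
            for ann in annotations:
                writer.writerow([ann.sample_index, ann.symbol])


def load_record(
    path: str | Path, lead: str | None = None
) -> tuple[ECGRecord, list[BeatAnnotation]]:
    """Load a record plus its beat annotations.

    ``path`` may point at a fixture record (``<name>.ecg``; extension
    optional) or, when the optional ``wfdb`` package is installed, at a WFDB
    record. Annotation symbols that are not beats are skipped with a logged
    count. ``lead`` selects the channel by name; for single-lead fixtures a
    mismatching name is an error listing the available lead.
    """
    path = Path(path)
    fixture = path if path.suffix == ".ecg" else path.with_suffix(".ecg")
    if fixture.exists():
        return _load_fixture(fixture, lead)
    if path.with_suffix(".hea").exists():
        return _load_wfdb(path, lead or "MLII")
    raise FileNotFoundError(f"no ECG record found at {path}")


def _load_fixture(
    path: Path, lead: str | None
) -> tuple[ECGRecord, list[BeatAnnotation]]:
    with open(path) as fh:
        header = fh.readline().strip()
        fields = dict(item.split("=", 1) for item in header.split())
        samples = np.loadtxt(fh, dtype=float, ndmin=1)
    lead_name = fields.get("lead", "MLII")
    if lead is not None and lead != lead_name:
        raise ValueError(
            f"lead {lead!r} not present in {path.name}; available: {lead_name!r}"
        )
    record = ECGRecord(
        record_id=fields.get("record_id", path.stem),
        fs=float(fields["fs"]),
        samples=samples,
        lead_name=lead_name,
    )
    annotations = _load_annotations(path.with_suffix(".ann"), len(record))
    return record, annotations


def _load_annotations(path: Path, n_samples: int) -> list[BeatAnnotation]:
    if not path.exists():
        return []
    annotations: list[BeatAnnotation] = []
    skipped = 0
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is not None and header and header[0] != "sample_index":
            fh.seek(0)          # headerless sidecar
            reader = csv.reader(fh)
        for row in reader:
            if not row:
                continue
            idx, symbol = int(row[0]), row[1]
            if not 0 <= idx < n_samples:
                raise ValueError(
                    f"annotation index {idx} outside record of {n_samples} samples"
                )
            if map_symbol_to_aami(symbol) == UNMAPPED:
                skipped += 1
                continue
            annotations.append(BeatAnnotation(sample_index=idx, symbol=symbol))
    if skipped:
        logger.info("skipped %d non-beat annotation(s) in %s", skipped, path.name)
    return annotations


def _load_wfdb(path: Path, lead: str) -> tuple[ECGRecord, list[BeatAnnotation]]:
    try:
        import wfdb  # optional, for real MIT-BIH records
    except ImportError as exc:  # pragma: no cover - exercised only with wfdb
        raise ImportError(
            "reading native WFDB records requires the optional 'wfdb' package; "
            "use the plain-text fixture layout otherwise"
        ) from exc
    rec = wfdb.rdrecord(str(path))  # pragma: no cover
    if lead not in rec.sig_name:  # pragma: no cover
        raise ValueError(
            f"lead {lead!r} not present in {path.name}; available: {rec.sig_name}"
        )
    channel = rec.sig_name.index(lead)  # pragma: no cover
    record = ECGRecord(  # pragma: no cover
        record_id=rec.record_name, fs=float(rec.fs),
        samples=rec.p_signal[:, channel], lead_name=lead,
    )
    ann = wfdb.rdann(str(path), "atr")  # pragma: no cover
    annotations = [  # pragma: no cover
        BeatAnnotation(sample_index=int(i), symbol=s)
        for i, s in zip(ann.sample, ann.symbol)
        if len(s) == 1 and map_symbol_to_aami(s) != UNMAPPED
    ]
    return record, annotations  # pragma: no cover
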