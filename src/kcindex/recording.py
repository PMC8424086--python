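"""Four-limb accelerometer recordings: containers, disk I/O, synchronization.

A subject is recorded with four tri-axial accelerometers (left/right wrist,
left/right ankle), nominally at 150 Hz for 10 minutes. Each device keeps its
own clock, so samples carry device-local timestamps; clocks of one subject's
devices agree to better than a millisecond, and :func:`synchronize` resamples
all four streams onto one common uniform grid before any analysis.

On-disk format (inspectable, diff-able):

* one CSV per limb, ``<limb>.csv`` with header ``t_s,ax,ay,az`` — time in
  seconds since recording start, acceleration in the unit declared by the
  sidecar;
* a per-subject sidecar ``subject.json`` with ``subject_id``, ``unit``
  (``"g"`` or ``"m_s2"``), ``nominal_rate_hz`` and an optional ``gm_label``
  (``"N"``, ``"PR"`` or ``"CS"``).

Internally acceleration is always m/s²; readers convert from g on load
(1 g = 9.80665 m/s²). Every downstream feature is scale-invariant, so the
unit choice cannot affect results (this is asserted end-to-end in the tests).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import (
    EmptyRecordingError,
    FormatError,
    InsufficientOverlapError,
    MissingLimbError,
    NotSynchronizedError,
)

LIMB_IDS = ("LW", "RW", "LA", "RA")
GM_LABELS = ("N", "PR", "CS")
#: abnormal general-movement patterns (poor repertoire, cramped synchronized)
ABNORMAL_LABELS = ("PR", "CS")
G_TO_MS2 = 9.80665

_RATE_TOL = 0.05  # median sampling interval must be within ±5% of nominal


@dataclass
class LimbRecording:
    """One sensor's timestamped tri-axial acceleration stream for one limb.

    Parameters
    ----------
    limb_id : {"LW", "RW", "LA", "RA"}
    timestamps : ndarray, shape (n,)
        Seconds since recording start, device-local, strictly increasing.
    accel : ndarray, shape (n, 3)
        Acceleration in m/s².
    nominal_rate : float
        Nominal sampling rate in Hz (150 by default).
    """

    limb_id: str
    timestamps: np.ndarray
    accel: np.ndarray
    nominal_rate: float = 150.0

    def __post_init__(self):
        if self.limb_id not in LIMB_IDS:
            raise FormatError(f"unknown limb_id {self.limb_id!r}, expected one of {LIMB_IDS}")
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        if self.accel.ndim != 2 or self.accel.shape[1] != 3:
            raise FormatError(f"{self.limb_id}: accel must have shape (n, 3)")
        if len(self.timestamps) != len(self.accel):
            raise FormatError(f"{self.limb_id}: timestamps and accel lengths differ")
        dt = np.diff(self.timestamps)
        if dt.size and dt.min() <= 0:
            row = int(np.argmax(dt <= 0)) + 1
            raise FormatError(
                f"{self.limb_id}: timestamps not strictly increasing at row {row}"
            )
        if dt.size:
            med = float(np.median(dt))
            expected = 1.0 / self.nominal_rate
            if not (1 - _RATE_TOL) * expected <= med <= (1 + _RATE_TOL) * expected:
                raise FormatError(
                    f"{self.limb_id}: median sampling interval {med:.6g} s deviates "
                    f"more than {_RATE_TOL:.0%} from nominal {expected:.6g} s"
                )

    @property
    def n_samples(self) -> int:
        return len(self.timestamps)

    @property
    def duration(self) -> float:
        """Time span covered by the recording, in seconds."""
        if self.n_samples < 2:
            return 0.0
        return float(self.timestamps[-1] - self.timestamps[0])


@dataclass
class SubjectRecording:
    """The four limb recordings of one subject plus identity and GM label.

    ``gm_label`` is the clinical General Movement Assessment class when known:
    N (normal), PR (poor repertoire) or CS (cramped synchronized); PR and CS
    together form the abnormal (Ab) class. ``synchronized`` is set by
    :func:`synchronize` once all limbs share one uniform time grid (``rate``).
    """

    subject_id: str
    limbs: dict[str, LimbRecording]
    gm_label: str | None = None
    pma_weeks: float | None = None
    synchronized: bool = field(default=False, compare=False)
    rate: float | None = field(default=None, compare=False)

    def __post_init__(self):
        for limb_id in LIMB_IDS:
            if limb_id not in self.limbs:
                raise MissingLimbError(limb_id)
        if self.gm_label is not None and self.gm_label not in GM_LABELS:
            raise FormatError(f"unknown gm_label {self.gm_label!r}")

    def __iter__(self):
        return (self.limbs[limb_id] for limb_id in LIMB_IDS)

    @property
    def duration(self) -> float:
        """Duration of the common grid (synchronized) or shortest limb span."""
        return min(limb.duration for limb in self)

    def scaled(self, factor: float) -> "SubjectRecording":
        """Copy with every acceleration multiplied by ``factor`` (diagnostics)."""
        limbs = {
            lid: replace(limb, accel=limb.accel * factor)
            for lid, limb in self.limbs.items()
        }
        return replace(self, limbs=limbs)


# ---------------------------------------------------------------------------
# disk I/O

def _sidecar_path(directory: Path) -> Path:
    return directory / "subject.json"


def write_subject(rec: SubjectRecording, path: str | Path, unit: str = "m_s2") -> Path:
    """Write a subject to ``path`` as four limb CSVs plus ``subject.json``.

    Values are written with 17 significant digits so the read→write→read
    round trip is exact for float64.
    """
    if unit not in ("g", "m_s2"):
        raise FormatError(f"unknown unit {unit!r}")
    directory = Path(path)
    directory.mkdir(parents=True, exist_ok=True)
    scale = 1.0 / G_TO_MS2 if unit == "g" else 1.0
    for limb_id in LIMB_IDS:
        limb = rec.limbs[limb_id]
        table = np.column_stack([limb.timestamps, limb.accel * scale])
        np.savetxt(
            directory / f"{limb_id}.csv",
            table,
            fmt="%.17g",
            delimiter=",",
            header="t_s,ax,ay,az",
            comments="",
            newline="\n",
        )
    sidecar = {
        "subject_id": rec.subject_id,
        "unit": unit,
        "nominal_rate_hz": rec.limbs["LW"].nominal_rate,
        "gm_label": rec.gm_label,
    }
    if rec.pma_weeks is not None:
        sidecar["pma_weeks"] = rec.pma_weeks
    _sidecar_path(directory).write_text(json.dumps(sidecar, indent=2) + "\n")
    return directory


def read_subject(path: str | Path, unit_decl: str | None = None) -> SubjectRecording:
    """Read a subject directory written in the per-limb CSV + sidecar format.

    Parameters
    ----------
    path : directory containing ``LW.csv``, ``RW.csv``, ``LA.csv``, ``RA.csv``
        and optionally ``subject.json``.
    unit_decl : {"g", "m_s2"}, optional
        Overrides the sidecar's declared unit. Acceleration in g is converted
        to m/s² on load.

    The returned recording is *not* synchronized yet.
    """
    directory = Path(path)
    sidecar: dict = {}
    sc_path = _sidecar_path(directory)
    if sc_path.exists():
        sidecar = json.loads(sc_path.read_text())
    unit = unit_decl if unit_decl is not None else sidecar.get("unit", "m_s2")
    if unit not in ("g", "m_s2"):
        raise FormatError(f"unknown unit {unit!r}")
    scale = G_TO_MS2 if unit == "g" else 1.0
    nominal_rate = float(sidecar.get("nominal_rate_hz", 150.0))

    limbs: dict[str, LimbRecording] = {}
    for limb_id in LIMB_IDS:
        csv_path = directory / f"{limb_id}.csv"
        if not csv_path.exists():
            raise MissingLimbError(limb_id)
        table = _read_limb_csv(csv_path)
        limbs[limb_id] = LimbRecording(
            limb_id=limb_id,
            timestamps=table[:, 0],
            accel=table[:, 1:] * scale,
            nominal_rate=nominal_rate,
        )
    return SubjectRecording(
        subject_id=str(sidecar.get("subject_id", directory.name)),
        limbs=limbs,
        gm_label=sidecar.get("gm_label"),
        pma_weeks=sidecar.get("pma_weeks"),
    )


def _read_limb_csv(csv_path: Path) -> np.ndarray:
    try:
        table = np.loadtxt(csv_path, delimiter=",", skiprows=1, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{csv_path.name}: cannot parse ({exc})") from exc
    if table.shape[1] != 4:
        raise FormatError(f"{csv_path.name}: expected 4 columns t_s,ax,ay,az")
    dt = np.diff(table[:, 0])
    if dt.size and dt.min() <= 0:
        # +2: one for the header line, one for 1-based row numbering
        row = int(np.argmax(dt <= 0)) + 2
        raise FormatError(
            f"{csv_path.name}: timestamps not strictly increasing at row {row}"
        )
    return table


# ---------------------------------------------------------------------------
# synchronization

def synchronize(
    rec: SubjectRecording,
    target_rate: float | None = None,
    min_duration_s: float = 600.0,
    duration_tol: float = 0.05,
) -> SubjectRecording:
    """Resample all four limbs onto one common uniform time grid.

    The grid runs at ``target_rate`` (the limbs' nominal rate by default)
    over the intersection of the four limb time spans, left-aligned to the
    latest start so no limb is extrapolated. Per-device clock discrepancies
    are below one millisecond — far under one sample period at 150 Hz — so
    linear interpolation is used; its error is negligible at these offsets
    and it preserves sample ordering.

    Raises
    ------
    InsufficientOverlapError
        If the common span is shorter than ``min_duration_s`` less the
        ``duration_tol`` relative tolerance (600 s − 5% by default).
    """
    for limb in rec:
        if limb.n_samples < 2:
            raise EmptyRecordingError(f"{limb.limb_id}: fewer than 2 samples")
    if target_rate is None:
        target_rate = rec.limbs["LW"].nominal_rate
    start = max(limb.timestamps[0] for limb in rec)
    end = min(limb.timestamps[-1] for limb in rec)
    overlap = end - start
    required = min_duration_s * (1.0 - duration_tol)
    if overlap < required:
        raise InsufficientOverlapError(overlap_s=max(overlap, 0.0), required_s=required)

    n = int(np.floor(overlap * target_rate)) + 1
    grid = start + np.arange(n) / target_rate
    limbs = {}
    for limb in rec:
        accel = np.column_stack(
            [np.interp(grid, limb.timestamps, limb.accel[:, k]) for k in range(3)]
        )
        limbs[limb.limb_id] = LimbRecording(
            limb_id=limb.limb_id,
            timestamps=grid,
            accel=accel,
            nominal_rate=target_rate,
        )
    return replace(rec, limbs=limbs, synchronized=True, rate=float(target_rate))


def trim_settling(rec: SubjectRecording, settle_s: float) -> SubjectRecording:
    """Drop the first ``settle_s`` seconds from all limbs identically.

    Recordings are normally started only after the sensors have settled, so
    the default pipeline uses ``settle_s = 0``; this is an optional guard for
    recordings that include strap-on artifacts.
    """
    if settle_s < 0:
        raise ValueError("settle_s must be >= 0")
    if not rec.synchronized:
        raise NotSynchronizedError("trim_settling requires a synchronized recording")
    if settle_s == 0:
        return rec
    t0 = rec.limbs["LW"].timestamps[0]
    keep = rec.limbs["LW"].timestamps >= t0 + settle_s
    if not keep.any():
        raise EmptyRecordingError(
            f"settle_s={settle_s} s leaves no samples of a "
            f"{rec.duration:.1f} s recording"
        )
    limbs = {
        lid: replace(limb, timestamps=limb.timestamps[keep], accel=limb.accel[keep])
        for lid, limb in rec.limbs.items()
    }
    return replace(rec, limbs=limbs)
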