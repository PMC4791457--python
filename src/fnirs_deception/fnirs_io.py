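"""Plain-text I/O for raw fNIRS recordings and stimulus event tables.

A continuous-wave fNIRS device reports, for each *voxel* (source-detector
measurement region on the forehead), one light-intensity signal per
wavelength.  A recording therefore consists of an ``[samples x voxels x 2]``
intensity array at a fixed sampling rate, a resting *baseline* interval that
anchors all relative concentration changes, and a table of stimulus events
(one per interview question, each labelled with a response class
``m in {1, 2, 3, 4}``: induced lie, induced truth, non-induced lie,
non-induced truth).

On-disk dialect (transparent, diffable CSV; UTF-8, '.' decimal separator):

``<prefix>.intensity.csv``
    ``#``-prefixed ``key=value`` header block (``subject_id``, ``fs``,
    ``wavelengths``, ``baseline``), then a CSV body with columns
    ``time_s, v1_w<l1>, v1_w<l2>, ..., v<V>_w<l1>, v<V>_w<l2>``.
``<prefix>.events.csv``
    columns ``time_s, question_id, class_label``.

Sample ``k`` occurs at ``t_k = k / fs`` with ``k`` starting at 0; the
``time_s`` column is informative only and is regenerated on write.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "StimulusEvent",
    "RawRecording",
    "RecordingFormatError",
    "read_recording",
    "write_recording",
    "DEFAULT_WAVELENGTHS",
    "ANALYSIS_WINDOW_S",
    "CLASS_LABELS",
]

#: 730/850 nm pair of the imager (one wavelength below 780 nm, one above).
DEFAULT_WAVELENGTHS: tuple[float, float] = (730.0, 850.0)

#: Post-stimulus analysis window (seconds); every event must leave room for it.
ANALYSIS_WINDOW_S: float = 5.0

#: Response classes: 1 induced lie, 2 induced truth, 3 non-induced lie,
#: 4 non-induced truth.
CLASS_LABELS: tuple[int, ...] = (1, 2, 3, 4)


class RecordingFormatError(ValueError):
    """Structured parse/validation error naming the offending row/column."""


@dataclass(frozen=True, order=True)
class StimulusEvent:
    """One stimulus: the end of a spoken question."""

    time_s: float
    question_id: int
    class_label: int

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise RecordingFormatError(
                f"event question_id={self.question_id}: class_label "
                f"{self.class_label} not in {CLASS_LABELS}"
            )


@dataclass
class RawRecording:
    """Raw two-wavelength intensity time series plus event metadata.

    ``intensity`` has shape ``[samples, n_voxels, 2]`` with the last axis
    ordered like ``wavelengths``.  Values are arbitrary positive light-
    intensity units (proportional detector voltages).
    """

    subject_id: str
    fs: float
    wavelengths: tuple[float, float]
    intensity: np.ndarray
    baseline_interval: tuple[float, float]
    events: list[StimulusEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.validate()

    # -- derived geometry ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.intensity.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """t_k = k / fs for k = 0..n_samples-1."""
        return np.arange(self.n_samples) / self.fs

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if not self.fs > 0:
            raise RecordingFormatError(f"fs must be positive, got {self.fs}")
        w1, w2 = self.wavelengths
        if not (w1 < 780.0 < w2):
            raise RecordingFormatError(
                f"wavelength pair must straddle 780 nm (l1 < 780 < l2), "
                f"got ({w1}, {w2})"
            )
        if self.intensity.ndim != 3 or self.intensity.shape[2] != 2:
            raise RecordingFormatError(
                f"intensity must have shape [samples, voxels, 2], "
                f"got {self.intensity.shape}"
            )
        bad = ~(np.isfinite(self.intensity) & (self.intensity > 0))
        if bad.any():
            k, v, w = (int(i[0]) for i in np.nonzero(bad))
            raise RecordingFormatError(
                "non-positive intensity: sample "
                f"{k}, voxel {v + 1}, wavelength index {w} "
                f"(value {self.intensity[k, v, w]!r}); light intensity must "
                "be strictly positive and finite"
            )
        t0, t1 = self.baseline_interval
        if not (0.0 <= t0 < t1 <= self.duration_s):
            raise RecordingFormatError(
                f"baseline interval [{t0}, {t1}) must lie within the "
                f"recording [0, {self.duration_s:.6g})"
            )
        times = [e.time_s for e in self.events]
        if any(b > a for a, b in zip(times[1:], times)):
            raise RecordingFormatError("events must be sorted ascending by time")
        qids = [e.question_id for e in self.events]
        if len(set(qids)) != len(qids):
            dup = next(q for q in qids if qids.count(q) > 1)
            raise RecordingFormatError(f"duplicate question_id {dup}")
        for e in self.events:
            if e.time_s < t1:
                raise RecordingFormatError(
                    f"baseline [{t0}, {t1}) must precede all events; event "
                    f"question_id={e.question_id} at t={e.time_s}"
                )
            if e.time_s + ANALYSIS_WINDOW_S > self.duration_s:
                raise RecordingFormatError(
                    f"event question_id={e.question_id} at t={e.time_s}: "
                    f"{ANALYSIS_WINDOW_S}-s analysis window extends past "
                    f"recording end {self.duration_s:.6g}"
                )

    # -- convenience --------------------------------------------------------
    def event_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": [e.time_s for e in self.events],
                "question_id": [e.question_id for e in self.events],
                "class_label": [e.class_label for e in self.events],
            }
        )


# ---------------------------------------------------------------------------
# dialect helpers
# ---------------------------------------------------------------------------

def _wl_tag(w: float) -> str:
    return f"{int(w)}" if float(w).is_integer() else f"{w:g}"


def _expected_columns(n_voxels: int, wavelengths: tuple[float, float]) -> list[str]:
    cols = ["time_s"]
    for v in range(1, n_voxels + 1):
        for w in wavelengths:
            cols.append(f"v{v}_w{_wl_tag(w)}")
    return cols


def _paths(path: str | Path) -> tuple[Path, Path]:
    """Resolve a prefix or either member file to the (intensity, events) pair."""
    p = Path(path)
    name = p.name
    for suffix in (".intensity.csv", ".events.csv"):
        if name.endswith(suffix):
            p = p.with_name(name[: -len(suffix)])
            break
    return (
        p.with_name(p.name + ".intensity.csv"),
        p.with_name(p.name + ".events.csv"),
    )


def write_recording(rec: RawRecording, path: str | Path) -> tuple[Path, Path]:
    """Write ``rec`` to ``<prefix>.intensity.csv`` + ``<prefix>.events.csv``.

    Floats are written with 17 significant digits so the round trip is exact
    to double precision.  Returns the two paths written.
    """
    rec.validate()
    ipath, epath = _paths(path)
    ipath.parent.mkdir(parents=True, exist_ok=True)

    cols = _expected_columns(rec.n_voxels, rec.wavelengths)
    flat = rec.intensity.reshape(rec.n_samples, rec.n_voxels * 2)
    body = pd.DataFrame(
        np.column_stack([rec.times, flat]), columns=cols
    )
    t0, t1 = rec.baseline_interval
    header = (
        f"# subject_id={rec.subject_id}\n"
        f"# fs={rec.fs!r}\n"
        f"# wavelengths={rec.wavelengths[0]!r},{rec.wavelengths[1]!r}\n"
        f"# baseline={t0!r},{t1!r}\n"
    )
    with open(ipath, "w", encoding="utf-8", newline="") as fh:
        fh.write(header)
        body.to_csv(fh, index=False, float_format="%.17g")
    rec.event_table().to_csv(epath, index=False, float_format="%.17g")
    return ipath, epath


def _parse_header(ipath: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(ipath, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" not in body:
                raise RecordingFormatError(
                    f"{ipath.name}: malformed header line {line!r} "
                    "(expected '# key=value')"
                )
            key, val = body.split("=", 1)
            meta[key.strip()] = val.strip()
    missing = {"subject_id", "fs", "wavelengths", "baseline"} - meta.keys()
    if missing:
        raise RecordingFormatError(
            f"{ipath.name}: malformed header, missing keys {sorted(missing)}"
        )
    return meta


def read_recording(path: str | Path) -> RawRecording:
    """Read a recording written in the documented dialect.

    ``path`` may be the common prefix or either member file.  Structural
    problems (shuffled columns, non-positive intensity, events outside the
    recording, duplicate question ids) raise :class:`RecordingFormatError`
    naming the offending row/column.
    """
    ipath, epath = _paths(path)
    if not ipath.exists():
        raise FileNotFoundError(ipath)
    meta = _parse_header(ipath)
    try:
        fs = float(meta["fs"])
        wavelengths = tuple(float(x) for x in meta["wavelengths"].split(","))
        baseline = tuple(float(x) for x in meta["baseline"].split(","))
    except ValueError as exc:
        raise RecordingFormatError(f"{ipath.name}: malformed header: {exc}") from exc
    if len(wavelengths) != 2 or len(baseline) != 2:
        raise RecordingFormatError(
            f"{ipath.name}: header wavelengths/baseline must be pairs"
        )

    body = pd.read_csv(ipath, comment="#")
    n_chan = len(body.columns) - 1
    if n_chan <= 0 or n_chan % 2:
        raise RecordingFormatError(
            f"{ipath.name}: expected 1 + 2*V columns, got {len(body.columns)}"
        )
    n_voxels = n_chan // 2
    expected = _expected_columns(n_voxels, wavelengths)  # type: ignore[arg-type]
    got = list(body.columns)
    if got != expected:
        mism = next(
            (i for i, (a, b) in enumerate(zip(got, expected)) if a != b), None
        )
        raise RecordingFormatError(
            f"{ipath.name}: column order mismatch at column {mism}: "
            f"got {got[mism]!r}, expected {expected[mism]!r}"
        )
    intensity = body[expected[1:]].to_numpy(dtype=float).reshape(-1, n_voxels, 2)

    events: list[StimulusEvent] = []
    if epath.exists():
        etab = pd.read_csv(epath)
        need = ["time_s", "question_id", "class_label"]
        if list(etab.columns) != need:
            raise RecordingFormatError(
                f"{epath.name}: expected columns {need}, got {list(etab.columns)}"
            )
        for i, row in etab.iterrows():
            events.append(
                StimulusEvent(
                    time_s=float(row["time_s"]),
                    question_id=int(row["question_id"]),
                    class_label=int(row["class_label"]),
                )
            )
    return RawRecording(
        subject_id=str(meta["subject_id"]),
        fs=fs,
        wavelengths=wavelengths,  # type: ignore[arg-type]
        intensity=intensity,
        baseline_interval=baseline,  # type: ignore[arg-type]
        events=events,
    )


def recordings_equal(a: RawRecording, b: RawRecording, rtol: float = 1e-9) -> bool:
    """Value equality of two recordings within relative tolerance ``rtol``."""
    return (
        a.subject_id == b.subject_id
        and np.isclose(a.fs, b.fs, rtol=rtol)
        and np.allclose(a.wavelengths, b.wavelengths, rtol=rtol)
        and np.allclose(a.baseline_interval, b.baseline_interval, rtol=rtol)
        and a.intensity.shape == b.intensity.shape
        and np.allclose(a.intensity, b.intensity, rtol=rtol)
        and len(a.events) == len(b.events)
        and all(
            np.isclose(x.time_s, y.time_s, rtol=rtol)
            and x.question_id == y.question_id
            and x.class_label == y.class_label
            for x, y in zip(a.events, b.events)
        )
    )
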