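"""Core data model for nociceptive withdrawal reflex (NWR) EMG recordings.

A recording session stimulates up to ten electrode sites on the sole of the
foot, four times each, and stores one tibialis-anterior surface-EMG trace per
stimulation: a 1000 ms window sampled at 2000 Hz that includes 200 ms of
pre-stimulation activity.  The reflex itself is quantified in a post-stimulus
window, conventionally 60-180 ms.

This module provides the immutable containers (:class:`EMGTrace`,
:class:`Subject`, :class:`Cohort`, :class:`ReflexWindow`), plain-text
readers/writers, reflex-window extraction, and the pre-stimulation
quiescence check.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import BoundsError, IntegrityError, ParseError

__all__ = [
    "EMGTrace",
    "Subject",
    "Cohort",
    "ReflexWindow",
    "QualityFlag",
    "AcquisitionParams",
    "load_cohort",
    "write_cohort",
    "extract_reflex_window",
    "check_prestim_activity",
]

#: Default acquisition geometry: 2000 Hz, 1000 ms stored window with 200 ms
#: of pre-stimulation activity.
DEFAULT_SAMPLING_RATE_HZ = 2000.0
DEFAULT_PRESTIM_MS = 200.0

GROUPS = ("h", "p")  # healthy / patient
GENDERS = ("G1", "G2")  # male / female

_TRACE_COLUMNS = ["subject_id", "site_id", "repetition", "sample_index", "amplitude"]


class QualityFlag(Enum):
    """Outcome of the pre-stimulation muscle-activity check."""

    PASS = "pass"
    FAIL = "fail"


@dataclass(frozen=True)
class ReflexWindow:
    """Post-stimulation quantification window, in milliseconds.

    The default 60-180 ms interval is the conventional NWR window for the
    tibialis anterior; it skips early non-nociceptive components.
    """

    start_ms: float = 60.0
    end_ms: float = 180.0

    def __post_init__(self) -> None:
        if not (0 <= self.start_ms < self.end_ms):
            raise ValueError(
                f"reflex window requires 0 <= start < end, got "
                f"[{self.start_ms}, {self.end_ms}] ms"
            )


@dataclass(frozen=True)
class EMGTrace:
    """One recorded EMG signal for a single stimulation.

    Amplitudes are signed (raw, not rectified) in arbitrary microvolt-scale
    units.  ``stim_onset_index`` marks the sample at which the electrical
    stimulus was delivered; everything before it is pre-stimulation activity.
    """

    subject_id: str
    site_id: int
    repetition: int
    samples: np.ndarray
    sampling_rate: float = DEFAULT_SAMPLING_RATE_HZ
    stim_onset_index: int = int(DEFAULT_PRESTIM_MS * DEFAULT_SAMPLING_RATE_HZ / 1000)

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1:
            raise ValueError("samples must be a 1-D amplitude vector")
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if not 1 <= self.site_id <= 10:
            raise ValueError(f"site_id must be in 1..10, got {self.site_id}")
        if not 1 <= self.repetition <= 4:
            raise ValueError(f"repetition must be in 1..4, got {self.repetition}")
        prestim_samples = math.ceil(DEFAULT_PRESTIM_MS * self.sampling_rate / 1000)
        if self.stim_onset_index < prestim_samples:
            raise ValueError(
                f"trace must contain {DEFAULT_PRESTIM_MS:g} ms of pre-stimulation "
                f"activity ({prestim_samples} samples at {self.sampling_rate:g} Hz); "
                f"stim_onset_index={self.stim_onset_index}"
            )
        post_samples = samples.size - self.stim_onset_index
        if post_samples < math.ceil(180.0 * self.sampling_rate / 1000):
            raise ValueError(
                "trace too short: must cover at least 180 ms post-stimulation"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EMGTrace):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.site_id == other.site_id
            and self.repetition == other.repetition
            and self.sampling_rate == other.sampling_rate
            and self.stim_onset_index == other.stim_onset_index
            and np.array_equal(self.samples, other.samples)
        )

    __hash__ = None  # type: ignore[assignment]


@dataclass
class Subject:
    """A participant: demographics plus their recorded traces.

    ``group`` is ``"h"`` (healthy) or ``"p"`` (chronic-pain patient);
    ``gender`` is ``"G1"`` (male) or ``"G2"`` (female), following the
    stratification labels used throughout the package.
    """

    subject_id: str
    group: str
    gender: str
    age: float
    traces: list[EMGTrace] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.gender not in GENDERS:
            raise ValueError(f"gender must be one of {GENDERS}, got {self.gender!r}")
        if not 0 <= self.age <= 120:
            raise ValueError(f"age must be in [0, 120], got {self.age}")
        seen: set[tuple[int, int]] = set()
        for tr in self.traces:
            key = (tr.site_id, tr.repetition)
            if key in seen:
                raise IntegrityError(
                    f"subject {self.subject_id!r}: duplicate trace for "
                    f"site {key[0]}, repetition {key[1]}"
                )
            seen.add(key)

    def trace(self, site_id: int, repetition: int) -> EMGTrace | None:
        """Return the trace for (site, repetition), or None if absent."""
        for tr in self.traces:
            if tr.site_id == site_id and tr.repetition == repetition:
                return tr
        return None

    def traces_for_site(self, site_id: int) -> list[EMGTrace]:
        """All traces recorded at one stimulation site, ordered by repetition."""
        return sorted(
            (tr for tr in self.traces if tr.site_id == site_id),
            key=lambda tr: tr.repetition,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Subject):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.group == other.group
            and self.gender == other.gender
            and self.age == other.age
            and sorted(self.traces, key=lambda t: (t.site_id, t.repetition))
            == sorted(other.traces, key=lambda t: (t.site_id, t.repetition))
        )


@dataclass
class Cohort:
    """A collection of subjects with unique identifiers."""

    subjects: list[Subject] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise IntegrityError(f"duplicate subject ids: {dupes}")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    def subject(self, subject_id: str) -> Subject:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    def subset(self, subject_ids: Iterable[str]) -> list[Subject]:
        """Subjects in the given id collection, in cohort order."""
        wanted = set(subject_ids)
        return [s for s in self.subjects if s.subject_id in wanted]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        key = lambda s: s.subject_id
        return sorted(self.subjects, key=key) == sorted(other.subjects, key=key)


@dataclass(frozen=True)
class AcquisitionParams:
    """Recording geometry shared by all traces of a cohort file."""

    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ
    prestim_ms: float = DEFAULT_PRESTIM_MS
    window_ms: tuple[float, float] = (60.0, 180.0)

    @property
    def stim_onset_index(self) -> int:
        return math.ceil(self.prestim_ms * self.sampling_rate_hz / 1000)


# ---------------------------------------------------------------------------
# I/O: long-format TSV trace table + JSON metadata
# ---------------------------------------------------------------------------

def load_cohort(trace_table_path: str | Path, metadata_path: str | Path) -> Cohort:
    """Load a cohort from a trace table (TSV) and a metadata document (JSON).

    The trace table is tab-separated with a header row and columns
    ``subject_id, site_id, repetition, sample_index, amplitude`` in long
    format.  The metadata JSON carries per-subject demographics and the
    acquisition parameters used to reconstruct stimulus timing.

    Raises
    ------
    ParseError
        On malformed rows (the message names the offending line number).
    IntegrityError
        On duplicate (subject, site, repetition, sample_index) rows or on
        trace subjects missing from the metadata.
    """
    trace_table_path = Path(trace_table_path)
    metadata_path = Path(metadata_path)

    with open(metadata_path) as fh:
        meta = json.load(fh)
    acq_raw = meta.get("acquisition", {})
    acq = AcquisitionParams(
        sampling_rate_hz=float(acq_raw.get("sampling_rate_hz", DEFAULT_SAMPLING_RATE_HZ)),
        prestim_ms=float(acq_raw.get("prestim_ms", DEFAULT_PRESTIM_MS)),
        window_ms=tuple(acq_raw.get("window_ms", (60.0, 180.0))),  # type: ignore[arg-type]
    )

    try:
        table = pd.read_csv(
            trace_table_path,
            sep="\t",
            dtype={"subject_id": str},
            float_precision="round_trip",
        )
    except pd.errors.EmptyDataError:
        table = pd.DataFrame(columns=_TRACE_COLUMNS)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{trace_table_path}: {exc}") from exc

    missing = [c for c in _TRACE_COLUMNS if c not in table.columns]
    if missing:
        raise ParseError(f"{trace_table_path}: missing columns {missing}")

    for col in ("site_id", "repetition", "sample_index", "amplitude"):
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = coerced.isna() & table[col].notna() | table[col].isna()
        if bad.any():
            # +2: one for the header row, one for 0- vs 1-based numbering
            line = int(bad.idxmax()) + 2
            raise ParseError(
                f"{trace_table_path}: malformed value in column {col!r} at line {line}"
            )
        table[col] = coerced
    for col in ("site_id", "repetition", "sample_index"):
        table[col] = table[col].astype(int)

    dup = table.duplicated(
        subset=["subject_id", "site_id", "repetition", "sample_index"], keep=False
    )
    if dup.any():
        first = table.loc[dup].iloc[0]
        raise IntegrityError(
            "duplicate sample rows for subject "
            f"{first['subject_id']!r}, site {first['site_id']}, "
            f"repetition {first['repetition']}, sample {first['sample_index']}"
        )

    demo: dict[str, Mapping] = {
        str(rec["subject_id"]): rec for rec in meta.get("subjects", [])
    }
    trace_subjects = list(dict.fromkeys(table["subject_id"]))  # preserve order
    unknown = [sid for sid in trace_subjects if sid not in demo]
    if unknown:
        raise IntegrityError(
            f"subjects present in trace table but absent from metadata: {unknown}"
        )

    subjects: list[Subject] = []
    grouped = dict(tuple(table.groupby("subject_id", sort=False)))
    # metadata order defines cohort order; subjects may legitimately lack traces
    for sid, rec in demo.items():
        traces: list[EMGTrace] = []
        if sid in grouped:
            for (site, rep), block in grouped[sid].groupby(
                ["site_id", "repetition"], sort=True
            ):
                block = block.sort_values("sample_index")
                idx = block["sample_index"].to_numpy()
                if not np.array_equal(idx, np.arange(idx.size)):
                    raise IntegrityError(
                        f"subject {sid!r}, site {site}, repetition {rep}: "
                        "sample indices are not contiguous from 0"
                    )
                traces.append(
                    EMGTrace(
                        subject_id=sid,
                        site_id=int(site),
                        repetition=int(rep),
                        samples=block["amplitude"].to_numpy(dtype=float),
                        sampling_rate=acq.sampling_rate_hz,
                        stim_onset_index=acq.stim_onset_index,
                    )
                )
        subjects.append(
            Subject(
                subject_id=sid,
                group=str(rec["group"]),
                gender=str(rec["gender"]),
                age=float(rec["age"]),
                traces=traces,
            )
        )
    return Cohort(subjects=subjects)


def write_cohort(
    cohort: Cohort, trace_table_path: str | Path, metadata_path: str | Path
) -> None:
    """Write a cohort as a TSV trace table plus JSON metadata.

    Amplitudes are written with 17 significant digits, which round-trips
    IEEE-754 doubles exactly, so ``load_cohort(write_cohort(C)) == C``.
    """
    trace_table_path = Path(trace_table_path)
    metadata_path = Path(metadata_path)

    rates = {tr.sampling_rate for s in cohort for tr in s.traces}
    onsets = {tr.stim_onset_index for s in cohort for tr in s.traces}
    if len(rates) > 1 or len(onsets) > 1:
        raise IntegrityError(
            "cohort mixes acquisition parameters; cannot serialize to one file"
        )
    rate = rates.pop() if rates else DEFAULT_SAMPLING_RATE_HZ
    onset = onsets.pop() if onsets else int(DEFAULT_PRESTIM_MS * rate / 1000)

    with open(trace_table_path, "w") as fh:
        fh.write("\t".join(_TRACE_COLUMNS) + "\n")
        for s in cohort:
            for tr in sorted(s.traces, key=lambda t: (t.site_id, t.repetition)):
                sid, site, rep = s.subject_id, tr.site_id, tr.repetition
                for i, a in enumerate(tr.samples):
                    fh.write(f"{sid}\t{site}\t{rep}\t{i}\t{a:.17g}\n")

    meta = {
        "subjects": [
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "gender": s.gender,
                "age": s.age,
            }
            for s in cohort
        ],
        "acquisition": {
            "sampling_rate_hz": rate,
            "prestim_ms": onset * 1000.0 / rate,
            "window_ms": [60.0, 180.0],
        },
    }
    with open(metadata_path, "w") as fh:
        json.dump(meta, fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Window extraction and quality check
# ---------------------------------------------------------------------------

def window_sample_indices(
    window: ReflexWindow, sampling_rate: float, stim_onset_index: int
) -> tuple[int, int]:
    """Half-open sample-index range [start, stop) covering the window."""
    start = stim_onset_index + math.ceil(window.start_ms * sampling_rate / 1000)
    stop = stim_onset_index + math.ceil(window.end_ms * sampling_rate / 1000)
    return start, stop


def extract_reflex_window(trace: EMGTrace, window: ReflexWindow) -> np.ndarray:
    """Amplitudes within the post-stimulation reflex window.

    Millisecond bounds are converted to sample indices with a ceiling and
    the window is half-open on the right, so a 60-180 ms window at 2000 Hz
    yields exactly 240 samples.
    """
    start, stop = window_sample_indices(
        window, trace.sampling_rate, trace.stim_onset_index
    )
    if stop > trace.samples.size:
        raise BoundsError(
            f"reflex window [{window.start_ms}, {window.end_ms}] ms needs samples "
            f"up to index {stop} but trace has only {trace.samples.size}"
        )
    return trace.samples[start:stop]


def check_prestim_activity(trace: EMGTrace, rms_limit: float) -> QualityFlag:
    """Flag whether the pre-stimulation segment is quiescent.

    Computes the root-mean-square of all samples before stimulus onset
    (at least 200 ms by the trace invariant) and compares it against
    ``rms_limit``; PASS when RMS <= limit.  The trace is never modified,
    and the check is scale-equivariant: scaling amplitudes and limit by
    the same positive factor preserves the flag.
    """
    if trace.stim_onset_index <= 0:
        raise BoundsError("trace has no pre-stimulation segment")
    segment = trace.samples[: trace.stim_onset_index]
    rms = float(np.sqrt(np.mean(np.square(segment))))
    return QualityFlag.PASS if rms <= rms_limit else QualityFlag.FAIL
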