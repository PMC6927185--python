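"""Metadata maps and the measurement filename convention.

An IMAGING-PAM induction-curve export is a multi-frame TIFF whose frame
order is fixed by the instrument software: frames 1 and 2 are the
dark-adapted minimal and maximal fluorescence (Fo, Fm), frames 3 and 4 the
red and NIR absorptivity images, and every following pair of frames is one
F'/Fm' saturating-pulse measurement of the induction curve.  Two small CSV
"metadata maps" travel with the images: a frame map giving the semantic
role of every frame, and a genotype map relating tray and ROI position to
genotype.  Filenames follow ``treatment-YYYYMMDD-sampleid.tif``.
"""

from __future__ import annotations

import csv
import datetime as _dt
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "FrameRole",
    "FrameEntry",
    "FrameMap",
    "GenotypeMap",
    "MeasurementID",
    "FilenameParseError",
    "MapValidationError",
    "GenotypeLookupError",
    "parse_filename",
    "format_filename",
    "default_frame_map",
    "load_frame_map",
    "write_frame_map",
    "load_genotype_map",
    "write_genotype_map",
    "lookup_genotype",
]


class FilenameParseError(ValueError):
    """A measurement filename does not follow treatment-YYYYMMDD-sampleid.tif."""


class MapValidationError(ValueError):
    """A metadata map violates its structural invariants."""


class GenotypeLookupError(KeyError):
    """A (sample_id, roi_position) pair is absent from the genotype map."""


class FrameRole(str, Enum):
    """Semantic role of a frame in the instrument's fixed export order."""

    Fo = "Fo"
    Fm = "Fm"
    RedAbs = "RedAbs"
    NIRAbs = "NIRAbs"
    Fprime = "Fprime"
    Fmprime = "Fmprime"


#: the fixed roles of frames 1-4 in every Walz export
_HEADER_ROLES = (FrameRole.Fo, FrameRole.Fm, FrameRole.RedAbs, FrameRole.NIRAbs)


@dataclass(frozen=True)
class FrameEntry:
    """One frame of the stack: 1-based index, role, and induction step.

    ``induction_step`` and ``induction_time`` are ``None`` for the four
    header frames (Fo, Fm, and the two absorptivity images).
    """

    frame_index: int
    role: FrameRole
    induction_step: Optional[int] = None
    induction_time: Optional[float] = None


@dataclass(frozen=True)
class MeasurementID:
    """Identity of one tray measurement, parsed from its filename."""

    treatment: str
    date: _dt.date
    sample_id: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.treatment}-{self.date:%Y%m%d}-{self.sample_id}"


@dataclass
class FrameMap:
    """Ordered semantic labelling of the frames of one stack.

    ``first_pair_is_dark_adapted`` records that frames 5/6 repeat the
    dark-adapted Fo/Fm pair, i.e. induction step 1 is the dark-adapted
    measurement (the instrument's default induction-curve protocol).
    """

    entries: list[FrameEntry]
    first_pair_is_dark_adapted: bool = True

    def __post_init__(self) -> None:
        self.validate()

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def n_induction_steps(self) -> int:
        return sum(1 for e in self.entries if e.role is FrameRole.Fprime)

    def validate(self) -> None:
        errors: list[str] = []
        for i, e in enumerate(self.entries, start=1):
            if e.frame_index != i:
                errors.append(
                    f"frame_index {e.frame_index} at position {i}: frames must be "
                    "contiguous starting at 1"
                )
        n = len(self.entries)
        if n < 4:
            errors.append(f"a frame map needs at least the 4 header frames, got {n}")
        if n % 2 != 0:
            errors.append(f"frame count must be even (pairs of F'/Fm'), got {n}")
        for i, want in enumerate(_HEADER_ROLES):
            if i < n and self.entries[i].role is not want:
                errors.append(
                    f"frame {i + 1} must be {want.value}, got {self.entries[i].role.value}"
                )
        for e in self.entries[4:]:
            odd = e.frame_index % 2 == 1
            want = FrameRole.Fprime if odd else FrameRole.Fmprime
            if e.role is not want:
                errors.append(
                    f"frame {e.frame_index} must be {want.value}, got {e.role.value}"
                )
                continue
            step = (e.frame_index - 3) // 2
            if e.induction_step != step:
                errors.append(
                    f"frame {e.frame_index} must carry induction step {step}, "
                    f"got {e.induction_step}"
                )
        if errors:
            raise MapValidationError("; ".join(errors))

    def entry(self, role: FrameRole, induction_step: Optional[int] = None) -> FrameEntry:
        """Return the unique entry with this role (and step, for F'/Fm')."""
        matches = [
            e
            for e in self.entries
            if e.role is role
            and (induction_step is None or e.induction_step == induction_step)
        ]
        if not matches:
            raise KeyError(f"no frame with role={role.value}, step={induction_step}")
        if len(matches) > 1:
            raise KeyError(
                f"role={role.value} is ambiguous without an induction step "
                f"({len(matches)} matches)"
            )
        return matches[0]


def parse_filename(name: str | Path) -> MeasurementID:
    """Parse ``treatment-YYYYMMDD-sampleid.tif`` into a :class:`MeasurementID`.

    >>> parse_filename("fluc-20190901-tray2.tif")
    MeasurementID(treatment='fluc', date=datetime.date(2019, 9, 1), sample_id='tray2')
    """
    name = Path(name).name
    stem, dot, ext = name.rpartition(".")
    if not dot or ext.lower() not in ("tif", "tiff"):
        raise FilenameParseError(f"{name!r}: extension must be .tif or .tiff")
    tokens = stem.split("-")
    if len(tokens) != 3:
        raise FilenameParseError(
            f"{name!r}: stem must be treatment-YYYYMMDD-sampleid "
            f"(exactly two hyphens), got {len(tokens)} token(s): {tokens}"
        )
    treatment, datestr, sample_id = tokens
    if not treatment:
        raise FilenameParseError(f"{name!r}: empty treatment token")
    if not sample_id:
        raise FilenameParseError(f"{name!r}: empty sample id token")
    try:
        date = _dt.datetime.strptime(datestr, "%Y%m%d").date()
    except ValueError as exc:
        raise FilenameParseError(
            f"{name!r}: date token {datestr!r} is not a valid YYYYMMDD date"
        ) from exc
    return MeasurementID(treatment=treatment, date=date, sample_id=sample_id)


def format_filename(mid: MeasurementID, ext: str = "tif") -> str:
    """Inverse of :func:`parse_filename` for valid measurement identities."""
    for token, label in ((mid.treatment, "treatment"), (mid.sample_id, "sample_id")):
        if not token or "-" in token:
            raise ValueError(f"{label} {token!r} must be non-empty and hyphen-free")
    return f"{mid.treatment}-{mid.date:%Y%m%d}-{mid.sample_id}.{ext}"


def default_frame_map(
    n_pairs: int = 15, times: Optional[Sequence[float]] = None
) -> FrameMap:
    """Frame map of the instrument's induction-curve protocol.

    The default (``n_pairs=15``) is the 34-frame export: Fo, Fm, two
    absorptivity frames, then 15 F'/Fm' pairs of which the first repeats
    the dark-adapted Fo/Fm.

    Parameters
    ----------
    n_pairs : number of F'/Fm' pairs (induction steps), >= 1.
    times : optional induction times in seconds, one per pair, strictly
        increasing; both frames of a pair share its time.
    """
    if n_pairs < 1:
        raise ValueError(f"n_pairs must be >= 1, got {n_pairs}")
    if times is not None:
        times = list(times)
        if len(times) != n_pairs:
            raise ValueError(f"times must have length {n_pairs}, got {len(times)}")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("times must be strictly increasing")
    entries = [
        FrameEntry(i + 1, role) for i, role in enumerate(_HEADER_ROLES)
    ]
    for k in range(1, n_pairs + 1):
        t = times[k - 1] if times is not None else None
        entries.append(FrameEntry(2 * k + 3, FrameRole.Fprime, k, t))
        entries.append(FrameEntry(2 * k + 4, FrameRole.Fmprime, k, t))
    return FrameMap(entries=entries, first_pair_is_dark_adapted=True)


_FRAME_MAP_HEADER = ["frameid", "parameter", "induction_step", "induction_time"]


def write_frame_map(fmap: FrameMap, path: str | Path) -> None:
    """Write a frame map as CSV (columns frameid, parameter, induction_step,
    induction_time); empty fields for the header frames."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_FRAME_MAP_HEADER)
        for e in fmap.entries:
            w.writerow(
                [
                    e.frame_index,
                    e.role.value,
                    "" if e.induction_step is None else e.induction_step,
                    "" if e.induction_time is None else e.induction_time,
                ]
            )


def load_frame_map(path: str | Path) -> FrameMap:
    """Load and validate a frame-map CSV written by :func:`write_frame_map`."""
    entries: list[FrameEntry] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in _FRAME_MAP_HEADER[:2] if c not in (reader.fieldnames or [])]
        if missing:
            raise MapValidationError(f"{path}: missing column(s) {missing}")
        for row in reader:
            try:
                role = FrameRole(row["parameter"].strip())
            except ValueError as exc:
                raise MapValidationError(
                    f"{path}: unknown parameter {row['parameter']!r}"
                ) from exc
            step_raw = (row.get("induction_step") or "").strip()
            time_raw = (row.get("induction_time") or "").strip()
            entries.append(
                FrameEntry(
                    frame_index=int(row["frameid"]),
                    role=role,
                    induction_step=int(step_raw) if step_raw else None,
                    induction_time=float(time_raw) if time_raw else None,
                )
            )
    entries.sort(key=lambda e: e.frame_index)
    return FrameMap(entries=entries)


@dataclass
class GenotypeMap:
    """Mapping (sample_id, roi_position) -> genotype, loaded from CSV."""

    entries: dict[tuple[str, int], str] = field(default_factory=dict)

    def lookup(self, sample_id: str, roi_position: int, strict: bool = True) -> str:
        key = (sample_id, roi_position)
        if key in self.entries:
            return self.entries[key]
        if strict:
            raise GenotypeLookupError(
                f"no genotype for sample_id={sample_id!r}, roi={roi_position}"
            )
        logger.warning(
            "no genotype for sample_id=%r roi=%d; using sentinel 'unknown'",
            sample_id,
            roi_position,
        )
        return "unknown"

    @property
    def sample_ids(self) -> list[str]:
        return sorted({sid for sid, _ in self.entries})


_GENOTYPE_HEADER = ["sampleid", "roi", "genotype"]


def write_genotype_map(gmap: GenotypeMap, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_GENOTYPE_HEADER)
        for (sid, roi), geno in sorted(gmap.entries.items()):
            w.writerow([sid, roi, geno])


def load_genotype_map(path: str | Path, n_roi: Optional[int] = None) -> GenotypeMap:
    """Load and validate a genotype-map CSV.

    Parameters
    ----------
    n_roi : size of the configured ROI layout; when given, roi positions
        outside ``1..n_roi`` are validation errors.
    """
    entries: dict[tuple[str, int], str] = {}
    errors: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in _GENOTYPE_HEADER if c not in (reader.fieldnames or [])]
        if missing:
            raise MapValidationError(f"{path}: missing column(s) {missing}")
        for lineno, row in enumerate(reader, start=2):
            sid = row["sampleid"].strip()
            try:
                roi = int(row["roi"])
            except ValueError:
                errors.append(f"line {lineno}: roi {row['roi']!r} is not an integer")
                continue
            if roi < 1 or (n_roi is not None and roi > n_roi):
                errors.append(f"line {lineno}: roi {roi} outside layout 1..{n_roi}")
            key = (sid, roi)
            if key in entries:
                errors.append(f"line {lineno}: duplicate entry for {key}")
            entries[key] = row["genotype"].strip()
    if errors:
        raise MapValidationError(f"{path}: " + "; ".join(errors))
    return GenotypeMap(entries=entries)


def lookup_genotype(
    gmap: GenotypeMap, sample_id: str, roi_position: int, strict: bool = True
) -> str:
    """Genotype for one tray/ROI; strict mode raises on a missing entry,
    lenient mode returns the sentinel ``"unknown"`` and logs a warning."""
    return gmap.lookup(sample_id, roi_position, strict=strict)
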