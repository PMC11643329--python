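"""Shared domain types and plain-text readers/writers.

Conventions used across the package:

* point coordinates are in **nm**, areas in **µm²**; conversion to and from
  pixels happens only at image I/O through ``ImageFrame.pixel_size``;
* genomic coordinates are 0-based half-open (BED dialect) everywhere;
* analysis is 2D by default — a ``z`` coordinate, when present, is carried
  through but ignored unless explicitly requested.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("solidhub")

__all__ = [
    "Localization",
    "Trajectory",
    "ImageFrame",
    "GenomicInterval",
    "ContactRecord",
    "RunConfig",
    "InputFormatError",
    "RecordError",
    "ConsistencyError",
    "UndefinedValueError",
    "GenerationError",
    "FitError",
    "read_localizations",
    "write_localizations",
    "read_intervals",
    "write_intervals",
    "read_contacts",
    "write_contacts",
    "read_image",
    "write_image",
]


class InputFormatError(ValueError):
    """The file as a whole is malformed (e.g. a required column is absent)."""


class RecordError(ValueError):
    """A single row/record is invalid; the message carries the line number."""


class ConsistencyError(ValueError):
    """Two inputs that must agree (shapes, resolutions, id spaces) do not."""


class UndefinedValueError(ValueError):
    """The requested statistic is undefined for the given (empty) input."""


class GenerationError(RuntimeError):
    """A synthetic-data generator could not satisfy its placement constraints."""


class FitError(RuntimeError):
    """A curve fit failed to converge; the message carries diagnostics."""


@dataclass(frozen=True)
class Localization:
    """A single-molecule localization: one fluorophore detection in one frame.

    Coordinates are in nm.  ``z`` is optional and unused by the default 2D
    analysis.  ``channel`` and ``cell_id`` are small integer labels used to
    group localizations before tracking.
    """

    frame: int
    x: float
    y: float
    z: float | None = None
    channel: int = 0
    cell_id: int = 0

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise ValueError(f"frame must be >= 0, got {self.frame}")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite coordinate ({self.x}, {self.y})")
        if self.z is not None and not math.isfinite(self.z):
            raise ValueError(f"non-finite z coordinate {self.z}")


@dataclass(frozen=True)
class Trajectory:
    """A frame-linked chain of localizations with no gaps.

    Frames increase strictly by exactly 1 and all points share a channel and
    cell; both are enforced at construction.
    """

    id: int
    points: tuple[Localization, ...]

    def __init__(self, id: int, points: Sequence[Localization]) -> None:
        points = tuple(points)
        if not points:
            raise ValueError("a trajectory needs at least one localization")
        frames = [p.frame for p in points]
        for a, b in zip(frames, frames[1:]):
            if b != a + 1:
                raise ValueError(f"gap or disorder in frames: {a} -> {b}")
        if len({(p.channel, p.cell_id) for p in points}) != 1:
            raise ValueError("all points of a trajectory must share channel and cell")
        object.__setattr__(self, "id", id)
        object.__setattr__(self, "points", points)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def n_steps(self) -> int:
        """Number of frame-to-frame displacements (length − 1)."""
        return len(self.points) - 1

    def duration_ms(self, frame_interval_ms: float) -> float:
        return self.n_steps * frame_interval_ms

    def xy(self) -> np.ndarray:
        """(n, 2) array of coordinates in nm."""
        return np.array([(p.x, p.y) for p in self.points], dtype=float)


@dataclass
class ImageFrame:
    """A 2D grayscale image with physical pixel size in µm."""

    pixels: np.ndarray
    pixel_size: float  # µm per pixel
    channel: int = 0
    time_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2D, got shape {self.pixels.shape}")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval [start, end) with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"need 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of + - ., got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Overlap length in bp with another interval (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class ContactRecord:
    """One binned, normalized Hi-C contact between two genomic bins.

    ``bin_a``/``bin_b`` are bin start coordinates (bp) at a fixed
    ``resolution``; ``value`` is the balanced (ICE-normalized) contact
    probability.
    """

    chrom_a: str
    bin_a: int
    chrom_b: str
    bin_b: int
    resolution: int
    value: float

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.bin_a % self.resolution or self.bin_b % self.resolution:
            raise ValueError(
                f"bins ({self.bin_a}, {self.bin_b}) must be multiples of the "
                f"resolution {self.resolution}"
            )
        if not (math.isfinite(self.value) and self.value >= 0):
            raise ValueError(f"contact value must be finite and >= 0, got {self.value}")

    @property
    def is_trans(self) -> bool:
        return self.chrom_a != self.chrom_b

    def canonical(self) -> "ContactRecord":
        """The same contact with (chrom, bin) pairs in sorted order."""
        if (self.chrom_a, self.bin_a) <= (self.chrom_b, self.bin_b):
            return self
        return ContactRecord(
            self.chrom_b, self.bin_b, self.chrom_a, self.bin_a,
            self.resolution, self.value,
        )


@dataclass
class RunConfig:
    """Analysis parameters with the defaults used throughout the package.

    Tracking and condensate-membership defaults: 400 nm maximum linking
    distance with no gaps; a localization counts as inside a condensate when
    strictly more than 4 other localizations fall within 7.5 nm of it pooled
    over the whole acquisition; trajectories enter displacement statistics
    when they have at least 5 points and span at least 80 ms.
    """

    frame_interval_ms: float = 20.0
    max_link_distance_nm: float = 400.0
    condensate_radius_nm: float = 7.5
    condensate_min_neighbors: int = 4
    min_track_points: int = 5
    min_track_duration_ms: float = 80.0
    rng_seed: int = 0
    # imaging
    edge_sigma_px: float = 2.5
    close_radius_px: int = 2
    open_radius_px: int = 2
    erode_radius_px: int = 0
    min_area_um2: float = 0.05
    background_radius_px: int = 25
    hub_min_overlap_frac: float = 0.25
    # genomics
    contact_resolution_bp: int = 5000
    contact_cutoff: float = 2.0
    motif_min_coverage: float = 0.9

    def __post_init__(self) -> None:
        for name in (
            "frame_interval_ms", "max_link_distance_nm", "condensate_radius_nm",
            "min_track_duration_ms", "edge_sigma_px", "min_area_um2",
            "contact_resolution_bp", "contact_cutoff",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.min_track_points < 1:
            raise ValueError("min_track_points must be >= 1")
        if self.condensate_min_neighbors < 0:
            raise ValueError("condensate_min_neighbors must be >= 0")

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)


# ---------------------------------------------------------------------------
# localization tables


_LOC_ALIASES = {
    "x": ("x", "x_nm"),
    "y": ("y", "y_nm"),
    "z": ("z", "z_nm"),
    "frame": ("frame",),
    "channel": ("channel",),
    "cell_id": ("cell_id", "cell"),
}


def _resolve_column(columns: Iterable[str], key: str) -> str | None:
    lower = {c.lower(): c for c in columns}
    for alias in _LOC_ALIASES[key]:
        if alias in lower:
            return lower[alias]
    return None


def read_localizations(path: str | Path, config: RunConfig | None = None) -> list[Localization]:
    """Read a delimited localization table (header with frame, x, y in nm).

    Optional columns ``z``/``z_nm``, ``channel`` and ``cell``/``cell_id`` are
    honoured when present.  Row order is preserved.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {key: _resolve_column(df.columns, key) for key in _LOC_ALIASES}
    missing = [k for k in ("frame", "x", "y") if cols[k] is None]
    if missing:
        raise InputFormatError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    out: list[Localization] = []
    for i, row in enumerate(df.itertuples(index=False)):
        rowd = dict(zip(df.columns, row))
        try:
            out.append(
                Localization(
                    frame=int(rowd[cols["frame"]]),
                    x=float(rowd[cols["x"]]),
                    y=float(rowd[cols["y"]]),
                    z=float(rowd[cols["z"]]) if cols["z"] else None,
                    channel=int(rowd[cols["channel"]]) if cols["channel"] else 0,
                    cell_id=int(rowd[cols["cell_id"]]) if cols["cell_id"] else 0,
                )
            )
        except (TypeError, ValueError) as exc:
            raise RecordError(f"{path}: line {i + 2}: {exc}") from exc
    log.info("read %d localizations from %s", len(out), path)
    return out


def write_localizations(path: str | Path, locs: Sequence[Localization]) -> None:
    has_z = any(p.z is not None for p in locs)
    cols = ["frame", "x_nm", "y_nm"] + (["z_nm"] if has_z else []) + ["channel", "cell"]
    rows = []
    for p in locs:
        row = [p.frame, p.x, p.y] + ([p.z if p.z is not None else ""] if has_z else [])
        rows.append(row + [p.channel, p.cell_id])
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# BED intervals


def read_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read a 3+ column BED file into 0-based half-open intervals.

    Strand is taken from column 6 when present, else ".".
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise RecordError(f"{path}: line {lineno}: fewer than 3 BED columns")
            try:
                strand = fields[5] if len(fields) >= 6 else "."
                out.append(
                    GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
                )
            except ValueError as exc:
                raise RecordError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_intervals(path: str | Path, intervals: Sequence[GenomicInterval]) -> None:
    """Write intervals as 6-column BED (name ".", score 0, strand kept)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# contact lists


_CONTACT_COLS = ["chromA", "binA", "chromB", "binB", "value"]


def read_contacts(path: str | Path, resolution: int) -> list[ContactRecord]:
    """Read a 5-column contact list (chromA binA chromB binB value)."""
    df = pd.read_csv(path, sep=None, engine="python")
    lower = {c.lower(): c for c in df.columns}
    missing = [c for c in _CONTACT_COLS if c.lower() not in lower]
    if missing:
        raise InputFormatError(f"{path}: missing column(s) {missing}")
    out: list[ContactRecord] = []
    for i, row in df.iterrows():
        try:
            out.append(
                ContactRecord(
                    str(row[lower["chroma"]]), int(row[lower["bina"]]),
                    str(row[lower["chromb"]]), int(row[lower["binb"]]),
                    resolution, float(row[lower["value"]]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise RecordError(f"{path}: line {i + 2}: {exc}") from exc
    return out


def write_contacts(path: str | Path, contacts: Sequence[ContactRecord]) -> None:
    rows = [
        (c.chrom_a, c.bin_a, c.chrom_b, c.bin_b, c.value) for c in contacts
    ]
    pd.DataFrame(rows, columns=_CONTACT_COLS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# images


def read_image(path: str | Path, pixel_size: float, channel: int = 0,
               time_index: int = 0) -> ImageFrame:
    import tifffile

    return ImageFrame(tifffile.imread(path), pixel_size, channel, time_index)


def write_image(path: str | Path, frame: ImageFrame) -> None:
    import tifffile

    tifffile.imwrite(path, np.asarray(frame.pixels, dtype=np.float32))
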