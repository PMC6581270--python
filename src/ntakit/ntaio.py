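"""Reading, writing and combining NanoSight-style experiment-summary files.

Nanoparticle tracking analysis (NTA) instruments export one table per
experiment: a short preamble of ``key: value`` metadata lines, then a
header row naming every measurement, then one row per particle-size bin
holding the measured concentration (particles/mL) in that bin for each
measurement.  The dialect accepted here is:

* UTF-8 text, comma separated, ``.`` decimal separator;
* a preamble of ``key: value`` lines that must include
  ``NTA Version: <x.y>`` and may include ``Bin width (nm)``,
  ``Size min (nm)`` and ``Size max (nm)``; unknown keys are preserved
  verbatim in order;
* a header row whose first cell is ``Bin centre (nm)`` followed by one
  unique, non-empty name per measurement;
* one data row per bin: the bin centre, then one non-negative count per
  measurement.  Blank cells are errors, never silently zero.

Bins are half-open intervals ``[centre - w/2, centre + w/2)`` on a
uniform grid of width ``w`` nanometres.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import FormatError, GridMismatchError, VersionError

__all__ = [
    "AcquisitionMeta",
    "WideExperimentTable",
    "read_experiment_summary",
    "write_experiment_summary",
    "combine_experiments",
    "tables_allclose",
]

logger = logging.getLogger(__name__)

HEADER_FIRST_CELL = "Bin centre (nm)"
VERSION_KEY = "NTA Version"
BIN_WIDTH_KEY = "Bin width (nm)"
SIZE_MIN_KEY = "Size min (nm)"
SIZE_MAX_KEY = "Size max (nm)"
KNOWN_VERSION = "3.2"
_REL_TOL = 1e-9


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition metadata from the file preamble.

    Parameters
    ----------
    software_version : str
        Version token of the NTA export software, e.g. ``"3.2"``.
    bin_width : float
        Histogram bin width in nm, > 0.
    size_min, size_max : float
        Lower/upper edge of the size grid in nm; the span must be an
        integer multiple of ``bin_width``.
    extra : tuple of (str, str)
        Preamble lines other than the recognised keys, in file order.
    """

    software_version: str
    bin_width: float
    size_min: float
    size_max: float
    extra: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.software_version:
            raise VersionError("software_version must be a non-empty token")
        if not (self.bin_width > 0):
            raise FormatError(f"bin_width must be > 0, got {self.bin_width}")
        if not (self.size_min >= 0):
            raise FormatError(f"size_min must be >= 0, got {self.size_min}")
        if not (self.size_max > self.size_min):
            raise FormatError(
                f"size_max ({self.size_max}) must exceed size_min ({self.size_min})"
            )
        span = self.size_max - self.size_min
        n = span / self.bin_width
        if abs(n - round(n)) > _REL_TOL * max(1.0, n):
            raise FormatError(
                f"size span {span} nm is not an integer multiple of "
                f"bin width {self.bin_width} nm"
            )

    @property
    def n_bins(self) -> int:
        return round((self.size_max - self.size_min) / self.bin_width)

    def bin_centers(self) -> np.ndarray:
        """Centres of the half-open bins, ``size_min + w/2 .. size_max - w/2``."""
        return self.size_min + self.bin_width * (np.arange(self.n_bins) + 0.5)


@dataclass(frozen=True)
class WideExperimentTable:
    """One experiment in instrument-export ('wide') layout.

    ``counts[i, j]`` is the concentration (particles/mL) in size bin
    ``bin_centers[i]`` for measurement ``measurement_names[j]``.
    """

    meta: AcquisitionMeta
    bin_centers: np.ndarray
    measurement_names: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        centers = np.asarray(self.bin_centers, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "bin_centers", centers)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "measurement_names", tuple(self.measurement_names))
        if centers.ndim != 1 or counts.ndim != 2:
            raise FormatError("bin_centers must be 1-D and counts 2-D")
        if counts.shape != (centers.size, len(self.measurement_names)):
            raise FormatError(
                f"counts shape {counts.shape} does not match "
                f"{centers.size} bins x {len(self.measurement_names)} measurements"
            )
        if len(self.measurement_names) == 0:
            raise FormatError("a table needs at least one measurement")
        if any(not name for name in self.measurement_names):
            raise FormatError("measurement names must be non-empty")
        if len(set(self.measurement_names)) != len(self.measurement_names):
            dupes = _duplicates(self.measurement_names)
            raise FormatError(f"duplicate measurement names: {sorted(dupes)}")
        _check_grid(centers, self.meta)
        if not np.all(np.isfinite(counts)):
            raise FormatError("counts must be finite")
        if np.any(counts < 0):
            raise FormatError("counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.bin_centers.size

    @property
    def n_measurements(self) -> int:
        return len(self.measurement_names)

    def to_frame(self) -> pd.DataFrame:
        """Counts as a DataFrame indexed by bin centre (nm)."""
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.bin_centers, name="particle_size"),
            columns=list(self.measurement_names),
        )


def _duplicates(names) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for n in names:
        (dupes if n in seen else seen).add(n)
    return dupes


def _check_grid(centers: np.ndarray, meta: AcquisitionMeta) -> None:
    expected = meta.bin_centers()
    if centers.size != expected.size:
        raise FormatError(
            f"{centers.size} bin rows but metadata implies {expected.size} bins"
        )
    scale = max(1.0, float(meta.size_max))
    if not np.allclose(centers, expected, rtol=0.0, atol=_REL_TOL * scale):
        raise FormatError(
            "bin centres are not uniformly spaced on the declared grid "
            f"({meta.size_min}..{meta.size_max} nm at {meta.bin_width} nm)"
        )


def _num(x: float) -> str:
    """Compact decimal rendering, round-trippable well within 1e-9."""
    return format(float(x), ".12g")


def read_experiment_summary(
    path,
    particle_range: tuple[float, float] | None = None,
    bin_width: float | None = None,
) -> WideExperimentTable:
    """Parse one experiment-summary file.

    The number of measurements is always inferred from the header row.
    ``particle_range`` and ``bin_width`` override the preamble values;
    either way the bin-centre column must agree with the resulting grid.

    Raises
    ------
    VersionError
        No ``NTA Version`` line in the preamble.
    FormatError
        Blank or non-numeric cells, duplicate names, or a bin column
        inconsistent with the declared grid.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()

    version: str | None = None
    extra: list[tuple[str, str]] = []
    declared: dict[str, float] = {}
    header_idx = None
    for i, line in enumerate(lines):
        if line.split(",")[0].strip() == HEADER_FIRST_CELL:
            header_idx = i
            break
        if not line.strip():
            continue
        key, sep, value = line.partition(":")
        if not sep:
            raise FormatError(f"{path}: preamble line {i + 1} is not 'key: value'")
        key, value = key.strip(), value.strip()
        if key == VERSION_KEY:
            if not value:
                raise VersionError(f"{path}: empty '{VERSION_KEY}' value")
            version = value
        elif key in (BIN_WIDTH_KEY, SIZE_MIN_KEY, SIZE_MAX_KEY):
            try:
                declared[key] = float(value)
            except ValueError:
                raise FormatError(f"{path}: non-numeric value for '{key}': {value!r}")
        else:
            extra.append((key, value))
    if header_idx is None:
        raise FormatError(f"{path}: no '{HEADER_FIRST_CELL}' header row found")
    if version is None:
        raise VersionError(f"{path}: preamble has no '{VERSION_KEY}' line")
    if version != KNOWN_VERSION:
        logger.warning(
            "%s: NTA software version %r differs from the tested version %r; "
            "parsing with the same dialect",
            path, version, KNOWN_VERSION,
        )

    header = [c.strip() for c in lines[header_idx].split(",")]
    names = header[1:]
    if not names:
        raise FormatError(f"{path}: header row declares no measurements")
    if any(not n for n in names):
        raise FormatError(f"{path}: blank measurement name in header row")
    dupes = _duplicates(names)
    if dupes:
        raise FormatError(f"{path}: duplicate measurement names: {sorted(dupes)}")

    data_rows = [ln for ln in lines[header_idx + 1:] if ln.strip()]
    if not data_rows:
        raise FormatError(f"{path}: no data rows after the header")
    centers = np.empty(len(data_rows))
    counts = np.empty((len(data_rows), len(names)))
    for r, line in enumerate(data_rows):
        cells = line.split(",")
        if len(cells) != len(names) + 1:
            raise FormatError(
                f"{path}: row {header_idx + 2 + r} has {len(cells)} cells, "
                f"expected {len(names) + 1}"
            )
        for c, cell in enumerate(cells):
            text = cell.strip()
            if not text:
                raise FormatError(
                    f"{path}: blank cell at row {header_idx + 2 + r}, "
                    f"column {c + 1} ({'bin centre' if c == 0 else names[c - 1]})"
                )
            try:
                value = float(text)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric cell {text!r} at row "
                    f"{header_idx + 2 + r}, column {c + 1}"
                )
            if c == 0:
                centers[r] = value
            else:
                counts[r, c - 1] = value

    # Resolve the grid: explicit arguments beat preamble, preamble beats inference.
    w = bin_width if bin_width is not None else declared.get(BIN_WIDTH_KEY)
    if w is None:
        if centers.size < 2:
            raise FormatError(
                f"{path}: cannot infer bin width from a single bin; "
                "declare it in the preamble or pass bin_width"
            )
        w = float(np.median(np.diff(centers)))
    if particle_range is not None:
        lo, hi = float(particle_range[0]), float(particle_range[1])
    else:
        lo = declared.get(SIZE_MIN_KEY, centers[0] - w / 2)
        hi = declared.get(SIZE_MAX_KEY, centers[-1] + w / 2)

    diffs = np.diff(centers)
    if centers.size > 1 and not np.allclose(diffs, w, rtol=_REL_TOL, atol=_REL_TOL * w):
        raise FormatError(f"{path}: bin spacing is not uniform at width {w} nm")

    meta = AcquisitionMeta(
        software_version=version,
        bin_width=float(w),
        size_min=float(lo),
        size_max=float(hi),
        extra=tuple(extra),
    )
    table = WideExperimentTable(
        meta=meta, bin_centers=centers, measurement_names=tuple(names), counts=counts
    )
    logger.info(
        "read %s: version %s, %d bins (%g..%g nm), %d measurements",
        path, version, table.n_bins, lo, hi, table.n_measurements,
    )
    return table


def write_experiment_summary(table: WideExperimentTable, path) -> None:
    """Emit ``table`` in the experiment-summary dialect.

    Deterministic: writing the same table twice yields byte-identical
    files, and ``read(write(T))`` reproduces ``T`` (metadata exactly,
    counts within relative 1e-9).
    """
    m = table.meta
    lines = [
        f"{VERSION_KEY}: {m.software_version}",
        f"{BIN_WIDTH_KEY}: {_num(m.bin_width)}",
        f"{SIZE_MIN_KEY}: {_num(m.size_min)}",
        f"{SIZE_MAX_KEY}: {_num(m.size_max)}",
    ]
    lines += [f"{k}: {v}" for k, v in m.extra]
    lines.append(",".join([HEADER_FIRST_CELL, *table.measurement_names]))
    for i in range(table.n_bins):
        row = [_num(table.bin_centers[i])]
        row += [_num(v) for v in table.counts[i]]
        lines.append(",".join(row))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def combine_experiments(tables) -> WideExperimentTable:
    """Column-wise concatenation of experiments sharing one bin grid.

    Metadata comes from the first table, with a ``Combined`` note
    appended when more than one file is merged.  Measurement order is
    input order; duplicate names across inputs are an error.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("combine_experiments needs at least one table")
    first = tables[0]
    if len(tables) == 1:
        return first
    for t in tables[1:]:
        if t.n_bins != first.n_bins or not math.isclose(
            t.meta.bin_width, first.meta.bin_width, rel_tol=_REL_TOL
        ):
            raise GridMismatchError(
                f"bin grids differ: {first.n_bins} bins at {first.meta.bin_width} nm "
                f"vs {t.n_bins} bins at {t.meta.bin_width} nm"
            )
        if not np.allclose(t.bin_centers, first.bin_centers, rtol=_REL_TOL):
            raise GridMismatchError("bin centres differ between tables")
    names: list[str] = []
    for t in tables:
        names.extend(t.measurement_names)
    dupes = _duplicates(names)
    if dupes:
        raise FormatError(
            f"duplicate measurement names across combined tables: {sorted(dupes)}"
        )
    meta = replace(
        first.meta,
        extra=first.meta.extra + (("Combined", f"{len(tables)} tables"),),
    )
    return WideExperimentTable(
        meta=meta,
        bin_centers=first.bin_centers,
        measurement_names=tuple(names),
        counts=np.hstack([t.counts for t in tables]),
    )


def tables_allclose(a: WideExperimentTable, b: WideExperimentTable,
                    rtol: float = _REL_TOL) -> bool:
    """Metadata-exact, counts-within-``rtol`` equality of two tables."""
    return (
        a.meta.software_version == b.meta.software_version
        and math.isclose(a.meta.bin_width, b.meta.bin_width, rel_tol=rtol)
        and math.isclose(a.meta.size_min, b.meta.size_min, rel_tol=rtol, abs_tol=rtol)
        and math.isclose(a.meta.size_max, b.meta.size_max, rel_tol=rtol)
        and a.measurement_names == b.measurement_names
        and a.counts.shape == b.counts.shape
        and np.allclose(a.bin_centers, b.bin_centers, rtol=rtol)
        and np.allclose(a.counts, b.counts, rtol=rtol, atol=0.0)
    )
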