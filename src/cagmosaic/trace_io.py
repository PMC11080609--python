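"""I/O for fragment-analysis peak tables and clinical visit tables.

Fragment-sizing software (e.g. GeneMapper) exports one row per called peak:
sample name, called allele, peak size in base pairs, peak height, area under
the peak and the scan/data-point index of the apex.  This module reads such
exports into :class:`Trace` objects, joins sample-sheet metadata, and maps
peak sizes in bp to integer CAG repeat counts through a per-plate internal
standard (:class:`SizeCalibration`).

Peak *calling* from raw fluorescence and binary chromatogram containers
(ABIF/.fsa) are out of scope: the pipeline starts at called peak tables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from cagmosaic.errors import (
    CalibrationError,
    PeakRowParseError,
    PeakTableFormatError,
)

logger = logging.getLogger(__name__)

SUPPORTED_GENES = ("ATXN1", "ATXN2", "ATXN3", "ATXN7")

#: Lower bound (in repeats) of the pathological range per locus; used as the
#: default lower edge of the expanded-allele analysis window.
PATHOLOGICAL_THRESHOLD = {"ATXN1": 39, "ATXN2": 33, "ATXN3": 55, "ATXN7": 36}


def round_half_away(x: float) -> int:
    """Round to the nearest integer with ties going away from zero.

    Electrophoretic mobility drift is sub-repeat, so nearest-repeat binning
    with a deterministic tie rule is used throughout.
    """
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


@dataclass(frozen=True)
class Peak:
    """One called fluorescence peak of a fragment-sizing trace."""

    size_bp: float
    height: float
    area: float | None = None
    scan: int | None = None

    def __post_init__(self):
        if not self.size_bp > 0:
            raise ValueError(f"peak size must be positive, got {self.size_bp}")
        if self.height < 0:
            raise ValueError(f"peak height must be >= 0, got {self.height}")


@dataclass
class Trace:
    """All peaks of one sample, plus the metadata the cohort analyses need."""

    sample_id: str
    peaks: list[Peak]
    individual_id: str | None = None
    gene: str | None = None
    tissue: str | None = None
    age_at_sample: float | None = None
    plate_id: str | None = None

    def __post_init__(self):
        if not self.peaks:
            raise ValueError(f"trace {self.sample_id!r} has no peaks")
        if self.gene is not None and self.gene not in SUPPORTED_GENES:
            raise ValueError(
                f"unsupported gene {self.gene!r}; expected one of {SUPPORTED_GENES}"
            )
        self.peaks = sorted(self.peaks, key=lambda p: p.size_bp)

    def scaled(self, factor: float) -> "Trace":
        """Return a copy with every peak height multiplied by ``factor``."""
        peaks = [replace(p, height=p.height * factor) for p in self.peaks]
        return Trace(
            sample_id=self.sample_id,
            peaks=peaks,
            individual_id=self.individual_id,
            gene=self.gene,
            tissue=self.tissue,
            age_at_sample=self.age_at_sample,
            plate_id=self.plate_id,
        )


@dataclass(frozen=True)
class SizeCalibration:
    """Linear bp-to-CAG map anchored on a plate's internal-standard sample.

    A sample of known repeat count is run on every plate; its modal peak size
    (``anchor_bp``) pins the map, and CAG is a trinucleotide so the default
    slope is 3 bp per repeat.
    """

    anchor_bp: float
    anchor_cag: int
    plate_id: str | None = None
    gene: str | None = None
    repeat_unit_bp: float = 3.0

    def __post_init__(self):
        if not self.repeat_unit_bp > 0:
            raise CalibrationError(
                f"repeat_unit_bp must be positive, got {self.repeat_unit_bp}"
            )
        if self.anchor_cag < 1:
            raise CalibrationError(f"anchor_cag must be >= 1, got {self.anchor_cag}")

    def cag_to_bp(self, cag: int) -> float:
        return self.anchor_bp + (cag - self.anchor_cag) * self.repeat_unit_bp


def bp_to_cag(size_bp: float, cal: SizeCalibration) -> int:
    """Map a peak size in bp to an integer CAG count via the plate standard.

    ``anchor_cag + round((size_bp - anchor_bp) / repeat_unit_bp)`` with
    rounding half away from zero.  A computed repeat below 1 indicates a
    peak far outside the calibrated range and raises
    :class:`~cagmosaic.errors.CalibrationError`.
    """
    cag = cal.anchor_cag + round_half_away((size_bp - cal.anchor_bp) / cal.repeat_unit_bp)
    if cag < 1:
        raise CalibrationError(
            f"size {size_bp} bp maps to repeat count {cag} < 1 "
            f"(anchor {cal.anchor_bp} bp = {cal.anchor_cag} CAG)"
        )
    return cag


@dataclass(frozen=True)
class VisitRecord:
    """One individual-visit of the longitudinal cohort."""

    individual_id: str
    gene: str
    age: float
    cag_n: int
    sara: float | None = None
    disease_duration: float | None = None
    status_clinical: str | None = None  # premanifest | manifest
    status_sara: str | None = None  # preataxic | ataxic
    ei: float | None = None

    #: SARA cutoff separating preataxic from ataxic carriers.
    SARA_ATAXIA_CUTOFF = 3.5

    def __post_init__(self):
        if self.sara is not None and not 0 <= self.sara <= 40:
            raise ValueError(f"SARA must lie in [0, 40], got {self.sara}")
        if self.sara is not None:
            expected = "ataxic" if self.sara > self.SARA_ATAXIA_CUTOFF else "preataxic"
            if self.status_sara is None:
                object.__setattr__(self, "status_sara", expected)
            elif self.status_sara != expected:
                raise ValueError(
                    f"status_sara {self.status_sara!r} inconsistent with "
                    f"SARA {self.sara} (cutoff {self.SARA_ATAXIA_CUTOFF})"
                )


@dataclass(frozen=True)
class TableDialect:
    """Column-name mapping for a peak-table export format."""

    sample: str = "sample"
    size_bp: str = "size_bp"
    height: str = "height"
    area: str | None = "area"
    scan: str | None = "scan"
    sep: str = "\t"

    @property
    def mandatory(self) -> tuple[str, str, str]:
        return (self.sample, self.size_bp, self.height)


#: Dialect matching the field list of a GeneMapper sample-plot export.
GENEMAPPER_DIALECT = TableDialect(
    sample="Sample Name",
    size_bp="Size",
    height="Height",
    area="Area",
    scan="Data Point",
)

DEFAULT_DIALECT = TableDialect()


def _parse_number(value, column: str, line: int) -> float:
    try:
        out = float(value)
    except (TypeError, ValueError):
        raise PeakRowParseError(
            f"line {line}: non-numeric value {value!r} in column {column!r}",
            line=line,
        ) from None
    if math.isnan(out):
        raise PeakRowParseError(
            f"line {line}: missing value in column {column!r}", line=line
        )
    return out


def read_peak_table(
    path: str | Path,
    dialect: TableDialect = DEFAULT_DIALECT,
    sample_sheet: str | Path | pd.DataFrame | None = None,
) -> list[Trace]:
    """Read a peak-table export into one :class:`Trace` per sample.

    Parameters
    ----------
    path:
        TSV/CSV file with one row per called peak.
    dialect:
        Column-name mapping; :data:`GENEMAPPER_DIALECT` matches the sizing
        software's export fields, :data:`DEFAULT_DIALECT` the package's own
        normalized column names.
    sample_sheet:
        Optional table (path or DataFrame) keyed by ``sample_id`` supplying
        ``individual_id``, ``gene``, ``tissue``, ``age``, ``plate_id``.

    Peaks are sorted by size.  A header-only file yields an empty list with
    a logged warning.
    """
    df = pd.read_csv(path, sep=dialect.sep, dtype=str)
    for col in dialect.mandatory:
        if col not in df.columns:
            raise PeakTableFormatError(
                f"{path}: mandatory column {col!r} is missing "
                f"(found: {list(df.columns)})"
            )
    if df.empty:
        logger.warning("%s: peak table has a header but no rows", path)
        return []

    meta: Mapping[str, dict] = {}
    if sample_sheet is not None:
        sheet = (
            sample_sheet
            if isinstance(sample_sheet, pd.DataFrame)
            else pd.read_csv(sample_sheet, sep="\t")
        )
        if "sample_id" not in sheet.columns:
            raise PeakTableFormatError("sample sheet lacks a 'sample_id' column")
        meta = sheet.set_index("sample_id").to_dict(orient="index")

    traces: list[Trace] = []
    for sample_id, rows in df.groupby(dialect.sample, sort=False):
        peaks = []
        for idx, row in rows.iterrows():
            line = idx + 2  # header is line 1
            size = _parse_number(row[dialect.size_bp], dialect.size_bp, line)
            height = _parse_number(row[dialect.height], dialect.height, line)
            area = scan = None
            if dialect.area and dialect.area in rows.columns:
                raw = row[dialect.area]
                if pd.notna(raw) and str(raw).strip():
                    area = _parse_number(raw, dialect.area, line)
            if dialect.scan and dialect.scan in rows.columns:
                raw = row[dialect.scan]
                if pd.notna(raw) and str(raw).strip():
                    scan = int(_parse_number(raw, dialect.scan, line))
            peaks.append(Peak(size_bp=size, height=height, area=area, scan=scan))
        info = meta.get(sample_id, {})
        age = info.get("age")
        traces.append(
            Trace(
                sample_id=str(sample_id),
                peaks=peaks,
                individual_id=info.get("individual_id"),
                gene=info.get("gene"),
                tissue=info.get("tissue"),
                age_at_sample=float(age) if age is not None and pd.notna(age) else None,
                plate_id=info.get("plate_id"),
            )
        )
    return traces


def write_peak_table(
    traces: Iterable[Trace], path: str | Path, dialect: TableDialect = DEFAULT_DIALECT
) -> None:
    """Write traces back to a peak table readable by :func:`read_peak_table`."""
    rows = []
    for tr in traces:
        for p in tr.peaks:
            row = {
                dialect.sample: tr.sample_id,
                dialect.size_bp: p.size_bp,
                dialect.height: p.height,
            }
            if dialect.area:
                row[dialect.area] = p.area
            if dialect.scan:
                row[dialect.scan] = p.scan
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=dialect.sep, index=False)


def normalize_traces(
    traces: Iterable[Trace], calibrations: Mapping[tuple, SizeCalibration] | SizeCalibration
) -> pd.DataFrame:
    """Flatten traces into the normalized long table used downstream.

    Columns: ``sample_id, individual_id, gene, tissue, cag, height``.
    ``calibrations`` is either a single calibration or a mapping keyed by
    ``(plate_id, gene)``.
    """
    rows = []
    for tr in traces:
        cal = (
            calibrations
            if isinstance(calibrations, SizeCalibration)
            else calibrations[(tr.plate_id, tr.gene)]
        )
        for p in tr.peaks:
            rows.append(
                {
                    "sample_id": tr.sample_id,
                    "individual_id": tr.individual_id,
                    "gene": tr.gene,
                    "tissue": tr.tissue,
                    "cag": bp_to_cag(p.size_bp, cal),
                    "height": p.height,
                }
            )
    return pd.DataFrame(rows)


def read_visit_table(path: str | Path) -> pd.DataFrame:
    """Read the clinical visit table (TSV) used by the cohort analyses.

    Expects at least ``individual_id, gene, age, cag_n``; optional columns
    ``sara, disease_duration, status_clinical, status_sara, ei`` are carried
    through.  ``status_sara`` is derived from SARA (> 3.5 means ataxic) when
    absent.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"individual_id", "gene", "age", "cag_n"}
    missing = required - set(df.columns)
    if missing:
        raise PeakTableFormatError(
            f"{path}: visit table is missing columns {sorted(missing)}"
        )
    if "status_sara" not in df.columns and "sara" in df.columns:
        df["status_sara"] = df["sara"].map(
            lambda s: None
            if pd.isna(s)
            else ("ataxic" if s > VisitRecord.SARA_ATAXIA_CUTOFF else "preataxic")
        )
    return df


def load_calibrations(path: str | Path) -> dict[tuple, SizeCalibration]:
    """Load per-plate calibrations from a YAML file.

    The file holds a list of mappings with keys ``plate_id, gene, anchor_bp,
    anchor_cag`` and optional ``repeat_unit_bp``.
    """
    with open(path) as fh:
        entries = yaml.safe_load(fh) or []
    out: dict[tuple, SizeCalibration] = {}
    for entry in entries:
        cal = SizeCalibration(**entry)
        out[(cal.plate_id, cal.gene)] = cal
    return out
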