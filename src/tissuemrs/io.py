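"""Spectra/metadata containers, delimited-text I/O and run configuration.

The on-disk format for a spectra matrix is delimited text: the first row
is the chemical-shift (ppm) axis, every following row is one sample, the
first column holds the sample id.  Metadata is a delimited table with
columns ``sample_id, patient_id, tumor_content_pct, fat_pct,
connective_pct, glandular_pct, necrotic_pct``.

In-memory, the ppm axis is canonically *descending* (NMR plotting
convention); readers reorder columns if a file stores the axis
ascending.  All interval arguments throughout the package are given as
``(upper, lower)`` ppm pairs, interpreted inclusively on the grid.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("tissuemrs")

METADATA_COLUMNS = [
    "sample_id",
    "patient_id",
    "tumor_content_pct",
    "fat_pct",
    "connective_pct",
    "glandular_pct",
    "necrotic_pct",
]


class SpectraFormatError(ValueError):
    """Raised when a spectra or metadata file violates the format contract."""


@dataclass
class SpectrumSet:
    """A set of 1D spectra on a shared chemical-shift axis.

    Attributes
    ----------
    intensities : (n_samples, n_variables) float array, arbitrary units.
    ppm : (n_variables,) strictly descending chemical-shift axis.
    sample_ids : unique sample identifiers, one per row.
    """

    intensities: np.ndarray
    ppm: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.intensities.ndim != 2:
            raise SpectraFormatError("intensities must be a 2D matrix")
        n, p = self.intensities.shape
        if self.ppm.shape != (p,):
            raise SpectraFormatError(
                f"ppm axis length {self.ppm.shape} does not match {p} variables"
            )
        if len(self.sample_ids) != n:
            raise SpectraFormatError("sample id count does not match row count")
        if len(set(self.sample_ids)) != n:
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise SpectraFormatError(f"duplicate sample ids: {dupes}")
        d = np.diff(self.ppm)
        if np.any(d >= 0):
            if np.all(d > 0):  # ascending input: canonicalize
                self.ppm = self.ppm[::-1].copy()
                self.intensities = self.intensities[:, ::-1].copy()
            else:
                raise SpectraFormatError("ppm axis is not strictly monotone")
        if not np.all(np.isfinite(self.intensities)):
            bad = np.argwhere(~np.isfinite(self.intensities))[0]
            raise SpectraFormatError(
                f"non-finite intensity at row {bad[0]} column {bad[1]}"
            )

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_variables(self) -> int:
        return self.intensities.shape[1]

    def copy(self) -> "SpectrumSet":
        return SpectrumSet(
            self.intensities.copy(), self.ppm.copy(), list(self.sample_ids)
        )

    def take_variables(self, mask: np.ndarray) -> "SpectrumSet":
        """Return a new set keeping only the variables where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.ppm.shape:
            raise ValueError("mask length does not match variable count")
        return SpectrumSet(
            self.intensities[:, mask], self.ppm[mask], list(self.sample_ids)
        )

    def window_mask(self, upper: float, lower: float) -> np.ndarray:
        """Boolean mask of grid points with ``lower <= ppm <= upper``."""
        if upper < lower:
            raise ValueError("interval must be given as (upper, lower)")
        return (self.ppm >= lower) & (self.ppm <= upper)


def write_spectra(spectra: SpectrumSet, path: str | Path, sep: str = "\t") -> None:
    """Write a SpectrumSet as delimited text (header row = ppm axis)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("ppm" + sep + sep.join(f"{v:.17g}" for v in spectra.ppm) + "\n")
        for sid, row in zip(spectra.sample_ids, spectra.intensities):
            fh.write(str(sid) + sep + sep.join(f"{v:.17g}" for v in row) + "\n")


def read_spectra(path: str | Path, sep: str = "\t") -> SpectrumSet:
    """Read a delimited spectra file into a canonical (descending-axis) set.

    Raises
    ------
    SpectraFormatError
        On ragged rows, non-numeric cells, a non-monotone axis or
        duplicate sample ids; the message names the offending row/column.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split(sep)
        if len(header) < 2:
            raise SpectraFormatError(f"{path}: header row has no ppm values")
        try:
            ppm = np.array([float(v) for v in header[1:]])
        except ValueError as exc:
            raise SpectraFormatError(f"{path}: non-numeric ppm header: {exc}") from exc
        ids: list[str] = []
        rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split(sep)
            if len(cells) != len(header):
                raise SpectraFormatError(
                    f"{path}: row {lineno} has {len(cells)} cells, expected {len(header)}"
                )
            ids.append(cells[0])
            try:
                rows.append(np.array([float(v) for v in cells[1:]]))
            except ValueError:
                bad = next(
                    i for i, v in enumerate(cells[1:]) if not _is_number(v)
                )
                raise SpectraFormatError(
                    f"{path}: non-numeric cell at row {lineno}, column {bad + 2}"
                ) from None
    if not rows:
        raise SpectraFormatError(f"{path}: no sample rows")
    return SpectrumSet(np.vstack(rows), ppm, ids)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def read_metadata(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read and validate a sample metadata table.

    Requires ``sample_id``, ``patient_id`` and ``tumor_content_pct``
    columns; tumor content must lie in [0, 100] and sample ids must be
    unique.
    """
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "patient_id": str})
    return validate_metadata(df)


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("sample_id", "patient_id", "tumor_content_pct") if c not in df.columns]
    if missing:
        raise SpectraFormatError(f"metadata missing required columns: {missing}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise SpectraFormatError(f"duplicate sample ids in metadata: {dupes}")
    if df["tumor_content_pct"].isna().any():
        bad = df.loc[df["tumor_content_pct"].isna(), "sample_id"].tolist()
        raise SpectraFormatError(f"tumor_content_pct missing for samples: {bad}")
    tc = df["tumor_content_pct"].to_numpy(dtype=float)
    if np.any((tc < 0) | (tc > 100)):
        bad = df.loc[(tc < 0) | (tc > 100), "sample_id"].tolist()
        raise SpectraFormatError(
            f"tumor_content_pct outside [0, 100] for samples: {bad}"
        )
    return df


def write_metadata(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index=False)


def join(spectra: SpectrumSet, metadata: pd.DataFrame) -> tuple[SpectrumSet, pd.DataFrame]:
    """Align metadata rows to the spectra row order.

    Nothing is dropped silently: any id present on one side only raises
    an error listing the unmatched ids.
    """
    validate_metadata(metadata)
    meta_ids = set(metadata["sample_id"])
    spec_ids = set(spectra.sample_ids)
    only_spec = sorted(spec_ids - meta_ids)
    only_meta = sorted(meta_ids - spec_ids)
    if only_spec or only_meta:
        raise SpectraFormatError(
            "unmatched sample ids — "
            f"spectra only: {only_spec}; metadata only: {only_meta}"
        )
    aligned = (
        metadata.set_index("sample_id")
        .loc[spectra.sample_ids]
        .reset_index()
    )
    return spectra, aligned


# --------------------------------------------------------------------------
# Run configuration

@dataclass
class RunConfig:
    """All tunable pipeline parameters with their study defaults.

    Preprocessing: AsLS smoothness ``asls_lambda`` = 1e7, asymmetry
    ``asls_p`` = 1e-4, difference order ``asls_d`` = 2; 39 alignment
    intervals.  Validation: nested Monte-Carlo leave-20%-out with 80
    outer and 20 inner repetitions.
    """

    # region selection / deletion (ppm)
    select_upper: float = 4.7
    select_lower: float = -0.08
    removal_threshold: float = 3.0
    deletion_regions: tuple[tuple[float, float], ...] = ((3.691, 3.642), (4.400, 4.200))
    # AsLS baseline
    asls_lambda: float = 1e7
    asls_p: float = 1e-4
    asls_d: int = 2
    asls_max_iter: int = 50
    # alignment
    n_intervals: int = 39
    max_lag: int | None = None  # None -> 10% of interval width
    alignment_intervals: tuple[tuple[float, float], ...] | None = None
    # chemometrics / validation
    max_lv: int = 15
    outer_fraction: float = 0.20
    inner_fraction: float = 0.20
    n_outer: int = 80
    n_inner: int = 20
    threshold: float = 0.5
    # scheme + seeds
    scheme: str = "tumor_gt0"
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a flat key/value YAML document; keyword overrides win."""
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "deletion_regions" in raw:
            raw["deletion_regions"] = tuple(tuple(r) for r in raw["deletion_regions"])
        if raw.get("alignment_intervals") is not None:
            raw["alignment_intervals"] = tuple(
                tuple(r) for r in raw["alignment_intervals"]
            )
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        doc["deletion_regions"] = [list(r) for r in self.deletion_regions]
        if self.alignment_intervals is not None:
            doc["alignment_intervals"] = [list(r) for r in self.alignment_intervals]
        with Path(path).open("w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


# --------------------------------------------------------------------------
# Optional JCAMP-DX single-spectrum reader (standard dialect, XYDATA)

def read_jcampdx(path: str | Path, sample_id: str | None = None) -> SpectrumSet:
    """Read a single 1D spectrum from a JCAMP-DX file (XYDATA, AFFN form).

    Supports the plain ``(X++(Y..Y))`` table with AFFN (space-separated
    decimal) values, the dialect most 1D NMR exporters emit.  The X axis
    is converted to ppm via FIRSTX/LASTX (already in ppm for NMR dumps
    using ``XUNITS=PPM``).
    """
    path = Path(path)
    fields: dict[str, str] = {}
    ydata: list[float] = []
    in_table = False
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("##"):
                key, _, val = line[2:].partition("=")
                key = key.strip().upper().replace(" ", "")
                if key == "XYDATA":
                    in_table = True
                    continue
                if key == "END":
                    in_table = False
                fields[key] = val.strip()
                continue
            if in_table and line:
                vals = line.replace(",", " ").split()
                # first value on each line is the X start; rest are Y
                ydata.extend(float(v) for v in vals[1:])
    if not ydata:
        raise SpectraFormatError(f"{path}: no XYDATA table found")
    firstx = float(fields.get("FIRSTX", "0"))
    lastx = float(fields.get("LASTX", str(len(ydata) - 1)))
    yfactor = float(fields.get("YFACTOR", "1"))
    npoints = int(fields.get("NPOINTS", str(len(ydata))))
    if npoints != len(ydata):
        raise SpectraFormatError(
            f"{path}: NPOINTS={npoints} but {len(ydata)} Y values read"
        )
    ppm = np.linspace(firstx, lastx, npoints)
    y = np.array(ydata) * yfactor
    sid = sample_id or fields.get("TITLE", path.stem) or path.stem
    return SpectrumSet(y[None, :], ppm, [sid])
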