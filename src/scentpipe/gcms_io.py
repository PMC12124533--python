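"""Reading, writing and validating GC-MS chromatograms and sample manifests.

A chromatogram is carried as a time x m/z matrix of nonnegative ion counts
(:class:`RawChromatogram`).  On disk the package uses a plain-CSV matrix
dialect: the first column holds retention time in minutes, the header row
holds the raw (possibly non-integer) m/z values, and each cell holds an ion
count.  An optional mzML reader maps centroided spectra onto the same
in-memory container.

Sample metadata (source site, risk class, optional age/PSA) travels in a
manifest CSV with columns ``sample_id, source, risk[, age, psa]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RISK_LEVELS",
    "RawChromatogram",
    "SampleMeta",
    "Dataset",
    "ValidationReport",
    "ChromatogramParseError",
    "ManifestError",
    "read_chromatogram",
    "write_chromatogram",
    "read_manifest",
    "write_manifest",
    "validate_dataset",
]

#: The three clinical risk strata: biopsy-negative controls, Gleason <= 6
#: (low risk), Gleason >= 7 (high risk).
RISK_LEVELS = ("Control", "LowRisk", "HighRisk")


class ChromatogramParseError(ValueError):
    """Raised when a chromatogram file violates the matrix dialect."""


class ManifestError(ValueError):
    """Raised when a sample manifest is malformed."""


@dataclass
class RawChromatogram:
    """A raw ion chromatogram: intensity I(t, m/z) on a time x m/z grid.

    Parameters
    ----------
    times
        Retention times in minutes, strictly increasing, length T.
    mz_raw
        Raw m/z values (may be non-integer), length M.
    intensity
        T x M matrix of nonnegative ion counts.
    """

    times: np.ndarray
    mz_raw: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mz_raw = np.asarray(self.mz_raw, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.times.ndim != 1 or self.mz_raw.ndim != 1:
            raise ChromatogramParseError("times and mz_raw must be 1-D")
        if self.intensity.shape != (self.times.size, self.mz_raw.size):
            raise ChromatogramParseError(
                f"intensity shape {self.intensity.shape} does not match "
                f"(T={self.times.size}, M={self.mz_raw.size})"
            )
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            bad = int(np.flatnonzero(np.diff(self.times) <= 0)[0]) + 1
            raise ChromatogramParseError(
                f"time axis not strictly increasing at row {bad} "
                f"(t={self.times[bad]:g} after t={self.times[bad - 1]:g})"
            )
        if self.intensity.size and np.nanmin(self.intensity) < 0:
            r, c = np.argwhere(self.intensity < 0)[0]
            raise ChromatogramParseError(
                f"negative intensity {self.intensity[r, c]:g} at "
                f"row {int(r)}, m/z column {int(c)}"
            )

    @property
    def n_timesteps(self) -> int:
        return self.times.size

    @property
    def n_channels(self) -> int:
        return self.mz_raw.size

    @property
    def span_minutes(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])


@dataclass(frozen=True)
class SampleMeta:
    """Clinical and provenance metadata for one urine sample."""

    sample_id: str
    source: str
    risk: str
    age: float | None = None
    psa: float | None = None

    def __post_init__(self) -> None:
        if self.risk not in RISK_LEVELS:
            raise ManifestError(
                f"sample {self.sample_id!r}: unknown risk label {self.risk!r}; "
                f"expected one of {RISK_LEVELS}"
            )


@dataclass
class Dataset:
    """A list of (chromatogram, metadata) records plus the ordered source set."""

    records: list[tuple[RawChromatogram, SampleMeta]]
    sources: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ids = [m.sample_id for _, m in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ManifestError(f"duplicate sample ids in dataset: {dup}")
        if not self.sources:
            seen: list[str] = []
            for _, m in self.records:
                if m.source not in seen:
                    seen.append(m.source)
            self.sources = tuple(seen)
        for _, m in self.records:
            if m.source not in self.sources:
                raise ManifestError(
                    f"sample {m.sample_id!r} has source {m.source!r} "
                    f"outside declared sources {self.sources}"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def metas(self) -> list[SampleMeta]:
        return [m for _, m in self.records]


@dataclass
class ValidationReport:
    """Report-only outcome of dataset validation; the dataset is untouched."""

    kept: int
    rejected: int
    reasons: dict[str, str] = field(default_factory=dict)

    @property
    def kept_ids(self) -> int:  # pragma: no cover - convenience alias
        return self.kept


def read_chromatogram(path, format: str = "csv_matrix") -> RawChromatogram:
    """Read a chromatogram file into a validated :class:`RawChromatogram`.

    ``csv_matrix`` is the package's native dialect (first column = retention
    time in minutes, header = raw m/z values, cells = ion counts).  ``mzml``
    requires :mod:`pyteomics` and maps each spectrum's scan start time and
    (m/z, intensity) pairs onto the union grid of observed m/z values.
    """
    if format == "csv_matrix":
        return _read_csv_matrix(path)
    if format == "mzml":
        return _read_mzml(path)
    raise ValueError(f"unknown chromatogram format {format!r}")


def _read_csv_matrix(path) -> RawChromatogram:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV surface as parse errors
        raise ChromatogramParseError(f"{path}: cannot parse CSV ({exc})") from exc
    if df.shape[1] < 2:
        raise ChromatogramParseError(
            f"{path}: need a time column plus at least one m/z column"
        )
    try:
        mz_raw = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise ChromatogramParseError(
            f"{path}: header m/z values must be numeric ({exc})"
        ) from exc
    times = df.iloc[:, 0].to_numpy(dtype=float)
    intensity = df.iloc[:, 1:].to_numpy(dtype=float)
    return RawChromatogram(times=times, mz_raw=mz_raw, intensity=intensity)


def _read_mzml(path) -> RawChromatogram:
    try:
        from pyteomics import mzml as _mzml
        from pyteomics.auxiliary import PyteomicsError
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "mzML support requires pyteomics (install the 'mzml' extra)"
        ) from exc
    times: list[float] = []
    spectra: list[tuple[np.ndarray, np.ndarray]] = []
    try:
        reader_cm = _mzml.read(str(path))
    except PyteomicsError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "mzML support requires pyteomics with psims (install the 'mzml' extra)"
        ) from exc
    with reader_cm as reader:
        for spec in reader:
            if spec.get("ms level", 1) != 1:
                continue
            scan = spec["scanList"]["scan"][0]
            t = float(scan["scan start time"])
            times.append(t)
            spectra.append(
                (
                    np.asarray(spec["m/z array"], dtype=float),
                    np.asarray(spec["intensity array"], dtype=float),
                )
            )
    if not spectra:
        raise ChromatogramParseError(f"{path}: no MS1 spectra found")
    grid = np.unique(np.concatenate([mz for mz, _ in spectra]))
    intensity = np.zeros((len(spectra), grid.size))
    for i, (mz, inten) in enumerate(spectra):
        idx = np.searchsorted(grid, mz)
        # nearest-channel assignment onto the union grid; absent channels stay 0
        idx = np.clip(idx, 0, grid.size - 1)
        left = np.clip(idx - 1, 0, grid.size - 1)
        use_left = np.abs(grid[left] - mz) < np.abs(grid[idx] - mz)
        idx = np.where(use_left, left, idx)
        np.add.at(intensity[i], idx, inten)
    order = np.argsort(times)
    return RawChromatogram(
        times=np.asarray(times)[order], mz_raw=grid, intensity=intensity[order]
    )


def write_chromatogram(chrom: RawChromatogram, path) -> None:
    """Write the CSV matrix dialect; integer counts round-trip bit-exactly."""
    inten = chrom.intensity
    as_int = np.all(inten == np.floor(inten))
    with open(path, "w") as fh:
        fh.write("time_min," + ",".join(repr(float(m)) for m in chrom.mz_raw) + "\n")
        for t, row in zip(chrom.times, inten):
            if as_int:
                cells = ",".join(str(int(v)) for v in row)
            else:
                cells = ",".join(repr(float(v)) for v in row)
            fh.write(f"{float(t)!r},{cells}\n")


def read_manifest(path) -> list[SampleMeta]:
    """Read and validate a sample manifest CSV."""
    df = pd.read_csv(path, dtype={"sample_id": str, "source": str, "risk": str})
    required = {"sample_id", "source", "risk"}
    missing = required - set(df.columns)
    if missing:
        raise ManifestError(f"{path}: manifest missing columns {sorted(missing)}")
    dup = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dup:
        raise ManifestError(f"{path}: duplicate sample_id(s) {sorted(set(dup))}")
    metas = []
    for _, row in df.iterrows():
        metas.append(
            SampleMeta(
                sample_id=row["sample_id"],
                source=row["source"],
                risk=row["risk"],
                age=float(row["age"]) if "age" in df.columns and pd.notna(row.get("age")) else None,
                psa=float(row["psa"]) if "psa" in df.columns and pd.notna(row.get("psa")) else None,
            )
        )
    return metas


def write_manifest(metas: list[SampleMeta], path) -> None:
    rows = [
        {
            "sample_id": m.sample_id,
            "source": m.source,
            "risk": m.risk,
            "age": m.age,
            "psa": m.psa,
        }
        for m in metas
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def validate_dataset(d: Dataset, max_gap_factor: float = 5.0) -> ValidationReport:
    """Flag records that violate the pipeline's assumptions (report only).

    A record is rejected when its matrix is empty, contains NaN, or its time
    axis has a gap larger than ``max_gap_factor`` times the median sampling
    interval.  Mirrors the study's policy of dropping corrupted acquisitions
    rather than imputing them.
    """
    reasons: dict[str, str] = {}
    for chrom, meta in d.records:
        if chrom.n_timesteps == 0 or chrom.n_channels == 0:
            reasons[meta.sample_id] = "empty chromatogram"
            continue
        if np.isnan(chrom.intensity).any():
            reasons[meta.sample_id] = "NaN intensity (corrupted acquisition)"
            continue
        if chrom.n_timesteps > 2:
            dt = np.diff(chrom.times)
            if dt.max() > max_gap_factor * np.median(dt):
                reasons[meta.sample_id] = (
                    f"time-axis gap {dt.max():.3g} min exceeds "
                    f"{max_gap_factor:g}x median interval"
                )
    return ValidationReport(
        kept=len(d.records) - len(reasons), rejected=len(reasons), reasons=reasons
    )
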