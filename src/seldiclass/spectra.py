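"""Core data model for SELDI-TOF serum spectra and their CSV dialects.

A spectrum is an intensity profile over a mass-to-charge (m/z) grid in
Daltons.  A study cohort is a :class:`SpectraSet`: every sample shares one
grid (exact m/z equality — no resampling is performed) and carries a class
label, ``cancer`` or ``control``.  Three plain-text formats are supported:

* per-sample CSV with header ``mz,intensity``;
* a label manifest CSV with header ``sample_id,label`` (labels are the
  literal strings ``cancer`` / ``control``, case-insensitive);
* a wide-matrix CSV with header ``mz,<id1>,<id2>,...`` — one shared m/z
  column and one intensity column per sample.

Group-level summaries (per-class mean spectrum, min/max envelopes, and the
per-feature means/variances that feed the two-sample t statistic) live here
as well.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    FormatError,
    InsufficientDataError,
    ManifestError,
)

CANCER = "cancer"
CONTROL = "control"
CLASSES = (CONTROL, CANCER)


def normalize_label(raw: str) -> str:
    """Map a manifest label to the canonical ``cancer``/``control`` strings.

    ``disease`` is accepted as a synonym for ``cancer``; matching is
    case-insensitive and whitespace-tolerant.
    """
    label = str(raw).strip().lower()
    if label in (CANCER, "disease"):
        return CANCER
    if label == CONTROL:
        return CONTROL
    raise ManifestError(f"unknown class label {raw!r}; expected 'cancer' or 'control'")


@dataclass(frozen=True)
class MzGrid:
    """Strictly increasing sequence of m/z positions in Daltons."""

    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise FormatError("m/z grid must be one-dimensional with length >= 2")
        if not np.all(np.isfinite(values)):
            raise FormatError("m/z grid contains non-finite values")
        if np.any(values <= 0):
            raise FormatError("m/z values must be positive")
        if np.any(np.diff(values) <= 0):
            raise FormatError("m/z values must be strictly increasing")

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other) -> bool:
        return isinstance(other, MzGrid) and np.array_equal(self.values, other.values)

    def index_of(self, mz: float) -> int:
        """Index of the grid point nearest to ``mz``."""
        return int(np.argmin(np.abs(self.values - mz)))


@dataclass(frozen=True)
class Spectrum:
    """One sample's intensity profile (arbitrary units, non-negative)."""

    sample_id: str
    intensities: np.ndarray

    def __post_init__(self):
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", y)
        if y.ndim != 1:
            raise FormatError(f"sample {self.sample_id!r}: intensities must be 1-D")
        if not np.all(np.isfinite(y)):
            raise FormatError(f"sample {self.sample_id!r}: non-finite intensity")
        if np.any(y < 0):
            raise FormatError(f"sample {self.sample_id!r}: negative intensity")


@dataclass
class SpectraSet:
    """A labelled cohort of spectra on one shared m/z grid."""

    grid: MzGrid
    spectra: list[Spectrum]
    labels: dict[str, str]

    def __post_init__(self):
        seen: set[str] = set()
        for spec in self.spectra:
            if len(spec.intensities) != len(self.grid):
                raise AlignmentError(
                    f"sample {spec.sample_id!r}: {len(spec.intensities)} intensities "
                    f"for a grid of {len(self.grid)} points"
                )
            if spec.sample_id in seen:
                raise ManifestError(f"duplicate sample id {spec.sample_id!r}")
            seen.add(spec.sample_id)
            if spec.sample_id not in self.labels:
                raise ManifestError(f"sample {spec.sample_id!r} has no label")
        self.labels = {sid: normalize_label(lab) for sid, lab in self.labels.items()}

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.spectra]

    @property
    def n_samples(self) -> int:
        return len(self.spectra)

    @property
    def n_features(self) -> int:
        return len(self.grid)

    def intensity_matrix(self) -> np.ndarray:
        """Samples-by-features intensity matrix (rows follow ``spectra`` order)."""
        return np.vstack([s.intensities for s in self.spectra])

    def label_array(self) -> np.ndarray:
        return np.array([self.labels[s.sample_id] for s in self.spectra])

    def class_counts(self) -> dict[str, int]:
        labels = self.label_array()
        return {cls: int(np.sum(labels == cls)) for cls in CLASSES}

    def class_matrix(self, cls: str) -> np.ndarray:
        mask = self.label_array() == cls
        return self.intensity_matrix()[mask]

    def subset(self, sample_ids: Sequence[str]) -> "SpectraSet":
        """New SpectraSet restricted to ``sample_ids`` (order preserved)."""
        wanted = set(sample_ids)
        spectra = [s for s in self.spectra if s.sample_id in wanted]
        labels = {s.sample_id: self.labels[s.sample_id] for s in spectra}
        return SpectraSet(self.grid, spectra, labels)


@dataclass(frozen=True)
class GroupStats:
    """Per-feature means and unbiased variances for the two classes.

    These are the ingredients of the two-sample t statistic:
    cancer-group mean/variance, control-group mean/variance, group sizes.
    Variances use the n-1 denominator.
    """

    mean_cancer: np.ndarray
    mean_control: np.ndarray
    var_cancer: np.ndarray
    var_control: np.ndarray
    n_cancer: int
    n_control: int


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

def _read_two_column_csv(path: Path | str, columns: tuple[str, str]) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    if list(frame.columns[: len(columns)]) != list(columns):
        raise FormatError(
            f"{path}: expected header {','.join(columns)!r}, got "
            f"{','.join(map(str, frame.columns))!r}"
        )
    return frame


def read_sample_csv(path: Path | str) -> tuple[MzGrid, Spectrum]:
    """Read one per-sample ``mz,intensity`` CSV.

    The sample id is the file stem.  Rows must be numeric, m/z strictly
    increasing, intensities non-negative; at least two rows are required.
    """
    path = Path(path)
    frame = _read_two_column_csv(path, ("mz", "intensity"))
    if len(frame) < 2:
        raise FormatError(f"{path}: spectrum needs at least 2 rows, got {len(frame)}")
    values = np.empty((len(frame), 2))
    for j, col in enumerate(("mz", "intensity")):
        for i, cell in enumerate(frame[col]):
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-numeric {col} value {cell!r} at data row {i + 1}"
                ) from None
    grid = MzGrid(values[:, 0])
    return grid, Spectrum(path.stem, values[:, 1])


def write_sample_csv(path: Path | str, grid: MzGrid, spectrum: Spectrum) -> None:
    """Write a per-sample CSV; numbers use ``repr`` precision so the file
    round-trips bit-exactly through :func:`read_sample_csv`."""
    with open(path, "w") as fh:
        fh.write("mz,intensity\n")
        for mz, y in zip(grid.values, spectrum.intensities):
            fh.write(f"{float(mz)!r},{float(y)!r}\n")


def read_labels_manifest(path: Path | str) -> dict[str, str]:
    """Read a ``sample_id,label`` manifest into a dict of canonical labels."""
    frame = _read_two_column_csv(path, ("sample_id", "label"))
    labels: dict[str, str] = {}
    for sid, lab in zip(frame["sample_id"], frame["label"]):
        sid = str(sid)
        if sid in labels:
            raise ManifestError(f"{path}: duplicate manifest entry for {sid!r}")
        labels[sid] = normalize_label(lab)
    return labels


def write_labels_manifest(path: Path | str, labels: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id,label\n")
        for sid, lab in labels.items():
            fh.write(f"{sid},{lab}\n")


def read_wide_matrix(path: Path | str, labels: Mapping[str, str]) -> SpectraSet:
    """Read a wide-matrix CSV (``mz`` column + one column per sample)."""
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    if frame.columns[0] != "mz":
        raise FormatError(f"{path}: first column must be 'mz', got {frame.columns[0]!r}")
    if frame.shape[1] < 2:
        raise FormatError(f"{path}: wide matrix has no sample columns")
    grid = MzGrid(frame["mz"].to_numpy(dtype=float))
    spectra = [
        Spectrum(str(col), frame[col].to_numpy(dtype=float))
        for col in frame.columns[1:]
    ]
    missing = [s.sample_id for s in spectra if s.sample_id not in labels]
    if missing:
        raise ManifestError(f"{path}: unlabeled samples {missing}")
    return SpectraSet(grid, spectra, {s.sample_id: labels[s.sample_id] for s in spectra})


def write_wide_matrix(path: Path | str, sset: SpectraSet) -> None:
    ids = sset.sample_ids
    with open(path, "w") as fh:
        fh.write("mz," + ",".join(ids) + "\n")
        matrix = sset.intensity_matrix()
        for i, mz in enumerate(sset.grid.values):
            row = ",".join(repr(float(v)) for v in matrix[:, i])
            fh.write(f"{float(mz)!r},{row}\n")


def assemble_spectra_set(
    samples: Iterable[tuple[MzGrid, Spectrum]],
    labels: Mapping[str, str],
) -> SpectraSet:
    """Assemble per-sample spectra into a :class:`SpectraSet`.

    All samples must share an *identical* grid (exact equality after
    parsing); the manifest must label every sample.
    """
    samples = list(samples)
    if not samples:
        raise InsufficientDataError("no samples to assemble")
    grid0, first = samples[0]
    for grid, spec in samples[1:]:
        if grid != grid0:
            raise AlignmentError(
                f"samples {first.sample_id!r} and {spec.sample_id!r} are on "
                "different m/z grids (exact equality required)"
            )
    spectra = [spec for _, spec in samples]
    for spec in spectra:
        if spec.sample_id not in labels:
            raise ManifestError(f"sample {spec.sample_id!r} missing from manifest")
    return SpectraSet(grid0, spectra, {s.sample_id: labels[s.sample_id] for s in spectra})


# ---------------------------------------------------------------------------
# Group-level summaries
# ---------------------------------------------------------------------------

def group_stats(sset: SpectraSet) -> GroupStats:
    """Per-feature class means and unbiased (n-1) variances.

    Both classes need at least two samples for the variance to exist.
    """
    counts = sset.class_counts()
    for cls in CLASSES:
        if counts[cls] < 2:
            raise InsufficientDataError(
                f"class {cls!r} has {counts[cls]} sample(s); need >= 2"
            )
    xc = sset.class_matrix(CANCER)
    xn = sset.class_matrix(CONTROL)
    return GroupStats(
        mean_cancer=xc.mean(axis=0),
        mean_control=xn.mean(axis=0),
        var_cancer=xc.var(axis=0, ddof=1),
        var_control=xn.var(axis=0, ddof=1),
        n_cancer=counts[CANCER],
        n_control=counts[CONTROL],
    )


def group_summary(sset: SpectraSet) -> pd.DataFrame:
    """Per-class mean spectrum and min/max envelope at every m/z point.

    Returns a long-format frame with columns ``mz,class,mean,min,max`` —
    the tabular equivalent of a group-average-and-envelope plot.
    """
    counts = sset.class_counts()
    rows = []
    for cls in CLASSES:
        if counts[cls] < 1:
            raise InsufficientDataError(f"class {cls!r} is empty")
        matrix = sset.class_matrix(cls)
        rows.append(
            pd.DataFrame(
                {
                    "mz": sset.grid.values,
                    "class": cls,
                    "mean": matrix.mean(axis=0),
                    "min": matrix.min(axis=0),
                    "max": matrix.max(axis=0),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
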