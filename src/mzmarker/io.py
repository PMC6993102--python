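"""Feature-table container, serialization, peak binning and normalization.

The in-memory object is :class:`IntensityMatrix`: replicate mass spectra
as rows over nominal (integer) m/z channels as columns, with each row
tied to a patient and each patient to a binary class (``case`` /
``control``). The on-disk format is delimited text with the header
``patient_id,class,replicate,mz_<c0>,mz_<c1>,...``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, ParseError

POSITIVE_CLASS = "case"
NEGATIVE_CLASS = "control"
CLASS_LABELS = (POSITIVE_CLASS, NEGATIVE_CLASS)


@dataclass
class IntensityMatrix:
    """Replicate spectra (rows) by nominal m/z channels (columns).

    Invariants enforced on construction: non-negative intensities,
    strictly increasing integer m/z labels, every row's patient mapped
    to exactly one class in ``patient_class``. ``normalized`` records
    whether rows have been divided by their own maximum.
    """

    values: np.ndarray
    mz: np.ndarray
    patient_id: np.ndarray
    replicate: np.ndarray
    patient_class: dict[str, str] = field(default_factory=dict)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mz = np.asarray(self.mz, dtype=int)
        self.patient_id = np.asarray(self.patient_id, dtype=object)
        self.replicate = np.asarray(self.replicate, dtype=int)
        if self.values.ndim != 2:
            raise ConfigError("values must be a 2-D array")
        n_rows, n_channels = self.values.shape
        if self.mz.shape != (n_channels,):
            raise ConfigError("mz labels must match the number of columns")
        if np.any(np.diff(self.mz) <= 0):
            raise ConfigError("mz labels must be strictly increasing")
        if self.patient_id.shape != (n_rows,) or self.replicate.shape != (n_rows,):
            raise ConfigError("row metadata must match the number of rows")
        if np.any(self.values < 0):
            r, c = np.argwhere(self.values < 0)[0]
            raise ConfigError(
                f"negative intensity at row {r}, channel mz_{self.mz[c]}"
            )
        missing = {p for p in self.patient_id if p not in self.patient_class}
        if missing:
            raise ConfigError(f"rows reference patients without a class: {sorted(missing)[:5]}")
        bad = {p: c for p, c in self.patient_class.items() if c not in CLASS_LABELS}
        if bad:
            raise ConfigError(f"unknown class labels: {bad}")

    # -- basic geometry -------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def row_class(self) -> np.ndarray:
        """Per-row class label, inherited from the row's patient."""
        return np.array([self.patient_class[p] for p in self.patient_id], dtype=object)

    @property
    def y(self) -> np.ndarray:
        """Per-row binary label: 1 for the positive (case) class."""
        return (self.row_class == POSITIVE_CLASS).astype(int)

    @property
    def patients(self) -> list[str]:
        """Distinct patients in row order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.patient_id:
            seen.setdefault(p, None)
        return list(seen)

    def copy(self) -> "IntensityMatrix":
        return replace(
            self,
            values=self.values.copy(),
            mz=self.mz.copy(),
            patient_id=self.patient_id.copy(),
            replicate=self.replicate.copy(),
            patient_class=dict(self.patient_class),
        )

    # -- selection ------------------------------------------------------
    def channel_index(self, mz_label: int) -> int:
        idx = np.flatnonzero(self.mz == mz_label)
        if idx.size != 1:
            raise KeyError(f"unknown channel mz_{mz_label}")
        return int(idx[0])

    def channel_values(self, mz_label: int) -> np.ndarray:
        return self.values[:, self.channel_index(mz_label)]

    def select_channels(self, mz_labels: Sequence[int]) -> "IntensityMatrix":
        """Restrict to ``mz_labels`` (kept in ascending m/z order)."""
        labels = sorted(int(m) for m in mz_labels)
        cols = [self.channel_index(m) for m in labels]
        return replace(
            self,
            values=self.values[:, cols].copy(),
            mz=np.array(labels, dtype=int),
            patient_id=self.patient_id.copy(),
            replicate=self.replicate.copy(),
            patient_class=dict(self.patient_class),
        )

    def subset_patients(self, patients: Iterable[str]) -> "IntensityMatrix":
        """Rows of the given patients only (replicates follow patients)."""
        wanted = set(patients)
        unknown = wanted - set(self.patient_class)
        if unknown:
            raise ConfigError(f"unknown patients: {sorted(unknown)[:5]}")
        mask = np.array([p in wanted for p in self.patient_id])
        return replace(
            self,
            values=self.values[mask].copy(),
            mz=self.mz.copy(),
            patient_id=self.patient_id[mask].copy(),
            replicate=self.replicate[mask].copy(),
            patient_class={p: c for p, c in self.patient_class.items() if p in wanted},
        )


# ---------------------------------------------------------------------------
# delimited-text round trip
# ---------------------------------------------------------------------------

_META_COLUMNS = ("patient_id", "class", "replicate")


def _delimiter_for(path: Path, dialect: str | None) -> str:
    if dialect in ("comma", "csv"):
        return ","
    if dialect in ("tab", "tsv"):
        return "\t"
    if dialect is None:
        return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    raise ConfigError(f"unknown dialect {dialect!r}")


def load_feature_table(path: str | Path, dialect: str | None = None) -> IntensityMatrix:
    """Read a delimited feature table into an :class:`IntensityMatrix`.

    The header must start with ``patient_id,class,replicate`` followed by
    ``mz_<label>`` columns; channel order is preserved. Duplicate
    (patient, replicate) keys, non-numeric cells and negative intensities
    raise :class:`ParseError` naming the offending row/column.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=_delimiter_for(path, dialect))
    if tuple(frame.columns[:3]) != _META_COLUMNS:
        raise ParseError(
            f"{path}: header must start with {','.join(_META_COLUMNS)}, "
            f"got {list(frame.columns[:3])}"
        )
    mz_cols = list(frame.columns[3:])
    bad = [c for c in mz_cols if not c.startswith("mz_")]
    if bad:
        raise ParseError(f"{path}: non-channel columns after metadata: {bad[:5]}")
    mz = np.array([int(c[3:]) for c in mz_cols])

    keys = list(zip(frame["patient_id"], frame["replicate"]))
    dupes = pd.Series(keys)[pd.Series(keys).duplicated()]
    if not dupes.empty:
        raise ParseError(f"{path}: duplicate (patient, replicate) keys: {list(dupes[:3])}")

    values = np.empty((len(frame), len(mz_cols)))
    for j, col in enumerate(mz_cols):
        numeric = pd.to_numeric(frame[col], errors="coerce")
        if numeric.isna().any():
            row = int(numeric.index[numeric.isna()][0])
            raise ParseError(f"{path}: non-numeric cell at data row {row}, column {col}")
        values[:, j] = numeric.to_numpy()
    if (values < 0).any():
        r, c = np.argwhere(values < 0)[0]
        raise ParseError(f"{path}: negative intensity at data row {r}, column {mz_cols[c]}")

    patient_class: dict[str, str] = {}
    for p, cls in zip(frame["patient_id"], frame["class"]):
        if p in patient_class and patient_class[p] != cls:
            raise ParseError(f"{path}: patient {p!r} has conflicting class labels")
        patient_class[str(p)] = str(cls)

    return IntensityMatrix(
        values=values,
        mz=mz,
        patient_id=frame["patient_id"].astype(str).to_numpy(dtype=object),
        replicate=frame["replicate"].to_numpy(),
        patient_class=patient_class,
    )


def write_feature_table(
    matrix: IntensityMatrix, path: str | Path, dialect: str | None = None
) -> None:
    """Write ``matrix`` in the delimited feature-table format."""
    path = Path(path)
    frame = pd.DataFrame(matrix.values, columns=[f"mz_{m}" for m in matrix.mz])
    frame.insert(0, "replicate", matrix.replicate)
    frame.insert(0, "class", matrix.row_class)
    frame.insert(0, "patient_id", matrix.patient_id)
    frame.to_csv(path, sep=_delimiter_for(path, dialect), index=False)


# ---------------------------------------------------------------------------
# peak binning
# ---------------------------------------------------------------------------


def bin_peaks(
    peak_lists: Sequence[tuple[np.ndarray, np.ndarray]],
    mz_start: float,
    mz_end: float,
    width: float = 1.0,
    patient_id: Sequence[str] | None = None,
    replicate: Sequence[int] | None = None,
    patient_class: Mapping[str, str] | None = None,
) -> IntensityMatrix:
    """Bin centroided peak lists to nominal m/z channels.

    Each channel ``k`` covers the half-open interval
    ``[mz_start + k*width, mz_start + (k+1)*width)`` and holds the sum of
    intensities of the peaks that fall inside it; the channel count is
    ``ceil((mz_end - mz_start)/width)``. Peaks outside
    ``[mz_start, mz_end)`` are dropped with a warning giving their count.
    """
    if width <= 0 or mz_end <= mz_start:
        raise ConfigError("need width > 0 and mz_end > mz_start")
    n_channels = int(np.ceil((mz_end - mz_start) / width))
    labels = np.floor(mz_start + width * np.arange(n_channels)).astype(int)
    if len(set(labels.tolist())) != n_channels:
        raise ConfigError(
            "bin width produces non-unique integer channel labels; use width >= 1"
        )
    values = np.zeros((len(peak_lists), n_channels))
    dropped = 0
    for i, (mzs, intensities) in enumerate(peak_lists):
        mzs = np.asarray(mzs, dtype=float)
        intensities = np.asarray(intensities, dtype=float)
        in_range = (mzs >= mz_start) & (mzs < mz_end)
        dropped += int((~in_range).sum())
        idx = ((mzs[in_range] - mz_start) // width).astype(int)
        np.add.at(values[i], idx, intensities[in_range])
    if dropped:
        warnings.warn(f"bin_peaks: dropped {dropped} peaks outside [{mz_start}, {mz_end})")
    n = len(peak_lists)
    pid = np.array(patient_id if patient_id is not None else [f"S{i:04d}" for i in range(n)],
                   dtype=object)
    rep = np.array(replicate if replicate is not None else [1] * n)
    classes = dict(patient_class) if patient_class is not None else {
        p: NEGATIVE_CLASS for p in pid
    }
    return IntensityMatrix(values, labels, pid, rep, classes)


def read_mzml_peaks(path: str | Path) -> list[tuple[np.ndarray, np.ndarray]]:
    """Read centroided spectra from an mzML 1.1 file as (m/z, intensity) pairs.

    Requires the optional ``pyteomics`` dependency.
    """
    try:
        from pyteomics import mzml  # noqa: PLC0415 - optional dependency
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError("reading mzML requires the optional 'pyteomics' package") from exc
    peaks = []
    with mzml.MzML(str(path)) as reader:
        for spectrum in reader:
            peaks.append((spectrum["m/z array"], spectrum["intensity array"]))
    return peaks


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def normalize_rows(matrix: IntensityMatrix) -> IntensityMatrix:
    """Divide every row by its own maximum intensity (base-peak scaling).

    All-zero rows are left unchanged and reported with a warning, never
    dropped (dropping would silently unbalance replicate counts). The
    operation is idempotent.
    """
    out = matrix.copy()
    row_max = out.values.max(axis=1)
    zero_rows = row_max == 0
    if zero_rows.any():
        warnings.warn(
            f"normalize_rows: {int(zero_rows.sum())} all-zero rows left as zeros"
        )
    scale = np.where(zero_rows, 1.0, row_max)
    out.values = out.values / scale[:, None]
    out.normalized = True
    return out
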