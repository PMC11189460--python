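"""Text I/O for MRM chromatograms, run sheets, and peak-area matrices.

The toolkit consumes chromatograms as plain tab-separated text in long
format — one row per acquired point — with the header
``sample_id  transition_key  rt_min  intensity``.  One file per sample and
one combined file are both accepted.  Vendor raw files are expected to be
converted upstream (e.g. with ProteoWizard's MSConvert); parsing them is
out of scope here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ChromatogramTrace",
    "TraceFormatError",
    "SampleRole",
    "AreaMatrix",
    "read_chromatograms",
    "write_chromatograms",
    "read_runsheet",
    "write_runsheet",
    "read_area_matrix",
    "write_area_matrix",
]

TRACE_COLUMNS = ["sample_id", "transition_key", "rt_min", "intensity"]
RUNSHEET_COLUMNS = ["sample_id", "injection_order", "role", "group", "calibration_level"]
SAMPLE_ROLES = ("study", "blank", "pooled_qc", "calibrant")


class TraceFormatError(ValueError):
    """A chromatogram file violates the TSV trace contract."""


class SampleRole:  # simple namespace, not an enum: roles appear as strings in files
    STUDY = "study"
    BLANK = "blank"
    POOLED_QC = "pooled_qc"
    CALIBRANT = "calibrant"


@dataclass
class ChromatogramTrace:
    """One transition's time–intensity series for one injection.

    ``times`` are retention times in minutes, strictly increasing;
    ``intensities`` are detector counts, non-negative on input.
    """

    sample_id: str
    transition_key: str
    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.intensities.shape:
            raise TraceFormatError(
                f"times/intensities shape mismatch for {self.sample_id}/{self.transition_key}"
            )
        if self.times.size < 2:
            raise TraceFormatError(
                f"trace {self.sample_id}/{self.transition_key} has < 2 points"
            )
        if not np.all(np.diff(self.times) > 0):
            raise TraceFormatError(
                f"times not strictly increasing for {self.sample_id}/{self.transition_key}"
            )

    def __len__(self) -> int:
        return self.times.size

    @property
    def sampling_interval(self) -> float:
        """Median spacing between consecutive points (minutes)."""
        return float(np.median(np.diff(self.times)))

    def replace_intensities(self, intensities: np.ndarray) -> "ChromatogramTrace":
        return ChromatogramTrace(
            self.sample_id, self.transition_key, self.times.copy(), np.asarray(intensities, float)
        )


@dataclass
class AreaMatrix:
    """Integrated peak areas: injections (rows) × transitions (columns).

    Missing areas are NaN, never 0 — a zero would silently enter the
    normalization chain.  The run sheet travels with the matrix so that
    downstream stages can see injection order and sample roles.
    """

    values: pd.DataFrame
    runsheet: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample_id rows in AreaMatrix: {dup}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate transition columns in AreaMatrix: {dup}")
        self.values = self.values.astype(float)
        if not self.runsheet.empty:
            missing = set(self.values.index) - set(self.runsheet["sample_id"])
            if missing:
                raise ValueError(f"samples absent from run sheet: {sorted(missing)}")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def transitions(self) -> list[str]:
        return list(self.values.columns)

    def role_samples(self, role: str) -> list[str]:
        if self.runsheet.empty:
            return []
        sel = self.runsheet.loc[self.runsheet["role"] == role, "sample_id"]
        return [s for s in sel if s in self.values.index]

    def subset_samples(self, samples: Iterable[str]) -> "AreaMatrix":
        samples = [s for s in self.values.index if s in set(samples)]
        rs = self.runsheet
        if not rs.empty:
            rs = rs[rs["sample_id"].isin(samples)].reset_index(drop=True)
        return AreaMatrix(self.values.loc[samples].copy(), rs)


def _parse_trace_frame(df: pd.DataFrame, origin: str) -> list[ChromatogramTrace]:
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(f"{origin}: missing columns {missing}")
    neg = df.index[df["intensity"] < 0]
    if len(neg):
        # +2: one for the header, one for 0-based indexing
        raise TraceFormatError(
            f"{origin}: negative intensity at line {int(neg[0]) + 2}"
        )
    traces = []
    for (sample_id, key), grp in df.groupby(["sample_id", "transition_key"], sort=True):
        grp = grp.sort_values("rt_min")
        t = grp["rt_min"].to_numpy(float)
        y = grp["intensity"].to_numpy(float)
        if np.any(np.diff(t) == 0):
            # collapse duplicate time points by mean intensity
            warnings.warn(
                f"{origin}: duplicate time points in {sample_id}/{key}, averaging",
                stacklevel=2,
            )
            agg = grp.groupby("rt_min", sort=True)["intensity"].mean()
            t, y = agg.index.to_numpy(float), agg.to_numpy(float)
        if np.any(np.diff(t) < 0):
            raise TraceFormatError(f"{origin}: non-monotone time in {sample_id}/{key}")
        traces.append(ChromatogramTrace(str(sample_id), str(key), t, y))
    return traces


def read_chromatograms(
    path_or_dir: str | Path, known_keys: Iterable[str] | None = None
) -> list[ChromatogramTrace]:
    """Read chromatogram traces from one TSV file or a directory of them.

    Returns one :class:`ChromatogramTrace` per (sample, transition) pair,
    times sorted.  If ``known_keys`` (e.g. the panel's transition keys) is
    given, unknown keys raise a warning but the traces are kept.
    """
    path = Path(path_or_dir)
    files = sorted(path.glob("*.tsv")) if path.is_dir() else [path]
    if not files:
        raise FileNotFoundError(f"no .tsv trace files under {path}")
    traces: list[ChromatogramTrace] = []
    for f in files:
        df = pd.read_csv(f, sep="\t")
        traces.extend(_parse_trace_frame(df, str(f)))
    if known_keys is not None:
        known = set(known_keys)
        unknown = {t.transition_key for t in traces} - known
        if unknown:
            warnings.warn(
                f"traces contain transition keys not in the panel: {sorted(unknown)[:5]}"
                + ("…" if len(unknown) > 5 else ""),
                stacklevel=2,
            )
    return traces


def write_chromatograms(traces: Iterable[ChromatogramTrace], path: str | Path) -> None:
    """Write traces to a single long-format TSV (inverse of read)."""
    frames = [
        pd.DataFrame(
            {
                "sample_id": tr.sample_id,
                "transition_key": tr.transition_key,
                "rt_min": tr.times,
                "intensity": tr.intensities,
            }
        )
        for tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_runsheet(path: str | Path) -> pd.DataFrame:
    """Read the run sheet CSV: sample_id, injection_order, role, group, calibration_level."""
    df = pd.read_csv(path)
    missing = [c for c in ("sample_id", "injection_order", "role") if c not in df.columns]
    if missing:
        raise TraceFormatError(f"run sheet missing columns: {missing}")
    for col in ("group", "calibration_level"):
        if col not in df.columns:
            df[col] = np.nan
    if df["injection_order"].duplicated().any():
        raise TraceFormatError("run sheet injection_order values are not unique")
    if df["sample_id"].duplicated().any():
        raise TraceFormatError("run sheet sample_id values are not unique")
    bad = set(df["role"]) - set(SAMPLE_ROLES)
    if bad:
        raise TraceFormatError(f"unknown sample roles in run sheet: {sorted(bad)}")
    df["sample_id"] = df["sample_id"].astype(str)
    df["injection_order"] = df["injection_order"].astype(int)
    return df[RUNSHEET_COLUMNS]


def write_runsheet(runsheet: pd.DataFrame, path: str | Path) -> None:
    runsheet.to_csv(path, index=False)


def write_area_matrix(matrix: AreaMatrix, path: str | Path) -> None:
    """Write the area matrix as CSV: samples as rows, transitions as columns.

    Missing cells are written as empty strings (locale-safe), and the file
    round-trips exactly through :func:`read_area_matrix`.
    """
    out = matrix.values.copy()
    out.index.name = "sample_id"
    out.to_csv(path, na_rep="")


def read_area_matrix(path: str | Path, runsheet: pd.DataFrame | None = None) -> AreaMatrix:
    df = pd.read_csv(path, index_col="sample_id")
    df.index = df.index.astype(str)
    df.index.name = None
    return AreaMatrix(df, runsheet if runsheet is not None else pd.DataFrame())
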