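"""Readers/writers for partition summary tables and per-probe results tables.

The partition summary dialect is a plain CSV with one row per partition:

    well,partition,blue_T1,...,blue_T4,green_T1,...,red_T4

Row order is significant: rolling-window normalization operates on file
order, so readers preserve it and require the ``partition`` column to be
0-based, unique and contiguous in that order.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from .errors import PartitionTableError, ResultsTableError
from .panel import CHANNELS

__all__ = [
    "PartitionTable",
    "ProbeResult",
    "ResultsTable",
    "partition_columns",
    "read_partition_table",
    "read_results",
    "write_partition_table",
    "write_results",
]

N_TEMPS = 4


def partition_columns() -> List[str]:
    """Header of the partition summary CSV dialect, in order."""
    cols = ["well", "partition"]
    for c in CHANNELS:
        cols += [f"{c}_T{t}" for t in range(1, N_TEMPS + 1)]
    return cols


@dataclass
class PartitionTable:
    """Raw fluorescence for one well.

    ``fluorescence`` has shape ``(n_partitions, 4 channels, 4 temperatures)``
    with channels ordered as :data:`meltplex.panel.CHANNELS`.
    """

    well_id: str
    fluorescence: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.fluorescence, dtype=float)
        if arr.ndim != 3 or arr.shape[1:] != (len(CHANNELS), N_TEMPS):
            raise PartitionTableError(
                f"fluorescence must have shape (n, {len(CHANNELS)}, {N_TEMPS}); "
                f"got {arr.shape}"
            )
        if arr.shape[0] == 0:
            raise PartitionTableError("partition table must contain at least one partition")
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr).all(axis=(1, 2))).ravel()
            raise PartitionTableError(
                f"non-finite fluorescence at partition index(es) {bad[:10].tolist()}"
            )
        if (arr < 0).any():
            bad = np.argwhere((arr < 0).any(axis=(1, 2))).ravel()
            raise PartitionTableError(
                f"negative fluorescence at partition index(es) {bad[:10].tolist()}"
            )
        self.fluorescence = arr

    @property
    def n_partitions(self) -> int:
        return self.fluorescence.shape[0]

    def to_frame(self) -> pd.DataFrame:
        n = self.n_partitions
        data = {"well": [self.well_id] * n, "partition": np.arange(n)}
        for ci, c in enumerate(CHANNELS):
            for t in range(N_TEMPS):
                data[f"{c}_T{t + 1}"] = self.fluorescence[:, ci, t]
        return pd.DataFrame(data, columns=partition_columns())

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PartitionTable":
        missing = [c for c in partition_columns() if c not in df.columns]
        if missing:
            raise PartitionTableError(f"missing column(s): {', '.join(missing)}")
        if len(df) == 0:
            raise PartitionTableError("empty partition table")
        wells = df["well"].astype(str).unique()
        if len(wells) != 1:
            raise PartitionTableError(
                f"expected a single well per table, found {len(wells)}: {wells[:5].tolist()}"
            )
        idx = pd.to_numeric(df["partition"], errors="coerce")
        if idx.isna().any() or not np.array_equal(idx.to_numpy(), np.arange(len(df))):
            raise PartitionTableError(
                "partition indices must be 0-based, unique and contiguous in row order"
            )
        n = len(df)
        arr = np.empty((n, len(CHANNELS), N_TEMPS), dtype=float)
        for ci, c in enumerate(CHANNELS):
            for t in range(N_TEMPS):
                col = f"{c}_T{t + 1}"
                vals = pd.to_numeric(df[col], errors="coerce").to_numpy()
                bad = np.flatnonzero(~np.isfinite(vals) | (vals < 0))
                if bad.size:
                    raise PartitionTableError(
                        f"column {col!r}: invalid fluorescence at row(s) "
                        f"{(bad + 2)[:10].tolist()} (1-based file lines incl. header)"
                    )
                arr[:, ci, t] = vals
        return cls(well_id=str(wells[0]), fluorescence=arr)


def read_partition_table(path) -> PartitionTable:
    """Read one well's partition summary CSV, preserving row order."""
    path = Path(path)
    try:
        # round_trip parsing: the writer emits shortest-repr floats and the
        # default (fast) parser would lose the last ulp
        df = pd.read_csv(path, dtype={"well": str}, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise PartitionTableError(f"{path}: empty file") from None
    except pd.errors.ParserError as exc:
        raise PartitionTableError(f"{path}: parse error: {exc}") from None
    try:
        return PartitionTable.from_frame(df)
    except PartitionTableError as exc:
        raise PartitionTableError(f"{path}: {exc}") from None


def write_partition_table(table: PartitionTable, path) -> None:
    """Write the CSV dialect with full float precision (exact round-trip)."""
    if not isinstance(table, PartitionTable):
        raise PartitionTableError("expected a PartitionTable")
    df = table.to_frame()
    # str(float) is the shortest repr that round-trips; determinism relies on it
    df.to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# results tables


@dataclass
class ProbeResult:
    """Per-probe quantification summary for one well."""

    probe_id: str
    positives: int
    analyzed: int
    lam: float  # copies per partition
    copies_per_uL: float
    total_copies: float
    ci95_low: float
    ci95_high: float
    allele_fraction: Optional[float] = None
    flags: List[str] = field(default_factory=list)

    def validate(self) -> None:
        if not 0 <= self.positives <= self.analyzed:
            raise ResultsTableError(
                f"{self.probe_id}: positives {self.positives} outside [0, {self.analyzed}]"
            )
        finite = all(
            math.isfinite(v) for v in (self.lam, self.total_copies, self.ci95_low, self.ci95_high)
        )
        if finite:
            if self.lam < 0:
                raise ResultsTableError(f"{self.probe_id}: negative lambda {self.lam}")
            if not (self.ci95_low <= self.total_copies <= self.ci95_high):
                raise ResultsTableError(
                    f"{self.probe_id}: CI [{self.ci95_low}, {self.ci95_high}] does not "
                    f"bracket total_copies {self.total_copies}"
                )


@dataclass
class ResultsTable:
    """One record per probe for one well."""

    well_id: str
    records: List[ProbeResult]

    def validate(self) -> None:
        for r in self.records:
            r.validate()

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "well": self.well_id,
                    "probe_id": r.probe_id,
                    "positives": r.positives,
                    "analyzed": r.analyzed,
                    "lambda": r.lam,
                    "copies_per_uL": r.copies_per_uL,
                    "total_copies": r.total_copies,
                    "ci95_low": r.ci95_low,
                    "ci95_high": r.ci95_high,
                    "allele_fraction": r.allele_fraction,
                    "flags": ";".join(r.flags),
                }
            )
        return pd.DataFrame(rows)


def write_results(results: ResultsTable, path, metadata: Optional[dict] = None) -> None:
    """Write the results CSV (floats at 6 significant digits) plus a JSON sidecar.

    The sidecar (``<path>.meta.json``) carries run metadata: panel hash,
    seed, software version — whatever the caller supplies. It contains no
    timestamps so repeated runs are byte-identical.
    """
    results.validate()
    path = Path(path)
    df = results.to_frame()
    df.to_csv(path, index=False, float_format="%.6g", lineterminator="\n")
    sidecar = dict(metadata or {})
    sidecar.setdefault("n_probes", len(results.records))
    sidecar.setdefault("well", results.well_id)
    Path(str(path) + ".meta.json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def read_results(path) -> ResultsTable:
    """Read a results CSV written by :func:`write_results`."""
    df = pd.read_csv(Path(path))
    wells = df["well"].astype(str).unique()
    if len(wells) != 1:
        raise ResultsTableError(f"expected a single well, found {len(wells)}")
    records = []
    for _, row in df.iterrows():
        af = row.get("allele_fraction")
        flags = row.get("flags")
        records.append(
            ProbeResult(
                probe_id=str(row["probe_id"]),
                positives=int(row["positives"]),
                analyzed=int(row["analyzed"]),
                lam=float(row["lambda"]),
                copies_per_uL=float(row["copies_per_uL"]),
                total_copies=float(row["total_copies"]),
                ci95_low=float(row["ci95_low"]),
                ci95_high=float(row["ci95_high"]),
                allele_fraction=None if pd.isna(af) else float(af),
                flags=[] if pd.isna(flags) or flags == "" else str(flags).split(";"),
            )
        )
    return ResultsTable(well_id=str(wells[0]), records=records)
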