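"""Core data model for chromatin traces and trace-table I/O.

A *trace* is the set of 3D localizations of all imaged genomic loci for one
chromosome copy in one cell.  Traces are stored as a dense ``(N, L, D)``
array of nanometre coordinates with ``NaN`` marking missing localizations.
Two on-disk dialects are supported:

* ``fofct_csv`` — a FOF-CT-style CSV with ``Trace_ID, Chrom, Chrom_Start,
  Chrom_End, X, Y, Z`` columns (plus optional ``Cell_ID``, ``Condition``,
  ``Role``, ``Burst_State``); ``#``-prefixed lines are comments.
* ``simple_tsv`` — a flat TSV with ``trace_id, locus_index, x_nm, y_nm,
  z_nm`` and optional genomic / metadata columns.

Genomic intervals are 0-based half-open; loci are ordered by genomic start,
with repeat-imaged copies (role ``repeat``) appended after the initially
imaged loci.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TraceSet",
    "GroundTruthPair",
    "TraceFormatError",
    "read_traces",
    "write_traces",
]

MISSING = np.nan

_FOFCT_REQUIRED = ["Trace_ID", "Chrom", "Chrom_Start", "Chrom_End", "X", "Y", "Z"]
_TSV_REQUIRED = ["trace_id", "locus_index", "x_nm", "y_nm", "z_nm"]


class TraceFormatError(ValueError):
    """Raised when a trace table is malformed (missing columns, duplicates)."""


@dataclass
class TraceSet:
    """Localizations of ``L`` genomic loci across ``N`` traces in ``D`` dims.

    Attributes
    ----------
    positions : ndarray, shape (N, L, D)
        Coordinates in nm; ``NaN`` marks a missing entry.
    locus_table : DataFrame
        Per-locus ``chrom``, ``start``, ``end`` (bp, 0-based half-open) and
        ``role`` (``initial`` or ``repeat``).
    trace_meta : DataFrame
        Per-trace ``cell_id``, ``allele_id``, ``condition`` and optional
        ``burst_state`` (``none`` | ``initial_burst`` | ``later_burst``).
    repeat_pairs : list of (int, int)
        ``(initial_locus_index, repeat_locus_index)`` pairs targeting the
        same genomic segment.
    """

    positions: np.ndarray
    locus_table: pd.DataFrame
    trace_meta: pd.DataFrame
    repeat_pairs: list[tuple[int, int]] = field(default_factory=list)
    parse_report: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3:
            raise ValueError("positions must have shape (N, L, D)")
        n, l, d = self.positions.shape
        if d not in (1, 2, 3):
            raise ValueError(f"D must be 1, 2 or 3, got {d}")
        if n < 1 or l < 2:
            raise ValueError("need N >= 1 traces and L >= 2 loci")
        finite_or_nan = np.isfinite(self.positions) | np.isnan(self.positions)
        if not finite_or_nan.all():
            raise ValueError("non-missing coordinates must be finite")
        if len(self.locus_table) != l:
            raise ValueError("locus_table length must equal L")
        if len(self.trace_meta) != n:
            raise ValueError("trace_meta length must equal N")
        for a, r in self.repeat_pairs:
            if a == r:
                raise ValueError("repeat pair must reference distinct loci")
            la, lr = self.locus_table.iloc[a], self.locus_table.iloc[r]
            if (la["chrom"], la["start"], la["end"]) != (lr["chrom"], lr["start"], lr["end"]):
                raise ValueError(f"repeat pair ({a}, {r}) targets differing genomic intervals")

    # -- basic geometry -------------------------------------------------

    @property
    def n_traces(self) -> int:
        return self.positions.shape[0]

    @property
    def n_loci(self) -> int:
        return self.positions.shape[1]

    @property
    def n_dims(self) -> int:
        return self.positions.shape[2]

    @property
    def localized(self) -> np.ndarray:
        """Boolean (N, L): True where all D coordinates are present."""
        return np.isfinite(self.positions).all(axis=2)

    def detection_efficiency(self) -> np.ndarray:
        """Fraction of loci localized, per trace (repeat loci excluded)."""
        init = (self.locus_table["role"] == "initial").to_numpy()
        return self.localized[:, init].mean(axis=1)

    # -- manipulation ---------------------------------------------------

    def copy(self) -> "TraceSet":
        return TraceSet(
            self.positions.copy(),
            self.locus_table.copy(),
            self.trace_meta.copy(),
            list(self.repeat_pairs),
        )

    def with_positions(self, positions: np.ndarray) -> "TraceSet":
        """Same metadata, new coordinate tensor of identical shape."""
        if positions.shape != self.positions.shape:
            raise ValueError("shape mismatch")
        return TraceSet(positions, self.locus_table.copy(), self.trace_meta.copy(), list(self.repeat_pairs))

    def subset_traces(self, index: np.ndarray) -> "TraceSet":
        return TraceSet(
            self.positions[index],
            self.locus_table.copy(),
            self.trace_meta.iloc[index].reset_index(drop=True),
            list(self.repeat_pairs),
        )

    def drop_repeats(self) -> "TraceSet":
        """Keep only initially imaged loci (the default input to correction)."""
        keep = np.flatnonzero((self.locus_table["role"] == "initial").to_numpy())
        return TraceSet(
            self.positions[:, keep, :],
            self.locus_table.iloc[keep].reset_index(drop=True),
            self.trace_meta.copy(),
            [],
        )

    def equals(self, other: "TraceSet", atol: float = 0.0) -> bool:
        if self.positions.shape != other.positions.shape:
            return False
        a, b = self.positions, other.positions
        same_nan = np.isnan(a) == np.isnan(b)
        close = np.isclose(a, b, atol=atol, rtol=0.0, equal_nan=True)
        if not (same_nan.all() and close.all()):
            return False
        lt_cols = ["chrom", "start", "end", "role"]
        if not self.locus_table[lt_cols].reset_index(drop=True).equals(
            other.locus_table[lt_cols].reset_index(drop=True)
        ):
            return False
        return sorted(self.repeat_pairs) == sorted(other.repeat_pairs)


@dataclass
class GroundTruthPair:
    """An observed trace set together with its simulation ground truth.

    ``observed.positions = truth.positions + injected_noise`` wherever a
    localization is present.
    """

    observed: TraceSet
    truth: TraceSet
    injected_noise: np.ndarray

    def __post_init__(self) -> None:
        if self.observed.positions.shape != self.truth.positions.shape:
            raise ValueError("observed and truth must share a shape")
        if self.injected_noise.shape != self.truth.positions.shape:
            raise ValueError("injected_noise must match positions shape")
        o, t, e = self.observed.positions, self.truth.positions, self.injected_noise
        ok = np.isnan(o) | np.isclose(o, t + e, atol=1e-6)
        if not ok.all():
            raise ValueError("observed != truth + injected_noise")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _assemble(df: pd.DataFrame) -> TraceSet:
    """Build a TraceSet from a normalized long-form dataframe.

    Expects columns: cell_id, allele_id, condition, chrom, start, end, role,
    burst_state, x, y, z (floats, NaN allowed).
    """
    df = df.copy()
    df["role"] = df["role"].fillna("initial")
    # loci ordered genomically, initial before repeat copies
    loci = (
        df[["chrom", "start", "end", "role"]]
        .drop_duplicates()
        .sort_values(["role", "chrom", "start", "end"], kind="stable")
        .reset_index(drop=True)
    )
    locus_key = {tuple(r): i for i, r in enumerate(loci.itertuples(index=False, name=None))}
    df["_locus"] = [
        locus_key[(c, s, e, r)]
        for c, s, e, r in zip(df["chrom"], df["start"], df["end"], df["role"])
    ]

    traces = (
        df[["cell_id", "allele_id", "condition"]]
        .drop_duplicates()
        .reset_index(drop=True)
    )
    trace_key = {tuple(r): i for i, r in enumerate(traces.itertuples(index=False, name=None))}
    df["_trace"] = [
        trace_key[(c, a, k)] for c, a, k in zip(df["cell_id"], df["allele_id"], df["condition"])
    ]

    dup = df.duplicated(subset=["_trace", "_locus"], keep=False)
    if dup.any():
        bad = df[dup].iloc[0]
        raise TraceFormatError(
            f"duplicate (trace, locus) row: trace {bad['allele_id']!r} at "
            f"{bad['chrom']}:{int(bad['start'])}-{int(bad['end'])} ({bad['role']})"
        )

    n, l = len(traces), len(loci)
    pos = np.full((n, l, 3), np.nan)
    pos[df["_trace"], df["_locus"], 0] = df["x"].to_numpy()
    pos[df["_trace"], df["_locus"], 1] = df["y"].to_numpy()
    pos[df["_trace"], df["_locus"], 2] = df["z"].to_numpy()

    burst = df.groupby("_trace")["burst_state"].first()
    meta = traces.rename(columns={})
    meta["burst_state"] = [burst.get(i, None) for i in range(n)]
    meta["burst_state"] = meta["burst_state"].fillna("none")

    # pair repeat copies with the initial locus of the same interval
    pairs = []
    for ri in range(l):
        if loci.loc[ri, "role"] != "repeat":
            continue
        match = loci[
            (loci["role"] == "initial")
            & (loci["chrom"] == loci.loc[ri, "chrom"])
            & (loci["start"] == loci.loc[ri, "start"])
            & (loci["end"] == loci.loc[ri, "end"])
        ]
        if len(match):
            pairs.append((int(match.index[0]), ri))

    n_rows = len(df)
    n_entries_missing = int(np.isnan(df[["x", "y", "z"]].to_numpy()).sum())
    ts = TraceSet(pos, loci, meta, pairs)
    ts.parse_report = {
        "rows": n_rows,
        "rows_accepted": n_rows,
        "missing_coordinate_entries": n_entries_missing,
    }
    return ts


def read_traces(path, dialect: str = "fofct_csv") -> TraceSet:
    """Read a trace table; unparseable coordinate cells become missing.

    The returned set carries a ``parse_report`` dict counting input rows and
    missing/unparseable coordinate entries.
    """
    if dialect == "fofct_csv":
        raw = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
        missing = [c for c in _FOFCT_REQUIRED if c not in raw.columns]
        if missing:
            raise TraceFormatError(f"missing mandatory column(s): {', '.join(missing)}")
        df = pd.DataFrame(
            {
                "cell_id": raw.get("Cell_ID", pd.Series([""] * len(raw))).fillna(""),
                "allele_id": raw["Trace_ID"],
                "condition": raw.get("Condition", pd.Series([""] * len(raw))).fillna(""),
                "chrom": raw["Chrom"],
                "start": pd.to_numeric(raw["Chrom_Start"]).astype(int),
                "end": pd.to_numeric(raw["Chrom_End"]).astype(int),
                "role": raw.get("Role", pd.Series([None] * len(raw))),
                "burst_state": raw.get("Burst_State", pd.Series([None] * len(raw))),
                "x": pd.to_numeric(raw["X"], errors="coerce"),
                "y": pd.to_numeric(raw["Y"], errors="coerce"),
                "z": pd.to_numeric(raw["Z"], errors="coerce"),
            }
        )
        return _assemble(df)
    if dialect == "simple_tsv":
        raw = pd.read_csv(path, sep="\t", comment="#", dtype=str, skip_blank_lines=True)
        missing = [c for c in _TSV_REQUIRED if c not in raw.columns]
        if missing:
            raise TraceFormatError(f"missing mandatory column(s): {', '.join(missing)}")
        idx = pd.to_numeric(raw["locus_index"]).astype(int)
        df = pd.DataFrame(
            {
                "cell_id": raw.get("cell_id", pd.Series([""] * len(raw))).fillna(""),
                "allele_id": raw["trace_id"],
                "condition": raw.get("condition", pd.Series([""] * len(raw))).fillna(""),
                "chrom": raw.get("chrom", pd.Series(["unknown"] * len(raw))).fillna("unknown"),
                "start": pd.to_numeric(raw["start"]).astype(int) if "start" in raw else idx,
                "end": pd.to_numeric(raw["end"]).astype(int) if "end" in raw else idx + 1,
                "role": raw.get("role", pd.Series([None] * len(raw))),
                "burst_state": raw.get("burst_state", pd.Series([None] * len(raw))),
                "x": pd.to_numeric(raw["x_nm"], errors="coerce"),
                "y": pd.to_numeric(raw["y_nm"], errors="coerce"),
                "z": pd.to_numeric(raw["z_nm"], errors="coerce"),
            }
        )
        return _assemble(df)
    raise ValueError(f"unknown dialect {dialect!r}")


def _fmt(v: float, decimals: int) -> str:
    return "" if np.isnan(v) else f"{v:.{decimals}f}"


def write_traces(ts: TraceSet, path, dialect: str = "fofct_csv", decimals: int = 3) -> None:
    """Write a TraceSet so that ``read_traces`` recovers an equal set.

    Coordinates are written at a fixed decimal precision (default 3 decimals
    of nm); missing entries become empty cells.  Only D=3 sets are writable.
    """
    if ts.n_dims != 3:
        raise ValueError("only 3-dimensional trace sets can be written to disk")
    lt, meta = ts.locus_table, ts.trace_meta
    buf = io.StringIO()
    if dialect == "fofct_csv":
        buf.write("# written by lear; coordinates in nm\n")
        buf.write("Trace_ID,Cell_ID,Condition,Chrom,Chrom_Start,Chrom_End,X,Y,Z,Role,Burst_State\n")
        for i in range(ts.n_traces):
            for ell in range(ts.n_loci):
                x, y, z = ts.positions[i, ell]
                buf.write(
                    f"{meta['allele_id'].iloc[i]},{meta['cell_id'].iloc[i]},"
                    f"{meta['condition'].iloc[i]},{lt['chrom'].iloc[ell]},"
                    f"{int(lt['start'].iloc[ell])},{int(lt['end'].iloc[ell])},"
                    f"{_fmt(x, decimals)},{_fmt(y, decimals)},{_fmt(z, decimals)},"
                    f"{lt['role'].iloc[ell]},{meta['burst_state'].iloc[i]}\n"
                )
    elif dialect == "simple_tsv":
        buf.write("trace_id\tcell_id\tcondition\tlocus_index\tchrom\tstart\tend\trole"
                  "\tburst_state\tx_nm\ty_nm\tz_nm\n")
        for i in range(ts.n_traces):
            for ell in range(ts.n_loci):
                x, y, z = ts.positions[i, ell]
                buf.write(
                    f"{meta['allele_id'].iloc[i]}\t{meta['cell_id'].iloc[i]}\t"
                    f"{meta['condition'].iloc[i]}\t{ell}\t{lt['chrom'].iloc[ell]}\t"
                    f"{int(lt['start'].iloc[ell])}\t{int(lt['end'].iloc[ell])}\t"
                    f"{lt['role'].iloc[ell]}\t{meta['burst_state'].iloc[i]}\t"
                    f"{_fmt(x, decimals)}\t{_fmt(y, decimals)}\t{_fmt(z, decimals)}\n"
                )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
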