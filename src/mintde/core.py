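"""Data model for paired time-course assays.

A :class:`TimeCourseAssay` holds one assay's log-fold-change (LFC)
measurements as a dense ``(gene, time, replicate)`` tensor.  Values are LFC
relative to the baseline time point, which is always the smallest time on
the grid.  An :class:`AssayPair` couples two assays (e.g. transcriptome and
proteome) over identical gene and time grids; replicate counts may differ
between the two assays.

Readers accept tidy long-format delimited text (columns ``gene_id``,
``time``, ``replicate``, ``value``) or one wide matrix per assay (a
``gene_id`` column followed by ``<time>_<replicate>`` columns).  All writers
emit TSV with floats at 17 significant digits so that a write/read round
trip is numerically exact.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TimeCourseAssay",
    "AssayPair",
    "ValidationError",
    "read_assay",
    "write_assay",
    "pair_assays",
]

#: Format used for every float written to disk (17 significant digits:
#: enough to round-trip IEEE doubles exactly).
FLOAT_FMT = "%.17g"

#: Default policy for missing (gene, time, replicate) cells.
MISSING_POLICY_DEFAULT = "error"


class ValidationError(ValueError):
    """Raised when an input file or assay violates the data contract."""


def _delimiter_for(path: str) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


@dataclass
class TimeCourseAssay:
    """One assay's LFC time-courses.

    Parameters
    ----------
    assay_name:
        Label for the assay (e.g. ``"mrna"`` or ``"protein"``).
    gene_ids:
        Ordered, unique gene labels (length ``G``).  Input order is
        preserved everywhere; ranking is the only reordering downstream.
    times:
        Strictly increasing numeric time labels (length ``T + 1``).  The
        smallest time is the baseline.
    replicate_ids:
        Replicate labels (length ``B``).
    values:
        ``(G, T + 1, B)`` array of LFC values.  ``NaN`` marks a missing
        cell, which is only permitted under the ``"drop"`` missing policy.
    missing_policy:
        ``"error"`` (default; any missing cell is a validation error) or
        ``"drop"`` (missing cells are carried as NaN and downstream tests
        use per-cell available replicate counts).
    """

    assay_name: str
    gene_ids: list[str]
    times: np.ndarray
    replicate_ids: list[str]
    values: np.ndarray
    missing_policy: str = MISSING_POLICY_DEFAULT

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.replicate_ids = [str(r) for r in self.replicate_ids]
        self.validate()

    # -- basic shape accessors -------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_times(self) -> int:
        """Number of time points including baseline (T + 1)."""
        return len(self.times)

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_ids)

    @property
    def baseline_time(self) -> float:
        return float(self.times[0])

    def validate(self) -> "TimeCourseAssay":
        G, nt, B = self.values.shape if self.values.ndim == 3 else (0, 0, 0)
        if self.values.ndim != 3:
            raise ValidationError(
                f"values must be 3-D (gene, time, replicate); got shape "
                f"{self.values.shape}"
            )
        if G < 1 or nt < 2 or B < 1:
            raise ValidationError(
                f"need G >= 1, T >= 1, B >= 1; got G={G}, T+1={nt}, B={B}"
            )
        if G != len(self.gene_ids):
            raise ValidationError("gene_ids length does not match values")
        if nt != len(self.times):
            raise ValidationError("times length does not match values")
        if B != len(self.replicate_ids):
            raise ValidationError("replicate_ids length does not match values")
        if len(set(self.gene_ids)) != G:
            dupes = pd.Index(self.gene_ids)
            dupes = sorted(set(dupes[dupes.duplicated()]))
            raise ValidationError(f"duplicate gene_ids: {dupes[:5]}")
        if not np.all(np.diff(self.times) > 0):
            raise ValidationError("times must be strictly increasing")
        if self.missing_policy not in ("error", "drop"):
            raise ValidationError(
                f"unknown missing_policy {self.missing_policy!r}"
            )
        nan_mask = np.isnan(self.values)
        if nan_mask.any():
            if self.missing_policy == "error":
                g, t, b = map(int, np.argwhere(nan_mask)[0])
                raise ValidationError(
                    "missing value at (gene={}, time={}, replicate={}) under "
                    "missing_policy='error'".format(
                        self.gene_ids[g], self.times[t], self.replicate_ids[b]
                    )
                )
            # even under "drop", the baseline must be observed for every gene
            all_missing_baseline = nan_mask[:, 0, :].all(axis=1)
            if all_missing_baseline.any():
                g = int(np.flatnonzero(all_missing_baseline)[0])
                raise ValidationError(
                    f"baseline time {self.baseline_time:g} entirely missing "
                    f"for gene {self.gene_ids[g]}"
                )
        return self

    def gene_index(self) -> pd.Index:
        return pd.Index(self.gene_ids, name="gene_id")

    def subset_genes(self, gene_ids: list[str]) -> "TimeCourseAssay":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [pos[g] for g in gene_ids]
        return TimeCourseAssay(
            assay_name=self.assay_name,
            gene_ids=list(gene_ids),
            times=self.times.copy(),
            replicate_ids=list(self.replicate_ids),
            values=self.values[idx],
            missing_policy=self.missing_policy,
        )

    def to_long(self) -> pd.DataFrame:
        """Tidy long-format view: gene_id, time, replicate, value."""
        G, nt, B = self.values.shape
        return pd.DataFrame(
            {
                "gene_id": np.repeat(self.gene_ids, nt * B),
                "time": np.tile(np.repeat(self.times, B), G),
                "replicate": np.tile(self.replicate_ids, G * nt),
                "value": self.values.ravel(),
            }
        )


@dataclass
class AssayPair:
    """Two assays over identical gene and time grids (replicates may differ)."""

    x: TimeCourseAssay
    y: TimeCourseAssay

    def __post_init__(self) -> None:
        if self.x.gene_ids != self.y.gene_ids:
            raise ValidationError("paired assays must share identical gene_ids")
        if not np.array_equal(self.x.times, self.y.times):
            raise ValidationError("paired assays must share identical time grids")

    @property
    def gene_ids(self) -> list[str]:
        return self.x.gene_ids

    @property
    def times(self) -> np.ndarray:
        return self.x.times


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_table(path: str) -> pd.DataFrame:
    if not os.path.exists(path):
        raise ValidationError(f"input file does not exist: {path}")
    return pd.read_csv(path, sep=_delimiter_for(path), dtype=str)


def _coerce_numeric(series: pd.Series, colname: str) -> np.ndarray:
    # parsed with Python's correctly rounded float() so that values written
    # at 17 significant digits round-trip bit-exactly
    out = np.empty(len(series), dtype=float)
    for i, raw in enumerate(series.to_numpy()):
        if raw is None or (isinstance(raw, float) and np.isnan(raw)):
            out[i] = np.nan
            continue
        try:
            out[i] = float(raw)
        except (TypeError, ValueError):
            raise ValidationError(
                f"non-numeric {colname} {raw!r} at data row {i + 1}"
            ) from None
    return out


def _assemble(
    df: pd.DataFrame, assay_name: str, missing_policy: str
) -> TimeCourseAssay:
    """Build an assay from a tidy frame with gene_id/time/replicate/value."""
    # duplicate (gene, time, replicate) triples are a hard error
    dup = df.duplicated(subset=["gene_id", "time", "replicate"], keep=False)
    if dup.any():
        r = df[dup].iloc[0]
        raise ValidationError(
            f"duplicate (gene, time, replicate) entry: "
            f"({r['gene_id']}, {r['time']}, {r['replicate']})"
        )
    gene_ids = list(dict.fromkeys(df["gene_id"]))  # first-occurrence order
    times = np.array(sorted(set(df["time"].astype(float))))
    rep_ids = sorted(set(df["replicate"].astype(str)), key=_replicate_key)
    G, nt, B = len(gene_ids), len(times), len(rep_ids)

    gi = {g: i for i, g in enumerate(gene_ids)}
    ti = {t: i for i, t in enumerate(times)}
    ri = {r: i for i, r in enumerate(rep_ids)}
    values = np.full((G, nt, B), np.nan)
    rows_g = df["gene_id"].map(gi).to_numpy()
    rows_t = df["time"].astype(float).map(ti).to_numpy()
    rows_r = df["replicate"].astype(str).map(ri).to_numpy()
    values[rows_g, rows_t, rows_r] = df["value"].to_numpy(dtype=float)
    return TimeCourseAssay(
        assay_name=assay_name,
        gene_ids=gene_ids,
        times=times,
        replicate_ids=rep_ids,
        values=values,
        missing_policy=missing_policy,
    )


def _replicate_key(label: str):
    """Sort replicate labels numerically when possible, else lexically."""
    try:
        return (0, float(label), label)
    except ValueError:
        return (1, 0.0, label)


def read_assay(
    path: str,
    format: str = "long",
    assay_name: str | None = None,
    missing_policy: str = MISSING_POLICY_DEFAULT,
) -> TimeCourseAssay:
    """Read one assay from delimited text.

    ``format="long"`` expects columns gene_id, time, replicate, value.
    ``format="wide"`` expects a gene_id column followed by columns named
    ``<time>_<replicate>``.  Delimiter is inferred from the extension
    (``.csv`` -> comma, otherwise tab).
    """
    if assay_name is None:
        assay_name = os.path.splitext(os.path.basename(path))[0]
    df = _read_table(path)
    if format == "long":
        required = ["gene_id", "time", "replicate", "value"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(f"long format missing columns: {missing}")
        df = df[required].copy()
        df["time"] = _coerce_numeric(df["time"], "time")
        df["value"] = _coerce_numeric(df["value"], "value")
    elif format == "wide":
        if "gene_id" not in df.columns:
            raise ValidationError("wide format requires a gene_id column")
        long_rows = df.melt(
            id_vars="gene_id", var_name="time_rep", value_name="value"
        )
        split = long_rows["time_rep"].str.rsplit("_", n=1, expand=True)
        if split.shape[1] != 2 or split.isna().any().any():
            raise ValidationError(
                "wide column headers must be named <time>_<replicate>"
            )
        long_rows["time"] = _coerce_numeric(split[0], "time")
        long_rows["replicate"] = split[1]
        long_rows["value"] = _coerce_numeric(long_rows["value"], "value")
        df = long_rows[["gene_id", "time", "replicate", "value"]]
    else:
        raise ValidationError(f"unknown format {format!r}")
    assay = _assemble(df, assay_name, missing_policy)
    if assay.n_times < 2:
        raise ValidationError("need a baseline plus at least one time point")
    return assay


def write_assay(assay: TimeCourseAssay, path: str, format: str = "long") -> None:
    """Write an assay as TSV (or CSV by extension), 17 significant digits."""
    sep = _delimiter_for(path)
    if format == "long":
        df = assay.to_long()
        df.to_csv(path, sep=sep, index=False, float_format=FLOAT_FMT)
    elif format == "wide":
        G, nt, B = assay.values.shape
        cols = {"gene_id": assay.gene_ids}
        for ti, t in enumerate(assay.times):
            tlab = f"{t:g}"
            for bi, r in enumerate(assay.replicate_ids):
                cols[f"{tlab}_{r}"] = assay.values[:, ti, bi]
        pd.DataFrame(cols).to_csv(
            path, sep=sep, index=False, float_format=FLOAT_FMT
        )
    else:
        raise ValidationError(f"unknown format {format!r}")


def pair_assays(
    x: TimeCourseAssay, y: TimeCourseAssay, join: str = "strict"
) -> AssayPair:
    """Couple two assays into an :class:`AssayPair`.

    ``join="strict"`` errors unless gene sets and time grids are identical;
    ``join="inner"`` intersects gene sets (preserving x's order) and still
    requires identical time grids.
    """
    if not np.array_equal(x.times, y.times):
        raise ValidationError(
            f"time grids differ between {x.assay_name!r} and {y.assay_name!r}"
        )
    if join == "strict":
        if x.gene_ids != y.gene_ids:
            raise ValidationError(
                "strict join requires identical gene sets and order"
            )
        return AssayPair(x=x, y=y)
    if join == "inner":
        common = set(x.gene_ids) & set(y.gene_ids)
        if not common:
            raise ValidationError("empty gene intersection")
        keep = [g for g in x.gene_ids if g in common]
        return AssayPair(x=x.subset_genes(keep), y=y.subset_genes(keep))
    raise ValidationError(f"unknown join {join!r}")
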