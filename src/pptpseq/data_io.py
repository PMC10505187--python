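"""Readers and writers for the tabular artifacts of a sort-seq screen.

All computation lives elsewhere; this module only parses, validates schemas,
and serializes. Canonical on-disk formats are tab-separated text files:

* ``bins.tsv`` — the sorting design: per-bin log10 fluorescence boundaries,
  cells sorted ``C_j`` and reads sequenced ``R_j``. An optional
  ``replicate_id`` column gives each replicate its own sort statistics.
* ``counts.tsv`` — long-format per-variant per-bin read counts ``r_ij``.
* ``library.tsv`` / ``promoters.tsv`` — sgRNA and promoter annotations.
* ``binding.tsv`` — optional BED-like TF binding sites with fold enrichment.

Outer bin boundaries are open (the sorter keeps everything below the first
interior boundary and above the last); they are serialized as the literal
strings ``-inf`` / ``inf`` so that round trips are bit exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "BinSpec",
    "LibraryAnnotation",
    "VariantBinCounts",
    "read_bin_spec",
    "read_counts",
    "read_library",
    "read_binding",
    "write_table",
    "make_bins",
    "boundaries_ln",
    "included_mask",
]

LN10 = math.log(10.0)


class SchemaError(ValueError):
    """A required column is missing or has the wrong dtype."""


class ValidationError(ValueError):
    """Schema-valid input violates a domain invariant."""


@dataclass(frozen=True)
class BinSpec:
    """One fluorescence-sorting gate.

    Boundaries are in log10 fluorescence (arbitrary units); the first bin's
    lower and the last bin's upper boundary are ``-inf`` / ``+inf``.
    ``cells_sorted`` is the number of cells the sorter deposited in the bin
    (``C_j``) and ``reads_total`` the number of sequencing reads carrying the
    bin's barcode (``R_j``).
    """

    bin_index: int
    lower_log10: float
    upper_log10: float
    cells_sorted: float
    reads_total: float
    included: bool = True


@dataclass
class VariantBinCounts:
    """Raw reads ``r_ij`` for one sgRNA-promoter variant across all bins."""

    sgrna_id: str
    promoter_id: str
    replicate_id: str
    reads: np.ndarray

    def __post_init__(self) -> None:
        self.reads = np.asarray(self.reads, dtype=float)
        if np.any(self.reads < 0):
            raise ValidationError(
                f"negative read count for variant "
                f"({self.sgrna_id}, {self.promoter_id}, {self.replicate_id})"
            )


@dataclass
class LibraryAnnotation:
    """sgRNA and promoter annotation tables for one combinatorial library.

    ``sgrnas`` has columns ``sgrna_id, target_tf, is_control``; ``promoters``
    has ``promoter_id, operon, genes, tf_gene_of_promoter`` where ``genes`` is
    a list of gene names and ``tf_gene_of_promoter`` names the TF gene the
    promoter itself drives (empty if none — used for autoregulation calls).
    """

    sgrnas: pd.DataFrame
    promoters: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["promoter_id", "operon", "genes", "tf_gene_of_promoter"]
        )
    )

    def __post_init__(self) -> None:
        s = self.sgrnas
        _require(s, ["sgrna_id", "target_tf", "is_control"], "library")
        ctrl = s["is_control"].astype(bool)
        bad = s.loc[ctrl & (s["target_tf"].fillna("") != ""), "sgrna_id"]
        if len(bad):
            raise ValidationError(
                f"control sgRNAs must have empty target_tf: {sorted(bad)}"
            )
        bad = s.loc[~ctrl & (s["target_tf"].fillna("") == ""), "sgrna_id"]
        if len(bad):
            raise ValidationError(
                f"non-control sgRNAs must have a target_tf: {sorted(bad)}"
            )
        if s["sgrna_id"].duplicated().any():
            raise ValidationError("duplicate sgrna_id in library table")
        p = self.promoters
        _require(
            p, ["promoter_id", "operon", "genes", "tf_gene_of_promoter"], "promoters"
        )
        if p["promoter_id"].duplicated().any():
            raise ValidationError("duplicate promoter_id in promoter table")

    @property
    def control_ids(self) -> list[str]:
        mask = self.sgrnas["is_control"].astype(bool)
        return self.sgrnas.loc[mask, "sgrna_id"].tolist()

    def target_tf_of(self, sgrna_id: str) -> str:
        row = self.sgrnas.loc[self.sgrnas["sgrna_id"] == sgrna_id]
        if row.empty:
            raise KeyError(sgrna_id)
        return str(row["target_tf"].iloc[0] or "")


def _require(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing column(s): {missing}")


# ---------------------------------------------------------------------------
# bin specs


def validate_bins(bins: Sequence[BinSpec]) -> None:
    """Check ordering, contiguity and open outer boundaries."""
    if len(bins) < 3:
        raise ValidationError(f"need at least 3 bins, got {len(bins)}")
    idx = [b.bin_index for b in bins]
    if idx != sorted(idx) or len(set(idx)) != len(idx):
        raise ValidationError("bin_index must be unique and sorted")
    if bins[0].lower_log10 != -math.inf:
        raise ValidationError("first bin's lower boundary must be -inf")
    if bins[-1].upper_log10 != math.inf:
        raise ValidationError("last bin's upper boundary must be inf")
    for a, b in zip(bins, bins[1:]):
        if a.upper_log10 != b.lower_log10:
            raise ValidationError(
                f"bins {a.bin_index} and {b.bin_index} are not contiguous "
                f"({a.upper_log10} != {b.lower_log10})"
            )
    interior = [b.upper_log10 for b in bins[:-1]]
    if any(x >= y for x, y in zip(interior, interior[1:])):
        raise ValidationError("bin boundaries must be strictly increasing")
    for b in bins:
        if b.cells_sorted < 0 or b.reads_total < 0:
            raise ValidationError(f"negative counts in bin {b.bin_index}")


def make_bins(
    edges_log10: Sequence[float],
    cells_sorted: Sequence[float] | None = None,
    reads_total: Sequence[float] | None = None,
    included: Sequence[bool] | None = None,
) -> list[BinSpec]:
    """Build a contiguous bin collection from J-1 interior edges.

    ``edges_log10`` holds the interior boundaries only; the outer boundaries
    are open. A J-bin design therefore takes J-1 edges.
    """
    edges = [-math.inf, *map(float, edges_log10), math.inf]
    n = len(edges) - 1
    cells = list(cells_sorted) if cells_sorted is not None else [0.0] * n
    reads = list(reads_total) if reads_total is not None else [0.0] * n
    incl = list(included) if included is not None else [True] * n
    bins = [
        BinSpec(j + 1, edges[j], edges[j + 1], cells[j], reads[j], bool(incl[j]))
        for j in range(n)
    ]
    validate_bins(bins)
    return bins


def boundaries_ln(bins: Sequence[BinSpec]) -> np.ndarray:
    """Bin edges on the natural-log fluorescence scale, length J+1.

    Interior log10 boundaries are converted once by multiplying ln 10; the
    outer entries stay infinite so the normal CDF evaluates to 0 and 1 there.
    """
    edges = np.array(
        [bins[0].lower_log10] + [b.upper_log10 for b in bins], dtype=float
    )
    out = edges * LN10
    out[0] = -np.inf if math.isinf(edges[0]) else out[0]
    out[-1] = np.inf if math.isinf(edges[-1]) else out[-1]
    return out


def included_mask(bins: Sequence[BinSpec]) -> np.ndarray:
    return np.array([b.included for b in bins], dtype=bool)


_BIN_COLUMNS = [
    "bin_index",
    "lower_log10",
    "upper_log10",
    "cells_sorted",
    "reads_total",
    "included",
]


def _bins_from_frame(df: pd.DataFrame) -> list[BinSpec]:
    df = df.sort_values("bin_index")
    bins = [
        BinSpec(
            bin_index=int(r.bin_index),
            lower_log10=float(r.lower_log10),
            upper_log10=float(r.upper_log10),
            cells_sorted=float(r.cells_sorted),
            reads_total=float(r.reads_total),
            included=_as_bool(r.included),
        )
        for r in df.itertuples(index=False)
    ]
    validate_bins(bins)
    return bins


def _as_bool(x: object) -> bool:
    if isinstance(x, str):
        return x.strip().lower() in {"true", "1", "yes"}
    return bool(x)


def read_bin_spec(
    path: str | Path, format: str | None = None
) -> list[BinSpec] | dict[str, list[BinSpec]]:
    """Read a sorting design from TSV or JSON.

    Returns an ordered list of :class:`BinSpec`. If the table carries a
    ``replicate_id`` column, returns a dict mapping replicate to its bins
    (boundaries must agree across replicates; ``C_j``/``R_j`` may differ).
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "tsv"
    if format == "json":
        df = pd.read_json(path)
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown format {format!r}")
    _require(df, _BIN_COLUMNS, "bins")
    for col in ("lower_log10", "upper_log10"):
        df[col] = df[col].astype(float)  # "-inf"/"inf" strings parse directly
    if "replicate_id" in df.columns:
        out: dict[str, list[BinSpec]] = {}
        for rep, sub in df.groupby("replicate_id", sort=True):
            out[str(rep)] = _bins_from_frame(sub)
        ref = next(iter(out.values()))
        for rep, bins in out.items():
            if [(b.lower_log10, b.upper_log10) for b in bins] != [
                (b.lower_log10, b.upper_log10) for b in ref
            ]:
                raise ValidationError(
                    f"replicate {rep} has different bin boundaries"
                )
        return out
    return _bins_from_frame(df)


# ---------------------------------------------------------------------------
# counts


def read_counts(
    path: str | Path, bins: Sequence[BinSpec] | int
) -> list[VariantBinCounts]:
    """Read long-format read counts into dense per-variant vectors.

    The table needs columns ``sgrna_id, promoter_id, replicate_id, bin,
    reads``; (variant, bin) rows that are absent are zero reads. Bin indices
    must lie in the design's 1..J range and duplicates are rejected.
    """
    n_bins = len(bins) if not isinstance(bins, int) else bins
    df = pd.read_csv(path, sep="\t")
    _require(df, ["sgrna_id", "promoter_id", "replicate_id", "bin", "reads"], "counts")
    if (df["reads"] < 0).any():
        bad = df.loc[df["reads"] < 0].iloc[0]
        raise ValidationError(
            f"negative reads for ({bad.sgrna_id}, {bad.promoter_id}, bin {bad.bin})"
        )
    out_of_range = ~df["bin"].between(1, n_bins)
    if out_of_range.any():
        bad = df.loc[out_of_range, "bin"].iloc[0]
        raise ValidationError(f"bin index {bad} outside design range 1..{n_bins}")
    key_cols = ["sgrna_id", "promoter_id", "replicate_id", "bin"]
    dup = df.duplicated(key_cols, keep=False)
    if dup.any():
        bad = df.loc[dup, key_cols].iloc[0].tolist()
        raise ValidationError(f"duplicate (variant, bin) row: {bad}")
    records: list[VariantBinCounts] = []
    for (sg, pr, rep), sub in df.groupby(
        ["sgrna_id", "promoter_id", "replicate_id"], sort=True
    ):
        reads = np.zeros(n_bins)
        reads[sub["bin"].to_numpy(dtype=int) - 1] = sub["reads"].to_numpy(dtype=float)
        records.append(VariantBinCounts(str(sg), str(pr), str(rep), reads))
    return records


def counts_to_frame(records: Iterable[VariantBinCounts]) -> pd.DataFrame:
    """Long-format frame of all nonzero and zero count rows (dense)."""
    rows = []
    for rec in records:
        for j, r in enumerate(rec.reads, start=1):
            rows.append((rec.sgrna_id, rec.promoter_id, rec.replicate_id, j, int(r)))
    return pd.DataFrame(
        rows, columns=["sgrna_id", "promoter_id", "replicate_id", "bin", "reads"]
    )


# ---------------------------------------------------------------------------
# library and binding tables


def read_library(
    sgrna_path: str | Path, promoter_path: str | Path | None = None
) -> LibraryAnnotation:
    sg = pd.read_csv(sgrna_path, sep="\t", dtype={"sgrna_id": str, "target_tf": str})
    sg["target_tf"] = sg.get("target_tf", "").fillna("")
    sg["is_control"] = sg["is_control"].map(_as_bool)
    if promoter_path is None:
        return LibraryAnnotation(sgrnas=sg)
    pr = pd.read_csv(promoter_path, sep="\t", dtype=str).fillna("")
    pr["genes"] = pr["genes"].map(lambda s: s.split(";") if s else [])
    return LibraryAnnotation(sgrnas=sg, promoters=pr)


def read_binding(path: str | Path) -> pd.DataFrame:
    """Read a BED-like binding-site table (0-based half-open intervals)."""
    df = pd.read_csv(path, sep="\t")
    _require(
        df,
        ["tf", "promoter_id", "site_start", "site_end", "fold_enrichment", "tss_position"],
        "binding",
    )
    if (df["fold_enrichment"] <= 0).any():
        raise ValidationError("fold_enrichment must be positive")
    if (df["site_end"] <= df["site_start"]).any():
        raise ValidationError("site_end must exceed site_start (half-open interval)")
    return df


# ---------------------------------------------------------------------------
# generic writer


def _format_value(x: object) -> str:
    if x is None:
        return "NA"
    if isinstance(x, float):
        if math.isnan(x):
            return "NA"
        if math.isinf(x):
            return "inf" if x > 0 else "-inf"
        return f"{x:.6g}"
    if isinstance(x, (list, tuple, set, frozenset)):
        return ";".join(str(v) for v in sorted(map(str, x)))
    if isinstance(x, (bool, np.bool_)):
        return str(bool(x))
    return str(x)


def write_table(records: object, path: str | Path) -> None:
    """Write a collection of records (dataclasses or a DataFrame) as TSV.

    Floats are rendered at 6 significant digits and missing values as ``NA``;
    list-valued fields are semicolon-joined.
    """
    path = Path(path)
    if isinstance(records, pd.DataFrame):
        df = records
        header = list(df.columns)
        rows = df.itertuples(index=False)
        with open(path, "w") as fh:
            fh.write("\t".join(header) + "\n")
            for row in rows:
                fh.write("\t".join(_format_value(v) for v in row) + "\n")
        return
    records = list(records)
    if records and not hasattr(records[0], "__dataclass_fields__"):
        raise TypeError("write_table expects a DataFrame or dataclass records")
    if records:
        header = [f.name for f in dc_fields(records[0])]
    else:
        header = []
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for rec in records:
            fh.write(
                "\t".join(_format_value(getattr(rec, name)) for name in header) + "\n"
            )


def write_bin_spec(
    bins: Sequence[BinSpec] | dict[str, Sequence[BinSpec]], path: str | Path
) -> None:
    """Serialize bins (optionally per replicate) with exact inf sentinels."""
    rows = []
    if isinstance(bins, dict):
        for rep, bs in bins.items():
            for b in bs:
                rows.append((rep, *_bin_row(b)))
        cols = ["replicate_id", *_BIN_COLUMNS]
    else:
        rows = [_bin_row(b) for b in bins]
        cols = _BIN_COLUMNS
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(map(str, row)) + "\n")


def _bin_row(b: BinSpec) -> tuple:
    lo = "-inf" if math.isinf(b.lower_log10) else repr(b.lower_log10)
    hi = "inf" if math.isinf(b.upper_log10) else repr(b.upper_log10)
    return (b.bin_index, lo, hi, b.cells_sorted, b.reads_total, b.included)
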