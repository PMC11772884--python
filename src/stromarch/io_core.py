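"""Readers, writers, bin aggregation and QC filters for spatial expression data.

The central container is :class:`SpotGrid`, a sparse long-format table of
per-spot gene counts on an integer grid with a physical pitch.  Raw
sub-micron spots (``bin_size=1``) are aggregated into coarser bins (e.g.
bin50, 50x50 spots = 25 um at 0.5 um pitch) before quality control.
Annotated cells travel as plain :class:`pandas.DataFrame` objects with a
declared column contract (see :func:`validate_cell_table`), and region
annotations as a :class:`RegionMask` label array aligned to the bin grid.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpotGrid",
    "RegionMask",
    "QCReport",
    "GemFormatError",
    "ValidationError",
    "read_gem",
    "write_gem",
    "aggregate_bins",
    "qc_filter",
    "read_cell_table",
    "write_cell_table",
    "validate_cell_table",
    "read_region_mask",
    "write_region_mask",
    "read_expression",
    "write_expression_mtx",
]

GEM_COLUMNS = ("gene", "x", "y", "count")

#: Required columns of an annotated cell table.
CELL_COLUMNS = ("cell_id", "x_um", "y_um", "cell_type", "sample_id", "group")

#: Recognized sample groups (presence/absence of the fibrotic ring).
GROUPS = ("FRpos", "FRneg")


class GemFormatError(ValueError):
    """Raised when a GEM-like TSV does not conform to the expected layout."""


class ValidationError(ValueError):
    """Raised when data violate a container invariant."""


@dataclass
class SpotGrid:
    """Sparse per-spot gene counts on an integer grid.

    Parameters
    ----------
    records
        Long-format table with columns ``gene`` (str), ``x``, ``y`` (int,
        0-based grid coordinates) and ``count`` (non-negative int).
        Duplicate ``(gene, x, y)`` triples are summed on construction.
    pitch_um
        Physical center-to-center spot distance per grid unit.
    bin_size
        1 for raw spots; >1 after :func:`aggregate_bins`.
    """

    records: pd.DataFrame
    pitch_um: float = 0.5
    bin_size: int = 1

    def __post_init__(self) -> None:
        if self.pitch_um <= 0:
            raise ValidationError(f"pitch_um must be > 0, got {self.pitch_um}")
        if self.bin_size < 1:
            raise ValidationError(f"bin_size must be >= 1, got {self.bin_size}")
        df = self.records
        missing = [c for c in GEM_COLUMNS if c not in df.columns]
        if missing:
            raise GemFormatError(f"missing column(s): {', '.join(missing)}")
        df = df.loc[:, list(GEM_COLUMNS)].copy()
        if len(df):
            neg = np.asarray(df["count"] < 0)
            if neg.any():
                row = int(np.flatnonzero(neg)[0])
                raise ValidationError(f"negative count at row {row}")
            df["x"] = df["x"].astype(np.int64)
            df["y"] = df["y"].astype(np.int64)
            df["count"] = df["count"].astype(np.int64)
            # canonicalize: sum duplicates, stable gene/x/y order
            df = (
                df.groupby(["gene", "x", "y"], as_index=False, sort=True)["count"]
                .sum()
            )
        else:
            df = df.astype({"x": np.int64, "y": np.int64, "count": np.int64})
        object.__setattr__(self, "records", df.reset_index(drop=True))

    @property
    def total_count(self) -> int:
        return int(self.records["count"].sum())

    @property
    def genes(self) -> list[str]:
        return sorted(self.records["gene"].unique())

    def gene_marginals(self) -> pd.Series:
        """Total count per gene (invariant under bin aggregation)."""
        return self.records.groupby("gene")["count"].sum()

    def bin_totals(self) -> pd.DataFrame:
        """Per-(x, y) total count and number of distinct genes."""
        g = self.records.groupby(["x", "y"])
        out = g["count"].sum().rename("total").to_frame()
        out["n_genes"] = g["gene"].nunique()
        return out.reset_index()


@dataclass
class RegionMask:
    """Region labels on the bin grid, indexed ``labels[y, x]``.

    Labels: 0 background, 1 tumor, 2 liver, 3 stroma.
    """

    labels: np.ndarray
    pitch_um: float

    BACKGROUND = 0
    TUMOR = 1
    LIVER = 2
    STROMA = 3
    NAMES = {0: "background", 1: "tumor", 2: "liver", 3: "stroma"}

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 2:
            raise ValidationError("RegionMask labels must be 2D")
        if not np.isin(arr, list(self.NAMES)).all():
            raise ValidationError("RegionMask labels must be in {0,1,2,3}")
        if self.pitch_um <= 0:
            raise ValidationError("pitch_um must be > 0")
        object.__setattr__(self, "labels", arr.astype(np.int16))

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def bin_of(self, x_um: np.ndarray, y_um: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map physical coordinates to (col, row) bin indices (floor)."""
        bx = np.floor(np.asarray(x_um, dtype=float) / self.pitch_um).astype(np.int64)
        by = np.floor(np.asarray(y_um, dtype=float) / self.pitch_um).astype(np.int64)
        return bx, by


@dataclass
class QCReport:
    """Summary of a bin-level QC pass.

    The chip-level rule (median distinct genes per bin > 500) is
    report-only: it flags a chip, it never removes bins.
    """

    n_bins_before: int
    n_bins_removed: int
    median_genes_per_bin: float
    median_genes_pass: bool
    max_mito_frac: float
    warnings: list[str] = field(default_factory=list)

    MEDIAN_GENES_THRESHOLD = 500

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def read_gem(path: str | Path, pitch_um: float = 0.5) -> SpotGrid:
    """Read a GEM-like TSV (columns gene, x, y, count; extras ignored)."""
    path = Path(path)
    header = pd.read_csv(path, sep="\t", nrows=0)
    missing = [c for c in GEM_COLUMNS if c not in header.columns]
    if missing:
        raise GemFormatError(
            f"{path.name}: missing required column(s): {', '.join(missing)}"
        )
    df = pd.read_csv(path, sep="\t", usecols=list(GEM_COLUMNS), dtype={"gene": str})
    return SpotGrid(records=df, pitch_um=pitch_um, bin_size=1)


def write_gem(grid: SpotGrid, path: str | Path) -> None:
    """Write a SpotGrid as a tab-separated GEM file."""
    grid.records.to_csv(path, sep="\t", index=False)


def aggregate_bins(grid: SpotGrid, bin_size: int) -> SpotGrid:
    """Aggregate a raw spot grid into ``bin_size`` x ``bin_size`` bins.

    Output coordinates are half-open floor bins ``(x // bin_size,
    y // bin_size)``; the total count and the per-gene marginals are
    conserved, and the physical pitch scales by ``bin_size``.
    """
    if bin_size < 1:
        raise ValidationError(f"bin_size must be >= 1, got {bin_size}")
    if grid.bin_size != 1:
        raise ValidationError("aggregate_bins expects a raw (bin_size=1) grid")
    df = grid.records.copy()
    df["x"] = df["x"] // bin_size
    df["y"] = df["y"] // bin_size
    return SpotGrid(records=df, pitch_um=grid.pitch_um * bin_size, bin_size=bin_size)


def qc_filter(
    grid: SpotGrid,
    mito_genes: Iterable[str] = (),
    max_mito_frac: float = 0.25,
) -> tuple[SpotGrid, QCReport]:
    """Remove bins whose mitochondrial count fraction exceeds the threshold.

    A bin survives iff mito_count / total_count <= ``max_mito_frac`` (the
    fraction of an empty bin is defined as 0, so empty bins are kept).
    The report carries the median number of distinct genes per bin and
    whether it clears the chip-level >500 rule; that rule never filters.
    """
    if grid.bin_size <= 1:
        raise ValidationError("qc_filter expects an aggregated grid (bin_size > 1)")
    mito = set(mito_genes)
    df = grid.records
    totals = df.groupby(["x", "y"])["count"].sum()
    mito_totals = (
        df[df["gene"].isin(mito)].groupby(["x", "y"])["count"].sum()
        if mito
        else pd.Series(dtype=np.int64)
    )
    mito_totals = mito_totals.reindex(totals.index, fill_value=0)
    denom = totals.to_numpy(dtype=float)
    frac = np.where(denom > 0, mito_totals.to_numpy(dtype=float) / np.maximum(denom, 1), 0.0)
    keep = frac <= max_mito_frac
    keep_bins = set(totals.index[keep])
    kept = df[[xy in keep_bins for xy in zip(df["x"], df["y"])]]

    n_genes = df.groupby(["x", "y"])["gene"].nunique()
    median_genes = float(np.median(n_genes)) if len(n_genes) else 0.0
    warns: list[str] = []
    if keep.sum() == 0:
        warns.append("all bins removed by the mitochondrial filter")
        warnings.warn(warns[-1])
    report = QCReport(
        n_bins_before=int(len(totals)),
        n_bins_removed=int((~keep).sum()),
        median_genes_per_bin=median_genes,
        median_genes_pass=median_genes > QCReport.MEDIAN_GENES_THRESHOLD,
        max_mito_frac=max_mito_frac,
        warnings=warns,
    )
    out = SpotGrid(records=kept, pitch_um=grid.pitch_um, bin_size=grid.bin_size)
    return out, report


def validate_cell_table(
    cells: pd.DataFrame, vocabulary: Sequence[str] | None = None
) -> pd.DataFrame:
    """Check the cell-table column contract and invariants.

    Requires columns ``cell_id, x_um, y_um, cell_type, sample_id, group``
    (``parent_lineage`` optional), finite coordinates, cell ids unique
    within each sample, and — when a vocabulary is declared — cell types
    drawn from it.
    """
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise ValidationError(f"cell table missing column(s): {', '.join(missing)}")
    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    if not np.isfinite(xy).all():
        raise ValidationError("cell coordinates must be finite")
    dup = cells.duplicated(subset=["sample_id", "cell_id"])
    if dup.any():
        raise ValidationError("cell_id must be unique within each sample")
    bad_group = set(cells["group"].unique()) - set(GROUPS)
    if bad_group:
        raise ValidationError(f"unknown group label(s): {sorted(bad_group)}")
    if vocabulary is not None:
        unknown = set(cells["cell_type"].unique()) - set(vocabulary)
        if unknown:
            raise ValidationError(f"cell types outside vocabulary: {sorted(unknown)}")
    return cells


def read_cell_table(path: str | Path, vocabulary: Sequence[str] | None = None) -> pd.DataFrame:
    return validate_cell_table(pd.read_csv(path), vocabulary)


def write_cell_table(cells: pd.DataFrame, path: str | Path) -> None:
    validate_cell_table(cells).to_csv(path, index=False)


def write_expression_mtx(expr: pd.DataFrame, prefix: str | Path) -> None:
    """Write a cells x genes matrix as MatrixMarket with index sidecars.

    Produces ``<prefix>.mtx`` plus ``<prefix>.cells.tsv`` and
    ``<prefix>.genes.tsv`` (one id per line, matrix order).
    """
    from scipy import io as sio, sparse

    prefix = Path(prefix)
    sio.mmwrite(str(prefix.with_suffix(".mtx")), sparse.csr_matrix(expr.to_numpy()))
    prefix.with_suffix(".cells.tsv").write_text("\n".join(map(str, expr.index)) + "\n")
    prefix.with_suffix(".genes.tsv").write_text("\n".join(map(str, expr.columns)) + "\n")


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a cells x genes matrix from CSV (index column = cell ids) or
    from MatrixMarket ``.mtx`` with ``.cells.tsv``/``.genes.tsv`` sidecars."""
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy import io as sio

        X = sio.mmread(str(path)).toarray()
        cells = path.with_suffix(".cells.tsv").read_text().splitlines()
        genes = path.with_suffix(".genes.tsv").read_text().splitlines()
        return pd.DataFrame(X, index=cells, columns=genes)
    return pd.read_csv(path, index_col=0)


def write_region_mask(mask: RegionMask, path: str | Path) -> None:
    """Write a RegionMask as a TIFF label image (pitch in the description tag)."""
    import tifffile

    tifffile.imwrite(
        path, mask.labels.astype(np.uint8), description=json.dumps({"pitch_um": mask.pitch_um})
    )


def read_region_mask(path: str | Path, pitch_um: float | None = None) -> RegionMask:
    import tifffile

    with tifffile.TiffFile(str(path)) as tif:
        arr = tif.asarray()
        if pitch_um is None:
            desc = tif.pages[0].tags.get("ImageDescription")
            if desc is None:
                raise ValidationError("pitch_um not stored in TIFF; pass it explicitly")
            pitch_um = float(json.loads(desc.value)["pitch_um"])
    return RegionMask(labels=arr, pitch_um=pitch_um)
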