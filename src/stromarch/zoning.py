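"""Tumor-margin compartmentalization and layer-enrichment statistics.

The tumor-normal boundary is the set of tumor bins 4-adjacent to
non-tumor (liver or stroma) bins.  An exact Euclidean distance field to
that set, signed positive into the tumor, drives three derived
annotations:

* signed layer index: layers of one bin width (25 um for bin50) counted
  outward from the boundary, positive on the tumor side;
* zones: tumor core / tumor edge (within 500 um inside), liver edge
  (within 500 um outside, or the full fibrotic-ring width for FR+
  tumors) and distal;
* area-normalized layer enrichment: per cell type t and layer window i,
  normalized(i) = (c_t(i) / s(i)) / sum_k c_t(k) / s(k), where s(i) is
  the layer-window area measured in bins of the distance field.  Rows
  sum to 1 per type, making density profiles comparable across types
  and samples regardless of how much area each layer covers.

Tile-level immune and stroma scores from segmented area inputs:
rho1 = (IS1 + IS2) / (S1 + S2) and F1 = S1 / (S1 + S2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .io_core import RegionMask, ValidationError

__all__ = [
    "Boundary",
    "ScoreInputs",
    "detect_boundary",
    "assign_layers",
    "assign_zones",
    "layer_enrichment",
    "immune_stroma_scores",
]

ZONE_LABELS = ("tumor_core", "tumor_edge", "liver_edge", "distal")


class BoundaryError(ValueError):
    """Raised when a mask admits no tumor-normal boundary."""


@dataclass
class Boundary:
    """Boundary bin set and the signed Euclidean distance field (um).

    ``signed_distance_um[y, x]`` is the exact Euclidean distance from the
    bin center to the nearest boundary bin center, positive in tumor
    bins, negative in liver/stroma bins, NaN in background.
    """

    is_boundary: np.ndarray
    signed_distance_um: np.ndarray
    pitch_um: float

    def distance_at(self, x_um, y_um):
        """Signed distance (um) of physical points; NaN outside the field."""
        bx = np.floor(np.asarray(x_um, dtype=float) / self.pitch_um).astype(np.int64)
        by = np.floor(np.asarray(y_um, dtype=float) / self.pitch_um).astype(np.int64)
        h, w = self.signed_distance_um.shape
        inside = (bx >= 0) & (bx < w) & (by >= 0) & (by < h)
        out = np.full(np.shape(bx), np.nan, dtype=float)
        out[inside] = self.signed_distance_um[by[inside], bx[inside]]
        return out


def detect_boundary(mask: RegionMask) -> Boundary:
    """Locate the tumor-normal boundary and its signed distance field.

    Boundary bins are tumor bins with at least one 4-adjacent liver or
    stroma bin.  Distances are exact (Euclidean distance transform to
    the boundary set, scaled by the bin pitch).
    """
    labels = mask.labels
    tumor = labels == RegionMask.TUMOR
    nontumor = (labels == RegionMask.LIVER) | (labels == RegionMask.STROMA)
    if not tumor.any() or not nontumor.any():
        raise BoundaryError("mask must contain both tumor and non-tumor bins")

    adj = np.zeros_like(tumor)
    adj[:-1, :] |= nontumor[1:, :]
    adj[1:, :] |= nontumor[:-1, :]
    adj[:, :-1] |= nontumor[:, 1:]
    adj[:, 1:] |= nontumor[:, :-1]
    boundary = tumor & adj
    if not boundary.any():
        raise BoundaryError("tumor and non-tumor regions are not adjacent")

    dist = ndi.distance_transform_edt(~boundary) * mask.pitch_um
    signed = np.where(tumor, dist, -dist)
    signed[~(tumor | nontumor)] = np.nan
    return Boundary(is_boundary=boundary, signed_distance_um=signed, pitch_um=mask.pitch_um)


def _layer_index(d: np.ndarray, layer_width_um: float) -> np.ndarray:
    """Signed layer index: i = sign(d) * ceil(|d| / width); d = 0 -> +1."""
    i = np.sign(d) * np.ceil(np.abs(d) / layer_width_um)
    i = np.where(d == 0, 1, i)
    return i


def assign_layers(
    cells: pd.DataFrame,
    boundary: Boundary,
    layer_width_um: float = 25.0,
    max_layers: int = 80,
) -> pd.DataFrame:
    """Attach signed distance and layer index to each cell.

    Layer i covers distances ((i-1)*w, i*w] on the tumor side (i > 0) and
    [-|i|*w, -(|i|-1)*w) on the liver side (i < 0); a cell exactly on the
    boundary (d = 0) falls in layer +1 by convention.  Layers beyond
    ``max_layers`` on either side (default: 2 mm at 25 um width) and
    cells outside the distance field are flagged unassigned (NaN layer).
    """
    d = boundary.distance_at(cells["x_um"].to_numpy(), cells["y_um"].to_numpy())
    layer = np.full(len(cells), np.nan)
    ok = np.isfinite(d)
    layer[ok] = _layer_index(d[ok], layer_width_um)
    layer[np.abs(layer) > max_layers] = np.nan
    n_out = int((~ok).sum())
    if n_out:
        warnings.warn(f"{n_out} cell(s) outside the distance field left unassigned")
    out = cells.copy()
    out["d_um"] = d
    out["layer"] = layer
    return out


def assign_zones(
    table: pd.DataFrame,
    group: str,
    margin_um: float = 500.0,
    fr_width_um: float | None = None,
) -> pd.DataFrame:
    """Assign the four margin zones from the signed distance.

    tumor_core: d > margin; tumor_edge: 0 <= d <= margin; liver_edge:
    -w <= d < 0 with w = margin (FR-) or the fibrotic-ring width (FR+);
    distal: d < -w.  d = 0 sits on the tumor side, consistently with
    layer +1.
    """
    if group not in ("FRpos", "FRneg"):
        raise ValidationError("group must be FRpos or FRneg")
    if group == "FRpos":
        if fr_width_um is None:
            raise ValidationError("fr_width_um is required for FRpos samples")
        w = fr_width_um
    else:
        w = margin_um
    d = table["d_um"].to_numpy(dtype=float)
    zone = np.where(
        d > margin_um,
        "tumor_core",
        np.where(d >= 0, "tumor_edge", np.where(d >= -w, "liver_edge", "distal")),
    ).astype(object)
    zone[~np.isfinite(d)] = None
    out = table.copy()
    out["zone"] = zone
    return out


def _window_index(layer: np.ndarray, window: int) -> np.ndarray:
    """Group signed layers into consecutive non-overlapping windows of
    ``window`` layers; window i > 0 covers layers (i-1)*w+1 .. i*w."""
    return np.sign(layer) * np.ceil(np.abs(layer) / window)


def layer_enrichment(
    table: pd.DataFrame,
    boundary: Boundary,
    window: int = 5,
    layer_width_um: float = 25.0,
    max_layers: int = 80,
    denominator: str = "none",
    lineage_col: str = "parent_lineage",
    type_col: str = "cell_type",
) -> pd.DataFrame:
    """Area-normalized per-type enrichment across layer windows.

    For each type t and window i, value(i) = (v_t(i)/s(i)) /
    sum_k v_t(k)/s(k); s(i) is the window area in bins of the distance
    field, and v_t(i) is the raw count (``denominator="none"``), the
    within-window fraction of all cells (``"all_cells"``), or the
    within-window fraction of the type's parent lineage
    (``"parent_lineage"``, e.g. fibroblast subsets over all fibroblasts
    in situ).  Rows sum to 1; a type absent everywhere yields an all-zero
    row with a warning (0/0 defined as 0).

    Returns a wide DataFrame: rows = cell types, columns = signed window
    indices (liver side negative).
    """
    if denominator not in ("none", "all_cells", "parent_lineage"):
        raise ValidationError(f"unknown denominator mode {denominator!r}")
    d_field = boundary.signed_distance_um
    finite = np.isfinite(d_field)
    bin_layers = _layer_index(d_field[finite], layer_width_um)
    bin_windows = _window_index(bin_layers, window)
    win_ids, win_bins = np.unique(bin_windows, return_counts=True)
    keep = np.abs(win_ids) <= np.ceil(max_layers / window)
    area = pd.Series(
        win_bins[keep] * boundary.pitch_um**2, index=win_ids[keep].astype(int)
    )
    if area.empty:
        raise ValidationError("no layers with positive area in range")

    all_types = sorted(table[type_col].astype(str).unique())
    cells = table.dropna(subset=["layer"]).copy()
    cells["window"] = _window_index(cells["layer"].to_numpy(dtype=float), window).astype(int)
    cells = cells[cells["window"].isin(area.index)]
    counts = (
        cells.groupby([type_col, "window"]).size().unstack(fill_value=0)
        .reindex(index=all_types, columns=area.index, fill_value=0)
    )

    if denominator == "all_cells":
        totals = counts.sum(axis=0).to_numpy(dtype=float)
        v = counts.to_numpy(dtype=float) / np.where(totals > 0, totals, 1.0)
    elif denominator == "parent_lineage":
        lin_of_type = cells.groupby(type_col)[lineage_col].first()
        lin_counts = (
            cells.groupby([lineage_col, "window"]).size().unstack(fill_value=0)
            .reindex(columns=area.index, fill_value=0)
        )
        v = np.zeros(counts.shape, dtype=float)
        for r, t in enumerate(counts.index):
            if t not in lin_of_type.index:
                continue  # type has no assigned cells anywhere
            ref = lin_counts.loc[lin_of_type[t]].to_numpy(dtype=float)
            v[r] = counts.loc[t].to_numpy(dtype=float) / np.where(ref > 0, ref, 1.0)
    else:
        v = counts.to_numpy(dtype=float)

    dens = v / area.to_numpy(dtype=float)
    row_tot = dens.sum(axis=1, keepdims=True)
    absent = row_tot[:, 0] == 0
    if absent.any():
        warnings.warn(
            f"type(s) absent from all layers: {list(counts.index[absent])}; rows set to 0"
        )
    norm = np.divide(dens, row_tot, out=np.zeros_like(dens), where=row_tot > 0)
    return pd.DataFrame(norm, index=counts.index, columns=area.index)


@dataclass
class ScoreInputs:
    """Segmented areas feeding the tile-level scores (any common unit).

    S1: stroma area; S2: parenchymal area; IS1/IS2: immune-infiltrated
    portions of each.
    """

    S1: float
    S2: float
    IS1: float
    IS2: float

    def __post_init__(self) -> None:
        if min(self.S1, self.S2, self.IS1, self.IS2) < 0:
            raise ValidationError("areas must be non-negative")
        if self.IS1 > self.S1 or self.IS2 > self.S2:
            raise ValidationError("infiltrated area cannot exceed its compartment")


def immune_stroma_scores(inputs: ScoreInputs) -> tuple[float, float]:
    """Immune score rho1 = (IS1+IS2)/(S1+S2) and stroma score F1 = S1/(S1+S2)."""
    denom = inputs.S1 + inputs.S2
    if denom == 0:
        raise ValidationError("S1 + S2 = 0: scores undefined")
    return (inputs.IS1 + inputs.IS2) / denom, inputs.S1 / denom
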