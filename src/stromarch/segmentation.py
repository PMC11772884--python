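"""Nuclei-seeded iterative cell segmentation of high-resolution spatial data.

The procedure has three stages:

1. an intensity threshold separating nuclear staining from background is
   computed on the (median-filtered) nuclei image
   (:func:`compute_initial_threshold`);
2. nuclei are separated by marker-based watershed; candidate nuclei whose
   interior is not brighter than their immediate surround (the "smudged
   region" guard) are discarded (:func:`watershed_nuclei`);
3. each nucleus expands synchronously over the occupied RNA spot grid,
   claiming 4-adjacent spots in order of decreasing transformed signal
   ln(tanh(count)), until it reaches a class-specific size cap (2500 spots
   for HCC nuclei, 900 for non-HCC) or no adjacent spot remains
   (:func:`expand_cells`).

Expansion semantics (the parts the formula leaves open) are fixed as:
4-connectivity; adjacency evaluated against start-of-round territory;
within a round, spots are processed in decreasing transformed-signal order
(ties by grid position); a contested spot goes to the not-yet-full cell
whose seed centroid is nearest, ties to the lower cell id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.measure import label as cc_label, regionprops
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .io_core import RegionMask, SpotGrid, ValidationError

__all__ = [
    "NucleiImage",
    "NucleiLabelMap",
    "SegmentationParams",
    "SegmentationResult",
    "compute_initial_threshold",
    "watershed_nuclei",
    "transform_counts",
    "expand_cells",
    "benchmark_segmentation",
]


@dataclass
class NucleiImage:
    """Grayscale nuclei-staining image registered to the spot-grid frame.

    ``scale`` is pixels per grid unit and ``offset`` the pixel coordinate
    of grid origin, so ``grid_x = (col - offset[1]) / scale`` and
    ``grid_y = (row - offset[0]) / scale``.
    """

    data: np.ndarray
    pitch_um: float
    scale: float = 1.0
    offset: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 2:
            raise ValidationError("nuclei image must be 2D")
        if not np.isfinite(arr).all():
            raise ValidationError("nuclei image intensities must be finite")
        if (arr < 0).any():
            raise ValidationError("nuclei image intensities must be non-negative")
        object.__setattr__(self, "data", arr)

    def pixel_to_grid(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        gx = (np.asarray(col, dtype=float) - self.offset[1]) / self.scale
        gy = (np.asarray(row, dtype=float) - self.offset[0]) / self.scale
        return gx, gy


@dataclass
class NucleiLabelMap:
    """Watershed output: labeled nuclei plus centroids in grid coordinates."""

    labels: np.ndarray
    centroids: pd.DataFrame  # columns: nucleus_id, x, y (grid coords)

    @property
    def n_nuclei(self) -> int:
        return int(len(self.centroids))


@dataclass
class SegmentationParams:
    """Knobs of the iterative segmentation.

    ``lightness_ratio`` is the minimal interior/surround mean-intensity
    ratio a watershed candidate must exceed (surround = 2-pixel ring);
    ``size_threshold_map`` caps cell size in bin-1 spots per nucleus class.
    """

    lightness_ratio: float = 1.2
    size_threshold_map: Mapping[str, int] = field(
        default_factory=lambda: {"HCC": 2500, "nonHCC": 900}
    )
    class_of_nucleus: Mapping[int, str] | None = None
    default_class: str = "nonHCC"
    smooth_sigma: float = 1.0
    median_size: int = 3
    min_distance: int = 5
    min_size_px: int = 20
    count_transform: str = "log_tanh"  # or "log1p"

    def __post_init__(self) -> None:
        if self.lightness_ratio <= 1:
            raise ValidationError("lightness_ratio must be > 1")
        if any(v < 1 for v in self.size_threshold_map.values()):
            raise ValidationError("size thresholds must be >= 1")


@dataclass
class SegmentationResult:
    """Spot-to-cell assignment with per-cell summaries.

    ``assignments`` has one row per assigned occupied spot (x, y, cell_id,
    count, signal); ``cells`` one row per nucleus (cell_id, seed/centroid
    coordinates, n_spots, nucleus class, size threshold); ``gene_counts``
    is long-format (cell_id, gene, count).
    """

    assignments: pd.DataFrame
    cells: pd.DataFrame
    gene_counts: pd.DataFrame

    def cell_gene_matrix(self) -> pd.DataFrame:
        """Cells x genes dense count matrix (cells as rows)."""
        return (
            self.gene_counts.pivot_table(
                index="cell_id", columns="gene", values="count", aggfunc="sum", fill_value=0
            )
            .sort_index()
        )


def _exact_otsu(values: np.ndarray) -> float:
    """Exact Otsu threshold: between-class-variance maximization over all
    splits between distinct sorted intensities (no histogram binning, so
    the maximizer is found even when the variance curve is nearly flat)."""
    v = np.sort(values.ravel())
    n = v.size
    splits = np.nonzero(np.diff(v) > 0)[0]  # lower class = v[: s + 1]
    cs = np.cumsum(v)
    k = (splits + 1).astype(float)
    w0 = k / n
    mu0 = cs[splits] / k
    mu1 = (cs[-1] - cs[splits]) / (n - k)
    var = w0 * (1.0 - w0) * (mu0 - mu1) ** 2
    j = int(np.argmax(var))
    return float((v[splits[j]] + v[splits[j] + 1]) / 2.0)


def compute_initial_threshold(image: NucleiImage, median_size: int = 3) -> float:
    """Initial watershed threshold: exact Otsu on the median-filtered image.

    A constant image has no foreground/background split; its constant is
    returned (with a warning) so that strict thresholding yields zero
    foreground pixels.
    """
    arr = ndi.median_filter(image.data, size=median_size)
    lo, hi = float(arr.min()), float(arr.max())
    if lo == hi:
        warnings.warn("constant image: returning max intensity (no foreground)")
        return hi
    return _exact_otsu(arr)


def watershed_nuclei(
    image: NucleiImage, threshold: float, params: SegmentationParams | None = None
) -> NucleiLabelMap:
    """Separate nuclei by marker-based watershed with a lightness guard.

    The thresholded, smoothed image is split at the ridges of its
    Euclidean distance transform.  Each candidate nucleus must have mean
    interior intensity exceeding ``lightness_ratio`` times the mean
    intensity of a 2-pixel surrounding ring (computed on the raw image);
    smudged candidates failing the guard are discarded.
    """
    params = params or SegmentationParams()
    raw = image.data
    proc = ndi.median_filter(raw, size=params.median_size)
    if params.smooth_sigma > 0:
        proc = ndi.gaussian_filter(proc, sigma=params.smooth_sigma)
    mask = proc > threshold
    if not mask.any():
        return NucleiLabelMap(
            labels=np.zeros_like(raw, dtype=np.int32),
            centroids=pd.DataFrame(columns=["nucleus_id", "x", "y"]),
        )
    cc = cc_label(mask)
    sizes = np.bincount(cc.ravel())
    mask = sizes[cc] >= params.min_size_px
    mask[cc == 0] = False
    dist = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(
        dist, min_distance=params.min_distance, labels=cc_label(mask), exclude_border=False
    )
    markers = np.zeros_like(raw, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    labels = watershed(-dist, markers, mask=mask)

    # lightness guard: interior vs 2-px surrounding ring, on the raw image
    keep: list[int] = []
    for region in regionprops(labels):
        sl = tuple(
            slice(max(s.start - 3, 0), min(s.stop + 3, n))
            for s, n in zip(region.slice, labels.shape)
        )
        win = labels[sl] == region.label
        ring = ndi.binary_dilation(win, iterations=2) & ~win
        interior_mean = raw[sl][win].mean()
        ring_vals = raw[sl][ring]
        ratio = np.inf if ring_vals.size == 0 or ring_vals.mean() == 0 else (
            interior_mean / ring_vals.mean()
        )
        if ratio > params.lightness_ratio:
            keep.append(region.label)

    out = np.zeros_like(labels, dtype=np.int32)
    rows = []
    for new_id, old in enumerate(sorted(keep), start=1):
        sel = labels == old
        out[sel] = new_id
        rr, cc = np.nonzero(sel)
        gx, gy = image.pixel_to_grid(rr.mean(), cc.mean())
        rows.append({"nucleus_id": new_id, "x": float(gx), "y": float(gy)})
    centroids = pd.DataFrame(rows, columns=["nucleus_id", "x", "y"])
    return NucleiLabelMap(labels=out, centroids=centroids)


def transform_counts(count, mode: str = "log_tanh"):
    """Outlier-damping transform of raw spot counts.

    Default is the literal ln(tanh(count)) with the count-0 convention
    transform(0) = 0 (ln(0) is undefined; an empty spot carries no
    signal).  ``mode="log1p"`` substitutes ln(1 + count).  Both are
    monotone non-decreasing for count >= 1, so expansion priority is
    unaffected by the choice.
    """
    arr = np.asarray(count, dtype=float)
    if (arr < 0).any():
        raise ValidationError("counts must be non-negative")
    if mode == "log1p":
        res = np.log1p(arr)
    elif mode == "log_tanh":
        with np.errstate(divide="ignore"):
            res = np.where(arr == 0, 0.0, np.log(np.tanh(arr)))
    else:
        raise ValidationError(f"unknown transform mode: {mode}")
    if np.isscalar(count) or np.ndim(count) == 0:
        return float(res)
    return res


def _nucleus_classes(
    nuclei: NucleiLabelMap, params: SegmentationParams, mask: RegionMask | None, pitch_um: float
) -> dict[int, str]:
    classes: dict[int, str] = {}
    for _, row in nuclei.centroids.iterrows():
        nid = int(row["nucleus_id"])
        if params.class_of_nucleus is not None and nid in params.class_of_nucleus:
            classes[nid] = params.class_of_nucleus[nid]
        elif mask is not None:
            bx, by = mask.bin_of(row["x"] * pitch_um, row["y"] * pitch_um)
            bx, by = int(bx), int(by)
            h, w = mask.shape
            if 0 <= by < h and 0 <= bx < w and mask.labels[by, bx] == RegionMask.TUMOR:
                classes[nid] = "HCC"
            else:
                classes[nid] = "nonHCC"
        else:
            classes[nid] = params.default_class
    return classes


def expand_cells(
    nuclei: NucleiLabelMap,
    grid: SpotGrid,
    params: SegmentationParams | None = None,
    region_mask: RegionMask | None = None,
) -> SegmentationResult:
    """Grow every nucleus synchronously over the occupied spot grid.

    All cells expand in rounds.  In a round, each cell may claim the
    unclaimed occupied spots 4-adjacent to its start-of-round territory;
    spots are processed in decreasing order of the transformed signal
    (ties by (y, x)); a spot adjacent to several cells goes to the
    nearest-seed not-yet-full cell, ties to the lower cell id.  A cell
    stops at its size threshold or when it claims nothing in a round.
    Each nucleus class looks up its threshold in
    ``params.size_threshold_map`` (HCC 2500 spots, non-HCC 900).
    """
    params = params or SegmentationParams()
    if grid.bin_size != 1:
        raise ValidationError("expand_cells expects a raw (bin_size=1) grid")
    if nuclei.n_nuclei == 0:
        warnings.warn("no nuclei: empty segmentation")
        empty_assign = pd.DataFrame(columns=["x", "y", "cell_id", "count", "signal"])
        return SegmentationResult(
            assignments=empty_assign,
            cells=pd.DataFrame(
                columns=["cell_id", "seed_x", "seed_y", "centroid_x", "centroid_y",
                         "n_spots", "nucleus_class", "size_threshold"]
            ),
            gene_counts=pd.DataFrame(columns=["cell_id", "gene", "count"]),
        )

    spots = grid.records.groupby(["x", "y"], as_index=False)["count"].sum()
    seeds_x = nuclei.centroids["x"].to_numpy(dtype=float)
    seeds_y = nuclei.centroids["y"].to_numpy(dtype=float)
    seed_ix = np.rint(seeds_x).astype(np.int64)
    seed_iy = np.rint(seeds_y).astype(np.int64)

    xs = spots["x"].to_numpy()
    ys = spots["y"].to_numpy()
    x0 = int(min(xs.min(initial=seed_ix.min()), seed_ix.min()))
    y0 = int(min(ys.min(initial=seed_iy.min()), seed_iy.min()))
    x1 = int(max(xs.max(initial=seed_ix.max()), seed_ix.max()))
    y1 = int(max(ys.max(initial=seed_iy.max()), seed_iy.max()))
    w, h = x1 - x0 + 1, y1 - y0 + 1

    count2d = np.zeros((h, w), dtype=np.int64)
    count2d[ys - y0, xs - x0] = spots["count"].to_numpy()
    occupied = count2d > 0

    n_cells = nuclei.n_nuclei
    classes = _nucleus_classes(nuclei, params, region_mask, grid.pitch_um)
    thr = np.zeros(n_cells + 1, dtype=np.int64)
    for i, nid in enumerate(nuclei.centroids["nucleus_id"], start=1):
        cls = classes[int(nid)]
        if cls not in params.size_threshold_map:
            raise ValidationError(f"no size threshold for nucleus class {cls!r}")
        thr[i] = params.size_threshold_map[cls]

    terr = np.zeros((h, w), dtype=np.int64)  # 0 = unassigned
    sizes = np.zeros(n_cells + 1, dtype=np.int64)
    for i in range(1, n_cells + 1):
        py, px = seed_iy[i - 1] - y0, seed_ix[i - 1] - x0
        if terr[py, px] != 0:
            warnings.warn(f"seed collision: nucleus {i} shares a spot with {terr[py, px]}")
            continue
        terr[py, px] = i
        if occupied[py, px]:
            sizes[i] = 1

    shifts = ((-1, 0), (1, 0), (0, -1), (0, 1))
    while True:
        # neighbor cell ids from the 4 shifted territory maps
        neigh = np.zeros((4, h, w), dtype=np.int64)
        for a, (dy, dx) in enumerate(shifts):
            src = terr[
                max(dy, 0): h + min(dy, 0),
                max(dx, 0): w + min(dx, 0),
            ]
            neigh[a,
                  max(-dy, 0): h + min(-dy, 0),
                  max(-dx, 0): w + min(-dx, 0)] = src
        cand = occupied & (terr == 0) & (neigh > 0).any(axis=0)
        if not cand.any():
            break
        cy, cx = np.nonzero(cand)
        counts = count2d[cy, cx]
        order = np.lexsort((cx, cy, -counts))
        n_claims = 0
        for idx in order:
            py, px = cy[idx], cx[idx]
            cells_adj = np.unique(neigh[:, py, px])
            cells_adj = cells_adj[(cells_adj > 0) & (sizes[cells_adj] < thr[cells_adj])]
            if cells_adj.size == 0:
                continue
            gx, gy = px + x0, py + y0
            d2 = (seeds_x[cells_adj - 1] - gx) ** 2 + (seeds_y[cells_adj - 1] - gy) ** 2
            winner = int(cells_adj[np.lexsort((cells_adj, d2))[0]])
            terr[py, px] = winner
            sizes[winner] += 1
            n_claims += 1
        if n_claims == 0:
            break

    assigned = occupied & (terr > 0)
    ay, ax = np.nonzero(assigned)
    assignments = pd.DataFrame(
        {
            "x": ax + x0,
            "y": ay + y0,
            "cell_id": terr[ay, ax],
            "count": count2d[ay, ax],
        }
    )
    assignments["signal"] = transform_counts(
        assignments["count"].to_numpy(), mode=params.count_transform
    )
    assignments = assignments.sort_values(["cell_id", "y", "x"]).reset_index(drop=True)

    cell_rows = []
    for i in range(1, n_cells + 1):
        sub = assignments[assignments["cell_id"] == i]
        n_spots = len(sub)
        assert n_spots <= thr[i], "cell exceeded its size threshold"
        cell_rows.append(
            {
                "cell_id": i,
                "seed_x": seeds_x[i - 1],
                "seed_y": seeds_y[i - 1],
                "centroid_x": float(sub["x"].mean()) if n_spots else seeds_x[i - 1],
                "centroid_y": float(sub["y"].mean()) if n_spots else seeds_y[i - 1],
                "n_spots": n_spots,
                "nucleus_class": classes[int(nuclei.centroids["nucleus_id"].iloc[i - 1])],
                "size_threshold": int(thr[i]),
            }
        )
    cells = pd.DataFrame(cell_rows)

    gene_counts = grid.records.merge(
        assignments[["x", "y", "cell_id"]], on=["x", "y"], how="inner"
    )
    gene_counts = (
        gene_counts.groupby(["cell_id", "gene"], as_index=False)["count"].sum()
    )
    return SegmentationResult(assignments=assignments, cells=cells, gene_counts=gene_counts)


def _assignment_table(obj) -> pd.DataFrame:
    """Normalize predictions/truth to a (unit, label) table."""
    if isinstance(obj, NucleiLabelMap):
        rr, cc = np.nonzero(obj.labels)
        return pd.DataFrame({"unit": [f"{r},{c}" for r, c in zip(rr, cc)],
                             "label": obj.labels[rr, cc]})
    if isinstance(obj, SegmentationResult):
        a = obj.assignments
        return pd.DataFrame(
            {"unit": [f"{x},{y}" for x, y in zip(a["x"], a["y"])], "label": a["cell_id"]}
        )
    if isinstance(obj, np.ndarray):
        rr, cc = np.nonzero(obj)
        return pd.DataFrame({"unit": [f"{r},{c}" for r, c in zip(rr, cc)],
                             "label": obj[rr, cc]})
    if isinstance(obj, pd.DataFrame):  # columns x, y, cell_id
        return pd.DataFrame(
            {"unit": [f"{x},{y}" for x, y in zip(obj["x"], obj["y"])],
             "label": obj["cell_id"]}
        )
    raise ValidationError(f"cannot interpret {type(obj)} as a segmentation")


def benchmark_segmentation(pred, truth, iou_threshold: float = 0.5) -> dict[str, float]:
    """Object-level precision/recall/F1 by greedy IoU matching, plus the
    fraction of truth-assigned units given to the matched predicted object.

    ``pred`` and ``truth`` may each be a :class:`NucleiLabelMap`, a
    :class:`SegmentationResult`, a label array, or an (x, y, cell_id)
    assignment table; both must live on the same frame.
    """
    P = _assignment_table(pred)
    T = _assignment_table(truth)
    n_pred = P["label"].nunique()
    n_truth = T["label"].nunique()
    if n_truth == 0 and n_pred == 0:
        return {"precision": 1.0, "recall": 1.0, "f1": 1.0, "spot_accuracy": 1.0}

    inter = (
        P.merge(T, on="unit", suffixes=("_p", "_t"))
        .groupby(["label_p", "label_t"])
        .size()
        .rename("inter")
        .reset_index()
    )
    sz_p = P.groupby("label")["unit"].size()
    sz_t = T.groupby("label")["unit"].size()
    if len(inter):
        inter["iou"] = inter["inter"] / (
            sz_p.loc[inter["label_p"]].to_numpy()
            + sz_t.loc[inter["label_t"]].to_numpy()
            - inter["inter"]
        )
        inter = inter.sort_values("iou", ascending=False)
    used_p: set = set()
    used_t: set = set()
    matches: dict = {}
    for _, row in inter.iterrows():
        if row["iou"] < iou_threshold:
            break
        if row["label_p"] in used_p or row["label_t"] in used_t:
            continue
        used_p.add(row["label_p"])
        used_t.add(row["label_t"])
        matches[row["label_t"]] = row["label_p"]

    n_match = len(matches)
    precision = n_match / n_pred if n_pred else 0.0
    recall = n_match / n_truth if n_truth else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0

    merged = T.merge(P, on="unit", how="left", suffixes=("_t", "_p"))
    ok = np.array(
        [matches.get(t) == p for t, p in zip(merged["label_t"], merged["label_p"])]
    )
    spot_accuracy = float(ok.mean()) if len(merged) else 1.0
    return {
        "precision": float(precision),
        "recall": float(recall),
        "f1": float(f1),
        "spot_accuracy": spot_accuracy,
    }
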