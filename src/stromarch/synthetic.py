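"""Ground-truthed synthetic tissue generator.

Emulates the two stromal architectures of hepatocellular carcinoma
margins: FR+ tumors carry a fibroblast-dense fibrotic ring (stroma
annulus of configurable width, default 500 um) at the tumor-liver
interface, FR- tumors carry intratumoral stroma and no ring.  The
generator plants everything downstream analyses are meant to recover:

* per-zone per-type cell intensities (inhomogeneous Poisson process,
  realized by uniform thinning over the domain);
* co-localization hubs — clustered niches in which anchor cells of one
  type carry partner cells of a second type at exponential radial
  offsets with a single interpretable distance scale (default 20 um):
  CAF-FAP with PDCD1+ CD8 T cells in the FR- tumor core, CAF-C7 with
  SPP1+ macrophages in the FR+ ring;
* type-specific marker genes plus mitochondrial genes at a fixed rate;
* a nuclei-staining image (Gaussian blobs at cell centers + noise) and a
  bin-1 spot grid whose transcripts are scattered over each cell's
  footprint, with the exact spot-to-cell map retained as ground truth.

All randomness flows from one seed through spawned child generators.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
import yaml

from .io_core import RegionMask, SpotGrid, ValidationError
from .segmentation import NucleiImage

__all__ = [
    "PairConfig",
    "TissueConfig",
    "SyntheticTissue",
    "generate_tissue",
    "truth_report",
    "frpos_config",
    "frneg_config",
    "segmentation_config",
    "generate_expression_cohort",
    "DEFAULT_LINEAGE",
]

#: Parent lineage of each cell type in the default vocabulary.
DEFAULT_LINEAGE = {
    "HCC": "HCC",
    "Hepatocyte": "Hepatocyte",
    "Fibroblast": "Fibroblast",
    "CAF-FAP": "Fibroblast",
    "CAF-C7": "Fibroblast",
    "Tcell": "Tcell",
    "CD8_PDCD1": "Tcell",
    "Macrophage": "Macrophage",
    "Macrophage_SPP1": "Macrophage",
}

ZONES = ("tumor_core", "tumor_edge", "liver_edge", "distal")


@dataclass
class PairConfig:
    """A planted co-localization hub between two cell types.

    ``n_niches`` niche centers are placed uniformly in ``zone``; each
    niche receives ~Poisson(``cells_per_niche``) anchor cells of
    ``type_a`` scattered with Gaussian sd ``niche_sigma_um``; each anchor
    independently carries a ``type_b`` partner with probability
    ``pair_fraction`` at an exponential radial offset of scale
    ``pair_scale_um`` (so the mean planted offset equals the scale).

    The defaults make the pair the locally dominant population — the
    defining feature of a hub.  Background cells sitting within one
    niche radius + one neighborhood radius (~70 um) of a niche center
    share the hub's neighborhood profile, so the design rule is that
    anchors per niche (~24) are at least twice the expected background
    cells of the densest type in that halo disk (~12 at 800 cells/mm2),
    giving aggregates of ~45 pair cells — the size and density of small
    lymphoid aggregates.
    """

    type_a: str
    type_b: str
    zone: str
    n_niches: int = 8
    cells_per_niche: float = 24.0
    niche_sigma_um: float = 20.0
    pair_scale_um: float = 20.0
    pair_fraction: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 <= self.pair_fraction <= 1.0:
            raise ValidationError("pair fraction must be in [0, 1]")
        if self.zone not in ZONES:
            raise ValidationError(f"unknown zone {self.zone!r}")


def _default_markers() -> dict[str, dict[str, float]]:
    # 3 markers per type, mean counts per transcript-equivalent weight
    panel = {}
    for t in DEFAULT_LINEAGE:
        tag = t.replace("-", "_")
        panel[t] = {f"{tag}_M{j}": 10.0 for j in range(1, 4)}
    return panel


@dataclass
class TissueConfig:
    """Full parameterization of one synthetic tissue.

    Units: micrometres and cells per mm^2.  ``intensity[zone][type]`` is
    the background Poisson intensity of each cell type in each zone;
    co-localization hubs add clustered cells on top of it.
    """

    archetype: str = "FRpos"
    domain_um: tuple[float, float] = (2400.0, 2400.0)
    tumor_center_um: tuple[float, float] | None = None
    tumor_radius_um: float = 900.0
    fr_width_um: float = 500.0
    margin_um: float = 500.0
    intensity: dict = field(default_factory=dict)
    colocalization: list = field(default_factory=list)
    markers: dict = field(default_factory=_default_markers)
    background_gene_means: dict = field(
        default_factory=lambda: {f"BG{j}": 2.0 for j in range(1, 11)}
    )
    mito_genes: tuple[str, ...] = tuple(f"MT-{g}" for g in ("ND1", "CO1", "CYB"))
    mito_rate: float = 0.05
    transcripts_per_cell: float = 300.0
    cell_radius_um: float = 4.0
    min_separation_um: float = 0.0
    spot_pitch_um: float = 0.5
    mask_pitch_um: float = 25.0
    blob_sigma_um: float = 2.0
    blob_intensity: float = 200.0
    noise_sigma: float = 5.0
    nucleus_radius_um: float = 2.5
    render_image: bool = False
    render_spots: bool = False
    sample_id: str = "S1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.archetype not in ("FRpos", "FRneg"):
            raise ValidationError("archetype must be FRpos or FRneg")
        if self.archetype == "FRpos" and self.fr_width_um <= 0:
            raise ValidationError("fr_width_um must be > 0 for FRpos")
        for zone, per_type in self.intensity.items():
            if zone not in ZONES:
                raise ValidationError(f"unknown zone {zone!r} in intensity map")
            if any(v < 0 for v in per_type.values()):
                raise ValidationError("intensities must be >= 0")
        self.colocalization = [
            p if isinstance(p, PairConfig) else PairConfig(**p) for p in self.colocalization
        ]

    @property
    def liver_width_um(self) -> float:
        """Width of the liver-edge zone (full FR width for FR+ tumors)."""
        return self.fr_width_um if self.archetype == "FRpos" else self.margin_um

    @property
    def center(self) -> tuple[float, float]:
        if self.tumor_center_um is not None:
            return self.tumor_center_um
        return (self.domain_um[0] / 2.0, self.domain_um[1] / 2.0)

    def signed_distance(self, x_um, y_um):
        """True signed distance to the tumor border (+ inside the tumor)."""
        cx, cy = self.center
        r = np.hypot(np.asarray(x_um, dtype=float) - cx, np.asarray(y_um, dtype=float) - cy)
        return self.tumor_radius_um - r

    def zone_of(self, x_um, y_um):
        d = self.signed_distance(x_um, y_um)
        w = self.liver_width_um
        out = np.where(
            d > self.margin_um,
            "tumor_core",
            np.where(d >= 0, "tumor_edge", np.where(d >= -w, "liver_edge", "distal")),
        )
        return out if np.ndim(x_um) else str(out)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TissueConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("domain_um", "tumor_center_um", "mito_genes"):
            if d.get(key) is not None and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


def frpos_config(seed: int = 0, **overrides) -> TissueConfig:
    """FR+ archetype: fibroblast-dense fibrotic ring at the interface.

    Background intensities (cells/mm^2) follow a tumor whose stroma is
    pushed to the margin: fibroblast-rich ring, fibroblast-poor core.
    A CAF-C7 / SPP1+ macrophage hub is planted in the ring; CAF-FAP and
    PDCD1+ CD8 T cells are present but scattered in the core, so core
    pair distances reflect chance proximity only.
    """
    intensity = {
        "tumor_core": {
            "HCC": 800, "Tcell": 100, "Macrophage": 80, "Fibroblast": 40,
            "CAF-FAP": 80, "CD8_PDCD1": 80,
        },
        "tumor_edge": {"HCC": 700, "Tcell": 120, "Macrophage": 100, "Fibroblast": 80},
        "liver_edge": {"Fibroblast": 700, "Macrophage": 120, "Tcell": 80, "Hepatocyte": 30},
        "distal": {"Hepatocyte": 800, "Fibroblast": 60, "Tcell": 60, "Macrophage": 60},
    }
    coloc = [PairConfig("CAF-C7", "Macrophage_SPP1", zone="liver_edge")]
    cfg = dict(
        archetype="FRpos", intensity=intensity, colocalization=coloc,
        sample_id="FRpos_1", seed=seed,
    )
    cfg.update(overrides)
    return TissueConfig(**cfg)


def frneg_config(seed: int = 0, **overrides) -> TissueConfig:
    """FR- archetype: no ring; stroma and a CAF-FAP / PDCD1+ CD8 hub
    inside the tumor."""
    intensity = {
        "tumor_core": {"HCC": 800, "Tcell": 100, "Macrophage": 80, "Fibroblast": 150},
        "tumor_edge": {"HCC": 700, "Tcell": 120, "Macrophage": 100, "Fibroblast": 150},
        "liver_edge": {"Hepatocyte": 700, "Fibroblast": 60, "Tcell": 80, "Macrophage": 80},
        "distal": {"Hepatocyte": 800, "Fibroblast": 40, "Tcell": 60, "Macrophage": 60},
    }
    coloc = [PairConfig("CAF-FAP", "CD8_PDCD1", zone="tumor_core")]
    cfg = dict(
        archetype="FRneg", intensity=intensity, colocalization=coloc,
        sample_id="FRneg_1", seed=seed,
    )
    cfg.update(overrides)
    return TissueConfig(**cfg)


def segmentation_config(seed: int = 0, **overrides) -> TissueConfig:
    """Small dense tissue with rendered nuclei image and spot grid.

    Cells are hard-core separated (>= 14 um) so footprints stay disjoint
    and nuclei blobs are >= 3 sigma apart, the regime the iterative
    segmentation targets; ~250 cells in a 400x400 um field (the
    candidate intensity is thinned by the hard-core constraint).
    """
    intensity = {
        "tumor_core": {"HCC": 2800},
        "tumor_edge": {"HCC": 2800},
        "liver_edge": {"Hepatocyte": 2800},
        "distal": {"Hepatocyte": 2800},
    }
    cfg = dict(
        archetype="FRneg",
        domain_um=(400.0, 400.0),
        tumor_center_um=(0.0, 200.0),
        tumor_radius_um=210.0,
        margin_um=100.0,
        intensity=intensity,
        colocalization=[],
        min_separation_um=14.0,
        render_image=True,
        render_spots=True,
        mask_pitch_um=25.0,
        sample_id="SEG_1",
        seed=seed,
    )
    cfg.update(overrides)
    return TissueConfig(**cfg)


@dataclass
class SyntheticTissue:
    """One generated tissue with full ground truth."""

    cells: pd.DataFrame
    mask: RegionMask
    config: TissueConfig
    image: NucleiImage | None = None
    grid: SpotGrid | None = None
    spot_truth: pd.DataFrame | None = None  # x, y, cell_id
    truth_nuclei: np.ndarray | None = None
    pair_offsets: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)


def _total_intensity(cfg: TissueConfig) -> float:
    tot = sum(v for per_type in cfg.intensity.values() for v in per_type.values())
    tot += sum(p.n_niches * p.cells_per_niche for p in cfg.colocalization)
    return tot


def _sample_background(cfg: TissueConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Thinned uniform Poisson sampling of the per-zone background types."""
    W, H = cfg.domain_um
    area_mm2 = (W / 1000.0) * (H / 1000.0)
    types = sorted({t for per_type in cfg.intensity.values() for t in per_type})
    rows = []
    for t in types:
        lam = area_mm2 * max(cfg.intensity[z].get(t, 0.0) for z in cfg.intensity)
        # rejection: sample at the max-over-zones rate, accept at zone rate
        n = rng.poisson(lam)
        if n == 0 or lam == 0:
            continue
        x = rng.uniform(0, W, n)
        y = rng.uniform(0, H, n)
        zone = cfg.zone_of(x, y)
        rate = np.array([cfg.intensity.get(z, {}).get(t, 0.0) for z in zone])
        keep = rng.uniform(0, lam / area_mm2, n) < rate
        for xi, yi, zi in zip(x[keep], y[keep], zone[keep]):
            rows.append((t, xi, yi, zi))
    return pd.DataFrame(rows, columns=["cell_type", "x_um", "y_um", "true_zone"])


def _sample_niches(cfg: TissueConfig, rng: np.random.Generator):
    """Clustered co-localization hubs; returns (cells, planted offsets)."""
    W, H = cfg.domain_um
    rows, offsets = [], []
    for pi, pair in enumerate(cfg.colocalization):
        centers = []
        while len(centers) < pair.n_niches:
            x, y = rng.uniform(0, W), rng.uniform(0, H)
            if cfg.zone_of(x, y) == pair.zone:
                centers.append((x, y))
        for cx, cy in centers:
            n_a = rng.poisson(pair.cells_per_niche)
            for _ in range(n_a):
                ax = np.clip(cx + rng.normal(0, pair.niche_sigma_um), 0, W)
                ay = np.clip(cy + rng.normal(0, pair.niche_sigma_um), 0, H)
                rows.append((pair.type_a, ax, ay, str(cfg.zone_of(ax, ay))))
                if rng.uniform() < pair.pair_fraction:
                    r = rng.exponential(pair.pair_scale_um)
                    th = rng.uniform(0, 2 * np.pi)
                    bx = np.clip(ax + r * np.cos(th), 0, W)
                    by = np.clip(ay + r * np.sin(th), 0, H)
                    rows.append((pair.type_b, bx, by, str(cfg.zone_of(bx, by))))
                    offsets.append((pi, pair.type_a, pair.type_b, float(np.hypot(bx - ax, by - ay))))
    cells = pd.DataFrame(rows, columns=["cell_type", "x_um", "y_um", "true_zone"])
    off = pd.DataFrame(offsets, columns=["pair_index", "type_a", "type_b", "offset_um"])
    return cells, off


def _enforce_separation(cells: pd.DataFrame, min_sep: float, rng: np.random.Generator) -> pd.DataFrame:
    """Hard-core thinning: keep a random maximal subset with pairwise
    distance >= min_sep (dart throwing over the sampled points)."""
    from scipy.spatial import cKDTree

    order = rng.permutation(len(cells))
    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    kept: list[int] = []
    kept_xy: list[np.ndarray] = []
    tree = None
    for i in order:
        if kept:
            tree = cKDTree(np.array(kept_xy))
            if tree.query_ball_point(xy[i], r=min_sep):
                continue
        kept.append(i)
        kept_xy.append(xy[i])
    return cells.iloc[sorted(kept)].reset_index(drop=True)


def _build_mask(cfg: TissueConfig) -> RegionMask:
    W, H = cfg.domain_um
    p = cfg.mask_pitch_um
    nx, ny = int(np.ceil(W / p)), int(np.ceil(H / p))
    xs = (np.arange(nx) + 0.5) * p
    ys = (np.arange(ny) + 0.5) * p
    gx, gy = np.meshgrid(xs, ys)
    d = cfg.signed_distance(gx, gy)
    labels = np.full((ny, nx), RegionMask.LIVER, dtype=np.int16)
    labels[d >= 0] = RegionMask.TUMOR
    if cfg.archetype == "FRpos":
        labels[(d < 0) & (d >= -cfg.fr_width_um)] = RegionMask.STROMA
    return RegionMask(labels=labels, pitch_um=p)


def _render(cfg: TissueConfig, cells: pd.DataFrame, rng: np.random.Generator):
    """Nuclei image, truth nuclei label map, spot grid and spot truth."""
    W, H = cfg.domain_um
    p = cfg.spot_pitch_um
    nx, ny = int(np.ceil(W / p)), int(np.ceil(H / p))
    cx = cells["x_um"].to_numpy() / p
    cy = cells["y_um"].to_numpy() / p

    image = truth_nuclei = grid = spot_truth = None
    if cfg.render_image:
        sigma_px = cfg.blob_sigma_um / p
        img = np.zeros((ny, nx), dtype=float)
        ix = np.clip(np.rint(cx).astype(int), 0, nx - 1)
        iy = np.clip(np.rint(cy).astype(int), 0, ny - 1)
        np.add.at(img, (iy, ix), cfg.blob_intensity * 2 * np.pi * sigma_px**2)
        img = ndi.gaussian_filter(img, sigma=sigma_px)
        if cfg.noise_sigma > 0:
            img = img + rng.normal(0, cfg.noise_sigma, size=img.shape)
        img = np.clip(img, 0, None)
        image = NucleiImage(data=img, pitch_um=p)

        truth_nuclei = np.zeros((ny, nx), dtype=np.int32)
        r_px = cfg.nucleus_radius_um / p
        rad = int(np.ceil(r_px))
        yy, xx = np.mgrid[-rad: rad + 1, -rad: rad + 1]
        disk = (yy**2 + xx**2) <= r_px**2
        for k, (jx, jy) in enumerate(zip(ix, iy), start=1):
            sly = slice(max(jy - rad, 0), min(jy + rad + 1, ny))
            slx = slice(max(jx - rad, 0), min(jx + rad + 1, nx))
            dsub = disk[
                sly.start - (jy - rad): disk.shape[0] - ((jy + rad + 1) - sly.stop),
                slx.start - (jx - rad): disk.shape[1] - ((jx + rad + 1) - slx.stop),
            ]
            sub = truth_nuclei[sly, slx]
            sub[dsub & (sub == 0)] = k

    if cfg.render_spots:
        gene_rows = []
        map_rows = []
        for k, row in enumerate(cells.itertuples(), start=1):
            n_tr = rng.poisson(cfg.transcripts_per_cell)
            if n_tr == 0:
                continue
            genes, probs = _gene_probs(cfg, row.cell_type)
            gidx = rng.choice(len(genes), size=n_tr, p=probs)
            rr = cfg.cell_radius_um * np.sqrt(rng.uniform(0, 1, n_tr))
            th = rng.uniform(0, 2 * np.pi, n_tr)
            sx = np.clip(np.floor((row.x_um + rr * np.cos(th)) / p).astype(int), 0, nx - 1)
            sy = np.clip(np.floor((row.y_um + rr * np.sin(th)) / p).astype(int), 0, ny - 1)
            for gi, xi, yi in zip(gidx, sx, sy):
                gene_rows.append((genes[gi], xi, yi))
            map_rows.append(pd.DataFrame({"x": sx, "y": sy, "cell_id": k}))
        recs = pd.DataFrame(gene_rows, columns=["gene", "x", "y"])
        recs["count"] = 1
        grid = SpotGrid(records=recs, pitch_um=p, bin_size=1)
        if map_rows:
            m = pd.concat(map_rows, ignore_index=True)
            # a spot contested between overlapping footprints goes to the
            # cell contributing the most transcripts there
            m = (
                m.groupby(["x", "y", "cell_id"]).size().rename("n").reset_index()
                .sort_values(["x", "y", "n", "cell_id"], ascending=[True, True, False, True])
                .drop_duplicates(["x", "y"])
                .loc[:, ["x", "y", "cell_id"]]
                .reset_index(drop=True)
            )
            spot_truth = m
        else:
            spot_truth = pd.DataFrame(columns=["x", "y", "cell_id"])
    return image, truth_nuclei, grid, spot_truth


def _gene_probs(cfg: TissueConfig, cell_type: str):
    means = dict(cfg.background_gene_means)
    means.update(cfg.markers.get(cell_type, {}))
    genes = sorted(means)
    w = np.array([means[g] for g in genes], dtype=float)
    w = w / w.sum() * (1.0 - cfg.mito_rate)
    if cfg.mito_genes:
        genes = genes + list(cfg.mito_genes)
        w = np.concatenate([w, np.full(len(cfg.mito_genes), cfg.mito_rate / len(cfg.mito_genes))])
    return genes, w / w.sum()


def generate_tissue(config: TissueConfig) -> SyntheticTissue:
    """Generate one synthetic tissue; deterministic given the config seed."""
    if _total_intensity(config) <= 0:
        raise ValidationError("zero total intensity: nothing to generate")
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(4)
    rng_bg, rng_pairs, rng_sep, rng_render = (np.random.default_rng(c) for c in children)

    bg = _sample_background(config, rng_bg)
    hubs, offsets = _sample_niches(config, rng_pairs)
    parts = [df for df in (bg, hubs) if len(df)]
    if not parts:
        raise ValidationError("configuration produced no cells")
    cells = pd.concat(parts, ignore_index=True)
    if config.min_separation_um > 0:
        cells = _enforce_separation(cells, config.min_separation_um, rng_sep)

    cells = cells.sort_values(["y_um", "x_um"], kind="mergesort").reset_index(drop=True)
    cells.insert(0, "cell_id", [f"{config.sample_id}_c{i}" for i in range(len(cells))])
    cells["sample_id"] = config.sample_id
    cells["group"] = config.archetype
    cells["parent_lineage"] = cells["cell_type"].map(lambda t: DEFAULT_LINEAGE.get(t, t))
    cells["true_d_um"] = config.signed_distance(
        cells["x_um"].to_numpy(), cells["y_um"].to_numpy()
    )

    mask = _build_mask(config)
    image, truth_nuclei, grid, spot_truth = _render(config, cells, rng_render)
    provenance = {
        "seed": config.seed,
        "child_seeds": [list(map(int, c.entropy if isinstance(c.entropy, tuple) else [c.entropy]))
                        + list(c.spawn_key) for c in children],
        "archetype": config.archetype,
        "n_cells": int(len(cells)),
    }
    return SyntheticTissue(
        cells=cells, mask=mask, config=config, image=image, grid=grid,
        spot_truth=spot_truth, truth_nuclei=truth_nuclei, pair_offsets=offsets,
        provenance=provenance,
    )


def truth_report(tissue: SyntheticTissue) -> dict:
    """Exact ground truth: per-zone per-type counts and planted pair offsets."""
    counts = (
        tissue.cells.groupby(["true_zone", "cell_type"]).size().rename("n").reset_index()
    )
    offsets = tissue.pair_offsets if tissue.pair_offsets is not None else pd.DataFrame(
        columns=["pair_index", "type_a", "type_b", "offset_um"]
    )
    assert int(counts["n"].sum()) == len(tissue.cells)
    return {
        "zone_type_counts": counts,
        "pair_offsets": offsets,
        "n_cells": int(len(tissue.cells)),
        "archetype": tissue.config.archetype,
    }


def write_truth_report(report: dict, path: str | Path) -> None:
    out = {
        "n_cells": report["n_cells"],
        "archetype": report["archetype"],
        "zone_type_counts": report["zone_type_counts"].to_dict(orient="records"),
        "pair_offsets": report["pair_offsets"].to_dict(orient="records"),
    }
    Path(path).write_text(json.dumps(out, indent=2))


def generate_expression_cohort(
    n_samples: int = 4,
    n_cells: int = 200,
    n_genes: int = 1000,
    n_programs: int = 3,
    program_size: int = 100,
    active_frac: float = 0.75,
    base_mean: float = 0.3,
    program_mean: float = 3.0,
    seed: int = 0,
):
    """Cells x genes count matrices sharing planted expression programs.

    Each sample draws Poisson background at ``base_mean`` per gene; a
    fraction ``active_frac`` of cells activates one of ``n_programs``
    shared programs (disjoint blocks of ``program_size`` genes boosted by
    ``program_mean``).  Returns ``(samples, planted_sets)`` where samples
    is a list of DataFrames (index = cell ids, columns = genes).
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{j:04d}" for j in range(n_genes)]
    planted = [
        set(genes[k * program_size: (k + 1) * program_size]) for k in range(n_programs)
    ]
    samples = []
    for s in range(n_samples):
        lam = np.full((n_cells, n_genes), base_mean)
        states = np.where(
            rng.uniform(size=n_cells) < active_frac, rng.integers(0, n_programs, n_cells), -1
        )
        for k in range(n_programs):
            lam[states == k, k * program_size: (k + 1) * program_size] += program_mean
        X = rng.poisson(lam)
        samples.append(
            pd.DataFrame(X, index=[f"s{s}_c{i}" for i in range(n_cells)], columns=genes)
        )
    return samples, planted
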