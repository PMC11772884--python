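import numpy as np
import pandas as pd
import pytest

from stromarch.io_core import RegionMask, ValidationError
from stromarch.zoning import (
    Boundary,
    BoundaryError,
    ScoreInputs,
    assign_layers,
    assign_zones,
    detect_boundary,
    immune_stroma_scores,
    layer_enrichment,
)

from _reference import brute_force_signed_distance


def half_plane_mask(split_col=4, width=8, height=5, pitch=25.0):
    lab = np.full((height, width), RegionMask.LIVER, np.int16)
    lab[:, :split_col] = RegionMask.TUMOR
    return RegionMask(labels=lab, pitch_um=pitch)


class TestDetectBoundary:
    def test_half_plane_boundary_and_linear_distances(self):
        mask = half_plane_mask()
        b = detect_boundary(mask)
        by, bx = np.nonzero(b.is_boundary)
        assert set(bx) == {3}  # tumor column adjacent to liver
        # distances grow linearly with column offset from the boundary column
        assert np.allclose(b.signed_distance_um[0, :4], [75, 50, 25, 0])
        assert np.allclose(b.signed_distance_um[0, 4:], [-25, -50, -75, -100])

    def test_single_label_mask_is_an_error(self):
        lab = np.full((4, 4), RegionMask.TUMOR, np.int16)
        with pytest.raises(BoundaryError):
            detect_boundary(RegionMask(labels=lab, pitch_um=25.0))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_blob_masks(self, seed):
        rng = np.random.default_rng(seed)
        lab = np.full((20, 20), RegionMask.LIVER, np.int16)
        import scipy.ndimage as ndi

        blob = np.zeros((20, 20), bool)
        blob[tuple(rng.integers(0, 20, size=(2, 4)))] = True
        blob = ndi.binary_dilation(blob, iterations=int(rng.integers(2, 5)))
        lab[blob] = RegionMask.TUMOR
        lab[rng.uniform(size=(20, 20)) < 0.1] = RegionMask.STROMA
        if not (lab == RegionMask.TUMOR).any():
            pytest.skip("degenerate draw")
        mask = RegionMask(labels=lab, pitch_um=25.0)
        got = detect_boundary(mask).signed_distance_um
        want = brute_force_signed_distance(lab, 25.0)
        assert np.allclose(got, want, equal_nan=True)


def boundary_from_values(values_um, pitch=25.0):
    """1-row Boundary whose bins carry the given signed distances."""
    arr = np.asarray(values_um, dtype=float)[None, :]
    return Boundary(is_boundary=arr == 0, signed_distance_um=arr, pitch_um=pitch)


def cells_at_bins(n, pitch=25.0, **cols):
    df = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "x_um": (np.arange(n) + 0.5) * pitch,
            "y_um": 0.5 * pitch,
        }
    )
    for k, v in cols.items():
        df[k] = v
    return df


class TestAssignLayers:
    def test_ceiling_arithmetic_and_boundary_convention(self):
        b = boundary_from_values([10.0, -30.0, 0.0, 60.0, -10.0])
        cells = cells_at_bins(5)
        out = assign_layers(cells, b, layer_width_um=25.0)
        assert out["layer"].tolist() == [1.0, -2.0, 1.0, 3.0, -1.0]

    def test_cell_outside_field_flagged(self):
        b = boundary_from_values([10.0])
        cells = cells_at_bins(1)
        cells.loc[0, "x_um"] = 1e6
        with pytest.warns(UserWarning, match="unassigned"):
            out = assign_layers(cells, b)
        assert np.isnan(out["layer"]).all()

    def test_max_layers_ceiling(self):
        b = boundary_from_values([10.0, 990.0])
        out = assign_layers(cells_at_bins(2), b, max_layers=3)
        assert out["layer"].tolist()[0] == 1.0
        assert np.isnan(out["layer"].iloc[1])


class TestAssignZones:
    def table(self, d):
        return pd.DataFrame({"d_um": d})

    def test_beyond_margin_is_tumor_core(self):
        out = assign_zones(self.table([600.0]), "FRneg")
        assert out["zone"].iloc[0] == "tumor_core"

    def test_frpos_liver_edge_spans_full_ring_width(self):
        out = assign_zones(self.table([-700.0]), "FRpos", fr_width_um=800.0)
        assert out["zone"].iloc[0] == "liver_edge"

    def test_strict_cut_at_distal(self):
        out = assign_zones(self.table([-501.0, -500.0]), "FRneg")
        assert out["zone"].tolist() == ["distal", "liver_edge"]

    def test_boundary_cell_is_tumor_side(self):
        out = assign_zones(self.table([0.0]), "FRneg")
        assert out["zone"].iloc[0] == "tumor_edge"

    def test_frpos_requires_ring_width(self):
        with pytest.raises(ValidationError):
            assign_zones(self.table([0.0]), "FRpos")


class TestLayerEnrichment:
    def enrich(self, d_values, cell_layers_d, window=1, **kw):
        b = boundary_from_values(d_values)
        cells = cells_at_bins(len(cell_layers_d), cell_type="T")
        # place each cell in the bin holding the wanted distance
        pos = {v: i for i, v in enumerate(d_values)}
        cells["x_um"] = [(pos[v] + 0.5) * 25.0 for v in cell_layers_d]
        table = assign_layers(cells, b)
        return layer_enrichment(table, b, window=window, **kw)

    def test_two_equal_area_windows_split_evenly(self):
        # layers +1 and +2, one bin each, 10 cells each
        vals = [10.0, 30.0]
        out = self.enrich(vals, [10.0] * 10 + [30.0] * 10)
        assert np.allclose(out.loc["T"].to_numpy(), [0.5, 0.5])

    def test_equal_densities_under_area_normalization(self):
        # areas (1, 2, 1) bins with counts (1, 2, 1) -> equal 1/3 shares
        vals = [10.0, 30.0, 40.0, 60.0]  # layers 1, 2, 2, 3
        out = self.enrich(vals, [10.0, 30.0, 40.0, 60.0])
        assert np.allclose(out.loc["T"].to_numpy(), [1 / 3, 1 / 3, 1 / 3])

    def test_single_window_normalizes_to_one(self):
        out = self.enrich([10.0], [10.0, 10.0, 10.0], window=5)
        assert np.allclose(out.loc["T"].to_numpy(), [1.0])

    def test_absent_type_yields_zero_row_with_warning(self):
        b = boundary_from_values([10.0, 30.0])
        cells = cells_at_bins(2, cell_type=["A", "A"])
        table = assign_layers(cells, b)
        table = pd.concat(
            [table, pd.DataFrame([{"cell_id": "x", "x_um": -99.0, "y_um": 12.5,
                                   "cell_type": "B", "d_um": np.nan, "layer": np.nan}])],
            ignore_index=True,
        )
        with pytest.warns(UserWarning, match="absent"):
            out = layer_enrichment(table, b, window=1)
        assert np.allclose(out.loc["B"].to_numpy(), 0.0)

    def test_rows_sum_to_one_on_random_tables(self):
        rng = np.random.default_rng(3)
        vals = list(rng.permutation(np.arange(-20, 21) * 12.5 + 6.25))
        b = boundary_from_values(vals)
        n = 400
        cells = cells_at_bins(n, cell_type=rng.choice(["A", "B", "C"], n))
        cells["x_um"] = (rng.integers(0, len(vals), n) + 0.5) * 25.0
        table = assign_layers(cells, b)
        for denom in ("none", "all_cells"):
            out = layer_enrichment(table, b, window=5, denominator=denom)
            assert np.allclose(out.sum(axis=1).to_numpy(), 1.0, atol=1e-12)

    def test_lineage_denominator_uses_parent_population(self):
        # 2 windows, equal areas; subset counts (1, 1) but lineage totals (1, 2):
        # within-lineage fractions (1, 0.5) -> enrichment (2/3, 1/3)
        vals = [10.0, 30.0]
        b = boundary_from_values(vals)
        cells = cells_at_bins(
            3,
            cell_type=["CAF", "CAF", "Fibro"],
            parent_lineage=["F", "F", "F"],
        )
        cells["x_um"] = [12.5, 37.5, 37.5]
        table = assign_layers(cells, b)
        out = layer_enrichment(table, b, window=1, denominator="parent_lineage")
        assert np.allclose(out.loc["CAF"].to_numpy(), [2 / 3, 1 / 3])


class TestImmuneStromaScores:
    def test_no_infiltration_gives_zero_immune_score(self):
        rho, f1 = immune_stroma_scores(ScoreInputs(S1=3, S2=5, IS1=0, IS2=0))
        assert rho == 0.0

    def test_pure_stroma_gives_stroma_score_one(self):
        _, f1 = immune_stroma_scores(ScoreInputs(S1=4, S2=0, IS1=1, IS2=0))
        assert f1 == 1.0

    def test_worked_arithmetic(self):
        rho, f1 = immune_stroma_scores(ScoreInputs(S1=2, S2=8, IS1=1, IS2=1))
        assert rho == pytest.approx(0.2)
        assert f1 == pytest.approx(0.2)

    def test_zero_total_area_is_error(self):
        with pytest.raises(ValidationError):
            immune_stroma_scores(ScoreInputs(S1=0, S2=0, IS1=0, IS2=0))

    def test_infiltration_bounded_by_compartment(self):
        with pytest.raises(ValidationError):
            ScoreInputs(S1=1, S2=1, IS1=2, IS2=0)


class TestOnSyntheticTissue:
    def test_fibroblast_peak_sides_match_architecture(self, frpos_zoned, frneg_zoned):
        for (tissue, boundary, table), side in ((frpos_zoned, -1), (frneg_zoned, +1)):
            out = layer_enrichment(table, boundary, window=5)
            lineage = (
                table.dropna(subset=["layer"])
                .assign(window=lambda d: np.sign(d["layer"]) * np.ceil(np.abs(d["layer"]) / 5))
            )
            fib = lineage[lineage["parent_lineage"] == "Fibroblast"]
            b2 = boundary
            merged = layer_enrichment(
                fib.assign(cell_type="Fibroblast_lineage"), b2, window=5
            )
            peak = merged.loc["Fibroblast_lineage"].idxmax()
            assert np.sign(peak) == side

    def test_every_assigned_cell_has_exactly_one_zone(self, frpos_zoned):
        _, _, table = frpos_zoned
        assigned = table[np.isfinite(table["d_um"])]
        assert assigned["zone"].isin(
            ["tumor_core", "tumor_edge", "liver_edge", "distal"]
        ).all()
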