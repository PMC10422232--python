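"""Raster I/O, site sampling, and per-pixel map inference."""

import json

import numpy as np
import pytest

from phenocycle import (
    ClassMap,
    GridTransform,
    LabeledDataset,
    ModelSpec,
    RasterStack,
    predict_map,
    read_map,
    read_stack,
    sample_sites,
    simulate_extent_dataset,
    simulate_raster,
    train,
    write_map,
    write_stack,
)
from phenocycle.classify import predict
from phenocycle.series import reconstruct


@pytest.fixture(scope="module")
def small_scene():
    return simulate_raster(8, 8, seed=21, noise_sd=0.0, missing_prob=0.0)


class TestStackIO:
    def test_roundtrip_bit_exact(self, tmp_path, small_scene):
        stack, _, _ = small_scene
        path = tmp_path / "stack.tif"
        write_stack(stack, path)
        back = read_stack(path)
        np.testing.assert_array_equal(
            back.cube.astype(np.float32), stack.cube.astype(np.float32)
        )
        assert back.transform == stack.transform
        assert back.crs == stack.crs

    def test_missing_values_roundtrip_as_nan(self, tmp_path):
        cube = np.full((3, 2, 2), 0.5)
        cube[1, 0, 0] = np.nan
        stack = RasterStack(cube=cube, transform=GridTransform(0, 0, 1, -1))
        path = tmp_path / "s.tif"
        write_stack(stack, path)
        back = read_stack(path)
        assert np.isnan(back.cube[1, 0, 0])
        assert np.isfinite(back.cube[0, 0, 0])

    def test_single_band_file_warns_but_loads(self, tmp_path, caplog):
        stack = RasterStack(
            cube=np.zeros((1, 2, 2)), transform=GridTransform(0, 0, 1, -1)
        )
        path = tmp_path / "one.tif"
        write_stack(stack, path)
        with caplog.at_level("WARNING"):
            back = read_stack(path)
        assert back.n_times == 1
        assert "too short" in caplog.text


class TestMapIO:
    def test_roundtrip_grid_legend_nodata(self, tmp_path):
        grid = np.array([[0, 1], [2, -1]], dtype=np.int16)
        cmap = ClassMap(
            grid=grid,
            legend={0: "a", 1: "b", 2: "c"},
            transform=GridTransform(10.0, 20.0, 0.1, -0.1),
            nodata=-1,
            params={"task": "intensity"},
        )
        path = tmp_path / "map.tif"
        write_map(cmap, path)
        back = read_map(path)
        np.testing.assert_array_equal(back.grid, grid)
        assert back.legend == {0: "a", 1: "b", 2: "c"}
        assert back.nodata == -1
        assert back.params["task"] == "intensity"
        assert back.transform == cmap.transform

    def test_codes_outside_legend_rejected(self):
        with pytest.raises(ValueError, match="not in legend"):
            ClassMap(
                grid=np.array([[7]]),
                legend={0: "a"},
                transform=GridTransform(0, 0, 1, -1),
            )


class TestSampleSites:
    def _write_sites(self, path, features):
        path.write_text(json.dumps({"type": "FeatureCollection", "features": features}))

    def test_point_maps_to_containing_pixel(self, tmp_path, small_scene):
        stack, ext, _ = small_scene
        x, y = stack.transform.pixel_center(3, 5)
        sites = tmp_path / "sites.geojson"
        self._write_sites(
            sites,
            [{
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [x, y]},
                "properties": {"label": int(ext.grid[3, 5])},
            }],
        )
        ds = sample_sites(stack, sites)
        assert len(ds) == 1
        np.testing.assert_array_equal(ds.series[0].values, stack.cube[:, 3, 5])

    def test_polygon_yields_covered_pixels(self, tmp_path, small_scene):
        stack, _, _ = small_scene
        t = stack.transform
        # rectangle spanning exactly the 2x2 pixel block rows 1-2, cols 1-2
        x0 = t.x0 + 1 * t.dx
        x1 = t.x0 + 3 * t.dx
        y0 = t.y0 + 1 * t.dy
        y1 = t.y0 + 3 * t.dy
        poly = {
            "type": "Polygon",
            "coordinates": [[[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]]],
        }
        sites = tmp_path / "poly.geojson"
        self._write_sites(
            sites,
            [{"type": "Feature", "geometry": poly, "properties": {"label": 1}}],
        )
        ds = sample_sites(stack, sites)
        assert len(ds) == 4
        assert set(ds.labels.tolist()) == {1}

    def test_polygon_cap_limits_pixels(self, tmp_path, small_scene):
        stack, _, _ = small_scene
        t = stack.transform
        poly = {
            "type": "Polygon",
            "coordinates": [[
                [t.x0, t.y0],
                [t.x0 + 8 * t.dx, t.y0],
                [t.x0 + 8 * t.dx, t.y0 + 8 * t.dy],
                [t.x0, t.y0 + 8 * t.dy],
                [t.x0, t.y0],
            ]],
        }
        sites = tmp_path / "big.geojson"
        self._write_sites(
            sites,
            [{"type": "Feature", "geometry": poly, "properties": {"label": 0}}],
        )
        ds = sample_sites(stack, sites, cap_per_polygon=5, seed=0)
        assert len(ds) == 5

    def test_out_of_bounds_geometry_skipped(self, tmp_path, small_scene, caplog):
        stack, _, _ = small_scene
        sites = tmp_path / "oob.geojson"
        self._write_sites(
            sites,
            [{
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [999.0, 999.0]},
                "properties": {"label": 1},
            }],
        )
        with caplog.at_level("WARNING"):
            ds = sample_sites(stack, sites)
        assert len(ds) == 0
        assert "outside raster bounds" in caplog.text

    def test_missing_label_property_rejected(self, tmp_path, small_scene):
        stack, _, _ = small_scene
        sites = tmp_path / "nolabel.geojson"
        self._write_sites(
            sites,
            [{
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [44.01, 35.99]},
                "properties": {},
            }],
        )
        with pytest.raises(ValueError, match="label"):
            sample_sites(stack, sites)

    def test_empty_collection_warns(self, tmp_path, small_scene, caplog):
        stack, _, _ = small_scene
        sites = tmp_path / "empty.geojson"
        self._write_sites(sites, [])
        with caplog.at_level("WARNING"):
            ds = sample_sites(stack, sites)
        assert len(ds) == 0


class TestPredictMap:
    def test_threshold_map_matches_truth_at_zero_noise(self, small_scene):
        stack, _, inten = small_scene
        out = predict_map(stack, task="intensity", method="threshold")
        np.testing.assert_array_equal(out.grid, inten.grid)

    def test_all_nodata_stack_gives_all_nodata_map(self):
        cube = np.full((24, 3, 3), np.nan)
        stack = RasterStack(cube=cube, transform=GridTransform(0, 0, 1, -1))
        out = predict_map(stack, task="intensity", method="threshold")
        assert np.all(out.grid == out.nodata)

    def test_pixel_independence_and_single_pixel_consistency(self, small_scene):
        stack, _, _ = small_scene
        train_ds = simulate_extent_dataset(30, 30, seed=21)
        recon = LabeledDataset(
            [reconstruct(s) for s in train_ds.series],
            train_ds.labels,
            train_ds.class_names,
        )
        model = train(recon, ModelSpec("random_forest", seed=21))
        full = predict_map(stack, model=model, task="extent")
        rng = np.random.default_rng(0)
        for _ in range(10):
            r, c = rng.integers(0, 8, size=2)
            single = predict(model, [reconstruct(stack.pixel_series(r, c))])[0]
            assert full.grid[r, c] == single

    def test_tiling_never_changes_outputs(self, small_scene):
        stack, _, _ = small_scene
        a = predict_map(stack, task="intensity", method="threshold", tile_size=3)
        b = predict_map(stack, task="intensity", method="threshold", tile_size=256)
        np.testing.assert_array_equal(a.grid, b.grid)

    def test_geometry_preserved(self, small_scene):
        stack, _, _ = small_scene
        out = predict_map(stack, task="intensity", method="threshold")
        assert out.transform == stack.transform
        assert out.crs == stack.crs

    def test_band_count_mismatch_rejected(self, small_scene):
        stack, _, _ = small_scene
        ds = simulate_extent_dataset(5, 5, seed=0)
        recon = LabeledDataset(
            [reconstruct(s) for s in ds.series], ds.labels, ds.class_names
        )
        model = train(recon, ModelSpec("random_forest", seed=0))  # 24 features
        short_stack = RasterStack(
            cube=np.full((12, 2, 2), 0.4), transform=stack.transform
        )
        with pytest.raises(ValueError, match="composites"):
            predict_map(short_stack, model=model, task="extent")

    def test_end_to_end_determinism(self, tmp_path):
        paths = []
        for run in ("a", "b"):
            stack, _, _ = simulate_raster(6, 6, seed=33)
            ds = simulate_extent_dataset(20, 20, seed=33)
            recon = LabeledDataset(
                [reconstruct(s) for s in ds.series], ds.labels, ds.class_names
            )
            model = train(recon, ModelSpec("random_forest", seed=33))
            out = predict_map(stack, model=model, task="extent")
            p = tmp_path / f"map_{run}.tif"
            write_map(out, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()
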