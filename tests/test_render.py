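"""Rendering identities, scaling rules and image export determinism."""

import json

import numpy as np
import pytest

from hilbertmaps.layout import build_layout
from hilbertmaps.render import (
    CLASS_GAP,
    CLASS_ZERO,
    RenderOptions,
    aggregate_map,
    animation_frames,
    average_map,
    colorless_map,
    differential_map,
    intensity_map,
    overlay_path,
    save_png,
    save_svg,
)
from hilbertmaps.taxonomy import LinearOrder


def vec(layout, **values):
    out = {t: 0.0 for t in layout.assignment}
    out.update(values)
    return out


@pytest.fixture
def layout4():
    order = LinearOrder(taxa=["a", "b", "c", "d"],
                        groups={"g": [("g1", 0, 2), ("g2", 2, 4)]})
    return build_layout(order, k=1)


class TestIntensityMap:
    def test_all_zero_sample(self, layout4):
        r = intensity_map(vec(layout4), layout4)
        assert (r.intensity == 0).all()
        assert (r.classes == CLASS_ZERO).all()

    def test_single_nonzero_taxon_saturates(self, layout4):
        r = intensity_map(vec(layout4, b=0.4), layout4)
        assert r.intensity.max() == 1.0
        lit = np.argwhere(r.intensity == 1.0)
        assert len(lit) == 1  # exactly the taxon's single cell

    def test_max_normalization_example(self, layout4):
        r = intensity_map(vec(layout4, a=0.2, b=0.8), layout4)
        vals = sorted(v for v in r.intensity.ravel() if v > 0)
        assert vals == pytest.approx([0.25, 1.0])

    def test_sub_tau_renders_zero_class(self, layout4):
        opts = RenderOptions(tau=0.05)
        r = intensity_map(vec(layout4, a=0.01, b=0.99), layout4, opts)
        (ax, ay) = layout4.assignment["a"][0], None
        # taxon a is below tau: zero intensity and zero class
        from hilbertmaps.layout import cells_of

        (cell,) = cells_of(layout4, "a")
        x, y = cell
        assert r.intensity[y, x] == 0.0
        assert r.classes[y, x] == CLASS_ZERO

    def test_merged_taxon_paints_all_cells_one_value(self):
        order = LinearOrder(taxa=["a", "b"], groups={})
        layout = build_layout(order, k=1)  # 2 cells each
        r = intensity_map({"a": 0.3, "b": 0.6}, layout)
        from hilbertmaps.layout import cells_of

        for t, expected in [("a", 0.5), ("b", 1.0)]:
            for x, y in cells_of(layout, t):
                assert r.intensity[y, x] == pytest.approx(expected)

    def test_log_scale_orders_intensities(self, layout4):
        opts = RenderOptions(scale="log", tau=1e-4)
        r = intensity_map(vec(layout4, a=1e-3, b=1e-2, c=1e-1), layout4, opts)
        vals = sorted(v for v in r.intensity.ravel() if v > 0)
        assert vals[-1] == pytest.approx(1.0)
        assert len(vals) == 3
        # log spacing is even for decade-spaced abundances
        assert np.diff(vals) == pytest.approx([1 / 3, 1 / 3], abs=1e-9)

    def test_missing_taxa_rejected(self, layout4):
        with pytest.raises(ValueError, match="missing"):
            intensity_map({"a": 1.0}, layout4)

    def test_metadata_always_present(self, layout4):
        r = intensity_map(vec(layout4, a=1.0), layout4)
        for key in ("level", "orientation", "scale", "tau", "order_provenance"):
            assert key in r.metadata

    def test_gap_cells_keep_gap_class(self):
        order = LinearOrder(taxa=["a", "b", "c"], groups={"g": [("x", 0, 3)]})
        layout = build_layout(order, k=2, reserve_gaps=True)
        r = intensity_map({"a": 1.0, "b": 0.0, "c": 0.5}, layout)
        assert (r.classes == CLASS_GAP).sum() == 13  # 16 cells - 3 taxa


class TestDerivedMaps:
    def test_differential_identity_zero(self, layout4):
        a = vec(layout4, a=0.5, b=0.5)
        r = differential_map(a, a, layout4)
        assert (r.intensity == 0).all()
        assert r.signed

    def test_differential_antisymmetry(self, layout4):
        a = vec(layout4, a=0.6, b=0.1, c=0.3)
        b = vec(layout4, a=0.1, b=0.7, d=0.2)
        fwd = differential_map(a, b, layout4)
        rev = differential_map(b, a, layout4)
        assert np.allclose(fwd.intensity, -rev.intensity)

    def test_differential_hand_example(self, layout4):
        a = vec(layout4, a=0.5, b=0.3, c=0.2)
        b = vec(layout4, a=0.1, b=0.5, c=0.2, d=0.2)
        r = differential_map(a, b, layout4)
        from hilbertmaps.layout import cells_of

        # raw diffs: a=+0.4, b=-0.2, c=0.0, d=-0.2; scaled by max|.|=0.4
        expected = {"a": 1.0, "b": -0.5, "c": 0.0, "d": -0.5}
        for t, e in expected.items():
            (x, y) = cells_of(layout4, t)[0]
            assert r.intensity[y, x] == pytest.approx(e)

    def test_average_of_identical_samples(self, layout4):
        s = vec(layout4, a=0.25, b=0.75)
        single = intensity_map(s, layout4)
        avg = average_map([s, s, s], layout4)
        assert np.allclose(avg.intensity, single.intensity)

    def test_average_against_brute_force(self, layout4):
        rng = np.random.default_rng(5)
        samples = []
        for _ in range(5):
            raw = rng.random(4)
            raw /= raw.sum()
            samples.append(dict(zip(["a", "b", "c", "d"], raw)))
        avg = average_map(samples, layout4)
        brute = {
            t: sum(s[t] for s in samples) / len(samples)
            for t in ["a", "b", "c", "d"]
        }
        expect = intensity_map(brute, layout4)
        assert np.allclose(avg.intensity, expect.intensity)

    def test_aggregate_sum_vs_mean_scale_invariant(self, layout4):
        samples = [vec(layout4, a=0.2, b=0.8), vec(layout4, a=0.6, b=0.4)]
        # sum and mean differ by a constant factor; max normalization
        # makes their intensity grids identical
        s = aggregate_map(samples, layout4, reducer="sum")
        m = average_map(samples, layout4)
        assert np.allclose(s.intensity, m.intensity)


class TestAnimation:
    def test_constant_series_identical_frames(self, layout4):
        s = vec(layout4, a=0.3, b=0.7)
        frames = animation_frames([("t0", s), ("t1", s), ("t2", s)], layout4)
        assert len(frames) == 3
        for f in frames[1:]:
            assert np.array_equal(f.intensity, frames[0].intensity)

    def test_global_scale_shared(self, layout4):
        series = [
            ("t0", vec(layout4, a=0.2)),
            ("t1", vec(layout4, a=0.4)),
            ("t2", vec(layout4, a=0.8)),
        ]
        frames = animation_frames(series, layout4)
        peaks = [f.intensity.max() for f in frames]
        assert peaks == pytest.approx([0.25, 0.5, 1.0])
        assert all(f.metadata["scale_max"] == pytest.approx(0.8) for f in frames)

    def test_needs_two_samples(self, layout4):
        with pytest.raises(ValueError):
            animation_frames([("t0", vec(layout4))], layout4)


class TestOverlaysAndExport:
    def test_path_polyline(self, layout4):
        r = intensity_map(vec(layout4, a=1.0), layout4)
        overlay_path(r, layout4)
        assert len(r.path) == 4
        assert all(
            abs(a[0] - b[0]) + abs(a[1] - b[1]) == 1
            for a, b in zip(r.path, r.path[1:])
        )

    def test_path_level_mismatch(self, layout4):
        big = build_layout(
            LinearOrder(taxa=[f"t{i}" for i in range(16)], groups={}), k=2
        )
        r = intensity_map(vec(layout4, a=1.0), layout4)
        with pytest.raises(ValueError):
            overlay_path(r, big)

    def test_colorless_map(self, layout16):
        r = colorless_map(layout16, "genus")
        assert (r.intensity == 0).all()
        assert r.boundaries
        assert r.metadata["map_type"] == "colorless"

    def test_png_and_svg_deterministic(self, tmp_path, layout4):
        r = intensity_map(vec(layout4, a=0.2, b=0.8), layout4)
        opts = RenderOptions(cell_px=4)
        p1 = save_png(r, tmp_path / "m1.png", layout4, opts)
        p2 = save_png(r, tmp_path / "m2.png", layout4, opts)
        assert p1.read_bytes() == p2.read_bytes()
        s1 = save_svg(r, tmp_path / "m1.svg", layout4, opts)
        s2 = save_svg(r, tmp_path / "m2.svg", layout4, opts)
        assert s1.read_text() == s2.read_text()

    def test_sidecar_metadata_written(self, tmp_path, layout4):
        r = intensity_map(vec(layout4, a=1.0), layout4)
        save_png(r, tmp_path / "m.png", layout4)
        meta = json.loads((tmp_path / "m.png.json").read_text())
        assert meta["level"] == 1
        assert "orientation" in meta

    def test_gap_distinct_from_zero_in_rgb(self, tmp_path):
        from hilbertmaps.render import _to_rgb, GAP_RGB

        order = LinearOrder(taxa=["a", "b", "c"], groups={"g": [("x", 0, 3)]})
        layout = build_layout(order, k=2, reserve_gaps=True)
        r = intensity_map({"a": 1.0, "b": 0.0, "c": 0.5}, layout)
        rgb = _to_rgb(r, layout, RenderOptions())
        gap_colors = {tuple(rgb[y, x]) for y in range(4) for x in range(4)
                      if r.classes[y, x] == CLASS_GAP}
        zero_colors = {tuple(rgb[y, x]) for y in range(4) for x in range(4)
                       if r.classes[y, x] == CLASS_ZERO}
        assert gap_colors == {GAP_RGB}
        assert zero_colors and GAP_RGB not in zero_colors

    def test_animation_export(self, tmp_path, layout4):
        series = [("t0", vec(layout4, a=0.2)), ("t1", vec(layout4, b=0.9))]
        frames = animation_frames(series, layout4)
        from hilbertmaps.render import save_animation

        out = save_animation(frames, tmp_path / "movie.gif", layout4,
                             RenderOptions(cell_px=4))
        assert out.exists() and out.stat().st_size > 0
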