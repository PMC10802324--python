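import numpy as np
import pandas as pd
import pytest

from batchray import (
    FeatureMatrix,
    PlotSpec,
    SampleAnnotation,
    add_trend,
    assign_styles,
    build_plot_spec,
    compute_centroids,
    compute_pca,
    dual_variable_spec,
    generate_dichotomy,
    generate_trend,
    render,
    SyntheticSpec,
    align_samples,
)


@pytest.fixture
def fitted(small_matrix, small_annotation):
    r = compute_pca(small_matrix, 2)
    c = compute_centroids(r, small_annotation, "batch")
    return r, c


class TestBuildPlotSpec:
    def test_counting_contract(self, fitted, small_annotation):
        r, c = fitted
        spec = build_plot_spec(r, c, small_annotation, "batch")
        assert len(spec.points) == 4
        assert len(spec.centroids) == 2
        assert len(spec.rays) == 4
        assert spec.arrows == []

    def test_ray_endpoints_exact(self, rng):
        """Every ray starts exactly at its group centroid and ends exactly
        at a member point; centroids recomputed independently agree."""
        data = rng.standard_normal((18, 6))
        labels = list(np.repeat(["a", "b", "c"], 6))
        m = FeatureMatrix(
            data.T, [f"f{i}" for i in range(6)], [f"s{j}" for j in range(18)]
        )
        ann = SampleAnnotation(pd.DataFrame({"g": labels}, index=m.sample_ids))
        r = compute_pca(m, 2)
        c = compute_centroids(r, ann, "g")
        spec = build_plot_spec(r, c, ann, "g")
        points = {p.sample_id: (p.x, p.y) for p in spec.points}
        cents = {cen.group: (cen.x, cen.y) for cen in spec.centroids}
        for ray, sid, g in zip(spec.rays, m.sample_ids, labels):
            assert (ray.x0, ray.y0) == cents[g]
            assert (ray.x1, ray.y1) == points[sid]
        # independent recomputation of centroid coordinates
        for i, g in enumerate(["a", "b", "c"]):
            mask = np.array(labels) == g
            np.testing.assert_allclose(
                cents[g], r.scores[mask, :2].mean(axis=0), atol=1e-12
            )

    def test_singleton_group_zero_length_ray(self, small_matrix):
        ann = SampleAnnotation(
            pd.DataFrame({"g": ["solo", "rest", "rest", "rest"]},
                         index=small_matrix.sample_ids)
        )
        r = compute_pca(small_matrix, 2)
        c = compute_centroids(r, ann, "g")
        spec = build_plot_spec(r, c, ann, "g")
        solo_rays = [ray for ray in spec.rays if ray.group == "solo"]
        assert len(solo_rays) == 1
        assert (solo_rays[0].x0, solo_rays[0].y0) == (solo_rays[0].x1, solo_rays[0].y1)

    def test_axis_labels_carry_explained_variance(self, fitted, small_annotation):
        r, c = fitted
        spec = build_plot_spec(r, c, small_annotation, "batch")
        assert spec.axis_labels[0].startswith("PC1 (")
        assert "%" in spec.axis_labels[0]

    def test_component_out_of_range(self, fitted, small_annotation):
        r, c = fitted
        with pytest.raises(ValueError, match="out of range"):
            build_plot_spec(r, c, small_annotation, "batch", components=(1, 3))

    def test_json_round_trip(self, fitted, small_annotation):
        r, c = fitted
        spec = build_plot_spec(r, c, small_annotation, "batch")
        back = PlotSpec.from_json(spec.to_json())
        assert back == spec


class TestAddTrend:
    def test_three_groups_two_arrows(self):
        spec = _trend_spec(n_groups=3)
        assert len(spec.arrows) == 2

    def test_one_group_zero_arrows(self, small_matrix):
        ann = SampleAnnotation(
            pd.DataFrame({"g": ["only"] * 4}, index=small_matrix.sample_ids)
        )
        r = compute_pca(small_matrix, 2)
        c = compute_centroids(r, ann, "g")
        spec = add_trend(build_plot_spec(r, c, ann, "g"), c, ["only"])
        assert spec.arrows == []

    def test_arrows_follow_declared_order_and_reverse(self):
        spec_fwd = _trend_spec(n_groups=4)
        order = [f"t{j + 1:02d}" for j in range(4)]
        starts = [(a.x0, a.y0) for a in spec_fwd.arrows]
        cents = {c.group: (c.x, c.y) for c in spec_fwd.centroids}
        assert starts == [cents[g] for g in order[:-1]]
        # reversing the order reverses every arrow
        spec_rev = _trend_spec(n_groups=4, order=order[::-1])
        fwd = [(a.x0, a.y0, a.x1, a.y1) for a in spec_fwd.arrows]
        rev = [(a.x1, a.y1, a.x0, a.y0) for a in spec_rev.arrows]
        assert fwd == rev[::-1]

    def test_drift_arrows_aligned_with_drift_direction(self):
        """Synthetic temporal drift: consecutive centroid arrows all point
        the same way along the drift axis after projection."""
        spec = _trend_spec(n_groups=5, drift=2.0, samples=15)
        vecs = np.array([[a.x1 - a.x0, a.y1 - a.y0] for a in spec.arrows])
        mean_dir = vecs.mean(axis=0)
        assert all(v @ mean_dir > 0 for v in vecs)

    def test_order_must_be_permutation(self):
        sspec = SyntheticSpec(n_groups=3, samples_per_group=5, n_features=20, seed=1)
        m, ann = generate_trend(sspec)
        aligned, _ = align_samples(m, ann, "time")
        r = compute_pca(aligned, 2)
        c = compute_centroids(r, ann, "time")
        spec = build_plot_spec(r, c, ann, "time")
        with pytest.raises(ValueError, match="permutation"):
            add_trend(spec, c, ["t01", "t02", "bogus"])


def _trend_spec(n_groups, drift=1.0, samples=8, order=None):
    sspec = SyntheticSpec(
        n_groups=n_groups, samples_per_group=samples, n_features=30,
        drift_per_step=drift, seed=11,
    )
    m, ann = generate_trend(sspec)
    aligned, _ = align_samples(m, ann, "time")
    r = compute_pca(aligned, 2)
    c = compute_centroids(r, ann, "time")
    spec = build_plot_spec(r, c, ann, "time")
    return add_trend(spec, c, order or ann.levels("time"))


class TestDualVariableSpec:
    def test_counting_contract(self, rng):
        sspec = SyntheticSpec(
            n_groups=4, samples_per_group=6, n_features=40,
            dichotomy_fraction=0.2, seed=2,
        )
        m, ann = generate_dichotomy(sspec)
        aligned, _ = align_samples(m, ann, "batch")
        r = compute_pca(aligned, 2)
        spec = dual_variable_spec(r, ann, "batch", "sex")
        assert len(spec.centroids) == 4
        assert {p.shape_key for p in spec.points} == {"female", "male"}

    def test_same_variable_degenerates_to_single_spec(self, small_matrix, small_annotation):
        r = compute_pca(small_matrix, 2)
        c = compute_centroids(r, small_annotation, "batch")
        single = build_plot_spec(r, c, small_annotation, "batch")
        dual = dual_variable_spec(r, small_annotation, "batch", "batch")
        assert [(p.x, p.y, p.color_key) for p in dual.points] == [
            (p.x, p.y, p.color_key) for p in single.points
        ]
        assert dual.rays == single.rays

    def test_hidden_dichotomy_separates_points_not_batches(self):
        """Hidden-variable centroids sit far apart while batch centroids
        interleave: the dichotomy is visible through point styling only."""
        sspec = SyntheticSpec(
            n_groups=3, samples_per_group=40, n_features=200,
            group_mean_shift=0.0, dichotomy_fraction=0.1,
            dichotomy_effect=8.0, seed=4,
        )
        m, ann = generate_dichotomy(sspec)
        aligned, _ = align_samples(m, ann, "batch")
        r = compute_pca(aligned, 2)
        sex_c = compute_centroids(r, ann, "sex")
        batch_c = compute_centroids(r, ann, "batch")
        sex_sep = np.linalg.norm(sex_c.centroids[0] - sex_c.centroids[1])
        # batch centroids sit near the origin apart from chance sex
        # imbalance within batches; the dichotomy dwarfs them
        batch_spread = np.linalg.norm(batch_c.centroids, axis=1).max()
        assert sex_sep > 3 * batch_spread
        # every batch mixes both sexes (the dichotomy crosses batches)
        crosstab = ann.table.groupby(["batch", "sex"]).size().unstack()
        assert (crosstab > 0).all().all()


class TestRenderAndStyles:
    def test_color_assignment_pure_function_of_sorted_levels(self):
        s1 = assign_styles(["b", "a", "c"])
        s2 = assign_styles(["c", "b", "a"])
        assert s1 == s2
        assert len({v[0] for v in s1.values()}) == 3

    def test_palette_overflow_reuses_colors_with_new_shapes(self):
        levels = [f"lv{i:02d}" for i in range(25)]
        styles = assign_styles(levels)
        first, again = styles["lv00"], styles["lv20"]
        assert first[0] == again[0] and first[1] != again[1]

    def test_render_svg_nonzero_and_deterministic(self, tmp_path, fitted, small_annotation):
        r, c = fitted
        spec = build_plot_spec(r, c, small_annotation, "batch")
        p1, p2 = tmp_path / "a.svg", tmp_path / "b.svg"
        render(spec, p1)
        render(spec, p2)
        assert p1.stat().st_size > 0
        assert p1.read_bytes() == p2.read_bytes()

    def test_no_arrows_means_fewer_path_elements(self, tmp_path, fitted, small_annotation):
        r, c = fitted
        plain = build_plot_spec(r, c, small_annotation, "batch")
        assert plain.arrows == []
        with_trend = add_trend(plain, c, ["b1", "b2"])
        svg_plain = render(plain, tmp_path / "plain.svg").read_text()
        svg_trend = render(with_trend, tmp_path / "trend.svg").read_text()
        assert svg_trend.count("<path") > svg_plain.count("<path")

    @pytest.mark.parametrize("fmt", ["png", "pdf"])
    def test_other_formats_written(self, tmp_path, fitted, small_annotation, fmt):
        r, c = fitted
        spec = build_plot_spec(r, c, small_annotation, "batch")
        out = render(spec, tmp_path / f"plot.{fmt}")
        assert out.stat().st_size > 0

    def test_unknown_format_rejected(self, fitted, small_annotation, tmp_path):
        r, c = fitted
        spec = build_plot_spec(r, c, small_annotation, "batch")
        with pytest.raises(ValueError, match="format"):
            render(spec, tmp_path / "plot.bmp")
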