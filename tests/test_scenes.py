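"""Synthetic scene generation and end-to-end plot-LAI recovery."""

from __future__ import annotations

import numpy as np
import pytest

from wheatlai import (
    classify_vegetation,
    compute_ndvi,
    compute_metrics,
    generate_scene,
    grid_layout,
    make_dataset,
    predict_plot_lai,
    resample_to_bands,
    train_rfr,
)
from wheatlai.scenes import SceneSpec


def _spec(dry_soil, lai, cover, **over):
    layout = grid_layout(1, len(lai), plot_w=1.0, plot_h=2.0, gap=0.3)
    kwargs = dict(
        layout=layout,
        true_lai={p.plot_id: lai[i] for i, p in enumerate(layout)},
        cover={p.plot_id: cover[i] for i, p in enumerate(layout)},
        soil=dry_soil,
        pixel_size=0.05,
        seed=11,
    )
    kwargs.update(over)
    return SceneSpec(**kwargs)


class TestGenerateScene:
    def test_full_cover_noise_free_is_homogeneous(self, dry_soil):
        spec = _spec(dry_soil, [2.5], [1.0])
        rmap, mask, truth = generate_scene(spec)
        poly = spec.layout[0].polygon
        from wheatlai import plot_mean_reflectance

        means = plot_mean_reflectance(rmap, poly)
        veg = truth.iloc[0][[f"veg_{b}" for b in ("Blue", "Green", "Red", "RedEdge", "NIR")]]
        assert means == pytest.approx(veg.to_numpy(dtype=float), abs=1e-12)

    def test_bare_plot_equals_soil(self, dry_soil, bands):
        spec = _spec(dry_soil, [1.5], [0.0])
        rmap, _, _ = generate_scene(spec)
        from wheatlai import plot_mean_reflectance

        means = plot_mean_reflectance(rmap, spec.layout[0].polygon)
        assert means == pytest.approx(resample_to_bands(dry_soil, bands), abs=1e-12)

    def test_partial_cover_mixture(self, dry_soil):
        spec = _spec(dry_soil, [1.0], [0.4])
        rmap, _, truth = generate_scene(spec)
        from wheatlai import plot_mean_reflectance

        row = truth.iloc[0]
        frac = row["n_vegetation_pixels"] / row["n_pixels"]
        veg = row[[f"veg_{b}" for b in ("Blue", "Green", "Red", "RedEdge", "NIR")]].to_numpy(float)
        soil = row[[f"soil_{b}" for b in ("Blue", "Green", "Red", "RedEdge", "NIR")]].to_numpy(float)
        expected = frac * veg + (1 - frac) * soil
        # compare over the untrimmed plot so the pixel sets coincide
        means = plot_mean_reflectance(rmap, spec.layout[0].polygon)
        assert means == pytest.approx(expected, abs=1e-9)
        assert abs(frac - 0.4) < 0.01  # rounding to whole pixels only

    def test_seed_reproducibility(self, dry_soil):
        a = generate_scene(_spec(dry_soil, [1.0, 3.0], [0.3, 0.8]))
        b = generate_scene(_spec(dry_soil, [1.0, 3.0], [0.3, 0.8]))
        assert np.array_equal(a[0].values, b[0].values)
        assert np.array_equal(a[1].values, b[1].values)

    def test_mask_recovered_by_classification(self, dry_soil):
        """Noise-free healthy canopy vs soil separates exactly at NDVI 0.5."""
        spec = _spec(dry_soil, [3.0, 4.0], [0.5, 0.7])
        rmap, truth_mask, _ = generate_scene(spec)
        ndvi = compute_ndvi(rmap)
        mask = classify_vegetation(ndvi, 0.5)
        assert np.array_equal(mask.values, truth_mask.values)

    def test_mixed_pixel_mode(self, dry_soil):
        spec = _spec(dry_soil, [2.0], [0.6], mixed_pixels=True)
        rmap, mask, truth = generate_scene(spec)
        assert not mask.values.any()  # no pure vegetation pixels
        row = truth.iloc[0]
        veg = row[[f"veg_{b}" for b in ("Blue", "Green", "Red", "RedEdge", "NIR")]].to_numpy(float)
        soil = row[[f"soil_{b}" for b in ("Blue", "Green", "Red", "RedEdge", "NIR")]].to_numpy(float)
        from wheatlai import plot_mean_reflectance

        means = plot_mean_reflectance(rmap, spec.layout[0].polygon)
        assert means == pytest.approx(0.6 * veg + 0.4 * soil, abs=1e-9)


@pytest.fixture(scope="module")
def p3_model(dry_soil):
    """Forest trained on a Set#3 dataset simulated over the default dry soil."""
    ds = make_dataset("p3", dry_soil, 6000, seed=314)
    return train_rfr(ds, n_estimators=100, seed=314)


class TestPredictionMethods:
    def test_full_cover_methods_agree(self, dry_soil, bands, p3_model):
        spec = _spec(dry_soil, [2.0, 3.5], [1.0, 1.0])
        rmap, _, _ = generate_scene(spec)
        soil_b = resample_to_bands(dry_soil, bands)
        rfr = predict_plot_lai(rmap, spec.layout, p3_model, "RFR")
        lcb = predict_plot_lai(rmap, spec.layout, p3_model, "RFR+LCB",
                               soil_bands=soil_b, threshold=0.5)
        assert np.array_equal(
            rfr["predicted_LAI"].to_numpy(), lcb["predicted_LAI"].to_numpy()
        )

    def test_zero_cover_predicts_soil_response(self, dry_soil, bands, p3_model):
        spec = _spec(dry_soil, [2.0], [0.0])
        rmap, _, _ = generate_scene(spec)
        soil_b = resample_to_bands(dry_soil, bands)
        lcb = predict_plot_lai(rmap, spec.layout, p3_model, "RFR+LCB",
                               soil_bands=soil_b, threshold=0.5)
        direct = p3_model.predict(soil_b)
        assert lcb["predicted_LAI"].iloc[0] == pytest.approx(direct, abs=1e-9)

    def test_sparse_scene_mean_error_ordering(self, dry_soil, bands, p3_model):
        """Across sparse low-LAI plots over the training background, the mean
        |error| of the corrected method never exceeds the raw method (with a
        matching background and exact classification the two coincide)."""
        rng = np.random.default_rng(5)
        lai = rng.uniform(0.8, 1.8, 8).round(2).tolist()
        cover = rng.uniform(0.25, 0.45, 8).round(2).tolist()
        spec = _spec(dry_soil, lai, cover)
        rmap, _, _ = generate_scene(spec)
        soil_b = resample_to_bands(dry_soil, bands)
        rfr = predict_plot_lai(rmap, spec.layout, p3_model, "RFR")
        lcb = predict_plot_lai(rmap, spec.layout, p3_model, "RFR+LCB",
                               soil_bands=soil_b, threshold=0.5)
        mae_rfr = np.mean(np.abs(rfr["predicted_LAI"].to_numpy() - lai))
        mae_lcb = np.mean(np.abs(lcb["predicted_LAI"].to_numpy() - lai))
        assert mae_lcb <= mae_rfr

    def test_lcb_robust_to_local_background(self, dry_soil, bands, p3_model):
        """The point of locally calibrated background correction: plot
        predictions become nearly invariant to what the local background
        actually is (training soil vs bright crop residue), whereas raw
        aggregation shifts substantially."""
        lai = [1.0, 1.4, 1.8, 1.2]
        cover = [0.4, 0.3, 0.45, 0.35]
        residue = np.full(dry_soil.size, 0.28)  # flat bright residue, NDVI ~ 0
        soil_b = resample_to_bands(dry_soil, bands)
        preds = {}
        for name, scene_soil in (("train", dry_soil), ("residue", residue)):
            spec = _spec(dry_soil, lai, cover, soil=scene_soil)
            rmap, _, _ = generate_scene(spec)
            preds["rfr", name] = predict_plot_lai(
                rmap, spec.layout, p3_model, "RFR"
            )["predicted_LAI"].to_numpy()
            preds["lcb", name] = predict_plot_lai(
                rmap, spec.layout, p3_model, "RFR+LCB",
                soil_bands=soil_b, threshold=0.5,
            )["predicted_LAI"].to_numpy()
        shift_rfr = np.abs(preds["rfr", "train"] - preds["rfr", "residue"])
        shift_lcb = np.abs(preds["lcb", "train"] - preds["lcb", "residue"])
        assert np.all(shift_lcb < shift_rfr)
        assert shift_lcb.max() < 0.1

    def test_end_to_end_recovery(self, dry_soil, bands, p3_model):
        """20 plots, LAI ~ U(0.2, 4.5), cover increasing with LAI:
        corrected plot predictions correlate strongly with truth."""
        rng = np.random.default_rng(99)
        lai = np.sort(rng.uniform(0.2, 4.5, 20))
        cover = np.clip(0.15 + 0.85 * (1 - np.exp(-0.9 * lai)), 0, 1)
        spec = _spec(dry_soil, lai.tolist(), cover.tolist(), seed=99)
        rmap, _, _ = generate_scene(spec)
        soil_b = resample_to_bands(dry_soil, bands)
        lcb = predict_plot_lai(rmap, spec.layout, p3_model, "RFR+LCB",
                               soil_bands=soil_b, threshold=0.5)
        m = compute_metrics(lai, lcb["predicted_LAI"].to_numpy())
        assert m.r >= 0.9
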