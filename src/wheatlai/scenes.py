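"""Synthetic UAV scene generator with known per-plot LAI and cover fraction.

Emulates a plot-trial reflectance map so the imaging pipeline and both
prediction methods can be exercised end to end with full ground truth: each
plot is filled with a random subset of pure vegetation pixels (at the
plot's cover fraction) whose 5-band values come from the forward canopy
model run at the plot's true LAI, and pure soil pixels valued at the soil's
band reflectance; optional additive Gaussian band noise on top.  Pixels are
binary (no mixed pixels) by default, mirroring the classification
assumption of the pipeline; a mixed-pixel mode area-weights the two
endmembers instead, to probe resolution effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .bands import BAND_NAMES, N_BANDS, default_micasense_bands, resample_to_bands
from .imaging import BinaryMask, PlotLayout, ReflectanceMap
from .sail import simulate_canopy_reflectance
from .spectra import CanopyParams, LeafParams, ViewGeometry, as_spectrum

__all__ = ["SceneSpec", "generate_scene", "grid_layout"]

#: Mid-range wheat leaf used for vegetation pixels unless overridden.
DEFAULT_LEAF = LeafParams(Ns=1.75, Cab=45.0, Car=10.0, Cw=0.015, Cm=0.0055)
DEFAULT_ALA = 45.0
DEFAULT_GEOM = ViewGeometry(SZA=35.0, VZA=0.0, RAA=0.0)


@dataclass
class SceneSpec:
    """Recipe for one synthetic scene.

    ``layout`` carries the plot polygons; ``true_lai`` and ``cover`` map
    plot ids to the plot's true LAI (m^2 m^-2) and vegetation cover fraction
    in [0, 1].  ``soil`` is the background spectrum on the 1 nm grid;
    ``noise_sd`` is the additive Gaussian reflectance noise per band.
    """

    layout: list[PlotLayout]
    true_lai: dict[str, float]
    cover: dict[str, float]
    soil: np.ndarray
    pixel_size: float = 0.02
    noise_sd: float = 0.0
    seed: int = 0
    leaf: LeafParams = DEFAULT_LEAF
    ala: float = DEFAULT_ALA
    geometry: ViewGeometry = DEFAULT_GEOM
    hspot: float = 0.2
    mixed_pixels: bool = False
    bands: tuple = field(default_factory=default_micasense_bands)

    def __post_init__(self) -> None:
        self.soil = as_spectrum(self.soil, "soil")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for pid in (p.plot_id for p in self.layout):
            if not 0.0 <= self.cover[pid] <= 1.0:
                raise ValueError(f"plot {pid}: cover fraction outside [0, 1]")


def grid_layout(
    n_rows: int,
    n_cols: int,
    plot_w: float = 2.0,
    plot_h: float = 7.0,
    gap: float = 0.5,
    stage: str | None = None,
) -> list[PlotLayout]:
    """A regular grid of rectangular plots (ids ``r{i}c{j}``), origin at (0, 0)."""
    layouts = []
    for i in range(n_rows):
        for j in range(n_cols):
            x0 = gap + j * (plot_w + gap)
            y0 = -(gap + i * (plot_h + gap))
            poly = shapely.box(x0, y0 - plot_h, x0 + plot_w, y0)
            layouts.append(PlotLayout(plot_id=f"r{i}c{j}", polygon=poly, stage=stage))
    return layouts


def generate_scene(spec: SceneSpec) -> tuple[ReflectanceMap, BinaryMask, pd.DataFrame]:
    """Render the scene; returns (map, ground-truth mask, ground-truth table).

    Pixels outside every plot are soil.  Within a plot, ``cover`` of the
    pixels (chosen at random with the spec seed) are vegetation.  The truth
    table records per plot: true LAI, cover fraction, the vegetation and
    soil band reflectance used, and realised pixel counts.
    """
    rng = np.random.default_rng(spec.seed)
    soil_bands = resample_to_bands(spec.soil, spec.bands)

    bounds = shapely.unary_union([p.polygon for p in spec.layout]).bounds
    pad = 2 * spec.pixel_size
    x_min, y_min, x_max, y_max = (
        bounds[0] - pad, bounds[1] - pad, bounds[2] + pad, bounds[3] + pad
    )
    cols = int(np.ceil((x_max - x_min) / spec.pixel_size))
    rows = int(np.ceil((y_max - y_min) / spec.pixel_size))
    origin = (x_min, y_max)

    values = np.empty((N_BANDS, rows, cols), dtype=float)
    values[:] = soil_bands[:, None, None]
    veg_mask = np.zeros((rows, cols), dtype=bool)

    xs = x_min + (np.arange(cols) + 0.5) * spec.pixel_size
    ys = y_max - (np.arange(rows) + 0.5) * spec.pixel_size
    X, Y = np.meshgrid(xs, ys)

    records = []
    for plot in spec.layout:
        lai = float(spec.true_lai[plot.plot_id])
        cover = float(spec.cover[plot.plot_id])
        canopy = CanopyParams(LAI=lai, ALA=spec.ala, hspot=spec.hspot)
        veg_spectrum = simulate_canopy_reflectance(
            spec.leaf, canopy, spec.geometry, spec.soil
        )
        veg_bands = resample_to_bands(veg_spectrum, spec.bands)

        inside = shapely.contains_xy(plot.polygon, X.ravel(), Y.ravel()).reshape(rows, cols)
        idx = np.flatnonzero(inside)
        if spec.mixed_pixels:
            mixed = cover * veg_bands[:, None] + (1 - cover) * soil_bands[:, None]
            values.reshape(N_BANDS, -1)[:, idx] = mixed
            n_veg = int(round(cover * idx.size))
        else:
            n_veg = int(round(cover * idx.size))
            veg_idx = rng.choice(idx, size=n_veg, replace=False)
            values.reshape(N_BANDS, -1)[:, veg_idx] = veg_bands[:, None]
            veg_mask.reshape(-1)[veg_idx] = True

        records.append(
            {
                "plot_id": plot.plot_id,
                "true_LAI": lai,
                "cover": cover,
                "n_pixels": int(idx.size),
                "n_vegetation_pixels": n_veg,
                **{f"veg_{b}": veg_bands[i] for i, b in enumerate(BAND_NAMES)},
                **{f"soil_{b}": soil_bands[i] for i, b in enumerate(BAND_NAMES)},
            }
        )

    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)
    values = np.clip(values, 0.0, 1.0)

    rmap = ReflectanceMap(values=values, pixel_size=spec.pixel_size, origin=origin)
    return rmap, BinaryMask(values=veg_mask), pd.DataFrame.from_records(records)
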