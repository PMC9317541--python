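"""Plot-scale imaging pipeline: NDVI classification, background correction,
plot trimming and aggregation, and the two plot-LAI prediction methods.

The pipeline mirrors a UAV phenotyping workflow.  From a calibrated 5-band
reflectance map: (1) NDVI is computed from the NIR and Red bands; (2) a
vegetation/background binary map is obtained by thresholding NDVI (stage-
specific thresholds); (3) under the "RFR+LCB" method (Locally Calibrated
Background) background pixels are replaced by the band reflectance of the
very soil spectrum used to train the regression model, so plot means feed
the model data whose background matches its training conditions; (4) plots
are trimmed inward by 10% per side and per-band means over pixel centers
inside the trimmed polygon are predicted with the trained forest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .bands import BAND_NAMES, N_BANDS
from .regressor import RFRModel, predict_lai

__all__ = [
    "ReflectanceMap",
    "BinaryMask",
    "PlotLayout",
    "STAGE_THRESHOLDS",
    "compute_ndvi",
    "classify_vegetation",
    "resolve_threshold",
    "correct_background",
    "trim_plot",
    "plot_mean_reflectance",
    "predict_plot_lai",
    "load_plot_layouts",
    "save_plot_layouts",
]

logger = logging.getLogger(__name__)

#: Empirical NDVI thresholds per growth stage.
STAGE_THRESHOLDS = {"tillering": 0.5, "elongation": 0.65, "flag_leaf": 0.75}

_NODATA_DEFAULT = -9999.0


@dataclass
class ReflectanceMap:
    """A 5-band reflectance raster with a north-up square-pixel transform.

    ``values`` has shape ``(5, rows, cols)`` in the package band order.
    ``origin`` is the (x, y) map coordinate of the top-left corner of the
    top-left pixel; ``pixel_size`` is the ground sampling distance in map
    units (m).  ``nodata`` marks invalid pixels in every band.
    """

    values: np.ndarray
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = _NODATA_DEFAULT

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[0] != N_BANDS:
            raise ValueError(f"values must have shape (5, rows, cols), got {self.values.shape}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        valid = self.valid_mask()
        vv = self.values[:, valid]
        if vv.size and (vv.min() < 0 or vv.max() > 1):
            if vv.max() > 1.5:
                logger.warning(
                    "reflectance values look integer-scaled (max=%.1f); rescaling by 1e-4",
                    vv.max(),
                )
                scaled = self.values / 10000.0
                scaled[:, ~valid] = self.nodata
                self.values = scaled
            else:
                raise ValueError("valid reflectance values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[1:]

    def valid_mask(self) -> np.ndarray:
        """True where all five bands carry data."""
        return np.all(self.values != self.nodata, axis=0)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates (x, y) of every pixel center, each (rows, cols)."""
        rows, cols = self.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(cols) + 0.5) * self.pixel_size
        ys = y0 - (np.arange(rows) + 0.5) * self.pixel_size
        return np.meshgrid(xs, ys)

    def copy(self) -> "ReflectanceMap":
        return ReflectanceMap(
            values=self.values.copy(),
            pixel_size=self.pixel_size,
            origin=self.origin,
            nodata=self.nodata,
        )

    def save(self, path: str | Path) -> None:
        """Write as a multiband float TIFF plus a JSON georeferencing sidecar."""
        import tifffile

        path = Path(path)
        tifffile.imwrite(path, self.values.astype(np.float32), photometric="minisblack")
        meta = {
            "band_order": list(BAND_NAMES),
            "pixel_size": self.pixel_size,
            "origin": list(self.origin),
            "nodata": self.nodata,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ReflectanceMap":
        import tifffile

        path = Path(path)
        values = np.asarray(tifffile.imread(path), dtype=float)
        meta_path = path.with_suffix(path.suffix + ".json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        order = meta.get("band_order", list(BAND_NAMES))
        if tuple(order) != BAND_NAMES:
            raise ValueError(f"raster band order {order} does not match {BAND_NAMES}")
        return cls(
            values=values,
            pixel_size=float(meta.get("pixel_size", 1.0)),
            origin=tuple(meta.get("origin", (0.0, 0.0))),
            nodata=float(meta.get("nodata", _NODATA_DEFAULT)),
        )


@dataclass
class BinaryMask:
    """Vegetation (1) / background (0) raster aligned to a ReflectanceMap."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("mask must be 2-D")


@dataclass(frozen=True)
class PlotLayout:
    """One plot: footprint polygon, optional stage label and trim fraction."""

    plot_id: str
    polygon: BaseGeometry
    stage: str | None = None
    trim_fraction: float = 0.10
    exclusions: tuple[BaseGeometry, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.polygon.is_empty or self.polygon.area <= 0:
            raise ValueError(f"plot {self.plot_id}: degenerate footprint polygon")
        if not 0.0 <= self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must be in [0, 0.5)")


def compute_ndvi(rmap: ReflectanceMap) -> np.ndarray:
    """Per-pixel (NIR - Red)/(NIR + Red); nodata propagates, NIR+Red=0 -> nodata."""
    red = rmap.values[BAND_NAMES.index("Red")]
    nir = rmap.values[BAND_NAMES.index("NIR")]
    ndvi = np.full(rmap.shape, rmap.nodata, dtype=float)
    ok = rmap.valid_mask() & ((nir + red) != 0)
    ndvi[ok] = (nir[ok] - red[ok]) / (nir[ok] + red[ok])
    return ndvi


def resolve_threshold(threshold: float | str) -> float:
    """Map a stage label to its NDVI threshold, or pass a number through."""
    if isinstance(threshold, str):
        try:
            return STAGE_THRESHOLDS[threshold]
        except KeyError:
            raise ValueError(
                f"unknown stage {threshold!r}; expected one of {sorted(STAGE_THRESHOLDS)}"
            ) from None
    return float(threshold)


def classify_vegetation(
    ndvi: np.ndarray, threshold: float | str, nodata: float = _NODATA_DEFAULT
) -> BinaryMask:
    """Vegetation iff NDVI strictly exceeds the threshold; nodata -> background.

    The comparison is strict so that pixels exactly at the threshold remain
    background (the thresholds are chosen to classify soil as background).
    """
    thr = resolve_threshold(threshold)
    if not -1.0 < thr < 1.0:
        raise ValueError(f"threshold={thr} must lie in (-1, 1)")
    ndvi = np.asarray(ndvi, dtype=float)
    mask = (ndvi != nodata) & (ndvi > thr)
    return BinaryMask(values=mask)


def correct_background(
    rmap: ReflectanceMap, mask: BinaryMask, soil_bands: np.ndarray
) -> ReflectanceMap:
    """Replace background pixels by the training soil's band reflectance.

    ``soil_bands`` must be the 5-band resampling of the exact soil spectrum
    used to simulate the training set of the model that will consume the
    corrected map.  Vegetation pixels are untouched; the operation is
    idempotent.
    """
    if mask.values.shape != rmap.shape:
        raise ValueError("mask and map grids do not match")
    soil_bands = np.asarray(soil_bands, dtype=float).reshape(-1)
    if soil_bands.shape != (N_BANDS,):
        raise ValueError(f"soil_bands must have {N_BANDS} values")
    out = rmap.copy()
    background = rmap.valid_mask() & ~mask.values
    for b in range(N_BANDS):
        band = out.values[b]
        band[background] = soil_bands[b]
    return out


def trim_plot(polygon: BaseGeometry, fraction: float = 0.10) -> BaseGeometry:
    """Shrink a rectangle-like plot inward by ``fraction`` of each side length.

    A 2 x 7 m plot at fraction 0.10 becomes 1.6 x 5.6 m about the same
    center.  Implemented on the minimum rotated rectangle so slightly
    rotated plots trim along their own axes.
    """
    if not 0.0 <= fraction < 0.5:
        raise ValueError("trim fraction must be in [0, 0.5)")
    if fraction == 0.0:
        return polygon
    rect = polygon.minimum_rotated_rectangle
    coords = np.asarray(rect.exterior.coords)[:4]
    center = coords.mean(axis=0)
    shrunk = center + (coords - center) * (1.0 - 2.0 * fraction)
    return shapely.Polygon(shrunk)


def plot_mean_reflectance(
    rmap: ReflectanceMap,
    polygon: BaseGeometry,
    exclusions: tuple[BaseGeometry, ...] = (),
) -> np.ndarray:
    """Per-band mean over valid pixels whose centers fall inside the polygon.

    Pixels inside any exclusion polygon (e.g. harvested quadrat areas) are
    left out.  Raises if no valid pixel center falls inside.
    """
    X, Y = rmap.pixel_centers()
    inside = shapely.contains_xy(polygon, X.ravel(), Y.ravel()).reshape(rmap.shape)
    for excl in exclusions:
        inside &= ~shapely.contains_xy(excl, X.ravel(), Y.ravel()).reshape(rmap.shape)
    sel = inside & rmap.valid_mask()
    if not np.any(sel):
        raise ValueError("no valid pixels inside the plot polygon")
    return rmap.values[:, sel].mean(axis=1)


def predict_plot_lai(
    rmap: ReflectanceMap,
    layout: list[PlotLayout],
    model: RFRModel,
    method: str = "RFR+LCB",
    soil_bands: np.ndarray | None = None,
    threshold: float | str | None = None,
) -> pd.DataFrame:
    """Per-plot LAI with either prediction method.

    ``"RFR"`` aggregates the original map per trimmed plot and predicts;
    ``"RFR+LCB"`` first replaces classified background pixels by
    ``soil_bands`` (NDVI threshold resolved from ``threshold`` or each
    plot's stage label), then aggregates and predicts.  Returns a table with
    plot id, method, threshold, pixel count, band means and predicted LAI.
    """
    if tuple(model.band_order) != BAND_NAMES:
        raise ValueError("model band order does not match the raster band order")
    method = method.upper().replace("_", "+")
    if method not in {"RFR", "RFR+LCB"}:
        raise ValueError(f"unknown method {method!r}; expected 'RFR' or 'RFR+LCB'")

    corrected: dict[float, ReflectanceMap] = {}
    ndvi = None
    if method == "RFR+LCB":
        if soil_bands is None:
            raise ValueError("RFR+LCB requires the training soil band reflectance")
        ndvi = compute_ndvi(rmap)

    records = []
    for plot in layout:
        if method == "RFR+LCB":
            thr = resolve_threshold(
                threshold if threshold is not None else (plot.stage or "flag_leaf")
            )
            if thr not in corrected:
                mask = classify_vegetation(ndvi, thr, nodata=rmap.nodata)
                corrected[thr] = correct_background(rmap, mask, soil_bands)
            source, thr_used = corrected[thr], thr
        else:
            source, thr_used = rmap, np.nan
        poly = trim_plot(plot.polygon, plot.trim_fraction)
        means = plot_mean_reflectance(source, poly, plot.exclusions)
        X, Y = source.pixel_centers()
        n_pix = int(
            (
                shapely.contains_xy(poly, X.ravel(), Y.ravel()).reshape(source.shape)
                & source.valid_mask()
            ).sum()
        )
        rec = {
            "plot_id": plot.plot_id,
            "method": method,
            "threshold": thr_used,
            "n_pixels": n_pix,
        }
        rec.update({f"mean_{b}": means[i] for i, b in enumerate(BAND_NAMES)})
        rec["predicted_LAI"] = predict_lai(model, means)
        records.append(rec)
    return pd.DataFrame.from_records(records)


def load_plot_layouts(path: str | Path) -> list[PlotLayout]:
    """Read plot layouts from a GeoJSON FeatureCollection."""
    data = json.loads(Path(path).read_text())
    layouts = []
    for feat in data["features"]:
        props = feat.get("properties", {}) or {}
        layouts.append(
            PlotLayout(
                plot_id=str(props.get("plot_id", len(layouts))),
                polygon=shape(feat["geometry"]),
                stage=props.get("stage"),
                trim_fraction=float(props.get("trim_fraction", 0.10)),
            )
        )
    return layouts


def save_plot_layouts(layouts: list[PlotLayout], path: str | Path) -> None:
    """Write plot layouts as a GeoJSON FeatureCollection."""
    features = [
        {
            "type": "Feature",
            "geometry": mapping(p.polygon),
            "properties": {
                "plot_id": p.plot_id,
                "stage": p.stage,
                "trim_fraction": p.trim_fraction,
            },
        }
        for p in layouts
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=2)
    )
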