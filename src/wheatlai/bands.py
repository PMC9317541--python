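"""Camera band response functions and 1 nm -> 5-band resampling.

The target sensor is a 5-band multispectral camera (blue / green / red /
red-edge / NIR).  Throughout the package band values are ordered
``(Blue, Green, Red, RedEdge, NIR)``; the order is exported as
:data:`BAND_NAMES` and asserted wherever band vectors cross a module
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import N_WAVELENGTHS, WAVELENGTHS, as_spectrum

__all__ = [
    "BAND_NAMES",
    "N_BANDS",
    "BandDefinition",
    "default_micasense_bands",
    "gaussian_band",
    "resample_to_bands",
    "load_band_responses",
]

#: Fixed band order used by every array-like interface in the package.
BAND_NAMES: tuple[str, ...] = ("Blue", "Green", "Red", "RedEdge", "NIR")
N_BANDS = len(BAND_NAMES)

#: (center nm, bandwidth nm) of the MicaSense RedEdge bands, in BAND_NAMES order.
MICASENSE_CENTERS_BANDWIDTHS: tuple[tuple[float, float], ...] = (
    (475.0, 20.0),
    (560.0, 20.0),
    (668.0, 10.0),
    (717.0, 10.0),
    (840.0, 40.0),
)


@dataclass(frozen=True)
class BandDefinition:
    """A named spectral band with a normalised response on the shared grid."""

    name: str
    center: float
    bandwidth: float
    response: np.ndarray

    def __post_init__(self) -> None:
        resp = np.asarray(self.response, dtype=float)
        if resp.shape != (N_WAVELENGTHS,):
            raise ValueError(
                f"band response must be on the {N_WAVELENGTHS}-sample grid"
            )
        if np.any(resp < 0):
            raise ValueError("band response weights must be non-negative")
        total = resp.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError("band response weights must sum to 1")
        object.__setattr__(self, "response", resp)


def gaussian_band(name: str, center: float, bandwidth: float) -> BandDefinition:
    """Synthesise a Gaussian band response with FWHM equal to ``bandwidth``.

    The Gaussian is centred at ``center``, truncated at +/- 2 FWHM and
    renormalised to unit sum.  This is a synthetic surrogate for the camera
    manufacturer's measured response curves, reproducing the published
    centre/bandwidth semantics; measured curves can be supplied with
    :func:`load_band_responses`.
    """
    sigma = bandwidth / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    resp = np.exp(-0.5 * ((WAVELENGTHS - center) / sigma) ** 2)
    resp[np.abs(WAVELENGTHS - center) > 2.0 * bandwidth] = 0.0
    resp /= resp.sum()
    return BandDefinition(name=name, center=center, bandwidth=bandwidth, response=resp)


def default_micasense_bands() -> tuple[BandDefinition, ...]:
    """The five MicaSense RedEdge bands with synthesised Gaussian responses.

    Centres/bandwidths: Blue 475/20, Green 560/20, Red 668/10,
    RedEdge 717/10, NIR 840/40 nm.
    """
    return tuple(
        gaussian_band(name, c, bw)
        for name, (c, bw) in zip(BAND_NAMES, MICASENSE_CENTERS_BANDWIDTHS)
    )


def _response_matrix(bands) -> np.ndarray:
    bands = tuple(bands)
    if len(bands) != N_BANDS:
        raise ValueError(f"expected {N_BANDS} bands, got {len(bands)}")
    names = tuple(b.name for b in bands)
    if names != BAND_NAMES:
        raise ValueError(f"bands must be ordered {BAND_NAMES}, got {names}")
    return np.stack([b.response for b in bands])


def resample_to_bands(spectrum: np.ndarray, bands=None) -> np.ndarray:
    """Response-weighted band means of a 1 nm spectrum (or batch).

    ``spectrum`` may be ``(2101,)`` or ``(n, 2101)``; the result is ``(5,)``
    or ``(n, 5)`` in :data:`BAND_NAMES` order.
    """
    if bands is None:
        bands = default_micasense_bands()
    R = _response_matrix(bands)
    spec = np.asarray(spectrum, dtype=float)
    if spec.ndim == 1:
        as_spectrum(spec, "spectrum", check_bounds=False)
        return spec @ R.T
    if spec.ndim == 2 and spec.shape[1] == N_WAVELENGTHS:
        return spec @ R.T
    raise ValueError(
        f"spectrum must have {N_WAVELENGTHS} samples per row, got shape {spec.shape}"
    )


def support_indices(bands=None) -> np.ndarray:
    """Grid indices where at least one band response is non-zero.

    Simulating only these wavelengths yields the same band values as the
    full grid, since all other weights are exactly zero.
    """
    if bands is None:
        bands = default_micasense_bands()
    R = _response_matrix(bands)
    return np.flatnonzero(R.sum(axis=0) > 0)


def load_band_responses(paths: dict[str, str]) -> tuple[BandDefinition, ...]:
    """Load measured band response tables (two-column CSV per band).

    ``paths`` maps each band name in :data:`BAND_NAMES` to a CSV file of
    ``wavelength_nm, weight`` rows.  Weights are interpolated onto the
    shared grid (zero outside the tabulated range) and renormalised.
    """
    import pandas as pd

    missing = set(BAND_NAMES) - set(paths)
    if missing:
        raise ValueError(f"missing response files for bands: {sorted(missing)}")
    bands = []
    for name in BAND_NAMES:
        tab = pd.read_csv(paths[name])
        wl = tab.iloc[:, 0].to_numpy(dtype=float)
        wt = tab.iloc[:, 1].to_numpy(dtype=float)
        resp = np.interp(WAVELENGTHS, wl, wt, left=0.0, right=0.0)
        resp = np.clip(resp, 0.0, None)
        if resp.sum() <= 0:
            raise ValueError(f"band {name}: response is zero on the 400-2500 nm grid")
        resp /= resp.sum()
        center = float(np.sum(WAVELENGTHS * resp))
        bands.append(
            BandDefinition(name=name, center=center, bandwidth=float("nan"), response=resp)
        )
    return tuple(bands)
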