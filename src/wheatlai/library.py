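"""Synthetic spectral coefficient library for the leaf and soil optical models.

The leaf radiative transfer model needs, at every wavelength, a leaf-interior
refractive index and one specific absorption coefficient per absorber
(chlorophyll a+b, carotenoids, anthocyanins, brown pigment, water, dry
matter), plus reference dry/wet soil reflectance endmembers for the canopy
lower boundary.  The published calibration tables for these quantities are
distributed as data files with the reference model code and are not
redistributable here, so this module generates a *synthetic* library: smooth
parametric curves (Gaussian absorption bands on the shared 1 nm grid, a
slowly varying refractive index, logistic-rise soil curves) whose amplitudes
were calibrated once against canonical published leaf optical properties
(fresh-leaf reflectance/transmittance levels in the visible and NIR, water
band depths in the SWIR) and typical bare-soil reflectance.

All quantities produced here are synthetic stand-ins with realistic spectral
shape; they are not the published calibration data.  Absorption coefficients
are expressed per unit of the corresponding leaf constituent (so that, e.g.,
``Cab * kab`` is the dimensionless optical depth contribution of chlorophyll
in a single elementary layer of an Ns = 1 leaf).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .spectra import WAVELENGTHS, SoilLibrary

__all__ = ["SpectralCoefficients", "synthetic_prospect_coefficients", "default_soil_library"]


def _gauss(center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((WAVELENGTHS - center) / sigma) ** 2)


def _logistic(center: float, width: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(WAVELENGTHS - center) / width))


@dataclass(frozen=True)
class SpectralCoefficients:
    """Per-wavelength leaf-model coefficients on the 400-2500 nm grid.

    ``nr`` is the refractive index; the ``k*`` arrays are specific absorption
    coefficients for chlorophyll a+b, carotenoids, anthocyanins, brown
    pigment, water and dry matter respectively.
    """

    nr: np.ndarray
    kab: np.ndarray
    kcar: np.ndarray
    kant: np.ndarray
    kbrown: np.ndarray
    kw: np.ndarray
    km: np.ndarray


@lru_cache(maxsize=1)
def synthetic_prospect_coefficients() -> SpectralCoefficients:
    """Build the synthetic leaf coefficient library (cached).

    Band placement follows the known absorption features: the chlorophyll
    Soret band near 430 nm and red band near 672 nm, carotenoid absorption
    confined below ~550 nm, anthocyanins near 550 nm, liquid-water overtone
    bands at 970/1200/1450/1940/2500 nm, and dry matter absorption rising
    through the SWIR with cellulose/lignin features near 1730 and 2100 nm.
    """
    wl = WAVELENGTHS

    # Refractive index: smooth decline from ~1.52 (blue) towards ~1.40 (SWIR).
    nr = 1.40 + 0.12 * np.exp(-(wl - 400.0) / 900.0)

    # Chlorophyll a+b, per ug cm^-2.
    kab = (
        0.085 * _gauss(420.0, 42.0)
        + 0.071 * _gauss(672.0, 23.0)
        + 0.018 * _gauss(620.0, 90.0)
        + 0.010 * _gauss(500.0, 50.0)
    )
    kab[wl > 780.0] = 0.0

    # Carotenoids, per ug cm^-2; absorb only in the blue.
    kcar = 0.110 * _gauss(450.0, 28.0) + 0.085 * _gauss(485.0, 26.0)
    kcar[wl > 580.0] = 0.0

    # Anthocyanins, per ug cm^-2 (zero in the wheat parameter sets).
    kant = 0.060 * _gauss(548.0, 35.0)
    kant[wl > 650.0] = 0.0

    # Brown pigment, unitless content; broad decay through the visible.
    kbrown = 0.9 * np.exp(-(wl - 400.0) / 250.0)

    # Liquid water, per g cm^-2 (equivalent water thickness in cm).
    kw = (
        0.45 * _gauss(970.0, 28.0)
        + 1.2 * _gauss(1200.0, 40.0)
        + 29.0 * _gauss(1450.0, 55.0)
        + 85.0 * _gauss(1940.0, 70.0)
        + 45.0 * _gauss(2500.0, 120.0)
        + 3.0 * _logistic(1350.0, 150.0)
    )
    kw[wl < 900.0] = 0.0

    # Dry matter, per g cm^-2.
    km = (
        6.0 * _logistic(1300.0, 200.0)
        + 40.0 * _logistic(2000.0, 150.0)
        + 8.0 * _gauss(1730.0, 50.0)
        + 12.0 * _gauss(2100.0, 60.0)
        + 0.8
    )

    return SpectralCoefficients(nr=nr, kab=kab, kcar=kcar, kant=kant,
                                kbrown=kbrown, kw=kw, km=km)


@lru_cache(maxsize=1)
def default_soil_library() -> SoilLibrary:
    """Synthetic default dry/wet soil reflectance endmembers (cached).

    The dry curve rises smoothly from ~0.06 in the blue to ~0.42 in the
    SWIR plateau with shallow water features at 1450/1940 nm; the wet curve
    is a darkened copy with deeper water bands, the usual behaviour of a
    moist soil surface.
    """
    wl = WAVELENGTHS
    dry = 0.055 + 0.40 * (1.0 - np.exp(-(wl - 400.0) / 950.0))
    dry -= 0.045 * _gauss(1450.0, 70.0) + 0.075 * _gauss(1940.0, 90.0)
    dry -= 0.030 * _logistic(2200.0, 120.0)
    dry = np.clip(dry, 0.01, 1.0)

    # Wetting darkens progressively more at longer wavelengths (water film
    # absorption), so the wet/dry ratio declines from ~0.70 in the blue
    # towards ~0.42 in the SWIR; this spectral-shape change is what makes
    # the wetness factor identifiable from visible/NIR bands.
    ratio = 0.70 - 0.30 * (1.0 - np.exp(-(wl - 400.0) / 800.0))
    wet = dry * ratio
    wet -= 0.035 * _gauss(1450.0, 80.0) + 0.050 * _gauss(1940.0, 100.0)
    wet = np.clip(wet, 0.01, 1.0)

    return SoilLibrary(dry=dry, wet=wet, name="default_synthetic")
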