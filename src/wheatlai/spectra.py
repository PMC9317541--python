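"""Fixed wavelength grid and the parameter types of the canopy radiative transfer model.

Every spectrum in this package lives on a single shared grid: 400--2500 nm at a
1 nm step (2101 samples).  Spectra are plain ``numpy`` arrays on that grid;
helpers here validate shape and bounds so downstream code can assume both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

WL_MIN = 400
WL_MAX = 2500
WL_STEP = 1
#: The shared 400-2500 nm, 1 nm wavelength grid (2101 samples).
WAVELENGTHS: np.ndarray = np.arange(WL_MIN, WL_MAX + WL_STEP, WL_STEP, dtype=float)
N_WAVELENGTHS = WAVELENGTHS.size


class SpectrumGridError(ValueError):
    """A spectrum is not on the shared 400-2500 nm / 1 nm grid."""


def as_spectrum(values, name: str = "spectrum", check_bounds: bool = True) -> np.ndarray:
    """Coerce ``values`` to a float array on the standard grid.

    Parameters
    ----------
    values : array-like
        Reflectance (or weight) samples; must have exactly 2101 entries.
    name : str
        Used in error messages.
    check_bounds : bool
        If true, require every sample to lie in [0, 1].
    """
    arr = np.asarray(values, dtype=float)
    if arr.shape != (N_WAVELENGTHS,):
        raise SpectrumGridError(
            f"{name} must have shape ({N_WAVELENGTHS},) on the 400-2500 nm 1 nm grid, "
            f"got {arr.shape}"
        )
    if check_bounds and (np.any(arr < 0) or np.any(arr > 1)):
        raise ValueError(f"{name} has values outside [0, 1]")
    return arr


def _check_range(value: float, lo: float, hi: float, name: str,
                 lo_open: bool = False, hi_open: bool = False) -> None:
    bad = value < lo or value > hi
    bad = bad or (lo_open and value == lo) or (hi_open and value == hi)
    if bad:
        lb = "(" if lo_open else "["
        rb = ")" if hi_open else "]"
        raise ValueError(f"{name}={value} outside {lb}{lo}, {hi}{rb}")


@dataclass(frozen=True)
class LeafParams:
    """Leaf biophysical inputs of the PROSPECT-D leaf optical model.

    Attributes
    ----------
    Ns : float
        Leaf mesophyll structure parameter (number of elementary plates,
        unitless, >= 1).
    Cab : float
        Chlorophyll a+b content, ug cm^-2.
    Car : float
        Carotenoid content, ug cm^-2.
    Cant : float
        Anthocyanin content, ug cm^-2 (0 in the wheat parameter sets).
    Cbrown : float
        Brown pigment content, unitless (0 in the wheat parameter sets).
    Cw : float
        Equivalent water thickness, g cm^-2.
    Cm : float
        Dry matter content, g cm^-2.
    """

    Ns: float
    Cab: float
    Car: float
    Cw: float
    Cm: float
    Cant: float = 0.0
    Cbrown: float = 0.0

    def __post_init__(self) -> None:
        if self.Ns < 1:
            raise ValueError(f"Ns={self.Ns} must be >= 1")
        for fname in ("Cab", "Car", "Cant", "Cbrown", "Cw", "Cm"):
            v = getattr(self, fname)
            if v < 0:
                raise ValueError(f"{fname}={v} must be >= 0")


@dataclass(frozen=True)
class CanopyParams:
    """Canopy architecture inputs of the 4SAIL model.

    Attributes
    ----------
    LAI : float
        Leaf area index, m^2 m^-2.
    ALA : float
        Average leaf inclination angle of the ellipsoidal leaf inclination
        distribution, degrees, in (0, 90).
    hspot : float
        Hot-spot size parameter (leaf size / canopy height), m m^-1.
    """

    LAI: float
    ALA: float
    hspot: float

    def __post_init__(self) -> None:
        if self.LAI < 0:
            raise ValueError(f"LAI={self.LAI} must be >= 0")
        _check_range(self.ALA, 0.0, 90.0, "ALA", lo_open=True, hi_open=True)
        if self.hspot < 0:
            raise ValueError(f"hspot={self.hspot} must be >= 0")


@dataclass(frozen=True)
class ViewGeometry:
    """Sun/view geometry and diffuse illumination fraction.

    ``skyl`` may be left ``None``, in which case the simulation derives it
    from the solar zenith angle (see :func:`wheatlai.sail.compute_skyl`).
    At nadir view (VZA = 0) the relative azimuth has no effect on the
    simulated reflectance.
    """

    SZA: float
    VZA: float = 0.0
    RAA: float = 0.0
    skyl: float | None = None

    def __post_init__(self) -> None:
        _check_range(self.SZA, 0.0, 90.0, "SZA", hi_open=True)
        _check_range(self.VZA, 0.0, 90.0, "VZA", hi_open=True)
        _check_range(self.RAA, -180.0, 180.0, "RAA")
        if self.skyl is not None:
            _check_range(self.skyl, 0.0, 1.0, "skyl")


@dataclass(frozen=True)
class LeafOptics:
    """Directional-hemispherical leaf reflectance and transmittance spectra."""

    reflectance: np.ndarray
    transmittance: np.ndarray

    def __post_init__(self) -> None:
        r = as_spectrum(self.reflectance, "leaf reflectance")
        t = as_spectrum(self.transmittance, "leaf transmittance")
        if np.any(r + t > 1.0 + 1e-9):
            raise ValueError("leaf reflectance + transmittance exceeds 1")
        object.__setattr__(self, "reflectance", r)
        object.__setattr__(self, "transmittance", t)


@dataclass(frozen=True)
class SoilLibrary:
    """Reference dry and wet soil reflectance endmembers."""

    dry: np.ndarray
    wet: np.ndarray
    name: str = "soil"

    def __post_init__(self) -> None:
        object.__setattr__(self, "dry", as_spectrum(self.dry, "dry soil"))
        object.__setattr__(self, "wet", as_spectrum(self.wet, "wet soil"))
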