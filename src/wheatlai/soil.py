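"""Soil background model and calibration from observed band reflectance.

A field soil is modelled as a brightness-scaled mixture of the reference dry
and wet endmembers,

    Rsoil = asoil * (psoil * Rdry + (1 - psoil) * Rwet),

with ``psoil`` in [0, 1] interpolating wetness and ``asoil`` a multiplicative
brightness factor.  Calibration recovers ``(asoil, psoil)`` from the 5-band
reflectance of bare-soil pixels by minimising the summed per-band deviation
between the resampled mixture and the observation.  The problem is a smooth
2-D fit, solved by a deterministic coarse grid search followed by local
refinement (no random initialisation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .bands import N_BANDS, default_micasense_bands, resample_to_bands
from .spectra import SoilLibrary

__all__ = ["SoilFit", "mix_soil", "calibrate_soil"]

ASOIL_BOUNDS = (0.01, 3.0)


@dataclass(frozen=True)
class SoilFit:
    """Result of a soil calibration: factors, residual and fitted spectrum."""

    asoil: float
    psoil: float
    residual: float
    fitted_spectrum: np.ndarray

    def __post_init__(self) -> None:
        if self.asoil <= 0:
            raise ValueError("asoil must be > 0")
        if not 0.0 <= self.psoil <= 1.0:
            raise ValueError("psoil must be in [0, 1]")
        if self.residual < 0:
            raise ValueError("residual must be >= 0")


def mix_soil(
    library: SoilLibrary,
    asoil: float,
    psoil: float,
    brightness_on_dry_only: bool = False,
) -> np.ndarray:
    """Evaluate the soil mixture model, clipped to [0, 1].

    By default ``asoil`` scales the whole wet/dry mixture (a brightness
    factor on the soil spectrum).  ``brightness_on_dry_only`` switches to the
    alternative reading in which ``asoil`` scales the dry endmember alone.
    """
    if asoil <= 0:
        raise ValueError(f"asoil={asoil} must be > 0")
    if not 0.0 <= psoil <= 1.0:
        raise ValueError(f"psoil={psoil} outside [0, 1]")
    if brightness_on_dry_only:
        spec = asoil * psoil * library.dry + (1.0 - psoil) * library.wet
    else:
        spec = asoil * (psoil * library.dry + (1.0 - psoil) * library.wet)
    return np.clip(spec, 0.0, 1.0)


def _band_objective(
    observed: np.ndarray,
    dry_b: np.ndarray,
    wet_b: np.ndarray,
    least_squares: bool,
    brightness_on_dry_only: bool,
):
    def f(theta):
        a, p = theta
        if brightness_on_dry_only:
            model = a * p * dry_b + (1.0 - p) * wet_b
        else:
            model = a * (p * dry_b + (1.0 - p) * wet_b)
        dev = model - observed
        return float(np.sum(dev ** 2) if least_squares else np.sum(np.abs(dev)))

    return f


def calibrate_soil(
    observed: np.ndarray,
    bands=None,
    library: SoilLibrary | None = None,
    least_squares: bool = False,
    brightness_on_dry_only: bool = False,
) -> SoilFit:
    """Fit ``(asoil, psoil)`` to observed bare-soil band reflectance.

    Parameters
    ----------
    observed : ndarray, shape (5,)
        Mean band reflectance of bare-soil pixels, in the package band order.
    bands : sequence of BandDefinition, optional
        Camera bands; defaults to the bundled 5-band set.
    library : SoilLibrary, optional
        Dry/wet endmembers; defaults to the bundled synthetic default soil.
    least_squares : bool
        Use squared deviations instead of the default absolute deviations.
    brightness_on_dry_only : bool
        Alternative mixture parenthesisation (see :func:`mix_soil`).

    Notes
    -----
    Because the fit is done on band-resampled (not clipped) mixtures, the
    recovered factors are exact for self-generated observations.  A coarse
    0.01-step grid over ``asoil`` in [0.01, 3] x ``psoil`` in [0, 1] is
    scanned first; the best cell is refined with a bounded Nelder-Mead
    polish.  Deterministic given inputs.
    """
    observed = np.asarray(observed, dtype=float).reshape(-1)
    if observed.shape != (N_BANDS,):
        raise ValueError(f"observed band reflectance must have {N_BANDS} values")
    if bands is None:
        bands = default_micasense_bands()
    if library is None:
        from .library import default_soil_library

        library = default_soil_library()

    dry_b = resample_to_bands(library.dry, bands)
    wet_b = resample_to_bands(library.wet, bands)
    if np.allclose(dry_b, wet_b) and np.allclose(dry_b, 0.0):
        raise ValueError("unidentifiable fit: degenerate soil library (dry = wet = 0)")

    obj = _band_objective(observed, dry_b, wet_b, least_squares, brightness_on_dry_only)

    a_grid = np.arange(ASOIL_BOUNDS[0], ASOIL_BOUNDS[1] + 1e-9, 0.01)
    p_grid = np.arange(0.0, 1.0 + 1e-9, 0.01)
    # Vectorised scan of the full grid.
    A, P = np.meshgrid(a_grid, p_grid, indexing="ij")
    if brightness_on_dry_only:
        model = A[..., None] * P[..., None] * dry_b + (1.0 - P[..., None]) * wet_b
    else:
        model = A[..., None] * (P[..., None] * dry_b + (1.0 - P[..., None]) * wet_b)
    dev = model - observed
    score = np.sum(dev ** 2, axis=-1) if least_squares else np.sum(np.abs(dev), axis=-1)
    i, j = np.unravel_index(int(np.argmin(score)), score.shape)
    x0 = np.array([A[i, j], P[i, j]])

    res = minimize(
        obj,
        x0,
        method="Nelder-Mead",
        bounds=[ASOIL_BOUNDS, (0.0, 1.0)],
        options={"xatol": 1e-7, "fatol": 1e-12, "maxiter": 2000},
    )
    best = res.x if res.fun <= obj(x0) else x0
    asoil, psoil = float(best[0]), float(np.clip(best[1], 0.0, 1.0))
    fitted = mix_soil(library, asoil, psoil, brightness_on_dry_only)
    return SoilFit(
        asoil=asoil,
        psoil=psoil,
        residual=float(obj((asoil, psoil))),
        fitted_spectrum=fitted,
    )
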