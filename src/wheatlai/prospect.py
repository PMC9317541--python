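"""PROSPECT-D leaf optical properties model.

The leaf is represented as a stack of ``Ns`` elementary plates separated by
air spaces (the generalised plate model).  A single elementary layer absorbs
according to the summed optical depth of the leaf constituents and refracts
at its surfaces following Fresnel theory averaged over the incidence solid
angle; the ``Ns - 1`` remaining layers are added analytically with the
Stokes system for a pile of identical plates.

The implementation is vectorised: the batch entry point takes parameter
arrays of shape ``(n,)`` and returns reflectance/transmittance arrays of
shape ``(n, 2101)`` on the shared wavelength grid.
"""

from __future__ import annotations

import numpy as np
from scipy.special import exp1

from .library import SpectralCoefficients, synthetic_prospect_coefficients
from .spectra import LeafOptics, LeafParams

__all__ = ["prospect_d", "prospect_batch", "tav"]


def tav(theta_deg: float, nr: np.ndarray) -> np.ndarray:
    """Average transmissivity of a dielectric plane surface.

    Fresnel transmittance averaged over all directions of incidence within a
    cone of half-angle ``theta_deg``, for relative refractive index ``nr``
    (Stern's integral in the closed form used by plate-model leaf optics).
    """
    theta = np.deg2rad(theta_deg)
    nr = np.asarray(nr, dtype=float)
    if theta_deg == 0:
        return 4.0 * nr / (nr + 1.0) ** 2

    n2 = nr * nr
    npx = n2 + 1.0
    nm = n2 - 1.0
    a = (nr + 1.0) ** 2 / 2.0
    k = -((n2 - 1.0) ** 2) / 4.0
    sin2 = np.sin(theta) ** 2

    if np.isclose(theta_deg, 90.0):
        b1 = np.zeros_like(nr)
    else:
        b1 = np.sqrt((sin2 - npx / 2.0) ** 2 + k)
    b2 = sin2 - npx / 2.0
    b = b1 - b2

    ts = (k ** 2 / (6.0 * b ** 3) + k / b - b / 2.0) - (
        k ** 2 / (6.0 * a ** 3) + k / a - a / 2.0
    )
    tp1 = -2.0 * n2 * (b - a) / npx ** 2
    tp2 = -2.0 * n2 * npx * np.log(b / a) / nm ** 2
    tp3 = n2 * (1.0 / b - 1.0 / a) / 2.0
    tp4 = (
        16.0 * n2 ** 2 * (n2 ** 2 + 1.0)
        * np.log((2.0 * npx * b - nm ** 2) / (2.0 * npx * a - nm ** 2))
        / (npx ** 3 * nm ** 2)
    )
    tp5 = (
        16.0 * n2 ** 3
        * (1.0 / (2.0 * npx * b - nm ** 2) - 1.0 / (2.0 * npx * a - nm ** 2))
        / npx ** 3
    )
    tp = tp1 + tp2 + tp3 + tp4 + tp5
    return (ts + tp) / (2.0 * sin2)


def _layer_transmissivity(k: np.ndarray) -> np.ndarray:
    """Isotropic transmissivity of one elementary layer of optical depth k."""
    tau = np.ones_like(k)
    pos = k > 0
    kp = k[pos]
    tau[pos] = (1.0 - kp) * np.exp(-kp) + kp ** 2 * exp1(kp)
    return np.clip(tau, 0.0, 1.0)


def prospect_batch(
    Ns: np.ndarray,
    Cab: np.ndarray,
    Car: np.ndarray,
    Cant: np.ndarray,
    Cbrown: np.ndarray,
    Cw: np.ndarray,
    Cm: np.ndarray,
    coeffs: SpectralCoefficients | None = None,
    wl_idx: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised PROSPECT-D over ``n`` leaves.

    All parameter arrays are broadcast to a common shape ``(n,)``; returns
    ``(reflectance, transmittance)`` arrays of shape ``(n, 2101)``, or
    ``(n, len(wl_idx))`` when ``wl_idx`` restricts the wavelength grid.
    """
    if coeffs is None:
        coeffs = synthetic_prospect_coefficients()
    if wl_idx is not None:
        coeffs = SpectralCoefficients(
            **{
                name: getattr(coeffs, name)[wl_idx]
                for name in ("nr", "kab", "kcar", "kant", "kbrown", "kw", "km")
            }
        )
    Ns, Cab, Car, Cant, Cbrown, Cw, Cm = np.broadcast_arrays(
        *(np.atleast_1d(np.asarray(a, dtype=float))
          for a in (Ns, Cab, Car, Cant, Cbrown, Cw, Cm))
    )
    n = Ns.shape[0]
    Nsc = Ns[:, None]

    # Optical depth of one elementary layer.
    k = (
        Cab[:, None] * coeffs.kab
        + Car[:, None] * coeffs.kcar
        + Cant[:, None] * coeffs.kant
        + Cbrown[:, None] * coeffs.kbrown
        + Cw[:, None] * coeffs.kw
        + Cm[:, None] * coeffs.km
    ) / Nsc
    tau = _layer_transmissivity(k)

    nr = coeffs.nr
    talf = np.broadcast_to(tav(40.0, nr), (n, nr.size))
    ralf = 1.0 - talf
    t12 = np.broadcast_to(tav(90.0, nr), (n, nr.size))
    r12 = 1.0 - t12
    t21 = t12 / nr ** 2
    r21 = 1.0 - t21

    # Top surface side (oblique illumination through a 40 deg cone).
    denom = 1.0 - r21 ** 2 * tau ** 2
    Ta = talf * tau * t21 / denom
    Ra = ralf + r21 * tau * Ta
    # Interior plates see diffuse light.
    t = t12 * tau * t21 / denom
    r = r12 + r21 * tau * t

    # Stokes pile of Ns - 1 identical diffuse layers.
    with np.errstate(divide="ignore", invalid="ignore"):
        D = np.sqrt(
            np.maximum((1.0 + r + t) * (1.0 + r - t), 0.0)
            * np.maximum((1.0 - r + t) * (1.0 - r - t), 0.0)
        )
        rq = r ** 2
        tq = t ** 2
        a = (1.0 + rq - tq + D) / (2.0 * r)
        b = (1.0 - rq + tq + D) / (2.0 * t)
        bNm1 = b ** (Nsc - 1.0)
        bN2 = bNm1 ** 2
        a2 = a ** 2
        denom2 = a2 * bN2 - 1.0
        Rsub = a * (bN2 - 1.0) / denom2
        Tsub = bNm1 * (a2 - 1.0) / denom2

    # Degenerate (conservative or opaque) layers: limit of the Stokes system.
    bad = (r + t >= 1.0) | ~np.isfinite(Rsub) | ~np.isfinite(Tsub)
    if np.any(bad):
        Tsub_lim = np.where(
            t + (1.0 - t) * (Nsc - 1.0) > 0,
            t / np.maximum(t + (1.0 - t) * (Nsc - 1.0), 1e-300),
            0.0,
        )
        Tsub = np.where(bad, Tsub_lim, Tsub)
        Rsub = np.where(bad, 1.0 - Tsub_lim, Rsub)

    denom3 = 1.0 - Rsub * r
    tran = Ta * Tsub / denom3
    refl = Ra + Ta * Rsub * t / denom3
    return np.clip(refl, 0.0, 1.0), np.clip(tran, 0.0, 1.0)


def prospect_d(leaf: LeafParams, coeffs: SpectralCoefficients | None = None) -> LeafOptics:
    """Leaf directional-hemispherical reflectance and transmittance.

    Parameters
    ----------
    leaf : LeafParams
        Validated leaf constituents (validation happens at construction).
    coeffs : SpectralCoefficients, optional
        Coefficient library override; defaults to the bundled synthetic one.
    """
    refl, tran = prospect_batch(
        leaf.Ns, leaf.Cab, leaf.Car, leaf.Cant, leaf.Cbrown, leaf.Cw, leaf.Cm,
        coeffs=coeffs,
    )
    return LeafOptics(reflectance=refl[0], transmittance=tran[0])
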