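"""4SAIL canopy bidirectional reflectance model and the PROSAIL-D composition.

4SAIL treats the canopy as a horizontally homogeneous turbid medium of
absorbing/scattering leaf elements above a Lambertian soil, and solves the
four-stream (direct solar, upward/downward diffuse, radiance in the view
direction) system analytically.  Leaf inclination follows the ellipsoidal
distribution parameterised by its mean inclination angle, discretised on 18
five-degree zenith bins.  The hot-spot correction uses the standard
20-node exponential-kernel integral.

The batch core is vectorised over canopy realisations: leaf optics of shape
``(n, 2101)`` plus per-row scalars give an ``(n, 2101)`` reflectance block.

The simulated observation is the directional reflectance factor for the
actual mixture of direct sun and diffuse sky illumination:
``R = skyl * rdot + (1 - skyl) * rsot`` where ``rsot`` is the bidirectional
(sun -> view) term and ``rdot`` the hemispherical-directional term.  The
direct/diffuse irradiance ratio is taken spectrally flat, so ``skyl`` enters
as a plain mixing weight.
"""

from __future__ import annotations

import numpy as np

from .spectra import (
    CanopyParams,
    LeafOptics,
    ViewGeometry,
    as_spectrum,
)

__all__ = [
    "compute_skyl",
    "foursail",
    "simulate_canopy_reflectance",
    "sail_batch",
    "ellipsoidal_lidf",
]

_N_LIDF_BINS = 18
_LIDF_CENTERS_DEG = (np.arange(_N_LIDF_BINS) + 0.5) * (90.0 / _N_LIDF_BINS)


def compute_skyl(sza: float | np.ndarray) -> float | np.ndarray:
    """Diffuse illumination fraction as a function of solar zenith angle.

    Empirical clear-sky relation used by the standard canopy-model driver,
    evaluated on the solar elevation angle and clamped to [0, 1]:
    ``skyl = 0.847 - 1.61 sin(h) + 1.04 sin^2(h)`` with ``h = 90 - SZA``.
    """
    sza_arr = np.asarray(sza, dtype=float)
    if np.any(sza_arr < 0) or np.any(sza_arr >= 90):
        raise ValueError("SZA must lie in [0, 90) degrees")
    sh = np.sin(np.deg2rad(90.0 - sza_arr))
    skyl = 0.847 - 1.61 * sh + 1.04 * sh * sh
    skyl = np.clip(skyl, 0.0, 1.0)
    return float(skyl) if np.isscalar(sza) else skyl


def ellipsoidal_lidf(ala_deg: np.ndarray) -> np.ndarray:
    """Ellipsoidal leaf inclination distribution on 18 five-degree bins.

    ``ala_deg`` has shape ``(n,)``; returns bin frequencies ``(n, 18)``
    summing to 1 per row.  Uses Campbell's eccentricity parameterisation of
    the ellipsoid by the mean inclination angle.
    """
    ala = np.atleast_1d(np.asarray(ala_deg, dtype=float))
    excent = np.exp(
        -1.6184e-5 * ala ** 3 + 2.1145e-3 * ala ** 2 - 1.2390e-1 * ala + 3.2491
    )
    n = ala.shape[0]
    edges = np.deg2rad(np.arange(_N_LIDF_BINS + 1) * (90.0 / _N_LIDF_BINS))
    tl1 = edges[:-1][None, :]
    tl2 = edges[1:][None, :]
    e = excent[:, None]

    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        x1 = e / np.sqrt(1.0 + e ** 2 * np.tan(tl1) ** 2)
        x2 = e / np.sqrt(1.0 + e ** 2 * np.tan(tl2) ** 2)
        alph = e / np.sqrt(np.abs(1.0 - e ** 2))
        alph2 = alph ** 2
        x12 = x1 ** 2
        x22 = x2 ** 2
        # prolate branch (excent > 1)
        alpx1 = np.sqrt(alph2 + x12)
        alpx2 = np.sqrt(alph2 + x22)
        dum_p = x1 * alpx1 + alph2 * np.log(x1 + alpx1)
        freq_p = np.abs(dum_p - (x2 * alpx2 + alph2 * np.log(x2 + alpx2)))
        # oblate branch (excent < 1)
        almx1 = np.sqrt(np.maximum(alph2 - x12, 0.0))
        almx2 = np.sqrt(np.maximum(alph2 - x22, 0.0))
        dum_o = x1 * almx1 + alph2 * np.arcsin(np.clip(x1 / alph, -1.0, 1.0))
        freq_o = np.abs(dum_o - (x2 * almx2 + alph2 * np.arcsin(np.clip(x2 / alph, -1.0, 1.0))))

    freq_s = np.abs(np.cos(tl1) - np.cos(tl2)) * np.ones((n, 1))
    spherical = np.abs(excent - 1.0) < 1e-6
    freq = np.where(
        spherical[:, None], freq_s, np.where(e > 1.0, freq_p, freq_o)
    )
    return freq / freq.sum(axis=1, keepdims=True)


def _volscatt(tts: np.ndarray, tto: np.ndarray, psi: np.ndarray):
    """Geometric scattering factors per (row, leaf-inclination-bin).

    Returns ``chi_s, chi_o, frho, ftau`` of shape ``(n, 18)``: the direct
    and view-direction extinction cross-sections and the bidirectional
    volume-scattering functions of a leaf slope bin.
    """
    tts = tts[:, None]
    tto = tto[:, None]
    psi = np.abs(psi)[:, None]
    ttl = np.deg2rad(_LIDF_CENTERS_DEG)[None, :]

    cts = np.cos(np.deg2rad(tts))
    cto = np.cos(np.deg2rad(tto))
    sts = np.sin(np.deg2rad(tts))
    sto = np.sin(np.deg2rad(tto))
    cospsi = np.cos(np.deg2rad(psi))
    psir = np.deg2rad(psi)
    cttl = np.cos(ttl)
    sttl = np.sin(ttl)

    cs = cttl * cts
    co = cttl * cto
    ss = sttl * sts
    so = sttl * sto

    with np.errstate(divide="ignore", invalid="ignore"):
        cosbts = np.where(np.abs(ss) > 1e-6, -cs / np.where(ss == 0, 1.0, ss), 5.0)
        cosbto = np.where(np.abs(so) > 1e-6, -co / np.where(so == 0, 1.0, so), 5.0)

    bts = np.where(np.abs(cosbts) < 1.0, np.arccos(np.clip(cosbts, -1, 1)), np.pi)
    ds = np.where(np.abs(cosbts) < 1.0, ss, cs)
    chi_s = 2.0 / np.pi * ((bts - np.pi / 2.0) * cs + np.sin(bts) * ss)

    # view zenith is < 90 degrees throughout this package
    bto = np.where(np.abs(cosbto) < 1.0, np.arccos(np.clip(cosbto, -1, 1)), np.pi)
    do_ = np.where(np.abs(cosbto) < 1.0, so, co)
    chi_o = 2.0 / np.pi * ((bto - np.pi / 2.0) * co + np.sin(bto) * so)

    btran1 = np.abs(bts - bto)
    btran2 = 2.0 * np.pi - bts - bto

    psir_b = np.broadcast_to(psir, bts.shape)
    c1 = psir_b <= btran1
    c2 = psir_b <= btran2
    bt1 = np.where(c1, psir_b, btran1)
    bt2 = np.where(c1, btran1, np.where(c2, psir_b, btran2))
    bt3 = np.where(c1, btran2, np.where(c2, btran2, psir_b))

    t1 = 2.0 * cs * co + ss * so * cospsi
    t2 = np.where(
        bt2 > 0.0,
        np.sin(bt2) * (2.0 * ds * do_ + ss * so * np.cos(bt1) * np.cos(bt3)),
        0.0,
    )
    denom = 2.0 * np.pi ** 2
    frho = np.maximum(((np.pi - bt2) * t1 + t2) / denom, 0.0)
    ftau = np.maximum((-bt2 * t1 + t2) / denom, 0.0)
    return chi_s, chi_o, frho, ftau


def _jfunc1(k, l, t):
    """J1(k, l, t) = (exp(-l t) - exp(-k t)) / (k - l), series-guarded."""
    delta = (k - l) * t
    safe = np.abs(delta) > 1e-3
    kl = np.where(safe, k - l, 1.0)
    j_exact = (np.exp(-l * t) - np.exp(-k * t)) / kl
    j_series = 0.5 * t * (np.exp(-k * t) + np.exp(-l * t)) * (1.0 - delta * delta / 12.0)
    return np.where(safe, j_exact, j_series)


def _jfunc2(k, l, t):
    """J2(k, l, t) = (1 - exp(-(k + l) t)) / (k + l)."""
    return (1.0 - np.exp(-(k + l) * t)) / (k + l)


def _hotspot_sumint(alf, ks, ko, lai):
    """Hot-spot corrected path-overlap integral (20-node exponential kernel).

    Returns ``(tsstoo, sumint)`` for rows with a finite, positive hot-spot
    kernel parameter ``alf``.
    """
    fhot = lai * np.sqrt(ko * ks)
    x1 = np.zeros_like(alf)
    y1 = np.zeros_like(alf)
    f1 = np.ones_like(alf)
    fint = (1.0 - np.exp(-alf)) * 0.05
    sumint = np.zeros_like(alf)
    for istep in range(1, 21):
        if istep < 20:
            x2 = -np.log(1.0 - istep * fint) / alf
        else:
            x2 = np.ones_like(alf)
        y2 = -(ko + ks) * lai * x2 + fhot * (1.0 - np.exp(-alf * x2)) / alf
        f2 = np.exp(y2)
        with np.errstate(divide="ignore", invalid="ignore"):
            inc = (f2 - f1) * (x2 - x1) / (y2 - y1)
        sumint = sumint + np.where(np.isfinite(inc), inc, 0.0)
        x1, y1, f1 = x2, y2, f2
    return f1, sumint


def sail_batch(
    rho: np.ndarray,
    tau: np.ndarray,
    lai: np.ndarray,
    ala: np.ndarray,
    hspot: np.ndarray,
    tts: np.ndarray,
    tto: np.ndarray,
    psi: np.ndarray,
    rsoil: np.ndarray,
    skyl: np.ndarray,
) -> np.ndarray:
    """Vectorised 4SAIL over ``n`` canopy realisations.

    Parameters
    ----------
    rho, tau : ndarray, shape (n, w)
        Leaf reflectance and transmittance spectra.
    lai, ala, hspot, tts, tto, psi, skyl : ndarray, shape (n,)
        Canopy structure and geometry per row (angles in degrees).
    rsoil : ndarray, shape (w,) or (n, w)
        Lambertian soil background reflectance.

    Returns
    -------
    ndarray, shape (n, w)
        Directional canopy reflectance factor mixing the bidirectional and
        hemispherical-directional terms by the diffuse fraction ``skyl``.
    """
    rho = np.atleast_2d(np.asarray(rho, dtype=float))
    tau = np.atleast_2d(np.asarray(tau, dtype=float))
    n, w = rho.shape
    lai, ala, hspot, tts, tto, psi, skyl = (
        np.broadcast_to(np.atleast_1d(np.asarray(a, dtype=float)), (n,)).copy()
        for a in (lai, ala, hspot, tts, tto, psi, skyl)
    )
    rsoil = np.asarray(rsoil, dtype=float)
    if rsoil.ndim == 1:
        rsoil = np.broadcast_to(rsoil, (n, w))

    out = np.empty((n, w), dtype=float)

    # Bare-soil limit: no canopy, the observation is the soil itself.
    bare = lai <= 0.0
    if np.any(bare):
        out[bare] = rsoil[bare]
    veg = ~bare
    if not np.any(veg):
        return out

    rho_v = rho[veg]
    tau_v = tau[veg]
    lai_v = lai[veg][:, None]
    rs = rsoil[veg]
    skyl_v = skyl[veg][:, None]
    tts_v = tts[veg]
    tto_v = tto[veg]
    psi_v = psi[veg]
    hspot_v = hspot[veg]

    lidf = ellipsoidal_lidf(ala[veg])
    chi_s, chi_o, frho, ftau = _volscatt(tts_v, tto_v, psi_v)

    cts = np.cos(np.deg2rad(tts_v))[:, None]
    cto = np.cos(np.deg2rad(tto_v))[:, None]
    ctscto = cts * cto
    cttl2 = np.cos(np.deg2rad(_LIDF_CENTERS_DEG))[None, :] ** 2

    ks = np.sum(chi_s / cts * lidf, axis=1)[:, None]
    ko = np.sum(chi_o / cto * lidf, axis=1)[:, None]
    bf = np.sum(cttl2 * lidf, axis=1)[:, None]
    sob = np.sum(frho * np.pi / ctscto * lidf, axis=1)[:, None]
    sof = np.sum(ftau * np.pi / ctscto * lidf, axis=1)[:, None]

    sdb = 0.5 * (ks + bf)
    sdf = 0.5 * (ks - bf)
    dob = 0.5 * (ko + bf)
    dof = 0.5 * (ko - bf)
    ddb = 0.5 * (1.0 + bf)
    ddf = 0.5 * (1.0 - bf)

    sigb = ddb * rho_v + ddf * tau_v
    sigf = ddf * rho_v + ddb * tau_v
    att = 1.0 - sigf
    m2 = np.maximum((att + sigb) * (att - sigb), 0.0)
    m = np.sqrt(m2)
    sb = sdb * rho_v + sdf * tau_v
    sf = sdf * rho_v + sdb * tau_v
    vb = dob * rho_v + dof * tau_v
    vf = dof * rho_v + dob * tau_v
    wsc = sob * rho_v + sof * tau_v

    e1 = np.exp(-m * lai_v)
    e2 = e1 ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        rinf = np.where(sigb > 0, (att - m) / np.where(sigb == 0, 1.0, sigb), 0.0)
    rinf2 = rinf ** 2
    re = rinf * e1
    denom = np.maximum(1.0 - rinf2 * e2, 1e-12)

    J1ks = _jfunc1(ks, m, lai_v)
    J2ks = _jfunc2(ks, m, lai_v)
    J1ko = _jfunc1(ko, m, lai_v)
    J2ko = _jfunc2(ko, m, lai_v)

    Ps = (sf + sb * rinf) * J1ks
    Qs = (sf * rinf + sb) * J2ks
    Pv = (vf + vb * rinf) * J1ko
    Qv = (vf * rinf + vb) * J2ko

    tdd = (1.0 - rinf2) * e1 / denom
    rdd = rinf * (1.0 - e2) / denom
    tsd = (Ps - re * Qs) / denom
    rsd = (Qs - re * Ps) / denom
    tdo = (Pv - re * Qv) / denom
    rdo = (Qv - re * Pv) / denom

    tss = np.exp(-ks * lai_v)
    too = np.exp(-ko * lai_v)

    z = _jfunc2(ks, ko, lai_v)
    g1 = (z - J1ks * too) / (ko + m)
    g2 = (z - J1ko * tss) / (ks + m)
    Tv1 = (vf * rinf + vb) * g1
    Tv2 = (vf + vb * rinf) * g2
    T1 = Tv1 * (sf + sb * rinf)
    T2 = Tv2 * (sf * rinf + sb)
    T3 = (rdo * Qs + tdo * Ps) * rinf
    rsod = (T1 + T2 - T3) / np.maximum(1.0 - rinf2, 1e-12)

    # Hot spot: path-overlap between sun and view directions.
    tan_s = np.tan(np.deg2rad(tts_v))
    tan_o = np.tan(np.deg2rad(tto_v))
    dso = np.sqrt(
        np.maximum(
            tan_s ** 2 + tan_o ** 2 - 2.0 * tan_s * tan_o * np.cos(np.deg2rad(np.abs(psi_v))),
            0.0,
        )
    )[:, None]

    ks1 = ks[:, :1]
    ko1 = ko[:, :1]
    lai1 = lai_v[:, :1]
    hs = hspot_v[:, None]
    tsstoo = tss[:, :1] * too[:, :1]
    sumint = _jfunc2(ks1, ko1, lai1) / lai1

    hot = (hs[:, 0] > 0)
    if np.any(hot):
        alf = (dso[hot] / hs[hot]) * 2.0 / (ks1[hot] + ko1[hot])
        pure = alf[:, 0] <= 1e-12  # exact sun/view alignment
        tsstoo_h = np.empty_like(alf)
        sumint_h = np.empty_like(alf)
        if np.any(pure):
            tsstoo_h[pure] = tss[hot][pure][:, :1]
            sumint_h[pure] = (1.0 - tss[hot][pure][:, :1]) / (
                ks1[hot][pure] * lai1[hot][pure]
            )
        rest = ~pure
        if np.any(rest):
            f1, s = _hotspot_sumint(
                alf[rest], ks1[hot][rest], ko1[hot][rest], lai1[hot][rest]
            )
            tsstoo_h[rest] = f1
            sumint_h[rest] = s
        tsstoo[hot] = tsstoo_h
        sumint[hot] = sumint_h

    rsos = wsc * lai_v * sumint

    dn = np.maximum(1.0 - rs * rdd, 1e-12)
    rddt = rdd + tdd * rs * tdd / dn
    rdot = rdo + tdd * rs * (tdo + too) / dn
    rsodt = rsod + ((tss + tsd) * tdo + (tsd + tss * rs * rdd) * too) * rs / dn
    rsost = rsos + tsstoo * rs
    rsot = rsost + rsodt
    _ = rddt  # hemispherical-hemispherical term, computed for completeness

    out[veg] = np.clip(skyl_v * rdot + (1.0 - skyl_v) * rsot, 0.0, 1.0)
    return out


def foursail(
    optics: LeafOptics,
    canopy: CanopyParams,
    geom: ViewGeometry,
    soil: np.ndarray,
) -> np.ndarray:
    """Canopy directional reflectance for a single parameter combination.

    The hot-spot parameter is used exactly as supplied; see
    :func:`simulate_canopy_reflectance` for the convention that zeroes it
    away from the sun-view alignment.  ``geom.skyl`` defaults to
    :func:`compute_skyl` of the solar zenith angle when unset.
    """
    soil = as_spectrum(soil, "soil")
    skyl = geom.skyl if geom.skyl is not None else compute_skyl(geom.SZA)
    out = sail_batch(
        optics.reflectance[None, :],
        optics.transmittance[None, :],
        np.array([canopy.LAI]),
        np.array([canopy.ALA]),
        np.array([canopy.hspot]),
        np.array([geom.SZA]),
        np.array([geom.VZA]),
        np.array([geom.RAA]),
        soil,
        np.array([skyl]),
    )
    return out[0]


def simulate_canopy_reflectance(
    leaf,
    canopy: CanopyParams,
    geom: ViewGeometry,
    soil: np.ndarray,
    coeffs=None,
) -> np.ndarray:
    """Full PROSAIL-D forward simulation for one parameter combination.

    Composes the leaf optical model with 4SAIL.  The hot-spot effect only
    occurs when the view and sun directions coincide; following that
    convention the supplied ``hspot`` is used only when ``VZA == SZA`` and
    is reset to 0 otherwise.
    """
    from .prospect import prospect_d

    optics = prospect_d(leaf, coeffs=coeffs)
    hspot_eff = canopy.hspot if geom.VZA == geom.SZA else 0.0
    eff_canopy = CanopyParams(LAI=canopy.LAI, ALA=canopy.ALA, hspot=hspot_eff)
    return foursail(optics, eff_canopy, geom, soil)
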