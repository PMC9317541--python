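"""Independent scalar transcription of the leaf/canopy radiative transfer models.

A deliberately plain, loop-per-wavelength implementation of the plate-model
leaf optics and the four-stream canopy model, written directly from the
published algorithm descriptions and kept free of the package's vectorised
code paths.  It shares only the coefficient data and the wavelength grid
with the package, and serves as the oracle for the reference-equivalence
tests: agreement between this transcription and the production code checks
the vectorisation, broadcasting and masking logic.

Not optimised on purpose; use small panels.
"""

from __future__ import annotations

import math

from scipy.special import exp1

from wheatlai.library import synthetic_prospect_coefficients
from wheatlai.spectra import N_WAVELENGTHS


def ref_tav(theta_deg: float, n: float) -> float:
    theta = math.radians(theta_deg)
    if theta_deg == 0:
        return 4.0 * n / (n + 1.0) ** 2
    n2 = n * n
    npx = n2 + 1.0
    nm = n2 - 1.0
    a = (n + 1.0) ** 2 / 2.0
    k = -((n2 - 1.0) ** 2) / 4.0
    sin2 = math.sin(theta) ** 2
    b1 = 0.0 if abs(theta_deg - 90.0) < 1e-12 else math.sqrt((sin2 - npx / 2.0) ** 2 + k)
    b2 = sin2 - npx / 2.0
    b = b1 - b2
    ts = (k * k / (6.0 * b ** 3) + k / b - b / 2.0) - (
        k * k / (6.0 * a ** 3) + k / a - a / 2.0
    )
    tp = (
        -2.0 * n2 * (b - a) / npx ** 2
        - 2.0 * n2 * npx * math.log(b / a) / nm ** 2
        + n2 * (1.0 / b - 1.0 / a) / 2.0
        + 16.0 * n2 ** 2 * (n2 ** 2 + 1.0)
        * math.log((2.0 * npx * b - nm ** 2) / (2.0 * npx * a - nm ** 2))
        / (npx ** 3 * nm ** 2)
        + 16.0 * n2 ** 3
        * (1.0 / (2.0 * npx * b - nm ** 2) - 1.0 / (2.0 * npx * a - nm ** 2))
        / npx ** 3
    )
    return (ts + tp) / (2.0 * sin2)


def ref_prospect(Ns, Cab, Car, Cant, Cbrown, Cw, Cm):
    """Scalar plate-model leaf optics; returns (refl, tran) python lists."""
    c = synthetic_prospect_coefficients()
    refl = [0.0] * N_WAVELENGTHS
    tran = [0.0] * N_WAVELENGTHS
    for i in range(N_WAVELENGTHS):
        k = (
            Cab * c.kab[i] + Car * c.kcar[i] + Cant * c.kant[i]
            + Cbrown * c.kbrown[i] + Cw * c.kw[i] + Cm * c.km[i]
        ) / Ns
        if k <= 0:
            tau = 1.0
        else:
            tau = (1.0 - k) * math.exp(-k) + k * k * float(exp1(k))
        tau = min(max(tau, 0.0), 1.0)
        n = float(c.nr[i])
        talf = ref_tav(40.0, n)
        ralf = 1.0 - talf
        t12 = ref_tav(90.0, n)
        r12 = 1.0 - t12
        t21 = t12 / (n * n)
        r21 = 1.0 - t21
        denom = 1.0 - r21 * r21 * tau * tau
        Ta = talf * tau * t21 / denom
        Ra = ralf + r21 * tau * Ta
        t = t12 * tau * t21 / denom
        r = r12 + r21 * tau * t
        if r + t >= 1.0:
            Tsub = t / (t + (1.0 - t) * (Ns - 1.0))
            Rsub = 1.0 - Tsub
        else:
            D = math.sqrt(
                (1.0 + r + t) * (1.0 + r - t) * (1.0 - r + t) * (1.0 - r - t)
            )
            rq = r * r
            tq = t * t
            a = (1.0 + rq - tq + D) / (2.0 * r)
            b = (1.0 - rq + tq + D) / (2.0 * t)
            bNm1 = b ** (Ns - 1.0)
            bN2 = bNm1 * bNm1
            a2 = a * a
            denom2 = a2 * bN2 - 1.0
            Rsub = a * (bN2 - 1.0) / denom2
            Tsub = bNm1 * (a2 - 1.0) / denom2
        denom3 = 1.0 - Rsub * r
        tran[i] = Ta * Tsub / denom3
        refl[i] = Ra + Ta * Rsub * t / denom3
    return refl, tran


def ref_campbell_lidf(ala: float, n_bins: int = 18):
    excent = math.exp(
        -1.6184e-5 * ala ** 3 + 2.1145e-3 * ala ** 2 - 1.2390e-1 * ala + 3.2491
    )
    freq = []
    for i in range(n_bins):
        tl1 = math.radians(i * 90.0 / n_bins)
        tl2 = math.radians((i + 1) * 90.0 / n_bins)
        x1 = excent / math.sqrt(1.0 + excent ** 2 * math.tan(tl1) ** 2)
        x2 = excent / math.sqrt(1.0 + excent ** 2 * math.tan(tl2) ** 2)
        if abs(excent - 1.0) < 1e-6:
            freq.append(abs(math.cos(tl1) - math.cos(tl2)))
        else:
            alph = excent / math.sqrt(abs(1.0 - excent ** 2))
            alph2 = alph * alph
            if excent > 1.0:
                alpx1 = math.sqrt(alph2 + x1 * x1)
                alpx2 = math.sqrt(alph2 + x2 * x2)
                dum = x1 * alpx1 + alph2 * math.log(x1 + alpx1)
                freq.append(abs(dum - (x2 * alpx2 + alph2 * math.log(x2 + alpx2))))
            else:
                almx1 = math.sqrt(alph2 - x1 * x1)
                almx2 = math.sqrt(alph2 - x2 * x2)
                dum = x1 * almx1 + alph2 * math.asin(x1 / alph)
                freq.append(abs(dum - (x2 * almx2 + alph2 * math.asin(x2 / alph))))
    total = sum(freq)
    return [f / total for f in freq]


def _ref_volscatt(tts, tto, psi, ttl):
    cts = math.cos(math.radians(tts))
    cto = math.cos(math.radians(tto))
    sts = math.sin(math.radians(tts))
    sto = math.sin(math.radians(tto))
    cospsi = math.cos(math.radians(psi))
    psir = math.radians(psi)
    cttl = math.cos(math.radians(ttl))
    sttl = math.sin(math.radians(ttl))
    cs = cttl * cts
    co = cttl * cto
    ss = sttl * sts
    so = sttl * sto
    cosbts = -cs / ss if abs(ss) > 1e-6 else 5.0
    cosbto = -co / so if abs(so) > 1e-6 else 5.0
    if abs(cosbts) < 1.0:
        bts = math.acos(cosbts)
        ds = ss
    else:
        bts = math.pi
        ds = cs
    chi_s = 2.0 / math.pi * ((bts - math.pi / 2.0) * cs + math.sin(bts) * ss)
    if abs(cosbto) < 1.0:
        bto = math.acos(cosbto)
        do_ = so
    else:
        bto = math.pi
        do_ = co
    chi_o = 2.0 / math.pi * ((bto - math.pi / 2.0) * co + math.sin(bto) * so)
    btran1 = abs(bts - bto)
    btran2 = 2.0 * math.pi - bts - bto
    if psir <= btran1:
        bt1, bt2, bt3 = psir, btran1, btran2
    elif psir <= btran2:
        bt1, bt2, bt3 = btran1, psir, btran2
    else:
        bt1, bt2, bt3 = btran1, btran2, psir
    t1 = 2.0 * cs * co + ss * so * cospsi
    t2 = 0.0
    if bt2 > 0.0:
        t2 = math.sin(bt2) * (2.0 * ds * do_ + ss * so * math.cos(bt1) * math.cos(bt3))
    denom = 2.0 * math.pi ** 2
    frho = max(((math.pi - bt2) * t1 + t2) / denom, 0.0)
    ftau = max((-bt2 * t1 + t2) / denom, 0.0)
    return chi_s, chi_o, frho, ftau


def _j1(k, l, t):
    if abs((k - l) * t) > 1e-3:
        return (math.exp(-l * t) - math.exp(-k * t)) / (k - l)
    return 0.5 * t * (math.exp(-k * t) + math.exp(-l * t)) * (
        1.0 - ((k - l) * t) ** 2 / 12.0
    )


def _j2(k, l, t):
    return (1.0 - math.exp(-(k + l) * t)) / (k + l)


def ref_sail(refl_leaf, tran_leaf, lai, ala, hspot, tts, tto, psi, rsoil, skyl):
    """Scalar four-stream canopy reflectance; leaf optics and soil are lists."""
    if lai <= 0:
        return list(rsoil)
    psi = abs(psi)
    lidf = ref_campbell_lidf(ala)
    cts = math.cos(math.radians(tts))
    cto = math.cos(math.radians(tto))
    ks = ko = bf = sob = sof = 0.0
    for i, f in enumerate(lidf):
        ttl = (i + 0.5) * 5.0
        chi_s, chi_o, frho, ftau = _ref_volscatt(tts, tto, psi, ttl)
        ks += chi_s / cts * f
        ko += chi_o / cto * f
        bf += math.cos(math.radians(ttl)) ** 2 * f
        sob += frho * math.pi / (cts * cto) * f
        sof += ftau * math.pi / (cts * cto) * f
    sdb = 0.5 * (ks + bf)
    sdf = 0.5 * (ks - bf)
    dob = 0.5 * (ko + bf)
    dof = 0.5 * (ko - bf)
    ddb = 0.5 * (1.0 + bf)
    ddf = 0.5 * (1.0 - bf)
    tss = math.exp(-ks * lai)
    too = math.exp(-ko * lai)

    # hot-spot overlap integral, shared across wavelengths
    tan_s = math.tan(math.radians(tts))
    tan_o = math.tan(math.radians(tto))
    dso = math.sqrt(
        max(tan_s ** 2 + tan_o ** 2 - 2.0 * tan_s * tan_o * math.cos(math.radians(psi)), 0.0)
    )
    if hspot > 0:
        alf = (dso / hspot) * 2.0 / (ks + ko)
        if alf <= 1e-12:
            tsstoo = tss
            sumint = (1.0 - tss) / (ks * lai)
        else:
            fhot = lai * math.sqrt(ko * ks)
            x1 = y1 = 0.0
            f1 = 1.0
            fint = (1.0 - math.exp(-alf)) * 0.05
            sumint = 0.0
            for istep in range(1, 21):
                x2 = 1.0 if istep == 20 else -math.log(1.0 - istep * fint) / alf
                y2 = -(ko + ks) * lai * x2 + fhot * (1.0 - math.exp(-alf * x2)) / alf
                f2 = math.exp(y2)
                if y2 != y1:
                    sumint += (f2 - f1) * (x2 - x1) / (y2 - y1)
                x1, y1, f1 = x2, y2, f2
            tsstoo = f1
    else:
        tsstoo = tss * too
        sumint = _j2(ks, ko, lai) / lai

    out = []
    for i in range(len(refl_leaf)):
        rho = refl_leaf[i]
        tau = tran_leaf[i]
        rs = rsoil[i]
        sigb = ddb * rho + ddf * tau
        sigf = ddf * rho + ddb * tau
        att = 1.0 - sigf
        m = math.sqrt(max((att + sigb) * (att - sigb), 0.0))
        sb = sdb * rho + sdf * tau
        sf = sdf * rho + sdb * tau
        vb = dob * rho + dof * tau
        vf = dof * rho + dob * tau
        w = sob * rho + sof * tau
        e1 = math.exp(-m * lai)
        e2 = e1 * e1
        rinf = (att - m) / sigb if sigb > 0 else 0.0
        rinf2 = rinf * rinf
        re = rinf * e1
        denom = max(1.0 - rinf2 * e2, 1e-12)
        J1ks = _j1(ks, m, lai)
        J2ks = _j2(ks, m, lai)
        J1ko = _j1(ko, m, lai)
        J2ko = _j2(ko, m, lai)
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
        z = _j2(ks, ko, lai)
        g1 = (z - J1ks * too) / (ko + m)
        g2 = (z - J1ko * tss) / (ks + m)
        Tv1 = (vf * rinf + vb) * g1
        Tv2 = (vf + vb * rinf) * g2
        T1 = Tv1 * (sf + sb * rinf)
        T2 = Tv2 * (sf * rinf + sb)
        T3 = (rdo * Qs + tdo * Ps) * rinf
        rsod = (T1 + T2 - T3) / max(1.0 - rinf2, 1e-12)
        rsos = w * lai * sumint
        dn = max(1.0 - rs * rdd, 1e-12)
        rdot = rdo + tdd * rs * (tdo + too) / dn
        rsodt = rsod + ((tss + tsd) * tdo + (tsd + tss * rs * rdd) * too) * rs / dn
        rsost = rsos + tsstoo * rs
        rsot = rsost + rsodt
        out.append(min(max(skyl * rdot + (1.0 - skyl) * rsot, 0.0), 1.0))
    return out


def ref_prosail(Ns, Cab, Car, Cant, Cbrown, Cw, Cm, lai, ala, hspot,
                tts, tto, psi, rsoil, skyl):
    refl, tran = ref_prospect(Ns, Cab, Car, Cant, Cbrown, Cw, Cm)
    return ref_sail(refl, tran, lai, ala, hspot, tts, tto, psi, rsoil, skyl)
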