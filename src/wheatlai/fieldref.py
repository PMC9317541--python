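"""Ground-reference LAI methods: ceptometer light interception and quadrats.

The light-interception baseline inverts the Beer-Lambert law: measured
fIPAR = 1 - I_below / I_above gives LAI = -ln(1 - fIPAR) / K with wheat
extinction coefficient K = 0.65 by default.  Quadrat harvests give LAI, leaf
water content and leaf dry matter content from sub-sample leaf area and
weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CeptometerRecord",
    "QuadratSample",
    "fipar_from_par",
    "lai_from_fipar",
    "fit_k",
    "quadrat_traits",
    "DEFAULT_K",
]

#: Wheat canopy light extinction coefficient (meta-analysis consensus value).
DEFAULT_K = 0.65


@dataclass(frozen=True)
class CeptometerRecord:
    """Paired above- (I0) and below-canopy (Ii) PAR readings, replicated."""

    I0: np.ndarray
    Ii: np.ndarray

    def __post_init__(self) -> None:
        I0 = np.atleast_1d(np.asarray(self.I0, dtype=float))
        Ii = np.atleast_1d(np.asarray(self.Ii, dtype=float))
        if I0.shape != Ii.shape:
            raise ValueError("I0 and Ii must be paired")
        if np.any(I0 <= 0):
            raise ValueError("I0 readings must be > 0")
        if np.any(Ii < 0) or np.any(Ii > I0):
            raise ValueError("Ii readings must satisfy 0 <= Ii <= I0")
        object.__setattr__(self, "I0", I0)
        object.__setattr__(self, "Ii", Ii)


@dataclass(frozen=True)
class QuadratSample:
    """Sub-sample leaf area/weights and quadrat dry weight (cm^2 / g units)."""

    LA_sub: float   # sub-sample green leaf area, cm^2
    LFW_sub: float  # sub-sample green leaf fresh weight, g
    LDW_sub: float  # sub-sample green leaf dry weight, g
    DW_sub: float   # sub-sample dry weight, g
    DW_main: float  # quadrat-sample dry weight, g
    QA: float       # quadrat ground area, cm^2

    def __post_init__(self) -> None:
        for name in ("LA_sub", "LFW_sub", "LDW_sub", "DW_sub", "DW_main", "QA"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.LDW_sub > self.LFW_sub:
            raise ValueError("LDW_sub cannot exceed LFW_sub")
        if self.DW_sub > self.DW_main:
            raise ValueError("DW_sub cannot exceed DW_main")


def fipar_from_par(rec: CeptometerRecord) -> float:
    """Replicate-mean fraction of intercepted PAR, in [0, 1]."""
    return float(np.mean(1.0 - rec.Ii / rec.I0))


def lai_from_fipar(fipar: float, K: float = DEFAULT_K) -> float:
    """Beer-Lambert LAI = -ln(1 - fIPAR) / K (m^2 m^-2)."""
    if K <= 0:
        raise ValueError("K must be > 0")
    if not 0.0 <= fipar < 1.0:
        if fipar == 1.0:
            raise ValueError("saturated interception: fIPAR = 1 gives infinite LAI")
        raise ValueError(f"fIPAR={fipar} outside [0, 1)")
    return float(-np.log(1.0 - fipar) / K)


def fit_k(fipar, lai, nonlinear: bool = False) -> float:
    """Estimate the extinction coefficient K from paired (fIPAR, LAI) data.

    Default: least-squares slope through the origin of -ln(1 - fIPAR)
    regressed on LAI (the linearised Beer-Lambert relation), which is
    deterministic and exact on noiseless data.  ``nonlinear=True`` instead
    fits fIPAR = 1 - exp(-K LAI) directly by least squares.
    """
    fipar = np.asarray(fipar, dtype=float).reshape(-1)
    lai = np.asarray(lai, dtype=float).reshape(-1)
    if fipar.shape != lai.shape or fipar.size < 1:
        raise ValueError("fipar and lai must be paired and non-empty")
    if np.any(fipar >= 1.0) or np.any(fipar < 0.0):
        raise ValueError("all fIPAR values must lie in [0, 1)")
    if np.all(lai == 0):
        raise ValueError("degenerate data: all LAI values are 0")

    if nonlinear:
        from scipy.optimize import minimize_scalar

        def sse(k):
            return float(np.sum((1.0 - np.exp(-k * lai) - fipar) ** 2))

        res = minimize_scalar(sse, bounds=(1e-6, 10.0), method="bounded")
        return float(res.x)

    y = -np.log(1.0 - fipar)
    return float(np.sum(lai * y) / np.sum(lai * lai))


def quadrat_traits(s: QuadratSample) -> tuple[float, float, float]:
    """(LAI, Cw, Cm) from a quadrat sample.

    LAI = (LA_sub x DW_main) / (QA x DW_sub): the sub-sample specific leaf
    area scaled to the quadrat biomass, per unit ground area.  The cm^2/cm^2
    ratio is already the dimensionless m^2 m^-2 LAI - no unit conversion is
    applied.  Cw = (LFW_sub - LDW_sub)/LA_sub and Cm = LDW_sub/LA_sub are in
    g cm^-2.
    """
    lai = (s.LA_sub * s.DW_main) / (s.QA * s.DW_sub)
    cw = (s.LFW_sub - s.LDW_sub) / s.LA_sub
    cm = s.LDW_sub / s.LA_sub
    return float(lai), float(cw), float(cm)
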