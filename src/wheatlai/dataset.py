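"""Parameter-space sampling and synthetic training-set generation.

Three nested parameter sets (p1, p2, p3) define uniform sampling ranges for
the leaf, canopy and geometry inputs of the canopy radiative transfer model.
p1 spans the broad literature ranges for wheat; p2 narrows Cm, Cw and LAI to
field-observed ranges; p3 additionally caps LAI at 5 m^2 m^-2.  A dataset is
the row-aligned triple (parameter draws, simulated 5-band reflectance, known
LAI), fully determined by (set id, soil, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bands import (
    BAND_NAMES,
    default_micasense_bands,
    support_indices,
    _response_matrix,
)
from .prospect import prospect_batch
from .sail import compute_skyl, sail_batch
from .spectra import as_spectrum

__all__ = [
    "ParameterSpace",
    "SyntheticDataset",
    "parameter_space",
    "sample_parameters",
    "generate_dataset",
    "PARAMETER_COLUMNS",
]

PARAMETER_COLUMNS = (
    "Ns", "Cab", "Car", "Cant", "Cbrown", "Cm", "Cw",
    "ALA", "LAI", "hspot", "psoil", "SZA", "VZA", "RAA",
)

#: (min, max) ranges; a scalar denotes a fixed parameter.
_BASE_SPEC: dict[str, tuple[float, float] | float] = {
    "Ns": (1.0, 2.5),
    "Cab": (0.0, 90.0),
    "Car": (0.0, 20.0),
    "Cant": 0.0,
    "Cbrown": 0.0,
    "Cm": (0.001, 0.02),
    "Cw": (0.001, 0.05),
    "ALA": (20.0, 70.0),
    "LAI": (0.0, 8.0),
    "hspot": (0.01, 0.5),
    "psoil": 1.0,
    "SZA": (20.0, 70.0),
    "VZA": 0.0,
    "RAA": (-90.0, 90.0),
}

_SET_OVERRIDES: dict[str, dict[str, tuple[float, float]]] = {
    "p1": {},
    "p2": {"Cm": (0.001, 0.01), "Cw": (0.001, 0.03), "LAI": (0.0, 7.0)},
    "p3": {"Cm": (0.001, 0.01), "Cw": (0.001, 0.03), "LAI": (0.0, 5.0)},
}


@dataclass(frozen=True)
class ParameterSpace:
    """Per-parameter fixed values or uniform ranges for one set id."""

    set_id: str
    spec: dict[str, tuple[float, float] | float]

    def __post_init__(self) -> None:
        for name in PARAMETER_COLUMNS:
            if name not in self.spec:
                raise ValueError(f"parameter space missing {name}")
        for name, v in self.spec.items():
            if isinstance(v, tuple) and v[0] > v[1]:
                raise ValueError(f"{name}: range min {v[0]} > max {v[1]}")

    def range(self, name: str) -> tuple[float, float]:
        v = self.spec[name]
        return v if isinstance(v, tuple) else (v, v)


def parameter_space(set_id: str) -> ParameterSpace:
    """Return the sampling specification for set id ``p1``, ``p2`` or ``p3``."""
    if set_id not in _SET_OVERRIDES:
        raise ValueError(f"unknown parameter set {set_id!r}; expected p1, p2 or p3")
    spec = dict(_BASE_SPEC)
    spec.update(_SET_OVERRIDES[set_id])
    return ParameterSpace(set_id=set_id, spec=spec)


def sample_parameters(space: ParameterSpace, n: int, seed: int) -> pd.DataFrame:
    """Draw ``n`` independent parameter combinations.

    Ranged parameters are sampled Uniform(min, max); fixed parameters are
    constant columns.  Reproducible given ``seed``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    cols = {}
    for name in PARAMETER_COLUMNS:
        v = space.spec[name]
        if isinstance(v, tuple):
            cols[name] = rng.uniform(v[0], v[1], size=n)
        else:
            cols[name] = np.full(n, float(v))
    return pd.DataFrame(cols, columns=list(PARAMETER_COLUMNS))


@dataclass
class SyntheticDataset:
    """Row-aligned parameter draws, 5-band reflectance and known LAI."""

    parameters: pd.DataFrame
    reflectance: np.ndarray
    lai: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.parameters)
        if self.reflectance.shape != (n, len(BAND_NAMES)):
            raise ValueError("reflectance block not aligned with parameters")
        if self.lai.shape != (n,):
            raise ValueError("lai block not aligned with parameters")

    def __len__(self) -> int:
        return len(self.parameters)

    def take(self, idx: np.ndarray) -> "SyntheticDataset":
        return SyntheticDataset(
            parameters=self.parameters.iloc[idx].reset_index(drop=True),
            reflectance=self.reflectance[idx],
            lai=self.lai[idx],
            provenance=dict(self.provenance),
        )

    def to_dir(self, path: str | Path) -> None:
        """Write the dataset as parameter CSV + reflectance CSV + JSON sidecar."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.parameters.to_csv(path / "parameters.csv", index=False)
        pd.DataFrame(self.reflectance, columns=list(BAND_NAMES)).assign(
            LAI=self.lai
        ).to_csv(path / "reflectance.csv", index=False)
        (path / "provenance.json").write_text(json.dumps(self.provenance, indent=2))

    @classmethod
    def from_dir(cls, path: str | Path) -> "SyntheticDataset":
        path = Path(path)
        params = pd.read_csv(path / "parameters.csv")
        refl = pd.read_csv(path / "reflectance.csv")
        prov = json.loads((path / "provenance.json").read_text())
        return cls(
            parameters=params,
            reflectance=refl[list(BAND_NAMES)].to_numpy(dtype=float),
            lai=refl["LAI"].to_numpy(dtype=float),
            provenance=prov,
        )


def generate_dataset(
    params: pd.DataFrame,
    soil: np.ndarray,
    bands=None,
    chunk_size: int = 2000,
    provenance: dict | None = None,
) -> SyntheticDataset:
    """Simulate band reflectance for every parameter row.

    For each row the leaf model and canopy model are run on the full 1 nm
    grid and the spectrum is resampled to the 5 camera bands.  The diffuse
    fraction is derived from the row's solar zenith angle, and the hot-spot
    parameter is zeroed whenever the view and sun zenith angles differ (it
    only takes effect at the exact alignment).  Deterministic given inputs.
    """
    missing = set(PARAMETER_COLUMNS) - set(params.columns)
    if missing:
        raise ValueError(f"parameter table missing columns: {sorted(missing)}")
    soil = as_spectrum(soil, "soil")
    if bands is None:
        bands = default_micasense_bands()

    # Simulate only wavelengths inside the band supports: every other
    # response weight is exactly zero, so the band values are unchanged.
    wl_idx = support_indices(bands)
    R = _response_matrix(bands)[:, wl_idx]
    soil_sub = soil[wl_idx]

    n = len(params)
    refl = np.empty((n, len(BAND_NAMES)), dtype=float)
    for start in range(0, n, chunk_size):
        stop = min(start + chunk_size, n)
        block = params.iloc[start:stop]
        try:
            rho, tau = prospect_batch(
                block["Ns"].to_numpy(), block["Cab"].to_numpy(),
                block["Car"].to_numpy(), block["Cant"].to_numpy(),
                block["Cbrown"].to_numpy(), block["Cw"].to_numpy(),
                block["Cm"].to_numpy(),
                wl_idx=wl_idx,
            )
            sza = block["SZA"].to_numpy()
            vza = block["VZA"].to_numpy()
            hspot_eff = np.where(vza == sza, block["hspot"].to_numpy(), 0.0)
            spectra = sail_batch(
                rho, tau,
                block["LAI"].to_numpy(), block["ALA"].to_numpy(), hspot_eff,
                sza, vza, block["RAA"].to_numpy(),
                soil_sub, compute_skyl(sza),
            )
        except Exception as exc:  # pragma: no cover - defensive re-raise
            raise RuntimeError(
                f"simulation failed in rows {start}..{stop - 1}: {exc}"
            ) from exc
        refl[start:stop] = spectra @ R.T

    return SyntheticDataset(
        parameters=params.reset_index(drop=True),
        reflectance=refl,
        lai=params["LAI"].to_numpy(dtype=float),
        provenance=provenance or {},
    )


def make_dataset(
    set_id: str,
    soil: np.ndarray,
    n: int,
    seed: int,
    soil_id: str = "s1",
    bands=None,
) -> SyntheticDataset:
    """Convenience wrapper: sample a parameter set and simulate it.

    Provenance records the conventional dataset name ``Dp{set}s{soil}``
    together with the seed.
    """
    space = parameter_space(set_id)
    params = sample_parameters(space, n, seed)
    prov = {
        "dataset": f"D{set_id}{soil_id}",
        "set_id": set_id,
        "soil_id": soil_id,
        "seed": int(seed),
        "n": int(n),
    }
    return generate_dataset(params, soil, bands=bands, provenance=prov)
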