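"""Three-component copepod body-density model.

A copepod is modelled as a volume mixture of three components —
structural ("other") tissue, storage lipid, and internal water:

    rho_cop = f_lipid * rho_lipid(T, P) + f_tissue * rho_tissue
              + (1 - f_tissue - f_lipid) * rho_water(T, S, P)

with the tissue fraction fixed (default 0.2) and its density constant
(default 1.08 g/cm³); the water fraction takes up whatever volume the
lipid does not, and the internal water is assumed to match the ambient
seawater.  The lipid phase follows a linear pressure–volume–temperature
response around a reference state:

    rho_lipid = rho0 * (1 - alpha * (T - T0) + kappa * (P - P0))

Storage wax esters are lighter, more thermally expandable and more
compressible than seawater, which is the mechanism of interest here: the
seawater-minus-copepod density gap of a lipid-rich individual shrinks as
it moves deeper.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .morphometry import LipidQuant
from .seawater import pressure_at_depth, seawater_density

__all__ = [
    "CTDProfile",
    "LipidPVTParams",
    "BodyCompositionModel",
    "DEFAULT_PVT",
    "lipid_density",
    "copepod_density",
    "density_at_depth",
    "pressure_at_depth",
    "seawater_density",
]


@dataclass(frozen=True)
class CTDProfile:
    """Depth-indexed temperature and salinity from a CTD cast."""

    depth: tuple[float, ...]  # m, strictly increasing
    temperature: tuple[float, ...]  # degC
    salinity: tuple[float, ...]  # PSU

    def __post_init__(self) -> None:
        d = np.asarray(self.depth, dtype=float)
        t = np.asarray(self.temperature, dtype=float)
        s = np.asarray(self.salinity, dtype=float)
        if not (len(d) == len(t) == len(s)) or len(d) < 2:
            raise ValueError("depth/temperature/salinity must be equal length >= 2")
        if np.any(np.diff(d) <= 0):
            raise ValueError("CTD depths must be strictly increasing")
        object.__setattr__(self, "depth", tuple(map(float, d)))
        object.__setattr__(self, "temperature", tuple(map(float, t)))
        object.__setattr__(self, "salinity", tuple(map(float, s)))

    def interpolate(self, z: float) -> tuple[float, float]:
        """Linearly interpolated (T, S) at depth z; extrapolation raises."""
        d = np.asarray(self.depth)
        if z < d[0] or z > d[-1]:
            raise ValueError(
                f"depth {z} m outside profile range [{d[0]}, {d[-1]}] m; "
                "refusing to extrapolate"
            )
        return (
            float(np.interp(z, d, self.temperature)),
            float(np.interp(z, d, self.salinity)),
        )


@dataclass(frozen=True)
class LipidPVTParams:
    """Linear PVT response of the storage-lipid (wax ester) phase.

    Defaults are representative literature values for a calanoid wax-ester
    mixture — reference density 0.902 g/cm³ at 0 °C and surface pressure,
    thermal expansivity 7.0e-4 /°C and compressibility 9.0e-6 /dbar — both
    response coefficients well above seawater's (~2.5e-4 /°C and ~4.3e-6
    per dbar).  The compressibility margin matters: because the internal
    water tracks ambient density and the tissue phase is treated as
    incompressible, the seawater-minus-copepod density gap of a lipid-rich
    individual only shrinks with depth when
    f_lipid·(kappa·rho0 − ∂rho_w/∂P) exceeds f_tissue·∂rho_w/∂P.
    These are configuration values, not measured constants of this package.
    """

    rho0: float = 0.902  # g/cm^3 at (T0, P0)
    alpha: float = 7.0e-4  # 1/degC
    kappa: float = 9.0e-6  # 1/dbar
    T0: float = 0.0  # degC
    P0: float = 0.0  # dbar

    def __post_init__(self) -> None:
        if not 0.8 < self.rho0 < 1.0:
            raise ValueError("rho0 outside the plausible lipid band (0.8, 1.0) g/cm^3")
        if self.alpha < 0 or self.kappa < 0:
            raise ValueError("alpha and kappa must be non-negative")


DEFAULT_PVT = LipidPVTParams()


@dataclass(frozen=True)
class BodyCompositionModel:
    """Volume fractions of the three-component mixture; they sum to 1."""

    f_lipid: float
    f_tissue: float = 0.2
    rho_tissue: float = 1.08  # g/cm^3

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_lipid <= 1.0 - self.f_tissue:
            raise ValueError(
                f"lipid fraction {self.f_lipid} exceeds non-tissue budget "
                f"{1.0 - self.f_tissue}"
            )
        if not 0.0 <= self.f_tissue <= 1.0:
            raise ValueError("tissue fraction outside [0, 1]")

    @property
    def f_water(self) -> float:
        return 1.0 - self.f_tissue - self.f_lipid

    def density(self, rho_lipid: float, rho_water) -> float | np.ndarray:
        return (
            self.f_lipid * rho_lipid
            + self.f_tissue * self.rho_tissue
            + self.f_water * np.asarray(rho_water, dtype=float)
        )


def lipid_density(T, P, params: LipidPVTParams = DEFAULT_PVT) -> float | np.ndarray:
    """Wax-ester density (g/cm³) from the linear PVT response."""
    t = np.asarray(T, dtype=float)
    p = np.asarray(P, dtype=float)
    out = params.rho0 * (1.0 - params.alpha * (t - params.T0) + params.kappa * (p - params.P0))
    return float(out) if out.ndim == 0 else out


def copepod_density(
    f_lipid: float,
    rho_lipid,
    rho_water,
    *,
    f_tissue: float = 0.2,
    rho_tissue: float = 1.08,
) -> float | np.ndarray:
    """Mixture density of an individual with lipid volume fraction f_lipid.

    rho_cop = f_lipid·rho_lipid + f_tissue·rho_tissue
              + (1 − f_tissue − f_lipid)·rho_water, all in g/cm³.
    """
    model = BodyCompositionModel(f_lipid=f_lipid, f_tissue=f_tissue, rho_tissue=rho_tissue)
    return model.density(rho_lipid, rho_water)


def density_at_depth(
    quant: LipidQuant,
    profile: CTDProfile,
    z: float,
    params: LipidPVTParams = DEFAULT_PVT,
    *,
    f_tissue: float = 0.2,
    rho_tissue: float = 1.08,
    eos=seawater_density,
) -> float:
    """Individual copepod density (g/cm³) at depth z on a CTD profile.

    Interpolates T and S at z, converts depth to pressure (1 dbar/m),
    and composes the seawater EOS, the lipid PVT response and the
    three-component mixture with ``f_lipid = quant.lipid_volume_fraction``.
    The ``eos`` hook accepts any callable with the ``(T, S, P) -> g/cm³``
    signature (e.g. a TEOS-10 implementation).
    """
    t, s = profile.interpolate(z)
    p = pressure_at_depth(z)
    rho_w = eos(t, s, p)
    rho_l = lipid_density(t, p, params)
    return float(
        copepod_density(
            quant.lipid_volume_fraction,
            rho_l,
            rho_w,
            f_tissue=f_tissue,
            rho_tissue=rho_tissue,
        )
    )
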