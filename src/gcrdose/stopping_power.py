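"""Electronic stopping power (LET) and CSDA ranges for GCR ions in compounds.

Unrestricted electronic stopping is computed from the Bethe formula with the
Barkas parameterization of the effective charge, which captures the partial
neutralization of slow heavy ions by electron pickup.  Shell and density
corrections are omitted; the formula is used down to a validity floor of
0.1 MeV/n, below which CSDA ranges are extrapolated with a power law.

Compound targets are handled by Bragg additivity: the mass stopping power of
a mixture is the mass-fraction-weighted sum of the elemental mass stopping
powers, and the mean excitation energy is the corresponding log-average.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid

log = logging.getLogger(__name__)

# Physical constants
ELECTRON_MC2_MEV = 0.51099895  # electron rest energy [MeV]
NUCLEON_MC2_MEV = 931.49410  # atomic mass unit rest energy [MeV]
BETHE_K = 0.307075  # 4*pi*N_A*r_e^2*m_e*c^2 [MeV cm^2 / mol]
AVOGADRO = 6.02214076e23

#: Lowest kinetic energy per nucleon [MeV/n] at which the uncorrected Bethe
#: formula is evaluated.  Below this the logarithm may turn over and shell
#: corrections would dominate.
BETHE_E_MIN_MEV_N = 0.1

# Elemental target data: symbol -> (Z, atomic weight, mean excitation energy I [eV]).
# I-values are the standard recommended values used by stopping-power tables.
TARGET_ELEMENTS: dict[str, tuple[int, float, float]] = {
    "H": (1, 1.008, 19.2),
    "He": (2, 4.0026, 41.8),
    "Li": (3, 6.94, 40.0),
    "Be": (4, 9.0122, 63.7),
    "B": (5, 10.81, 76.0),
    "C": (6, 12.011, 78.0),
    "N": (7, 14.007, 82.0),
    "O": (8, 15.999, 95.0),
    "F": (9, 18.998, 115.0),
    "Na": (11, 22.990, 149.0),
    "Mg": (12, 24.305, 156.0),
    "Al": (13, 26.982, 166.0),
    "Si": (14, 28.085, 173.0),
    "P": (15, 30.974, 173.0),
    "S": (16, 32.06, 180.0),
    "Cl": (17, 35.45, 174.0),
    "Ar": (18, 39.948, 188.0),
    "K": (19, 39.098, 190.0),
    "Ca": (20, 40.078, 191.0),
    "Ti": (22, 47.867, 233.0),
    "Cr": (24, 51.996, 257.0),
    "Mn": (25, 54.938, 272.0),
    "Fe": (26, 55.845, 286.0),
    "Cu": (29, 63.546, 322.0),
}


@dataclass(frozen=True)
class Material:
    """A homogeneous compound or mixture target.

    Parameters
    ----------
    name : str
        Label used in reports and CLI flags.
    mass_fractions : dict
        Elemental mass fractions, summing to one.
    density : float
        Bulk density in g/cm^3.
    mean_excitation_energy : float, optional
        I-value in eV.  When omitted it is computed from Bragg additivity
        over the elemental I-values.
    """

    name: str
    mass_fractions: dict[str, float]
    density: float
    mean_excitation_energy: float | None = None

    def __post_init__(self) -> None:
        total = sum(self.mass_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"mass fractions of {self.name!r} sum to {total!r}, expected 1"
            )
        if self.density <= 0:
            raise ValueError(f"density of {self.name!r} must be positive")
        for sym in self.mass_fractions:
            if sym not in TARGET_ELEMENTS:
                raise ValueError(f"unknown target element {sym!r} in {self.name!r}")

    @classmethod
    def from_formula(
        cls, name: str, formula: dict[str, int | float], density: float
    ) -> "Material":
        """Build a material from a stoichiometric formula, e.g. ``{"C": 2, "H": 4}``."""
        masses = {s: n * TARGET_ELEMENTS[s][1] for s, n in formula.items()}
        total = sum(masses.values())
        fractions = {s: m / total for s, m in masses.items()}
        # guard against float round-off in the sum-to-one invariant
        first = next(iter(fractions))
        fractions[first] += 1.0 - sum(fractions.values())
        return cls(name=name, mass_fractions=fractions, density=density)

    def with_density(self, density: float) -> "Material":
        return replace(self, density=density)

    @property
    def mean_z_over_a(self) -> float:
        """Electron density term <Z/A> [mol/g]."""
        return sum(
            w * TARGET_ELEMENTS[s][0] / TARGET_ELEMENTS[s][1]
            for s, w in self.mass_fractions.items()
        )

    @property
    def i_value_eV(self) -> float:
        """Mean excitation energy via Bragg additivity unless overridden."""
        if self.mean_excitation_energy is not None:
            return self.mean_excitation_energy
        num = sum(
            w
            * TARGET_ELEMENTS[s][0]
            / TARGET_ELEMENTS[s][1]
            * math.log(TARGET_ELEMENTS[s][2])
            for s, w in self.mass_fractions.items()
        )
        return math.exp(num / self.mean_z_over_a)


def _mix(materials_fracs: list[tuple[Material, float]], name: str, density: float) -> Material:
    fractions: dict[str, float] = {}
    for mat, w in materials_fracs:
        for s, f in mat.mass_fractions.items():
            fractions[s] = fractions.get(s, 0.0) + w * f
    first = next(iter(fractions))
    fractions[first] += 1.0 - sum(fractions.values())
    return Material(name=name, mass_fractions=fractions, density=density)


#: ICRU four-element soft-tissue surrogate, unit density.
ICRU_TISSUE = Material(
    "tissue",
    {"H": 0.101, "C": 0.111, "N": 0.026, "O": 0.762},
    density=1.0,
)

ALUMINUM = Material("Al", {"Al": 1.0}, density=2.70)

POLYETHYLENE = Material.from_formula("PE", {"C": 2, "H": 4}, density=0.94)

_PEEK = Material.from_formula("PEEK", {"C": 19, "H": 12, "O": 3}, density=1.30)
#: CF/PEEK laminate: 60 % carbon fiber / 40 % PEEK matrix by mass, 1.55 g/cm^3.
CFRP = _mix(
    [(Material("CF", {"C": 1.0}, density=1.8), 0.60), (_PEEK, 0.40)],
    name="CFRP",
    density=1.55,
)

MATERIALS: dict[str, Material] = {
    "tissue": ICRU_TISSUE,
    "Al": ALUMINUM,
    "PE": POLYETHYLENE,
    "CFRP": CFRP,
}


def beta_from_energy(energy_MeV_n):
    """Speed relative to light for a kinetic energy per nucleon in MeV/n."""
    E = np.asarray(energy_MeV_n, dtype=float)
    if np.any(E <= 0):
        raise ValueError("kinetic energy per nucleon must be positive")
    gamma = 1.0 + E / NUCLEON_MC2_MEV
    return np.sqrt(1.0 - gamma**-2)


def effective_charge(Z: int, beta):
    """Barkas effective charge Z* = Z(1 - exp(-125 beta Z^(-2/3)))."""
    if not 1 <= Z <= 26:
        raise ValueError(f"projectile charge Z={Z} outside 1..26")
    b = np.asarray(beta, dtype=float)
    if np.any((b <= 0) | (b >= 1)):
        raise ValueError("beta must lie in (0, 1)")
    return Z * (1.0 - np.exp(-125.0 * b * Z ** (-2.0 / 3.0)))


@dataclass(frozen=True)
class IonState:
    """A projectile ion at a given kinetic energy per nucleon."""

    Z: int
    A: int
    E: float  # MeV/n

    @property
    def beta(self) -> float:
        return float(beta_from_energy(self.E))

    @property
    def z_eff(self) -> float:
        return float(effective_charge(self.Z, self.beta))

    def let(self, material: Material) -> float:
        return float(let_keV_um(self.Z, self.E, material))


def mass_stopping_power(Z: int, energy_MeV_n, material: Material):
    """Electronic mass stopping power [MeV cm^2/g].

    Bethe formula with Barkas effective charge; energies below the 0.1 MeV/n
    validity floor are rejected.
    """
    E = np.asarray(energy_MeV_n, dtype=float)
    if np.any(E < BETHE_E_MIN_MEV_N):
        raise ValueError(
            f"energy below Bethe validity floor {BETHE_E_MIN_MEV_N} MeV/n"
        )
    b = beta_from_energy(E)
    gamma = 1.0 + E / NUCLEON_MC2_MEV
    zs = effective_charge(Z, b)
    arg = 2.0 * ELECTRON_MC2_MEV * 1e6 * b**2 * gamma**2 / material.i_value_eV
    return (
        BETHE_K
        * material.mean_z_over_a
        * zs**2
        / b**2
        * (np.log(arg) - b**2)
    )


def let_keV_um(Z: int, energy_MeV_n, material: Material):
    """Linear energy transfer in keV/µm at the material's bulk density."""
    S = mass_stopping_power(Z, energy_MeV_n, material)  # MeV cm^2/g
    # MeV/cm -> keV/um: 1 MeV/cm = 0.1 keV/um
    return S * material.density * 0.1


class RangeEnergyTable:
    """Precomputed CSDA range-energy relation for one ion in one material.

    The range is the continuous-slowing-down integral of the inverse stopping
    power in mass-thickness units (g/cm^2).  Below the Bethe validity floor
    the relation is extended with a power law R ~ E^1.8 so that slowing-down
    bookkeeping has no gap; the extension is logged once per table.
    """

    _warned: set[tuple[int, str]] = set()

    def __init__(
        self,
        Z: int,
        A: int,
        material: Material,
        e_min: float = BETHE_E_MIN_MEV_N,
        e_max: float = 1.2e5,
        n: int = 800,
    ) -> None:
        self.Z, self.A, self.material = Z, A, material
        self.energy = np.geomspace(e_min, e_max, n)
        S = mass_stopping_power(Z, self.energy, material)  # per total ion energy
        inv = A / S  # d(range)/d(E per nucleon) [g/cm^2 per MeV/n]
        R = cumulative_trapezoid(inv, self.energy, initial=0.0)
        # offset so that R(e_min) equals the power-law extrapolation value
        self._r_floor = inv[0] * self.energy[0] / 1.8
        self.range = R + self._r_floor
        key = (Z, material.name)
        if key not in RangeEnergyTable._warned:
            RangeEnergyTable._warned.add(key)
            log.debug(
                "range table Z=%d in %s: power-law extrapolation below %.1f MeV/n",
                Z,
                material.name,
                e_min,
            )

    def range_of_energy(self, E):
        E = np.asarray(E, dtype=float)
        below = E < self.energy[0]
        R = np.interp(E, self.energy, self.range)
        if np.any(below):
            R = np.where(
                below, self._r_floor * (E / self.energy[0]) ** 1.8, R
            )
        return R

    def energy_of_range(self, R):
        R = np.asarray(R, dtype=float)
        E = np.interp(R, self.range, self.energy)
        below = R < self._r_floor
        if np.any(below):
            with np.errstate(invalid="ignore"):
                E = np.where(
                    below,
                    self.energy[0] * np.maximum(R / self._r_floor, 0.0) ** (1 / 1.8),
                    E,
                )
        return E


def csda_range(Z: int, A: int, material: Material, energy_MeV_n):
    """CSDA range in g/cm^2 for the given ion and material."""
    table = RangeEnergyTable(Z, A, material)
    return table.range_of_energy(energy_MeV_n)
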