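"""Biological weighting of absorbed dose: ICRP-60 quality factor and
track-structure relative biological effectiveness.

Two weights are supported:

* ``qf_icrp`` - the ICRP (1990) quality factor, a piecewise function of LET
  alone: 1 below 10 keV/um, 0.32*L - 2.2 between 10 and 100, 300/sqrt(L)
  above 100.  Both breakpoints are assigned to the middle branch, which keeps
  the function continuous at L = 10 (the value at L = 100 is then 29.8 rather
  than 30.0).

* ``rbe_gamma_acute`` - an RBE referenced to acute (0.5-3 Gy) gamma rays from
  the targeted-effects track-structure model.  The ion-kill probability

      P = (1 - exp(-Z*^2 / (kappa beta^2)))^m

  switches between a gamma-like mode (weight 1 - P) and a track-core mode
  whose effect per dose is 6.24 sigma0 P / (alpha_gamma L); 6.24 carries the
  fluence-to-dose unit conversion at unit density.  Unlike the quality
  factor, this weight depends on the ion's charge and velocity, not on LET
  alone.  The model parameters are endpoint-specific fit constants and must
  be supplied explicitly - there are no silent defaults.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .gcr_source import ElementSpec
from .stopping_power import Material, beta_from_energy, effective_charge, let_keV_um


def qf_icrp(let_keV_um_values):
    """ICRP-60 quality factor as a function of LET [keV/um]."""
    L = np.asarray(let_keV_um_values, dtype=float)
    if np.any(L <= 0):
        raise ValueError("LET must be positive")
    return np.where(
        L < 10.0, 1.0, np.where(L <= 100.0, 0.32 * L - 2.2, 300.0 / np.sqrt(L))
    )


@dataclass(frozen=True)
class RBEParameters:
    """Endpoint-specific constants of the track-structure RBE model.

    sigma0_um2 : saturation action cross section [um^2]
    alpha_gamma_per_gy : linear coefficient of the acute-gamma dose response [1/Gy]
    m : hit-number exponent (>= 1)
    kappa : track-structure saturation parameter
    """

    sigma0_um2: float
    alpha_gamma_per_gy: float
    m: float
    kappa: float
    endpoint: str = ""
    placeholder: bool = False

    def __post_init__(self) -> None:
        for name in ("sigma0_um2", "alpha_gamma_per_gy", "m", "kappa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"RBE parameter {name} must be positive")
        if self.m < 1:
            raise ValueError("hit-number exponent m must be >= 1")


def load_parameter_set(name: str) -> RBEParameters:
    """Load a named RBE parameter set shipped with the package."""
    text = resources.files("gcrdose.data").joinpath("rbe_parameter_sets.yaml").read_text()
    sets = yaml.safe_load(text)
    if name not in sets:
        raise KeyError(
            f"unknown RBE parameter set {name!r}; available: {sorted(sets)}"
        )
    entry = sets[name]
    return RBEParameters(
        sigma0_um2=float(entry["sigma0_um2"]),
        alpha_gamma_per_gy=float(entry["alpha_gamma_per_gy"]),
        m=float(entry["m"]),
        kappa=float(entry["kappa"]),
        endpoint=str(entry.get("endpoint", name)),
        placeholder=bool(entry.get("placeholder", False)),
    )


def ion_kill_probability(Z: int, energy_MeV_n, params: RBEParameters):
    """P = (1 - exp(-Z*^2/(kappa beta^2)))^m, in (0, 1) for physical inputs."""
    beta = beta_from_energy(energy_MeV_n)
    zs = effective_charge(Z, beta)
    return (1.0 - np.exp(-(zs**2) / (params.kappa * beta**2))) ** params.m


def rbe_gamma_acute(
    Z: int,
    energy_MeV_n,
    let_keV_um_values,
    params: RBEParameters | None,
    strict_literal: bool = False,
):
    """Track-structure RBE for an ion of charge ``Z`` at the given energy/LET.

    The default form weights the ion-kill term by P,

        RBE = (1 - P) + 6.24 sigma0 P / (alpha_gamma L),

    which tends to 1 at low LET where P -> 0.  ``strict_literal=True``
    evaluates the unweighted ion-kill term 6.24 sigma0/(alpha_gamma L)
    instead (for comparison only; it diverges as L -> 0).
    """
    if params is None:
        raise ValueError("RBE parameters required: pass an RBEParameters instance")
    L = np.asarray(let_keV_um_values, dtype=float)
    if np.any(L <= 0):
        raise ValueError("LET must be positive")
    P = ion_kill_probability(Z, energy_MeV_n, params)
    ion_kill = 6.24 * params.sigma0_um2 / (params.alpha_gamma_per_gy * L)
    if strict_literal:
        return (1.0 - P) + ion_kill
    return (1.0 - P) + ion_kill * P


def export_weight_curves(
    elements: list[ElementSpec],
    params: RBEParameters,
    tissue: Material,
    e_min: float = 1.0,
    e_max: float = 1.0e4,
    n: int = 400,
) -> pd.DataFrame:
    """Per-element (Z, E, LET, QF, RBE) curves over 1 MeV/n .. 10 GeV/n.

    The quality factor depends on LET only (one curve for all elements); the
    RBE differs between elements at the same LET.
    """
    E = np.geomspace(e_min, e_max, n)
    frames = []
    for elem in elements:
        L = let_keV_um(elem.Z, E, tissue)
        frames.append(
            pd.DataFrame(
                {
                    "Z": elem.Z,
                    "symbol": elem.symbol,
                    "E_MeV_n": E,
                    "LET_keV_um": L,
                    "QF_ICRP": qf_icrp(L),
                    "RBE_gamma_acute": rbe_gamma_acute(elem.Z, E, L, params),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
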