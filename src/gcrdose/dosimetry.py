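"""Absorbed dose, dose-averaged quality factor / RBE, and effective dose
equivalents from GCR spectra, in free space or behind shields.

Per element i the pipeline computes the absorbed dose rate D_i in tissue, the
dose-vs-LET distribution it came from, and the dose-weighted mean of each
biological weight,

    <w> = sum_L w(L) dD(L) / sum_L dD(L),

and then the effective dose equivalent as the per-element sum

    H_E = sum_i D_i <w>_i .

Two dose estimators are provided:

* thin target - D = k * integral Phi(E) L(E) dE with k = 1.602e-9 Gy per
  (keV/um) per cm^-2 at unit density: the dose to an infinitesimal tissue
  layer facing the unperturbed fluence.

* tissue slab (default, 30 cm) - the spectrum is range-shifted through the
  slab in thin sublayers and the deposited energy is averaged over the slab
  mass.  This restores body self-shielding: low-energy particles stop in the
  first centimeters, slowed particles deposit at raised LET, and heavy ions
  with ranges shorter than the slab contribute only partially.  Nuclear
  fragmentation inside the tissue is not modeled.

Because the quality factor is a function of LET alone it can be averaged
over the dose-vs-LET distribution; the track-structure RBE depends on charge
and velocity, so it is accumulated alongside the energy deposition where
(Z, E) are still known.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bio_weighting import RBEParameters, qf_icrp, rbe_gamma_acute
from .gcr_source import DifferentialSpectrum
from .spectra import LETSpectrum, default_let_edges
from .stopping_power import (
    BETHE_E_MIN_MEV_N,
    ICRU_TISSUE,
    Material,
    RangeEnergyTable,
    let_keV_um,
)
from .transport_1d import ShieldConfig, transmit

#: Gy per (keV/um * cm^-2) at unit density.
GY_PER_KEV_UM_CM2 = 1.602e-9

#: Gy per (MeV deposited per gram).
GY_PER_MEV_G = 1.602e-10


@dataclass(frozen=True)
class ThinTarget:
    """Dose to an infinitesimal tissue layer in the unperturbed field."""


@dataclass(frozen=True)
class SlabPhantom:
    """Dose averaged over a tissue slab of the given depth [g/cm^2]."""

    depth: float = 30.0
    sublayer: float = 0.5

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("slab depth must be positive")
        if not 0 < self.sublayer <= self.depth:
            raise ValueError("sublayer must be in (0, depth]")


@dataclass(frozen=True)
class DoseLETDistribution:
    """Absorbed dose rate [mGy/yr] binned by LET in tissue."""

    let_edges: np.ndarray
    dose: np.ndarray  # mGy/yr per bin

    @property
    def let(self) -> np.ndarray:
        return np.sqrt(self.let_edges[:-1] * self.let_edges[1:])

    def total(self) -> float:
        return float(self.dose.sum())

    def __add__(self, other: "DoseLETDistribution") -> "DoseLETDistribution":
        if not np.allclose(self.let_edges, other.let_edges):
            raise ValueError("dose distributions are not on a common LET grid")
        return DoseLETDistribution(self.let_edges, self.dose + other.dose)


@dataclass(frozen=True)
class ElementDose:
    """Per-element dosimetry result."""

    Z: int
    symbol: str
    dose_mGy_yr: float
    dose_vs_let: DoseLETDistribution
    mean_qf: float
    mean_rbe: float | None


def mean_weight(dose_by_let: DoseLETDistribution, weight) -> float:
    """Dose-weighted mean of a LET-dependent weight function.

    ``weight`` is a callable LET -> weight, e.g. :func:`~gcrdose.qf_icrp`.
    """
    total = dose_by_let.total()
    if total <= 0:
        raise ValueError("total dose is zero; mean weight undefined")
    return float(np.sum(dose_by_let.dose * weight(dose_by_let.let)) / total)


def _accumulate(
    dist: np.ndarray,
    rbe_sum: list[float],
    edges: np.ndarray,
    Z: int,
    energies: np.ndarray,
    lets: np.ndarray,
    doses: np.ndarray,
    rbe_params: RBEParameters | None,
) -> None:
    idx = np.clip(np.searchsorted(edges, lets) - 1, 0, dist.size - 1)
    np.add.at(dist, idx, doses)
    if rbe_params is not None:
        rbe = rbe_gamma_acute(Z, energies, lets, rbe_params)
        rbe_sum[0] += float(np.sum(rbe * doses))


def absorbed_dose_element(
    spec: DifferentialSpectrum,
    tissue: Material = ICRU_TISSUE,
    phantom: ThinTarget | SlabPhantom = SlabPhantom(),
    rbe_params: RBEParameters | None = None,
    let_edges: np.ndarray | None = None,
) -> ElementDose:
    """Absorbed dose rate and dose-vs-LET distribution for one element."""
    if let_edges is None:
        let_edges = default_let_edges()
    Z, A = spec.element.Z, spec.element.A
    E = spec.energy
    dist = np.zeros(let_edges.size - 1)
    rbe_sum = [0.0]

    if isinstance(phantom, ThinTarget):
        e_ok = np.maximum(E, BETHE_E_MIN_MEV_N)
        L = let_keV_um(Z, e_ok, tissue)
        widths = np.gradient(E)
        # mGy/yr contribution per grid cell at the local LET
        doses = GY_PER_KEV_UM_CM2 * 1e3 * spec.flux * widths * L / tissue.density
        _accumulate(dist, rbe_sum, let_edges, Z, e_ok, L, doses, rbe_params)
    else:
        table = RangeEnergyTable(Z, A, tissue)
        n_layers = int(round(phantom.depth / phantom.sublayer))
        step = phantom.depth / n_layers
        widths = np.gradient(E)
        fluence = spec.flux * widths  # particles/(cm^2 yr) per cell
        e_now = E.astype(float).copy()
        alive = fluence > 0
        for _ in range(n_layers):
            if not np.any(alive):
                break
            r_now = table.range_of_energy(e_now)
            r_new = r_now - step
            stopped = alive & (r_new <= 0)
            surviving = alive & ~stopped
            e_new = np.where(surviving, table.energy_of_range(np.maximum(r_new, 0.0)), 0.0)
            de_per_n = np.where(alive, e_now - e_new, 0.0)
            # energy deposited in this layer per unit area [MeV/cm^2]
            edep = fluence * de_per_n * A
            e_mid = np.maximum(
                np.where(stopped, 0.5 * e_now, 0.5 * (e_now + e_new)),
                BETHE_E_MIN_MEV_N,
            )
            L = let_keV_um(Z, e_mid, tissue)
            doses = GY_PER_MEV_G * 1e3 * edep / phantom.depth  # mGy/yr slab average
            sel = doses > 0
            _accumulate(
                dist, rbe_sum, let_edges, Z, e_mid[sel], L[sel], doses[sel], rbe_params
            )
            alive = surviving
            e_now = np.where(alive, e_new, e_now)

    total = float(dist.sum())
    dvl = DoseLETDistribution(let_edges, dist)
    if total > 0:
        mqf = mean_weight(dvl, qf_icrp)
        mrbe = (rbe_sum[0] / total) if rbe_params is not None else None
    else:
        mqf, mrbe = 1.0, (1.0 if rbe_params is not None else None)
    return ElementDose(
        Z=Z,
        symbol=spec.element.symbol,
        dose_mGy_yr=total,
        dose_vs_let=dvl,
        mean_qf=mqf,
        mean_rbe=mrbe,
    )


@dataclass(frozen=True)
class DoseBreakdown:
    """Per-element doses and totals for one exposure configuration."""

    per_element: pd.DataFrame  # columns: Z, symbol, D_mGy_yr, mean_QF, mean_RBE
    total_dose_mGy_yr: float
    mean_qf: float
    he_icrp_mSv_yr: float
    mean_rbe: float | None
    he_rbe: float | None  # relative units (no DDREF); not commensurable with mSv
    dose_vs_let: DoseLETDistribution


def dose_breakdown(
    source: list[DifferentialSpectrum],
    tissue: Material = ICRU_TISSUE,
    phantom: ThinTarget | SlabPhantom = SlabPhantom(),
    rbe_params: RBEParameters | None = None,
    ddref: float = 1.0,
) -> DoseBreakdown:
    """Table-style breakdown: D_i, mean QF_i, mean RBE_i per element, with
    totals and both effective dose equivalents.

    ``ddref`` optionally divides the RBE-weighted dose equivalent (reporting
    scalar only; default 1 leaves it off).
    """
    rows = []
    dists = []
    for spec in source:
        ed = absorbed_dose_element(spec, tissue, phantom, rbe_params)
        rows.append(
            {
                "Z": ed.Z,
                "symbol": ed.symbol,
                "D_mGy_yr": ed.dose_mGy_yr,
                "mean_QF": ed.mean_qf,
                "mean_RBE": ed.mean_rbe if ed.mean_rbe is not None else np.nan,
            }
        )
        dists.append(ed.dose_vs_let)
    df = pd.DataFrame(rows).sort_values("Z", ignore_index=True)
    total = float(df["D_mGy_yr"].sum())
    if total <= 0:
        raise ValueError("source deposits no dose")
    he_icrp = float((df["D_mGy_yr"] * df["mean_QF"]).sum())
    if rbe_params is not None:
        he_rbe = float((df["D_mGy_yr"] * df["mean_RBE"]).sum()) / ddref
        mean_rbe = he_rbe * ddref / total
    else:
        he_rbe, mean_rbe = None, None
    total_dist = dists[0]
    for d in dists[1:]:
        total_dist = total_dist + d
    return DoseBreakdown(
        per_element=df,
        total_dose_mGy_yr=total,
        mean_qf=he_icrp / total,
        he_icrp_mSv_yr=he_icrp,
        mean_rbe=mean_rbe,
        he_rbe=he_rbe,
        dose_vs_let=total_dist,
    )


def effective_dose_equivalent(
    breakdown: DoseBreakdown, weight: str = "qf"
) -> float:
    """H_E = sum_i D_i w_i for w in {QF_ICRP ("qf"), RBE_gamma-acute ("rbe")}.

    The QF-weighted value is in mSv/yr; the RBE-weighted value is a relative
    (no-DDREF) quantity and is not commensurable with it.
    """
    df = breakdown.per_element
    if weight == "qf":
        return float((df["D_mGy_yr"] * df["mean_QF"]).sum())
    if weight == "rbe":
        if df["mean_RBE"].isna().any():
            raise ValueError("breakdown was computed without RBE parameters")
        return float((df["D_mGy_yr"] * df["mean_RBE"]).sum())
    raise ValueError("weight must be 'qf' or 'rbe'")


def shielding_report(
    source: list[DifferentialSpectrum],
    shields: list[ShieldConfig],
    tissue: Material = ICRU_TISSUE,
    phantom: ThinTarget | SlabPhantom = SlabPhantom(),
    rbe_params: RBEParameters | None = None,
) -> pd.DataFrame:
    """Relative dose and dose-equivalent table across shield configurations.

    ``shields`` must include a zero-thickness entry, which defines the
    free-space reference; every ratio column is relative to it.
    """
    if not any(s.mass_thickness == 0 for s in shields):
        raise ValueError("shields must include the unshielded (zero-thickness) reference")
    ref = None
    rows = []
    ordered = sorted(shields, key=lambda s: (s.mass_thickness > 0, s.material.name))
    for shield in ordered:
        result = transmit(source, shield)
        bd = dose_breakdown(result.combined(), tissue, phantom, rbe_params)
        if shield.mass_thickness == 0 and ref is None:
            ref = bd
        rows.append((shield, bd))
    out = []
    for shield, bd in rows:
        rec = {
            "material": "none" if shield.mass_thickness == 0 else shield.material.name,
            "thickness_gcm2": shield.mass_thickness,
            "rel_dose": bd.total_dose_mGy_yr / ref.total_dose_mGy_yr,
            "mean_QF": bd.mean_qf,
            "rel_HE_ICRP": bd.he_icrp_mSv_yr / ref.he_icrp_mSv_yr,
        }
        if rbe_params is not None:
            rec["mean_RBE"] = bd.mean_rbe
            rec["rel_HE_RBE"] = bd.he_rbe / ref.he_rbe
        out.append(rec)
    return pd.DataFrame(out)
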