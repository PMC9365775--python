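"""Quality factor and RBE as functions of LET for the major GCR ions.

The ICRP-60 quality factor is a single curve in LET, peaking at 29.8 at
100 keV/um.  The track-structure RBE depends on charge and velocity, so
different ions at the same LET carry different weights - the fundamental
reason the two dose-equivalent scales disagree about heavy-ion importance.
"""

import gcrdose as g
from gcrdose.bio_weighting import export_weight_curves

params = g.load_parameter_set("lymphocyte-simple-exchange")
elements = [g.element(Z) for Z in (1, 2, 6, 26)]
curves = export_weight_curves(elements, params, g.ICRU_TISSUE)

print(f"QF curve maximum: {curves['QF_ICRP'].max():.1f} "
      f"at LET {curves.loc[curves['QF_ICRP'].idxmax(), 'LET_keV_um']:.0f} keV/um")

for symbol, grp in curves.groupby("symbol", sort=False):
    peak = grp.loc[grp["RBE_gamma_acute"].idxmax()]
    print(f"{symbol:>2}: RBE peaks at {peak['RBE_gamma_acute']:.2f} "
          f"(LET {peak['LET_keV_um']:.1f} keV/um, E {peak['E_MeV_n']:.0f} MeV/n)")
print("note: RBE values use the shipped PLACEHOLDER parameter set")
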