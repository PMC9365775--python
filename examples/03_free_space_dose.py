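"""Free-space dose breakdown: absorbed dose, mean QF/RBE, dose equivalents.

Computes the per-element absorbed dose rate in a 30-cm tissue slab, the
dose-averaged ICRP-60 quality factor and track-structure RBE, and the two
effective dose equivalents.  The QF-weighted H_E is in mSv/yr; the
RBE-weighted value uses placeholder endpoint parameters and carries no
DDREF, so only its structure (not its absolute scale) is meaningful.
"""

import gcrdose as g
from gcrdose.dosimetry import dose_breakdown

source = g.build_full_source()
params = g.load_parameter_set("lymphocyte-simple-exchange")
bd = dose_breakdown(source, rbe_params=params)

print(f"{'Z':>3} {'el':>3} {'D [mGy/yr]':>11} {'<QF>':>6} {'<RBE>':>6}")
for _, row in bd.per_element.iterrows():
    if row["symbol"] in ("H", "He", "C", "O", "Si", "Fe"):
        print(f"{row['Z']:>3.0f} {row['symbol']:>3} {row['D_mGy_yr']:>11.2f} "
              f"{row['mean_QF']:>6.2f} {row['mean_RBE']:>6.2f}")

print(f"\ntotal absorbed dose rate : {bd.total_dose_mGy_yr:7.1f} mGy/yr")
print(f"total mean QF_ICRP       : {bd.mean_qf:7.2f}")
print(f"H_E(ICRP)                : {bd.he_icrp_mSv_yr:7.1f} mSv/yr")
print(f"total mean RBE (placeholder params): {bd.mean_rbe:.2f}")
print("heavy ions carry little dose but dominate H_E through their high QF")
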