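"""Convert energy spectra to LET spectra in ICRU four-element tissue.

The LET(E) relation of each ion falls to a minimum near 2-3 GeV/n and rises
slowly beyond it, so the broad relativistic part of each spectrum piles up
just above the minimum LET.  The resulting spectral modes scale roughly with
Z^2: ~0.9 keV/um for He up to ~150 keV/um for Fe.
"""

import gcrdose as g
from gcrdose.spectra import energy_to_let, sum_let_spectra

source = g.build_full_source()

let_spectra = []
for symbol in ("H", "He", "C", "O", "Fe"):
    spec = next(s for s in source if s.element.symbol == symbol)
    ls = energy_to_let(spec, g.ICRU_TISSUE)
    let_spectra.append(ls)
    conserved = ls.total_fluence() / spec.total_fluence()
    print(f"{symbol:>2}: LET-spectrum mode {ls.mode():8.2f} keV/um "
          f"(fluence conserved to {conserved:.4f})")

total = sum_let_spectra(let_spectra)
print(f"\nsummed spectrum: mode at {total.mode():.2f} keV/um "
      "(proton pile-up dominates the composite)")
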