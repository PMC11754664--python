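#!/usr/bin/env python
"""Time-resolved fluorescence analysis: reconvolution fits and FLT/FA KDs.

Generates photon-counting decays for a labeled-DNA titration, fits them
globally with lifetimes linked across titration points, reduces each decay
to its intensity-weighted lifetime, and extracts the dissociation constant
from the lifetime-vs-concentration curve; a parallel steady-state
anisotropy titration is fit the same way.  Tables land under results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from paibind.binding import hill
from paibind.fluorescence import (
    PolarizedMeasurement,
    anisotropy,
    fit_decays_global,
    summarize_lifetime,
    titration_kd_from_observable,
)
from paibind.recovery import recover_flt_kd
from paibind.synthetic import SimScenario, gen_flt_titration

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

# --- FLT titration at the published transposase/DR-core constant ----------
conc, wfs = gen_flt_titration(SimScenario(
    "flt_titration", {"kd_nM": 29.4}, {}, seed=7))
fits = fit_decays_global(wfs, link_lifetimes=True)
taus = [summarize_lifetime(f)[0] for f in fits]
fit = titration_kd_from_observable(conc, taus)
print(f"linked lifetimes: tau1 {fits[0].tau1_ns:.3f} ns, "
      f"tau2 {fits[0].tau2_ns:.3f} ns (truth 1.0 / 4.0)")
print(f"FLT titration KD {fit.kd_nM:.2f} nM (truth 29.4 nM)")
pd.DataFrame({"conc_nM": conc, "tau_iw_ns": taus}).to_csv(
    OUT / "flt_titration.csv", index=False)

rec = recover_flt_kd(kd_nM=29.4, n_seeds=50)
print(f"recovery over 50 realizations: mean KD {rec.mean:.2f} nM, "
      f"SD {rec.sd:.2f} nM")

# --- FA titration at the published anisotropy-assay constant --------------
rng = np.random.default_rng(11)
kd_fa = 23.9
frac = hill(conc, kd_fa, 1.0)
fa = []
for f in frac:
    # bound DNA tumbles slower: higher anisotropy
    ivh = 1.0
    ivv = (1.0 + 0.15 * f) / (1.0 - 0.05 * f)
    fa.append(anisotropy(PolarizedMeasurement(ivv, ivh, 1.03))
              + 0.002 * rng.standard_normal())
fa_fit = titration_kd_from_observable(conc, fa)
print(f"FA titration KD {fa_fit.kd_nM:.2f} nM (truth {kd_fa} nM, "
      f"g-factor 1.03)")
pd.DataFrame({"conc_nM": conc, "fa": fa}).to_csv(
    OUT / "fa_titration.csv", index=False)
print(f"wrote {OUT / 'flt_titration.csv'} and {OUT / 'fa_titration.csv'}")
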