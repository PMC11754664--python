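#!/usr/bin/env python
"""MST binding analysis: mode selection and KD recovery for every assay.

Simulates the full set of transposase/DNA titrations at their published
dissociation constants -- biphasic (specific + nonspecific) curves for the
transposon binding sites and monophasic curves for the nonspecific control
duplexes -- then runs baseline normalization, AICc model selection and Hill
fitting, and tabulates recovered constants under results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from paibind.binding import fit_binding, normalize_baseline, select_binding_model
from paibind.recovery import recover_binding_kd
from paibind.synthetic import SimScenario, gen_titration

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

# published ground truths: specific KDs (nM) per protein/DNA pair and the
# micromolar nonspecific mode shared by all transposon-site curves
SPECIFIC_KD = {
    ("SB10", "DR-core"): 25.3, ("SB10", "Li"): 17.3, ("SB10", "Lo"): 16.6,
    ("SB100X", "DR-core"): 17.3, ("SB100X", "Li"): 23.6, ("SB100X", "Lo"): 23.0,
}
NONSPECIFIC_KD_uM = {"SB10": 2.60, "SB100X": 0.56,
                     "SB100X-H19Y/NS1": 2.71, "SB100X-H19Y/NS2": 3.43}

rows = []
for (protein, dna), kd in SPECIFIC_KD.items():
    kd2 = NONSPECIFIC_KD_uM[protein] * 1e3
    # the first (specific) transition is sampled densely, mirroring the
    # experimental protocol for resolving nanomolar constants; noise is 2%
    # of each mode's amplitude
    sc = SimScenario(
        "titration",
        {"kd_nM": [kd, kd2], "amplitude": [0.5, 0.5], "conc_min_nM": 0.5,
         "conc_max_nM": 5e4, "n_points": 40,
         "protein": protein, "dna": dna},
        {"sigma": 0.01, "replicates": 3}, seed=hash((protein, dna)) % 2**31)
    series = normalize_baseline(gen_titration(sc))
    n_modes, fit = select_binding_model(series)
    rows.append({
        "protein": protein, "dna": dna, "true_kd1_nM": kd,
        "true_kd2_nM": kd2, "selected_modes": n_modes,
        "kd1_nM": fit.modes[0].kd_nM,
        "kd2_nM": fit.modes[1].kd_nM if fit.n_modes == 2 else np.nan,
        "flags": ";".join(fit.flags),
    })

biphasic = pd.DataFrame(rows)
biphasic.to_csv(OUT / "binding_biphasic.csv", index=False)
print("Biphasic transposon-site titrations (specific + nonspecific modes):")
print(biphasic.to_string(index=False, float_format=lambda x: f"{x:.3g}"))

print("\nMonophasic recovery studies (100 noise realizations each):")
rec_rows = []
for label, kd_nM, cmin, cmax in [
    ("SB10/DR-core specific", 25.3, 1.0, 500.0),
    ("SB100X/NS1 nonspecific", 560.0, 10.0, 2e4),
    ("SB100X-H19Y/NS1 nonspecific", 2710.0, 50.0, 5e4),
    ("SB100X-H19Y/NS2 nonspecific", 3430.0, 50.0, 5e4),
    ("H19Y/DR-core pH 5.2 (weak)", 510000.0, 1000.0, 5e6),
]:
    r = recover_binding_kd(kd_nM, cmin, cmax, n_seeds=100)
    rec_rows.append({"assay": label, "true_kd_nM": kd_nM,
                     "mean_kd_nM": r.mean, "sd_nM": r.sd,
                     "rel_err": r.relative_error})
    print(f"  {label}: {r.mean:.4g} nM (truth {kd_nM:g}, "
          f"rel. err {100 * r.relative_error:.2f}%)")
pd.DataFrame(rec_rows).to_csv(OUT / "binding_recovery.csv", index=False)
print(f"\nwrote {OUT / 'binding_biphasic.csv'} and {OUT / 'binding_recovery.csv'}")
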