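#!/usr/bin/env python
"""NMR titration analysis: CSP mapping, restraint selection, diffusion.

Simulates free/DNA-bound amide peak lists with perturbations planted on the
DNA-recognition helix, computes the weighted chemical-shift-perturbation
profile with its 1/2-SD thresholds, selects docking restraint residues
(CSP > 2 SD and > 50% surface accessibility), and fits Stejskal-Tanner
gradient attenuation to call the oligomeric state.  Tables under results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from paibind.nmr import (
    classify_oligomer,
    fit_diffusion,
    select_active_residues,
    weighted_csp,
)
from paibind.synthetic import SimScenario, gen_gradient_series, gen_peaklists

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

# interface residues: recognition helix H3 plus the H2-H3 loop
INTERFACE = {r: (0.12, 0.7) for r in (36, 37, 40, 41, 44, 45)} | \
    {r: (0.08, 0.45) for r in (28, 29, 30)}

free, bound = gen_peaklists(SimScenario(
    "peaklists", {"residues": list(range(1, 56)), "interface": INTERFACE,
                  "drop_probability": 0.05},
    {"jitter_ppm": 0.004}, seed=3))
profile = weighted_csp(free, bound)
print(f"CSP profile over {np.isfinite(profile.delta).sum()} residues: "
      f"mean {profile.mean:.4f} ppm, SD {profile.sd:.4f} ppm")
print(f"1-SD / 2-SD thresholds: {profile.threshold(1):.4f} / "
      f"{profile.threshold(2):.4f} ppm")
print(f"broadened beyond detection: {profile.missing_in_bound}")

# surface accessibility: recognition helix and loops exposed, helix cores
# buried (emulating the relative-SASA table a structure would provide)
rng = np.random.default_rng(5)
access = {int(r): float(np.clip(0.4 + 0.3 * rng.standard_normal(), 0, 1))
          for r in profile.residues}
access.update({r: 0.8 for r in INTERFACE})
access[37] = 0.2  # one recognition residue buried: excluded by the SASA rule
active = select_active_residues(profile, access)
print(f"active residues for docking restraints (>2 SD, >50% exposed): "
      f"{sorted(active)}")

pd.DataFrame({"residue": profile.residues, "csp_ppm": profile.delta,
              "active": [int(r) in active for r in profile.residues]}
             ).to_csv(OUT / "csp_profile.csv", index=False)

# --- PFG diffusion --------------------------------------------------------
att = gen_gradient_series(SimScenario(
    "gradient_series", {"d_m2_s": 1.86e-10}, {"sigma_frac": 0.01}, seed=2))
res = fit_diffusion(att)
call = classify_oligomer(res, d_monomer=1.9e-10, d_dimer=1.3e-10)
print(f"fitted D = {res.d_m2_s:.3e} +/- {res.d_se:.1e} m^2/s -> {call} "
      f"(references: monomer 1.9e-10, dimer 1.3e-10)")
pd.DataFrame({"g_T_m": att.g_T_m, "intensity": att.intensity}).to_csv(
    OUT / "pfg_attenuation.csv", index=False)
print(f"wrote {OUT / 'csp_profile.csv'} and {OUT / 'pfg_attenuation.csv'}")
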