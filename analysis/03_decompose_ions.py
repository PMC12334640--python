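#!/usr/bin/env python
"""Single-ion volumes from the simulated campaign, both estimation routes.

Route A (grand fit): one nonlinear least squares over all 2040 raw
densities with per-ion quadratic thermal-expansion parameters and the
proton pinned to its literature polynomial.  Route B (two-stage):
per-temperature weighted decompositions of the salt-level fits followed
by a quadratic refit per ion.  Writes the ion x temperature table and
the cation/anion curvature-contrast test, and reports recovery of the
injected ionic truth.
"""

import json
from pathlib import Path

import pandas as pd

from ionvol import SALTS, curvature_contrast, default_context, fit_salt, \
    global_ionic_fit, read_density_csv
from ionvol.ions import per_t_ionic_fit
from ionvol.literature import ION_VOLUMES

OUT = Path(__file__).resolve().parents[1] / "results"
records = read_density_csv(OUT / "synthetic_density.csv")
ctx = default_context()

ion_set = global_ionic_fit(records, ctx=ctx)
table = ion_set.table()
table.round(3).to_csv(OUT / "ion_volumes.csv")

fits = {name: fit_salt([r for r in records if r.solute == name],
                       spec, ctx, "quadratic")
        for name, spec in SALTS.items()}
per_t = per_t_ionic_fit(fits)

print("ion volume table (grand fit):")
print(table.round(2))
print("\nrecovery of injected truth (grand fit vs two-stage):")
for ion, mod in ion_set.models.items():
    truth = ION_VOLUMES[ion][0]
    se = mod.se()[0]
    print(f"  {ion:6s} truth {truth:8.2f}  grand {mod.V_ref:8.2f} "
          f"(se {se:.2f}, {(mod.V_ref - truth) / se:+.1f} se)  "
          f"two-stage {per_t.models[ion].V_ref:8.2f}")

test = curvature_contrast(ion_set)
(OUT / "curvature_test.json").write_text(
    json.dumps(test, indent=2, default=float) + "\n")
print(f"\ncurvature contrast (fitted betas): z = {test['statistic']:.2f}, "
      f"p = {test['p']:.2e}; cation mean beta "
      f"{test['mean_cation_beta']:.2e}, anion mean {test['mean_anion_beta']:.2e}")
print("(one synthetic campaign at this design resolves beta to ~1.8e-3 "
      "cm³/mol/K² per monovalent ion — ~4x the published ionic SEs — so "
      "the contrast direction is recovered but significance varies by "
      "realization; the published-coefficient test lives in script 04)")
print(f"-> {OUT / 'ion_volumes.csv'}, {OUT / 'curvature_test.json'}")
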