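#!/usr/bin/env python
"""Simulate the densimetry campaign: 16 salts + HCl, 20-40 °C, m = 1e-3
to 3e-2 mol/kg, three dilution series per solute, instrument noise
7e-6 g/cm³ and per-series solvent offsets below 2e-5 g/cm³.

The ionic ground truth is the published self-consistent ion set; salt
truths are assembled by additivity.  Writes the tidy CSV consumed by the
later stages plus a ground-truth sidecar for recovery checks.
"""

import json
from pathlib import Path

from ionvol import default_context, write_density_csv
from ionvol.literature import ion_truth_models
from ionvol.synth import DensityDesign, gen_full_study

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

design = DensityDesign(seed=20250918)
records, truth = gen_full_study(ion_truth_models(), design, default_context())
write_density_csv(records, OUT / "synthetic_density.csv")
(OUT / "synthetic_density_truth.json").write_text(
    json.dumps(truth, indent=2, default=float) + "\n")

print(f"wrote {len(records)} density records "
      f"({len({r.solute for r in records})} solutes, "
      f"{len({r.T for r in records})} temperatures) "
      f"-> {OUT / 'synthetic_density.csv'}")
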