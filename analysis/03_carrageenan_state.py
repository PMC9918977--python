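#!/usr/bin/env python
"""Classify the carrageenan chain state in each simulated gel condition.

The helix-quality index (mean fingerprint-component FWHM) separates the
sharp helical gel from the smooth coil; the perturbed helix — protein mixed
into warm polysaccharide, then cooled — keeps the component positions of the
helix but broadens them, i.e. the protein degrades helix quality without
abolishing the helical state.  Also demonstrates protein subtraction via
Amide II scaling on a protein-contaminated mixture.
"""

import json
from pathlib import Path

import numpy as np

from carragel import conformation, spectra, synthetic

ROOT = Path(__file__).resolve().parents[1] / "results"

report = {}
for state in ("helix", "coil", "perturbed_helix"):
    s = spectra.read_spectrum(ROOT / "data" / f"carrageenan_{state}.csv")
    v = conformation.classify_conformation(s)
    report[state] = {
        "state": v.state,
        "quality_index": round(v.quality_index, 2),
        "resolved_centers": [round(c, 1) for c in v.resolved_centers],
    }
    print(f"{state:16s} -> {v.state:5s}  quality {v.quality_index:5.2f} cm^-1  "
          f"centers {[round(c) for c in v.resolved_centers]}")

print("note: perturbed helix keeps the helix band positions but a larger "
      "quality index — the protein perturbs interchain packing.")

# protein-subtraction demonstration: carrageenan + 0.7 x protein
carr = synthetic.make_carrageenan_spectrum("helix", seed=0, noise_sigma=0.0)
prot = synthetic.make_protein_spectrum("native", grid=carr.wavenumbers)
mix = carr.with_absorbance(carr.absorbance + 0.7 * prot.absorbance)
recovered, scale = conformation.protein_subtract(mix, prot)
v = conformation.classify_conformation(recovered)
rms = float(np.sqrt(np.mean((recovered.absorbance - carr.absorbance) ** 2)))
print(f"protein subtraction: recovered scale {scale:.3f} (true 0.70), "
      f"residual rms {rms:.2e}, mixture still classified {v.state}")
report["protein_subtraction_demo"] = {
    "true_scale": 0.7, "recovered_scale": round(scale, 4),
    "residual_rms": rms, "verdict": v.state,
}

(ROOT / "conformation.json").write_text(json.dumps(report, indent=2) + "\n")
print("wrote results/conformation.json")
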