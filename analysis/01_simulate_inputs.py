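#!/usr/bin/env python
"""Generate the synthetic study inputs consumed by the downstream analyses.

Writes, under results/data/:
  native_gapdh.csv / gel_gapdh.csv    Amide I spectra (noiseless presets)
  carrageenan_{helix,coil,perturbed_helix}.csv   fingerprint spectra
  mixing_series.csv                   supernatant A280 over q = 0.1 ... 1.0
  poses.pdb + poses_energies.csv      3-cluster docking-pose cloud

All generators are seeded; rerunning reproduces the files bit-for-bit.
"""

from pathlib import Path

import pandas as pd

from carragel import docking, spectra, synthetic

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 0

for preset in ("native", "gel"):
    s = synthetic.make_protein_spectrum(preset, seed=SEED)
    spectra.write_spectrum(OUT / f"{preset}_gapdh.csv", s)
    print(f"wrote {preset}_gapdh.csv ({len(s)} points, "
          f"{s.wavenumbers[0]:.0f}-{s.wavenumbers[-1]:.0f} cm^-1)")

for state in ("helix", "coil", "perturbed_helix"):
    s = synthetic.make_carrageenan_spectrum(state, seed=SEED, noise_sigma=0.01)
    spectra.write_spectrum(OUT / f"carrageenan_{state}.csv", s)
    print(f"wrote carrageenan_{state}.csv ({len(s)} points, 1 % noise)")

series = synthetic.make_mixing_series(q_star=0.2, seed=SEED)
pd.DataFrame({"q": series.q, "a280": series.a280}).to_csv(
    OUT / "mixing_series.csv", index=False
)
print(f"wrote mixing_series.csv ({series.q.size} ratios, breakpoint at q = 0.2)")

cloud = synthetic.PoseCloudSpec(
    cluster_centres=[(0.0, 0.0, 0.0), (50.0, 0.0, 0.0), (0.0, 55.0, 0.0)],
    sizes=[40, 35, 25],
    sigma=3.0,
    energy_means=[-3.3, -3.0, -1.5],
    energy_sigma=0.3,
    seed=SEED,
)
poses = synthetic.make_pose_cloud(cloud)
docking.write_poses(OUT / "poses.pdb", poses, OUT / "poses_energies.csv")
print(f"wrote poses.pdb / poses_energies.csv ({len(poses)} poses, 3 sites)")
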