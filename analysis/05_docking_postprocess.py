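#!/usr/bin/env python
"""Cluster the docking-pose cloud and map binding sites and epitopes.

Energy-ranked leader clustering (15 A centroid cutoff) condenses the pose
cloud into candidate sites; the population-versus-energy table separates
true positives (populous AND within 1 kcal/mol of the minimum) from decoys.
Binding energies are then normalized per protein-contacting disaccharide
(3 repeats for a hexamer fragment, 10 for a double-helical fragment), and a
toy S-loop structure demonstrates epitope mapping by heavy-atom contacts.
"""

import json
from pathlib import Path

import numpy as np
from biotite.structure import AtomArray

from carragel import docking

ROOT = Path(__file__).resolve().parents[1] / "results"

poses = docking.read_poses(
    ROOT / "data" / "poses.pdb",
    ROOT / "data" / "poses_energies.csv",
    residues_per_disaccharide=1,
)
clusters = docking.cluster_poses(poses, cutoff=15.0)
table = docking.population_energy_table(clusters)
selected = docking.true_positives(clusters)

print(f"{len(poses)} poses -> {len(clusters)} clusters")
print(table.to_string(index=False))
print(f"true positives: {len(selected)} "
      f"(populations {[c.population for c in selected]})")
print("the populous low-energy clusters are the binding sites; the "
      "high-energy cloud is populous but uncompetitive and is rejected. "
      "Leader clustering may shear an outlying pose off a site into a tiny "
      "satellite cluster — those fall below the population floor and are "
      "likewise discarded.")

best = table["best_energy"].min()
print(f"per-disaccharide normalization of the best site ({best:.2f} kcal/mol "
      f"total): hexamer (3 repeats) -> {docking.energy_per_disaccharide(best, 3):.2f}, "
      f"double helix (10 repeats) -> {docking.energy_per_disaccharide(best, 10):.2f} "
      "kcal/mol per repeat")

# epitope mapping on a toy S-loop: residues numbered as the NAD-groove epitope
sloop = [("A", 184, "THR"), ("A", 186, "LYS"), ("A", 191, "PRO"),
         ("A", 192, "SER"), ("A", 194, "LYS")]
structure = AtomArray(len(sloop))
structure.coord = np.array([[4.0 * i, 0.0, 0.0] for i in range(len(sloop))])
structure.chain_id = np.array([r[0] for r in sloop])
structure.res_id = np.array([r[1] for r in sloop])
structure.res_name = np.array([r[2] for r in sloop])
structure.atom_name = np.full(len(sloop), "CA")
structure.element = np.full(len(sloop), "C")
structure.hetero = np.full(len(sloop), False)
ligand = docking.Pose(("C",) * 5, structure.coord + [0.0, 3.0, 0.0], best)
report = docking.contact_residues(ligand, structure)
print(f"epitope demo: contacts {[f'{n}{i}' for _, i, n in report.contact_residues]} "
      f"-> matched '{report.matched_epitope}' (Jaccard {report.overlap:.2f})")

table.to_csv(ROOT / "docking_clusters.csv", index=False)
(ROOT / "docking_summary.json").write_text(json.dumps({
    "n_poses": len(poses),
    "n_clusters": len(clusters),
    "true_positive_populations": [c.population for c in selected],
    "best_energy": float(best),
    "per_disaccharide_hexamer": docking.energy_per_disaccharide(best, 3),
    "per_disaccharide_double_helix": docking.energy_per_disaccharide(best, 10),
    "epitope_match": report.matched_epitope,
    "epitope_overlap": report.overlap,
}, indent=2) + "\n")
print("wrote results/docking_clusters.csv and results/docking_summary.json")
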