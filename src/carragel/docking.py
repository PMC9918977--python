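"""Post-processing of blind-docking pose sets.

Blind docking of carrageenan fragments over the whole GAPDH surface yields
~1000 candidate poses; the analysis here turns those into binding sites:

* energy-ranked leader clustering with a positional cutoff (ligand-centroid
  distance, deliberately orientation-blind) groups poses by location;
* the population-versus-energy table separates true binding sites (populous
  and near the energy minimum) from false positives;
* binding energies are normalized per disaccharide repeat in direct protein
  contact, so fragments of different length are comparable (e.g. 3 repeats
  for a hexamer, 10 for a double-helical fragment);
* contact residues within a heavy-atom cutoff define the binding epitope,
  which can be compared (Jaccard overlap) against the epitopes seen in the
  GAPDH oligomers: the S-loop in the NAD-binding groove, the OP-contact
  helix, and the edge beta-strands of the OR contact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from biotite.structure import AtomArray
from biotite.structure.io.pdb import PDBFile
from scipy.spatial import cKDTree

__all__ = [
    "Pose",
    "PoseCluster",
    "EpitopeReport",
    "EPITOPES",
    "cluster_poses",
    "population_energy_table",
    "true_positives",
    "energy_per_disaccharide",
    "count_interacting_disaccharides",
    "contact_residues",
    "read_structure",
    "read_poses",
    "write_poses",
]

#: GAPDH binding epitopes (residue numbers) reported for the docking hits
EPITOPES: dict[str, frozenset[int]] = {
    # polar/basic S-loop residues lining the NAD-binding groove (T184, K186,
    # P191, S192, K194) — shared by all oligomeric states
    "OR-groove S-loop": frozenset({184, 186, 191, 192, 194}),
    # aromatic/non-polar residues of the L40-Y49 helix at the OP contact
    "OP helix": frozenset({37, 42, 46}),
    # S-loop part of the OP contact (P191, K194, W196, R200)
    "OP S-loop": frozenset({191, 194, 196, 200}),
    # edge beta-strands N239-G247 and A232-P236 of the OR contact, closest
    # contacts N205/I206/P208/F233 plus basic R197/R200
    "OR edge": frozenset({205, 206, 208, 233, 197, 200}
                         | set(range(239, 248)) | set(range(232, 237))),
}


@dataclass
class Pose:
    """A docked ligand pose: coordinates, scored energy, repeat-unit map."""

    elements: tuple[str, ...]
    coords: np.ndarray                       # (n_atoms, 3), Angstrom
    energy: float
    disaccharide_map: np.ndarray | None = None  # per-atom ordinal, 1-based

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if self.coords.shape[0] < 1:
            raise ValueError("pose must have at least one atom")
        if len(self.elements) != self.coords.shape[0]:
            raise ValueError("elements and coords length mismatch")
        if not np.isfinite(self.energy):
            raise ValueError("energy must be finite")
        if self.disaccharide_map is not None:
            m = np.asarray(self.disaccharide_map, dtype=int)
            if m.size != self.coords.shape[0]:
                raise ValueError("disaccharide_map length mismatch")
            ordinals = np.unique(m)
            if not np.array_equal(ordinals, np.arange(1, ordinals.size + 1)):
                raise ValueError("disaccharide ordinals must be contiguous from 1")
            self.disaccharide_map = m

    @property
    def heavy(self) -> np.ndarray:
        """Boolean mask of heavy (non-hydrogen) atoms."""
        return np.array([e.upper() not in ("H", "D") for e in self.elements])

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)


@dataclass
class PoseCluster:
    """Poses sharing a spatial locus; leader = lowest-energy member."""

    member_ids: list[int]
    population: int
    best_energy: float
    centroid: np.ndarray                      # leader's ligand centroid

    def __post_init__(self) -> None:
        if self.population != len(self.member_ids) or self.population < 1:
            raise ValueError("population must equal the number of members (>= 1)")


def cluster_poses(poses: list[Pose], cutoff: float = 15.0) -> list[PoseCluster]:
    """Energy-ranked leader clustering on ligand-centroid distance.

    Poses are visited by ascending energy (ties broken by input index); each
    joins the first existing cluster whose leader centroid lies within
    *cutoff*, otherwise it founds a new cluster.  Centroid distance is used
    as the positional measure so the grouping is independent of fragment
    orientation.  Populations sum to the number of input poses and the result
    does not depend on input order.
    """
    if not poses:
        raise ValueError("no poses to cluster")
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    order = sorted(range(len(poses)), key=lambda i: (poses[i].energy, i))
    leaders: list[np.ndarray] = []
    members: list[list[int]] = []
    for i in order:
        c = poses[i].centroid
        for k, lead in enumerate(leaders):
            if float(np.linalg.norm(c - lead)) <= cutoff:
                members[k].append(i)
                break
        else:
            leaders.append(c)
            members.append([i])
    return [
        PoseCluster(
            member_ids=m,
            population=len(m),
            best_energy=min(poses[i].energy for i in m),
            centroid=lead,
        )
        for lead, m in zip(leaders, members)
    ]


def population_energy_table(clusters: list[PoseCluster]) -> pd.DataFrame:
    """Scatter-ready table of (population, best_energy), sorted by energy."""
    if not clusters:
        raise ValueError("no clusters")
    df = pd.DataFrame({
        "population": [c.population for c in clusters],
        "best_energy": [c.best_energy for c in clusters],
    })
    return df.sort_values("best_energy", kind="stable", ignore_index=True)


def true_positives(
    clusters: list[PoseCluster],
    min_population_frac: float = 0.05,
    energy_margin: float = 1.0,
) -> list[PoseCluster]:
    """Clusters that are both populous and energetically competitive.

    A cluster is a true positive if its population is at least
    ``min_population_frac`` of all poses *and* its best energy lies within
    ``energy_margin`` kcal/mol of the global minimum — a quantitative stand-in
    for reading the population-versus-energy scatter by eye.
    """
    if not 0 < min_population_frac <= 1:
        raise ValueError("min_population_frac must be in (0, 1]")
    total = sum(c.population for c in clusters)
    e_min = min(c.best_energy for c in clusters)
    return [
        c for c in clusters
        if c.population >= min_population_frac * total
        and c.best_energy <= e_min + energy_margin
    ]


def energy_per_disaccharide(total_energy: float, n_interacting: int) -> float:
    """Binding energy normalized per protein-contacting disaccharide repeat."""
    if n_interacting < 1:
        raise ValueError("n_interacting must be >= 1")
    return total_energy / n_interacting


def _protein_heavy_coords(protein) -> np.ndarray:
    if isinstance(protein, AtomArray):
        mask = ~np.isin(protein.element, ("H", "D"))
        return protein.coord[mask]
    coords = np.asarray(protein, dtype=float).reshape(-1, 3)
    if coords.shape[0] < 1:
        raise ValueError("protein must have at least one atom")
    return coords


def count_interacting_disaccharides(
    pose: Pose, protein, cutoff: float = 4.0
) -> int:
    """Distinct disaccharide repeats with a heavy atom within *cutoff* of the
    protein (heavy atoms only on both sides)."""
    if pose.disaccharide_map is None:
        raise ValueError("pose has no disaccharide_map")
    pcoords = _protein_heavy_coords(protein)
    heavy = pose.heavy
    d, _ = cKDTree(pcoords).query(pose.coords[heavy], k=1)
    return int(np.unique(pose.disaccharide_map[heavy][d <= cutoff]).size)


@dataclass
class EpitopeReport:
    """Protein residues contacted by a pose and the best-matching epitope."""

    contact_residues: list[tuple[str, int, str]]   # (chain, number, name)
    matched_epitope: str | None
    overlap: float                                  # Jaccard, in [0, 1]
    per_epitope: dict[str, float] = field(default_factory=dict)


def contact_residues(
    pose: Pose,
    structure: AtomArray,
    cutoff: float = 4.0,
    epitopes: dict[str, frozenset[int]] = EPITOPES,
) -> EpitopeReport:
    """Residues with a heavy atom within *cutoff* of a ligand heavy atom.

    The contact set is compared against each named epitope by Jaccard overlap
    of residue numbers; an empty contact set is a valid empty report.
    """
    mask = ~np.isin(structure.element, ("H", "D"))
    pcoord = structure.coord[mask]
    lig = pose.coords[pose.heavy]
    if lig.shape[0] == 0:
        raise ValueError("pose has no heavy atoms")
    d, _ = cKDTree(lig).query(pcoord, k=1)
    hit = d <= cutoff
    contacts: list[tuple[str, int, str]] = []
    seen: set[tuple[str, int]] = set()
    for chain, num, name in zip(
        structure.chain_id[mask][hit],
        structure.res_id[mask][hit],
        structure.res_name[mask][hit],
    ):
        key = (str(chain), int(num))
        if key not in seen:
            seen.add(key)
            contacts.append((str(chain), int(num), str(name)))
    contacts.sort(key=lambda t: (t[0], t[1]))
    numbers = {n for _, n, _ in contacts}
    per: dict[str, float] = {}
    for name, residues in epitopes.items():
        union = numbers | residues
        per[name] = len(numbers & residues) / len(union) if union else 0.0
    matched = max(per, key=per.get) if per else None
    overlap = per.get(matched, 0.0) if matched is not None else 0.0
    if overlap == 0.0:
        matched = None
    return EpitopeReport(contacts, matched, overlap, per)


# ---------------------------------------------------------------------------
# structure and pose I/O (PDB + CSV energy table)
# ---------------------------------------------------------------------------

def read_structure(path) -> AtomArray:
    """First model of a PDB file as a biotite AtomArray."""
    return PDBFile.read(str(path)).get_structure(model=1)


def read_poses(
    pdb_path,
    energies,
    residues_per_disaccharide: int = 2,
) -> list[Pose]:
    """Load a pose set from a multi-model PDB plus a pose-energy table.

    *energies* is a CSV path or DataFrame with columns ``model`` (1-based,
    matching MODEL records) and ``energy`` (kcal/mol).  Consecutive ligand
    residues are grouped into disaccharide repeats (two pyranose rings per
    repeat by default).
    """
    if not isinstance(energies, pd.DataFrame):
        energies = pd.read_csv(energies)
    if not {"model", "energy"}.issubset(energies.columns):
        raise ValueError("energy table needs 'model' and 'energy' columns")
    emap = dict(zip(energies["model"].astype(int), energies["energy"].astype(float)))
    stack = PDBFile.read(str(pdb_path)).get_structure()
    poses: list[Pose] = []
    for i in range(stack.stack_depth()):
        model_no = i + 1
        if model_no not in emap:
            raise ValueError(f"no energy for model {model_no}")
        atoms = stack[i]
        res_ids = atoms.res_id
        _, res_rank = np.unique(res_ids, return_inverse=True)
        dmap = res_rank // residues_per_disaccharide + 1
        poses.append(Pose(
            elements=tuple(atoms.element),
            coords=np.array(atoms.coord),
            energy=emap[model_no],
            disaccharide_map=dmap,
        ))
    return poses


def write_poses(pdb_path, poses: list[Pose], energy_csv_path=None) -> None:
    """Write a pose set as a multi-model PDB (+ optional energy CSV).

    All poses must share an atom layout (true for synthetic clouds).
    """
    n = poses[0].coords.shape[0]
    if any(p.coords.shape[0] != n for p in poses):
        raise ValueError("all poses must have the same number of atoms")
    from biotite.structure import AtomArrayStack

    stack = AtomArrayStack(len(poses), n)
    stack.coord = np.stack([p.coords for p in poses])
    stack.element = np.array([e.upper() for e in poses[0].elements])
    stack.atom_name = np.array(
        [f"{e.upper()}{i + 1}" for i, e in enumerate(poses[0].elements)]
    )
    if poses[0].disaccharide_map is not None:
        stack.res_id = np.asarray(poses[0].disaccharide_map, dtype=int)
    else:
        stack.res_id = np.ones(n, dtype=int)
    stack.res_name = np.full(n, "LIG")
    stack.chain_id = np.full(n, "L")
    stack.hetero = np.full(n, True)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(pdb_path))
    if energy_csv_path is not None:
        pd.DataFrame({
            "model": np.arange(1, len(poses) + 1),
            "energy": [p.energy for p in poses],
        }).to_csv(energy_csv_path, index=False)
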