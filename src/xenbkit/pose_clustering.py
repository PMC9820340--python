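"""Ligand pose clustering over trajectory frames.

Pipeline: superpose every frame onto every other by the protein (fit)
selection, measure the ligand's heavy-atom RMSD without re-fitting the ligand
— so what is measured is the pose relative to the binding site — then run
DBSCAN on the precomputed distance matrix (defaults eps = 1.5 Angstrom,
min_points = 5) and pick each cluster's medoid as its representative
conformation.  Binding-site contacts are the residues with any atom within a
cutoff (default 3.0 Angstrom) of any ligand atom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import kabsch_superpose
from .struct_io import AtomSelection, Structure, Trajectory

#: Clustering defaults: neighborhood radius (Angstrom RMSD) and minimum
#: neighbor count (the point itself included).
DEFAULT_EPS = 1.5
DEFAULT_MIN_POINTS = 5
DEFAULT_CONTACT_CUTOFF = 3.0


@dataclass
class RMSDMatrix:
    """Symmetric pairwise ligand-RMSD matrix over frames, Angstrom."""

    frame_ids: list[int]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.frame_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match frame_ids length")
        if np.any(self.values < 0):
            raise ValueError("RMSD matrix entries must be nonnegative")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("RMSD matrix must be symmetric (within 1e-9)")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-9):
            raise ValueError("RMSD matrix diagonal must be zero")

    def index_of(self, frame_id: int) -> int:
        try:
            return self.frame_ids.index(frame_id)
        except ValueError as exc:
            raise KeyError(f"frame {frame_id} not in matrix") from exc


@dataclass
class ClusterResult:
    labels: np.ndarray  # per-frame; -1 = noise, 0..k-1 = clusters
    medoid_frames: list[int]  # one frame id per cluster, by label
    parameters: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.medoid_frames)

    def members(self, label: int, frame_ids: list[int]) -> list[int]:
        return [fid for fid, lab in zip(frame_ids, self.labels) if lab == label]


@dataclass
class ContactSet:
    residues: list[tuple[str, int, str]]  # (chain, residue_id, residue_name)
    cutoff: float


def ligand_rmsd_matrix(
    traj: Trajectory, ligand: AtomSelection, fit: AtomSelection
) -> RMSDMatrix:
    """Pairwise ligand RMSD between frames after superposing by ``fit``.

    Entry (i, j) superposes frame j onto frame i using the fit selection
    (e.g. protein heavy atoms), then takes the raw RMSD of the ligand
    selection; (i, j) and (j, i) are averaged (they coincide analytically for
    a unique optimal fit).  The ligand selection must exclude hydrogens.
    """
    topo = traj.topology
    ligand.validate(topo)
    fit.validate(topo)
    if len(ligand) == 0 or len(fit) == 0:
        raise ValueError("ligand and fit selections must be nonempty")
    hydrogens = [i for i in ligand.indices if topo.atoms[i].element.upper() == "H"]
    if hydrogens:
        names = [topo.atoms[i].name for i in hydrogens]
        raise ValueError(
            f"ligand selection must exclude hydrogens; found {names}"
        )
    lig = list(ligand.indices)
    fit_idx = list(fit.indices)
    n = traj.n_frames
    values = np.zeros((n, n))
    lig_coords = traj.frames[:, lig, :]
    fit_coords = traj.frames[:, fit_idx, :]
    for i in range(n):
        for j in range(i + 1, n):
            transform, _ = kabsch_superpose(fit_coords[j], fit_coords[i])
            moved = transform.apply(lig_coords[j])
            d_ij = float(
                np.sqrt(np.mean(np.sum((moved - lig_coords[i]) ** 2, axis=1)))
            )
            inv, _ = kabsch_superpose(fit_coords[i], fit_coords[j])
            moved_back = inv.apply(lig_coords[i])
            d_ji = float(
                np.sqrt(np.mean(np.sum((moved_back - lig_coords[j]) ** 2, axis=1)))
            )
            values[i, j] = values[j, i] = 0.5 * (d_ij + d_ji)
    return RMSDMatrix(list(range(n)), values)


def dbscan(
    matrix: RMSDMatrix,
    eps: float = DEFAULT_EPS,
    min_points: int = DEFAULT_MIN_POINTS,
) -> ClusterResult:
    """Classic DBSCAN on a precomputed distance matrix.

    A core point has at least ``min_points`` neighbors within ``eps``
    (counting itself).  Clusters are the connected components of core points
    under eps-adjacency; border points (non-core with a core neighbor) join
    the cluster of their lowest-labeled core neighbor; everything else is
    noise (-1).  Labels are assigned in order of each component's smallest
    frame index, so the output is deterministic and reorder-equivariant up to
    relabeling.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if min_points < 1:
        raise ValueError("min_points must be >= 1")
    dist = matrix.values
    n = dist.shape[0]
    adjacency = dist <= eps
    neighbor_counts = adjacency.sum(axis=1)  # self included (zero diagonal)
    core = neighbor_counts >= min_points
    labels = np.full(n, -1, dtype=int)
    next_label = 0
    for start in range(n):
        if not core[start] or labels[start] != -1:
            continue
        # flood-fill the core component containing `start`
        stack = [start]
        labels[start] = next_label
        while stack:
            p = stack.pop()
            for q in np.nonzero(adjacency[p] & core)[0]:
                if labels[q] == -1:
                    labels[q] = next_label
                    stack.append(q)
        next_label += 1
    # attach border points to the lowest-labeled core neighbor
    for p in range(n):
        if core[p] or not adjacency[p][core].any():
            continue
        core_neighbor_labels = labels[np.nonzero(adjacency[p] & core)[0]]
        labels[p] = int(core_neighbor_labels.min())
    medoids = [
        medoid(matrix, [matrix.frame_ids[i] for i in np.nonzero(labels == lab)[0]])
        for lab in range(next_label)
    ]
    return ClusterResult(
        labels=labels,
        medoid_frames=medoids,
        parameters={"eps": eps, "min_points": min_points},
    )


def medoid(matrix: RMSDMatrix, cluster_members: list[int]) -> int:
    """The member minimizing summed RMSD to the others; ties -> lowest frame id."""
    if not cluster_members:
        raise ValueError("medoid of an empty member list is undefined")
    idx = [matrix.index_of(fid) for fid in cluster_members]
    sub = matrix.values[np.ix_(idx, idx)]
    sums = sub.sum(axis=1)
    best = min(range(len(idx)), key=lambda k: (sums[k], cluster_members[k]))
    return cluster_members[best]


def contact_residues(
    structure: Structure,
    ligand: AtomSelection,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> ContactSet:
    """Residues with any atom within ``cutoff`` of any ligand atom.

    The ligand's own residue(s) are excluded; results are sorted by residue
    id (then chain).  Hydrogens count like any other atom.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ligand.validate(structure)
    if len(ligand) == 0:
        raise ValueError("ligand selection is empty")
    lig_idx = set(ligand.indices)
    lig_residues = {
        (structure.atoms[i].chain, structure.atoms[i].residue_id)
        for i in ligand.indices
    }
    other_idx = [
        i
        for i, a in enumerate(structure.atoms)
        if i not in lig_idx and (a.chain, a.residue_id) not in lig_residues
    ]
    found: set[tuple[str, int, str]] = set()
    if other_idx:
        coords = structure.coords
        tree = cKDTree(coords[other_idx])
        for i in ligand.indices:
            for k in tree.query_ball_point(coords[i], cutoff):
                a = structure.atoms[other_idx[k]]
                found.add((a.chain, a.residue_id, a.residue_name))
    residues = sorted(found, key=lambda r: (r[1], r[0]))
    return ContactSet(residues=residues, cutoff=cutoff)
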