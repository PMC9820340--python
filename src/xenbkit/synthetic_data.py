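"""Synthetic fixtures: enzyme-ligand trajectories, toy rings, and orbital tables.

The trajectory generator emulates what a long explicit-solvent simulation of a
flavoenzyme-nitroaromatic complex delivers to the analysis stages: a fixed
binding-pocket scaffold (an FMN-like cofactor residue carrying the hydride
donor atom N5 plus a few pocket residues), and a rigid planar
trinitrotoluene-like ligand whose pose is re-drawn each frame from a small
set of Gaussian modes.  Poses are sampled, not propagated — there is no
force field, no solvent, no dynamics.  The hydride acceptor-donor (HAD)
distance is realized exactly as a Gaussian with the recipe's mean and
standard deviation by sliding the ligand along the donor-acceptor axis, so
distributional tests have closed-form expectations.  An optional escape event
makes the ligand drift out of the pocket at a constant rate, the unstable
counterpart to a bound complex.

Everything is deterministic under the recipe seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .reactivity import OrbitalEnergies
from .struct_io import Atom, Structure, Trajectory, read_orbital_table

_ORBITAL_FIXTURE = "data/orbital_energies.csv"

#: Geometry constants for the ligand template, Angstrom.
_RING_BOND = 1.39
_C_N_NITRO = 1.47
_N_O = 1.22
_C_H = 1.08
_C_C_METHYL = 1.50

#: Base pose: ligand plane height above the cofactor plane and the lateral
#: offset that puts the acceptor nitro nitrogen ~3.5 Angstrom from donor N5.
_STACK_HEIGHT = 3.3
_BASE_HAD = 3.5


class GeometryError(ValueError):
    """A recipe asks for a ligand placement that collides with the scaffold."""


@dataclass(frozen=True)
class PoseMode:
    """One Gaussian ligand pose mode: rigid displacement + isotropic noise."""

    displacement: tuple[float, float, float]  # Angstrom
    weight: float
    sd: float  # positional standard deviation, Angstrom


@dataclass(frozen=True)
class EscapeEvent:
    escape_frame: int
    drift_rate: float  # Angstrom per frame


@dataclass
class ComplexRecipe:
    """Parameters of one synthetic enzyme-ligand trajectory."""

    n_frames: int = 500
    frame_interval: float = 0.02  # ns (50 frames per ns)
    pose_modes: list[PoseMode] = field(
        default_factory=lambda: [PoseMode((0.0, 0.0, 0.0), 1.0, 0.3)]
    )
    had_mean: float = 3.5  # Angstrom
    had_sd: float = 0.2
    escape: EscapeEvent | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not self.pose_modes:
            raise ValueError("at least one pose mode required")
        if any(m.sd <= 0 for m in self.pose_modes):
            raise ValueError("pose mode standard deviations must be positive")
        total = sum(m.weight for m in self.pose_modes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pose mode weights must sum to 1 (got {total})")
        if self.had_sd <= 0:
            raise ValueError("had_sd must be positive")


def full_scale_recipe(seed: int = 0, **kwargs) -> ComplexRecipe:
    """The full-length preset: 10,000 frames at 50 frames/ns (200 ns)."""
    return ComplexRecipe(n_frames=10_000, frame_interval=0.02, seed=seed, **kwargs)


def _rot2d(v: np.ndarray, angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1], 0.0])


def make_ring(n: int = 6, bond_length: float = 1.39, element: str = "C") -> Structure:
    """Regular planar n-gon in the xy-plane, centered at the origin.

    For a hexagon the bond length equals the circumradius, the benzene-like
    fixture geometry.
    """
    if n < 3:
        raise ValueError("a ring needs at least 3 atoms")
    radius = bond_length / (2.0 * np.sin(np.pi / n))
    atoms = []
    for k in range(n):
        angle = np.pi / 2 - 2 * np.pi * k / n
        pos = radius * np.array([np.cos(angle), np.sin(angle), 0.0])
        atoms.append(Atom(element, f"{element}{k + 1}", "RNG", 1, "A", pos))
    return Structure(atoms, title=f"{n}-membered {element} ring")


def tnt_template() -> Structure:
    """A rigid planar TNT-like molecule: ring C1-C6, methyl C7, nitro groups
    on C2/C4/C6 (N2, N4, N6 with O{k}1/O{k}2), ring H3/H5 and methyl H71-H73.

    16 heavy atoms + 5 hydrogens, centered on the ring centroid, xy-plane.
    """
    atoms: list[Atom] = []

    def add(element: str, name: str, pos: np.ndarray) -> None:
        atoms.append(Atom(element, name, "TNT", 500, "A", pos))

    ring = {}
    for k in range(1, 7):
        angle = np.pi / 2 - np.pi / 3 * (k - 1)
        pos = _RING_BOND * np.array([np.cos(angle), np.sin(angle), 0.0])
        ring[k] = pos
        add("C", f"C{k}", pos)
    out = {k: ring[k] / np.linalg.norm(ring[k]) for k in ring}
    add("C", "C7", ring[1] + _C_C_METHYL * out[1])
    for k in (2, 4, 6):
        n_pos = ring[k] + _C_N_NITRO * out[k]
        add("N", f"N{k}", n_pos)
        add("O", f"O{k}1", n_pos + _N_O * _rot2d(out[k], 60.0))
        add("O", f"O{k}2", n_pos + _N_O * _rot2d(out[k], -60.0))
    for k in (3, 5):
        add("H", f"H{k}", ring[k] + _C_H * out[k])
    c7 = ring[1] + _C_C_METHYL * out[1]
    u = out[1]
    p = _rot2d(u, 90.0)
    z = np.array([0.0, 0.0, 1.0])
    for name, direction in (
        ("H71", 0.33 * u + 0.94 * z),
        ("H72", 0.33 * u + 0.82 * p + 0.10 * z),
        ("H73", 0.33 * u - 0.82 * p + 0.10 * z),
    ):
        add("H", name, c7 + 1.09 * direction / np.linalg.norm(direction))
    return Structure(atoms, title="TNT-like planar ligand template")


def _scaffold_atoms() -> list[Atom]:
    """Binding pocket: FMN-like residue (N5 at the origin, plane z=0) and
    three pocket residues placed ~2.8 Angstrom from the base ligand pose,
    plus one distant residue that must never register as a contact."""

    def atom(element, name, resname, resid, pos):
        return Atom(element, name, resname, resid, "A", np.asarray(pos, float))

    fmn = [
        atom("N", "N5", "FMN", 400, (0.0, 0.0, 0.0)),
        atom("C", "C4A", "FMN", 400, (1.39, 0.0, 0.0)),
        atom("C", "C5A", "FMN", 400, (-0.70, -1.20, 0.0)),
        atom("N", "N10", "FMN", 400, (-1.39, 1.20, 0.0)),
        atom("C", "C10", "FMN", 400, (0.0, 2.00, 0.0)),
    ]
    lig = tnt_template().coords + _base_translation()
    # ligand template atom order: C1..C6 -> 0..5, C7 -> 6, N4 group -> 10..12,
    # N6 group -> 13..15
    c1, c5, n4, n6 = lig[0], lig[4], lig[10], lig[13]

    def offset(base, direction, dist):
        direction = np.asarray(direction, float)
        return base + dist * direction / np.linalg.norm(direction)

    tyr65 = [
        atom("C", "CZ", "TYR", 65, offset(c1, (0, 0, 1), 2.8)),
        atom("O", "OH", "TYR", 65, offset(c1, (0, 0, 1), 4.2)),
        atom("C", "CE1", "TYR", 65, offset(c1, (0.5, 0.3, 1), 3.4)),
    ]
    leu129 = [
        atom("C", "CD1", "LEU", 129, offset(n4, (0.0, -0.87, 0.5), 2.8)),
        atom("C", "CG", "LEU", 129, offset(n4, (0.0, -0.87, 0.5), 4.3)),
    ]
    tyr335 = [
        atom("C", "CE2", "TYR", 335, offset(n6, (-0.85, 0.3, 0.43), 2.8)),
        atom("C", "CD2", "TYR", 335, offset(n6, (-0.85, 0.3, 0.43), 4.3)),
    ]
    gly200 = [
        atom("C", "CA", "GLY", 200, (10.0, -9.0, 9.0)),
        atom("C", "C", "GLY", 200, (11.3, -9.0, 9.0)),
    ]
    return fmn + tyr65 + leu129 + tyr335 + gly200


def _base_translation() -> np.ndarray:
    """Rigid translation putting the template's N2 acceptor ~3.5 A from N5."""
    template = tnt_template()
    n2_local = next(
        a.position for a in template.atoms if a.name == "N2"
    )
    lateral = np.sqrt(max(_BASE_HAD**2 - _STACK_HEIGHT**2, 0.0))
    n2_target = np.array([lateral, 0.0, _STACK_HEIGHT])
    return n2_target - n2_local


def make_pocket_complex() -> Structure:
    """Static pocket + ligand complex at the base pose (frame-0 geometry)."""
    scaffold = _scaffold_atoms()
    template = tnt_template()
    shift = _base_translation()
    lig = [
        Atom(a.element, a.name, a.residue_name, a.residue_id, a.chain,
             a.position + shift)
        for a in template.atoms
    ]
    return Structure(scaffold + lig, title="synthetic XenB-like pocket with TNT ligand")


def make_complex_trajectory(recipe: ComplexRecipe) -> Trajectory:
    """Sample an enzyme-ligand trajectory from a recipe.

    Per frame: a pose mode is drawn by weight, the ligand is displaced by the
    mode vector plus isotropic Gaussian noise, then slid along the donor ->
    acceptor (N5 -> N2) axis so the realized HAD distance equals a
    N(had_mean, had_sd) draw.  After an escape event the slide is dropped and
    the ligand drifts away at the event's rate instead.
    """
    topo = make_pocket_complex()
    n_scaffold = len(_scaffold_atoms())
    base = topo.coords
    lig_base = base[n_scaffold:]
    n5 = base[[i for i, a in enumerate(topo.atoms) if a.name == "N5"][0]]
    n2_row = [
        i - n_scaffold
        for i, a in enumerate(topo.atoms)
        if a.name == "N2" and a.residue_name == "TNT"
    ][0]
    heavy_lig = np.array(
        [a.element.upper() != "H" for a in topo.atoms[n_scaffold:]]
    )
    scaffold_coords = base[:n_scaffold]

    # refuse recipes whose mode centers bury the ligand in the scaffold
    for mode in recipe.pose_modes:
        displaced = lig_base[heavy_lig] + np.asarray(mode.displacement, float)
        dmin = np.min(
            np.linalg.norm(
                displaced[:, None, :] - scaffold_coords[None, :, :], axis=2
            )
        )
        if dmin < 0.8:
            raise GeometryError(
                f"pose mode displacement {mode.displacement} places the ligand "
                f"{dmin:.2f} Angstrom from the scaffold (< 0.8)"
            )

    rng = np.random.default_rng(recipe.seed)
    n = recipe.n_frames
    mode_idx = rng.choice(
        len(recipe.pose_modes), size=n, p=[m.weight for m in recipe.pose_modes]
    )
    noise = rng.standard_normal((n, 3))
    had_targets = rng.normal(recipe.had_mean, recipe.had_sd, size=n)
    escape_dir = np.array([1.0, 1.0, 1.0]) / np.sqrt(3.0)

    # HAD offsets per mode: a displaced mode keeps its own donor-acceptor
    # distance, so the slide below never fights the planted mode geometry.
    d_base = float(np.linalg.norm(lig_base[n2_row] - n5))
    mode_offsets = [
        float(
            np.linalg.norm(
                lig_base[n2_row] + np.asarray(m.displacement, float) - n5
            )
        )
        - d_base
        for m in recipe.pose_modes
    ]

    frames = np.empty((n, topo.n_atoms, 3))
    frames[:, :n_scaffold, :] = scaffold_coords[None, :, :]
    for i in range(n):
        mode = recipe.pose_modes[mode_idx[i]]
        disp = np.asarray(mode.displacement, float) + mode.sd * noise[i]
        lig = lig_base + disp
        escaped = (
            recipe.escape is not None and i >= recipe.escape.escape_frame
        )
        if escaped:
            steps = i - recipe.escape.escape_frame + 1
            lig = lig + recipe.escape.drift_rate * steps * escape_dir
        else:
            # slide along the donor->acceptor axis so the realized HAD equals
            # the Gaussian draw plus this mode's geometric offset
            delta = lig[n2_row] - n5
            dist = np.linalg.norm(delta)
            target = had_targets[i] + mode_offsets[mode_idx[i]]
            lig = lig + (target - dist) * (delta / dist)
        frames[i, n_scaffold:, :] = lig
    times = recipe.frame_interval * np.arange(n, dtype=float)
    return Trajectory(topo, frames, frame_times=times)


def table2_fixture() -> list[OrbitalEnergies]:
    """The packaged seven-compound frontier-orbital fixture (eV)."""
    path = resources.files("xenbkit").joinpath(_ORBITAL_FIXTURE)
    with resources.as_file(path) as p:
        return read_orbital_table(p)


def printed_gaps() -> dict[str, float]:
    """The published per-compound HOMO-LUMO gaps (eV) as printed.

    Kept separately from the orbital-energy columns because the published
    gaps were computed from unrounded energies: differencing the rounded
    orbital columns does not reproduce them for every compound.
    """
    path = resources.files("xenbkit").joinpath(_ORBITAL_FIXTURE)
    with resources.as_file(path) as p:
        df = pd.read_csv(p)
    return dict(zip(df["compound"], df["gap_printed"].astype(float)))
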