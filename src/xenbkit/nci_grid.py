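"""Promolecular non-covalent interaction (NCI) index on volumetric grids.

The molecular electron density is approximated promolecularly: a sum of
spherical free-atom densities, each modelled as a sum of decaying
exponentials rho_atom(r) = sum_i c_i exp(-r / zeta_i) in atomic units.  From
the analytic density, gradient, and Hessian the reduced density gradient

    s = |grad rho| / (2 (3 pi^2)^(1/3) rho^(4/3))

is computed pointwise.  Weak-interaction regions are the low-s, low-density
points; they are classified by sign(lambda2) * rho, where lambda2 is the
middle eigenvalue of the density Hessian: negative means attractive
(hydrogen-bond-like), near zero van der Waals, positive repulsive (steric
crowding, e.g. ring centers).

The shipped proatom parameters are occupation-normalized exponential shells
built from Clementi-Raimondi screened exponents: a shell of occupation n and
exponent z contributes (n z^3 / pi) exp(-2 z r), which is the exact 1s shell
density and integrates to n electrons for every shell.  They are data, not
doctrine: any parameter table with positive coefficients can be swapped in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .struct_io import (
    BOHR_PER_ANGSTROM,
    AtomSelection,
    Structure,
    VolumetricGrid,
)

#: (coefficient, decay length) pairs per element, atomic units.
PROATOM_PARAMETERS: dict[str, list[tuple[float, float]]] = {
    "H": [(0.318310, 0.500000)],
    "C": [(116.211625, 0.088141), (2.648386, 0.310887), (2.453778, 0.318898)],
    "N": [(188.495129, 0.075018), (4.532024, 0.259916), (6.727252, 0.260824)],
    "O": [(285.896735, 0.065292), (7.210964, 0.222638), (14.055190, 0.224558)],
    "P": [
        (1964.117064, 0.034346), (73.775283, 0.102556), (321.441403, 0.090560),
        (4.234181, 0.265873), (4.126432, 0.306974),
    ],
    "S": [
        (2389.508726, 0.032173), (95.552673, 0.094084), (410.162111, 0.083493),
        (6.085559, 0.235593), (7.768545, 0.273628),
    ],
}

#: Default grid spacing for NCI fields, Angstrom.
DEFAULT_SPACING = 0.15
DEFAULT_S_MAX = 0.5
DEFAULT_SIGNED_RHO_CUT = 0.01  # a.u.

_RDG_PREFACTOR = 2.0 * (3.0 * np.pi**2) ** (1.0 / 3.0)


@dataclass(frozen=True)
class ProatomModel:
    """Spherical free-atom densities as sums of exponentials, atomic units."""

    terms: dict[str, tuple[tuple[float, float], ...]]

    def __post_init__(self) -> None:
        clean = {}
        for el, pairs in self.terms.items():
            pairs = tuple((float(c), float(z)) for c, z in pairs)
            if not pairs or any(c <= 0 or z <= 0 for c, z in pairs):
                raise ValueError(
                    f"proatom {el}: coefficients and decay lengths must be positive"
                )
            clean[el.upper()] = pairs
        object.__setattr__(self, "terms", clean)

    @classmethod
    def default(cls) -> "ProatomModel":
        return cls({el: tuple(pairs) for el, pairs in PROATOM_PARAMETERS.items()})

    def density(self, element: str, r: np.ndarray) -> np.ndarray:
        """rho_atom(r), r in Bohr."""
        r = np.asarray(r, dtype=float)
        out = np.zeros_like(r)
        for c, zeta in self._pairs(element):
            out += c * np.exp(-r / zeta)
        return out

    def _pairs(self, element: str) -> tuple[tuple[float, float], ...]:
        pairs = self.terms.get(element.upper())
        if pairs is None:
            raise KeyError(
                f"element {element!r} missing from the proatom model "
                f"(available: {', '.join(sorted(self.terms))})"
            )
        return pairs


@dataclass
class NCIGrid:
    """Co-registered NCI fields on one grid: geometry in Angstrom, fields in a.u."""

    origin: np.ndarray  # Angstrom
    axes: np.ndarray  # (3, 3) Angstrom
    shape: tuple[int, int, int]
    rho: np.ndarray  # density, a.u., z-fastest
    grad: np.ndarray  # (N, 3) density gradient, a.u.
    hessian: np.ndarray  # (N, 3, 3), a.u.
    lambda2: np.ndarray  # middle Hessian eigenvalue, a.u.
    s: np.ndarray | None = None  # reduced gradient, dimensionless

    @property
    def signed_lambda2_rho(self) -> np.ndarray:
        return np.sign(self.lambda2) * self.rho

    def points(self) -> np.ndarray:
        return self._geometry(self.rho).points()

    def _geometry(self, values: np.ndarray) -> VolumetricGrid:
        return VolumetricGrid(self.origin, self.axes, self.shape, values)

    def rho_grid(self) -> VolumetricGrid:
        return self._geometry(self.rho)

    def s_grid(self) -> VolumetricGrid:
        if self.s is None:
            raise ValueError("reduced gradient not yet computed")
        return self._geometry(self.s)

    def signed_rho_grid(self) -> VolumetricGrid:
        return self._geometry(self.signed_lambda2_rho)


@dataclass
class NCIClassification:
    """Partition of retained (s < s_max) grid points by sign(lambda2) * rho."""

    s_max: float
    signed_rho_cut: float  # a.u.
    attractive: np.ndarray  # point indices
    van_der_waals: np.ndarray
    repulsive: np.ndarray
    centroids: dict[str, np.ndarray | None]  # Angstrom, None when empty

    @property
    def counts(self) -> dict[str, int]:
        return {
            "attractive": int(self.attractive.size),
            "van_der_waals": int(self.van_der_waals.size),
            "repulsive": int(self.repulsive.size),
        }

    @property
    def n_retained(self) -> int:
        return sum(self.counts.values())


def grid_from_box(
    lower: np.ndarray,
    upper: np.ndarray,
    spacing: float = DEFAULT_SPACING,
) -> VolumetricGrid:
    """Axis-aligned grid covering [lower, upper] (Angstrom) at ~spacing steps."""
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    span = np.maximum(upper - lower, 0.0)
    shape = tuple(int(np.ceil(s / spacing)) + 1 for s in span)
    axes = np.diag([spacing] * 3)
    return VolumetricGrid(lower, axes, shape, np.zeros(int(np.prod(shape))))


def promolecular_fields(
    structure: Structure,
    model: ProatomModel | None = None,
    grid: VolumetricGrid | None = None,
    spacing: float = DEFAULT_SPACING,
    padding: float = 2.0,
) -> NCIGrid:
    """Promolecular density, gradient, and Hessian on a grid.

    All derivatives are analytic (accumulated per exponential term); the
    middle Hessian eigenvalue lambda2 is computed at every point.  When no
    grid is given, an axis-aligned box around the structure plus ``padding``
    Angstrom is used.  Hydrogens may legitimately be absent from heavy-atom
    structures; a warning is emitted so the omission is visible.
    """
    model = model or ProatomModel.default()
    if grid is None:
        coords = structure.coords
        grid = grid_from_box(
            coords.min(axis=0) - padding, coords.max(axis=0) + padding, spacing
        )
    missing = sorted(
        {a.element.upper() for a in structure.atoms} - set(model.terms)
    )
    if missing:
        raise KeyError(
            f"element(s) missing from the proatom model: {', '.join(missing)}"
        )
    if not any(a.element.upper() == "H" for a in structure.atoms):
        warnings.warn(
            "structure carries no hydrogens; promolecular fields are "
            "heavy-atom only",
            stacklevel=2,
        )
    points_b = grid.points() * BOHR_PER_ANGSTROM
    n = points_b.shape[0]
    rho = np.zeros(n)
    grad = np.zeros((n, 3))
    hess = np.zeros((n, 3, 3))
    eye = np.eye(3)
    for atom in structure.atoms:
        center_b = atom.position * BOHR_PER_ANGSTROM
        delta = points_b - center_b[None, :]
        r = np.linalg.norm(delta, axis=1)
        r_safe = np.maximum(r, 1e-12)
        u = delta / r_safe[:, None]
        for c, zeta in model._pairs(atom.element):
            e = c * np.exp(-r_safe / zeta)
            f1 = -e / zeta  # d rho / d r
            f2 = e / zeta**2  # d2 rho / d r2
            rho += e
            grad += f1[:, None] * u
            uuT = u[:, :, None] * u[:, None, :]
            hess += f2[:, None, None] * uuT
            hess += (f1 / r_safe)[:, None, None] * (eye[None, :, :] - uuT)
    eigvals = np.linalg.eigvalsh(hess)  # ascending
    return NCIGrid(
        origin=grid.origin.copy(),
        axes=grid.axes.copy(),
        shape=grid.shape,
        rho=rho,
        grad=grad,
        hessian=hess,
        lambda2=eigvals[:, 1],
    )


def reduced_gradient(rho: np.ndarray, grad: np.ndarray) -> np.ndarray:
    """Pointwise reduced density gradient s = |grad rho| / (2 (3 pi^2)^(1/3) rho^(4/3))."""
    rho = np.asarray(rho, dtype=float)
    grad = np.asarray(grad, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("reduced gradient requires strictly positive density")
    gnorm = np.linalg.norm(grad, axis=-1)
    return gnorm / (_RDG_PREFACTOR * rho ** (4.0 / 3.0))


def nci_fields(
    structure: Structure,
    model: ProatomModel | None = None,
    grid: VolumetricGrid | None = None,
    spacing: float = DEFAULT_SPACING,
    padding: float = 2.0,
) -> NCIGrid:
    """promolecular_fields plus the reduced gradient, in one call."""
    out = promolecular_fields(structure, model, grid, spacing, padding)
    out.s = reduced_gradient(out.rho, out.grad)
    return out


def classify_nci(
    grid: NCIGrid,
    s_max: float = DEFAULT_S_MAX,
    signed_rho_cut: float = DEFAULT_SIGNED_RHO_CUT,
) -> NCIClassification:
    """Partition low-reduced-gradient points into attractive / vdW / repulsive.

    Retains points with s < s_max, then splits by sign(lambda2)*rho against
    +/- signed_rho_cut.  An empty retention yields an empty classification
    with a warning, not an error.
    """
    if s_max <= 0 or signed_rho_cut <= 0:
        raise ValueError("thresholds must be positive")
    if grid.s is None:
        grid.s = reduced_gradient(grid.rho, grid.grad)
    retained = np.nonzero(grid.s < s_max)[0]
    if retained.size == 0:
        warnings.warn("no grid points below s_max; empty NCI classification",
                      stacklevel=2)
    signed = grid.signed_lambda2_rho[retained]
    attractive = retained[signed < -signed_rho_cut]
    repulsive = retained[signed > signed_rho_cut]
    vdw = retained[np.abs(signed) <= signed_rho_cut]
    points = grid.points() if retained.size else None
    centroids = {
        name: (points[idx].mean(axis=0) if idx.size else None)
        for name, idx in [
            ("attractive", attractive),
            ("van_der_waals", vdw),
            ("repulsive", repulsive),
        ]
    }
    return NCIClassification(
        s_max=s_max,
        signed_rho_cut=signed_rho_cut,
        attractive=attractive,
        van_der_waals=vdw,
        repulsive=repulsive,
        centroids=centroids,
    )


def interfacial_nci(
    complex_structure: Structure,
    ligand: AtomSelection,
    model: ProatomModel | None = None,
    margin: float = 3.0,
    spacing: float = DEFAULT_SPACING,
    s_max: float = DEFAULT_S_MAX,
    signed_rho_cut: float = DEFAULT_SIGNED_RHO_CUT,
) -> tuple[NCIGrid, NCIClassification]:
    """NCI fields in a box around the ligand, padded by ``margin`` Angstrom.

    The density includes every atom of the complex, so enzyme-ligand
    interface features fall inside the box; the default margin of 3 Angstrom
    matches the usual contact-residue shell.
    """
    ligand.validate(complex_structure)
    if len(ligand) == 0:
        raise ValueError("ligand selection is empty")
    coords = complex_structure.coords[list(ligand.indices)]
    grid = grid_from_box(coords.min(axis=0) - margin, coords.max(axis=0) + margin,
                         spacing)
    fields = nci_fields(complex_structure, model, grid)
    return fields, classify_nci(fields, s_max, signed_rho_cut)
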