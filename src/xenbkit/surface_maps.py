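"""Point-charge electrostatic potential maps and ring-current bookkeeping.

The electrostatic potential is evaluated at monopole (point-charge) level,
V(r) = sum_a q_a / |r - R_a| in atomic units, from user-supplied partial
charges (e.g. a RESP fit).  Extrema are reported on a van der Waals-scaled
shell around the molecule — the surface region a reaction partner actually
probes; for nitroaromatics the minima localize on the nitro oxygens.

Ring current strengths (RCS, nA/T) arrive as two integrated components per
ring: a diatropic (positive) and a paratropic (negative) contribution.  The
net value classifies the ring: aromatic when clearly positive, antiaromatic
when clearly negative, non-aromatic near zero.  For the benzene reference
the components 17.60 and -4.95 nA/T give a net of 12.7 (one decimal).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .struct_io import BOHR_PER_ANGSTROM, Structure, VolumetricGrid

#: Bondi-style van der Waals radii, Angstrom.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98,
}

#: Benzene GIMIC reference components, nA/T (diatropic, paratropic).
BENZENE_RING_CURRENT = {"diatropic": 17.60, "paratropic": -4.95}

#: Net-RCS magnitude below which a ring is called non-aromatic, nA/T.
DEFAULT_RCS_THRESHOLD = 1.0


@dataclass
class ChargeSet:
    """Per-atom partial charges (elementary charge), aligned to a Structure."""

    charges: np.ndarray
    total_tolerance: float = 1e-6

    def __post_init__(self) -> None:
        self.charges = np.asarray(self.charges, dtype=float).ravel()
        total = self.charges.sum()
        if abs(total - round(total)) > self.total_tolerance:
            raise ValueError(
                f"total charge {total:.8f} is not integral within "
                f"{self.total_tolerance}"
            )

    def __len__(self) -> int:
        return self.charges.size


def point_charge_esp(
    structure: Structure, charges: ChargeSet, grid: VolumetricGrid
) -> VolumetricGrid:
    """Coulomb potential of atom-centered point charges on a grid, a.u.

    Grid nodes must not coincide with any nucleus (the bare Coulomb potential
    diverges there); that is enforced, not patched over.
    """
    if len(charges) != structure.n_atoms:
        raise ValueError(
            f"charge count {len(charges)} does not match atom count "
            f"{structure.n_atoms}"
        )
    points_b = grid.points() * BOHR_PER_ANGSTROM
    centers_b = structure.coords * BOHR_PER_ANGSTROM
    potential = np.zeros(points_b.shape[0])
    for q, center in zip(charges.charges, centers_b):
        r = np.linalg.norm(points_b - center[None, :], axis=1)
        if np.any(r < 1e-3):
            raise ValueError(
                "grid point coincides with a nucleus; offset the grid origin"
            )
        potential += q / r
    return VolumetricGrid(grid.origin, grid.axes, grid.shape, potential)


@dataclass(frozen=True)
class EspExtremum:
    value: float  # a.u.
    location: np.ndarray  # Angstrom
    nearest_atom: int  # index into the structure


@dataclass(frozen=True)
class EspExtrema:
    minimum: EspExtremum
    maximum: EspExtremum
    shell: tuple[float, float]  # vdW scale factors bounding the band


def esp_extrema(
    potential: VolumetricGrid,
    structure: Structure,
    shell: tuple[float, float] = (1.2, 2.0),
) -> EspExtrema:
    """Min/max potential over grid nodes in a vdW-scaled surface band.

    A node belongs to the band when it lies outside every atom's inner scaled
    radius (scale_lo * r_vdW) and within some atom's outer scaled radius
    (scale_hi * r_vdW).
    """
    lo, hi = shell
    if not (hi > lo > 1.0):
        raise ValueError("shell scales must satisfy hi > lo > 1")
    points = potential.points()
    coords = structure.coords
    radii = np.array(
        [VDW_RADII.get(a.element.upper(), 1.7) for a in structure.atoms]
    )
    # distance from every node to every atom, scaled by that atom's radius
    diff = points[:, None, :] - coords[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    scaled = dist / radii[None, :]
    in_band = np.all(scaled >= lo, axis=1) & np.any(scaled <= hi, axis=1)
    if not in_band.any():
        raise ValueError(
            "no grid nodes fall in the vdW shell band; use a finer or larger grid"
        )
    band_idx = np.nonzero(in_band)[0]
    band_vals = potential.values[band_idx]

    def _extremum(k: int) -> EspExtremum:
        node = band_idx[k]
        nearest = int(np.argmin(dist[node]))
        return EspExtremum(float(potential.values[node]), points[node], nearest)

    return EspExtrema(
        minimum=_extremum(int(np.argmin(band_vals))),
        maximum=_extremum(int(np.argmax(band_vals))),
        shell=(lo, hi),
    )


@dataclass(frozen=True)
class RingCurrentRecord:
    label: str
    diatropic: float  # nA/T, >= 0
    paratropic: float  # nA/T, <= 0
    net: float  # nA/T
    classification: str  # aromatic | antiaromatic | non-aromatic

    def __post_init__(self) -> None:
        if abs(self.net - (self.diatropic + self.paratropic)) > 1e-9:
            raise ValueError("net must equal diatropic + paratropic")


def net_ring_current(
    diatropic: float,
    paratropic: float,
    label: str = "",
    threshold: float = DEFAULT_RCS_THRESHOLD,
) -> RingCurrentRecord:
    """Net ring current strength and aromaticity call from the two components.

    Sign convention: the diatropic component is nonnegative, the paratropic
    component nonpositive.  Classification (strict inequalities): aromatic if
    net > threshold, antiaromatic if net < -threshold, else non-aromatic.
    """
    if diatropic < 0:
        raise ValueError("diatropic component must be >= 0 (sign convention)")
    if paratropic > 0:
        raise ValueError("paratropic component must be <= 0 (sign convention)")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    net = diatropic + paratropic
    if net > threshold:
        cls = "aromatic"
    elif net < -threshold:
        cls = "antiaromatic"
    else:
        cls = "non-aromatic"
    return RingCurrentRecord(label, diatropic, paratropic, net, cls)


def format_rcs(value: float, decimals: int = 1) -> str:
    """Display rounding for RCS values: half away from zero (12.65 -> '12.7')."""
    quantum = Decimal(1).scaleb(-decimals)
    return str(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))
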