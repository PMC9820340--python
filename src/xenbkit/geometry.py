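"""Rigid-body superposition, RMSD, and hydride acceptor-donor distance analysis.

The HAD (hydride acceptor-donor) distance is measured from the flavin
cofactor's N5 atom — the hydride donor of an FMN-dependent reductase — to a
reducible acceptor atom of the bound nitroaromatic ligand (a nitro-group
nitrogen or a ring carbon).  Its per-frame time series and normalized
histogram summarize whether an enzyme-ligand complex stays poised for hydride
transfer over a trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .struct_io import AtomSelection, Structure, Trajectory, select_single_atom


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation + translation, applied as ``x @ R.T + t``."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        tr = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tr)
        if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthogonal")
        if not np.isclose(np.linalg.det(rot), 1.0, atol=1e-8):
            raise ValueError("rotation must be proper (det +1); reflections excluded")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def _kabsch_rotation(mobile_c: np.ndarray, ref_c: np.ndarray) -> np.ndarray:
    """Optimal proper rotation mapping centered mobile onto centered reference."""
    h = mobile_c.T @ ref_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def kabsch_superpose(
    mobile: Structure | np.ndarray,
    reference: Structure | np.ndarray,
    mobile_selection: AtomSelection | None = None,
    reference_selection: AtomSelection | None = None,
) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition (Kabsch), reflections excluded.

    Returns the transform taking the mobile selection onto the reference
    selection and the minimized RMSD over proper rotations + translations.
    Selections must be the same size (>= 3) and correspond atom-by-atom in
    order.
    """
    mob = mobile.coords if isinstance(mobile, Structure) else np.asarray(mobile, float)
    ref = (
        reference.coords
        if isinstance(reference, Structure)
        else np.asarray(reference, float)
    )
    if mobile_selection is not None:
        mob = mob[list(mobile_selection.indices)]
    if reference_selection is not None:
        ref = ref[list(reference_selection.indices)]
    if mob.shape != ref.shape:
        raise ValueError(
            f"selection sizes differ: {mob.shape[0]} vs {ref.shape[0]} atoms"
        )
    if mob.shape[0] < 3:
        raise ValueError("superposition needs at least 3 corresponding atoms")
    mob_mean = mob.mean(axis=0)
    ref_mean = ref.mean(axis=0)
    rot = _kabsch_rotation(mob - mob_mean, ref - ref_mean)
    translation = ref_mean - rot @ mob_mean
    transform = RigidTransform(rot, translation)
    fitted = transform.apply(mob)
    fitted_rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return transform, fitted_rmsd


def rmsd(a: np.ndarray, b: np.ndarray, fit: bool = False) -> float:
    """Root-mean-square deviation between corresponding coordinate sets.

    ``fit=True`` first removes the optimal rigid motion (Kabsch); ``fit=False``
    compares the raw coordinates as given.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate counts differ: {a.shape} vs {b.shape}")
    if fit:
        _, value = kabsch_superpose(a, b)
        return value
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


@dataclass
class DistanceSeries:
    """Per-frame donor-acceptor distance, Angstrom."""

    label: str
    times: np.ndarray  # ns
    values: np.ndarray  # Angstrom

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.values.size and np.any(self.values <= 0):
            raise ValueError("distances must be positive")


@dataclass
class DistanceDistribution:
    """Normalized histogram of a distance series (probability mass per bin)."""

    bin_edges: np.ndarray  # Angstrom, strictly increasing, len = n_bins + 1
    probability: np.ndarray  # mass per bin, sums to 1

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.probability = np.asarray(self.probability, dtype=float)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if self.probability.size != self.bin_edges.size - 1:
            raise ValueError("need one probability per bin")
        if np.any(self.probability < 0) or abs(self.probability.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must be nonnegative and sum to 1")


def had_series(
    traj: Trajectory,
    donor: AtomSelection | str,
    acceptors: dict[str, AtomSelection | str],
) -> dict[str, DistanceSeries]:
    """Per-frame HAD distances from one donor atom to each named acceptor atom.

    ``donor`` and each acceptor may be an AtomSelection or a selection
    expression; each must resolve to exactly one atom (ambiguity is an error
    naming the matches).
    """
    donor_idx = _resolve_one(traj.topology, donor, "donor")
    times = (
        traj.frame_times
        if traj.frame_times is not None
        else np.arange(traj.n_frames, dtype=float)
    )
    out = {}
    for label, acc in acceptors.items():
        acc_idx = _resolve_one(traj.topology, acc, f"acceptor {label!r}")
        deltas = traj.frames[:, acc_idx, :] - traj.frames[:, donor_idx, :]
        out[label] = DistanceSeries(
            label=label, times=times, values=np.linalg.norm(deltas, axis=1)
        )
    return out


def _resolve_one(structure: Structure, sel: AtomSelection | str, what: str) -> int:
    if isinstance(sel, str):
        return select_single_atom(structure, sel)
    sel.validate(structure)
    if len(sel) != 1:
        names = [structure.atoms[i].name for i in sel.indices]
        raise ValueError(f"{what} must resolve to exactly one atom; matched {names}")
    return sel.indices[0]


def distance_distribution(
    series: DistanceSeries, bin_width: float = 0.1
) -> DistanceDistribution:
    """Histogram a distance series into bins of fixed width, normalized to 1.

    Bins cover [min, max] of the series; a constant series gets a single bin.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if series.values.size == 0:
        raise ValueError("cannot histogram an empty series")
    lo = float(series.values.min())
    hi = float(series.values.max())
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width - 1e-12)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(series.values, bins=edges)
    return DistanceDistribution(edges, counts / counts.sum())


@dataclass(frozen=True)
class StabilityResult:
    label: str  # "stable" | "unstable"
    bound_fraction: float
    cutoff: float  # Angstrom
    occupancy: float  # required bound fraction

    @property
    def stable(self) -> bool:
        return self.label == "stable"


def classify_stability(
    series: DistanceSeries, cutoff: float = 6.0, occupancy: float = 0.8
) -> StabilityResult:
    """Call a complex stable when the HAD distance stays short often enough.

    Stable iff the fraction of frames with distance <= ``cutoff`` is at least
    ``occupancy``.  Both parameters are reported back in the result so the
    criterion is always explicit.
    """
    if not 0 < occupancy <= 1:
        raise ValueError("occupancy must be in (0, 1]")
    if series.values.size == 0:
        raise ValueError("cannot classify an empty series")
    frac = float(np.mean(series.values <= cutoff))
    label = "stable" if frac >= occupancy else "unstable"
    return StabilityResult(label, frac, cutoff, occupancy)
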