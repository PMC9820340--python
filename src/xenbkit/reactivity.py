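"""Conceptual-DFT global reactivity descriptors from frontier orbital energies.

Within the Koopmans approximation the vertical ionization energy and electron
affinity of a closed-shell molecule are taken from the frontier orbital
eigenvalues, I = -eps_HOMO and A = -eps_LUMO.  From these two numbers the
standard global descriptors follow:

    gap   = eps_LUMO - eps_HOMO = I - A
    chi   = (I + A) / 2                  electronegativity (= -mu)
    eta   = (I - A) / 2                  global hardness
    omega = chi**2 / (2 eta)             electrophilicity index
    omega_minus = (3I + A)**2 / (16 (I - A))   electrodonating power
    omega_plus  = (I + 3A)**2 / (16 (I - A))   electroaccepting power
    net_electrophilicity = omega_plus + omega_minus

All energies are in eV.  ``omega_minus - omega_plus == chi`` and
``2 eta omega == chi**2`` hold identically; they are convenient self-checks.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from decimal import ROUND_DOWN, ROUND_HALF_EVEN, Decimal


class DegenerateGapError(ZeroDivisionError):
    """HOMO and LUMO coincide: hardness vanishes and omega-type indices diverge."""


@dataclass(frozen=True)
class OrbitalEnergies:
    """Frontier orbital eigenvalues of one compound, in eV."""

    compound: str
    eps_homo: float
    eps_lumo: float

    def __post_init__(self) -> None:
        if self.eps_lumo < self.eps_homo:
            raise ValueError(
                f"{self.compound}: eps_lumo ({self.eps_lumo}) lies below eps_homo "
                f"({self.eps_homo}); an occupied level above the unoccupied one is "
                "unphysical here"
            )


@dataclass(frozen=True)
class ReactivityProfile:
    """The seven global reactivity descriptors of one compound, in eV."""

    compound: str
    gap: float
    chi: float
    eta: float
    omega: float
    omega_minus: float
    omega_plus: float
    net_electrophilicity: float


DESCRIPTOR_NAMES = tuple(
    f.name for f in fields(ReactivityProfile) if f.name != "compound"
)


def descriptors(orb: OrbitalEnergies) -> ReactivityProfile:
    """Compute the seven global descriptors from one compound's orbital energies.

    Raises
    ------
    DegenerateGapError
        If eps_lumo == eps_homo (hardness is zero).
    ValueError
        If eps_lumo < eps_homo.
    """
    if orb.eps_lumo < orb.eps_homo:
        raise ValueError(f"{orb.compound}: eps_lumo < eps_homo")
    if orb.eps_lumo == orb.eps_homo:
        raise DegenerateGapError(
            f"{orb.compound}: degenerate HOMO/LUMO gap; omega-type descriptors "
            "divide by the hardness"
        )
    ion = -orb.eps_homo  # ionization energy I
    aff = -orb.eps_lumo  # electron affinity A
    gap = ion - aff
    chi = (ion + aff) / 2.0
    eta = gap / 2.0
    omega = chi * chi / (2.0 * eta)
    omega_minus = (3.0 * ion + aff) ** 2 / (16.0 * gap)
    omega_plus = (ion + 3.0 * aff) ** 2 / (16.0 * gap)
    return ReactivityProfile(
        compound=orb.compound,
        gap=gap,
        chi=chi,
        eta=eta,
        omega=omega,
        omega_minus=omega_minus,
        omega_plus=omega_plus,
        net_electrophilicity=omega_plus + omega_minus,
    )


def format_value(value: float, decimals: int = 1, mode: str = "truncate") -> str:
    """Render one descriptor at a fixed number of decimals.

    ``truncate`` chops toward zero (10.571 -> "10.5"); ``round_half_even``
    is banker's rounding (10.571 -> "10.6").
    """
    if decimals < 0:
        raise ValueError("decimals must be >= 0")
    rounding = {"truncate": ROUND_DOWN, "round_half_even": ROUND_HALF_EVEN}.get(mode)
    if rounding is None:
        raise ValueError(f"unknown mode {mode!r}; use 'truncate' or 'round_half_even'")
    # absorb binary-float representation noise (5.9 arriving as
    # 5.8999999999999995) before the display-mode quantization
    exact = Decimal(repr(value)).quantize(
        Decimal(1).scaleb(-9), rounding=ROUND_HALF_EVEN
    )
    return str(exact.quantize(Decimal(1).scaleb(-decimals), rounding=rounding))


def format_profile(
    profile: ReactivityProfile, decimals: int = 1, mode: str = "truncate"
) -> dict[str, str]:
    """Render every descriptor of a profile as fixed-decimal strings."""
    out = {"compound": profile.compound}
    for name in DESCRIPTOR_NAMES:
        out[name] = format_value(getattr(profile, name), decimals, mode)
    return out


def rank_values(
    labels: list[str], values: list[float], tie_tolerance: float = 0.0
) -> list[list[str]]:
    """Sort labels by value descending, grouping near-ties.

    A new group starts when a value falls more than ``tie_tolerance`` below the
    current group's representative (its first, largest member).  Within a group
    labels keep the descending-value order (input order breaks exact ties).
    """
    if len(labels) != len(values):
        raise ValueError("labels and values must have equal length")
    order = sorted(range(len(values)), key=lambda i: (-values[i], i))
    groups: list[list[str]] = []
    rep = None
    for i in order:
        if rep is None or rep - values[i] > tie_tolerance:
            groups.append([labels[i]])
            rep = values[i]
        else:
            groups[-1].append(labels[i])
    return groups


def rank_compounds(
    profiles: list[ReactivityProfile], key: str, tie_tolerance: float = 0.0
) -> list[list[str]]:
    """Order compounds by one descriptor, descending, near-ties grouped."""
    if key not in DESCRIPTOR_NAMES:
        raise KeyError(
            f"unknown descriptor {key!r}; valid keys: {', '.join(DESCRIPTOR_NAMES)}"
        )
    return rank_values(
        [p.compound for p in profiles],
        [getattr(p, key) for p in profiles],
        tie_tolerance,
    )
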