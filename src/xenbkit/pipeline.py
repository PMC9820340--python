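"""Config-driven analysis pipeline producing one combined per-run report.

A run configuration is a YAML mapping naming the stages to execute and their
inputs; only the requested stages run, and every number in the report is
accompanied by the parameters that produced it.  All file references are
checked before any computation starts.

Stages and their keys::

    reactivity:
        orbital_table: path           # delimited table of eps_HOMO/eps_LUMO
        decimals: 1                   # optional
        mode: truncate                # or round_half_even
        rank_key: gap                 # optional ranking
        tie_tolerance: 0.05
    had:
        trajectory: path              # multi-model PDB or multi-frame XYZ
        donor: "resname FMN and name N5"
        acceptors: {2NO2: "resname TNT and name N2", ...}
        bin_width: 0.1
        cutoff: 6.0
        occupancy: 0.8
    cluster:
        trajectory: path
        ligand: "resname TNT and not element H"
        fit: "resname FMN"
        eps: 1.5
        min_points: 5
        contacts_cutoff: 3.0
    nci:
        structure: path               # single-frame PDB/XYZ
        ligand: "resname TNT and not element H"
        margin: 3.0
        spacing: 0.15
        s_max: 0.5
        signed_rho_cut: 0.01
    esp:
        structure: path
        charges: path                 # delimited: atom index, charge
        spacing: 0.4
    rcs:
        components: path              # delimited: label, diatropic, paratropic
        threshold: 1.0
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    geometry,
    nci_grid,
    pose_clustering,
    reactivity,
    struct_io,
    surface_maps,
)

logger = logging.getLogger("xenbkit")

#: One auditable block of every convention-level default.
DEFAULTS = {
    "eps": 1.5,  # DBSCAN neighborhood radius, Angstrom RMSD
    "min_points": 5,  # DBSCAN minimum neighbors (self included)
    "contacts_cutoff": 3.0,  # contact-residue shell, Angstrom
    "s_max": 0.5,  # NCI reduced-gradient retention threshold
    "signed_rho_cut": 0.01,  # NCI sign(lambda2)*rho band, a.u.
    "bin_width": 0.1,  # HAD histogram bin, Angstrom
    "stability_cutoff": 6.0,  # HAD stability distance, Angstrom
    "stability_occupancy": 0.8,  # required bound fraction
    "rcs_threshold": 1.0,  # non-aromatic band half-width, nA/T
    "nci_spacing": 0.15,  # NCI grid spacing, Angstrom
    "esp_spacing": 0.4,  # ESP grid spacing, Angstrom
}

_STAGE_FILE_KEYS = {
    "reactivity": ["orbital_table"],
    "had": ["trajectory"],
    "cluster": ["trajectory"],
    "nci": ["structure"],
    "esp": ["structure", "charges"],
    "rcs": ["components"],
}


class ConfigError(ValueError):
    """The run configuration is incomplete or references missing files."""


def _preflight(config: dict) -> None:
    for stage, keys in _STAGE_FILE_KEYS.items():
        section = config.get(stage)
        if section is None:
            continue
        for key in keys:
            if key not in section:
                raise ConfigError(f"stage {stage!r}: missing required input {key!r}")
            path = Path(section[key])
            if not path.exists():
                raise ConfigError(f"stage {stage!r}: file not found: {path}")


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> Path:
    """Execute the configured stages; return the report path.

    Deterministic given the config (and any seeds it names): the report body
    carries no timestamps.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict) or not config:
        raise ConfigError("empty run configuration")
    unknown = set(config) - set(_STAGE_FILE_KEYS)
    if unknown:
        raise ConfigError(f"unknown stage(s): {', '.join(sorted(unknown))}")
    _preflight(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.StreamHandler(sys.stderr)
    logger.addHandler(handler)
    try:
        sections = []
        for stage in _STAGE_FILE_KEYS:
            if stage in config:
                logger.info("running stage %s", stage)
                runner = globals()[f"_stage_{stage}"]
                sections.append(runner(config[stage], out_dir))
        report = out_dir / "report.txt"
        report.write_text("\n\n".join(sections) + "\n")
        return report
    finally:
        logger.removeHandler(handler)


def _fmt_params(params: dict) -> str:
    return ", ".join(f"{k}={v}" for k, v in params.items())


def _stage_reactivity(section: dict, out_dir: Path) -> str:
    decimals = int(section.get("decimals", 1))
    mode = section.get("mode", "truncate")
    orbs = struct_io.read_orbital_table(section["orbital_table"])
    profiles = [reactivity.descriptors(o) for o in orbs]
    rows = [reactivity.format_profile(p, decimals, mode) for p in profiles]
    df = pd.DataFrame(rows)
    df.to_csv(out_dir / "reactivity.csv", index=False)
    lines = [
        "## Global reactivity descriptors (eV)",
        f"parameters: decimals={decimals}, mode={mode}",
        df.to_string(index=False),
    ]
    if "rank_key" in section:
        tol = float(section.get("tie_tolerance", 0.0))
        groups = reactivity.rank_compounds(profiles, section["rank_key"], tol)
        order = " > ".join(
            g[0] if len(g) == 1 else "{" + ", ".join(g) + "}" for g in groups
        )
        lines.append(
            f"ranking by {section['rank_key']} (tie_tolerance={tol}): {order}"
        )
    return "\n".join(lines)


def _stage_had(section: dict, out_dir: Path) -> str:
    traj = struct_io.read_trajectory(section["trajectory"])
    bin_width = float(section.get("bin_width", DEFAULTS["bin_width"]))
    cutoff = float(section.get("cutoff", DEFAULTS["stability_cutoff"]))
    occupancy = float(section.get("occupancy", DEFAULTS["stability_occupancy"]))
    series = geometry.had_series(traj, section["donor"], section["acceptors"])
    lines = [
        "## HAD distance analysis",
        f"parameters: bin_width={bin_width} A, stability cutoff={cutoff} A, "
        f"occupancy={occupancy}, donor={section['donor']!r}",
    ]
    for label, ds in series.items():
        dist = geometry.distance_distribution(ds, bin_width)
        stab = geometry.classify_stability(ds, cutoff, occupancy)
        pd.DataFrame({"time_ns": ds.times, "distance_A": ds.values}).to_csv(
            out_dir / f"had_{label}.csv", index=False
        )
        pd.DataFrame(
            {
                "bin_left_A": dist.bin_edges[:-1],
                "bin_right_A": dist.bin_edges[1:],
                "probability": dist.probability,
            }
        ).to_csv(out_dir / f"had_{label}_hist.csv", index=False)
        lines.append(
            f"{label}: mean={ds.values.mean():.3f} A, sd={ds.values.std():.3f} A, "
            f"bound_fraction={stab.bound_fraction:.3f} -> {stab.label}"
        )
    return "\n".join(lines)


def _stage_cluster(section: dict, out_dir: Path) -> str:
    traj = struct_io.read_trajectory(section["trajectory"])
    eps = float(section.get("eps", DEFAULTS["eps"]))
    min_points = int(section.get("min_points", DEFAULTS["min_points"]))
    contacts_cutoff = float(
        section.get("contacts_cutoff", DEFAULTS["contacts_cutoff"])
    )
    ligand = struct_io.select_atoms(traj.topology, section["ligand"])
    fit = struct_io.select_atoms(traj.topology, section["fit"])
    matrix = pose_clustering.ligand_rmsd_matrix(traj, ligand, fit)
    result = pose_clustering.dbscan(matrix, eps, min_points)
    pd.DataFrame(
        {"frame": matrix.frame_ids, "label": result.labels}
    ).to_csv(out_dir / "cluster_labels.csv", index=False)
    lines = [
        "## Ligand pose clustering",
        f"parameters: eps={eps} A, min_points={min_points}, "
        f"contacts_cutoff={contacts_cutoff} A, ligand={section['ligand']!r}, "
        f"fit={section['fit']!r}",
        f"clusters: {result.n_clusters}, "
        f"noise frames: {int(np.sum(result.labels == -1))} / {traj.n_frames}",
    ]
    for label, frame in enumerate(result.medoid_frames):
        medoid_structure = traj.frame_structure(frame)
        struct_io.write_structure(
            medoid_structure, out_dir / f"medoid_cluster{label}.pdb"
        )
        contacts = pose_clustering.contact_residues(
            medoid_structure, ligand, contacts_cutoff
        )
        desc = ", ".join(f"{name}{rid}" for _, rid, name in contacts.residues)
        size = int(np.sum(result.labels == label))
        lines.append(
            f"cluster {label}: {size} frames, medoid frame {frame}, "
            f"contacts within {contacts_cutoff} A: {desc or 'none'}"
        )
    return "\n".join(lines)


def _stage_nci(section: dict, out_dir: Path) -> str:
    structure = struct_io.read_structure(section["structure"])
    ligand = struct_io.select_atoms(structure, section["ligand"])
    margin = float(section.get("margin", 3.0))
    spacing = float(section.get("spacing", DEFAULTS["nci_spacing"]))
    s_max = float(section.get("s_max", DEFAULTS["s_max"]))
    cut = float(section.get("signed_rho_cut", DEFAULTS["signed_rho_cut"]))
    fields, classification = nci_grid.interfacial_nci(
        structure, ligand, margin=margin, spacing=spacing,
        s_max=s_max, signed_rho_cut=cut,
    )
    struct_io.write_grid(fields.signed_rho_grid(), structure, out_dir / "nci_signed_rho.cube")
    struct_io.write_grid(fields.s_grid(), structure, out_dir / "nci_rdg.cube")
    counts = classification.counts
    pd.DataFrame([counts]).to_csv(out_dir / "nci_counts.csv", index=False)
    return "\n".join(
        [
            "## Interfacial NCI",
            f"parameters: margin={margin} A, spacing={spacing} A, "
            f"s_max={s_max}, signed_rho_cut={cut} a.u., "
            f"ligand={section['ligand']!r}",
            f"retained points (s < s_max): {classification.n_retained}",
            f"attractive: {counts['attractive']}, "
            f"van der Waals: {counts['van_der_waals']}, "
            f"repulsive: {counts['repulsive']}",
        ]
    )


def _stage_esp(section: dict, out_dir: Path) -> str:
    structure = struct_io.read_structure(section["structure"])
    table = pd.read_csv(section["charges"], sep=None, engine="python")
    charges = surface_maps.ChargeSet(table.iloc[:, -1].to_numpy())
    spacing = float(section.get("spacing", DEFAULTS["esp_spacing"]))
    coords = structure.coords
    grid = nci_grid.grid_from_box(
        coords.min(axis=0) - 4.0 + 0.05, coords.max(axis=0) + 4.0, spacing
    )
    potential = surface_maps.point_charge_esp(structure, charges, grid)
    struct_io.write_grid(potential, structure, out_dir / "esp.cube")
    extrema = surface_maps.esp_extrema(potential, structure)
    vmin, vmax = extrema.minimum, extrema.maximum
    return "\n".join(
        [
            "## Point-charge electrostatic potential",
            f"parameters: spacing={spacing} A, shell={extrema.shell}",
            f"min: {vmin.value:.5f} a.u. near atom "
            f"{structure.atoms[vmin.nearest_atom].name}",
            f"max: {vmax.value:.5f} a.u. near atom "
            f"{structure.atoms[vmax.nearest_atom].name}",
        ]
    )


def _stage_rcs(section: dict, out_dir: Path) -> str:
    table = pd.read_csv(section["components"], sep=None, engine="python")
    threshold = float(section.get("threshold", DEFAULTS["rcs_threshold"]))
    records = [
        surface_maps.net_ring_current(
            float(row["diatropic"]), float(row["paratropic"]),
            label=str(row["label"]), threshold=threshold,
        )
        for _, row in table.iterrows()
    ]
    df = pd.DataFrame(
        {
            "label": [r.label for r in records],
            "diatropic_nAT": [r.diatropic for r in records],
            "paratropic_nAT": [r.paratropic for r in records],
            "net_nAT": [surface_maps.format_rcs(r.net) for r in records],
            "classification": [r.classification for r in records],
        }
    )
    df.to_csv(out_dir / "ring_currents.csv", index=False)
    return "\n".join(
        [
            "## Ring current strengths (nA/T)",
            f"parameters: non-aromatic threshold={threshold} nA/T",
            df.to_string(index=False),
        ]
    )
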