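"""Readers and writers for configurations and columnar data.

GRO files are read through MDAnalysis (which performs the nm → Å
conversion) and written directly; extended-XYZ files carry the box and
time on the comment line as ``key=value`` pairs.  Molecule typing uses a
residue-name map from the run configuration, e.g.::

    residues:
      SOL: {species: water, roles: {OW: water_O, HW1: water_H, HW2: water_H}}
      OCT: {species: octanol,
            roles: {O1: hydroxyl_O, HO1: hydroxyl_H, C8: terminal_C}}

Atom names absent from a residue's role map default to ``chain_C`` for
carbons and ``other`` otherwise.
"""

from __future__ import annotations

import numpy as np

from .core import (
    Atom,
    Box,
    CHAIN_C,
    Frame,
    Molecule,
    OTHER,
    Trajectory,
)
from .thermo import PressureSeries

DEFAULT_RESIDUE_MAP = {
    "SOL": {
        "species": "water",
        "roles": {"OW": "water_O", "HW1": "water_H", "HW2": "water_H"},
    },
    "OCT": {
        "species": "octanol",
        "roles": {"O1": "hydroxyl_O", "HO1": "hydroxyl_H", "C8": "terminal_C"},
    },
}


def _role_for(atom_name: str, element: str, roles: dict) -> str:
    if atom_name in roles:
        return roles[atom_name]
    return CHAIN_C if element.upper().startswith("C") else OTHER


def _element_of(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "X"


def read_gro(path, residue_map: dict | None = None, time: float = 0.0) -> Frame:
    """Read a GRO configuration into a typed Frame (positions in Å)."""
    import MDAnalysis as mda

    residue_map = residue_map or DEFAULT_RESIDUE_MAP
    u = mda.Universe(str(path))
    dims = u.dimensions  # Å after MDAnalysis conversion
    box = Box(float(dims[0]), float(dims[1]), float(dims[2]))
    molecules = []
    for mol_id, res in enumerate(u.residues):
        entry = residue_map.get(res.resname)
        if entry is None:
            raise ValueError(f"residue {res.resname!r} not in the residue map")
        roles = entry["roles"]
        atoms = [
            Atom(
                int(a.ix),
                _element_of(a.name),
                _role_for(a.name, _element_of(a.name), roles),
                a.position.astype(float),
            )
            for a in res.atoms
        ]
        molecules.append(Molecule(mol_id, entry["species"], atoms))
    return Frame(time, molecules, box)


def write_gro(frame: Frame, path, names: dict | None = None) -> None:
    """Write a Frame as GRO (Å → nm on output)."""
    resnames = {"water": "SOL", "octanol": "OCT"}
    lines = [f"hingeflow frame t={frame.time} ps", ""]
    n_atoms = sum(len(m.atoms) for m in frame.molecules)
    lines[1] = str(n_atoms)
    role_names = {
        "water_O": ["OW"],
        "water_H": ["HW1", "HW2"],
        "hydroxyl_O": ["O1"],
        "hydroxyl_H": ["HO1"],
        "terminal_C": ["C8"],
    }
    idx = 1
    for m in frame.molecules:
        res = resnames[m.species]
        seen: dict = {}
        chain_idx = 0
        for a in m.atoms:
            if a.role == "chain_C":
                chain_idx += 1
                name = f"C{chain_idx}"
            elif a.role in role_names:
                k = seen.get(a.role, 0)
                seen[a.role] = k + 1
                name = role_names[a.role][min(k, len(role_names[a.role]) - 1)]
            else:
                name = f"{a.element}{idx % 10}"
            x, y, z = a.position / 10.0
            lines.append(
                f"{(m.id + 1) % 100000:>5d}{res:<5s}{name:>5s}{idx % 100000:>5d}"
                f"{x:8.3f}{y:8.3f}{z:8.3f}"
            )
            idx += 1
    L = frame.box.lengths / 10.0
    lines.append(f"{L[0]:10.5f}{L[1]:10.5f}{L[2]:10.5f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_xyz(trajectory_or_frame, path, role_map: bool = True) -> None:
    """Write frames as extended XYZ with box/time on the comment line."""
    frames = (
        trajectory_or_frame.frames
        if isinstance(trajectory_or_frame, Trajectory)
        else [trajectory_or_frame]
    )
    with open(path, "w") as fh:
        for frame in frames:
            rows = []
            for m in frame.molecules:
                for a in m.atoms:
                    rows.append(
                        f"{a.element} {a.position[0]:.5f} {a.position[1]:.5f} "
                        f"{a.position[2]:.5f} {m.species} {a.role} {m.id}"
                    )
            b = frame.box
            per = "".join("T" if p else "F" for p in b.periodicity)
            fh.write(f"{len(rows)}\n")
            fh.write(
                f"Lx={b.Lx} Ly={b.Ly} Lz={b.Lz} periodic={per} time={frame.time}\n"
            )
            fh.write("\n".join(rows) + "\n")


def read_xyz(path, sampling_interval: float | None = None) -> Trajectory:
    """Read extended XYZ written by :func:`write_xyz` back into a Trajectory."""
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        n = int(lines[i])
        meta = dict(kv.split("=", 1) for kv in lines[i + 1].split())
        per = tuple(c == "T" for c in meta.get("periodic", "TTT"))
        box = Box(float(meta["Lx"]), float(meta["Ly"]), float(meta["Lz"]), per)
        time = float(meta.get("time", 0.0))
        by_mol: dict[int, list] = {}
        species_of: dict[int, str] = {}
        for k, row in enumerate(lines[i + 2 : i + 2 + n]):
            el, x, y, z, species, role, mol_id = row.split()
            mol_id = int(mol_id)
            by_mol.setdefault(mol_id, []).append(
                Atom(k, el, role, np.array([float(x), float(y), float(z)]))
            )
            species_of[mol_id] = species
        molecules = [
            Molecule(mid, species_of[mid], atoms)
            for mid, atoms in sorted(by_mol.items())
        ]
        frames.append(Frame(time, molecules, box))
        i += 2 + n
    if sampling_interval is None:
        sampling_interval = (
            frames[1].time - frames[0].time if len(frames) > 1 else 1.0
        )
    return Trajectory(frames, sampling_interval)


def read_pressure_series(path, L_z: float, N_int: int = 2) -> PressureSeries:
    """Columnar text (time, Pxx, Pyy, Pzz) → PressureSeries."""
    data = np.loadtxt(path)
    if data.ndim == 1:
        data = data[None, :]
    return PressureSeries(
        data[:, 0], data[:, 1], data[:, 2], data[:, 3], L_z, N_int
    )


def write_pressure_series(series: PressureSeries, path) -> None:
    header = "time_ps Pxx_bar Pyy_bar Pzz_bar"
    np.savetxt(
        path,
        np.column_stack([series.times, series.P_xx, series.P_yy, series.P_zz]),
        header=header,
    )
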