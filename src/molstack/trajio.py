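"""Trajectory readers and writers (XYZ, multi-model PDB) and the
metatrajectory builder.

Supported formats are deliberately plain text:

* **XYZ** — standard atom blocks; the comment line carries the box, time
  stamp and replica label as ``box=Lx,Ly,Lz time=t replica=r``.
* **PDB** — MODEL/ENDMDL multi-model files with a CRYST1 record for the
  (orthorhombic) box; residue sequence numbers encode molecule membership.

Lengths are Å throughout, times ns. Frames without an explicit time stamp
are assigned uniform spacing (``frame_spacing`` ns).
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

from .errors import MolstackError, TrajectoryFormatError
from .topology import Frame, Topology, Trajectory

_TIME_TOL = 1e-9


def _parse_xyz_comment(comment: str) -> dict:
    out: dict = {}
    for token in comment.split():
        if "=" not in token:
            continue
        key, value = token.split("=", 1)
        if key == "box":
            out["box"] = np.array([float(x) for x in value.split(",")])
        elif key == "time":
            out["time"] = float(value)
        elif key == "replica":
            out["replica_id"] = value
    return out


def read_xyz(path, topology: Topology, box=None, frame_spacing: float = 1.0,
             replica_id=None) -> Trajectory:
    """Read an XYZ trajectory against a known topology.

    ``box`` is required when the comment lines carry no ``box=`` field.
    """
    lines = Path(path).read_text().splitlines()
    frames: list[Frame] = []
    pos = 0
    frame_index = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n_atoms = int(lines[pos].strip())
        except ValueError as exc:
            raise TrajectoryFormatError(
                f"{path}: frame {frame_index}: bad atom-count line {lines[pos]!r}",
                frame_index=frame_index, partial_frames=frames) from exc
        if n_atoms != topology.n_atoms:
            raise TrajectoryFormatError(
                f"{path}: frame {frame_index}: {n_atoms} atoms, topology has "
                f"{topology.n_atoms}", frame_index=frame_index, partial_frames=frames)
        if len(lines) < pos + 2 + n_atoms:
            raise TrajectoryFormatError(
                f"{path}: frame {frame_index} truncated",
                frame_index=frame_index, partial_frames=frames)
        meta = _parse_xyz_comment(lines[pos + 1])
        coords = np.empty((n_atoms, 3))
        for i in range(n_atoms):
            parts = lines[pos + 2 + i].split()
            if len(parts) < 4:
                raise TrajectoryFormatError(
                    f"{path}: frame {frame_index}: bad atom line {lines[pos + 2 + i]!r}",
                    frame_index=frame_index, partial_frames=frames)
            coords[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frame_box = meta.get("box", box)
        if frame_box is None:
            raise MolstackError(
                f"{path}: frame {frame_index} has no box; pass box= explicitly")
        frames.append(Frame(
            coordinates=coords,
            box=frame_box,
            time=meta.get("time", frame_index * frame_spacing),
            replica_id=replica_id if replica_id is not None else meta.get("replica_id", 0),
        ))
        pos += 2 + n_atoms
        frame_index += 1
    return Trajectory(topology, frames)


def write_xyz(trajectory: Trajectory, path) -> None:
    topo = trajectory.topology
    elements = [a.element for m in topo.molecules for a in m.atoms]
    with open(path, "w") as fh:
        for frame in trajectory.frames:
            bx, by, bz = frame.box
            fh.write(f"{topo.n_atoms}\n")
            fh.write(f"box={bx:.6f},{by:.6f},{bz:.6f} "
                     f"time={frame.time:.6f} replica={frame.replica_id}\n")
            for element, (x, y, z) in zip(elements, frame.coordinates):
                fh.write(f"{element:<2s} {x:14.6f} {y:14.6f} {z:14.6f}\n")


def read_pdb(path, topology: Topology, frame_spacing: float = 1.0,
             replica_id=0) -> Trajectory:
    """Read a MODEL/ENDMDL multi-model PDB; box from CRYST1."""
    frames: list[Frame] = []
    box = None
    coords: list[list[float]] = []
    in_model = False
    frame_index = 0
    for line in Path(path).read_text().splitlines():
        record = line[:6].strip()
        if record == "CRYST1":
            box = np.array([float(line[6:15]), float(line[15:24]), float(line[24:33])])
        elif record == "MODEL":
            in_model = True
            coords = []
        elif record in ("ATOM", "HETATM"):
            coords.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
        elif record == "ENDMDL":
            if len(coords) != topology.n_atoms:
                raise TrajectoryFormatError(
                    f"{path}: frame {frame_index}: {len(coords)} atoms, topology "
                    f"has {topology.n_atoms}",
                    frame_index=frame_index, partial_frames=frames)
            if box is None:
                raise MolstackError(f"{path}: no CRYST1 record before frame {frame_index}")
            frames.append(Frame(coordinates=np.array(coords), box=box,
                                time=frame_index * frame_spacing,
                                replica_id=replica_id))
            frame_index += 1
            in_model = False
    if in_model:
        raise TrajectoryFormatError(
            f"{path}: frame {frame_index} truncated (MODEL without ENDMDL)",
            frame_index=frame_index, partial_frames=frames)
    return Trajectory(topology, frames)


def write_pdb(trajectory: Trajectory, path) -> None:
    """Write a multi-model PDB (HETATM records, chain per molecule species)."""
    topo = trajectory.topology
    with open(path, "w") as fh:
        # CRYST1 repeated per model, as trajectory-style PDB writers do
        for model, frame in enumerate(trajectory.frames, start=1):
            bx, by, bz = frame.box
            fh.write(f"CRYST1{bx:9.3f}{by:9.3f}{bz:9.3f}"
                     f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n")
            fh.write(f"MODEL     {model:4d}\n")
            serial = 1
            for mol_index, mol in enumerate(topo.molecules):
                resname = mol.species[:3].upper()
                resseq = (mol_index % 9999) + 1
                for atom, xyz in zip(mol.atoms, frame.coordinates[topo.atom_slice(mol_index)]):
                    x, y, z = xyz
                    fh.write(
                        f"HETATM{serial % 100000:5d} {atom.name[:4]:<4s}{resname:>4s} "
                        f"A{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                        f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}\n")
                    serial += 1
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_trajectory(path, topology: Topology, **kwargs) -> Trajectory:
    """Dispatch on file suffix (.xyz / .pdb)."""
    suffix = Path(path).suffix.lower()
    if suffix == ".xyz":
        return read_xyz(path, topology, **kwargs)
    if suffix == ".pdb":
        kwargs.pop("box", None)
        return read_pdb(path, topology, **kwargs)
    raise MolstackError(f"unsupported trajectory format {suffix!r}")


def write_trajectory(trajectory: Trajectory, path) -> None:
    suffix = Path(path).suffix.lower()
    if suffix == ".xyz":
        write_xyz(trajectory, path)
    elif suffix == ".pdb":
        write_pdb(trajectory, path)
    else:
        raise MolstackError(f"unsupported trajectory format {suffix!r}")


def build_metatrajectory(replicas: list[Trajectory], retain_tail: float) -> Trajectory:
    """Concatenate the last ``retain_tail`` ns of each replica.

    Discarding all but the tail of every independent run removes the
    approach-to-equilibrium portion; the concatenation is analyzed as one
    ensemble. Replica labels and original time stamps are preserved, so a
    4 × 250 ns set with ``retain_tail=200`` yields an 800 ns metatrajectory.
    """
    if not replicas:
        raise MolstackError("no replicas given")
    if retain_tail <= 0:
        raise MolstackError("retain_tail must be > 0")
    frames = []
    for k, replica in enumerate(replicas):
        if not replica.frames:
            raise MolstackError(f"replica {k} has no frames")
        times = np.array([f.time for f in replica.frames])
        if np.any(np.diff(times) < 0):
            raise MolstackError(f"replica {k}: time stamps not non-decreasing")
        span = times[-1] - times[0]
        if span + _TIME_TOL < retain_tail:
            raise MolstackError(
                f"replica {k} spans {span:g} ns < retain_tail {retain_tail:g} ns")
        cut = times[-1] - retain_tail
        frames.extend(f for f, t in zip(replica.frames, times) if t >= cut - _TIME_TOL)
    if any(r.topology.n_atoms != replicas[0].topology.n_atoms for r in replicas):
        raise MolstackError("replicas have differing atom counts")
    return Trajectory(replicas[0].topology, frames)


def retained_duration(replicas: list[Trajectory], retain_tail: float) -> float:
    """Total analyzed duration: replicas × retain_tail (ns)."""
    if math.isnan(retain_tail):
        raise MolstackError("retain_tail must be a number")
    return len(replicas) * retain_tail
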