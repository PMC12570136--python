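"""Frames and trajectories, with multi-model PDB and plain-text XYZ I/O.

Internal units follow the GROMACS convention: nanometres for coordinates
and picoseconds for time.  PDB files store angstroms, so coordinates are
divided by 10 on reading and multiplied by 10 on writing.

The XYZ dialect is a per-frame plain-text format:

    <n_atoms>
    time=<ps>
    <atom name> <x nm> <y nm> <z nm>     (n_atoms lines)

repeated once per frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .topology import Topology

__all__ = ["Frame", "Trajectory", "FrameShapeError", "read_frames", "write_frames"]


class FrameShapeError(ValueError):
    """A frame's atom count disagrees with the topology."""


@dataclass
class Frame:
    """One conformation: per-atom coordinates in nm, optional time (ps)."""

    coordinates: np.ndarray
    time: float | None = None
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be an (n_atoms, 3) array")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")


@dataclass
class Trajectory:
    topology: Topology
    frames: list[Frame] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("a trajectory needs at least one frame")
        n = self.topology.n_atoms
        for i, fr in enumerate(self.frames):
            if fr.coordinates.shape[0] != n:
                raise FrameShapeError(
                    f"frame {i}: {fr.coordinates.shape[0]} atoms, topology has {n}"
                )
        times = [fr.time for fr in self.frames if fr.time is not None]
        if len(times) == len(self.frames) and len(times) > 1:
            if not all(b > a for a, b in zip(times, times[1:])):
                raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coordinate_array(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) stacked coordinates."""
        return np.stack([fr.coordinates for fr in self.frames])

    def sliced(self, start: int = 0, stop: int | None = None) -> "Trajectory":
        frames = self.frames[start:stop]
        if not frames:
            raise ValueError("empty analysis window after discarding frames")
        return Trajectory(self.topology, frames)


def _read_pdb_frames(lines: list[str], n_atoms: int) -> list[Frame]:
    frames: list[Frame] = []
    coords: list[list[float]] = []
    any_model = any(line[:6].strip() == "MODEL" for line in lines)

    def flush(frame_idx: int) -> None:
        nonlocal coords
        if not coords:
            return
        if len(coords) != n_atoms:
            raise FrameShapeError(
                f"frame {frame_idx}: {len(coords)} atoms, expected {n_atoms}"
            )
        frames.append(Frame(np.array(coords) / 10.0))  # angstrom -> nm
        coords = []

    for line in lines:
        record = line[:6].strip()
        if record == "ENDMDL":
            flush(len(frames))
        elif record in ("ATOM", "HETATM"):
            coords.append(
                [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            )
    if coords:  # file without trailing ENDMDL, or plain single-structure PDB
        flush(len(frames))
    if not frames and not any_model:
        raise FrameShapeError("no coordinates found in PDB source")
    return frames


def _read_xyz_frames(lines: list[str], n_atoms: int) -> list[Frame]:
    frames: list[Frame] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        declared = int(lines[i].strip())
        comment = lines[i + 1].strip()
        time = None
        if comment.startswith("time="):
            time = float(comment[5:].split()[0])
        block = lines[i + 2 : i + 2 + declared]
        if declared != n_atoms or len(block) < declared:
            raise FrameShapeError(
                f"frame {len(frames)}: {declared} atoms declared, expected {n_atoms}"
            )
        coords = np.array(
            [[float(v) for v in ln.split()[1:4]] for ln in block]
        )
        frames.append(Frame(coords, time=time))
        i += 2 + declared
    return frames


def read_frames(source: str | Iterable[str], topology: Topology) -> Trajectory:
    """Read a multi-model PDB or XYZ-dialect text into a Trajectory."""
    if isinstance(source, str):
        lines = source.splitlines()
    else:
        lines = list(source)
    stripped = next((ln for ln in lines if ln.strip()), "")
    first = stripped.split()[0] if stripped.split() else ""
    if first.isdigit():
        frames = _read_xyz_frames(lines, topology.n_atoms)
    else:
        frames = _read_pdb_frames(lines, topology.n_atoms)
    if not frames:
        raise FrameShapeError("source contains no frames")
    return Trajectory(topology, frames)


def _pdb_atom_line(idx: int, atom, xyz_ang: Sequence[float]) -> str:
    name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
    return (
        f"ATOM  {idx % 100000:5d} {name:<4s} {atom.residue_name:<3s} "
        f"{atom.chain_id}{atom.residue_index % 10000:4d}    "
        f"{xyz_ang[0]:8.3f}{xyz_ang[1]:8.3f}{xyz_ang[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}"
    )


def write_frames(trajectory: Trajectory, format: str = "pdb") -> str:
    """Serialize a trajectory as multi-model PDB ('pdb') or XYZ dialect ('xyz')."""
    if trajectory.topology.n_atoms == 0:
        raise ValueError("cannot write an empty selection")
    atoms = trajectory.topology.atoms
    out: list[str] = []
    if format == "pdb":
        for m, fr in enumerate(trajectory.frames, start=1):
            out.append(f"MODEL     {m:4d}")
            ang = fr.coordinates * 10.0
            for i, atom in enumerate(atoms):
                out.append(_pdb_atom_line(atom.serial, atom, ang[i]))
            out.append("ENDMDL")
        out.append("END")
    elif format == "xyz":
        for m, fr in enumerate(trajectory.frames):
            out.append(str(len(atoms)))
            t = fr.time if fr.time is not None else float(m)
            out.append(f"time={t:.6f}")
            for i, atom in enumerate(atoms):
                x, y, z = fr.coordinates[i]
                out.append(f"{atom.name} {x:.6f} {y:.6f} {z:.6f}")
    else:
        raise ValueError(f"unsupported trajectory format {format!r}")
    return "\n".join(out) + "\n"
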