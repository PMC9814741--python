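"""Trajectory containers and coordinate I/O for monomer-center trajectories.

Coordinates are stored in nanometres in orthorhombic periodic boxes. Two plain
text dialects are supported: extended XYZ (``Lattice="ax 0 0 0 by 0 0 0 cz"``
and ``Time=<ns>`` on the comment line) and a sequence of GRO frames (box on the
last line of each frame). XYZ files default to Angstrom on disk, GRO to nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import re

import numpy as np

__all__ = [
    "Box",
    "Frame",
    "Trajectory",
    "CenterSelection",
    "TrajectoryError",
    "minimum_image",
    "compute_centers",
    "read_trajectory",
    "write_trajectory",
]


class TrajectoryError(ValueError):
    """Malformed trajectory data (parse, shape or selection problems)."""


@dataclass(frozen=True)
class Box:
    """Orthorhombic simulation cell.

    Parameters
    ----------
    lengths : array-like of 3 floats
        Edge lengths in nm, all positive.
    periodic : array-like of 3 bools, optional
        Which axes are periodic; all by default.
    """

    lengths: np.ndarray
    periodic: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        lengths = np.asarray(self.lengths, dtype=float).reshape(3)
        if not np.all(np.isfinite(lengths)) or np.any(lengths <= 0):
            raise TrajectoryError(f"box lengths must be positive and finite, got {lengths}")
        periodic = self.periodic
        periodic = (
            np.ones(3, dtype=bool)
            if periodic is None
            else np.asarray(periodic, dtype=bool).reshape(3)
        )
        object.__setattr__(self, "lengths", lengths)
        object.__setattr__(self, "periodic", periodic)


def minimum_image(disp: np.ndarray, box: Box) -> np.ndarray:
    """Map displacement vectors to their minimum image.

    Each component along a periodic axis ends in ``(-L/2, L/2]``; aperiodic
    axes pass through unchanged.
    """
    disp = np.asarray(disp, dtype=float)
    out = disp.copy()
    for ax in range(3):
        if box.periodic[ax]:
            L = box.lengths[ax]
            out[..., ax] -= L * np.round(out[..., ax] / L)
            # round() sends exactly -L/2 to -L/2; fold onto +L/2
            comp = out[..., ax]
            comp[comp <= -L / 2] += L
    return out


@dataclass(frozen=True)
class Frame:
    """One snapshot: M center coordinates (nm) in a periodic box at a time (ns)."""

    coords: np.ndarray
    box: Box
    time: float = 0.0

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
            raise TrajectoryError(f"coords must be M x 3 with M >= 1, got shape {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise TrajectoryError("coordinates must be finite")
        object.__setattr__(self, "coords", coords)

    @property
    def n_centers(self) -> int:
        return self.coords.shape[0]


@dataclass
class Trajectory:
    """Ordered frames with constant particle count and a system label."""

    frames: list
    system_id: str = "system"
    sampling_interval: float = 1.0  # ns between consecutive frames

    def __post_init__(self):
        if len(self.frames) < 1:
            raise TrajectoryError("a trajectory needs at least one frame")
        M = self.frames[0].n_centers
        for k, fr in enumerate(self.frames):
            if fr.n_centers != M:
                raise TrajectoryError(
                    f"frame {k} has {fr.n_centers} particles, expected {M}"
                )
        times = [fr.time for fr in self.frames]
        if any(t1 < t0 for t0, t1 in zip(times, times[1:])):
            raise TrajectoryError("frame times must be monotone non-decreasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_centers(self) -> int:
        return self.frames[0].n_centers


@dataclass(frozen=True)
class CenterSelection:
    """Bead-index groups, one per monomer; the group COG is the SOAP center."""

    groups: tuple

    def __post_init__(self):
        groups = tuple(tuple(int(i) for i in g) for g in self.groups)
        if not groups or any(len(g) == 0 for g in groups):
            raise TrajectoryError("selection groups must be non-empty")
        flat = [i for g in groups for i in g]
        if len(set(flat)) != len(flat):
            raise TrajectoryError("selection groups must be disjoint")
        if any(i < 0 for i in flat):
            raise TrajectoryError("bead indices must be non-negative")
        object.__setattr__(self, "groups", groups)


def compute_centers(raw_coords: np.ndarray, box: Box, selection: CenterSelection,
                    time: float = 0.0) -> Frame:
    """Center of geometry of each bead group, minimum-image unwrapped.

    Each group is unwrapped relative to its first bead (molecules are assumed
    whole, i.e. no bead further than half the smallest box length from that
    reference), then averaged. Returns a Frame with one center per group.
    """
    raw = np.asarray(raw_coords, dtype=float)
    if raw.ndim != 2 or raw.shape[1] != 3:
        raise TrajectoryError(f"raw coordinates must be N x 3, got {raw.shape}")
    n = raw.shape[0]
    half_min = 0.5 * float(np.min(box.lengths[box.periodic])) if np.any(box.periodic) else np.inf
    centers = np.empty((len(selection.groups), 3))
    for gi, group in enumerate(selection.groups):
        if max(group) >= n:
            raise TrajectoryError(
                f"group {gi} refers to bead {max(group)} but frame has {n} beads"
            )
        ref = raw[group[0]]
        disp = minimum_image(raw[list(group)] - ref, box)
        if np.any(np.linalg.norm(disp, axis=1) > half_min):
            raise TrajectoryError(
                f"group {gi} spans more than half the box; COG is ambiguous"
            )
        centers[gi] = ref + disp.mean(axis=0)
    return Frame(coords=centers, box=box, time=time)


# --------------------------------------------------------------------------
# extended XYZ

_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')
_TIME_RE = re.compile(r"Time=([0-9eE+\-.]+)")


def _parse_xyz(lines, unit_scale: float):
    frames = []
    k = 0
    nlines = len(lines)
    while k < nlines:
        if not lines[k].strip():
            k += 1
            continue
        try:
            nat = int(lines[k].strip())
        except ValueError as exc:
            raise TrajectoryError(f"line {k + 1}: expected particle count, got {lines[k]!r}") from exc
        if k + 1 >= nlines:
            raise TrajectoryError(f"line {k + 2}: missing comment line")
        comment = lines[k + 1]
        m = _LATTICE_RE.search(comment)
        if m is None:
            raise TrajectoryError(f"line {k + 2}: missing Lattice= box specification")
        cell = np.array([float(x) for x in m.group(1).split()])
        if cell.size != 9:
            raise TrajectoryError(f"line {k + 2}: Lattice must have 9 numbers")
        cell = cell.reshape(3, 3)
        if np.any(cell - np.diag(np.diag(cell)) != 0):
            raise TrajectoryError(f"line {k + 2}: non-orthorhombic lattice is unsupported")
        tm = _TIME_RE.search(comment)
        time = float(tm.group(1)) if tm else float(len(frames))
        coords = np.empty((nat, 3))
        for j in range(nat):
            ln = k + 2 + j
            if ln >= nlines:
                raise TrajectoryError(f"line {ln + 1}: truncated frame")
            parts = lines[ln].split()
            if len(parts) < 4:
                raise TrajectoryError(f"line {ln + 1}: expected 'symbol x y z'")
            try:
                coords[j] = [float(p) for p in parts[1:4]]
            except ValueError as exc:
                raise TrajectoryError(f"line {ln + 1}: bad coordinate field") from exc
        box = Box(lengths=np.diag(cell) * unit_scale)
        frames.append(Frame(coords=coords * unit_scale, box=box, time=time))
        k += 2 + nat
    return frames


def _parse_gro(lines):
    frames = []
    k = 0
    nlines = len(lines)
    while k < nlines:
        if not lines[k].strip():
            k += 1
            continue
        title = lines[k]
        tm = re.search(r"t=\s*([0-9eE+\-.]+)", title)
        time = float(tm.group(1)) if tm else float(len(frames))
        try:
            nat = int(lines[k + 1].strip())
        except (IndexError, ValueError) as exc:
            raise TrajectoryError(f"line {k + 2}: expected atom count") from exc
        if k + 2 + nat >= nlines:
            raise TrajectoryError(f"line {k + 3}: truncated GRO frame (missing box line)")
        coords = np.empty((nat, 3))
        for j in range(nat):
            ln = lines[k + 2 + j]
            try:
                coords[j] = [float(ln[20:28]), float(ln[28:36]), float(ln[36:44])]
            except (ValueError, IndexError) as exc:
                raise TrajectoryError(f"line {k + 3 + j}: bad GRO coordinate columns") from exc
        boxparts = lines[k + 2 + nat].split()
        if len(boxparts) < 3:
            raise TrajectoryError(f"line {k + 3 + nat}: GRO box line needs 3 lengths")
        if len(boxparts) > 3 and any(float(x) != 0.0 for x in boxparts[3:]):
            raise TrajectoryError(f"line {k + 3 + nat}: triclinic GRO box is unsupported")
        box = Box(lengths=[float(x) for x in boxparts[:3]])
        frames.append(Frame(coords=coords, box=box, time=time))
        k += 3 + nat
    return frames


def read_trajectory(path, format: str = "extended-xyz", system_id: str | None = None,
                    unit: str | None = None) -> Trajectory:
    """Read a coordinate trajectory.

    Parameters
    ----------
    format : {"extended-xyz", "gro-sequence"}
    unit : {"A", "nm"}, optional
        On-disk length unit. Defaults to Angstrom for XYZ, nm for GRO.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if format == "extended-xyz":
        scale = 0.1 if (unit is None or unit == "A") else 1.0
        frames = _parse_xyz(lines, scale)
    elif format == "gro-sequence":
        if unit not in (None, "nm"):
            raise TrajectoryError("GRO files are defined in nm")
        frames = _parse_gro(lines)
    else:
        raise TrajectoryError(f"unknown trajectory format {format!r}")
    if not frames:
        raise TrajectoryError(f"{path}: no frames found")
    times = [fr.time for fr in frames]
    dt = times[1] - times[0] if len(times) > 1 else 1.0
    sysid = system_id if system_id is not None else str(path)
    return Trajectory(frames=frames, system_id=sysid, sampling_interval=dt or 1.0)


def write_trajectory(traj: Trajectory, path, format: str = "extended-xyz",
                     unit: str | None = None) -> None:
    """Write a trajectory; re-readable by :func:`read_trajectory`.

    Coordinates and boxes are printed with 6 decimals.
    """
    if format == "extended-xyz":
        scale = 10.0 if (unit is None or unit == "A") else 1.0
        with open(path, "w") as fh:
            for fr in traj.frames:
                L = fr.box.lengths * scale
                fh.write(f"{fr.n_centers}\n")
                fh.write(
                    f'Lattice="{L[0]:.6f} 0 0 0 {L[1]:.6f} 0 0 0 {L[2]:.6f}" '
                    f"Properties=species:S:1:pos:R:3 Time={fr.time:.6f}\n"
                )
                for x, y, z in fr.coords * scale:
                    fh.write(f"X {x:.6f} {y:.6f} {z:.6f}\n")
    elif format == "gro-sequence":
        with open(path, "w") as fh:
            for fr in traj.frames:
                fh.write(f"{traj.system_id} t= {fr.time:.6f}\n{fr.n_centers}\n")
                for j, (x, y, z) in enumerate(fr.coords):
                    resid = (j % 99999) + 1
                    fh.write(f"{resid:>5d}{'MON':<5s}{'C':>5s}{resid:>5d}"
                             f"{x:8.3f}{y:8.3f}{z:8.3f}\n")
                L = fr.box.lengths
                fh.write(f"  {L[0]:.5f}  {L[1]:.5f}  {L[2]:.5f}\n")
    else:
        raise TrajectoryError(f"unknown trajectory format {format!r}")
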