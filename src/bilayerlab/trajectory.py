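"""Core trajectory data model and I/O.

Coordinates are stored in Ångström and times in nanoseconds throughout the
package. Boxes are orthorhombic; triclinic cells are rejected at load time.
Binary MD formats (DCD/XTC with a PDB/PSF topology) are read through
MDAnalysis; a plain-text XYZ format with a YAML sidecar carrying ``dt``,
``box`` and the ``wrapped`` flag serves as the documented text fallback and
is what the synthetic generators write.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from bilayerlab.errors import FormatError, UnwrapAmbiguityWarning, ValidationError

#: Per-frame center-of-mass series, shape (n_frames, 3), Å.
ComSeries = np.ndarray

_ROLE_NAMES = (
    "backbone_end_a",
    "backbone_end_b",
    "cor_ring_atoms",
    "ch3_terminal",
    "cf3_terminal",
)


@dataclass(frozen=True)
class Trajectory:
    """Particle positions over time in an orthorhombic periodic cell.

    Attributes
    ----------
    positions : ndarray, shape (n_frames, n_particles, 3)
        Cartesian coordinates in Å.
    box : ndarray, shape (n_frames, 3)
        Orthorhombic box edge lengths in Å, per frame.
    dt : float
        Time between stored frames in ns; frame k is at t = k * dt.
    wrapped : bool
        True when every coordinate lies inside the primary cell [0, L).
    """

    positions: np.ndarray
    box: np.ndarray
    dt: float
    wrapped: bool

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 3 or pos.shape[2] != 3:
            raise ValidationError(
                f"positions must have shape (n_frames, n_particles, 3), got {pos.shape}"
            )
        box = np.asarray(self.box, dtype=float)
        if box.ndim == 1:
            box = np.broadcast_to(box, (pos.shape[0], 3)).copy()
        if box.shape != (pos.shape[0], 3):
            raise ValidationError(
                f"box must have shape (n_frames, 3), got {box.shape}"
            )
        if not np.all(box > 0):
            raise ValidationError("all box lengths must be > 0 in every frame")
        if self.dt <= 0:
            raise ValidationError(f"dt must be > 0, got {self.dt}")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "box", box)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Frame times t_k = k * dt in ns."""
        return np.arange(self.n_frames) * self.dt

    def validate_wrapped(self) -> None:
        """Check the wrapped-coordinate invariant (each component in [0, L))."""
        if not self.wrapped:
            return
        if np.any(self.positions < 0) or np.any(self.positions >= self.box[:, None, :]):
            raise ValidationError("wrapped trajectory has coordinates outside [0, box)")


@dataclass(frozen=True)
class AdditiveMolecule:
    """Structural roles of one additive molecule (0-based atom indices)."""

    backbone_end_a: int
    backbone_end_b: int
    cor_ring_atoms: np.ndarray
    ch3_terminal: int
    cf3_terminal: int

    def __post_init__(self) -> None:
        ring = np.atleast_1d(np.asarray(self.cor_ring_atoms, dtype=int))
        if ring.size == 0:
            raise ValidationError("cor_ring_atoms must be nonempty")
        object.__setattr__(self, "cor_ring_atoms", ring)

    def all_indices(self) -> np.ndarray:
        return np.concatenate(
            [
                [self.backbone_end_a, self.backbone_end_b],
                self.cor_ring_atoms,
                [self.ch3_terminal, self.cf3_terminal],
            ]
        ).astype(int)


@dataclass
class GroupSpec:
    """Named particle index sets plus per-molecule structural roles.

    ``groups`` maps free-form names ("lipids", "water", "additives",
    "headgroups", ...) to 0-based index arrays. ``additive_molecules``
    assigns the five structural roles (backbone ends, central-ring atoms,
    CH3/CF3 terminal carbons) per additive molecule. ``headgroup_atoms``
    marks one phosphorus-like atom per lipid.
    """

    groups: dict[str, np.ndarray] = field(default_factory=dict)
    additive_molecules: list[AdditiveMolecule] = field(default_factory=list)
    headgroup_atoms: np.ndarray | None = None
    masses: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.groups = {
            str(k): np.atleast_1d(np.asarray(v, dtype=int)) for k, v in self.groups.items()
        }
        if self.headgroup_atoms is not None:
            self.headgroup_atoms = np.atleast_1d(np.asarray(self.headgroup_atoms, dtype=int))
        if self.masses is not None:
            self.masses = np.asarray(self.masses, dtype=float)

    def group(self, name: str) -> np.ndarray:
        try:
            return self.groups[name]
        except KeyError:
            raise ValidationError(f"unknown group {name!r}; have {sorted(self.groups)}")

    @property
    def n_additives(self) -> int:
        return len(self.additive_molecules)

    def validate(self, n_particles: int) -> None:
        """Check index bounds and role disjointness against a trajectory size."""
        for name, idx in self.groups.items():
            if idx.size and (idx.min() < 0 or idx.max() >= n_particles):
                raise ValidationError(
                    f"group {name!r} has index out of range [0, {n_particles})"
                )
        lip = set(self.groups.get("lipids", np.empty(0, int)).tolist())
        add = set(self.groups.get("additives", np.empty(0, int)).tolist())
        if lip & add:
            raise ValidationError("a particle cannot be both lipid and additive")
        for m, mol in enumerate(self.additive_molecules):
            for role in _ROLE_NAMES:
                val = getattr(mol, role)
                idx = np.atleast_1d(np.asarray(val, dtype=int))
                if idx.min() < 0 or idx.max() >= n_particles:
                    raise ValidationError(
                        f"additive molecule {m}: role {role!r} index out of range "
                        f"[0, {n_particles})"
                    )
        if self.headgroup_atoms is not None and self.headgroup_atoms.size:
            if self.headgroup_atoms.min() < 0 or self.headgroup_atoms.max() >= n_particles:
                raise ValidationError("headgroup_atoms: index out of range")
        if self.masses is not None and len(self.masses) != n_particles:
            raise ValidationError(
                f"masses length {len(self.masses)} != n_particles {n_particles}"
            )


# ---------------------------------------------------------------------------
# geometry operations


def wrap(traj: Trajectory) -> Trajectory:
    """Fold all coordinates back into the primary cell [0, L)."""
    pos = np.mod(traj.positions, traj.box[:, None, :])
    return replace(traj, positions=pos, wrapped=True)


def unwrap(traj: Trajectory) -> Trajectory:
    """Remove periodic jumps by accumulating minimum-image displacements.

    Frame 0 is left unchanged; each subsequent frame adds the minimum-image
    displacement from its predecessor. Valid only when particles move less
    than half a box length between stored frames; a displacement at or above
    half the box triggers an :class:`UnwrapAmbiguityWarning` naming the first
    offending frame and particle.
    """
    if not traj.wrapped:
        return traj
    if traj.n_frames < 2:
        return replace(traj, wrapped=False)
    pos = traj.positions
    disp = np.diff(pos, axis=0)
    box = traj.box[1:, None, :]
    disp = disp - box * np.round(disp / box)
    bad = np.abs(disp) >= box / 2.0
    if np.any(bad):
        f, p, _ = np.argwhere(bad)[0]
        warnings.warn(
            f"displacement of particle {p} into frame {f + 1} reaches half the box; "
            "unwrapping is ambiguous",
            UnwrapAmbiguityWarning,
            stacklevel=2,
        )
    out = np.empty_like(pos)
    out[0] = pos[0]
    np.cumsum(disp, axis=0, out=disp)
    out[1:] = pos[0] + disp
    return replace(traj, positions=out, wrapped=False)


def group_com(
    traj: Trajectory,
    indices: Sequence[int] | np.ndarray,
    masses: np.ndarray | None = None,
) -> ComSeries:
    """Per-frame (mass-weighted) center of mass of a particle group, Å.

    Uniform masses are assumed when ``masses`` is None.
    """
    idx = np.atleast_1d(np.asarray(indices, dtype=int))
    if idx.size == 0:
        raise ValidationError("group_com: empty index set")
    sub = traj.positions[:, idx, :]
    if masses is None:
        return sub.mean(axis=1)
    m = np.asarray(masses, dtype=float)
    if m.size == traj.n_particles:
        m = m[idx]
    elif m.size != idx.size:
        raise ValidationError("masses must match either n_particles or the index set")
    return np.einsum("fpk,p->fk", sub, m) / m.sum()


def subtract_com_motion(
    traj: Trajectory,
    reference: Sequence[int] | np.ndarray,
    masses: np.ndarray | None = None,
) -> Trajectory:
    """Translate every frame so the reference group's COM stays at its frame-0 value.

    Removes collective drift (e.g. of the whole lipid ensemble or the whole
    system) without changing any intra-frame geometry. The input must be
    unwrapped; the output is marked unwrapped as well.
    """
    if traj.wrapped:
        raise ValidationError("subtract_com_motion requires an unwrapped trajectory")
    com = group_com(traj, reference, masses=masses)
    shift = com - com[0]
    return replace(traj, positions=traj.positions - shift[:, None, :], wrapped=False)


# ---------------------------------------------------------------------------
# plain-text XYZ + sidecar I/O


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.yaml")


def write_xyz(
    traj: Trajectory,
    path: str | Path,
    elements: Sequence[str] | None = None,
) -> Path:
    """Write frame-blocked XYZ plus a YAML sidecar with dt/box/wrapped metadata."""
    path = Path(path)
    n = traj.n_particles
    if elements is None:
        elements = ["X"] * n
    if len(elements) != n:
        raise ValidationError("elements length must equal n_particles")
    with path.open("w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{n}\nframe {f}\n")
            for el, (x, y, z) in zip(elements, traj.positions[f]):
                fh.write(f"{el} {x:.10g} {y:.10g} {z:.10g}\n")
    box = traj.box
    if np.allclose(box, box[0]):
        box_meta = box[0].tolist()
    else:
        box_meta = box.tolist()
    meta = {"dt": float(traj.dt), "box": box_meta, "wrapped": bool(traj.wrapped)}
    with _sidecar_path(path).open("w") as fh:
        yaml.safe_dump(meta, fh)
    return path


def read_xyz(path: str | Path, dt: float | None = None) -> Trajectory:
    """Read frame-blocked XYZ with its YAML sidecar (dt, box, wrapped)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"trajectory file not found: {path}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(
            f"XYZ sidecar {sidecar.name} not found; it must provide dt and box"
        )
    with sidecar.open() as fh:
        meta = yaml.safe_load(fh)
    frames: list[np.ndarray] = []
    with path.open() as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            try:
                n = int(header)
            except ValueError as exc:
                raise FormatError(f"bad XYZ atom-count line: {header!r}") from exc
            fh.readline()  # comment
            rows = np.empty((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                if len(parts) < 4:
                    raise FormatError(f"truncated XYZ frame {len(frames)}")
                rows[i] = [float(v) for v in parts[1:4]]
            frames.append(rows)
    if not frames:
        raise FormatError(f"no frames in {path}")
    pos = np.stack(frames)
    box = np.asarray(meta["box"], dtype=float)
    if box.ndim == 1:
        box = np.broadcast_to(box, (pos.shape[0], 3)).copy()
    return Trajectory(
        positions=pos,
        box=box,
        dt=float(dt if dt is not None else meta["dt"]),
        wrapped=bool(meta.get("wrapped", True)),
    )


# ---------------------------------------------------------------------------
# group file I/O


def _spec_to_mapping(spec: GroupSpec) -> dict:
    doc: dict = {"index_base": 0, "groups": {k: v.tolist() for k, v in spec.groups.items()}}
    if spec.headgroup_atoms is not None:
        doc["headgroup_atoms"] = spec.headgroup_atoms.tolist()
    if spec.masses is not None:
        doc["masses"] = spec.masses.tolist()
    if spec.additive_molecules:
        doc["additive_molecules"] = [
            {
                "backbone_end_a": int(m.backbone_end_a),
                "backbone_end_b": int(m.backbone_end_b),
                "cor_ring_atoms": m.cor_ring_atoms.tolist(),
                "ch3_terminal": int(m.ch3_terminal),
                "cf3_terminal": int(m.cf3_terminal),
            }
            for m in spec.additive_molecules
        ]
    return doc


def write_group_file(spec: GroupSpec, path: str | Path, dt: float | None = None) -> Path:
    """Serialize a GroupSpec to the YAML group-file format."""
    path = Path(path)
    doc = _spec_to_mapping(spec)
    if dt is not None:
        doc["dt"] = float(dt)
    with path.open("w") as fh:
        yaml.safe_dump(doc, fh)
    return path


def _mapping_to_spec(doc: Mapping) -> tuple[GroupSpec, float | None]:
    base = int(doc.get("index_base", 0))

    def shift(arr) -> np.ndarray:
        return np.atleast_1d(np.asarray(arr, dtype=int)) - base

    groups = {k: shift(v) for k, v in (doc.get("groups") or {}).items()}
    mols = []
    for m in doc.get("additive_molecules") or []:
        missing = [r for r in _ROLE_NAMES if r not in m]
        if missing:
            raise ValidationError(f"additive molecule missing roles: {missing}")
        mols.append(
            AdditiveMolecule(
                backbone_end_a=int(m["backbone_end_a"]) - base,
                backbone_end_b=int(m["backbone_end_b"]) - base,
                cor_ring_atoms=shift(m["cor_ring_atoms"]),
                ch3_terminal=int(m["ch3_terminal"]) - base,
                cf3_terminal=int(m["cf3_terminal"]) - base,
            )
        )
    head = doc.get("headgroup_atoms")
    masses = doc.get("masses")
    spec = GroupSpec(
        groups=groups,
        additive_molecules=mols,
        headgroup_atoms=shift(head) if head is not None else None,
        masses=np.asarray(masses, dtype=float) if masses is not None else None,
    )
    dt = doc.get("dt")
    return spec, (float(dt) if dt is not None else None)


def read_group_file(path: str | Path) -> tuple[GroupSpec, float | None]:
    """Parse the YAML group file; returns (GroupSpec, optional dt override)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"group file not found: {path}")
    with path.open() as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise FormatError(f"group file {path} is not a mapping")
    return _mapping_to_spec(doc)


# ---------------------------------------------------------------------------
# top-level loader


_BINARY_SUFFIXES = {".dcd", ".xtc", ".trr"}


def load_trajectory(
    path: str | Path,
    topology: str | Path | None = None,
    group_file: str | Path | None = None,
) -> tuple[Trajectory, GroupSpec]:
    """Load a trajectory (binary MD format or XYZ fallback) plus its group file.

    Format is inferred from the extension. DCD/XTC/TRR require a PDB or PSF
    topology and go through MDAnalysis; masses are taken from the topology
    when available. ``dt`` can be overridden by the group file.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"trajectory file not found: {path}")
    spec = GroupSpec()
    dt_override: float | None = None
    if group_file is not None:
        spec, dt_override = read_group_file(group_file)

    if path.suffix.lower() in _BINARY_SUFFIXES:
        traj = _load_mdanalysis(path, topology, dt_override)
    elif path.suffix.lower() == ".xyz":
        traj = read_xyz(path, dt=dt_override)
    else:
        raise FormatError(f"unsupported trajectory format: {path.suffix!r}")

    spec.validate(traj.n_particles)
    return traj, spec


def _load_mdanalysis(path: Path, topology: str | Path | None, dt_override: float | None) -> Trajectory:
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover
        raise FormatError("MDAnalysis is required for binary trajectory formats") from exc
    if topology is None:
        raise FormatError("binary trajectory formats require a PDB or PSF topology")
    u = mda.Universe(str(topology), str(path))
    frames, boxes = [], []
    for ts in u.trajectory:
        dims = ts.dimensions
        if dims is None or not np.allclose(dims[3:], 90.0):
            raise FormatError("only orthorhombic cells are supported")
        frames.append(ts.positions.astype(float).copy())
        boxes.append(np.asarray(dims[:3], dtype=float))
    # MDAnalysis reports dt in ps; stored frames in ns.
    dt = dt_override if dt_override is not None else float(u.trajectory.dt) * 1e-3
    return Trajectory(
        positions=np.stack(frames), box=np.stack(boxes), dt=dt, wrapped=True
    )
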