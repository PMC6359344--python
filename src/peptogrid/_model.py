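"""Core data containers shared across the package.

The public modules (:mod:`peptogrid.molio`, :mod:`peptogrid.gridmap`,
:mod:`peptogrid.rescore`) re-export these; importing from here directly is
fine but not required.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: sentinel used by readers for formats that do not carry SYBYL types
UNTYPED = "untyped"

#: recognised pose provenance tags
SOURCES = ("vina", "plants", "ledock", "synthetic")


@dataclass
class AtomRecord:
    """One ligand atom.

    ``res_name``/``res_seq`` identify the amino-acid residue the atom belongs
    to; they are what the template-based typer resolves against.
    """

    atom_name: str
    element: str
    coords: np.ndarray  # shape (3,), Angstrom
    sybyl_type: str = UNTYPED
    vdw_radius: float = 0.0
    res_name: str = ""
    res_seq: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError(f"coords must be a 3-vector, got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.atom_name!r}")

    @property
    def typed(self) -> bool:
        return self.sybyl_type != UNTYPED


@dataclass
class Pose:
    """An ordered atom list for one docking pose of one peptide."""

    pose_id: str
    sequence: str
    source: str
    atoms: list[AtomRecord]
    native_score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}; expected one of {SOURCES}")
        if not self.atoms:
            raise ValueError(f"pose {self.pose_id!r} has no atoms")

    def __len__(self) -> int:
        return len(self.atoms)

    def coords_array(self) -> np.ndarray:
        """All atom coordinates as an (n_atoms, 3) array."""
        return np.stack([a.coords for a in self.atoms])


@dataclass
class DockingBox:
    """Axis-aligned docking box defining the grid lattice.

    The lattice is a vertex grid: per axis there are ``floor(edge/step) + 1``
    vertices, the first at ``origin = center - edges/2``.  A single vertex
    lattice serves both map accumulation and score lookup.
    """

    center: np.ndarray  # (3,), Angstrom
    edges: np.ndarray  # (3,), Angstrom
    step: float = 0.1

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.edges = np.asarray(self.edges, dtype=float)
        if self.center.shape != (3,) or self.edges.shape != (3,):
            raise ValueError("center and edges must be 3-vectors")
        if not np.all(self.edges > 0):
            raise ValueError("box edges must be positive")
        if not self.step > 0:
            raise ValueError("grid step must be positive")
        if self.step > float(np.min(self.edges)):
            raise ValueError("grid step exceeds the smallest box edge")

    @property
    def origin(self) -> np.ndarray:
        return self.center - self.edges / 2.0

    @property
    def shape(self) -> tuple[int, int, int]:
        # tolerance absorbs e.g. 30/0.1 = 299.9999... under binary floats
        return tuple(int(math.floor(e / self.step + 1e-9)) + 1 for e in self.edges)

    def vertex_position(self, index) -> np.ndarray:
        """Cartesian position of a lattice vertex (fractional indices allowed)."""
        return self.origin + np.asarray(index, dtype=float) * self.step

    def __eq__(self, other) -> bool:
        if not isinstance(other, DockingBox):
            return NotImplemented
        return (
            np.allclose(self.center, other.center)
            and np.allclose(self.edges, other.edges)
            and math.isclose(self.step, other.step)
        )


@dataclass
class PoseSet:
    """A collection of poses sharing one docking box."""

    poses: list[Pose]
    box: Optional[DockingBox] = None

    def __post_init__(self) -> None:
        ids = [p.pose_id for p in self.poses]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate pose_ids: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.poses)

    def __iter__(self):
        return iter(self.poses)

    @property
    def n_atoms_total(self) -> int:
        return sum(len(p) for p in self.poses)


@dataclass
class RescoredPose:
    """A pose with its frequency-map score attached.

    ``raw_sr`` is the mean frequency-map value over the pose's atoms;
    ``normalized_score`` rescales raw scores by the run maximum into [0, 1];
    ``rank`` 1 is the best pose.
    """

    pose_id: str
    sequence: str
    source: str
    raw_sr: float
    normalized_score: float = 0.0
    rank: int = 0
    native_score: Optional[float] = None


@dataclass
class FrequencyGrid:
    """Per-atom-type occurrence counts over the docking-box vertex lattice.

    ``counts`` maps a SYBYL type to a dense float32 array of the box shape;
    types that never occurred may be absent from the dict (treated as all
    zero).  float32 holds exact integers up to 2**24, far beyond any
    realistic per-vertex occurrence count.
    """

    box: DockingBox
    type_axis: tuple[str, ...]
    counts: dict[str, np.ndarray] = field(default_factory=dict)
    n_poses: int = 0
    n_atoms_total: int = 0
    n_atoms_outside: int = 0
    weighting: str = "raw_count"

    def array_for(self, sybyl_type: str) -> np.ndarray:
        """Counts array for a type (a shared zero array when type never occurred)."""
        if sybyl_type not in self.type_axis:
            raise KeyError(f"type {sybyl_type!r} is not on the grid's type axis")
        arr = self.counts.get(sybyl_type)
        if arr is None:
            arr = np.zeros(self.box.shape, dtype=np.float32)
        return arr
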