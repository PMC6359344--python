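"""Per-atom-type occurrence-frequency maps over the docking box.

The map is accumulated on a vertex lattice with a default step of 0.1 Å:
every atom of every pose marks all lattice vertices inside its van der Waals
sphere (closed ball, so boundary ties are included), and the counter of the
atom's SYBYL type is incremented there.  Atoms partially outside the box
contribute only their in-box vertices; atoms entirely outside contribute
nothing and are tallied in a diagnostics counter.  Grids persist to HDF5
with one chunked, compressed dataset per atom type.

In raw-count mode the accumulation is additive: the grid of a concatenated
pose set equals the elementwise sum of the grids of its parts.  Because the
final pose score is normalized by the run maximum, any global positive
rescaling of the grid — including the optional per-pose-fraction weighting —
leaves the final ranking unchanged.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional

import h5py
import numpy as np

from ._model import AtomRecord, DockingBox, FrequencyGrid, Pose, PoseSet
from .atom_typing import supported_alphabet

__all__ = [
    "DockingBox",
    "FrequencyGrid",
    "rasterize_atom",
    "build_frequency_grid",
    "save_grid",
    "load_grid",
    "export_volumetric",
    "GridIntegrityError",
]


class GridIntegrityError(ValueError):
    """A persisted grid file is inconsistent or truncated."""


def rasterize_atom(atom: AtomRecord, box: DockingBox) -> np.ndarray:
    """Lattice vertices within the atom's van der Waals sphere, clipped to the box.

    Returns an (n, 3) int array of vertex indices; empty when the sphere
    misses the box entirely.  Membership uses the closed ball
    ``|vertex - center| <= vdw_radius``.
    """
    if atom.vdw_radius <= 0:
        raise ValueError(f"atom {atom.atom_name!r} has no positive vdW radius")
    origin, step, shape = box.origin, box.step, box.shape
    frac = (atom.coords - origin) / step
    # slightly oversized bounding box; the distance test prunes the excess.
    # The epsilon keeps vertices lying exactly on the sphere (atom centered
    # on a vertex, radius a multiple of the step) from being lost to
    # floating-point rounding.
    r_steps = atom.vdw_radius / step + 1e-9
    lo = np.maximum(np.ceil(frac - r_steps).astype(int), 0)
    hi = np.minimum(np.floor(frac + r_steps).astype(int), np.array(shape) - 1)
    if np.any(lo > hi):
        return np.empty((0, 3), dtype=int)
    axes = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
    # squared distance separates over axes: d2[i,j,k] = dx2[i]+dy2[j]+dz2[k]
    d2 = [((ax * step + origin[d]) - atom.coords[d]) ** 2 for d, ax in enumerate(axes)]
    inside = (
        d2[0][:, None, None] + d2[1][None, :, None] + d2[2][None, None, :]
        <= atom.vdw_radius ** 2 * (1.0 + 1e-12)
    )
    ii, jj, kk = np.nonzero(inside)
    return np.column_stack([axes[0][ii], axes[1][jj], axes[2][kk]])


def build_frequency_grid(
    poses: PoseSet | Iterable[Pose],
    box: Optional[DockingBox] = None,
    weighting: str = "raw_count",
    include_hydrogens: bool = True,
    type_axis: Optional[tuple[str, ...]] = None,
) -> FrequencyGrid:
    """Accumulate a per-type occurrence grid from a typed pose ensemble.

    Parameters
    ----------
    poses
        Typed poses (every atom needs a SYBYL type and radius).
    box
        Docking box; defaults to ``poses.box`` for a PoseSet.
    weighting
        ``"raw_count"`` adds 1 per atom per vertex; ``"per_pose_fraction"``
        adds ``1/n_poses`` so values are per-pose occupancy fractions.
    include_hydrogens
        When False, atoms typed ``"H"`` are skipped entirely.
    """
    if box is None:
        box = getattr(poses, "box", None)
    if box is None:
        raise ValueError("no docking box: pass box= or use a PoseSet with one")
    if weighting not in ("raw_count", "per_pose_fraction"):
        raise ValueError(f"unknown weighting {weighting!r}")
    pose_list = list(poses)
    if not pose_list:
        raise ValueError("empty pose set")
    axis = tuple(type_axis) if type_axis is not None else supported_alphabet()

    untyped = [
        (p.pose_id, a.atom_name)
        for p in pose_list for a in p.atoms if not a.typed
    ]
    if untyped:
        raise ValueError(
            f"{len(untyped)} untyped atom(s), e.g. {untyped[:3]}; "
            "run atom_typing.assign_types first"
        )

    increment = 1.0 if weighting == "raw_count" else 1.0 / len(pose_list)
    counts: dict[str, np.ndarray] = {}
    n_atoms_total = 0
    n_outside = 0
    for pose in pose_list:
        for atom in pose.atoms:
            if not include_hydrogens and atom.sybyl_type == "H":
                continue
            if atom.sybyl_type not in axis:
                raise ValueError(
                    f"atom type {atom.sybyl_type!r} not on the grid type axis"
                )
            n_atoms_total += 1
            idx = rasterize_atom(atom, box)
            if idx.shape[0] == 0:
                n_outside += 1
                continue
            arr = counts.get(atom.sybyl_type)
            if arr is None:
                arr = counts[atom.sybyl_type] = np.zeros(box.shape, dtype=np.float32)
            np.add.at(arr, (idx[:, 0], idx[:, 1], idx[:, 2]), np.float32(increment))
    return FrequencyGrid(
        box=box, type_axis=axis, counts=counts,
        n_poses=len(pose_list), n_atoms_total=n_atoms_total,
        n_atoms_outside=n_outside, weighting=weighting,
    )


def save_grid(grid: FrequencyGrid, path: str | Path) -> None:
    """Persist a grid to HDF5: one dataset per type under ``/counts``."""
    with h5py.File(path, "w") as fh:
        fh.attrs["center"] = grid.box.center
        fh.attrs["edges"] = grid.box.edges
        fh.attrs["origin"] = grid.box.origin
        fh.attrs["step"] = grid.box.step
        fh.attrs["shape"] = np.array(grid.box.shape)
        fh.attrs["type_axis"] = list(grid.type_axis)
        fh.attrs["n_poses"] = grid.n_poses
        fh.attrs["n_atoms_total"] = grid.n_atoms_total
        fh.attrs["n_atoms_outside"] = grid.n_atoms_outside
        fh.attrs["weighting"] = grid.weighting
        group = fh.create_group("counts")
        for styp, arr in grid.counts.items():
            group.create_dataset(
                styp, data=arr, compression="gzip", compression_opts=4,
                chunks=True,
            )


def load_grid(path: str | Path) -> FrequencyGrid:
    """Load a grid saved by :func:`save_grid`, verifying shape metadata."""
    try:
        fh = h5py.File(path, "r")
    except OSError as exc:
        raise GridIntegrityError(f"cannot open grid file {path}: {exc}") from exc
    with fh:
        try:
            box = DockingBox(
                center=fh.attrs["center"][:],
                edges=fh.attrs["edges"][:],
                step=float(fh.attrs["step"]),
            )
            type_axis = tuple(str(t) for t in fh.attrs["type_axis"])
            stored_shape = tuple(int(s) for s in fh.attrs["shape"])
            grid = FrequencyGrid(
                box=box, type_axis=type_axis,
                n_poses=int(fh.attrs["n_poses"]),
                n_atoms_total=int(fh.attrs["n_atoms_total"]),
                n_atoms_outside=int(fh.attrs["n_atoms_outside"]),
                weighting=str(fh.attrs["weighting"]),
            )
        except KeyError as exc:
            raise GridIntegrityError(f"grid file {path} missing metadata: {exc}")
        if stored_shape != box.shape:
            raise GridIntegrityError(
                f"stored shape {stored_shape} inconsistent with box-derived "
                f"shape {box.shape}"
            )
        for styp in fh["counts"]:
            arr = fh["counts"][styp][:]
            if arr.shape != box.shape:
                raise GridIntegrityError(
                    f"dataset {styp!r} has shape {arr.shape}, expected {box.shape}"
                )
            if styp not in type_axis:
                raise GridIntegrityError(f"dataset {styp!r} not on the type axis")
            grid.counts[str(styp)] = arr
    return grid


def export_volumetric(grid: FrequencyGrid, sybyl_type: str, path: str | Path,
                      fmt: str = "dx") -> None:
    """Export one atom type's counts as an OpenDX scalar field for viewers."""
    if fmt != "dx":
        raise ValueError(f"unsupported format {fmt!r}")
    arr = grid.array_for(sybyl_type)
    nx, ny, nz = arr.shape
    origin = grid.box.origin
    step = grid.box.step
    with Path(path).open("w") as fh:
        fh.write(f"# PeptoGrid occurrence map, type {sybyl_type}\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {origin[0]:.6f} {origin[1]:.6f} {origin[2]:.6f}\n")
        fh.write(f"delta {step:.6f} 0 0\n")
        fh.write(f"delta 0 {step:.6f} 0\n")
        fh.write(f"delta 0 0 {step:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items "
                 f"{arr.size} data follows\n")
        flat = arr.ravel(order="C")
        for i in range(0, flat.size, 3):
            fh.write(" ".join(f"{v:.6g}" for v in flat[i:i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')
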