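"""Readers and writers for multi-pose docking output files.

Three dialects are supported, one per docking program:

* **PDBQT** (AutoDock Vina): fixed-column PDB-like records grouped in
  ``MODEL``/``ENDMDL`` blocks, the Vina energy on a ``REMARK VINA RESULT``
  line per model.
* **Tripos MOL2** (PLANTS): one ``@<TRIPOS>MOLECULE`` record per pose; the
  only format that carries SYBYL atom types natively, so typing is read
  verbatim rather than inferred.
* **DOK** (LeDock): PDB-like pose blocks terminated by ``END``, with the
  pose score on a ``REMARK ... Score`` line.

Readers are permissive about blank lines and trailing whitespace but strict
about column positions in the fixed-column formats.  Coordinates are used
exactly as printed — no recentering — so grid placement matches the
docking-box definition.
"""

from __future__ import annotations

import csv
import re
import warnings
from pathlib import Path
from typing import Iterable, Optional

from ._model import UNTYPED, AtomRecord, DockingBox, Pose, PoseSet, RescoredPose
from .atom_typing import SYBYL_ALPHABET, THREE_TO_ONE

__all__ = [
    "read_vina_pdbqt",
    "read_mol2_poses",
    "read_ledock_dok",
    "write_pdbqt",
    "write_mol2",
    "write_dok",
    "write_ranked_csv",
    "ParseError",
    "EmptyInputError",
]


class ParseError(ValueError):
    """Malformed record in a pose file; the message names the line."""


class EmptyInputError(ValueError):
    """A pose file contained no poses."""


# AutoDock atom types -> chemical element (the common peptide subset)
_AUTODOCK_ELEMENTS = {
    "A": "C", "C": "C", "N": "N", "NA": "N", "NS": "N",
    "OA": "O", "OS": "O", "O": "O", "SA": "S", "S": "S",
    "HD": "H", "HS": "H", "H": "H", "P": "P",
}

_VINA_RESULT_RE = re.compile(r"REMARK VINA RESULT:\s*(-?\d+(?:\.\d+)?)")
_DOK_SCORE_RE = re.compile(r"REMARK.*Score\s*:?\s*(-?\d+(?:\.\d+)?)", re.IGNORECASE)


def _parse_pdb_atom(line: str, lineno: int, element_hint: Optional[str] = None) -> AtomRecord:
    """Parse one fixed-column ATOM/HETATM record (PDB/PDBQT/DOK)."""
    try:
        name = line[12:16].strip()
        res_name = line[17:20].strip()
        res_seq = int(line[22:26].strip() or 0)
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"line {lineno}: malformed ATOM record: {exc}") from exc
    element = element_hint or line[76:78].strip() or _element_from_name(name)
    return AtomRecord(
        atom_name=name, element=element.capitalize(), coords=(x, y, z),
        res_name=res_name, res_seq=res_seq,
    )


def _element_from_name(name: str) -> str:
    stripped = name.lstrip("0123456789")
    return stripped[:1].upper() if stripped else "X"


def _sequence_from_residues(atoms: list[AtomRecord]) -> str:
    """One-letter sequence from ordered (res_seq, res_name) pairs, best effort."""
    seen: dict[int, str] = {}
    for a in atoms:
        if a.res_seq not in seen and a.res_name.upper() in THREE_TO_ONE:
            seen[a.res_seq] = THREE_TO_ONE[a.res_name.upper()]
    return "".join(seen[k] for k in sorted(seen))


def read_vina_pdbqt(path: str | Path, sequence: str = "",
                    box: Optional[DockingBox] = None) -> PoseSet:
    """Read an AutoDock Vina multi-MODEL PDBQT file into a PoseSet.

    One pose per ``MODEL`` block; ``native_score`` comes from the block's
    ``REMARK VINA RESULT`` line (kcal/mol); the element is inferred from the
    trailing AutoDock atom-type column.  SYBYL types are left ``"untyped"``
    for :func:`peptogrid.atom_typing.assign_types` to fill in.
    """
    path = Path(path)
    stem = path.stem
    poses: list[Pose] = []
    atoms: list[AtomRecord] = []
    score: Optional[float] = None
    in_model = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            rec = line.rstrip()
            if rec.startswith("MODEL"):
                if in_model:
                    raise ParseError(f"line {lineno}: nested MODEL block")
                in_model, atoms, score = True, [], None
            elif rec.startswith("ENDMDL"):
                if not in_model:
                    raise ParseError(f"line {lineno}: ENDMDL without MODEL")
                if not atoms:
                    raise ParseError(f"line {lineno}: MODEL block with no atoms")
                seq = sequence or _sequence_from_residues(atoms)
                poses.append(Pose(
                    pose_id=f"{stem}_m{len(poses) + 1}", sequence=seq,
                    source="vina", atoms=atoms, native_score=score,
                ))
                in_model = False
            elif rec.startswith(("ATOM", "HETATM")) and in_model:
                tail = rec[77:].strip()
                ad_type = tail.split()[0] if tail else ""
                element = _AUTODOCK_ELEMENTS.get(ad_type.upper())
                atoms.append(_parse_pdb_atom(line, lineno, element_hint=element))
            else:
                m = _VINA_RESULT_RE.search(rec)
                if m and in_model:
                    score = float(m.group(1))
    if in_model:
        raise ParseError(f"{path.name}: MODEL block not closed by ENDMDL")
    if not poses:
        raise EmptyInputError(f"{path.name}: no MODEL blocks found")
    return PoseSet(poses=poses, box=box)


def read_mol2_poses(path: str | Path, box: Optional[DockingBox] = None) -> PoseSet:
    """Read a multi-record Tripos MOL2 file (PLANTS output) into a PoseSet.

    SYBYL types are taken verbatim from the ATOM section; an unknown type
    string triggers a warning and the ``"untyped"`` sentinel.  An atom count
    differing from the MOLECULE header is a parse error.
    """
    path = Path(path)
    text = path.read_text()
    chunks = re.split(r"(?=@<TRIPOS>MOLECULE)", text)
    chunks = [c for c in chunks if c.startswith("@<TRIPOS>MOLECULE")]
    if not chunks:
        raise EmptyInputError(f"{path.name}: no @<TRIPOS>MOLECULE records found")
    poses: list[Pose] = []
    for imol, chunk in enumerate(chunks, 1):
        lines = chunk.splitlines()
        mol_name = lines[1].strip() if len(lines) > 1 else f"mol{imol}"
        try:
            counts = lines[2].split()
            n_atoms = int(counts[0])
        except (IndexError, ValueError) as exc:
            raise ParseError(f"molecule {imol}: malformed counts line") from exc
        try:
            astart = next(i for i, l in enumerate(lines) if l.strip() == "@<TRIPOS>ATOM")
        except StopIteration:
            raise ParseError(f"molecule {imol}: missing @<TRIPOS>ATOM section")
        atoms: list[AtomRecord] = []
        for line in lines[astart + 1:]:
            if line.startswith("@<TRIPOS>"):
                break
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ParseError(f"molecule {imol}: short ATOM line: {line!r}")
            name, x, y, z, styp = parts[1], *map(float, parts[2:5]), parts[5]
            if styp not in SYBYL_ALPHABET:
                warnings.warn(f"molecule {imol}: unknown SYBYL type {styp!r}; "
                              f"marking atom {name!r} untyped")
                styp = UNTYPED
            res_name, res_seq = "", 0
            if len(parts) >= 8:
                m = re.match(r"([A-Za-z]+)(\d+)", parts[7])
                if m:
                    res_name, res_seq = m.group(1), int(m.group(2))
            atoms.append(AtomRecord(
                atom_name=name, element=styp.split(".")[0].capitalize(),
                coords=(x, y, z), sybyl_type=styp,
                res_name=res_name, res_seq=res_seq,
            ))
        if len(atoms) != n_atoms:
            raise ParseError(
                f"molecule {imol}: header declares {n_atoms} atoms, found {len(atoms)}"
            )
        poses.append(Pose(
            pose_id=f"{mol_name}_{imol}" if mol_name else f"mol_{imol}",
            sequence=_sequence_from_residues(atoms),
            source="plants", atoms=atoms,
        ))
    return PoseSet(poses=poses, box=box)


def read_ledock_dok(path: str | Path, sequence: str = "",
                    box: Optional[DockingBox] = None) -> PoseSet:
    """Read a LeDock DOK file (PDB-like blocks ended by ``END``) into a PoseSet.

    ``native_score`` comes from each block's ``REMARK ... Score`` line when
    present; a block without one keeps the pose with no native score.
    """
    path = Path(path)
    stem = path.stem
    poses: list[Pose] = []
    atoms: list[AtomRecord] = []
    score: Optional[float] = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            rec = line.rstrip()
            if rec.startswith(("ATOM", "HETATM")):
                atoms.append(_parse_pdb_atom(line, lineno))
            elif rec.startswith("END"):
                if atoms:
                    seq = sequence or _sequence_from_residues(atoms)
                    poses.append(Pose(
                        pose_id=f"{stem}_p{len(poses) + 1}", sequence=seq,
                        source="ledock", atoms=atoms, native_score=score,
                    ))
                atoms, score = [], None
            else:
                m = _DOK_SCORE_RE.search(rec)
                if m:
                    score = float(m.group(1))
    if atoms:  # trailing block without END
        poses.append(Pose(
            pose_id=f"{stem}_p{len(poses) + 1}",
            sequence=sequence or _sequence_from_residues(atoms),
            source="ledock", atoms=atoms, native_score=score,
        ))
    if not poses:
        raise EmptyInputError(f"{path.name}: no pose blocks found")
    return PoseSet(poses=poses, box=box)


# one-letter -> three-letter for writers
_ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


def write_pdbqt(poses: PoseSet | Iterable[Pose], path: str | Path) -> None:
    """Write poses as a multi-MODEL PDBQT file (Vina output dialect)."""
    pose_list = list(poses)
    with Path(path).open("w") as fh:
        for i, pose in enumerate(pose_list, 1):
            fh.write(f"MODEL {i}\n")
            if pose.native_score is not None:
                fh.write(f"REMARK VINA RESULT:    {pose.native_score:8.1f}"
                         f"      0.000      0.000\n")
            for j, a in enumerate(pose.atoms, 1):
                ad = "A" if a.sybyl_type == "C.ar" else a.element.upper()
                fh.write(
                    f"ATOM  {j:5d} {a.atom_name:<4.4s}{a.res_name:>4.3s} A"
                    f"{a.res_seq:4d}    {a.coords[0]:8.3f}{a.coords[1]:8.3f}"
                    f"{a.coords[2]:8.3f}  0.00  0.00    "
                    f"{0.0:6.3f} {ad:<2s}\n"
                )
            fh.write("ENDMDL\n")


def write_mol2(poses: PoseSet | Iterable[Pose], path: str | Path) -> None:
    """Write poses as a multi-record Tripos MOL2 file with SYBYL types.

    Untyped atoms are written with their bare element symbol, which the
    reader will flag; type poses first for round-trip-clean fixtures.
    """
    pose_list = list(poses)
    with Path(path).open("w") as fh:
        for pose in pose_list:
            fh.write("@<TRIPOS>MOLECULE\n")
            fh.write(f"{pose.pose_id}\n")
            fh.write(f"{len(pose.atoms)} 0 0 0 0\n")
            fh.write("SMALL\nNO_CHARGES\n\n")
            fh.write("@<TRIPOS>ATOM\n")
            for j, a in enumerate(pose.atoms, 1):
                styp = a.sybyl_type if a.sybyl_type != UNTYPED else a.element
                sub = f"{a.res_name}{a.res_seq}" if a.res_name else "LIG1"
                fh.write(
                    f"{j:7d}  {a.atom_name:<8.8s}{a.coords[0]:10.4f}"
                    f"{a.coords[1]:10.4f}{a.coords[2]:10.4f} {styp:<7.7s}"
                    f"{1:3d}  {sub:<9.9s}{0.0:8.4f}\n"
                )


def write_dok(poses: PoseSet | Iterable[Pose], path: str | Path) -> None:
    """Write poses as a LeDock-style DOK file."""
    pose_list = list(poses)
    with Path(path).open("w") as fh:
        for i, pose in enumerate(pose_list, 1):
            if pose.native_score is not None:
                fh.write(f"REMARK Cluster {i:3d} Score: {pose.native_score:8.2f} "
                         f"kcal/mol\n")
            for j, a in enumerate(pose.atoms, 1):
                fh.write(
                    f"ATOM  {j:5d} {a.atom_name:<4.4s}{a.res_name:>4.3s} A"
                    f"{a.res_seq:4d}    {a.coords[0]:8.3f}{a.coords[1]:8.3f}"
                    f"{a.coords[2]:8.3f}  0.00  0.00          "
                    f"{a.element.upper():>2.2s}\n"
                )
            fh.write("END\n")


RANKED_CSV_COLUMNS = (
    "pose_id", "sequence", "source", "native_score",
    "raw_sr", "normalized_score", "rank",
)


def write_ranked_csv(results: list[RescoredPose], path: str | Path) -> None:
    """Write rescoring results as CSV, best rank first."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(RANKED_CSV_COLUMNS)
        for r in sorted(results, key=lambda r: r.rank):
            writer.writerow([
                r.pose_id, r.sequence, r.source,
                "" if r.native_score is None else r.native_score,
                repr(r.raw_sr), repr(r.normalized_score), r.rank,
            ])
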