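"""Tripos SYBYL atom typing for standard peptide ligands.

PDBQT and DOK pose files carry no SYBYL types, so atoms read from them must
be typed before grid accumulation.  Because the ligand universe is standard
peptides, typing is an exact template lookup on ``(residue name, atom name)``
with N-/C-terminal overrides, rather than general chemical perception.  The
table ships with the package as JSON and can be replaced wholesale for
different radii sets or protonation conventions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Optional

from ._model import UNTYPED, AtomRecord, Pose

__all__ = [
    "TypingTable",
    "load_default_table",
    "assign_types",
    "supported_alphabet",
    "TypingError",
]

#: fixed, documented ordering of the SYBYL types this package understands;
#: this is the grid's type axis.
SYBYL_ALPHABET: tuple[str, ...] = (
    "C.3",
    "C.2",
    "C.ar",
    "C.cat",
    "N.am",
    "N.4",
    "N.pl3",
    "N.ar",
    "O.2",
    "O.3",
    "O.co2",
    "S.3",
    "H",
)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class TypingError(ValueError):
    """Raised when atoms cannot be resolved against the typing table."""


@dataclass(frozen=True)
class TypingTable:
    """(residue, atom) -> SYBYL type templates plus element vdW radii."""

    backbone: dict[str, str]
    nterm: dict[str, str]
    cterm: dict[str, str]
    sidechains: dict[str, dict[str, str]]
    radii: dict[str, float]

    def __post_init__(self) -> None:
        for res, tmpl in self.sidechains.items():
            for atom, styp in tmpl.items():
                if styp not in SYBYL_ALPHABET:
                    raise ValueError(f"template type {styp!r} for {res}:{atom} "
                                     "is outside the supported alphabet")
        for el, r in self.radii.items():
            if not r > 0:
                raise ValueError(f"non-positive radius for element {el!r}")

    def lookup(self, res_name: str, atom_name: str,
               *, is_nterm: bool = False, is_cterm: bool = False) -> Optional[str]:
        """SYBYL type for one atom, or None when unresolvable."""
        res = res_name.upper()
        name = atom_name.upper()
        if name.startswith("H") or (name[:1].isdigit() and "H" in name):
            return "H"
        if is_nterm and name in self.nterm:
            return self.nterm[name]
        if is_cterm and name in self.cterm:
            return self.cterm[name]
        if name in self.backbone:
            return self.backbone[name]
        tmpl = self.sidechains.get(res)
        if tmpl is not None and name in tmpl:
            return tmpl[name]
        return None

    def radius_for(self, element: str) -> float:
        try:
            return self.radii[element.capitalize()]
        except KeyError:
            raise TypingError(f"no van der Waals radius for element {element!r}")


def load_default_table(path: Optional[str | Path] = None) -> TypingTable:
    """Load the packaged typing table, or a user override from *path*."""
    if path is None:
        text = resources.files("peptogrid.data").joinpath("sybyl_typing.json").read_text()
    else:
        text = Path(path).read_text()
    raw = json.loads(text)
    return TypingTable(
        backbone=raw["backbone"],
        nterm=raw["nterm"],
        cterm=raw["cterm"],
        sidechains=raw["sidechains"],
        radii=raw["radii"],
    )


def supported_alphabet() -> tuple[str, ...]:
    """The fixed, duplicate-free ordering of supported SYBYL types."""
    return SYBYL_ALPHABET


def assign_types(pose: Pose, table: Optional[TypingTable] = None) -> Pose:
    """Return a copy of *pose* with SYBYL types and vdW radii assigned.

    Terminal context is inferred from residue numbering: atoms of the first
    residue may match N-terminal overrides, atoms of the last residue
    C-terminal ones.  Idempotent; raises :class:`TypingError` listing every
    unresolvable atom.
    """
    if table is None:
        table = load_default_table()
    res_seqs = sorted({a.res_seq for a in pose.atoms})
    first, last = res_seqs[0], res_seqs[-1]
    typed_atoms: list[AtomRecord] = []
    failures: list[str] = []
    for atom in pose.atoms:
        styp = table.lookup(
            atom.res_name,
            atom.atom_name,
            is_nterm=atom.res_seq == first,
            is_cterm=atom.res_seq == last,
        )
        if styp is None:
            failures.append(f"{atom.res_name}{atom.res_seq}:{atom.atom_name}")
            continue
        typed_atoms.append(
            replace(atom, sybyl_type=styp, vdw_radius=table.radius_for(atom.element))
        )
    if failures:
        raise TypingError(
            f"pose {pose.pose_id!r}: cannot type {len(failures)} atom(s): "
            + ", ".join(failures[:10])
        )
    return replace(pose, atoms=typed_atoms)
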