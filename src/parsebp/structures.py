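"""Reading RNA decoy coordinate files into a uniform in-memory representation.

A decoy ensemble for one target is a directory of PDB/mmCIF files all
modelling the same nucleotide sequence.  Each file is reduced to an
:class:`RnaStructure`: an ordered list of nucleotide residues carrying the
atom coordinates needed downstream (the C1' trace for superposition, the
base ring and edge atoms for base-pair annotation).  Residue correspondence
across decoys is by ordinal position after sorting, never by author
numbering, because decoy sets use inconsistent numbering dialects.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .errors import (
    EmptyStructureError,
    EnsembleTooSmallError,
    StructureParseError,
)

logger = logging.getLogger(__name__)

#: Atom-name priority used for the per-residue representative point.
REPRESENTATIVE_ATOMS = ("C1'", "C4'", "P")

_STANDARD_BASES = frozenset("ACGU")


@dataclass
class Residue:
    """One nucleotide residue with named heavy-atom coordinates (Å)."""

    base: str  # one of A, C, G, U
    chain: str
    seqid: int
    icode: str = ""
    atoms: dict[str, np.ndarray] = field(default_factory=dict)
    incomplete: bool = False  # True when the C1' atom is missing

    def get(self, name: str) -> np.ndarray | None:
        return self.atoms.get(name)


@dataclass
class RnaStructure:
    """One decoy: identifier, sequence and ordered residue records."""

    id: str
    sequence: str
    residues: list[Residue]

    @property
    def length(self) -> int:
        return len(self.residues)

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.residues):
            raise ValueError("sequence/residue length mismatch")

    def representative_coords(
        self, priority: Sequence[str] = REPRESENTATIVE_ATOMS
    ) -> tuple[np.ndarray, np.ndarray]:
        """Return (mask, coords): per-residue representative atom positions.

        ``mask`` is a boolean array marking residues that have any of the
        priority atoms; ``coords`` has one row per residue (NaN where absent).
        """
        coords = np.full((self.length, 3), np.nan)
        mask = np.zeros(self.length, dtype=bool)
        for k, res in enumerate(self.residues):
            for name in priority:
                xyz = res.atoms.get(name)
                if xyz is not None:
                    coords[k] = xyz
                    mask[k] = True
                    break
        return mask, coords

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "RnaStructure":
        """Return a copy with every atom rigidly transformed (x' = R x + t)."""
        new_res = []
        for res in self.residues:
            atoms = {n: rotation @ xyz + translation for n, xyz in res.atoms.items()}
            new_res.append(
                Residue(res.base, res.chain, res.seqid, res.icode, atoms, res.incomplete)
            )
        return RnaStructure(self.id, self.sequence, new_res)


@dataclass
class Ensemble:
    """An ordered pool of decoys modelling one target sequence."""

    target_id: str
    structures: list[RnaStructure]

    @property
    def n(self) -> int:
        return len(self.structures)

    @property
    def common_length(self) -> int:
        return self.structures[0].length

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.structures)


def _base_letter(resname: str) -> str | None:
    """Map a residue name to its parent base letter, or None if not RNA-like."""
    info = gemmi.find_tabulated_residue(resname)
    if info is None or not info.is_nucleic_acid():
        return None
    letter = info.one_letter_code.upper()
    if letter == "T":  # thymine decoys occasionally appear; parent base is U
        letter = "U"
    return letter if letter in _STANDARD_BASES else None


def _normalize_atom_name(name: str) -> str:
    return name.strip().replace("*", "'").replace("′", "'")


_FORMATS = {
    "pdb": gemmi.CoorFormat.Pdb,
    "mmcif": gemmi.CoorFormat.Mmcif,
    "auto": gemmi.CoorFormat.Detect,
}


def read_structure(path: str | Path, format: str = "auto") -> RnaStructure:
    """Parse one coordinate file into an :class:`RnaStructure`.

    Only the first model of a multi-model file is used.  Non-nucleotide
    residues (waters, ions, protein) are dropped; modified nucleotides are
    mapped to their parent base when gemmi's chemical-component table
    identifies one, and dropped with a warning otherwise.  For alternate
    locations the highest-occupancy atom wins (ties: first encountered).
    """
    path = Path(path)
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=_FORMATS[format])
    except Exception as exc:  # gemmi raises RuntimeError/ValueError
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")

    model = st[0]
    residues: list[Residue] = []
    n_dropped_modified = 0
    for chain in model:
        for res in chain:
            letter = _base_letter(res.name)
            if letter is None:
                info = gemmi.find_tabulated_residue(res.name)
                if info is not None and info.is_nucleic_acid():
                    n_dropped_modified += 1
                continue
            atoms: dict[str, np.ndarray] = {}
            occ: dict[str, float] = {}
            for atom in res:
                if atom.is_hydrogen():
                    continue
                name = _normalize_atom_name(atom.name)
                o = atom.occ if atom.occ > 0 else 1.0
                if name in atoms and occ[name] >= o:
                    continue  # keep higher occupancy; ties keep first
                if name in atoms and occ[name] == o:
                    continue
                atoms[name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                occ[name] = o
            if not atoms:
                continue
            if not np.all(np.isfinite(np.concatenate(list(atoms.values())))):
                raise StructureParseError(f"{path}: non-finite coordinates in {res.name}")
            residues.append(
                Residue(
                    base=letter,
                    chain=chain.name,
                    seqid=res.seqid.num,
                    icode=(res.seqid.icode or "").strip(),
                    atoms=atoms,
                    incomplete="C1'" not in atoms,
                )
            )
    if n_dropped_modified:
        logger.warning(
            "%s: dropped %d modified nucleotide(s) without a standard parent",
            path.name,
            n_dropped_modified,
        )
    residues.sort(key=lambda r: (r.chain, r.seqid, r.icode))
    if not residues or all(r.incomplete for r in residues):
        raise EmptyStructureError(f"{path}: no nucleotide residue with a C1' atom")
    return RnaStructure(
        id=path.stem,
        sequence="".join(r.base for r in residues),
        residues=residues,
    )


_COORD_SUFFIXES = (".pdb", ".ent", ".cif", ".mmcif")


def read_ensemble(
    directory: str | Path,
    target_id: str | None = None,
    paths: Iterable[str | Path] | None = None,
) -> Ensemble:
    """Read all decoys for one target from a directory.

    Files are taken in lexicographic filename order (independent of the
    filesystem listing order).  Decoys whose sequence disagrees with the
    majority sequence of the pool are excluded with a warning; at least two
    consistent decoys must remain.
    """
    directory = Path(directory)
    if paths is None:
        paths = sorted(
            p for p in directory.iterdir() if p.suffix.lower() in _COORD_SUFFIXES
        )
    else:
        paths = sorted(Path(p) for p in paths)

    structures: list[RnaStructure] = []
    for p in paths:
        try:
            structures.append(read_structure(p))
        except (StructureParseError, EmptyStructureError) as exc:
            logger.warning("skipping %s: %s", p.name, exc)
    if len(structures) < 2:
        raise EnsembleTooSmallError(
            f"{directory}: need >=2 parseable decoys, got {len(structures)}"
        )

    counts = Counter(s.sequence for s in structures)
    # majority sequence; deterministic tie-break on the sequence string
    majority = max(counts.items(), key=lambda kv: (kv[1], kv[0]))[0]
    kept, excluded = [], []
    for s in structures:
        (kept if s.sequence == majority else excluded).append(s)
    for s in excluded:
        logger.warning(
            "excluding decoy %s: sequence/length inconsistent with majority", s.id
        )
    if len(kept) < 2:
        raise EnsembleTooSmallError(
            f"{directory}: only {len(kept)} decoys consistent with majority sequence"
        )
    return Ensemble(target_id=target_id or directory.name, structures=kept)
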