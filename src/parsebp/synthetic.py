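"""Synthetic RNA decoy ensembles with known ground-truth quality.

Emulates a CASP-style decoy pool for one target: an ideal A-form duplex is
the reference conformation, and decoys are generated at graded, known
distortion levels — Cartesian Gaussian noise on every atom (plus a random
rigid transform, which no similarity measure here should feel), and/or
glycosidic disruption of designed base pairs that breaks 2D annotation
geometry while leaving the backbone trace almost untouched.  Ground-truth
quality of a decoy is its TM-score to the unperturbed reference.

What this emulates and what it does not: graded global accuracy tiers and
decoys whose base pairing is inconsistent with their backbone fold — the
two signals the consensus scorer combines.  It does not emulate realistic
loop/junction topologies, compactness changes, or physically relaxed
geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .structures import Ensemble, Residue, RnaStructure
from .tmscore import TmParams, tm_score

# Standard base geometry in the base-pair reference frame (Å): base plane at
# z=0, glycosidic atoms on the -x side, Watson-Crick edge toward +x.  The
# complementary base of a WC pair is the template flipped (y, z) -> (-y, -z).
BASE_TEMPLATES: dict[str, dict[str, tuple[float, float, float]]] = {
    "A": {
        "C1'": (-2.479, 5.346, 0.0),
        "N9": (-1.291, 4.498, 0.0),
        "C8": (0.024, 4.897, 0.0),
        "N7": (0.877, 3.902, 0.0),
        "C5": (0.071, 2.771, 0.0),
        "C6": (0.369, 1.398, 0.0),
        "N6": (1.611, 0.909, 0.0),
        "N1": (-0.668, 0.532, 0.0),
        "C2": (-1.912, 1.023, 0.0),
        "N3": (-2.320, 2.290, 0.0),
        "C4": (-1.267, 3.124, 0.0),
    },
    "G": {
        "C1'": (-2.477, 5.399, 0.0),
        "N9": (-1.289, 4.551, 0.0),
        "C8": (0.023, 4.962, 0.0),
        "N7": (0.870, 3.969, 0.0),
        "C5": (0.071, 2.833, 0.0),
        "C6": (0.424, 1.460, 0.0),
        "O6": (1.554, 0.955, 0.0),
        "N1": (-0.700, 0.641, 0.0),
        "C2": (-1.999, 1.087, 0.0),
        "N2": (-2.949, 0.139, 0.0),
        "N3": (-2.342, 2.364, 0.0),
        "C4": (-1.265, 3.177, 0.0),
    },
    "C": {
        "C1'": (-2.477, 5.402, 0.0),
        "N1": (-1.285, 4.542, 0.0),
        "C2": (-1.472, 3.158, 0.0),
        "O2": (-2.628, 2.709, 0.0),
        "N3": (-0.391, 2.344, 0.0),
        "C4": (0.837, 2.868, 0.0),
        "N4": (1.875, 2.027, 0.0),
        "C5": (1.056, 4.275, 0.0),
        "C6": (-0.023, 5.068, 0.0),
    },
    "U": {
        "C1'": (-2.481, 5.354, 0.0),
        "N1": (-1.284, 4.500, 0.0),
        "C2": (-1.462, 3.131, 0.0),
        "O2": (-2.563, 2.608, 0.0),
        "N3": (-0.302, 2.397, 0.0),
        "C4": (0.989, 2.884, 0.0),
        "O4": (1.935, 2.094, 0.0),
        "C5": (1.089, 4.311, 0.0),
        "C6": (-0.024, 5.053, 0.0),
    },
}

#: Backbone pseudo-atom offsets relative to C1' in the template frame.
BACKBONE_OFFSETS = {"C4'": (-1.2, 0.9, 1.8), "P": (-2.5, 2.0, 4.0)}

#: Atoms that stay fixed when a base is rotated about its glycosidic bond.
BACKBONE_ATOMS = frozenset({"C1'", "C4'", "P"})

GLYCOSIDIC_N = {"A": "N9", "G": "N9", "C": "N1", "U": "N1"}
COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

# A-form helical parameters (standard fiber values).
RISE = 2.81  # Å per base pair
TWIST = 32.7  # degrees per base pair
X_DISPLACEMENT = -4.4  # Å; base-pair frame offset from the helix axis


def _rot_z(deg: float) -> np.ndarray:
    t = np.radians(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _template_atoms(base: str, flip: bool) -> dict[str, np.ndarray]:
    atoms = {}
    for name, xyz in BASE_TEMPLATES[base].items():
        atoms[name] = np.array(xyz, dtype=float)
    c1 = atoms["C1'"]
    for name, off in BACKBONE_OFFSETS.items():
        atoms[name] = c1 + np.array(off, dtype=float)
    if flip:
        atoms = {n: np.array([p[0], -p[1], -p[2]]) for n, p in atoms.items()}
    return atoms


def _default_sequence(n_bp: int) -> str:
    return "".join("GCAU"[k % 4] for k in range(n_bp))


def ideal_duplex(
    n_bp: int, sequence: str | None = None
) -> tuple[RnaStructure, list[tuple[int, int]]]:
    """Build an ideal A-form double helix of ``n_bp`` Watson-Crick pairs.

    ``sequence`` is the 5'->3' sequence of the first strand (default cycles
    GCAU); the second strand is its reverse complement.  Returns the
    structure (chains A and B concatenated, 2*n_bp residues) and the list of
    designed pair indices (0-based ordinal, i.e. (k, 2*n_bp-1-k)).
    """
    if n_bp < 2:
        raise ValueError("need at least 2 base pairs")
    seq1 = sequence or _default_sequence(n_bp)
    if len(seq1) != n_bp or any(b not in "ACGU" for b in seq1):
        raise ValueError("sequence must be ACGU of length n_bp")

    residues_a: list[Residue] = []
    residues_b: list[Residue] = []
    for k, base1 in enumerate(seq1):
        base2 = COMPLEMENT[base1]
        rot = _rot_z(k * TWIST)
        shift = np.array([0.0, 0.0, k * RISE])
        disp = np.array([X_DISPLACEMENT, 0.0, 0.0])
        at1 = {n: rot @ (p + disp) + shift
               for n, p in _template_atoms(base1, flip=False).items()}
        at2 = {n: rot @ (p + disp) + shift
               for n, p in _template_atoms(base2, flip=True).items()}
        residues_a.append(Residue(base1, "A", k + 1, atoms=at1))
        residues_b.append(Residue(base2, "B", 0, atoms=at2))
    # second strand runs antiparallel: 5'->3' order is helix step n-1 .. 0
    residues_b.reverse()
    for k, res in enumerate(residues_b):
        res.seqid = k + 1
    residues = residues_a + residues_b
    seq = "".join(r.base for r in residues)
    pairs = [(k, 2 * n_bp - 1 - k) for k in range(n_bp)]
    return RnaStructure(id=f"duplex_{n_bp}bp", sequence=seq, residues=residues), pairs


def extended_strand(n: int, spacing: float = 7.0) -> RnaStructure:
    """A fully extended single strand: residues along a line, no pairs."""
    if n < 1:
        raise ValueError("need at least 1 residue")
    seq = _default_sequence(n)
    residues = []
    for k, base in enumerate(seq):
        shift = np.array([k * spacing, 0.0, 0.0])
        atoms = {n_: p + shift for n_, p in _template_atoms(base, flip=False).items()}
        residues.append(Residue(base, "A", k + 1, atoms=atoms))
    return RnaStructure(id=f"strand_{n}nt", sequence=seq, residues=residues)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def perturb(s: RnaStructure, sigma: float, seed: int) -> RnaStructure:
    """Add i.i.d. Gaussian noise (std ``sigma`` Å) to every atom, then apply
    a random rigid transform.  ``sigma=0`` yields a pure rigid motion."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    rotation = _random_rotation(rng)
    translation = rng.uniform(-20.0, 20.0, size=3)
    residues = []
    for res in s.residues:
        atoms = {}
        for name, xyz in res.atoms.items():
            noisy = xyz + (rng.normal(0.0, sigma, size=3) if sigma > 0 else 0.0)
            atoms[name] = rotation @ noisy + translation
        residues.append(Residue(res.base, res.chain, res.seqid, res.icode, atoms))
    return RnaStructure(s.id, s.sequence, residues)


def disrupt_pairs(
    s: RnaStructure,
    designed_pairs: list[tuple[int, int]],
    fraction: float,
    seed: int,
) -> RnaStructure:
    """Geometrically break a fraction of designed pairs.

    For each selected pair, one partner's base is rotated 90-150 degrees
    about its glycosidic bond (the C1'-N9/N1 axis).  The sugar-phosphate
    backbone is untouched, so the C1' trace — and hence the 3D fold as a
    TM-score sees it — barely changes while the pairing geometry is lost.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_break = int(round(fraction * len(designed_pairs)))
    chosen = rng.choice(len(designed_pairs), size=n_break, replace=False)
    residues = [
        Residue(r.base, r.chain, r.seqid, r.icode, dict(r.atoms), r.incomplete)
        for r in s.residues
    ]
    for idx in sorted(chosen):
        i, j = designed_pairs[idx]
        k = int(rng.integers(0, 2))
        target = residues[(i, j)[k]]
        angle = np.radians(rng.uniform(90.0, 150.0)) * (1 if rng.random() < 0.5 else -1)
        c1 = target.atoms["C1'"]
        n_gly = target.atoms[GLYCOSIDIC_N[target.base]]
        axis = n_gly - c1
        axis = axis / np.linalg.norm(axis)
        kx, ky, kz = axis
        kmat = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
        rot = np.eye(3) + np.sin(angle) * kmat + (1 - np.cos(angle)) * (kmat @ kmat)
        for name in target.atoms:
            if name in BACKBONE_ATOMS:
                continue
            target.atoms[name] = rot @ (target.atoms[name] - c1) + c1
    return RnaStructure(s.id, s.sequence, residues)


@dataclass
class DecoySpec:
    """Recipe for one synthetic decoy pool.

    Defaults give a 32-nt duplex target with 12 decoys in three accuracy
    tiers (Cartesian noise sigma 0.1, 1.0 and 3.0 Å, four decoys each) and
    no base-pair disruption — the pool used throughout the test suite.
    """

    length: int = 32  # nucleotides; the duplex has length // 2 pairs
    noise_grid: tuple[float, ...] = (0.1,) * 4 + (1.0,) * 4 + (3.0,) * 4
    bp_disruption: tuple[float, ...] | None = None
    seed: int = 0

    @property
    def n_decoys(self) -> int:
        return len(self.noise_grid)

    def __post_init__(self) -> None:
        if self.length < 4 or self.length % 2:
            raise ValueError("length must be an even number >= 4")
        if any(s < 0 for s in self.noise_grid):
            raise ValueError("noise sigmas must be >= 0")
        if self.bp_disruption is None:
            self.bp_disruption = (0.0,) * self.n_decoys
        if len(self.bp_disruption) != self.n_decoys:
            raise ValueError("bp_disruption must match noise_grid length")
        if any(not 0 <= f <= 1 for f in self.bp_disruption):
            raise ValueError("bp_disruption fractions must be in [0, 1]")


def make_ensemble(
    spec: DecoySpec, out_dir: str | Path | None = None
) -> tuple[Ensemble, pd.DataFrame]:
    """Generate a decoy pool and its ground-truth quality table.

    Ground-truth quality of each decoy is its TM-score to the unperturbed
    reference duplex.  With ``out_dir`` set, decoy PDB files go to
    ``out_dir/decoys/`` and the reference plus ``truth.csv`` to ``out_dir``.
    Deterministic for a fixed spec.
    """
    reference, designed = ideal_duplex(spec.length // 2)
    seeds = np.random.SeedSequence(spec.seed).generate_state(2 * spec.n_decoys)
    structures = []
    rows = []
    target_id = f"synthetic_{spec.length}nt"
    for k, sigma in enumerate(spec.noise_grid):
        decoy = perturb(reference, sigma, int(seeds[2 * k] % (2**31)))
        frac = spec.bp_disruption[k]
        if frac > 0:
            decoy = disrupt_pairs(decoy, designed, frac,
                                  int(seeds[2 * k + 1] % (2**31)))
        decoy.id = f"decoy_{k:03d}"
        structures.append(decoy)
        rows.append({
            "target_id": target_id,
            "decoy_id": decoy.id,
            "tm": tm_score(decoy, reference, TmParams()),
        })
    ensemble = Ensemble(target_id=target_id, structures=structures)
    truth = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        decoy_dir = out_dir / "decoys"
        decoy_dir.mkdir(parents=True, exist_ok=True)
        write_pdb(reference, out_dir / "reference.pdb")
        for s in structures:
            write_pdb(s, decoy_dir / f"{s.id}.pdb")
        truth.to_csv(out_dir / "truth.csv", index=False)
    return ensemble, truth


def write_pdb(s: RnaStructure, path: str | Path) -> None:
    """Write a structure as a minimal single-model PDB file."""
    lines = []
    serial = 1
    prev_chain = None
    for res in s.residues:
        if prev_chain is not None and res.chain != prev_chain:
            lines.append("TER")
        prev_chain = res.chain
        for name in sorted(res.atoms):
            x, y, z = res.atoms[name]
            pdb_name = name if len(name) == 4 else f" {name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {pdb_name}{'':1s}{res.base:>3s} "
                f"{res.chain[:1]}{res.seqid:4d}{res.icode:1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {name[0]:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
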