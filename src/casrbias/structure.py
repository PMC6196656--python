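"""Residue-environment measurements on receptor structures and alignments.

The extracellular domain of the CaSR crystallises as a homodimer (one
protomer per chain). The measurements here are the ones used to reason about
disease-switch residues: minimum inter-protomer heavy-atom distances (e.g.
the Asn178 side chain against Asp48/Tyr246 of the opposing protomer),
donor-acceptor distances for asserting hydrogen bonds (default cutoff 3.5 A,
distance-only criterion), and per-column conservation of reference positions
in a multiple sequence alignment of receptor orthologs.

Structures are read with gemmi (PDB and mmCIF); only the first model is kept
and alternate locations are collapsed to the highest-occupancy conformer.
Residue numbering follows the author numbering of the file, which for CaSR
ECD structures matches the full-length 1078-residue protein numbering.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import AlignIO

try:
    import gemmi
except ImportError as exc:  # pragma: no cover
    raise ImportError("casrbias.structure requires gemmi") from exc

#: backbone atom names excluded by the side-chain selector
BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

DEFAULT_HBOND_CUTOFF = 3.5  # A, donor-acceptor heavy-atom distance


class StructureFormatError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


class SelectorError(KeyError):
    """Raised when a chain/residue/atom selector matches nothing."""


@dataclass(frozen=True)
class Atom:
    chain: str
    res_number: int
    res_name: str
    atom_name: str
    element: str
    x: float
    y: float
    z: float
    hetero: bool

    @property
    def pos(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class StructureModel:
    """Flat atomic model: first model, highest-occupancy conformers only."""

    atoms: list[Atom]
    model_id: str
    source: str

    def residue_atoms(self, chain: str, res_number: int) -> list[Atom]:
        found = [a for a in self.atoms if a.chain == chain and a.res_number == res_number]
        if not found:
            raise SelectorError(f"no residue {chain}/{res_number} in {self.source}")
        return found

    def atom(self, chain: str, res_number: int, atom_name: str) -> Atom:
        for a in self.residue_atoms(chain, res_number):
            if a.atom_name == atom_name:
                return a
        raise SelectorError(f"no atom {chain}/{res_number}/{atom_name} in {self.source}")

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Rigid-body transform (used for invariance checks)."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        atoms = []
        for a in self.atoms:
            x, y, z = R @ a.pos + t
            atoms.append(
                Atom(a.chain, a.res_number, a.res_name, a.atom_name, a.element,
                     float(x), float(y), float(z), a.hetero)
            )
        return StructureModel(atoms, self.model_id, self.source + "+rigid")


def load_structure(path: str | Path) -> StructureModel:
    """Parse a PDB or mmCIF file into a :class:`StructureModel`.

    Keeps all atoms of the first model with chain identity preserved and
    heteroatoms flagged; for alternate locations only the highest-occupancy
    conformer of each atom survives. Raises
    :class:`StructureFormatError` for unreadable or atom-free files.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"{path}: cannot parse coordinates: {exc}") from exc
    if len(st) == 0:
        raise StructureFormatError(f"{path}: file contains no models/atoms")
    st.setup_entities()
    model = st[0]
    best: dict[tuple[str, int, str], tuple[float, Atom]] = {}
    order: list[tuple[str, int, str]] = []
    for chain in model:
        for residue in chain:
            seqid = residue.seqid.num
            het = residue.het_flag == "H"
            for atom in residue:
                if not np.all(np.isfinite([atom.pos.x, atom.pos.y, atom.pos.z])):
                    raise StructureFormatError(
                        f"{path}: non-finite coordinates at {chain.name}/{seqid}/{atom.name}"
                    )
                key = (chain.name, seqid, atom.name)
                rec = Atom(
                    chain.name, seqid, residue.name, atom.name,
                    atom.element.name, atom.pos.x, atom.pos.y, atom.pos.z, het,
                )
                occ = float(atom.occ)
                if key not in best:
                    best[key] = (occ, rec)
                    order.append(key)
                elif occ > best[key][0]:
                    best[key] = (occ, rec)
    if not best:
        raise StructureFormatError(f"{path}: no atoms in first model")
    atoms = [best[k][1] for k in order]
    return StructureModel(atoms=atoms, model_id=str(model.num), source=path.stem)


def _heavy(atoms: Sequence[Atom]) -> list[Atom]:
    return [a for a in atoms if a.element.upper() not in ("H", "D")]


def min_interprotomer_distance(
    s: StructureModel,
    res_a: tuple[str, int],
    targets: Sequence[tuple[str, int]],
    side_chain_only_a: bool = False,
) -> float:
    """Minimum heavy-atom distance from one residue to a set of residues.

    With ``side_chain_only_a`` the probe residue contributes only its
    side-chain heavy atoms (backbone N/CA/C/O/OXT excluded). Targets always
    contribute all heavy atoms. For an inter-protomer measurement the caller
    selects residues on the opposing chain of the dimer.
    """
    a_atoms = _heavy(s.residue_atoms(*res_a))
    if side_chain_only_a:
        a_atoms = [a for a in a_atoms if a.atom_name not in BACKBONE_ATOMS]
    if not a_atoms:
        raise SelectorError(
            f"residue {res_a[0]}/{res_a[1]} has no selectable heavy atoms "
            f"(side_chain_only={side_chain_only_a})"
        )
    t_atoms: list[Atom] = []
    for chain, num in targets:
        t_atoms.extend(_heavy(s.residue_atoms(chain, num)))
    if not t_atoms:
        raise SelectorError(f"no heavy atoms among targets {list(targets)}")
    pa = np.array([a.pos for a in a_atoms])
    pt = np.array([a.pos for a in t_atoms])
    d = np.linalg.norm(pa[:, None, :] - pt[None, :, :], axis=-1)
    return float(d.min())


def hbond_distance(
    s: StructureModel,
    donor: tuple[str, int, str],
    acceptor: tuple[str, int, str],
    cutoff: float = DEFAULT_HBOND_CUTOFF,
) -> tuple[float, bool]:
    """Donor-acceptor distance and whether it satisfies the H-bond cutoff.

    Distance-only criterion (crystal structures lack hydrogens, so no angle
    term is applied); default cutoff 3.5 A between the donor and acceptor
    heavy atoms.
    """
    d_atom = s.atom(*donor)
    a_atom = s.atom(*acceptor)
    dist = float(np.linalg.norm(d_atom.pos - a_atom.pos))
    return dist, dist <= cutoff


# ---------------------------------------------------------------------------
# Alignment conservation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PositionConservation:
    position: int  # reference residue number (1-based, ungapped)
    column: int  # 0-based alignment column
    reference_residue: str
    fraction_identical: float  # among non-reference sequences; gaps mismatch
    gap_count: int


@dataclass(frozen=True)
class ConservationProfile:
    reference_id: str
    n_sequences: int  # non-reference sequences scored
    positions: tuple[PositionConservation, ...]

    def as_dict(self) -> dict[int, float]:
        return {p.position: p.fraction_identical for p in self.positions}


def conservation_at_positions(
    alignment: str | Path,
    reference_id: str,
    positions: Sequence[int],
) -> ConservationProfile:
    """Score conservation of reference positions in an aligned FASTA file.

    Each 1-based, ungapped position of the reference sequence is mapped to
    its alignment column; the score is the fraction of non-reference
    sequences whose residue at that column matches the reference residue
    (case-insensitive). Gap characters count as mismatches and are tallied.
    """
    aln = AlignIO.read(str(alignment), "fasta")
    ref = next((rec for rec in aln if rec.id == reference_id), None)
    if ref is None:
        raise KeyError(
            f"reference {reference_id!r} not in alignment "
            f"(ids: {', '.join(rec.id for rec in aln)})"
        )
    others = [rec for rec in aln if rec.id != reference_id]
    if not others:
        raise ValueError("alignment holds only the reference sequence")
    # map ungapped reference position -> alignment column
    col_of: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(str(ref.seq)):
        if ch not in "-.":
            pos += 1
            col_of[pos] = col
    ref_len = pos
    records = []
    for p in positions:
        if p < 1 or p > ref_len:
            raise IndexError(
                f"position {p} outside reference length {ref_len} (ungapped numbering)"
            )
        col = col_of[p]
        ref_res = str(ref.seq)[col].upper()
        gaps = sum(1 for rec in others if str(rec.seq)[col] in "-.")
        matches = sum(1 for rec in others if str(rec.seq)[col].upper() == ref_res)
        records.append(
            PositionConservation(
                position=p,
                column=col,
                reference_residue=ref_res,
                fraction_identical=matches / len(others),
                gap_count=gaps,
            )
        )
    return ConservationProfile(
        reference_id=reference_id,
        n_sequences=len(others),
        positions=tuple(records),
    )
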