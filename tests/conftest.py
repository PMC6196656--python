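"""Shared fixtures: tiny synthetic datasets and hand-written structure /
alignment files, all generated at test time."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from casrbias.dataset import ConcentrationResponseDataset, Scale
from casrbias.synthetic import PathwayParams, PhenotypeSpec, generate_dataset

WT_CA = PathwayParams(bottom=5.0, top=100.0, logec50=np.log10(3.0), hill_slope=2.0)
WT_PERK = PathwayParams(bottom=4.0, top=80.0, logec50=np.log10(3.0), hill_slope=2.0)


@pytest.fixture
def wt_spec() -> PhenotypeSpec:
    return PhenotypeSpec("WT", {"Ca": WT_CA, "pERK": WT_PERK}, noise_sd=4.0, n_replicates=6, seed=11)


@pytest.fixture
def noiseless_wt() -> ConcentrationResponseDataset:
    spec = PhenotypeSpec("WT", {"Ca": WT_CA, "pERK": WT_PERK}, noise_sd=0.0, n_replicates=2, seed=0)
    return generate_dataset(spec)


def make_dataset(rows, scale=Scale.RAW) -> ConcentrationResponseDataset:
    """rows: iterable of (genotype, pathway, conc, replicate, response)."""
    df = pd.DataFrame(rows, columns=["genotype", "pathway", "conc_mM", "replicate", "response"])
    return ConcentrationResponseDataset(df, scale=scale)


# ---------------------------------------------------------------------------
# structure fixtures
# ---------------------------------------------------------------------------

def format_pdb(atoms) -> str:
    """Render ATOM records. atoms: (chain, resnum, resname, name, element,
    x, y, z) or with trailing (occupancy, altloc)."""
    lines = []
    for i, atom in enumerate(atoms, start=1):
        chain, resnum, resname, name, element, x, y, z, *rest = atom
        occ = rest[0] if rest else 1.0
        altloc = rest[1] if len(rest) > 1 else " "
        pad_name = f" {name:<3s}" if len(name) < 4 else name
        lines.append(
            f"ATOM  {i:5d} {pad_name}{altloc}{resname:>3s} {chain}{resnum:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}          {element:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def three_atom_pdb(tmp_path: Path) -> Path:
    """Two-chain mini dimer: GLY A1 at the origin region, ALA B1 offset."""
    text = format_pdb(
        [
            ("A", 1, "GLY", "CA", "C", 0.0, 0.0, 0.0),
            ("A", 1, "GLY", "N", "N", -1.0, 0.0, 0.0),
            ("B", 1, "ALA", "CA", "C", 3.0, 4.0, 0.0),
        ]
    )
    path = tmp_path / "mini.pdb"
    path.write_text(text)
    return path


@pytest.fixture
def dimer_pdb(tmp_path: Path) -> Path:
    """Synthetic two-protomer fixture with side chains for distance modes."""
    text = format_pdb(
        [
            # chain A: ASN with backbone + side chain
            ("A", 178, "ASN", "N", "N", 0.0, 0.0, 0.0),
            ("A", 178, "ASN", "CA", "C", 1.5, 0.0, 0.0),
            ("A", 178, "ASN", "C", "C", 2.2, 1.3, 0.0),
            ("A", 178, "ASN", "O", "O", 1.6, 2.4, 0.0),
            ("A", 178, "ASN", "CB", "C", 2.0, -1.4, 0.0),
            ("A", 178, "ASN", "CG", "C", 3.5, -1.6, 0.0),
            ("A", 178, "ASN", "OD1", "O", 4.3, -0.7, 0.0),
            ("A", 178, "ASN", "ND2", "N", 3.9, -2.9, 0.0),
            # chain B: two target residues
            ("B", 48, "ASP", "CA", "C", 10.0, 0.0, 0.0),
            ("B", 48, "ASP", "OD1", "O", 8.0, -2.9, 0.0),
            ("B", 246, "TYR", "CA", "C", 0.0, 9.0, 0.0),
            ("B", 246, "TYR", "OH", "O", 0.0, 6.0, 0.0),
        ]
    )
    path = tmp_path / "dimer_synthetic.pdb"
    path.write_text(text)
    return path


def write_alignment(path: Path, records: dict[str, str]) -> Path:
    path.write_text("".join(f">{name}\n{seq}\n" for name, seq in records.items()))
    return path
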