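"""Shared fixtures: a BLOSUM62 matrix, a small fast synthetic domain set,
and a writer for toy PDB complexes used by the structure tests."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

import specmask as sk


@pytest.fixture(scope="session")
def blosum() -> sk.SubstitutionMatrix:
    return sk.SubstitutionMatrix.blosum62()


@pytest.fixture(scope="session")
def small_set():
    """4 families x 2 members, L=20, 2 planted columns — fast to evolve."""
    spec = sk.SyntheticSpec(
        n_families=4,
        kinases_per_family=2,
        L=20,
        planted_columns=[3, 11],
        n_peptide_positions=5,
        noise_sd=0.05,
        conserved_columns=[7],
        seed=11,
    )
    aln, profiles = sk.generate(spec)
    return spec, aln, profiles


def write_toy_pdb(path: Path, chains: dict[str, list[tuple[str, list[tuple[str, str, tuple[float, float, float]]]]]]) -> None:
    """Write a minimal PDB file.

    chains maps chain id -> list of residues; each residue is
    (three-letter resname, [(atom_name, element, (x, y, z)), ...]).
    """
    lines = []
    serial = 1
    for chain_id, residues in chains.items():
        for resseq, (resname, atoms) in enumerate(residues, start=1):
            for atom_name, element, (x, y, z) in atoms:
                lines.append(
                    f"ATOM  {serial:>5} {atom_name:<4}{resname:>4} {chain_id}"
                    f"{resseq:>4}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
                    f"          {element:>2}"
                )
                serial += 1
        lines.append("TER")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
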