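"""Minimum domain-residue-to-peptide distances from complex structures.

For each kinase-substrate (or domain-peptide) complex in PDB format, compute
per-domain-residue minimum atomic distances to the bound peptide chain, then
use the alignment to project residues onto alignment columns and take, per
column, the minimum over all structures.  This annotates each alignment
column with how close it can come to a substrate peptide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import is_aa
from Bio.SeqUtils import seq1
from scipy.spatial.distance import cdist

from .io import GAP, AlignedDomainSet, SpecMaskError

logger = logging.getLogger(__name__)

#: tolerated mismatch fraction between structure sequence and alignment record
MAX_MISMATCH_FRACTION = 0.05


@dataclass
class ComplexSpec:
    """One domain-peptide complex: a PDB file, its two chain ids and the
    alignment record id the domain chain corresponds to."""

    pdb_path: str | Path
    kinase_chain: str
    peptide_chain: str
    kinase_id: str


@dataclass
class StructureDistances:
    """Per-domain-residue minimum distances (Angstrom) plus the one-letter
    residue sequence, in ATOM-record order."""

    kinase_id: str
    sequence: str
    distances: np.ndarray


def _chain_residues(model, chain_id: str, what: str):
    if chain_id not in [c.id for c in model]:
        raise SpecMaskError(f"missing {what} chain '{chain_id}'")
    chain = model[chain_id]
    # standard amino acids only: waters, ligands, modified residues excluded
    return [res for res in chain if is_aa(res, standard=True)]


def _heavy_atom_coords(residue) -> np.ndarray:
    coords = [
        atom.coord
        for atom in residue.get_atoms()  # DisorderedAtom yields highest occupancy
        if (atom.element or "").upper() != "H"
    ]
    return np.asarray(coords, dtype=float)


def residue_min_distances(cx: ComplexSpec, all_atom: bool = True) -> StructureDistances:
    """Per-domain-residue minimum distance to any peptide-chain atom.

    First model only; hydrogens excluded; for disordered atoms the highest-
    occupancy alternate location is used.  With ``all_atom=False`` only the
    domain residues' C-alpha atoms are considered on the domain side.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("cx", str(cx.pdb_path))
    model = next(structure.get_models())
    kin = _chain_residues(model, cx.kinase_chain, "domain")
    pep = _chain_residues(model, cx.peptide_chain, "peptide")
    if not kin:
        raise SpecMaskError(f"no amino-acid residues on chain '{cx.kinase_chain}'")
    if not pep:
        raise SpecMaskError(f"no amino-acid residues on peptide chain '{cx.peptide_chain}'")
    pep_coords = np.vstack([_heavy_atom_coords(r) for r in pep])
    dists = []
    seq_letters = []
    for res in kin:
        if all_atom:
            coords = _heavy_atom_coords(res)
        else:
            coords = np.asarray([res["CA"].coord], dtype=float)
        dists.append(float(cdist(coords, pep_coords).min()))
        seq_letters.append(seq1(res.get_resname()))
    return StructureDistances(
        kinase_id=cx.kinase_id, sequence="".join(seq_letters), distances=np.array(dists)
    )


def map_to_columns(
    per_structure: list[tuple[ComplexSpec, StructureDistances]],
    aln: AlignedDomainSet,
) -> np.ndarray:
    """Per-alignment-column minimum substrate distance over all structures.

    Structure residue i corresponds to the i-th non-gap position of its
    alignment record (ungapped index correspondence).  A structure whose
    residue sequence mismatches its record by more than 5% is skipped with a
    warning; if every structure is skipped that is a hard error.  Columns
    with no mapped residue in any structure are NaN.
    """
    out = np.full(aln.L, np.nan)
    n_used = 0
    for cx, sd in per_structure:
        try:
            rec = aln.record(cx.kinase_id)
        except KeyError:
            logger.warning("structure '%s': id not in alignment; skipped", cx.kinase_id)
            continue
        cols = [p for p, ch in enumerate(rec.sequence) if ch != GAP]
        ungapped = "".join(rec.sequence[p] for p in cols)
        n = min(len(ungapped), len(sd.sequence))
        if n == 0:
            logger.warning("structure '%s': empty overlap; skipped", cx.kinase_id)
            continue
        mismatches = sum(1 for k in range(n) if ungapped[k] != sd.sequence[k])
        if mismatches / n > MAX_MISMATCH_FRACTION:
            logger.warning(
                "structure '%s': %.1f%% sequence mismatch vs alignment record; skipped",
                cx.kinase_id,
                100 * mismatches / n,
            )
            continue
        n_used += 1
        for k in range(n):
            p = cols[k]
            d = sd.distances[k]
            if np.isnan(out[p]) or d < out[p]:
                out[p] = d
    if n_used == 0:
        raise SpecMaskError("no structure could be mapped onto the alignment")
    return out
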