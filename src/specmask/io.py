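"""Domain data model and readers/writers.

Everything downstream is expressed in the coordinate system of a multiple
alignment of protein-domain sequences (:class:`AlignedDomainSet`).  Each
aligned record may carry an experimentally determined peptide-specificity
profile (:class:`SpecificityProfile`, a PSSM: peptide positions x 20 amino
acids).  A :class:`SpecificityMask` assigns every alignment column a score in
[0, 1] quantifying its contribution to substrate specificity.

Alignment columns are 0-based internally; every file written by this package
uses 1-based column numbers (the convention used when citing alignment
positions) and says so in its header.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, in the fixed order used by every matrix here.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
#: The only accepted gap symbol.  '.' and 'X' are rejected, not converted.
GAP: str = "-"
#: Full alphabet: amino acids plus gap.
ALPHABET: str = AMINO_ACIDS + GAP

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


class SpecMaskError(ValueError):
    """Raised on malformed or inconsistent input data."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DomainRecord:
    """One aligned domain sequence with its family/group annotation."""

    id: str
    family: str
    group: str
    sequence: str


@dataclass
class AlignedDomainSet:
    """A validated multiple alignment of domain sequences.

    Invariants (enforced on construction): all sequences share length ``L``,
    every non-gap character is a standard amino acid (upper-cased), record
    ids are unique and every record has a non-empty family label.
    """

    records: list[DomainRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise SpecMaskError("alignment has no records")
        L = len(self.records[0].sequence)
        if L < 1:
            raise SpecMaskError("alignment length must be >= 1")
        seen: set[str] = set()
        norm: list[DomainRecord] = []
        for rec in self.records:
            seq = rec.sequence.upper()
            if len(seq) != L:
                raise SpecMaskError(
                    f"ragged alignment: record '{rec.id}' has length "
                    f"{len(seq)}, expected {L}"
                )
            for col, ch in enumerate(seq):
                if ch not in ALPHABET:
                    raise SpecMaskError(
                        f"unknown residue character {ch!r} in record "
                        f"'{rec.id}' at column {col + 1} (1-based)"
                    )
            if rec.id in seen:
                raise SpecMaskError(f"duplicate record id '{rec.id}'")
            seen.add(rec.id)
            if not rec.family:
                raise SpecMaskError(f"record '{rec.id}' has an empty family label")
            norm.append(DomainRecord(rec.id, rec.family, rec.group, seq))
        self.records = norm

    @property
    def L(self) -> int:
        """Alignment length (number of columns)."""
        return len(self.records[0].sequence)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def record(self, rid: str) -> DomainRecord:
        for r in self.records:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def family_of(self, rid: str) -> str:
        return self.record(rid).family

    def encoded(self) -> np.ndarray:
        """Integer-encode the alignment: (n_records, L), amino acids 0..19,
        gap = 20.  Used by the vectorised similarity machinery."""
        n = len(self.records)
        out = np.empty((n, self.L), dtype=np.int8)
        lut = np.full(128, -1, dtype=np.int8)
        for ch, i in _AA_INDEX.items():
            lut[ord(ch)] = i
        lut[ord(GAP)] = 20
        for i, rec in enumerate(self.records):
            out[i] = lut[np.frombuffer(rec.sequence.encode("ascii"), dtype=np.uint8)]
        return out

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class SpecificityProfile:
    """One peptide-specificity PSSM for one domain.

    Rows are peptide positions (labels read verbatim from the source table,
    e.g. ``P-4`` .. ``P+4``); columns are the 20 amino acids.  Values are
    arbitrary finite preference scores, used as loaded (no renormalisation).
    """

    domain_id: str
    positions: list[str]
    aas: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not self.positions:
            raise SpecMaskError(f"profile '{self.domain_id}': no peptide positions")
        if len(set(self.positions)) != len(self.positions):
            raise SpecMaskError(
                f"profile '{self.domain_id}': duplicate position labels"
            )
        if list(self.aas) != list(AMINO_ACIDS) and sorted(self.aas) != sorted(
            AMINO_ACIDS
        ):
            raise SpecMaskError(
                f"profile '{self.domain_id}': amino-acid columns must be the "
                f"20 standard residues"
            )
        if self.values.shape != (len(self.positions), 20):
            raise SpecMaskError(
                f"profile '{self.domain_id}': values shape {self.values.shape} "
                f"does not match {len(self.positions)} positions x 20 residues"
            )
        if not np.all(np.isfinite(self.values)):
            raise SpecMaskError(f"profile '{self.domain_id}': non-finite entries")


@dataclass
class SpecificityMask:
    """Per-alignment-column contribution score in [0, 1]."""

    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1 or self.scores.size == 0:
            raise SpecMaskError("empty mask")
        if not np.all(np.isfinite(self.scores)):
            raise SpecMaskError("mask contains non-finite scores")
        if self.scores.min() < 0.0 or self.scores.max() > 1.0:
            bad = self.scores[(self.scores < 0) | (self.scores > 1)][0]
            raise SpecMaskError(f"mask score {bad!r} outside [0, 1]")

    def __len__(self) -> int:
        return self.scores.size


@dataclass
class SubstitutionMatrix:
    """A symmetric 20x20 residue substitution matrix (default BLOSUM62)."""

    scores: np.ndarray
    name: str = "BLOSUM62"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (20, 20):
            raise SpecMaskError("substitution matrix must be 20x20")
        if not np.allclose(self.scores, self.scores.T):
            raise SpecMaskError("substitution matrix must be symmetric")

    def score(self, a: str, b: str) -> float:
        try:
            return float(self.scores[_AA_INDEX[a], _AA_INDEX[b]])
        except KeyError as exc:
            raise SpecMaskError(f"unknown amino acid {exc.args[0]!r}") from None

    @property
    def min(self) -> float:
        return float(self.scores.min())

    @property
    def max(self) -> float:
        return float(self.scores.max())

    @classmethod
    def blosum62(cls) -> "SubstitutionMatrix":
        """BLOSUM62 restricted to the 20 standard residues."""
        m = substitution_matrices.load("BLOSUM62")
        scores = np.array(
            [[m[a, b] for b in AMINO_ACIDS] for a in AMINO_ACIDS], dtype=float
        )
        return cls(scores, name="BLOSUM62")

    @classmethod
    def from_ncbi_file(cls, path: str | Path, name: str | None = None) -> "SubstitutionMatrix":
        """Read a matrix in NCBI text format, restricted to the 20 residues."""
        m = substitution_matrices.read(str(path))
        missing = [a for a in AMINO_ACIDS if a not in m.alphabet]
        if missing:
            raise SpecMaskError(f"matrix lacks residues: {missing}")
        scores = np.array(
            [[m[a, b] for b in AMINO_ACIDS] for a in AMINO_ACIDS], dtype=float
        )
        return cls(scores, name=name or Path(path).stem)


@dataclass
class ColumnAnnotation:
    """Per-alignment-column metadata used in the downstream analyses."""

    column: int
    golden: bool = False
    conservation: float | None = None  # negative Shannon entropy, bits (<= 0)
    gap_fraction: float = 0.0
    min_substrate_distance: float | None = None  # Angstrom

    def __post_init__(self) -> None:
        if self.column < 0:
            raise SpecMaskError("column index must be >= 0")
        if not 0.0 <= self.gap_fraction <= 1.0:
            raise SpecMaskError("gap_fraction outside [0, 1]")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_alignment(path: str | Path, annotations: str | Path) -> AlignedDomainSet:
    """Read an aligned FASTA plus an id/family/group TSV annotation table.

    Record order follows the FASTA.  The id sets of the two files must match
    exactly; orphans on either side are a hard error.
    """
    seqs = list(SeqIO.parse(str(path), "fasta"))
    if not seqs:
        raise SpecMaskError(f"no FASTA records in {path}")
    ann = pd.read_csv(annotations, sep="\t", dtype=str).fillna("")
    for colname in ("id", "family", "group"):
        if colname not in ann.columns:
            raise SpecMaskError(f"annotation table lacks column '{colname}'")
    ann = ann.set_index("id")
    if ann.index.has_duplicates:
        dups = sorted(ann.index[ann.index.duplicated()])
        raise SpecMaskError(f"duplicate ids in annotation table: {dups}")
    fasta_ids = {s.id for s in seqs}
    tsv_ids = set(ann.index)
    orphans_fasta = sorted(fasta_ids - tsv_ids)
    orphans_tsv = sorted(tsv_ids - fasta_ids)
    if orphans_fasta or orphans_tsv:
        raise SpecMaskError(
            "id mismatch between alignment and annotations; "
            f"missing from TSV: {orphans_fasta}; missing from FASTA: {orphans_tsv}"
        )
    records = [
        DomainRecord(
            id=s.id,
            family=str(ann.loc[s.id, "family"]),
            group=str(ann.loc[s.id, "group"]),
            sequence=str(s.seq),
        )
        for s in seqs
    ]
    return AlignedDomainSet(records)


def write_alignment(aln: AlignedDomainSet, fasta: str | Path, annotations: str | Path) -> None:
    """Write aligned FASTA and the matching annotation TSV."""
    with open(fasta, "w") as fh:
        for rec in aln.records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")
    pd.DataFrame(
        {
            "id": [r.id for r in aln.records],
            "family": [r.family for r in aln.records],
            "group": [r.group for r in aln.records],
        }
    ).to_csv(annotations, sep="\t", index=False)


def read_profile(path: str | Path, domain_id: str | None = None) -> SpecificityProfile:
    """Read one PSSM TSV: rows = peptide positions, columns = 20 residues."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise SpecMaskError(f"non-numeric cell in profile {path}: {exc}") from None
    return SpecificityProfile(
        domain_id=domain_id or Path(path).stem,
        positions=[str(p) for p in df.index],
        aas=[str(a) for a in df.columns],
        values=values,
    )


def write_profile(profile: SpecificityProfile, path: str | Path) -> None:
    df = pd.DataFrame(profile.values, index=profile.positions, columns=profile.aas)
    df.to_csv(path, sep="\t")


def read_profiles(
    dir: str | Path, alignment: AlignedDomainSet
) -> dict[str, SpecificityProfile]:
    """Read every ``*.tsv`` PSSM in a directory, keyed by file stem.

    Coverage may be partial (most domain sets only have profiles for a
    minority of members), but every file stem must be an alignment record id
    and all profiles must share one position/residue layout.
    """
    dir = Path(dir)
    files = sorted(dir.glob("*.tsv"))
    if not files:
        logger.warning("no profile tables found in %s; prediction impossible", dir)
        return {}
    known = set(alignment.ids)
    profiles: dict[str, SpecificityProfile] = {}
    ref: SpecificityProfile | None = None
    for f in files:
        p = read_profile(f)
        if p.domain_id not in known:
            raise SpecMaskError(
                f"profile '{p.domain_id}' ({f}) has no matching alignment record"
            )
        if ref is None:
            ref = p
        else:
            if p.positions != ref.positions:
                raise SpecMaskError(
                    f"inconsistent positions: '{p.domain_id}' has "
                    f"{p.positions}, '{ref.domain_id}' has {ref.positions}"
                )
            if p.aas != ref.aas:
                raise SpecMaskError(
                    f"inconsistent residue columns in profile '{p.domain_id}'"
                )
        profiles[p.domain_id] = p
    return profiles


def write_profiles(profiles: Mapping[str, SpecificityProfile], dir: str | Path) -> None:
    dir = Path(dir)
    dir.mkdir(parents=True, exist_ok=True)
    for pid, prof in profiles.items():
        write_profile(prof, dir / f"{pid}.tsv")


def write_mask(mask: SpecificityMask, path: str | Path) -> None:
    """Write a mask as TSV of (1-based column, score), full float precision."""
    with open(path, "w") as fh:
        fh.write("# specificity mask; columns are 1-based\n")
        fh.write("column\tscore\n")
        for i, s in enumerate(mask.scores, start=1):
            fh.write(f"{i}\t{float(s)!r}\n")


def read_mask(path: str | Path) -> SpecificityMask:
    """Read a mask TSV; ``read(write(m)) == m`` bit-exactly."""
    scores: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("column"):
                continue
            _, val = line.split("\t")
            scores.append(float(val))
    if not scores:
        raise SpecMaskError(f"empty mask in {path}")
    return SpecificityMask(np.array(scores))


def write_column_annotations(
    annotations: Sequence[ColumnAnnotation], path: str | Path
) -> None:
    """Write per-column annotations as TSV (1-based column numbers)."""
    df = pd.DataFrame(
        {
            "column": [a.column + 1 for a in annotations],
            "golden": [int(a.golden) for a in annotations],
            "conservation": [a.conservation for a in annotations],
            "gap_fraction": [a.gap_fraction for a in annotations],
            "min_substrate_distance": [a.min_substrate_distance for a in annotations],
        }
    )
    with open(path, "w") as fh:
        fh.write("# per-column annotations; columns are 1-based\n")
        df.to_csv(fh, sep="\t", index=False)
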