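"""Synthetic domain sets with planted determinants of specificity.

The generator emulates the statistical structure the real pipeline consumes:
families of aligned sequences (family consensus plus per-member
substitutions) whose specificity profiles are a controlled function of a few
designated ("planted") alignment columns plus Gaussian noise.  Planted
column k deterministically drives peptide position k: the residue found
there selects, through a fixed residue-to-preference lookup, a unit one-hot
contribution to that row of the PSSM.  Decoy columns can be made
near-invariant kinome-wide without influencing any profile, so that high
conservation alone cannot explain a high evolved mask score.

Two control transforms mirror the standard negative controls: a uniform set
(every profile replaced by one constant matrix — no predictive challenge,
fitness pinned at zero) and a randomized set (profile-to-domain linkage
shuffled — sequence similarity becomes uninformative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .io import (
    AMINO_ACIDS,
    AlignedDomainSet,
    DomainRecord,
    SpecificityProfile,
    SpecMaskError,
)
from .evolution import DoSScoreVector

logger = logging.getLogger(__name__)

#: residue states allowed at planted columns: mutually dissimilar under
#: BLOSUM62, so donor matching at planted columns is crisp
PLANTED_STATES = ("W", "D", "R")

#: per-column substitution probability away from the family consensus
SUBSTITUTION_RATE = 0.1

#: probability that a conserved decoy column deviates from its global residue
DECOY_FLIP_RATE = 0.02


@dataclass
class SyntheticSpec:
    n_families: int = 8
    kinases_per_family: int = 4
    L: int = 60
    planted_columns: list[int] = field(default_factory=lambda: [10, 25, 40])
    n_peptide_positions: int = 9
    noise_sd: float = 0.05
    conserved_columns: list[int] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families * self.kinases_per_family < 4:
            raise SpecMaskError("need at least 4 sequences in total")
        for cols, name in (
            (self.planted_columns, "planted"),
            (self.conserved_columns, "conserved"),
        ):
            if any(c < 0 or c >= self.L for c in cols):
                raise SpecMaskError(f"{name} column outside [0, L)")
        if len(self.planted_columns) > self.n_peptide_positions:
            raise SpecMaskError(
                "more planted columns than peptide positions "
                "(one column drives one peptide position)"
            )
        if self.noise_sd < 0:
            raise SpecMaskError("noise_sd must be >= 0")


#: Standard test fixture: 8 families x 4 members, L=60, 3 planted columns,
#: 6 high-conservation decoys, 9 peptide positions, noise sd 0.05, seed 7.
FIX_A = SyntheticSpec(
    n_families=8,
    kinases_per_family=4,
    L=60,
    planted_columns=[10, 25, 40],
    n_peptide_positions=9,
    noise_sd=0.05,
    conserved_columns=[5, 15, 30, 45, 50, 55],
    seed=7,
)


def preference_vector(residue: str) -> np.ndarray:
    """Fixed lookup from a residue to a unit one-hot 20-dim preference.

    The preferred amino-acid index is (7 * residue_index + 3) mod 20; 7 is
    coprime with 20, so distinct residues map to distinct preferences.
    """
    try:
        i = AMINO_ACIDS.index(residue)
    except ValueError:
        raise SpecMaskError(f"unknown residue {residue!r}") from None
    v = np.zeros(20)
    v[(7 * i + 3) % 20] = 1.0
    return v


def _position_labels(n: int) -> list[str]:
    half = n // 2
    labels = []
    for off in range(-half, n - half):
        labels.append("P0" if off == 0 else f"P{off:+d}")
    return labels


def generate(spec: SyntheticSpec) -> tuple[AlignedDomainSet, dict[str, SpecificityProfile]]:
    """Generate an aligned domain set and matching specificity profiles.

    Fully deterministic given ``spec.seed``.  Sequences: per-family uniform
    consensus, per-member substitutions at rate 0.1; conserved decoy columns
    near-invariant across all families; planted columns i.i.d. per member
    over the three planted states.  Profiles: zeros plus the planted one-hot
    contributions plus N(0, noise_sd) on every entry.
    """
    rng = np.random.default_rng(spec.seed)
    aas = np.array(list(AMINO_ACIDS))
    planted = list(spec.planted_columns)
    conserved = [c for c in spec.conserved_columns if c not in planted]
    decoy_residue = {c: str(rng.choice(aas)) for c in conserved}
    labels = _position_labels(spec.n_peptide_positions)

    records: list[DomainRecord] = []
    profiles: dict[str, SpecificityProfile] = {}
    for f in range(spec.n_families):
        consensus = rng.choice(aas, size=spec.L)
        for k in range(spec.kinases_per_family):
            seq = consensus.copy()
            subs = rng.random(spec.L) < SUBSTITUTION_RATE
            seq[subs] = rng.choice(aas, size=int(subs.sum()))
            for c, r in decoy_residue.items():
                seq[c] = r if rng.random() >= DECOY_FLIP_RATE else str(rng.choice(aas))
            for c in planted:
                seq[c] = PLANTED_STATES[int(rng.integers(len(PLANTED_STATES)))]
            rid = f"F{f}_K{k}"
            records.append(
                DomainRecord(
                    id=rid, family=f"F{f}", group=f"G{f % 2}", sequence="".join(seq)
                )
            )
            values = np.zeros((spec.n_peptide_positions, 20))
            for pos, c in enumerate(planted):
                values[pos] += preference_vector(str(seq[c]))
            if spec.noise_sd > 0:
                values = values + rng.normal(0.0, spec.noise_sd, values.shape)
            profiles[rid] = SpecificityProfile(
                domain_id=rid,
                positions=list(labels),
                aas=list(AMINO_ACIDS),
                values=values,
            )
    return AlignedDomainSet(records), profiles


def make_uniform_control(
    profiles: dict[str, SpecificityProfile],
) -> dict[str, SpecificityProfile]:
    """Replace every profile by one shared constant matrix (uniform set)."""
    if not profiles:
        raise SpecMaskError("no profiles")
    any_p = next(iter(profiles.values()))
    const = float(np.mean([p.values.mean() for p in profiles.values()]))
    flat = np.full_like(any_p.values, const)
    return {
        pid: SpecificityProfile(
            domain_id=pid,
            positions=list(p.positions),
            aas=list(p.aas),
            values=flat.copy(),
        )
        for pid, p in profiles.items()
    }


def make_shuffled_control(
    profiles: dict[str, SpecificityProfile], seed: int
) -> dict[str, SpecificityProfile]:
    """Randomize the domain-to-profile linkage (randomized set).

    The multiset of matrices is preserved; for >= 2 profiles the identity
    permutation is redrawn so at least one domain changes its matrix.
    """
    ids = sorted(profiles)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    while len(ids) > 1 and np.array_equal(perm, np.arange(len(ids))):
        perm = rng.permutation(len(ids))
    out = {}
    for i, pid in enumerate(ids):
        src = profiles[ids[perm[i]]]
        out[pid] = SpecificityProfile(
            domain_id=pid,
            positions=list(src.positions),
            aas=list(src.aas),
            values=src.values.copy(),
        )
    return out


def planted_recovery(
    scores: DoSScoreVector | np.ndarray, spec: SyntheticSpec
) -> tuple[dict[int, float], float]:
    """How well do aggregated scores recover the planted columns?

    Returns per-planted-column ranks (descending scores, average-rank ties;
    rank 1 = highest score) and the fraction of planted columns ranked
    within the top k = 2 * |planted|.
    """
    arr = scores.scores if isinstance(scores, DoSScoreVector) else np.asarray(scores)
    if arr.size != spec.L:
        raise SpecMaskError("score vector length does not match spec.L")
    ranks = rankdata(-arr, method="average")
    k = 2 * len(spec.planted_columns)
    planted_ranks = {c: float(ranks[c]) for c in spec.planted_columns}
    hits = sum(1 for c in spec.planted_columns if ranks[c] <= k)
    return planted_ranks, hits / len(spec.planted_columns)
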