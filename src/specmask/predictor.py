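"""Mask-weighted similarity and leave-family-out PSSM prediction.

The prediction step: given a query domain, compare it to every other domain
that has an observed specificity profile, column by column, weighting each
column by the current specificity mask.  Per-column similarity is BLOSUM62
min-max rescaled to [0, 1] (gaps contribute ``gap_similarity``, default 0,
i.e. maximally dissimilar).  The mask-weighted similarity is

    w(i, j) = sum_p m_p * s(seq_i[p], seq_j[p]) / sum_p m_p

so high-mask columns are reinforced and zero-mask columns silenced; scaling
the whole mask by a positive constant changes nothing.  The query's PSSM is
then the donor-weighted mean

    P_hat(q) = sum_j w_j^alpha P_j / sum_j w_j^alpha

over eligible donors j (donors in the query's own family are excluded by
default, to avoid over-fitting).  The exponent alpha sharpens the weighting:
large alpha approaches nearest-neighbour prediction, alpha = 0 the plain
donor mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import (
    ALPHABET,
    AMINO_ACIDS,
    GAP,
    AlignedDomainSet,
    SpecificityMask,
    SpecificityProfile,
    SpecMaskError,
    SubstitutionMatrix,
)

logger = logging.getLogger(__name__)


@dataclass
class PredictionConfig:
    """Parameters of the PSSM prediction step.

    alpha : donor-weight sharpening exponent (>= 0).
    exclude_same_family : leave-family-out donor eligibility (default on).
    gap_similarity : per-column similarity assigned when either symbol is a
        gap, in [0, 1] (default 0).
    """

    alpha: float = 3.0
    exclude_same_family: bool = True
    gap_similarity: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha) or self.alpha < 0:
            raise SpecMaskError("alpha must be finite and >= 0")
        if not 0.0 <= self.gap_similarity <= 1.0:
            raise SpecMaskError("gap_similarity must lie in [0, 1]")


def positional_similarity(
    a: str, b: str, sm: SubstitutionMatrix, gap_similarity: float = 0.0
) -> float:
    """Similarity of two aligned symbols, rescaled to [0, 1].

    Non-gap pairs score ``(sm[a,b] - min(sm)) / (max(sm) - min(sm))`` with the
    extremes taken over the whole 20x20 matrix; any gap scores
    ``gap_similarity``.  Symmetric in its arguments.
    """
    if a not in ALPHABET or b not in ALPHABET:
        bad = a if a not in ALPHABET else b
        raise SpecMaskError(f"unknown symbol {bad!r}")
    if a == GAP or b == GAP:
        return float(gap_similarity)
    return (sm.score(a, b) - sm.min) / (sm.max - sm.min)


def similarity_table(sm: SubstitutionMatrix, gap_similarity: float = 0.0) -> np.ndarray:
    """21x21 lookup of rescaled similarities (index 20 = gap)."""
    t = np.empty((21, 21), dtype=float)
    t[:20, :20] = (sm.scores - sm.min) / (sm.max - sm.min)
    t[20, :] = gap_similarity
    t[:, 20] = gap_similarity
    return t


def mask_weighted_similarity(
    i: int,
    j: int,
    aln: AlignedDomainSet,
    mask: SpecificityMask,
    sm: SubstitutionMatrix,
    gap_similarity: float = 0.0,
) -> float:
    """Mask-weighted mean per-column similarity of records i and j.

    Returns 0.0 for an all-zero mask (every column silenced).
    """
    if len(mask) != aln.L:
        raise SpecMaskError(
            f"mask length {len(mask)} does not match alignment length {aln.L}"
        )
    m = mask.scores
    total = m.sum()
    if total == 0.0:
        return 0.0
    si = aln.records[i].sequence
    sj = aln.records[j].sequence
    sims = np.array(
        [positional_similarity(a, b, sm, gap_similarity) for a, b in zip(si, sj)]
    )
    return float(np.dot(m, sims) / total)


def frobenius_distance(A: np.ndarray, B: np.ndarray) -> float:
    """sqrt of the summed squared elementwise differences of two arrays."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise SpecMaskError(f"shape mismatch: {A.shape} vs {B.shape}")
    return float(np.sqrt(np.sum((A - B) ** 2)))


def eligible_donors(
    q: str,
    aln: AlignedDomainSet,
    profiles: dict[str, SpecificityProfile],
    exclude_same_family: bool = True,
) -> list[str]:
    """Donor ids for query q: profiled, not q, and (optionally) not q's family."""
    fam_q = aln.family_of(q)
    out = []
    for rec in aln.records:
        if rec.id == q or rec.id not in profiles:
            continue
        if exclude_same_family and rec.family == fam_q:
            continue
        out.append(rec.id)
    return out


def predict_profile(
    q: str,
    aln: AlignedDomainSet,
    profiles: dict[str, SpecificityProfile],
    mask: SpecificityMask,
    cfg: PredictionConfig,
    sm: SubstitutionMatrix,
) -> SpecificityProfile:
    """Predict the specificity profile of record q as a donor-weighted mean.

    If every donor weight is zero (e.g. an all-zero mask) the prediction
    falls back to the unweighted donor mean, so pathological masks still get
    a defined fitness downstream.
    """
    donors = eligible_donors(q, aln, profiles, cfg.exclude_same_family)
    if not donors:
        raise SpecMaskError(f"no donors for {q!r}")
    idx = {rid: k for k, rid in enumerate(aln.ids)}
    qi = idx[q]
    w = np.array(
        [
            mask_weighted_similarity(qi, idx[d], aln, mask, sm, cfg.gap_similarity)
            for d in donors
        ]
    )
    wa = w**cfg.alpha
    total = wa.sum()
    stack = np.stack([profiles[d].values for d in donors])
    if total == 0.0:
        pred = stack.mean(axis=0)
    else:
        pred = np.tensordot(wa / total, stack, axes=1)
    ref = profiles[donors[0]]
    return SpecificityProfile(
        domain_id=q, positions=list(ref.positions), aas=list(ref.aas), values=pred
    )


class PredictionContext:
    """Precomputed tensors for fast repeated fitness evaluation.

    Restricted to the profiled records: integer-encoded sequences, the
    (K, K, L) per-column similarity tensor, the donor-eligibility matrix and
    the (K, K, R*20) tensor of centered profile differences
    ``P_j - P_q``.  Queries that have no eligible donor at all are excluded
    once, with a warning.
    """

    def __init__(
        self,
        aln: AlignedDomainSet,
        profiles: dict[str, SpecificityProfile],
        cfg: PredictionConfig,
        sm: SubstitutionMatrix,
    ) -> None:
        prof_ids = [rid for rid in aln.ids if rid in profiles]
        if len(prof_ids) < 2:
            raise SpecMaskError("need >= 2 profiled records")
        fams = [aln.family_of(r) for r in prof_ids]
        if len(set(fams)) < 2:
            raise SpecMaskError("need profiled records from >= 2 families")
        self.cfg = cfg
        self.ids = prof_ids
        K = len(prof_ids)
        enc_all = aln.encoded()
        rows = [aln.ids.index(r) for r in prof_ids]
        enc = enc_all[rows]
        table = similarity_table(sm, cfg.gap_similarity)
        # S[i, j, p] = rescaled similarity of records i and j at column p
        self.S = table[enc[:, None, :], enc[None, :, :]]
        elig = np.ones((K, K), dtype=bool)
        np.fill_diagonal(elig, False)
        if cfg.exclude_same_family:
            fam = np.array(fams)
            elig &= fam[:, None] != fam[None, :]
        usable = elig.sum(axis=1) > 0
        for k in np.flatnonzero(~usable):
            logger.warning(
                "query '%s' has no eligible donors; skipped in fitness", prof_ids[k]
            )
        if not usable.any():
            raise SpecMaskError("no query has any eligible donor")
        self.eligible = elig
        self.usable = usable
        P = np.stack([profiles[r].values.ravel() for r in prof_ids])
        self.P = P
        # centered differences: exact zeros when donor and query profiles match
        self.Pdiff = P[None, :, :] - P[:, None, :]

    def distances(self, mask_scores: np.ndarray) -> np.ndarray:
        """Per-query Frobenius error of the leave-family-out prediction.

        Computed in centered form ``||sum_j a_j (P_j - P_q)||`` with
        normalised weights a, which is exactly 0.0 whenever all donor
        profiles equal the query's.  Entries for unusable queries are NaN.
        """
        total = mask_scores.sum()
        if total == 0.0:
            W = np.zeros_like(self.S[:, :, 0])
        else:
            W = self.S @ mask_scores / total
        A = np.where(self.eligible, W**self.cfg.alpha, 0.0)
        sums = A.sum(axis=1)
        degenerate = (sums == 0.0) & self.usable
        if degenerate.any():
            # all-zero weights: fall back to the unweighted donor mean
            A[degenerate] = self.eligible[degenerate].astype(float)
            sums = A.sum(axis=1)
        with np.errstate(invalid="ignore"):
            A = A / sums[:, None]
        resid = np.einsum("qj,qjf->qf", A, self.Pdiff)
        d = np.sqrt(np.sum(resid**2, axis=1))
        d[~self.usable] = np.nan
        return d
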