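"""Downstream analyses of evolved determinant-of-specificity (DoS) scores.

Covers: thresholded DoS calling; sequence-to-specificity Spearman
correlation restricted to residue subsets (do the called columns actually
encode specificity?); one-sided Fisher enrichment of a literature "golden
list"; per-column conservation (negative Shannon entropy) and gap fraction;
rank-sum comparison of conservation between residue sets; BLOSUM
pseudo-distance matrices and neighbor-joining dendrograms (whole-domain vs
DoS-only trees).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix
from skbio.tree import nj

from .io import (
    AMINO_ACIDS,
    GAP,
    AlignedDomainSet,
    SpecificityProfile,
    SpecMaskError,
    SubstitutionMatrix,
)
from .evolution import DoSScoreVector
from .predictor import frobenius_distance

logger = logging.getLogger(__name__)


@dataclass
class SubsetCorrelationReport:
    """Spearman correlation between subset-restricted sequence similarity and
    specificity similarity, over all pairs of profiled domains."""

    subset: list[int]
    n_columns: int
    fraction_of_alignment: float
    rho: float | None
    n_pairs: int


def call_dos(scores: DoSScoreVector | np.ndarray, threshold: float) -> list[int]:
    """Columns whose aggregated score strictly exceeds the threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise SpecMaskError("threshold must lie in [0, 1]")
    arr = scores.scores if isinstance(scores, DoSScoreVector) else np.asarray(scores)
    return [int(i) for i in np.flatnonzero(arr > threshold)]


def _pair_vectors(
    aln: AlignedDomainSet,
    profiles: dict[str, SpecificityProfile],
    subset: Sequence[int],
    sm: SubstitutionMatrix,
) -> tuple[np.ndarray, np.ndarray, int]:
    ids = [rid for rid in aln.ids if rid in profiles]
    K = len(ids)
    recs = {rid: aln.record(rid).sequence for rid in ids}
    xs, ys = [], []
    for a in range(K):
        for b in range(a + 1, K):
            sa, sb = recs[ids[a]], recs[ids[b]]
            x = 0.0
            for p in subset:
                ca, cb = sa[p], sb[p]
                x += sm.min if GAP in (ca, cb) else sm.score(ca, cb)
            y = -frobenius_distance(profiles[ids[a]].values, profiles[ids[b]].values)
            xs.append(x)
            ys.append(y)
    return np.array(xs), np.array(ys), K


def seq_spec_correlation(
    aln: AlignedDomainSet,
    profiles: dict[str, SpecificityProfile],
    subset: Sequence[int],
    sm: SubstitutionMatrix,
) -> SubsetCorrelationReport:
    """Does this column subset encode specificity?

    Per pair of profiled domains, x = summed BLOSUM score over the subset
    (gap pairs score the matrix minimum) and y = negative Frobenius distance
    between their observed profiles; the report's rho is the Spearman
    correlation of x with y (average-rank ties).  A constant x or y vector
    leaves rho undefined (None, with a warning).
    """
    subset = sorted(set(int(p) for p in subset))
    if not subset:
        raise SpecMaskError("subset must be non-empty")
    if subset[0] < 0 or subset[-1] >= aln.L:
        raise SpecMaskError("subset column outside alignment")
    n_prof = sum(1 for rid in aln.ids if rid in profiles)
    if n_prof < 3:
        raise SpecMaskError("need >= 3 profiled domains")
    x, y, K = _pair_vectors(aln, profiles, subset, sm)
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        logger.warning("constant similarity vector; Spearman rho undefined")
        rho = None
    else:
        rho = float(stats.spearmanr(x, y).statistic)
    return SubsetCorrelationReport(
        subset=list(subset),
        n_columns=len(subset),
        fraction_of_alignment=len(subset) / aln.L,
        rho=rho,
        n_pairs=K * (K - 1) // 2,
    )


def enrichment_test(
    called: Sequence[int], golden: Sequence[int], L: int
) -> tuple[float, float]:
    """One-sided (greater) Fisher exact test of golden-list enrichment.

    2x2 table over the L alignment columns: called-and-golden / called-only /
    golden-only / neither.  Returns (sample odds ratio, one-sided p via the
    hypergeometric tail).
    """
    called_s, golden_s = set(map(int, called)), set(map(int, golden))
    union = called_s | golden_s
    if union and (min(union) < 0 or max(union) >= L):
        raise SpecMaskError("column index outside [0, L)")
    if L < len(union):
        raise SpecMaskError("L smaller than |called U golden|")
    a = len(called_s & golden_s)
    b = len(called_s - golden_s)
    c = len(golden_s - called_s)
    d = L - a - b - c
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(odds), float(p)


def column_conservation(aln: AlignedDomainSet) -> pd.DataFrame:
    """Per-column conservation (negative Shannon entropy, bits, over non-gap
    residues) and gap fraction.  All-gap columns get NaN conservation."""
    enc = aln.encoded()
    n = len(aln)
    cons = np.full(aln.L, np.nan)
    gapf = np.zeros(aln.L)
    for p in range(aln.L):
        col = enc[:, p]
        gaps = int((col == 20).sum())
        gapf[p] = gaps / n
        if gaps == n:
            continue
        counts = np.bincount(col[col < 20], minlength=20)
        f = counts[counts > 0] / (n - gaps)
        cons[p] = float(np.sum(f * np.log2(f)))  # -entropy
    return pd.DataFrame({"conservation": cons, "gap_fraction": gapf})


def compare_conservation(
    set_a: Sequence[float], set_b: Sequence[float]
) -> tuple[float, float]:
    """Wilcoxon rank-sum comparison of two conservation-value sets.

    Exact null for combined n <= 20, normal approximation with continuity
    correction above.  Returns (median(a) - median(b), two-sided p).
    NaN values are dropped first; an empty set is a hard error.
    """
    a = np.asarray(set_a, dtype=float)
    b = np.asarray(set_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise SpecMaskError("empty set after dropping missing values")
    method = "exact" if a.size + b.size <= 20 else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(np.median(a) - np.median(b)), float(res.pvalue)


def blosum_distance_matrix(
    aln: AlignedDomainSet,
    subset: Sequence[int],
    sm: SubstitutionMatrix,
    ids: Sequence[str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Pairwise BLOSUM pseudo-distance restricted to a column subset.

    d(i, j) = sum over subset columns of (max(sm) - score), with gap pairs
    scored at the matrix minimum.  Symmetric with zero diagonal; the
    triangle inequality is NOT guaranteed (substitution scores are
    log-odds, not metric distances).
    """
    subset = sorted(set(int(p) for p in subset))
    if not subset:
        raise SpecMaskError("subset must be non-empty")
    if subset[0] < 0 or subset[-1] >= aln.L:
        raise SpecMaskError("subset column outside alignment")
    use_ids = list(ids) if ids is not None else aln.ids
    seqs = [aln.record(r).sequence for r in use_ids]
    K = len(use_ids)
    dist = np.zeros((K, K))
    for i in range(K):
        for j in range(i + 1, K):
            d = 0.0
            for p in subset:
                ca, cb = seqs[i][p], seqs[j][p]
                s = sm.min if GAP in (ca, cb) else sm.score(ca, cb)
                d += sm.max - s
            dist[i, j] = dist[j, i] = d
    return dist, use_ids


def build_dendrogram(dist: np.ndarray, labels: Sequence[str]) -> str:
    """Neighbor-joining tree (Saitou-Nei) from a distance matrix, as Newick.

    Negative branch lengths (possible on non-additive input) are clamped to
    zero with a logged warning.
    """
    dist = np.asarray(dist, dtype=float)
    K = dist.shape[0]
    if K < 3:
        raise SpecMaskError("need >= 3 taxa for a dendrogram")
    if dist.shape != (K, K) or len(labels) != K:
        raise SpecMaskError("distance matrix / labels shape mismatch")
    if not np.allclose(dist, dist.T) or np.any(np.diag(dist) != 0) or dist.min() < 0:
        raise SpecMaskError(
            "distance matrix must be symmetric, non-negative, zero-diagonal"
        )
    dm = DistanceMatrix(dist, list(labels))
    tree = nj(dm, neg_as_zero=False)
    n_clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            n_clamped += 1
    if n_clamped:
        logger.warning("clamped %d negative branch lengths to 0", n_clamped)
    return str(tree).strip()
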