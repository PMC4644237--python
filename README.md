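# specmask

Which residues of a protein domain encode its peptide substrate specificity?
For kinase (or SH2) domains, experimentally determined specificity profiles —
position-specific scoring matrices (PSSMs) giving the preference of a domain
for each amino acid at each substrate peptide position — exist for a minority
of domains, and whole-domain sequence similarity correlates poorly with
specificity similarity. `specmask` is a tool for scientists studying
domain–peptide recognition: it searches for the *determinants of specificity*
(DoS), the sparse set of alignment columns that actually carry the
specificity signal.

## The method

The central object is a **specificity mask** `m ∈ [0, 1]^L` over the `L`
columns of a domain alignment. Under a mask, the similarity of two domains is
the mask-weighted mean of per-column similarities (BLOSUM62, min–max rescaled
to [0, 1]; gaps score 0):

    w(i, j) = Σ_p m_p · s(x_ip, x_jp) / Σ_p m_p

and the PSSM of a query domain `q` is predicted from the domains with
observed profiles — excluding the query's own family, to avoid over-fitting —
as the sharpened weighted mean

    P̂_q = Σ_j w(q, j)^α P_j / Σ_j w(q, j)^α .

A mask's **fitness** is the median Frobenius distance between predicted and
observed PSSMs over all profiled domains (lower is better). A genetic
algorithm (a learning classifier system) evolves a population of masks —
elite survival, single-point cross-over, per-position mutation — until the
fitness cannot be improved further. Columns that consistently score high in
the converged masks of independent runs are the candidate DoS.

Downstream analyses: thresholded DoS calling; Spearman correlation between
subset-restricted sequence similarity and specificity similarity (do the
called columns really encode specificity?); one-sided Fisher enrichment
against a literature "golden list"; per-column conservation (negative Shannon
entropy) and rank-sum set comparisons; neighbor-joining dendrograms from
whole-domain vs DoS-only BLOSUM distances; and mapping of minimum
domain-to-peptide atomic distances from complex structures onto alignment
columns.

A fully seeded synthetic generator produces family-structured alignments
whose PSSMs are controlled functions of designated ("planted") columns plus
noise, together with the two standard negative controls (uniform profiles;
shuffled domain-to-profile linkage), so the entire pipeline is testable
without any external data.

## Worked example

Evolve masks on the bundled synthetic fixture (8 families × 4 domains,
L = 60, 3 planted columns) and analyse the result:

```python
import numpy as np
import specmask as sk

aln, profiles = sk.generate(sk.FIX_A)
cfg = sk.EvolutionConfig(population_size=40, max_generations=300,
                         convergence_window=300, alpha=3.0, seed=1, n_runs=3)
runs = sk.evolve_replicates(aln, profiles, cfg)
vec, dissim = sk.aggregate_runs(runs)
print(f"best fitness: {runs[0].best_fitness_trajectory[0]:.3f} -> "
      f"{runs[0].best_fitness_trajectory[-1]:.3f}")
called = sk.call_dos(vec, threshold=0.8)
print("called DoS columns (1-based):", [c + 1 for c in called])
ranks, hit = sk.planted_recovery(vec, sk.FIX_A)
print("planted column ranks:", ranks, "top-6 hit fraction:", hit)
sm = sk.SubstitutionMatrix.blosum62()
rho_dos = sk.seq_spec_correlation(aln, profiles, called, sm).rho
rho_all = sk.seq_spec_correlation(aln, profiles, range(aln.L), sm).rho
print(f"Spearman rho: DoS columns {rho_dos:.2f} vs whole domain {rho_all:.2f}")
odds, p = sk.enrichment_test(called, sk.FIX_A.planted_columns, aln.L)
print(f"golden-list enrichment: one-sided p = {p:.2e}")
```

prints

```
best fitness: 1.513 -> 1.176
called DoS columns (1-based): [11, 26, 41]
planted column ranks: {10: 1.0, 25: 3.0, 40: 2.0} top-6 hit fraction: 1.0
Spearman rho: DoS columns 0.86 vs whole domain 0.24
golden-list enrichment: one-sided p = 2.92e-05
```

The evolved masks single out exactly the three planted columns (1-based 11,
26, 41): prediction error drops as the population evolves, the called columns
carry a far stronger sequence-to-specificity correlation than the whole
domain, and the call set is significantly enriched for the true determinants.

The same pipeline is available from a shell:

```sh
specmask simulate --out data/
specmask evolve --alignment data/alignment.fasta --annotations data/annotations.tsv \
    --profiles data/profiles --alpha 3 --seed 1 --out run/
specmask analyze --alignment data/alignment.fasta --annotations data/annotations.tsv \
    --profiles data/profiles --scores run/dos_scores.tsv --threshold 0.8 --out analysis/
specmask tree --alignment data/alignment.fasta --annotations data/annotations.tsv \
    --out kinome.nwk
```

Every output directory contains a `manifest.json` (config snapshot, input
digests, seeds, version) and reruns with identical inputs are byte-identical.

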