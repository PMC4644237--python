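# Methods

## Model and procedure

`specmask` treats the question "which alignment columns encode peptide
specificity?" as a feature-weighting problem. A specificity mask assigns each
of the `L` alignment columns a weight in [0, 1]; the mask defines a weighted
sequence similarity, the similarity defines a leave-family-out prediction of
every observed specificity profile (PSSM), and the quality of those
predictions scores the mask. A genetic algorithm then searches mask space.

**Per-column similarity.** `s(a, b) = (B(a, b) − min B) / (max B − min B)`
with `B` = BLOSUM62 restricted to the 20 standard residues (min −4, max 11,
attained by W/W, so identical tryptophans score exactly 1). Columns where
either sequence has a gap score `gap_similarity` (default 0): a gapped column
counts as maximally dissimilar rather than being skipped, so alignments with
heavy gaps cannot inflate similarity. This functional form is a design choice
of this package: any bounded, monotone transform of the substitution score
would serve; min–max rescaling is the simplest one that makes the mask
combination scale-free.

**Mask-weighted similarity** is the mask-weighted *mean* of per-column
similarities, `w(i,j) = Σ m_p s_p / Σ m_p`. The ratio form makes the
similarity invariant to scaling the whole mask by a positive constant, which
is tested as a property; an all-zero mask silences everything (`w = 0`).

**Prediction.** For query `q`, donors are all profiled domains except `q`
itself and (by default) its own family — leave-family-out, so that trivially
similar close relatives cannot carry the prediction. The predicted PSSM is
`Σ w_j^α P_j / Σ w_j^α`. The exponent α trades breadth against sharpness:
α = 0 is the plain donor mean, large α approaches nearest-neighbour
prediction. α is chosen by scanning candidate values with short evolution
budgets (`select_alpha`); the package default is α = 3, which suits data
sets where several families carry partial signal. If every donor weight is
exactly zero the prediction falls back to the unweighted donor mean, keeping
fitness defined for degenerate masks.

**Fitness** is the *median* over profiled domains of the Frobenius distance
between predicted and observed PSSM (lower = fitter); the median makes the
score robust to a few unpredictable domains. Internally the residual is
computed in the centered form `‖Σ_j a_j (P_j − P_q)‖` with normalised
weights `a`, which is algebraically identical to `‖P̂_q − P_q‖` but is
*exactly* 0.0 in floating point when all donor profiles equal the query's —
the uniform negative control therefore sits at fitness 0.0 bit-exactly, not
merely near it. Queries with no eligible donor are excluded once, with a
warning; if none remain that is a hard error.

**Evolution.** Population of `population_size` masks initialised i.i.d.
uniform [0, 1]. Each generation the `⌈elite_fraction · n⌉` fittest masks
survive unchanged (ties broken by earlier population index — stable,
bit-reproducible); of the remaining slots a `crossover_rate` share is filled
by single-point cross-over of two distinct elite parents and the rest by
elite copies whose positions mutate independently with probability
`mutation_rate` (resampled uniform [0, 1]). Elitism makes the best-fitness
trajectory non-increasing by construction. Convergence is operationalised as
`convergence_window` generations without best-fitness improvement > 1e-9.
Fitness values are memoized per run keyed on the mask's byte representation
(an efficiency contract only). A run is a pure function of (inputs, config,
seed); replicate runs use seeds `seed, seed+1, …`.

**Aggregation.** Per-column DoS scores are the mean of the replicate runs'
final best masks. Run-to-run agreement is tracked as the per-generation mean
pairwise Frobenius distance between the runs' best masks (runs of unequal
length are compared up to the shortest); on converging runs this
dissimilarity falls as generations pass. `EvolutionResult` therefore stores
the best mask of every generation, not only the final one.

### Defaults and their rationale

| parameter | default | why |
|---|---|---|
| `population_size` | 100 | standard population scale for this class of search |
| `max_generations` | 2500 | generation budget at which kinome-scale runs converge |
| `n_runs` | 10 | replicate deployments for aggregation/robustness |
| `elite_fraction` | 0.2 | common GA elitism share; guarantees monotone best fitness |
| `mutation_rate` | 0.02 | per-position; ~1 mutation per mask at L ≈ 50–100 |
| `crossover_rate` | 0.5 | balanced subtle (mutation) vs abrupt (cross-over) moves |
| `convergence_window` | 250 | 10% of the budget without improvement ≈ converged |
| `alpha` | 3 | package default; scan with `select_alpha` per data set |
| `gap_similarity` | 0 | gaps are maximally dissimilar; configurable |

At the default kinome-scale configuration the search examines
`100 × 2500 = 250,000` candidate masks per deployment and 2,500,000 over ten
deployments (`models_explored`).

## Downstream analyses

- **DoS calling** (`call_dos`): columns strictly above a threshold
  (typical working points 0.8–0.9); monotone in the threshold.
- **Correlation validation** (`seq_spec_correlation`): per domain pair,
  x = summed BLOSUM62 score over the column subset (gap pairs score the
  matrix minimum), y = negative Frobenius distance of the observed PSSMs;
  Spearman rho with average-rank ties (scipy). A subset that truly encodes
  specificity raises rho relative to the whole domain.
- **Enrichment** (`enrichment_test`): one-sided (greater) Fisher exact test
  of called vs golden-list columns on the 2×2 table over L columns; p from
  the hypergeometric tail (scipy), odds ratio is the sample odds ratio.
- **Conservation** (`column_conservation`): per column, negative Shannon
  entropy (bits) of the residue frequencies among non-gap symbols, plus the
  gap fraction. This is the plain unweighted entropy measure of standard
  conservation tools; sequence weighting is deliberately not applied.
  Gaps are not counted as a 21st symbol; all-gap columns are missing.
- **Set comparison** (`compare_conservation`): two-sided Wilcoxon rank-sum
  with average-rank ties; exact null for combined n ≤ 20, normal
  approximation with continuity correction above (scipy).
- **Dendrograms** (`blosum_distance_matrix` + `build_dendrogram`):
  d(i,j) = Σ_p (max B − B(x_ip, x_jp)) over the chosen columns (gap pairs at
  the matrix minimum) — a non-negative symmetric *pseudo*-distance that may
  violate the triangle inequality, which neighbor joining tolerates. NJ is
  Saitou–Nei via scikit-bio; negative branch lengths are clamped to 0 with a
  logged warning. Whole-domain and DoS-only trees use the same transform,
  differing only in the column subset.
- **Structure mapping** (`residue_min_distances` + `map_to_columns`):
  all-atom (optionally C-alpha) minimum Euclidean distance from each domain
  residue to any peptide-chain atom; first model only, hydrogens excluded,
  highest-occupancy altloc, standard amino acids only (waters/ligands
  ignored). Residue i of the structure maps to the i-th non-gap column of
  the domain's alignment record; a structure mismatching its record by more
  than 5% is skipped with a warning. Per column, the minimum over
  structures is reported; adding a structure can only lower it.

## The synthetic generator

`generate(SyntheticSpec)` emulates exactly the statistical structure the
method needs: family-structured sequences whose profiles depend on a few
known columns.

- Sequences: one uniform consensus per family; each member substitutes each
  column with probability 0.1. Family structure matters because
  leave-family-out prediction must find its signal *across* families.
- Planted columns: each member draws i.i.d. from the three-state alphabet
  {W, D, R}. These residues are mutually dissimilar under BLOSUM62
  (rescaled match similarities 0.6–1.0 vs mismatches ≤ 0.13), so donor
  matching at planted columns is crisp, and with three states a query
  expects about one exact-triple-match donor at the standard fixture size —
  enough signal to optimise, not so much that the task is trivial.
- Profiles: zeros, plus, for planted column k, a unit one-hot preference at
  peptide position k selected by the residue through a fixed bijective
  lookup (index `(7·aa + 3) mod 20`), plus i.i.d. Gaussian noise
  (`noise_sd`) on every entry. One planted column drives exactly one
  peptide position — clean identifiability at desk scale; multi-column
  interactions are out of scope of the generator.
- Conservation decoys: designated columns held (near-)invariant kinome-wide
  (flip probability 0.02) with *no* influence on profiles, so a method that
  merely rewards conservation is caught.
- Controls: `make_uniform_control` (all profiles one constant matrix — no
  predictive challenge, fitness exactly 0) and `make_shuffled_control`
  (domain↔profile linkage permuted, multiset preserved, identity
  permutation redrawn).

The standard fixture `FIX_A` (8 families × 4 members, L = 60, planted
columns 10/25/40, decoys 5/15/30/45/50/55, 9 peptide positions, noise 0.05,
seed 7) is evolved in tests and in the acceptance script with population 40,
300 generations, α = 3 and 3 replicate runs — problem sizes chosen so the
full pipeline runs in seconds while leaving the planted signal clearly
recoverable.

**What the generator does not emulate:** real kinome phylogeny, realistic
PSSM value distributions and scales, inter-position dependencies within the
peptide, correlated (co-evolving) determinant columns, and alignment errors.
Passing tests therefore demonstrate that the machinery recovers planted
determinants under its own model assumptions, not that any particular
biological determinant set is correct.

## Numerical choices and edge cases

- Ties everywhere randomness is not explicitly invoked are broken by stable
  index order, so runs are bit-reproducible; all RNG flows from
  `numpy.random.default_rng(seed)`.
- Profiles are used exactly as loaded; no renormalisation on input (profile
  scale conventions differ between collections, and silently rescaling would
  corrupt them). PSSM position labels are read verbatim and never
  reinterpreted.
- Only `-` is accepted as a gap; `.` and `X` are rejected outright
  (fail-fast beats silent conversion).
- Columns are 0-based in the API and 1-based in every file output, stated in
  each file header.
- Spearman rho is reported as missing (with a warning) when either pair
  vector is constant.
- An empty profile directory yields an empty map plus a warning; downstream
  prediction then raises.

## Known limitations

- The mask couples all peptide positions through one similarity: it cannot
  attribute different determinants to different peptide positions within a
  single prediction (the synthetic recovery works because planted columns
  jointly raise donor weight).
- Profile coverage is typically partial; families without any profiled
  member can be predicted but never validated.
- The BLOSUM pseudo-distance is not metric; NJ trees built from it are
  descriptive dendrograms, not maximum-likelihood phylogenies.
- GA hyperparameters other than population size and generation budget are
  conventional defaults, exposed in `EvolutionConfig` for data sets where
  they matter.
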