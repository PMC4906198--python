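# Methods

## Model

HLA-DR binding specificity is modelled positionally: a 9-residue binding
core sits in a groove of nine pockets, and the binding strength of a
candidate core is the sum of independent per-pocket contributions read from
20-value pocket profiles (a PSSM). Only the anchor pockets 1, 4, 6, 7 and 9
contribute; pockets 2, 3, 5 and 8 are treated as non-selective and score
zero, following the TEPITOPE convention. Pocket 1 is conserved across HLA-DR
alleles and carries one shared profile; pockets 4, 6, 7 and 9 vary between
alleles and are the ones synthesized.

The model's central assumption is that alleles with similar pocket
pseudosequences (and, where known, similar pocket geometry) have similar
pocket profiles, so an uncharacterized allele's profile can be borrowed as a
convex combination of characterized ones, weighted by similarity rank.

## Similarity channels

The two channels are deliberately mapped onto a common (0, 1] scale:

* **Sequence.** A pocket pseudosequence of length n becomes a 20n-vector of
  concatenated substitution-matrix rows (bundled BLOSUM62 by default; any
  NCBI-format matrix can be supplied). Similarity is
  `exp(−d²/2b²)` of the Euclidean distance d between encodings. The plain
  positionwise substitution score `Σ_j M[a_j, b_j]` is also available
  (`raw_alignment_score`) as an alternative sequence channel for rank-only
  uses; it is unbounded and therefore not mixed with the structural channel.
* **Structure.** Minimal RMSD over proper rigid motions (Kabsch
  superposition, determinant +1; reflections are forbidden, matching
  standard structural-biology practice), again through `exp(−RMSD²/2b²)`.
  One representative atom per pocket residue: Cα by default, heavy-atom
  centroid as an option.

Both channels are *similarities* so that the three combination rules —
quadratic mean (`rms`, the default), arithmetic mean (`mean`) and `sum` —
operate on commensurate inputs. Downstream weighting uses only the ranking,
which makes `mean` and `sum` provably interchangeable (one is a strictly
monotone transform of the other); the property is asserted by tests rather
than assumed.

Structural data is an optional channel: registry entries without coordinates
(or a query without a structure) fall back to the sequence channel alone,
flagged per entry. This mirrors the practical situation where only a few
alleles have solved complex structures.

### Bandwidths

Each RBF bandwidth defaults to the median pairwise distance among the
registry entries of that pocket and channel (falling back to 1.0 for
registries of fewer than two entries or zero median). The default is
scale-free — it adapts to the spread of the registry — and deterministic
given the registry. Both bandwidths can be overridden.

## Rank weighting and synthesis

Entries sorted by descending combined similarity (stable sort; ties keep
registry order, for determinism) receive weights from the discretized gamma
density evaluated at the ranks i = 1…m,

    G(i) = i^(k−1) e^(−i/θ) / (θ^k Γ(k)),
    ω_i  = G(i)^α / Σ_j G(j)^α.

The Γ(k) and θ^k constants cancel under normalization but are kept for
fidelity to the density. Weights are computed in log space
(`softmax(α · log G)`), so large α cannot underflow. Defaults:

| parameter | default | meaning |
|-----------|---------|---------|
| k (shape) | 1 | with k = 1, G is strictly decreasing over ranks, so more similar entries always get larger weights |
| θ (scale) | 1 | rank-decay length; θ → m with tiny α approaches a plain average |
| α (exponent) | 3 | sharpening; concentrates weight on the top ranks (ω₁ ≈ 0.95 at α = 3, k = θ = 1) |
| mode | rms | channel combination rule |

The synthesized profile `Σ ω_i p_(i)` is a convex combination, so every
synthesized score lies within the range of the corresponding raw scores.
There is no exact-match shortcut: a query identical to a registry entry goes
through the same weighting, and the large-α limit recovers that entry's
profile to numerical precision — one code path, verified by the
concentration tests.

## Core prediction

All `len − 8` contiguous 9-mer windows are scored; the argmax is the
predicted core with leftmost tie-break (deterministic, recorded in the
prediction). Correctness against an annotated core is exact 9-mer string
equality — identical 9-mers at different offsets are indistinguishable in
the benchmark tables, so offsets are not compared. `X` residues (present in
the benchmark peptides, e.g. `XFVKQNAAALX`) score zero at their position
rather than being rejected. Pocket 1 is scored with the shared profile by
default; a flag restricts scoring to pockets {4, 6, 7, 9} since published
descriptions are ambiguous about whether pocket 1 enters the score or is
merely conserved.

Evaluation never crashes on an unresolvable allele: it emits a per-record
error row, counted as an error. The α-sweep runs one evaluation per
(mode, α) cell with everything else fixed and emits a long-format table.

## Synthetic data

The generators emulate the *structure* of the real problem, not its content:

* **Registries** draw m unique random pseudosequences and uniform [−2, 2]
  profiles (TEPITOPE profiles are signed and roughly this magnitude). Entry
  coordinates are one fixed template plus a shared perturbation direction
  scaled by i·noise, so the structural-similarity ordering is known by
  construction and re-verified at generation.
* **Planted-core peptides** place each pocket's best residue at the
  designated window (boosted residues are made distinct across pockets, and
  filler residues avoid them, which makes the designated window's margin at
  least `5·contrast − 20` analytically); the guarantee — margin ≥ contrast —
  is additionally verified exhaustively before the peptide is returned. The
  default contrast 6.0 makes the guarantee hold deterministically.
* **The decoy scenario** gives every non-top registry entry a profile that
  shares the true profile's base scores but boosts a different window more
  strongly. All window margins under the synthesized profile are then affine
  and increasing in the top-rank weight ω₁, and ω₁ is increasing in α, so
  per-record correctness is *provably* monotone in α — the sweep-monotonicity
  test asserts a theorem of the construction, not a tendency.
* **Noise-degradation rates** perturb the scoring profiles with one Gaussian
  draw per instance scaled by the noise level; margins are affine in the
  level, so each instance's correct region is an interval containing zero
  and recovery is nonincreasing in noise by construction.

What passing these tests shows: the pipeline's algebra (encoding, ranking,
weighting, convexity, argmax selection) is correct, deterministic and
self-consistent end to end. What it does not show: predictive accuracy on
real alleles, which depends on the quantitative profile registries. The
published reference-allele matrices are not redistributable and are not
bundled; the packaged registry skeleton lists the eleven reference alleles
so that users holding TEPITOPE-style matrices can drop them in via the TSV
interface. The benchmark accuracy numbers shipped with the dataset are
therefore static reference columns (recomputed only as error *counts* from
those columns), not outputs of this implementation.

## Numerical choices

* Superposition uses the closed-form SVD solution with determinant +1;
  RMSD is computed from explicit residuals after applying the optimal
  rotation, because the `Σ|a|² + Σ|b|² − 2Σσ` form loses half the digits
  near zero. Point sets with fewer than 3 points or with collinear geometry
  (second singular value ≤ 1e−9 of the first) are rejected: the optimal
  rotation is not unique there.
* The brute-force oracle used in tests is an Euler-angle grid search
  (15° global scan, ten best cells refined to 0.024°); several coarse cells
  are refined because distinct rotation basins can compete.
* Weight vectors must sum to 1 within 1e−12 (enforced at construction).
* PDB reading: first altloc in file order for disordered atoms; residues
  with insertion codes are rejected (the benchmark pockets carry none);
  non-standard residues become `X` in pseudosequences, and `X` is rejected
  at encoding time with a clear error.

## Problem sizes

Synthetic experiments default to registries of m = 5 entries with
pseudosequences of length n = 6 and peptides of length 15; the planted-core
recovery experiment uses 50 seeded instances and the noise probe 3 levels ×
50 instances. These sizes exercise every code path while keeping the full
suite and the acceptance script in the seconds range.

## Known limitations

* No mmCIF input, no α-chain pockets, no automatic chain identification.
* Pseudosequences are position-aligned by construction; there is no
  alignment search and no flexible or partial superposition.
* No binding-affinity (IC50) regression and no ROC/AUC machinery: the
  package predicts and evaluates discrete binding cores only.
* Which BLOSUM variant the original method used is not documented; BLOSUM62
  is the default here and any NCBI-format matrix can be substituted.
* The benchmark transcription inherits two known inconsistencies of its
  source (five PDB↔peptide pairings differ between the summary and benchmark
  listings; one pocket-composition cell needed normalisation); both are
  documented in the data-file headers.
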