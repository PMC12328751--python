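# Methods

This note documents the models, conventions and numerical choices behind
`crefkit`, and what the synthetic worlds do and do not establish.

## CREF matrices

The proximal regulatory region of a protein-coding gene is the window
−1000..+499 relative to the TSS (1500 bp, TSS at relative position 0), in
transcript orientation. The stated span "−1000 to +500" is ambiguous about
endpoint inclusivity; we fix the round 1500-bp convention and expose both
offsets as module constants. The TSS of a multi-transcript gene is the
start of its most upstream (5′) transcript: minimum transcript start on
the + strand, maximum transcript end on the − strand. Windows are clipped
to the chromosome and never padded; genes whose window truncates below a
minimum length (default 50 bp) are kept with the truncated window
(dropping is a flag). Internal coordinates are 0-based half-open; GFF3 is
read 1-based inclusive, and all reported intervals are 1-based inclusive.

The CREF matrix C̃ has one row per retained protein-coding gene and one
column per PWM; the entry is the motif's hit count in the gene's promoter.
Rows and columns are sorted by identifier so identical inputs give
byte-identical output.

## PWM scanning

Scanning follows the MATCH scheme: per-position information weights
I(i) = Σ_b f(i,b)·ln(4·f(i,b)); the matrix similarity score of a window is
mss = (Current − Min)/(Max − Min) with Current = Σ I(i)·f(i, bᵢ) and
Min/Max the per-position extrema; the core similarity score is the same
quantity on the consecutive 5-bp window of maximal summed information
(whole matrix if shorter). `N` scores as the positional minimum. Both
strands are scanned and overlapping hits all count; strand and overlap
policy are configuration, since the original pipelines do not state them.

TRANSFAC counts become frequencies with a pseudocount of 1% of the
position total spread uniformly over the four letters, floored at 10⁻⁴ and
renormalized — this keeps information weights finite while preserving
one-hot behaviour (a uniform count row stays uniform, information weight
exactly 0).

Proprietary cutoff tables are not reproducible, so cutoff profiles are
calibrated by simulation, deterministic under a seed (default 2000 samples
per estimate):

* **minFN** — the largest cutoff retaining ≥ 90% of windows sampled from
  the PWM itself (sensitivity target configurable).
* **minFP** — the smallest cutoff whose estimated hit rate on i.i.d.
  background windows (default uniform base composition) is ≤ 10⁻⁴ per
  window.
* **minSUM** — the cutoff on the grid [0.6, 1.0] step 0.005 minimizing
  estimated FN rate + FP rate; ties break to the smallest cutoff.

Core cutoffs are calibrated the same way on core scores. Empirically,
minFP dominates the other two profiles on random PWMs; the relation
between minSUM and minFN depends on how strongly the motif and background
score distributions overlap (minSUM exceeds minFN only when the motif's
10th percentile lies below the error-density crossing), so no ordering
between those two is assumed or asserted.

## Robust SVD and dual eigen-modules

C̃ is split into low-rank + sparse by the convex program
min ‖C‖★ + λ‖S‖₁ s.t. C̃ = C + S with λ = 1/√g (g = number of genes),
solved by inexact ALM: singular-value thresholding for C, soft
thresholding for S, penalty schedule μ₀ = 1.25/‖C̃‖₂ growing by 1.5 per
iteration, stopping at ‖C̃−C−S‖_F/‖C̃‖_F ≤ 10⁻⁷ (max 1000 iterations;
non-convergence warns and flags the result). All internals are
constructor parameters.

Classical SVD of C yields eigen-triplets (ρₖ, uₖ, vₖ). The leading
triplet is an adjusted average of the count matrix (all-positive loadings)
and is excluded from reported levels: reported level k corresponds to raw
component k with the baseline at raw index 0. Nine levels are reported by
default; lower-rank inputs report fewer and set a flag.

**Signs.** An SVD's sign per component is arbitrary. Cross-species
comparisons flip (uₖ, vₖ) pairs of the target so ⟨vₖ, vₖ_ref⟩ > 0; an
exactly zero inner product falls back to making the largest-|loading|
motif positive. A reference species with no external anchor is oriented by
making the sum of cubes of each motif-eigenvector nonnegative (same
fallback). Note that inner-product alignment cannot represent rotations
beyond ±90°: a 110° planted rotation aligns to −70°. Rotation *direction*
is therefore only meaningful relative to a basis orientation; synthetic
benchmarks fix each species' orientation against its own world's ground
truth (`synthetic.truth_decomposition`) before projecting.

**Spectrum statistics.** Shares are percentages of the singular-value
sum; the adjacent relative distance is δₖ = (ρₖ − ρₖ₊₁)/ρₖ (denominator:
the larger value — the quantity is not defined more precisely in the
literature we follow, so the convention is recorded in output metadata).

## Polarization degree

Loadings are split by sign into the two poles; within a pole each entry's
energy is its squared loading. Sort the pole's energies descending and
form the cumulative-energy step curve through the points
(j/n, Eⱼ/E_pole); the pole's polarization degree d is the *y* value where
the linearly interpolated curve crosses the anti-diagonal y = 1 − x: the
top (1−d) fraction of the pole's entries is the smallest head of the
curve holding at least d of the pole's energy. The published definition
lives in supplementary material we do not reproduce; this crossing
convention is calibrated to the published illustrative example (top 10%
of 1000 entries holding 90% of the energy → d⁺ = 0.9 exactly) and yields
exactly 0.5 for equal energies. Because sorted energies make the curve
concave, the computed d always satisfies the stated guarantee that the
top ⌈(1−d)·n⌉ entries hold ≥ d of the pole energy. Empty poles report
missing (None), not 0. The overall degree combines the two pole degrees
weighted by pole energy — an implementation-defined convenience, flagged
as such.

## Stability

The distance between subspaces is ρ₂(𝒳,𝒴) = ‖X⊥ᵀY‖₂ (the sine of the
largest principal angle), computed from an explicit orthonormal basis of
the complement. For the Gram matrix D = CᵀC with eigenvalues λₖ = ρₖ² and
a symmetric perturbation E, the level-(4,5) eigenspace satisfies

    ρ₂(span{v₄,v₅}, span{v̄₄,v̄₅}) ≤ 2‖E‖₂ / (min{λ₃−λ₄, λ₅−λ₆} − ‖E‖₂)

whenever the denominator is positive; otherwise the bound is reported
inapplicable. As δ₄ → 0 the individual eigenvectors v₄, v₅ destabilize
under fixed-size perturbations while their 2-D span stays bounded — the
mechanism that turns a near-degenerate spectrum into a plane of
interchangeable regulatory directions.

Shuffle stability permutes the entries of uₖ and vₖ at one level
independently, rebuilds C′ from all raw components with the shuffled pair
substituted, re-decomposes with classical SVD (the rebuilt matrix is
exact-rank and outlier-free; a robust pass is a flag) and records per
reported level the |PCC| of motif-eigenvectors and the Frobenius distance
of the level matrices ρₖuₖvₖᵀ. Motif resampling draws ⌊f·m⌋ columns
without replacement (defaults f = 0.9, 200 replicates — package choices,
as the original counts are not printed) and records reported-level
singular values; by default it decomposes the robust low-rank C. All
Monte-Carlo operations take explicit seeds; per-replicate streams derive
from `SeedSequence.spawn`, so results are order-independent.

A note on the √f sampling limit: a matrix with *literally* orthogonal
columns keeps every singular value equal to the column norm under column
subsampling. The √f scaling of singular values holds in the regime where
a low-rank matrix's right singular vectors spread evenly across columns,
so the column-subsampled Gram concentrates at f·σ²; the test suite
instantiates that regime.

## Enrichment at the poles

For a gene set of size K among g genes, genes are ranked toward the pole
(descending loadings for +, ascending for −, average ranks on ties) and
the statistic is the set's rank sum W (small when the set clusters at
the pole); the p-value is the one-sided lower tail over random K-subsets.
Two paths:

* **Exact** (default for K ≤ 10 and g ≤ 25, or on request): dynamic
  programming over the lattice of doubled ranks (midranks are
  half-integers), giving the exact permutation distribution including
  ties.
* **Normal**: a continuity-corrected normal approximation with Edgeworth
  corrections. The central moments of W under sampling without
  replacement are computed exactly (orders 2–6) from population power
  sums via set-partition identities, and the standardized cumulants feed
  Hermite-polynomial correction terms. A plain continuity-corrected
  normal misses extreme tails of small sets by a factor ~2; with the
  corrections the worst-case relative error over all C(12,4)
  configurations is ~6%.

Both poles are scored for every set; Benjamini–Hochberg adjustment is
applied within each pole (configurable to none/Bonferroni — the original
multiplicity handling is not printed). The test is rank-based, hence
invariant to monotone transforms of loadings, and exactly antisymmetric
under negating the eigenvector.

## MPCS analysis

A motif is an MPCS if it has at least one hit (both strands) on at least
one SINE consensus sequence at the chosen cutoff profile — minSUM by
default for identification, minFP for stringent lists. Per level, the top
n motifs (default n = 100) are taken by energy over both poles —
"top 100 at the two poles" is ambiguous between 100 total and 100 per
pole; the default is 100 total (a single count per level), with a
per-pole option. The 2×2 table [top-n vs rest] × [MPCS vs other] is
tested one-sided via the hypergeometric upper tail; the odds ratio and
cross-species relative changes 100·(k_target−k_ref)/k_ref are reported
(undefined when the reference count is zero).

## Synthetic worlds

* **PWM libraries**: per-position Dirichlet draws around a random
  consensus; the concentration parameter sets sharpness (10⁴ is
  near-one-hot). Alphabet restriction and revcomp-unique consensi support
  background-free constructions.
* **Matrix worlds**: C = U·diag(ρ)·Vᵀ from random orthonormal factors
  whose first component is nonnegative (an explicit baseline, emulating
  the adjusted-average leading triplet of real count matrices), plus
  uniformly placed sparse outliers. Count mode rounds and clips to
  nonnegative integers and re-records the realized SVD as truth, because
  recovery tests must target realized, not nominal, spectra. The sparse
  component is always re-recorded as raw − lowrank so the additive
  identity holds exactly in floating point. Rotated "species" apply an
  exact in-plane rotation to one eigen-pair (counterclockwise positive);
  they stay real-valued even for count-mode inputs, since re-rounding
  would destroy the planted angle.
* **Sequence worlds**: small multi-chromosome genomes with GFF3
  annotation (`gene`/`mRNA`, `biotype=protein_coding`, 1-based inclusive,
  some genes multi-transcript on both strands). Promoters receive
  Poisson-planted motif instances with a low-rank nonnegative rate matrix
  (rank and mean rate configurable; the default mean of 0.5–1 instance
  per gene-motif keeps 1500-bp windows uncrowded). Instances are placed
  non-overlapping with one background base of flank; instances are
  sampled from the PWM unless consensus-only is set. The background-free
  configuration uses the complement-closed motif alphabet {A, T} with a
  constant-G background: any window touching background scores below
  maximum on either strand, and revcomp-unique consensi ensure each
  planted instance hits exactly its own motif once — which is what makes
  exact count round-trips provable.

What the synthetic worlds do **not** emulate: transposon insertion
histories, chromatin or conservation structure, realistic motif
co-occurrence, dinucleotide background composition, or genome-scale g
and m (tests run at hundreds of genes and tens of motifs). Passing tests
establish the correctness of the algorithms under controlled spectra and
planted signals, not biological conclusions about real genomes; real
genome FASTA/GFF3 inputs are supported but large-scale runs are not part
of the test envelope.

## Problem sizes

Simulation-based tests use matrices around 200–300 genes × 60–80 motifs,
50 shuffle replicates, 200 perturbation trials and 2000-sample cutoff
calibrations — sizes chosen so every ground-truth recovery margin
(rotation to 0.5°, robust recovery to 10⁻³ relative error) is met with
comfortable slack while the whole suite stays interactive.

## Known limitations

* The polarization-degree crossing rule and the δ denominator are
  documented conventions calibrated to published worked examples, not
  reproductions of unpublished formulas.
* Conservation thresholds use replicate-quantile calibration
  (noise-perturbed or conspecific re-runs, quantile α = 0.05); the
  original threshold derivation is not printed in the sources we follow.
* Inner-product sign alignment folds rotations beyond ±90° back into
  (−90°, 90°); interpret rotation directions relative to the stated
  reference orientation.
* The Edgeworth-corrected normal path is an approximation; for very small
  sets the exact path is preferred (and is the default there).
* The IALM solver is dense; matrices far beyond ~10⁵×10³ would need a
  truncated-SVD variant.
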