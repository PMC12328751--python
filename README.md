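# crefkit

Dual eigen-analysis of **cis-regulatory element frequency (CREF)** matrices.

Comparative regulatory genomics often asks how the *proximal* regulatory
landscape of a genome differs between closely related species — dogs and
wolves, humans and apes — when the protein-coding sequences barely differ.
`crefkit` implements the CREF approach to that question: count, for every
protein-coding gene, how often each transcription-factor binding motif
occurs in the promoter window (−1000..+499 bp of the TSS), organize the
counts into a genes × motifs matrix C̃, and study the spectral structure of
that matrix.

The core model writes the count matrix as

    C̃ = C + S,      min ‖C‖★ + λ‖S‖₁  s.t.  C̃ = C + S,   λ = 1/√g,

where C is a low-rank component carrying the principal regulatory
structure and S a sparse component absorbing outliers (solved with the
inexact augmented Lagrange multiplier algorithm). Classical SVD of C,

    C = Σₖ ρₖ uₖ vₖᵀ,

yields **dual eigen-modules**: a singular value ρₖ, a gene-eigenvector uₖ
and a motif-eigenvector vₖ per level. The leading triplet behaves as an
adjusted average (the *baseline*) and is excluded from reported levels.
On top of the decomposition the package provides:

* **Polarization degree** d⁺/d⁻ — how strongly an eigenvector's energy
  (squared loadings) concentrates at its poles.
* **Cross-species comparison** — per-level Pearson correlations of
  motif-eigenvectors with empirical conservation thresholds, and rotation
  angles of a species' level-(4,5) eigen-pair inside a reference 2-D
  eigenspace (orthogonal Procrustes).
* **Stability analysis** — the subspace distance ρ₂(𝒳,𝒴) = ‖X⊥ᵀY‖₂, the
  Davis–Kahan-style perturbation bound
  2‖E‖₂ / (min{λ₃−λ₄, λ₅−λ₆} − ‖E‖₂) for the level-(4,5) eigenspace of
  D = CᵀC, shuffle-reconstruction simulations and motif-resampling spectra.
  When adjacent singular values nearly coincide (small relative distance
  δₖ = (ρₖ−ρₖ₊₁)/ρₖ) the individual eigenvectors destabilize while their
  2-D span persists — the degenerate geometry behind saltation-like jumps
  between regulatory modules.
* **Pole enrichment** — one-sided Wilcoxon rank-sum scoring of gene sets
  toward either pole of a polarized gene-eigenvector (exact for small
  sets, moment-corrected normal otherwise), with BH adjustment.
* **MPCS analysis** — motifs present on SINE consensus sequences, and
  Fisher (hypergeometric-tail) enrichment of MPCSs among the top motifs of
  each level.
* **MATCH-style PWM scanning** — information-weighted matrix/core
  similarity scores with simulation-calibrated minFN / minFP / minSUM
  cutoff profiles, reading TRANSFAC flat files.
* **Synthetic worlds** (`crefkit.synthetic`) — PWM libraries, count-matrix
  worlds with controlled spectra, planted eigen-plane rotations and sparse
  outliers, and small genomes (FASTA + GFF3) with Poisson-planted motif
  instances — every stage of the pipeline is testable against known ground
  truth without downloading genomes.

The decomposition stage follows scikit-learn conventions (`RobustSVD`,
`DualEigenDecomposition` with `fit` and trailing-underscore attributes);
the surrounding pipeline stages are plain functions.

## Worked example

Two synthetic "species": a base world with nine well-separated reported
levels, and a derived world whose level-(4,5) eigen-plane was rotated by
70° — the desk-scale analogue of a regulatory saltation.

```python
import numpy as np
from crefkit import (rpca_ialm, dual_decompose, align_signs,
                     spectrum_stats, polarization_degree)
from crefkit.compare import project_levels
from crefkit.synthetic import (MatrixWorldSpec, gen_matrix_world,
                               gen_rotated_species, truth_decomposition)

spec = MatrixWorldSpec(300, 80,
    spectrum=(120, 60, 42, 30, 21, 15, 10.5, 7.4, 5.2, 3.6, 2.5),
    outlier_density=0.005, outlier_magnitude=0.5, seed=2)
ancestor = gen_matrix_world(spec)
derived = gen_rotated_species(ancestor, 70.0, levels=(4, 5))

ref = align_signs(dual_decompose(rpca_ialm(ancestor.raw).lowrank_),
                  truth_decomposition(ancestor))
tgt = align_signs(dual_decompose(rpca_ialm(derived.raw).lowrank_), ref)

stats = spectrum_stats(ref.reported_spectrum())
print("level-4/5 relative distance: %.1f%%" % (100 * stats.deltas[3]))
proj = project_levels(ref, tgt, levels=(4, 5))
print("rotation angle: %.2f deg (%s), max leakage %.2e"
      % (proj.theta_deg, proj.direction, proj.leakage.max()))
pol = polarization_degree(ref.v(4))
print("level-4 polarization: d+=%.3f d-=%.3f" % (pol.d_plus, pol.d_minus))
```

Output:

```
level-4/5 relative distance: 28.6%
rotation angle: 70.00 deg (counterclockwise), max leakage 8.88e-16
level-4 motif-eigenvector polarization: d+=0.733 d-=0.731
```

The relative distance says levels 4 and 5 are spectrally well separated in
the reference, so the recovered rotation is meaningful; the planted 70°
rotation is recovered exactly through the full robust pipeline, and the
near-zero leakage confirms the two species share the same 2-D eigenspace.
The polarization degrees say that roughly the top quarter of motifs at
each pole carry about three quarters of the level-4 energy.

A `crefkit` command-line tool wraps the same stages for file-based runs
(`crefkit build`, `decompose`, `compare`, `stability`, `enrich`, `mpcs`,
`scan`); see `crefkit --help`.

## Documentation

`docs/methods.md` documents the model, the numerical conventions
(cutoff calibration, the crossing convention for polarization degree, the
δ denominator, IALM internals), what the synthetic worlds do and do not
emulate, and known limitations.
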