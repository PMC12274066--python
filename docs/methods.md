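# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the numerical choices that matter.

## Genome-size estimation

Assemblies are lower bounds on genome size; direct C-value measurements
(flow cytometry, Feulgen densitometry/image analysis) are not.  The
pipeline therefore (i) deduplicates C-value records per species (most
recent date wins; ties average), (ii) fits a weighted least squares of
C-value (converted to bp at 0.978×10⁹ bp/pg, configurable) on assembly
size, and (iii) uses the measured C-value where present and the WLS
prediction otherwise.  Weights are 1/assembly_size² — a multiplicative
error model, consistent with scatter that grows with size; `equal` weights
are available and recorded in the fitted model.  Predictions are floored at
the assembly size, since a genome cannot be smaller than its assembly.
Assembly/C-value Pearson correlations are reported on both raw and log
scales, as the two can differ.

Assembly QC uses inclusive thresholds: contig N50 ≥ 50 kb and ≥ 70%
complete universal single-copy orthologs (BUSCO); boundary rows are kept.

## Codon model and per-branch dN/dS

The substitution model is YN98 with F3X4 frequencies on the 61 sense codons
of the universal code: off-diagonal rates π_j·κ^[transition]·ω^[nonsyn]
between single-step codon pairs, zero otherwise, rescaled to one expected
substitution per unit branch length.  The chain is reversible, so all
linear algebra uses the √π-symmetrized eigendecomposition: transition
probabilities P(t), and the labeled-jump integrals

    I_L(t) = U ((U⁻¹ Q_L U) ∘ J(t)) U⁻¹,   J_kl = (e^{λ_k t} − e^{λ_l t})/(λ_k − λ_l),

with the analytic limit t·e^{λt} when eigenvalues coincide (the
decomposition is real and exact, so no uniformization fallback is needed).
Likelihoods use Felsenstein pruning over compressed site patterns with
per-node rescaling; codons containing a gap are missing data (partial
likelihood 1); an in-frame stop codon in the data is a hard error.

Fitting maximizes the likelihood over log κ ∈ log[0.05, 100] and
log ω ∈ log[10⁻⁴, 10] by L-BFGS-B from three starts (one fixed, two seeded
random), with F3X4 frequencies plugged in from observed positional counts
(+0.5 pseudocount per cell to avoid structural zeros).  Branch-length
handling is selectable: `fixed` (use the species-tree lengths), `scaled`
(co-estimate one gene-wide rate multiplier; the pipeline default — it
captures among-gene rate variation at one extra parameter, where free
per-branch re-estimation costs one numeric-gradient evaluation per branch
per iteration and is intractable at pipeline scale), or `free`.

Mapped counts K_N, K_S on a branch are posterior expectations given the
alignment (outside/inside vectors give the joint endpoint posterior; the
labeled integral gives E[jumps | endpoints]).  Neutral expectations O_N,
O_S come from the same fitted κ and π with ω reset to 1 and the matrix
rescaled, so O_N + O_S = l·n_sites exactly.  The per-species aggregation is
implemented exactly as

    dN = Σᵢ K_N(i) / Σᵢ (O_N(i)/l(i)),

with a `counts_only` alternative (Σ K / Σ O) exposed because the printed
denominator has unusual dimensionality; the default remains the printed
form and the two are not claimed to be equivalent.

Filters: a species is dropped from a gene when more than 10% of its
residues sit in insertion columns (columns where it has residues against a
majority of gaps; fraction over its residue count); genes with terminal
branch < 0.001 substitutions/site for a species are excluded from that
species (boundary kept); an externally produced gene blacklist is honored;
and a trimmed variant of the analysis removes species whose terminal branch
lies outside [0.01, 1] amino-acid substitutions/site (bounds kept).  GC3
gene sets take, among genes covering ≥ 95% of species, the 50 GC3-poorest
and 50 GC3-richest genes, ties broken lexicographically by gene id.

**Known limitation.**  With ~300-codon genes the plug-in F3X4 frequencies
are noisy enough to bias ω̂ — and hence the aggregated dN/dS — upward by a
few percent under neutrality (the bias disappears by ~1500 codons, where
the mean ω̂ is 1.000).  A sufficiently powerful calibration test will
detect this; it is a finite-sample property of the plug-in estimator, not
of the mapping machinery, whose components match brute-force enumeration
and endpoint-conditioned path sampling to numerical precision.

## TE content

Read-level repeat annotations at low coverage give an assembly-free
estimate: te_fraction = annotated bp / sampled bp, scaled to the
*estimated* genome size (not the assembly size).  Recent content keeps
annotations with divergence strictly below 5% (a read at exactly 5% is
excluded).  Partially annotated reads contribute only their annotated bp.
Divergence-landscape histograms use half-open bins [lo, hi).

## Comparative tests

Under Brownian motion, tip traits are MVN with covariance C ⊗ R, C the
shared-path-length matrix.  Independent contrasts follow the standard
recursion (standardized differences, precision-weighted ancestral values,
branch-variance extension v_i v_j/(v_i+v_j)); polytomies are resolved with
zero-length branches (warned); species missing a trait are pruned per trait
pair, so n varies across results.  The contrast regression is through the
origin with n−1 degrees of freedom; its slope equals the GLS slope under C,
which serves as the central correctness oracle (checked to 10⁻⁸ on random
trees).  The multivariate-Brownian fit uses the REML-style closed forms
μ̂ = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹Y and R̂ = (Y−1μ̂)ᵀC⁻¹(Y−1μ̂)/(n−1), which equal the
contrast outer-product estimator.  Pairwise significance comes from a
seeded parametric bootstrap under the fitted R with the tested covariance
zeroed; support is the fraction of null correlations below the observed
one, read like a posterior probability (flag outside (0.1, 0.9)).  This
replaces a full Bayesian MCMC coevolution analysis; it shares the reading
convention but is a frequentist calibration, recorded as such in output
metadata.  The duplication screen reruns analyses without species whose
BUSCO-duplicated score exceeds 30% (boundary kept).

## Synthetic data

The generators produce every input with the statistical structure the
analysis assumes, at a desk scale chosen once:

* **Trees** — Yule (pure birth), rescaled to root-to-tip depth 1; binary
  and ultrametric.  The empirical-phylogeny route is newick input.
* **Traits** — multivariate Brownian motion with per-unit-length covariance
  R_true; defaults plant a strong TE/genome-size coupling (corr 0.8) and,
  in drift-driven worlds, a mild negative coupling of both to the latent
  log-Ne (corr −0.35 scale).
* **ω link** — per-terminal-branch ω = exp(a + b·log-Ne at the branch
  midpoint), clipped to [0.01, 2]; defaults (a, b) = (−1, −0.35) give mean
  ω ≈ 0.37.  Without the link ω is constant and the drift hypothesis is
  false by construction.
* **Codon alignments** — exact CTMC simulation from stationarity; gap-free.
* **TE landscapes** — families aged uniformly, copy divergence
  d = 0.4·(1 − e^(−age/0.4)) plus Gaussian copy noise (sd 0.01), reads of
  150 bp placed uniformly at 0.25× coverage (the read-based annotation
  pipeline's coverage).  Read tables are exact multinomial samples, so the
  content estimator is unbiased by construction — which is what the tests
  verify.
* **C-value records** — lognormal measurement noise (sd 0.05) and
  assembly underestimation u(s) = u_max·s/(s+s½), increasing in size, with
  u_max = 0.3 and s½ = 2×10⁸ bp paired to the default genome scale.
* **Scale** — default genomes average ~10⁸ bp (small-insect scale) so that
  per-species read tables stay tractable; genome size and TE content are
  exponentiated Brownian traits, truncated so TE space fits in the genome.

Not emulated: indels and alignment error, read-annotation noise and
chimeric reads, satellite underestimation, per-method C-value biases,
lineage-specific mutation-rate/generation-time variation behind the shared
5% "recent" threshold (a per-species divergence-rate multiplier exists but
defaults to 1), and non-Brownian trait evolution.  Passing tests therefore
show the estimators and tests are correct and calibrated under the model's
own assumptions, not that real data satisfy those assumptions.

## Problem sizes and determinism

The default test suite and `scripts/acceptance.py` use scenario sizes of
6–200 species, 200–300 codons, and 50–1000 replicates per calibration —
sizes at which every check is informative while the whole analysis reruns
in minutes on one core.  Every random draw flows from an explicit seed;
pipeline outputs are byte-identical under a fixed seed, and the run
manifest records config, input digests and per-stage row counts.
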