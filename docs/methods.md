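# Methods

This note documents the models, estimators, numerical choices, and known
limitations behind `secretomics`. It is the design record; empirical
behaviour quoted here is exactly what the test suite and
`scripts/acceptance.py` compute.

## Reporter-ion model and impurity correction

Protein-level TMT quantification treats each protein's channel vector as a
noisy measurement of condition-specific abundance. Isotopic impurities of
the labeling reagents mix channels linearly: with `M[i, j]` the fraction of
channel *j*'s true signal observed in channel *i* (columns sum to ≤ 1),
the observed vector is `y = M x`. Correction solves this system with a
general LU-based linear solver rather than explicit determinant
(Cramer-style) expansion — mathematically identical for any nonsingular
`M`, numerically better behaved. Matrices with condition number ≥ 1e8 are
rejected. Small negative solutions, which arise when noise pushes a
near-zero channel below zero, are clamped to 0 and flagged rather than
treated as errors; rows with any missing channel cannot be solved and pass
through unchanged, flagged `uncorrected_missing`. The round-trip
(mix, then correct) restores intensities to ≈ 1e-12 relative error in
practice (tested at 1e-9 over 100 random mixing matrices).

## Filtering, ratios, normalization

Proteins are retained when supported by at least 2 unique peptide
sequences and quantified in every channel ("fully quantified"); the
completeness rule runs before ratio computation so logs are taken only on
positive, observed cells. For protein *g* and non-reference channel *s*,

    r[g, s] = log2 I[g, s] − mean_c∈ref log2 I[g, c]

i.e. the denominator is the geometric mean of the reference channels on
the intensity scale. The mean (not the per-replicate pairing) is used
because replicates are not paired across conditions; the median of the
reference log2 intensities is available via `reference_stat="median"`.
Median normalization subtracts each sample column's median so every
sample's ratio distribution is centered at 0 (idempotent by construction).

## Moderated t-test

The per-contrast test is the Smyth (2004) empirical-Bayes formulation.
Per protein, `logFC = mean(group_a) − mean(group_b)` and the pooled
variance `s_g²` has `d_g = n_a + n_b − 2` residual df. The prior
`(d0, s0²)` is estimated by the moment method on `z = log s_g²`: under the
scaled-F hierarchical model,

    E[z] = log s0² + ψ(d0/2) − log(d0/2) + ψ(d_g/2) − log(d_g/2)
    Var[z] = ψ′(d0/2) + ψ′(d_g/2)

so the excess of the sample variance of `z` over `ψ′(d_g/2)` is inverted
through the trigamma function (Newton iteration, relative tolerance 1e-8)
to give `d0`, and the mean equation gives `s0²`. Estimates of `d0` above
1e6 are treated as infinite (fully pooled variance, normal reference
distribution). The posterior variance and statistic are

    s̃_g² = (d0 s0² + d_g s_g²) / (d0 + d_g)
    t_g = logFC / (s̃_g √(1/n_a + 1/n_b)),   p from t with d0 + d_g df.

Forcing `d0 = 0` recovers the ordinary pooled two-sample t exactly; the
implementation reproduces Bioconductor limma's `eBayes` on a frozen
fixture to ~1e-13 in the statistic. Two-sided p-values are used; the
enrichment direction is asserted separately by the ratio threshold.

**Contrast versus the reference condition.** Ratios against a pooled
reference share the reference-mean term across samples, so a naive
one-sample t on ratio columns understates the standard error by
`√(1 + n_a/n_ref)` and inflates type-I error. The pipeline therefore runs
the test two-sample on channel-centered log2 intensities, treating the
reference channels as the second group, which is exact; each channel's
centering offset is the median over proteins of its log2 intensity
relative to the protein's plex mean (computed on ratios so protein
abundance does not leak into the offsets). A one-sample-on-ratios mode is
kept for compatibility with ratio-only workflows, with this caveat.

Benjamini–Hochberg adjustment is delegated to
`statsmodels.stats.multitest.multipletests` behind `bh_adjust`, with NaN
propagation (missing p-values are excluded from the test count) and
domain validation added; an independent sort/step-up/cummin oracle checks
it in the tests.

## FPR threshold calibration and hit calling

Positive controls (PC; annotated secreted genes) should be enriched,
negative controls (NC; annotated transcription factors) should not. For
candidate threshold *t*,

    FPR(t) = n_NC(logFC ≥ t) / (n_NC(logFC ≥ t) + n_PC(logFC ≥ t)),

defined as 0 when no control is at or above *t*. Candidate thresholds are
the distinct observed control logFC values (plus −∞): the empirical FPR
changes only there, so the sweep is exact. The calibrated threshold is the
**smallest candidate from which the FPR never again exceeds the target** —
robust to non-monotone empirical curves, conservative, deterministic.
Because hits use `logFC ≥ threshold`, any threshold strictly between two
adjacent control values selects the same hit set as the upper value; the
implementation reports the control value itself. Calibration is performed
independently per contrast. Proteins in both control lists are labeled
ambiguous (excluded, counted); identifier matching is case-insensitive.

Hits satisfy `p_adj < alpha` (default 0.05) **and**
`logFC ≥ threshold`; depleted proteins are never hits. Ordering is by
logFC descending with ties broken by protein id, which also fixes the
top-k composition summary.

## Over-representation analysis

The ORA p-value is the exact hypergeometric upper tail
`P(X ≥ k)` (`scipy.stats.hypergeom.sf(k−1, N, K, n)`) with the detected
proteome (all proteins surviving filtering and testing) as the default
universe — the sampling frame from which hits are drawn. Sets are
intersected with the universe first; sets with fewer than 2 universe genes
are skipped and reported. BH adjustment runs across the tested sets of a
collection. Web-tool results computed on different universes or annotation
versions will differ; the universe here is explicit and configurable.
GMT dialect: a line with a name and description but no genes is an empty
set (dropped, warned); a line with fewer than two fields is malformed.

## qPCR formulas

ΔΔCt assumes an amplification efficiency of exactly 2 per cycle:
`fold = 2^(−ΔΔCt)` with `ΔCt = Ct_target − Ct_reference` per sample and
`ΔΔCt = ΔCt_exp − ΔCt_ctrl`. Technical replicates are averaged on the Ct
scale before exponentiation. ChIP fold enrichment versus a non-tagged
control IP is `2^(−(Ct_IP − Ct_control))`. Efficiency-corrected (Pfaffl)
models are out of scope.

## Synthetic data: what it emulates, what it does not

The generator draws, per protein and channel,

    log2 I_true = baseline + effect(condition) + ε,   ε ~ N(0, σ)
    baseline ~ N(20, 2)  (log2 intensity units)

then applies the tridiagonal impurity matrix (each channel bleeds
`impurity_offdiag` into each neighbour, columns summing to 1), masks cells
missing completely at random, and assigns unique-peptide counts uniformly
over `min_peptides_range`.

Defaults are the study conditions of the emulated design: 4 conditions ×
3 replicates (TMTpro 12-plex, reference `Ctrl`), 2000 proteins, 10%
enriched per non-reference condition at a fixed true effect of 2.0 log2
units, noise σ = 0.3, 200 PC of which 80% are truly enriched and 200 NC
never enriched. Off-diagonal impurity 0.02, missing rate 0.02, and peptide
counts on [1, 8] are the package's own realism choices: a few percent
channel bleed and missingness are typical of TMTpro protein-level tables,
and the peptide range exercises the ≥2-peptide filter without dominating
attrition.

Deliberately **not** modeled: peptide/spectrum-level roll-up,
intensity-dependent variance trends, batch effects across plexes,
informative missingness (real MS missingness is abundance-dependent),
retention-time or fractionation artifacts, and correlated protein
abundances. Consequently, passing tests demonstrate the correctness of
the estimators and calibration logic under the stated generative model —
not robustness to every pathology of real reporter-ion data. The variance
structure of any particular deposited dataset is unknown here; generator
defaults are chosen for testability, not fidelity to a specific accession.

## Problem sizes and determinism

Simulation-based checks use 2000 proteins with 10 independent seeds for
null calibration and FPR recovery, 100 random matrices for the impurity
round-trip, and 1000 proteins for the no-shrinkage comparison — sizes at
which the checked quantities are stable to well within their asserted
tolerances while the whole suite runs in seconds. All randomness flows
through `numpy.random.default_rng` seeds carried in configs;
identical config ⇒ bitwise-identical output.

## Known limitations

* One factor, two-group contrasts only: no covariates, no multi-factor
  linear models, no intensity-trend (limma-trend) or permutation variants.
* FPR calibration needs both control classes among tested proteins and is
  undefined (reported as such) when no threshold meets the target.
* The moderated test assumes approximately normal log2 residuals;
  heavy-tailed contamination is not robustified.
* ORA treats gene sets as flat (no GO-hierarchy propagation) and ignores
  ranking beyond the hit/non-hit dichotomy.
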