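# Methods

## The enrichment model

The central statistic is a randomization (Monte-Carlo permutation) test for
overrepresentation of a disease-linked gene set within the significant
results of a two-group expression experiment. Let the *background* be the
universe of genes interrogated by the platform, the *significant list* the
`n` unique annotated symbols whose probes pass a nominal p-value cutoff, and
`x` the number of list members also present in the gene set (restricted to
the background, size `K`). The null distribution of the match count is built
empirically: `R` random lists of `n` items are drawn without replacement
from the background and each is scored for matches. The p-value is

    p = (1 + #{draws with matches >= x}) / (R + 1).

The `+1` pseudocount makes this a valid randomization p-value (never zero,
uniformly distributed-or-conservative under the null); the plain proportion
`#/R` is available as an option and differs by at most `1/(R+1)`.

**Assumptions.** The test is competitive and self-contained in the simplest
sense: every annotated background gene is equally likely to enter a random
list (gene mode). It conditions on the list size `n` and ignores gene-gene
correlation, gene length, and probe GC content. Enrichment p-values are
reported per set without cross-set multiplicity adjustment, since the
per-disease summaries already present all sets tested.

**Background modes.** "The entire microarray background" is ambiguous when
genes own several probes. Gene mode (default) samples unique annotated
symbols; the match count is then exactly Hypergeometric(N, K, n), which the
package exploits as an internal oracle (`hypergeom_oracle`, computed via
`scipy.stats.hypergeom`). Probe mode samples annotated probes, so
multi-probe genes are proportionally likelier to enter a random list; each
randomized probe list is collapsed to unique symbols before matching. Probe
mode has no closed form and is validated against exhaustive subset
enumeration on small backgrounds.

**Sampling implementation.** Sampling `n` of `N` without replacement uses
the random-keys order statistic: assign each universe item an iid
Uniform(0,1) key and take the `n` smallest. This is distributionally
identical to sequential draws and vectorizes across the `R` draws; key
matrices are generated in bounded chunks (≤ 8M keys) so a
10,000-draw × 41k-probe run stays within a few hundred MB.

**Reproducibility.** A single master seed is supplied by the user; each gene
set's RNG stream seed is derived from SHA-256 of its `disease|source` label
mixed with the master seed through `numpy.random.SeedSequence`. Adding,
removing, or reordering gene sets therefore never perturbs another set's
null, and identical inputs+seed reproduce every artifact byte for byte.

**Null adequacy.** A narrow, very discrete null cannot support a meaningful
p-value (the motivating study dropped one disorder's sets for this reason,
without stating a numeric rule). The package flags a null when it has fewer
than 5 distinct support points, standard deviation below 1 match, or more
than 50% of mass on its single most probable count. These three thresholds
are this package's own operationalization; they are configurable arguments
of `null_diagnostics` and flagged results are still reported, marked
"interpret with caution" — flags never fail a run.

## Differential expression

Per-probe two-group inference uses an empirical-Bayes moderated t. With
pooled residual variance `s_g^2` on `d = n1 + n2 − 2` df and a scaled
inverse-chi-square prior `(d0, s0^2)`, the posterior variance is the convex
combination `(d0·s0² + d·s²)/(d0 + d)` and the statistic is referred to
t on `d0 + d` df. The prior is estimated by moment matching on `log s²`
(mean and variance of log variances, trigamma inversion by Newton); when
the observed log-variances are under-dispersed relative to pure chi-square
noise the prior df is infinite and the common variance is the mean sample
variance. Setting the prior weight to zero recovers the ordinary
pooled-variance t-test exactly, which is the test suite's closed-form
oracle; the full moderated path is cross-checked against the reference
Bioconductor implementation (limma, via Rscript) to ~1e-8 on a fixture.

Fold change is reported on the linear scale, `2^(mean_case − mean_control)`
— the ratio of back-transformed group mean coefficients — and FDR adjustment
is Benjamini–Hochberg (delegated to statsmodels behind `bh_adjust`).
Expression input is assumed already log2-summarized; no background
correction or normalization is applied. A probe with zero variance in both
groups and zero prior variance gets p = 1 and a logged flag instead of
failing the run.

Significant-list membership uses strict inequality (`p < threshold`,
default 0.02) and the any-probe rule: a gene qualifies if any of its probes
passes. Unannotated probes stay in the DE table but never reach gene-level
operations. Symbol matching between array annotation and disease databases
is case folding only (uppercase + strip); no orthology mapping.

## Synthetic studies

The generator emulates the structure of a two-group array study: a platform
whose annotated genes carry 1–3 probes each (default mix 80/15/5%, mean
1.25, echoing the observed redundancy of ~1.2 probes per significant gene)
plus a fraction of unannotated probes (default 17%); log2 intensities =
per-gene baseline N(8, 1.5²) + group effect + N(0, noise_sd²) noise; a
`de_fraction` of genes spiked with a fixed-magnitude random-sign effect
shared by all their probes; and disease gene sets drawn without replacement
with per-gene weights ∝ `enrichment_odds` for spiked genes in "enriched"
sets (odds 1 = truth-independent, the negative-control condition).
Weighted sampling uses successive draws with weight renormalization (exact).

Defaults follow the motivating study design where it states them (5 samples
per group; 10,000 draws; p < 0.02 selection; p < 0.01 reporting cutoff) and
desk-scale choices elsewhere: 2,000 genes (~3,000 probes), 10% spiked at
|log2 FC| = 2 over residual sd 0.25, 100-gene sets. A platform-scale preset
pins the platform at 41,346 probes (~19,000 genes, 300-gene sets). What the
generator does *not* model — probe-sequence effects, batch/chip effects,
normalization artifacts, correlated gene modules — bounds what passing tests
show: they validate the statistics (calibration, power, oracle equivalence,
determinism), not robustness to array chemistry.

## Validation experiments and problem sizes

The replicate-study drivers (`pymset.validation`) use single-probe,
fully-annotated platforms, since probe redundancy is exercised separately
and only slows a 1,000-replicate experiment. Sizes used by the test suite
and acceptance script, chosen once as the package's reference conditions:

- Oracle grid: (N,K,n) ∈ {(20,5,4), (30,10,8), (25,12,6), (12,6,5)}, all
  support points, R = 100,000; agreement within 3 Monte-Carlo SE.
- Probe-mode enumeration: 10 probes over 8 genes (two duplicated), n = 4,
  all C(10,4) = 210 subsets vs R = 50,000 draws.
- Type-I calibration: 1,000 replicate desk-scale studies, odds 1, R = 999
  draws per test; empirical rate of p < 0.05 expected in [0.03, 0.07]
  (slightly conservative because the null is discrete and the p-value
  carries the pseudocount).
- Power: 200 replicates at odds 20 (otherwise reference conditions);
  enriched set p < 0.01 in ≥ 90% of runs, control set at calibration rate.
- Platform-scale smoke: one full pipeline run at 41,346 probes, 10 sets,
  R = 10,000.

## Numerical choices and limitations

- Random keys are continuous, so ties occur with probability zero; no
  tie-break is needed.
- `trigamma` inversion runs Newton from `x = 0.5 + 1/y`, tolerance 1e-10
  relative; arguments > 1e7 use the asymptotic `1/sqrt(y)` start.
- Degenerate inputs: empty significant list → hard error advising a looser
  threshold; gene set disjoint from the background → K = 0, x = 0, p = 1
  with all adequacy flags raised; n = N → all mass at K matches.
- The p-value floor is `1/(R+1)`; discriminating between sets below the
  floor requires more draws, not a smaller reported number.
- Mean p per disease is the arithmetic mean over all its sets including
  non-significant ones; the reporting cutoff (default 0.01) and control
  tagging are configuration, not logic.
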