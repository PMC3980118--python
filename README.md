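# pymset

Randomization-test gene-set enrichment for two-group expression studies.

## The problem

A common question after a microarray (or any genome-wide two-group)
experiment is whether the genes that changed look like the genes already
linked to some condition: does the expression signature of, say, the
post-partum maternal brain statistically resemble gene databases curated for
schizophrenia or bipolar disorder? `pymset` implements the Modular
Single-set Enrichment Test (MSET), a randomization test that answers exactly
this, together with the two stages around it:

1. **Moderated differential expression.** For each probe, a two-group
   empirical-Bayes moderated t-test: the per-probe residual variance
   `s_g^2` (on `d` degrees of freedom) is shrunk toward a prior `s_0^2`
   estimated from all probes,

   ```
   s̃_g² = (d₀·s₀² + d·s_g²) / (d₀ + d),
   t_g  = (mean_case − mean_control) / sqrt(s̃_g²·(1/n₁ + 1/n₂)),
   ```

   referred to a t distribution on `d₀ + d` degrees of freedom, with
   Benjamini–Hochberg FDR adjustment and linear-scale fold changes
   `2^(mean_case − mean_control)`.

2. **MSET.** Build the significant list: the `n` unique annotated gene
   symbols with nominal `p < 0.02` (default). For each disease gene set,
   count the observed matches `x`, then draw `R = 10,000` random lists of
   `n` items without replacement from the array background and histogram
   their match counts. The enrichment p-value is

   ```
   p = (1 + #{draws with matches ≥ x}) / (R + 1).
   ```

   Nulls that are too narrow or too discrete for a meaningful p-value are
   flagged "interpret with caution". In gene mode the null is exactly
   hypergeometric, which the package uses as an internal oracle.

3. **Reporting.** Per-disease summaries (sets significant at the reporting
   cutoff, mean p over all sets, negative-control tagging) and the
   cross-database core-gene table: significant genes present in *every*
   database tested for a disease.

A synthetic-study generator (`pymset.simulate`) produces complete studies —
platform annotation with probe-per-gene redundancy, spiked two-group
expression, and gene sets with controlled enrichment — with ground truth, so
calibration and power of the whole pipeline are testable without any
external data.

## Worked example

```sh
pymset simulate --out study --seed 6
pymset run --expr study/expression.tsv --groups study/groups.tsv \
    --annotation study/annotation.tsv --gmt study/gene_sets.gmt \
    --out results_demo --draws 2000 --seed 7 --control arthritis_control
```

The simulated study has 2,000 annotated genes on 3,011 probes (512
unannotated, some genes on 2–3 probes), 5 case vs 5 control samples, and 10%
of genes spiked at |log2 FC| = 2. The run logs the significant-list size
(n = 235 annotated genes at p < 0.02) and each set's K, observed matches and
p to stderr, and writes `results_demo/enrichment.tsv`:

```
disease            source  K    observed_matches  p_value
disorder           dbA     100  17                0.05947026487
arthritis_control  dbB     100  19                0.02498750625
```

Both sets were generated independent of the spiked genes (`enrichment_odds`
defaults to 1), so against a null centred at `n·K/N ≈ 11.8` neither count is
remarkable — this seed's control happens to sit at p ≈ 0.025, a useful
reminder that one negative control at one seed is noisy. Regenerate the
study with `enrichment_odds: 20` in a YAML config (`pymset simulate
--config cfg.yaml --out study20`) and the `disorder` set jumps to 71
observed matches with `p = 0.0004997...` — the pseudocount floor
`1/(R+1)` at 2,000 draws — while the control is unchanged at 19.

Per-set null histograms land in `null_distributions.json`; a Figure-style
plot of any null with the observed count marked is available via
`pymset.mset.plot_null`.

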