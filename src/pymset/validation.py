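"""Monte-Carlo validation experiments for the enrichment test.

These drivers run complete synthetic studies end to end (generate platform,
expression and gene sets; fit the moderated test; build the significant
list; run the randomization test) and aggregate the per-study enrichment
p-values, to measure type-I calibration (null gene sets should yield p < a
at rate ~a) and power (strongly enriched sets should yield small p).

Replicate studies use single-probe genes with full annotation: probe
redundancy and unannotated probes are exercised elsewhere and only slow
down a many-replicate experiment without changing what it measures.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from . import diffexpr, mset, simulate


def study_pvalues(seed: int,
                  labels: Sequence[tuple[str, str, bool]],
                  n_genes: int = 2_000,
                  set_size: int = 100,
                  de_fraction: float = 0.1,
                  effect_size: float = 2.0,
                  noise_sd: float = 0.25,
                  n_per_group: int = 5,
                  enrichment_odds: float = 1.0,
                  draws: int = 999,
                  threshold: float = 0.02) -> dict[str, float]:
    """One synthetic study through the whole pipeline; per-label MSET p."""
    cfg = simulate.SimConfig(
        n_genes=n_genes, annotated_fraction=1.0,
        probe_multiplicity={1: 1.0}, n_per_group=n_per_group,
        de_fraction=de_fraction, effect_size=effect_size, noise_sd=noise_sd,
        set_size=set_size, enrichment_odds=enrichment_odds, seed=seed)
    annotation = simulate.gen_background(cfg)
    expr, truth = simulate.gen_expression(annotation, cfg)
    sets = simulate.gen_gene_sets(annotation, truth, cfg, labels)
    de = diffexpr.fit_two_group(expr)
    sig = mset.select_significant(de, annotation, threshold=threshold)
    background = mset.Background.from_annotation(annotation, mode="gene")
    results = mset.test_collection(sig, background, sets, draws=draws,
                                   master_seed=seed)
    return {f"{r.disease}|{r.source}": r.p_value for r in results}


def calibration_rate(n_replicates: int, base_seed: int,
                     alpha: float = 0.05,
                     n_genes: int = 2_000,
                     set_size: int = 100,
                     draws: int = 999) -> float:
    """Fraction of replicate studies where a truth-independent gene set
    (enrichment odds 1) reports enrichment p < alpha. Should be ~alpha."""
    labels = [("dz", "db", False)]
    hits = 0
    for rep in range(n_replicates):
        p = study_pvalues(base_seed + rep, labels, n_genes=n_genes,
                          set_size=set_size, draws=draws)["dz|db"]
        hits += p < alpha
    return hits / n_replicates


def power_rates(n_replicates: int, base_seed: int,
                enrichment_odds: float = 20.0,
                alpha_power: float = 0.01,
                alpha_control: float = 0.05,
                draws: int = 999) -> tuple[float, float]:
    """(power, control false-positive rate) over replicate studies with one
    enriched and one truth-independent gene set, at the reference study
    conditions (2,000 genes, 10% spiked at |log2 FC| 2, sd 0.25, 5 vs 5,
    100-gene sets)."""
    labels = [("dz", "db_enr", True), ("ctrl", "db_null", False)]
    power_hits = control_hits = 0
    for rep in range(n_replicates):
        ps = study_pvalues(base_seed + rep, labels,
                           enrichment_odds=enrichment_odds, draws=draws)
        power_hits += ps["dz|db_enr"] < alpha_power
        control_hits += ps["ctrl|db_null"] < alpha_control
    return power_hits / n_replicates, control_hits / n_replicates


def oracle_grid_deviation(grid: Sequence[tuple[int, int, int]],
                          draws: int, seed: int) -> list[dict]:
    """Compare the gene-mode Monte-Carlo tail against the exact
    hypergeometric tail at every support point of every (N, K, n) grid cell.
    Returns one record per point with the deviation in MC standard errors."""
    out = []
    for N, K, n in grid:
        bg = mset.Background(mode="gene",
                             probe_symbols=tuple(f"G{i}" for i in range(N)))
        members = {f"G{i}" for i in range(K)}
        null = mset.draw_null(bg, n, members, draws=draws, seed=seed)
        for x in range(min(n, K) + 1):
            exact = mset.hypergeom_oracle(N, K, n, x)
            mc = mset.mset_pvalue(x, null, pseudocount=False)
            se = float(np.sqrt(exact * (1 - exact) / draws))
            out.append({"N": N, "K": K, "n": n, "x": x, "exact": exact,
                        "mc": mc, "se": se,
                        "z": abs(mc - exact) / se if se > 0 else 0.0})
    return out
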