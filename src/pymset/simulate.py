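"""Synthetic two-group microarray studies with known ground truth.

Generates everything the pipeline consumes — a probe annotation with
controlled probe-per-gene redundancy and an unannotated probe fraction, a
log2 expression matrix with a spiked fraction of truly differential genes,
and disease gene sets whose overlap with the spiked genes is controlled by
an odds multiplier — so calibration and power of the downstream statistics
can be tested without any external data.

The expression model is deliberately simple: per-gene log2 baselines drawn
from a broad normal, a fixed-magnitude random-sign group effect on spiked
genes (shared by all probes of the gene), and iid Gaussian residual noise.
It tests the statistics, not array chemistry.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .io import ExpressionMatrix, GeneSet, GeneSetCollection, ProbeAnnotation
from .mset import derive_stream_seed

_BASELINE_MEAN = 8.0   # typical log2 array intensity
_BASELINE_SD = 1.5

# Sub-stream tags so the background / expression / set draws are independent.
_STREAM_BACKGROUND = 11
_STREAM_EXPRESSION = 12
_STREAM_SETS = 13


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic study.

    Defaults are the desk-scale preset: 2,000 annotated genes carried by
    ~3,000 probes (probe-per-gene multiplicity mixing 1-3 copies, mean 1.25,
    emulating the redundancy of an expression array where some genes own
    several probesets and a fraction of probes is unannotated), 5 samples
    per group, 10% of genes truly differential at |log2 FC| = 2 over
    residual sd 0.25, and 100-gene disease sets.
    """

    n_genes: int = 2_000
    annotated_fraction: float = 0.83
    probe_multiplicity: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.80, 2: 0.15, 3: 0.05})
    n_per_group: int = 5
    de_fraction: float = 0.10
    effect_size: float = 2.0
    noise_sd: float = 0.25
    set_size: int = 100
    enrichment_odds: float = 1.0
    seed: int = 0
    n_probes_total: int | None = None  # pin the platform size exactly

    def __post_init__(self) -> None:
        if not 0 <= self.annotated_fraction <= 1:
            raise ValueError("annotated_fraction must lie in [0, 1]")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.n_per_group < 2:
            raise ValueError("need n_per_group >= 2")
        if self.enrichment_odds < 0 or self.effect_size < 0:
            raise ValueError("enrichment_odds and effect_size must be >= 0")
        if self.set_size > self.n_genes:
            raise ValueError("set_size cannot exceed n_genes")


def paper_scale_config(seed: int = 0) -> SimConfig:
    """Platform-scale preset: 41,346 probes, ~19,000 annotated genes,
    matching the scale of a full expression array."""
    return SimConfig(n_genes=19_000, n_probes_total=41_346,
                     set_size=300, seed=seed)


def load_config(path: str | Path) -> SimConfig:
    """Read a SimConfig from a YAML key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "probe_multiplicity" in raw:
        raw["probe_multiplicity"] = {int(k): float(v)
                                     for k, v in raw["probe_multiplicity"].items()}
    return SimConfig(**raw)


def gen_background(cfg: SimConfig) -> ProbeAnnotation:
    """Probe annotation: per-gene probe multiplicities drawn from the
    configured distribution, plus unannotated filler probes."""
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, _STREAM_BACKGROUND]))
    mults = np.array(sorted(cfg.probe_multiplicity), dtype=int)
    probs = np.array([cfg.probe_multiplicity[m] for m in mults], dtype=float)
    probs = probs / probs.sum()
    per_gene = rng.choice(mults, size=cfg.n_genes, p=probs)

    mapping: dict[str, str] = {}
    probe_no = 0
    for g in range(cfg.n_genes):
        sym = f"G{g:05d}"
        for _ in range(int(per_gene[g])):
            mapping[f"probe_{probe_no:06d}"] = sym
            probe_no += 1
    n_annot = probe_no

    if cfg.n_probes_total is not None:
        n_unannot = cfg.n_probes_total - n_annot
        if n_unannot < 0:
            raise ValueError(
                f"n_probes_total={cfg.n_probes_total} below the "
                f"{n_annot} annotated probes drawn")
    elif cfg.annotated_fraction <= 0:
        # Degenerate config: platform of unannotated probes only.
        mapping.clear()
        n_unannot, n_annot = cfg.n_genes, 0
    else:
        n_unannot = round(n_annot * (1 - cfg.annotated_fraction)
                          / cfg.annotated_fraction)
    for _ in range(n_unannot):
        mapping[f"probe_{probe_no:06d}"] = fio.UNANNOTATED
        probe_no += 1
    return ProbeAnnotation(symbol_of_probe=mapping)


def gen_expression(annotation: ProbeAnnotation,
                   cfg: SimConfig) -> tuple[ExpressionMatrix, frozenset[str]]:
    """Expression matrix plus the ground-truth set of spiked genes.

    log2 intensity = gene baseline + group effect (spiked genes only, random
    sign, magnitude ``effect_size``, applied to the case group and shared by
    all probes of the gene) + N(0, noise_sd) residual noise.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, _STREAM_EXPRESSION]))
    probes = annotation.probe_ids
    genes = sorted(annotation.unique_symbols())
    n_spiked = round(cfg.de_fraction * len(genes))
    spiked = frozenset(rng.choice(genes, size=n_spiked, replace=False)) \
        if n_spiked else frozenset()
    signs = {g: s for g, s in zip(sorted(spiked),
                                  rng.choice([-1.0, 1.0], size=len(spiked)))}

    baseline_of_gene = dict(zip(genes, rng.normal(_BASELINE_MEAN,
                                                  _BASELINE_SD, len(genes))))
    n = cfg.n_per_group
    samples = [f"case_{i+1}" for i in range(n)] + \
              [f"ctrl_{i+1}" for i in range(n)]
    groups = {s: (fio.CASE_LABEL if s.startswith("case") else fio.CONTROL_LABEL)
              for s in samples}

    base = np.empty(len(probes))
    effect = np.zeros(len(probes))
    for i, p in enumerate(probes):
        sym = annotation.symbol(p)
        if sym:
            base[i] = baseline_of_gene[sym]
            if sym in spiked:
                effect[i] = signs[sym] * cfg.effect_size
        else:
            base[i] = rng.normal(_BASELINE_MEAN, _BASELINE_SD)

    noise = rng.normal(0.0, cfg.noise_sd, size=(len(probes), 2 * n))
    values = base[:, None] + noise
    values[:, :n] += effect[:, None]
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=probes, columns=samples),
        groups=groups)
    return matrix, spiked


def gen_gene_sets(annotation: ProbeAnnotation, truth: frozenset[str],
                  cfg: SimConfig,
                  labels: Sequence[tuple[str, str, bool]]) -> GeneSetCollection:
    """Disease gene sets with controlled overlap with the spiked genes.

    For an enriched label, each spiked gene's selection weight is multiplied
    by ``enrichment_odds``; sets for non-enriched labels (or odds 1) are
    drawn independently of the truth. Sampling is without replacement by
    successive draws with weight renormalization, which is exact.
    """
    genes = sorted(annotation.unique_symbols())
    if cfg.set_size > len(genes):
        raise ValueError(
            f"set_size={cfg.set_size} exceeds {len(genes)} annotated genes")
    truth_mask = np.fromiter((g in truth for g in genes), dtype=bool,
                             count=len(genes))
    entries = []
    for disease, source, enriched in labels:
        seed = derive_stream_seed(cfg.seed + _STREAM_SETS, disease, source)
        rng = np.random.default_rng(seed)
        w = np.ones(len(genes))
        if enriched:
            w[truth_mask] = cfg.enrichment_odds
        chosen: list[str] = []
        weights = w.copy()
        for _ in range(cfg.set_size):
            total = weights.sum()
            if total <= 0:
                raise ValueError(
                    f"cannot draw {cfg.set_size} genes for ({disease}, "
                    f"{source}): all remaining weights are zero")
            idx = rng.choice(len(genes), p=weights / total)
            chosen.append(genes[idx])
            weights[idx] = 0.0
        entries.append(GeneSet(disease=disease, source=source,
                               symbols=frozenset(chosen)))
    return GeneSetCollection(entries=tuple(entries))


DEFAULT_LABELS: tuple[tuple[str, str, bool], ...] = (
    ("disorder", "dbA", True),
    ("arthritis_control", "dbB", False),
)


def gen_study(cfg: SimConfig, out_dir: str | Path,
              labels: Sequence[tuple[str, str, bool]] = DEFAULT_LABELS,
              ) -> dict[str, Path]:
    """Write a complete synthetic study: expression TSV, group map TSV,
    annotation TSV, GMT gene sets, and a truth JSON (spiked genes and each
    set's overlap with truth). Byte-identical across runs with one seed."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create study directory {out_dir}: {exc}")

    annotation = gen_background(cfg)
    expr, truth = gen_expression(annotation, cfg)
    sets = gen_gene_sets(annotation, truth, cfg, labels)

    paths = {
        "expression": out_dir / "expression.tsv",
        "groups": out_dir / "groups.tsv",
        "annotation": out_dir / "annotation.tsv",
        "gene_sets": out_dir / "gene_sets.gmt",
        "truth": out_dir / "truth.json",
    }
    fio.write_expression(expr, paths["expression"], paths["groups"])
    fio.write_annotation(annotation, paths["annotation"])
    fio.write_gmt(sets, paths["gene_sets"])

    truth_doc = {
        "spiked_genes": sorted(truth),
        "config": _config_dict(cfg),
        "labels": [{"disease": d, "source": s, "enriched": e}
                   for d, s, e in labels],
        "set_overlap_with_truth": {
            f"{e.disease}|{e.source}": len(e.symbols & truth) for e in sets},
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth_doc, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


def _config_dict(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    d["probe_multiplicity"] = {int(k): float(v)
                               for k, v in cfg.probe_multiplicity.items()}
    return d
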