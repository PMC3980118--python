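"""End-to-end pipeline: read inputs, score differential expression, build the
significant annotated gene list, run MSET per gene set, aggregate per-disease
summaries, and write all artifacts."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path


from . import __version__
from . import io as fio
from . import diffexpr, mset, report

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Failure in a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass(frozen=True)
class RunConfig:
    expression: Path
    groups: Path
    annotation: Path
    gmt: Path
    out_dir: Path
    de_threshold: float = 0.02
    report_cutoff: float = 0.01
    draws: int = 10_000
    background_mode: str = "gene"
    pseudocount: bool = True
    seed: int = 0
    control_diseases: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in ("de_threshold", "report_cutoff"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.draws < 100:
            raise ValueError("draws must be >= 100")


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Execute the full pipeline; returns the artifact paths written.

    Stage failures raise :class:`PipelineError` naming the stage. Inadequate
    (narrow/discrete) nulls never fail the run; they only carry flags.
    """

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return deco

    @stage("formats_io")
    def inputs():
        expr = fio.read_expression(cfg.expression, cfg.groups)
        annotation = fio.read_annotation(cfg.annotation)
        sets = fio.read_gmt(cfg.gmt)
        return expr, annotation, sets

    expr, annotation, sets = inputs

    @stage("diffexpr")
    def de():
        return diffexpr.fit_two_group(expr)

    @stage("mset_core")
    def enrichment():
        sig = mset.select_significant(de, annotation,
                                      threshold=cfg.de_threshold)
        if sig.n < 50:
            log.info("significant list has only %d genes; a looser "
                     "threshold broadens the null and stabilizes the "
                     "randomization p-value", sig.n)
        background = mset.Background.from_annotation(
            annotation, mode=cfg.background_mode)
        results = mset.test_collection(
            sig, background, sets, draws=cfg.draws, master_seed=cfg.seed,
            pseudocount=cfg.pseudocount)
        return sig, background, results

    sig, background, results = enrichment
    log.info("significant annotated genes: n=%d (p < %g)", sig.n,
             cfg.de_threshold)
    for r in results:
        log.info("MSET %s/%s: K=%d x=%d p=%.4g%s", r.disease, r.source,
                 r.K, r.x, r.p_value,
                 " [caution]" if r.diagnostics.any_flag else "")

    @stage("study_report")
    def outputs():
        sets_by_disease = {d: sets.for_disease(d) for d in sets.diseases()}
        summaries = report.summarize_all(results, sig, sets_by_disease,
                                         cutoff=cfg.report_cutoff)
        de_out = de.copy()
        de_out.insert(0, "symbol", [annotation.symbol_of_probe.get(p, "")
                                    for p in de_out.index])
        paths = fio.write_results(de_out, results, cfg.out_dir)
        summary_path = Path(cfg.out_dir) / "disease_summaries.tsv"
        report.summaries_table(summaries).to_csv(
            summary_path, sep="\t", index=False, float_format="%.10g")
        paths["summaries"] = summary_path
        paths["report"] = report.render_report(
            summaries, results, Path(cfg.out_dir) / "report.md",
            control_diseases=cfg.control_diseases, cutoff=cfg.report_cutoff)
        paths["manifest"] = _write_manifest(cfg, sig, results)
        return paths

    return outputs


def _write_manifest(cfg: RunConfig, sig, results) -> Path:
    manifest = {
        "pymset_version": __version__,
        "config": {k: (str(v) if isinstance(v, Path) else
                       list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
        "n_significant_annotated_genes": sig.n,
        "results": [{"disease": r.disease, "source": r.source, "K": r.K,
                     "x": r.x, "p_value": r.p_value,
                     "flagged": r.diagnostics.any_flag} for r in results],
    }
    path = Path(cfg.out_dir) / "run_manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return path
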