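"""Disease-level aggregation of MSET results and the cross-database
core-gene table (significant genes appearing in every database tested for a
disease), plus a human-readable markdown report."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .io import GeneSet
from .mset import MsetResult, SignificantList


@dataclass(frozen=True)
class DiseaseSummary:
    disease: str
    n_sets: int
    n_significant: int
    mean_p: float
    core_genes: frozenset[str]

    def __post_init__(self) -> None:
        if not 0 <= self.n_significant <= self.n_sets:
            raise ValueError("n_significant must lie in [0, n_sets]")
        if not 0 < self.mean_p <= 1:
            raise ValueError("mean_p must lie in (0, 1]")


def summarize_disease(results: Sequence[MsetResult],
                      core_genes: Iterable[str] = (),
                      cutoff: float = 0.01) -> DiseaseSummary:
    """Per-disease summary: sets with p below the reporting cutoff and the
    arithmetic mean p over all sets (significant or not)."""
    if not results:
        raise ValueError("need at least one result for a disease summary")
    diseases = {r.disease for r in results}
    if len(diseases) != 1:
        raise ValueError(f"results span multiple diseases: {sorted(diseases)}")
    ps = [r.p_value for r in results]
    return DiseaseSummary(
        disease=results[0].disease,
        n_sets=len(results),
        n_significant=sum(p < cutoff for p in ps),
        mean_p=sum(ps) / len(ps),
        core_genes=frozenset(core_genes),
    )


def intersect_all_sets(sig: SignificantList,
                       sets: Sequence[GeneSet]) -> frozenset[str]:
    """Significant genes that are members of every gene set for a disease."""
    if not sets:
        raise ValueError("need at least one gene set")
    core = frozenset(sig.symbols)
    for gs in sets:
        core &= gs.symbols
    return core


def summarize_all(results: Sequence[MsetResult], sig: SignificantList,
                  sets_by_disease: dict[str, Sequence[GeneSet]],
                  cutoff: float = 0.01) -> list[DiseaseSummary]:
    """Compose per-disease summaries (with core genes) for every disease that
    has results, preserving first-appearance order."""
    order: list[str] = []
    for r in results:
        if r.disease not in order:
            order.append(r.disease)
    out = []
    for disease in order:
        rs = [r for r in results if r.disease == disease]
        core = intersect_all_sets(sig, list(sets_by_disease[disease])) \
            if disease in sets_by_disease else frozenset()
        out.append(summarize_disease(rs, core_genes=core, cutoff=cutoff))
    return out


def summaries_table(summaries: Sequence[DiseaseSummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "disease": s.disease,
        "n_sets": s.n_sets,
        "n_significant": s.n_significant,
        "mean_p": s.mean_p,
        "core_genes": ";".join(sorted(s.core_genes)),
    } for s in summaries])


def render_report(summaries: Sequence[DiseaseSummary],
                  results: Sequence[MsetResult], out: str | Path,
                  control_diseases: Iterable[str] = (),
                  cutoff: float = 0.01) -> Path:
    """Write the markdown report: disease summary table, per-set rows with
    caution flags, core-gene table, and a negative-control section for any
    disease tagged as a control."""
    out = Path(out)
    controls = set(control_diseases)
    lines: list[str] = ["# Gene-set enrichment report", ""]

    lines += [f"## Disease summaries (reporting cutoff p < {cutoff:g})", "",
              "| disease | significant sets | mean p |",
              "|---|---|---|"]
    for s in summaries:
        tag = " (negative control)" if s.disease in controls else ""
        lines.append(f"| {s.disease}{tag} | {s.n_significant} of {s.n_sets} "
                     f"| {s.mean_p:.4g} |")

    lines += ["", "## Per-set results", "",
              "| disease | source | K | observed | p | note |",
              "|---|---|---|---|---|---|"]
    for r in results:
        note = "interpret with caution" if r.diagnostics.any_flag else ""
        lines.append(f"| {r.disease} | {r.source} | {r.K} | {r.x} "
                     f"| {r.p_value:.4g} | {note} |")

    lines += ["", "## Core genes (present in every database per disease)", "",
              "| disease | core genes |", "|---|---|"]
    for s in summaries:
        genes = ", ".join(sorted(s.core_genes)) if s.core_genes else "none"
        lines.append(f"| {s.disease} | {genes} |")

    if controls:
        lines += ["", "## Negative controls", ""]
        for s in summaries:
            if s.disease in controls:
                lines.append(
                    f"- {s.disease}: {s.n_significant} of {s.n_sets} sets "
                    f"significant, mean p = {s.mean_p:.4g} (no enrichment "
                    f"expected).")

    try:
        out.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write report to {out}: {exc}")
    return out
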