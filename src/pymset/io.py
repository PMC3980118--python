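"""Readers/writers for the pipeline's external formats.

All gene symbols pass through :func:`normalize_symbol` (uppercase, surrounding
whitespace stripped) so that mouse-style array symbols (``Fabp7``) match the
human-centric disease databases (``FABP7``). No orthology mapping is applied
beyond case folding.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

CASE_LABEL = "case"
CONTROL_LABEL = "control"
UNANNOTATED = ""


def normalize_symbol(symbol: str) -> str:
    """Normalize a gene symbol: strip surrounding whitespace, uppercase.

    Idempotent: ``normalize_symbol(normalize_symbol(s)) == normalize_symbol(s)``.
    """
    return symbol.strip().upper()


@dataclass(frozen=True)
class ExpressionMatrix:
    """Log2 probe intensities for a two-group design.

    ``values`` is a probes x samples DataFrame; ``groups`` maps every sample id
    to ``"case"`` or ``"control"``.
    """

    values: pd.DataFrame
    groups: Mapping[str, str]

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()][0]
            raise ValueError(f"duplicate probe id: {dup!r}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        missing = [s for s in v.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples missing from group map: {missing}")
        bad = {s: g for s, g in self.groups.items()
               if g not in (CASE_LABEL, CONTROL_LABEL)}
        if bad:
            raise ValueError(f"unknown group labels: {bad}")
        for grp in (CASE_LABEL, CONTROL_LABEL):
            n = sum(1 for s in v.columns if self.groups[s] == grp)
            if n < 2:
                raise ValueError(f"need >=2 samples in group {grp!r}, got {n}")
        if not np.isfinite(v.to_numpy(dtype=float)).all():
            raise ValueError("expression values must all be finite")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]


@dataclass(frozen=True)
class ProbeAnnotation:
    """Probe -> normalized gene symbol map; ``""`` marks an unannotated probe."""

    symbol_of_probe: Mapping[str, str]

    def __post_init__(self) -> None:
        for probe, sym in self.symbol_of_probe.items():
            if sym != UNANNOTATED and (not sym or sym != normalize_symbol(sym)):
                raise ValueError(
                    f"symbol for probe {probe!r} is not normalized: {sym!r}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.symbol_of_probe)

    def symbol(self, probe: str) -> str:
        return self.symbol_of_probe[probe]

    def is_annotated(self, probe: str) -> bool:
        return self.symbol_of_probe[probe] != UNANNOTATED

    def annotated_probes(self) -> list[str]:
        return [p for p, s in self.symbol_of_probe.items() if s != UNANNOTATED]

    def unique_symbols(self) -> set[str]:
        return {s for s in self.symbol_of_probe.values() if s != UNANNOTATED}


@dataclass(frozen=True)
class GeneSet:
    disease: str
    source: str
    symbols: frozenset[str]

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError(
                f"empty gene set for ({self.disease!r}, {self.source!r})")


@dataclass(frozen=True)
class GeneSetCollection:
    entries: tuple[GeneSet, ...]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for e in self.entries:
            key = (e.disease, e.source)
            if key in seen:
                raise ValueError(f"duplicate (disease, source) pair: {key}")
            seen.add(key)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def diseases(self) -> list[str]:
        out: list[str] = []
        for e in self.entries:
            if e.disease not in out:
                out.append(e.disease)
        return out

    def for_disease(self, disease: str) -> list[GeneSet]:
        return [e for e in self.entries if e.disease == disease]


def read_expression(path: str | Path,
                    groups: str | Path | Mapping[str, str]) -> ExpressionMatrix:
    """Read a probes x samples TSV (first column probe id, header of sample ids).

    ``groups`` is either a two-column TSV path (sample TAB group) or an inline
    sample->group mapping. Group labels in files may be the study's own
    ("maternal"/"virgin") or the generic "case"/"control".
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate probe id {dup!r}")
    values = pd.DataFrame(index=df.index.astype(str),
                          columns=df.columns.astype(str), dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[col] = pd.to_numeric(df[col], errors="raise").to_numpy()
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce")
        else:
            continue
        i = int(np.where(bad.isna().to_numpy())[0][0])
        raise ValueError(
            f"{path}: non-numeric value at probe {df.index[i]!r}, "
            f"sample {col!r} (row {i + 2}, column {j + 2})")
    group_map = _load_groups(groups)
    return ExpressionMatrix(values=values, groups=group_map)


_GROUP_ALIASES = {
    "case": CASE_LABEL, "maternal": CASE_LABEL, "postpartum": CASE_LABEL,
    "control": CONTROL_LABEL, "virgin": CONTROL_LABEL,
}


def _load_groups(groups: str | Path | Mapping[str, str]) -> dict[str, str]:
    if isinstance(groups, (str, Path)):
        df = pd.read_csv(groups, sep="\t", header=None, dtype=str,
                         names=["sample", "group"])
        raw = dict(zip(df["sample"], df["group"]))
    else:
        raw = dict(groups)
    out: dict[str, str] = {}
    for sample, grp in raw.items():
        key = str(grp).strip().lower()
        if key not in _GROUP_ALIASES:
            raise ValueError(f"unknown group label {grp!r} for sample {sample!r}")
        out[str(sample)] = _GROUP_ALIASES[key]
    return out


def write_expression(expr: ExpressionMatrix, path: str | Path,
                     groups_path: str | Path | None = None) -> None:
    expr.values.to_csv(path, sep="\t", index_label="probe_id",
                       float_format="%.6f")
    if groups_path is not None:
        with open(groups_path, "w") as fh:
            for s in expr.sample_ids:
                fh.write(f"{s}\t{expr.groups[s]}\n")


def read_annotation(path: str | Path) -> ProbeAnnotation:
    """Read a two-column TSV (probe TAB symbol); empty symbol = unannotated."""
    path = Path(path)
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            probe = parts[0].strip()
            sym = parts[1] if len(parts) > 1 else ""
            if probe in mapping:
                raise ValueError(f"{path}:{lineno}: duplicate probe id {probe!r}")
            mapping[probe] = (normalize_symbol(sym)
                              if sym.strip() else UNANNOTATED)
    return ProbeAnnotation(symbol_of_probe=mapping)


def write_annotation(annotation: ProbeAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for probe, sym in annotation.symbol_of_probe.items():
            fh.write(f"{probe}\t{sym}\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets in GMT format (name TAB description TAB member...).

    The set name encodes disease and source database as ``disease|source``.
    Duplicate members within a line are collapsed after normalization; the
    collapse count is logged.
    """
    path = Path(path)
    entries: list[GeneSet] = []
    n_collapsed = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated "
                    f"fields, got {len(parts)}")
            name = parts[0]
            if "|" in name:
                disease, source = name.split("|", 1)
            else:
                disease, source = name, "unspecified"
            members = [normalize_symbol(m) for m in parts[2:] if m.strip()]
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
            unique = frozenset(members)
            n_collapsed += len(members) - len(unique)
            entries.append(GeneSet(disease=disease.strip(),
                                   source=source.strip(), symbols=unique))
    if n_collapsed:
        log.info("read_gmt(%s): collapsed %d duplicate members within sets",
                 path, n_collapsed)
    return GeneSetCollection(entries=tuple(entries))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in collection:
            members = "\t".join(sorted(e.symbols))
            fh.write(f"{e.disease}|{e.source}\t{e.disease} ({e.source})\t"
                     f"{members}\n")


def write_results(de_table: pd.DataFrame, mset_results: Sequence,
                  out_dir: str | Path) -> dict[str, Path]:
    """Write pipeline outputs: DE table TSV, enrichment TSV, null-histogram JSON.

    Returns the paths written, keyed ``de_table`` / ``enrichment`` / ``nulls``.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_test"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}")

    de_path = out_dir / "de_table.tsv"
    de_table.to_csv(de_path, sep="\t", index_label="probe_id",
                    float_format="%.10g")

    enr_path = out_dir / "enrichment.tsv"
    rows = []
    for r in mset_results:
        rows.append({
            "disease": r.disease,
            "source": r.source,
            "set_size_in_background": r.K,
            "background_size": r.null.background_size,
            "significant_list_size": r.null.list_size,
            "observed_matches": r.x,
            "p_value": f"{r.p_value:.10g}",
            "flag_few_support_points": r.diagnostics.few_support_points,
            "flag_narrow_sd": r.diagnostics.narrow_sd,
            "flag_mass_concentrated": r.diagnostics.mass_concentrated,
        })
    pd.DataFrame(rows).to_csv(enr_path, sep="\t", index=False)

    nulls_path = out_dir / "null_distributions.json"
    payload = {
        f"{r.disease}|{r.source}": {
            "draws": r.null.draws,
            "seed": r.null.seed,
            "match_counts": {str(k): int(v)
                             for k, v in sorted(r.null.match_counts.items())},
        }
        for r in mset_results
    }
    with open(nulls_path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")

    return {"de_table": de_path, "enrichment": enr_path, "nulls": nulls_path}
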