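"""Tabular and interval file formats shared by the pipeline.

TSV is the canonical tabular dialect (header required, ``#`` comments
allowed); intervals use BED (0-based half-open, BED3 or BED4 with the name
column carrying the deficiency or gene id).  All writers are deterministic:
stable row ordering and floats at 6 significant digits.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from .genome_mapping import (
    DeficiencyRecord,
    GeneGroup,
    GeneModel,
    GenomicInterval,
    MappingError,
)
from .screen_scoring import (
    CrossRecord,
    PhenotypeCounts,
    ScreenError,
    ScreenResult,
)

__all__ = [
    "fmt",
    "read_screen_table",
    "write_screen_table",
    "read_bed",
    "write_bed",
    "read_deficiency_bed",
    "read_gene_bed",
    "read_gene_groups",
    "write_gene_groups",
    "read_gene_list",
    "write_gene_list",
    "write_screen_result",
    "load_config",
    "setup_logging",
]

logger = logging.getLogger(__name__)

SCREEN_COLUMNS = [
    "df_id",
    "transgene",
    "stage",
    "n_mild",
    "n_moderate",
    "n_severe",
    "n_eclosed",
]


def fmt(x: float) -> str:
    """Fixed 6-significant-digit float formatting for stable diffs."""
    return f"{x:.6g}"


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(levelname)s %(name)s: %(message)s",
    )


# --- screen tables ----------------------------------------------------------


def read_screen_table(path: str | Path) -> list[CrossRecord]:
    """Read per-cross screen records; transgene-only controls carry an empty
    df_id.  Errors name the offending 1-based data row.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype={"df_id": str}, keep_default_na=False
    )
    missing = set(SCREEN_COLUMNS) - set(df.columns)
    if missing:
        raise ScreenError(f"{path}: missing columns {sorted(missing)}")

    records: list[CrossRecord] = []
    seen: dict[tuple[str, str, str], int] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        try:
            counts = PhenotypeCounts(
                int(row.n_mild), int(row.n_moderate), int(row.n_severe)
            )
            eclosed = None if row.n_eclosed == "" else int(row.n_eclosed)
            rec = CrossRecord(
                str(row.df_id), str(row.transgene), str(row.stage), counts, eclosed
            )
        except (ScreenError, ValueError) as exc:
            raise ScreenError(f"{path} row {row_no}: {exc}") from exc
        key = (rec.df_id, rec.transgene, rec.stage)
        if key in seen:
            raise ScreenError(
                f"{path} row {row_no}: duplicate record for {key} "
                f"(first at row {seen[key]})"
            )
        seen[key] = row_no
        records.append(rec)
    return records


def write_screen_table(records: Iterable[CrossRecord], path: str | Path) -> None:
    rows = [
        {
            "df_id": r.df_id,
            "transgene": r.transgene,
            "stage": r.stage,
            "n_mild": r.counts.n_mild,
            "n_moderate": r.counts.n_moderate,
            "n_severe": r.counts.n_severe,
            "n_eclosed": r.n_eclosed,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=SCREEN_COLUMNS).to_csv(path, sep="\t", index=False)


# --- BED --------------------------------------------------------------------


def read_bed(path: str | Path) -> list[tuple[GenomicInterval, str]]:
    """BED3/BED4 intervals with their name (empty for BED3); track, browser
    and comment lines are tolerated.
    """
    out: list[tuple[GenomicInterval, str]] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise MappingError(f"{path} line {line_no}: fewer than 3 columns")
            try:
                interval = GenomicInterval(
                    fields[0], int(fields[1]), int(fields[2])
                )
            except (MappingError, ValueError) as exc:
                raise MappingError(f"{path} line {line_no}: {exc}") from exc
            name = fields[3] if len(fields) > 3 else ""
            out.append((interval, name))
    return out


def write_bed(records: Iterable[tuple[GenomicInterval, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for interval, name in records:
            cols = [interval.chrom, str(interval.start), str(interval.end)]
            if name:
                cols.append(name)
            fh.write("\t".join(cols) + "\n")


def read_deficiency_bed(path: str | Path) -> list[DeficiencyRecord]:
    return [DeficiencyRecord(name, iv) for iv, name in read_bed(path)]


def read_gene_bed(path: str | Path) -> list[GeneModel]:
    return [GeneModel(name, iv) for iv, name in read_bed(path)]


# --- gene groups and lists --------------------------------------------------


def read_gene_groups(path: str | Path) -> list[GeneGroup]:
    """Two-column TSV ``group_id<TAB>gene_id`` -> GeneGroup list (sorted)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if list(df.columns[:2]) != ["group_id", "gene_id"]:
        raise MappingError(f"{path}: expected columns group_id, gene_id")
    return [
        GeneGroup(gid, frozenset(sub["gene_id"]))
        for gid, sub in df.groupby("group_id", sort=True)
    ]


def write_gene_groups(groups: Iterable[GeneGroup], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("group_id\tgene_id\n")
        for g in sorted(groups, key=lambda g: g.group_id):
            for gene in sorted(g.members):
                fh.write(f"{g.group_id}\t{gene}\n")


def read_gene_list(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {
            line.strip() for line in fh if line.strip() and not line.startswith("#")
        }


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(genes):
            fh.write(gene + "\n")


# --- screen results ---------------------------------------------------------


def write_screen_result(result: ScreenResult, outdir: str | Path) -> None:
    """Per-Df TSV plus a summary JSON, deterministically ordered."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    eff = {(e.df_id, e.stage, e.transgene): e for e in result.effects}
    rows = []
    for call in sorted(result.calls, key=lambda c: c.df_id):
        row: dict[str, object] = {"df_id": call.df_id}
        for tg in ("common", "rare"):
            e = eff.get((call.df_id, "primary", tg))
            row[f"fc_{tg}"] = fmt(e.fold_change) if e else ""
            row[f"ecl_{tg}"] = fmt(e.eclosion_ratio) if e else ""
            row[f"call_{tg}"] = e.call if e else ""
        row["category"] = call.category
        row["detail"] = call.differential_detail or ""
        row["stage_passed"] = call.stage_passed
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "modifier_calls.tsv", sep="\t", index=False)

    summary = {}
    for s in (result.primary_summary, result.secondary_summary):
        summary[s.stage] = {
            "n_dfs_tested": s.n_dfs_tested,
            "n_enhancer": s.n_enhancer,
            "n_suppressor": s.n_suppressor,
            "n_differential": s.n_differential,
            "n_not_modifier": s.n_not_modifier,
            "n_needs_review": s.n_needs_review,
            "percentages": s.percentages(),
            "percentages_int": s.percentages_int(),
        }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


# --- configuration ----------------------------------------------------------


def load_config(path: str | Path | None) -> dict:
    """YAML or JSON config file -> dict (empty when no path is given)."""
    if path is None:
        return {}
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text) or {}
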