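"""End-to-end analysis orchestration and report rendering.

``analyze_dataset`` chains classification, CCD extraction, summary
tables, fate-proportion tables, growth curves, and the standard group
comparisons into a single :class:`AnalysisReport`; ``render_report``
writes it as machine-readable JSON and human-readable Markdown.  The
report is deterministic for a fixed input (no timestamps), so reruns
are byte-identical.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .ccd_stats import (
    DivisionRecord,
    TestResult,
    compute_ccds,
    fate_proportions_by_generation,
    growth_curve,
    records_frame,
    summarize_ccd,
)
from .fates import (
    DEFAULT_DIVISION_THRESHOLD_H,
    ColonyClass,
    ColonyClassification,
    DivisionType,
    classify_dataset,
)
from .lineage_io import DEFAULT_FRAME_INTERVAL_H, ColonyDataset, read_lineage_table


@dataclass
class AnalysisReport:
    """All derived tables for one lineage dataset."""

    census: dict[str, int]
    division_type_counts: dict[str, dict[str, int]]
    ccd_by_class: pd.DataFrame
    ccd_by_type: pd.DataFrame
    ccd_by_aligned_generation: pd.DataFrame
    ccd_first_generations: pd.DataFrame
    fate_tables: dict[str, pd.DataFrame]
    growth_curves: pd.DataFrame
    tests: list[TestResult]
    provenance: dict
    records: list[DivisionRecord] = field(repr=False, default_factory=list)
    classifications: dict[str, ColonyClassification] = field(
        repr=False, default_factory=dict
    )


def _ccd_values(records, colony_class, division_type=None):
    return [
        r.ccd
        for r in records
        if r.ccd is not None
        and r.division_type is not DivisionType.UNKNOWN
        and r.colony_class is colony_class
        and (division_type is None or r.division_type is division_type)
    ]


def _growth_table(dataset: ColonyDataset, classifications) -> pd.DataFrame:
    rows = []
    for cls_value in ("EXPANDING", "DIFFERENTIATING"):
        curves = [
            growth_curve(tree)
            for tree in dataset
            if classifications[tree.colony_id].colony_class.value == cls_value
        ]
        if not curves:
            continue
        merged: dict[int, list[int]] = {}
        for c in curves:
            for g, n in zip(c["generation"], c["n_cells"]):
                merged.setdefault(int(g), []).append(int(n))
        for g in sorted(merged):
            counts = merged[g]
            rows.append(
                {
                    "colony_class": cls_value,
                    "generation": g,
                    "mean_cells": float(np.mean(counts)),
                    "n_colonies": len(counts),
                }
            )
    return pd.DataFrame(
        rows, columns=["colony_class", "generation", "mean_cells", "n_colonies"]
    )


def analyze_dataset(
    dataset: ColonyDataset,
    threshold: float = DEFAULT_DIVISION_THRESHOLD_H,
    source: str | None = None,
    first_k: int = 3,
) -> AnalysisReport:
    """Run the full lineage analysis on an in-memory dataset."""
    if len(dataset) == 0:
        raise ValueError("no colonies in input")
    classifications = classify_dataset(dataset, threshold)
    census = {c.value: 0 for c in ColonyClass}
    for cls in classifications.values():
        census[cls.colony_class.value] += 1

    records = compute_ccds(dataset, classifications)
    type_counts: dict[str, dict[str, int]] = {}
    for r in records:
        by_class = type_counts.setdefault(r.colony_class.value, {})
        by_class[r.division_type.value] = by_class.get(r.division_type.value, 0) + 1

    tests: list[TestResult] = []
    exp = _ccd_values(records, ColonyClass.EXPANDING)
    dif = _ccd_values(records, ColonyClass.DIFFERENTIATING)
    if exp and dif:
        from .ccd_stats import compare_groups

        tests.append(compare_groups([exp, dif], "ranksum"))
        for dt in (DivisionType.PP, DivisionType.PD, DivisionType.DD):
            e = _ccd_values(records, ColonyClass.EXPANDING, dt)
            d = _ccd_values(records, ColonyClass.DIFFERENTIATING, dt)
            if e and d:
                tests.append(compare_groups([e, d], "ranksum"))
        for cls in (ColonyClass.EXPANDING, ColonyClass.DIFFERENTIATING):
            by_type = [
                _ccd_values(records, cls, dt)
                for dt in (DivisionType.PP, DivisionType.PD, DivisionType.DD)
            ]
            if all(len(g) >= 2 for g in by_type):
                tests.append(
                    compare_groups(by_type, "kruskal_dunn", labels=["PP", "PD", "DD"])
                )

    fate_tables = {
        "forward_expanding": fate_proportions_by_generation(
            dataset, classifications, "forward", ColonyClass.EXPANDING
        ),
        "td_differentiating": fate_proportions_by_generation(
            dataset, classifications, "td", ColonyClass.DIFFERENTIATING
        ),
        "fo_expanding": fate_proportions_by_generation(
            dataset, classifications, "fo", ColonyClass.EXPANDING
        ),
    }

    provenance = {
        "source": source,
        "threshold_h": threshold,
        "frame_interval_h": dataset.frame_interval,
        "donor_id": dataset.donor_id,
        "n_colonies": len(dataset),
        "n_cells": dataset.n_cells,
        "n_divisions": dataset.n_divisions,
        "package": "clonekinetics",
        "version": __version__,
    }

    return AnalysisReport(
        census=census,
        division_type_counts=type_counts,
        ccd_by_class=summarize_ccd(records, "colony_class"),
        ccd_by_type=summarize_ccd(records, "division_type"),
        ccd_by_aligned_generation=summarize_ccd(records, "aligned_generation"),
        ccd_first_generations=summarize_ccd(records, "first_k_generations", k=first_k),
        fate_tables=fate_tables,
        growth_curves=_growth_table(dataset, classifications),
        tests=tests,
        provenance=provenance,
        records=records,
        classifications=classifications,
    )


def run_analysis(
    lineage_path: str | Path,
    threshold: float = DEFAULT_DIVISION_THRESHOLD_H,
    frame_interval: float = DEFAULT_FRAME_INTERVAL_H,
    first_k: int = 3,
) -> AnalysisReport:
    """Read a lineage table and analyze it."""
    dataset = read_lineage_table(lineage_path, frame_interval=frame_interval)
    return analyze_dataset(
        dataset, threshold=threshold, source=str(lineage_path), first_k=first_k
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _clean(obj):
    if isinstance(obj, float) and math.isnan(obj):
        return None
    if isinstance(obj, dict):
        return {k: _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return _clean(float(obj))
    return obj


def _frame_records(df: pd.DataFrame) -> list[dict]:
    return _clean(df.to_dict(orient="records"))


def _test_dict(t: TestResult) -> dict:
    d = {
        "method": t.method,
        "statistic": t.statistic,
        "p_value": t.p_value,
        "group_sizes": list(t.group_sizes),
    }
    if t.details:
        d["details"] = t.details
    if t.pairwise:
        d["pairwise"] = [_test_dict(p) for p in t.pairwise]
    return _clean(d)


def report_to_dict(report: AnalysisReport) -> dict:
    return {
        "census": report.census,
        "division_type_counts": report.division_type_counts,
        "ccd_by_class": _frame_records(report.ccd_by_class),
        "ccd_by_type": _frame_records(report.ccd_by_type),
        "ccd_by_aligned_generation": _frame_records(report.ccd_by_aligned_generation),
        "ccd_first_generations": _frame_records(report.ccd_first_generations),
        "fate_tables": {
            k: _frame_records(v) for k, v in report.fate_tables.items()
        },
        "growth_curves": _frame_records(report.growth_curves),
        "tests": [_test_dict(t) for t in report.tests],
        "provenance": _clean(report.provenance),
    }


def _md_table(rows: list[dict]) -> str:
    if not rows:
        return "_no data_\n"
    cols = list(rows[0].keys())

    def fmt(v):
        if v is None:
            return ""
        if isinstance(v, float):
            return f"{v:.4g}"
        return str(v)

    lines = [
        "| " + " | ".join(cols) + " |",
        "| " + " | ".join("---" for _ in cols) + " |",
    ]
    for r in rows:
        lines.append("| " + " | ".join(fmt(r.get(c)) for c in cols) + " |")
    return "\n".join(lines) + "\n"


def markdown_from_dict(d: dict) -> str:
    """Render a report dictionary as Markdown."""
    parts = ["# Lineage analysis report\n"]
    parts.append("## Colony census\n")
    parts.append(
        _md_table([{"colony_class": k, "n": v} for k, v in d["census"].items()])
    )
    parts.append("\n## Division outcomes\n")
    outcome_rows = []
    for cls, counts in d["division_type_counts"].items():
        row = {"colony_class": cls}
        row.update(counts)
        outcome_rows.append(row)
    parts.append(_md_table(outcome_rows))
    parts.append("\n## Cell cycle durations\n")
    parts.append("\n### By colony class\n")
    parts.append(_md_table(d["ccd_by_class"]))
    parts.append("\n### By division type\n")
    parts.append(_md_table(d["ccd_by_type"]))
    parts.append("\n### By backward-aligned generation\n")
    parts.append(_md_table(d["ccd_by_aligned_generation"]))
    parts.append("\n### First generations only\n")
    parts.append(_md_table(d["ccd_first_generations"]))
    parts.append("\n## Fate proportions by generation\n")
    for name, rows in d["fate_tables"].items():
        parts.append(f"\n### {name}\n")
        parts.append(_md_table(rows))
    parts.append("\n## Growth curves\n")
    parts.append(_md_table(d["growth_curves"]))
    parts.append("\n## Statistical tests\n")
    test_rows = [
        {
            "method": t["method"],
            "statistic": t["statistic"],
            "p_value": t["p_value"],
            "group_sizes": "/".join(str(s) for s in t["group_sizes"]),
        }
        for t in d["tests"]
    ]
    parts.append(_md_table(test_rows))
    parts.append("\n## Provenance\n")
    parts.append(
        _md_table([{"key": k, "value": v} for k, v in d["provenance"].items()])
    )
    return "\n".join(parts)


def render_report(report: AnalysisReport, out_dir: str | Path) -> dict[str, Path]:
    """Write ``report.json`` and ``report.md`` under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    d = report_to_dict(report)
    json_path = out_dir / "report.json"
    json_path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")
    md_path = out_dir / "report.md"
    md_path.write_text(markdown_from_dict(d))
    return {"json": json_path, "markdown": md_path}


def fates_frame(classifications: Mapping[str, ColonyClassification]) -> pd.DataFrame:
    """Per-cell fate table: ``colony_id,cell_id,fate``."""
    rows = [
        {"colony_id": cid, "cell_id": cell_id, "fate": fate.value}
        for cid, cls in classifications.items()
        for cell_id, fate in cls.fates.items()
    ]
    return pd.DataFrame(rows, columns=["colony_id", "cell_id", "fate"])


def divisions_frame(report: AnalysisReport) -> pd.DataFrame:
    """Per-division table with type, generations, and colony class."""
    return records_frame(report.records)
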