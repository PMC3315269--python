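"""Readers and writers for indicator tables and results, plus the report.

All tabular interchange is CSV (comma separator, ``.`` decimal point,
UTF-8, header row). Indicator tables have a leading ``unit_id`` column and
one column per indicator; empty cells are missing values. The results
writer emits scores at 12 significant digits so a write/read round trip
reproduces every score bit-exactly from the decimal text.
"""

from __future__ import annotations

import csv
import string
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ScreeningConfig
from .errors import InputDataError
from .model import (
    POLLUTION_BURDEN,
    POPULATION_CHARACTERISTICS,
    ComponentSpec,
    ExcludedUnit,
    IndicatorValueMatrix,
    ReferenceDistribution,
    ScoreCard,
)

RESULT_FIXED_COLUMNS = (
    "pollution_burden",
    "population_characteristics",
    "cumulative_impact",
    "rank",
)


def read_indicator_table(path: str | Path) -> IndicatorValueMatrix:
    """Read a units x indicators CSV into a matrix, validating as it goes.

    Fail-fast policy: the first malformed feature (missing ``unit_id``
    header, duplicate unit id, non-numeric cell) raises an
    ``InputDataError`` naming the offending row/column.
    """
    path = Path(path)
    if not path.exists():
        raise InputDataError(f"indicator table not found: {path}")
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as e:
        raise InputDataError(f"cannot parse {path} as CSV: {e}") from e
    if df.columns.size == 0 or df.columns[0] != "unit_id":
        raise InputDataError(f"{path}: first column must be 'unit_id', got {list(df.columns[:1])}")
    if df.columns.size < 2:
        raise InputDataError(f"{path}: no indicator columns found")
    unit_ids = df["unit_id"].astype(str).tolist()
    dupes = sorted({u for u in unit_ids if unit_ids.count(u) > 1})
    if dupes:
        raise InputDataError(f"{path}: duplicate unit_id(s): {', '.join(dupes)}")
    indicator_ids = [str(c) for c in df.columns[1:]]
    values = np.full((len(unit_ids), len(indicator_ids)), np.nan)
    for j, col in enumerate(indicator_ids):
        for i, cell in enumerate(df[col].tolist()):
            cell = cell.strip()
            if cell == "":
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise InputDataError(
                    f"{path}: non-numeric cell {cell!r} at row {i + 2} "
                    f"(unit {unit_ids[i]!r}), column {col!r}"
                ) from None
    return IndicatorValueMatrix(unit_ids=unit_ids, indicator_ids=indicator_ids, values=values)


def references_from_matrix(matrix: IndicatorValueMatrix) -> dict[str, ReferenceDistribution]:
    """Build one reference distribution per column from a (reference) table."""
    return {
        ind: ReferenceDistribution.from_values(ind, matrix.column(ind))
        for ind in matrix.indicator_ids
    }


def _fmt(x: float) -> str:
    """12 significant digits; integers render without trailing zeros."""
    return format(float(x), ".12g")


def anonymize_ids(unit_ids: list[str]) -> dict[str, str]:
    """Map unit ids to sequential letters A, B, ..., Z, AA, AB, ... (rank order)."""
    out = {}
    letters = string.ascii_uppercase
    for k, u in enumerate(unit_ids):
        label = ""
        k2 = k
        while True:
            label = letters[k2 % 26] + label
            k2 = k2 // 26 - 1
            if k2 < 0:
                break
        out[u] = label
    return out


def write_results(
    ranked: list[tuple[int, ScoreCard]],
    path: str | Path,
    specs: dict[str, ComponentSpec],
    anonymize: bool = False,
) -> None:
    """Write the ranked score table as CSV.

    Columns: unit_id, one per indicator score, one per component score,
    the two group sums, cumulative_impact, rank.
    """
    if not ranked:
        raise InputDataError("no score cards to write")
    cards = [c for _, c in ranked]
    indicator_ids = list(cards[0].indicator_scores)
    component_ids = list(cards[0].component_scores)
    name_map = anonymize_ids([c.unit_id for c in cards]) if anonymize else None
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["unit_id", *indicator_ids, *component_ids, *RESULT_FIXED_COLUMNS]
        )
        for rank, c in ranked:
            row = [name_map[c.unit_id] if name_map else c.unit_id]
            row += [
                "" if c.indicator_scores[i] is None else str(c.indicator_scores[i])
                for i in indicator_ids
            ]
            row += [_fmt(c.component_scores[cid]) for cid in component_ids]
            row += [
                _fmt(c.pollution_burden),
                _fmt(c.population_characteristics),
                _fmt(c.cumulative_impact),
                str(rank),
            ]
            w.writerow(row)


def write_excluded(excluded: list[ExcludedUnit], path: str | Path) -> None:
    """Companion CSV of units dropped from ranking, with reason codes."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["unit_id", "reason_code", "detail"])
        for e in excluded:
            w.writerow([e.unit_id, e.reason_code, e.detail])


def read_results(path: str | Path, component_ids: list[str]) -> pd.DataFrame:
    """Read back a results CSV written by :func:`write_results`."""
    path = Path(path)
    if not path.exists():
        raise InputDataError(f"results file not found: {path}")
    df = pd.read_csv(path)
    if df.empty:
        raise InputDataError(f"{path}: results table is empty")
    missing = [c for c in ("unit_id", *RESULT_FIXED_COLUMNS) if c not in df.columns]
    if missing:
        raise InputDataError(f"{path}: missing result columns: {', '.join(missing)}")
    for cid in component_ids:
        if cid not in df.columns:
            raise InputDataError(f"{path}: missing component column {cid!r}")
    return df


# ---------------------------------------------------------------------------
# Ranked shaded report
# ---------------------------------------------------------------------------

class ScreeningReport:
    """Ranked table of component and cumulative scores with shading.

    One row per unit, ordered from highest to lowest cumulative impact.
    Shading intensity is per column: score divided by that column's maximum
    possible value, so a 10/10 exposures cell and a 3/3 sensitive-
    populations cell are equally dark.
    """

    def __init__(self, config: ScreeningConfig, rows: list[dict]):
        self.config = config
        self.rows = rows  # each: unit, rank, scores {col: (value, intensity)}
        self.columns = [
            *config.component_specs,
            POLLUTION_BURDEN,
            POPULATION_CHARACTERISTICS,
            "cumulative_impact",
        ]

    _TITLES = {
        POLLUTION_BURDEN: "Pollution burden",
        POPULATION_CHARACTERISTICS: "Population characteristics",
        "cumulative_impact": "Cumulative impact",
    }

    def column_title(self, col: str) -> str:
        return self._TITLES.get(col, col.replace("_", " ").capitalize())

    def to_text(self) -> str:
        nd_comp = self.config.round_display.get("component", 1)
        nd_cum = self.config.round_display.get("cumulative", 0)
        headers = ["Unit", "Rank", *(self.column_title(c) for c in self.columns)]
        body: list[list[str]] = []
        for r in self.rows:
            cells = [r["unit"], str(r["rank"])]
            for col in self.columns:
                v, _ = r["scores"][col]
                nd = nd_cum if col == "cumulative_impact" else nd_comp
                cells.append(f"{v:.{nd}f}" if nd > 0 else f"{v:.0f}")
            body.append(cells)
        widths = [max(len(h), *(len(b[k]) for b in body)) for k, h in enumerate(headers)]
        lines = [
            "  ".join(h.ljust(widths[k]) for k, h in enumerate(headers)),
            "  ".join("-" * w for w in widths),
        ]
        lines += ["  ".join(c.ljust(widths[k]) for k, c in enumerate(cells)) for cells in body]
        return "\n".join(lines) + "\n"

    def to_html(self) -> str:
        nd_comp = self.config.round_display.get("component", 1)
        nd_cum = self.config.round_display.get("cumulative", 0)
        head_cells = "".join(
            f"<th>{self.column_title(c)}</th>" for c in self.columns
        )
        rows_html = []
        for r in self.rows:
            cells = [f"<td>{r['unit']}</td>", f"<td>{r['rank']}</td>"]
            for col in self.columns:
                v, intensity = r["scores"][col]
                nd = nd_cum if col == "cumulative_impact" else nd_comp
                # darker = higher score; keep text legible on dark cells
                alpha = round(0.85 * intensity, 3)
                fg = "#fff" if intensity > 0.6 else "#000"
                cells.append(
                    f'<td style="background: rgba(178, 24, 43, {alpha}); '
                    f'color: {fg}">{v:.{nd}f}</td>'
                )
            rows_html.append("<tr>" + "".join(cells) + "</tr>")
        return (
            "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
            "<title>Cumulative impact screening report</title>"
            "<style>body{font-family:sans-serif}table{border-collapse:collapse}"
            "td,th{border:1px solid #999;padding:4px 8px;text-align:right}"
            "td:first-child,th:first-child{text-align:left}</style></head><body>"
            "<h1>Cumulative impact screening report</h1>"
            f"<table><thead><tr><th>Unit</th><th>Rank</th>{head_cells}</tr></thead>"
            "<tbody>" + "\n".join(rows_html) + "</tbody></table></body></html>\n"
        )


def render_report(
    ranked: list[tuple[int, ScoreCard]],
    config: ScreeningConfig,
    anonymize: bool = False,
) -> ScreeningReport:
    """Build the ranked shaded report from already-ranked score cards."""
    if not ranked:
        raise InputDataError("no score cards to report")
    specs = config.component_specs
    max_burden = sum(s.max_score for s in specs.values() if s.group == POLLUTION_BURDEN)
    max_popchar = sum(
        s.max_score for s in specs.values() if s.group == POPULATION_CHARACTERISTICS
    )
    col_max = {cid: float(s.max_score) for cid, s in specs.items()}
    col_max[POLLUTION_BURDEN] = float(max_burden)
    col_max[POPULATION_CHARACTERISTICS] = float(max_popchar)
    col_max["cumulative_impact"] = float(max_burden * max_popchar)
    name_map = anonymize_ids([c.unit_id for _, c in ranked]) if anonymize else None
    rows = []
    for rank, c in ranked:
        scores: dict[str, tuple[float, float]] = {}
        for cid in specs:
            v = c.component_scores[cid]
            scores[cid] = (v, v / col_max[cid])
        scores[POLLUTION_BURDEN] = (
            c.pollution_burden,
            c.pollution_burden / col_max[POLLUTION_BURDEN],
        )
        scores[POPULATION_CHARACTERISTICS] = (
            c.population_characteristics,
            c.population_characteristics / col_max[POPULATION_CHARACTERISTICS],
        )
        scores["cumulative_impact"] = (
            c.cumulative_impact,
            c.cumulative_impact / col_max["cumulative_impact"],
        )
        rows.append(
            {
                "unit": name_map[c.unit_id] if name_map else c.unit_id,
                "rank": rank,
                "scores": scores,
            }
        )
    return ScreeningReport(config=config, rows=rows)
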