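"""Traffic-light matrix reporting.

Each ranked candidate-indication pair becomes one matrix row; each of the
nine TPP criteria becomes a colored cell: met preferred (dark green), met
minimum (light green), partially met minimum (yellow), did not meet minimum
(red), not yet known (grey). CSV is the canonical, lossless machine output;
HTML and SVG are presentation renderings with a legend.
"""

from __future__ import annotations

import csv
import html
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .errors import JoinError
from .registry import PHASE_ORDER, Indication, MatchLevel, Phase
from .tpp_engine import MatchProfile, Rank, RankedCandidate, ScoringScheme

__all__ = [
    "COLOR_BY_LEVEL",
    "DEFAULT_COLOR_HEX",
    "LEGEND",
    "MatrixCell",
    "MatrixRow",
    "TrafficLightMatrix",
    "build_matrix",
    "parse_matrix_csv",
    "render",
]

#: Pure function MatchLevel -> color token (bijective over the five levels).
COLOR_BY_LEVEL: dict[MatchLevel, str] = {
    MatchLevel.MET_PREFERRED: "dark_green",
    MatchLevel.MET_MINIMUM: "light_green",
    MatchLevel.PARTIALLY_MET: "yellow",
    MatchLevel.NOT_MET: "red",
    MatchLevel.UNKNOWN: "grey",
}

#: Presentation hex values; overridable at render time.
DEFAULT_COLOR_HEX: dict[str, str] = {
    "dark_green": "#1a7a3c",
    "light_green": "#8fd08f",
    "yellow": "#f2d21f",
    "red": "#d93025",
    "grey": "#b3b3b3",
}

LEGEND: tuple[tuple[str, str], ...] = (
    ("dark_green", "met preferred"),
    ("light_green", "met minimum"),
    ("yellow", "partially met minimum"),
    ("red", "did not meet minimum"),
    ("grey", "not yet known"),
)


@dataclass(frozen=True)
class MatrixCell:
    label: str
    criterion_id: str
    color: str
    level: MatchLevel


@dataclass(frozen=True)
class MatrixRow:
    label: str
    candidate_id: str
    indication: Indication
    phase: Phase
    rank: Rank
    total_score: float
    cells: tuple[MatrixCell, ...]


@dataclass(frozen=True)
class TrafficLightMatrix:
    criterion_ids: tuple[str, ...]
    rows: tuple[MatrixRow, ...]


def build_matrix(
    profiles: Mapping[tuple[str, str], MatchProfile] | Sequence[MatchProfile],
    ranked: Sequence[RankedCandidate],
    scheme: ScoringScheme,
) -> TrafficLightMatrix:
    """Join profiles with ranked rows into a deterministic matrix model.

    Rows are ordered by phase descending, then total score descending, then
    label alphabetically. Every profile must have a matching ranked entry.
    """
    if not isinstance(profiles, Mapping):
        profiles = {(p.candidate_id, p.indication.value): p for p in profiles}
    ranked_by_key = {(rc.candidate_id, rc.indication.value): rc for rc in ranked}
    rows: list[MatrixRow] = []
    for key, profile in profiles.items():
        rc = ranked_by_key.get(key)
        if rc is None:
            raise JoinError(f"profile {key} has no ranked entry")
        label = f"{rc.name} ({rc.indication.value})"
        cells = tuple(
            MatrixCell(label, cid, COLOR_BY_LEVEL[profile.levels[cid]], profile.levels[cid])
            for cid in scheme.criterion_ids
        )
        rows.append(
            MatrixRow(label, rc.candidate_id, rc.indication, rc.phase, rc.rank, rc.total_score, cells)
        )
    rows.sort(key=lambda r: (-PHASE_ORDER[r.phase], -r.total_score, r.label))
    return TrafficLightMatrix(scheme.criterion_ids, tuple(rows))


# --------------------------------------------------------------------------
# Renderers

_MATRIX_CSV_HEADER = (
    "label",
    "candidate_id",
    "indication",
    "phase",
    "rank",
    "total_score",
    "criterion_id",
    "level",
    "color",
)


def _render_csv(matrix: TrafficLightMatrix, path: Path) -> None:
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_MATRIX_CSV_HEADER)
        for row in matrix.rows:
            for cell in row.cells:
                writer.writerow(
                    [
                        row.label,
                        row.candidate_id,
                        row.indication.value,
                        row.phase.value,
                        row.rank.value,
                        repr(row.total_score),
                        cell.criterion_id,
                        cell.level.value,
                        cell.color,
                    ]
                )


def parse_matrix_csv(path: str | Path) -> TrafficLightMatrix:
    """Inverse of the CSV renderer: rebuild the matrix model losslessly."""
    rows: list[MatrixRow] = []
    criterion_ids: list[str] = []
    current: list[MatrixCell] = []
    meta: tuple | None = None

    def flush() -> None:
        if meta is not None:
            rows.append(MatrixRow(*meta, tuple(current)))

    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for raw in reader:
            key = (raw["candidate_id"], raw["indication"])
            row_meta = (
                raw["label"],
                raw["candidate_id"],
                Indication(raw["indication"]),
                Phase(raw["phase"]),
                Rank(raw["rank"]),
                float(raw["total_score"]),
            )
            if meta is None or (meta[1], meta[2].value) != key:
                flush()
                meta = row_meta
                current = []
            if raw["criterion_id"] not in criterion_ids:
                criterion_ids.append(raw["criterion_id"])
            current.append(
                MatrixCell(
                    raw["label"], raw["criterion_id"], raw["color"], MatchLevel(raw["level"])
                )
            )
    flush()
    n = len(rows[0].cells) if rows else len(criterion_ids)
    return TrafficLightMatrix(tuple(criterion_ids[:n] or criterion_ids), tuple(rows))


def _legend_html(colors: Mapping[str, str]) -> str:
    items = "".join(
        f'<li><span class="swatch" style="background:{colors[token]}"></span> '
        f"{token}: {html.escape(meaning)}</li>"
        for token, meaning in LEGEND
    )
    return f'<ul class="legend">{items}</ul>'


def _render_html(
    matrix: TrafficLightMatrix, path: Path, colors: Mapping[str, str]
) -> None:
    head = "".join(f"<th>{html.escape(cid)}</th>" for cid in matrix.criterion_ids)
    body_rows = []
    for row in matrix.rows:
        cells = "".join(
            f'<td style="background:{colors[cell.color]}" title="{cell.level.value}"></td>'
            for cell in row.cells
        )
        body_rows.append(
            f"<tr><td>{html.escape(row.label)}</td><td>{row.phase.value}</td>"
            f"{cells}<td class='rank'>{row.rank.value}</td></tr>"
        )
    doc = (
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        "<title>TPP match matrix</title><style>"
        "table{border-collapse:collapse}td,th{border:1px solid #444;"
        "padding:4px 8px;min-width:1.5em}.swatch{display:inline-block;"
        "width:1em;height:1em;border:1px solid #444;margin-right:.4em}"
        "</style></head><body><h1>TPP match matrix</h1>"
        f"<table><thead><tr><th>candidate</th><th>phase</th>{head}<th>rank</th>"
        f"</tr></thead><tbody>{''.join(body_rows)}</tbody></table>"
        f"<h2>Legend</h2>{_legend_html(colors)}</body></html>\n"
    )
    path.write_text(doc, encoding="utf-8")


def _render_svg(
    matrix: TrafficLightMatrix, path: Path, colors: Mapping[str, str]
) -> None:
    cell, label_w, header_h = 24, 260, 120
    width = label_w + cell * (len(matrix.criterion_ids) + 1) + 10
    legend_h = 20 * len(LEGEND) + 30
    height = header_h + cell * len(matrix.rows) + legend_h + 10
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}" '
        f'font-family="sans-serif" font-size="11">'
    ]
    for j, cid in enumerate(matrix.criterion_ids + ("rank",)):
        x = label_w + j * cell + cell / 2
        parts.append(
            f'<text x="{x}" y="{header_h - 6}" transform="rotate(-60 {x} {header_h - 6})">'
            f"{html.escape(cid)}</text>"
        )
    for i, row in enumerate(matrix.rows):
        y = header_h + i * cell
        parts.append(f'<text x="4" y="{y + cell - 8}">{html.escape(row.label)}</text>')
        for j, c in enumerate(row.cells):
            parts.append(
                f'<rect x="{label_w + j * cell}" y="{y}" width="{cell}" height="{cell}" '
                f'fill="{colors[c.color]}" stroke="#444"/>'
            )
        parts.append(
            f'<text x="{label_w + len(row.cells) * cell + 4}" y="{y + cell - 8}">'
            f"{row.rank.value}</text>"
        )
    y0 = header_h + cell * len(matrix.rows) + 20
    parts.append(f'<text x="4" y="{y0}">Legend:</text>')
    for k, (token, meaning) in enumerate(LEGEND):
        y = y0 + 14 + k * 20
        parts.append(
            f'<rect x="4" y="{y - 10}" width="14" height="14" fill="{colors[token]}" stroke="#444"/>'
            f'<text x="24" y="{y + 2}">{token}: {html.escape(meaning)}</text>'
        )
    parts.append("</svg>\n")
    path.write_text("".join(parts), encoding="utf-8")


def render(
    matrix: TrafficLightMatrix,
    format: str,
    path: str | Path,
    colors: Mapping[str, str] | None = None,
) -> Path:
    """Render the matrix to ``csv`` (canonical), ``html`` or ``svg``."""
    path = Path(path)
    colors = dict(DEFAULT_COLOR_HEX, **(colors or {}))
    if format == "csv":
        _render_csv(matrix, path)
    elif format == "html":
        _render_html(matrix, path, colors)
    elif format == "svg":
        _render_svg(matrix, path, colors)
    else:
        raise ValueError(f"unsupported render format {format!r} (expected csv, html or svg)")
    return path
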