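"""Totals, percentage shares, and deterministic table rendering.

Rounding convention (matches the published tables cell-for-cell): lives
saved are rounded to integers, shares and rates to one decimal, always
nearest with ties away from zero. Shares are computed from UNROUNDED
channel values against the unrounded total, then rounded for display
(e.g. 6,433 of 34,477 prints as 18.7).
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .engine import LivesSavedResult
from .scenarios import MissedOpportunityRow


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round to ``ndigits`` decimals, ties away from zero (the convention
    of the published tables, unlike banker's rounding)."""
    scale = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


@dataclass(frozen=True)
class ShareTable:
    """Per-channel lives saved with percentage shares of the total.

    ``rows`` hold (channel, lives saved rounded to integer, share percent
    to one decimal); the total row is the rounded sum of the unrounded
    channel values.
    """

    rows: tuple[tuple[str, int, float], ...]
    total: int
    total_share: float = 100.0


def shares(values: Mapping[str, float]) -> ShareTable:
    """Percentage share per channel: ``100 x value / sum(values)`` from
    unrounded inputs, one-decimal rounding. Negative values yield negative
    shares. Raises on an all-zero input (empty share base)."""
    total = sum(values.values())
    if total == 0.0:
        raise ValueError("empty share base: channel values sum to zero")
    rows = tuple(
        (ch, int(round_half_away(v)), round_half_away(100.0 * v / total, 1))
        for ch, v in values.items()
    )
    return ShareTable(rows=rows, total=int(round_half_away(total)))


def aggregate_fixture(table: pd.DataFrame, column: str) -> int:
    """Integer sum of a printed lives-saved column over the data rows
    (negatives included, NA rows skipped, the printed total row excluded)."""
    if column not in table.columns:
        raise KeyError(f"unknown column {column!r}; have {list(table.columns)}")
    data = table[table["intervention"] != "Total"] if "intervention" in table.columns else table
    return int(data[column].dropna().sum())


def coverage_change(table: pd.DataFrame, row: str) -> Optional[float]:
    """Endline minus baseline coverage for the named fixture row, to one
    decimal; ``None`` where either anchor is NA (channel disabled)."""
    match = table[table["intervention"] == row]
    if match.empty:
        raise KeyError(f"no fixture row named {row!r}")
    rec = match.iloc[0]
    if pd.isna(rec["baseline_coverage"]) or pd.isna(rec["endline_coverage"]):
        return None
    return round_half_away(float(rec["endline_coverage"]) - float(rec["baseline_coverage"]), 1)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

Renderable = Union[LivesSavedResult, ShareTable, Sequence[MissedOpportunityRow]]


def _result_frame(result: LivesSavedResult) -> pd.DataFrame:
    return result.to_frame()


def _share_frame(table: ShareTable) -> pd.DataFrame:
    rows = [{"channel": ch, "lives_saved": v, "share": s} for ch, v, s in table.rows]
    rows.append({"channel": "Total", "lives_saved": table.total, "share": table.total_share})
    return pd.DataFrame(rows, columns=["channel", "lives_saved", "share"])


def _mot_frame(rows: Sequence[MissedOpportunityRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "intervention_id": r.intervention_id,
                "baseline_coverage": r.baseline_coverage,
                "lives_saved_neonatal": r.deaths_averted_neonatal,
                "lives_saved_1to59m": r.deaths_averted_1to59m,
                "lives_saved_total": r.total,
            }
            for r in rows
        ],
        columns=[
            "intervention_id",
            "baseline_coverage",
            "lives_saved_neonatal",
            "lives_saved_1to59m",
            "lives_saved_total",
        ],
    )


def _to_frame(obj: Renderable) -> pd.DataFrame:
    if isinstance(obj, LivesSavedResult):
        return _result_frame(obj)
    if isinstance(obj, ShareTable):
        return _share_frame(obj)
    return _mot_frame(list(obj))


def render(obj: Renderable, format: str = "csv", path=None) -> str:
    """Render a result, share table, or missed-opportunity ranking.

    ``csv`` (canonical machine format, plain integers, no thousands
    separators), ``json`` (records), or ``text`` (human-readable; share
    tables print ``value(share)`` and integers carry thousands
    separators). Output is deterministic: fixed row ordering and decimal
    formatting, so equal inputs render to identical bytes.
    """
    df = _to_frame(obj)
    if format == "csv":
        out = df.to_csv(index=False, float_format="%.6f", lineterminator="\n")
    elif format == "json":
        records = json.loads(df.to_json(orient="records", double_precision=6))
        out = json.dumps(records, indent=2, sort_keys=True) + "\n"
    elif format == "text":
        out = _render_text(obj, df)
    else:
        raise ValueError(f"unknown format {format!r}")
    if path is not None:
        Path(path).write_text(out, encoding="utf-8")
    return out


def _render_text(obj: Renderable, df: pd.DataFrame) -> str:
    buf = io.StringIO()
    if isinstance(obj, ShareTable):
        width = max(len(str(c)) for c, _, _ in obj.rows) if obj.rows else 5
        for ch, v, s in obj.rows:
            buf.write(f"{ch:<{width}}  {v:>12,}({s:.1f})\n")
        buf.write(f"{'Total':<{width}}  {obj.total:>12,}({obj.total_share:.1f})\n")
    else:
        buf.write(df.to_string(index=False, float_format=lambda v: f"{v:,.1f}"))
        buf.write("\n")
    return buf.getvalue()
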