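"""Report containers and renderers (plain table, CSV, JSON).

Numeric rounding happens only here, at render time; the domain modules keep
full precision internally.  CSV and JSON renderings round-trip losslessly
through :func:`report_from_json`.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .chamber import round_half_up

__all__ = ["Report", "render_report", "report_from_json", "REPORT_KINDS"]

REPORT_KINDS = ("design_table", "characterization", "percent_table", "simulation")

#: render-time rounding per report kind: column-suffix → decimals
_ROUNDING = {
    "design_table": {"length_cm": 1, "achieved_resistance": 0, "relative_error": 4},
    "characterization": {"resistance": 0},
    "percent_table": {"R": 2, "E1": 2, "E2": 2},
    "simulation": {},
}


@dataclass(frozen=True)
class Report:
    kind: str
    rows: tuple[Mapping[str, object], ...]
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in REPORT_KINDS:
            raise ValueError(f"unknown report kind {self.kind!r}; expected {REPORT_KINDS}")
        object.__setattr__(self, "rows", tuple(dict(r) for r in self.rows))
        meta = {"tool": "coroflow", "version": __version__, **dict(self.metadata)}
        object.__setattr__(self, "metadata", meta)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.rows))


def _rounded_frame(report: Report) -> pd.DataFrame:
    df = report.to_frame()
    for col in df.columns:
        for suffix, nd in _ROUNDING.get(report.kind, {}).items():
            if col == suffix or col.endswith(suffix):
                df[col] = df[col].map(
                    lambda x: round_half_up(float(x), nd) if pd.notna(x) else x
                )
    return df


def render_report(report: Report, fmt: str = "table") -> str:
    """Render a report as a plain text table, RFC-4180 CSV, or JSON."""
    if fmt == "table":
        df = _rounded_frame(report)
        if df.empty:
            return "(empty report)\n"
        return df.to_string(index=False) + "\n"
    if fmt == "csv":
        df = report.to_frame()
        buf = io.StringIO()
        df.to_csv(buf, index=False, lineterminator="\r\n")
        return buf.getvalue()
    if fmt == "json":
        return json.dumps(
            {"kind": report.kind, "metadata": dict(report.metadata),
             "rows": [dict(r) for r in report.rows]},
            indent=2,
        )
    raise ValueError(f"unknown format {fmt!r}; expected table, csv or json")


def report_from_json(text: str) -> Report:
    data = json.loads(text)
    return Report(kind=data["kind"], rows=tuple(data["rows"]), metadata=data.get("metadata", {}))


def write_report(report: Report, path: str | Path, fmt: str | None = None) -> Path:
    path = Path(path)
    if fmt is None:
        fmt = {".csv": "csv", ".json": "json"}.get(path.suffix.lower(), "table")
    path.write_text(render_report(report, fmt))
    return path
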