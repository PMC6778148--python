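"""HTML/TSV report layer aggregating pipeline outputs."""

from __future__ import annotations

import html

import pandas as pd

_PAGE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>{title}</title>
<style>
body {{ font-family: sans-serif; margin: 2em; }}
table {{ border-collapse: collapse; margin-bottom: 2em; }}
th, td {{ border: 1px solid #999; padding: 4px 8px; text-align: left; }}
th {{ background: #eee; }}
</style></head><body>
<h1>{title}</h1>
{sections}
</body></html>
"""


def _table(df: pd.DataFrame, caption: str) -> str:
    head = "".join(f"<th>{html.escape(str(c))}</th>" for c in df.columns)
    rows = "".join(
        "<tr>" + "".join(f"<td>{html.escape(str(v))}</td>" for v in row) + "</tr>"
        for row in df.itertuples(index=False)
    )
    return (f"<h2>{html.escape(caption)}</h2>"
            f"<table><thead><tr>{head}</tr></thead><tbody>{rows}</tbody></table>")


def build_report(
    qc_table: pd.DataFrame | None = None,
    cluster_table: pd.DataFrame | None = None,
    elisa_table: pd.DataFrame | None = None,
    rounds_table: pd.DataFrame | None = None,
    title: str = "Selection campaign report",
) -> str:
    """Single-page HTML report over whichever pipeline outputs exist."""
    sections = []
    if qc_table is not None:
        counts = qc_table["status"].value_counts()
        summary = pd.DataFrame({
            "status": counts.index,
            "reads": counts.values,
        })
        sections.append(_table(summary, "Read validity"))
        invalid = qc_table[qc_table["status"] == "invalid"]
        if len(invalid):
            reasons = invalid["reasons"].str.split(";").explode().value_counts()
            sections.append(_table(
                pd.DataFrame({"reason": reasons.index, "reads": reasons.values}),
                "Failure reasons"))
    if cluster_table is not None:
        sections.append(_table(cluster_table, "Clusters"))
    if elisa_table is not None:
        sections.append(_table(elisa_table, "Phage-ELISA specificity"))
    if rounds_table is not None:
        sections.append(_table(rounds_table, "Panning enrichment per round"))
    return _PAGE.format(title=html.escape(title), sections="\n".join(sections))
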