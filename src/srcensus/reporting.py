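"""Group-level summary tables of the event census.

Fractions are always emitted with explicit numerator (genes with AS) and
denominator (genes in the group) columns, so a reader can audit any printed
ratio; per-type means are per gene experiencing AS.
"""

from __future__ import annotations

import json
import logging
from typing import Iterable, Mapping

import pandas as pd

from .as_events import EVENT_TYPES, EventCounts
from .io_formats import _atomic_write

log = logging.getLogger(__name__)

UNGROUPED = "UG"


def summarize_by_group(
    counts: Iterable[EventCounts], grouping: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Per-group census: genes, genes with AS, fraction, per-type means.

    Genes absent from ``grouping`` fall into the ``UG`` bucket; group labels
    without any genes are dropped with a warning.
    """
    grouping = dict(grouping or {})
    counts = list(counts)
    rows = []
    seen_groups = set()
    for c in counts:
        group = grouping.get(c.gene_id, UNGROUPED)
        seen_groups.add(group)
        rows.append(
            {
                "group": group,
                "gene_id": c.gene_id,
                "any_AS": c.any_AS,
                **{t: getattr(c, t) for t in EVENT_TYPES},
            }
        )
    empty = sorted(set(grouping.values()) - seen_groups)
    for g in empty:
        log.warning("group %r has no genes; row suppressed", g)
    if not rows:
        return pd.DataFrame(
            columns=["group", "n_genes", "n_genes_AS", "frac_AS",
                     *[f"{t}_per_AS_gene" for t in EVENT_TYPES]]
        )
    df = pd.DataFrame(rows)
    out = []
    for group, sub in df.groupby("group", sort=True):
        n = len(sub)
        n_as = int(sub["any_AS"].sum())
        rec = {
            "group": group,
            "n_genes": n,
            "n_genes_AS": n_as,
            "frac_AS": n_as / n,
        }
        as_rows = sub[sub["any_AS"]]
        for t in EVENT_TYPES:
            rec[f"{t}_per_AS_gene"] = float(as_rows[t].mean()) if n_as else float("nan")
        out.append(rec)
    return pd.DataFrame(out)


def write_group_summary(df: pd.DataFrame, path, format: str = "tsv") -> None:
    if format == "tsv":
        _atomic_write(path, df.to_csv(sep="\t", index=False))
    elif format == "json":
        _atomic_write(path, json.dumps(df.to_dict(orient="records"), indent=1) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_grouping(path) -> dict[str, str]:
    """Read a two-column gene_id -> group TSV (header optional)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: grouping file needs two tab-separated columns")
    first = df.iloc[0]
    if {str(first[0]).lower(), str(first[1]).lower()} & {"gene_id", "group"}:
        df = df.iloc[1:]
    return dict(zip(df[0], df[1]))
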