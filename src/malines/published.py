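"""Published per-group summary statistics, bundled as reference data.

The TSV under ``data/`` carries the per-group summary table of the
P. pacificus mutation-accumulation study this package reimplements: five
groups (strain x bacterial diet), their mutation counts by type,
spectrum summaries, and mean per-site per-generation rates with the
printed 95% confidence half-widths (units: SNV rates x1e-9,
insertion/deletion rates x1e-10). These published values are inputs for
consistency arithmetic (column totals, fold changes between group means,
rate-range extrema) — the raw sequencing data behind them is not needed
for any computation in this package.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .rates import fold_change

__all__ = [
    "load_group_summaries",
    "snv_total",
    "rate_fold_change",
    "rate_range",
]

_RATE_COLUMNS = {"SNV": "u_snv_e9", "insertion": "u_ins_e10", "deletion": "u_del_e10"}


def load_group_summaries() -> pd.DataFrame:
    """The published five-group summary table as a DataFrame."""
    ref = resources.files("malines.data") / "published_group_summaries.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def snv_total(df: pd.DataFrame | None = None) -> int:
    """Total SNV count over all groups."""
    df = load_group_summaries() if df is None else df
    return int(df["n_snv"].sum())


def _select(df: pd.DataFrame, strains=None, diets=None, newly_analyzed=None):
    sel = df
    if strains is not None:
        sel = sel[sel["strain"].isin(strains)]
    if diets is not None:
        sel = sel[sel["diet"].isin(diets)]
    if newly_analyzed is not None:
        sel = sel[sel["newly_analyzed"] == int(newly_analyzed)]
    return sel


def rate_fold_change(
    mtype: str,
    strains=None,
    diets=None,
    decimals: int = 1,
    df: pd.DataFrame | None = None,
) -> float:
    """max/min fold change of mean rates over the selected groups."""
    df = load_group_summaries() if df is None else df
    sel = _select(df, strains=strains, diets=diets)
    return fold_change(list(sel[_RATE_COLUMNS[mtype]]), decimals=decimals)


def rate_range(
    mtype: str,
    strains=None,
    newly_analyzed: bool | None = None,
    df: pd.DataFrame | None = None,
) -> tuple[float, float]:
    """(min, max) of mean rates over the selected groups, printed units."""
    df = load_group_summaries() if df is None else df
    sel = _select(df, strains=strains, newly_analyzed=newly_analyzed)
    col = sel[_RATE_COLUMNS[mtype]]
    return float(col.min()), float(col.max())
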