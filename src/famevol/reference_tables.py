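"""Published reference summaries for the seven-primate actin gene family.

The packaged TSVs hold the published per-group and per-species summary
statistics (divergence d, Ka, Ks, Ka/Ks for 14 orthologous groups, 20
complex groups and 7 species) and the complex-group copy-number matrix.
They let the aggregation and testing layers be exercised end-to-end — and
the published averages and P-values re-derived — without access to the
seven genome assemblies ("replay" mode).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .stats import TTestResult, welch_t_test


def _data_path(name: str):
    return resources.files("famevol") / "data" / name


def load_reference_table1() -> pd.DataFrame:
    """Per-group / per-species d, Ka, Ks, Ka/Ks rows.

    Columns: ``name, block, d, Ka, Ks, KaKs`` with ``block`` one of
    ``orthologous`` (14 rows), ``complex`` (20), ``species`` (7).
    """
    with resources.as_file(_data_path("reference_table1.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_reference_table2() -> tuple[pd.DataFrame, pd.Series]:
    """Complex-group copy-number matrix.

    Returns ``(per_group_rows, published_totals_row)``; the totals row is
    kept separate so bookkeeping can be checked against it.
    """
    with resources.as_file(_data_path("reference_table2.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    totals = df[df["group"] == "Total"].iloc[0]
    groups = df[df["group"] != "Total"].reset_index(drop=True)
    return groups, totals


def replay_block_means(table1: pd.DataFrame | None = None) -> pd.DataFrame:
    """Column means of each block (the table's "Average" rows)."""
    t1 = load_reference_table1() if table1 is None else table1
    return t1.groupby("block")[["d", "Ka", "Ks", "KaKs"]].mean()


def replay_welch_tests(
    table1: pd.DataFrame | None = None,
) -> dict[str, TTestResult]:
    """Welch tests of complex vs orthologous groups on each column."""
    t1 = load_reference_table1() if table1 is None else table1
    cx = t1[t1["block"] == "complex"]
    ortho = t1[t1["block"] == "orthologous"]
    return {
        col: welch_t_test(cx[col].to_numpy(), ortho[col].to_numpy())
        for col in ("d", "Ka", "Ks", "KaKs")
    }
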