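"""Expression aggregation and coefficient-of-variation contrasts.

Microarray expression for a gene is typically measured by several probes
across several biological samples; the expression level of a gene in a
tissue is taken as the mean over all probe x sample values.  Expression
*variability* is then contrasted between orthologs and paralogs with the
coefficient of variation (CV = SD/mean): per tissue, the CV across a tree
group's members (the same gene in different species) is compared with the
CV across a species' gene complement (different genes in one genome).
Low ortholog CVs with high paralog CVs indicate conserved expression of
each gene copy alongside functional diversification among copies.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import welch_t_test

TISSUES = ("brain", "heart", "liver", "kidney", "testis")


def aggregate_probes(raw: pd.DataFrame, tissues: Sequence[str] = TISSUES) -> pd.DataFrame:
    """Collapse a long (gene, probe, sample, tissue, value) table.

    Each gene x tissue cell becomes the mean over every probe and sample;
    genes with no probe in a tissue get ``NaN`` there.  Returns a gene x
    tissue frame restricted to the requested tissues.
    """
    required = {"gene", "probe", "sample", "tissue", "value"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"expression table missing columns {sorted(missing)}")
    bad = set(raw["tissue"]) - set(tissues)
    if bad:
        raise ValueError(f"unknown tissues {sorted(bad)}")
    if (raw["value"] < 0).any() or not np.isfinite(raw["value"]).all():
        raise ValueError("expression values must be finite and non-negative")
    mat = raw.pivot_table(index="gene", columns="tissue", values="value", aggfunc="mean")
    return mat.reindex(columns=list(tissues))


def cv(values: Sequence[float]) -> float:
    """Coefficient of variation: sample SD divided by the mean."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("CV needs at least 2 values")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero-mean values")
    return float(arr.std(ddof=1) / mean)


def _cell_cvs(
    expr: pd.DataFrame, cells: Mapping[str, list[str]], tissue: str
) -> pd.Series:
    """CV per cell (group or species) for one tissue; cells with <2
    usable values are dropped."""
    out = {}
    col = expr[tissue]
    for label, members in cells.items():
        vals = col.reindex(members).dropna()
        if len(vals) >= 2 and vals.mean() > 0:
            out[label] = cv(vals.to_numpy())
    return pd.Series(out, dtype=float)


def cv_contrast(
    expr: pd.DataFrame,
    groups: Mapping[str, list[str]],
    species_map: Mapping[str, str],
    tissues: Sequence[str] = TISSUES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-tissue ortholog-vs-paralog CV contrast.

    ``groups`` maps group id -> member gene ids (orthologs); ``species_map``
    maps gene id -> species tag (paralog cells).  For each tissue the two
    CV collections are compared with a two-tailed Welch t-test.  Returns
    ``(contrast_table, cv_records)`` where ``cv_records`` holds every
    individual CV (long format, for inspection or plotting).
    """
    species_cells: dict[str, list[str]] = {}
    for gene in expr.index:
        if gene in species_map:
            species_cells.setdefault(species_map[gene], []).append(gene)

    contrast_rows = []
    cv_rows = []
    for tissue in tissues:
        g_cvs = _cell_cvs(expr, groups, tissue)
        s_cvs = _cell_cvs(expr, species_cells, tissue)
        for label, value in g_cvs.items():
            cv_rows.append({"label": label, "unit": "group", "tissue": tissue, "cv": value})
        for label, value in s_cvs.items():
            cv_rows.append({"label": label, "unit": "species", "tissue": tissue, "cv": value})
        if len(g_cvs) < 2 or len(s_cvs) < 2:
            contrast_rows.append(
                {
                    "tissue": tissue,
                    "mean_cv_groups": np.nan,
                    "mean_cv_species": np.nan,
                    "n_groups": len(g_cvs),
                    "n_species": len(s_cvs),
                    "t": np.nan,
                    "df": np.nan,
                    "p": np.nan,
                    "skipped": True,
                }
            )
            continue
        res = welch_t_test(s_cvs.to_numpy(), g_cvs.to_numpy())
        contrast_rows.append(
            {
                "tissue": tissue,
                "mean_cv_groups": float(g_cvs.mean()),
                "mean_cv_species": float(s_cvs.mean()),
                "n_groups": len(g_cvs),
                "n_species": len(s_cvs),
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "skipped": False,
            }
        )
    return pd.DataFrame(contrast_rows), pd.DataFrame(cv_rows)


def cv_threshold_counts(
    cv_records: pd.DataFrame, low: float = 0.4, high: float = 1.50
) -> dict[str, float]:
    """Descriptive counts against conventional CV cut-offs.

    Reports how many group (ortholog) CVs fall below ``low`` and what
    fraction of species (paralog) CVs exceed ``high``.
    """
    g = cv_records.loc[cv_records["unit"] == "group", "cv"]
    s = cv_records.loc[cv_records["unit"] == "species", "cv"]
    return {
        "n_group_cvs": int(len(g)),
        "n_group_cvs_below_low": int((g < low).sum()),
        "n_species_cvs": int(len(s)),
        "frac_species_cvs_above_high": float((s > high).mean()) if len(s) else float("nan"),
        "min_species_cv": float(s.min()) if len(s) else float("nan"),
    }
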