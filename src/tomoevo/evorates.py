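"""Evolutionary-rate (dN/dS) summaries over ortholog pairs.

Consumes pairwise rate tables (one row per ortholog-cluster member, e.g.
codeml model-0 output merged across clusters), reduces clusters to
one-to-one pairs by minimum synonymous divergence dS, summarizes omega
(dN/dS) by gene group (phylostratum or anatomical region), and matches
species pairs by median-dS divergence.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import ValidationError

__all__ = ["select_min_ds_orthologs", "summarize_rates", "match_species_pair_by_ds"]


def select_min_ds_orthologs(rates: pd.DataFrame, focal_side: str = "a") -> pd.DataFrame:
    """Pick one partner per focal gene: the row with minimal dS.

    Ties are broken by minimal omega, then lexicographic partner id.  Rows
    with undefined omega (dS = 0) are excluded.  Returns columns
    (focal_gene, partner, dN, dS, omega), one row per focal gene.
    """
    if focal_side not in ("a", "b"):
        raise ValueError("focal_side must be 'a' or 'b'")
    focal, partner = (("gene_a", "gene_b") if focal_side == "a" else ("gene_b", "gene_a"))
    df = rates.dropna(subset=["omega"]).copy()
    if df.empty:
        return pd.DataFrame(columns=["focal_gene", "partner", "dN", "dS", "omega"])
    df = df.rename(columns={focal: "focal_gene", partner: "partner"})
    df = df.sort_values(["focal_gene", "dS", "omega", "partner"], kind="mergesort")
    out = df.drop_duplicates("focal_gene", keep="first")
    return out[["focal_gene", "partner", "dN", "dS", "omega"]].reset_index(drop=True)


def summarize_rates(selected: pd.DataFrame, grouping: pd.Series) -> pd.DataFrame:
    """Per-group omega summaries: n, median and quartiles (linear, type-7).

    ``grouping`` maps focal gene -> group label; grouped genes without a
    selected pair are skipped (their count is reported as ``n_missing``).
    Groups with no pairs report n = 0 and NaN statistics.
    """
    grouping = pd.Series(grouping)
    joined = selected.assign(group=selected["focal_gene"].map(grouping))
    rows = []
    groups = pd.unique(grouping.dropna())
    covered = set(selected["focal_gene"])
    for g in sorted(groups, key=str):
        omega = joined.loc[joined["group"] == g, "omega"].to_numpy()
        missing = int(sum(1 for gene, lab in grouping.items()
                          if lab == g and gene not in covered))
        if omega.size:
            q1, med, q3 = np.percentile(omega, [25, 50, 75])  # linear interpolation
        else:
            q1 = med = q3 = np.nan
        rows.append({"group": g, "n": int(omega.size), "n_missing": missing,
                     "median_omega": med, "q1_omega": q1, "q3_omega": q3})
    return pd.DataFrame(rows)


def match_species_pair_by_ds(candidates: dict[str, pd.DataFrame],
                             reference_median_ds: float) -> tuple[str, pd.Series]:
    """Choose the candidate species pair whose median dS best matches a reference.

    Ties pick the larger median dS (the more conservative, i.e. more
    diverged, pair).  Returns (chosen name, per-candidate median dS).
    """
    if not candidates:
        raise ValidationError("no candidate species pairs")
    medians = {}
    for name, rates in candidates.items():
        ds = rates["dS"].dropna()
        if ds.empty:
            raise ValidationError(f"candidate {name!r} has no dS values")
        medians[name] = float(ds.median())
    series = pd.Series(medians).sort_index()
    chosen = min(series.items(),
                 key=lambda kv: (abs(kv[1] - reference_median_ds), -kv[1]))[0]
    return chosen, series
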