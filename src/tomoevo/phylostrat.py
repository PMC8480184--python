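"""Phylostratigraphy: gene-age assignment over a ladder phylogeny.

A gene's phylostratum is the deepest stratum of the ladder containing a
taxon with a detectable homolog (protein hits below the protein e-value
threshold, or nucleotide hits below the nucleotide threshold — the
nucleotide search rescues genes whose open reading frames were
mis-annotated).  Genes without qualifying hits are stratum 1, i.e.
specific to the focal species.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .comparative import bh_fdr, fisher_exact_2x2
from .io_formats import LadderConfig, ValidationError

__all__ = ["assign_phylostrata", "age_composition", "young_fraction_test"]


def _qualifying(hits: pd.DataFrame, threshold: float, universe: set[str]) -> pd.DataFrame:
    if hits is None or len(hits) == 0:
        return pd.DataFrame(columns=["query_id", "target_taxon"])
    out = hits[(hits["evalue"] < threshold) & hits["query_id"].isin(universe)]
    return out[["query_id", "target_taxon"]]


def assign_phylostrata(protein_hits: pd.DataFrame,
                       nucleotide_hits: pd.DataFrame | None,
                       ladder: LadderConfig,
                       universe) -> pd.Series:
    """Assign each universe gene its phylostratum index (1 = youngest).

    Evidence is the union of protein hits with ``evalue < protein_threshold``
    and nucleotide hits with ``evalue < nucleotide_threshold``; the stratum
    is the maximum stratum index over taxa with evidence.  Genes with no
    qualifying hits are stratum 1.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty gene universe")
    stratum_of = ladder.taxon_stratum()
    for name, hits in (("protein", protein_hits), ("nucleotide", nucleotide_hits)):
        if hits is None or len(hits) == 0:
            continue
        unknown = set(hits["target_taxon"]) - set(stratum_of)
        if unknown:
            raise ValidationError(f"{name} hits target taxa absent from ladder: {sorted(unknown)}")
    evidence = pd.concat([
        _qualifying(protein_hits, ladder.protein_threshold, universe),
        _qualifying(nucleotide_hits, ladder.nucleotide_threshold, universe),
    ], ignore_index=True)
    ages = pd.Series(1, index=sorted(universe), dtype=int, name="stratum")
    if len(evidence):
        evidence["stratum"] = evidence["target_taxon"].map(stratum_of)
        deepest = evidence.groupby("query_id")["stratum"].max()
        ages.loc[deepest.index] = np.maximum(1, deepest.astype(int))
    ages.index.name = "gene_id"
    return ages


def age_composition(ages: pd.Series, regional_sets: dict[str, set[str]],
                    universe, n_strata: int | None = None) -> pd.DataFrame:
    """Per-set phylostratum counts and fractions, plus the genome-wide "Ref".

    Returns a long DataFrame (set, stratum, count, fraction); fractions of a
    nonempty set sum to 1, empty sets report zero counts and fractions.
    """
    universe = set(universe)
    if n_strata is None:
        n_strata = int(ages.max())
    rows = []
    sets = dict(regional_sets)
    sets["Ref"] = universe
    for name, genes in sets.items():
        genes = set(genes)
        if name != "Ref" and not genes <= universe:
            raise ValidationError(f"set {name!r} contains genes outside the universe")
        strata = ages.reindex(sorted(genes)).dropna().astype(int)
        counts = strata.value_counts().reindex(range(1, n_strata + 1), fill_value=0)
        total = counts.sum()
        for s in range(1, n_strata + 1):
            rows.append({
                "set": name, "stratum": s, "count": int(counts[s]),
                "fraction": counts[s] / total if total else 0.0,
            })
    return pd.DataFrame(rows)


def young_fraction_test(ages: pd.Series, regional_sets: dict[str, set[str]],
                        young_strata, universe) -> pd.DataFrame:
    """Test each region's regional genes for excess of young phylostrata.

    One-sided (greater) Fisher's exact test of young vs old membership of
    the regional set against the rest of the universe, BH-corrected across
    regions; regions are also ranked by young fraction (rank 1 = highest).
    """
    young_strata = set(int(s) for s in young_strata)
    if not young_strata:
        raise ValidationError("young_strata must be nonempty")
    universe = set(universe)
    is_young = ages.reindex(sorted(universe)).astype(int).isin(young_strata)
    young_all = set(is_young.index[is_young])
    rows = []
    for region in sorted(regional_sets):
        genes = set(regional_sets[region]) & universe
        k_young = len(genes & young_all)
        k_old = len(genes) - k_young
        rest = universe - genes
        r_young = len(rest & young_all)
        r_old = len(rest) - r_young
        odds, p = fisher_exact_2x2([[k_young, k_old], [r_young, r_old]],
                                   alternative="greater")
        rows.append({
            "region": region, "n_regional": len(genes), "n_young": k_young,
            "young_fraction": k_young / len(genes) if genes else 0.0,
            "odds_ratio": odds, "p": p,
        })
    df = pd.DataFrame(rows)
    df["q"] = bh_fdr(df["p"].to_numpy())
    order = df.sort_values(["young_fraction", "region"],
                           ascending=[False, True], kind="mergesort").index
    ranks = pd.Series(np.arange(1, len(df) + 1), index=order)
    df["rank"] = ranks.reindex(df.index).astype(int)
    return df
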