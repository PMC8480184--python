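"""One-to-one orthology and overrepresentation statistics.

Reciprocal-best-hit (RBH) ortholog calling from combined-database BLAST
tables, region-by-region sharing of regional orthologs, and protein-domain
overrepresentation per region, all tested with Fisher's exact test against
a background of expressed genes and corrected by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io_formats import ValidationError
from .spatial import RegionProfile

__all__ = [
    "OrthologMap", "call_rbh_orthologs", "fisher_exact_2x2", "bh_fdr",
    "region_overlap_tests", "within_species_overlap_tests", "domain_enrichment",
]


@dataclass
class OrthologMap:
    """Set of one-to-one ortholog pairs between two taxa."""

    taxon_a: str
    taxon_b: str
    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        a_seen, b_seen = set(), set()
        for ga, gb in self.pairs:
            if ga in a_seen or gb in b_seen:
                raise ValidationError(f"gene appears in more than one pair: ({ga}, {gb})")
            a_seen.add(ga)
            b_seen.add(gb)
        self.pairs = sorted(self.pairs)

    def a_to_b(self) -> dict[str, str]:
        return dict(self.pairs)

    def b_to_a(self) -> dict[str, str]:
        return {gb: ga for ga, gb in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=[self.taxon_a, self.taxon_b])


def _best_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """Best target per query: lowest e-value, then highest bitscore, then id."""
    ordered = hits.sort_values(
        ["query_id", "evalue", "bitscore", "target_id"],
        ascending=[True, True, False, True], kind="mergesort")
    return ordered.drop_duplicates("query_id", keep="first")


def call_rbh_orthologs(hits: pd.DataFrame, taxon_a: str, taxon_b: str,
                       max_evalue: float = 1e-3,
                       reject_if_within_species_hit_better: bool = True) -> OrthologMap:
    """Call one-to-one orthologs as cross-taxon reciprocal best hits.

    Self-hits are removed and hits filtered to ``evalue < max_evalue``.  A
    pair (a, b) is emitted iff b is a's best cross-taxon hit and vice versa
    (ties: higher bitscore, then lexicographic target id).  With
    ``reject_if_within_species_hit_better`` (combined-database semantics), a
    gene whose best within-species non-self hit strictly outranks its best
    cross-species hit is treated as having an inparalog and is excluded.
    """
    hits = hits[(hits["query_id"] != hits["target_id"]) &
                (hits["evalue"] < max_evalue)]
    hits = hits[hits["query_taxon"].isin([taxon_a, taxon_b]) &
                hits["target_taxon"].isin([taxon_a, taxon_b])]
    cross = hits[hits["query_taxon"] != hits["target_taxon"]]
    if cross.empty:
        return OrthologMap(taxon_a, taxon_b, [])
    best_cross = _best_hits(cross).set_index("query_id")

    excluded: set[str] = set()
    if reject_if_within_species_hit_better:
        within = hits[hits["query_taxon"] == hits["target_taxon"]]
        if not within.empty:
            best_within = _best_hits(within).set_index("query_id")
            shared = best_cross.index.intersection(best_within.index)
            for q in shared:
                bw, bc = best_within.loc[q], best_cross.loc[q]
                if (bw["evalue"], -bw["bitscore"]) < (bc["evalue"], -bc["bitscore"]):
                    excluded.add(q)

    best = {q: row["target_id"] for q, row in best_cross.iterrows() if q not in excluded}
    taxon_of = dict(zip(cross["query_id"], cross["query_taxon"]))
    pairs = []
    for q, t in best.items():
        if taxon_of.get(q) == taxon_a and best.get(t) == q:
            pairs.append((q, t))
    return OrthologMap(taxon_a, taxon_b, sorted(set(pairs)))


# ---------------------------------------------------------------------------
# Exact tests and FDR
# ---------------------------------------------------------------------------

def _hypergeom_logpmf_support(r1: int, r2: int, c1: int):
    """Log-pmf of table entry a over its support for fixed margins."""
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    a = np.arange(lo, hi + 1)
    n = r1 + r2

    def logc(n_, k_):
        return gammaln(n_ + 1) - gammaln(k_ + 1) - gammaln(n_ - k_ + 1)

    logpmf = logc(r1, a) + logc(r2, c1 - a) - logc(n, c1)
    return a, logpmf


def fisher_exact_2x2(table, alternative: str = "two-sided") -> tuple[float, float]:
    """Fisher's exact test for a 2x2 table of non-negative integers.

    Two-sided p sums hypergeometric probabilities of same-margin tables
    whose probability is <= the observed one (relative tie tolerance 1e-7);
    'greater' sums the upper tail of the [0][0] cell.  Returns the sample
    odds ratio (ad/bc; inf when bc = 0 and ad > 0, 0 when ad = 0).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValidationError("negative entries in contingency table")
    if not np.all(np.equal(np.mod(t, 1), 0)):
        raise ValidationError("non-integer entries in contingency table")
    a, b, c, d = (int(x) for x in t.ravel())
    ad, bc = a * d, b * c
    if bc > 0:
        odds = ad / bc
    elif ad > 0:
        odds = np.inf
    else:
        odds = 0.0
    r1, r2, c1 = a + b, c + d, a + c
    if r1 == 0 or r2 == 0 or c1 == 0 or (b + d) == 0:
        return odds, 1.0
    support, logpmf = _hypergeom_logpmf_support(r1, r2, c1)
    obs = logpmf[support == a][0]
    if alternative == "two-sided":
        mask = logpmf <= obs + np.log1p(1e-7)
    elif alternative == "greater":
        mask = support >= a
    elif alternative == "less":
        mask = support <= a
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = float(np.exp(logpmf[mask] - obs).sum() * np.exp(obs))
    return odds, min(p, 1.0)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


# ---------------------------------------------------------------------------
# Region-pair ortholog sharing
# ---------------------------------------------------------------------------

def _overlap_row(unit, k, K, n, N, alternative):
    if K == 0 or n == 0:
        odds, p = 0.0, 1.0
    else:
        odds, p = fisher_exact_2x2(
            [[k, K - k], [n - k, N - K - n + k]], alternative=alternative)
    return {"unit": unit, "k": k, "K": K, "n": n, "N": N, "odds_ratio": odds, "p": p}


def region_overlap_tests(rp_a: RegionProfile, rp_b: RegionProfile,
                         orthologs: OrthologMap,
                         alternative: str = "two-sided") -> pd.DataFrame:
    """Cross-species sharing of regional one-to-one orthologs per region pair.

    The universe is ortholog pairs expressed (in >= 1 region) in both
    species; for a region pair, K/n are the pairs regional in the a/b-side
    region and k the pairs regional in both.  q is BH-adjusted across all
    region pairs of this analysis.
    """
    idx_a = {g: i for i, g in enumerate(rp_a.gene_ids)}
    idx_b = {g: i for i, g in enumerate(rp_b.gene_ids)}
    universe = [(ga, gb) for ga, gb in orthologs.pairs
                if ga in idx_a and gb in idx_b
                and rp_a.expressed[idx_a[ga]].any() and rp_b.expressed[idx_b[gb]].any()]
    N = len(universe)
    ia = np.array([idx_a[ga] for ga, _ in universe], dtype=int)
    ib = np.array([idx_b[gb] for _, gb in universe], dtype=int)
    rows = []
    for j_a, ra in enumerate(rp_a.region_labels):
        in_a = rp_a.regional[ia, j_a] if N else np.zeros(0, bool)
        for j_b, rb in enumerate(rp_b.region_labels):
            in_b = rp_b.regional[ib, j_b] if N else np.zeros(0, bool)
            rows.append(_overlap_row((ra, rb), int((in_a & in_b).sum()),
                                     int(in_a.sum()), int(in_b.sum()), N, alternative))
    df = pd.DataFrame(rows)
    df[["region_a", "region_b"]] = pd.DataFrame(df["unit"].tolist(), index=df.index)
    df["q"] = bh_fdr(df["p"].to_numpy())
    return df[["region_a", "region_b", "k", "K", "n", "N", "odds_ratio", "p", "q"]]


def within_species_overlap_tests(rp: RegionProfile,
                                 alternative: str = "two-sided") -> pd.DataFrame:
    """Gene sharing between regions of one species (incl. self pairs).

    Universe = that species' expressed genes; the self-pair overlap k equals
    the region's regional-gene count intersected with the universe.
    """
    genes = np.asarray(rp.gene_ids)
    expressed_any = rp.expressed.any(axis=1)
    N = int(expressed_any.sum())
    rows = []
    for j_a, ra in enumerate(rp.region_labels):
        set_a = rp.regional[:, j_a] & expressed_any
        for j_b, rb in enumerate(rp.region_labels):
            set_b = rp.regional[:, j_b] & expressed_any
            rows.append(_overlap_row((ra, rb), int((set_a & set_b).sum()),
                                     int(set_a.sum()), int(set_b.sum()), N, alternative))
    df = pd.DataFrame(rows)
    df[["region_a", "region_b"]] = pd.DataFrame(df["unit"].tolist(), index=df.index)
    df["q"] = bh_fdr(df["p"].to_numpy())
    return df[["region_a", "region_b", "k", "K", "n", "N", "odds_ratio", "p", "q"]]


# ---------------------------------------------------------------------------
# Protein-domain overrepresentation
# ---------------------------------------------------------------------------

def domain_enrichment(rp: RegionProfile, domains: pd.DataFrame,
                      alternative: str = "two-sided") -> pd.DataFrame:
    """Overrepresentation of protein domains among each region's regional genes.

    Fisher's exact test of regional-set x domain membership against a
    background of all expressed genes, BH-corrected across every
    (region, domain) pair.  Also reports the member count and the cumulative
    expression (sum of pooled median normalized counts of the member
    regional genes in that region).
    """
    universe = rp.expressed_any()
    if not universe:
        raise ValidationError("no expressed genes in profile")
    dom_sets: dict[str, set[str]] = {}
    for dom, sub in domains.groupby("domain_id"):
        members = set(sub["gene_id"]) & universe
        if not members:
            warnings.warn(f"domain {dom!r} has no members in the expressed universe; skipped")
            continue
        dom_sets[dom] = members
    idx = {g: i for i, g in enumerate(rp.gene_ids)}
    N = len(universe)
    rows = []
    for j, region in enumerate(rp.region_labels):
        regional = {g for g in rp.gene_ids if rp.regional[idx[g], j]} & universe
        K = len(regional)
        for dom in sorted(dom_sets):
            members = dom_sets[dom]
            inter = regional & members
            row = _overlap_row((region, dom), len(inter), K, len(members), N, alternative)
            row["cumulative_expression"] = float(
                sum(rp.median_norm[idx[g], j] for g in inter))
            rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=["region", "domain", "k", "K", "n", "N",
                                     "odds_ratio", "p", "q", "cumulative_expression"])
    df[["region", "domain"]] = pd.DataFrame(df["unit"].tolist(), index=df.index)
    df["q"] = bh_fdr(df["p"].to_numpy())
    return df[["region", "domain", "k", "K", "n", "N", "odds_ratio", "p", "q",
               "cumulative_expression"]]
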