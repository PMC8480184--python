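"""Synthetic two-species tomo-seq experiments with full ground truth.

Generates everything the pipeline consumes — per-specimen gene x section
count matrices for two nematode-like species, marker configurations, a
ladder phylogeny with protein/nucleotide homology hits, cross-species
ortholog hits, protein-domain tables, ortholog-cluster rate tables and a
small transcript assembly — with a known truth record for every planted
structure (region boundaries, regional genes, ortholog pairs, gene ages,
age-biased sperm regions, omega trends, representative isoforms).

Counts are negative binomial around a per-gene baseline with per-section
library-size variation, so that normalization by section totals is
actually necessary; regional genes carry a fold increase inside their
region and marker genes a stronger one; one marker set peaks in both
sperm-related regions to exercise first/second peak ordinals.  A single
seed governs all draws through named ``SeedSequence`` child streams, so
regeneration is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats as io
from .io_formats import (LadderConfig, MarkerConfig, RegionSpec, SectionCounts,
                         ValidationError)

__all__ = ["SynthParams", "SynthTruth", "SynthExperiment",
           "generate_experiment", "evaluate_recovery"]

# ladder used for the focal species: stratum 1 = focal only, deeper strata
# cover increasingly distant nematode taxa
DEFAULT_STRATA = [
    ["pacificus"],
    ["exspectatus", "arcanus"],
    ["fissidentatus"],
    ["elegans"],
    ["xylophilus"],
    ["spiralis"],
]


@dataclass
class SynthParams:
    """Generator settings; defaults are the experimental conditions being emulated.

    Four specimens of ~40 sections each, ~29% of genes regional, modest
    (4-fold) regional enrichment, strong (10-fold) marker enrichment,
    negative-binomial dispersion 0.3, ~30% one-to-one orthology and a
    reference age distribution with roughly one third species-specific
    genes.
    """

    n_specimens: int = 4
    n_sections: int = 40
    n_genes: int = 3000
    n_regions: int = 8
    regional_fraction: float = 0.29
    fold: float = 4.0
    marker_fold: float = 10.0
    markers_per_region: int = 10
    # the two-peak sperm marker is a large co-expressed family (MSP-like);
    # averaging many members keeps its z signal, whose ceiling is low because
    # it is elevated in two regions, reliably above the peak threshold
    n_sperm_markers: int = 40
    dispersion: float = 0.3
    libsize_sigma: float = 0.3
    base_mean: float = 10.0
    base_sigma: float = 0.6
    ortholog_fraction: float = 0.3
    conservation: float = 0.6
    ref_distribution: tuple = (0.30, 0.12, 0.08, 0.10, 0.15, 0.25)
    young_strata: tuple = (1, 2, 3)
    young_boost: float = 3.0
    omega_mean_base: float = 0.4
    omega_decay: float = 0.7
    omega_shape: float = 4.0
    decoy_rate: float = 0.3
    nt_rescue_fraction: float = 0.1
    extra_partner_prob: float = 0.5
    reference_median_ds: float = 2.1
    candidate_median_ds: dict = field(default_factory=lambda: {
        "pacificus-exspectatus": 0.3,
        "pacificus-fissidentatus": 1.9,
        "pacificus-distant": 3.5,
    })
    n_candidate_pairs: int = 300
    n_refprep_genes: int = 60
    taxon_a: str = "Ppa"
    taxon_b: str = "Cel"

    def __post_init__(self) -> None:
        if self.n_regions < 7:
            raise ValidationError("need >= 7 regions (two sperm regions + indirect)")
        if self.n_sections < 3 * self.n_regions:
            raise ValidationError(
                f"{self.n_regions} regions do not fit in {self.n_sections} sections")
        if abs(sum(self.ref_distribution) - 1.0) > 1e-9:
            raise ValidationError("ref_distribution must sum to 1")
        if len(self.ref_distribution) != len(DEFAULT_STRATA):
            raise ValidationError("ref_distribution length must match ladder depth")

    @property
    def region_labels(self) -> list[str]:
        return [f"R{i + 1}" for i in range(self.n_regions)]

    @property
    def sperm_regions(self) -> tuple[str, str]:
        # the two MSP-like regions flanking the indirectly defined one
        return "R4", "R6"

    @property
    def indirect_region(self) -> str:
        return "R5"


@dataclass
class SynthTruth:
    """Ground truth for every planted structure of one experiment."""

    seed: int
    params: dict
    region_labels: list
    sperm_regions: list
    indirect_region: str
    boundaries: dict        # taxon -> specimen -> region -> first 0-based section
    regional: dict          # taxon -> gene -> region
    markers: dict           # taxon -> region -> [marker genes]
    ortholog_pairs: list    # [(gene_a, gene_b)]
    conserved: list         # parallel bools
    strata: dict            # focal gene -> stratum index
    young_boost: float
    rates_true_partner: dict
    omega_means: dict       # stratum -> planted mean omega
    planted_domains: dict   # taxon -> [(region, domain)]
    refprep_expected: dict  # gene -> [transcript, rule]
    candidate_medians: dict

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "SynthTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SynthExperiment:
    """In-memory bundle of all generated inputs."""

    params: SynthParams
    counts: dict            # taxon -> [SectionCounts]
    marker_cfg: dict        # taxon -> MarkerConfig
    ladder: LadderConfig
    taxon_map: dict         # id prefix -> taxon
    protein_hits: pd.DataFrame
    nucleotide_hits: pd.DataFrame
    ortho_hits: pd.DataFrame
    domains: dict           # taxon -> DataFrame
    rates_close: pd.DataFrame
    rate_candidates: dict   # name -> DataFrame
    transcripts: list       # [(id, seq)]
    refprep_hits: pd.DataFrame

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for taxon, scs in self.counts.items():
            for sc in scs:
                io.write_section_counts(sc, out / f"counts_{sc.specimen_id}.tsv")
            io.write_marker_config(self.marker_cfg[taxon], out / f"markers_{taxon}.yaml")
            io.write_domain_table(self.domains[taxon], out / f"domains_{taxon}.tsv")
        io.write_ladder_config(self.ladder, out / "ladder.yaml")
        io.write_hit_table(self.protein_hits, out / "hits_phylostrat_protein.tsv")
        io.write_hit_table(self.nucleotide_hits, out / "hits_phylostrat_nucleotide.tsv")
        io.write_hit_table(self.ortho_hits, out / "hits_orthologs.tsv")
        io.write_rates_table(self.rates_close, out / "rates_close.tsv")
        for name, df in self.rate_candidates.items():
            io.write_rates_table(df, out / f"rates_candidate_{name}.tsv")
        io.write_fasta(self.transcripts, out / "transcripts.fasta")
        io.write_hit_table(self.refprep_hits, out / "refprep_protein_hits.tsv")
        with open(out / "taxon_map.yaml", "w") as fh:
            import yaml
            yaml.safe_dump(self.taxon_map, fh, sort_keys=True)


def _child_rngs(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    """Named, order-independent child streams from a single master seed."""
    return {name: np.random.default_rng(np.random.SeedSequence([int(seed), i]))
            for i, name in enumerate(names)}


def _negbin(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draws with var = mean + dispersion * mean^2 (Poisson at 0)."""
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _specimen_boundaries(rng, p: SynthParams) -> np.ndarray:
    """First 0-based section index of each region (length n_regions).

    Boundaries jitter by +-1 between specimens but every region keeps a
    minimum width so marker runs cannot vanish into the smoothing window.
    The two sperm-related regions are kept narrow (like the spermatheca
    peaks they emulate): a marker elevated in two regions has a bounded
    z-score, so its combined span must stay a small fraction of the axis.
    """
    base_w = p.n_sections // p.n_regions
    min_w = min(4, base_w)
    sperm_idx = {p.region_labels.index(r) for r in p.sperm_regions}
    widths = np.full(p.n_regions, base_w, dtype=int)
    widths[: p.n_sections - base_w * p.n_regions] += 1  # spread the remainder
    for i in sorted(sperm_idx):  # narrow sperm regions; surplus to the ends
        surplus = widths[i] - min_w
        widths[i] = min_w
        widths[0] += surplus - surplus // 2
        widths[-1] += surplus // 2
    starts = np.concatenate([[0], np.cumsum(widths)])
    for i in range(1, p.n_regions):
        shift = int(rng.integers(-1, 2))
        lo_l = min_w - 1 if (i - 1) in sperm_idx else min_w
        lo_r = min_w - 1 if i in sperm_idx else min_w
        hi_l = min_w + 1 if (i - 1) in sperm_idx else p.n_sections
        hi_r = min_w + 1 if i in sperm_idx else p.n_sections
        w_l = starts[i] + shift - starts[i - 1]
        w_r = starts[i + 1] - (starts[i] + shift)
        if lo_l <= w_l <= hi_l and lo_r <= w_r <= hi_r:
            starts[i] += shift
    return starts[:-1]


def _marker_layout(p: SynthParams, taxon: str):
    """Marker gene ids per region and the MarkerConfig (shared sperm set)."""
    s1, s2 = p.sperm_regions
    markers: dict[str, list[str]] = {}
    msp = [f"{taxon}_msp_{j + 1}" for j in range(p.n_sperm_markers)]
    for r in p.region_labels:
        if r == p.indirect_region:
            continue
        if r in (s1, s2):
            markers[r] = msp
        else:
            markers[r] = [f"{taxon}_mk{r}_{j + 1}" for j in range(p.markers_per_region)]
    regions = []
    for r in p.region_labels:
        if r == p.indirect_region:
            regions.append(RegionSpec(label=r, between=(s1, s2)))
        else:
            peak = 2 if r == s2 else 1
            regions.append(RegionSpec(label=r, markers=tuple(markers[r]), peak=peak))
    return markers, MarkerConfig(regions)


def _species_counts(rng, p: SynthParams, taxon: str, gene_ids, base,
                    regional: dict[str, str], markers: dict[str, list[str]]):
    """All specimens' SectionCounts plus true boundaries per specimen."""
    marker_regions: dict[str, list[str]] = {}
    for region, genes in markers.items():
        for g in genes:
            marker_regions.setdefault(g, []).append(region)
    scs, bounds = [], {}
    for s in range(p.n_specimens):
        starts = _specimen_boundaries(rng, p)
        region_of = np.empty(p.n_sections, dtype=object)
        for i, r in enumerate(p.region_labels):
            end = starts[i + 1] if i + 1 < p.n_regions else p.n_sections
            region_of[starts[i]:end] = r
        mean = np.tile(base[:, None], (1, p.n_sections)).astype(float)
        for gi, g in enumerate(gene_ids):
            boost_regions = marker_regions.get(g)
            if boost_regions:
                for r in boost_regions:
                    mean[gi, region_of == r] *= p.marker_fold
            elif g in regional:
                mean[gi, region_of == regional[g]] *= p.fold
        libsize = np.exp(rng.normal(0.0, p.libsize_sigma, size=p.n_sections))
        counts = _negbin(rng, mean * libsize[None, :], p.dispersion)
        spec_id = f"{taxon}_w{s + 1}"
        scs.append(SectionCounts(spec_id, list(gene_ids),
                                 [f"s{i + 1:02d}" for i in range(p.n_sections)],
                                 counts.astype(np.int64)))
        bounds[spec_id] = {r: int(starts[i]) for i, r in enumerate(p.region_labels)}
    return scs, bounds


def _assign_regional(rng, p: SynthParams, candidates: list[str],
                     strata: dict[str, int] | None) -> dict[str, str]:
    """Sample regional genes into per-region quotas.

    The planted sperm regions draw their regional genes with weight beta for
    young-stratum genes, so their stratum distribution is the reference with
    the young:old odds multiplied by exactly beta (and equal to the
    reference when beta = 1); the other regions draw uniformly.
    """
    n_regional = min(int(round(p.regional_fraction * p.n_genes)), len(candidates))
    labels = p.region_labels
    quota = np.full(len(labels), n_regional // len(labels))
    quota[: n_regional - quota.sum()] += 1
    young = set(p.young_strata)
    sperm = set(p.sperm_regions)
    pool = np.arange(len(candidates))
    out: dict[str, str] = {}
    # sperm regions sample first so their weighted draw sees the full pool
    order = sorted(range(len(labels)), key=lambda j: labels[j] not in sperm)
    for j in order:
        w = np.ones(len(pool))
        if strata is not None and labels[j] in sperm:
            for i, ci in enumerate(pool):
                if strata.get(candidates[ci]) in young:
                    w[i] = p.young_boost
        take = rng.choice(len(pool), size=int(quota[j]), replace=False, p=w / w.sum())
        for ci in pool[take]:
            out[candidates[ci]] = labels[j]
        pool = np.delete(pool, take)
    return out


def generate_experiment(params: SynthParams | None = None, seed: int = 0,
                        out_dir: str | Path | None = None):
    """Generate a full synthetic experiment; returns (SynthExperiment, SynthTruth)."""
    p = params or SynthParams()
    rngs = _child_rngs(seed, [
        "strata", "regional_a", "regional_b", "counts_a", "counts_b",
        "orthologs", "hits_phylo", "hits_ortho", "domains_a", "domains_b",
        "rates", "candidates", "refprep",
    ])
    ta, tb = p.taxon_a, p.taxon_b
    genes_a = [f"{ta}_g{i:05d}" for i in range(p.n_genes)]
    genes_b = [f"{tb}_g{i:05d}" for i in range(p.n_genes)]
    markers_a, cfg_a = _marker_layout(p, ta)
    markers_b, cfg_b = _marker_layout(p, tb)
    marker_genes_a = sorted({g for gs in markers_a.values() for g in gs})
    marker_genes_b = sorted({g for gs in markers_b.values() for g in gs})
    all_a = genes_a + marker_genes_a
    all_b = genes_b + marker_genes_b

    # gene ages for the focal species (iid from the reference distribution)
    strata_draw = rngs["strata"].choice(
        np.arange(1, len(p.ref_distribution) + 1), size=len(all_a),
        p=np.asarray(p.ref_distribution))
    strata = {g: int(s) for g, s in zip(all_a, strata_draw)}

    regional_a = _assign_regional(rngs["regional_a"], p, genes_a, strata)

    # one-to-one orthologs; conserved pairs inherit the region label
    n_orth = int(round(p.ortholog_fraction * p.n_genes))
    orng = rngs["orthologs"]
    ia = sorted(orng.choice(p.n_genes, size=n_orth, replace=False))
    ib = orng.permutation(p.n_genes)[:n_orth]
    pairs = [(genes_a[i], genes_b[j]) for i, j in zip(ia, ib)]
    conserved = orng.random(n_orth) < p.conservation
    regional_b: dict[str, str] = {}
    for (ga, gb), cons in zip(pairs, conserved):
        if cons and ga in regional_a:
            regional_b[gb] = regional_a[ga]
    # fill species B up to the same regional fraction with independent genes
    free_b = [g for g in genes_b if g not in regional_b]
    n_more = int(round(p.regional_fraction * p.n_genes)) - len(regional_b)
    if n_more > 0:
        extra = _assign_regional(
            rngs["regional_b"],
            dataclasses.replace(p, regional_fraction=n_more / p.n_genes),
            free_b, None)
        regional_b.update(extra)

    counts_a, bounds_a = _species_counts(rngs["counts_a"], p, ta, all_a,
                                         np.exp(rngs["counts_a"].normal(
                                             np.log(p.base_mean), p.base_sigma, len(all_a))),
                                         regional_a, markers_a)
    counts_b, bounds_b = _species_counts(rngs["counts_b"], p, tb, all_b,
                                         np.exp(rngs["counts_b"].normal(
                                             np.log(p.base_mean), p.base_sigma, len(all_b))),
                                         regional_b, markers_b)

    ladder = LadderConfig(focal_taxon=DEFAULT_STRATA[0][0],
                          strata=[list(t) for t in DEFAULT_STRATA])
    taxon_map = {f"{ta}_": DEFAULT_STRATA[0][0], f"{tb}_": "elegans"}
    for taxa in DEFAULT_STRATA:
        for t in taxa:
            taxon_map[f"{t}:"] = t

    protein_hits, nucleotide_hits = _phylostrat_hits(rngs["hits_phylo"], p, ladder,
                                                     all_a, strata, taxon_map)
    ortho_hits = _ortholog_hits(rngs["hits_ortho"], p, pairs, genes_a, genes_b,
                                taxon_map)
    domains_a, planted_a = _domain_tables(rngs["domains_a"], p, all_a, regional_a)
    domains_b, planted_b = _domain_tables(rngs["domains_b"], p, all_b, regional_b)
    rates_close, true_partner, omega_means = _rates_table(rngs["rates"], p, all_a, strata)
    rate_candidates = _candidate_tables(rngs["candidates"], p)
    transcripts, refprep_hits, refprep_expected = _refprep_inputs(rngs["refprep"], p, taxon_map)

    exp = SynthExperiment(
        params=p,
        counts={ta: counts_a, tb: counts_b},
        marker_cfg={ta: cfg_a, tb: cfg_b},
        ladder=ladder, taxon_map=taxon_map,
        protein_hits=protein_hits, nucleotide_hits=nucleotide_hits,
        ortho_hits=ortho_hits,
        domains={ta: domains_a, tb: domains_b},
        rates_close=rates_close, rate_candidates=rate_candidates,
        transcripts=transcripts, refprep_hits=refprep_hits,
    )
    truth = SynthTruth(
        seed=int(seed),
        params=dataclasses.asdict(p),
        region_labels=p.region_labels,
        sperm_regions=list(p.sperm_regions),
        indirect_region=p.indirect_region,
        boundaries={ta: bounds_a, tb: bounds_b},
        regional={ta: dict(sorted(regional_a.items())),
                  tb: dict(sorted(regional_b.items()))},
        markers={ta: markers_a, tb: markers_b},
        ortholog_pairs=[list(pr) for pr in pairs],
        conserved=[bool(c) for c in conserved],
        strata=strata,
        young_boost=p.young_boost,
        rates_true_partner=true_partner,
        omega_means={str(k): v for k, v in omega_means.items()},
        planted_domains={ta: planted_a, tb: planted_b},
        refprep_expected=refprep_expected,
        candidate_medians=dict(p.candidate_median_ds),
    )
    if out_dir is not None:
        exp.write(out_dir)
        truth.to_json(Path(out_dir) / "truth.json")
    return exp, truth


def _hit_row(q, t, q_tax, t_tax, evalue, bitscore, qend=np.nan):
    return {"query_id": q, "target_id": t, "query_taxon": q_tax,
            "target_taxon": t_tax, "evalue": evalue, "bitscore": bitscore,
            "query_end": qend}


def _phylostrat_hits(rng, p: SynthParams, ladder: LadderConfig, genes, strata,
                     taxon_map):
    """Protein + nucleotide hit tables encoding each gene's stratum.

    Qualifying hits reach every stratum up to the gene's own (always the
    deepest); a fraction of genes carry their deepest evidence only as a
    nucleotide hit (mis-annotated ORF rescue); decoy hits to deeper strata
    stay above the e-value threshold.
    """
    focal = ladder.focal_taxon
    prot, nuc = [], []
    n_strata = ladder.n_strata
    for g in genes:
        k = strata[g]
        rescue = k >= 2 and rng.random() < p.nt_rescue_fraction
        for j in range(2, k + 1):
            if j < k and rng.random() > 0.7:
                continue
            taxon = ladder.strata[j - 1][rng.integers(len(ladder.strata[j - 1]))]
            target = f"{taxon}:{g}"
            if j == k and rescue:
                nuc.append(_hit_row(g, target, focal, taxon,
                                    10.0 ** -rng.uniform(6, 30),
                                    float(rng.uniform(60, 300))))
            else:
                prot.append(_hit_row(g, target, focal, taxon,
                                     10.0 ** -rng.uniform(4, 50),
                                     float(rng.uniform(60, 300))))
        if k < n_strata and rng.random() < p.decoy_rate:
            j = int(rng.integers(k + 1, n_strata + 1))
            taxon = ladder.strata[j - 1][rng.integers(len(ladder.strata[j - 1]))]
            prot.append(_hit_row(g, f"{taxon}:{g}", focal, taxon,
                                 float(rng.uniform(2e-3, 0.5)),
                                 float(rng.uniform(20, 40))))
    cols = io.HIT_COLUMNS
    return (pd.DataFrame(prot, columns=cols), pd.DataFrame(nuc, columns=cols))


def _ortholog_hits(rng, p: SynthParams, pairs, genes_a, genes_b, taxon_map):
    """Cross-species BLAST-like hits whose reciprocal best hits are the pairs."""
    tax_a = taxon_map[f"{p.taxon_a}_"]
    tax_b = taxon_map[f"{p.taxon_b}_"]
    rows = []
    b_pool = list(genes_b)
    for ga, gb in pairs:
        ev = 10.0 ** -rng.uniform(20, 80)
        bs = float(rng.uniform(150, 400))
        rows.append(_hit_row(ga, gb, tax_a, tax_b, ev, bs))
        rows.append(_hit_row(gb, ga, tax_b, tax_a, ev, bs))
        if rng.random() < 0.4:  # worse decoy hit to a wrong partner
            decoy = b_pool[rng.integers(len(b_pool))]
            if decoy != gb:
                rows.append(_hit_row(ga, decoy, tax_a, tax_b,
                                     min(ev * 10.0 ** rng.uniform(3, 10), 5e-4),
                                     bs * 0.5))
    # unpaired genes with a strong within-species paralog hit (inparalogs)
    unpaired = sorted(set(genes_a) - {ga for ga, _ in pairs})
    n_inpara = min(len(unpaired) // 10, 50)
    for g in unpaired[:n_inpara]:
        para = unpaired[rng.integers(len(unpaired))]
        if para == g:
            continue
        rows.append(_hit_row(g, para, tax_a, tax_a, 10.0 ** -rng.uniform(60, 90),
                             float(rng.uniform(300, 500))))
        gb = genes_b[rng.integers(len(genes_b))]
        rows.append(_hit_row(g, gb, tax_a, tax_b, 10.0 ** -rng.uniform(5, 15),
                             float(rng.uniform(50, 100))))
    return pd.DataFrame(rows, columns=io.HIT_COLUMNS)


def _domain_tables(rng, p: SynthParams, genes, regional: dict[str, str]):
    """Background domains plus domains planted inside regional gene sets."""
    rows = []
    for d in range(20):
        dom = f"PF{10000 + d:05d}"
        members = rng.choice(len(genes), size=30, replace=False)
        for m in sorted(members):
            rows.append({"gene_id": genes[m], "domain_id": dom})
    planted = []
    by_region: dict[str, list[str]] = {}
    for g, r in regional.items():
        by_region.setdefault(r, []).append(g)
    targets = [p.sperm_regions[0], "R2", p.region_labels[-1]]
    for d, region in enumerate(targets):
        pool = sorted(by_region.get(region, []))
        if len(pool) < 8:
            continue
        dom = f"DUF{700 + d}"
        members = rng.choice(len(pool), size=min(12, len(pool)), replace=False)
        for m in sorted(members):
            rows.append({"gene_id": pool[m], "domain_id": dom})
        planted.append([region, dom])
    return (pd.DataFrame(rows, columns=["gene_id", "domain_id"])
            .drop_duplicates(ignore_index=True), planted)


def _rates_table(rng, p: SynthParams, genes, strata):
    """Ortholog-cluster rates vs the sister species with an age-omega trend.

    Genes of stratum >= 2 (those with homologs beyond the focal species) get
    a true partner whose dS is minimal within its cluster; planted mean
    omega decreases geometrically with stratum index (older = more
    constrained).
    """
    rows = []
    true_partner: dict[str, str] = {}
    n_strata = len(p.ref_distribution)
    omega_means = {k: p.omega_mean_base * p.omega_decay ** (k - 2)
                   for k in range(2, n_strata + 1)}
    shape = p.omega_shape
    for g in genes:
        k = strata[g]
        if k < 2:
            continue
        mean = omega_means[k]
        ds = float(np.exp(rng.normal(np.log(0.3), 0.4)))
        omega = float(rng.gamma(shape, mean / shape))
        partner = f"exspectatus:{g}"
        rows.append({"gene_a": g, "gene_b": partner,
                     "dN": omega * ds, "dS": ds, "omega": omega})
        true_partner[g] = partner
        if rng.random() < p.extra_partner_prob:  # a paralogous cluster member
            ds2 = ds * (1.0 + rng.uniform(0.05, 1.0))
            om2 = float(rng.gamma(shape, mean / shape))
            rows.append({"gene_a": g, "gene_b": f"exspectatus:{g}_p2",
                         "dN": om2 * ds2, "dS": ds2, "omega": om2})
    return (pd.DataFrame(rows, columns=io.RATES_COLUMNS), true_partner, omega_means)


def _candidate_tables(rng, p: SynthParams):
    """Candidate species-pair rate tables with planted median dS levels."""
    out = {}
    for name in sorted(p.candidate_median_ds):
        med = p.candidate_median_ds[name]
        ds = np.exp(rng.normal(np.log(med), 0.5, size=p.n_candidate_pairs))
        out[name] = pd.DataFrame({
            "gene_a": [f"{name}:q{i}" for i in range(p.n_candidate_pairs)],
            "gene_b": [f"{name}:t{i}" for i in range(p.n_candidate_pairs)],
            "dN": 0.1 * ds, "dS": ds, "omega": 0.1,
        })
    return out


def _random_seq(rng, length: int) -> str:
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
    # avoid an accidental terminal poly-A
    return seq[:-1] + "G"


def _refprep_inputs(rng, p: SynthParams, taxon_map):
    """Small transcript assembly with planted representative-isoform answers."""
    transcripts, hit_rows = [], []
    expected: dict[str, list] = {}
    tax_a = taxon_map[f"{p.taxon_a}_"]
    scenarios = ["single_tailed", "tail_tie", "untailed", "single"]
    for i in range(p.n_refprep_genes):
        gene = f"{p.taxon_a}_rp{i:03d}"
        scenario = scenarios[rng.integers(len(scenarios))]
        if scenario == "single":
            tid = f"{gene}.t1"
            transcripts.append((tid, _random_seq(rng, int(rng.integers(150, 400)))))
            expected[gene] = [tid, "longest"]
        elif scenario == "single_tailed":
            tids = [f"{gene}.t{j + 1}" for j in range(int(rng.integers(2, 4)))]
            winner = tids[rng.integers(len(tids))]
            for tid in tids:
                seq = _random_seq(rng, int(rng.integers(150, 400)))
                if tid == winner:
                    seq += "A" * int(rng.integers(6, 15))
                transcripts.append((tid, seq))
            expected[gene] = [winner, "polya"]
        elif scenario == "tail_tie":
            lens = [int(rng.integers(200, 400)), int(rng.integers(200, 400))]
            tids = [f"{gene}.t1", f"{gene}.t2"]
            fracs = [0.9, 0.5]
            for tid, ln, frac in zip(tids, lens, fracs):
                seq = _random_seq(rng, ln) + "A" * 8
                transcripts.append((tid, seq))
                hit_rows.append(_hit_row(tid, f"elegans:P{i}", tax_a, "elegans",
                                         10.0 ** -rng.uniform(10, 40),
                                         float(rng.uniform(100, 300)),
                                         qend=int(frac * len(seq))))
            expected[gene] = [tids[0], "alignment"]
        else:  # untailed: fall through to longest
            lens = sorted({int(rng.integers(150, 400)) for _ in range(3)})
            tids = [f"{gene}.t{j + 1}" for j in range(len(lens))]
            order = rng.permutation(len(lens))
            for tid, oi in zip(tids, order):
                transcripts.append((tid, _random_seq(rng, lens[oi])))
                if lens[oi] == lens[-1]:
                    expected[gene] = [tid, "longest"]
        # build isoform groups downstream via transcript-id prefix "gene."
    return transcripts, pd.DataFrame(hit_rows, columns=io.HIT_COLUMNS), expected


# ---------------------------------------------------------------------------
# Recovery evaluation against the truth record
# ---------------------------------------------------------------------------

def _boundary_errors(truth: SynthTruth, taxon: str, assignments) -> list[int]:
    """Per internal region, |inferred - true| first-section index."""
    errs = []
    for ra in assignments:
        true_starts = truth.boundaries[taxon][ra.specimen_id]
        inferred = {}
        for i, lab in enumerate(ra.region_of):
            inferred.setdefault(lab, i)
        for r in truth.region_labels[1:]:
            if r in inferred:
                errs.append(abs(inferred[r] - true_starts[r]))
            else:
                errs.append(len(ra.region_of))  # missing region: maximal error
    return errs


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return prec, rec, f1


def evaluate_recovery(truth: SynthTruth, results: dict) -> dict:
    """Score pipeline outputs against the planted truth.

    ``results`` may provide: ``assignments`` (taxon -> [RegionAssignment]),
    ``profiles`` (taxon -> RegionProfile), ``orthologs`` (OrthologMap),
    ``ages`` (Series), ``young_test`` (DataFrame), ``rate_summary``
    (per-stratum DataFrame), ``selected_pairs`` (DataFrame).  Only the
    provided stages are scored.
    """
    report: dict = {}
    marker_genes = {t: {g for gs in truth.markers[t].values() for g in gs}
                    for t in truth.markers}

    if "assignments" in results:
        for taxon, ras in results["assignments"].items():
            errs = _boundary_errors(truth, taxon, ras)
            report[f"boundary_errors_{taxon}"] = errs
            report[f"boundary_within_1_{taxon}"] = (
                float(np.mean([e <= 1 for e in errs])) if errs else float("nan"))

    if "profiles" in results:
        for taxon, rp in results["profiles"].items():
            truth_pairs = {(g, r) for g, r in truth.regional[taxon].items()}
            genes = [g for g in rp.gene_ids if g not in marker_genes[taxon]]
            idx = {g: i for i, g in enumerate(rp.gene_ids)}
            pred = {(g, r) for g in genes
                    for j, r in enumerate(rp.region_labels) if rp.regional[idx[g], j]}
            truth_pairs = {(g, r) for g, r in truth_pairs if g in idx}
            tp = len(pred & truth_pairs)
            prec, rec, f1 = _prf(tp, len(pred) - tp, len(truth_pairs) - tp)
            report[f"regional_precision_{taxon}"] = prec
            report[f"regional_recall_{taxon}"] = rec
            report[f"regional_f1_{taxon}"] = f1

    if "orthologs" in results:
        pred = set(map(tuple, results["orthologs"].pairs))
        true = set(map(tuple, truth.ortholog_pairs))
        tp = len(pred & true)
        prec, rec, f1 = _prf(tp, len(pred) - tp, len(true) - tp)
        report["ortholog_precision"] = prec
        report["ortholog_recall"] = rec
        report["ortholog_f1"] = f1

    if "ages" in results:
        ages = results["ages"]
        truth_strata = pd.Series(truth.strata)
        shared = ages.index.intersection(truth_strata.index)
        if len(shared) == 0:
            raise ValidationError("no overlap between assigned ages and truth universe")
        report["stratum_accuracy"] = float(
            (ages.loc[shared] == truth_strata.loc[shared]).mean())

    if "young_test" in results:
        yt = results["young_test"].set_index("region")
        ranks = {r: int(yt.loc[r, "rank"]) for r in truth.sperm_regions if r in yt.index}
        report["young_rank_sperm_regions"] = ranks
        report["young_q_sperm_regions"] = {
            r: float(yt.loc[r, "q"]) for r in truth.sperm_regions if r in yt.index}
        report["young_top2_recovered"] = bool(
            ranks and sorted(ranks.values()) == list(range(1, len(ranks) + 1)))

    if "rate_summary" in results:
        rs = results["rate_summary"].dropna(subset=["median_omega"])
        rs = rs[rs["n"] > 0].sort_values("group")
        med = rs["median_omega"].to_numpy()
        report["omega_medians_by_stratum"] = {
            str(g): float(m) for g, m in zip(rs["group"], med)}
        report["omega_trend_decreasing"] = bool(np.all(np.diff(med) < 0)) if len(med) > 1 else False

    if "selected_pairs" in results:
        sel = results["selected_pairs"]
        truth_partner = truth.rates_true_partner
        hits = sum(1 for _, row in sel.iterrows()
                   if truth_partner.get(row["focal_gene"]) == row["partner"])
        report["min_ds_partner_accuracy"] = hits / len(sel) if len(sel) else float("nan")
    return report
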