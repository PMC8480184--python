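"""End-to-end orchestration over a directory of pipeline inputs.

Runs normalize -> segment -> pool -> orthologs -> overlaps -> domain
enrichment -> phylostratigraphy -> rates in dependency order, writing one
TSV per stage plus a structured run log (stage, parameters, input hashes)
and a plain-text summary.  Reruns with identical inputs and configuration
are bit-identical.

The expected input layout is the one the synthetic generator writes
(``counts_<taxon>_*.tsv``, ``markers_<taxon>.yaml``, ``ladder.yaml``,
``hits_*.tsv``, ``domains_<taxon>.tsv``, ``rates_*.tsv``,
``taxon_map.yaml``); each stage is also callable directly on in-memory
objects for real tabular data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import comparative, evorates, io_formats as io, phylostrat, spatial


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and its context."""


@dataclass
class RunConfig:
    """All paths and thresholds for one pipeline run.

    Default thresholds: regional genes need median z-score > 1; orthology
    and protein phylostratigraphy use e-value < 1e-3, nucleotide rescue
    e-value < 1e-5; enrichment significance is FDR-corrected q < 0.05.
    """

    input_dir: str
    out_dir: str
    taxon_a_prefix: str = "Ppa"
    taxon_b_prefix: str = "Cel"
    min_z: float = 1.0
    smooth_window: int = 5
    min_specimens: int | None = None
    max_evalue: float = 1e-3
    fdr_alpha: float = 0.05
    young_strata: tuple = (1, 2, 3)
    reference_median_ds: float = 2.1
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if "young_strata" in doc:
            doc["young_strata"] = tuple(doc["young_strata"])
        return cls(**doc)


def validate_config(cfg: RunConfig) -> list[str]:
    """Return a list of problems (empty means the config is runnable)."""
    problems: list[str] = []
    root = Path(cfg.input_dir)
    if not root.is_dir():
        return [f"input directory {root} does not exist"]
    if not 0 < cfg.fdr_alpha < 1:
        problems.append(f"fdr_alpha must be in (0, 1), got {cfg.fdr_alpha}")
    for name, val in (("min_z", cfg.min_z), ("max_evalue", cfg.max_evalue)):
        if val <= 0:
            problems.append(f"{name} must be positive, got {val}")
    if cfg.smooth_window < 1 or cfg.smooth_window % 2 == 0:
        problems.append(f"smooth_window must be a positive odd int, got {cfg.smooth_window}")
    for fname in ("ladder.yaml", "hits_orthologs.tsv", "taxon_map.yaml"):
        if not (root / fname).exists():
            problems.append(f"missing input file {root / fname}")
    for prefix in (cfg.taxon_a_prefix, cfg.taxon_b_prefix):
        counts = sorted(root.glob(f"counts_{prefix}_*.tsv"))
        if not counts:
            problems.append(f"no count matrices counts_{prefix}_*.tsv in {root}")
            continue
        marker_path = root / f"markers_{prefix}.yaml"
        if not marker_path.exists():
            problems.append(f"missing marker config {marker_path}")
            continue
        try:
            mcfg = io.read_marker_config(marker_path)
        except Exception as exc:
            problems.append(f"{marker_path}: {exc}")
            continue
        genes = set(pd.read_csv(counts[0], sep="\t", usecols=[0]).iloc[:, 0].astype(str))
        for region in mcfg.regions:
            for m in region.markers or ():
                if m not in genes:
                    problems.append(
                        f"marker {m!r} of region {region.label} absent from {counts[0].name}")
    return problems


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def run_spatial_stage(counts_paths, marker_cfg_path, min_z=1.0, smooth_window=5,
                      min_specimens=None):
    """Normalize, segment and pool one species' specimens."""
    mcfg = io.read_marker_config(marker_cfg_path)
    zps, ras = [], []
    for path in counts_paths:
        path = Path(path)
        sc = io.read_section_counts(path, specimen_id=path.stem.removeprefix("counts_"))
        zp = spatial.normalize_and_zscore(sc)
        zps.append(zp)
        ras.append(spatial.segment_regions(zp, mcfg, min_z=min_z,
                                           smooth_window=smooth_window))
    rp = spatial.pool_regions(zps, ras, min_specimens=min_specimens)
    return zps, ras, rp


def run_all(cfg: RunConfig) -> dict:
    """Run every stage; returns in-memory results keyed by stage name."""
    problems = validate_config(cfg)
    if problems:
        raise PipelineError("invalid configuration: " + "; ".join(problems))
    root = Path(cfg.input_dir)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    results: dict = {}

    def stage(name: str, inputs: list[Path], params: dict):
        log.append({"stage": name,
                    "inputs": {p.name: _sha256(p) for p in sorted(inputs)},
                    "params": {k: (list(v) if isinstance(v, tuple) else v)
                               for k, v in params.items()}})

    with open(root / "taxon_map.yaml") as fh:
        taxon_map = yaml.safe_load(fh)

    profiles, assignments, zprofiles = {}, {}, {}
    for prefix in (cfg.taxon_a_prefix, cfg.taxon_b_prefix):
        counts_paths = sorted(root.glob(f"counts_{prefix}_*.tsv"))
        marker_path = root / f"markers_{prefix}.yaml"
        try:
            zps, ras, rp = run_spatial_stage(
                counts_paths, marker_path, min_z=cfg.min_z,
                smooth_window=cfg.smooth_window, min_specimens=cfg.min_specimens)
        except Exception as exc:
            raise PipelineError(f"spatial stage ({prefix}): {exc}") from exc
        stage(f"spatial_{prefix}", counts_paths + [marker_path],
              {"min_z": cfg.min_z, "smooth_window": cfg.smooth_window})
        zprofiles[prefix], assignments[prefix], profiles[prefix] = zps, ras, rp
        _write_tsv(pd.concat([ra.to_frame() for ra in ras], ignore_index=True),
                   out / f"assignments_{prefix}.tsv")
        rp.to_frame().to_csv(out / f"profile_{prefix}.tsv", sep="\t",
                             index_label="gene", float_format="%.6g")

    taxon_a = taxon_map[f"{cfg.taxon_a_prefix}_"]
    taxon_b = taxon_map[f"{cfg.taxon_b_prefix}_"]
    try:
        ortho_hits = io.read_hit_table(root / "hits_orthologs.tsv", taxon_map)
        orthologs = comparative.call_rbh_orthologs(
            ortho_hits, taxon_a, taxon_b, max_evalue=cfg.max_evalue)
    except Exception as exc:
        raise PipelineError(f"ortholog stage: {exc}") from exc
    stage("orthologs", [root / "hits_orthologs.tsv"], {"max_evalue": cfg.max_evalue})
    _write_tsv(orthologs.to_frame(), out / "orthologs.tsv")
    results["orthologs"] = orthologs

    rp_a = profiles[cfg.taxon_a_prefix]
    rp_b = profiles[cfg.taxon_b_prefix]
    cross = comparative.region_overlap_tests(rp_a, rp_b, orthologs)
    _write_tsv(cross, out / "overlap_cross.tsv")
    results["overlap_cross"] = cross
    for prefix in (cfg.taxon_a_prefix, cfg.taxon_b_prefix):
        within = comparative.within_species_overlap_tests(profiles[prefix])
        _write_tsv(within, out / f"overlap_within_{prefix}.tsv")
        results[f"overlap_within_{prefix}"] = within
    stage("overlaps", [], {})

    enriched_counts = {}
    for prefix in (cfg.taxon_a_prefix, cfg.taxon_b_prefix):
        dom_path = root / f"domains_{prefix}.tsv"
        if not dom_path.exists():
            continue
        domains = io.read_domain_table(dom_path)
        enr = comparative.domain_enrichment(profiles[prefix], domains)
        _write_tsv(enr, out / f"domain_enrichment_{prefix}.tsv")
        results[f"domains_{prefix}"] = enr
        enriched_counts[prefix] = int((enr["q"] < cfg.fdr_alpha).sum())
        stage(f"domains_{prefix}", [dom_path], {"fdr_alpha": cfg.fdr_alpha})

    ladder = io.read_ladder_config(root / "ladder.yaml")
    protein_hits = io.read_hit_table(root / "hits_phylostrat_protein.tsv", taxon_map)
    nt_path = root / "hits_phylostrat_nucleotide.tsv"
    nucleotide_hits = io.read_hit_table(nt_path, taxon_map) if nt_path.exists() else None
    universe = set(rp_a.gene_ids)
    try:
        ages = phylostrat.assign_phylostrata(protein_hits, nucleotide_hits, ladder, universe)
    except Exception as exc:
        raise PipelineError(f"phylostratigraphy stage: {exc}") from exc
    stage("ages", [root / "hits_phylostrat_protein.tsv"],
          {"protein_threshold": ladder.protein_threshold,
           "nucleotide_threshold": ladder.nucleotide_threshold})
    ages.rename("stratum").to_frame().to_csv(out / "ages.tsv", sep="\t")
    results["ages"] = ages

    regional_sets = {r: s & universe for r, s in rp_a.regional_sets().items()}
    comp = phylostrat.age_composition(ages, regional_sets, universe,
                                      n_strata=ladder.n_strata)
    _write_tsv(comp, out / "age_composition.tsv")
    results["age_composition"] = comp
    young = phylostrat.young_fraction_test(ages, regional_sets,
                                           cfg.young_strata, universe)
    _write_tsv(young, out / "young_fraction.tsv")
    results["young_test"] = young

    rates_path = root / "rates_close.tsv"
    if rates_path.exists():
        rates = io.read_rates_table(rates_path)
        selected = evorates.select_min_ds_orthologs(rates)
        _write_tsv(selected, out / "rates_selected.tsv")
        results["selected_pairs"] = selected
        by_stratum = evorates.summarize_rates(selected, ages)
        _write_tsv(by_stratum, out / "rates_by_stratum.tsv")
        results["rate_summary"] = by_stratum
        region_of = {g: r for r, genes in regional_sets.items() for g in genes}
        by_region = evorates.summarize_rates(selected, pd.Series(region_of))
        _write_tsv(by_region, out / "rates_by_region.tsv")
        results["rates_by_region"] = by_region
        stage("rates", [rates_path], {})

    candidates = {
        path.stem.removeprefix("rates_candidate_"): io.read_rates_table(path)
        for path in sorted(root.glob("rates_candidate_*.tsv"))
    }
    if candidates:
        chosen, medians = evorates.match_species_pair_by_ds(
            candidates, cfg.reference_median_ds)
        match = medians.rename("median_ds").to_frame()
        match["chosen"] = (match.index == chosen).astype(int)
        match.to_csv(out / "species_pair_match.tsv", sep="\t",
                     index_label="pair", float_format="%.6g")
        results["species_pair"] = (chosen, medians)
        stage("species_pair", [], {"reference_median_ds": cfg.reference_median_ds})

    results["profiles"] = {p: profiles[p] for p in profiles}
    results["assignments"] = assignments
    results["zprofiles"] = zprofiles

    n_expressed = {p: len(profiles[p].expressed_any()) for p in profiles}
    n_regional = {p: int(profiles[p].regional.any(axis=1).sum()) for p in profiles}
    summary = [
        f"expressed genes: " + ", ".join(f"{p}={n}" for p, n in n_expressed.items()),
        f"regional genes: " + ", ".join(f"{p}={n}" for p, n in n_regional.items()),
        f"one-to-one orthologs: {len(orthologs)}",
        f"enriched domains (q < {cfg.fdr_alpha}): "
        + ", ".join(f"{p}={n}" for p, n in enriched_counts.items()),
        "young-fraction ranks: "
        + ", ".join(f"{r}:{int(k)}" for r, k in
                    zip(young["region"], young["rank"])),
    ]
    if "species_pair" in results:
        chosen, medians = results["species_pair"]
        summary.append(f"matched species pair: {chosen} "
                       f"(median dS {medians[chosen]:.3g})")
    (out / "summary.txt").write_text("\n".join(summary) + "\n")
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True)
    return results
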