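"""Readers, writers and validated containers for every external format.

All tabular formats are plain TSV; homology hits follow the BLAST
``outfmt 6`` column convention; marker/ladder configurations are YAML.
Readers never reorder rows or columns silently, and every writer/reader
pair round-trips exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class ValidationError(ValueError):
    """Contents are well-formed but violate a domain invariant."""


# ---------------------------------------------------------------------------
# Section count matrices
# ---------------------------------------------------------------------------

@dataclass
class SectionCounts:
    """One specimen's gene x section transcript-count matrix.

    Columns are physical cryosections ordered anterior to posterior;
    rows are genes.  Counts are non-negative integers.
    """

    specimen_id: str
    gene_ids: list[str]
    section_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.section_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.section_ids)} sections"
            )
        if len(self.section_ids) < 2:
            raise ValidationError("at least 2 sections required")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValidationError(f"duplicate gene ids: {dupes[:5]}")
        if len(set(self.section_ids)) != len(self.section_ids):
            raise ValidationError("duplicate section ids")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            g, s = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at gene {self.gene_ids[g]!r}, "
                f"section {self.section_ids[s]!r}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.section_ids)


def read_section_counts(path: str | Path, specimen_id: str | None = None) -> SectionCounts:
    """Read a gene x section count TSV (header = section ids, col 0 = gene ids)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse TSV: {exc}") from exc
    mat = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, val in enumerate(df[col].to_numpy()):
            try:
                iv = int(val)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-integer cell {val!r} at row {df.index[i]!r}, "
                    f"column {col!r}"
                ) from None
            if iv < 0:
                raise FormatError(
                    f"{path}: negative cell {iv} at row {df.index[i]!r}, column {col!r}"
                )
            mat[i, j] = iv
    sid = specimen_id if specimen_id is not None else path.stem
    try:
        return SectionCounts(sid, [str(g) for g in df.index], [str(c) for c in df.columns], mat)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_section_counts(sc: SectionCounts, path: str | Path) -> None:
    sc.to_frame().to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# Homology hit tables (BLAST outfmt-6 dialects)
# ---------------------------------------------------------------------------

#: full 12-column BLAST tabular layout
BLAST12_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]
#: reduced dialect: the columns the pipeline actually consumes
BLAST6_COLUMNS = ["qseqid", "sseqid", "pident", "length", "evalue", "bitscore"]

HIT_COLUMNS = ["query_id", "target_id", "query_taxon", "target_taxon",
               "evalue", "bitscore", "query_end"]


def resolve_taxon(gene_id: str, taxon_map: Mapping[str, str]) -> str | None:
    """Resolve a gene id to its taxon by longest matching id prefix."""
    best = None
    best_len = -1
    for prefix, taxon in taxon_map.items():
        if gene_id.startswith(prefix) and len(prefix) > best_len:
            best, best_len = taxon, len(prefix)
    return best


def read_hit_table(path: str | Path, taxon_map: Mapping[str, str],
                   dialect: str = "blast12") -> pd.DataFrame:
    """Read a homology hit table; all rows retained (no threshold applied).

    Returns a DataFrame with columns ``query_id, target_id, query_taxon,
    target_taxon, evalue, bitscore, query_end`` (``query_end`` is NaN for the
    reduced dialect).  Taxa are resolved from id prefixes via ``taxon_map``.
    """
    path = Path(path)
    cols = {"blast12": BLAST12_COLUMNS, "blast6": BLAST6_COLUMNS}.get(dialect)
    if cols is None:
        raise ValueError(f"unknown hit-table dialect {dialect!r}")
    try:
        raw = pd.read_csv(path, sep="\t", header=None, names=cols, dtype={0: str, 1: str})
    except pd.errors.EmptyDataError:
        raw = pd.DataFrame(columns=cols)
    if len(raw.columns) != len(cols):  # pragma: no cover
        raise FormatError(f"{path}: expected {len(cols)} columns, got {len(raw.columns)}")
    df = pd.DataFrame({
        "query_id": raw["qseqid"].astype(str),
        "target_id": raw["sseqid"].astype(str),
    })
    for side, col in (("query", "query_id"), ("target", "target_id")):
        df[f"{side}_taxon"] = [resolve_taxon(g, taxon_map) for g in df[col]]
        bad = df.loc[df[f"{side}_taxon"].isna(), col]
        if len(bad):
            raise ValidationError(
                f"{path}: unresolvable taxon for ids: {sorted(set(bad))[:10]}"
            )
    df["evalue"] = pd.to_numeric(raw["evalue"], errors="raise").astype(float)
    df["bitscore"] = pd.to_numeric(raw["bitscore"], errors="raise").astype(float)
    df["query_end"] = (pd.to_numeric(raw["qend"], errors="raise").astype(float)
                       if dialect == "blast12" else np.nan)
    if (df["evalue"] < 0).any():
        raise ValidationError(f"{path}: negative e-values")
    return df[HIT_COLUMNS]


def write_hit_table(hits: pd.DataFrame, path: str | Path) -> None:
    """Write hits as 12-column BLAST tabular (unused columns zero-filled)."""
    qend = hits["query_end"].fillna(0).astype(int) if "query_end" in hits else 0
    out = pd.DataFrame({
        "qseqid": hits["query_id"], "sseqid": hits["target_id"],
        "pident": 100.0, "length": 0, "mismatch": 0, "gapopen": 0,
        "qstart": 1, "qend": qend, "sstart": 0, "send": 0,
        "evalue": hits["evalue"].map("{:.6g}".format),
        "bitscore": hits["bitscore"].map("{:.6g}".format),
    })
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Protein-domain membership
# ---------------------------------------------------------------------------

def read_domain_table(path: str | Path) -> pd.DataFrame:
    """Read (gene_id, domain_id) pairs; duplicates are dropped on load."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["gene_id", "domain_id"])
    if not {"gene_id", "domain_id"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns gene_id, domain_id")
    return df[["gene_id", "domain_id"]].drop_duplicates(ignore_index=True)


def write_domain_table(domains: pd.DataFrame, path: str | Path) -> None:
    domains[["gene_id", "domain_id"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Ortholog-pair evolutionary rates
# ---------------------------------------------------------------------------

RATES_COLUMNS = ["gene_a", "gene_b", "dN", "dS", "omega"]


def validate_rates(df: pd.DataFrame, rel_tol: float = 1e-6) -> pd.DataFrame:
    for col in ("dN", "dS", "omega"):
        if (df[col].dropna() < 0).any():
            raise ValidationError(f"negative values in {col}")
    ok = df["dS"] > 0
    both = ok & df["omega"].notna() & df["dN"].notna()
    expect = df.loc[both, "dN"] / df.loc[both, "dS"]
    bad = ~np.isclose(df.loc[both, "omega"], expect, rtol=rel_tol, atol=1e-12)
    if bad.any():
        i = df.loc[both].index[bad][0]
        raise ValidationError(
            f"omega inconsistent with dN/dS at row {i}: "
            f"{df.loc[i, 'omega']} vs {expect.loc[i]}"
        )
    return df


def read_rates_table(path: str | Path) -> pd.DataFrame:
    """Read pairwise rates (gene_a, gene_b, dN, dS, omega); 'NA' -> undefined."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str},
                         na_values=["NA"], keep_default_na=True)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=RATES_COLUMNS)
    if not set(RATES_COLUMNS) <= set(df.columns):
        raise FormatError(f"{path}: expected columns {RATES_COLUMNS}")
    df = df[RATES_COLUMNS].copy()
    for col in ("dN", "dS", "omega"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
    return validate_rates(df)


def write_rates_table(rates: pd.DataFrame, path: str | Path) -> None:
    out = rates[RATES_COLUMNS].copy()
    for col in ("dN", "dS", "omega"):
        out[col] = out[col].map(lambda v: "NA" if pd.isna(v) else f"{v:.12g}")
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Marker and ladder configurations
# ---------------------------------------------------------------------------

@dataclass
class RegionSpec:
    """One region along the A-P axis: marker-defined or indirect."""

    label: str
    markers: tuple[str, ...] | None = None
    peak: int | None = None          # which A-P occurrence of the marker peak
    between: tuple[str, str] | None = None  # (left anchor, right anchor)

    @property
    def is_marker(self) -> bool:
        return self.markers is not None


@dataclass
class MarkerConfig:
    """Ordered region definitions used to segment a specimen."""

    regions: list[RegionSpec]

    def __post_init__(self) -> None:
        labels = [r.label for r in self.regions]
        if len(set(labels)) != len(labels):
            raise ValidationError("region labels not unique")
        marker_labels = {r.label for r in self.regions if r.is_marker}
        for r in self.regions:
            if r.is_marker:
                if not r.markers or r.peak is None or r.peak < 1:
                    raise ValidationError(f"region {r.label}: invalid marker spec")
            else:
                if r.between is None:
                    raise ValidationError(
                        f"region {r.label}: neither marker-defined nor indirect")
                left, right = r.between
                if left not in marker_labels or right not in marker_labels:
                    raise ValidationError(
                        f"region {r.label}: anchors {r.between} not marker-defined regions")
                order = {lab: i for i, lab in enumerate(labels)}
                if not order[left] < order[r.label] < order[right]:
                    raise ValidationError(
                        f"region {r.label}: anchors {r.between} do not flank it in order")

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.regions]


@dataclass
class LadderConfig:
    """Ladder-phylogeny phylostratum definition for one focal species.

    Stratum 1 (youngest) contains only the focal taxon; increasing index
    means increasingly distant taxon groups.
    """

    focal_taxon: str
    strata: list[list[str]]
    protein_threshold: float = 1e-3
    nucleotide_threshold: float = 1e-5

    def __post_init__(self) -> None:
        if not self.strata or set(self.strata[0]) != {self.focal_taxon}:
            raise ValidationError("stratum 1 must contain exactly the focal taxon")
        seen: set[str] = set()
        for taxa in self.strata:
            if seen & set(taxa):
                raise ValidationError(f"taxa in multiple strata: {seen & set(taxa)}")
            seen |= set(taxa)
        if self.protein_threshold <= 0 or self.nucleotide_threshold <= 0:
            raise ValidationError("thresholds must be > 0")

    @property
    def n_strata(self) -> int:
        return len(self.strata)

    def taxon_stratum(self) -> dict[str, int]:
        return {t: i + 1 for i, taxa in enumerate(self.strata) for t in taxa}


def read_marker_config(path: str | Path) -> MarkerConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    regions = []
    for entry in doc["regions"]:
        regions.append(RegionSpec(
            label=str(entry["label"]),
            markers=tuple(entry["markers"]) if "markers" in entry else None,
            peak=int(entry["peak"]) if "peak" in entry else None,
            between=tuple(entry["between"]) if "between" in entry else None,
        ))
    return MarkerConfig(regions)


def write_marker_config(cfg: MarkerConfig, path: str | Path) -> None:
    doc = {"regions": []}
    for r in cfg.regions:
        entry: dict = {"label": r.label}
        if r.is_marker:
            entry["markers"] = list(r.markers)
            entry["peak"] = r.peak
        else:
            entry["between"] = list(r.between)
        doc["regions"].append(entry)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_ladder_config(path: str | Path) -> LadderConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return LadderConfig(
        focal_taxon=str(doc["focal_taxon"]),
        strata=[[str(t) for t in taxa] for taxa in doc["strata"]],
        protein_threshold=float(doc.get("protein_threshold", 1e-3)),
        nucleotide_threshold=float(doc.get("nucleotide_threshold", 1e-5)),
    )


def write_ladder_config(cfg: LadderConfig, path: str | Path) -> None:
    doc = {
        "focal_taxon": cfg.focal_taxon,
        "strata": [list(t) for t in cfg.strata],
        "protein_threshold": cfg.protein_threshold,
        "nucleotide_threshold": cfg.nucleotide_threshold,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA; ids must be unique, sequences non-empty, returned uppercase."""
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValidationError(f"{path}: empty sequence for {rec.id!r}")
        records.append((rec.id, seq))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path), "fasta",
    )
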