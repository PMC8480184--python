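"""Normalization, z-scoring, marker-peak segmentation and region pooling.

The spatial unit is a 20 um cryosection; a specimen is a gene x section
count matrix ordered anterior to posterior.  Counts are normalized by
section totals, z-scored per gene across a specimen's sections, specimens
are segmented into contiguous anatomical regions via marker-gene peaks,
and specimens are pooled into a region profile of median z-scores from
which expressed (median normalized count > 0) and regional (median
z-score > 1) genes are called.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.ndimage import median_filter
from scipy.spatial.distance import squareform

from .io_formats import MarkerConfig, SectionCounts, ValidationError


class SegmentationError(ValueError):
    """Marker peaks cannot be reconciled with the region configuration."""


@dataclass
class ZProfile:
    """Per-specimen normalized expression and per-gene z-score profiles.

    ``normalized[g, s] = counts[g, s] / sum_g counts[g, s]``; ``z`` rows are
    centred/scaled with the sample (n-1) standard deviation, and are NaN for
    genes whose normalized values are constant across sections.
    """

    specimen_id: str
    gene_ids: list[str]
    section_ids: list[str]
    normalized: np.ndarray
    z: np.ndarray
    detected: np.ndarray  # per gene: any nonzero count in this specimen

    def z_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.z, index=self.gene_ids, columns=self.section_ids)


@dataclass
class RegionAssignment:
    """Map from each section of one specimen to a contiguous region."""

    specimen_id: str
    section_ids: list[str]
    region_of: list[str]  # one label per section, A-P order
    region_order: list[str]

    def __post_init__(self) -> None:
        if len(self.region_of) != len(self.section_ids):
            raise ValidationError("one region per section required")
        # contiguity + order check
        runs: list[str] = []
        for lab in self.region_of:
            if not runs or runs[-1] != lab:
                runs.append(lab)
        if runs != [r for r in self.region_order if r in set(runs)] or len(set(runs)) != len(runs):
            raise ValidationError(f"regions not contiguous/ordered: {runs}")

    def sections_of(self, region: str) -> list[int]:
        return [i for i, lab in enumerate(self.region_of) if lab == region]

    def boundaries(self) -> list[int]:
        """0-based first-section index of each region after the first."""
        out = []
        for i in range(1, len(self.region_of)):
            if self.region_of[i] != self.region_of[i - 1]:
                out.append(i)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "specimen": self.specimen_id,
            "section": self.section_ids,
            "section_index": np.arange(1, len(self.section_ids) + 1),  # 1-based report
            "region": self.region_of,
        })


@dataclass
class RegionProfile:
    """Pooled gene x region profile over specimens.

    ``median_z`` pools the z-scores of every section assigned to a region in
    every specimen; ``regional`` is ``median_z > 1`` (strict), ``expressed``
    is ``median_norm > 0``.
    """

    gene_ids: list[str]
    region_labels: list[str]
    median_z: np.ndarray
    median_norm: np.ndarray
    expressed: np.ndarray
    regional: np.ndarray

    def regional_sets(self) -> dict[str, set[str]]:
        genes = np.asarray(self.gene_ids)
        return {r: set(genes[self.regional[:, j]])
                for j, r in enumerate(self.region_labels)}

    def expressed_any(self) -> set[str]:
        genes = np.asarray(self.gene_ids)
        return set(genes[self.expressed.any(axis=1)])

    def to_frame(self) -> pd.DataFrame:
        mz = pd.DataFrame(self.median_z, index=self.gene_ids, columns=self.region_labels)
        out = mz.add_prefix("median_z.")
        mn = pd.DataFrame(self.median_norm, index=self.gene_ids,
                          columns=[f"median_norm.{r}" for r in self.region_labels])
        reg = pd.DataFrame(self.regional.astype(int), index=self.gene_ids,
                           columns=[f"regional.{r}" for r in self.region_labels])
        exp = pd.DataFrame(self.expressed.astype(int), index=self.gene_ids,
                           columns=[f"expressed.{r}" for r in self.region_labels])
        return pd.concat([out, mn, reg, exp], axis=1)


def normalize_and_zscore(sc: SectionCounts) -> ZProfile:
    """Normalize by section totals and z-score each gene across sections.

    Sections with a zero total count are dropped with a warning; if all
    totals are zero an error is raised.  z rows use the sample (n-1)
    standard deviation; constant rows are NaN.
    """
    totals = sc.counts.sum(axis=0)
    keep = totals > 0
    if not keep.any():
        raise ValidationError(f"{sc.specimen_id}: all section totals are zero")
    if not keep.all():
        dropped = [s for s, k in zip(sc.section_ids, keep) if not k]
        warnings.warn(f"{sc.specimen_id}: dropping zero-total sections {dropped}")
    counts = sc.counts[:, keep].astype(float)
    sections = [s for s, k in zip(sc.section_ids, keep) if k]
    normalized = counts / counts.sum(axis=0, keepdims=True)
    mean = normalized.mean(axis=1, keepdims=True)
    sd = normalized.std(axis=1, ddof=1, keepdims=True)
    constant = normalized.max(axis=1) == normalized.min(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (normalized - mean) / sd
    z[constant, :] = np.nan
    detected = counts.sum(axis=1) > 0
    return ZProfile(sc.specimen_id, list(sc.gene_ids), sections, normalized, z, detected)


def _running_median(signal: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return signal.copy()
    if window % 2 == 0:
        raise ValueError("smooth_window must be odd")
    return median_filter(signal, size=window, mode="nearest")


def detect_marker_peaks(zp: ZProfile, markers, min_z: float = 1.0,
                        smooth_window: int = 3) -> list[tuple[int, int, int]]:
    """Find A-P-ordered peaks of a marker set's mean z signal.

    The per-section signal is the mean z over available markers, smoothed by
    a running median; peaks are maximal contiguous runs of sections with
    smoothed signal > ``min_z``.  Returns ``(start, end, peak)`` 0-based
    inclusive intervals; ``peak`` is the most anterior argmax in the run.
    """
    idx = {g: i for i, g in enumerate(zp.gene_ids)}
    rows = []
    for m in markers:
        if m not in idx:
            warnings.warn(f"{zp.specimen_id}: marker {m!r} absent; skipped")
            continue
        row = zp.z[idx[m]]
        if np.isnan(row).all():
            warnings.warn(f"{zp.specimen_id}: marker {m!r} has undefined z; skipped")
            continue
        rows.append(row)
    if not rows:
        raise ValidationError(f"{zp.specimen_id}: no usable markers among {list(markers)}")
    signal = _running_median(np.mean(rows, axis=0), smooth_window)
    above = signal > min_z
    peaks: list[tuple[int, int, int]] = []
    i = 0
    n = len(signal)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            peak = i + int(np.argmax(signal[i:j + 1]))
            peaks.append((i, j, peak))
            i = j + 1
        else:
            i += 1
    return peaks


def segment_regions(zp: ZProfile, cfg: MarkerConfig, min_z: float = 1.0,
                    smooth_window: int = 3) -> RegionAssignment:
    """Partition a specimen's sections into the configured regions.

    Marker-defined regions are seeded by the requested A-P occurrence of
    their marker set's peak; boundaries between consecutive seeded regions
    fall at the midpoint of the inter-peak gap (ties: extra section to the
    anterior region); indirect regions take the sections strictly between
    their anchors; the first/last regions absorb leading/trailing sections.
    """
    n = len(zp.section_ids)
    # peaks per unique marker set (regions may share a set, e.g. a two-peak
    # sperm marker whose 1st/2nd occurrences seed two regions)
    peak_cache: dict[tuple[str, ...], list[tuple[int, int, int]]] = {}
    seeds: dict[str, tuple[int, int]] = {}
    for r in cfg.regions:
        if not r.is_marker:
            continue
        key = tuple(r.markers)
        if key not in peak_cache:
            peak_cache[key] = detect_marker_peaks(zp, key, min_z, smooth_window)
        peaks = peak_cache[key]
        if len(peaks) < r.peak:
            raise SegmentationError(
                f"{zp.specimen_id}: region {r.label}: peak #{r.peak} of markers "
                f"{list(r.markers)} not found ({len(peaks)} peak(s) detected)")
        start, end, _ = peaks[r.peak - 1]
        seeds[r.label] = (start, end)

    marker_regions = [r.label for r in cfg.regions if r.is_marker]
    intervals = [seeds[lab] for lab in marker_regions]
    for (s1, e1), (s2, e2), l1, l2 in zip(intervals, intervals[1:],
                                          marker_regions, marker_regions[1:]):
        if not e1 < s2:
            raise SegmentationError(
                f"{zp.specimen_id}: seeded peaks for {l1} (ends {e1 + 1}) and {l2} "
                f"(starts {s2 + 1}) are out of configured A-P order")

    if not cfg.regions[0].is_marker or not cfg.regions[-1].is_marker:
        raise SegmentationError("first and last regions must be marker-defined")

    # extents start as the seed intervals, then gaps are apportioned
    extent = {lab: list(seeds[lab]) for lab in marker_regions}
    labels_in_order = cfg.labels
    pos = {lab: i for i, lab in enumerate(labels_in_order)}
    indirect_gap: dict[str, tuple[int, int]] = {}
    for left, right in zip(marker_regions, marker_regions[1:]):
        between = [lab for lab in labels_in_order[pos[left] + 1:pos[right]]]
        indirect = [lab for lab in between
                    if not next(r for r in cfg.regions if r.label == lab).is_marker]
        gap_start, gap_end = extent[left][1] + 1, extent[right][0] - 1  # inclusive
        if indirect:
            if len(indirect) > 1:
                raise SegmentationError(
                    f"multiple indirect regions {indirect} between {left} and {right}")
            spec = next(r for r in cfg.regions if r.label == indirect[0])
            if spec.between != (left, right):
                raise SegmentationError(
                    f"region {indirect[0]}: anchors {spec.between} do not match "
                    f"flanking marker regions ({left}, {right})")
            indirect_gap[indirect[0]] = (gap_start, gap_end)
        else:
            gap = gap_end - gap_start + 1
            take_left = (gap + 1) // 2  # tie -> anterior
            extent[left][1] += take_left
            extent[right][0] -= gap - take_left
    extent[marker_regions[0]][0] = 0
    extent[marker_regions[-1]][1] = n - 1

    region_of = [None] * n
    for lab, (s, e) in extent.items():
        for i in range(s, e + 1):
            region_of[i] = lab
    for lab, (s, e) in indirect_gap.items():
        for i in range(s, e + 1):
            region_of[i] = lab
    if any(lab is None for lab in region_of):  # pragma: no cover - by construction
        raise SegmentationError("unassigned sections remain")
    present = [lab for lab in labels_in_order if lab in set(region_of)]
    return RegionAssignment(zp.specimen_id, list(zp.section_ids), region_of, present)


def pool_regions(zps: list[ZProfile], ras: list[RegionAssignment],
                 min_specimens: int | None = None) -> RegionProfile:
    """Pool specimens into a region profile of median z / normalized counts.

    The gene universe is the genes detected (nonzero total) in at least
    ``min_specimens`` specimens (default: all of them).  Undefined z entries
    are excluded from medians; an all-undefined pool leaves NaN and the gene
    is not regional there.
    """
    if len(zps) != len(ras) or not zps:
        raise ValidationError("need matching, nonempty ZProfile/RegionAssignment lists")
    if min_specimens is None:
        min_specimens = len(zps)
    label_sets = {tuple(ra.region_order) for ra in ras}
    if len(label_sets) != 1:
        raise ValidationError(f"specimens disagree on region labels: {label_sets}")
    regions = list(ras[0].region_order)

    det = pd.DataFrame(0, index=zps[0].gene_ids, columns=range(len(zps)))
    for i, zp in enumerate(zps):
        det[i] = pd.Series(zp.detected.astype(int), index=zp.gene_ids)
    det = det.fillna(0)
    genes = [g for g in zps[0].gene_ids if det.loc[g].sum() >= min_specimens]
    if not genes:
        raise ValidationError("empty gene universe after detection filter")

    n_g, n_r = len(genes), len(regions)
    median_z = np.full((n_g, n_r), np.nan)
    median_norm = np.full((n_g, n_r), np.nan)
    for j, region in enumerate(regions):
        z_cols, n_cols = [], []
        for zp, ra in zip(zps, ras):
            sec = ra.sections_of(region)
            if sec:
                zf = zp.z_frame().reindex(genes)
                nf = pd.DataFrame(zp.normalized, index=zp.gene_ids,
                                  columns=zp.section_ids).reindex(genes)
                z_cols.append(zf.iloc[:, sec].to_numpy())
                n_cols.append(nf.iloc[:, sec].to_numpy())
        if not z_cols:
            raise ValidationError(f"region {region}: no pooled sections")
        zs = np.concatenate(z_cols, axis=1)
        ns = np.concatenate(n_cols, axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            median_z[:, j] = np.nanmedian(zs, axis=1)
            median_norm[:, j] = np.nanmedian(ns, axis=1)
    expressed = np.nan_to_num(median_norm, nan=0.0) > 0
    regional = np.where(np.isnan(median_z), -np.inf, median_z) > 1.0
    return RegionProfile(genes, regions, median_z, median_norm, expressed, regional)


# ---------------------------------------------------------------------------
# Hierarchical clustering (1 - Pearson, complete linkage)
# ---------------------------------------------------------------------------

def _complete_linkage_from_corr(features: pd.DataFrame):
    """Complete linkage on 1 - pairwise-complete Pearson over columns."""
    corr = features.corr(method="pearson", min_periods=2)
    bad = [c for c in corr.columns if corr[c].isna().all()]
    if bad:
        warnings.warn(f"excluding zero-variance/undefined columns: {bad}")
        corr = corr.drop(index=bad, columns=bad)
    if corr.shape[0] < 2:
        raise ValidationError("fewer than 2 clusterable items")
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="complete")
    return Z, list(corr.columns)


def cluster_sections(zps: list[ZProfile]):
    """Cluster all specimens' sections on 1 - Pearson of z profiles.

    Correlations use genes with defined z in both sections (pairwise
    complete).  Returns (scipy linkage matrix, leaf labels
    ``specimen:section``).
    """
    common = set(zps[0].gene_ids)
    for zp in zps[1:]:
        common &= set(zp.gene_ids)
    genes = [g for g in zps[0].gene_ids if g in common]
    cols = {}
    for zp in zps:
        zf = zp.z_frame().reindex(genes)
        for s in zp.section_ids:
            cols[f"{zp.specimen_id}|{s}"] = zf[s].to_numpy()
    features = pd.DataFrame(cols)
    if features.shape[1] < 2:
        raise ValidationError("need at least 2 sections")
    return _complete_linkage_from_corr(features)


def cluster_regions_by_orthologs(rp_a: RegionProfile, rp_b: RegionProfile,
                                 orthologs, label_a: str = "A", label_b: str = "B"):
    """Cluster both species' regions on median z of one-to-one orthologs.

    Feature vectors are the pooled median z-scores restricted to ortholog
    pairs regional in at least one species (species-a gene for a-regions,
    its partner for b-regions).  Returns (linkage matrix, leaf labels).
    """
    idx_a = {g: i for i, g in enumerate(rp_a.gene_ids)}
    idx_b = {g: i for i, g in enumerate(rp_b.gene_ids)}
    pairs = []
    for ga, gb in orthologs.pairs:
        if ga in idx_a and gb in idx_b and (
                rp_a.regional[idx_a[ga]].any() or rp_b.regional[idx_b[gb]].any()):
            pairs.append((ga, gb))
    if not pairs:
        raise ValidationError("no ortholog pairs pass the regional-in-either filter")
    cols = {}
    for j, r in enumerate(rp_a.region_labels):
        cols[f"{label_a}|{r}"] = np.array([rp_a.median_z[idx_a[ga], j] for ga, _ in pairs])
    for j, r in enumerate(rp_b.region_labels):
        cols[f"{label_b}|{r}"] = np.array([rp_b.median_z[idx_b[gb], j] for _, gb in pairs])
    return _complete_linkage_from_corr(pd.DataFrame(cols))


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_dist):
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        return f"({rec(node.left, node.dist)},{rec(node.right, node.dist)}):{length:.6g}"

    return rec(tree, tree.dist) + ";"
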