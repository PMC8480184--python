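"""Reference-transcriptome preparation: isoform selection and ORF extraction.

Reduces a strand-specific transcriptome assembly to one representative
isoform per gene by three rules — prefer the isoform with a poly-A tail
(a terminal run of six or more adenines); among several tailed isoforms
prefer the one whose best protein hit aligns most 3' on the transcript;
otherwise fall back to the longest isoform — and extracts the longest
stop-free translatable peptide from each representative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio.Data import CodonTable

from .io_formats import ValidationError

__all__ = ["has_polya_tail", "IsoformGroup", "select_isoform",
           "select_reference_isoforms", "longest_orf_peptide", "best_protein_hits"]

_STANDARD = CodonTable.unambiguous_dna_by_name["Standard"]
_FORWARD = dict(_STANDARD.forward_table)
_STOPS = set(_STANDARD.stop_codons)


def has_polya_tail(seq: str, min_run: int = 6) -> bool:
    """True iff the sequence ends in a run of >= ``min_run`` adenines."""
    if not seq:
        raise ValidationError("empty sequence")
    seq = seq.upper()
    run = len(seq) - len(seq.rstrip("A"))
    return run >= min_run


@dataclass
class IsoformGroup:
    """All assembled isoforms of one gene, with their best protein hits.

    ``protein_hits`` maps transcript id -> (target_id, evalue, bitscore,
    query_alignment_end) where the alignment end is 1-based on the
    transcript.
    """

    gene_id: str
    isoforms: list[tuple[str, str]]
    protein_hits: dict[str, tuple[str, float, float, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.isoforms:
            raise ValidationError(f"{self.gene_id}: no isoforms")
        lengths = {tid: len(seq) for tid, seq in self.isoforms}
        for tid, (_, _, _, qend) in self.protein_hits.items():
            if tid in lengths and qend > lengths[tid]:
                raise ValidationError(
                    f"{self.gene_id}/{tid}: alignment end {qend} beyond length {lengths[tid]}")


def _longest(isoforms: list[tuple[str, str]]) -> str:
    """Longest isoform; ties resolved lexicographically on transcript id."""
    return min(isoforms, key=lambda it: (-len(it[1]), it[0]))[0]


def select_isoform(group: IsoformGroup, min_polya_run: int = 6,
                   relative_alignment_end: bool = True) -> tuple[str, str]:
    """Pick the representative isoform of a gene; returns (transcript, rule).

    Rule "polya": exactly one isoform carries a poly-A tail.  Rule
    "alignment": among several tailed isoforms, the one whose best protein
    hit ends most 3' (alignment end normalized by transcript length unless
    ``relative_alignment_end`` is off; ties -> longest, then lexicographic).
    Rule "longest": no tail, or the tie is unresolvable by hits.
    """
    tailed = [(tid, seq) for tid, seq in group.isoforms
              if has_polya_tail(seq, min_polya_run)]
    if len(tailed) == 1:
        return tailed[0][0], "polya"
    if len(tailed) > 1:
        scored = []
        for tid, seq in tailed:
            hit = group.protein_hits.get(tid)
            if hit is not None:
                _, _, _, qend = hit
                score = qend / len(seq) if relative_alignment_end else float(qend)
                scored.append((tid, seq, score))
        if scored:
            best = min(scored, key=lambda t: (-t[2], -len(t[1]), t[0]))
            return best[0], "alignment"
        return _longest(tailed), "longest"
    return _longest(group.isoforms), "longest"


def select_reference_isoforms(groups: list[IsoformGroup], **kwargs) -> pd.DataFrame:
    """Apply isoform selection to every gene; returns (gene, transcript, rule)."""
    rows = []
    for group in groups:
        tid, rule = select_isoform(group, **kwargs)
        rows.append({"gene": group.gene_id, "transcript": tid, "rule": rule})
    return pd.DataFrame(rows)


def best_protein_hits(hits: pd.DataFrame) -> dict[str, tuple[str, float, float, int]]:
    """Best protein hit per transcript (lowest e-value, then highest bitscore).

    Expects the io_formats hit-table columns with ``query_end`` populated
    (the 12-column dialect).
    """
    out: dict[str, tuple[str, float, float, int]] = {}
    ordered = hits.sort_values(["query_id", "evalue", "bitscore", "target_id"],
                               ascending=[True, True, False, True], kind="mergesort")
    for _, row in ordered.drop_duplicates("query_id", keep="first").iterrows():
        out[row["query_id"]] = (row["target_id"], float(row["evalue"]),
                                float(row["bitscore"]), int(row["query_end"]))
    return out


def longest_orf_peptide(seq: str) -> str:
    """Longest stop-free translatable peptide over the three forward frames.

    A start codon is not required (partial peptides allowed); codons
    containing ambiguity characters translate to 'X' without breaking the
    run.  Ties prefer the most 5' start position, then the lowest frame.
    Sequences shorter than one codon yield the empty peptide.
    """
    seq = seq.upper()
    best = ""           # peptide
    best_key = None     # (-length, start_nt, frame)
    for frame in range(3):
        pep_chars: list[str] = []
        run_start = frame
        pos = frame
        codons = [(seq[i:i + 3], i) for i in range(frame, len(seq) - 2, 3)]
        for codon, i in codons + [(None, None)]:
            if codon is None or codon in _STOPS:
                if pep_chars:
                    key = (-len(pep_chars), run_start, frame)
                    if best_key is None or key < best_key:
                        best_key = key
                        best = "".join(pep_chars)
                pep_chars = []
                if i is not None:
                    run_start = i + 3
            else:
                if not pep_chars:
                    run_start = i
                pep_chars.append(_FORWARD.get(codon, "X"))
    return best
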