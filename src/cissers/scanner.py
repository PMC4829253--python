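"""Motif scanning and the site census engine.

Every table and marker workflow in this package rests on one operation:
locate all matches of a set of degenerate patterns in every record of a
multi-FASTA dataset, optionally restricted to a window measured from the
5' or 3' end of each sequence.

Match coordinates are recognition-site starts (0-based); cleavage offsets
only matter during digestion.  Two overlap disciplines are supported:
``non_overlapping`` (the default; after a match the scan resumes at the
match end, i.e. scripting-language global-match semantics) and
``overlapping`` (resume one base after the match start, so self-overlapping
degenerate motifs report every occurrence).  Scanning the minus strand is
performed by matching the reverse-complement pattern against the forward
text and labeling hits with strand '-'.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .enzyme_db import MotifPattern, reverse_complement_pattern
from .sequence_io import SequenceRecord

__all__ = [
    "RegionSpec",
    "MatchSite",
    "SiteIndex",
    "scan_record",
    "scan_dataset",
    "associate_with_annotation",
    "promoter_census",
]

NON_OVERLAPPING = "non_overlapping"
OVERLAPPING = "overlapping"


@dataclass(frozen=True)
class RegionSpec:
    """Which part of each record to census.

    ``whole`` scans everything.  ``five_prime``/``three_prime`` scan the
    half-open offset window [start, end) measured from the chosen end of
    each record; for ``three_prime`` the absolute window is computed from
    each record's own length.  Matches upstream of the window (between the
    sequence start and the window start) are tallied separately as the
    pre-cut area — they matter when downstream applications impose minimum
    fragment lengths.
    """

    mode: str = "whole"
    start: int = 0
    end: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("whole", "five_prime", "three_prime"):
            raise ValueError(f"unknown region mode {self.mode!r}")
        if self.mode != "whole" and not (0 <= self.start < self.end):
            raise ValueError("windowed region requires 0 <= start < end")

    def window_for(self, seq_len: int) -> tuple[int, int, bool]:
        """Absolute half-open window for a record of ``seq_len`` bases.

        Returns (win_start, win_end, truncated); a record shorter than the
        window contributes only what fits.
        """
        if self.mode == "whole":
            return 0, seq_len, False
        if self.mode == "five_prime":
            lo, hi = self.start, self.end
        else:  # three_prime: offsets measured from the 3' end
            lo, hi = seq_len - self.end, seq_len - self.start
        truncated = lo < 0 or hi > seq_len
        return max(0, lo), min(seq_len, hi), truncated


@dataclass(frozen=True)
class MatchSite:
    record_id: str
    pattern_name: str
    start: int
    strand: str = "+"


def _compiled(p: MotifPattern) -> re.Pattern:
    return re.compile(p.to_regex())


def scan_record(
    seq: str, p: MotifPattern, overlap_mode: str = NON_OVERLAPPING
) -> list[int]:
    """All match start positions of ``p`` in ``seq``, left to right.

    A pattern longer than the sequence simply yields no matches.
    """
    if overlap_mode not in (NON_OVERLAPPING, OVERLAPPING):
        raise ValueError(f"unknown overlap mode {overlap_mode!r}")
    rx = _compiled(p)
    if overlap_mode == NON_OVERLAPPING:
        return [m.start() for m in rx.finditer(seq)]
    return [m.start() for m in re.compile(f"(?={rx.pattern})").finditer(seq)]


class SiteIndex:
    """Per-(pattern, record) sorted match positions plus aggregates.

    ``n_precut_matches`` counts matches between the sequence start and the
    census window start; post-window matches are retained so that the
    window-partition identity (in-region + pre-cut + post-region =
    whole-sequence) is checkable.
    """

    def __init__(self, region: RegionSpec, n_records: int):
        self.region = region
        self.n_records = n_records
        # (pattern_name, record_id, strand) -> sorted in-region starts
        self._hits: dict[tuple[str, str, str], list[int]] = {}
        self._records_cut: dict[str, set[str]] = {}
        self._totals: dict[str, int] = {}
        self._precut: dict[str, int] = {}
        self._post: dict[str, int] = {}
        self.n_truncated_records = 0
        self.pattern_names: list[str] = []
        self.record_ids: set[str] = set()

    def _register_pattern(self, name: str) -> None:
        if name not in self._totals:
            self.pattern_names.append(name)
            self._records_cut[name] = set()
            self._totals[name] = 0
            self._precut[name] = 0
            self._post[name] = 0

    def add_matches(
        self,
        pattern_name: str,
        record_id: str,
        strand: str,
        in_region: list[int],
        n_precut: int,
        n_post: int,
    ) -> None:
        self._register_pattern(pattern_name)
        if in_region:
            self._hits[(pattern_name, record_id, strand)] = sorted(in_region)
            self._records_cut[pattern_name].add(record_id)
            self._totals[pattern_name] += len(in_region)
        self._precut[pattern_name] += n_precut
        self._post[pattern_name] += n_post

    def positions(self, pattern_name: str, record_id: str, strand: str = "+") -> list[int]:
        return self._hits.get((pattern_name, record_id, strand), [])

    def records_cut(self, pattern_name: str) -> set[str]:
        return self._records_cut.get(pattern_name, set())

    def n_records_matched(self, pattern_name: str) -> int:
        return len(self.records_cut(pattern_name))

    def n_total_matches(self, pattern_name: str) -> int:
        return self._totals.get(pattern_name, 0)

    def n_precut_matches(self, pattern_name: str) -> int:
        return self._precut.get(pattern_name, 0)

    def n_post_matches(self, pattern_name: str) -> int:
        return self._post.get(pattern_name, 0)

    def iter_sites(self) -> Iterable[MatchSite]:
        for (pname, rid, strand), starts in sorted(self._hits.items()):
            for s in starts:
                yield MatchSite(rid, pname, s, strand)

    def merge(self, other: "SiteIndex") -> None:
        """Collate another chunk's index into this one (exact integer sums;
        record-id sets are unioned)."""
        if other.region != self.region:
            raise ValueError("cannot merge site indexes with different regions")
        self.n_records += other.n_records
        self.n_truncated_records += other.n_truncated_records
        for name in other.pattern_names:
            self._register_pattern(name)
            self._records_cut[name] |= other._records_cut[name]
            self._totals[name] += other._totals[name]
            self._precut[name] += other._precut[name]
            self._post[name] += other._post[name]
        self._hits.update(other._hits)
        self.record_ids |= other.record_ids


def scan_dataset(
    records: Sequence[SequenceRecord],
    patterns: Sequence[MotifPattern],
    region: RegionSpec = RegionSpec(),
    strand_mode: str = "forward",
    overlap_mode: str = NON_OVERLAPPING,
) -> SiteIndex:
    """Census all patterns over all records.

    ``strand_mode='both'`` additionally scans each pattern's reverse
    complement against the forward text and reports those hits with
    strand '-' (no deduplication: a palindromic site appears once per
    strand representation).
    """
    if strand_mode not in ("forward", "both"):
        raise ValueError(f"unknown strand mode {strand_mode!r}")
    if not records:
        raise ValueError("scan_dataset requires at least one record")
    if not patterns:
        raise ValueError("scan_dataset requires at least one pattern")
    index = SiteIndex(region, n_records=len(records))
    jobs: list[tuple[MotifPattern, str]] = [(p, "+") for p in patterns]
    if strand_mode == "both":
        jobs += [(reverse_complement_pattern(p), "-") for p in patterns]
    for rec in records:
        index.record_ids.add(rec.id)
        win_lo, win_hi, truncated = region.window_for(rec.length)
        if truncated:
            index.n_truncated_records += 1
        for pat, strand in jobs:
            starts = scan_record(rec.seq, pat, overlap_mode)
            in_region, precut, post = [], 0, 0
            for s in starts:
                if win_lo <= s < win_hi:
                    in_region.append(s)
                elif s < win_lo:
                    precut += 1
                else:
                    post += 1
            index.add_matches(pat.name, rec.id, strand, in_region, precut, post)
    return index


@dataclass
class AnnotationResult:
    """Gene association of motif matches for a family of patterns."""

    associated_counts: dict[str, int] = field(default_factory=dict)
    genes_hit: dict[str, set[tuple[str, int, str]]] = field(default_factory=dict)
    genes_hit_by_all: set[tuple[str, int, str]] = field(default_factory=set)
    warnings: list[str] = field(default_factory=list)

    @property
    def total_associated(self) -> int:
        return sum(self.associated_counts.values())


def associate_with_annotation(
    site_index: SiteIndex,
    gene_starts: Iterable[tuple[str, int, str]],
    pattern_lengths: dict[str, int],
    family: Optional[Sequence[str]] = None,
) -> AnnotationResult:
    """Associate ATG-terminated motif matches with annotated gene starts.

    ``gene_starts`` holds (record_id, position, strand) triples on the same
    0-based forward coordinates as the matches: for a '+' gene ``position``
    is the index of the A of the start codon, and a match whose last three
    bases occupy [position, position+3) is associated; for a '-' gene
    ``position`` is the leftmost forward-strand index of the codon (the
    'CAT' image), and a '-' strand match starting there is associated.

    Returns per-pattern associated counts, the genes each pattern hits, and
    the genes hit by every pattern in ``family`` (default: all patterns).
    """
    genes = list(gene_starts)
    result = AnnotationResult()
    for rid, _pos, _strand in genes:
        if site_index.record_ids and rid not in site_index.record_ids:
            result.warnings.append(f"annotation references unknown record {rid}")
    plus_genes = {(rid, pos) for rid, pos, s in genes if s == "+"}
    minus_genes = {(rid, pos) for rid, pos, s in genes if s == "-"}
    names = family if family is not None else list(site_index.pattern_names)
    for name in names:
        plen = pattern_lengths[name]
        hit: set[tuple[str, int, str]] = set()
        count = 0
        for (pname, rid, strand), starts in site_index._hits.items():
            if pname != name:
                continue
            for s in starts:
                if strand == "+" and (rid, s + plen - 3) in plus_genes:
                    count += 1
                    hit.add((rid, s + plen - 3, "+"))
                elif strand == "-" and (rid, s) in minus_genes:
                    count += 1
                    hit.add((rid, s, "-"))
        result.associated_counts[name] = count
        result.genes_hit[name] = hit
    sets = [result.genes_hit[n] for n in names]
    result.genes_hit_by_all = set.intersection(*sets) if sets else set()
    return result


def promoter_census(
    records: Sequence[SequenceRecord],
    patterns: Sequence[MotifPattern],
    gene_starts: Iterable[tuple[str, int, str]],
    overlap_mode: str = NON_OVERLAPPING,
):
    """Forward-strand whole-sequence census of a motif family plus gene
    association — the AT-rich promoter-element workflow.

    Returns (DataFrame with one row per motif: total sites and
    gene-associated sites, annotated with grand totals, and the number of
    genes carrying every motif in the family).
    """
    import pandas as pd

    index = scan_dataset(records, patterns, RegionSpec(), "forward", overlap_mode)
    lengths = {p.name: p.length for p in patterns}
    assoc = associate_with_annotation(index, gene_starts, lengths)
    rows = [
        {
            "motif_name": p.name,
            "motif": p.iupac,
            "n_sites": index.n_total_matches(p.name),
            "n_gene_associated": assoc.associated_counts[p.name],
        }
        for p in patterns
    ]
    table = pd.DataFrame(rows)
    table.attrs["total_sites"] = int(table["n_sites"].sum())
    table.attrs["total_gene_associated"] = int(table["n_gene_associated"].sum())
    table.attrs["n_genes_with_all_motifs"] = len(assoc.genes_hit_by_all)
    return table
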