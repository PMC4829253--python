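"""In-silico restriction digestion, lane linking, amplicon prediction, and
CAPS candidate ranking.

A digest turns recognition-site matches into fragment lengths: cut
coordinates are match start + top-strand cleavage offset, pooled across
enzymes, deduplicated and sorted; fragments are the gaps between
consecutive cut points including the sequence ends (linear topology,
complete digestion).  Only the top-strand offset is modeled — at gel
resolution, fragment length is governed by top-strand cut positions.

A CAPS (cleaved amplified polymorphic sequence) marker exists when a
polymorphism creates or destroys a restriction site, so allele sequences
digest into visually distinguishable band patterns.  ``rank_caps_candidates``
scores every enzyme by how many allele pairs it resolves on a gel, given a
band-size resolution tolerance.
"""

from __future__ import annotations

import warnings as _warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .enzyme_db import Enzyme, MotifPattern, reverse_complement_pattern
from .scanner import NON_OVERLAPPING, scan_record
from .sequence_io import SequenceRecord

__all__ = [
    "FragmentLane",
    "CapsCandidate",
    "digest_sequence",
    "link_lanes",
    "predict_amplicons",
    "rank_caps_candidates",
]


@dataclass(frozen=True)
class FragmentLane:
    """A labeled multiset of fragment lengths destined for one gel lane."""

    label: str
    fragments: tuple[int, ...]  # sorted, with multiplicity
    source: str = "single"  # single | linked | ladder

    def __post_init__(self) -> None:
        object.__setattr__(self, "fragments", tuple(sorted(self.fragments)))
        if any(f < 1 for f in self.fragments):
            raise ValueError("fragment lengths must be >= 1")

    @property
    def multiset(self) -> Counter:
        return Counter(self.fragments)

    @property
    def total_length(self) -> int:
        return sum(self.fragments)

    def band_lengths(self) -> list[int]:
        """Distinct lengths (one band per distinct length on a gel)."""
        return sorted(set(self.fragments))


def _cut_positions(seq: str, enzymes: Sequence[Enzyme], strand_mode: str) -> set[int]:
    cuts: set[int] = set()
    length = len(seq)
    for enz in enzymes:
        offset = enz.cut_offset_top
        if offset is None:
            _warnings.warn(
                f"{enz.name}: no cut offset on record; cutting at site start",
                stacklevel=3,
            )
            offset = 0
        pats = [enz.pattern()]
        if strand_mode == "both":
            pats.append(reverse_complement_pattern(enz.pattern()))
        for pat in pats:
            for s in scan_record(seq, pat, NON_OVERLAPPING):
                cuts.add(min(max(s + offset, 0), length))  # clamp Type IIS overhangs
    return cuts


def digest_sequence(
    record: SequenceRecord,
    enzymes: Sequence[Enzyme],
    strand_mode: str = "forward",
    label: Optional[str] = None,
) -> FragmentLane:
    """Digest one sequence with one or more enzymes.

    With no enzymes (or no sites) the lane holds the single undigested
    full-length fragment.  Coincident cuts (isoschizomers, clamped offsets)
    collapse to one cut point, so zero-length fragments never appear.
    """
    length = record.length
    cuts = sorted(c for c in _cut_positions(record.seq, enzymes, strand_mode)
                  if 0 < c < length)
    bounds = [0] + cuts + [length]
    frags = [b - a for a, b in zip(bounds, bounds[1:]) if b > a]
    return FragmentLane(label=label or record.id, fragments=tuple(frags))


def link_lanes(lanes: Sequence[FragmentLane], label: str) -> FragmentLane:
    """Pool two or more lanes into one composite lane (multiset union by
    sum of multiplicities) — the virtual heterozygote."""
    if len(lanes) < 2:
        raise ValueError("link_lanes requires at least two lanes")
    pooled: list[int] = []
    for lane in lanes:
        pooled.extend(lane.fragments)
    return FragmentLane(label=label, fragments=tuple(pooled), source="linked")


def predict_amplicons(
    record: SequenceRecord,
    fwd_oligo: MotifPattern,
    rev_oligo: MotifPattern,
    max_len: int,
) -> list[tuple[int, int, int]]:
    """Predict PCR amplicon spans from two oligos entered as motifs.

    The forward oligo anneals where it matches the forward text; the
    reverse oligo anneals where its reverse complement matches the forward
    text.  Every (forward start i, reverse-match end j) pair with j > i and
    j - i <= max_len yields an amplicon (i, j, j - i), enumerated in
    genomic order.
    """
    fwd_starts = scan_record(record.seq, fwd_oligo, "overlapping")
    rc = reverse_complement_pattern(rev_oligo)
    rev_ends = [s + rc.length for s in scan_record(record.seq, rc, "overlapping")]
    out = []
    for i in fwd_starts:
        for j in rev_ends:
            if j > i and j - i <= max_len:
                out.append((i, j, j - i))
    out.sort()
    return out


@dataclass(frozen=True)
class CapsCandidate:
    """One enzyme's ability to distinguish a set of allele sequences."""

    enzyme_name: str
    n_distinct_patterns: int
    resolvable_pairs: int
    n_fragments_total: int
    lanes: tuple[FragmentLane, ...] = field(compare=False)


def _lanes_differ(
    a: FragmentLane, b: FragmentLane, resolution_bp: Optional[float]
) -> bool:
    """True when two band patterns are distinguishable on a gel.

    Bands closer than the resolution tolerance co-migrate: with
    ``resolution_bp=None`` the tolerance is 5% of the larger length
    (agarose-like), otherwise the fixed base-pair value.  Lanes with
    different band counts always differ.
    """
    xs, ys = a.band_lengths(), b.band_lengths()
    if len(xs) != len(ys):
        return True
    for x, y in zip(xs, ys):
        tol = 0.05 * max(x, y) if resolution_bp is None else resolution_bp
        if abs(x - y) > tol:
            return True
    return False


def rank_caps_candidates(
    allele_records: Sequence[SequenceRecord],
    enzymes: Sequence[Enzyme],
    resolution_bp: Optional[float] = None,
) -> list[CapsCandidate]:
    """Rank enzymes by how many allele pairs they resolve.

    Candidates are ordered by resolvable pairs (descending), then by fewest
    total fragments (simpler gels read better), then name.  The ranking is
    invariant to allele input order.  Enzymes resolving no pair are still
    returned (at the bottom) so the caller can report "no candidate".
    """
    if len(allele_records) < 2:
        raise ValueError("rank_caps_candidates requires at least two alleles")
    alleles = sorted(allele_records, key=lambda r: r.id)
    out = []
    for enz in sorted(enzymes, key=lambda e: e.name):
        lanes = tuple(digest_sequence(rec, [enz]) for rec in alleles)
        pairs = 0
        distinct: list[FragmentLane] = []
        for i, lane in enumerate(lanes):
            for other in lanes[i + 1 :]:
                if _lanes_differ(lane, other, resolution_bp):
                    pairs += 1
            if not any(not _lanes_differ(lane, d, resolution_bp) for d in distinct):
                distinct.append(lane)
        out.append(
            CapsCandidate(
                enzyme_name=enz.name,
                n_distinct_patterns=len(distinct),
                resolvable_pairs=pairs,
                n_fragments_total=sum(len(l.fragments) for l in lanes),
                lanes=lanes,
            )
        )
    out.sort(key=lambda c: (-c.resolvable_pairs, c.n_fragments_total, c.enzyme_name))
    return out
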