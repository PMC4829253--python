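"""Poly-A tail / poly-T head detection and trimming (trimest-style).

Transcriptome reads carry an adenine tract at the 3' end — or, when the
read was sequenced from the other strand, a thymine tract at the 5' end.
Preprocessing orients every read 5'→3', removes the homopolymer tract, and
routes reads without a recognizable tract to a rejected set that is not
analyzed further.

Detection rule: a tail is seeded by a run of at least ``min_run``
consecutive A's whose start lies within ``search_window`` bases of the 3'
end.  Once seeded, the tail is extended toward 5' without regard to the
window bound, tolerating isolated single non-A characters; two consecutive
non-A characters terminate the extension.  Everything from the tail start
to the sequence end is removed.
"""

from __future__ import annotations

from dataclasses import dataclass

from .sequence_io import SequenceRecord, reverse_complement

__all__ = [
    "PolyAConfig",
    "TrimResult",
    "find_polya_tail",
    "find_polyt_head",
    "trim_record",
    "preprocess_dataset",
]

TRIMMED = "trimmed"
REORIENTED = "reoriented+trimmed"
NO_TAIL = "no_tail"


@dataclass(frozen=True)
class PolyAConfig:
    """Tail-search parameters.

    search_window: bases from the sequence end within which a tail may
        start (the user-facing "how far into the sequence" dial).
    min_run: consecutive A's required to seed a tail.
    max_nonA_interruptions: consecutive non-A characters tolerated inside
        the tail; the tail stops once more than this many are met.
    """

    search_window: int = 50
    min_run: int = 4
    max_nonA_interruptions: int = 1

    def __post_init__(self) -> None:
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        if self.search_window < self.min_run:
            raise ValueError("search_window must be >= min_run")


@dataclass(frozen=True)
class TrimResult:
    """Outcome of a tail search.

    ``trim_index`` is where the retained sequence ends (0-based, half-open):
    retained = seq[:trim_index], tail = seq[trim_index:], so the original
    is always reconstructible.
    """

    status: str
    trim_index: int
    tail_length: int


def _no_tail(seq: str) -> TrimResult:
    return TrimResult(NO_TAIL, len(seq), 0)


def _seed_run_start(seq: str, cfg: PolyAConfig, base: str) -> int | None:
    """Start of the run containing the rightmost ``min_run``-long stretch of
    ``base`` that begins within the search window from the 3' end; None if
    no such stretch exists.  The run start itself may precede the window."""
    window_start = max(0, len(seq) - cfg.search_window)
    i = len(seq) - cfg.min_run
    while i >= window_start:
        if all(c == base for c in seq[i : i + cfg.min_run]):
            # seeded inside the window; the run itself may extend beyond it
            while i > 0 and seq[i - 1] == base:
                i -= 1
            return i
        i -= 1
    return None


def _extend_tail(seq: str, start: int, base: str, max_gap: int) -> int:
    """Extend a tail 5'-ward from ``start``: up to ``max_gap`` consecutive
    non-``base`` characters are swallowed when followed (5'-ward) by more
    ``base``; returns the final tail start."""
    i = start
    while i > 0:
        if seq[i - 1] == base:
            i -= 1
            continue
        # try to jump over 1..max_gap interrupting characters
        jumped = False
        for gap in range(1, max_gap + 1):
            j = i - gap - 1
            if j >= 0 and seq[j] == base and all(
                seq[k] != base for k in range(j + 1, i)
            ):
                i = j
                jumped = True
                break
        if not jumped:
            break
    return i


def find_polya_tail(seq: str, cfg: PolyAConfig = PolyAConfig()) -> TrimResult:
    """Locate a 3' poly-A tail; ``no_tail`` is a status, not an error."""
    seed = _seed_run_start(seq, cfg, "A")
    if seed is None:
        return _no_tail(seq)
    start = _extend_tail(seq, seed, "A", cfg.max_nonA_interruptions)
    return TrimResult(TRIMMED, start, len(seq) - start)


def find_polyt_head(seq: str, cfg: PolyAConfig = PolyAConfig()) -> TrimResult:
    """Locate a 5' poly-T head (the reverse-complement image of a tail).

    The result is expressed on the reverse-complemented sequence: on
    detection the read should be reverse-complemented, after which the head
    becomes a 3' poly-A tail at ``trim_index``.
    """
    rc = reverse_complement(seq)
    res = find_polya_tail(rc, cfg)
    if res.status == NO_TAIL:
        return _no_tail(seq)
    return TrimResult(REORIENTED, res.trim_index, res.tail_length)


def _terminal_run(seq: str, base: str, from_end: bool) -> int:
    n = 0
    it = reversed(seq) if from_end else iter(seq)
    for c in it:
        if c != base:
            break
        n += 1
    return n


def trim_record(
    record: SequenceRecord, cfg: PolyAConfig = PolyAConfig()
) -> tuple[SequenceRecord, TrimResult]:
    """Apply tail/head detection to one record.

    When both a poly-T head and a poly-A tail are present the longer
    terminal homopolymer run wins; ties go to the poly-A tail.  The
    returned record is always 5'→3' oriented with the tail removed.
    """
    tail = find_polya_tail(record.seq, cfg)
    head = find_polyt_head(record.seq, cfg)
    if tail.status != NO_TAIL and head.status != NO_TAIL:
        a_run = _terminal_run(record.seq, "A", from_end=True)
        t_run = _terminal_run(record.seq, "T", from_end=False)
        chosen = head if t_run > a_run else tail
    elif tail.status != NO_TAIL:
        chosen = tail
    elif head.status != NO_TAIL:
        chosen = head
    else:
        return record, tail
    if chosen.status == REORIENTED:
        oriented = record.reverse_complement()
    else:
        oriented = record
    trimmed = SequenceRecord(
        id=record.id,
        seq=oriented.seq[: chosen.trim_index],
        origin_orientation=oriented.origin_orientation,
    )
    return trimmed, chosen


def preprocess_dataset(
    records: list[SequenceRecord], cfg: PolyAConfig = PolyAConfig()
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Partition reads into (trimmed, rejected).

    Every input record lands in exactly one output set; trimmed records are
    5'→3' with the tail removed.  Reads whose retained portion is empty
    (all-homopolymer reads) are routed to the rejected set.
    """
    trimmed: list[SequenceRecord] = []
    rejected: list[SequenceRecord] = []
    for rec in records:
        out, res = trim_record(rec, cfg)
        if res.status == NO_TAIL or not out.seq:
            rejected.append(rec)
        else:
            trimmed.append(out)
    return trimmed, rejected
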