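"""Synthetic-data generators with machine-readable ground truth.

Everything the test suite and acceptance checks consume is generated here,
seeded and fully reproducible:

* 60-base poly-T probes with a known recognition site embedded dead
  center — the classic construct for verifying site identification and
  gel prediction;
* poly-A-tailed / poly-T-headed reads for trimming;
* SNP allele pairs in which a point substitution destroys a restriction
  site (the CAPS marker situation);
* random datasets with patterns planted into a known fraction of records,
  plus a truth table of every planted position;
* a synthetic annotated genome carrying promoter-like motifs upstream of
  known gene starts, for the motif-to-gene association workflow.

Default generation parameters mirror the validation constructs the tool
was originally exercised with (60-base probes; a 13.55% canonical
polyadenylation-signal plant rate typical of EST 3' ends).
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import pandas as pd

from .enzyme_db import Enzyme, IUPAC_SETS, compile_motif
from .scanner import OVERLAPPING, scan_record
from .sequence_io import SequenceRecord

__all__ = [
    "make_polyT_probe",
    "make_tailed_read",
    "make_tailed_dataset",
    "make_snp_allele_pair",
    "make_random_dataset",
    "make_annotated_genome",
]

DEFAULT_SEED = 42


def make_polyT_probe(site: str, total_len: int = 60, name: Optional[str] = None) -> SequenceRecord:
    """A poly-T probe: T padding with ``site`` embedded at the center.

    Layout: floor((total_len - len(site))/2) T's, the site, then the
    remaining T's — exactly ``total_len`` bases.
    """
    if len(site) > total_len:
        raise ValueError("site longer than probe length")
    left = (total_len - len(site)) // 2
    right = total_len - len(site) - left
    return SequenceRecord(
        id=name or (f"probe_{site}" if site else "probe_T"),
        seq="T" * left + site.upper() + "T" * right,
    )


def _random_seq(rng: random.Random, length: int, gc: float = 0.5) -> str:
    w_gc, w_at = gc / 2, (1 - gc) / 2
    return "".join(
        rng.choices("ACGT", weights=[w_at, w_gc, w_gc, w_at], k=length)
    )


def make_tailed_read(
    rng: random.Random,
    core_len: int = 120,
    tail_len: int = 12,
    as_polyt_head: bool = False,
    gc: float = 0.5,
    name: str = "read",
) -> tuple[SequenceRecord, str]:
    """One read with a poly-A tail (or its reverse-complement image, a
    poly-T head).  Returns (record, expected retained core 5'->3').

    The core is generated so the trim boundary is unambiguous: its last two
    bases are non-A (a single trailing non-A flanked by an A would be
    legitimately swallowed by the interruption rule), no seedable A-run
    sits inside the 3' search window, and the mirror conditions hold for
    the 5' end with T — so trimming recovers exactly this core and a
    second trim pass finds nothing.
    """
    while True:
        core = _random_seq(rng, core_len, gc)
        if core[-1] == "A" or core[-2] == "A" or core[0] == "T" or core[1] == "T":
            continue
        if "AAAA" in core[-60:] or "TTTT" in core[:60]:
            continue
        break
    if as_polyt_head:
        from .sequence_io import reverse_complement

        return (
            SequenceRecord(id=name, seq=reverse_complement(core + "A" * tail_len)),
            core,
        )
    return SequenceRecord(id=name, seq=core + "A" * tail_len), core


def make_tailed_dataset(
    n_tailed: int,
    n_untailed: int,
    seed: int = DEFAULT_SEED,
    core_len: int = 120,
    tail_len: int = 12,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """A read set with known tail status; truth table gives the expected
    partition and retained cores."""
    rng = random.Random(seed)
    records, truth = [], []
    for i in range(n_tailed):
        headed = i % 2 == 1  # alternate tails and heads
        rec, core = make_tailed_read(
            rng, core_len, tail_len, as_polyt_head=headed, name=f"tailed_{i}"
        )
        records.append(rec)
        truth.append({"record_id": rec.id, "has_tail": True, "core": core})
    for i in range(n_untailed):
        while True:
            seq = _random_seq(rng, core_len)
            if "AAAA" not in seq and "TTTT" not in seq:
                break
        rec = SequenceRecord(id=f"untailed_{i}", seq=seq)
        records.append(rec)
        truth.append({"record_id": rec.id, "has_tail": False, "core": seq})
    return records, pd.DataFrame(truth)


def _concrete_site(enzyme: Enzyme, rng: random.Random) -> str:
    return "".join(rng.choice(sorted(IUPAC_SETS[c])) for c in enzyme.site)


def make_snp_allele_pair(
    template_len: int,
    enzyme: Enzyme,
    seed: int = DEFAULT_SEED,
    gc: float = 0.5,
) -> tuple[SequenceRecord, SequenceRecord, int]:
    """Reference/alternate allele pair where one SNP destroys the enzyme's
    recognition site.

    The reference contains exactly one occurrence of the site; the
    alternate is identical except for a single substitution at a
    non-degenerate site position, chosen so the site no longer matches and
    no new occurrence is created.  Returns (ref, alt, snp_position).
    """
    rng = random.Random(seed)
    pat = enzyme.pattern()
    nondegen = [i for i, s in enumerate(pat.allowed) if len(s) == 1]
    if not nondegen:
        raise ValueError(f"{enzyme.name}: site has no non-degenerate position")
    site_len = pat.length
    for _attempt in range(1000):
        insert_at = rng.randrange(1, template_len - site_len)
        concrete = _concrete_site(enzyme, rng)
        template = (
            _random_seq(rng, insert_at, gc)
            + concrete
            + _random_seq(rng, template_len - insert_at - site_len, gc)
        )
        if len(scan_record(template, pat, OVERLAPPING)) != 1:
            continue
        pos_in_site = rng.choice(nondegen)
        snp_pos = insert_at + pos_in_site
        old = template[snp_pos]
        for new in sorted(set("ACGT") - {old}, key=lambda b: rng.random()):
            alt = template[:snp_pos] + new + template[snp_pos + 1 :]
            if not scan_record(alt, pat, OVERLAPPING):
                return (
                    SequenceRecord(id="allele_ref", seq=template),
                    SequenceRecord(id="allele_alt", seq=alt),
                    snp_pos,
                )
    raise RuntimeError("could not construct a clean SNP allele pair")


LengthSpec = Union[int, tuple[int, int], Callable[[random.Random], int]]


def _draw_length(spec: LengthSpec, rng: random.Random) -> int:
    if callable(spec):
        return spec(rng)
    if isinstance(spec, tuple):
        return rng.randint(spec[0], spec[1])
    return spec


def make_random_dataset(
    n: int,
    length_dist: LengthSpec = 300,
    gc: float = 0.5,
    seed: int = DEFAULT_SEED,
    planted: Sequence[tuple[str, float]] = (),
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Random records with patterns planted into known fractions.

    ``planted`` is a list of (IUPAC pattern, fraction) pairs; for each, a
    round(n·fraction)-sized random subset of records receives one embedded
    occurrence at a random position (planting never overwrites an earlier
    plant in the same record).  Returns the records and a ground-truth
    table of (record_id, pattern, position).
    """
    for _, frac in planted:
        if not 0 <= frac <= 1:
            raise ValueError("planted fractions must lie in [0, 1]")
    rng = random.Random(seed)
    seqs: dict[str, list[str]] = {}
    occupied: dict[str, list[tuple[int, int]]] = {}
    records_order = [f"seq_{i}" for i in range(n)]
    for rid in records_order:
        seqs[rid] = list(_random_seq(rng, _draw_length(length_dist, rng), gc))
        occupied[rid] = []
    truth = []
    for iupac, frac in planted:
        pat = compile_motif(iupac, iupac)
        k = round(n * frac)
        chosen = rng.sample(records_order, k)
        word_pool = None
        for rid in chosen:
            L = len(seqs[rid])
            if L < pat.length:
                continue
            for _ in range(200):
                pos = rng.randrange(0, L - pat.length + 1)
                span = (pos, pos + pat.length)
                if all(span[1] <= a or span[0] >= b for a, b in occupied[rid]):
                    break
            else:
                continue
            if word_pool is None and pat.degeneracy <= 4096:
                word_pool = list(pat.expansions())
            word = (
                rng.choice(word_pool)
                if word_pool is not None
                else "".join(rng.choice(sorted(s)) for s in pat.allowed)
            )
            seqs[rid][span[0] : span[1]] = list(word)
            occupied[rid].append(span)
            truth.append({"record_id": rid, "pattern": iupac, "position": span[0]})
    records = [SequenceRecord(id=rid, seq="".join(seqs[rid])) for rid in records_order]
    columns = ["record_id", "pattern", "position"]
    return records, pd.DataFrame(truth, columns=columns)


def promoter_motif_family(
    spacers: Sequence[int] = tuple(range(4, 13)), prefix: str = "atRichTss"
) -> list[tuple[str, str]]:
    """The AT-rich promoter motif family: WWWWWW, an N spacer of each
    requested width, then the ATG start codon."""
    return [(f"{prefix}-{s}N", "W" * 6 + "N" * s + "ATG") for s in spacers]


@dataclass(frozen=True)
class AnnotatedGenome:
    """A synthetic genome with known gene starts and planted upstream motifs.

    ``expected_counts`` has one row per motif with the exact number of
    matches the genome contains (``n_sites``) and how many coincide with an
    annotated gene start (``n_gene_associated``).
    """

    record: SequenceRecord
    gene_starts: tuple[tuple[str, int, str], ...]  # (record_id, ATG position, strand)
    motifs: tuple[tuple[str, str], ...]
    expected_counts: pd.DataFrame
    n_genes_with_all_motifs: int


def make_annotated_genome(
    n_genes: int = 400,
    spacing: int = 200,
    spacers: Sequence[int] = tuple(range(4, 13)),
    p_no_motif: float = 0.2,
    intergenic_plants_per_motif: int = 10,
    seed: int = DEFAULT_SEED,
) -> AnnotatedGenome:
    """Genome of ``n_genes`` forward-strand genes every ``spacing`` bases,
    carrying an AT-rich promoter motif family with exact ground truth.

    The background alphabet is {C, G}; A and T occur only inside planted
    motif heads and ATG codons, so motif matches are exactly the planted
    ones.  Each gene either carries no family motif or a *contiguous* range
    of spacer widths [s1, s2]: the upstream bases covered by the union of
    those motifs' W-windows are written A/T, the rest stay C/G.  Contiguity
    makes the set of family members matching at that gene exactly the
    chosen range (any other member's W-window would cover a C/G base).  A
    gene drawing the full range carries every motif.  Additional motif
    occurrences are planted between genes (their ATG is unannotated), so
    total and gene-associated counts differ as in a real genome.
    """
    if spacing < 120:
        raise ValueError("spacing must be >= 120 to keep plants separated")
    rng = random.Random(seed)
    spacers = sorted(spacers)
    genome = list("".join(rng.choice("CG")
                          for _ in range(n_genes * spacing + spacing)))
    gene_positions = []
    gene_ranges: dict[int, tuple[int, int]] = {}  # atg position -> (s1, s2)
    for g in range(n_genes):
        atg = spacing * (g + 1)
        genome[atg : atg + 3] = list("ATG")
        gene_positions.append(atg)
        if rng.random() < p_no_motif:
            continue
        i = rng.randrange(len(spacers))
        j = rng.randrange(len(spacers))
        s1, s2 = spacers[min(i, j)], spacers[max(i, j)]
        gene_ranges[atg] = (s1, s2)
        # a spacer-s motif starts at atg-6-s, so its W-window is
        # [atg-6-s, atg-s); the union over s1..s2 is [atg-6-s2, atg-s1)
        for pos in range(atg - 6 - s2, atg - s1):
            genome[pos] = rng.choice("AT")
        # an A/T window ending in "AT" next to a background G would forge
        # an unplanned ATG; pin the boundary base to C
        genome[atg - s1] = "C"
    # intergenic plants: one motif word each, isolated inside a gene-free slot
    intergenic: dict[int, int] = {s: 0 for s in spacers}
    slot = 0
    for s in spacers:
        for _ in range(intergenic_plants_per_motif):
            block = slot % n_genes
            lane = slot // n_genes
            start = spacing * block + 30 + lane * 30
            if start + 6 + s + 3 > spacing * block + spacing - 60:
                raise ValueError("spacing too small for requested intergenic plants")
            word = [rng.choice("AT") for _ in range(6)]
            word += ["C"] + [rng.choice("CG") for _ in range(s - 1)]  # no forged ATG
            word += list("ATG")
            genome[start : start + len(word)] = word
            intergenic[s] += 1
            slot += 1
    rows = []
    for s in spacers:
        n_gene = sum(1 for (s1, s2) in gene_ranges.values() if s1 <= s <= s2)
        rows.append(
            {
                "motif_name": f"atRichTss-{s}N",
                "n_sites": n_gene + intergenic[s],
                "n_gene_associated": n_gene,
            }
        )
    full = (spacers[0], spacers[-1])
    n_all = sum(1 for r in gene_ranges.values() if r == full)
    record = SequenceRecord(id="synthetic_genome", seq="".join(genome))
    return AnnotatedGenome(
        record=record,
        gene_starts=tuple(("synthetic_genome", pos, "+") for pos in gene_positions),
        motifs=tuple(promoter_motif_family(spacers)),
        expected_counts=pd.DataFrame(rows),
        n_genes_with_all_motifs=n_all,
    )
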