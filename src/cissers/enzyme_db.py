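"""Enzyme catalogue and degenerate-motif compilation.

Restriction enzymes are described by an IUPAC recognition site plus an
optional top-strand cleavage offset (REBASE convention: ``G^AATTC`` means
the top strand is cut one base after the site start).  Custom motifs —
promoter elements, polyadenylation signals, PCR oligos — are first-class
citizens of the same catalogue and are compiled with identical semantics.

The 15 IUPAC nucleotide letters are expanded into per-position allowed-base
sets; matching a subject letter requires the subject's concrete-base set to
be a subset of the pattern's allowed set (so a subject ``N`` matches only a
pattern ``N``, never a pattern ``A`` — a conservative rule for genomes with
ambiguity calls).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Optional

__all__ = [
    "IUPAC_SETS",
    "Enzyme",
    "MotifPattern",
    "EnzymeDatabase",
    "ParseWarning",
    "compile_motif",
    "parse_enzyme_list",
    "reverse_complement_pattern",
]

#: IUPAC nucleotide code -> set of concrete bases it denotes.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: reverse lookup: frozenset of bases -> canonical IUPAC letter.
_SET_TO_LETTER = {v: k for k, v in IUPAC_SETS.items()}


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme or user-defined motif entry.

    ``cut_offset_top`` is the distance from the recognition-site start to
    the top-strand cleavage point; it may be negative or exceed the site
    length for Type IIS enzymes that cut outside their recognition site.
    Enzymes sharing an identical site string are isoschizomers and share
    ``group_key``.
    """

    name: str
    site: str
    cut_offset_top: Optional[int] = None
    is_custom: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("enzyme name must be non-empty")
        bad = _illegal_letters(self.site)
        if not self.site:
            raise ValueError(f"{self.name}: recognition site must be non-empty")
        if bad:
            raise ValueError(
                f"{self.name}: illegal IUPAC letter(s) {bad} in site {self.site!r}"
            )

    @property
    def group_key(self) -> str:
        """Isoschizomer group identifier: the site string itself."""
        return self.site

    def pattern(self) -> "MotifPattern":
        return compile_motif(self.name, self.site)


def _illegal_letters(site: str) -> list[str]:
    return sorted({c for c in site.upper() if c not in IUPAC_SETS})


@dataclass(frozen=True)
class MotifPattern:
    """A compiled degenerate pattern: per-position allowed-base sets."""

    name: str
    iupac: str
    allowed: tuple[frozenset[str], ...]

    def __len__(self) -> int:
        return len(self.allowed)

    @property
    def length(self) -> int:
        return len(self.allowed)

    def matches_at(self, seq: str, pos: int) -> bool:
        """Subset-match the subject window starting at ``pos``.

        A subject letter matches iff the concrete bases it could be are all
        allowed at that position.
        """
        if pos < 0 or pos + len(self.allowed) > len(seq):
            return False
        for off, want in enumerate(self.allowed):
            got = IUPAC_SETS.get(seq[pos + off])
            if got is None or not got <= want:
                return False
        return True

    def char_class(self, i: int) -> str:
        """Regex character class for position ``i`` under subset semantics."""
        want = self.allowed[i]
        letters = sorted(c for c, s in IUPAC_SETS.items() if s <= want)
        return letters[0] if len(letters) == 1 else "[" + "".join(letters) + "]"

    def to_regex(self) -> str:
        return "".join(self.char_class(i) for i in range(len(self.allowed)))

    def expansions(self) -> Iterator[str]:
        """Yield every concrete word the pattern accepts (lexicographic)."""
        def rec(i: int, prefix: str) -> Iterator[str]:
            if i == len(self.allowed):
                yield prefix
                return
            for b in sorted(self.allowed[i]):
                yield from rec(i + 1, prefix + b)

        yield from rec(0, "")

    @property
    def degeneracy(self) -> int:
        """Number of concrete words the pattern accepts."""
        n = 1
        for s in self.allowed:
            n *= len(s)
        return n


def compile_motif(name: str, iupac: str) -> MotifPattern:
    """Compile an IUPAC string into a :class:`MotifPattern`.

    Raises ``ValueError`` naming the first offending position if a letter
    is not one of the 15 IUPAC nucleotide codes.
    """
    iupac = iupac.upper()
    if not iupac:
        raise ValueError(f"{name}: motif must be non-empty")
    allowed = []
    for i, c in enumerate(iupac):
        try:
            allowed.append(IUPAC_SETS[c])
        except KeyError:
            raise ValueError(
                f"{name}: illegal IUPAC letter {c!r} at position {i}"
            ) from None
    return MotifPattern(name=name, iupac=iupac, allowed=tuple(allowed))


def reverse_complement_pattern(p: MotifPattern) -> MotifPattern:
    """Reverse-complement a pattern (an involution).

    Position ``i`` of the result allows the complements of the bases the
    input allowed at position ``len-1-i``; W and N are self-complementary.
    """
    comp = tuple(
        frozenset(b.translate(_COMPLEMENT) for b in s) for s in reversed(p.allowed)
    )
    iupac = "".join(_SET_TO_LETTER[s] for s in comp)
    return MotifPattern(name=p.name, iupac=iupac, allowed=comp)


@dataclass(frozen=True)
class ParseWarning:
    """One malformed input line, reported rather than silently dropped."""

    line_no: int
    line: str
    reason: str


class EnzymeDatabase:
    """Ordered, name-unique collection of enzymes and custom motifs.

    Iteration order is deterministic (sorted by name).  Parse warnings from
    :func:`parse_enzyme_list` are carried on ``.warnings``.
    """

    def __init__(self, enzymes: Optional[list[Enzyme]] = None):
        self._by_name: dict[str, Enzyme] = {}
        self.warnings: list[ParseWarning] = []
        for e in enzymes or []:
            self.add(e)

    def add(self, enzyme: Enzyme) -> None:
        if enzyme.name in self._by_name:
            raise ValueError(f"duplicate enzyme name: {enzyme.name}")
        self._by_name[enzyme.name] = enzyme

    def add_custom_motif(
        self, name: str, iupac: str, cut_offset_top: Optional[int] = None
    ) -> Enzyme:
        """Register a user-defined motif; selectable like any enzyme."""
        enz = Enzyme(name=name, site=iupac.upper(), cut_offset_top=cut_offset_top,
                     is_custom=True)
        self.add(enz)
        return enz

    def __len__(self) -> int:
        return len(self._by_name)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self) -> Iterator[Enzyme]:
        for name in sorted(self._by_name):
            yield self._by_name[name]

    def get(self, name: str) -> Enzyme:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"no enzyme named {name!r} in database") from None

    def select(self, names: list[str]) -> list[Enzyme]:
        return [self.get(n) for n in names]

    def filter(
        self,
        site_length: Optional[int] = None,
        max_degeneracy: Optional[int] = None,
        name_contains: Optional[str] = None,
        site_contains: Optional[str] = None,
    ) -> list[Enzyme]:
        """Programmatic counterpart of the GUI's filtering/search window."""
        out = []
        for e in self:
            if site_length is not None and len(e.site) != site_length:
                continue
            if max_degeneracy is not None and e.pattern().degeneracy > max_degeneracy:
                continue
            if name_contains and name_contains.lower() not in e.name.lower():
                continue
            if site_contains and site_contains.upper() not in e.site:
                continue
            out.append(e)
        return out

    def isoschizomer_groups(self) -> dict[str, list[Enzyme]]:
        """Partition the database by identical recognition site."""
        groups: dict[str, list[Enzyme]] = {}
        for e in self:
            groups.setdefault(e.group_key, []).append(e)
        return groups

    def group_representatives(self) -> dict[str, tuple[str, bool]]:
        """Map each member name -> (alphabetically first member of its
        isoschizomer group, group has >1 member)."""
        reps = {}
        for members in self.isoschizomer_groups().values():
            label = min(m.name for m in members)
            multi = len(members) > 1
            for m in members:
                reps[m.name] = (label, multi)
        return reps


_CARET_RE = re.compile(r"\^")


def _parse_site_field(raw: str) -> tuple[str, Optional[int]]:
    """Split caret notation: ``G^AATTC`` -> (``GAATTC``, 1)."""
    if "^" in raw:
        if raw.count("^") > 1:
            raise ValueError("more than one caret in site")
        offset = raw.index("^")
        return _CARET_RE.sub("", raw), offset
    return raw, None


def parse_enzyme_list(text: str) -> EnzymeDatabase:
    """Parse a line-oriented enzyme table into an :class:`EnzymeDatabase`.

    Format: ``name<TAB>site[<TAB>cut_offset]`` (whitespace-separated also
    accepted); ``#`` comments and blank lines skipped; caret notation in
    the site column sets the cut offset.  Malformed lines become
    :class:`ParseWarning` entries on the returned database — they are
    reported, never silently dropped.  Empty input is an error.
    """
    db = EnzymeDatabase()
    n_data_lines = 0
    for line_no, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        n_data_lines += 1
        fields = stripped.split()
        if len(fields) < 2:
            db.warnings.append(ParseWarning(line_no, line, "expected name and site"))
            continue
        name, raw_site = fields[0], fields[1].upper()
        try:
            site, caret_offset = _parse_site_field(raw_site)
        except ValueError as exc:
            db.warnings.append(ParseWarning(line_no, line, str(exc)))
            continue
        offset = caret_offset
        if len(fields) >= 3:
            try:
                offset = int(fields[2])
            except ValueError:
                db.warnings.append(
                    ParseWarning(line_no, line, f"bad cut offset {fields[2]!r}")
                )
                continue
        try:
            enz = Enzyme(name=name, site=site, cut_offset_top=offset)
            db.add(enz)
        except ValueError as exc:
            db.warnings.append(ParseWarning(line_no, line, str(exc)))
    if n_data_lines == 0:
        raise ValueError("empty enzyme list")
    return db


def load_bundled_enzymes() -> EnzymeDatabase:
    """Load the starter enzyme file shipped with the package."""
    from importlib.resources import files

    text = (files("cissers") / "data" / "enzymes.tsv").read_text(encoding="utf-8")
    return parse_enzyme_list(text)
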