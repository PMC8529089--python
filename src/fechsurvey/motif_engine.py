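"""PROSITE-style motif scanning and MCF ([2Fe-2S] motif) calling.

The consensus iron-sulfur cluster motif in ferrochelatases is
``C-X(1,11)-C-X(1,11)-C``: three coordinating cysteines separated by one
to eleven arbitrary residues. X deliberately matches any residue
*including* cysteine, so an adjacent-cysteine XCCX arrangement (all four
coordinating cysteines close together) still matches, as does the CXC
arrangement. A sequence is a motif-containing ferrochelatase (MCF) only
when a consensus hit lies entirely within an internal insertion or the
C-terminal tail; hits elsewhere in the protein do not qualify.

The pattern language implemented here is the subset needed for the
survey: literal residues, ``X``, ``X(n)`` and ``X(n,m)``, with optional
``-`` separators.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from fechsurvey.reference_mapping import RegionAnnotation

#: Consensus [2Fe-2S] coordination motif.
CONSENSUS_2FE2S = "C-X(1,11)-C-X(1,11)-C"

#: Partial/diagnostic cysteine groupings and the CAB-domain tail motif.
PATTERN_CATALOG = {
    "consensus_2fe2s": CONSENSUS_2FE2S,
    "cx3cc": "C-X(3)-C-C",
    "cx9cc": "C-X(9)-C-C",
    "exxnxr": "E-X(2)-N-X-R",
}

_AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")

_TOKEN_RE = re.compile(r"X\((\d+)(?:,(\d+))?\)|X|[A-WYZ]")


@dataclass(frozen=True)
class PatternElement:
    """One pattern element: a literal residue or a bounded wildcard run."""

    literal: str | None  # None for wildcard runs
    min_len: int = 1
    max_len: int = 1


@dataclass(frozen=True)
class MotifPattern:
    elements: tuple[PatternElement, ...]
    source_text: str

    def __post_init__(self) -> None:
        if not any(e.literal for e in self.elements):
            raise ValueError(f"pattern {self.source_text!r} has no literal element")


@dataclass(frozen=True)
class MotifHit:
    """A scanner match, 1-based inclusive, keyed by its literal positions."""

    start: int
    end: int
    literal_positions: tuple[int, ...]
    spacer_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("hit start after end")
        prev = self.start - 1
        for p in self.literal_positions:
            if not (self.start <= p <= self.end) or p <= prev:
                raise ValueError("literal positions not increasing within span")
            prev = p


@dataclass(frozen=True)
class GroupingFlags:
    """Cysteine groupings and C-terminal character of one sequence."""

    has_xccx: bool
    has_cxc: bool
    has_cx3cc: bool
    has_cx9cc: bool
    has_exxnxr: bool
    his_rich_tail: bool
    xccx_positions: tuple[int, ...] = ()
    cxc_positions: tuple[int, ...] = ()
    cx3cc_positions: tuple[int, ...] = ()
    cx9cc_positions: tuple[int, ...] = ()
    exxnxr_positions: tuple[int, ...] = ()


@dataclass(frozen=True)
class MCFCall:
    """Verdict: is the sequence a motif-containing ferrochelatase?"""

    is_mcf: bool
    qualifying_location: str  # insertion | c_terminal | none
    all_hits: tuple[tuple[MotifHit, str], ...]
    reason: str


def compile_pattern(prosite_text: str) -> MotifPattern:
    """Compile a PROSITE-subset pattern string.

    Accepts literal residues, ``X``, ``X(n)``, ``X(n,m)``; ``-``
    separators and whitespace are ignored. Malformed bounds (m < n),
    empty patterns and non-amino-acid literals are errors.
    """
    text = prosite_text.strip().rstrip(".")
    stripped = text.replace("-", "").replace(" ", "").upper()
    if not stripped:
        raise ValueError("empty pattern")
    elements: list[PatternElement] = []
    pos = 0
    while pos < len(stripped):
        m = _TOKEN_RE.match(stripped, pos)
        if m is None:
            raise ValueError(
                f"pattern {prosite_text!r}: cannot parse at offset {pos}"
            )
        tok = m.group(0)
        if tok.startswith("X("):
            n = int(m.group(1))
            mx = int(m.group(2)) if m.group(2) is not None else n
            if mx < n:
                raise ValueError(
                    f"pattern {prosite_text!r}: wildcard bounds ({n},{mx}) with max < min"
                )
            elements.append(PatternElement(None, n, mx))
        elif tok == "X":
            elements.append(PatternElement(None, 1, 1))
        else:
            if tok not in _AA_LETTERS:
                raise ValueError(
                    f"pattern {prosite_text!r}: illegal residue letter {tok!r}"
                )
            elements.append(PatternElement(tok))
        pos = m.end()
    return MotifPattern(elements=tuple(elements), source_text=prosite_text)


def scan(sequence: str, pattern: MotifPattern) -> list[MotifHit]:
    """Enumerate all matches of ``pattern`` in ``sequence``.

    Every match is reported, including overlapping ones. Alternative
    wildcard realizations that pin the literal residues to the same
    sequence positions are collapsed to a single hit (one hit per distinct
    tuple of literal positions); because X may itself match a cysteine,
    distinct literal tuples over the same stretch are distinct hits.
    Positions are 1-based inclusive.
    """
    seq = sequence.upper()
    n = len(seq)
    elements = pattern.elements
    found: dict[tuple[int, ...], MotifHit] = {}

    def backtrack(ei: int, pos: int, literals: list[int], spacers: list[int], start: int) -> None:
        if ei == len(elements):
            key = tuple(literals)
            if key not in found:
                found[key] = MotifHit(
                    start=start + 1,
                    end=pos,
                    literal_positions=key,
                    spacer_lengths=tuple(spacers),
                )
            return
        el = elements[ei]
        if el.literal is not None:
            if pos < n and seq[pos] == el.literal:
                literals.append(pos + 1)
                backtrack(ei + 1, pos + 1, literals, spacers, start)
                literals.pop()
        else:
            for run in range(el.min_len, el.max_len + 1):
                if pos + run > n:
                    break
                spacers.append(run)
                backtrack(ei + 1, pos + run, literals, spacers, start)
                spacers.pop()

    for start in range(n):
        backtrack(0, start, [], [], start)
    return sorted(found.values(), key=lambda h: (h.literal_positions))


def _slice(seq: str, span: tuple[int, int] | None) -> str:
    if span is None:
        return ""
    return seq[span[0] - 1 : span[1]]


def detect_groupings(
    sequence: str,
    regions: RegionAnnotation | None = None,
    his_rich_threshold: float = 0.15,
) -> GroupingFlags:
    """Flag diagnostic cysteine groupings and C-terminal character.

    XCCX = an adjacent cysteine pair with non-cysteine neighbors on both
    sides; CXC = two cysteines separated by one non-cysteine. CX(3)CC and
    CX(9)CC are literal spacings (partial motifs missing the fourth
    cysteine). The CAB-domain EXXNXR motif is searched only in the
    C-terminal tail, and ``his_rich_tail`` is true when the tail's
    histidine fraction reaches ``his_rich_threshold``. Without a region
    annotation the tail-specific flags are False.
    """
    seq = sequence.upper()
    n = len(seq)
    xccx = []
    for i in range(n - 1):
        if seq[i] == "C" and seq[i + 1] == "C":
            left_ok = i == 0 or seq[i - 1] != "C"
            right_ok = i + 2 >= n or seq[i + 2] != "C"
            if left_ok and right_ok:
                xccx.append(i + 1)
    cxc = [
        i + 1
        for i in range(n - 2)
        if seq[i] == "C" and seq[i + 1] != "C" and seq[i + 2] == "C"
    ]
    cx3cc = [
        h.start for h in scan(seq, compile_pattern(PATTERN_CATALOG["cx3cc"]))
    ]
    cx9cc = [
        h.start for h in scan(seq, compile_pattern(PATTERN_CATALOG["cx9cc"]))
    ]
    exxnxr: list[int] = []
    his_rich = False
    if regions is not None and regions.c_tail is not None:
        tail = _slice(seq, regions.c_tail)
        offset = regions.c_tail[0] - 1
        exxnxr = [
            h.start + offset
            for h in scan(tail, compile_pattern(PATTERN_CATALOG["exxnxr"]))
        ]
        if tail:
            his_rich = tail.count("H") / len(tail) >= his_rich_threshold
    return GroupingFlags(
        has_xccx=bool(xccx),
        has_cxc=bool(cxc),
        has_cx3cc=bool(cx3cc),
        has_cx9cc=bool(cx9cc),
        has_exxnxr=bool(exxnxr),
        his_rich_tail=his_rich,
        xccx_positions=tuple(xccx),
        cxc_positions=tuple(cxc),
        cx3cc_positions=tuple(cx3cc),
        cx9cc_positions=tuple(cx9cc),
        exxnxr_positions=tuple(exxnxr),
    )


def _hit_location(hit: MotifHit, regions: RegionAnnotation) -> str:
    for lo, hi in regions.insertions:
        if all(lo <= p <= hi for p in hit.literal_positions):
            return "insertion"
    if regions.c_tail is not None:
        lo, hi = regions.c_tail
        if all(lo <= p <= hi for p in hit.literal_positions):
            return "c_terminal"
    return "other"


def call_mcf(hits: Iterable[MotifHit], regions: RegionAnnotation) -> MCFCall:
    """Decide MCF status from consensus hits and the region annotation.

    A hit qualifies when *all* its literal cysteines lie within a single
    internal insertion span, or all within the C-terminal tail; hits
    anywhere else (including straddling a boundary) are recorded but do
    not qualify. When both locations carry qualifying hits the insertion
    is reported as the qualifying location.
    """
    located = tuple((h, _hit_location(h, regions)) for h in hits)
    locations = {loc for _, loc in located}
    if "insertion" in locations:
        return MCFCall(True, "insertion", located, "consensus motif in internal insertion")
    if "c_terminal" in locations:
        return MCFCall(True, "c_terminal", located, "consensus motif in C-terminal tail")
    if located:
        return MCFCall(False, "none", located, "motif outside insertion/C-terminus")
    return MCFCall(False, "none", located, "no consensus motif")


def hits_table_rows(
    record_id: str,
    pattern_name: str,
    hits: Sequence[MotifHit],
    located: Sequence[tuple[MotifHit, str]] | None = None,
    is_mcf: bool | None = None,
) -> list[dict]:
    """Rows for the per-record hit TSV (record, pattern, span, location)."""
    loc_by_key = (
        {h.literal_positions: loc for h, loc in located} if located else {}
    )
    rows = []
    for h in hits:
        rows.append(
            {
                "record_id": record_id,
                "pattern": pattern_name,
                "start": h.start,
                "end": h.end,
                "literal_positions": ",".join(map(str, h.literal_positions)),
                "location": loc_by_key.get(h.literal_positions, ""),
                "is_mcf": "" if is_mcf is None else int(is_mcf),
            }
        )
    return rows
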