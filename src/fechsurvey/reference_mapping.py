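"""Reference mapping: pairwise global alignment and region annotation.

Each candidate sequence is aligned to a single reference ferrochelatase
(human numbering, catalytic His at 263) with an affine-gap Needleman-
Wunsch/Gotoh aligner. The alignment drives three curation steps:

* catalytic-His verification (sequences whose column at reference
  position 263 is not His are non-functional and dropped),
* annotation of the N-terminal extension, internal insertion(s) and
  C-terminal tail relative to the reference core span,
* extraction of the conserved core (extensions/insertions/tails removed)
  for the motif-free phylogeny.

Scores are integer-valued; a gap of length L costs
``gap_open + (L - 1) * gap_extend`` (both negative). The traceback
tie-break is fixed (diagonal, then up, then left) so alignments are
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices
from numba import njit

from fechsurvey.io_metadata import ProteinRecord

NEG_INF = np.int64(-(10**9))

DEFAULT_GAP_OPEN = -11
DEFAULT_GAP_EXTEND = -1


@dataclass(frozen=True)
class ReferenceProfile:
    """Reference ferrochelatase: sequence, catalytic His, core span.

    ``core_span`` (1-based inclusive) delimits the mature conserved fold,
    excluding the reference's own targeting sequence and any residues
    beyond the fold; the catalytic His must lie inside it.
    """

    sequence: str
    catalytic_his_pos: int = 263
    core_span: tuple[int, int] = (1, 0)

    def __post_init__(self) -> None:
        n = len(self.sequence)
        lo, hi = self.core_span
        if not (1 <= self.catalytic_his_pos <= n):
            raise ValueError("catalytic_his_pos outside sequence")
        if self.sequence[self.catalytic_his_pos - 1] != "H":
            raise ValueError(
                f"reference position {self.catalytic_his_pos} is "
                f"{self.sequence[self.catalytic_his_pos - 1]!r}, not H"
            )
        if not (1 <= lo <= hi <= n):
            raise ValueError(f"core_span {self.core_span} outside [1, {n}]")
        if not (lo <= self.catalytic_his_pos <= hi):
            raise ValueError("catalytic His not inside core_span")


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment: equal-length gapped strings plus the score."""

    aligned_query: str
    aligned_ref: str
    score: int

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_ref):
            raise ValueError("aligned strings differ in length")
        for a, b in zip(self.aligned_query, self.aligned_ref):
            if a == "-" and b == "-":
                raise ValueError("gap/gap column in alignment")


@dataclass(frozen=True)
class RegionAnnotation:
    """1-based inclusive spans partitioning a query sequence.

    ``core`` always exists; ``insertions`` are nested within it. The union
    of n_ext, core and c_tail covers the whole query.
    """

    core: tuple[int, int]
    n_ext: tuple[int, int] | None = None
    insertions: tuple[tuple[int, int], ...] = ()
    c_tail: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        spans = []
        if self.n_ext is not None:
            spans.append(self.n_ext)
        spans.append(self.core)
        if self.c_tail is not None:
            spans.append(self.c_tail)
        for lo, hi in spans + list(self.insertions):
            if lo > hi or lo < 1:
                raise ValueError(f"bad span ({lo}, {hi})")
        for (_, hi_a), (lo_b, _) in zip(spans, spans[1:]):
            if hi_a + 1 != lo_b:
                raise ValueError("spans not contiguous")
        for lo, hi in self.insertions:
            if not (self.core[0] <= lo <= hi <= self.core[1]):
                raise ValueError("insertion not nested in core")

    @property
    def query_length(self) -> int:
        last = self.c_tail[1] if self.c_tail else self.core[1]
        return last

    def in_span(self, pos: int, span: tuple[int, int] | None) -> bool:
        return span is not None and span[0] <= pos <= span[1]


def _default_matrix() -> np.ndarray:
    """BLOSUM62 as a 26x26 int matrix indexed by ``ord(aa) - 65``.

    Letters absent from the matrix alphabet score as X does.
    """
    blosum = substitution_matrices.load("BLOSUM62")
    alphabet = blosum.alphabet
    mat = np.zeros((26, 26), dtype=np.int64)
    x_idx = alphabet.index("X")
    for i in range(26):
        a = chr(65 + i)
        ai = alphabet.index(a) if a in alphabet else x_idx
        for j in range(26):
            b = chr(65 + j)
            bj = alphabet.index(b) if b in alphabet else x_idx
            mat[i, j] = int(blosum[ai, bj])
    return mat


_BLOSUM62_26 = None


def blosum62_matrix() -> np.ndarray:
    """Cached 26x26 BLOSUM62 lookup (see :func:`_default_matrix`)."""
    global _BLOSUM62_26
    if _BLOSUM62_26 is None:
        _BLOSUM62_26 = _default_matrix()
    return _BLOSUM62_26


def read_substitution_matrix(path: str | Path) -> np.ndarray:
    """Read an NCBI-format scoring matrix file into the 26x26 layout."""
    m = substitution_matrices.read(str(path))
    alphabet = m.alphabet
    out = np.zeros((26, 26), dtype=np.int64)
    fallback = alphabet.index("X") if "X" in alphabet else None
    for i in range(26):
        a = chr(65 + i)
        ai = alphabet.index(a) if a in alphabet else fallback
        for j in range(26):
            b = chr(65 + j)
            bj = alphabet.index(b) if b in alphabet else fallback
            if ai is None or bj is None:
                continue
            out[i, j] = int(m[ai, bj])
    return out


def simple_matrix(match: int, mismatch: int) -> np.ndarray:
    """Uniform match/mismatch matrix (useful for toy examples and tests)."""
    mat = np.full((26, 26), mismatch, dtype=np.int64)
    np.fill_diagonal(mat, match)
    return mat


def _encode(seq: str) -> np.ndarray:
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).astype(np.int64) - 65
    if codes.min(initial=0) < 0 or codes.max(initial=0) > 25:
        raise ValueError("sequence contains non-letter characters")
    return codes


@njit(cache=False)
def _gotoh_fill(q, r, sub, go, ge):  # pragma: no cover - exercised via global_align
    n = q.shape[0]
    m = r.shape[0]
    neg = -(10**9)
    M = np.full((n + 1, m + 1), neg, dtype=np.int64)
    Ix = np.full((n + 1, m + 1), neg, dtype=np.int64)  # query vs gap ("up")
    Iy = np.full((n + 1, m + 1), neg, dtype=np.int64)  # gap vs ref ("left")
    M[0, 0] = 0
    for i in range(1, n + 1):
        Ix[i, 0] = go + (i - 1) * ge
    for j in range(1, m + 1):
        Iy[0, j] = go + (j - 1) * ge
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            s = sub[qi, r[j - 1]]
            best = M[i - 1, j - 1]
            if Ix[i - 1, j - 1] > best:
                best = Ix[i - 1, j - 1]
            if Iy[i - 1, j - 1] > best:
                best = Iy[i - 1, j - 1]
            M[i, j] = best + s
            a = M[i - 1, j] + go
            b = Ix[i - 1, j] + ge
            c = Iy[i - 1, j] + go
            best = a
            if b > best:
                best = b
            if c > best:
                best = c
            Ix[i, j] = best
            a = M[i, j - 1] + go
            b = Iy[i, j - 1] + ge
            c = Ix[i, j - 1] + go
            best = a
            if b > best:
                best = b
            if c > best:
                best = c
            Iy[i, j] = best
    return M, Ix, Iy


def global_align(
    query: str,
    ref: str,
    substitution: np.ndarray | None = None,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> PairwiseAlignment:
    """Optimal global alignment under affine gap penalties (Gotoh).

    ``substitution`` is a 26x26 integer matrix indexed by ``ord(aa) - 65``
    (default BLOSUM62). Gap penalties are negative; a run of L gaps costs
    ``gap_open + (L - 1) * gap_extend``. On score ties the traceback
    prefers the diagonal move, then the vertical (query-consuming) move,
    then the horizontal move, making the reported alignment deterministic.
    """
    if not query or not ref:
        raise ValueError("global_align requires non-empty sequences")
    if gap_open > 0 or gap_extend > 0:
        raise ValueError("gap penalties must be <= 0")
    sub = blosum62_matrix() if substitution is None else substitution
    q = _encode(query)
    r = _encode(ref)
    M, Ix, Iy = _gotoh_fill(q, r, sub, np.int64(gap_open), np.int64(gap_extend))

    n, m = len(query), len(ref)
    # choose end state, tie-break M > Ix > Iy
    end_scores = (M[n, m], Ix[n, m], Iy[n, m])
    score = int(max(end_scores))
    state = end_scores.index(max(end_scores))

    out_q: list[str] = []
    out_r: list[str] = []
    i, j = n, m
    go, ge = gap_open, gap_extend
    while i > 0 or j > 0:
        if state == 0:  # M: diagonal
            out_q.append(query[i - 1])
            out_r.append(ref[j - 1])
            target = M[i, j] - sub[q[i - 1], r[j - 1]]
            i -= 1
            j -= 1
            if M[i, j] == target:
                state = 0
            elif Ix[i, j] == target:
                state = 1
            else:
                state = 2
        elif state == 1:  # Ix: query residue vs gap
            out_q.append(query[i - 1])
            out_r.append("-")
            val = Ix[i, j]
            i -= 1
            if i == 0 and j == 0:
                break
            if M[i, j] + go == val:
                state = 0
            elif Ix[i, j] + ge == val:
                state = 1
            else:
                state = 2
        else:  # Iy: gap vs ref residue
            out_q.append("-")
            out_r.append(ref[j - 1])
            val = Iy[i, j]
            j -= 1
            if i == 0 and j == 0:
                break
            if M[i, j] + go == val:
                state = 0
            elif Iy[i, j] + ge == val:
                state = 2
            else:
                state = 1
    return PairwiseAlignment(
        aligned_query="".join(reversed(out_q)),
        aligned_ref="".join(reversed(out_r)),
        score=score,
    )


def his_status_from_alignment(
    aln: PairwiseAlignment, ref: ReferenceProfile
) -> tuple[bool, int | None, str]:
    """Catalytic-His status read off an existing query/reference alignment.

    Returns ``(ok, query_position, reason)``: ``ok`` is True iff the query
    column aligned to the reference's catalytic His holds an H. The query
    position is 1-based, or None when that reference column is deleted in
    the query (reason ``"deleted"``).
    """
    qpos = 0
    rpos = 0
    for qc, rc in zip(aln.aligned_query, aln.aligned_ref):
        if qc != "-":
            qpos += 1
        if rc != "-":
            rpos += 1
            if rpos == ref.catalytic_his_pos:
                if qc == "-":
                    return False, None, "deleted"
                if qc == "H":
                    return True, qpos, "ok"
                return False, qpos, f"substituted:{qc}"
    raise AssertionError("reference exhausted before catalytic position")


def verify_catalytic_his(
    query: ProteinRecord,
    ref: ReferenceProfile,
    substitution: np.ndarray | None = None,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> tuple[bool, int | None, str]:
    """Check the catalytic histidine via alignment to the reference.

    The query is trimmed per its ``trim_span`` first. See
    :func:`his_status_from_alignment` for the return convention.
    """
    seq = query.trimmed_sequence
    aln = global_align(seq, ref.sequence, substitution, gap_open, gap_extend)
    return his_status_from_alignment(aln, ref)


def annotate_regions(
    alignment: PairwiseAlignment,
    ref: ReferenceProfile,
    min_insertion: int = 15,
    min_tail: int = 10,
) -> RegionAnnotation:
    """Partition the query into N-extension, core (+insertions) and C-tail.

    Query residues aligned before the reference core span form the
    N-terminal extension (reported when at least one residue long).
    Maximal query runs aligned to reference gaps strictly inside the core
    span, of length >= ``min_insertion``, are internal insertions; shorter
    runs are absorbed into the core. Query residues aligned after the core
    span form the C-terminal tail when at least ``min_tail`` long,
    otherwise they too are absorbed into the core.
    """
    lo, hi = ref.core_span
    labels: list[str] = []  # per query residue: 'n', 'c' (core), 'i', 't'
    rpos = 0
    for qc, rc in zip(alignment.aligned_query, alignment.aligned_ref):
        if rc != "-":
            rpos += 1
        if qc == "-":
            continue
        if rc != "-":
            if rpos < lo:
                labels.append("n")
            elif rpos > hi:
                labels.append("t")
            else:
                labels.append("c")
        else:
            # query insertion relative to the reference, between rpos and rpos+1
            if rpos < lo:
                labels.append("n")
            elif rpos >= hi:
                labels.append("t")
            else:
                labels.append("i")

    n = len(labels)
    # demote short insertion runs to core
    i = 0
    while i < n:
        if labels[i] == "i":
            j = i
            while j < n and labels[j] == "i":
                j += 1
            if j - i < min_insertion:
                for k in range(i, j):
                    labels[k] = "c"
            i = j
        else:
            i += 1
    # demote a short tail to core
    t_len = sum(1 for x in labels if x == "t")
    if 0 < t_len < min_tail:
        labels = ["c" if x == "t" else x for x in labels]

    n_ext = None
    n_len = sum(1 for x in labels if x == "n")
    if n_len:
        n_ext = (1, n_len)
    tail = None
    t_len = sum(1 for x in labels if x == "t")
    if t_len:
        tail = (n - t_len + 1, n)
    core_lo = n_len + 1
    core_hi = n - t_len
    if core_lo > core_hi:
        raise ValueError("query has no core residues against the reference")
    insertions: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if labels[i] == "i":
            j = i
            while j < n and labels[j] == "i":
                j += 1
            insertions.append((i + 1, j))
            i = j
        else:
            i += 1
    return RegionAnnotation(
        core=(core_lo, core_hi),
        n_ext=n_ext,
        insertions=tuple(insertions),
        c_tail=tail,
    )


def extract_core(record: ProteinRecord, regions: RegionAnnotation) -> str:
    """Core sequence: N-extension, internal insertions and C-tail removed."""
    seq = record.trimmed_sequence
    if regions.query_length != len(seq):
        raise ValueError("region annotation does not match sequence length")
    out = []
    for pos in range(regions.core[0], regions.core[1] + 1):
        if any(lo <= pos <= hi for lo, hi in regions.insertions):
            continue
        out.append(seq[pos - 1])
    return "".join(out)


def prune_gap_columns(
    rows: Sequence[str], threshold: float = 0.95
) -> tuple[list[str], list[int]]:
    """Drop alignment columns whose gap fraction strictly exceeds ``threshold``.

    Returns the pruned rows (order preserved) and the removed column
    indices, 1-based. A column at exactly the threshold is kept.
    """
    if not rows:
        return [], []
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("ragged alignment: rows differ in length")
    nrows = len(rows)
    removed = []
    keep_mask = []
    for j in range(width):
        gaps = sum(1 for r in rows if r[j] == "-")
        drop = gaps / nrows > threshold
        keep_mask.append(not drop)
        if drop:
            removed.append(j + 1)
    pruned = [
        "".join(ch for ch, keep in zip(row, keep_mask) if keep) for row in rows
    ]
    return pruned, removed


def project_to_reference(
    aln: PairwiseAlignment, ref: ReferenceProfile, core_only: bool = False
) -> str:
    """Project the query onto reference columns (reference-anchored row).

    Returns a gapped string of length ``len(ref.sequence)`` (or the core
    span width with ``core_only``): for each reference position, the query
    residue aligned to it, or ``-`` when the reference position is deleted
    in the query. Query residues aligned to reference gaps (insertions,
    tails) are dropped, so projected rows from different queries are
    mutually comparable as a pseudo-MSA.
    """
    row = []
    for qc, rc in zip(aln.aligned_query, aln.aligned_ref):
        if rc != "-":
            row.append(qc if qc != "-" else "-")
    if core_only:
        lo, hi = ref.core_span
        row = row[lo - 1 : hi]
    return "".join(row)


def read_aligned_fasta(path: str | Path) -> tuple[list[str], list[str]]:
    """Read an aligned FASTA; returns (labels, equal-length gapped rows)."""
    labels, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        labels.append(rec.description.split()[0])
        rows.append(str(rec.seq).upper())
    if not rows:
        raise ValueError(f"no alignment rows in {path}")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError(f"ragged alignment in {path}")
    return labels, rows


def write_aligned_fasta(
    labels: Sequence[str], rows: Sequence[str], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for label, row in zip(labels, rows):
            fh.write(f">{label}\n")
            for i in range(0, len(row), 60):
                fh.write(row[i : i + 60] + "\n")


def read_reference_profile(path: str | Path) -> ReferenceProfile:
    """Read a reference profile TSV with columns his_pos, core_start, core_end, sequence."""
    import csv

    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        row = next(iter(reader), None)
    if row is None:
        raise ValueError(f"empty reference profile {path}")
    return ReferenceProfile(
        sequence=row["sequence"].strip().upper(),
        catalytic_his_pos=int(row["his_pos"]),
        core_span=(int(row["core_start"]), int(row["core_end"])),
    )


def write_reference_profile(ref: ReferenceProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("his_pos\tcore_start\tcore_end\tsequence\n")
        fh.write(
            f"{ref.catalytic_his_pos}\t{ref.core_span[0]}\t{ref.core_span[1]}\t{ref.sequence}\n"
        )
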