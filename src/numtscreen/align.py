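"""Affine-gap pairwise alignment with reproducible INDEL placement.

Two alignment modes are provided: global (Needleman-Wunsch/Gotoh) and
"fit" mapping of a partial amplicon onto a full-length reference gene
(reference overhangs are free). Both use an affine gap cost of
``gap_open + L * gap_extend`` for a gap of length ``L`` and break ties
deterministically, preferring match/mismatch over deletion (gap in the
query) over insertion (gap in the reference) during traceback. After
traceback every gap run is shifted to its left-most score-equivalent
position, so INDEL coordinates inside homopolymer runs are reproducible.

Coordinates are 1-based inclusive relative to the reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_NEG = -1.0e30


class AlignmentError(ValueError):
    """Raised on invalid alignment input."""


class UnalignableError(AlignmentError):
    """Raised when a partial cannot be mapped to the reference at the
    required identity floor (usually wrong-locus or reverse-complement
    input; the mapper does not auto-orient)."""


@dataclass(frozen=True)
class Scoring:
    """Alignment scoring scheme.

    Defaults discourage spurious terminal micro-indels in high-identity
    mappings, where INDEL calls must reflect true length variants.
    """

    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -6.0
    gap_extend: float = -1.0


DEFAULT_SCORING = Scoring()


@dataclass
class PairwiseAlignment:
    """A gapped pairwise alignment of a query ``a`` against a reference
    ``b``; ``ref_offset`` is the 1-based reference position of the first
    aligned reference column (1 for global alignments)."""

    aligned_a: str
    aligned_b: str
    score: float
    ref_offset: int = 1

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise AlignmentError("aligned rows differ in length")

    @property
    def identity(self) -> float:
        """Fraction of aligned columns where both rows agree."""
        cols = len(self.aligned_a)
        if cols == 0:
            return 0.0
        matches = sum(
            1 for x, y in zip(self.aligned_a, self.aligned_b) if x == y and x != "-"
        )
        return matches / cols

    def to_fasta(self, name_a: str = "query", name_b: str = "reference") -> str:
        return f">{name_a}\n{self.aligned_a}\n>{name_b}\n{self.aligned_b}\n"


@dataclass
class MappedPartial:
    """A partial mapped onto a full-length reference gene."""

    alignment: PairwiseAlignment
    reference: str
    frame_offset: int  # codon phase of the partial's first aligned base

    @property
    def ref_offset(self) -> int:
        return self.alignment.ref_offset


@dataclass
class IndelEvent:
    """An interior insertion or deletion relative to the reference.

    ``ref_position`` is the 1-based reference coordinate of the base
    immediately left of the event (left-most placement);
    ``homopolymer_len`` records the length of the reference homopolymer
    run containing the event, since placement within such runs is
    inherently ambiguous.
    """

    kind: str  # "insertion" | "deletion"
    ref_position: int
    length: int
    residues: str
    homopolymer_len: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "deletion"):
            raise AlignmentError(f"unknown indel kind {self.kind!r}")
        if self.length < 1 or len(self.residues) != self.length:
            raise AlignmentError("indel length/residues mismatch")


def _dp_matrices(a: str, b: str, sc: Scoring, fit: bool):
    """Fill the three Gotoh state matrices.

    States: M ends in a match/mismatch column; X ends with a gap in the
    reference (insertion, consumes query); Y ends with a gap in the
    query (deletion, consumes reference).
    """
    n, m = len(a), len(b)
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    go = sc.gap_open + sc.gap_extend  # cost of opening (first gap column)
    ge = sc.gap_extend

    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    if fit:
        M[0, :] = 0.0  # free leading reference overhang
    else:
        M[0, 0] = 0.0
        Y[0, 1:] = sc.gap_open + ge * np.arange(1, m + 1)
    X[1:, 0] = sc.gap_open + ge * np.arange(1, n + 1)

    js = np.arange(1, m + 1, dtype=float)
    for i in range(1, n + 1):
        sub = np.where(bb == aa[i - 1], sc.match, sc.mismatch)
        prev = np.maximum(np.maximum(M[i - 1, :-1], X[i - 1, :-1]), Y[i - 1, :-1])
        M[i, 1:] = sub + prev
        X[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], Y[i - 1, 1:]) + go, X[i - 1, 1:] + ge
        )
        # Y has intra-row dependence; a gap covering columns k+1..j costs
        # open + (j-k)*extend, so Y[i,j] = open + j*ge + max_{k<j}(C[i,k] - k*ge)
        C = np.maximum(M[i], X[i])
        run = np.maximum.accumulate(C[:-1] - ge * np.arange(0, m))
        Y[i, 1:] = sc.gap_open + ge * js + run
    return M, X, Y


def _traceback(a, b, sc, fit, M, X, Y):
    """Recover one optimal alignment with deterministic tie-breaking
    (M over Y over X)."""
    n, m = len(a), len(b)
    go = sc.gap_open + sc.gap_extend
    ge = sc.gap_extend

    if fit:
        V = np.maximum(M[n], X[n])
        j = int(np.argmax(V))  # first occurrence: left-most end on ties
        state = "M" if M[n, j] >= X[n, j] else "X"
        score = float(V[j])
        trailing = m - j
    else:
        j = m
        vals = (M[n, m], Y[n, m], X[n, m])
        state = ("M", "Y", "X")[int(np.argmax(vals))]
        score = float(max(vals))
        trailing = 0

    i = n
    cols_a: list[str] = []
    cols_b: list[str] = []
    eps = 1e-6
    while i > 0 or (not fit and j > 0):
        if fit and i == 0:
            break
        if state == "M":
            cols_a.append(a[i - 1])
            cols_b.append(b[j - 1])
            tgt = M[i, j] - (sc.match if a[i - 1] == b[j - 1] else sc.mismatch)
            i -= 1
            j -= 1
            if i == 0 and (fit or j == 0):
                break
            for s, mat in (("M", M), ("Y", Y), ("X", X)):
                if abs(mat[i, j] - tgt) < eps:
                    state = s
                    break
            else:  # pragma: no cover - numerical safety
                raise AlignmentError("traceback failed in state M")
        elif state == "Y":  # gap in query, consumes reference
            cols_a.append("-")
            cols_b.append(b[j - 1])
            here = Y[i, j]
            j -= 1
            if abs(M[i, j] + go - here) < eps:
                state = "M"
            elif abs(Y[i, j] + ge - here) < eps:
                state = "Y"
            elif abs(X[i, j] + go - here) < eps:
                state = "X"
            else:  # pragma: no cover
                raise AlignmentError("traceback failed in state Y")
        else:  # X: gap in reference, consumes query
            cols_a.append(a[i - 1])
            cols_b.append("-")
            here = X[i, j]
            i -= 1
            if i == 0 and fit:
                break
            if abs(M[i, j] + go - here) < eps:
                state = "M"
            elif abs(Y[i, j] + go - here) < eps:
                state = "Y"
            elif abs(X[i, j] + ge - here) < eps:
                state = "X"
            elif i == 0 and j == 0:
                break
            else:  # pragma: no cover
                raise AlignmentError("traceback failed in state X")

    cols_a.reverse()
    cols_b.reverse()
    return "".join(cols_a), "".join(cols_b), score, j, trailing


def _shift_gaps_left(top: str, bot: str) -> tuple[str, str]:
    """Shift every gap run to its left-most score-equivalent placement
    (moves indels to the left edge of homopolymer/repeat context)."""
    a = list(top)
    b = list(bot)
    changed = True
    while changed:
        changed = False
        for row, other in ((a, b), (b, a)):
            i = 0
            L = len(row)
            while i < L:
                if row[i] != "-":
                    i += 1
                    continue
                s = i
                e = i
                while e + 1 < L and row[e + 1] == "-":
                    e += 1
                while (
                    s > 0
                    and row[s - 1] != "-"
                    and other[s - 1] != "-"
                    and other[s - 1] == other[e]
                ):
                    row[e] = row[s - 1]
                    row[s - 1] = "-"
                    s -= 1
                    e -= 1
                    changed = True
                i = e + 1
    return "".join(a), "".join(b)


def nw_align(
    a: str,
    b: str,
    match: float = DEFAULT_SCORING.match,
    mismatch: float = DEFAULT_SCORING.mismatch,
    gap_open: float = DEFAULT_SCORING.gap_open,
    gap_extend: float = DEFAULT_SCORING.gap_extend,
) -> PairwiseAlignment:
    """Optimal global alignment of ``a`` against ``b`` under an affine
    gap cost ``gap_open + L * gap_extend``."""
    if not a or not b:
        raise AlignmentError("sequences must be non-empty")
    sc = Scoring(match, mismatch, gap_open, gap_extend)
    M, X, Y = _dp_matrices(a, b, sc, fit=False)
    ra, rb, score, _, _ = _traceback(a, b, sc, False, M, X, Y)
    ra, rb = _shift_gaps_left(ra, rb)
    return PairwiseAlignment(ra, rb, score, ref_offset=1)


def map_partial_to_reference(
    partial: str,
    reference: str,
    scoring: Scoring = DEFAULT_SCORING,
    min_identity: float = 0.6,
) -> MappedPartial:
    """Semiglobal mapping of a partial gene fragment onto a full-length
    reference gene starting at codon position 1.

    Reference overhangs carry no penalty. ``frame_offset`` in {0,1,2} is
    the codon phase ``(ref_offset - 1) mod 3`` of the partial's first
    aligned base. Raises :class:`UnalignableError` when alignment
    identity falls below ``min_identity`` (signals wrong-locus input;
    reverse-complement partials are not auto-oriented).
    """
    if not partial or not reference:
        raise AlignmentError("sequences must be non-empty")
    M, X, Y = _dp_matrices(partial, reference, scoring, fit=True)
    ra, rb, score, j0, _ = _traceback(partial, reference, scoring, True, M, X, Y)
    ra, rb = _shift_gaps_left(ra, rb)
    ref_offset = j0 + 1
    # canonicalise: edge deletion columns belong to the reference overhang
    while ra and ra[0] == "-":
        ra = ra[1:]
        rb = rb[1:]
        ref_offset += 1
    while ra and ra[-1] == "-":
        ra = ra[:-1]
        rb = rb[:-1]
    aln = PairwiseAlignment(ra, rb, score, ref_offset=ref_offset)
    if aln.identity < min_identity:
        raise UnalignableError(
            f"alignment identity {aln.identity:.2f} below floor {min_identity:.2f}; "
            "input may be from the wrong locus or reverse-complemented"
        )
    return MappedPartial(aln, reference, frame_offset=(ref_offset - 1) % 3)


def _homopolymer_len(reference: str, ref_position: int, base: str) -> int:
    """Length of the run of ``base`` in ``reference`` adjacent to the
    1-based ``ref_position`` (the base left of the event)."""
    idx = ref_position  # 0-based index of the base right of the event
    run = 0
    i = idx
    while i < len(reference) and reference[i] == base:
        run += 1
        i += 1
    i = idx - 1
    while i >= 0 and reference[i] == base:
        run += 1
        i -= 1
    return max(run, 1)


def call_indels(mapped: MappedPartial) -> list[IndelEvent]:
    """Report maximal interior gap runs of a mapped partial as INDEL
    events in reference coordinates. Gap runs abutting the 5' or 3'
    terminus of the partial are amplicon overhangs, not INDELs."""
    top = mapped.alignment.aligned_a
    bot = mapped.alignment.aligned_b
    ncols = len(top)
    events: list[IndelEvent] = []
    refpos = mapped.alignment.ref_offset - 1  # last consumed ref coordinate
    c = 0
    while c < ncols:
        if top[c] != "-" and bot[c] != "-":
            refpos += 1
            c += 1
            continue
        s = c
        gap_row = top if top[c] == "-" else bot
        while c < ncols and gap_row[c] == "-":
            c += 1
        e = c - 1
        start_pos = refpos
        if gap_row is top:
            run_res = bot[s : e + 1]
            refpos += len(run_res)
        else:
            run_res = top[s : e + 1]
        if s == 0 or e == ncols - 1:
            continue  # terminal overhang
        kind = "deletion" if gap_row is top else "insertion"
        events.append(
            IndelEvent(
                kind=kind,
                ref_position=start_pos,
                length=len(run_res),
                residues=run_res,
                homopolymer_len=_homopolymer_len(
                    mapped.reference, start_pos, run_res[0]
                ),
            )
        )
    return events


def progressive_align(seqs: list[str], scoring: Scoring = DEFAULT_SCORING) -> list[str]:
    """Pairwise-progressive (centre-star on the first sequence) multiple
    alignment; adequate for near-identical gene copies, not a general
    MSA heuristic."""
    if not seqs:
        raise AlignmentError("no sequences to align")
    rows = [seqs[0]]
    center = seqs[0]
    for s in seqs[1:]:
        aln = nw_align(
            s, center, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
        )
        new_rows: list[list[str]] = [[] for _ in rows]
        new_row: list[str] = []
        i = 0  # column in current master rows
        master_center = rows[0]
        k = 0  # column in aln (center gapped as aligned_b)
        ca, cb = aln.aligned_a, aln.aligned_b
        while i < len(master_center) or k < len(ca):
            mc = master_center[i] if i < len(master_center) else None
            ac = cb[k] if k < len(ca) else None
            if mc == "-" and (ac is None or ac != "-"):
                for r, nr in zip(rows, new_rows):
                    nr.append(r[i])
                new_row.append("-")
                i += 1
            elif ac == "-":
                for nr in new_rows:
                    nr.append("-")
                new_row.append(ca[k])
                k += 1
            else:
                for r, nr in zip(rows, new_rows):
                    nr.append(r[i])
                new_row.append(ca[k])
                i += 1
                k += 1
        rows = ["".join(nr) for nr in new_rows]
        rows.append("".join(new_row))
    return rows
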