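"""Anchor-guided bisulfite alignment.

The protected (5mC-patched) Read2 prefix retains reference base composition
and is aligned conventionally ("anchor").  The bisulfite-converted Read1 is
then positioned by local alignment against the reference window extending
inward from each anchor, using an asymmetric-wildcard scoring in which a
read T may match a reference C (CT mode; the converse never matches), or a
read A a reference G (GA mode, used for reverse-complemented queries of
minus-strand fragments).

Scoring follows the GPS scheme: +5 match, 0 mismatch, -6 per gapped base
(linear).  Because mismatches cost nothing, local alignments extend freely
through them; specificity comes from the minimum-score cutoff
(``min_sw_score``, default 100 ~ 20 matched bases).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pysam

from .io import ReferenceSet, ReadPair
from .preprocess import BoundaryAnnotation, PipelineParams

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ScoringScheme:
    match: int = 5
    mismatch: int = 0
    gap_per_base: int = -6
    bisulfite_mode: str = "off"  # off | CT | GA

    def __post_init__(self) -> None:
        if self.bisulfite_mode not in ("off", "CT", "GA"):
            raise ValueError(f"unknown bisulfite mode {self.bisulfite_mode!r}")


@dataclass
class Alignment:
    """A local alignment of ``query[q_start:q_end]`` to ``target[t_start:t_end]``."""

    score: int
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    cigar: list[tuple[str, int]]  # ops M/I/D; I consumes query only, D target only

    def aligned_columns(self) -> Iterator[tuple[int, int]]:
        """Yield (query_pos, target_pos) for every M column."""
        q, t = self.q_start, self.t_start
        for op, ln in self.cigar:
            if op == "M":
                for k in range(ln):
                    yield q + k, t + k
                q += ln
                t += ln
            elif op == "I":
                q += ln
            elif op == "D":
                t += ln


@dataclass
class Placement:
    """A query placed on the reference.

    ``query`` is stored in aligned (reference-forward) orientation, i.e.
    reverse-complemented for minus-strand placements, matching SAM
    convention.  ``cigar``/``q_start``/``q_end`` refer to that orientation.
    """

    contig: str
    start0: int
    strand: str
    score: int
    cigar: list[tuple[str, int]]
    q_start: int
    q_end: int
    query: str
    n_candidates: int = 1

    @property
    def end0(self) -> int:
        return self.start0 + sum(ln for op, ln in self.cigar if op in "MD")

    def aligned_columns(self) -> Iterator[tuple[int, int]]:
        """Yield (query_pos, absolute reference_pos) for every M column."""
        q, t = self.q_start, self.start0
        for op, ln in self.cigar:
            if op == "M":
                for k in range(ln):
                    yield q + k, t + k
                q += ln
                t += ln
            elif op == "I":
                q += ln
            elif op == "D":
                t += ln


@dataclass
class PairedPlacement:
    pair_id: str
    r2_placement: Placement
    r1_placement: Placement
    pair_distance: int
    r1_keep: int = 0  # usable R1 read coordinates: [0, r1_keep)
    r2_keep: int = 0  # usable R2 read coordinates: [0, r2_keep)
    pair: ReadPair | None = None


@dataclass
class Unplaced:
    pair_id: str
    reason: str


# ---------------------------------------------------------------------------
# Smith-Waterman

_C, _G, _T, _A, _N = (ord(c) for c in "CGTAN")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _sub_row(qc: int, t: np.ndarray, scheme: ScoringScheme) -> np.ndarray:
    mask = t == qc
    if scheme.bisulfite_mode == "CT" and qc == _T:
        mask = mask | (t == _C)
    elif scheme.bisulfite_mode == "GA" and qc == _A:
        mask = mask | (t == _G)
    if qc == _N:
        mask = np.zeros_like(mask)
    else:
        mask = mask & (t != _N)
    return np.where(mask, np.int32(scheme.match), np.int32(scheme.mismatch))


def _sub_score(qc: int, tc: int, scheme: ScoringScheme) -> int:
    if qc == _N or tc == _N:
        return scheme.mismatch
    if qc == tc:
        return scheme.match
    if scheme.bisulfite_mode == "CT" and tc == _C and qc == _T:
        return scheme.match
    if scheme.bisulfite_mode == "GA" and tc == _G and qc == _A:
        return scheme.match
    return scheme.mismatch


def _dp_matrix_numpy(q: np.ndarray, t: np.ndarray, scheme: ScoringScheme) -> np.ndarray:
    n, m = len(q), len(t)
    g = -scheme.gap_per_base  # positive penalty
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    off = g * np.arange(m, dtype=np.int32)
    sub_cache: dict[int, np.ndarray] = {}
    prev = H[0]
    for i in range(1, n + 1):
        qc = int(q[i - 1])
        sub = sub_cache.get(qc)
        if sub is None:
            sub = sub_cache[qc] = _sub_row(qc, t, scheme)
        cand = prev[:-1] + sub
        np.maximum(cand, prev[1:] - g, out=cand)
        np.maximum(cand, 0, out=cand)
        # left gaps: best over k<j of cand[k] - g*(j-k), via running max
        run = np.maximum.accumulate(cand + off)
        row = H[i]
        row[1:] = cand
        if m > 1:
            np.maximum(row[2:], run[:-1] - off[1:], out=row[2:])
        prev = row
    return H


try:  # compiled kernel; the numpy path above is the fallback
    from numba import njit

    @njit(cache=True)
    def _fill_kernel(H, q, t, match, mismatch, gap, mode):  # pragma: no cover
        n = q.shape[0]
        m = t.shape[0]
        for i in range(1, n + 1):
            qc = q[i - 1]
            for j in range(1, m + 1):
                tc = t[j - 1]
                if qc == 78 or tc == 78:  # N
                    s = mismatch
                elif qc == tc:
                    s = match
                elif mode == 1 and tc == 67 and qc == 84:  # ref C / read T
                    s = match
                elif mode == 2 and tc == 71 and qc == 65:  # ref G / read A
                    s = match
                else:
                    s = mismatch
                v = H[i - 1, j - 1] + s
                u = H[i - 1, j] - gap
                if u > v:
                    v = u
                w = H[i, j - 1] - gap
                if w > v:
                    v = w
                if v < 0:
                    v = 0
                H[i, j] = v

    _MODE_NUM = {"off": 0, "CT": 1, "GA": 2}

    def _dp_matrix(q, t, scheme):
        H = np.zeros((len(q) + 1, len(t) + 1), dtype=np.int32)
        _fill_kernel(
            H,
            q.astype(np.int32),
            t.astype(np.int32),
            scheme.match,
            scheme.mismatch,
            -scheme.gap_per_base,
            _MODE_NUM[scheme.bisulfite_mode],
        )
        return H

except ImportError:  # pragma: no cover
    _dp_matrix = _dp_matrix_numpy


def _traceback(H, q, t, scheme, i, j):
    g = -scheme.gap_per_base
    ops: list[str] = []
    while i > 0 and j > 0 and H[i, j] > 0:
        sub = _sub_score(int(q[i - 1]), int(t[j - 1]), scheme)
        if H[i, j] == H[i - 1, j - 1] + sub:
            ops.append("M")
            i -= 1
            j -= 1
        elif H[i, j] == H[i - 1, j] - g:
            ops.append("I")
            i -= 1
        else:
            ops.append("D")
            j -= 1
    ops.reverse()
    cigar: list[tuple[str, int]] = []
    for op in ops:
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + 1)
        else:
            cigar.append((op, 1))
    return i, j, cigar


def sw_local(query: str, target: str, scheme: ScoringScheme | None = None) -> Alignment:
    """Maximal-scoring local alignment of ``query`` against ``target``.

    Deterministic tie-breaking: among co-optimal cells the alignment ending
    at the smallest target position (then query position) is chosen, with a
    diagonal-first traceback (fewest gaps).
    """
    scheme = scheme or ScoringScheme()
    if not query or not target:
        return Alignment(0, 0, 0, 0, 0, [])
    q, t = _encode(query), _encode(target)
    H = _dp_matrix(q, t, scheme)
    best = int(H.max())
    if best <= 0:
        return Alignment(0, 0, 0, 0, 0, [])
    cells = np.argwhere(H == best)
    order = np.lexsort((cells[:, 0], cells[:, 1]))  # smallest end col, then row
    i_end, j_end = (int(x) for x in cells[order[0]])
    i0, j0, cigar = _traceback(H, q, t, scheme, i_end, j_end)
    return Alignment(best, i0, i_end, j0, j_end, cigar)


# ---------------------------------------------------------------------------
# Anchor alignment (exact k-mer seed + SW extension)


class AnchorAligner:
    """Exact k-mer seeded anchor aligner over a desk-scale reference.

    Builds an index of all ``k``-mers (default 20) of every contig's
    forward strand; anchors are looked up both as-is (plus-strand
    placements) and reverse-complemented (minus-strand placements), each
    candidate diagonal then rescored with :func:`sw_local` in plain mode.
    """

    def __init__(self, ref: ReferenceSet, k: int = 20):
        self.ref = ref
        self.k = k
        self.index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in ref.contigs.items():
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos : pos + k]
                if "N" in kmer:
                    continue
                self.index.setdefault(kmer, []).append((name, pos))

    def _candidates(self, seq: str) -> set[tuple[str, int]]:
        diags: set[tuple[str, int]] = set()
        k = self.k
        for off in range(len(seq) - k + 1):
            for contig, pos in self.index.get(seq[off : off + k], ()):
                diags.add((contig, pos - off))
        return diags

    def align(self, anchor_seq: str, params: PipelineParams) -> list[Placement]:
        pad = 8
        placements: list[Placement] = []
        seen: set[tuple[str, int, str]] = set()
        for strand, seq in (("+", anchor_seq), ("-", revcomp(anchor_seq))):
            if len(seq) < self.k:
                continue
            for contig, diag in self._candidates(seq):
                ref_seq = self.ref[contig]
                ws = max(0, diag - pad)
                window = ref_seq[ws : diag + len(seq) + pad]
                aln = sw_local(seq, window, ScoringScheme())
                if aln.score < params.min_sw_score:
                    continue
                start0 = ws + aln.t_start
                key = (contig, start0, strand)
                if key in seen:
                    continue
                seen.add(key)
                placements.append(
                    Placement(
                        contig,
                        start0,
                        strand,
                        aln.score,
                        aln.cigar,
                        aln.q_start,
                        aln.q_end,
                        seq,
                    )
                )
        placements.sort(key=lambda p: (-p.score, p.contig, p.start0, p.strand != "+"))
        if placements:
            top = placements[0].score
            n_best = sum(1 for p in placements if p.score == top)
            for p in placements:
                p.n_candidates = n_best
        return placements[: params.max_hits]


def import_anchor_sam(path, ref: ReferenceSet) -> dict[str, list[Placement]]:
    """Ingest externally produced anchor alignments (e.g. bowtie2 -k 20).

    Returns a map from read name to placements, taken verbatim from the SAM
    records (score from the AS tag when present).
    """
    out: dict[str, list[Placement]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped or seg.query_sequence is None:
                continue
            if seg.reference_name not in ref.contigs:
                raise KeyError(f"SAM contig {seg.reference_name!r} absent from reference")
            cigar: list[tuple[str, int]] = []
            q_start = 0
            q_len = 0
            for op, ln in seg.cigartuples or ():
                if op in (0, 7, 8):  # M/=/X collapse to M
                    if cigar and cigar[-1][0] == "M":
                        cigar[-1] = ("M", cigar[-1][1] + ln)
                    else:
                        cigar.append(("M", ln))
                    q_len += ln
                elif op == 1:
                    cigar.append(("I", ln))
                    q_len += ln
                elif op == 2:
                    cigar.append(("D", ln))
                elif op == 4:
                    if not cigar:
                        q_start = ln
            score = seg.get_tag("AS") if seg.has_tag("AS") else 0
            out.setdefault(seg.query_name, []).append(
                Placement(
                    seg.reference_name,
                    seg.reference_start,
                    "-" if seg.is_reverse else "+",
                    int(score),
                    cigar,
                    q_start,
                    q_start + q_len,
                    seg.query_sequence,
                )
            )
    for placements in out.values():
        top = max(p.score for p in placements)
        n_best = sum(1 for p in placements if p.score == top)
        for p in placements:
            p.n_candidates = n_best
    return out


# ---------------------------------------------------------------------------
# R1 positioning


def position_r1(
    pair_id: str,
    r1_seq: str,
    r2_placements: list[Placement],
    ref: ReferenceSet,
    params: PipelineParams,
) -> PairedPlacement | Unplaced:
    """Place R1 within ``max_pair_distance`` of each anchor, keep the best.

    The anchor strand dictates the fragment orientation: a minus-strand
    anchor means the fragment is the plus strand (R1 aligned in CT mode
    against the window left of the anchor's right edge); a plus-strand
    anchor means a minus-strand fragment (reverse-complemented R1 aligned
    in GA mode against the window right of the anchor start).  Equal best
    scores across different anchors are ambiguous.
    """
    best: tuple[int, Placement, Placement] | None = None
    ambiguous = False
    for r2p in r2_placements:
        ref_seq = ref[r2p.contig]
        if r2p.strand == "-":
            hi = r2p.end0
            lo = max(0, hi - params.max_pair_distance)
            query = r1_seq
            mode = "CT"
            r1_strand = "+"
        else:
            lo = r2p.start0
            hi = min(len(ref_seq), lo + params.max_pair_distance)
            query = revcomp(r1_seq)
            mode = "GA"
            r1_strand = "-"
        window = ref_seq[lo:hi]
        aln = sw_local(query, window, ScoringScheme(bisulfite_mode=mode))
        if aln.score < params.min_sw_score:
            continue
        r1p = Placement(
            r2p.contig,
            lo + aln.t_start,
            r1_strand,
            aln.score,
            aln.cigar,
            aln.q_start,
            aln.q_end,
            query,
        )
        if best is None or aln.score > best[0]:
            best = (aln.score, r1p, r2p)
            ambiguous = False
        elif aln.score == best[0] and (
            r1p.contig != best[1].contig or r1p.start0 != best[1].start0
        ):
            ambiguous = True
    if best is None:
        return Unplaced(pair_id, "low_score")
    if ambiguous:
        return Unplaced(pair_id, "ambiguous")
    _, r1p, r2p = best
    left = min(r1p.start0, r2p.start0)
    right = max(r1p.end0, r2p.end0)
    return PairedPlacement(pair_id, r2p, r1p, right - left)


# ---------------------------------------------------------------------------
# Trimming


def trim_paired(
    pp: PairedPlacement,
    ref: ReferenceSet,
    boundary: BoundaryAnnotation,
    params: PipelineParams,
) -> PairedPlacement:
    """Set treatment-consistent keep-spans on a placed pair.

    R2 keeps only its protected prefix ``[0, r2_boundary)`` — the converted
    tail is insufficiently-cut material, unusable for variant calling.  R1
    is scanned 3'->5' along its alignment for the first converted base
    (read T at reference C for plus fragments, read A at reference G for
    minus); everything 3' of that position is potentially 5mC-patched
    (excessively cut) and is dropped.  If the aligned reference span shows
    no fragment-strand cytosine at all, the whole read is kept (degenerate,
    no evidence either way); if cytosines exist but none is converted, the
    whole read is dropped (fully patched).
    """
    pp.r2_keep = boundary.r2_boundary or 0
    r1p = pp.r1_placement
    ref_seq = ref[r1p.contig]
    L = len(r1p.query)
    cols = list(r1p.aligned_columns())
    if r1p.strand == "+":
        ref_c, conv = "C", "T"
        cols_scan = reversed(cols)  # read 3' end = largest query pos

        def to_keep(qpos: int) -> int:
            return qpos + 1
    else:
        # query is revcomp(R1); R1's 3' end is the smallest revcomp coordinate
        ref_c, conv = "G", "A"
        cols_scan = iter(cols)

        def to_keep(qpos: int) -> int:
            return L - qpos
    saw_c = False
    k = 0
    for qpos, tpos in cols_scan:
        if ref_seq[tpos] != ref_c:
            continue
        saw_c = True
        if r1p.query[qpos] == conv:
            k = to_keep(qpos)
            break
    if not saw_c:
        k = L
    pp.r1_keep = k
    return pp
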