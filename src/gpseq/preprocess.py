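"""Quality filtering, duplicate removal and treatment-boundary detection.

The Read2 5' prefix is the T4-polymerase 5mC patch: its cytosines were
incorporated as 5-methyl-dCTP and survive bisulfite treatment, so Read2
retains reference base composition up to the patch boundary and shows G->A
conversion beyond it (Read2 reads the complement of the converted fragment
strand).  Since somatic methylation is almost exclusively CpG, a G in a
non-CpG dinucleotide (5'-[A/T/G]G-3') is patch evidence; the last such G
scanning 5'->3' marks the treatment boundary, and the prefix up to and
including it is the alignment anchor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

from .io import ReadPair


@dataclass
class PipelineParams:
    """Tunable thresholds of the GPS data-processing pipeline.

    Defaults follow the published protocol: Q>=35 for >=70% of bases per
    mate, anchors shorter than 35 nt discarded, up to 20 anchor hits,
    R1 searched within 1 kb of each anchor, 5/0/-6 alignment scoring with a
    minimum local score of 100, and ASM called at >=70 percentage points
    difference with >=5x coverage per allele group.
    """

    qc_qual_cutoff: int = 35
    qc_min_fraction: float = 0.70
    min_anchor_len: int = 35
    max_hits: int = 20
    max_pair_distance: int = 1000
    min_sw_score: int = 100
    asm_min_diff: float = 70.0
    asm_min_cov: int = 5
    trim_default_len: int = 100
    var_min_alt_count: int = 2
    var_min_alt_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.qc_min_fraction <= 1.0:
            raise ValueError("qc_min_fraction must be in [0,1]")
        for name in (
            "qc_qual_cutoff",
            "min_anchor_len",
            "max_hits",
            "max_pair_distance",
            "min_sw_score",
            "asm_min_diff",
            "asm_min_cov",
            "trim_default_len",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class BoundaryAnnotation:
    """Read2 treatment boundary: index one past the last protected base."""

    r2_boundary: int | None
    anchor_seq: str
    discarded: bool = False
    reason: str | None = None


def _qualified_fraction(qual: str, cutoff: int) -> float:
    if not qual:
        return 0.0
    phred = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int16) - 33
    return float((phred >= cutoff).mean())


def quality_filter(pair: ReadPair, params: PipelineParams) -> tuple[bool, str | None]:
    """Keep a pair iff both mates have >= ``qc_min_fraction`` of bases at
    Q >= ``qc_qual_cutoff``.  Returns (keep, reason)."""
    if not pair.r1_seq or not pair.r2_seq:
        return False, "empty_read"
    for qual in (pair.r1_qual, pair.r2_qual):
        if _qualified_fraction(qual, params.qc_qual_cutoff) < params.qc_min_fraction:
            return False, "low_quality"
    return True, None


def deduplicate(pairs: Iterable[ReadPair]) -> Iterator[ReadPair]:
    """Drop pairs whose (R1, R2) sequence tuple was already seen.

    Keys on exact sequence identity (like the protocol's sort|uniq on
    pasted sequence lines), not on alignment coordinates; the first
    occurrence survives, input order is preserved.
    """
    seen: set[tuple[str, str]] = set()
    for p in pairs:
        key = (p.r1_seq, p.r2_seq)
        if key in seen:
            continue
        seen.add(key)
        yield p


_H = frozenset("ATG")


def detect_r2_boundary(r2_seq: str, params: PipelineParams) -> BoundaryAnnotation:
    """Locate the last 5'-[A/T/G]G-3' dinucleotide in Read2.

    The boundary G is included in the anchor (one more provably protected
    base).  Anchors shorter than ``min_anchor_len`` are discarded.
    """
    boundary = None
    for i in range(len(r2_seq) - 1, 0, -1):
        if r2_seq[i] == "G" and r2_seq[i - 1] in _H:
            boundary = i + 1
            break
    if boundary is None:
        return BoundaryAnnotation(None, "", True, "no_boundary")
    if boundary < params.min_anchor_len:
        return BoundaryAnnotation(boundary, r2_seq[:boundary], True, "too_short")
    return BoundaryAnnotation(boundary, r2_seq[:boundary])


# ---------------------------------------------------------------------------
# Sanger-clone incorporation-length estimator


@dataclass
class IncorporationEstimate:
    length: int
    orientation: str  # A | B
    resolved_by_ref: bool = False


def _find_insert(clone_seq: str, primer_fwd: str, primer_idx: str):
    from .align import revcomp

    p_fwd = clone_seq.find(primer_fwd)
    p_idx_rc = clone_seq.find(revcomp(primer_idx))
    if p_fwd != -1 and p_idx_rc != -1 and p_fwd < p_idx_rc:
        return clone_seq[p_fwd + len(primer_fwd) : p_idx_rc], "A"
    p_idx = clone_seq.find(primer_idx)
    p_fwd_rc = clone_seq.find(revcomp(primer_fwd))
    if p_idx != -1 and p_fwd_rc != -1 and p_idx < p_fwd_rc:
        return clone_seq[p_idx + len(primer_idx) : p_fwd_rc], "B"
    raise ValueError("primers (or their reverse complements) not found flanking an insert")


def _noncpg_c_positions(seq: str) -> list[int]:
    # C not followed by G on this strand (a terminal C counts as non-CpG)
    return [i for i, b in enumerate(seq) if b == "C" and (i + 1 >= len(seq) or seq[i + 1] != "G")]


def _noncpg_g_positions(seq: str) -> list[int]:
    return [i for i, b in enumerate(seq) if b == "G" and (i == 0 or seq[i - 1] != "C")]


def estimate_incorporation_length(
    clone_seq: str,
    primer_fwd: str,
    primer_idx: str,
    ref: str | None = None,
) -> IncorporationEstimate:
    """Estimate the 5mC incorporation (patch) length from a Sanger clone.

    Orientation A (forward primer at 5', revcomp index primer at 3'): the
    patch sits at the insert 3' end; its extent is the distance from the 3'
    terminus to the farthest retained non-CpG C (scanning 3'->5', the last
    one seen), inclusive.  Orientation B (index primer at 5'): the patch is
    read from the 5' end; its extent runs to the last non-CpG G scanning
    5'->3', inclusive.  No retained non-CpG base means no patch evidence
    (length 0).

    When ``ref`` (the matching reference region) is supplied, distal
    retained bases that are contradicted by conversion-proven positions
    (read T at non-CpG reference C, or read A at non-CpG reference G,
    between them and the terminus) are treated as artifacts and the
    boundary moves inward past them.
    """
    insert, orientation = _find_insert(clone_seq.upper(), primer_fwd.upper(), primer_idx.upper())
    if not insert:
        raise ValueError("empty insert between primers")
    n = len(insert)
    if orientation == "A":
        evid = _noncpg_c_positions(insert)
        naive = (n - min(evid)) if evid else 0
    else:
        evid = _noncpg_g_positions(insert)
        naive = (max(evid) + 1) if evid else 0
    if ref is None:
        return IncorporationEstimate(naive, orientation)

    from .align import ScoringScheme, sw_local

    aln = sw_local(insert, ref.upper(), ScoringScheme())
    conv: list[int] = []  # insert positions proven bisulfite-converted
    for qpos, tpos in aln.aligned_columns():
        rb = ref.upper()[tpos]
        ib = insert[qpos]
        if orientation == "A":
            noncpg = tpos + 1 >= len(ref) or ref.upper()[tpos + 1] != "G"
            if rb == "C" and ib == "T" and noncpg:
                conv.append(qpos)
        else:
            noncpg = tpos == 0 or ref.upper()[tpos - 1] != "C"
            if rb == "G" and ib == "A" and noncpg:
                conv.append(qpos)
    if orientation == "A":
        # patch = [boundary, n); it may not contain a proven conversion
        limit = max(conv) if conv else -1
        ok = [i for i in evid if i > limit]
        refined = (n - min(ok)) if ok else 0
    else:
        # patch = [0, boundary); boundary must precede the first conversion
        limit = min(conv) if conv else n
        ok = [i for i in evid if i < limit]
        refined = (max(ok) + 1) if ok else 0
    return IncorporationEstimate(refined, orientation, resolved_by_ref=refined != naive)
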