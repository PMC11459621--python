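"""Per-cytosine methylation pileup from trimmed Read1 spans.

Only Read1 contributes methylation: Read2's protected prefix is
artificially methylated by the 5mC patch and must never enter the pileup
(the core GPS asymmetry).  This is enforced structurally — the pileup
consumes only ``r1_placement`` and ``r1_keep``.

The level at a reference cytosine is 100 * C / (C + T) over contributing
read bases (strand-symmetric: G / (G + A) read on the reverse-complemented
query for minus-strand fragments).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .align import PairedPlacement
from .io import ReferenceSet


@dataclass
class MethylationRecord:
    contig: str
    pos0: int
    strand: str
    context: str  # CpG | nonCpG
    count_meth: int
    count_unmeth: int

    @property
    def level_percent(self) -> float:
        return 100.0 * self.count_meth / (self.count_meth + self.count_unmeth)


def _context(ref_seq: str, pos: int, strand: str) -> str:
    if strand == "+":
        return "CpG" if pos + 1 < len(ref_seq) and ref_seq[pos + 1] == "G" else "nonCpG"
    return "CpG" if pos > 0 and ref_seq[pos - 1] == "C" else "nonCpG"


def _accumulate(pp: PairedPlacement, ref: ReferenceSet, counts) -> None:
    r1 = pp.r1_placement
    k = pp.r1_keep
    if k <= 0:
        return
    ref_seq = ref[r1.contig]
    L = len(r1.query)
    if r1.strand == "+":
        ref_c, meth_base, unmeth_base, strand = "C", "C", "T", "+"

        def in_keep(qpos: int) -> bool:
            return qpos < k
    else:
        # query is revcomp(R1); original read coordinate i = L-1-qpos
        ref_c, meth_base, unmeth_base, strand = "G", "G", "A", "-"

        def in_keep(qpos: int) -> bool:
            return qpos >= L - k
    for qpos, tpos in r1.aligned_columns():
        if not in_keep(qpos) or ref_seq[tpos] != ref_c:
            continue
        b = r1.query[qpos]
        if b == meth_base:
            counts.setdefault((r1.contig, tpos, strand), [0, 0])[0] += 1
        elif b == unmeth_base:
            counts.setdefault((r1.contig, tpos, strand), [0, 0])[1] += 1


def pileup_methylation(
    paired_placements: Iterable[PairedPlacement],
    ref: ReferenceSet,
    merge_strands: bool = False,
) -> list[MethylationRecord]:
    """Pile up trimmed R1 bases at reference cytosines.

    With ``merge_strands`` the two strands of a CpG are combined into a
    single record at the C position of the plus strand; non-CpG sites are
    never merged.
    """
    counts: dict[tuple[str, int, str], list[int]] = {}
    for pp in paired_placements:
        _accumulate(pp, ref, counts)
    if merge_strands:
        merged: dict[tuple[str, int, str], list[int]] = {}
        for (contig, pos, strand), (m, u) in counts.items():
            ctx = _context(ref[contig], pos, strand)
            if ctx == "CpG" and strand == "-":
                key = (contig, pos - 1, "+")
            else:
                key = (contig, pos, strand)
            acc = merged.setdefault(key, [0, 0])
            acc[0] += m
            acc[1] += u
        counts = merged
    records = [
        MethylationRecord(contig, pos, strand, _context(ref[contig], pos, strand), m, u)
        for (contig, pos, strand), (m, u) in counts.items()
        if m + u >= 1
    ]
    records.sort(key=lambda r: (r.contig, r.pos0, r.strand))
    return records


def conversion_efficiency(records: Iterable[MethylationRecord], ref: ReferenceSet) -> float:
    """Bisulfite conversion efficiency (%) from the unmethylated spike-in.

    Every retained C on a control contig is a conversion failure, so
    efficiency = 100 * sum(unmeth) / sum(meth + unmeth) over control
    records.  Raises if the control has no coverage.
    """
    n_meth = n_total = 0
    for r in records:
        if ref.is_control(r.contig):
            n_meth += r.count_meth
            n_total += r.count_meth + r.count_unmeth
    if n_total == 0:
        raise ValueError("no coverage on control contigs; conversion efficiency undefined")
    return 100.0 * (n_total - n_meth) / n_total
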