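"""Readers/writers for the standard formats the pipeline touches.

All in-memory coordinates are 0-based, half-open.  Conversion to 1-based
happens only at SAM emission (delegated to pysam).  TSV reports keep the
internal 0-based convention.
"""

from __future__ import annotations

import gzip
import io as io_module
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

import pysam
from Bio.SeqIO.QualityIO import FastqGeneralIterator

DNA_RE = re.compile(r"^[ACGTN]*$")
_MATE_SUFFIX = re.compile(r"/[12]$")


class FormatError(ValueError):
    """Malformed FASTA/FASTQ/SAM input."""


@dataclass
class ReferenceSet:
    """A reference genome plus the names of unmethylated spike-in contigs.

    ``control_contigs`` flags contigs (e.g. the lambda spike-in) that are
    known to carry no methylation and are used to estimate bisulfite
    conversion efficiency.
    """

    contigs: dict[str, str]
    control_contigs: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for name in self.contigs:
            if not name or any(c.isspace() for c in name):
                raise FormatError(f"invalid contig name {name!r}")
        missing = self.control_contigs - set(self.contigs)
        if missing:
            raise FormatError(f"control contigs absent from reference: {sorted(missing)}")

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def is_control(self, name: str) -> bool:
        return name in self.control_contigs


@dataclass
class ReadPair:
    """One sequenced fragment: R1/R2 sequences and Phred+33 quality strings."""

    id: str
    r1_seq: str
    r2_seq: str
    r1_qual: str
    r2_qual: str

    def __post_init__(self) -> None:
        if len(self.r1_seq) != len(self.r1_qual) or len(self.r2_seq) != len(self.r2_qual):
            raise FormatError(f"read {self.id}: sequence/quality length mismatch")


def _open(path, mode: str = "rt") -> IO:
    path = str(path)
    if path.endswith(".gz"):
        if "w" in mode:
            # fixed mtime so identical content gives identical bytes
            raw = gzip.GzipFile(path, "wb", mtime=0)
            return raw if "b" in mode else io_module.TextIOWrapper(raw)
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, control_contigs: Iterable[str] = ()) -> ReferenceSet:
    """Read a FASTA file into a :class:`ReferenceSet`.

    Lowercase bases are uppercased; duplicate record names and non-IUPAC
    characters (outside A/C/G/T/N after uppercasing) raise
    :class:`FormatError` naming the offending record.
    """
    contigs: dict[str, str] = {}
    name = None
    chunks: list[str] = []

    def _flush() -> None:
        if name is None:
            return
        seq = "".join(chunks).upper()
        if not DNA_RE.match(seq):
            raise FormatError(f"record {name!r}: non-IUPAC characters in sequence")
        if name in contigs:
            raise FormatError(f"duplicate contig name {name!r}")
        contigs[name] = seq

    with _open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                name = line[1:].split()[0] if line[1:].split() else ""
                chunks = []
            else:
                if name is None:
                    raise FormatError("sequence data before first FASTA header")
                chunks.append(line.strip())
        _flush()
    if not contigs:
        raise FormatError(f"{path}: empty FASTA")
    return ReferenceSet(contigs, set(control_contigs))


def write_fasta(ref: ReferenceSet, path, width: int = 70) -> None:
    with _open(path, "wt") as fh:
        for name, seq in ref.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ


def _pair_id(name1: str, name2: str) -> str:
    a = _MATE_SUFFIX.sub("", name1.split()[0])
    b = _MATE_SUFFIX.sub("", name2.split()[0])
    # ids are matched positionally; differing names are tolerated, R1 wins
    return a if a == b else a


def read_fastq_pairs(path_r1, path_r2) -> Iterator[ReadPair]:
    """Stream record-synchronized mate files as :class:`ReadPair` objects."""
    with _open(path_r1) as f1, _open(path_r2) as f2:
        it1 = FastqGeneralIterator(f1)
        it2 = FastqGeneralIterator(f2)
        idx = 0
        while True:
            rec1 = next(it1, None)
            rec2 = next(it2, None)
            if rec1 is None and rec2 is None:
                return
            if rec1 is None or rec2 is None:
                raise FormatError(
                    f"mate files out of sync: one file ended at record {idx}"
                )
            (n1, s1, q1), (n2, s2, q2) = rec1, rec2
            if len(s1) != len(q1) or len(s2) != len(q2):
                raise FormatError(f"record {idx}: sequence/quality length mismatch")
            yield ReadPair(_pair_id(n1, n2), s1.upper(), s2.upper(), q1, q2)
            idx += 1


def write_fastq_pairs(pairs: Iterable[ReadPair], path_r1, path_r2) -> None:
    with _open(path_r1, "wt") as f1, _open(path_r2, "wt") as f2:
        for p in pairs:
            f1.write(f"@{p.id}/1\n{p.r1_seq}\n+\n{p.r1_qual}\n")
            f2.write(f"@{p.id}/2\n{p.r2_seq}\n+\n{p.r2_qual}\n")


# ---------------------------------------------------------------------------
# TSV reports


def _fmt_level(x: float) -> str:
    s = f"{x:.4f}".rstrip("0")
    return s + "0" if s.endswith(".") else s


METH_HEADER = ["contig", "start", "strand", "context", "count_meth", "count_unmeth", "level_percent"]
VARIANT_HEADER = ["contig", "pos0", "ref_base", "alt_base", "coverage", "alt_count"]
ASM_HEADER = VARIANT_HEADER + [
    "cyt_contig",
    "cyt_pos0",
    "cyt_strand",
    "level_with_alt",
    "cov_with_alt",
    "level_without_alt",
    "cov_without_alt",
    "diff",
    "is_asm",
]


def write_methylation_report(records, path) -> None:
    with _open(path, "wt") as fh:
        fh.write("\t".join(METH_HEADER) + "\n")
        for r in records:
            fh.write(
                f"{r.contig}\t{r.pos0}\t{r.strand}\t{r.context}\t"
                f"{r.count_meth}\t{r.count_unmeth}\t{_fmt_level(r.level_percent)}\n"
            )


def write_variant_report(records, path) -> None:
    with _open(path, "wt") as fh:
        fh.write("\t".join(VARIANT_HEADER) + "\n")
        for v in records:
            fh.write(
                f"{v.contig}\t{v.pos0}\t{v.ref_base}\t{v.alt_base}\t{v.coverage}\t{v.alt_count}\n"
            )


def write_asm_report(records, path) -> None:
    with _open(path, "wt") as fh:
        fh.write("\t".join(ASM_HEADER) + "\n")
        for a in records:
            s = a.site
            fh.write(
                f"{s.contig}\t{s.pos0}\t{s.ref_base}\t{s.alt_base}\t{s.coverage}\t{s.alt_count}\t"
                f"{a.cyt_contig}\t{a.cyt_pos0}\t{a.cyt_strand}\t"
                f"{_fmt_level(a.level_with_alt)}\t{a.cov_with_alt}\t"
                f"{_fmt_level(a.level_without_alt)}\t{a.cov_without_alt}\t"
                f"{_fmt_level(a.diff)}\t{int(a.is_asm)}\n"
            )


def write_report(records, kind: str, path) -> None:
    """Dispatch on report ``kind``: ``methylation`` | ``variants`` | ``asm``."""
    writer = {
        "methylation": write_methylation_report,
        "variants": write_variant_report,
        "asm": write_asm_report,
    }.get(kind)
    if writer is None:
        raise ValueError(f"unknown report kind {kind!r}")
    writer(records, path)


# ---------------------------------------------------------------------------
# SAM

_CIGAR_NUM = {"M": 0, "I": 1, "D": 2, "S": 4}


def sam_header(ref: ReferenceSet) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": len(s)} for n, s in ref.contigs.items()],
    }


def _segment(header, name, placement, qual, is_read1, mate, tlen):
    seg = pysam.AlignedSegment(header)
    seg.query_name = name
    flag = 0x1 | 0x2 | (0x40 if is_read1 else 0x80)
    if placement.strand == "-":
        flag |= 0x10
    if mate.strand == "-":
        flag |= 0x20
    seg.flag = flag
    seg.reference_name = placement.contig
    seg.reference_start = placement.start0
    seg.mapping_quality = 60 if placement.n_candidates <= 1 else 3
    cig = []
    if placement.q_start:
        cig.append((_CIGAR_NUM["S"], placement.q_start))
    cig.extend((_CIGAR_NUM[op], ln) for op, ln in placement.cigar)
    tail = len(placement.query) - placement.q_end
    if tail:
        cig.append((_CIGAR_NUM["S"], tail))
    seg.cigartuples = cig
    seg.query_sequence = placement.query
    if qual is not None:
        seg.query_qualities = pysam.qualitystring_to_array(qual)
    seg.next_reference_name = mate.contig
    seg.next_reference_start = mate.start0
    seg.template_length = tlen
    seg.set_tag("AS", int(placement.score))
    return seg


def write_sam(paired_placements, ref: ReferenceSet, path) -> None:
    """Emit placed pairs as a minimal SAM file (1-based POS via pysam)."""
    header = pysam.AlignmentHeader.from_dict(sam_header(ref))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for pp in paired_placements:
            r1, r2 = pp.r1_placement, pp.r2_placement
            left = min(r1.start0, r2.start0)
            right = max(r1.end0, r2.end0)
            span = right - left
            t1 = span if r1.start0 <= r2.start0 else -span
            # R2's stored query is the anchor prefix; slice quality to match
            q1 = pp.pair.r1_qual[: len(r1.query)] if pp.pair else None
            q2 = pp.pair.r2_qual[: len(r2.query)] if pp.pair else None
            if q1 is not None and r1.strand == "-":
                q1 = q1[::-1]
            if q2 is not None and r2.strand == "-":
                q2 = q2[::-1]
            out.write(_segment(header, pp.pair_id, r1, q1, True, r2, t1))
            out.write(_segment(header, pp.pair_id, r2, q2, False, r1, -t1))
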