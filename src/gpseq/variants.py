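"""Variant candidates from protected Read2 segments and allele-specific
methylation (ASM) detection.

The Read2 prefix up to the treatment boundary retains reference base
composition (its cytosines were 5mC-protected), so it supports ordinary
variant pileup — unlike bisulfite-converted material.  For each candidate
heterozygous site, read pairs are partitioned by the protected base they
show at the site, and the two groups' Read1 methylation pileups are
contrasted per cytosine; a difference >= 70 percentage points with >= 5x
coverage in both groups is called ASM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .align import PairedPlacement
from .io import ReferenceSet
from .methylation import pileup_methylation, _context
from .preprocess import PipelineParams


@dataclass
class VariantSite:
    contig: str
    pos0: int
    ref_base: str
    alt_base: str
    coverage: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.alt_base == self.ref_base:
            raise ValueError("alt_base equals ref_base")
        if not 1 <= self.alt_count <= self.coverage:
            raise ValueError("alt_count outside [1, coverage]")


@dataclass
class ASMRecord:
    site: VariantSite
    cyt_contig: str
    cyt_pos0: int
    cyt_strand: str
    level_with_alt: float
    cov_with_alt: int
    level_without_alt: float
    cov_without_alt: int

    @property
    def diff(self) -> float:
        return abs(self.level_with_alt - self.level_without_alt)

    def is_asm_at(self, params: PipelineParams) -> bool:
        return (
            self.diff >= params.asm_min_diff
            and self.cov_with_alt >= params.asm_min_cov
            and self.cov_without_alt >= params.asm_min_cov
        )

    # populated by asm_scan with the params in force
    is_asm: bool = False


def _protected_columns(pp: PairedPlacement):
    """Yield (absolute ref pos, reference-sense read base) for every aligned
    Read2 base inside the protected keep-span."""
    r2 = pp.r2_placement
    k = pp.r2_keep
    L = len(r2.query)
    for qpos, tpos in r2.aligned_columns():
        # query is stored reference-forward; for '-' placements the original
        # read coordinate is L-1-qpos
        read_coord = qpos if r2.strand == "+" else L - 1 - qpos
        if read_coord < k:
            yield tpos, r2.query[qpos]


def call_variant_candidates(
    paired_placements: Sequence[PairedPlacement],
    ref: ReferenceSet,
    params: PipelineParams,
) -> list[VariantSite]:
    """Pileup over protected Read2 spans; report (site, alt) with
    alt_count >= ``var_min_alt_count`` and alt fraction >=
    ``var_min_alt_fraction``."""
    counts: dict[tuple[str, int], dict[str, int]] = {}
    for pp in paired_placements:
        contig = pp.r2_placement.contig
        for tpos, base in _protected_columns(pp):
            if base == "N":
                continue
            counts.setdefault((contig, tpos), {}).setdefault(base, 0)
            counts[(contig, tpos)][base] += 1
    sites: list[VariantSite] = []
    for (contig, pos), bases in counts.items():
        ref_base = ref[contig][pos]
        coverage = sum(bases.values())
        for alt, cnt in bases.items():
            if alt == ref_base or alt == "N":
                continue
            if cnt >= params.var_min_alt_count and cnt / coverage >= params.var_min_alt_fraction:
                sites.append(VariantSite(contig, pos, ref_base, alt, coverage, cnt))
    sites.sort(key=lambda s: (s.contig, s.pos0, s.alt_base))
    return sites


def build_protected_index(
    paired_placements: Sequence[PairedPlacement],
) -> dict[tuple[str, int], list[tuple[int, str]]]:
    """Map (contig, ref pos) -> [(pair index, protected base), ...]."""
    index: dict[tuple[str, int], list[tuple[int, str]]] = {}
    for i, pp in enumerate(paired_placements):
        contig = pp.r2_placement.contig
        for tpos, base in _protected_columns(pp):
            index.setdefault((contig, tpos), []).append((i, base))
    return index


def group_pairs_by_allele(
    site: VariantSite,
    paired_placements: Sequence[PairedPlacement],
    index: dict[tuple[str, int], list[tuple[int, str]]] | None = None,
) -> tuple[list[int], list[int]]:
    """Partition pair indices by the protected Read2 base at the site.

    Pairs showing the alt base go to the first group, the ref base to the
    second; any other base (or no protected coverage) joins neither.
    """
    if index is None:
        index = build_protected_index(paired_placements)
    with_alt: list[int] = []
    without_alt: list[int] = []
    for i, base in index.get((site.contig, site.pos0), ()):
        if base == site.alt_base:
            with_alt.append(i)
        elif base == site.ref_base:
            without_alt.append(i)
    return with_alt, without_alt


def asm_scan(
    sites: Iterable[VariantSite],
    paired_placements: Sequence[PairedPlacement],
    ref: ReferenceSet,
    params: PipelineParams,
) -> list[ASMRecord]:
    """Contrast per-cytosine methylation between allele groups at each site.

    For every cytosine covered >= ``asm_min_cov`` in BOTH groups an
    :class:`ASMRecord` is emitted; ``is_asm`` applies the published
    thresholds (difference >= 70 pp, coverage >= 5 per group).
    """
    out: list[ASMRecord] = []
    index = build_protected_index(paired_placements)
    for site in sites:
        with_idx, without_idx = group_pairs_by_allele(site, paired_placements, index)
        if not with_idx or not without_idx:
            continue
        pile_with = {
            (r.contig, r.pos0, r.strand): r
            for r in pileup_methylation((paired_placements[i] for i in with_idx), ref)
        }
        pile_without = {
            (r.contig, r.pos0, r.strand): r
            for r in pileup_methylation((paired_placements[i] for i in without_idx), ref)
        }
        for key in sorted(set(pile_with) & set(pile_without)):
            a, b = pile_with[key], pile_without[key]
            cov_a = a.count_meth + a.count_unmeth
            cov_b = b.count_meth + b.count_unmeth
            if cov_a < params.asm_min_cov or cov_b < params.asm_min_cov:
                continue
            rec = ASMRecord(
                site,
                key[0],
                key[1],
                key[2],
                a.level_percent,
                cov_a,
                b.level_percent,
                cov_b,
            )
            rec.is_asm = rec.is_asm_at(params)
            out.append(rec)
    out.sort(key=lambda r: (r.site.contig, r.site.pos0, r.site.alt_base, r.cyt_pos0, r.cyt_strand))
    return out
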