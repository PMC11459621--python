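"""Synthetic GPS library generator.

Emulates the library chemistry end to end: random fragmentation (truncated
normal lengths clipped to 200-500 bp), T4-polymerase excision/re-synthesis
of 36-150 nt per 3' end with 5-methyl-dCTP (the "patch", whose cytosines
never convert), bisulfite conversion of the rest (unmethylated C -> T at
``conversion_rate``; methylated C -> T only at ``meth_protection_failure``),
an unmethylated lambda-like spike-in at 0.1% of fragments, paired-end
150 bp sequencing with uniform substitution errors, and PCR duplicates.

Read1 is the first ``read_length`` nt of the converted fragment strand;
Read2 is the reverse complement of its last ``read_length`` nt, so the
fragment strand's own 3' patch appears (unconverted, complemented) at
Read2's 5' end while conversions show up as G->A in the Read2 tail.

Ground truth (per-read provenance, per-cytosine methylation probabilities,
planted heterozygous variants and allele-linked methylation) is recorded so
every downstream stage can be validated exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ReadPair, ReferenceSet, write_fasta, write_fastq_pairs

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_C, _CODE_G = 1, 2


@dataclass
class MethModel:
    """Per-CpG methylation-probability law.

    ``beta_mixture`` draws each CpG's probability from a weighted mixture
    of Beta distributions (default: 30% lowly methylated Beta(1,9), 70%
    highly methylated Beta(9,1) — the bimodal pattern of somatic CpG
    methylation).  ``binary`` assigns probability exactly 1 with chance
    ``p_meth`` and 0 otherwise, for exact round-trip checks.
    """

    kind: str = "beta_mixture"
    weights: tuple[float, ...] = (0.3, 0.7)
    betas: tuple[tuple[float, float], ...] = ((1.0, 9.0), (9.0, 1.0))
    p_meth: float = 0.7

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "binary":
            return (rng.random(n) < self.p_meth).astype(np.float64)
        if self.kind == "beta_mixture":
            w = np.asarray(self.weights, dtype=np.float64)
            comp = rng.choice(len(w), size=n, p=w / w.sum())
            out = np.empty(n)
            for k, (a, b) in enumerate(self.betas):
                sel = comp == k
                out[sel] = rng.beta(a, b, int(sel.sum()))
            return out
        raise ValueError(f"unknown meth model kind {self.kind!r}")


@dataclass
class SimConfig:
    genome_length: int = 100_000
    gc_fraction: float = 0.42
    n_pairs: int = 10_000
    frag_len_mean: float = 330.0
    frag_len_sd: float = 60.0
    frag_len_bounds: tuple[int, int] = (200, 500)
    t4_excision_bounds: tuple[int, int] = (36, 150)
    conversion_rate: float = 0.995
    meth_protection_failure: float = 0.005
    seq_error_rate: float = 0.001
    read_length: int = 150
    lambda_fraction: float = 0.001
    lambda_length: int = 10_000
    n_het_snv: int = 0
    n_asm_loci: int = 0
    asm_window: int = 300
    site_spacing: int = 2000
    duplicate_fraction: float = 0.02
    noncpg_level: float = 0.0
    meth_model: MethModel = field(default_factory=MethModel)
    base_quality: int = 37
    seed: int = 0
    main_contig: str = "sim1"
    control_contig: str = "lambda_ctrl"
    allow_cpg_change: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.meth_model, dict):
            mm = dict(self.meth_model)
            if "weights" in mm:
                mm["weights"] = tuple(mm["weights"])
            if "betas" in mm:
                mm["betas"] = tuple(tuple(ab) for ab in mm["betas"])
            self.meth_model = MethModel(**mm)
        self.frag_len_bounds = tuple(self.frag_len_bounds)
        self.t4_excision_bounds = tuple(self.t4_excision_bounds)
        for name in (
            "gc_fraction",
            "conversion_rate",
            "meth_protection_failure",
            "seq_error_rate",
            "lambda_fraction",
            "duplicate_fraction",
            "noncpg_level",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.frag_len_bounds[0] < 2 or self.frag_len_bounds[0] > self.frag_len_bounds[1]:
            raise ValueError(f"bad frag_len_bounds {self.frag_len_bounds}")
        t_lo, t_hi = self.t4_excision_bounds
        if not (1 <= t_lo <= t_hi < self.frag_len_bounds[0]):
            raise ValueError(
                f"t4_excision_bounds {self.t4_excision_bounds} must lie in "
                f"[1, {self.frag_len_bounds[0]})"
            )
        if self.n_asm_loci > self.n_het_snv:
            raise ValueError("n_asm_loci cannot exceed n_het_snv")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)


@dataclass
class MethylomeTruth:
    """Per-cytosine methylation probability, keyed (contig, pos0, strand).

    Keys exist only at reference cytosines on the given strand (C on '+',
    G on '-').  ``allele_overrides`` maps keys at ASM loci to per-haplotype
    probabilities (ref-haplotype, alt-haplotype).
    """

    entries: dict[tuple[str, int, str], tuple[float, str]] = field(default_factory=dict)
    allele_overrides: dict[tuple[str, int, str], tuple[float, float]] = field(default_factory=dict)

    def prob(self, contig: str, pos0: int, strand: str, hap: int = 0) -> float:
        key = (contig, pos0, strand)
        if key in self.allele_overrides:
            return self.allele_overrides[key][hap]
        entry = self.entries.get(key)
        return entry[0] if entry else 0.0


@dataclass
class VariantTruth:
    contig: str
    pos0: int
    ref: str
    alt: str
    kind: str  # "asm" | "neutral"


@dataclass
class TruthTables:
    variants: list[VariantTruth] = field(default_factory=list)
    asm_loci: dict[int, list[tuple[int, str]]] = field(default_factory=dict)
    provenance: pd.DataFrame | None = None


# ---------------------------------------------------------------------------


def _draw_contig(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def _decode(codes: np.ndarray) -> str:
    return bytes(_BASES[codes]).decode("ascii")


def encode_seq(seq: str) -> np.ndarray:
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _methylome_for_contig(
    contig: str, codes: np.ndarray, config: SimConfig, rng: np.random.Generator, control: bool
) -> dict[tuple[str, int, str], tuple[float, str]]:
    L = len(codes)
    is_c = codes == _CODE_C
    is_g = codes == _CODE_G
    cpg_c = is_c.copy()
    cpg_c[:-1] &= is_g[1:]
    cpg_c[-1] = False
    cpg_pos = np.nonzero(cpg_c)[0]
    probs = (
        np.zeros(len(cpg_pos)) if control else config.meth_model.draw(len(cpg_pos), rng)
    )
    eps = 0.0 if control else config.noncpg_level
    entries: dict[tuple[str, int, str], tuple[float, str]] = {}
    for pos, p in zip(cpg_pos.tolist(), probs.tolist()):
        entries[(contig, pos, "+")] = (p, "CpG")
        entries[(contig, pos + 1, "-")] = (p, "CpG")
    noncpg_c = np.nonzero(is_c & ~cpg_c)[0]
    for pos in noncpg_c.tolist():
        entries[(contig, pos, "+")] = (eps, "nonCpG")
    cpg_g = np.zeros(L, dtype=bool)
    cpg_g[1:] = is_c[:-1] & is_g[1:]
    noncpg_g = np.nonzero(is_g & ~cpg_g)[0]
    for pos in noncpg_g.tolist():
        entries[(contig, pos, "-")] = (eps, "nonCpG")
    return entries


def generate_reference(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[ReferenceSet, MethylomeTruth]:
    """Draw the main contig and the unmethylated control contig, plus the
    per-cytosine methylation-probability truth."""
    rng = rng or np.random.default_rng(config.seed)
    main = _draw_contig(config.genome_length, config.gc_fraction, rng)
    lam = _draw_contig(config.lambda_length, config.gc_fraction, rng)
    ref = ReferenceSet(
        {config.main_contig: _decode(main), config.control_contig: _decode(lam)},
        {config.control_contig},
    )
    methylome = MethylomeTruth()
    methylome.entries.update(_methylome_for_contig(config.main_contig, main, config, rng, False))
    methylome.entries.update(_methylome_for_contig(config.control_contig, lam, config, rng, True))
    return ref, methylome


# ---------------------------------------------------------------------------


def _creates_or_destroys_cpg(codes: np.ndarray, pos: int, alt_code: int) -> bool:
    L = len(codes)
    ref_code = codes[pos]
    # destroys: position participates in an existing CpG
    if ref_code == _CODE_C and pos + 1 < L and codes[pos + 1] == _CODE_G:
        return True
    if ref_code == _CODE_G and pos > 0 and codes[pos - 1] == _CODE_C:
        return True
    # creates
    if alt_code == _CODE_C and pos + 1 < L and codes[pos + 1] == _CODE_G:
        return True
    if alt_code == _CODE_G and pos > 0 and codes[pos - 1] == _CODE_C:
        return True
    return False


def plant_alleles(
    ref: ReferenceSet,
    methylome: MethylomeTruth,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> TruthTables:
    """Plant heterozygous SNVs >= ``site_spacing`` apart; the first
    ``n_asm_loci`` become ASM loci whose CpGs within +/- ``asm_window`` are
    fully methylated on the alt haplotype and unmethylated on the ref one.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    truth = TruthTables()
    n = config.n_het_snv
    if n == 0:
        return truth
    contig = config.main_contig
    codes = encode_seq(ref[contig])
    L = len(codes)
    step = L // (n + 1)
    if step < config.site_spacing:
        raise ValueError(
            f"genome of {L} bp too small for {n} sites at {config.site_spacing} bp spacing"
        )
    for k in range(n):
        target = (k + 1) * step
        placed = None
        # drift must not bring adjacent sites below the spacing contract
        max_delta = max(1, (step - config.site_spacing) // 2)
        for delta in range(0, max_delta):
            for pos in (target + delta, target - delta) if delta else (target,):
                if pos < 1 or pos >= L - 1:
                    continue
                ref_code = int(codes[pos])
                alts = [c for c in rng.permutation(4).tolist() if c != ref_code]
                for alt_code in alts:
                    if not config.allow_cpg_change and _creates_or_destroys_cpg(
                        codes, pos, alt_code
                    ):
                        continue
                    placed = (pos, ref_code, alt_code)
                    break
                if placed:
                    break
            if placed:
                break
        if placed is None:
            raise ValueError(f"could not place heterozygous site near {target}")
        pos, ref_code, alt_code = placed
        kind = "asm" if k < config.n_asm_loci else "neutral"
        truth.variants.append(
            VariantTruth(contig, pos, _decode(np.array([ref_code], np.uint8)),
                         _decode(np.array([alt_code], np.uint8)), kind)
        )
        if kind == "asm":
            lo, hi = max(0, pos - config.asm_window), min(L, pos + config.asm_window + 1)
            linked: list[tuple[int, str]] = []
            for key in (
                (contig, p, s)
                for p in range(lo, hi)
                for s in ("+", "-")
            ):
                entry = methylome.entries.get(key)
                if entry and entry[1] == "CpG":
                    methylome.allele_overrides[key] = (0.0, 1.0)
                    linked.append((key[1], key[2]))
            truth.asm_loci[pos] = linked
    return truth


# ---------------------------------------------------------------------------


def _prob_arrays(ref, methylome, contig):
    L = len(ref[contig])
    plus = np.zeros(L)
    minus = np.zeros(L)
    for (c, pos, strand), (p, _ctx) in methylome.entries.items():
        if c != contig:
            continue
        (plus if strand == "+" else minus)[pos] = p
    return plus, minus


def simulate_pairs(
    ref: ReferenceSet,
    methylome: MethylomeTruth,
    truth: TruthTables,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[ReadPair]:
    """Emit read pairs per the GPS chemistry and fill ``truth.provenance``."""
    rng = rng or np.random.default_rng(config.seed + 2)
    main, ctrl = config.main_contig, config.control_contig
    codes = {name: encode_seq(seq) for name, seq in ref.contigs.items()}
    lens = {name: len(seq) for name, seq in ref.contigs.items()}

    # haplotype-specific methylation probability arrays for the main contig
    plus0, minus0 = _prob_arrays(ref, methylome, main)
    plus1, minus1 = plus0.copy(), minus0.copy()
    for (c, pos, strand), (p_ref, p_alt) in methylome.allele_overrides.items():
        if c != main:
            continue
        tgt0, tgt1 = (plus0, plus1) if strand == "+" else (minus0, minus1)
        tgt0[pos] = p_ref
        tgt1[pos] = p_alt
    lam_plus, lam_minus = _prob_arrays(ref, methylome, ctrl)
    prob = {
        (main, 0): (plus0, minus0),
        (main, 1): (plus1, minus1),
        (ctrl, 0): (lam_plus, lam_minus),
        (ctrl, 1): (lam_plus, lam_minus),
    }
    var_pos = np.array([v.pos0 for v in truth.variants], dtype=np.int64)
    var_alt = np.array([encode_seq(v.alt)[0] for v in truth.variants], dtype=np.uint8)

    n = config.n_pairs
    lo, hi = config.frag_len_bounds
    t_lo, t_hi = config.t4_excision_bounds
    is_lam = rng.random(n) < config.lambda_fraction
    flens = np.clip(np.rint(rng.normal(config.frag_len_mean, config.frag_len_sd, n)), lo, hi)
    flens = flens.astype(np.int64)
    strands = rng.integers(0, 2, n)  # 0 -> '+', 1 -> '-'
    haps = rng.integers(0, 2, n)
    patch_left = rng.integers(t_lo, t_hi + 1, n)
    patch_right = rng.integers(t_lo, t_hi + 1, n)
    start_u = rng.random(n)
    dup_mask = rng.random(n) < config.duplicate_fraction

    rl = config.read_length
    qual_char = chr(33 + config.base_quality)
    pairs: list[ReadPair] = []
    prov: list[dict] = []
    err = config.seq_error_rate

    def _apply_errors(read_codes: np.ndarray) -> np.ndarray:
        if err <= 0 or len(read_codes) == 0:
            return read_codes
        mask = rng.random(len(read_codes)) < err
        n_err = int(mask.sum())
        if n_err:
            shift = rng.integers(1, 4, n_err).astype(np.uint8)
            read_codes = read_codes.copy()
            read_codes[mask] = (read_codes[mask] + shift) % 4
        return read_codes

    for idx in range(n):
        contig = ctrl if is_lam[idx] else main
        L = lens[contig]
        flen = int(min(flens[idx], L))
        fstart = int(start_u[idx] * (L - flen + 1))
        fend = fstart + flen
        hap = int(haps[idx])
        strand = "+" if strands[idx] == 0 else "-"
        frag = codes[contig][fstart:fend].copy()
        if contig == main and hap == 1 and len(var_pos):
            sel = (var_pos >= fstart) & (var_pos < fend)
            if sel.any():
                frag[var_pos[sel] - fstart] = var_alt[sel]
        p_plus, p_minus = prob[(contig, hap)]
        if strand == "+":
            probs_frag = p_plus[fstart:fend]
            patch = int(patch_right[idx])
        else:
            frag = (3 - frag)[::-1]
            probs_frag = p_minus[fstart:fend][::-1]
            patch = int(patch_left[idx])
        cpos = np.nonzero(frag == _CODE_C)[0]
        if len(cpos):
            p = probs_frag[cpos]
            meth = rng.random(len(cpos)) < p
            u = rng.random(len(cpos))
            protected = cpos >= flen - patch
            convert = ~protected & np.where(
                meth, u < config.meth_protection_failure, u < config.conversion_rate
            )
            conv = frag.copy()
            conv[cpos[convert]] = 3  # C -> T
        else:
            conv = frag
        r1 = _apply_errors(conv[:rl])
        r2 = _apply_errors((3 - conv)[::-1][:rl])
        pid = f"sim{idx:07d}"
        pair = ReadPair(pid, _decode(r1), _decode(r2), qual_char * len(r1), qual_char * len(r2))
        pairs.append(pair)
        rec = {
            "id": pid,
            "contig": contig,
            "start": fstart,
            "end": fend,
            "strand": strand,
            "hap": hap,
            "patch_left": int(patch_left[idx]),
            "patch_right": int(patch_right[idx]),
            "frag_patch": patch,
            "is_lambda": bool(is_lam[idx]),
            "is_duplicate": False,
            "r1_len": len(r1),
            "r2_len": len(r2),
            "r1_true_start": fstart if strand == "+" else fend - len(r1),
        }
        prov.append(rec)
        if dup_mask[idx]:
            dup_id = pid + "d"
            pairs.append(ReadPair(dup_id, pair.r1_seq, pair.r2_seq, pair.r1_qual, pair.r2_qual))
            prov.append({**rec, "id": dup_id, "is_duplicate": True})
    truth.provenance = pd.DataFrame(prov)
    return pairs


def simulate_library(
    config: SimConfig,
) -> tuple[ReferenceSet, MethylomeTruth, TruthTables, list[ReadPair]]:
    """Reference + methylome + planted alleles + reads from one seeded stream."""
    rng = np.random.default_rng(config.seed)
    ref, methylome = generate_reference(config, rng)
    truth = plant_alleles(ref, methylome, config, rng)
    pairs = simulate_pairs(ref, methylome, truth, config, rng)
    return ref, methylome, truth, pairs


# ---------------------------------------------------------------------------


def write_truth(truth: TruthTables, methylome: MethylomeTruth, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if truth.provenance is not None:
        truth.provenance.to_csv(out / "provenance.tsv", sep="\t", index=False)
    pd.DataFrame(
        [asdict(v) for v in truth.variants]
    ).to_csv(out / "variants.tsv", sep="\t", index=False)
    rows = [
        {"site_pos0": site, "cpg_pos0": pos, "cpg_strand": strand}
        for site, linked in truth.asm_loci.items()
        for pos, strand in linked
    ]
    pd.DataFrame(rows).to_csv(out / "asm_truth.tsv", sep="\t", index=False)
    meth_rows = [
        {"contig": c, "pos0": p, "strand": s, "prob": prob, "context": ctx}
        for (c, p, s), (prob, ctx) in sorted(methylome.entries.items())
    ]
    pd.DataFrame(meth_rows).to_csv(out / "methylome.tsv", sep="\t", index=False)


def write_library(config: SimConfig, out_prefix) -> tuple[ReferenceSet, MethylomeTruth, TruthTables]:
    """CLI entry: simulate and write FASTQ pair, reference FASTA and truth."""
    ref, methylome, truth, pairs = simulate_library(config)
    prefix = str(out_prefix)
    write_fastq_pairs(pairs, prefix + "_R1.fastq.gz", prefix + "_R2.fastq.gz")
    write_fasta(ref, prefix + "_ref.fa")
    write_truth(truth, methylome, prefix + "_truth")
    return ref, methylome, truth
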