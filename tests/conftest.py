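from __future__ import annotations

import numpy as np
import pytest

from gpseq.align import Placement, PairedPlacement
from gpseq.pipeline import align_pairs, preprocess_pairs
from gpseq.preprocess import PipelineParams
from gpseq.simulate import SimConfig, simulate_library


@pytest.fixture(scope="session")
def params() -> PipelineParams:
    return PipelineParams()


def run_library(cfg: SimConfig, params: PipelineParams):
    """Simulate and run preprocess + guided alignment; return everything."""
    ref, methylome, truth, pairs = simulate_library(cfg)
    kept, counters = preprocess_pairs(pairs, params)
    placed, acounters = align_pairs(kept, ref, params)
    counters.update(acounters)
    return {
        "config": cfg,
        "ref": ref,
        "methylome": methylome,
        "truth": truth,
        "pairs": pairs,
        "kept": kept,
        "placed": placed,
        "counters": counters,
    }


@pytest.fixture(scope="session")
def small_run(params):
    """Light default-chemistry run for unit-level checks."""
    cfg = SimConfig(
        genome_length=20_000,
        n_pairs=1200,
        lambda_length=4000,
        lambda_fraction=0.01,
        n_het_snv=4,
        n_asm_loci=2,
        site_spacing=2000,
        seed=7,
    )
    return run_library(cfg, params)


@pytest.fixture(scope="session")
def exact_run(params):
    """Deterministic chemistry: binary methylome, full conversion, no errors."""
    cfg = SimConfig(
        genome_length=100_000,
        n_pairs=20_000,
        conversion_rate=1.0,
        meth_protection_failure=0.0,
        seq_error_rate=0.0,
        meth_model={"kind": "binary", "p_meth": 0.7},
        seed=11,
    )
    return run_library(cfg, params)


@pytest.fixture(scope="session")
def stochastic_run(params):
    """Published chemistry: 99.5% conversion, 0.1% error, Beta methylome."""
    cfg = SimConfig(genome_length=60_000, n_pairs=12_000, seed=5)
    return run_library(cfg, params)


@pytest.fixture(scope="session")
def variant_run(params):
    """50 planted het SNVs, error-free chemistry."""
    cfg = SimConfig(
        genome_length=110_000,
        n_pairs=20_000,
        n_het_snv=50,
        conversion_rate=1.0,
        meth_protection_failure=0.0,
        seq_error_rate=0.0,
        seed=13,
    )
    return run_library(cfg, params)


@pytest.fixture(scope="session")
def asm_run(params):
    """10 ASM + 10 neutral het loci at deep coverage, error-free chemistry."""
    cfg = SimConfig(
        genome_length=50_000,
        n_pairs=36_000,
        n_het_snv=20,
        n_asm_loci=10,
        conversion_rate=1.0,
        meth_protection_failure=0.0,
        seq_error_rate=0.0,
        seed=17,
    )
    return run_library(cfg, params)


def protected_coverage(truth, contig: str, pos: int) -> int:
    """Truth-side protected (patch) coverage of a position, ex duplicates."""
    prov = truth.provenance
    prov = prov[(~prov.is_duplicate) & (prov.contig == contig)]
    plus = (
        (prov.strand == "+")
        & (prov.end - prov.frag_patch <= pos)
        & (prov.end > pos)
    )
    minus = (
        (prov.strand == "-")
        & (prov.start <= pos)
        & (prov.start + prov.frag_patch > pos)
    )
    return int(plus.sum() + minus.sum())


def make_placement(contig, start0, strand, query, q_start=0, q_end=None, score=None):
    """Ungapped placement helper for constructed-scenario tests."""
    q_end = len(query) if q_end is None else q_end
    return Placement(
        contig,
        start0,
        strand,
        score if score is not None else 5 * (q_end - q_start),
        [("M", q_end - q_start)],
        q_start,
        q_end,
        query,
    )


def make_paired(pair_id, r1_placement, r2_placement, r1_keep=None, r2_keep=None):
    pp = PairedPlacement(
        pair_id,
        r2_placement,
        r1_placement,
        abs(r1_placement.start0 - r2_placement.start0),
    )
    pp.r1_keep = len(r1_placement.query) if r1_keep is None else r1_keep
    pp.r2_keep = len(r2_placement.query) if r2_keep is None else r2_keep
    return pp
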