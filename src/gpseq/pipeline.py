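"""End-to-end GPS pipeline: simulate/load -> preprocess -> guided align ->
methylation -> variants/ASM, with a machine-readable run manifest.

A run is fully determined by its configuration (including the seed):
identical config gives byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .align import (
    AnchorAligner,
    PairedPlacement,
    Placement,
    Unplaced,
    import_anchor_sam,
    position_r1,
    trim_paired,
)
from .io import (
    ReadPair,
    ReferenceSet,
    read_fasta,
    read_fastq_pairs,
    write_asm_report,
    write_fastq_pairs,
    write_methylation_report,
    write_sam,
    write_variant_report,
)
from .methylation import conversion_efficiency, pileup_methylation
from .preprocess import (
    BoundaryAnnotation,
    PipelineParams,
    deduplicate,
    detect_r2_boundary,
    quality_filter,
)
from .simulate import SimConfig, simulate_library, write_truth
from .variants import asm_scan, call_variant_candidates

log = logging.getLogger("gpseq")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunManifest:
    seed: int
    config: dict
    counters: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)
    version: str = __version__

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(**json.loads(text))

    def write(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def _params_from_dict(d: dict | None) -> PipelineParams:
    d = d or {}
    known = {f.name for f in fields(PipelineParams)}
    unknown = set(d) - known
    if unknown:
        raise PipelineError("config", f"unknown params keys: {sorted(unknown)}")
    return PipelineParams(**d)


# ---------------------------------------------------------------------------
# Stages


def preprocess_pairs(
    pairs: list[ReadPair], params: PipelineParams
) -> tuple[list[tuple[ReadPair, BoundaryAnnotation]], dict]:
    """QC filter -> exact dedup -> Read2 boundary detection."""
    counters = {"pairs_in": len(pairs)}
    qc_kept = [p for p in pairs if quality_filter(p, params)[0]]
    counters["dropped_qc"] = counters["pairs_in"] - len(qc_kept)
    unique = list(deduplicate(qc_kept))
    counters["dropped_duplicate"] = len(qc_kept) - len(unique)
    kept: list[tuple[ReadPair, BoundaryAnnotation]] = []
    n_nob = n_short = 0
    for p in unique:
        ann = detect_r2_boundary(p.r2_seq, params)
        if ann.discarded:
            if ann.reason == "no_boundary":
                n_nob += 1
            else:
                n_short += 1
            continue
        kept.append((p, ann))
    counters["dropped_no_boundary"] = n_nob
    counters["dropped_short_anchor"] = n_short
    counters["boundary_ok"] = len(kept)
    return kept, counters


def align_pairs(
    kept: list[tuple[ReadPair, BoundaryAnnotation]],
    ref: ReferenceSet,
    params: PipelineParams,
    anchor_map: dict[str, list[Placement]] | None = None,
) -> tuple[list[PairedPlacement], dict]:
    """Anchor each Read2 prefix, position Read1 within 1 kb, trim both."""
    aligner = None if anchor_map is not None else AnchorAligner(ref)
    placed: list[PairedPlacement] = []
    counters = {"unanchored": 0, "unplaced_low_score": 0, "unplaced_ambiguous": 0}
    for pair, ann in kept:
        if anchor_map is not None:
            r2_placements = anchor_map.get(pair.id, [])[: params.max_hits]
        else:
            r2_placements = aligner.align(ann.anchor_seq, params)
        if not r2_placements:
            counters["unanchored"] += 1
            continue
        result = position_r1(pair.id, pair.r1_seq, r2_placements, ref, params)
        if isinstance(result, Unplaced):
            counters[f"unplaced_{result.reason}"] += 1
            continue
        result.pair = pair
        trim_paired(result, ref, ann, params)
        placed.append(result)
    counters["placed"] = len(placed)
    return placed, counters


def placements_table(placed: list[PairedPlacement]) -> pd.DataFrame:
    rows = [
        {
            "pair_id": pp.pair_id,
            "contig": pp.r1_placement.contig,
            "r1_start0": pp.r1_placement.start0,
            "r1_strand": pp.r1_placement.strand,
            "r1_score": pp.r1_placement.score,
            "r1_keep": pp.r1_keep,
            "r2_start0": pp.r2_placement.start0,
            "r2_strand": pp.r2_placement.strand,
            "r2_score": pp.r2_placement.score,
            "r2_keep": pp.r2_keep,
            "r2_candidates": pp.r2_placement.n_candidates,
            "pair_distance": pp.pair_distance,
        }
        for pp in placed
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------


def run_pipeline(config: dict, out_dir, seed: int | None = None) -> RunManifest:
    """Execute the full pipeline from a config dict (sections sim/params/io).

    Either a ``sim`` section (the library is simulated) or an ``io`` section
    with ``r1``/``r2``/``ref`` paths must be present.  ``seed`` overrides
    the config seed for both simulation and parameters.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = dict(config or {})
    params = _params_from_dict(config.get("params"))
    if seed is None:
        seed = int(config.get("seed", params.seed))
    manifest = RunManifest(seed=seed, config=config)

    truth = None
    if "sim" in config:
        sim_cfg = dict(config["sim"] or {})
        sim_cfg.setdefault("seed", seed)
        sim = SimConfig.from_dict(sim_cfg)
        log.info("simulating %d pairs over %d bp", sim.n_pairs, sim.genome_length)
        ref, methylome, truth, pairs = simulate_library(sim)
        write_fastq_pairs(pairs, out / "sim_R1.fastq.gz", out / "sim_R2.fastq.gz")
        from .io import write_fasta

        write_fasta(ref, out / "ref.fa")
        write_truth(truth, methylome, out / "truth")
        manifest.files["r1"] = "sim_R1.fastq.gz"
        manifest.files["r2"] = "sim_R2.fastq.gz"
    elif "io" in config:
        io_cfg = config["io"]
        ref = read_fasta(io_cfg["ref"], control_contigs=io_cfg.get("control_contigs", ()))
        pairs = list(read_fastq_pairs(io_cfg["r1"], io_cfg["r2"]))
    else:
        raise PipelineError("config", "need a 'sim' or 'io' section")

    kept, counters = preprocess_pairs(pairs, params)
    log.info("preprocess: %s", counters)
    if not kept:
        raise PipelineError("preprocess", "no pairs left after QC/boundary filtering")

    anchor_map = None
    if "io" in config and config["io"].get("anchor_sam"):
        anchor_map = import_anchor_sam(config["io"]["anchor_sam"], ref)
    placed, acounters = align_pairs(kept, ref, params, anchor_map)
    counters.update(acounters)
    log.info("align: %s", acounters)
    if not placed:
        raise PipelineError("align", "no pairs placed")

    write_sam(placed, ref, out / "aligned.sam")
    placements_table(placed).to_csv(out / "pairs.tsv", sep="\t", index=False)

    meth = pileup_methylation(placed, ref)
    write_methylation_report(meth, out / "meth.tsv")
    counters["methylation_sites"] = len(meth)
    conv: float | None = None
    if any(ref.is_control(r.contig) for r in meth):
        conv = conversion_efficiency(meth, ref)
        (out / "conversion.json").write_text(
            json.dumps({"conversion_efficiency_percent": round(conv, 4)}) + "\n"
        )

    sites = call_variant_candidates(placed, ref, params)
    write_variant_report(sites, out / "variants.tsv")
    counters["variant_candidates"] = len(sites)
    asm = asm_scan(sites, placed, ref, params)
    write_asm_report(asm, out / "asm.tsv")
    counters["asm_records"] = len(asm)
    counters["asm_positive"] = sum(1 for a in asm if a.is_asm)

    manifest.counters = counters
    # names are relative to the run directory so identical configs give
    # byte-identical manifests regardless of where they run
    manifest.files.update(
        {name: name for name in ("aligned.sam", "pairs.tsv", "meth.tsv", "variants.tsv", "asm.tsv")}
    )
    manifest.write(out / "manifest.json")
    log.info("done: %s", {k: counters[k] for k in ("pairs_in", "placed")})
    return manifest


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
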