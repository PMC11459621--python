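# gpseq — a guide positioning sequencing (GPS) toolkit

GPS is a bisulfite library method that captures DNA methylation and
genetic variation from the same read pairs.  During library preparation,
T4 DNA polymerase removes 36–150 nt from each 3′ end of a 200–500 bp
fragment and re-synthesises the span with 5-methyl-dCTP.  Cytosines in
that "patch" are methylated and survive bisulfite conversion, so Read2
begins with a stretch of unconverted, reference-identical sequence — an
**anchor** that can be aligned conventionally and used to call variants —
while Read1 carries the ordinary bisulfite methylation signal.

`gpseq` implements the data-processing side of GPS end to end, plus a
simulator that emulates the chemistry so the whole pipeline can be
validated against known ground truth:

- **simulate** — synthetic GPS libraries (FASTQ pairs, reference, truth
  tables): fragmentation, T4 excision/5mC patching, bisulfite conversion,
  a 0.1% unmethylated spike-in, sequencing error, PCR duplicates, planted
  heterozygous SNVs and allele-specific-methylation (ASM) loci.
- **preprocess** — quality filtering (≥70% of bases at Q≥35 in both
  mates), exact duplicate removal, and Read2 treatment-boundary detection:
  the last 5′-[A/T/G]G-3′ (non-CpG G) scanning 5′→3′ marks the patch
  boundary; anchors shorter than 35 nt are discarded.
- **align** — anchors are placed by exact 20-mer seeding + local
  alignment (up to 20 hits, or imported from an external SAM); Read1 is
  positioned by Smith–Waterman within 1 kb inward of each anchor using
  bisulfite-aware scoring (match +5, mismatch 0, gap −6; read T matches
  reference C, or A matches G for the reverse orientation).  Both mates
  are then trimmed to treatment-consistent spans.
- **methylation** — per-cytosine levels `100·C/(C+T)` from trimmed Read1
  spans only, and conversion efficiency from the spike-in.
- **asm** — variant candidates from the protected Read2 prefixes; read
  pairs grouped by allele at each site; per-cytosine methylation contrast
  between groups, called ASM at ≥70 percentage points difference with ≥5×
  coverage per group.

## Worked example

Write `demo.yaml`:

```yaml
seed: 7
sim:
  genome_length: 20000
  n_pairs: 8000
  lambda_length: 5000
  n_het_snv: 6
  n_asm_loci: 2
  site_spacing: 2000
  conversion_rate: 1.0       # error-free chemistry for a clean demo
  meth_protection_failure: 0.0
  seq_error_rate: 0.0
```

then run

```sh
gps run --config demo.yaml --out-dir demo_out
```

which prints the stage counters:

```json
{"pairs_in": 8158, "dropped_qc": 0, "dropped_duplicate": 158,
 "dropped_no_boundary": 0, "dropped_short_anchor": 328, "boundary_ok": 7672,
 "unanchored": 0, "unplaced_low_score": 0, "unplaced_ambiguous": 0,
 "placed": 7672, "methylation_sites": 8441, "variant_candidates": 6,
 "asm_records": 217, "asm_positive": 19}
```

8,158 simulated pairs (8,000 + 158 PCR duplicates) enter; duplicates and
short anchors are removed; all 7,672 surviving pairs are anchored and
placed.  All 6 planted heterozygous SNVs are recovered in
`demo_out/variants.tsv`:

```
contig  pos0   ref_base  alt_base  coverage  alt_count
sim1    2857   C         T         34        16
sim1    5714   T         C         49        25
...
```

and `demo_out/asm.tsv` flags 19 cytosines near the two planted ASM loci
with a 100-point methylation difference between allele groups, e.g.

```
contig pos0  alt  cyt_pos0  level_with_alt cov  level_without_alt cov  diff   is_asm
sim1   2857  T    2616      100.0          6    0.0               7    100.0  1
```

`demo_out/conversion.json` reports the spike-in conversion efficiency
(100.0% here, since the demo sets conversion_rate to 1; at the default
0.995 chemistry it lands near 99.5%).  `demo_out/meth.tsv` holds the
per-cytosine pileup (0-based positions, strand-resolved, CpG/nonCpG
context), `aligned.sam` the placements, and `manifest.json` the config,
seed and counters.  Re-running with the same config reproduces every
output byte for byte.

Other subcommands (`gps simulate`, `gps preprocess`, `gps align`,
`gps methylation`, `gps asm`, `gps clone-length`) expose the individual
stages; `gps clone-length` estimates the 5mC incorporation length of a
Sanger-sequenced library clone from its primer-flanked insert.

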