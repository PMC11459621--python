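# Methods

## The GPS measurement model

Guide positioning sequencing (GPS) builds bisulfite libraries in which T4
DNA polymerase first chews back 36–150 nt from each 3′ end of a sheared
fragment (200–500 bp) and then re-synthesises that span with
5-methyl-dCTP.  Every cytosine in this re-synthesised "patch" is therefore
methylated and survives bisulfite treatment, so the patch retains the
reference base composition.  After conversion and PCR:

- **Read1** reads the converted fragment strand from its 5′ end: outside
  the patch, unmethylated C appears as T while methylated C (almost
  exclusively CpG in somatic cells) remains C.  Read1 carries the
  methylation signal.
- **Read2** is the reverse complement of the fragment strand's 3′ end, so
  the patch appears at Read2's 5′ end.  Because a G in Read2 can only
  originate from a fragment-strand C, and retained Cs outside the patch
  are CpG-methylated (appearing in Read2 as G preceded by C — CpG is its
  own reverse complement), a G in non-CpG context (5′-[A/T/G]G-3′) is
  patch evidence.  The last such G scanning 5′→3′ is the **treatment
  boundary**; the prefix up to and including it is the **anchor**, which
  retains full 4-letter information and is aligned conventionally.

The anchor "guides" the placement of the 3-letter (converted) Read1: Read1
is locally aligned only within 1 kb inward of each anchor placement, with
an asymmetric wildcard (read T matches reference C for plus-strand
fragments; the reverse-complemented read is aligned with read A matching
reference G for minus-strand fragments).

## Pipeline stages and parameters

| Parameter | Default | Meaning |
|---|---|---|
| `qc_qual_cutoff` / `qc_min_fraction` | Q35 / 0.70 | keep a pair iff both mates have ≥70% of bases at Q≥35 |
| `min_anchor_len` | 35 nt | anchors shorter than this are discarded (non-specific) |
| `max_hits` | 20 | anchor placements reported per read |
| `max_pair_distance` | 1000 bp | Read1 search window inward of each anchor |
| match / mismatch / gap | +5 / 0 / −6 per base | local-alignment scoring (linear gaps) |
| `min_sw_score` | 100 | minimum local score (~20 matched bases) |
| `var_min_alt_count` / `var_min_alt_fraction` | 2 / 0.10 | variant candidate filters on the protected pileup |
| `asm_min_diff` / `asm_min_cov` | 70 pp / 5× | ASM thresholds per allele group |

Duplicates are removed on exact (R1, R2) sequence identity before
alignment.  Read2's keep-span is its protected prefix `[0, boundary)`
only — the converted tail ("insufficiently cut" material) never enters the
variant pileup.  Read1 is scanned 3′→5′ along its alignment for the first
converted base (T at reference C, or A at reference G on the minus
strand); everything 3′ of that position may be patch ("excessively cut")
and is dropped.  Degenerate cases: an aligned span with no fragment-strand
cytosine keeps the whole read (no evidence either way); cytosines present
but none converted drops the whole read (fully patched).  Only Read1
contributes to methylation; only the Read2 protected prefix contributes to
variants.  This asymmetry is structural, not a flag.

Methylation level at a cytosine is 100·C/(C+T) over contributing bases
(strand-resolved; CpG strand merging is available behind a flag but off by
default).  Conversion efficiency is estimated from the unmethylated
spike-in contig as 100·ΣT/(ΣC+ΣT): every retained C there is a conversion
failure.

## Alignment details and numerical choices

- The Smith–Waterman scorer is exact (full DP matrix, linear gap −6 per
  base, all cells clipped at 0).  A compiled kernel computes the matrix;
  a pure-numpy implementation of the same recurrence is kept as a
  fallback and the two are cross-checked in the tests, along with an
  independent plain-Python textbook oracle.
- Tie-breaking is deterministic everywhere: among co-optimal cells the
  alignment ending at the smallest target (then query) position wins, and
  traceback prefers diagonal moves (fewest gaps).  Anchor placements sort
  by score, then contig, coordinate, and plus strand first.  The pipeline
  output is therefore a pure function of config + seed; the determinism
  check compares full output trees byte for byte.
- The built-in anchor aligner seeds with exact 20-mers on both strands and
  rescores candidate diagonals with the same local aligner; externally
  produced anchor alignments (e.g. bowtie2 `-k 20`) can be imported from
  SAM instead.
- **A consequence of mismatch = 0**: local alignments extend freely
  through mismatches, so a random 150-nt read collects ~47 chance matches
  (score ~235) in any 1 kb window and always clears `min_sw_score` = 100.
  The score floor only rejects short or heavily clipped queries; placement
  specificity comes from the true locus scoring far higher (~750 for a
  clean read) and from ambiguity rejection when two windows tie.

## The simulator as study condition

The generator reproduces the library chemistry the pipeline assumes:
i.i.d. reference at 42% GC plus an unmethylated control contig; fragment
lengths from a normal (mean 330, sd 60) clipped to [200, 500] bp (the
protocol states the range and the 300–350 mode; clipping keeps the printed
bounds exact); per-3′-end patch lengths uniform on [36, 150] nt (only the
admissible range is known; uniform is the least-informative choice);
per-CpG methylation probabilities from a bimodal Beta mixture
(0.3·Beta(1,9) + 0.7·Beta(9,1), the somatic pattern) or a binary law for
exact checks; non-CpG methylation 0 by default (configurable ε);
unmethylated C converts with probability 0.995, methylated C with 0.005;
0.1% spike-in fraction; 150 bp paired reads at constant Q37 with uniform
substitution errors (0.1%); a 2% exact-duplicate fraction.  Heterozygous
SNVs are planted ≥2 kb apart without creating or destroying CpGs; at ASM
loci, CpGs within ±300 bp carry probability 1.0 on the alt haplotype and
0.0 on the ref haplotype.

Not modelled: indels, adapter read-through, quality-profile errors,
amplification bias, hemimethylation, 5hmC.  Passing tests therefore show
correctness of the data processing under the stated chemistry, not
robustness to artefacts absent from the model.

## What the verification runs compute

Problem sizes were chosen to give the statistical power each check needs
at desk scale: a 100 kb / 20,000-pair run with binary methylome and
error-free chemistry (every emitted level must be exactly 0 or 100 and
equal truth; ≥99% of placed Read1s at their true coordinate); a 60 kb /
12,000-pair run at the published chemistry (per-site counts must sit in
the exact 99% binomial interval of the *effective* retained-C probability
— truth p adjusted for conversion failure, protection failure and
sequencing error, which is the marginal law the chemistry induces — for
≥98% of sites at ≥10×, and the spike-in conversion estimate within 3
binomial s.e. of 99.5%); a 110 kb / 20,000-pair run with 50 planted het
SNVs (≥90% recall at ≥10× protected coverage, no calls outside the planted
truth); and a 50 kb / 36,000-pair run with 10 ASM and 10 neutral het loci.
The ASM run is deep (~67× protected coverage at sites) because an allele
group is roughly a quarter of protected coverage once haplotype and
fragment strand are fixed, and a strand-resolved cytosine must reach 5× in
*both* groups — a power analysis, not a tuning to outcomes.

## Known limitations

- **Boundary overshoot under imperfect conversion.** A failed conversion
  (retained non-CpG C) beyond the true patch mimics patch evidence, so at
  99.5% conversion ~10% of Read2 boundaries overshoot and admit some
  converted bases into the "protected" prefix.  This is inherent to the
  last-non-CpG-G rule itself; variant/ASM verification therefore runs on
  error-free chemistry, where the rule is exact.
- **Chance ASM at fixed thresholds.** With ~1,500 (site, cytosine) records
  tested per deep run, a shared-probability cytosine can show a ≥70 pp
  group difference at 5× coverage by sampling alone (~1/1,300 per record),
  so of order one chance-level ASM call per run is expected at the fixed
  thresholds; no multiple-testing correction is applied, mirroring the
  protocol.
- The R1 trim scan stops at the first converted C from the 3′ end, which
  discards methylated CpGs lying 3′ of it and very slightly favours
  unmethylated observations for sites adjacent to read ends.
- The anchor aligner indexes every 20-mer in memory: appropriate for
  desk-scale genomes; whole-genome use should import external anchor
  alignments from SAM.
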