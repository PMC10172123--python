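# asmflag

Read-depth based reliability flagging for phased diploid genome assemblies.

## The problem

After assembling a diploid genome from long reads, every base of the result
is a hypothesis. Mapping the same reads back to the assembly turns depth of
coverage into evidence: a correctly assembled haploid region attracts depth
near the sequencing mean μ; a **falsely duplicated** region splits its reads
between the spurious copies and sits near μ/2; a **collapsed** repeat (k true
copies assembled as one) attracts k·μ; an **erroneous** region has almost no
read support. `asmflag` fits a constrained mixture model to the genome-wide
depth histogram and labels every base of the assembly as `Err`, `Dup`, `Hap`,
`Col`, or `Unk` (contested after block merging), emitting a five-label BED and
summary statistics (unreliable fraction, N50 of unreliable blocks).

The coverage model is a four-component mixture over integer depths d:

```
P(d) = w_e Pois(d; λ) + w_d N(d; μ/2, σ_d) + w_h N(d; μ, σ_h) + Σ_k w_k N(d; k·μ, σ_k)
```

with λ ∈ [0, 10] (estimated from depths below 10 only), the duplicated mean
tied to μ/2, and the collapsed means tied to k·μ for k = 2…5. Only μ is a
free location parameter. The model is fit by EM per 5 Mb window (contigs
≤ 5 Mb fall back to a whole-genome fit), each depth is assigned to the most
probable weighted component, and three corrections follow:

1. **Satellite bias** — human satellite arrays (HSat1/2/3) have systematic
   HiFi coverage drops or rises; annotated intervals are refit with the EM
   start point at 0.75×/1.25×/1.25× the genome mean and relabeled.
2. **High-MAPQ rescue** — a `Dup` block with more than five MAPQ>20
   alignments throughout is relabeled `Hap` (low MAPQ, not low depth, is the
   real signature of false duplication).
3. **Merging** — per component, blocks closer than 1 kb merge; bases claimed
   by two or more components become `Unk`.

The package also implements the alignment hygiene that precedes the coverage
analysis: dropping chimeric reads, sub-2 kb alignments and alignments with a
gap-compressed mismatch ratio above 1% (never filtering on MAPQ); removing
alignments that carry the alternate allele at confident biallelic SNPs
(VAF ≥ 0.3, GQ ≥ 10); and re-ranking a primary alignment against near-tied
secondaries by single-nucleotide markers — read bases mismatched against
some but not all candidate placements — scoring each candidate by minus the
summed base qualities of its mismatched markers.

A seeded synthetic-data module generates coverage tracks with planted
errors/duplications/collapses, satellite biases, MAPQ-filtered auxiliary
tracks, and two-haplotype read-alignment fixtures, so the whole pipeline is
testable without any external data.

## Worked example

Generate an 11 Mb demonstration assembly (two contigs; one planted erroneous,
duplicated and collapsed region each on the large contig, a biased HSat2
interval, and one duplication on the small contig), then flag it:

```sh
asmflag simulate --out-dir demo --seed 1
asmflag flag -c demo/read_alignment.cov \
    --hsat demo/hsat.bed --hq-cov demo/read_alignment.hq.cov \
    -o demo/eval
```

which logs

```
INFO asmflag: flagged 11000000 bases: 1.7273% unreliable (N50 60000)
```

`demo/eval.summary.tsv` then reports, per label, the base counts and
fractions, e.g. `fraction_Hap 0.982727` (the reliable fraction),
`fraction_Err 0.005455`, `fraction_Dup 0.005909`, `fraction_Col 0.005909`,
`unreliable_n50 60000` — the planted 2.3% of defective bases are recovered
as unreliable, the rest stays green. `demo/eval.flags.bed` holds the
per-base labels:

```
chr_a   1000000 1060000 Err 0 + 1000000 1060000 204,0,0
chr_a   1060000 3010000 Hap 0 + 1060000 3010000 0,153,0
```

and `demo/eval.models.json` the fitted window models; the whole-genome fit
recovers the simulated conditions (haploid mean 39.74 at truth 40, Poisson
mean 0.75):

```
"hap_mean": 39.74, "err_lambda": 0.75, "weights": [0.0055, 0.0082, 0.9693, ...]
```

Other subcommands: `depth2cov` (samtools-depth table → run-length `.cov`),
`cov2counts` (depth histogram), `fit` (mixture fit only), `run` (depth table
in, BED out), `secphase` (marker-based primary re-ranking of a SAM),
`filter-alt` (alt-allele read removal against a VCF).

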