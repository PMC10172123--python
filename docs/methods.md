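# Methods

## The coverage mixture

`asmflag` models the read-depth histogram of a phased diploid assembly as a
finite mixture over integer depths. The component set encodes how specific
misassembly classes distort depth when the sequencing reads are mapped back
to the assembly:

| component | distribution | location | free parameters |
|---|---|---|---|
| erroneous (`Err`) | Poisson(λ) | λ ∈ [0, 10] | λ, weight |
| falsely duplicated (`Dup`) | Normal | tied to μ/2 | σ_d, weight |
| haploid (`Hap`) | Normal | μ | μ, σ_h, weight |
| collapsed (`Col`) | Normal family | tied to k·μ, k = 2…n+1 | σ_k, weights |

Only μ is a free location parameter. The ties are structural, not
initialization: the duplicated and collapsed means are derived fields and
cannot drift during fitting. The number of collapsed sub-components
defaults to 4 (copy numbers 2–5); higher copy numbers are rare enough that
adding components mostly costs identifiability.

Densities are evaluated at integer depths without a continuity correction.
Depth is a count, and at the coverage scales the model targets (tens of
reads) the Gaussian-at-integers approximation error is far below the noise
floor of any window histogram.

### EM details

* **E-step** in log space (`logsumexp`), so no underflow guards are needed
  at extreme depths.
* **M-step** order: mixing weights; Poisson mean; tied haploid mean; s.d.s.
  The tied mean has the closed form
  μ = Σ_c Σ_d r_cd n_d m_c d / σ_c² ÷ Σ_c Σ_d r_cd n_d m_c² / σ_c²
  over the Gaussian family with tie multipliers m_c ∈ {1/2, 1, 2, …}, using
  the current s.d.s; the s.d.s are then re-estimated around the new tied
  means. This is generalized (coordinate-ascent) EM, so the likelihood is
  still non-decreasing.
* **Erroneous component restriction**: λ is re-estimated from
  responsibilities at depths 0–9 only and clamped to [0, 10]; its density
  is still evaluated at all depths in the E-step. The restriction keeps the
  Poisson mode from absorbing genuine low-coverage modes, at the price that
  strict monotonicity of the likelihood is no longer guaranteed when a
  well-populated depth mode sits right at the bound (λ ≈ 8–10); in
  realistic coverage regimes (λ ≲ 5, μ ≳ 12) monotonicity holds and is
  asserted to 1e−8 slack in the tests.
* **Variance floor** of 0.5 reads on every s.d. prevents zero-variance
  spikes on quantized histograms; since the per-component Q function is
  unimodal in σ², flooring is exact constrained maximization and preserves
  monotonicity.
* **Initialization**: weights (0.05, 0.05, 0.80, 0.10/n split over
  collapsed), λ = 1, μ = the configured start coverage, all s.d.s = μ/8.
  The start coverage is the one deliberately exposed knob, because the
  likelihood is multimodal in μ (the haploid mode must be seeded near the
  truth; the satellite correction exploits exactly this).
* **Convergence**: relative log-likelihood change < 1e−6 or 300 iterations.
* **Degenerate inputs**: histograms with fewer than two distinct depths or
  fewer than 10⁴ bases raise a degenerate-fit error; windowed callers fall
  back to the whole-genome model.

### Assignment

Each depth 0…max is labeled by the argmax of weight × density; collapsed
sub-components pool into the single `Col` label. Exact ties (measure-zero
in theory, possible on integer depths) break toward the safer ordering
`Hap` > `Dup` > `Col` > `Err`, making output deterministic.

## Pipeline order and corrections

The order is fixed: windowed labeling → satellite correction → high-MAPQ
correction → merge/finalize.

* **Windows**: 5 Mb default (configurable), one model per window, contigs
  ≤ 5 Mb and degenerate windows fall back to the whole-genome model. The
  final short window of a contig stands alone rather than merging into its
  neighbour; at 5 Mb windows a short tail still holds plenty of bases, and
  keeping windows aligned to a fixed grid makes results reproducible
  across runs with different contig subsets.
* **Satellite correction**: per HSat class, the class-restricted histogram
  is refit with the EM start point at multiplier × genome mean coverage —
  0.75 for HSat1 (HiFi coverage drops there), 1.25 for HSat2 and HSat3
  (rises) — and the class's intervals are relabeled from the refit model.
  The multipliers move the start point, not the answer: EM then converges
  to the local coverage mode, which is what makes biased-but-correct
  satellite sequence come out `Hap`.
* **High-MAPQ correction**: a maximal `Dup` run whose *minimum*
  MAPQ-filtered depth exceeds 5 is relabeled `Hap`. The minimum (rather
  than mean) is the conservative aggregation: a single unsupported base
  keeps the block `Dup`.
* **Merge/finalize**: per component, blocks with gaps strictly below 1 kb
  merge, absorbing the gap; bases claimed by two or more components after
  merging become `Unk`. `Unk` itself never gap-merges — it is a resolution
  product, not a component — which is also what makes finalization
  idempotent. However many labels contest a base, the result is the same
  single `Unk` label.

## The synthetic-data generator

The generator emulates the depth structure the model assumes: a haploid
background at mean μ = 40 reads (matching a ~40× HiFi experiment), planted
regions at label-appropriate multipliers (erroneous ≈ 0.02μ, duplicated
0.5μ, collapsed k·μ), satellite intervals that multiply the local mean, and
optional negative-binomial overdispersion (default Poisson, so closed-form
oracles stay simple).

Depth is drawn **blockwise**, one draw per 5 kb block, rather than per
base. Real per-base HiFi depth has the Poisson marginal but is strongly
autocorrelated on the scale of the ~20 kb reads; blockwise-iid draws at a
~5 kb scale reproduce both the marginal and, approximately, the length
distribution of threshold-crossing excursions, which is what the block
merging logic actually sees. Per-base-iid noise would cross assignment
boundaries hundreds of times more often than real data and make merging
behaviour unrepresentative.

The 50 Mb benchmark (`benchmark_spec`) plants 2% non-haploid bases as 50%
erroneous, 40% collapsed and 10% falsely duplicated, with the duplication
as a single 100 kb region at a contig end. Coverage drops and collapses
dominate the unreliable fraction of long-read diploid assemblies, while
false duplication is the rarest failure mode and concentrates at contig
boundaries; placing it at the end of a 5.2 Mb contig also means its
fitting window is short, which is exactly the regime where the duplicated
component carries enough local weight to be separable at all. One 4.8 Mb
contig is deliberately below the windowing threshold to exercise the
whole-genome fallback.

What the generator does **not** emulate: sequence-level read errors in the
coverage track, mappability structure, GC bias, satellite-internal depth
gradients, and depth autocorrelation beyond the block scale. Passing the
end-to-end tests therefore demonstrates that the model, assignment, and
correction machinery behave as designed under their own assumptions — not
that real assemblies will show the same recovery rates.

The alignment fixture draws reads from one of two homologous sequences
differing at known marker positions, gives each read one candidate
alignment per haplotype with extended (`=`/`X`) operations, and assigns the
primary flag at random — emulating an aligner that cannot distinguish
near-identical haplotypes — so the marker-based re-ranker has planted
truth to recover.

## Alignment hygiene choices

* **Chimeric** means: the read has at least one supplementary alignment;
  all its alignments are then dropped.
* **Gap-compressed mismatch ratio** = (mismatched columns + indel runs) /
  (matched + mismatched columns + indel runs); each contiguous indel run
  counts once regardless of length. Plain `M` CIGAR operations are
  rejected — the caller needs `=`/`X` resolution.
* The 2 kb length rule applies to the reference-consuming span.
* An alignment whose base at a confident SNP equals the alternate allele
  is removed; a deletion spanning the SNP carries no base and is retained
  (the rule targets substitutions).
* Re-ranking considers secondaries whose aligner score (AS tag, falling
  back to matched-minus-mismatched columns) is at least 0.99 of the
  primary's — "almost as high" made concrete and configurable. Markers are
  read offsets mismatched in ≥ 1 but not all candidates; read insertions
  and clipped bases count as mismatches for that candidate (no assembly
  counterpart), deletions contribute nothing. Ties keep the original
  primary; a winning secondary is promoted and the remaining candidates
  are discarded.

## Numerical and interface conventions

Coordinates are 0-based half-open everywhere internally; samtools-depth
input (1-based positions) and the `.cov` dialect (header `>contig length`,
then `start end depth` records, 1-based inclusive) convert at the I/O
boundary. Depth values are integers capped at 2³¹−1. Tracks are kept in
maximal run-length form and validated to tile each contig exactly.

## Problem sizes

The shipped tests run the full pipeline at 50 Mb (seconds on one CPU), fit
histograms of 10⁵–10⁶ bases, and verify oracles exhaustively over depths
0–200 and read fixtures ≤ 2 kb. These sizes were chosen so every property
is checked at a scale where brute-force verification remains exact while
the statistical regime (≈40× coverage, percent-scale defect fractions)
matches the intended application.

## Known limitations

* The duplicated component is intrinsically hard at 40×: Poisson(μ/2) and
  the haploid mode overlap, and with realistic (small) duplication weights
  the posterior boundary sits well below the midpoint, so a substantial
  minority of genuinely duplicated bases labels as `Hap` or `Unk`. This is
  a property of the model class, and it is why the high-MAPQ correction
  exists for the converse confusion.
* Windows are fit independently; nothing regularizes parameters across
  adjacent windows, so labels can change exactly at window boundaries.
* A satellite's systematic coverage shift can distort the fit of its
  *neighbourhood* (the window containing it); only the annotated interval
  itself is refit and relabeled.
* The re-ranker assumes candidates agree on read orientation as stored in
  SEQ; fixtures are forward-strand.
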