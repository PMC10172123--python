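"""Seeded synthetic fixtures with known truth for every pipeline stage.

The coverage simulator emulates the depth structure the mixture model
assumes for a phased diploid assembly: a haploid background around the
sequencing mean, planted regions with erroneous (near-zero), falsely
duplicated (half) and collapsed (integer-multiple) depth, and optional
satellite intervals whose local mean is multiplied by a platform bias.
Depth is drawn blockwise (one draw per ``block_size`` bases) so tracks
have realistic run-length structure rather than per-base i.i.d. noise.

The alignment simulator builds two homologous sequences differing at
known marker positions, draws reads from haplotype 1 with substitution
errors, and gives each read a primary and a secondary candidate — the
fixture for marker-based re-ranking and alt-read filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alnfilter import AlignmentRecord
from .coverage import CoverageTrack
from .errors import ParseError

_TRUTH_LABELS = ("Err", "Dup", "Col")


@dataclass(frozen=True)
class RegionPlant:
    """A planted non-haploid region: its true label and depth multiplier
    relative to the haploid mean (Err ~0.02, Dup 0.5, Col 2, 3, ...)."""

    contig: str
    start: int
    end: int
    label: str
    multiplier: float

    def __post_init__(self) -> None:
        if self.label not in _TRUTH_LABELS:
            raise ValueError(f"plant label must be one of {_TRUTH_LABELS}")
        if self.multiplier < 0:
            raise ValueError("plant multiplier must be >= 0")
        if self.start >= self.end:
            raise ValueError("empty plant interval")


@dataclass(frozen=True)
class HsatPlant:
    """A satellite interval whose local mean is multiplied by ``bias``
    (HiFi drops on HSat1, rises on HSat2/3)."""

    contig: str
    start: int
    end: int
    cls: str  # HSat1 | HSat2 | HSat3
    bias: float

    def __post_init__(self) -> None:
        if self.cls not in ("HSat1", "HSat2", "HSat3"):
            raise ValueError(f"unknown HSat class {self.cls!r}")
        if self.bias <= 0:
            raise ValueError("bias must be positive")


@dataclass
class SimSpec:
    """Conditions of a simulated assembly coverage experiment.

    Defaults follow a ~40x HiFi sequencing experiment, the regime the
    mixture model is designed for.
    """

    contig_lengths: dict[str, int]
    hap_mean: float = 40.0
    plants: list[RegionPlant] = field(default_factory=list)
    hsat_plants: list[HsatPlant] = field(default_factory=list)
    noise: str = "poisson"  # poisson | negative_binomial
    dispersion: float = 0.1  # nb: var = mean + dispersion * mean^2
    # one depth draw per block: HiFi depth decorrelates on the scale of the
    # ~20 kb reads, so ~5 kb blockwise-iid draws approximate real
    # threshold-crossing behaviour far better than per-base noise
    block_size: int = 5_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise not in ("poisson", "negative_binomial"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        if self.hap_mean <= 0:
            raise ValueError("hap_mean must be positive")
        self._validate_plants()

    def _validate_plants(self) -> None:
        by_contig: dict[str, list[tuple[int, int]]] = {}
        for p in self.plants:
            if p.contig not in self.contig_lengths:
                raise ParseError(f"plant on unknown contig {p.contig!r}")
            if p.end > self.contig_lengths[p.contig]:
                raise ParseError(f"plant {p} exceeds contig bounds")
            by_contig.setdefault(p.contig, []).append((p.start, p.end))
        for contig, spans in by_contig.items():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                if s2 < e1:
                    raise ParseError(
                        f"overlapping plants on {contig!r}: "
                        f"({s1},{e1}) and ({s2},{e2})"
                    )


def _draw_depths(rng: np.random.Generator, mean: float, n: int, spec: SimSpec) -> np.ndarray:
    if mean <= 0:
        return np.zeros(n, dtype=np.int64)
    if spec.noise == "poisson":
        return rng.poisson(mean, n).astype(np.int64)
    r = 1.0 / spec.dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, n).astype(np.int64)


def _elementary_intervals(spec: SimSpec, contig: str) -> list[tuple[int, int, str, float]]:
    """Split a contig at every plant/HSat boundary.

    Returns (start, end, truth_label, mean_multiplier) intervals tiling
    the contig; HSat biases multiply the label's own multiplier.
    """
    n = spec.contig_lengths[contig]
    cuts = {0, n}
    for p in spec.plants:
        if p.contig == contig:
            cuts.update((p.start, p.end))
    for h in spec.hsat_plants:
        if h.contig == contig:
            cuts.update((h.start, h.end))
    bounds = sorted(cuts)
    out = []
    for a, b in zip(bounds, bounds[1:]):
        label, mult = "Hap", 1.0
        for p in spec.plants:
            if p.contig == contig and p.start <= a and b <= p.end:
                label, mult = p.label, p.multiplier
                break
        for h in spec.hsat_plants:
            if h.contig == contig and h.start <= a and b <= h.end:
                mult *= h.bias
                break
        out.append((a, b, label, mult))
    return out


def simulate_coverage(spec: SimSpec) -> tuple[CoverageTrack, list[tuple[str, int, int, str]]]:
    """Draw a depth track and its truth BED from a simulation spec.

    Depth within each elementary interval is drawn blockwise around
    ``multiplier * hap_mean``; the truth records the planted label of
    every base (background is Hap).  Fully reproducible per seed.
    """
    rng = np.random.default_rng(spec.seed)
    track = CoverageTrack(spec.contig_lengths)
    truth: list[tuple[str, int, int, str]] = []
    for contig in spec.contig_lengths:
        starts_all, ends_all, depths_all = [], [], []
        for a, b, label, mult in _elementary_intervals(spec, contig):
            mean = mult * spec.hap_mean
            length = b - a
            nblocks = -(-length // spec.block_size)
            draws = _draw_depths(rng, mean, nblocks, spec)
            bs = a + spec.block_size * np.arange(nblocks, dtype=np.int64)
            be = np.minimum(bs + spec.block_size, b)
            starts_all.append(bs)
            ends_all.append(be)
            depths_all.append(draws)
            if truth and truth[-1][0] == contig and truth[-1][2] == a and truth[-1][3] == label:
                truth[-1] = (contig, truth[-1][1], b, label)
            else:
                truth.append((contig, a, b, label))
        track.set_blocks(
            contig,
            np.concatenate(starts_all),
            np.concatenate(ends_all),
            np.concatenate(depths_all),
        )
    return track, truth


def simulate_hq_track(
    spec: SimSpec,
    dup_true_hap_regions: list[tuple[str, int, int]] | None = None,
) -> CoverageTrack:
    """A MAPQ>20 auxiliary depth track matching a simulated assembly.

    Most of the genome keeps high-confidence support (~0.8x the haploid
    mean).  Planted Dup and Err regions get depth 0 — except intervals in
    ``dup_true_hap_regions``, which emulate mislabeled-but-real haploid
    sequence and get solid high-quality support (always above 5 reads).
    """
    rng = np.random.default_rng(spec.seed + 7919)
    regions = dup_true_hap_regions or []
    hq_spec_plants = []
    for p in spec.plants:
        rescued = any(
            c == p.contig and s <= p.start and p.end <= e for c, s, e in regions
        )
        if rescued:
            continue
        if p.label in ("Dup", "Err"):
            hq_spec_plants.append(RegionPlant(p.contig, p.start, p.end, p.label, 0.0))
    track = CoverageTrack(spec.contig_lengths)
    base_mean = 0.8 * spec.hap_mean
    for contig in spec.contig_lengths:
        n = spec.contig_lengths[contig]
        cuts = {0, n}
        zero = []
        rescue = []
        for p in hq_spec_plants:
            if p.contig == contig:
                cuts.update((p.start, p.end))
                zero.append((p.start, p.end))
        for c, s, e in regions:
            if c == contig:
                cuts.update((s, e))
                rescue.append((s, e))
        bounds = sorted(cuts)
        starts_all, ends_all, depths_all = [], [], []
        for a, b in zip(bounds, bounds[1:]):
            length = b - a
            nblocks = -(-length // spec.block_size)
            if any(s <= a and b <= e for s, e in zero):
                draws = np.zeros(nblocks, dtype=np.int64)
            elif any(s <= a and b <= e for s, e in rescue):
                draws = np.maximum(_draw_depths(rng, base_mean, nblocks, spec), 6)
            else:
                draws = _draw_depths(rng, base_mean, nblocks, spec)
            bs = a + spec.block_size * np.arange(nblocks, dtype=np.int64)
            be = np.minimum(bs + spec.block_size, b)
            starts_all.append(bs)
            ends_all.append(be)
            depths_all.append(draws)
        track.set_blocks(
            contig,
            np.concatenate(starts_all),
            np.concatenate(ends_all),
            np.concatenate(depths_all),
        )
    return track


# ---------------------------------------------------------------------------
# Two-haplotype alignment fixtures
# ---------------------------------------------------------------------------

_ALPHABET = np.array(list("ACGT"))


@dataclass
class ReadSimResult:
    hap1: str
    hap2: str
    marker_positions: list[int]  # positions where hap1 != hap2
    records: list[AlignmentRecord]
    truth_haplotype: dict[str, str]  # read id -> source contig name


def _columns_to_cigar(read: str, ref: str) -> list[tuple[str, int]]:
    ops = np.where(np.frombuffer(read.encode(), np.uint8)
                   == np.frombuffer(ref.encode(), np.uint8), "=", "X")
    cigar: list[tuple[str, int]] = []
    for op in ops:
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + 1)
        else:
            cigar.append((op, 1))
    return cigar


def simulate_read_alignments(
    seq_length: int = 1_000,
    n_markers: int = 20,
    error_rate: float = 0.002,
    n_reads: int = 50,
    read_length: int = 300,
    base_qual: int = 30,
    seed: int = 0,
) -> ReadSimResult:
    """Reads from haplotype 1 aligned against both haplotypes.

    Two homologous contigs (``hap1``, ``hap2``) differ at ``n_markers``
    random positions.  Each read is a substring of hap1 with substitution
    errors at ``error_rate``; it gets one gapless candidate alignment per
    haplotype, with the primary flag assigned at random (emulating an
    aligner that cannot tell near-identical haplotypes apart).  AS tags
    carry the match count so the near-tie gate admits both candidates.
    """
    if n_markers >= seq_length:
        raise ValueError("more markers than positions")
    rng = np.random.default_rng(seed)
    hap1 = _ALPHABET[rng.integers(0, 4, seq_length)]
    hap2 = hap1.copy()
    marker_pos = np.sort(rng.choice(seq_length, size=n_markers, replace=False))
    for p in marker_pos:
        choices = [b for b in "ACGT" if b != hap1[p]]
        hap2[p] = choices[rng.integers(0, 3)]
    hap1_s = "".join(hap1)
    hap2_s = "".join(hap2)

    records: list[AlignmentRecord] = []
    truth: dict[str, str] = {}
    for i in range(n_reads):
        start = int(rng.integers(0, seq_length - read_length + 1))
        read = list(hap1_s[start : start + read_length])
        n_err = rng.binomial(read_length, error_rate)
        err_pos = rng.choice(read_length, size=n_err, replace=False)
        for p in err_pos:
            choices = [b for b in "ACGT" if b != read[p]]
            read[p] = choices[rng.integers(0, 3)]
        read_s = "".join(read)
        read_id = f"read{i}"
        truth[read_id] = "hap1"
        quals = np.full(read_length, base_qual, dtype=np.int64)
        primary_is_hap1 = bool(rng.integers(0, 2))
        for contig, ref_s in (("hap1", hap1_s), ("hap2", hap2_s)):
            cigar = _columns_to_cigar(read_s, ref_s[start : start + read_length])
            matches = sum(n for op, n in cigar if op == "=")
            records.append(
                AlignmentRecord(
                    read_id=read_id,
                    contig=contig,
                    start=start,
                    mapq=0,
                    cigar=cigar,
                    is_secondary=(contig == "hap1") != primary_is_hap1,
                    seq=read_s,
                    quals=quals,
                    score=matches,
                )
            )
    return ReadSimResult(
        hap1=hap1_s,
        hap2=hap2_s,
        marker_positions=[int(p) for p in marker_pos],
        records=records,
        truth_haplotype=truth,
    )


def write_depth_tsv(track: CoverageTrack, out) -> None:
    """Emit a samtools-depth style table (contig, 1-based pos, depth),
    reporting every base as ``-aa`` would."""
    close = False
    if isinstance(out, (str, bytes)):
        out = open(out, "w")
        close = True
    try:
        import pandas as pd

        for contig in track.contigs():
            s, e, d = track.arrays(contig)
            depths = np.repeat(d, e - s)
            frame = pd.DataFrame(
                {
                    "contig": contig,
                    "pos": np.arange(1, len(depths) + 1, dtype=np.int64),
                    "depth": depths,
                }
            )
            frame.to_csv(out, sep="\t", header=False, index=False)
    finally:
        if close:
            out.close()


def write_truth_bed(truth: list[tuple[str, int, int, str]], out) -> None:
    close = False
    if isinstance(out, (str, bytes)):
        out = open(out, "w")
        close = True
    try:
        for contig, start, end, label in truth:
            out.write(f"{contig}\t{start}\t{end}\t{label}\n")
    finally:
        if close:
            out.close()


def write_markers_vcf(sim: ReadSimResult, out) -> None:
    """Minimal VCF of the haplotype-discriminating positions on hap1
    (ref = hap1 base, alt = hap2 base), with VAF/GQ FORMAT fields."""
    close = False
    if isinstance(out, (str, bytes)):
        out = open(out, "w")
        close = True
    try:
        out.write("##fileformat=VCFv4.2\n")
        out.write(f"##contig=<ID=hap1,length={len(sim.hap1)}>\n")
        out.write(f"##contig=<ID=hap2,length={len(sim.hap2)}>\n")
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        out.write('##FORMAT=<ID=VAF,Number=1,Type=Float,Description="Variant allele fraction">\n')
        out.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for p in sim.marker_positions:
            out.write(
                f"hap1\t{p + 1}\t.\t{sim.hap1[p]}\t{sim.hap2[p]}\t50\tPASS\t.\t"
                f"GT:VAF:GQ\t0/1:0.5:50\n"
            )
    finally:
        if close:
            out.close()


def benchmark_spec(seed: int = 0) -> SimSpec:
    """A 50 Mb diploid-assembly benchmark with 2% planted non-haploid bases.

    Six contigs emulate a realistic assembly mix: four 10 Mb contigs, one
    5.2 Mb contig whose terminal 100 kb is falsely duplicated (false
    duplications concentrate at contig ends), and one 4.8 Mb contig short
    enough to be labeled under the whole-genome model.  Planted bases are
    50% erroneous, 40% collapsed and 10% falsely duplicated, reflecting
    that coverage drops and collapses dominate the unreliable fraction of
    long-read diploid assemblies while false duplication is the rarest
    failure mode.
    """
    lengths = {f"chr{i}": 10_000_000 for i in range(1, 5)}
    lengths["chr5"] = 5_200_000
    lengths["chr6"] = 4_800_000
    plants = [
        # erroneous: 10 x 50 kb scattered
        RegionPlant("chr1", 800_000, 850_000, "Err", 0.02),
        RegionPlant("chr1", 6_200_000, 6_250_000, "Err", 0.02),
        RegionPlant("chr2", 1_500_000, 1_550_000, "Err", 0.02),
        RegionPlant("chr2", 7_900_000, 7_950_000, "Err", 0.02),
        RegionPlant("chr3", 2_400_000, 2_450_000, "Err", 0.02),
        RegionPlant("chr3", 9_100_000, 9_150_000, "Err", 0.02),
        RegionPlant("chr4", 3_300_000, 3_350_000, "Err", 0.02),
        RegionPlant("chr4", 8_600_000, 8_650_000, "Err", 0.02),
        RegionPlant("chr5", 2_000_000, 2_050_000, "Err", 0.02),
        RegionPlant("chr6", 1_000_000, 1_050_000, "Err", 0.02),
        # collapsed: 8 x 50 kb scattered, two true copies merged into one
        RegionPlant("chr1", 3_500_000, 3_550_000, "Col", 2.0),
        RegionPlant("chr1", 8_700_000, 8_750_000, "Col", 2.0),
        RegionPlant("chr2", 4_600_000, 4_650_000, "Col", 2.0),
        RegionPlant("chr2", 9_300_000, 9_350_000, "Col", 2.0),
        RegionPlant("chr3", 5_800_000, 5_850_000, "Col", 2.0),
        RegionPlant("chr4", 1_200_000, 1_250_000, "Col", 2.0),
        RegionPlant("chr4", 6_700_000, 6_750_000, "Col", 2.0),
        RegionPlant("chr6", 3_200_000, 3_250_000, "Col", 2.0),
        # falsely duplicated: one 100 kb region at a contig end
        RegionPlant("chr5", 5_050_000, 5_150_000, "Dup", 0.5),
    ]
    return SimSpec(contig_lengths=lengths, hap_mean=40.0, plants=plants, seed=seed)


def default_demo_spec(seed: int = 0) -> SimSpec:
    """A compact demonstration genome: one 8 Mb and one 3 Mb contig with
    one planted region of each error class and one biased satellite."""
    return SimSpec(
        contig_lengths={"chr_a": 8_000_000, "chr_b": 3_000_000},
        hap_mean=40.0,
        plants=[
            RegionPlant("chr_a", 1_000_000, 1_060_000, "Err", 0.02),
            RegionPlant("chr_a", 3_000_000, 3_080_000, "Dup", 0.5),
            RegionPlant("chr_a", 5_500_000, 5_560_000, "Col", 2.0),
            RegionPlant("chr_b", 1_200_000, 1_250_000, "Dup", 0.5),
        ],
        hsat_plants=[HsatPlant("chr_a", 6_500_000, 6_700_000, "HSat2", 1.6)],
        seed=seed,
    )
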