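"""Alignment hygiene for read-to-diploid-assembly mappings.

Three concerns live here:

* bulk filtering — drop chimeric reads (any read with a supplementary
  alignment), alignments spanning <2 kb of reference, and alignments
  whose gap-compressed mismatch ratio exceeds 1%.  Mapping quality is
  deliberately NOT a filter: reads in homozygous regions map equally well
  to both haplotypes and legitimately carry MAPQ 0.
* alt-read removal — given a set of high-confidence biallelic SNPs called
  on the alignments, remove any alignment that carries the alternate
  allele at one or more SNPs (such reads likely belong on the other
  haplotype or sit on an assembly error).
* marker-based primary re-ranking — when a secondary alignment scores
  almost as high as the primary, compare the candidates column by column
  in read coordinates, collect single-nucleotide markers (read bases
  mismatching some but not all candidates), score each candidate as minus
  the summed base qualities of its mismatched markers, and promote the
  best-scoring candidate to primary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pysam

from .errors import ParseError

log = logging.getLogger(__name__)

READ_CONSUMING = {"=", "X", "I", "S"}
REF_CONSUMING = {"=", "X", "D"}
_CIGAR_OPS = "MIDNSHP=X"  # pysam numeric op order

DEFAULT_MIN_LENGTH = 2_000
DEFAULT_MAX_MISMATCH_RATIO = 0.01
DEFAULT_SECPHASE_GATE = 0.99


@dataclass
class AlignmentRecord:
    """Minimal alignment representation for filtering and re-ranking.

    ``cigar`` uses extended ops ('=', 'X', 'I', 'D', 'S', 'H', and 'M'
    when the aligner did not distinguish match from mismatch); ``quals``
    are phred integers over the read in SEQ orientation.
    """

    read_id: str
    contig: str
    start: int  # 0-based reference start
    mapq: int
    cigar: list[tuple[str, int]]
    is_secondary: bool = False
    is_supplementary: bool = False
    is_reverse: bool = False
    seq: str | None = None
    quals: np.ndarray | None = None
    score: int | None = None  # aligner score (AS tag) when available

    def __post_init__(self) -> None:
        for op, n in self.cigar:
            if n <= 0:
                raise ParseError(f"{self.read_id}: non-positive cigar run {op}{n}")
            if op not in "MIDNSHP=X":
                raise ParseError(f"{self.read_id}: unknown cigar op {op!r}")

    @property
    def role(self) -> str:
        if self.is_supplementary:
            return "supplementary"
        if self.is_secondary:
            return "secondary"
        return "primary"

    @property
    def ref_span(self) -> int:
        return sum(n for op, n in self.cigar if op in REF_CONSUMING or op == "M")

    @property
    def read_length(self) -> int:
        return sum(n for op, n in self.cigar if op in READ_CONSUMING or op == "M")

    @property
    def end(self) -> int:
        return self.start + self.ref_span

    # -- pysam bridge ------------------------------------------------------

    @classmethod
    def from_pysam(cls, seg: "pysam.AlignedSegment") -> "AlignmentRecord":
        cigar = [(_CIGAR_OPS[op], n) for op, n in (seg.cigartuples or [])]
        quals = None
        if seg.query_qualities is not None:
            quals = np.asarray(seg.query_qualities, dtype=np.int64)
        score = None
        if seg.has_tag("AS"):
            score = int(seg.get_tag("AS"))
        return cls(
            read_id=seg.query_name,
            contig=seg.reference_name,
            start=seg.reference_start,
            mapq=seg.mapping_quality,
            cigar=cigar,
            is_secondary=seg.is_secondary,
            is_supplementary=seg.is_supplementary,
            is_reverse=seg.is_reverse,
            seq=seg.query_sequence,
            quals=quals,
            score=score,
        )

    def to_pysam(self, header: "pysam.AlignmentHeader") -> "pysam.AlignedSegment":
        seg = pysam.AlignedSegment(header)
        seg.query_name = self.read_id
        seg.reference_id = header.get_tid(self.contig)
        seg.reference_start = self.start
        seg.mapping_quality = self.mapq
        seg.cigarstring = "".join(f"{n}{op}" for op, n in self.cigar)
        flag = 0
        if self.is_secondary:
            flag |= 0x100
        if self.is_supplementary:
            flag |= 0x800
        if self.is_reverse:
            flag |= 0x10
        seg.flag = flag
        if self.seq is not None:
            seg.query_sequence = self.seq
            if self.quals is not None:
                seg.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in self.quals)
                )
        if self.score is not None:
            seg.set_tag("AS", self.score)
        return seg


def read_sam(path) -> tuple["pysam.AlignmentHeader", list[AlignmentRecord]]:
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        return fh.header, [AlignmentRecord.from_pysam(s) for s in fh]


def write_sam(path, header: "pysam.AlignmentHeader", records: list[AlignmentRecord]) -> None:
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for rec in records:
            out.write(rec.to_pysam(header))


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def gap_compressed_mismatch_ratio(rec: AlignmentRecord) -> float:
    """Mismatch ratio where each contiguous indel run counts as one event.

    (mismatched columns + indel runs) / (matched columns + mismatched
    columns + indel runs).  Requires extended '='/'X' cigar ops; plain 'M'
    cannot distinguish match from mismatch.
    """
    matches = mismatches = gaps = 0
    for op, n in rec.cigar:
        if op == "M":
            raise ParseError(
                f"{rec.read_id}: cigar has ambiguous 'M' ops; re-align with "
                f"--eqx-style output to get '='/'X'"
            )
        elif op == "=":
            matches += n
        elif op == "X":
            mismatches += n
        elif op in "ID":
            gaps += 1  # one event per run, regardless of length
    denom = matches + mismatches + gaps
    if denom == 0:
        raise ParseError(f"{rec.read_id}: alignment has no aligned columns")
    return (mismatches + gaps) / denom


def filter_alignments(
    records: list[AlignmentRecord],
    min_length: int = DEFAULT_MIN_LENGTH,
    max_ratio: float = DEFAULT_MAX_MISMATCH_RATIO,
) -> list[AlignmentRecord]:
    """Drop chimeric reads, short alignments and divergent alignments.

    A read is chimeric when any of its alignments is supplementary; all
    alignments of such a read are removed.  Length is the reference span;
    the boundary cases are kept (length exactly ``min_length`` passes,
    ratio exactly ``max_ratio`` passes).  MAPQ is never consulted.
    """
    chimeric = {r.read_id for r in records if r.is_supplementary}
    out = []
    for rec in records:
        if rec.read_id in chimeric:
            continue
        if rec.ref_span < min_length:
            continue
        if gap_compressed_mismatch_ratio(rec) > max_ratio:
            continue
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# SNP selection and alt-read removal
# ---------------------------------------------------------------------------

SnpSet = dict  # contig -> {0-based position: (ref_base, alt_base)}

_BASES = frozenset("ACGT")


def select_snps(
    vcf_path,
    min_vaf: float = 0.3,
    min_gq: float = 10.0,
) -> SnpSet:
    """High-confidence biallelic SNPs from a VCF.

    Keeps PASS, biallelic, single-base substitutions whose first sample has
    VAF >= ``min_vaf`` and GQ >= ``min_gq`` (exclusion is strict: VAF 0.30
    / GQ 10 are kept).  Records missing VAF or GQ are skipped with a
    warning.  Multiallelic records are excluded.
    """
    snps: SnpSet = {}
    with pysam.VariantFile(vcf_path) as vcf:
        for rec in vcf:
            filters = list(rec.filter.keys())
            if filters and filters != ["PASS"]:
                continue
            if rec.alts is None or len(rec.alts) != 1:
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
                continue
            if len(rec.samples) == 0:
                warnings.warn(f"SNP at {rec.chrom}:{rec.pos} has no sample data; skipped")
                continue
            sample = rec.samples[0]
            vaf = sample.get("VAF")
            gq = sample.get("GQ")
            if isinstance(vaf, tuple):
                vaf = vaf[0] if vaf else None
            if vaf is None or gq is None:
                warnings.warn(
                    f"SNP at {rec.chrom}:{rec.pos} missing VAF/GQ; skipped"
                )
                continue
            if vaf < min_vaf or gq < min_gq:
                continue
            snps.setdefault(rec.chrom, {})[rec.pos - 1] = (ref, alt)
    return snps


def read_snps_tsv(path_or_stream) -> SnpSet:
    """SNPs from a 4-column TSV: contig, 1-based position, ref, alt."""
    close = False
    stream = path_or_stream
    if isinstance(path_or_stream, (str, bytes)):
        stream = open(path_or_stream)
        close = True
    snps: SnpSet = {}
    try:
        for i, line in enumerate(stream, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError("expected contig, pos, ref, alt", line=i)
            contig, pos, ref, alt = parts[0], parts[1], parts[2], parts[3]
            if ref not in _BASES or alt not in _BASES:
                raise ParseError(f"non-SNP alleles {ref!r}/{alt!r}", line=i)
            snps.setdefault(contig, {})[int(pos) - 1] = (ref, alt)
    finally:
        if close:
            stream.close()
    return snps


def read_base_at(rec: AlignmentRecord, ref_pos: int) -> str | None:
    """The read base aligned to a reference position, or None when the
    position falls in a deletion or outside the alignment."""
    if rec.seq is None:
        raise ParseError(f"{rec.read_id}: sequence required for allele lookup")
    if not (rec.start <= ref_pos < rec.end):
        return None
    ref = rec.start
    read = 0
    for op, n in rec.cigar:
        consumes_ref = op in REF_CONSUMING or op == "M"
        consumes_read = op in READ_CONSUMING or op == "M"
        if consumes_ref and ref <= ref_pos < ref + n:
            if consumes_read:
                return rec.seq[read + (ref_pos - ref)]
            return None  # deletion spans the position
        if consumes_ref:
            ref += n
        if consumes_read:
            read += n
    return None


def filter_alt_reads(
    records: list[AlignmentRecord], snps: SnpSet
) -> tuple[list[AlignmentRecord], list[AlignmentRecord]]:
    """Split alignments into (retained, removed) by alternate-allele support.

    An alignment is removed when its aligned base equals the alternate
    allele at one or more SNPs.  A deletion over a SNP position carries no
    base and does not count as alt support.  SNPs on contigs absent from
    the records are ignored with a warning.
    """
    seen_contigs = {r.contig for r in records}
    for contig in snps:
        if contig not in seen_contigs:
            warnings.warn(f"SNPs on contig {contig!r} have no alignments; ignored")
    retained, removed = [], []
    for rec in records:
        contig_snps = snps.get(rec.contig, {})
        is_alt = False
        for pos in sorted(contig_snps):
            if pos < rec.start:
                continue
            if pos >= rec.end:
                break
            _, alt = contig_snps[pos]
            if read_base_at(rec, pos) == alt:
                is_alt = True
                break
        (removed if is_alt else retained).append(rec)
    return retained, removed


# ---------------------------------------------------------------------------
# Marker-based primary re-ranking
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Marker:
    """A read position that discriminates between candidate alignments."""

    read_offset: int
    qual: int
    mismatch_status: tuple[bool, ...]  # one entry per candidate


def _mismatch_profile(rec: AlignmentRecord) -> np.ndarray:
    """Boolean per-read-base mismatch vector for one candidate.

    '=' columns are matches; 'X' columns mismatches; read insertions and
    clipped bases have no assembly counterpart for this candidate and
    count as mismatches; deletions consume no read base.
    """
    n = rec.read_length
    profile = np.zeros(n, dtype=bool)
    read = 0
    for op, length in rec.cigar:
        if op == "M":
            raise ParseError(
                f"{rec.read_id}: 'M' cigar ops cannot be compared per column; "
                f"extended '='/'X' ops required"
            )
        if op in READ_CONSUMING:
            if op in ("X", "I", "S"):
                profile[read : read + length] = True
            read += length
    return profile


def compute_markers(candidates: list[AlignmentRecord]) -> list[Marker]:
    """Single-nucleotide markers across a read's candidate alignments:
    read bases mismatched in at least one candidate but not all."""
    if not candidates:
        return []
    lengths = {c.read_length for c in candidates}
    if len(lengths) != 1:
        raise ParseError(
            f"{candidates[0].read_id}: candidates disagree on read length "
            f"{sorted(lengths)}"
        )
    quals = next((c.quals for c in candidates if c.quals is not None), None)
    if quals is None:
        raise ParseError(f"{candidates[0].read_id}: base qualities required")
    profiles = np.stack([_mismatch_profile(c) for c in candidates])  # (C, L)
    some = profiles.any(axis=0)
    not_all = ~profiles.all(axis=0)
    marker_pos = np.flatnonzero(some & not_all)
    return [
        Marker(int(p), int(quals[p]), tuple(bool(x) for x in profiles[:, p]))
        for p in marker_pos
    ]


def consistency_scores(candidates: list[AlignmentRecord], markers: list[Marker]) -> list[int]:
    """Per-candidate score: minus the summed base qualities of the markers
    the candidate mismatches.  Higher (closer to zero) is better."""
    scores = [0] * len(candidates)
    for m in markers:
        for i, bad in enumerate(m.mismatch_status):
            if bad:
                scores[i] -= m.qual
    return scores


def _alignment_score(rec: AlignmentRecord) -> float:
    if rec.score is not None:
        return float(rec.score)
    # fallback: matched minus mismatched columns
    return float(
        sum(n for op, n in rec.cigar if op == "=")
        - sum(n for op, n in rec.cigar if op == "X")
    )


def secphase_rerank(
    alignments: list[AlignmentRecord],
    gate: float = DEFAULT_SECPHASE_GATE,
) -> tuple[AlignmentRecord, list[AlignmentRecord], list[Marker]]:
    """Re-rank one read's primary against its near-tied secondaries.

    Secondaries whose aligner score is at least ``gate`` times the
    primary's enter the comparison.  Markers are computed over the
    candidates, each candidate scored by marker base qualities, and the
    best candidate wins (ties keep the original primary).  When a
    secondary wins it is promoted to primary and the other alignments are
    discarded; otherwise the input is returned unchanged.

    Returns (chosen primary, discarded alignments, markers).
    """
    primaries = [a for a in alignments if a.role == "primary"]
    if len(primaries) != 1:
        raise ParseError(
            f"expected exactly one primary alignment, got {len(primaries)}"
        )
    primary = primaries[0]
    secondaries = [a for a in alignments if a.role == "secondary"]
    p_score = _alignment_score(primary)
    threshold = gate * p_score if p_score >= 0 else p_score / gate
    near = [s for s in secondaries if _alignment_score(s) >= threshold]
    if not near:
        return primary, [], []

    candidates = [primary] + near
    markers = compute_markers(candidates)
    if not markers:
        return primary, [], []
    scores = consistency_scores(candidates, markers)
    best = int(np.argmax(scores))
    if scores[best] <= scores[0]:
        best = 0  # ties (and worse) keep the original primary
    if best == 0:
        return primary, [], markers
    winner = replace(candidates[best], is_secondary=False)
    discarded = [a for a in alignments if a is not candidates[best]]
    return winner, discarded, markers


def secphase_rerank_all(
    records: list[AlignmentRecord], gate: float = DEFAULT_SECPHASE_GATE
) -> tuple[list[AlignmentRecord], int]:
    """Apply re-ranking to every read group of a record list.

    Returns the updated records and the number of reads whose primary was
    swapped.  Reads without both a primary and a secondary pass through.
    """
    by_read: dict[str, list[AlignmentRecord]] = {}
    order: list[str] = []
    for rec in records:
        if rec.read_id not in by_read:
            order.append(rec.read_id)
        by_read.setdefault(rec.read_id, []).append(rec)
    out: list[AlignmentRecord] = []
    swapped = 0
    for read_id in order:
        group = by_read[read_id]
        has_primary = any(a.role == "primary" for a in group)
        has_secondary = any(a.role == "secondary" for a in group)
        if not (has_primary and has_secondary):
            out.extend(group)
            continue
        chosen, discarded, _ = secphase_rerank(group, gate=gate)
        if discarded:
            swapped += 1
            out.append(chosen)
        else:
            out.extend(group)
    return out, swapped
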