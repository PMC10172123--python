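"""Windowed model fitting, per-base labeling, corrections and final BED.

The pipeline turns a depth track into five-way labeled blocks:

1. fit a whole-genome mixture, then one model per 5 Mb window of every
   contig longer than 5 Mb (short contigs and degenerate windows use the
   whole-genome model);
2. label each base by the most probable component of its window's model;
3. optionally relabel human-satellite classes (HSat1/2/3) after a refit
   whose EM start point reflects the class's systematic HiFi coverage
   bias (0.75x / 1.25x / 1.25x the genome mean);
4. optionally rescue falsely-Dup blocks supported by more than five
   MAPQ>20 alignments, relabeling them Hap;
5. merge same-label blocks closer than 1 kb and mark spans contested by
   two or more labels as Unk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .coverage import CoverageHistogram, CoverageTrack, Window, split_track_by_window, track_to_histogram
from .errors import DegenerateFitError, ParseError
from .mixture import (
    LABEL_COL,
    LABEL_DUP,
    LABEL_ERR,
    LABEL_HAP,
    LABEL_NAMES,
    LABEL_UNK,
    AssignmentTable,
    FitOptions,
    MixtureModel,
    assign_components,
    fit_mixture,
    refit_with_init,
)

log = logging.getLogger(__name__)

LABEL_CODES = {name: i for i, name in enumerate(LABEL_NAMES)}

# BED col9 palette: Err red, Dup orange, Hap green, Col purple, Unk grey
LABEL_COLORS = {
    "Err": "204,0,0",
    "Dup": "255,153,0",
    "Hap": "0,153,0",
    "Col": "102,0,204",
    "Unk": "128,128,128",
}

HSAT_MULTIPLIERS = {"HSat1": 0.75, "HSat2": 1.25, "HSat3": 1.25}


@dataclass(frozen=True)
class FlagBlock:
    """A labeled half-open interval on a contig; the pipeline's output unit."""

    contig: str
    start: int
    end: int
    label: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("FlagBlock must be non-empty")
        if self.label not in LABEL_CODES:
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class FlagSummary:
    total_bases: int
    label_bases: dict[str, int]
    label_fractions: dict[str, float]
    unreliable_bases: int
    unreliable_fraction: float
    unreliable_n50: int
    n_blocks: dict[str, int]

    def to_tsv(self) -> str:
        lines = ["metric\tvalue"]
        lines.append(f"total_bases\t{self.total_bases}")
        for name in LABEL_NAMES:
            lines.append(f"bases_{name}\t{self.label_bases.get(name, 0)}")
            lines.append(f"fraction_{name}\t{self.label_fractions.get(name, 0.0):.6f}")
            lines.append(f"blocks_{name}\t{self.n_blocks.get(name, 0)}")
        lines.append(f"unreliable_bases\t{self.unreliable_bases}")
        lines.append(f"unreliable_fraction\t{self.unreliable_fraction:.6f}")
        lines.append(f"unreliable_n50\t{self.unreliable_n50}")
        return "\n".join(lines) + "\n"


@dataclass
class FlagResult:
    """Finalized blocks, the fitted models, and the summary statistics."""

    blocks: list[FlagBlock]
    models: dict[Window, MixtureModel]
    summary: FlagSummary
    fallback_windows: list[Window] = field(default_factory=list)


@dataclass
class FlagConfig:
    window_size: int = 5_000_000
    min_contig: int = 5_000_000
    merge_dist: int = 1_000
    hq_min_support: int = 5  # strictly more than this relabels Dup -> Hap
    n_collapsed: int = 4
    max_iter: int = 300
    tol: float = 1e-6
    min_window_bases: int = 10_000  # thinner windows fall back
    init_coverage: float | None = None  # default: genome-wide mean depth
    seed: int = 0

    def fit_options(self, init_coverage: float) -> FitOptions:
        return FitOptions(
            init_coverage=init_coverage,
            max_iter=self.max_iter,
            tol=self.tol,
            n_collapsed=self.n_collapsed,
            seed=self.seed,
            min_bases=self.min_window_bases,
        )


# ---------------------------------------------------------------------------
# Per-base labeling
# ---------------------------------------------------------------------------


def _labels_for_slice(
    track: CoverageTrack, contig: str, start: int, end: int, table: AssignmentTable
) -> np.ndarray:
    """Per-base int8 labels for a slice, via the depth->label table."""
    s, e, d = track.slice_arrays(contig, start, end)
    if d.size and int(d.max()) > table.max_depth:
        raise ParseError(
            f"depth {int(d.max())} on {contig} exceeds assignment table "
            f"(max {table.max_depth})"
        )
    return np.repeat(table.labels[d], e - s)


def flag_track(track: CoverageTrack, table: AssignmentTable) -> list[FlagBlock]:
    """Label every base of a track with one model's assignment table.

    Returns maximal runs of identically labeled bases, tiling each contig.
    """
    blocks: list[FlagBlock] = []
    for contig in track.contigs():
        s, e, d = track.arrays(contig)
        if int(d.max()) > table.max_depth:
            raise ParseError(
                f"depth {int(d.max())} on {contig} exceeds assignment table"
            )
        labels = table.labels[d]
        keep = np.concatenate(([True], labels[1:] != labels[:-1]))
        starts = s[keep]
        labs = labels[keep]
        ends = np.concatenate((starts[1:], [track.lengths[contig]]))
        blocks.extend(
            FlagBlock(contig, int(a), int(b), LABEL_NAMES[l])
            for a, b, l in zip(starts, ends, labs)
        )
    return blocks


def run_windowed_flagging(
    track: CoverageTrack, config: FlagConfig
) -> tuple[dict[str, np.ndarray], dict[Window, MixtureModel], list[Window]]:
    """Fit per-window models and label every base.

    Returns per-contig per-base label arrays (int8), the fitted models
    keyed by window (including the pooled whole-genome window), and the
    list of windows that fell back to the whole-genome model.
    """
    genome_hist = track_to_histogram(track)
    genome_mean = genome_hist.mean()
    init = config.init_coverage if config.init_coverage is not None else genome_mean
    wg_opts = config.fit_options(init)
    wg_model = fit_mixture(genome_hist, wg_opts)
    max_depth = genome_hist.max_depth
    wg_table = assign_components(wg_model, max_depth)

    total_len = sum(track.lengths.values())
    wg_window = Window("*", 0, total_len, "whole_genome")
    models: dict[Window, MixtureModel] = {wg_window: wg_model}
    fallbacks: list[Window] = []

    labels: dict[str, np.ndarray] = {}
    windowed = split_track_by_window(track, config.window_size, config.min_contig)
    by_contig: dict[str, list[tuple[Window, CoverageHistogram]]] = {}
    for win, hist in windowed:
        by_contig.setdefault(win.contig, []).append((win, hist))

    for contig in track.contigs():
        n = track.lengths[contig]
        if contig not in by_contig:  # short contig: whole-genome model
            labels[contig] = _labels_for_slice(track, contig, 0, n, wg_table)
            continue
        parts = []
        for win, hist in by_contig[contig]:
            try:
                model = fit_mixture(hist, config.fit_options(init))
                table = assign_components(model, max_depth)
                models[win] = model
            except DegenerateFitError as exc:
                log.warning(
                    "window %s:%d-%d fell back to the whole-genome model (%s)",
                    win.contig, win.start, win.end, exc,
                )
                fallbacks.append(win)
                table = wg_table
            parts.append(_labels_for_slice(track, contig, win.start, win.end, table))
        labels[contig] = np.concatenate(parts)
    return labels, models, fallbacks


# ---------------------------------------------------------------------------
# Corrections
# ---------------------------------------------------------------------------


def apply_hsat_correction(
    labels: dict[str, np.ndarray],
    hsat_regions: list[tuple[str, int, int, str]],
    track: CoverageTrack,
    genome_mean: float,
    config: FlagConfig,
) -> dict[str, np.ndarray]:
    """Relabel satellite regions after a bias-aware refit.

    ``hsat_regions`` are (contig, start, end, class) intervals with class
    in HSat1/HSat2/HSat3.  Per class, a mixture is refit on the pooled
    class histogram with the EM start point at the class multiplier times
    the genome mean, and the resulting table overwrites labels inside the
    class's intervals.  Degenerate class fits leave labels untouched.
    """
    out = {c: arr.copy() for c, arr in labels.items()}
    by_class: dict[str, list[tuple[str, int, int]]] = {}
    for contig, start, end, cls in hsat_regions:
        if cls not in HSAT_MULTIPLIERS:
            raise ParseError(f"unknown HSat class {cls!r}")
        if contig not in track.lengths:
            raise ParseError(f"HSat region on unknown contig {contig!r}")
        by_class.setdefault(cls, []).append((contig, start, end))

    for cls, regions in by_class.items():
        hist = track_to_histogram(track, region=regions)
        opts = config.fit_options(genome_mean)  # init overwritten by refit
        try:
            model = refit_with_init(
                hist, opts, HSAT_MULTIPLIERS[cls], reference_mean=genome_mean
            )
        except DegenerateFitError as exc:
            log.warning("HSat class %s refit degenerate, labels kept (%s)", cls, exc)
            continue
        table = assign_components(model, max(hist.max_depth, 0))
        for contig, start, end in regions:
            out[contig][start:end] = _labels_for_slice(track, contig, start, end, table)
    return out


def apply_mapq_correction(
    labels: dict[str, np.ndarray],
    hq_track: CoverageTrack,
    min_support: int = 5,
) -> dict[str, np.ndarray]:
    """Rescue Dup blocks backed by high-confidence alignments.

    A maximal Dup run whose minimum MAPQ-filtered depth exceeds
    ``min_support`` (strictly more than five by default) is relabeled
    Hap; all other labels are untouched.
    """
    out = {}
    for contig, arr in labels.items():
        arr = arr.copy()
        is_dup = arr == LABEL_DUP
        if is_dup.any():
            edges = np.flatnonzero(np.diff(is_dup.astype(np.int8)))
            bounds = np.concatenate(([0], edges + 1, [len(arr)]))
            for a, b in zip(bounds[:-1], bounds[1:]):
                if is_dup[a] and hq_track.min_depth_in(contig, int(a), int(b)) > min_support:
                    arr[a:b] = LABEL_HAP
        out[contig] = arr
    return out


# ---------------------------------------------------------------------------
# Merging and finalization
# ---------------------------------------------------------------------------


def _runs(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    change = np.flatnonzero(np.diff(arr)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(arr)]))
    return starts, ends, arr[starts]


def _merge_close(starts: np.ndarray, ends: np.ndarray, merge_dist: int):
    """Merge sorted disjoint intervals whose gap is strictly below merge_dist."""
    if len(starts) == 0:
        return starts, ends
    keep_new = np.concatenate(([True], starts[1:] - ends[:-1] >= merge_dist))
    out_s = starts[keep_new]
    out_e = np.maximum.reduceat(ends, np.flatnonzero(keep_new))
    return out_s, out_e


def merge_and_finalize(
    labels: dict[str, np.ndarray],
    merge_dist: int,
    lengths: dict[str, int] | None = None,
) -> list[FlagBlock]:
    """Merge per-label blocks closer than ``merge_dist`` and resolve conflicts.

    Each label's blocks are merged independently, absorbing sub-threshold
    gaps; any base claimed by two or more labels after merging becomes
    Unk.  The result tiles every contig exactly once.
    """
    blocks: list[FlagBlock] = []
    for contig, arr in labels.items():
        n = len(arr)
        claim_count = np.zeros(n, dtype=np.int8)
        claimed_label = np.full(n, -1, dtype=np.int8)
        starts, ends, vals = _runs(arr)
        for lab in np.unique(vals):
            sel = vals == lab
            if lab == LABEL_UNK:
                # Unk is a resolution product, not a component: it claims
                # its own bases but never absorbs gaps
                ms, me = starts[sel], ends[sel]
            else:
                ms, me = _merge_close(starts[sel], ends[sel], merge_dist)
            for a, b in zip(ms, me):
                claim_count[a:b] += 1
                claimed_label[a:b] = lab
        final = np.where(claim_count > 1, LABEL_UNK, claimed_label).astype(np.int8)
        # every base carried a label before merging, so none is unclaimed
        fs, fe, fv = _runs(final)
        blocks.extend(
            FlagBlock(contig, int(a), int(b), LABEL_NAMES[v])
            for a, b, v in zip(fs, fe, fv)
        )
    return blocks


def n50(block_lengths) -> int:
    """N50 of a set of block lengths: the largest L such that blocks of
    length >= L cover at least half the total length."""
    lens = np.sort(np.asarray(list(block_lengths), dtype=np.int64))[::-1]
    if lens.size == 0:
        return 0
    half = lens.sum() / 2.0
    idx = int(np.searchsorted(np.cumsum(lens), half))
    return int(lens[min(idx, lens.size - 1)])


def summarize(blocks: list[FlagBlock]) -> FlagSummary:
    """Per-label base fractions plus size statistics of the non-Hap blocks."""
    label_bases = {name: 0 for name in LABEL_NAMES}
    n_blocks = {name: 0 for name in LABEL_NAMES}
    unreliable_lens = []
    for b in blocks:
        label_bases[b.label] += b.length
        n_blocks[b.label] += 1
        if b.label != "Hap":
            unreliable_lens.append(b.length)
    total = sum(label_bases.values())
    fractions = {k: (v / total if total else 0.0) for k, v in label_bases.items()}
    unreliable = sum(unreliable_lens)
    return FlagSummary(
        total_bases=total,
        label_bases=label_bases,
        label_fractions=fractions,
        unreliable_bases=unreliable,
        unreliable_fraction=(unreliable / total if total else 0.0),
        unreliable_n50=n50(unreliable_lens),
        n_blocks=n_blocks,
    )


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def run_pipeline(
    track: CoverageTrack,
    config: FlagConfig | None = None,
    hsat_regions: list[tuple[str, int, int, str]] | None = None,
    hq_track: CoverageTrack | None = None,
) -> FlagResult:
    """The full flagging pipeline on one depth track.

    Order is fixed: windowed labeling, HSat correction, MAPQ correction,
    merge/finalize.
    """
    config = config or FlagConfig()
    labels, models, fallbacks = run_windowed_flagging(track, config)
    if hsat_regions:
        genome_mean = track_to_histogram(track).mean()
        labels = apply_hsat_correction(labels, hsat_regions, track, genome_mean, config)
    if hq_track is not None:
        labels = apply_mapq_correction(labels, hq_track, config.hq_min_support)
    blocks = merge_and_finalize(labels, config.merge_dist, track.lengths)
    return FlagResult(
        blocks=blocks,
        models=models,
        summary=summarize(blocks),
        fallback_windows=fallbacks,
    )


def write_bed(blocks: list[FlagBlock], out, colors: bool = True) -> None:
    """Write flag blocks as BED (col4 label; col9 RGB when colors=True)."""
    close = False
    if isinstance(out, (str, bytes)):
        out = open(out, "w")
        close = True
    try:
        for b in blocks:
            if colors:
                out.write(
                    f"{b.contig}\t{b.start}\t{b.end}\t{b.label}\t0\t+\t"
                    f"{b.start}\t{b.end}\t{LABEL_COLORS[b.label]}\n"
                )
            else:
                out.write(f"{b.contig}\t{b.start}\t{b.end}\t{b.label}\n")
    finally:
        if close:
            out.close()
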