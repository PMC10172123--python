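import io

import numpy as np
import pytest

from asmflag.coverage import CoverageTrack


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_track(per_base: dict[str, list[int]]) -> CoverageTrack:
    """Build a track from explicit per-base depths (test helper)."""
    track = CoverageTrack({c: len(d) for c, d in per_base.items()})
    for contig, depths in per_base.items():
        track.set_per_base(contig, np.asarray(depths, dtype=np.int64))
    return track


def depth_stream(rows) -> io.StringIO:
    """samtools-depth style stream from (contig, pos, depth) rows."""
    return io.StringIO("".join(f"{c}\t{p}\t{d}\n" for c, p, d in rows))
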