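"""Self-contained reference experiments built from the forge + analysis stack."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import depth as depth_mod
from .forge.reads import SimConfig, simulate_alignments
from .forge.reference import forge_reference
from .forge.segmap import SegmentMap


def heterozygous_duplication_depth(seed: int, length: int = 2_000_000,
                                   dup: tuple[int, int] = (800_001, 1_200_000),
                                   depth: float = 30.0, window: int = 1000,
                                   workdir: str | Path | None = None) -> dict:
    """Depth signature of a one-extra-copy duplication on one haplotype.

    Forges a diploid in which one haplotype carries a tandem duplication of
    ``dup``, simulates error-free paired-end coverage, computes windowed
    depth normalized by the genome median and returns the percent elevation
    of mean normalized depth inside the duplicated interval (three copies
    against a diploid background: expected +50%).
    """
    import tempfile

    genome = forge_reference(1, [length], 0, seed=seed)
    bal = SegmentMap.identity("chr1", length, "dup_hap").apply_tandem_duplication(*dup)
    if workdir is None:
        tmp = tempfile.TemporaryDirectory()
        sam = Path(tmp.name) / "dup.sam"
    else:
        tmp = None
        sam = Path(workdir) / "dup.sam"
    cfg = SimConfig(depth=depth, seed=seed + 1, error_rate=0.0)
    simulate_alignments(genome, bal, cfg, sam)
    track = depth_mod.window_depth(sam, window, genome.masked_intervals)
    r = track.ratios["chr1"]
    ok = track.usable["chr1"]
    starts = track.starts["chr1"]
    inside = (starts >= dup[0]) & (starts + window - 1 <= dup[1]) & ok
    outside = ~((starts + window - 1 >= dup[0]) & (starts <= dup[1])) & ok
    # elevation is measured against background: the depth level of windows
    # outside the duplicated interval
    background = float(np.median(r[outside]))
    mean_inside = float(np.mean(r[inside]))
    elevation = (mean_inside / background - 1.0) * 100.0
    if tmp is not None:
        tmp.cleanup()
    return {
        "percent_elevation": float(elevation),
        "mean_ratio_inside": mean_inside,
        "background_ratio": background,
        "n_windows_inside": int(inside.sum()),
        "genome_length": length,
    }
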