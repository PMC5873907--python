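"""Windowed read depth, change-point segmentation and copy-ratio calls.

Depth is summarized as read-start counts in fixed windows, normalized by the
genome-median window count so that diploid background sits at ratio 1.0. In
a balancer/reference heterozygote one extra copy of a segment on the
balancer haplotype gives three copies against a diploid background — an
expected ratio of 1.5 — while a deficiency on one haplotype gives 0.5.
Segmentation is least-squares binary segmentation with a BIC-style penalty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

GAIN_THRESHOLD = 1.25  # midpoint between diploid (1.0) and one extra copy (1.5)
LOSS_THRESHOLD = 0.75  # midpoint between diploid and one-copy (0.5)


@dataclass
class DepthTrack:
    window_size: int
    chroms: list[str]
    starts: dict[str, np.ndarray]       # 1-based window starts per chrom
    counts: dict[str, np.ndarray]       # read starts per window
    usable: dict[str, np.ndarray]       # False for masked windows
    genome_median: float = 0.0
    ratios: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if not self.ratios:
            all_counts = np.concatenate([self.counts[c][self.usable[c]]
                                         for c in self.chroms]) if self.chroms else []
            if len(all_counts) == 0:
                raise ValueError("no usable windows in depth track")
            self.genome_median = float(np.median(all_counts))
            if self.genome_median <= 0:
                raise ValueError("median window count is zero; track unusable")
            self.ratios = {c: self.counts[c] / self.genome_median for c in self.chroms}

    @property
    def total_count(self) -> int:
        return int(sum(self.counts[c].sum() for c in self.chroms))

    def write_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write('track type=bedGraph name="normalized depth"\n')
            for c in self.chroms:
                for s, r, ok in zip(self.starts[c], self.ratios[c], self.usable[c]):
                    if ok:
                        fh.write(f"{c}\t{s - 1}\t{s - 1 + self.window_size}\t{r:.4f}\n")


@dataclass
class SegmentCall:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    mean_ratio: float
    label: str  # normal | gain | loss
    n_windows: int


def window_depth(sam_path, window_size: int = 1000,
                 mask: list[tuple[str, int, int]] | None = None) -> DepthTrack:
    """Count primary-alignment read starts per window.

    Windows overlapping a masked interval by more than half are flagged
    unusable and excluded from the normalization median.
    """
    af = pysam.AlignmentFile(str(sam_path))
    lengths = {sq["SN"]: sq["LN"] for sq in af.header.get("SQ", [])}
    if not lengths:
        raise ValueError("SAM header lacks @SQ lines")
    chroms = sorted(lengths)
    counts = {c: np.zeros(max(1, -(-lengths[c] // window_size)), dtype=np.int64)
              for c in chroms}
    n_records = 0
    for rec in af:
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            continue
        n_records += 1
        counts[rec.reference_name][rec.reference_start // window_size] += 1
    if n_records == 0:
        raise ValueError("empty alignment stream")
    starts = {c: np.arange(len(counts[c]), dtype=np.int64) * window_size + 1
              for c in chroms}
    usable = {c: np.ones(len(counts[c]), dtype=bool) for c in chroms}
    for mc, ms, me in (mask or []):
        if mc not in usable:
            continue
        w = usable[mc]
        ws = starts[mc]
        we = np.minimum(ws + window_size - 1, lengths[mc])
        ov = np.maximum(0, np.minimum(we, me) - np.maximum(ws, ms) + 1)
        w &= ~(ov > (we - ws + 1) / 2)
    for c in chroms:
        if not usable[c].any():
            warnings.warn(f"{c}: no usable windows (fully masked)")
    track = DepthTrack(window_size, chroms, starts, counts, usable)
    return track


def _sse(prefix, prefix2, i, j) -> float:
    """Sum of squared deviations of x[i:j] from its mean, via prefix sums."""
    n = j - i
    s = prefix[j] - prefix[i]
    s2 = prefix2[j] - prefix2[i]
    return s2 - s * s / n


def best_single_split(x: np.ndarray) -> tuple[int, float]:
    """Exhaustive least-squares single change point of x.

    Returns (split index k, SSE reduction): the segmentation [0:k), [k:n).
    """
    n = len(x)
    c1 = np.cumsum(x)
    c2 = np.cumsum(x * x)
    ks = np.arange(1, n)
    left = c2[ks - 1] - c1[ks - 1] ** 2 / ks
    totals2, totals = c2[-1], c1[-1]
    right = (totals2 - c2[ks - 1]) - (totals - c1[ks - 1]) ** 2 / (n - ks)
    full = totals2 - totals ** 2 / n
    gains = full - (left + right)
    k = int(np.argmax(gains))
    return int(ks[k]), float(gains[k])


def segment_track(track: DepthTrack, penalty: float | None = None,
                  min_segment_windows: int = 3) -> list[SegmentCall]:
    """Binary segmentation of normalized ratios with a BIC-style penalty.

    The penalty per change point defaults to 4 * sigma^2 * log(n), with
    sigma^2 estimated robustly from first differences; the multiplier keeps
    the expected extreme spurious SSE gain (which itself grows like
    2 sigma^2 log n) safely below the threshold. Adjacent segments shorter
    than ``min_segment_windows`` are merged into their nearer neighbor.
    Masked windows are carried with their segment but excluded from means.
    """
    calls: list[SegmentCall] = []
    for chrom in track.chroms:
        r = track.ratios[chrom]
        ok = track.usable[chrom]
        x = r[ok]
        idx = np.flatnonzero(ok)
        n = len(x)
        if n == 0:
            continue
        if n < 10:
            calls.append(_make_call(track, chrom, idx, x, 0, n))
            continue
        if penalty is None:
            diffs = np.diff(x)
            sigma2 = float(np.median(np.abs(diffs)) / 0.6745) ** 2 / 2 or 1e-6
            pen = 4.0 * sigma2 * np.log(n)
        else:
            pen = penalty
        bounds = sorted(_binseg(x, 0, n, pen, min_segment_windows))
        bounds = _merge_short([0] + bounds + [n], x, min_segment_windows)
        for a, b in zip(bounds[:-1], bounds[1:]):
            calls.append(_make_call(track, chrom, idx, x, a, b))
    return calls


def _binseg(x, lo, hi, pen, min_len) -> list[int]:
    if hi - lo < 2 * min_len:
        return []
    k, gain = best_single_split(x[lo:hi])
    if gain <= pen:
        return []
    k += lo
    return _binseg(x, lo, k, pen, min_len) + [k] + _binseg(x, k, hi, pen, min_len)


def _merge_short(bounds: list[int], x: np.ndarray, min_len: int) -> list[int]:
    bounds = list(bounds)
    changed = True
    while changed and len(bounds) > 2:
        changed = False
        lens = np.diff(bounds)
        i = int(np.argmin(lens))
        if lens[i] < min_len:
            # drop the boundary whose removal best matches neighboring means
            if i == 0:
                del bounds[1]
            elif i == len(lens) - 1:
                del bounds[-2]
            else:
                m = float(np.mean(x[bounds[i]:bounds[i + 1]]))
                left = float(np.mean(x[bounds[i - 1]:bounds[i]]))
                right = float(np.mean(x[bounds[i + 1]:bounds[i + 2]]))
                del bounds[i + 1 if abs(m - left) <= abs(m - right) else i]
            changed = True
    return bounds


def _make_call(track, chrom, idx, x, a, b) -> SegmentCall:
    w = track.window_size
    first, last = idx[a], idx[b - 1]
    start = int(track.starts[chrom][first])
    end = int(track.starts[chrom][last]) + w - 1
    mean = float(np.mean(x[a:b]))
    return SegmentCall(chrom, start, end, mean, "normal", b - a)


def call_copy_segments(segments: list[SegmentCall],
                       junctions: list | None = None,
                       gain_threshold: float = GAIN_THRESHOLD,
                       loss_threshold: float = LOSS_THRESHOLD) -> list[SegmentCall]:
    """Label segments by the heterozygote copy model and refine extents.

    gain: mean ratio >= 1.25 (expected 1.5 for one extra copy on one
    haplotype); loss: <= 0.75 (expected 0.5). When a junction call's flank
    falls within one window of a segment boundary, the boundary is refined
    to base-pair precision from the flank.
    """
    out = []
    for seg in segments:
        label = "normal"
        if seg.mean_ratio >= gain_threshold:
            label = "gain"
        elif seg.mean_ratio <= loss_threshold:
            label = "loss"
        start, end = seg.start, seg.end
        if junctions and label != "normal":
            win = max(1, (seg.end - seg.start + 1) // max(1, seg.n_windows))
            for j in junctions:
                for chrom, pos, _ in (j.flank_a, j.flank_b):
                    if chrom != seg.chrom:
                        continue
                    if abs(pos - start) <= win:
                        start = pos
                    elif abs(pos - end) <= win:
                        end = pos
        out.append(SegmentCall(seg.chrom, start, end, seg.mean_ratio, label,
                               seg.n_windows))
    return out


def duplication_report(gains: list[SegmentCall], junctions: list | None,
                       annotation: list | None) -> list[dict]:
    """Per-gain extent, size (end - start), copy ratio, bounding junctions,
    and a census of annotation features wholly inside the extent."""
    report = []
    for g in gains:
        entry = {
            "chrom": g.chrom, "start": g.start, "end": g.end,
            "size": g.end - g.start,  # printed-table convention
            "copy_ratio": round(g.mean_ratio, 3),
            "bounding_junctions": [],
            "census": {},
        }
        for j in (junctions or []):
            for chrom, pos, _ in (j.flank_a, j.flank_b):
                if chrom == g.chrom and g.start - 1 <= pos <= g.end + 1:
                    entry["bounding_junctions"].append((chrom, pos))
        for m in (annotation or []):
            if m.chrom == g.chrom and g.start <= m.start and m.end <= g.end:
                entry["census"][m.biotype] = entry["census"].get(m.biotype, 0) + 1
        report.append(entry)
    return report


def write_segments_tsv(segments: list[SegmentCall], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame([{
        "chrom": s.chrom, "start": s.start, "end": s.end,
        "mean_ratio": round(s.mean_ratio, 4), "label": s.label,
        "n_windows": s.n_windows,
    } for s in segments]).to_csv(path, sep="\t", index=False)


def write_calls_bed(segments: list[SegmentCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in segments:
            if s.label != "normal":
                fh.write(f"{s.chrom}\t{s.start - 1}\t{s.end}\t{s.label}\t"
                         f"{s.mean_ratio:.3f}\n")
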