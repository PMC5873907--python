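"""Oriented segment maps: the coordinate backbone of derivative chromosomes.

A derivative (balancer-like) chromosome is modelled as an ordered list of
oriented reference segments. All public coordinates are 1-based inclusive,
matching the convention used for every printed dm6 breakpoint. Segments with
strand ``-`` contribute the reverse complement of the reference slice.

Breakpoint flanks follow the retained-flank convention: a flank is the last
reference base retained on its side of a junction; a junction deletion of
``d`` bases removes the bases strictly between the retained flanks, while a
duplication of ``d`` bases leaves ``d`` bases present on both sides.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

SPACER_PREFIX = "*spacer:"


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class Segment:
    """One oriented reference slice, 1-based inclusive coordinates."""

    chrom: str
    start: int
    end: int
    strand: str  # '+' or '-'

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"empty or invalid segment {self}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def is_spacer(self) -> bool:
        return self.chrom.startswith(SPACER_PREFIX)

    def flipped(self) -> "Segment":
        return replace(self, strand="-" if self.strand == "+" else "+")

    def base_at(self, offset: int) -> tuple[str, int, str]:
        """Reference (chrom, pos, strand) underlying derivative offset (0-based
        within this segment)."""
        if self.strand == "+":
            return self.chrom, self.start + offset, "+"
        return self.chrom, self.end - offset, "-"


@dataclass
class SegmentMap:
    """Ordered, oriented reference segments defining a derivative chromosome.

    ``junction_deltas[i]`` is the signed bp recorded at the junction between
    ``segments[i]`` and ``segments[i+1]`` (+ duplicated, − deleted, 0 blunt or
    uneventful adjacency), used as simulation ground truth.
    ``spacers`` maps synthetic spacer names (low-complexity filler with no
    reference locus) to their sequences.
    """

    derivative_name: str
    segments: list[Segment]
    junction_deltas: list[int] = field(default_factory=list)
    spacers: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.segments:
            raise ValueError("a SegmentMap needs at least one segment")
        if not self.junction_deltas:
            self.junction_deltas = [0] * (len(self.segments) - 1)
        if len(self.junction_deltas) != len(self.segments) - 1:
            raise ValueError("junction_deltas must have len(segments) - 1 entries")
        self._reindex()

    def _reindex(self):
        self._cum = [0]
        for seg in self.segments:
            self._cum.append(self._cum[-1] + seg.length)

    # ------------------------------------------------------------------ basics

    @classmethod
    def identity(cls, chrom: str, length: int, name: str | None = None) -> "SegmentMap":
        return cls(name or chrom, [Segment(chrom, 1, length, "+")])

    @property
    def length(self) -> int:
        return self._cum[-1]

    def _locate(self, dpos: int) -> tuple[int, int]:
        """(segment index, 0-based offset) for a 1-based derivative position."""
        if not 1 <= dpos <= self.length:
            raise ValueError(f"derivative position {dpos} outside 1..{self.length}")
        i = bisect.bisect_right(self._cum, dpos - 1) - 1
        return i, dpos - 1 - self._cum[i]

    def map_coordinate(self, dpos: int) -> tuple[str, int, str]:
        """Reference (chrom, pos, strand) underlying a derivative position.

        Spacer positions map to the spacer's synthetic name.
        """
        i, off = self._locate(dpos)
        return self.segments[i].base_at(off)

    def invert_coordinate(self, chrom: str, ref_pos: int) -> list[tuple[int, str]]:
        """All derivative (position, strand) pairs over a reference base.

        Multi-valued inside duplicated segments; empty if the base was deleted.
        """
        hits = []
        for i, seg in enumerate(self.segments):
            if seg.chrom == chrom and seg.start <= ref_pos <= seg.end:
                if seg.strand == "+":
                    off = ref_pos - seg.start
                else:
                    off = seg.end - ref_pos
                hits.append((self._cum[i] + off + 1, seg.strand))
        return hits

    # ----------------------------------------------------------------- slicing

    def _slice(self, dstart: int, dend: int) -> tuple[list[Segment], list[int]]:
        """Oriented sub-segments (and interior junction deltas) covering the
        derivative interval [dstart, dend], 1-based inclusive."""
        if dstart > dend:
            raise ValueError(f"empty slice {dstart}..{dend}")
        i0, off0 = self._locate(dstart)
        i1, off1 = self._locate(dend)
        out: list[Segment] = []
        deltas: list[int] = []
        for i in range(i0, i1 + 1):
            seg = self.segments[i]
            a = off0 if i == i0 else 0
            b = off1 if i == i1 else seg.length - 1
            if seg.strand == "+":
                out.append(replace(seg, start=seg.start + a, end=seg.start + b))
            else:
                out.append(replace(seg, start=seg.end - b, end=seg.end - a))
            if i < i1:
                deltas.append(self.junction_deltas[i])
        return out, deltas

    @staticmethod
    def _revflip(segs: list[Segment], deltas: list[int]) -> tuple[list[Segment], list[int]]:
        return [s.flipped() for s in reversed(segs)], list(reversed(deltas))

    def _rebuild(self, parts: list[tuple[list[Segment], list[int]]],
                 joints: list[int], name: str | None = None) -> "SegmentMap":
        """Concatenate (segments, deltas) parts with the given joint deltas."""
        segs: list[Segment] = []
        deltas: list[int] = []
        for k, (ps, pd) in enumerate(parts):
            if k > 0:
                deltas.append(joints[k - 1])
            segs.extend(ps)
            deltas.extend(pd)
        m = SegmentMap(name or self.derivative_name, segs, deltas, dict(self.spacers))
        return m._normalized()

    def _normalized(self) -> "SegmentMap":
        """Merge adjacent colinear segments whose joint delta is 0."""
        segs = [self.segments[0]]
        deltas: list[int] = []
        for seg, d in zip(self.segments[1:], self.junction_deltas):
            prev = segs[-1]
            mergeable = (
                d == 0
                and not prev.is_spacer
                and prev.chrom == seg.chrom
                and prev.strand == seg.strand
                and (
                    (prev.strand == "+" and seg.start == prev.end + 1)
                    or (prev.strand == "-" and seg.end == prev.start - 1)
                )
            )
            if mergeable:
                if prev.strand == "+":
                    segs[-1] = replace(prev, end=seg.end)
                else:
                    segs[-1] = replace(prev, start=seg.start)
            else:
                segs.append(seg)
                deltas.append(d)
        return SegmentMap(self.derivative_name, segs, deltas, dict(self.spacers))

    # -------------------------------------------------------------- operations

    def apply_inversion(self, left_flank: int, right_flank: int,
                        delta_left: int = 0, delta_right: int = 0) -> "SegmentMap":
        """Invert the derivative interval between two retained flanks.

        ``left_flank`` / ``right_flank`` are derivative coordinates of the last
        retained base on each side of the inversion. With zero deltas, bases
        ``left_flank+1 .. right_flank-1`` appear reverse-complemented. A
        positive delta duplicates that many flank bases into the inverted core
        (they appear on both sides of the junction); a negative delta deletes
        that many core bases adjacent to the junction.
        """
        L, R = left_flank, right_flank
        if not (1 <= L < R <= self.length):
            raise ValueError(f"flanks {L},{R} outside map span 1..{self.length}")
        # delta_left >= 0 duplicates bases L-delta+1..L; < 0 deletes L+1..L+|delta|
        core_start = L - delta_left + 1 if delta_left >= 0 else L + 1 + (-delta_left)
        core_end = R - 1 + delta_right if delta_right >= 0 else R - 1 - (-delta_right)
        if core_start < 1 or core_end > self.length or core_start > core_end:
            raise ValueError("inversion core empty or outside map after applying deltas")
        left, left_d = self._slice(1, L) if L >= 1 else ([], [])
        core = self._revflip(*self._slice(core_start, core_end))
        right, right_d = self._slice(R, self.length)
        return self._rebuild([(left, left_d), core, (right, right_d)],
                             joints=[delta_left, delta_right])

    def apply_tandem_duplication(self, start: int, end: int) -> "SegmentMap":
        """Duplicate the derivative interval [start, end] in place (tandem)."""
        if not (1 <= start <= end <= self.length):
            raise ValueError("duplication interval outside map span")
        parts = []
        if start > 1:
            parts.append(self._slice(1, start - 1))
        dup = self._slice(start, end)
        parts.append(dup)
        parts.append(self._slice(start, end))
        if end < self.length:
            parts.append(self._slice(end + 1, self.length))
        joints = [0] * (len(parts) - 1)
        # record the tandem junction as a duplication of the full interval
        joints[len(parts) - 2 - (1 if end < self.length else 0)] = end - start + 1
        return self._rebuild(parts, joints)

    def apply_complex_duplication(self, dupA: tuple[int, int], dupB: tuple[int, int],
                                  inverted_seg: tuple[int, int], spacer: str,
                                  spacer_id: str | None = None) -> "SegmentMap":
        """Mirror-image double duplication with low-complexity spacers.

        ``inverted_seg``, ``dupA`` and ``dupB`` are consecutive derivative
        intervals (I immediately followed by A, A by B). The duplicated unit
        D = A+B spans the existing I/A boundary; the result is

            prefix + revcomp(I) + revcomp(D) + D + spacer + spacer + suffix

        so A and B each appear twice in mirror-image orientation around a
        blunt mirror junction, joined to the inverted segment, with the
        low-complexity spacer juxtaposed to the distal end of the second
        copy. The derivative grows by len(A) + len(B) + 2*len(spacer), and
        the event leaves three placeable junctions whose flanks chain by
        proximity (prefix|I', I'|D-mirror, and the blunt mirror point).
        """
        (a1, a2), (b1, b2), (i1, i2) = dupA, dupB, inverted_seg
        if a2 >= b1 and b2 >= a1:
            raise ValueError("dupA and dupB overlap")
        if not (1 <= i1 <= i2 < a1 <= a2 < b1 <= b2 <= self.length):
            raise ValueError("expected inverted_seg < dupA < dupB inside the map span")
        if i2 + 1 != a1 or a2 + 1 != b1:
            raise ValueError(
                "inverted_seg, dupA and dupB must be consecutive derivative intervals"
            )
        sid = spacer_id or f"sp{len(self.spacers) + 1}"
        name = SPACER_PREFIX + sid
        new_spacers = dict(self.spacers)
        if spacer:
            new_spacers[sid] = spacer
            sp_seg = ([Segment(name, 1, len(spacer), "+")], [])
        else:
            sp_seg = None

        parts: list[tuple[list[Segment], list[int]]] = []
        if i1 > 1:
            parts.append(self._slice(1, i1 - 1))
        parts.append(self._revflip(*self._slice(i1, i2)))
        parts.append(self._revflip(*self._slice(a1, b2)))
        parts.append(self._slice(a1, b2))
        if sp_seg:
            parts.append(sp_seg)
            parts.append(sp_seg)
        if b2 < self.length:
            parts.append(self._slice(b2 + 1, self.length))
        joints = [0] * (len(parts) - 1)
        m = self._rebuild(parts, joints)
        m.spacers = new_spacers
        return m

    # ------------------------------------------------------------- sequence

    def build_sequence(self, chromosomes: dict[str, str]) -> str:
        """Splice the derivative nucleotide sequence from reference chromosomes."""
        out = []
        for seg in self.segments:
            if seg.is_spacer:
                src = self.spacers[seg.chrom[len(SPACER_PREFIX):]]
            else:
                src = chromosomes[seg.chrom]
            piece = src[seg.start - 1: seg.end]
            out.append(piece if seg.strand == "+" else revcomp(piece))
        return "".join(out)

    def junctions(self) -> list[dict]:
        """Ground-truth novel adjacencies (non-colinear segment joints).

        Each flank is the junction-adjacent retained reference base with a
        side code: '+' means the retained sequence occupies reference
        coordinates <= pos (the junction is on the block's right in
        reference space), '-' means it occupies coordinates >= pos. An
        inversion therefore produces one (+,+) and one (-,-) junction.
        """
        out = []
        for i, d in enumerate(self.junction_deltas):
            a, b = self.segments[i], self.segments[i + 1]
            colinear = (
                not a.is_spacer and not b.is_spacer
                and a.chrom == b.chrom and a.strand == b.strand
                and ((a.strand == "+" and b.start == a.end + 1)
                     or (a.strand == "-" and b.end == a.start - 1))
            )
            if colinear and d == 0:
                continue
            # left-of-junction segment: derivative-last base; side from strand
            fa = (a.chrom, a.end, "+") if a.strand == "+" else (a.chrom, a.start, "-")
            # right-of-junction segment: derivative-first base
            fb = (b.chrom, b.start, "-") if b.strand == "+" else (b.chrom, b.end, "+")
            out.append({
                "derivative_pos": self._cum[i + 1],
                "flank_a": fa,
                "flank_b": fb,
                "delta": d,
                "spacer": a.is_spacer or b.is_spacer,
            })
        return out
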