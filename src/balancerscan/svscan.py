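"""Rearrangement junction calling from split and discordant read evidence.

The pipeline mirrors the classical short-read breakpoint workflow: isolate
split (primary + supplementary) and discordant pair evidence from a
coordinate-sorted SAM, cluster it jointly on both loci, de novo assemble
each cluster's reads into a junction contig, place the contig on the
reference as exactly two maximal ungapped blocks via unique k-mer anchoring,
and read the junction flanks off the block ends. Junctions are then paired
into component aberrations (simple inversions, or complex groups sharing
flank coordinates) and matched against a balancer catalog to fingerprint
the chromosome's identity.

Coordinates in calls and reports are 1-based inclusive; flanks are the last
retained reference base on each side of a junction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pysam

from .catalog import BalancerCatalog
from .forge.segmap import revcomp


@dataclass
class SvConfig:
    min_clip: int = 20
    discord_sds: float = 3.0
    cluster_radius: int = 500
    min_split_support: int = 2
    min_discordant_support: int = 3
    min_overlap: int = 20
    k: int = 31
    min_block_len: int = 30
    max_kmer_hits: int = 4
    cover_slack: int | None = None  # defaults to k: shorter ends cannot anchor
    pair_window: int = 2_000
    match_tol: int = 100
    masked_fraction_max: float = 0.5
    hamming_tolerant: bool = False
    max_cluster_reads: int = 120


@dataclass(frozen=True)
class Evidence:
    kind: str  # split | discordant
    query_name: str
    locus_a: tuple[str, int, str]  # (chrom, pos, side); side R: block left of junction
    locus_b: tuple[str, int, str]
    clip_length: int = 0
    insert_anomaly: str | int = 0


@dataclass
class EvidenceCluster:
    members: list[Evidence]
    footprint_a: tuple[str, int, int]
    footprint_b: tuple[str, int, int]
    support: tuple[int, int]  # (n_split, n_discordant)
    cluster_id: int = -1

    def __post_init__(self):
        ca, lo_a, hi_a = self.footprint_a
        cb, lo_b, hi_b = self.footprint_b
        for m in self.members:
            assert m.locus_a[0] == ca and lo_a <= m.locus_a[1] <= hi_a
            assert m.locus_b[0] == cb and lo_b <= m.locus_b[1] <= hi_b
        n_split = sum(1 for m in self.members if m.kind == "split")
        assert self.support == (n_split, len(self.members) - n_split)


@dataclass
class Contig:
    sequence: str
    member_reads: list[str]
    built_from: int
    assembled: bool = True


@dataclass
class Placement:
    status: str  # placed | unplaceable
    blocks: list[tuple[str, int, int, str, int, int]] = field(default_factory=list)
    # (chrom, ref_start, ref_end, strand, contig_start, contig_end) 1-based incl.
    n_candidate_blocks: int = 0


@dataclass
class JunctionCall:
    flank_a: tuple[str, int, str]  # (chrom, pos, strand)
    flank_b: tuple[str, int, str]
    delta: int
    support: tuple[int, int]
    contig_id: int
    kind: str = "rearrangement"  # rearrangement | local-indel
    inserted: int = 0
    masked_fraction: float = 0.0

    def sorted_flanks(self) -> tuple[tuple[str, int, str], tuple[str, int, str]]:
        return tuple(sorted([self.flank_a, self.flank_b]))


@dataclass
class AberrationCall:
    kind: str  # inversion | complex | complex/unpaired
    junctions: list[JunctionCall]
    sites: list[dict] = field(default_factory=list)
    label: str = ""


# --------------------------------------------------------------------- extract

# compact per-record tuples (pysam objects are too heavy to keep for a genome)
# (chrom, ref_start1, ref_end1, is_reverse, read_u, read_v, read_len, clip, seq)
_CHROM, _RS, _RE, _REV, _U, _V, _RL, _CLIP, _SEQ = range(9)


def _info(rec: pysam.AlignedSegment) -> tuple:
    qs, qe = rec.query_alignment_start, rec.query_alignment_end
    L = rec.infer_read_length()
    if rec.is_reverse:
        u, v = L - qe, L - qs
    else:
        u, v = qs, qe
    clip = max((ln for op, ln in (rec.cigartuples or []) if op == 4), default=0)
    seq = rec.query_sequence
    if rec.is_reverse and seq:
        seq = revcomp(seq)  # store in as-sequenced orientation
    return (rec.reference_name, rec.reference_start + 1, rec.reference_end,
            rec.is_reverse, u, v, L, clip, seq)


def _junction_flank(info: tuple, at_read_end: bool) -> tuple[str, int, str]:
    """Reference flank of the block side adjacent to the junction.

    ``at_read_end``: the junction lies at the block's high as-sequenced read
    coordinate. Returns (chrom, pos, strand); strand '+' means the retained
    block runs toward lower reference coordinates away from the junction.
    """
    at_ref_end = at_read_end != info[_REV]
    if at_ref_end:
        return (info[_CHROM], info[_RE], "+")
    return (info[_CHROM], info[_RS], "-")


def _canonical(a, b):
    return (a, b) if a <= b else (b, a)


def extract_evidence(sam_path, cfg: SvConfig | None = None,
                     insert_mean: float | None = None,
                     insert_sd: float | None = None):
    """Isolate split and discordant evidence from a coordinate-sorted SAM.

    Returns (evidence list, read sequences dict keyed by (query_name, end),
    stats dict). Concordant FR pairs within ``discord_sds`` standard
    deviations of the insert mean contribute nothing. Insert statistics are
    estimated from proper pairs (median / scaled MAD) unless given.
    """
    cfg = cfg or SvConfig()
    af = pysam.AlignmentFile(str(sam_path))
    if not af.header.get("SQ"):
        raise ValueError("SAM header lacks @SQ lines")
    so = af.header.get("HD", {}).get("SO")
    if so != "coordinate":
        raise ValueError("input SAM must be coordinate-sorted (HD SO:coordinate)")
    by_read: dict[tuple[str, int], dict] = {}
    tlens = []
    last = (-1, -1)
    for rec in af:
        if rec.is_unmapped or rec.is_secondary:
            continue
        key = (rec.reference_id, rec.reference_start)
        if key < last:
            raise ValueError("input SAM is not coordinate-sorted")
        last = key
        end = 1 if rec.is_read2 else 0
        slot = by_read.setdefault((rec.query_name, end), {"prim": None, "supp": []})
        if rec.is_supplementary:
            slot["supp"].append(_info(rec))
        else:
            slot["prim"] = _info(rec)
            if (rec.is_proper_pair and rec.template_length > 0
                    and not rec.mate_is_unmapped):
                tlens.append(rec.template_length)
    if insert_mean is None:
        if not tlens:
            raise ValueError("cannot estimate insert size: no proper pairs")
        arr = np.asarray(tlens, dtype=float)
        insert_mean = float(np.median(arr))
        insert_sd = float(1.4826 * np.median(np.abs(arr - insert_mean))) or 1.0
    elif insert_sd is None:
        raise ValueError("insert_sd must accompany insert_mean")

    evidence: list[Evidence] = []
    seqs: dict[tuple[str, int], str] = {}
    stats = {"insert_mean": insert_mean, "insert_sd": insert_sd,
             "n_reads": len(by_read), "n_mateless": 0}

    # split evidence: a primary with a long soft clip plus a supplementary
    for (qname, end), slot in sorted(by_read.items()):
        prim = slot["prim"]
        if prim is None or not slot["supp"]:
            continue
        if prim[_CLIP] < cfg.min_clip:
            continue
        for supp in slot["supp"]:
            if supp[_U] >= prim[_U]:  # primary block left of supplementary in read space
                fa = _junction_flank(prim, at_read_end=True)
                fb = _junction_flank(supp, at_read_end=False)
            else:
                fa = _junction_flank(supp, at_read_end=True)
                fb = _junction_flank(prim, at_read_end=False)
            a, b = _canonical(fa, fb)
            evidence.append(Evidence("split", qname, a, b, clip_length=prim[_CLIP]))
            seqs[(qname, end)] = prim[_SEQ]

    # discordant evidence: both mates' 3' ends point toward the junction
    qnames = sorted({q for q, _ in by_read})
    for qname in qnames:
        p1 = by_read.get((qname, 0), {}).get("prim")
        p2 = by_read.get((qname, 1), {}).get("prim")
        if p1 is None or p2 is None:
            stats["n_mateless"] += 1
            continue
        code = None
        if p1[_CHROM] != p2[_CHROM]:
            code = "XCHR"
        else:
            left, right = (p1, p2) if p1[_RS] <= p2[_RS] else (p2, p1)
            if left[_REV] == right[_REV]:
                code = "RR" if left[_REV] else "FF"
            elif left[_REV]:
                code = "RF"
            else:
                tlen = right[_RE] - left[_RS] + 1
                if abs(tlen - insert_mean) > cfg.discord_sds * insert_sd:
                    code = "LONG" if tlen > insert_mean else "SHORT"
        if code is None:
            continue
        fa = _junction_flank(p1, at_read_end=True)
        fb = _junction_flank(p2, at_read_end=True)
        a, b = _canonical(fa, fb)
        evidence.append(Evidence("discordant", qname, a, b, insert_anomaly=code))
        seqs[(qname, 0)] = p1[_SEQ]
        seqs[(qname, 1)] = p2[_SEQ]

    evidence.sort(key=lambda e: (e.locus_a, e.locus_b, e.kind, e.query_name))
    return evidence, seqs, stats


# --------------------------------------------------------------------- cluster


def cluster_evidence(evidence: list[Evidence], radius: int,
                     cfg: SvConfig | None = None) -> list[EvidenceCluster]:
    """Single-linkage clustering on both junction loci jointly.

    Two pieces of evidence link when they share both locus chromosomes and
    side signatures and both positions differ by at most ``radius``. Clusters
    below the support floor (``min_split_support`` splits or
    ``min_discordant_support`` discordants) are discarded. The result is
    independent of input order (clusters sorted by footprint).
    """
    cfg = cfg or SvConfig()
    if radius <= 0:
        raise ValueError("radius must be positive")
    buckets: dict[tuple, list[Evidence]] = {}
    for ev in evidence:
        key = (ev.locus_a[0], ev.locus_a[2], ev.locus_b[0], ev.locus_b[2])
        buckets.setdefault(key, []).append(ev)
    clusters: list[EvidenceCluster] = []
    for key in sorted(buckets):
        evs = sorted(buckets[key], key=lambda e: (e.locus_a[1], e.locus_b[1],
                                                  e.kind, e.query_name))
        parent = list(range(len(evs)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(evs)):
            for j in range(i + 1, len(evs)):
                if evs[j].locus_a[1] - evs[i].locus_a[1] > radius:
                    break
                if abs(evs[j].locus_b[1] - evs[i].locus_b[1]) <= radius:
                    parent[find(i)] = find(j)
        groups: dict[int, list[Evidence]] = {}
        for i, ev in enumerate(evs):
            groups.setdefault(find(i), []).append(ev)
        for g in groups.values():
            n_split = sum(1 for e in g if e.kind == "split")
            n_disc = len(g) - n_split
            if n_split < cfg.min_split_support and n_disc < cfg.min_discordant_support:
                continue
            fa = (key[0], min(e.locus_a[1] for e in g), max(e.locus_a[1] for e in g))
            fb = (key[2], min(e.locus_b[1] for e in g), max(e.locus_b[1] for e in g))
            clusters.append(EvidenceCluster(g, fa, fb, (n_split, n_disc)))
    clusters.sort(key=lambda c: (c.footprint_a, c.footprint_b))
    for i, c in enumerate(clusters):
        c.cluster_id = i
    return clusters


# -------------------------------------------------------------------- assemble


def _best_overlap(a: str, b: str, min_overlap: int, max_mismatch_per_50: int = 0):
    """Longest suffix(a)/prefix(b) overlap length >= min_overlap, else 0."""
    top = min(len(a), len(b))
    if max_mismatch_per_50 == 0:
        # leftmost occurrence of b's seed in a gives the longest exact overlap
        seed = b[:min_overlap]
        i = a.find(seed, len(a) - top)
        while i != -1:
            t = len(a) - i
            if a[i:] == b[:t]:
                return t
            i = a.find(seed, i + 1)
        return 0
    for t in range(top, min_overlap - 1, -1):
        allowed = (t // 50 + 1) * max_mismatch_per_50
        mism = sum(x != y for x, y in zip(a[-t:], b[:t]))
        if mism <= allowed:
            return t
    return 0


def assemble_cluster(cluster: EvidenceCluster, seqs: dict, cfg: SvConfig | None = None) -> Contig:
    """Greedy maximal-exact-overlap assembly of a cluster's member reads.

    Repeatedly merges the pair with the longest exact suffix-prefix overlap
    at least ``min_overlap`` (reads are tried in both orientations; ties are
    broken lexicographically by sequence). In Hamming-tolerant mode one
    mismatch is allowed per 50 bp of overlap. If nothing overlaps, the
    longest single read is returned flagged unassembled.
    """
    cfg = cfg or SvConfig()
    qnames = sorted({m.query_name for m in cluster.members})
    pool: list[str] = []
    members: list[str] = []
    for q in qnames:
        for end in (0, 1):
            s = seqs.get((q, end))
            if s:
                pool.append(s)
                members.append(q)
    if len(pool) > cfg.max_cluster_reads:
        pool = sorted(pool)[: cfg.max_cluster_reads]
    if not pool:
        raise ValueError("cluster has no member read sequences")
    if len(set(pool)) == 1:
        return Contig(pool[0], qnames, cluster.cluster_id, assembled=True)
    # deduplicate, drop strict substrings
    pool = sorted(set(pool), key=lambda s: (-len(s), s))
    kept = []
    for s in pool:
        if not any(s in t or revcomp(s) in t for t in kept):
            kept.append(s)
    pool = sorted(kept)
    mism = 1 if cfg.hamming_tolerant else 0
    merged_any = False
    while len(pool) > 1:
        best = None  # (t, merged_seq, a, b): longest overlap, lexicographic ties
        for a, b in itertools.permutations(pool, 2):
            for bb in (b, revcomp(b)):
                t = _best_overlap(a, bb, cfg.min_overlap, mism)
                if t:
                    cand = a + bb[t:]
                    if best is None or t > best[0] or (t == best[0] and cand < best[1]):
                        best = (t, cand, a, b)
        if best is None:
            break
        merged_any = True
        _, cand, a, b = best
        pool.remove(a)
        pool.remove(b)
        # drop reads now contained in the merged contig
        pool = [s for s in pool if s not in cand and revcomp(s) not in cand]
        pool.append(cand)
        pool.sort()
    contig = max(pool, key=lambda s: (len(s), s))
    return Contig(contig, qnames, cluster.cluster_id,
                  assembled=merged_any or len(pool) == 1)


# ----------------------------------------------------------------------- place


def _scan_anchors(contigs: list[str], genome: dict[str, str], k: int):
    """Hits of every contig k-mer (both strands) in the reference.

    Returns {(contig_idx, strand): [(contig_off, chrom, ref_off0)]}; k-mers
    hitting the reference more than ``max_hits`` times are handled later by
    the caller via the returned per-kmer hit counts.
    """
    index: dict[str, list[tuple[int, int, str]]] = {}
    for ci, seq in enumerate(contigs):
        for off in range(0, len(seq) - k + 1):
            kmer = seq[off: off + k]
            index.setdefault(kmer, []).append((ci, off, "+"))
            index.setdefault(revcomp(kmer), []).append((ci, off, "-"))
    hits: dict[tuple[int, str], list] = {}
    counts: dict[str, int] = {}
    for chrom in sorted(genome):
        s = genome[chrom]
        for p in range(0, len(s) - k + 1):
            kmer = s[p: p + k]
            entries = index.get(kmer)
            if not entries:
                continue
            counts[kmer] = counts.get(kmer, 0) + 1
            for ci, off, strand in entries:
                hits.setdefault((ci, strand), []).append((off, chrom, p, kmer))
    return hits, counts


def place_contigs(contigs: list[Contig], genome: dict[str, str],
                  cfg: SvConfig | None = None) -> list[Placement]:
    """Place each contig as exactly two maximal ungapped reference blocks.

    Anchoring uses exact unique k-mers (k-mers with more than
    ``max_kmer_hits`` genome occurrences are ignored, so contigs lying in
    low-complexity tracts legitimately fail to place); anchors on a shared
    (chrom, strand, diagonal) merge and are extended without gaps. A contig
    qualifies iff exactly two blocks of at least ``min_block_len`` on
    distinct loci cover it (ends may fall short by ``cover_slack``).
    """
    cfg = cfg or SvConfig()
    seqs = [c.sequence for c in contigs]
    for c in contigs:
        if cfg.k > len(c.sequence):
            raise ValueError("k exceeds contig length")
    hits, counts = _scan_anchors(seqs, genome, cfg.k)
    placements = []
    for ci, contig in enumerate(contigs):
        blocks = []
        for strand in "+-":
            by_diag: dict[tuple[str, int], list[tuple[int, int]]] = {}
            for off, chrom, p, kmer in hits.get((ci, strand), []):
                if counts.get(kmer, 0) > cfg.max_kmer_hits:
                    continue
                coff = off if strand == "+" else len(contig.sequence) - cfg.k - off
                # diagonal: ref position minus contig position on the aligned strand
                by_diag.setdefault((chrom, p - coff), []).append((coff, p))
            for (chrom, diag), anchors in by_diag.items():
                anchors.sort()
                cs = anchors[0][0]
                ce = anchors[-1][0] + cfg.k - 1
                blocks.append(_extend_block(contig.sequence, genome[chrom], chrom,
                                            strand, cs, ce, diag, cfg))
        # merge duplicates, drop contained blocks, sort by contig start
        blocks = sorted(set(blocks), key=lambda b: (b[4], -(b[5] - b[4])))
        maximal = []
        for b in blocks:
            if not any(o[4] <= b[4] and b[5] <= o[5] and o is not b for o in maximal):
                maximal.append(b)
        maximal = [b for b in maximal if b[5] - b[4] + 1 >= cfg.min_block_len]
        n = len(maximal)
        if n != 2:
            placements.append(Placement("unplaceable", maximal, n))
            continue
        b1, b2 = maximal
        covered_to = max(b1[5], b2[5])
        starts_at = min(b1[4], b2[4])
        distinct = (b1[0] != b2[0] or b1[3] != b2[3]
                    or abs(b1[1] - b2[1]) > cfg.k)
        slack = cfg.cover_slack if cfg.cover_slack is not None else cfg.k
        if (starts_at > slack + 1
                or covered_to < len(contig.sequence) - slack
                or not distinct):
            placements.append(Placement("unplaceable", maximal, n))
            continue
        placements.append(Placement("placed", maximal, n))
    return placements


def _extend_block(cseq: str, ref: str, chrom: str, strand: str,
                  cs: int, ce: int, diag: int, cfg: SvConfig):
    """Ungapped extension of an anchored run; returns a block tuple.

    Incoming cs/ce are 0-based offsets on the aligned strand ("probe"
    coordinates: the contig itself for '+', its reverse complement for '-');
    ref0 = diag + probe offset. The returned block reports forward contig
    coordinates.
    """
    probe = cseq if strand == "+" else revcomp(cseq)
    while cs > 0 and diag + cs - 1 >= 0 and probe[cs - 1] == ref[diag + cs - 1]:
        cs -= 1
    L = len(probe)
    while ce < L - 1 and diag + ce + 1 < len(ref) and probe[ce + 1] == ref[diag + ce + 1]:
        ce += 1
    ref_s, ref_e = diag + cs, diag + ce
    if strand == "-":
        cs, ce = len(cseq) - 1 - ce, len(cseq) - 1 - cs
    return (chrom, ref_s + 1, ref_e + 1, strand, cs + 1, ce + 1)


def place_contig(contig: Contig, genome: dict[str, str],
                 cfg: SvConfig | None = None) -> Placement:
    return place_contigs([contig], genome, cfg)[0]


# ------------------------------------------------------------------------ call


def call_junction(placement: Placement, cluster: EvidenceCluster,
                  local_indel_max: int = 10_000) -> JunctionCall:
    """Read the junction flanks and delta off a two-block placement.

    Flanks are the last reference-matching base of each block adjacent to
    the junction. Micro-homology at the junction (blocks overlapping in
    contig coordinates) is assigned to the left block. Colinear same-strand
    blocks with modest spacing are classified local-indel and carry the
    full signed delta; other junctions carry locally visible bases only
    (per-site deltas of inversions come from pairing the two junctions).
    """
    if placement.status != "placed":
        raise ValueError("placement is not a two-block placement")
    b1, b2 = sorted(placement.blocks, key=lambda b: b[4])
    chrom1, rs1, re1, s1, cs1, ce1 = b1
    chrom2, rs2, re2, s2, cs2, ce2 = b2
    homology = max(0, ce1 - cs2 + 1)
    inserted = max(0, cs2 - ce1 - 1)
    # flank of block1 at its high-contig end; side '+' = retained <= pos
    fa = (chrom1, re1, "+") if s1 == "+" else (chrom1, rs1, "-")
    # flank of block2 at its low-contig end, shifted past any homology
    if s2 == "+":
        fb = (chrom2, rs2 + homology, "-")
    else:
        fb = (chrom2, re2 - homology, "+")
    kind = "rearrangement"
    delta = 0
    if chrom1 == chrom2 and s1 == s2:
        # colinear gap: order-preserving spacing between the blocks in the
        # direction of traversal (negative = reference re-entry/overlap)
        gap = (fb[1] - fa[1] - 1) if s1 == "+" else (fa[1] - fb[1] - 1)
        if 0 <= gap <= local_indel_max:
            kind = "local-indel"  # plain deletion/insertion, not a rearrangement
            delta = -gap
        elif gap < 0:
            delta = -gap  # tandem-duplication junction: bases on both sides
    return JunctionCall(fa, fb, delta, cluster.support, cluster.cluster_id,
                        kind=kind, inserted=inserted)


def canonicalize_junction(genome: dict[str, str],
                          flank_a: tuple[str, int, str],
                          flank_b: tuple[str, int, str],
                          max_slide: int = 50):
    """Leftmost-in-derivative representation of a junction.

    When the reference base at the a-side flank equals the base the b-side
    would contribute at that derivative position, the breakpoint placement
    is ambiguous (micro-homology): the boundary can slide without changing
    the derivative sequence. Sliding as far left as possible makes flank
    comparison well defined.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    (ca, pa, sa), (cb, pb, sb) = flank_a, flank_b
    for _ in range(max_slide):
        if ca not in genome or cb not in genome:
            break
        # last derivative base contributed by the a side
        if sa == "+":
            if not 1 <= pa <= len(genome[ca]):
                break
            a_base = genome[ca][pa - 1]
        else:
            if not 1 <= pa <= len(genome[ca]):
                break
            a_base = comp.get(genome[ca][pa - 1], "N")
        # base the b side would contribute one derivative position earlier
        if sb == "-":
            if pb - 2 < 0:
                break
            b_base = genome[cb][pb - 2]
        else:
            if pb >= len(genome[cb]):
                break
            b_base = comp.get(genome[cb][pb], "N")
        if a_base != b_base or a_base == "N":
            break
        pa = pa - 1 if sa == "+" else pa + 1
        pb = pb - 1 if sb == "-" else pb + 1
        if pa < 1 or pb < 1:
            break
    return (ca, pa, sa), (cb, pb, sb)


def _site_delta(plus_pos: int, minus_pos: int) -> int:
    """Per-site delta from the two retained flanks meeting at a breakpoint.

    One product retains coordinates <= plus_pos, the other >= minus_pos;
    their overlap (positive: duplicated bases) or the gap strictly between
    them (negative: deleted bases) is ``plus_pos - minus_pos + 1``.
    """
    return plus_pos - minus_pos + 1


def pair_junctions(calls: list[JunctionCall], cfg: SvConfig | None = None) -> list[AberrationCall]:
    """Group junction calls into component aberrations.

    Calls whose flanks lie within ``pair_window`` of one another form a
    group; a group of two with the strand pattern of a single inversion is
    labeled ``inversion`` and per-site deltas are computed from its four
    flanks; larger or inconsistent groups are ``complex``; lone junctions
    are ``complex/unpaired``. Local-indel calls are excluded.
    """
    cfg = cfg or SvConfig()
    calls = [c for c in calls if c.kind != "local-indel"]
    n = len(calls)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def near(f1, f2):
        return f1[0] == f2[0] and abs(f1[1] - f2[1]) <= cfg.pair_window

    for i in range(n):
        for j in range(i + 1, n):
            fi = (calls[i].flank_a, calls[i].flank_b)
            fj = (calls[j].flank_a, calls[j].flank_b)
            if any(near(a, b) for a in fi for b in fj):
                parent[find(i)] = find(j)
    groups: dict[int, list[JunctionCall]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(calls[i])
    out = []
    for g in groups.values():
        g.sort(key=lambda c: c.sorted_flanks())
        if len(g) == 1:
            out.append(AberrationCall("complex/unpaired", g,
                                      sites=[_junction_site(g[0])]))
            continue
        if len(g) == 2:
            inv = _try_inversion(g[0], g[1], cfg)
            if inv is not None:
                out.append(inv)
                continue
        out.append(AberrationCall("complex", g,
                                  sites=[_junction_site(c) for c in g]))
    out.sort(key=lambda a: a.junctions[0].sorted_flanks())
    return out


def _junction_site(c: JunctionCall) -> dict:
    lo, hi = sorted([c.flank_a[1], c.flank_b[1]]) if c.flank_a[0] == c.flank_b[0] \
        else (c.flank_a[1], c.flank_b[1])
    return {"chrom": c.flank_a[0], "chrom_b": c.flank_b[0],
            "proximal": lo, "distal": hi, "delta": c.delta}


def _try_inversion(j1: JunctionCall, j2: JunctionCall, cfg: SvConfig) -> AberrationCall | None:
    """Two junctions forming one inversion.

    An inversion's head junction joins the two breakpoint-left blocks
    (sides +,+), its tail junction the two breakpoint-right blocks (-,-);
    each breakpoint site then pairs one '+' flank with one '-' flank on
    the same chromosome within ``pair_window``.
    """
    sides1 = {j1.flank_a[2], j1.flank_b[2]}
    sides2 = {j2.flank_a[2], j2.flank_b[2]}
    if not ((sides1 == {"+"} and sides2 == {"-"})
            or (sides1 == {"-"} and sides2 == {"+"})):
        return None
    head, tail = (j1, j2) if sides1 == {"+"} else (j2, j1)
    plus = sorted([head.flank_a, head.flank_b])
    minus = sorted([tail.flank_a, tail.flank_b])
    # match each '+' flank with the '-' flank at the same breakpoint site
    pairings = [(plus[0], minus[0], plus[1], minus[1]),
                (plus[0], minus[1], plus[1], minus[0])]
    for pa, ma, pb, mb in pairings:
        ok = (pa[0] == ma[0] and pb[0] == mb[0]
              and abs(pa[1] - ma[1]) <= cfg.pair_window
              and abs(pb[1] - mb[1]) <= cfg.pair_window)
        if not ok:
            continue
        site_a = {"chrom": pa[0], "proximal": min(pa[1], ma[1]),
                  "distal": max(pa[1], ma[1]), "delta": _site_delta(pa[1], ma[1])}
        site_b = {"chrom": pb[0], "proximal": min(pb[1], mb[1]),
                  "distal": max(pb[1], mb[1]), "delta": _site_delta(pb[1], mb[1])}
        sites = sorted([site_a, site_b], key=lambda s: (s["chrom"], s["proximal"]))
        sites[0]["site"], sites[1]["site"] = "head", "tail"
        return AberrationCall("inversion", [head, tail], sites=sites)
    return None


# -------------------------------------------------------------------- identify


def _site_matches(called: dict, cat_site, tol: int) -> bool:
    if called.get("chrom_b", called["chrom"]) != called["chrom"]:
        return False
    if called["chrom"] != cat_site.chrom:
        return False
    got = sorted([called["proximal"], called["distal"]])
    want = sorted([cat_site.proximal, cat_site.distal])
    return abs(got[0] - want[0]) <= tol and abs(got[1] - want[1]) <= tol


def identify_balancer(aberrations: list[AberrationCall], catalog: BalancerCatalog,
                      tol: int = 100) -> str:
    """Fingerprint the balancer identity from called aberrations.

    A catalog aberration is matched when each of its coordinate-known sites
    matches some called site within ``tol``. The result is the balancer all
    of whose matchable aberrations are matched, preferring the one matching
    the most; ties or no full match give "unknown".
    """
    called_sites = [s for ab in aberrations for s in ab.sites]
    matched = set()
    for ab_name in catalog.sites:
        known = catalog.matchable_sites(ab_name)
        if not known:
            continue
        if all(any(_site_matches(cs, ks, tol) for cs in called_sites) for ks in known):
            matched.add(ab_name)
    full = []
    for balancer, reqs in catalog.balancers.items():
        req_known = [a for a in reqs if catalog.matchable_sites(a)]
        if req_known and all(a in matched for a in req_known):
            full.append((len(req_known), balancer))
    if not full:
        return "unknown"
    full.sort(reverse=True)
    if len(full) > 1 and full[0][0] == full[1][0]:
        return "unknown"
    return full[0][1]


# ---------------------------------------------------------------------- driver


def masked_fraction(footprint: tuple[str, int, int],
                    mask: list[tuple[str, int, int]]) -> float:
    chrom, lo, hi = footprint
    if hi < lo:
        lo, hi = hi, lo
    span = hi - lo + 1
    cov = 0
    for mc, ms, me in mask:
        if mc == chrom:
            cov += max(0, min(hi, me) - max(lo, ms) + 1)
    return min(1.0, cov / span)


@dataclass
class SvScanResult:
    calls: list[JunctionCall]
    aberrations: list[AberrationCall]
    ambiguous: list[JunctionCall]
    local_indels: list[JunctionCall]
    unplaced: list[int]  # cluster ids
    stats: dict


def scan_sam(sam_path, genome: dict[str, str], cfg: SvConfig | None = None,
             mask: list[tuple[str, int, int]] | None = None) -> SvScanResult:
    """End-to-end junction calling on one coordinate-sorted SAM."""
    cfg = cfg or SvConfig()
    evidence, seqs, stats = extract_evidence(sam_path, cfg)
    clusters = cluster_evidence(evidence, cfg.cluster_radius, cfg)
    contigs = [assemble_cluster(c, seqs, cfg) for c in clusters]
    usable = [(cl, co) for cl, co in zip(clusters, contigs)
              if len(co.sequence) >= cfg.k]
    placements = place_contigs([co for _, co in usable], genome, cfg)
    calls, ambiguous, local_indels, unplaced = [], [], [], []
    for (cl, co), pl in zip(usable, placements):
        if pl.status != "placed":
            unplaced.append(cl.cluster_id)
            continue
        call = call_junction(pl, cl)
        call.flank_a, call.flank_b = canonicalize_junction(
            genome, call.flank_a, call.flank_b)
        if mask:
            mfa = masked_fraction(cl.footprint_a, mask)
            mfb = masked_fraction(cl.footprint_b, mask)
            call.masked_fraction = max(mfa, mfb)
        if call.kind == "local-indel":
            local_indels.append(call)
        elif call.masked_fraction > cfg.masked_fraction_max:
            ambiguous.append(call)
        else:
            calls.append(call)
    # deduplicate calls with identical flanks (several clusters, one junction)
    seen: dict = {}
    for c in calls:
        key = (c.sorted_flanks(),)
        if key in seen:
            old = seen[key]
            seen[key] = max(old, c, key=lambda x: x.support)
        else:
            seen[key] = c
    calls = sorted(seen.values(), key=lambda c: c.sorted_flanks())
    aberrations = pair_junctions(calls, cfg)
    stats.update({"n_evidence": len(evidence), "n_clusters": len(clusters),
                  "n_calls": len(calls), "n_unplaced": len(unplaced)})
    return SvScanResult(calls, aberrations, ambiguous, local_indels, unplaced, stats)
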