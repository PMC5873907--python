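"""Analytic paired-end read simulation for a balancer/reference heterozygote.

Fragments are drawn uniformly along each haplotype of a simulated diploid —
the reference haplotype and a derivative (balancer) haplotype defined by a
:class:`~balancerscan.forge.segmap.SegmentMap`. Alignments are *projected*
through the segment map rather than searched: a read crossing a junction is
emitted as a primary plus supplementary record with complementary soft
clips, and a pair straddling a junction inherits whatever orientation or
insert anomaly the lift-over implies. Output is coordinate-sorted SAM.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

from .reference import ReferenceGenome
from .segmap import SegmentMap, revcomp

MIN_SUPPLEMENTARY = 20  # bp of aligned block required to emit a record


@dataclass
class SimConfig:
    read_length: int = 150
    insert_mean: float = 400.0
    insert_sd: float = 40.0
    depth: float = 30.0
    error_rate: float = 0.001
    seed: int = 0
    haplotype_fraction: float = 0.5

    def __post_init__(self):
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if not 0.0 <= self.haplotype_fraction <= 1.0:
            raise ValueError("haplotype_fraction must lie in [0, 1]")
        if self.error_rate < 0 or self.error_rate > 0.2:
            raise ValueError("error_rate outside sane range")
        if self.insert_mean < 2 * self.read_length:
            raise ValueError("insert_mean should be at least twice the read length")


class _Molecule:
    """One haplotype molecule: a sequence plus a projector to reference blocks."""

    def __init__(self, name: str, seq: str, segmap: SegmentMap | None,
                 chrom: str | None = None):
        self.name = name
        self.seq = seq
        self.segmap = segmap
        self.chrom = chrom  # set for plain reference molecules

    def __len__(self):
        return len(self.seq)

    def project(self, start: int, end: int) -> list[tuple[str, int, int, str, int]]:
        """Alignment blocks for molecule interval [start, end] (1-based incl.).

        Returns (chrom, ref_start, ref_end, strand, molecule_offset) per
        maximal within-segment run; spacer runs get chrom None.
        """
        if self.segmap is None:
            return [(self.chrom, start, end, "+", 0)]
        blocks = []
        segs, _ = self.segmap._slice(start, end)
        off = 0
        for seg in segs:
            chrom = None if seg.is_spacer else seg.chrom
            blocks.append((chrom, seg.start, seg.end, seg.strand, off))
            off += seg.length
        return blocks


def _apply_snvs(seq: str, segmap: SegmentMap, variants) -> str:
    """Substitute planted SNV alt alleles into a derivative sequence."""
    if variants is None:
        return seq
    arr = bytearray(seq, "ascii")
    for v in variants.variants:
        if v.var_class != "snp":
            continue  # indels are represented in the VCF panel only
        for dpos, strand in segmap.invert_coordinate(v.chrom, v.pos):
            alt = v.alt if strand == "+" else revcomp(v.alt)
            arr[dpos - 1] = ord(alt)
    return arr.decode()


def simulate_alignments(ref: ReferenceGenome, balancer: SegmentMap, cfg: SimConfig,
                        out_sam: str | Path, variants=None,
                        max_resample: int = 50) -> dict:
    """Simulate a heterozygote's paired-end WGS and write coordinate-sorted SAM.

    Returns a small summary dict (fragment counts per haplotype).
    """
    rng = np.random.default_rng(cfg.seed)
    rl = cfg.read_length

    mapped_chroms = {s.chrom for s in balancer.segments if not s.is_spacer}
    deriv_seq = _apply_snvs(balancer.build_sequence(ref.chromosomes), balancer, variants)
    balancer_molecules = [_Molecule(balancer.derivative_name, deriv_seq, balancer)]
    for c in sorted(ref.chromosomes):
        if c not in mapped_chroms:
            balancer_molecules.append(_Molecule(c, ref.chromosomes[c], None, c))
    ref_molecules = [_Molecule(c, ref.chromosomes[c], None, c)
                     for c in sorted(ref.chromosomes)]

    genome_len = sum(ref.lengths.values())
    n_frags = int(round(cfg.depth * genome_len / (2 * rl)))
    # haplotype_fraction is the molar ratio of the two haplotypes; a fragment
    # is drawn from a haplotype in proportion to fraction x molecule length,
    # so equal molarity gives equal per-bp coverage and one extra copy of a
    # segment yields the 3:2 depth signature regardless of derivative length
    bal_len = sum(len(m) for m in balancer_molecules)
    ref_len = sum(len(m) for m in ref_molecules)
    w_bal = cfg.haplotype_fraction * bal_len
    w_ref = (1.0 - cfg.haplotype_fraction) * ref_len
    p_bal = w_bal / (w_bal + w_ref) if (w_bal + w_ref) > 0 else 0.0
    hap_is_balancer = rng.random(n_frags) < p_bal
    inserts = rng.normal(cfg.insert_mean, cfg.insert_sd, size=n_frags)
    inserts = np.maximum(inserts.round().astype(int), 2 * rl)

    chrom_names = sorted(ref.chromosomes)
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": ref.lengths[c]} for c in chrom_names],
        "PG": [{"ID": "balancerscan-forge", "PN": "balancerscan",
                "CL": f"seed={cfg.seed}"}],
    })
    tid = {c: i for i, c in enumerate(chrom_names)}

    records = []  # (sort_tid, sort_pos, serial, AlignedSegment)
    serial = 0
    summary = {"n_fragments": 0, "balancer_fragments": 0, "reference_fragments": 0,
               "skipped_fragments": 0}

    bal_cum = np.cumsum([len(m) for m in balancer_molecules]).astype(float)
    ref_cum = np.cumsum([len(m) for m in ref_molecules]).astype(float)

    for fi in range(n_frags):
        if hap_is_balancer[fi]:
            molecules, cum = balancer_molecules, bal_cum
        else:
            molecules, cum = ref_molecules, ref_cum
        insert = int(inserts[fi])
        mol = None
        for _ in range(max_resample):
            m = molecules[int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))] \
                if len(molecules) > 1 else molecules[0]
            if insert <= len(m):
                mol = m
                break
            insert = int(max(2 * rl, round(rng.normal(cfg.insert_mean, cfg.insert_sd))))
        if mol is None:
            summary["skipped_fragments"] += 1
            continue
        start = int(rng.integers(1, len(mol) - insert + 2))
        qname = f"frag{fi:08d}"
        r1 = _make_read(mol, start, start + rl - 1, False, rng, cfg)
        r2 = _make_read(mol, start + insert - rl, start + insert - 1, True, rng, cfg)
        recs = _records_for_pair(qname, r1, r2, header, tid)
        if recs is None:
            summary["skipped_fragments"] += 1
            continue
        for sort_key, seg in recs:
            records.append((sort_key[0], sort_key[1], serial, seg.to_string()))
            serial += 1
        summary["n_fragments"] += 1
        if hap_is_balancer[fi]:
            summary["balancer_fragments"] += 1
        else:
            summary["reference_fragments"] += 1

    records.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(out_sam, "w") as fh:
        fh.write(str(header))
        for _, _, _, line in records:
            fh.write(line + "\n")
    return summary


def _make_read(mol: _Molecule, mstart: int, mend: int, is_read2: bool,
               rng: np.random.Generator, cfg: SimConfig) -> dict:
    """Sequence + alignment runs for one read of a fragment.

    Runs are kept in read coordinates: (read_u, read_v, chrom, ref_start,
    ref_end, align_strand) with read_u/read_v 0-based half-open positions in
    the read as sequenced.
    """
    rl = cfg.read_length
    seq = mol.seq[mstart - 1: mend]
    blocks = mol.project(mstart, mend)
    if is_read2:
        seq = revcomp(seq)
    if cfg.error_rate > 0:
        n_err = rng.binomial(rl, cfg.error_rate)
        if n_err:
            arr = bytearray(seq, "ascii")
            for p in rng.integers(0, rl, size=n_err):
                cur = chr(arr[p])
                arr[p] = ord(str(rng.choice([b for b in "ACGT" if b != cur])))
            seq = arr.decode()
    runs = []
    for chrom, rs, re_, strand, off in blocks:
        blen = re_ - rs + 1
        u, v = off, off + blen  # molecule-forward read coords
        if is_read2:  # read coordinates are flipped relative to the molecule
            u, v = rl - v, rl - u
            strand = "-" if strand == "+" else "+"
        if chrom is not None:
            runs.append((u, v, chrom, rs, re_, strand))
    return {"seq": seq, "runs": sorted(runs), "is_read2": is_read2}


def _records_for_pair(qname: str, r1: dict, r2: dict, header, tid: dict):
    prim = []
    for r in (r1, r2):
        usable = [run for run in r["runs"] if run[1] - run[0] >= MIN_SUPPLEMENTARY]
        r["usable"] = usable
        prim.append(max(usable, key=lambda run: run[1] - run[0]) if usable else None)
    if prim[0] is None and prim[1] is None:
        return None  # both mates fall in spacer / unanchorable sequence
    out = []
    mate_info = []
    for r, p in zip((r1, r2), prim):
        if p is None:
            mate_info.append(None)
        else:
            u, v, chrom, rs, re_, strand = p
            mate_info.append((chrom, rs, strand, re_))
    for idx, (r, p) in enumerate(zip((r1, r2), prim)):
        other = mate_info[1 - idx]
        if p is None:
            # unmapped mate placed at its partner's coordinates
            oc, opos, *_ = other
            seg = pysam.AlignedSegment(header)
            seg.query_name = qname
            seg.query_sequence = r["seq"]
            seg.flag = (1 | 4 | (64 if idx == 0 else 128)
                        | (32 if other[2] == "-" else 0))
            seg.reference_id = tid[oc]
            seg.reference_start = opos - 1
            seg.next_reference_id = tid[oc]
            seg.next_reference_start = opos - 1
            out.append(((tid[oc], opos - 1), seg))
            continue
        for run in r["usable"]:
            is_supp = run is not p
            out.append(_one_record(qname, r, run, idx, other, header, tid, is_supp,
                                   mate_unmapped=other is None, primary=p))
    return out


def _one_record(qname, r, run, idx, other, header, tid, is_supp, mate_unmapped, primary):
    u, v, chrom, rs, re_, strand = run
    rl = len(r["seq"])
    seg = pysam.AlignedSegment(header)
    seg.query_name = qname
    flag = 1 | (64 if idx == 0 else 128)
    if strand == "-":
        flag |= 16
    if is_supp:
        flag |= 2048
    if mate_unmapped:
        flag |= 8
    elif other[2] == "-":
        flag |= 32
    if strand == "+":
        left, right, seq = u, rl - v, r["seq"]
    else:
        left, right, seq = rl - v, u, revcomp(r["seq"])
    cigar = (f"{left}S" if left else "") + f"{v - u}M" + (f"{right}S" if right else "")
    seg.flag = flag
    seg.reference_id = tid[chrom]
    seg.reference_start = rs - 1
    seg.cigarstring = cigar
    seg.query_sequence = seq
    if mate_unmapped:
        seg.next_reference_id = tid[chrom]
        seg.next_reference_start = rs - 1
    else:
        oc, opos, ostrand, oend = other
        seg.next_reference_id = tid[oc]
        seg.next_reference_start = opos - 1
        if not is_supp and oc == chrom:
            pu, pv, pchrom, prs, pre, pstrand = primary
            left = min(prs, opos)
            right = max(pre, oend)
            tlen = right - left + 1
            seg.template_length = tlen if prs <= opos else -tlen
            if pstrand != ostrand and tlen < 10 * rl:
                fwd_start = prs if pstrand == "+" else opos
                rev_start = opos if pstrand == "+" else prs
                if fwd_start <= rev_start:
                    seg.flag |= 2
    return ((tid[chrom], rs - 1), seg)
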