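"""Variant planting along a stock lineage tree, and crossover tracts.

Stocks descended from a common balancer isolate accumulate de novo SNP and
indel polymorphisms along each branch of their lineage: variants arising on
an ancestral branch are shared by every descendant stock, variants on a leaf
branch are stock-unique. Crossovers with a homolog replace a tract of one
stock's variants with the donor's — a terminal tract for a single crossover
(SCO), an interior tract for a double crossover (DCO).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .reference import ReferenceGenome

# QUAL draws span the quality threshold used for panel filtering (>220)
QUAL_LOW, QUAL_HIGH = 150.0, 320.0
SNP_FRACTION = 0.9  # remaining split between short insertions and deletions


@dataclass(frozen=True)
class Variant:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    var_class: str  # snp | ins | del
    lineage_label: str
    quality: float

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class VariantSet:
    stock: str
    variants: list[Variant] = field(default_factory=list)

    def __post_init__(self):
        self.variants.sort(key=lambda v: (v.chrom, v.pos))
        last: dict[str, int] = {}
        for v in self.variants:
            if v.pos <= last.get(v.chrom, 0):
                raise ValueError(f"{self.stock}: positions not strictly increasing "
                                 f"at {v.chrom}:{v.pos}")
            last[v.chrom] = v.pos
            if v.quality < 0:
                raise ValueError("negative quality score")

    def __len__(self):
        return len(self.variants)

    def by_label(self, label: str) -> list[Variant]:
        return [v for v in self.variants if v.lineage_label == label]

    def write_vcf(self, path, contig_lengths: dict[str, int], sample: str | None = None,
                  seed: int | None = None) -> None:
        """Write a VCF v4.2 file with heterozygous genotype calls.

        Balancer stocks are sequenced over the reference strain, so every
        balancer-haplotype variant is called heterozygous (0/1).
        """
        sample = sample or self.stock
        lines = ["##fileformat=VCFv4.2",
                 "##source=balancerscan-forge"]
        if seed is not None:
            lines.append(f"##balancerscan_seed={seed}")
        for c in sorted(contig_lengths):
            lines.append(f"##contig=<ID={c},length={contig_lengths[c]}>")
        lines.append('##INFO=<ID=VC,Number=1,Type=String,Description="Variant class">')
        lines.append('##INFO=<ID=LIN,Number=1,Type=String,Description="Lineage branch label">')
        lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
        lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample)
        for v in self.variants:
            lines.append("\t".join([
                v.chrom, str(v.pos), ".", v.ref, v.alt, f"{v.quality:.1f}", "PASS",
                f"VC={v.var_class};LIN={v.lineage_label}", "GT", "0/1",
            ]))
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def _tree_paths(lineage_tree: dict[str, str | None]) -> dict[str, list[str]]:
    """Root-to-node branch path for every node; validates acyclicity."""
    paths = {}
    for node in lineage_tree:
        path, seen, cur = [], set(), node
        while cur is not None:
            if cur in seen:
                raise ValueError(f"lineage tree has a cycle through {cur!r}")
            seen.add(cur)
            path.append(cur)
            cur = lineage_tree.get(cur)
        paths[node] = list(reversed(path))
    return paths


def plant_variants(genome: ReferenceGenome, lineage_tree: dict[str, str | None],
                   rates: dict[str, float], seed: int,
                   stocks: list[str] | None = None) -> dict[str, VariantSet]:
    """Draw per-branch variants and propagate them to descendant stocks.

    Parameters
    ----------
    lineage_tree
        child -> parent mapping (parent None for the root branch). Every key
        names a branch; variants drawn on a branch appear in all stocks whose
        root path includes it.
    rates
        per-branch, per-bp variant rate.
    stocks
        The stock (leaf) names to emit VariantSets for; defaults to nodes
        that are nobody's parent.
    """
    if any(r < 0 for r in rates.values()):
        raise ValueError("rates must be non-negative")
    paths = _tree_paths(lineage_tree)
    if stocks is None:
        parents = {p for p in lineage_tree.values() if p is not None}
        stocks = [n for n in lineage_tree if n not in parents]
    rng = np.random.default_rng(seed)
    genome_positions = [(c, len(s)) for c, s in sorted(genome.chromosomes.items())]
    total_len = sum(l for _, l in genome_positions)
    taken: set[tuple[str, int]] = set()
    branch_variants: dict[str, list[Variant]] = {}
    for branch in sorted(lineage_tree):
        rate = rates.get(branch, 0.0)
        n = rng.poisson(rate * total_len)
        out: list[Variant] = []
        attempts = 0
        while len(out) < n and attempts < 10 * n + 100:
            attempts += 1
            gpos = int(rng.integers(0, total_len))
            for chrom, L in genome_positions:
                if gpos < L:
                    break
                gpos -= L
            pos = gpos + 1
            if (chrom, pos) in taken or pos >= L:  # keep room for indel ref base
                continue
            taken.add((chrom, pos))
            ref_base = genome.chromosomes[chrom][pos - 1]
            if ref_base == "N":
                continue
            u = rng.random()
            qual = float(rng.uniform(QUAL_LOW, QUAL_HIGH))
            if u < SNP_FRACTION:
                alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
                out.append(Variant(chrom, pos, ref_base, alt, "snp", branch, qual))
            elif u < SNP_FRACTION + (1 - SNP_FRACTION) / 2:
                ins = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 6))))
                out.append(Variant(chrom, pos, ref_base, ref_base + ins, "ins", branch, qual))
            else:
                dlen = int(rng.integers(1, 6))
                ref_all = genome.chromosomes[chrom][pos - 1: pos - 1 + dlen + 1]
                if len(ref_all) < dlen + 1 or "N" in ref_all:
                    continue
                out.append(Variant(chrom, pos, ref_all, ref_base, "del", branch, qual))
        branch_variants[branch] = out
    result = {}
    for stock in stocks:
        vs = [v for br in paths[stock] for v in branch_variants.get(br, [])]
        result[stock] = VariantSet(stock, vs)
    return result


@dataclass(frozen=True)
class CrossoverTract:
    stock: str
    chrom: str
    start: int
    end: int
    kind: str  # SCO | DCO


def plant_crossover(recipient: VariantSet, donor: VariantSet, chrom: str,
                    breakpoints: list[int], chrom_length: int) -> tuple[VariantSet, CrossoverTract]:
    """Replace the recipient's variants in an exchanged tract with the donor's.

    One breakpoint gives an SCO whose tract runs to the distal chromosome
    end; two breakpoints give an interior DCO tract. Returns the modified
    VariantSet and the ground-truth tract.
    """
    if not breakpoints or len(breakpoints) > 2:
        raise ValueError("provide one (SCO) or two (DCO) breakpoints")
    if any(not (1 <= b <= chrom_length) for b in breakpoints):
        raise ValueError("breakpoint outside chromosome")
    if len(breakpoints) == 1:
        start, end, kind = breakpoints[0], chrom_length, "SCO"
    else:
        start, end = sorted(breakpoints)
        kind = "DCO"

    empty = len(breakpoints) == 2 and breakpoints[0] == breakpoints[1]

    def inside(v: Variant) -> bool:
        return (not empty) and v.chrom == chrom and start <= v.pos <= end

    kept = [v for v in recipient.variants if not inside(v)]
    moved = [replace(v, lineage_label=f"xo:{donor.stock}") for v in donor.variants if inside(v)]
    tract = CrossoverTract(recipient.stock, chrom, start, end, kind)
    return VariantSet(recipient.stock, kept + moved), tract
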