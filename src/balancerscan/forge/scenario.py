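"""Packaged synthetic study: a miniature second-chromosome balancer panel.

``build_mini_world`` forges a scaled-down analog of the published balancer
panel on one synthetic chromosome: four balancer types sharing a common
inversion, distinguished by type-specific inversions, one of them carrying
a mirror-image double-duplication rearrangement whose duplicated unit spans
an existing inversion junction (so the two duplicated segments lie far
apart on the reference, as in the real chromosome). Stocks descend from a
lineage tree with planted single- and double-crossover tracts donated by
unrelated wild chromosomes.

Everything is deterministic in one seed; ground truth (junctions, gains,
tracts, identities) is returned and written to a JSON manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..catalog import BalancerCatalog, BreakpointSite
from .reads import SimConfig, simulate_alignments
from .reference import ReferenceGenome, forge_reference
from .segmap import SegmentMap
from .variants import CrossoverTract, VariantSet, plant_crossover, plant_variants

CHROM = "chr1"

# inversion marks as fractions of the chromosome, with junction deltas
INVERSIONS = {
    "invA": (0.10, 0.22, 280, -153),   # shared by every balancer type
    "invB": (0.30, 0.40, -4, -12),
    "invC": (0.46, 0.56, -7, -10),
    "invD": (0.62, 0.68, 4, 2),
}
# complex duplication marks (requires invA): ref edges of the I/A boundary,
# the I outer edge, and the far end of the B piece
COMPLEX_MARKS = {"pA": 0.115, "pI": 0.16, "pB": 0.25}
SPACER_LEN = 3_000

BALANCERS = {
    "SM1m": ["invA", "invB"],
    "SM5m": ["invA", "invB", "invD", "cplx"],
    "SM6am": ["invA", "invB", "invC"],
    "CyOm": ["invA", "invC"],
}

STOCKS = {  # stock -> true balancer type
    "st223": "SM5m", "st240": "SM5m", "st504": "CyOm", "st31": "CyOm",
}
STOCK_LABELS = {  # declared genotype labels; st31 is deliberately mislabeled
    "st223": "SM5m", "st240": "SM5m", "st504": "CyOm", "st31": "SM5m",
}
LINEAGE = {
    "anc": None,
    "sm5_anc": "anc", "cyo_anc": "anc",
    "st223": "sm5_anc", "st240": "sm5_anc",
    "st504": "cyo_anc", "st31": "cyo_anc",
    "wild1": None, "wild2": None,
}
RATES = {
    "anc": 1e-3,        # polymorphisms shared by the whole panel
    "sm5_anc": 2e-4, "cyo_anc": 2e-4,   # type-specific divergence
    "st223": 5e-6, "st240": 5e-6, "st504": 5e-6, "st31": 5e-6,
    # wild donor chromosomes: standing natural variation is far denser than
    # de novo accumulation in stock (fly autosomes diverge at several per kb)
    "wild1": 1e-3, "wild2": 1e-3,
}
# crossovers: stock -> (kind, fractional breakpoints, donor)
CROSSOVERS = {
    "st240": ("DCO", (0.24, 0.285), "wild1"),
    "st504": ("SCO", (0.94,), "wild2"),
}


@dataclass
class MiniWorld:
    genome: ReferenceGenome
    maps: dict[str, SegmentMap]
    catalog: BalancerCatalog
    stock_types: dict[str, str]
    variant_sets: dict[str, VariantSet]
    tracts: list[CrossoverTract]
    gains: list[tuple[str, int, int]]  # expected 1.5x extents on SM5m (1-based)
    seed: int
    length: int
    manifest: dict = field(default_factory=dict)


def _dpos(m: SegmentMap, ref_pos: int, strand: str | None = None) -> int:
    hits = m.invert_coordinate(CHROM, ref_pos)
    if strand is not None:
        hits = [h for h in hits if h[1] == strand]
    if len(hits) != 1:
        raise RuntimeError(f"expected unique derivative preimage for {ref_pos}")
    return hits[0][0]


def _build_map(name: str, aberrations: list[str], length: int) -> SegmentMap:
    m = SegmentMap.identity(CHROM, length, name)
    for ab in aberrations:
        if ab == "cplx":
            continue
        f1, f2, dl, dr = INVERSIONS[ab]
        L = _dpos(m, int(f1 * length))
        R = _dpos(m, int(f2 * length))
        m = m.apply_inversion(L, R, dl, dr)
        m.derivative_name = name
    if "cplx" in aberrations:
        f1, f2, dl, dr = INVERSIONS["invA"]
        core_min = int(f1 * length) - dl + 1
        pA = int(COMPLEX_MARKS["pA"] * length)
        pI = int(COMPLEX_MARKS["pI"] * length)
        pB = int(COMPLEX_MARKS["pB"] * length)
        i1, i2 = _dpos(m, pI, "-"), _dpos(m, pA + 1, "-")
        a1, a2 = _dpos(m, pA, "-"), _dpos(m, core_min, "-")
        b1, b2 = _dpos(m, int(f2 * length), "+"), _dpos(m, pB, "+")
        rng = np.random.default_rng(int(hashlib.sha256(name.encode()).hexdigest(), 16)
                                    % (2 ** 31))
        spacer = "".join(rng.choice(["A", "T"], size=SPACER_LEN))
        m = m.apply_complex_duplication((a1, a2), (b1, b2), (i1, i2), spacer)
        m.derivative_name = name
    return m


def _mini_catalog(length: int) -> BalancerCatalog:
    """Catalog of the planted aberrations, sites in reference coordinates."""
    sites: dict[str, list[BreakpointSite]] = {}
    for ab in INVERSIONS:
        single = _build_map(ab, [ab], length)
        juncs = [j for j in single.junctions() if not j["spacer"]]
        j_plus = next(j for j in juncs if j["flank_a"][2] == "+")
        j_minus = next(j for j in juncs if j["flank_a"][2] == "-")
        plus = sorted([j_plus["flank_a"][1], j_plus["flank_b"][1]])
        minus = sorted([j_minus["flank_a"][1], j_minus["flank_b"][1]])
        head = sorted([plus[0], minus[0]])
        tail = sorted([plus[1], minus[1]])
        sites[ab] = [
            BreakpointSite(ab, f"{ab}-head", "head", CHROM, head[0], head[1], None),
            BreakpointSite(ab, f"{ab}-tail", "tail", CHROM, tail[0], tail[1], None),
        ]
    cplx_map = _build_map("cplx", ["invA", "cplx"], length)
    inva = {tuple(sorted((j["flank_a"][1], j["flank_b"][1])))
            for j in _build_map("invA", ["invA"], length).junctions()}
    rows = []
    for j in cplx_map.junctions():
        if j["spacer"]:
            continue
        pair = tuple(sorted((j["flank_a"][1], j["flank_b"][1])))
        if pair in inva:
            continue
        rows.append(BreakpointSite("cplx", f"cplx-{len(rows)}", "tail", CHROM,
                                   pair[0], pair[1], None))
    sites["cplx"] = rows
    return BalancerCatalog({b: sorted(a) for b, a in BALANCERS.items()}, sites)


def build_mini_world(length: int = 5_000_000, seed: int = 0,
                     gene_density: float = 40.0, with_aberrations: bool = True,
                     rate_scale: float = 1.0) -> MiniWorld:
    """Forge the mini balancer panel; deterministic in (length, seed).

    ``with_aberrations=False`` makes every balancer an identity chromosome
    and ``rate_scale=0`` silences variant planting (the null panel).
    """
    ab_flanks = _planted_flanks(length)
    genome = None
    for salt in range(20):  # re-draw until no mask sits near a planted flank
        g = forge_reference(1, [length], gene_density, seed=seed * 1000 + salt,
                            chrom_prefix="chr")
        if not _mask_near_flanks(g, ab_flanks, pad=1_000):
            genome = g
            break
    if genome is None:
        raise RuntimeError("could not place masked tracts clear of planted flanks")
    if with_aberrations:
        maps = {b: _build_map(b, abs_, length) for b, abs_ in BALANCERS.items()}
    else:
        maps = {b: SegmentMap.identity(CHROM, length, b) for b in BALANCERS}
    catalog = _mini_catalog(length)
    rates = {k: v * rate_scale for k, v in RATES.items()}
    variant_sets = plant_variants(genome, LINEAGE, rates, seed=seed + 17,
                                  stocks=list(STOCKS) + ["wild1", "wild2"])
    tracts = []
    if rate_scale > 0:
        for stock, (kind, fracs, donor) in CROSSOVERS.items():
            bps = [int(f * length) for f in fracs]
            vs, tract = plant_crossover(variant_sets[stock], variant_sets[donor],
                                        CHROM, bps, length)
            variant_sets[stock] = vs
            tracts.append(tract)
    f1, f2, dl, _ = INVERSIONS["invA"]
    gains = [
        (CHROM, int(f1 * length) - dl + 1, int(COMPLEX_MARKS["pA"] * length)),
        (CHROM, int(f2 * length), int(COMPLEX_MARKS["pB"] * length)),
    ]
    world = MiniWorld(genome, maps, catalog, dict(STOCKS), variant_sets, tracts,
                      gains, seed, length)
    world.manifest = {
        "seed": seed, "length": length,
        "stocks": dict(STOCKS),
        "balancers": {b: abs_ for b, abs_ in BALANCERS.items()},
        "junctions": {b: _canonical_junctions(genome, m) for b, m in maps.items()},
        "gains": [list(g) for g in gains],
        "tracts": [{"stock": t.stock, "chrom": t.chrom, "start": t.start,
                    "end": t.end, "kind": t.kind} for t in tracts],
    }
    return world


def _canonical_junctions(genome: ReferenceGenome, m: SegmentMap) -> list[dict]:
    """Manifest junction rows in the canonical (leftmost) representation."""
    from ..svscan import canonicalize_junction

    rows = []
    for j in m.junctions():
        fa, fb = j["flank_a"], j["flank_b"]
        if not j["spacer"]:
            fa, fb = canonicalize_junction(genome.chromosomes, fa, fb)
        rows.append({"flank_a": list(fa), "flank_b": list(fb),
                     "delta": j["delta"], "spacer": j["spacer"]})
    return rows


def _planted_flanks(length: int) -> list[int]:
    flanks = []
    for f1, f2, dl, dr in INVERSIONS.values():
        flanks += [int(f1 * length), int(f1 * length) - dl,
                   int(f2 * length), int(f2 * length) + dr]
    for f in COMPLEX_MARKS.values():
        flanks.append(int(f * length))
    return flanks


def _mask_near_flanks(genome: ReferenceGenome, flanks: list[int], pad: int) -> bool:
    for chrom, s, e in genome.masked_intervals:
        for f in flanks:
            if s - pad <= f <= e + pad:
                return True
    return False


def write_world(world: MiniWorld, outdir: str | Path,
                sim: SimConfig | None = None,
                sam_stocks: list[str] | None = None) -> dict:
    """Write all forge outputs; returns a dict of paths.

    ``sam_stocks`` limits read simulation to the named stocks (simulating
    every stock's WGS is the expensive part).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    world.genome.write_fasta(out / "reference.fa")
    world.genome.write_gff3(out / "annotation.gff3")
    world.genome.write_mask_bed(out / "mask.bed")
    world.catalog.to_tsv(out / "catalog.tsv")
    paths.update(reference=out / "reference.fa", annotation=out / "annotation.gff3",
                 mask=out / "mask.bed", catalog=out / "catalog.tsv")
    lengths = world.genome.lengths
    vdir = out / "vcf"
    vdir.mkdir(exist_ok=True)
    for stock in sorted(world.stock_types):
        p = vdir / f"{stock}.vcf"
        world.variant_sets[stock].write_vcf(p, lengths, seed=world.seed)
        paths[f"vcf:{stock}"] = p
    with open(out / "truth_junctions.bed", "w") as fh:
        for b, m in sorted(world.maps.items()):
            for j in m.junctions():
                if j["spacer"]:
                    continue
                for chrom, pos, side in (j["flank_a"], j["flank_b"]):
                    fh.write(f"{chrom}\t{pos - 1}\t{pos}\t{b}:{side}\n")
    with open(out / "truth_tracts.bed", "w") as fh:
        for t in world.tracts:
            fh.write(f"{t.chrom}\t{t.start - 1}\t{t.end}\t{t.stock}:{t.kind}\n")
    with open(out / "truth_gains.bed", "w") as fh:
        for chrom, s, e in world.gains:
            fh.write(f"{chrom}\t{s - 1}\t{e}\tgain\n")
    sim = sim or SimConfig(seed=world.seed + 101)
    summaries = {}
    for stock in (sam_stocks if sam_stocks is not None else sorted(world.stock_types)):
        bal = world.maps[world.stock_types[stock]]
        p = out / f"{stock}.sam"
        s = SimConfig(**{**sim.__dict__,
                         "seed": (sim.seed + _stable_offset(stock)) % (2 ** 31)})
        summaries[stock] = simulate_alignments(
            world.genome, bal, s, p, variants=world.variant_sets[stock])
        paths[f"sam:{stock}"] = p
    world.manifest["sim_summaries"] = summaries
    with open(out / "manifest.json", "w") as fh:
        json.dump(world.manifest, fh, indent=1, sort_keys=True)
    paths["manifest"] = out / "manifest.json"
    return paths


def _stable_offset(name: str) -> int:
    return int(hashlib.sha256(name.encode()).hexdigest(), 16) % 10_000
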