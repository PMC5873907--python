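"""Synthetic reference genomes with annotation and masked tracts.

The forge emulates the statistical structure a short-read rearrangement
analysis cares about: unique euchromatic sequence in which k-mer anchoring
works, interspersed low-complexity (two-letter) tracts in which it
legitimately fails — a stand-in for centric heterochromatin — and a gene
annotation with multi-exon coding transcripts for effect annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..annotation import TranscriptModel, write_gff3

MASKED_FRACTION = 0.02  # fraction of each chromosome emitted as 2-letter tracts
MASKED_TRACT_LEN = 2_000


@dataclass
class ReferenceGenome:
    chromosomes: dict[str, str]
    annotation: list[TranscriptModel] = field(default_factory=list)
    masked_intervals: list[tuple[str, int, int]] = field(default_factory=list)  # 1-based incl.

    def __post_init__(self):
        for name, seq in self.chromosomes.items():
            if set(seq) - set("ACGTN"):
                raise ValueError(f"{name}: sequence contains non-ACGTN characters")
        for chrom, s, e in self.masked_intervals:
            if not (1 <= s <= e <= len(self.chromosomes[chrom])):
                raise ValueError(f"masked interval {chrom}:{s}-{e} outside chromosome")
        for m in self.annotation:
            if m.end > len(self.chromosomes[m.chrom]):
                raise ValueError(f"{m.gene_name} extends beyond {m.chrom}")

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.chromosomes.items()}

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.chromosomes):
                fh.write(f">{name}\n")
                seq = self.chromosomes[name]
                for i in range(0, len(seq), width):
                    fh.write(seq[i: i + width] + "\n")

    def write_gff3(self, path: str | Path) -> None:
        write_gff3(self.annotation, path)

    def write_mask_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, s, e in sorted(self.masked_intervals):
                fh.write(f"{chrom}\t{s - 1}\t{e}\n")  # BED is 0-based half-open


def _random_gene(rng: np.random.Generator, chrom: str, lo: int, hi: int,
                 name: str, biotype: str) -> TranscriptModel | None:
    """Place one transcript inside [lo, hi] (1-based), or None if too tight."""
    span = hi - lo + 1
    if biotype == "tRNA":
        glen = int(rng.integers(70, 90))
    elif biotype in ("ncRNA", "snoRNA"):
        glen = int(rng.integers(200, 600))
    else:
        glen = int(rng.integers(900, min(4000, max(1000, span))))
    if glen + 2 > span:
        return None
    start = lo + int(rng.integers(0, span - glen))
    strand = "+" if rng.random() < 0.5 else "-"
    if biotype != "protein_coding":
        return TranscriptModel(name, chrom, strand, [(start, start + glen - 1)],
                               [], biotype)
    n_exons = int(rng.integers(2, 5))
    # carve glen into alternating exon/intron blocks
    cuts = sorted(rng.choice(np.arange(1, glen - 1), size=2 * n_exons - 2,
                             replace=False).tolist())
    bounds = [0] + cuts + [glen]
    exons = []
    for i in range(0, len(bounds) - 1, 2):
        exons.append((start + bounds[i], start + bounds[i + 1] - 1 if i + 1 < len(bounds) - 1
                      else start + glen - 1))
    exons = [(s, e) for s, e in exons if e >= s]
    if len(exons) < 2 or any(exons[i + 1][0] - exons[i][1] < 5 for i in range(len(exons) - 1)):
        return None
    # CDS spans all exons with small UTRs trimmed from the outer ones
    utr5 = int(rng.integers(10, 60))
    utr3 = int(rng.integers(10, 60))
    cds = [list(iv) for iv in exons]
    cds[0][0] += utr5
    cds[-1][1] -= utr3
    if cds[0][0] > cds[0][1] or cds[-1][0] > cds[-1][1]:
        return None
    total = sum(e - s + 1 for s, e in cds)
    trim = total % 3
    cds[-1][1] -= trim
    if cds[-1][0] > cds[-1][1]:
        return None
    if strand == "-":  # keep the initiator at the 5' end of the coding strand
        cds[0][0] += 0  # layout is symmetric; frames are derived at write time
    return TranscriptModel(name, chrom, strand, exons, [tuple(iv) for iv in cds],
                           "protein_coding")


def forge_reference(n_chroms: int, lengths: list[int], gene_density: float,
                    seed: int, chrom_prefix: str = "chr") -> ReferenceGenome:
    """Generate a deterministic random genome.

    Parameters
    ----------
    n_chroms, lengths
        Number of chromosomes and their lengths in bp.
    gene_density
        Genes per megabase. Roughly one gene in four is non-coding; every
        100-kb block receives at least one multi-exon coding gene when the
        density allows.
    seed
        Single integer controlling all draws.
    """
    if len(lengths) != n_chroms:
        raise ValueError("lengths must have n_chroms entries")
    if any(l <= 0 for l in lengths):
        raise ValueError("chromosome lengths must be positive")
    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    chroms: dict[str, str] = {}
    masked: list[tuple[str, int, int]] = []
    annotation: list[TranscriptModel] = []
    gene_counter = 0
    for ci in range(n_chroms):
        name = f"{chrom_prefix}{ci + 1}"
        L = lengths[ci]
        seq = rng.choice(alphabet, size=L)
        # low-complexity tracts: 2-letter alphabet runs, ~MASKED_FRACTION of the chromosome
        n_tracts = max(0, int(round(L * MASKED_FRACTION / MASKED_TRACT_LEN)))
        for _ in range(n_tracts):
            tlen = min(MASKED_TRACT_LEN, L)
            s = int(rng.integers(0, L - tlen + 1))
            two = alphabet[rng.choice(4, size=2, replace=False)]
            seq[s: s + tlen] = two[rng.integers(0, 2, size=tlen)]
            masked.append((name, s + 1, s + tlen))
        chroms[name] = seq.tobytes().decode()
        # genes: quasi-regular placement in slots so coding genes cover the chromosome
        n_genes = int(round(gene_density * L / 1e6))
        if n_genes > 0:
            slot_edges = np.linspace(1, L, n_genes + 1).astype(int)
            for gi in range(n_genes):
                lo, hi = int(slot_edges[gi]) + 50, int(slot_edges[gi + 1]) - 50
                if hi - lo < 300:
                    continue
                gene_counter += 1
                biotype = ("protein_coding" if gi % 4 != 3
                           else ["ncRNA", "tRNA", "snoRNA"][gi % 3])
                for _ in range(8):  # placement retries
                    m = _random_gene(rng, name, lo, hi, f"gene{gene_counter:04d}", biotype)
                    if m is not None:
                        annotation.append(m)
                        break
        masked.sort()
    genome = ReferenceGenome(chroms, annotation, masked)
    return genome
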