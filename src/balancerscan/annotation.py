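"""Transcript models and GFF3 input/output.

A :class:`TranscriptModel` is the minimal gene representation the annotator
needs: ordered exons, ordered CDS intervals with frame, a strand and a
biotype. Coordinates are 1-based inclusive throughout (GFF3 convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

BIOTYPES = ("protein_coding", "ncRNA", "tRNA", "snoRNA")


@dataclass
class TranscriptModel:
    gene_name: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # genomic order, 1-based inclusive
    cds: list[tuple[int, int]] = field(default_factory=list)
    biotype: str = "protein_coding"
    transcript_id: str = ""

    def __post_init__(self):
        if not self.transcript_id:
            self.transcript_id = self.gene_name + "-RA"
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        prev_end = 0
        for s, e in self.exons:
            if s <= prev_end:
                raise ValueError(f"{self.gene_name}: exons overlap or are unordered")
            if e < s:
                raise ValueError(f"{self.gene_name}: empty exon")
            prev_end = e
        for s, e in self.cds:
            if not any(xs <= s and e <= xe for xs, xe in self.exons):
                raise ValueError(f"{self.gene_name}: CDS interval outside exons")
        if self.biotype == "protein_coding":
            if self.cds_length % 3 != 0:
                raise ValueError(f"{self.gene_name}: CDS length not a multiple of 3")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def cds_sequence(self, chrom_seq: str) -> str:
        """Spliced CDS in translation order (reverse-complemented for '-')."""
        from .forge.segmap import revcomp

        s = "".join(chrom_seq[a - 1: b] for a, b in self.cds)
        return s if self.strand == "+" else revcomp(s)

    def genomic_to_cds(self, pos: int) -> int | None:
        """0-based position within the spliced CDS, or None if not coding."""
        off = 0
        for a, b in self.cds:
            if a <= pos <= b:
                off += pos - a
                break
            off += b - a + 1
        else:
            return None
        if self.strand == "+":
            return off
        return self.cds_length - 1 - off

    def intron_intervals(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
            if self.exons[i + 1][0] - self.exons[i][1] > 1
        ]


def write_gff3(models: list[TranscriptModel], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for m in sorted(models, key=lambda t: (t.chrom, t.start)):
        gid = m.gene_name
        tid = m.transcript_id
        lines.append("\t".join([
            m.chrom, "balancerscan", "gene", str(m.start), str(m.end), ".",
            m.strand, ".", f"ID=gene:{gid};Name={gid};biotype={m.biotype}",
        ]))
        lines.append("\t".join([
            m.chrom, "balancerscan", "mRNA" if m.biotype == "protein_coding" else "transcript",
            str(m.start), str(m.end), ".", m.strand, ".",
            f"ID=transcript:{tid};Parent=gene:{gid};biotype={m.biotype}",
        ]))
        for i, (s, e) in enumerate(m.exons, 1):
            lines.append("\t".join([
                m.chrom, "balancerscan", "exon", str(s), str(e), ".", m.strand, ".",
                f"ID=exon:{tid}.{i};Parent=transcript:{tid}",
            ]))
        # frame of each CDS interval in translation order
        cds = m.cds if m.strand == "+" else list(reversed(m.cds))
        phase, rows = 0, []
        for s, e in cds:
            rows.append((s, e, phase))
            phase = (3 - ((e - s + 1 - phase) % 3)) % 3
        for i, (s, e, ph) in enumerate(sorted(rows), 1):
            lines.append("\t".join([
                m.chrom, "balancerscan", "CDS", str(s), str(e), ".", m.strand,
                str(ph), f"ID=cds:{tid}.{i};Parent=transcript:{tid}",
            ]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[TranscriptModel]:
    """Load transcript models from a GFF3 file (via gffutils)."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    models = []
    for tr in list(db.features_of_type("mRNA")) + list(db.features_of_type("transcript")):
        gene_id = tr.attributes.get("Parent", [tr.id])[0].split(":", 1)[-1]
        biotype = tr.attributes.get("biotype", ["protein_coding"])[0]
        exons = [(f.start, f.end) for f in db.children(tr, featuretype="exon")]
        cds = [(f.start, f.end) for f in db.children(tr, featuretype="CDS")]
        models.append(TranscriptModel(
            gene_name=gene_id, chrom=tr.seqid, strand=tr.strand,
            exons=sorted(exons), cds=sorted(cds), biotype=biotype,
            transcript_id=tr.id.split(":", 1)[-1],
        ))
    return models
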