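"""Variant and junction consequence annotation against transcript models.

SNVs are evaluated at codon level on the coding strand of each overlapping
transcript: a change abolishing the initiator ATG is a start loss, an
in-frame premature stop a nonsense change, an amino-acid substitution
missense, otherwise synonymous; variants within two intronic bases of an
exon boundary are splice-site changes. Junctions disrupting a transcribed
span are reported per gene, and genes lying wholly inside a duplicated
segment are flagged as copy gains (present in three copies in a
balancer/reference heterozygote).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .annotation import TranscriptModel
from .forge.segmap import revcomp

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

EFFECT_ORDER = ["start_loss", "nonsense", "splice_site", "missense",
                "synonymous", "noncoding", "intronic", "intergenic"]
SPLICE_WINDOW = 2  # intronic bases on each side of an exon boundary


@dataclass(frozen=True)
class EffectCall:
    target_id: str  # variant or junction identifier
    gene_name: str
    effect: str
    detail: str = ""


def translate(seq: str) -> str:
    return "".join(CODON_TABLE.get(seq[i: i + 3], "X")
                   for i in range(0, len(seq) - 2, 3))


def worst_effect(effects: list[str]) -> str:
    ranked = [e for e in EFFECT_ORDER if e in effects]
    return ranked[0] if ranked else "intergenic"


def _splice_positions(model: TranscriptModel) -> set[int]:
    pos = set()
    for s, e in model.intron_intervals():
        for d in range(SPLICE_WINDOW):
            if s + d <= e:
                pos.add(s + d)
            if e - d >= s:
                pos.add(e - d)
    return pos


def annotate_variant(chrom: str, pos: int, ref: str, alt: str,
                     models: list[TranscriptModel],
                     genome: dict[str, str], var_id: str | None = None) -> list[EffectCall]:
    """Effect calls for one variant, one per overlapping transcript.

    SNVs get codon-level classification; indels receive positional classes
    only (splice_site / intronic / intergenic, or a coding-indel note).
    A variant overlapping no transcript yields a single intergenic call.
    """
    if chrom not in genome:
        raise ValueError(f"variant on unknown contig {chrom!r}")
    seq = genome[chrom]
    if seq[pos - 1: pos - 1 + len(ref)].upper() != ref.upper():
        raise ValueError(f"ref allele mismatch at {chrom}:{pos}")
    vid = var_id or f"{chrom}:{pos}:{ref}>{alt}"
    is_snv = len(ref) == 1 and len(alt) == 1
    calls = []
    for m in models:
        if m.chrom != chrom or not (m.start <= pos <= m.end):
            continue
        in_exon = any(s <= pos <= e for s, e in m.exons)
        if pos in _splice_positions(m):
            calls.append(EffectCall(vid, m.gene_name, "splice_site",
                                    "within 2 bp of exon boundary"))
            continue
        if not in_exon:
            calls.append(EffectCall(vid, m.gene_name, "intronic", ""))
            continue
        cds_pos = m.genomic_to_cds(pos) if m.biotype == "protein_coding" else None
        if cds_pos is None or not is_snv:
            # exonic but outside any CDS (UTR / non-coding transcript), or an
            # indel: no codon-level claim is made
            detail = "coding indel" if (cds_pos is not None and not is_snv) \
                else "exonic, non-CDS"
            calls.append(EffectCall(vid, m.gene_name, "noncoding", detail))
            continue
        cds = m.cds_sequence(seq)
        base = alt if m.strand == "+" else revcomp(alt)
        mut = cds[:cds_pos] + base + cds[cds_pos + 1:]
        codon_i = cds_pos // 3
        old_aa = translate(cds[codon_i * 3: codon_i * 3 + 3])
        new_aa = translate(mut[codon_i * 3: codon_i * 3 + 3])
        if codon_i == 0 and old_aa == "M" and new_aa != "M":
            eff, detail = "start_loss", "initiator codon lost"
        elif new_aa == "*" and old_aa != "*":
            eff, detail = "nonsense", f"{old_aa}{codon_i + 1}*"
        elif new_aa != old_aa:
            eff, detail = "missense", f"{old_aa}{codon_i + 1}{new_aa}"
        else:
            eff, detail = "synonymous", f"{old_aa}{codon_i + 1}"
        calls.append(EffectCall(vid, m.gene_name, eff, detail))
    if not calls:
        calls.append(EffectCall(vid, "", "intergenic", ""))
    return calls


def annotate_junction(junction, models: list[TranscriptModel],
                      duplications: list | None = None,
                      junction_id: str | None = None) -> list[EffectCall]:
    """Disruption and copy-gain calls for one junction.

    A gene whose transcribed span contains a junction flank (so the junction
    separates parts of the transcript) is gene_disrupted, with the exon or
    intron named; genes wholly inside a duplicated segment are copy_gain.
    """
    jid = junction_id or f"jn:{junction.flank_a[0]}:{junction.flank_a[1]}"
    calls = []
    for m in models:
        for chrom, pos, _ in (junction.flank_a, junction.flank_b):
            if m.chrom != chrom or not (m.start <= pos <= m.end):
                continue
            detail = ""
            for i, (s, e) in enumerate(m.exons, 1):
                if s <= pos <= e:
                    detail = f"exon {i}"
                    break
            if not detail:
                for i, (s, e) in enumerate(m.intron_intervals(), 1):
                    if s <= pos <= e:
                        detail = f"intron {i}"
                        break
            calls.append(EffectCall(jid, m.gene_name, "gene_disrupted", detail))
            break  # one call per gene even if both flanks hit it
    for dup in duplications or []:
        for m in models:
            if (m.chrom == dup.chrom and dup.start <= m.start and m.end <= dup.end
                    and not any(c.gene_name == m.gene_name for c in calls)):
                calls.append(EffectCall(jid, m.gene_name, "copy_gain",
                                        "three copies in heterozygote"))
    return calls


def census_tables(effect_calls: list[EffectCall],
                  variant_classes: pd.Series | dict) -> pd.DataFrame:
    """Cross-tabulate sharing class x mutation class (published table shape).

    Rows are sharing classes, columns the four headline mutation classes.
    ``variant_classes`` maps the variant id of each effect call to its
    sharing class (stock_unique:* collapses to one row).
    """
    columns = ["missense", "splice_site", "nonsense", "start_loss"]
    if isinstance(variant_classes, pd.Series):
        variant_classes = variant_classes.to_dict()
    rows: dict[str, dict[str, int]] = {}
    for call in effect_calls:
        if call.effect not in columns:
            continue
        cls = variant_classes.get(call.target_id)
        if cls is None:
            continue
        cls = cls.split(":")[0]
        rows.setdefault(cls, {c: 0 for c in columns})[call.effect] += 1
    order = ["type_specific", "shared_all", "stock_unique", "other"]
    index = [c for c in order if c in rows] + [c for c in rows if c not in order]
    df = pd.DataFrame([[rows[r][c] for c in columns] for r in index],
                      index=index, columns=columns, dtype=int)
    df.index.name = "sharing_class"
    return df


def summarize_per_gene(calls: list[EffectCall]) -> pd.DataFrame:
    """Worst effect per gene (all per-transcript calls kept elsewhere)."""
    per_gene: dict[str, list[str]] = {}
    for c in calls:
        if c.gene_name:
            per_gene.setdefault(c.gene_name, []).append(c.effect)
    return pd.DataFrame([{"gene": g, "worst_effect": worst_effect(effs)}
                         for g, effs in sorted(per_gene.items())])
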