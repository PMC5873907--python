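"""Codon-level variant annotation, junction disruption, census tables."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from balancerscan import effects as ef
from balancerscan.annotation import TranscriptModel
from balancerscan.forge.reference import forge_reference
from balancerscan.forge.segmap import revcomp
from balancerscan.svscan import JunctionCall


def toy_gene(strand="+"):
    """Two-exon coding gene on a 200-bp contig.

    exon1 41..100 (CDS 51..100), intron 101..120, exon2 121..180
    (CDS 121..170): CDS length 100 + ... = 50 + 50 = 100 -> pad to 99.
    """
    return TranscriptModel("toy", "c", strand,
                           exons=[(41, 100), (121, 180)],
                           cds=[(51, 100), (121, 169)],  # 50 + 49 = 99 = 33 codons
                           biotype="protein_coding")


def toy_genome(model, seed=0):
    """Random 200-bp contig whose CDS is ATG followed by alanine codons."""
    rng = np.random.default_rng(seed)
    seq = list("".join(rng.choice(list("ACGT"), size=200)))
    cds_pos = []
    for s, e in model.cds:
        cds_pos.extend(range(s - 1, e))
    # Trp/Gln/Ala codons: stop-free, but one substitution away from a stop
    safe = "TGGCAAGCTGCA"
    for i, p in enumerate(cds_pos):
        seq[p] = safe[(i // 3 % 4) * 3 + i % 3]
    for i, p in enumerate(cds_pos[:3]):
        seq[p] = "ATG"[i]
    return {"c": "".join(seq)}


def brute_force_effect(genome, model, pos, alt):
    """Independent oracle: substitute, re-extract CDS, translate with Biopython."""
    seq = genome[model.chrom]
    mutated = seq[: pos - 1] + alt + seq[pos:]
    for s, e in model.intron_intervals():
        if (s <= pos <= s + 1) or (e - 1 <= pos <= e):
            return "splice_site"
    if not any(s <= pos <= e for s, e in model.exons):
        if model.start <= pos <= model.end:
            return "intronic"
        return "intergenic"
    if not any(s <= pos <= e for s, e in model.cds):
        return "noncoding"
    old = str(Seq(model.cds_sequence(seq)).translate())
    new = str(Seq(model.cds_sequence(mutated)).translate())
    if old[0] == "M" and new[0] != "M":
        return "start_loss"
    if old == new:
        return "synonymous"
    i = next(i for i, (a, b) in enumerate(zip(old, new)) if a != b)
    return "nonsense" if new[i] == "*" else "missense"


class TestAnnotateVariant:
    def test_synonymous_third_position_change(self):
        m = toy_gene()
        g = toy_genome(m)
        # find a third codon position where the change is silent
        for pos in range(56, 100, 3):  # third positions of + strand codons
            ref = g["c"][pos - 1]
            for alt in "ACGT":
                if alt != ref and brute_force_effect(g, m, pos, alt) == "synonymous":
                    calls = ef.annotate_variant("c", pos, ref, alt, [m], g)
                    assert calls[0].effect == "synonymous"
                    return
        pytest.fail("no synonymous change found in toy CDS")

    def test_nonsense_from_new_inframe_stop(self):
        m = toy_gene()
        g = toy_genome(m)
        found = False
        for pos in range(51, 101):
            ref = g["c"][pos - 1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                if brute_force_effect(g, m, pos, alt) == "nonsense":
                    calls = ef.annotate_variant("c", pos, ref, alt, [m], g)
                    assert calls[0].effect == "nonsense"
                    found = True
        assert found

    def test_intergenic_variant_has_no_gene(self):
        m = toy_gene()
        g = toy_genome(m)
        calls = ef.annotate_variant("c", 10, g["c"][9], "A" if g["c"][9] != "A"
                                    else "C", [m], g)
        assert calls == [ef.EffectCall(calls[0].target_id, "", "intergenic", "")]

    def test_splice_site_window_is_two_intronic_bases(self):
        m = toy_gene()
        g = toy_genome(m)
        for pos, want in [(101, "splice_site"), (102, "splice_site"),
                          (103, "intronic"), (119, "splice_site"),
                          (120, "splice_site"), (118, "intronic")]:
            ref = g["c"][pos - 1]
            alt = "A" if ref != "A" else "C"
            assert ef.annotate_variant("c", pos, ref, alt, [m], g)[0].effect == want

    def test_start_loss(self):
        m = toy_gene()
        g = toy_genome(m)
        ref = g["c"][50]  # A of ATG at CDS position 51
        assert ref == "A"
        calls = ef.annotate_variant("c", 51, "A", "G", [m], g)
        assert calls[0].effect == "start_loss"

    def test_ref_mismatch_rejected(self):
        m = toy_gene()
        g = toy_genome(m)
        wrong = "A" if g["c"][59] != "A" else "C"
        with pytest.raises(ValueError, match="mismatch"):
            ef.annotate_variant("c", 60, wrong, "G", [m], g)

    def test_unknown_contig_rejected(self):
        with pytest.raises(ValueError, match="contig"):
            ef.annotate_variant("zz", 1, "A", "T", [], {"c": "AAAA"})


def test_translation_oracle_on_1000_random_variants():
    genome_obj = forge_reference(1, [200_000], 50, seed=31)
    genome = genome_obj.chromosomes
    models = genome_obj.annotation
    rng = np.random.default_rng(7)
    n_checked = 0
    while n_checked < 1000:
        pos = int(rng.integers(1, 200_001))
        ref = genome["chr1"][pos - 1]
        if ref == "N":
            continue
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        calls = ef.annotate_variant("chr1", pos, ref, alt, models, genome)
        for m in models:
            if m.chrom != "chr1" or not (m.start <= pos <= m.end):
                continue
            if m.biotype != "protein_coding":
                continue
            want = brute_force_effect(genome, m, pos, alt)
            got = next(c.effect for c in calls if c.gene_name == m.gene_name)
            assert got == want, (pos, ref, alt, m.gene_name)
        n_checked += 1


def test_strand_invariance_of_effects():
    # reverse-complementing the locus and flipping the annotation strand
    # must leave every effect class unchanged
    m = toy_gene("+")
    g = toy_genome(m)
    L = len(g["c"])
    g_rc = {"c": revcomp(g["c"])}
    m_rc = TranscriptModel("toy", "c", "-",
                           exons=[(L - e + 1, L - s + 1) for s, e in m.exons],
                           cds=[(L - e + 1, L - s + 1) for s, e in m.cds],
                           biotype="protein_coding")
    rng = np.random.default_rng(3)
    for _ in range(80):
        pos = int(rng.integers(m.start, m.end + 1))
        ref = g["c"][pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        fwd = ef.annotate_variant("c", pos, ref, alt, [m], g)[0].effect
        pos_rc = L - pos + 1
        comp = dict(zip("ACGT", "TGCA"))
        rev = ef.annotate_variant("c", pos_rc, comp[ref], comp[alt],
                                  [m_rc], g_rc)[0].effect
        assert fwd == rev, (pos, ref, alt)


class TestAnnotateJunction:
    def test_flank_in_first_intron_reports_disruption_detail(self):
        m = toy_gene()
        j = JunctionCall(("c", 110, "+"), ("c", 5_000, "-"), 0, (5, 0), 0)
        calls = ef.annotate_junction(j, [m])
        assert calls == [ef.EffectCall(calls[0].target_id, "toy",
                                       "gene_disrupted", "intron 1")]

    def test_junction_between_genes_reports_nothing(self):
        m = toy_gene()
        j = JunctionCall(("c", 190, "+"), ("c", 5_000, "-"), 0, (5, 0), 0)
        assert ef.annotate_junction(j, [m]) == []

    def test_gene_inside_duplication_is_copy_gain(self):
        m = toy_gene()
        from balancerscan.depth import SegmentCall
        dup = SegmentCall("c", 1, 200, 1.5, "gain", 1)
        j = JunctionCall(("c", 5_000, "+"), ("c", 9_000, "-"), 0, (5, 0), 0)
        calls = ef.annotate_junction(j, [m], duplications=[dup])
        assert calls[0].effect == "copy_gain"


class TestCensus:
    def test_empty_inputs_give_empty_table(self):
        df = ef.census_tables([], {})
        assert list(df.columns) == ["missense", "splice_site", "nonsense",
                                    "start_loss"]
        assert len(df) == 0

    def test_single_unique_nonsense_lands_in_the_right_cell(self):
        calls = [ef.EffectCall("v1", "g", "nonsense", "")]
        df = ef.census_tables(calls, {"v1": "stock_unique:s1"})
        assert df.loc["stock_unique", "nonsense"] == 1
        assert int(df.to_numpy().sum()) == 1

    def test_census_additivity(self):
        rng = np.random.default_rng(11)
        effects = ["missense", "splice_site", "nonsense", "start_loss",
                   "synonymous", "intronic"]
        classes = ["shared_all", "type_specific:A", "stock_unique:s"]
        calls, mapping = [], {}
        for i in range(200):
            eff = effects[rng.integers(len(effects))]
            calls.append(ef.EffectCall(f"v{i}", "g", eff, ""))
            mapping[f"v{i}"] = classes[rng.integers(len(classes))]
        df = ef.census_tables(calls, mapping)
        countable = sum(1 for c in calls
                        if c.effect in ("missense", "splice_site", "nonsense",
                                        "start_loss"))
        assert int(df.to_numpy().sum()) == countable


def test_worst_effect_ordering():
    assert ef.worst_effect(["synonymous", "nonsense", "missense"]) == "nonsense"
    assert ef.worst_effect(["intronic"]) == "intronic"
    assert ef.worst_effect([]) == "intergenic"
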