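"""Panel merging, sharing classes, crossover tracts and distances."""

import itertools

import numpy as np
import pandas as pd
import pytest

from balancerscan import snps as sn
from balancerscan.forge.reference import forge_reference
from balancerscan.forge.variants import Variant, VariantSet
from balancerscan.svscan import JunctionCall

CLEN = {"c": 1_000_000}


def make_vcf(tmp_path, stock, variants):
    vs = VariantSet(stock, [Variant("c", p, r, a, "snp", lab, q)
                            for p, r, a, lab, q in variants])
    path = tmp_path / f"{stock}.vcf"
    vs.write_vcf(path, CLEN)
    return path


def panel_from(presence: dict[str, list[int]], types: dict[str, str],
               positions: list[int] | None = None,
               clen: dict | None = None) -> sn.PanelMatrix:
    """Build a PanelMatrix directly from a presence pattern (loci x stocks)."""
    stocks = sorted(presence)
    n = len(next(iter(presence.values())))
    positions = positions or [1000 * (i + 1) for i in range(n)]
    loci = pd.DataFrame({
        "chrom": ["c"] * n, "pos": positions, "ref": ["A"] * n,
        "alt": ["T"] * n, "var_class": ["snp"] * n, "qual_max": [300.0] * n,
    })
    pres = pd.DataFrame({s: [bool(v) for v in presence[s]] for s in stocks},
                        dtype=bool)
    return sn.PanelMatrix(stocks, types, loci, pres, clen or dict(CLEN))


# -------------------------------------------------------------------- loading

def test_qual_filter_boundary(tmp_path):
    vcfs = {"s1": make_vcf(tmp_path, "s1", [
        (100, "A", "T", "x", 219.0), (200, "A", "T", "x", 221.0)])}
    panel = sn.load_panel(vcfs, {"s1": "T1"}, qual_min=220.0)
    assert list(panel.loci["pos"]) == [200]


def test_single_stock_panel_all_unique(tmp_path):
    vcfs = {"s1": make_vcf(tmp_path, "s1", [(100, "A", "T", "x", 300.0),
                                            (200, "C", "G", "x", 300.0)])}
    panel = sn.classify_variants(sn.load_panel(vcfs, {"s1": "T1"}))
    assert all(c == "stock_unique:s1" for c in panel.classes)


def test_merging_file_with_itself_gives_identical_columns(tmp_path):
    rows = [(100, "A", "T", "x", 300.0), (200, "C", "G", "x", 250.0)]
    vcfs = {"a": make_vcf(tmp_path, "a", rows), "b": make_vcf(tmp_path, "b", rows)}
    panel = sn.load_panel(vcfs, {"a": "T1", "b": "T1"})
    assert (panel.presence["a"] == panel.presence["b"]).all()


def test_contig_mismatch_rejected(tmp_path):
    v1 = make_vcf(tmp_path, "s1", [(100, "A", "T", "x", 300.0)])
    vs = VariantSet("s2", [Variant("c", 100, "A", "T", "snp", "x", 300.0)])
    v2 = tmp_path / "s2.vcf"
    vs.write_vcf(v2, {"c": 999})
    with pytest.raises(ValueError, match="contigs"):
        sn.load_panel({"s1": v1, "s2": v2}, {"s1": "T1", "s2": "T1"})


# -------------------------------------------------------------- classification

TYPES3 = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c1": "C"}


def brute_force_class(row: dict[str, bool], types: dict[str, str]) -> str:
    # independent set-operation oracle
    tset = sorted(set(types.values()))
    full = [t for t in tset
            if all(row[s] for s in types if types[s] == t)]
    present = [s for s in row if row[s]]
    if len(full) >= 2:
        return "shared_all"
    if len(present) == 1:
        return f"stock_unique:{present[0]}"
    if len(full) == 1 and all(types[s] == full[0] for s in present):
        return f"type_specific:{full[0]}"
    return "other"


def test_classification_examples():
    panel = panel_from({
        "a1": [1, 1, 0, 1, 0], "a2": [1, 1, 0, 0, 0],
        "b1": [1, 0, 1, 0, 1], "b2": [1, 0, 0, 0, 1],
    }, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
    sn.classify_variants(panel)
    assert list(panel.classes) == [
        "shared_all",        # present in every stock of both types
        "type_specific:A",   # all A stocks, absent from all B stocks
        "stock_unique:b1",
        "stock_unique:a1",
        "type_specific:B",
    ]


def test_locus_in_two_of_three_same_type_stocks_is_other():
    panel = panel_from({"a1": [1], "a2": [1], "a3": [0], "b1": [0]},
                       {"a1": "A", "a2": "A", "a3": "A", "b1": "B"})
    sn.classify_variants(panel)
    assert list(panel.classes) == ["other"]


def test_classify_matches_bruteforce_oracle_on_all_patterns():
    stocks = sorted(TYPES3)
    patterns = list(itertools.product([0, 1], repeat=len(stocks)))[1:]
    presence = {s: [p[i] for p in patterns] for i, s in enumerate(stocks)}
    panel = sn.classify_variants(panel_from(presence, TYPES3))
    for i, p in enumerate(patterns):
        row = dict(zip(stocks, map(bool, p)))
        assert panel.classes.iloc[i] == brute_force_class(row, TYPES3), row


def test_partition_invariant_and_relabeling_symmetry():
    rng = np.random.default_rng(0)
    patterns = rng.integers(0, 2, size=(200, 5))
    patterns = patterns[patterns.sum(axis=1) > 0]
    stocks = sorted(TYPES3)
    presence = {s: patterns[:, i].tolist() for i, s in enumerate(stocks)}
    panel = sn.classify_variants(panel_from(presence, TYPES3))
    counts = panel.classes.map(lambda c: c.split(":")[0]).value_counts()
    assert counts.sum() == len(panel.loci)  # every passing locus classified once
    # relabeling stocks permutes rows but preserves class-count totals
    perm = {"a1": "b1", "b1": "a1", "a2": "b2", "b2": "a2", "c1": "c1"}
    presence2 = {perm[s]: presence[s] for s in stocks}
    types2 = {perm[s]: TYPES3[s] for s in stocks}
    panel2 = sn.classify_variants(panel_from(presence2, types2))
    c2 = panel2.classes.map(lambda c: c.split(":")[0]).value_counts()
    assert counts.to_dict() == c2.to_dict()


# ------------------------------------------------------------------- tracts

def tract_panel(unique_positions, other_positions, tract=None, clen=None):
    """s1 carries donor-unique variants inside the exchanged tract and the
    shared panel variants outside it (inside the tract it lacks them)."""
    pos = sorted(set(unique_positions) | set(other_positions))
    if tract is None and unique_positions:
        tract = (min(unique_positions), max(unique_positions))
    presence = {"s1": [], "s2": [], "s3": []}
    for p in pos:
        u = p in unique_positions
        in_tract = tract is not None and tract[0] <= p <= tract[1]
        presence["s1"].append(1 if u else (0 if in_tract else 1))
        presence["s2"].append(0 if u else 1)
        presence["s3"].append(0 if u else 1)
    types = {"s1": "A", "s2": "A", "s3": "B"}
    return sn.classify_variants(panel_from(presence, types, positions=pos,
                                           clen=clen))


def test_no_unique_loci_no_tracts():
    panel = panel_from({"s1": [1, 1], "s2": [1, 1]}, {"s1": "A", "s2": "A"})
    sn.classify_variants(panel)
    assert sn.detect_tracts(panel) == []


def test_interior_dco_tract_bracketed():
    unique = list(range(400_000, 430_000, 1_000))  # 30 unique SNPs
    others = list(range(10_000, 1_000_000, 50_000))
    panel = tract_panel(unique, others)
    tracts = sn.detect_tracts(panel, min_snps=10, max_gap=100_000)
    assert len(tracts) == 1
    t = tracts[0]
    assert t.kind == "DCO" and t.stock == "s1"
    assert t.start <= 400_000 and t.end >= 429_000
    assert t.inner_start == 400_000 and t.inner_end == 429_000


def test_distal_sco_tract_runs_to_chromosome_end():
    # distal-tip single-crossover geometry
    unique = list(range(940_000, 1_000_000, 2_000))
    others = list(range(10_000, 900_000, 40_000))
    panel = tract_panel(unique, others)
    tracts = sn.detect_tracts(panel, min_snps=10, max_gap=100_000)
    assert len(tracts) == 1 and tracts[0].kind == "SCO"
    assert tracts[0].end == 1_000_000


def test_tract_recovery_20_seeded_panels():
    ok = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        lo = int(rng.integers(200_000, 600_000))
        hi = lo + int(rng.integers(50_000, 200_000))
        unique = sorted(rng.integers(lo, hi, size=max(12, (hi - lo) // 8_000)))
        unique = [int(u) for u in unique]
        others = list(range(5_000, 1_000_000, 30_000))
        panel = tract_panel(unique, others, tract=(lo, hi))
        tracts = [t for t in sn.detect_tracts(panel, 10, 100_000)
                  if t.kind == "DCO"]
        if len(tracts) == 1 and tracts[0].start <= lo and tracts[0].end >= hi - 1:
            ok += 1
    assert ok == 20


# ---------------------------------------------------------------- ancestral

def test_identical_to_ancestor_gives_no_divergence():
    panel = panel_from({"t": [1, 0, 1], "anc": [1, 0, 1]},
                       {"t": "A", "anc": "A"})
    assert sn.ancestral_compare(panel, "t", "anc") == []


def test_diverged_stocks_flagged_against_snapshot():
    # two of three stocks carry planted interior exchanges; one is ancestral
    pos = list(range(100_000, 900_000, 4_000))
    anc = [1] * len(pos)
    t1 = [0 if 300_000 <= p <= 500_000 else 1 for p in pos]
    t2 = list(anc)
    panel = panel_from({"anc": anc, "t1": t1, "t2": t2},
                       {"anc": "A", "t1": "A", "t2": "A"}, positions=pos)
    assert sn.ancestral_compare(panel, "t1", "anc", min_snps=10)
    assert sn.ancestral_compare(panel, "t2", "anc", min_snps=10) == []


def test_empty_ancestor_rejected():
    panel = panel_from({"t": [1], "anc": [0]}, {"t": "A", "anc": "A"})
    with pytest.raises(ValueError, match="ancestor"):
        sn.ancestral_compare(panel, "t", "anc")


# ---------------------------------------------------------------- distances

def _tract(start, end, kind="DCO"):
    return sn.TractCall("s", "c", start, end, start, end, kind, 10)


def _junction(pos_a, pos_b):
    return JunctionCall(("c", pos_a, "+"), ("c", pos_b, "-"), 0, (3, 0), 0)


def test_breakpoint_distance_arithmetic():
    tracts = sn.breakpoint_distance([_tract(8_400_000, 8_500_000)],
                                    [_junction(6_012_739, 20_000_000)])
    assert tracts[0].distance_to_nearest_breakpoint == 2_387_261


def test_boundary_on_flank_gives_zero():
    tracts = sn.breakpoint_distance([_tract(6_012_739, 6_100_000)],
                                    [_junction(6_012_739, 20_000_000)])
    assert tracts[0].distance_to_nearest_breakpoint == 0


def test_no_junctions_gives_undefined_not_zero():
    tracts = sn.breakpoint_distance([_tract(100, 200)], [])
    assert tracts[0].distance_to_nearest_breakpoint is None


def test_planted_distance_respects_two_megabase_margin():
    # exchanges planted >= 2 Mb from every junction flank
    junctions = [_junction(3_000_000, 20_000_000)]
    tracts = [_tract(5_200_000, 6_000_000), _tract(14_000_000, 15_000_000)]
    out = sn.breakpoint_distance(tracts, junctions)
    assert min(t.distance_to_nearest_breakpoint for t in out) >= 2_000_000


# ------------------------------------------------------------------ heatmap

def test_heatmap_counts_unique_loci_per_bin():
    unique = list(range(400_000, 430_000, 1_000))
    others = list(range(10_000, 1_000_000, 50_000))
    panel = tract_panel(unique, others)
    mat = sn.heatmap_matrix(panel, bin_size=100_000)
    row = mat.loc["s1"]
    assert row.sum() == len(unique)
    assert row[("c", 400_001)] == sum(1 for u in unique if u > 400_000)
    assert (mat.loc["s2"] == 0).all()


def test_empty_panel_heatmap_is_header_only(tmp_path):
    panel = panel_from({"s1": [1], "s2": [1]}, {"s1": "A", "s2": "A"})
    sn.classify_variants(panel)
    panel.loci = panel.loci.iloc[:0]
    panel.presence = panel.presence.iloc[:0]
    panel.classes = panel.classes.iloc[:0]
    mat = sn.heatmap_matrix(panel, 100_000)
    sn.write_heatmap(mat, tmp_path / "h.tsv")
    assert (tmp_path / "h.tsv").exists()
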